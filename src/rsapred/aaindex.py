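"""AAindex1 physicochemical property tables and per-segment PCP features.

An AAindex1 flat file is a sequence of records, each describing one
amino-acid index: a mapping from the 20 standard residues to a real number
(a hydropathy scale, a helix propensity, an accessibility statistic, ...).
This module parses that format, drops indices with missing ("NA") values,
and turns an 11-residue sequence window into one feature per selected
property: the logistic-squashed mean of the property over the window's
in-sequence residues.

Feature values are mapped into (0, 1) with the standard logistic function

    x' = 1 / (1 + exp(-x))

applied to the window-averaged raw property value.
"""

from __future__ import annotations

import importlib.resources
import hashlib
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import numpy as np

#: Residue order of the two value rows in an AAindex1 ``I`` record.
AAINDEX_ORDER = "ARNDCQEGHILKMFPSTWYV"

STANDARD_RESIDUES = frozenset(AAINDEX_ORDER)

#: Ambiguity / nonstandard one-letter codes that receive a neutral
#: (table-mean) property value instead of raising.
AMBIGUOUS_RESIDUES = frozenset("XBZUJO")

#: Pad symbol used by window extraction at chain termini.
PAD = "-"


class AAindexParseError(ValueError):
    """Raised when an AAindex1 stream violates the flat-file layout."""


@dataclass(frozen=True)
class PropertyIndex:
    """One amino-acid index: 20 finite values keyed by residue letter."""

    accession: str
    description: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.values) != STANDARD_RESIDUES:
            missing = STANDARD_RESIDUES - set(self.values)
            raise ValueError(
                f"{self.accession}: values must cover the 20 standard residues "
                f"(missing {sorted(missing)})"
            )
        if not all(math.isfinite(v) for v in self.values.values()):
            raise ValueError(f"{self.accession}: non-finite property value")

    @property
    def mean_value(self) -> float:
        """Unweighted mean over the 20 standard residues (used to impute X/B/Z/U)."""
        return float(np.mean([self.values[a] for a in AAINDEX_ORDER]))

    def value_for(self, residue: str) -> float:
        """Property value for ``residue``; ambiguity codes get the table mean."""
        if residue in self.values:
            return self.values[residue]
        if residue in AMBIGUOUS_RESIDUES:
            return self.mean_value
        raise KeyError(f"no property value for residue {residue!r} in {self.accession}")


@dataclass
class PropertyTable:
    """Ordered collection of complete :class:`PropertyIndex` entries.

    Order is significant: feature position *i* in a PCP feature vector, and
    gene position *i* in a feature-selection chromosome, both refer to
    ``indices[i]``.
    """

    indices: list[PropertyIndex]
    source_version: str = "unversioned"
    n_excluded: int = 0
    _by_accession: dict[str, PropertyIndex] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_accession = {}
        for idx in self.indices:
            if idx.accession in self._by_accession:
                raise AAindexParseError(f"duplicate accession {idx.accession}")
            self._by_accession[idx.accession] = idx

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self):
        return iter(self.indices)

    def __contains__(self, accession: str) -> bool:
        return accession in self._by_accession

    @property
    def accessions(self) -> list[str]:
        return [idx.accession for idx in self.indices]

    def get(self, accession: str) -> PropertyIndex:
        return self._by_accession[accession]

    def subset(self, accessions: Sequence[str]) -> "PropertyTable":
        return PropertyTable(
            [self.get(a) for a in accessions], source_version=self.source_version
        )

    def content_hash(self) -> str:
        """SHA-256 over accessions and values; used to pin model archives."""
        h = hashlib.sha256()
        for idx in self.indices:
            h.update(idx.accession.encode())
            for a in AAINDEX_ORDER:
                h.update(repr(idx.values[a]).encode())
        return h.hexdigest()


def logistic_normalize(x: float) -> float:
    """Squash a raw feature value into (0, 1) with the logistic function.

    Strictly increasing; ``logistic_normalize(0) == 0.5`` and
    ``logistic_normalize(-x) == 1 - logistic_normalize(x)``.
    """
    x = float(x)
    if not math.isfinite(x):
        raise ValueError(f"logistic_normalize requires a finite input, got {x}")
    # scipy.special.expit without the import; overflow-safe split
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def _logistic_array(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def parse_aaindex(stream: TextIO | Iterable[str]) -> PropertyTable:
    """Parse AAindex1 flat-file text into a :class:`PropertyTable`.

    Records are delimited by ``//``.  Only ``H`` (accession), ``D``
    (description) and ``I`` (the header line followed by two rows of ten
    values) are interpreted; other record types (R, A, T, J, C, ...) are
    skipped.  Indices containing any ``NA`` value are excluded; the count
    of exclusions is kept on the returned table.
    """
    indices: list[PropertyIndex] = []
    n_excluded = 0
    version = "unversioned"

    accession: str | None = None
    description = ""
    value_rows: list[str] = []
    in_values = False
    seen: set[str] = set()

    def flush() -> None:
        nonlocal accession, description, value_rows, in_values, n_excluded
        if accession is None:
            if value_rows:
                raise AAindexParseError("value rows outside of a record")
            return
        if len(value_rows) != 2:
            raise AAindexParseError(
                f"{accession}: expected 2 value rows after I line, got {len(value_rows)}"
            )
        tokens = value_rows[0].split() + value_rows[1].split()
        if len(tokens) != 20:
            raise AAindexParseError(
                f"{accession}: expected 20 values, got {len(tokens)}"
            )
        if accession in seen:
            raise AAindexParseError(f"duplicate accession {accession}")
        seen.add(accession)
        if any(t.upper() in ("NA", "NA.", "N/A") for t in tokens):
            n_excluded += 1
        else:
            try:
                values = {a: float(t) for a, t in zip(AAINDEX_ORDER, tokens)}
            except ValueError as exc:
                raise AAindexParseError(f"{accession}: bad value ({exc})") from exc
            indices.append(PropertyIndex(accession, description.strip(), values))
        accession, description, value_rows, in_values = None, "", [], False

    for raw in stream:
        line = raw.rstrip("\n")
        if line.startswith("//"):
            flush()
            continue
        if line.startswith("H "):
            if accession is not None:
                raise AAindexParseError(
                    f"record {accession} not terminated before next H line"
                )
            accession = line[2:].strip()
            in_values = False
        elif line.startswith("D "):
            description += line[2:].strip() + " "
        elif line.startswith("I "):
            in_values = True
        elif line.startswith("* "):  # snapshot version pseudo-record
            version = line[2:].strip()
        elif in_values and line.strip():
            value_rows.append(line)
        elif line[:2] in ("R ", "A ", "T ", "J ", "C ") or line.startswith("  "):
            if not in_values:
                continue
    if accession is not None:
        raise AAindexParseError(f"unterminated record {accession} (missing //)")

    return PropertyTable(indices, source_version=version, n_excluded=n_excluded)


def write_aaindex(table: PropertyTable) -> str:
    """Serialize a table back to AAindex1 flat-file text (H/D/I records)."""
    chunks: list[str] = []
    if table.source_version != "unversioned":
        chunks.append(f"* {table.source_version}\n")
    for idx in table.indices:
        vals = [idx.values[a] for a in AAINDEX_ORDER]
        row1 = " ".join(f"{v:8.3f}" for v in vals[:10])
        row2 = " ".join(f"{v:8.3f}" for v in vals[10:])
        chunks.append(
            f"H {idx.accession}\n"
            f"D {idx.description}\n"
            "I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V\n"
            f"{row1}\n{row2}\n//\n"
        )
    return "".join(chunks)


def load_bundled_table() -> PropertyTable:
    """Load the AAindex1 snapshot shipped as package data.

    The snapshot is synthetic apart from the Kyte-Doolittle hydropathy
    entry (KYTJ820101): it holds that real scale plus a set of generated
    indices, and two deliberately incomplete (NA) records that the parser
    must exclude.  The version string is recorded on the returned table.
    """
    text = (
        importlib.resources.files("rsapred.data")
        .joinpath("aaindex_snapshot_synthetic.txt")
        .read_text()
    )
    return parse_aaindex(text.splitlines())


def window_mean_matrix(windows: Sequence[str], table: PropertyTable) -> np.ndarray:
    """Raw (un-squashed) window-mean property matrix, shape (n_windows, n_indices).

    Pad symbols are excluded from the mean; ambiguity codes contribute the
    property's residue-mean value.
    """
    n_props = len(table)
    lut = np.zeros((128, n_props))
    known = np.zeros(128, dtype=bool)
    for j, idx in enumerate(table):
        for a in AAINDEX_ORDER:
            lut[ord(a), j] = idx.values[a]
        for a in AMBIGUOUS_RESIDUES:
            lut[ord(a), j] = idx.mean_value
    for a in set(AAINDEX_ORDER) | AMBIGUOUS_RESIDUES:
        known[ord(a)] = True

    out = np.empty((len(windows), n_props))
    for i, window in enumerate(windows):
        codes = [ord(c) for c in window if c != PAD]
        if not codes:
            raise ValueError("window contains only pad symbols")
        for c in codes:
            if not known[c]:
                raise KeyError(f"no property value for residue {chr(c)!r}")
        out[i] = lut[codes].mean(axis=0)
    return out


def segment_pcp_features(
    segment, table: PropertyTable, selected: Sequence[str]
) -> np.ndarray:
    """PCP feature vector for one segment: one value per selected accession.

    Each value is ``logistic_normalize(mean(property over in-sequence window
    residues))``; output order follows ``selected``.
    """
    window = segment.window if hasattr(segment, "window") else str(segment)
    if len(window) != 11:
        raise ValueError(f"segment window must have length 11, got {len(window)}")
    if not selected:
        return np.empty(0)
    sub = table.subset(list(selected))
    raw = window_mean_matrix([window], sub)[0]
    return _logistic_array(raw)
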