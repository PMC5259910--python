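"""Chains, DSSP parsing, RSA labels, and 11-residue segment extraction.

A labelled chain carries, per residue, the absolute accessible surface
area (ASA, in square Angstrom) and a one-letter secondary-structure code
as assigned by DSSP from a 3D structure.  ASA is converted to relative
solvent accessibility (RSA, percent) by dividing by the residue's maximum
ASA in an extended Ala-X-Ala tripeptide and clamping to [0, 100].

Chains are cut into overlapping 11-residue windows; the central residue of
each window is the prediction target, the five residues on either side
provide context.  Windows crossing a chain terminus are padded with ``-``.
Segments are grouped by central residue: one regression model is trained
per standard amino acid, twenty in all.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field
from typing import Iterable, TextIO

import numpy as np
from Bio import SeqIO

from .aaindex import PAD, STANDARD_RESIDUES

logger = logging.getLogger(__name__)

WINDOW = 11
HALF_WINDOW = WINDOW // 2


class DSSPParseError(ValueError):
    """Raised when a stream does not follow the classic DSSP layout."""


def _load_max_asa() -> dict[str, float]:
    text = (
        importlib.resources.files("rsapred.data").joinpath("max_asa.tsv").read_text()
    )
    out: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("residue"):
            continue
        res, val = line.split("\t")
        out[res] = float(val)
    return out


#: Extended Ala-X-Ala maximum ASA per residue (square Angstrom).
MAX_ASA: dict[str, float] = _load_max_asa()


@dataclass
class ProteinChain:
    """A protein chain with optional per-residue ASA and DSSP annotations."""

    id: str
    sequence: str
    asa: np.ndarray | None = None  # square Angstrom, NaN where unknown
    ss: str | None = None  # DSSP summary letters, ' ' = coil/none

    def __post_init__(self) -> None:
        if self.asa is not None:
            self.asa = np.asarray(self.asa, dtype=float)
            if len(self.asa) != len(self.sequence):
                raise ValueError(
                    f"{self.id}: ASA length {len(self.asa)} != sequence "
                    f"length {len(self.sequence)}"
                )
            if np.nanmin(self.asa, initial=0.0) < 0:
                raise ValueError(f"{self.id}: negative ASA")
        if self.ss is not None and len(self.ss) != len(self.sequence):
            raise ValueError(f"{self.id}: SS length != sequence length")

    def __len__(self) -> int:
        return len(self.sequence)

    def rsa(self) -> np.ndarray:
        """Per-residue RSA in percent (NaN where ASA is missing)."""
        if self.asa is None:
            raise ValueError(f"{self.id}: chain has no ASA annotation")
        out = np.full(len(self), np.nan)
        for i, (res, a) in enumerate(zip(self.sequence, self.asa)):
            if np.isfinite(a) and res in MAX_ASA:
                out[i] = rsa_from_asa(a, res)
        return out


@dataclass
class SegmentRecord:
    """An 11-residue window centred on the prediction target."""

    chain_id: str
    center_position: int  # 0-based index into the chain
    window: str  # length 11, PAD at edges only
    center_residue: str = field(init=False)
    observed_rsa: float | None = None  # percent

    def __post_init__(self) -> None:
        if len(self.window) != WINDOW:
            raise ValueError(f"window must have length {WINDOW}")
        self.center_residue = self.window[HALF_WINDOW]
        if self.center_residue == PAD:
            raise ValueError("window centre must be a residue, not padding")


def rsa_from_asa(asa: float, residue: str) -> float:
    """Relative solvent accessibility (percent) from absolute ASA.

    ``100 * asa / max_asa(residue)`` clamped to [0, 100]; real structures can
    exceed the extended-tripeptide reference, hence the clamp.
    """
    if residue not in MAX_ASA:
        raise KeyError(f"unknown residue {residue!r} (no maximum-ASA reference)")
    if asa < 0:
        raise ValueError(f"negative ASA {asa}")
    rsa = 100.0 * asa / MAX_ASA[residue]
    if rsa > 100.0:
        logger.debug("RSA %.1f%% for %s clamped to 100%%", rsa, residue)
    return float(min(rsa, 100.0))


# ---------------------------------------------------------------------------
# DSSP

# Classic DSSP residue-line fixed columns (0-based, half-open)
_COL_RESNUM = slice(5, 10)
_COL_CHAIN = 11
_COL_AA = 13
_COL_SS = 16
_COL_ACC = slice(34, 38)


def parse_dssp(stream: TextIO | Iterable[str], file_id: str = "dssp") -> list[ProteinChain]:
    """Parse classic DSSP output into one :class:`ProteinChain` per chain.

    Residue lines after the ``#  RESIDUE`` header are read by fixed column:
    amino acid letter, structure-summary letter, and the ACC (ASA) column.
    Chain-break lines (``!``) and chain-letter changes split chains.
    Lowercase amino-acid letters (disulfide-bonded half-cystines) are mapped
    to ``C``.
    """
    lines = iter(stream)
    header_found = False
    for raw in lines:
        if raw.lstrip().startswith("#") and "RESIDUE" in raw:
            header_found = True
            break
    if not header_found:
        raise DSSPParseError("missing '#  RESIDUE' header line")

    chains: list[ProteinChain] = []
    seq: list[str] = []
    asa: list[float] = []
    ss: list[str] = []
    current_chain: str | None = None

    def flush() -> None:
        nonlocal seq, asa, ss, current_chain
        if seq:
            cid = f"{file_id}:{current_chain or '_'}"
            if any(c.id == cid for c in chains):
                cid = f"{cid}.{len(chains)}"
            chains.append(
                ProteinChain(cid, "".join(seq), np.array(asa), "".join(ss))
            )
        seq, asa, ss = [], [], []
        current_chain = None

    for raw in lines:
        line = raw.rstrip("\n")
        if len(line) <= _COL_AA or not line[:5].strip():
            continue
        aa = line[_COL_AA]
        if aa == "!":  # chain break
            flush()
            continue
        chain_letter = line[_COL_CHAIN] if len(line) > _COL_CHAIN else " "
        if current_chain is not None and chain_letter != current_chain:
            flush()
        current_chain = chain_letter
        if aa.islower():  # SS-bonded cysteine pairs are labelled a, b, c, ...
            logger.debug("half-cystine %r mapped to C", aa)
            aa = "C"
        seq.append(aa)
        ss_char = line[_COL_SS] if len(line) > _COL_SS else " "
        ss.append(ss_char if ss_char != " " else " ")
        acc_text = line[_COL_ACC].strip() if len(line) >= _COL_ACC.stop else ""
        try:
            asa.append(float(acc_text))
        except ValueError as exc:
            raise DSSPParseError(
                f"bad ACC field {acc_text!r} on line: {line[:40]!r}"
            ) from exc
    flush()
    return chains


def read_fasta(stream: TextIO | str) -> list[ProteinChain]:
    """Read protein sequences from FASTA into unannotated chains."""
    return [
        ProteinChain(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(stream, "fasta")
    ]


# ---------------------------------------------------------------------------
# Segmentation


def segment_chain(chain: ProteinChain) -> list[SegmentRecord]:
    """Cut a chain into one 11-residue window per residue, padding termini."""
    if len(chain) == 0:
        raise ValueError(f"{chain.id}: empty chain")
    rsa = chain.rsa() if chain.asa is not None else None
    padded = PAD * HALF_WINDOW + chain.sequence + PAD * HALF_WINDOW
    out = []
    for i in range(len(chain)):
        label = None
        if rsa is not None and np.isfinite(rsa[i]):
            label = float(rsa[i])
        out.append(
            SegmentRecord(chain.id, i, padded[i : i + WINDOW], observed_rsa=label)
        )
    return out


def group_by_center(
    segments: Iterable[SegmentRecord],
) -> dict[str, list[SegmentRecord]]:
    """Partition segments by central residue; nonstandard centres are dropped."""
    groups: dict[str, list[SegmentRecord]] = {}
    dropped = 0
    for seg in segments:
        if seg.center_residue in STANDARD_RESIDUES:
            groups.setdefault(seg.center_residue, []).append(seg)
        else:
            dropped += 1
    if dropped:
        logger.info("dropped %d segments with nonstandard central residues", dropped)
    return groups
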