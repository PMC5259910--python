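"""PSI-BLAST ASCII PSSM parsing and 231-value per-segment profile features.

Each residue position of a profile becomes a 21-dimensional vector: the 20
profile values squashed into (0, 1) with the logistic function, plus a
terminal flag that is 0 for every real position.  A segment's profile
feature is the concatenation of the 11 per-position vectors centred on the
target residue (centre +/- 5), 231 values in all.  Window positions beyond
the chain termini contribute a raw 0 for each of the 20 profile values
(0.5 after the logistic) and flag 1.

Two profile blocks appear in PSI-BLAST's ASCII output: the log-odds scores
(first 20 columns) and the weighted percentages (next 20).  The scores feed
the logistic by default; the percentage block can be selected instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, TextIO

import numpy as np

from .aaindex import _logistic_array, logistic_normalize
from .dataset import HALF_WINDOW, WINDOW

#: Residue column order of PSI-BLAST matrix output.
PSSM_ORDER = "ARNDCQEGHILKMFPSTWYV"

PROFILE_WIDTH = 21  # 20 values + terminal flag
SEGMENT_WIDTH = WINDOW * PROFILE_WIDTH  # 231


class PSSMParseError(ValueError):
    """Raised on malformed PSI-BLAST ASCII matrix text."""


@dataclass
class PSSMProfile:
    """Per-position evolutionary profile of one chain.

    ``scores`` holds the raw selected block (length x 20); ``vectors`` the
    normalized (length x 21) representation with the terminal flag column.
    """

    chain_id: str
    sequence: str
    scores: np.ndarray  # raw block, (L, 20)
    block: str = "scores"  # which ASCII block scores came from

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.sequence), 20):
            raise ValueError(
                f"{self.chain_id}: scores shape {self.scores.shape} does not "
                f"match sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def vectors(self) -> np.ndarray:
        """Normalized (L, 21) profile: logistic(20 values) + flag column of 0."""
        norm = _logistic_array(self.scores)
        flags = np.zeros((len(self), 1))
        return np.hstack([norm, flags])


def parse_pssm(
    stream: TextIO | Iterable[str], chain_id: str = "query", block: str = "scores"
) -> PSSMProfile:
    """Parse PSI-BLAST ASCII PSSM output (the ``-Q`` matrix file).

    ``block`` selects which 20-column block is kept: ``"scores"`` (log-odds,
    default) or ``"frequencies"`` (weighted percentages).
    """
    if block not in ("scores", "frequencies"):
        raise ValueError(f"unknown PSSM block {block!r}")
    lines = list(stream)
    header_i = None
    for i, line in enumerate(lines):
        toks = line.split()
        if len(toks) >= 20 and all(t in PSSM_ORDER and len(t) == 1 for t in toks[:20]):
            header_i = i
            break
    if header_i is None:
        raise PSSMParseError("no residue-letter header line found")

    seq: list[str] = []
    rows: list[list[float]] = []
    expected = None
    last_good = 0
    for line in lines[header_i + 1 :]:
        toks = line.split()
        if not toks:
            continue
        if not toks[0].isdigit():
            break  # footer (K, Lambda, ...)
        if len(toks) < 22:
            raise PSSMParseError(
                f"truncated PSSM row after position {last_good}: {line.strip()[:40]!r}"
            )
        pos = int(toks[0])
        if expected is not None and pos != expected:
            raise PSSMParseError(f"position {pos} out of order (expected {expected})")
        expected = pos + 1
        seq.append(toks[1])
        values = toks[2:]
        if block == "scores":
            sel = values[:20]
        else:
            if len(values) < 40:
                raise PSSMParseError(
                    f"row {pos} has no frequency block (only {len(values)} values)"
                )
            sel = values[20:40]
        try:
            rows.append([float(v) for v in sel])
        except ValueError as exc:
            raise PSSMParseError(f"bad value in row {pos}: {exc}") from exc
        last_good = pos
    if not rows:
        raise PSSMParseError("no PSSM rows found")
    return PSSMProfile(chain_id, "".join(seq), np.array(rows), block=block)


def write_pssm(profile: PSSMProfile) -> str:
    """Serialize a profile back to PSI-BLAST-style ASCII (scores block only).

    The frequency block is filled with zeros; round-trips the scores block.
    """
    head = "\nLast position-specific scoring matrix computed\n"
    letters = "   ".join(PSSM_ORDER)
    out = [head, f"            {letters}   {letters}\n"]
    for i, (res, row) in enumerate(zip(profile.sequence, profile.scores), start=1):
        scores = " ".join(f"{v:6.2f}" for v in row)
        freqs = " ".join("  0.00" for _ in row)
        out.append(f"{i:5d} {res}  {scores} {freqs}  0.00 0.00\n")
    return "".join(out)


def segment_pssm_features(profile: PSSMProfile, center: int) -> np.ndarray:
    """231-value profile feature for the window centred at ``center``.

    Concatenation of 11 21-vectors for positions ``center - 5 .. center + 5``;
    off-sequence positions contribute ``logistic(0) = 0.5`` for the 20
    profile values and terminal flag 1.
    """
    if not 0 <= center < len(profile):
        raise IndexError(f"center {center} outside chain of length {len(profile)}")
    vectors = profile.vectors
    pad = np.concatenate([np.full(20, logistic_normalize(0.0)), [1.0]])
    blocks = []
    for offset in range(-HALF_WINDOW, HALF_WINDOW + 1):
        j = center + offset
        blocks.append(vectors[j] if 0 <= j < len(profile) else pad)
    out = np.concatenate(blocks)
    assert out.shape == (SEGMENT_WIDTH,)
    return out
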