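"""Hydrophobic-spine analysis of alpha-helices.

Residues are classified along two axes: hydropathy (hydrophobic iff the
Kyte-Doolittle index is > 0, giving the seven residues A, C, I, L, M, F, V)
and exposure (exposed iff RSA >= 25%).  For each DSSP alpha-helix (maximal
run of code 'H') the exposure degree AED = n_exposed / n is computed.

A *hydrophobic spine* is a chain of exposed hydrophobic residues running up
one face of a helix, successive members spaced 3 or 4 positions apart (the
helical period is ~3.6 residues/turn, so +3/+4 neighbours sit on the same
face).  A spine is *perfect* when every member is exposed hydrophobic and
*imperfect* when up to ``max_interruptions`` face positions on the chain are
something else (e.g. an exposed hydrophilic residue bridging two member
runs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .aaindex import STANDARD_RESIDUES
from .dataset import ProteinChain

#: Kyte-Doolittle hydropathy index (KYTJ820101).
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

HYDROPATHY_THRESHOLD = 0.0
EXPOSURE_THRESHOLD = 25.0  # percent RSA; exposed iff rsa >= threshold (inclusive)


@dataclass(frozen=True)
class ResidueStatus:
    position: int
    residue: str
    hydropathy_class: str  # "hydrophobic" | "hydrophilic"
    exposure_class: str  # "exposed" | "buried"
    rsa: float

    @property
    def is_exposed_hydrophobic(self) -> bool:
        return self.hydropathy_class == "hydrophobic" and self.exposure_class == "exposed"


@dataclass
class HelixAnnotation:
    """A maximal DSSP 'H' run with per-residue status and exposure degree."""

    chain_id: str
    start: int  # 0-based, half-open [start, end)
    end: int
    statuses: list[ResidueStatus]

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def aed(self) -> float:
        """Helix exposure degree: exposed residue count / helix length."""
        n = len(self.statuses)
        return sum(s.exposure_class == "exposed" for s in self.statuses) / n

    def status_at(self, position: int) -> ResidueStatus:
        return self.statuses[position - self.start]


@dataclass
class SpineCall:
    helix: HelixAnnotation
    members: list[int]  # increasing chain positions
    interruptions: list[int] = field(default_factory=list)

    @property
    def spacings(self) -> list[int]:
        return [b - a for a, b in zip(self.members, self.members[1:])]

    @property
    def perfect(self) -> bool:
        return not self.interruptions

    def __post_init__(self) -> None:
        if any(s not in (3, 4) for s in self.spacings):
            raise ValueError(f"spine spacings must be 3 or 4, got {self.spacings}")
        if not set(self.interruptions) <= set(self.members):
            raise ValueError("interruptions must be member positions")


def classify_residue(
    letter: str,
    rsa: float,
    *,
    exposure_threshold: float = EXPOSURE_THRESHOLD,
    position: int = -1,
) -> ResidueStatus:
    """2x2 classification of one residue by hydropathy and exposure."""
    if letter not in STANDARD_RESIDUES:
        raise ValueError(f"nonstandard residue {letter!r}")
    if not 0.0 <= rsa <= 100.0:
        raise ValueError(f"RSA {rsa} outside [0, 100]")
    hydro = "hydrophobic" if KYTE_DOOLITTLE[letter] > HYDROPATHY_THRESHOLD else "hydrophilic"
    expo = "exposed" if rsa >= exposure_threshold else "buried"
    return ResidueStatus(position, letter, hydro, expo, float(rsa))


def extract_helices(
    chain: ProteinChain, *, exposure_threshold: float = EXPOSURE_THRESHOLD
) -> list[HelixAnnotation]:
    """Maximal runs of DSSP code 'H' (alpha-helix only; G and I do not count).

    Helices containing nonstandard residues or missing RSA are skipped.
    """
    if chain.ss is None or chain.asa is None:
        raise ValueError(f"{chain.id}: chain needs DSSP codes and ASA")
    rsa = chain.rsa()
    helices: list[HelixAnnotation] = []
    i = 0
    n = len(chain)
    while i < n:
        if chain.ss[i] != "H":
            i += 1
            continue
        j = i
        while j < n and chain.ss[j] == "H":
            j += 1
        try:
            statuses = [
                classify_residue(
                    chain.sequence[k],
                    rsa[k],
                    exposure_threshold=exposure_threshold,
                    position=k,
                )
                for k in range(i, j)
            ]
        except ValueError:
            statuses = None
        if statuses is not None and not any(np.isnan(rsa[i:j])):
            helices.append(HelixAnnotation(chain.id, i, j, statuses))
        i = j
    return helices


def neighbor_ratios(
    helices: Iterable[HelixAnnotation],
    offsets: Sequence[int] = tuple(range(1, 7)),
    aed_bin_width: float = 10.0,
) -> pd.DataFrame:
    """Exposed hydrophobic/hydrophilic neighbour ratios of exposed hydrophobic residues.

    For every exposed hydrophobic residue i in a helix and every offset d,
    the neighbour at i + d (same helix) is tallied by hydropathy class if it
    is exposed.  Tallies are binned by the helix's AED (percent bins of
    ``aed_bin_width``; the last bin is closed at 100).  The ratio is
    hydrophobic tally / hydrophilic tally, NaN when the denominator is zero.
    """
    n_bins = int(np.ceil(100.0 / aed_bin_width))
    phob = np.zeros((n_bins, len(offsets)), dtype=int)
    phil = np.zeros((n_bins, len(offsets)), dtype=int)
    for helix in helices:
        aed_pct = helix.aed * 100.0
        b = min(int(aed_pct // aed_bin_width), n_bins - 1)
        for s in helix.statuses:
            if not s.is_exposed_hydrophobic:
                continue
            for k, d in enumerate(offsets):
                j = s.position + d
                if j >= helix.end:
                    continue
                t = helix.status_at(j)
                if t.exposure_class != "exposed":
                    continue
                if t.hydropathy_class == "hydrophobic":
                    phob[b, k] += 1
                else:
                    phil[b, k] += 1
    rows = []
    for b in range(n_bins):
        lo = b * aed_bin_width
        for k, d in enumerate(offsets):
            ratio = phob[b, k] / phil[b, k] if phil[b, k] else np.nan
            rows.append(
                {
                    "aed_bin": f"[{lo:g},{min(lo + aed_bin_width, 100):g}{']' if b == n_bins - 1 else ')'}",
                    "offset": d,
                    "n_phobic": int(phob[b, k]),
                    "n_philic": int(phil[b, k]),
                    "ratio": ratio,
                }
            )
    return pd.DataFrame(rows)


def bridge_position(
    p: int, q: int, member_set: frozenset[int], helix: HelixAnnotation
) -> int | None:
    """Canonical interruption position bridging two spine members p < q.

    Two members whose gap is 6, 7 or 8 can be linked through one face
    position m with ``m - p`` and ``q - m`` both in {3, 4}.  The bridge
    must itself not be exposed hydrophobic (it would then simply be a
    member).  For a gap of 7 both offsets qualify geometrically; the
    exposed candidate is preferred (an exposed hydrophilic residue is what
    interrupts a face), ties broken toward the smaller offset.
    """
    gap = q - p
    if gap == 6:
        cands = [p + 3]
    elif gap == 8:
        cands = [p + 4]
    elif gap == 7:
        cands = [p + 3, p + 4]
    else:
        return None
    cands = [m for m in cands if m not in member_set]
    if not cands:
        return None
    if len(cands) == 2:
        exposed = [
            m for m in cands if helix.status_at(m).exposure_class == "exposed"
        ]
        cands = exposed or cands
    return cands[0]


def find_spines(
    helix: HelixAnnotation,
    min_members: int = 3,
    max_interruptions: int = 1,
) -> list[SpineCall]:
    """All maximal hydrophobic spines of one helix.

    A spine is a face chain p_1 < ... < p_k with all successive gaps in
    {3, 4}, whose exposed hydrophobic positions are its *members* and whose
    other positions (at most ``max_interruptions``, interior only, each
    bridging two members at gaps 6-8) are *interruptions*.  A call needs at
    least ``min_members`` members.  Returned chains are maximal: the member
    set of no other valid chain strictly contains theirs.
    """
    members = [
        s.position for s in helix.statuses if s.is_exposed_hydrophobic
    ]
    member_set = frozenset(members)

    # DFS over member sequences; consecutive members are linked directly
    # (gap 3/4) or through one canonical bridging interruption (gap 6-8)
    paths: list[tuple[tuple[int, ...], tuple[int, ...]]] = []  # (members, bridges)

    def extend(seq: tuple[int, ...], bridges: tuple[int, ...]) -> None:
        paths.append((seq, bridges))
        p = seq[-1]
        for q in members:
            if q <= p:
                continue
            gap = q - p
            if gap in (3, 4):
                extend(seq + (q,), bridges)
            elif gap in (6, 7, 8) and len(bridges) < max_interruptions:
                m = bridge_position(p, q, member_set, helix)
                if m is not None:
                    extend(seq + (q,), bridges + (m,))

    for p in members:
        extend((p,), ())

    valid = {
        seq: bridges
        for seq, bridges in paths
        if len(seq) >= min_members
    }
    member_sets = {seq: frozenset(seq) for seq in valid}
    calls = []
    for seq, bridges in valid.items():
        if any(
            member_sets[seq] < other
            for o, other in member_sets.items()
            if o != seq
        ):
            continue
        chain = sorted(set(seq) | set(bridges))
        calls.append(SpineCall(helix, chain, sorted(bridges)))
    calls.sort(key=lambda c: c.members)
    return calls


def scan_dataset(
    chains: Iterable[ProteinChain],
    aed_min: float = 90.0,
    min_members: int = 3,
    max_interruptions: int = 1,
    *,
    exposure_threshold: float = EXPOSURE_THRESHOLD,
) -> pd.DataFrame:
    """Scan annotated chains for hydrophobic spines in highly exposed helices.

    Helices are filtered to AED >= ``aed_min`` percent before spine calling.
    Returns one row per spine call (empty frame with the right columns when
    nothing is found); perfect/imperfect counts are simple value counts of
    the ``perfect`` column.
    """
    rows = []
    n_helices = 0
    for chain in chains:
        for helix in extract_helices(chain, exposure_threshold=exposure_threshold):
            n_helices += 1
            if helix.aed * 100.0 < aed_min:
                continue
            for call in find_spines(helix, min_members, max_interruptions):
                rows.append(
                    {
                        "chain": chain.id,
                        "helix_start": helix.start,
                        "helix_end": helix.end,
                        "aed": round(helix.aed, 4),
                        "members": ",".join(map(str, call.members)),
                        "spacings": ",".join(map(str, call.spacings)),
                        "interruptions": ",".join(map(str, call.interruptions)),
                        "perfect": call.perfect,
                    }
                )
    columns = [
        "chain", "helix_start", "helix_end", "aed",
        "members", "spacings", "interruptions", "perfect",
    ]
    df = pd.DataFrame(rows, columns=columns)
    df.attrs["n_helices"] = n_helices
    df.attrs["n_perfect"] = int(df["perfect"].sum()) if len(df) else 0
    df.attrs["n_imperfect"] = int((~df["perfect"]).sum()) if len(df) else 0
    return df
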