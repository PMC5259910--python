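"""Synthetic fixture generation for every pipeline stage.

Everything here is a pure function of (config, seed).  The generators
emulate the shapes of real inputs — sequences with helical segments,
per-position RSA labels with the ~3.6 residue/turn helical periodicity,
profile matrices concentrated on the true residue, classic-format DSSP
text — without claiming physical realism (see docs/methods.md for what
these fixtures do and do not exercise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .aaindex import AAINDEX_ORDER, PropertyIndex, PropertyTable, window_mean_matrix, _logistic_array
from .dataset import MAX_ASA, ProteinChain, SegmentRecord, WINDOW
from .pssm import PSSMProfile

HYDROPHOBIC = "ACILMFV"  # Kyte-Doolittle > 0
HYDROPHILIC = "RNDQEGHKPSTWY"

#: Helical period in residues per turn; +3/+4 neighbours share a face.
HELIX_PERIOD = 3.6


@dataclass
class SynthConfig:
    """Knobs of the synthetic study conditions.

    ``rsa_noise_sd`` is in RSA percentage points; ``helix_fraction`` is the
    target fraction of residues inside helices; ``exposure_amplitude``
    scales the one-face sinusoidal exposure model of helices.
    """

    n_chains: int = 50
    length_range: tuple[int, int] = (60, 120)
    helix_fraction: float = 0.45
    rsa_noise_sd: float = 2.0
    exposure_amplitude: float = 2.0
    n_properties: int = 200
    n_informative_pcps: int = 5
    n_segments: int = 160
    effect_range: tuple[float, float] = (1.0, 2.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains <= 0 or self.n_properties <= 0 or self.n_segments <= 0:
            raise ValueError("counts must be positive")
        if self.rsa_noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


# ---------------------------------------------------------------------------
# Property tables


def gen_property_table(
    n_properties: int,
    seed: int,
    prefix: str = "SYNP",
    rank: int = 5,
    common_sd: float = 1.4,
    jitter_sd: float = 1.4,
) -> PropertyTable:
    """A synthetic AAindex-style table of ``n_properties`` complete indices.

    Real amino-acid index collections are strongly collinear (many scales
    restate hydrophobicity or helix propensity), so each generated property
    is a shared low-rank component plus per-property jitter:
    ``v = A z + e`` with a fixed 20 x rank basis A, ``z ~ N(0, common_sd)``
    and ``e ~ N(0, jitter_sd)`` per residue.  ``rank=0`` gives independent
    Gaussian scales.
    """
    rng = np.random.default_rng(seed)
    if rank > 0:
        basis = rng.normal(0.0, 1.0, size=(20, rank))
        basis /= np.linalg.norm(basis, axis=0)
    indices = []
    for i in range(n_properties):
        vals = rng.normal(0.0, jitter_sd, size=20)
        if rank > 0:
            vals += basis @ rng.normal(0.0, common_sd, size=rank)
        indices.append(
            PropertyIndex(
                f"{prefix}{i + 1:04d}",
                f"Synthetic physicochemical scale #{i + 1} (generated)",
                dict(zip(AAINDEX_ORDER, map(float, np.round(vals, 3)))),
            )
        )
    return PropertyTable(indices, source_version=f"synthetic-{seed}")


# ---------------------------------------------------------------------------
# Chains with helical exposure structure


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def gen_chain(
    config: SynthConfig, rng: np.random.Generator, chain_id: str = "synth"
) -> tuple[ProteinChain, PSSMProfile]:
    """One synthetic chain plus its profile.

    Helix residues follow a one-face exposure model
    ``rsa_i = 100 * sigmoid(a * sin(2 pi i / 3.6 + phi)) + noise`` so that
    one helix face is systematically more exposed; coil RSA is uniform.
    ASA is stored as integers so DSSP-like text round-trips exactly.
    """
    length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
    seq = list(rng.choice(list(AAINDEX_ORDER), size=length))
    ss = [" "] * length

    target = int(config.helix_fraction * length)
    covered = 0
    attempts = 0
    while covered < target and attempts < 50:
        attempts += 1
        hlen = int(rng.integers(10, 23))
        start = int(rng.integers(0, max(1, length - hlen)))
        if any(ss[k] == "H" for k in range(max(0, start - 1), min(length, start + hlen + 1))):
            continue
        for k in range(start, min(length, start + hlen)):
            ss[k] = "H"
        covered += min(length, start + hlen) - start

    rsa = np.empty(length)
    i = 0
    while i < length:
        if ss[i] == "H":
            j = i
            while j < length and ss[j] == "H":
                j += 1
            phase = rng.uniform(0, 2 * math.pi)
            for t, k in enumerate(range(i, j)):
                base = 100.0 * _logistic(
                    config.exposure_amplitude
                    * math.sin(2 * math.pi * t / HELIX_PERIOD + phase)
                )
                rsa[k] = base + rng.normal(0.0, config.rsa_noise_sd)
            i = j
        else:
            rsa[i] = rng.uniform(0.0, 100.0)
            i += 1
    rsa = np.clip(rsa, 0.0, 100.0)

    asa = np.array(
        [round(rsa[k] / 100.0 * MAX_ASA[seq[k]]) for k in range(length)], dtype=float
    )
    chain = ProteinChain(chain_id, "".join(seq), asa, "".join(ss))
    profile = gen_profile(chain, rng)
    return chain, profile


def gen_profile(chain: ProteinChain, rng: np.random.Generator) -> PSSMProfile:
    """A profile concentrated on the true residue with symmetric noise."""
    scores = rng.normal(-2.0, 1.0, size=(len(chain), 20))
    for i, res in enumerate(chain.sequence):
        j = AAINDEX_ORDER.index(res) if res in AAINDEX_ORDER else None
        if j is not None:
            scores[i, j] = rng.normal(7.0, 1.0)
    return PSSMProfile(chain.id, chain.sequence, np.round(scores, 2))


def gen_chains(config: SynthConfig) -> list[tuple[ProteinChain, PSSMProfile]]:
    rng = np.random.default_rng(config.rng_seed)
    return [
        gen_chain(config, rng, chain_id=f"synth{i:03d}")
        for i in range(config.n_chains)
    ]


# ---------------------------------------------------------------------------
# Planted spines


def plant_spine(
    chain: ProteinChain,
    helix_index: int,
    spacings: Sequence[int],
    interruptions: Sequence[int] = (),
) -> tuple[ProteinChain, list[int]]:
    """Plant a hydrophobic spine into the ``helix_index``-th helix of a chain.

    ``spacings`` (each 3 or 4) define successive face positions from the
    helix start; ``interruptions`` are member ordinals (0-based, interior
    only) that become exposed *hydrophilic* instead of exposed hydrophobic.
    Every other helix residue is made buried hydrophilic so exactly the
    planted chain is detectable.  Returns the modified chain and the planted
    member positions (chain coordinates).
    """
    if not spacings:
        raise ValueError("spacings must be non-empty")
    if any(s not in (3, 4) for s in spacings):
        raise ValueError(f"spacings must be 3 or 4, got {list(spacings)}")
    k = len(spacings) + 1
    if any(not 0 < i < k - 1 for i in interruptions):
        raise ValueError("interruptions must be interior member ordinals")
    if chain.ss is None or chain.asa is None:
        raise ValueError("chain must carry SS and ASA annotations")

    helices = []
    i = 0
    while i < len(chain):
        if chain.ss[i] == "H":
            j = i
            while j < len(chain) and chain.ss[j] == "H":
                j += 1
            helices.append((i, j))
            i = j
        else:
            i += 1
    if helix_index >= len(helices):
        raise IndexError(f"chain has only {len(helices)} helices")
    start, end = helices[helix_index]
    span = sum(spacings)
    if end - start < span + 1:
        raise ValueError(
            f"helix of length {end - start} too short for spine span {span + 1}"
        )

    positions = [start]
    for s in spacings:
        positions.append(positions[-1] + s)

    seq = list(chain.sequence)
    asa = chain.asa.copy()
    inter = set(interruptions)
    for pos in range(start, end):
        seq[pos] = "S"
        asa[pos] = round(0.10 * MAX_ASA["S"])  # buried hydrophilic
    for ordinal, pos in enumerate(positions):
        if ordinal in inter:
            seq[pos] = "S"
            asa[pos] = round(0.60 * MAX_ASA["S"])  # exposed hydrophilic bridge
        else:
            seq[pos] = "L"
            asa[pos] = round(0.60 * MAX_ASA["L"])  # exposed hydrophobic member
    planted = ProteinChain(chain.id, "".join(seq), asa, chain.ss)
    return planted, positions


# ---------------------------------------------------------------------------
# Feature-selection benchmark


def gen_selection_benchmark(
    config: SynthConfig, table: PropertyTable | None = None, center: str = "A"
) -> dict:
    """Labelled single-centre segments whose RSA is driven by known properties.

    The label of each segment is a smooth nonlinear combination
    ``sum_j w_j sin(3 pi (f_j - 1/2))`` of the selected informative
    properties' logistic-squashed window means f_j, standardized to mean 50
    / sd 20 on the RSA percent scale, plus Gaussian noise of
    ``config.rsa_noise_sd``, clamped to [0, 100].  The nonlinearity matters:
    window means of *any* ~20 independent properties span the window's
    residue-composition space, so a linear target would be predictable from
    generic property subsets and the planted set would not be identifiable.
    Ground truth (informative accessions and weights) is returned beside
    the data.
    """
    rng = np.random.default_rng(config.rng_seed)
    if table is None:
        table = gen_property_table(config.n_properties, seed=config.rng_seed + 7919)
    if config.n_informative_pcps > len(table):
        raise ValueError("more informative properties requested than table size")

    informative = sorted(
        rng.choice(table.accessions, size=config.n_informative_pcps, replace=False)
    )
    lo, hi = config.effect_range
    weights = rng.uniform(lo, hi, size=config.n_informative_pcps)
    weights *= rng.choice([-1.0, 1.0], size=config.n_informative_pcps)

    half = WINDOW // 2
    windows = []
    for _ in range(config.n_segments):
        flank1 = "".join(rng.choice(list(AAINDEX_ORDER), size=half))
        flank2 = "".join(rng.choice(list(AAINDEX_ORDER), size=half))
        windows.append(flank1 + center + flank2)

    feats = _logistic_array(window_mean_matrix(windows, table.subset(informative)))
    raw = np.sin(3.0 * math.pi * (feats - 0.5)) @ weights
    z = (raw - raw.mean()) / raw.std()
    labels = 50.0 + 20.0 * z + rng.normal(0.0, config.rsa_noise_sd, size=len(z))
    labels = np.clip(labels, 0.0, 100.0)

    segments = [
        SegmentRecord(f"bench{i:04d}", half, windows[i], observed_rsa=float(labels[i]))
        for i in range(config.n_segments)
    ]
    return {
        "segments": segments,
        "table": table,
        "informative": list(informative),
        "weights": weights,
        "noise_sd": config.rsa_noise_sd,
    }


# ---------------------------------------------------------------------------
# Chains whose RSA is a (noiseless) function of bundled PCPs


def gen_pcp_rsa_chains(
    config: SynthConfig,
    table: PropertyTable,
    selected: Sequence[str],
    gain: float = 12.0,
) -> list[tuple[ProteinChain, PSSMProfile]]:
    """Chains whose per-residue RSA is a deterministic function of PCPs.

    The RSA of residue i is ``100 * sigmoid(gain * (u_i - 0.5))`` where u_i
    is the weight-averaged logistic window mean of the ``selected``
    properties — noiseless by construction (``rsa_noise_sd`` is ignored),
    for convergence checks of the regression stage.
    """
    rng = np.random.default_rng(config.rng_seed)
    weights = rng.uniform(*config.effect_range, size=len(selected))
    weights /= weights.sum()
    sub = table.subset(list(selected))
    out = []
    half = WINDOW // 2
    for c in range(config.n_chains):
        length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        seq = "".join(rng.choice(list(AAINDEX_ORDER), size=length))
        padded = "-" * half + seq + "-" * half
        windows = [padded[i : i + WINDOW] for i in range(length)]
        feats = _logistic_array(window_mean_matrix(windows, sub))
        u = feats @ weights
        rsa = 100.0 / (1.0 + np.exp(-gain * (u - 0.5)))
        asa = np.array([rsa[i] / 100.0 * MAX_ASA[seq[i]] for i in range(length)])
        chain = ProteinChain(f"pcpfn{c:03d}", seq, asa, " " * length)
        out.append((chain, gen_profile(chain, rng)))
    return out


# ---------------------------------------------------------------------------
# DSSP-like text


_DSSP_HEADER = (
    "==== Secondary Structure Definition (synthetic fixture) ====\n"
    "REFERENCE  synthetic chain annotations in classic DSSP layout\n"
    "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N    "
    "N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI    X-CA   Y-CA   Z-CA\n"
)


def write_dssp_like(chains: Sequence[ProteinChain]) -> str:
    """Classic fixed-column DSSP text for annotated chains.

    ASA values are written as integers in the ACC column; chains are
    separated by '!' break lines.  ``parse_dssp`` round-trips the sequence,
    ASA, and SS letters exactly (for integer ASA).
    """
    chain_letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    lines = [_DSSP_HEADER]
    serial = 0
    for ci, chain in enumerate(chains):
        if chain.asa is None or chain.ss is None:
            raise ValueError(f"{chain.id}: chain must be fully annotated")
        if ci > 0:
            serial += 1
            lines.append(f"{serial:5d}        !              0   0    0\n")
        letter = chain_letters[ci % len(chain_letters)]
        for i in range(len(chain)):
            serial += 1
            acc = int(round(chain.asa[i]))
            ss = chain.ss[i]
            # cols: 0-4 serial, 5-9 resnum, 11 chain, 13 AA, 16 SS,
            # 25-28 BP1, 29-32 BP2, 34-37 ACC
            lines.append(
                f"{serial:5d}{i + 1:5d} {letter} {chain.sequence[i]}  {ss}"
                + " " * 8
                + f"{0:4d}{0:4d} {acc:4d}\n"
            )
    return "".join(lines)
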