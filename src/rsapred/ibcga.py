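"""Inheritable biobjective combinatorial GA for informative-property selection.

The algorithm selects exactly *r* physicochemical properties out of *n*
candidates (search space C(n, r)) for one per-residue RSA regressor while
simultaneously tuning three 4-bit genes that encode the epsilon-SVR
hyperparameters C, gamma and epsilon.  Fitness is the 10-fold
cross-validated mean absolute error (percent RSA) of the SVR trained on the
masked property features.

The search sweeps r from ``r_start`` down to ``r_end``; each stage's best
chromosome seeds the next stage's population with one distinct active gene
disabled per copy (the inheritance mechanism).  Crossover is the
orthogonal-experimental-design "intelligent" operator: genes on which the
parents agree are copied, divergent genes are bucketed into at most seven
two-level factors, an L8 orthogonal array over the factors is evaluated,
and the children are the best array row and the main-effect-optimal
combination.  Every operator preserves popcount(mask) == r.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from .aaindex import PropertyTable, _logistic_array, window_mean_matrix
from .dataset import SegmentRecord

logger = logging.getLogger(__name__)

#: Standard two-level L8(2^7) orthogonal array (8 runs x 7 factors).
L8 = np.array(
    [
        [0, 0, 0, 0, 0, 0, 0],
        [0, 0, 0, 1, 1, 1, 1],
        [0, 1, 1, 0, 0, 1, 1],
        [0, 1, 1, 1, 1, 0, 0],
        [1, 0, 1, 0, 1, 0, 1],
        [1, 0, 1, 1, 0, 1, 0],
        [1, 1, 0, 0, 1, 1, 0],
        [1, 1, 0, 1, 0, 0, 1],
    ],
    dtype=int,
)

MAX_FACTORS = 7


@dataclass
class IBCGAConfig:
    """GA control parameters; defaults follow the study conditions."""

    population_size: int = 50
    crossover_rate: float = 0.8
    mutation_rate: float = 0.05
    r_start: int = 40
    r_end: int = 10
    generations_per_stage: int = 30
    stagnation_patience: int = 10
    runs: int = 30
    rng_seed: int = 0
    cv_folds: int = 10
    #: "screened" biases initial masks toward properties with good
    #: univariate CV MAE (one cheap pass over the table); "uniform" draws
    #: initial masks uniformly at random.
    init: str = "screened"

    def __post_init__(self) -> None:
        if not self.r_start >= self.r_end >= 1:
            raise ValueError("need r_start >= r_end >= 1")
        for rate in (self.crossover_rate, self.mutation_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class ChromosomeState:
    """One GA individual: binary PCP mask plus three 4-bit parameter genes."""

    pcp_mask: np.ndarray  # bool vector over the PropertyTable
    c_gene: int
    gamma_gene: int
    eps_gene: int
    fitness: float | None = None  # CV MAE percent; None = unevaluated

    def __post_init__(self) -> None:
        self.pcp_mask = np.asarray(self.pcp_mask, dtype=bool)
        for g in (self.c_gene, self.gamma_gene, self.eps_gene):
            if not 0 <= g <= 15:
                raise ValueError(f"4-bit gene out of range: {g}")

    @property
    def r(self) -> int:
        return int(self.pcp_mask.sum())

    @property
    def genes(self) -> tuple[int, int, int]:
        return (self.c_gene, self.gamma_gene, self.eps_gene)

    def key(self) -> tuple:
        return (self.pcp_mask.tobytes(), self.c_gene, self.gamma_gene, self.eps_gene)

    def copy(self) -> "ChromosomeState":
        return ChromosomeState(
            self.pcp_mask.copy(), self.c_gene, self.gamma_gene, self.eps_gene,
            self.fitness,
        )


def decode_params(chromosome: ChromosomeState) -> tuple[float, float, float]:
    """Decode the 4-bit genes to (C, gamma, epsilon) on powers-of-two grids.

    C in {2^-5 .. 2^10}, gamma in {2^-12 .. 2^3}, epsilon in {2^-10 .. 2^5};
    16 distinct grid points per gene.
    """
    return (
        2.0 ** (chromosome.c_gene - 5),
        2.0 ** (chromosome.gamma_gene - 12),
        2.0 ** (chromosome.eps_gene - 10),
    )


def cv_mae(
    X: np.ndarray,
    y: np.ndarray,
    params: tuple[float, float, float],
    fold_indices: Sequence[tuple[np.ndarray, np.ndarray]],
    tol: float = 1e-3,
    max_iter: int = -1,
) -> float:
    """Cross-validated MAE (percent) of an RBF epsilon-SVR on (X, y).

    ``tol`` is the SMO stopping tolerance and ``max_iter`` the iteration
    cap; GA fitness relaxes both (the MAE changes by < 0.01 percentage
    points, far below the fitness resolution that matters, at roughly a
    third of the cost).
    """
    C, gamma, eps = params
    err = 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for train_idx, test_idx in fold_indices:
            svr = SVR(
                kernel="rbf", C=C, gamma=gamma, epsilon=eps, tol=tol,
                max_iter=max_iter,
            )
            svr.fit(X[train_idx], y[train_idx])
            pred = np.clip(svr.predict(X[test_idx]), 0.0, 100.0)
            err += np.abs(pred - y[test_idx]).sum()
    return float(err / len(y))


class SegmentEvaluator:
    """Fitness oracle for one residue group: chromosome -> 10-CV MAE.

    The full (segments x properties) window-mean matrix is precomputed once;
    a chromosome's design matrix is a column slice of it.  The fold
    assignment is frozen at construction so fitness is a pure function of
    the chromosome; evaluations are memoised.
    """

    def __init__(
        self,
        segments: Sequence[SegmentRecord],
        table: PropertyTable,
        cv_folds: int = 10,
        fold_seed: int = 0,
    ) -> None:
        labelled = [s for s in segments if s.observed_rsa is not None]
        if len(labelled) < cv_folds:
            raise ValueError(
                f"{len(labelled)} labelled segments < {cv_folds} CV folds"
            )
        centers = {s.center_residue for s in labelled}
        if len(centers) > 1:
            raise ValueError(f"segments mix central residues: {sorted(centers)}")
        self.table = table
        self.segments = labelled
        self.y = np.array([s.observed_rsa for s in labelled])
        raw = window_mean_matrix([s.window for s in labelled], table)
        self.X_full = _logistic_array(raw)
        kf = KFold(n_splits=cv_folds, shuffle=True, random_state=fold_seed)
        self.folds = list(kf.split(self.X_full))
        self._cache: dict[tuple, float] = {}
        self.n_evaluations = 0

    def __call__(self, chromosome: ChromosomeState) -> float:
        key = chromosome.key()
        if key not in self._cache:
            if chromosome.r == 0:
                raise ValueError("chromosome selects no properties")
            X = self.X_full[:, chromosome.pcp_mask]
            self.n_evaluations += 1
            self._cache[key] = cv_mae(
                X, self.y, decode_params(chromosome), self.folds,
                tol=0.05, max_iter=5000,
            )
        chromosome.fitness = self._cache[key]
        return chromosome.fitness


def fitness_mae(
    chromosome: ChromosomeState,
    segments: Sequence[SegmentRecord],
    table: PropertyTable,
    cv_folds: int = 10,
    fold_seed: int = 0,
) -> float:
    """10-CV mean absolute error (percent) of one chromosome on one group."""
    return SegmentEvaluator(segments, table, cv_folds, fold_seed)(chromosome)


# ---------------------------------------------------------------------------
# Operators


def _repair(mask: np.ndarray, r: int, rng: np.random.Generator) -> None:
    """Randomly add/remove active genes in place until popcount == r."""
    active = np.flatnonzero(mask)
    inactive = np.flatnonzero(~mask)
    if len(active) > r:
        off = rng.choice(active, size=len(active) - r, replace=False)
        mask[off] = False
    elif len(active) < r:
        on = rng.choice(inactive, size=r - len(active), replace=False)
        mask[on] = True


def _assemble(
    p1: ChromosomeState,
    p2: ChromosomeState,
    factors: list[np.ndarray],
    levels: Sequence[int],
    r: int,
    rng: np.random.Generator,
) -> ChromosomeState:
    """Build a child from per-factor parent choices and repair to popcount r."""
    n = len(p1.pcp_mask)
    mask = p1.pcp_mask.copy()
    genes = list(p1.genes)
    for level, idx in zip(levels, factors):
        if level == 0:
            continue
        for g in idx:
            if g < n:
                mask[g] = p2.pcp_mask[g]
            else:
                genes[g - n] = p2.genes[g - n]
    _repair(mask, r, rng)
    return ChromosomeState(mask, *genes)


def intelligent_crossover(
    p1: ChromosomeState,
    p2: ChromosomeState,
    evaluator: Callable[[ChromosomeState], float],
    rng: np.random.Generator,
) -> tuple[ChromosomeState, ChromosomeState]:
    """Orthogonal-experimental-design crossover preserving popcount r.

    Genes on which the parents agree are copied.  Divergent genes are
    bucketed round-robin into <= 7 two-level factors (level 0 = parent 1's
    values, level 1 = parent 2's); each distinct L8 row is assembled,
    repaired to popcount r, and scored with ``evaluator``.  Child 1 is the
    best row; child 2 the main-effect-optimal level combination.
    """
    if p1.r != p2.r:
        raise ValueError(f"parents have different popcounts: {p1.r} != {p2.r}")
    r = p1.r
    n = len(p1.pcp_mask)
    divergent = list(np.flatnonzero(p1.pcp_mask != p2.pcp_mask))
    divergent += [n + i for i in range(3) if p1.genes[i] != p2.genes[i]]
    if not divergent:
        return p1.copy(), p2.copy()

    f = min(MAX_FACTORS, len(divergent))
    factors: list[np.ndarray] = [
        np.array(divergent[j::f], dtype=int) for j in range(f)
    ]
    rows = np.unique(L8[:, :f], axis=0)
    candidates = [
        _assemble(p1, p2, factors, row, r, rng) for row in rows
    ]
    fits = np.array([evaluator(c) for c in candidates])
    child1 = candidates[int(np.argmin(fits))].copy()

    # main effect of factor j: mean fitness at level 0 vs level 1
    best_levels = [
        0 if fits[rows[:, j] == 0].mean() <= fits[rows[:, j] == 1].mean() else 1
        for j in range(f)
    ]
    child2 = _assemble(p1, p2, factors, best_levels, r, rng)
    evaluator(child2)
    return child1, child2


def _mutate(
    chromosome: ChromosomeState, rate: float, rng: np.random.Generator
) -> ChromosomeState:
    """Swap mutation on the mask (preserves popcount) + 4-bit point mutation.

    The rate is per gene: each active gene is exchanged against a random
    inactive one with probability ``rate`` (Binomial(r, rate) swaps per
    individual), keeping popcount exactly r.
    """
    c = chromosome.copy()
    c.fitness = None
    n_swaps = int(rng.binomial(int(c.r), rate))
    if n_swaps:
        active = np.flatnonzero(c.pcp_mask)
        inactive = np.flatnonzero(~c.pcp_mask)
        n_swaps = min(n_swaps, len(active), len(inactive))
        off = rng.choice(active, size=n_swaps, replace=False)
        on = rng.choice(inactive, size=n_swaps, replace=False)
        c.pcp_mask[off] = False
        c.pcp_mask[on] = True
    genes = list(c.genes)
    for i in range(3):
        if rng.random() < rate:
            genes[i] ^= 1 << int(rng.integers(4))  # flip one random bit
    c.c_gene, c.gamma_gene, c.eps_gene = genes
    return c


def _tournament(
    population: list[ChromosomeState], rng: np.random.Generator, size: int = 2
) -> ChromosomeState:
    picks = rng.integers(len(population), size=size)
    return min((population[i] for i in picks), key=lambda c: c.fitness)


def run_stage(
    population: list[ChromosomeState],
    r: int,
    config: IBCGAConfig,
    evaluator: Callable[[ChromosomeState], float],
    rng: np.random.Generator,
) -> tuple[ChromosomeState, list[ChromosomeState]]:
    """One fixed-r stage: tournament selection, OED crossover, swap mutation.

    Returns (stage best, final population).  Deterministic for a given rng
    state; elitism of one keeps the stage best alive.
    """
    for c in population:
        if c.r != r:
            raise ValueError(f"individual has popcount {c.r}, stage requires {r}")
        evaluator(c)
    best = min(population, key=lambda c: c.fitness).copy()
    stagnant = 0
    for _ in range(config.generations_per_stage):
        new_pop = [best.copy()]
        while len(new_pop) < config.population_size:
            pa, pb = _tournament(population, rng), _tournament(population, rng)
            if rng.random() < config.crossover_rate:
                c1, c2 = intelligent_crossover(pa, pb, evaluator, rng)
            else:
                c1, c2 = pa.copy(), pb.copy()
            for child in (c1, c2):
                child = _mutate(child, config.mutation_rate, rng)
                assert child.r == r, "popcount invariant violated"
                evaluator(child)
                if len(new_pop) < config.population_size:
                    new_pop.append(child)
        population = new_pop
        gen_best = min(population, key=lambda c: c.fitness)
        if gen_best.fitness < best.fitness:
            best = gen_best.copy()
            stagnant = 0
        else:
            stagnant += 1
            if stagnant >= config.stagnation_patience:
                break
    return best, population


@dataclass
class IBCGAResult:
    """Outcome of a full multi-run, multi-stage search for one residue group."""

    best: ChromosomeState
    accessions: list[str]
    params: tuple[float, float, float]  # (C, gamma, epsilon)
    mae: float
    stage_bests: list[tuple[int, int, float]] = field(default_factory=list)
    # (run, r, mae) per stage


def _random_individual(
    n: int, r: int, rng: np.random.Generator, p: np.ndarray | None = None
) -> ChromosomeState:
    mask = np.zeros(n, dtype=bool)
    mask[rng.choice(n, size=r, replace=False, p=p)] = True
    return ChromosomeState(mask, *(int(g) for g in rng.integers(16, size=3)))


def screening_weights(evaluator: SegmentEvaluator) -> np.ndarray:
    """Initialization bias from univariate property relevance.

    Each property is scored alone (best CV MAE over two mid-grid
    hyperparameter points); scores are turned into sampling probabilities
    with a soft exponential so marginally informative properties seed the
    initial population more often while every property keeps support.
    """
    n = len(evaluator.table)
    maes = np.empty(n)
    for i in range(n):
        mask = np.zeros(n, dtype=bool)
        mask[i] = True
        maes[i] = min(
            evaluator(ChromosomeState(mask, c, g, e))
            for c, g, e in ((12, 13, 8), (14, 15, 9))
        )
    spread = np.median(maes) - maes.min()
    temperature = max(spread / 3.0, 1e-6)
    w = np.exp(-(maes - maes.min()) / temperature)
    return w / w.sum()


def run_ibcga(
    segments: Sequence[SegmentRecord],
    table: PropertyTable,
    config: IBCGAConfig,
) -> IBCGAResult:
    """Full staged search: r from r_start down to r_end, ``config.runs`` restarts.

    Each next stage's population inherits the stage best with one distinct
    active gene disabled per copy.  The answer is the minimal-MAE chromosome
    over all stages and runs.
    """
    evaluator = SegmentEvaluator(
        segments, table, cv_folds=config.cv_folds, fold_seed=config.rng_seed
    )
    n = len(table)
    init_p = screening_weights(evaluator) if config.init == "screened" else None
    archive: list[tuple[int, int, ChromosomeState]] = []
    for run in range(config.runs):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.rng_seed, spawn_key=(run,))
        )
        population = [
            _random_individual(n, config.r_start, rng, p=init_p)
            for _ in range(config.population_size)
        ]
        for r in range(config.r_start, config.r_end - 1, -1):
            stage_best, population = run_stage(
                population, r, config, evaluator, rng
            )
            archive.append((run, r, stage_best))
            logger.debug(
                "run %d stage r=%d best MAE %.3f%%", run, r, stage_best.fitness
            )
            if r > config.r_end:
                active = np.flatnonzero(stage_best.pcp_mask)
                population = []
                for i in range(config.population_size):
                    child = stage_best.copy()
                    child.fitness = None
                    child.pcp_mask[active[i % len(active)]] = False
                    if child.r != r - 1:  # duplicate disable hit same gene twice
                        _repair(child.pcp_mask, r - 1, rng)
                    population.append(child)
    _, _, best = min(archive, key=lambda t: t[2].fitness)
    accessions = [table.accessions[i] for i in np.flatnonzero(best.pcp_mask)]
    return IBCGAResult(
        best=best.copy(),
        accessions=accessions,
        params=decode_params(best),
        mae=best.fitness,
        stage_bests=[(run, r, c.fitness) for run, r, c in archive],
    )
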