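"""Per-residue epsilon-SVR RSA predictors: model, results, and metrics.

The estimator follows the model/results idiom: :class:`RSAModel` is built
from labelled, grouped segments plus per-residue feature selections;
``fit()`` trains one RBF-kernel epsilon-SVR per central residue (twenty for
a full dataset) on the concatenation

    [selected PCP features | 231 PSSM profile values | normalized length]

and returns an :class:`RSAResults` carrying the trained models, training
diagnostics, a ``summary()`` table, chain prediction and persistence.

Evaluation reports the mean absolute error

    MAE = (1/n) sum_i |V_i - V'_i|        (percent RSA)

and Pearson's correlation coefficient in its normalized-sum form

    CC = 1/(n-1) sum_i ((X_i - Xbar)/S_x) ((Y_i - Ybar)/S_y)

with sample standard deviations (ddof = 1).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
from sklearn.svm import SVR

from . import __version__
from .aaindex import PAD, PropertyTable, logistic_normalize, segment_pcp_features
from .dataset import HALF_WINDOW, ProteinChain, SegmentRecord, WINDOW, segment_chain
from .ibcga import IBCGAResult, cv_mae
from .pssm import PSSMProfile, SEGMENT_WIDTH, segment_pssm_features

logger = logging.getLogger(__name__)

MIN_GROUP_SIZE = 10


@dataclass(frozen=True)
class FeatureLayout:
    """Frozen description of a model's input vector."""

    selected_pcps: tuple[str, ...]
    use_pssm: bool = True
    use_length: bool = True

    @property
    def n_features(self) -> int:
        return (
            len(self.selected_pcps)
            + (SEGMENT_WIDTH if self.use_pssm else 0)
            + (1 if self.use_length else 0)
        )


@dataclass
class ResidueModel:
    """A trained epsilon-SVR for one central residue."""

    residue: str
    layout: FeatureLayout
    hyperparams: tuple[float, float, float]  # (C, gamma, epsilon)
    svr: SVR
    n_train: int
    cv_mae: float | None = None  # 10-CV MAE on the training group


@dataclass
class EvalReport:
    """MAE / CC evaluation of predicted against observed RSA."""

    mae: float
    cc: float | None
    n: int
    per_residue: dict[str, tuple[float, int]] = field(default_factory=dict)

    def __str__(self) -> str:
        cc = f"{self.cc:.4f}" if self.cc is not None else "undefined"
        lines = [f"n = {self.n}   MAE = {self.mae:.2f}%   CC = {cc}"]
        for res in sorted(self.per_residue):
            mae, n = self.per_residue[res]
            lines.append(f"  {res}: MAE = {mae:5.2f}%  (n = {n})")
        return "\n".join(lines)


def evaluate(
    pred: Sequence[float],
    obs: Sequence[float],
    residues: Sequence[str] | None = None,
) -> EvalReport:
    """Mean absolute error and Pearson CC between predictions and labels.

    CC uses sample standard deviations and the 1/(n-1) normalization; it is
    reported as ``None`` (undefined) when either series has zero variance
    or fewer than two points.
    """
    x = np.asarray(pred, dtype=float)
    y = np.asarray(obs, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    n = len(x)
    if n == 0:
        raise ValueError("nothing to evaluate")
    mae = float(np.abs(x - y).mean())
    cc: float | None = None
    if n >= 2:
        sx, sy = x.std(ddof=1), y.std(ddof=1)
        if sx > 0 and sy > 0:
            cc = float(
                np.sum((x - x.mean()) / sx * (y - y.mean()) / sy) / (n - 1)
            )
    per_residue: dict[str, tuple[float, int]] = {}
    if residues is not None:
        if len(residues) != n:
            raise ValueError("residues length mismatch")
        for res in sorted(set(residues)):
            sel = np.array([r == res for r in residues])
            per_residue[res] = (float(np.abs(x[sel] - y[sel]).mean()), int(sel.sum()))
    return EvalReport(mae=mae, cc=cc, n=n, per_residue=per_residue)


def build_feature_vector(
    segment: SegmentRecord,
    profile: PSSMProfile | None,
    chain_length: int,
    layout: FeatureLayout,
    table: PropertyTable,
) -> np.ndarray:
    """Assemble one segment's input vector according to ``layout``.

    Order: selected PCP features, then the 231 PSSM values, then the
    normalized sequence length ``logistic(L / 100)``.
    """
    parts = [segment_pcp_features(segment, table, layout.selected_pcps)]
    if layout.use_pssm:
        if profile is None:
            raise ValueError("layout includes PSSM features but no profile given")
        parts.append(segment_pssm_features(profile, segment.center_position))
    if layout.use_length:
        parts.append(np.array([logistic_normalize(chain_length / 100.0)]))
    vec = np.concatenate(parts)
    if vec.shape != (layout.n_features,):
        raise ValueError(
            f"layout mismatch: built {vec.shape[0]} features, "
            f"expected {layout.n_features}"
        )
    return vec


# grid limits of the 4-bit gene encoding (exponents of 2)
_GRID_BOUNDS = {"C": (-5, 10), "gamma": (-12, 3), "epsilon": (-10, 5)}


def _grid_refine(
    X: np.ndarray,
    y: np.ndarray,
    start: tuple[float, float, float],
    folds,
) -> tuple[tuple[float, float, float], float]:
    """Hill-climbing 3x3x3 grid search in log2 space around ``start``.

    Evaluates the +/- 1 exponent neighborhood by CV MAE and re-centres on
    the best point while it sits on the searched cube's boundary (staying
    inside the encoding's grid limits).
    """
    exps = [int(round(np.log2(v))) for v in start]
    bounds = list(_GRID_BOUNDS.values())
    cache: dict[tuple[int, int, int], float] = {}

    def score(e: tuple[int, int, int]) -> float:
        if e not in cache:
            cache[e] = cv_mae(X, y, tuple(2.0 ** v for v in e), folds)
        return cache[e]

    current = tuple(
        int(np.clip(e, lo, hi)) for e, (lo, hi) in zip(exps, bounds)
    )
    while True:
        neighborhood = [
            (current[0] + dc, current[1] + dg, current[2] + de)
            for dc in (-1, 0, 1)
            for dg in (-1, 0, 1)
            for de in (-1, 0, 1)
        ]
        neighborhood = [
            e
            for e in neighborhood
            if all(lo <= v <= hi for v, (lo, hi) in zip(e, bounds))
        ]
        best = min(neighborhood, key=score)
        if best == current:
            break
        current = best
    return tuple(2.0 ** v for v in current), cache[current]


class RSAModel:
    """Real-value RSA predictor bank, one epsilon-SVR per central residue.

    Parameters
    ----------
    groups : mapping residue letter -> labelled segments sharing that centre
    table : the physicochemical property table
    selections : mapping letter -> IBCGAResult, or letter ->
        (accession list, (C, gamma, epsilon)); defines each residue's PCP
        feature set and starting hyperparameters
    profiles : mapping chain id -> PSSMProfile (needed when use_pssm)
    chain_lengths : mapping chain id -> length (for the length feature)
    """

    def __init__(
        self,
        groups: Mapping[str, Sequence[SegmentRecord]],
        table: PropertyTable,
        selections: Mapping[str, IBCGAResult | tuple],
        profiles: Mapping[str, PSSMProfile] | None = None,
        chain_lengths: Mapping[str, int] | None = None,
        use_pssm: bool = True,
        use_length: bool = True,
    ) -> None:
        self.groups = {k: list(v) for k, v in groups.items()}
        self.table = table
        self.profiles = dict(profiles) if profiles else {}
        self.chain_lengths = dict(chain_lengths) if chain_lengths else {}
        self.use_pssm = use_pssm
        self.use_length = use_length
        self.selections: dict[str, tuple[list[str], tuple[float, float, float]]] = {}
        for letter, sel in selections.items():
            if isinstance(sel, IBCGAResult):
                self.selections[letter] = (sel.accessions, sel.params)
            else:
                accs, params = sel
                self.selections[letter] = (list(accs), tuple(params))

    @classmethod
    def from_chains(
        cls,
        chains: Sequence[ProteinChain],
        profiles: Mapping[str, PSSMProfile] | None,
        table: PropertyTable,
        selections: Mapping[str, IBCGAResult | tuple],
        **kwargs,
    ) -> "RSAModel":
        """Build the model directly from annotated chains."""
        from .dataset import group_by_center

        segments: list[SegmentRecord] = []
        lengths: dict[str, int] = {}
        for chain in chains:
            segments.extend(
                s for s in segment_chain(chain) if s.observed_rsa is not None
            )
            lengths[chain.id] = len(chain)
        return cls(
            group_by_center(segments),
            table,
            selections,
            profiles=profiles,
            chain_lengths=lengths,
            **kwargs,
        )

    def _design(
        self, letter: str, segments: Sequence[SegmentRecord], layout: FeatureLayout
    ) -> tuple[np.ndarray, np.ndarray]:
        X = np.empty((len(segments), layout.n_features))
        y = np.empty(len(segments))
        for i, seg in enumerate(segments):
            profile = self.profiles.get(seg.chain_id) if self.use_pssm else None
            if self.use_pssm and profile is None:
                raise KeyError(f"no PSSM profile for chain {seg.chain_id}")
            length = self.chain_lengths.get(seg.chain_id, 0)
            X[i] = build_feature_vector(seg, profile, length, layout, self.table)
            y[i] = seg.observed_rsa
        return X, y

    def fit(
        self,
        grid_refine: bool = False,
        cv_folds: int = 10,
        fold_seed: int = 0,
    ) -> "RSAResults":
        """Train one SVR per residue group; optionally re-tune (C, gamma, eps).

        Groups with fewer than ``MIN_GROUP_SIZE`` labelled segments are
        skipped with a warning; chains containing such residues fall back
        to the global-mean predictor at prediction time.
        """
        from sklearn.model_selection import KFold

        models: dict[str, ResidueModel] = {}
        all_labels: list[float] = []
        for letter in sorted(self.groups):
            segments = [
                s for s in self.groups[letter] if s.observed_rsa is not None
            ]
            if letter not in self.selections:
                logger.warning("no feature selection for %s; skipped", letter)
                continue
            if len(segments) < MIN_GROUP_SIZE:
                logger.warning(
                    "group %s has %d labelled segments (< %d); skipped",
                    letter, len(segments), MIN_GROUP_SIZE,
                )
                continue
            accessions, params = self.selections[letter]
            layout = FeatureLayout(
                tuple(accessions), self.use_pssm, self.use_length
            )
            X, y = self._design(letter, segments, layout)
            all_labels.extend(y)
            folds = None
            cv = None
            if len(segments) >= cv_folds:
                kf = KFold(n_splits=cv_folds, shuffle=True, random_state=fold_seed)
                folds = list(kf.split(X))
            if grid_refine and folds is not None:
                params, cv = _grid_refine(X, y, params, folds)
            elif folds is not None:
                cv = cv_mae(X, y, params, folds)
            C, gamma, eps = params
            svr = SVR(kernel="rbf", C=C, gamma=gamma, epsilon=eps)
            svr.fit(X, y)
            models[letter] = ResidueModel(
                residue=letter,
                layout=layout,
                hyperparams=(C, gamma, eps),
                svr=svr,
                n_train=len(segments),
                cv_mae=cv,
            )
        if not models:
            raise ValueError("no residue group could be trained")
        fallback = float(np.mean(all_labels))
        return RSAResults(
            models=models, table=self.table, fallback_mean=fallback
        )


class RSAResults:
    """Trained predictor bank: prediction, evaluation, summary, persistence."""

    def __init__(
        self,
        models: dict[str, ResidueModel],
        table: PropertyTable,
        fallback_mean: float,
    ) -> None:
        self.models = models
        self.table = table
        self.fallback_mean = fallback_mean

    def predict_chain(
        self, chain: ProteinChain, profile: PSSMProfile | None = None
    ) -> np.ndarray:
        """Per-residue RSA (percent, clamped to [0, 100]) for a whole chain.

        Residue i is predicted by the model of ``chain.sequence[i]``;
        letters without a model get the global training-mean RSA.
        """
        out = np.empty(len(chain))
        padded = PAD * HALF_WINDOW + chain.sequence + PAD * HALF_WINDOW
        for i, letter in enumerate(chain.sequence):
            model = self.models.get(letter)
            if model is None:
                logger.debug("no model for %r; using global mean", letter)
                out[i] = self.fallback_mean
                continue
            seg = SegmentRecord(chain.id, i, padded[i : i + WINDOW])
            vec = build_feature_vector(
                seg, profile, len(chain), model.layout, self.table
            )
            out[i] = model.svr.predict(vec[None, :])[0]
        return np.clip(out, 0.0, 100.0)

    def summary(self) -> str:
        """Human-readable per-residue table of the fitted predictor bank."""
        lines = [
            "RSA predictor bank (epsilon-SVR, RBF kernel)",
            f"property table: {self.table.source_version} "
            f"({len(self.table)} indices)",
            f"{'res':>3} {'#PCP':>5} {'n_train':>8} {'C':>9} {'gamma':>9} "
            f"{'eps':>8} {'CV MAE%':>8}",
        ]
        for letter in sorted(self.models):
            m = self.models[letter]
            C, g, e = m.hyperparams
            cv = f"{m.cv_mae:8.2f}" if m.cv_mae is not None else "     n/a"
            lines.append(
                f"{letter:>3} {len(m.layout.selected_pcps):>5} {m.n_train:>8} "
                f"{C:>9.4g} {g:>9.4g} {e:>8.4g} {cv}"
            )
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Versioned archive: manifest.json + joblib bundle of the SVR states."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        manifest = {
            "format_version": 1,
            "package_version": __version__,
            "aaindex_version": self.table.source_version,
            "aaindex_hash": self.table.content_hash(),
            "fallback_mean": self.fallback_mean,
            "models": {
                letter: {
                    "selected_pcps": list(m.layout.selected_pcps),
                    "use_pssm": m.layout.use_pssm,
                    "use_length": m.layout.use_length,
                    "hyperparams": list(m.hyperparams),
                    "n_train": m.n_train,
                    "cv_mae": m.cv_mae,
                }
                for letter, m in self.models.items()
            },
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
        joblib.dump(
            {letter: m.svr for letter, m in self.models.items()},
            path / "models.joblib",
        )
        joblib.dump(self.table, path / "table.joblib")

    @classmethod
    def load(cls, path: str | Path, table: PropertyTable | None = None) -> "RSAResults":
        """Load an archive; verifies the property-table hash when one is given."""
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        stored_table: PropertyTable = joblib.load(path / "table.joblib")
        if table is not None:
            if table.content_hash() != manifest["aaindex_hash"]:
                raise ValueError(
                    "property table hash mismatch: model was trained on "
                    f"{manifest['aaindex_version']}"
                )
            stored_table = table
        svrs = joblib.load(path / "models.joblib")
        models = {}
        for letter, meta in manifest["models"].items():
            models[letter] = ResidueModel(
                residue=letter,
                layout=FeatureLayout(
                    tuple(meta["selected_pcps"]),
                    meta["use_pssm"],
                    meta["use_length"],
                ),
                hyperparams=tuple(meta["hyperparams"]),
                svr=svrs[letter],
                n_train=meta["n_train"],
                cv_mae=meta["cv_mae"],
            )
        return cls(models, stored_table, manifest["fallback_mean"])
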