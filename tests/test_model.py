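"""Feature assembly, the SVR predictor bank, and the MAE/CC metrics."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from rsapred.dataset import ProteinChain, SegmentRecord, segment_chain
from rsapred.model import (
    FeatureLayout,
    RSAModel,
    RSAResults,
    build_feature_vector,
    evaluate,
)
from rsapred.pssm import PSSMProfile
from rsapred.synthetic import gen_property_table


@pytest.fixture(scope="module")
def ptable():
    return gen_property_table(30, seed=11)


def _profile(seq, seed=0):
    rng = np.random.default_rng(seed)
    return PSSMProfile("c", seq, np.round(rng.normal(0, 2, (len(seq), 20)), 2))


class TestFeatureVector:
    def test_layout_lengths(self, ptable):
        seg = SegmentRecord("c", 5, "ACDEFGHIKLM")
        prof = _profile("ACDEFGHIKLM")
        v0 = build_feature_vector(
            seg, prof, 11, FeatureLayout((), True, True), ptable
        )
        assert v0.shape == (232,)
        sel = tuple(ptable.accessions)
        v30 = build_feature_vector(
            seg, prof, 11, FeatureLayout(sel, True, True), ptable
        )
        assert v30.shape == (262,)

    def test_equals_manual_concatenation(self, ptable):
        from rsapred.aaindex import logistic_normalize, segment_pcp_features
        from rsapred.pssm import segment_pssm_features

        seg = SegmentRecord("c", 5, "ACDEFGHIKLM")
        prof = _profile("ACDEFGHIKLM")
        sel = tuple(ptable.accessions[:4])
        got = build_feature_vector(seg, prof, 47, FeatureLayout(sel), ptable)
        manual = np.concatenate(
            [
                segment_pcp_features(seg, ptable, sel),
                segment_pssm_features(prof, 5),
                [logistic_normalize(0.47)],
            ]
        )
        assert got == pytest.approx(manual)

    def test_pssm_layout_without_profile_rejected(self, ptable):
        seg = SegmentRecord("c", 5, "ACDEFGHIKLM")
        with pytest.raises(ValueError, match="profile"):
            build_feature_vector(seg, None, 11, FeatureLayout((), True, True), ptable)


class TestEvaluate:
    def test_perfect_prediction(self):
        rep = evaluate([1.0, 5.0, 9.0], [1.0, 5.0, 9.0])
        assert rep.mae == 0.0 and rep.cc == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        obs = np.array([10.0, 40.0, 90.0])
        rep = evaluate(100.0 - obs, obs)
        assert rep.cc == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        rep = evaluate([10.0, 20.0, 30.0], [20.0, 20.0, 50.0])
        assert rep.mae == pytest.approx(10.0)
        # Sx=10, Sy=sqrt(300), sum of z-products = 30/sqrt(300) -> /2
        assert rep.cc == pytest.approx(np.sqrt(3) / 2, abs=1e-12)

    def test_half_half_mae(self):
        rep = evaluate([50.0, 50.0], [0.0, 100.0])
        assert rep.mae == 50.0

    def test_zero_variance_cc_missing(self):
        rep = evaluate([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])
        assert rep.cc is None and rep.mae == pytest.approx(3.0)

    def test_matches_scipy_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 200))
            x, y = rng.uniform(0, 100, n), rng.uniform(0, 100, n)
            rep = evaluate(x, y)
            assert rep.cc == pytest.approx(scipy.stats.pearsonr(x, y)[0], abs=1e-9)
            assert rep.mae == pytest.approx(np.mean(np.abs(x - y)), abs=1e-9)

    @given(st.integers(0, 2 ** 32 - 1), st.floats(0.1, 5), st.floats(-50, 50))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_cc_affine_invariant_mae_translation_equivariant(self, seed, a, b):
        rng = np.random.default_rng(seed)
        x, y = rng.uniform(0, 100, 20), rng.uniform(0, 100, 20)
        base = evaluate(x, y)
        scaled = evaluate(a * x + b, y)
        assert scaled.cc == pytest.approx(base.cc, abs=1e-9)
        shifted = evaluate(x + b, y + b)
        assert shifted.mae == pytest.approx(base.mae, abs=1e-9)

    def test_per_residue_breakdown_sums(self):
        rep = evaluate([1, 2, 3, 4.0], [2, 2, 2, 2.0], residues=list("AABC"))
        assert sum(n for _, n in rep.per_residue.values()) == rep.n
        assert rep.per_residue["A"] == (pytest.approx(0.5), 2)


def _linear_chains(ptable, n_chains=8, seed=0):
    """Chains whose RSA is a noiseless increasing function of one property."""
    from rsapred.aaindex import _logistic_array, window_mean_matrix
    from rsapred.dataset import MAX_ASA

    rng = np.random.default_rng(seed)
    acc = ptable.accessions[0]
    chains = []
    for c in range(n_chains):
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 60))
        padded = "-" * 5 + seq + "-" * 5
        windows = [padded[i : i + 11] for i in range(60)]
        f = _logistic_array(window_mean_matrix(windows, ptable.subset([acc])))[:, 0]
        rsa = np.clip(100 * (4 * (f - 0.5) + 0.5), 0, 100)
        asa = np.array([rsa[i] / 100 * MAX_ASA[seq[i]] for i in range(60)])
        chains.append(ProteinChain(f"lin{c}", seq, asa, " " * 60))
    return chains, acc


class TestTrainPredict:
    def test_single_group_single_model(self, ptable):
        chains, acc = _linear_chains(ptable)
        model = RSAModel.from_chains(
            chains, None, ptable,
            {"A": ([acc], (256.0, 1.0, 0.25))},
            use_pssm=False,
        )
        results = model.fit()
        assert set(results.models) == {"A"}

    def test_noiseless_linear_target_training_mae_below_1pct(self, ptable):
        chains, acc = _linear_chains(ptable, n_chains=20)
        # one steep 1-D target: a narrow RBF width is needed to resolve it
        selections = {
            letter: ([acc], (1024.0, 128.0, 0.0625))
            for letter in "ACDEFGHIKLMNPQRSTVWY"
        }
        model = RSAModel.from_chains(
            chains, None, ptable, selections, use_pssm=False
        )
        results = model.fit()
        preds, obs = [], []
        for chain in chains:
            preds.extend(results.predict_chain(chain))
            obs.extend(chain.rsa())
        rep = evaluate(preds, obs)
        assert rep.mae < 1.0

    def test_grid_refine_local_optimality(self, ptable):
        from sklearn.model_selection import KFold

        from rsapred.ibcga import cv_mae
        from rsapred.model import _grid_refine

        chains, acc = _linear_chains(ptable, n_chains=3)
        segs = [s for c in chains for s in segment_chain(c)]
        layout = FeatureLayout((acc,), False, False)
        model = RSAModel(
            {"A": [s for s in segs if s.center_residue == "A"]},
            ptable, {"A": ([acc], (1.0, 1.0, 1.0))}, use_pssm=False,
            use_length=False,
        )
        group = [s for s in segs if s.center_residue == "A"]
        X, y = model._design("A", group, layout)
        kf = KFold(n_splits=5, shuffle=True, random_state=0)
        folds = list(kf.split(X))
        (C, g, e), best_mae = _grid_refine(X, y, (1.0, 1.0, 1.0), folds)
        # brute-force oracle: the chosen point beats its whole +/-1 cube
        e0 = tuple(int(np.log2(v)) for v in (C, g, e))
        for dc in (-1, 0, 1):
            for dg in (-1, 0, 1):
                for de in (-1, 0, 1):
                    cand = (e0[0] + dc, e0[1] + dg, e0[2] + de)
                    if not (-5 <= cand[0] <= 10 and -12 <= cand[1] <= 3
                            and -10 <= cand[2] <= 5):
                        continue
                    mae = cv_mae(X, y, tuple(2.0 ** v for v in cand), folds)
                    assert best_mae <= mae + 1e-9

    def test_predictions_clamped_and_length_preserved(self, ptable):
        chains, acc = _linear_chains(ptable, n_chains=6)
        model = RSAModel.from_chains(
            chains, None, ptable, {"A": ([acc], (256.0, 1.0, 0.25))},
            use_pssm=False,
        )
        results = model.fit()
        single = ProteinChain("one", "A")
        pred = results.predict_chain(single)
        assert pred.shape == (1,)
        assert 0.0 <= pred[0] <= 100.0

    def test_missing_letter_falls_back_to_global_mean(self, ptable):
        chains, acc = _linear_chains(ptable, n_chains=6)
        model = RSAModel.from_chains(
            chains, None, ptable, {"A": ([acc], (256.0, 1.0, 0.25))},
            use_pssm=False,
        )
        results = model.fit()
        pred = results.predict_chain(ProteinChain("w", "WWW"))
        assert np.allclose(pred, results.fallback_mean)

    def test_save_load_roundtrip_and_hash_guard(self, ptable, tmp_path):
        chains, acc = _linear_chains(ptable, n_chains=6)
        model = RSAModel.from_chains(
            chains, None, ptable, {"A": ([acc], (256.0, 1.0, 0.25))},
            use_pssm=False,
        )
        results = model.fit()
        results.save(tmp_path / "arch")
        loaded = RSAResults.load(tmp_path / "arch", table=ptable)
        chain = chains[0]
        assert loaded.predict_chain(chain) == pytest.approx(
            results.predict_chain(chain)
        )
        other = gen_property_table(30, seed=99)
        with pytest.raises(ValueError, match="hash mismatch"):
            RSAResults.load(tmp_path / "arch", table=other)

    def test_summary_lists_models(self, ptable):
        chains, acc = _linear_chains(ptable, n_chains=6)
        model = RSAModel.from_chains(
            chains, None, ptable, {"A": ([acc], (256.0, 1.0, 0.25))},
            use_pssm=False,
        )
        text = model.fit().summary()
        assert "epsilon-SVR" in text and "\n  A " in text
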