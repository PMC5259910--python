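"""Residue classification, helix exposure degree, and spine detection.

The spine-detector checks compare against an independent brute-force
oracle that enumerates every subset of exposed hydrophobic positions and
filters it by the documented chain rules, rather than walking the search
graph the implementation uses.
"""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from rsapred.dataset import MAX_ASA, ProteinChain
from rsapred.spine import (
    EXPOSURE_THRESHOLD,
    HelixAnnotation,
    KYTE_DOOLITTLE,
    classify_residue,
    extract_helices,
    find_spines,
    neighbor_ratios,
    scan_dataset,
)


def make_helix(statuses, start=0, chain_id="h"):
    """statuses: string of E (exposed hydrophobic), P (exposed philic), B (buried)."""
    residues = {"E": ("L", 60.0), "P": ("S", 60.0), "B": ("S", 10.0)}
    sts = []
    for i, code in enumerate(statuses):
        letter, rsa = residues[code]
        sts.append(classify_residue(letter, rsa, position=start + i))
    return HelixAnnotation(chain_id, start, start + len(statuses), sts)


# ---------------------------------------------------------------------------
# independent brute-force oracle


def oracle_bridge(p, q, members, helix):
    gap = q - p
    cands = {6: [p + 3], 8: [p + 4], 7: [p + 3, p + 4]}.get(gap, [])
    cands = [m for m in cands if m not in members]
    if len(cands) == 2:
        exposed = [m for m in cands if helix.status_at(m).exposure_class == "exposed"]
        if exposed:
            cands = exposed
    return cands[0] if cands else None


def oracle_spines(helix, min_members=3, max_interruptions=1):
    members = sorted(
        s.position for s in helix.statuses if s.is_exposed_hydrophobic
    )
    mset = set(members)
    valid = {}
    for k in range(min_members, len(members) + 1):
        for combo in combinations(members, k):
            bridges = []
            ok = True
            for p, q in zip(combo, combo[1:]):
                if q - p in (3, 4):
                    continue
                b = oracle_bridge(p, q, mset, helix) if q - p in (6, 7, 8) else None
                if b is None:
                    ok = False
                    break
                bridges.append(b)
            if ok and len(bridges) <= max_interruptions:
                valid[combo] = bridges
    result = []
    for combo, bridges in valid.items():
        if any(set(combo) < set(o) for o in valid if o != combo):
            continue
        result.append((tuple(sorted(set(combo) | set(bridges))), tuple(sorted(bridges))))
    return sorted(result)


def random_helix(rng, max_len=30):
    n = int(rng.integers(6, max_len + 1))
    codes = rng.choice(list("EPB"), size=n, p=[0.3, 0.4, 0.3])
    return make_helix("".join(codes))


# ---------------------------------------------------------------------------


class TestClassify:
    def test_exposed_hydrophobic(self):
        s = classify_residue("I", 30.0)
        assert (s.hydropathy_class, s.exposure_class) == ("hydrophobic", "exposed")

    def test_buried_hydrophilic(self):
        s = classify_residue("D", 10.0)
        assert (s.hydropathy_class, s.exposure_class) == ("hydrophilic", "buried")

    def test_boundary_rsa_25_is_exposed(self):
        assert classify_residue("A", EXPOSURE_THRESHOLD).exposure_class == "exposed"
        assert classify_residue("A", 24.999).exposure_class == "buried"

    def test_exactly_seven_hydrophobic_residues(self):
        phob = {a for a, v in KYTE_DOOLITTLE.items() if v > 0}
        assert phob == set("ACILMFV")
        for letter in KYTE_DOOLITTLE:
            s = classify_residue(letter, 50.0)
            assert (s.hydropathy_class == "hydrophobic") == (letter in phob)

    def test_nonstandard_residue_rejected(self):
        with pytest.raises(ValueError):
            classify_residue("X", 50.0)


class TestHelices:
    def _chain(self, seq, ss, rsa):
        asa = np.array([r / 100 * MAX_ASA[a] for a, r in zip(seq, rsa)])
        return ProteinChain("c", seq, asa, ss)

    def test_aed_half(self):
        chain = self._chain("L" * 10, "H" * 10, [60] * 5 + [10] * 5)
        (helix,) = extract_helices(chain)
        assert helix.aed == 0.5

    def test_aed_all_exposed(self):
        chain = self._chain("L" * 6, "H" * 6, [80] * 6)
        (helix,) = extract_helices(chain)
        assert helix.aed == 1.0

    def test_310_and_pi_helices_ignored(self):
        chain = self._chain("L" * 9, "GGGIIISSS", [50] * 9)
        assert extract_helices(chain) == []

    def test_maximal_runs_split(self):
        chain = self._chain("L" * 9, "HHH  HHHH", [50] * 9)
        helices = extract_helices(chain)
        assert [(h.start, h.end) for h in helices] == [(0, 3), (5, 9)]

    def test_aed_complements_buried_fraction(self, rng):
        for _ in range(20):
            helix = random_helix(rng)
            buried = sum(s.exposure_class == "buried" for s in helix.statuses)
            assert helix.aed == pytest.approx(1 - buried / len(helix))


class TestNeighborRatios:
    def test_all_philic_neighbors_ratio_zero(self):
        helix = make_helix("EPPEPPEPP")
        df = neighbor_ratios([helix])
        populated = df.dropna(subset=["ratio"])
        assert len(populated) > 0
        assert set(populated["ratio"]) <= {0.0} | set(
            populated[populated["n_phobic"] > 0]["ratio"]
        )

    def test_tallies_match_hand_enumeration(self):
        # helix EEPB: exposed-phobic at 0,1; exposed-philic at 2; buried at 3
        helix = make_helix("EEPB")
        df = neighbor_ratios([helix])
        b = df[df["aed_bin"] == "[70,80)"]  # AED = 3/4
        tall = {int(r.offset): (r.n_phobic, r.n_philic) for r in b.itertuples()}
        # i=0: d=1 -> E, d=2 -> P, d=3 -> buried (skip); i=1: d=1 -> P
        assert tall[1] == (1, 1)
        assert tall[2] == (0, 1)
        assert tall[3] == (0, 0)

    def test_equal_tallies_ratio_one(self):
        helix = make_helix("EEP")  # i=0: d1 E, d2 P -> 1/1 at AED bin
        df = neighbor_ratios([helix])
        row = df[(df["n_phobic"] == 1) & (df["n_philic"] == 1)]
        assert (row["ratio"] == 1.0).all() and len(row) >= 1

    def test_order_invariance_and_integer_tallies(self, rng):
        helices = [random_helix(rng) for _ in range(6)]
        a = neighbor_ratios(helices)
        b = neighbor_ratios(helices[::-1])
        pd.testing.assert_frame_equal(a, b)
        assert (a["n_phobic"] >= 0).all() and a["n_phobic"].dtype.kind == "i"

    def test_three_helix_fixture_matches_oracle_tally(self, rng):
        helices = [random_helix(rng, max_len=15) for _ in range(3)]
        df = neighbor_ratios(helices)
        # brute-force tally
        tall = {}
        for h in helices:
            b = min(int(h.aed * 100 // 10), 9)
            for s in h.statuses:
                if not s.is_exposed_hydrophobic:
                    continue
                for d in range(1, 7):
                    j = s.position + d
                    if j >= h.end:
                        continue
                    t = h.status_at(j)
                    if t.exposure_class != "exposed":
                        continue
                    key = (b, d, t.hydropathy_class)
                    tall[key] = tall.get(key, 0) + 1
        for row in df.itertuples():
            b = int(row.aed_bin.strip("[)]").split(",")[0]) // 10
            assert row.n_phobic == tall.get((b, row.offset, "hydrophobic"), 0)
            assert row.n_philic == tall.get((b, row.offset, "hydrophilic"), 0)


class TestFindSpines:
    def test_perfect_spine_exact_members(self):
        helix = make_helix("EPPEPPPEPPE")  # E at 0,3,7,10
        (call,) = find_spines(helix)
        assert call.members == [0, 3, 7, 10]
        assert call.spacings == [3, 4, 3]
        assert call.perfect

    def test_single_interruption_imperfect(self):
        helix = make_helix("EPPEPPBPPPE")  # E at 0,3,10; gap 7 bridged
        (call,) = find_spines(helix)
        assert not call.perfect
        assert len(call.interruptions) == 1
        assert call.interruptions[0] in (6, 7)

    def test_no_exposed_hydrophobic_no_spines(self):
        helix = make_helix("PPPBBBPPPBB")
        assert find_spines(helix) == []

    def test_members_inside_helix_and_spacing_invariant(self, rng):
        for _ in range(50):
            helix = random_helix(rng)
            for call in find_spines(helix):
                assert all(helix.start <= p < helix.end for p in call.members)
                assert set(call.spacings) <= {3, 4}
                assert call.perfect == (not call.interruptions)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(60):
            helix = random_helix(rng)
            got = sorted(
                (tuple(c.members), tuple(c.interruptions)) for c in find_spines(helix)
            )
            assert got == oracle_spines(helix)


class TestScanDataset:
    def _neutral_chain(self, seed_id, plant=None):
        """One 14-residue helix of buried hydrophilic residues, optionally
        with a spine planted into it."""
        from rsapred.synthetic import plant_spine

        n = 30
        seq = "S" * n
        ss = " " * 8 + "H" * 14 + " " * 8
        asa = np.full(n, round(0.10 * MAX_ASA["S"]))
        chain = ProteinChain(seed_id, seq, asa, ss)
        if plant is not None:
            chain, _ = plant_spine(chain, 0, [3, 4, 3], plant)
        return chain

    def test_aed_filter_removes_half_exposed_helix(self):
        seq = "L" * 10
        rsa = [60] * 5 + [10] * 5
        asa = np.array([r / 100 * MAX_ASA["L"] for r in rsa])
        chain = ProteinChain("c", seq, asa, "H" * 10)
        report = scan_dataset([chain], aed_min=90.0)
        assert len(report) == 0
        assert report.attrs["n_helices"] == 1

    def test_planted_spines_recovered_with_counts(self):
        chains = [
            self._neutral_chain("p1", plant=()),
            self._neutral_chain("p2", plant=(1,)),
            self._neutral_chain("n1"),
            self._neutral_chain("n2"),
        ]
        # planted helices have buried non-face residues: scan at a low AED cut
        report = scan_dataset(chains, aed_min=10.0)
        assert report.attrs["n_helices"] == 4
        assert report.attrs["n_perfect"] == 1
        assert report.attrs["n_imperfect"] == 1

    def test_empty_input_empty_report(self):
        report = scan_dataset([])
        assert len(report) == 0
        assert report.attrs["n_helices"] == 0
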