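import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from timegrn.expression import (
    DOWN,
    NONE,
    UP,
    DeseqRow,
    NanoStringAssay,
    classify_fpkm,
    classify_time_zero,
    integrate_platforms,
    nanostring_de,
    nanostring_normalize,
    read_nanostring,
    select_candidates,
    write_nanostring,
)


class TestClassifyFpkm:
    def test_clear_up(self):
        assert classify_fpkm(20, 10) == UP  # FC = 2

    def test_abundance_gate_blocks_up(self):
        assert classify_fpkm(9, 3) == NONE  # FC = 3 but induced <= 10

    def test_clear_down(self):
        assert classify_fpkm(5, 20) == DOWN  # FC = 0.25, uninduced > 10

    def test_zero_uninduced_is_up_never_down(self):
        assert classify_fpkm(15, 0) == UP
        assert classify_fpkm(5, 0) == NONE

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            classify_fpkm(-1, 5)

    @given(
        st.floats(0, 1000, allow_nan=False),
        st.floats(0, 1000, allow_nan=False),
        st.floats(1.01, 50, allow_nan=False),
    )
    @settings(deadline=None, max_examples=200)
    def test_scaling_never_flips_up_down(self, ind, unind, c):
        before = classify_fpkm(ind, unind)
        after = classify_fpkm(ind * c, unind * c)
        # fold change is unchanged; only the abundance gates can open
        assert {before, after} != {UP, DOWN}


class TestClassifyTimeZero:
    def test_all_clauses_satisfied(self):
        assert classify_time_zero(30, 10, 20) == UP

    def test_uninduced_5h_not_above_induced(self):
        assert classify_time_zero(30, 25, 20) == NONE

    def test_abundance_gate_fails(self):
        assert classify_time_zero(8, 2, 20) == NONE

    def test_zero_induced_5h_ratio_is_infinite(self):
        assert classify_time_zero(30, 0, 20) == UP


class TestSelectCandidates:
    def test_up_candidate(self):
        row = DeseqRow("g", 1.5, 0.01, 100, 10)
        assert select_candidates(row) == "up-candidate"

    def test_down_candidate(self):
        row = DeseqRow("g", -2.0, 0.01, 5, 300)
        assert select_candidates(row) == "down-candidate"

    def test_insignificant_rejected(self):
        row = DeseqRow("g", 1.5, 0.2, 100, 10)
        assert select_candidates(row) == "rejected"

    def test_base_mean_gates(self):
        assert select_candidates(DeseqRow("g", 1.5, 0.01, 44, 10)) == "rejected"
        assert select_candidates(DeseqRow("g", -1.5, 0.01, 100, 199)) == "rejected"

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            DeseqRow("g", 1.0, 1.5, 10, 10)


def make_assay(assay_id, endo, pos=None, neg=None, hk=None, **kw):
    pos = pos if pos is not None else {f"POS_{i}": v for i, v in enumerate([2400, 1200, 600, 300, 150, 75])}
    neg = neg if neg is not None else {f"NEG_{i}": 4.0 for i in range(8)}
    hk = hk if hk is not None else {"ACTB": 800.0, "GAPDH": 400.0}
    counts = {**endo, **pos, **neg, **hk}
    classes = {}
    classes.update({p: "endogenous" for p in endo})
    classes.update({p: "positive" for p in pos})
    classes.update({p: "negative" for p in neg})
    classes.update({p: "housekeeping" for p in hk})
    return NanoStringAssay(assay_id, counts, classes, **kw)


class TestNanostringNormalize:
    def test_identical_assays_give_unit_factors(self):
        assays = [make_assay(f"a{i}", {"G1": 100.0, "G2": 50.0}) for i in range(3)]
        res = nanostring_normalize(assays)
        assert all(math.isclose(v, 1.0) for v in res.plnf.values())
        assert all(math.isclose(v, 1.0) for v in res.lsnf.values())
        # output = input - background (clipped, 0 -> 1); negatives are
        # constant so background = mean + 2*0 = 4
        assert np.allclose(res.counts.loc["G1"], 96.0)
        assert np.allclose(res.counts.loc["G2"], 46.0)

    def test_background_clipping_and_zero_replacement(self):
        assays = [make_assay(f"a{i}", {"G1": 2.0, "G2": 4.0}) for i in range(3)]
        res = nanostring_normalize(assays)
        # G1: 2 - 4 < 0 -> clip to 0 -> replaced with 1; G2: 4 - 4 = 0 -> 1
        assert np.allclose(res.counts.loc["G1"], 1.0)
        assert np.allclose(res.counts.loc["G2"], 1.0)

    def test_doubled_assay_matches_unscaled_lanes(self):
        base = {"G1": 100.0, "G2": 50.0}
        assays = [make_assay(f"a{i}", base) for i in range(3)]
        scaled = make_assay("a3", base)
        scaled.counts = {p: 2 * v for p, v in scaled.counts.items()}
        res = nanostring_normalize(assays + [scaled])
        assert math.isclose(res.plnf["a3"], res.plnf["a0"] / 2, rel_tol=1e-12)
        assert np.allclose(res.counts["a3"], res.counts["a0"], rtol=1e-12)

    def test_hand_computed_plnf_factors(self):
        # positive geomeans 100, 200, 400 -> arithmetic mean 700/3;
        # PLNF = mean / geomean per lane (hand-computed oracle)
        assays = [
            make_assay("a", {"G1": 10.0}, pos={f"P{i}": 100.0 for i in range(6)}),
            make_assay("b", {"G1": 10.0}, pos={f"P{i}": 200.0 for i in range(6)}),
            make_assay("c", {"G1": 10.0}, pos={f"P{i}": 400.0 for i in range(6)}),
        ]
        res = nanostring_normalize(assays)
        mean = (100 + 200 + 400) / 3
        assert math.isclose(res.plnf["a"], mean / 100)
        assert math.isclose(res.plnf["b"], mean / 200)
        assert math.isclose(res.plnf["c"], mean / 400)

    def test_qc_failure_excluded(self):
        good = [make_assay(f"a{i}", {"G1": 100.0}) for i in range(2)]
        bad = make_assay("bad_fov", {"G1": 100.0}, fields_of_view=599)
        worse = make_assay("bad_density", {"G1": 100.0}, binding_density=3.0)
        res = nanostring_normalize(good + [bad, worse])
        assert res.excluded == ["bad_fov", "bad_density"]
        assert set(res.counts.columns) == {"a0", "a1"}

    def test_zero_positive_count_errors(self):
        a = make_assay("a", {"G1": 1.0}, pos={f"P{i}": 0.0 for i in range(6)})
        b = make_assay("b", {"G1": 1.0})
        with pytest.raises(ValueError, match="geometric mean"):
            nanostring_normalize([a, b])

    def test_per_lane_scale_factors_cancel_within_run(self):
        # lanes with identical content but arbitrary per-lane scale
        # factors normalize to identical endogenous columns
        rng = np.random.default_rng(5)
        base = {"G1": 100.0, "G2": 400.0, "G3": 20.0}
        assays = []
        for i in range(6):
            a = make_assay(f"a{i}", base)
            f = float(rng.uniform(0.5, 2.0))
            a.counts = {p: v * f for p, v in a.counts.items()}
            assays.append(a)
        res = nanostring_normalize(assays)
        for col in res.counts.columns[1:]:
            assert np.allclose(res.counts[col], res.counts.iloc[:, 0], rtol=1e-9)


class TestNanostringDe:
    def test_identical_triplicates_none(self):
        fc, p, d = nanostring_de([100, 100, 100], [100, 100, 100])
        assert fc == 1.0
        assert d == NONE

    def test_zero_variance_unequal_means(self):
        fc, p, d = nanostring_de([100, 100, 100], [50, 50, 50])
        assert fc == 2.0
        assert p == 0.0
        assert d == UP

    def test_hand_computed_t_test(self):
        # pooled-variance oracle: means 120 vs 100, s1^2=100, s2^2=25,
        # sp^2 = 62.5, t = 20/sqrt(62.5*2/3) = 3.0984, df=4, p = 0.036278
        fc, p, d = nanostring_de([120, 130, 110], [100, 95, 105])
        assert math.isclose(fc, 1.2)
        assert math.isclose(p, 0.03627782452189912, rel_tol=1e-9)
        assert d == UP

    def test_zero_uninduced_mean_is_infinite_fc(self):
        fc, p, d = nanostring_de([10, 12, 11], [0, 0, 0])
        assert fc == math.inf
        assert d == UP

    def test_fc_gate_blocks_significant_but_small_changes(self):
        fc, p, d = nanostring_de([110, 110, 110.1], [100, 100, 100.1])
        assert p < 0.05 and d == NONE

    def test_too_few_replicates(self):
        with pytest.raises(ValueError):
            nanostring_de([1], [2, 3])


def calls_frame(d, times):
    return pd.DataFrame({t: {g: v[i] for g, v in d.items()} for i, t in enumerate(times)})


class TestIntegratePlatforms:
    RNA_TIMES = (0, 5, 9, 12)
    NANO_TIMES = (1, 3, 5, 7, 9, 12)

    def test_agreement_retained(self):
        rna = calls_frame({"g": [NONE, UP, UP, UP]}, self.RNA_TIMES)
        nano = calls_frame({"g": [NONE, NONE, UP, NONE, UP, UP]}, self.NANO_TIMES)
        res = integrate_platforms(rna, nano)
        assert "g" in res.profile.index
        # RNA-seq wins at 0/5/9/12, nCounter fills 1/3/7
        assert list(res.profile.loc["g"]) == [NONE, NONE, NONE, UP, NONE, UP, UP]

    def test_contradiction_drops_gene(self):
        rna = calls_frame({"g": [NONE, NONE, UP, NONE]}, self.RNA_TIMES)
        nano = calls_frame({"g": [NONE, NONE, NONE, NONE, DOWN, NONE]}, self.NANO_TIMES)
        res = integrate_platforms(rna, nano)
        assert "g" not in res.profile.index
        assert "9" in res.dropped["g"]

    def test_none_is_not_a_contradiction(self):
        rna = calls_frame({"g": [NONE, NONE, UP, NONE]}, self.RNA_TIMES)
        nano = calls_frame({"g": [NONE] * 6}, self.NANO_TIMES)
        res = integrate_platforms(rna, nano)
        assert "g" in res.profile.index
        assert res.profile.loc["g", 9] == UP

    def test_missing_platform_dropped_with_reason(self):
        rna = calls_frame({"g": [NONE, UP, UP, UP]}, self.RNA_TIMES)
        nano = calls_frame({"h": [NONE] * 6}, self.NANO_TIMES)
        res = integrate_platforms(rna, nano)
        assert res.profile.empty
        assert "nCounter" in res.dropped["g"]
        assert "RNA-seq" in res.dropped["h"]

    def test_never_invents_directions(self):
        rng = np.random.default_rng(3)
        dirs = np.array([UP, DOWN, NONE])
        for _ in range(20):
            rna = calls_frame({"g": list(rng.choice(dirs, 4))}, self.RNA_TIMES)
            nano = calls_frame({"g": list(rng.choice(dirs, 6))}, self.NANO_TIMES)
            res = integrate_platforms(rna, nano)
            if "g" not in res.profile.index:
                continue
            for t in (0, 1, 3, 5, 7, 9, 12):
                v = res.profile.loc["g", t]
                if v != NONE:
                    sources = set()
                    if t in self.RNA_TIMES:
                        sources.add(rna.loc["g", t])
                    if t in self.NANO_TIMES:
                        sources.add(nano.loc["g", t])
                    assert v in sources


def test_nanostring_csv_round_trip(tmp_path):
    a = make_assay("lane1", {"G1": 10.0})
    a.meta = {"time": 5, "condition": "induced", "replicate": 1}
    path = tmp_path / "nano.csv"
    write_nanostring([a], path)
    (back,) = read_nanostring(path)
    assert back.counts == a.counts
    assert back.probe_classes == a.probe_classes
    assert back.meta == a.meta
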