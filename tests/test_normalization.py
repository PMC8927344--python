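import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import genorm_m_oracle, make_matrix
from zonalde.normalize import (
    NormalizationFactors,
    apply_normalization,
    background_thresholds,
    genorm_select,
    genorm_stability,
    housekeeping_factor,
    positive_factor,
    presence_filter,
    subtract_background,
)
from zonalde.rcc import CountMatrix


def _neg_matrix(per_sample_negatives: dict) -> CountMatrix:
    """Matrix whose only rows are the given negative-control counts."""
    df = pd.DataFrame(per_sample_negatives, dtype=float)
    df.index = [f"NEG_{i}" for i in range(len(df))]
    classes = pd.Series("Negative", index=df.index)
    return CountMatrix(df, classes)


class TestBackground:
    def test_zero_sd(self):
        m = _neg_matrix({"S1": [10] * 8})
        assert background_thresholds(m)["S1"] == pytest.approx(20.0)

    def test_direct_formula(self):
        # mean 5, sample SD 2 -> 2*(5 + 2*2) = 18
        vals = [3.0, 7.0, 4.0, 6.0, 5.0]  # mean 5
        sd = np.std(vals, ddof=1)
        m = _neg_matrix({"S1": vals})
        assert background_thresholds(m)["S1"] == pytest.approx(2 * (5 + 2 * sd))
        exact = _neg_matrix({"S1": [3.0, 7.0]})  # mean 5, sample SD 2*sqrt(2)
        sd2 = np.std([3.0, 7.0], ddof=1)
        assert background_thresholds(exact)["S1"] == pytest.approx(2 * (5 + 2 * sd2))

    def test_multiplier_switch(self):
        m = _neg_matrix({"S1": [10] * 4})
        assert background_thresholds(m, multiplier=1.0)["S1"] == pytest.approx(10.0)

    def test_random_negatives_match_oracle(self):
        rng = np.random.default_rng(11)
        neg = rng.poisson(6, size=(8, 5))
        m = _neg_matrix({f"S{j}": neg[:, j] for j in range(5)})
        t = background_thresholds(m)
        for j in range(5):
            expected = 2 * (neg[:, j].mean() + 2 * neg[:, j].std(ddof=1))
            assert t[f"S{j}"] == pytest.approx(expected)

    def test_single_negative_probe_rejected(self):
        m = _neg_matrix({"S1": [4]})
        with pytest.raises(ValueError, match="Negative"):
            background_thresholds(m)

    def test_subtraction_floors_at_zero_and_spares_controls(self, tiny_matrix):
        t = pd.Series(20.0, index=tiny_matrix.samples)
        out = subtract_background(tiny_matrix, t)
        assert out.counts.loc["GENE2", "S2"] == pytest.approx(20.0)  # 40 - 20
        assert out.counts.loc["GENE1", "S1"] == pytest.approx(80.0)
        # a count below the threshold floors at zero
        big_t = pd.Series(1e6, index=tiny_matrix.samples)
        zeroed = subtract_background(tiny_matrix, big_t)
        assert (zeroed.counts.loc[["GENE1", "GENE2"]] == 0).all().all()
        # control rows untouched in both
        for probe in ("POS_A", "NEG_A"):
            pd.testing.assert_series_equal(
                zeroed.counts.loc[probe], tiny_matrix.counts.loc[probe].astype(float)
            )

    def test_idempotent_given_same_thresholds(self, tiny_matrix):
        t = background_thresholds(tiny_matrix)
        once = subtract_background(tiny_matrix, t)
        # thresholds recomputed on the subtracted matrix are unchanged
        # (negative rows untouched), and zero-floored values stay put
        twice = subtract_background(subtract_background(tiny_matrix, t * 0), t)
        pd.testing.assert_frame_equal(once.counts, twice.counts)


class TestPositiveFactor:
    def test_identical_samples_give_unit_factors(self):
        m = make_matrix(
            {"S1": [100, 400], "S2": [100, 400]},
            {0: "Positive", 1: "Positive"},
        )
        f, flags = positive_factor(m)
        assert np.allclose(f, 1.0)
        assert not flags.any()

    def test_closed_form_two_samples(self):
        # geomeans (g, 2g) -> mean 1.5g -> factors (1.5, 0.75)
        m = make_matrix(
            {"S1": [100.0, 400.0], "S2": [200.0, 800.0]},
            {0: "Positive", 1: "Positive"},
        )
        f, flags = positive_factor(m)
        assert f["S1"] == pytest.approx(1.5)
        assert f["S2"] == pytest.approx(0.75)

    def test_band_flagging(self):
        # geomeans (1, 20) -> mean 10.5 -> factors (10.5, 0.525); first flagged
        m = make_matrix({"S1": [1.0], "S2": [20.0]}, {0: "Positive"})
        f, flags = positive_factor(m)
        assert f["S1"] == pytest.approx(10.5)
        assert f["S2"] == pytest.approx(0.525)
        assert bool(flags["S1"]) and not bool(flags["S2"])

    def test_zero_positive_count_rejected(self):
        m = make_matrix({"S1": [0.0], "S2": [20.0]}, {0: "Positive"})
        with pytest.raises(ValueError, match="zero"):
            positive_factor(m)


class TestGeNormStability:
    def test_proportional_genes_have_zero_m(self):
        expr = pd.DataFrame(
            {"S1": [10.0, 20.0], "S2": [30.0, 60.0], "S3": [5.0, 10.0]},
            index=["A", "B"],
        )
        m = genorm_stability(expr)
        assert m["A"] == pytest.approx(0.0, abs=1e-12)
        assert m["B"] == pytest.approx(0.0, abs=1e-12)

    def test_two_candidates_symmetric(self):
        rng = np.random.default_rng(5)
        expr = pd.DataFrame(rng.lognormal(5, 1, (2, 6)), index=["A", "B"])
        m = genorm_stability(expr)
        assert m["A"] == pytest.approx(m["B"])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        expr = pd.DataFrame(
            rng.lognormal(5, 1, (5, 8)), index=[f"H{i}" for i in range(5)]
        )
        pd.testing.assert_series_equal(
            genorm_stability(expr), genorm_m_oracle(expr), check_names=False
        )

    def test_nonpositive_rejected(self):
        expr = pd.DataFrame({"S1": [1.0, 0.0], "S2": [2.0, 3.0]}, index=["A", "B"])
        with pytest.raises(ValueError, match="positive"):
            genorm_stability(expr)


class TestGeNormSelect:
    def _planted(self, seed, n_stable=4, n_noisy=1, n_samples=12):
        rng = np.random.default_rng(seed)
        rows, names = [], []
        for i in range(n_stable):
            rows.append(2 ** (9 + rng.normal(0, 0.05, n_samples)))
            names.append(f"STABLE{i}")
        for i in range(n_noisy):
            rows.append(2 ** (9 + rng.normal(0, 1.0, n_samples)))
            names.append(f"NOISY{i}")
        return pd.DataFrame(rows, index=names)

    def test_noisy_gene_excluded_first(self):
        expr = self._planted(seed=7, n_stable=3, n_noisy=1)
        res = genorm_select(expr, stop="keep_n", keep_n=3)
        assert res.exclusion_order == ["NOISY0"]

    def test_keep_n_rule(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(
            rng.lognormal(6, 0.5, (30, 10)), index=[f"HK{i:02d}" for i in range(30)]
        )
        res = genorm_select(expr, stop="keep_n", keep_n=23)
        assert len(res.selected) == 23
        assert len(res.exclusion_order) == 7
        assert sorted(res.selected + res.exclusion_order) == sorted(expr.index)

    def test_degenerate_ties_deterministic(self):
        expr = pd.DataFrame(
            np.full((4, 5), 64.0), index=["D", "C", "B", "A"]
        )
        res1 = genorm_select(expr, stop="keep_n", keep_n=2)
        res2 = genorm_select(expr, stop="keep_n", keep_n=2)
        assert res1.exclusion_order == res2.exclusion_order == ["A", "B"]
        assert (res1.stability == 0).all()

    def test_cannot_keep_fewer_than_two(self):
        expr = self._planted(seed=1)
        with pytest.raises(ValueError, match="2"):
            genorm_select(expr, stop="keep_n", keep_n=1)


class TestHousekeepingFactorAndApply:
    def test_identical_samples_unit_factor(self, tiny_matrix):
        m = make_matrix(
            {"S1": [200.0, 400.0], "S2": [200.0, 400.0]},
            {0: "Housekeeping", 1: "Housekeeping"},
        )
        m.counts.index = ["HK1", "HK2"]
        m.code_class.index = ["HK1", "HK2"]
        f = housekeeping_factor(m, ["HK1", "HK2"])
        assert np.allclose(f, 1.0)

    def test_scaled_sample_factor_halves(self):
        m = make_matrix(
            {"S1": [200.0, 400.0], "S2": [400.0, 800.0]},
            {0: "Housekeeping", 1: "Housekeeping"},
        )
        m.counts.index = m.code_class.index = pd.Index(["HK1", "HK2"])
        f = housekeeping_factor(m, ["HK1", "HK2"])
        assert f["S2"] / f["S1"] == pytest.approx(0.5)

    def test_zero_reference_enters_as_one(self):
        m = make_matrix(
            {"S1": [0.0, 400.0], "S2": [100.0, 400.0]},
            {0: "Housekeeping", 1: "Housekeeping"},
        )
        m.counts.index = m.code_class.index = pd.Index(["HK1", "HK2"])
        f = housekeeping_factor(m, ["HK1", "HK2"])
        g1 = np.sqrt(1.0 * 400.0)  # zero replaced by 1
        g2 = np.sqrt(100.0 * 400.0)
        assert f["S1"] == pytest.approx((g1 + g2) / 2 / g1)
        assert m.counts.loc["HK1", "S1"] == 0.0  # matrix untouched

    def test_apply_equalizes_control_geomeans(self, tiny_matrix):
        f_pos, flags = positive_factor(tiny_matrix)
        f_hk = housekeeping_factor(tiny_matrix, ["HK1", "HK2"], positive=f_pos)
        factors = NormalizationFactors(f_pos, f_hk, flags)
        out = apply_normalization(tiny_matrix, factors)
        # positive geomean x its factor flat across samples
        pos = tiny_matrix.counts.loc[["POS_A", "POS_B"]]
        g_pos = np.exp(np.log(pos).mean(axis=0)) * f_pos
        assert g_pos.max() / g_pos.min() == pytest.approx(1.0, rel=1e-9)
        # fully normalized reference geomean flat across samples
        refs = out.counts.loc[["HK1", "HK2"]]
        geo = np.exp(np.log(refs).mean(axis=0))
        assert geo.max() / geo.min() == pytest.approx(1.0, rel=1e-9)

    def test_apply_unit_factors_is_identity(self, tiny_matrix):
        ones = pd.Series(1.0, index=tiny_matrix.samples)
        factors = NormalizationFactors(ones, ones, ones.astype(bool) & False)
        out = apply_normalization(tiny_matrix, factors)
        pd.testing.assert_frame_equal(out.counts, tiny_matrix.counts.astype(float))
        assert out.normalized

    def test_reapplication_rejected(self, tiny_matrix):
        ones = pd.Series(1.0, index=tiny_matrix.samples)
        factors = NormalizationFactors(ones, ones, ones.astype(bool) & False)
        out = apply_normalization(tiny_matrix, factors)
        with pytest.raises(ValueError, match="already"):
            apply_normalization(out, factors)

    def test_random_matrix_columnwise_multiplication(self, tiny_matrix):
        f_pos, flags = positive_factor(tiny_matrix)
        f_hk = housekeeping_factor(tiny_matrix, ["HK1", "HK2"])
        factors = NormalizationFactors(f_pos, f_hk, flags)
        out = apply_normalization(tiny_matrix, factors)
        for s in tiny_matrix.samples:
            np.testing.assert_allclose(
                out.counts[s], tiny_matrix.counts[s] * f_pos[s] * f_hk[s]
            )


class TestPresenceFilter:
    def _matrix(self, rows):
        df = pd.DataFrame(rows, dtype=float)
        df.index = [f"G{i}" for i in range(len(df))]
        return CountMatrix(df, pd.Series("Endogenous", index=df.index))

    def test_kept_when_one_group_expresses(self):
        m = self._matrix({f"A{i}": [50, 10] for i in range(4)} | {f"B{i}": [0, 10] for i in range(4)})
        groups = {"a": [f"A{i}" for i in range(4)], "b": [f"B{i}" for i in range(4)]}
        res = presence_filter(m, groups)
        assert "G0" in res.expressed and "G1" not in res.expressed

    def test_strict_count_threshold(self):
        m = self._matrix({f"A{i}": [39] for i in range(4)})
        res = presence_filter(m, {"a": list(m.samples)})
        assert res.expressed == []

    def test_boundary_fraction_kept(self):
        # 2 of 8 samples at >= 40 -> 0.25 >= 0.25 -> kept
        cols = {f"A{i}": [40 if i < 2 else 0] for i in range(8)}
        m = self._matrix(cols)
        res = presence_filter(m, {"a": list(m.samples)})
        assert res.expressed == ["G0"]
        assert res.pass_fraction.loc["G0", "a"] == pytest.approx(0.25)

    def test_empty_group_rejected(self, tiny_matrix):
        with pytest.raises(ValueError, match="empty"):
            presence_filter(tiny_matrix, {"a": []})

    @given(bump=st.integers(min_value=1, max_value=60))
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_min_count(self, bump):
        rng = np.random.default_rng(17)
        df = pd.DataFrame(
            rng.poisson(40, size=(20, 8)).astype(float),
            index=[f"G{i}" for i in range(20)],
            columns=[f"S{i}" for i in range(8)],
        )
        m = CountMatrix(df, pd.Series("Endogenous", index=df.index))
        groups = {"a": [f"S{i}" for i in range(4)], "b": [f"S{i}" for i in range(4, 8)]}
        base = set(presence_filter(m, groups, min_count=40).expressed)
        raised = set(presence_filter(m, groups, min_count=40 + bump).expressed)
        assert raised <= base
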