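import math

import numpy as np
import pandas as pd
import pytest

from conftest import fisher_right_oracle
from zonalde.enrich import (
    ACTIVATED,
    INHIBITED,
    UNDETERMINED,
    GeneSetCollection,
    RegulatorNetwork,
    activation_zscore,
    comparison_matrix,
    enrichment_table,
    fisher_enrichment,
    overlap_ratio,
    read_gmt,
    upstream_regulator_table,
    write_gmt,
)


class TestGMT:
    def test_basic_line(self):
        coll = read_gmt("S1\tdesc\tA\tB")
        assert coll["S1"] == {"A", "B"}
        assert coll.descriptions["S1"] == "desc"

    def test_duplicate_genes_within_line_deduplicated(self):
        coll = read_gmt("S1\tdesc\tA\tA\tB")
        assert coll["S1"] == {"A", "B"}

    def test_short_line_rejected(self):
        with pytest.raises(ValueError, match="3 fields"):
            read_gmt("S1\tdesc")

    def test_duplicate_set_name_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            read_gmt("S1\td\tA\tB\nS1\td\tC\tD")

    def test_round_trip(self):
        coll = read_gmt("S1\tone\tA\tB\nS2\ttwo\tC\tD\tE")
        back = read_gmt(write_gmt(coll))
        assert back.sets == coll.sets


class TestOverlapRatio:
    @pytest.mark.parametrize(
        "de,gset,expected",
        [
            (set("ABCDE"), {f"X{i}" for i in range(95)} | set("AB"), 2 / 97),
            (set("AB"), set("CD"), 0.0),
            (set("ABCD"), set("AB"), 1.0),
        ],
    )
    def test_known_values(self, de, gset, expected):
        assert overlap_ratio(de, gset) == pytest.approx(expected)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            overlap_ratio({"A"}, set())


class TestFisherEnrichment:
    def test_hypergeometric_enumeration_example(self):
        # universe 10, de 5, set 2, overlap 2 -> C(5,2)/C(10,2) = 10/45
        universe = {f"G{i}" for i in range(10)}
        de = {f"G{i}" for i in range(5)}
        gset = {"G0", "G1"}
        assert fisher_enrichment(de, gset, universe) == pytest.approx(10 / 45)

    def test_certain_event(self):
        universe = {"A", "B", "C"}
        assert fisher_enrichment(universe, {"A"}, universe) == pytest.approx(1.0)

    def test_empty_dataset(self):
        universe = {"A", "B", "C"}
        assert fisher_enrichment(set(), {"A"}, universe) == pytest.approx(1.0)

    def test_de_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            fisher_enrichment({"Z"}, {"A"}, {"A", "B"})

    def test_matches_enumeration_on_small_universes(self):
        rng = np.random.default_rng(9)
        for _ in range(300):
            n = rng.integers(4, 26)
            universe = [f"G{i}" for i in range(n)]
            de = set(rng.choice(universe, size=rng.integers(0, n + 1), replace=False))
            gset = set(
                rng.choice(universe, size=rng.integers(1, n + 1), replace=False)
            )
            a = len(de & gset)
            table = [
                [a, len(gset) - a],
                [len(de) - a, n - len(gset) - len(de) + a],
            ]
            assert fisher_enrichment(de, gset, universe) == pytest.approx(
                fisher_right_oracle(table), abs=1e-12
            )


def _edges(pairs):
    return pd.DataFrame(
        [{"regulator": "R", "target": t, "sign": s} for t, s in pairs]
    )


class TestActivationZscore:
    def test_all_agreeing(self):
        directions = {f"G{i}": 1 for i in range(9)}
        z, n = activation_zscore(directions, _edges([(f"G{i}", 1) for i in range(9)]))
        assert z == pytest.approx(3.0)
        assert n == 9

    def test_balanced_agreement_zero(self):
        directions = {f"G{i}": 1 for i in range(4)}
        edges = _edges([("G0", 1), ("G1", 1), ("G2", -1), ("G3", -1)])
        z, _ = activation_zscore(directions, edges)
        assert z == pytest.approx(0.0)

    def test_no_targets_in_dataset(self):
        z, n = activation_zscore({"A": 1}, _edges([("B", 1)]))
        assert math.isnan(z) and n == 0

    def test_antisymmetric_under_global_sign_flip(self):
        rng = np.random.default_rng(2)
        directions = {f"G{i}": int(s) for i, s in enumerate(rng.choice([-1, 1], 12))}
        pairs = [(f"G{i}", int(s)) for i, s in enumerate(rng.choice([-1, 1], 12))]
        z1, _ = activation_zscore(directions, _edges(pairs))
        z2, _ = activation_zscore(directions, _edges([(t, -s) for t, s in pairs]))
        assert z1 == pytest.approx(-z2)

    def test_invariant_to_edge_order(self):
        directions = {f"G{i}": 1 for i in range(6)}
        pairs = [(f"G{i}", (-1) ** i) for i in range(6)]
        z1, _ = activation_zscore(directions, _edges(pairs))
        z2, _ = activation_zscore(directions, _edges(pairs[::-1]))
        assert z1 == pytest.approx(z2)

    def test_weighted_variant(self):
        directions = {"A": 1, "B": 1}
        edges = pd.DataFrame(
            [
                {"regulator": "R", "target": "A", "sign": 1, "weight": 2.0},
                {"regulator": "R", "target": "B", "sign": -1, "weight": 1.0},
            ]
        )
        z, _ = activation_zscore(directions, edges)
        assert z == pytest.approx((2.0 - 1.0) / math.sqrt(5.0))

    def test_null_calibration(self):
        # random +-1 directions: z should be mean 0, SD 1
        rng = np.random.default_rng(123)
        n = 25
        edges = _edges([(f"G{i}", 1) for i in range(n)])
        zs = []
        for _ in range(10_000):
            directions = {f"G{i}": int(s) for i, s in enumerate(rng.choice([-1, 1], n))}
            zs.append(activation_zscore(directions, edges)[0])
        zs = np.array(zs)
        assert abs(zs.mean()) < 0.05
        assert abs(zs.std() - 1.0) < 0.05


def _de_table(genes, fcs, ps):
    return pd.DataFrame({"fc": fcs, "p": ps}, index=pd.Index(genes, name="gene"))


class TestUpstreamRegulators:
    def test_planted_regulator_activated(self):
        genes = [f"G{i}" for i in range(20)]
        table = _de_table(genes, [2.5] * 20, [0.001] * 20)
        net = RegulatorNetwork(
            pd.DataFrame(
                [{"regulator": "REG", "target": g, "sign": 1} for g in genes]
            )
        )
        out = upstream_regulator_table(table, net, genes)
        assert out.loc["REG", "state"] == ACTIVATED
        assert out.loc["REG", "z"] == pytest.approx(math.sqrt(20))

    def test_sign_flip_inverts_state(self):
        genes = [f"G{i}" for i in range(16)]
        table = _de_table(genes, [3.0] * 16, [0.01] * 16)
        edges = pd.DataFrame(
            [{"regulator": "REG", "target": g, "sign": 1} for g in genes]
        )
        up = upstream_regulator_table(table, RegulatorNetwork(edges.copy()), genes)
        flipped = edges.assign(sign=-edges["sign"])
        down = upstream_regulator_table(table, RegulatorNetwork(flipped), genes)
        assert up.loc["REG", "state"] == ACTIVATED
        assert down.loc["REG", "state"] == INHIBITED
        assert up.loc["REG", "z"] == pytest.approx(-down.loc["REG", "z"])

    def test_z_below_threshold_undetermined(self):
        # 7 of 9 agreeing -> z = 5/3 = 1.67 < 2
        genes = [f"G{i}" for i in range(9)]
        signs = [1] * 7 + [-1] * 2
        table = _de_table(genes, [2.5] * 9, [0.001] * 9)
        net = RegulatorNetwork(
            pd.DataFrame(
                [
                    {"regulator": "REG", "target": g, "sign": s}
                    for g, s in zip(genes, signs)
                ]
            )
        )
        out = upstream_regulator_table(table, net, genes)
        assert out.loc["REG", "z"] == pytest.approx(5 / 3)
        assert out.loc["REG", "state"] == UNDETERMINED

    def test_selection_regime_excludes_weak_genes(self):
        genes = ["A", "B"]
        table = _de_table(genes, [2.5, 1.8], [0.001, 0.001])  # B fails |FC|>2
        net = RegulatorNetwork(
            pd.DataFrame(
                [
                    {"regulator": "REG", "target": "A", "sign": 1},
                    {"regulator": "REG", "target": "B", "sign": 1},
                ]
            )
        )
        out = upstream_regulator_table(table, net, genes)
        assert out.loc["REG", "n_targets_in_dataset"] == 1


class TestComparisonMatrix:
    def _etab(self, z, p):
        return pd.DataFrame(
            {"z": z, "p": p}, index=pd.Index(["S1", "S2"], name="set")
        )

    def test_tf_only_classification(self):
        res = comparison_matrix(
            {
                "TF": self._etab([3.0, 0.5], [0.001, 0.5]),
                "TC": self._etab([0.2, 0.1], [0.9, 0.8]),
            }
        )
        assert res.loc["S1", "classification"] == "TF"
        assert res.loc["S2", "classification"] == "none"

    def test_identical_inputs_classified_both(self):
        e = self._etab([2.5, 0.0], [0.01, 0.7])
        res = comparison_matrix({"TF": e, "TC": e.copy()})
        assert res.loc["S1", "classification"] == "TC+TF"

    def test_single_contrast_rejected(self):
        with pytest.raises(ValueError):
            comparison_matrix({"TF": self._etab([1, 1], [0.5, 0.5])})


class TestEnrichmentTable:
    def test_ratio_variants_and_sorting(self):
        coll = GeneSetCollection(
            {"BIG": frozenset({"A", "B", "X"}), "SMALL": frozenset({"A"})}
        )
        universe = {"A", "B", "C", "D"}
        out = enrichment_table({"A", "B"}, coll, universe)
        assert out.loc["BIG", "ratio_full"] == pytest.approx(2 / 3)
        assert out.loc["BIG", "ratio_universe"] == pytest.approx(1.0)  # X not in universe
        assert out.loc["BIG", "minus_log10_p"] == pytest.approx(
            -math.log10(out.loc["BIG", "p"])
        )
        assert list(out.index) == list(out.sort_values(["p", "set"]).index)
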