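"""Hybrid combination, permutation p-values, stratification, BH FDR."""

import numpy as np
import pytest

import bomp
from bomp.core import FunctionalGroup, GeneMembers, GenotypeMatrix, SampleTable, VariantRecord
from bomp.engine import BompConfig, bh_adjust, bomp_statistic, permutation_test, _permuted_labels
from bomp.weights import WeightConfig


def manual_step_up(p):
    """Independent BH oracle: explicit sorted step-up with back-mapping."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def make_study(values, status, codons=None, gene="g1", length=64):
    values = np.asarray(values, dtype=np.int8)
    n, V = values.shape
    status = np.asarray(status, dtype=bool)
    codons = list(codons) if codons is not None else list(range(V))
    variants = []
    for j in range(V):
        case = int(values[status, j].sum())
        total = int(values[:, j].sum())
        variants.append(VariantRecord(f"v{j}", gene, codons[j], case, total - case))
    names = [f"s{i}" for i in range(n)]
    gm = GenotypeMatrix(names, variants, values)
    table = SampleTable(names, status)
    group = FunctionalGroup("grp", [GeneMembers(gene, length, np.arange(V))])
    return gm, table, group


class TestCombination:
    @pytest.mark.parametrize(
        "lb,lp,rule,expected",
        [
            (0.9152, 0.9832, "sum", 1.8984),
            (0.0, 0.0, "sum", 0.0),
            (0.9152, 0.9832, "max", 0.9832),
            (-0.5, 0.2, "max", 0.2),
        ],
    )
    def test_rules(self, lb, lp, rule, expected):
        assert bomp_statistic(lb, lp, rule) == pytest.approx(expected, abs=1e-12)

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            bomp_statistic(0.0, 0.0, "mean")


class TestPermutationTest:
    def setup_method(self):
        rng = np.random.default_rng(99)
        n = 24
        self.values = rng.integers(0, 2, size=(n, 8)).astype(np.int8)
        self.values[:8, 0] = 1  # plant extra case burden
        self.status = np.array([True] * 12 + [False] * 12)

    def test_p_values_on_add_one_grid(self):
        gm, table, group = make_study(self.values, self.status)
        res = permutation_test(gm, table, group, BompConfig(permutations=99), seed=1)
        B = res.n_permutations
        grid = {(k + 1) / (B + 1) for k in range(B + 1)}
        for p in (res.p_burden, res.p_position, res.p_combined):
            assert 1 / (B + 1) <= p <= 1.0
            assert any(abs(p - g) < 1e-12 for g in grid)

    def test_seed_determinism_bit_identical(self):
        gm, table, group = make_study(self.values, self.status)
        cfg = BompConfig(permutations=50)
        a = permutation_test(gm, table, group, cfg, seed=7)
        b = permutation_test(gm, table, group, cfg, seed=7)
        assert (a.llr_combined, a.p_burden, a.p_position, a.p_combined) == (
            b.llr_combined, b.p_burden, b.p_position, b.p_combined
        )
        c = permutation_test(gm, table, group, cfg, seed=8)
        assert (a.p_burden, a.p_position) != (c.p_burden, c.p_position) or (
            a.llr_combined == c.llr_combined
        )

    def test_observed_stat_reproduces_reference_components(self):
        gm, table, group = make_study(self.values, self.status)
        res = permutation_test(gm, table, group, BompConfig(permutations=5), seed=3)
        # burden: reference optimizer on raw counts (unit weights)
        burdens = self.values.sum(axis=1)
        ref = bomp.optimize_burden_threshold(
            burdens[self.status], burdens[~self.status]
        )
        assert res.llr_burden == pytest.approx(ref.llr, abs=1e-12)
        assert res.llr_combined == pytest.approx(
            res.llr_burden + res.llr_position, abs=1e-12
        )

    def test_zero_position_component_makes_combined_match_burden(self):
        """With every variant at one codon there is a single occupied window,
        so the position LLR is identically zero and p_combined == p_burden."""
        gm, table, group = make_study(
            self.values, self.status, codons=[5] * 8, length=8
        )
        cfg = BompConfig(permutations=99, ws_pairs=((8, 8),))
        res = permutation_test(gm, table, group, cfg, seed=2)
        assert res.llr_position == 0.0
        assert res.p_combined == res.p_burden

    def test_stratified_permutation_preserves_stratum_counts(self):
        rng = np.random.default_rng(0)
        status = np.array([True] * 3 + [False] * 9 + [True] * 8 + [False] * 4)
        strata = np.array(["a"] * 12 + ["b"] * 12)
        labels = _permuted_labels(status, strata, 200, rng)
        for block, expected in ((slice(0, 12), 3), (slice(12, 24), 8)):
            assert np.all(labels[:, block].sum(axis=1) == expected)

    def test_degenerate_stratum_warns(self):
        rng = np.random.default_rng(0)
        status = np.array([True, True, True, False])
        strata = np.array(["a", "a", "a", "b"])
        with pytest.warns(UserWarning, match="stratum"):
            _permuted_labels(status, strata, 5, rng)

    def test_planted_signal_detected(self, small_study):
        res = permutation_test(
            small_study.genotypes, small_study.samples, small_study.group,
            BompConfig(permutations=199,
                       weights=WeightConfig(mode="af")), seed=5,
        )
        assert res.p_combined <= 0.05

    def test_requires_at_least_one_permutation(self):
        gm, table, group = make_study(self.values, self.status)
        with pytest.raises(ValueError):
            permutation_test(gm, table, group, B=0, seed=1)


class TestBhAdjust:
    def test_single_value_identity(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_equal_values_unchanged(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_matches_independent_step_up_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            p = rng.random(int(rng.integers(1, 30))) * 0.999 + 1e-6
            assert bh_adjust(p) == pytest.approx(manual_step_up(p), abs=1e-12)

    def test_out_of_range_rejected(self):
        for bad in ([0.0, 0.5], [0.5, 1.2]):
            with pytest.raises(ValueError):
                bh_adjust(bad)
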