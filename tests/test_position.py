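"""Position statistic: segmentations, window counts, multinomial LLR."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from bomp.position import (
    DEFAULT_WS_PAIRS,
    GenePositionPlan,
    Segmentation,
    best_segmentation,
    enumerate_segmentations,
    multinomial_llr,
    window_counts,
)


class TestSegmentations:
    @pytest.mark.parametrize(
        "length,pairs,expected",
        [
            (500, DEFAULT_WS_PAIRS, 32),
            (24, [(8, 1)], 8),
            (8, [(8, 8)], 1),
            (1000, DEFAULT_WS_PAIRS, 32),
        ],
    )
    def test_candidate_counts(self, length, pairs, expected):
        assert len(enumerate_segmentations(length, pairs)) == expected

    @pytest.mark.parametrize("pair", [(8, 16), (8, 3)])
    def test_invalid_shift_rejected(self, pair):
        with pytest.raises(ValueError):
            enumerate_segmentations(100, [pair])

    @given(st.integers(1, 200), st.sampled_from([(8, 1), (16, 2), (32, 4), (64, 8)]))
    def test_partition_covers_every_codon_once(self, length, pair):
        for seg in enumerate_segmentations(length, [pair]):
            bounds = seg.boundaries
            assert bounds[0][0] == 0 and bounds[-1][1] == length
            for (a1, b1), (a2, b2) in zip(bounds, bounds[1:]):
                assert b1 == a2 and b1 > a1
            # interior windows have the nominal length
            for a, b in bounds[1:-1]:
                assert b - a == seg.window_size
            assert len(bounds) == seg.n_windows
            # window_of agrees with the boundary list
            for w, (a, b) in enumerate(bounds):
                assert np.all(seg.window_of(np.arange(a, b)) == w)

    def test_single_window_gene(self):
        seg = enumerate_segmentations(8, [(8, 8)])[0]
        assert seg.boundaries == [(0, 8)]


class TestWindowCounts:
    def test_counting_allele_copies(self):
        seg = Segmentation(8, 8, 0, 16)
        xc, xt = window_counts(seg, [0, 3, 9], [], [1, 1, 1], [])
        assert xc.tolist() == [2, 1] and xt.tolist() == [0, 0]

    def test_positions_mode_counts_distinct_codons(self):
        seg = Segmentation(8, 8, 0, 16)
        # two case samples heterozygous at codon 3: two mutation copies
        xc_m, _ = window_counts(seg, [3], [], [2], [], "mutations")
        xc_p, _ = window_counts(seg, [3], [], [2], [], "positions")
        assert xc_m.tolist() == [2, 0] and xc_p.tolist() == [1, 0]

    def test_no_variants_all_zero(self):
        seg = Segmentation(8, 8, 0, 16)
        xc, xt = window_counts(seg, [], [])
        assert xc.sum() == 0 and xt.sum() == 0

    def test_out_of_gene_position_rejected(self):
        seg = Segmentation(8, 8, 0, 16)
        with pytest.raises(ValueError):
            window_counts(seg, [16], [])


class TestMultinomialLlr:
    def test_disjoint_windows_worked_example(self):
        assert multinomial_llr([4, 0], [0, 4]) == pytest.approx(
            8 * np.log(5 / 3), abs=1e-9
        )

    def test_identical_distributions_exact_zero(self):
        assert multinomial_llr([2, 2], [2, 2]) == 0.0

    def test_equal_totals_different_shapes(self):
        assert multinomial_llr([6, 3], [3, 6]) == pytest.approx(
            0.9832222950914489, abs=1e-9
        )

    @given(
        st.lists(st.integers(0, 8), min_size=1, max_size=6),
        st.lists(st.integers(0, 8), min_size=1, max_size=6),
    )
    def test_label_swap_symmetry(self, a, b):
        k = min(len(a), len(b))
        a, b = a[:k], b[:k]
        assert multinomial_llr(a, b) == pytest.approx(multinomial_llr(b, a), abs=1e-12)

    def test_theta_vectors_normalized(self):
        xc = np.array([5, 0, 2], float)
        xt = np.array([1, 1, 0], float)
        for x in (xc, xt, xc + xt):
            theta = (x + 1) / (x.sum() + x.size)
            assert theta.sum() == pytest.approx(1.0, abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            multinomial_llr([-1, 2], [0, 0])


class TestBestSegmentation:
    def _random_gene(self, rng):
        L = int(rng.integers(8, 150))
        m = int(rng.integers(1, min(L, 12)))
        pos = np.sort(rng.choice(L, m, replace=False))
        n = int(rng.integers(4, 14))
        dose = rng.integers(0, 3, size=(n, m)).astype(float)
        labels = np.zeros(n, dtype=bool)
        labels[: n // 2] = True
        keep = dose.sum(axis=0) > 0
        return L, pos[keep], dose[:, keep], labels

    def test_selection_equals_exhaustive_oracle(self):
        """The returned LLR equals a brute-force maximum over every
        enumerated segmentation via the scalar multinomial_llr."""
        rng = np.random.default_rng(11)
        done = 0
        while done < 40:
            L, pos, dose, labels = self._random_gene(rng)
            if pos.size == 0:
                continue
            llr, seg = best_segmentation(L, pos, dose, labels)
            case_tot = dose[labels].sum(axis=0)
            ctrl_tot = dose[~labels].sum(axis=0)
            oracle = max(
                multinomial_llr(*window_counts(s, pos, pos, case_tot, ctrl_tot))
                for s in enumerate_segmentations(L)
            )
            assert llr == pytest.approx(oracle, abs=1e-10)
            done += 1

    def test_clustered_case_variants_found(self):
        """Case variants packed into one 8-codon window and control variants
        into another should align a window boundary between them."""
        L = 64
        pos = np.array([0, 1, 2, 3, 16, 17, 18, 19])
        n = 8
        dose = np.zeros((n, 8))
        dose[:4, :4] = 1  # cases carry the first cluster
        dose[4:, 4:] = 1  # controls the second
        labels = np.array([True] * 4 + [False] * 4)
        llr, seg = best_segmentation(L, pos, dose, labels)
        assert llr > 0
        assert seg.window_of([0])[0] != seg.window_of([16])[0]

    def test_identical_placements_zero(self):
        L, pos = 32, np.array([2, 9])
        dose = np.ones((6, 2))
        labels = np.array([True] * 3 + [False] * 3)
        llr, _ = best_segmentation(L, pos, dose, labels)
        assert llr == pytest.approx(0.0, abs=1e-12)

    def test_variant_order_invariance(self):
        rng = np.random.default_rng(5)
        L, pos, dose, labels = self._random_gene(rng)
        if pos.size > 1:
            perm = rng.permutation(pos.size)
            a, _ = best_segmentation(L, pos, dose, labels)
            b, _ = best_segmentation(L, pos[perm], dose[:, perm], labels)
            assert a == pytest.approx(b, abs=1e-12)


class TestBatchPlan:
    def test_plan_matches_reference(self):
        rng = np.random.default_rng(23)
        for _ in range(30):
            L = int(rng.integers(8, 150))
            m = int(rng.integers(1, min(L, 12)))
            pos = np.sort(rng.choice(L, m, replace=False))
            n = int(rng.integers(4, 12))
            dose = rng.integers(0, 3, size=(n, m)).astype(float)
            keep = dose.sum(axis=0) > 0
            pos, dose = pos[keep], dose[:, keep]
            if pos.size == 0:
                continue
            labels = rng.random((5, n)) < 0.5
            plan = GenePositionPlan(L, pos)
            case = labels.astype(float) @ dose
            best_direct, _ = plan.best_rows(case, total_counts=dose.sum(axis=0))
            for i in range(5):
                want, _ = best_segmentation(L, pos, dose, labels[i])
                assert best_direct[i] == pytest.approx(want, abs=1e-9)

    def test_empty_gene_contributes_zero(self):
        plan = GenePositionPlan(100, np.empty(0, dtype=int))
        out = plan.llr_rows(np.zeros((3, 0)), np.zeros((3, 0)))
        assert out.shape == (3, 32) and not out.any()
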