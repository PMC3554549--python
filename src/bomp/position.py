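"""Non-directional mutation position-distribution statistic.

The codons of a gene are partitioned into windows and the mutation counts
per window in cases and controls are modeled as multinomial draws. With
add-one smoothed parameter estimates

    theta_g,w = (x_g,w + 1) / (X_g + K),   g in {case, ctrl, pooled},

(K windows, X_g the group total) the statistic is the log ratio of the
separate-group multinomial likelihoods to the pooled one, evaluated at raw
counts (multinomial coefficients cancel):

    LLR = sum_w x_case,w ln(theta_case,w / theta_pool,w)
        + sum_w x_ctrl,w ln(theta_ctrl,w / theta_pool,w).

The statistic is symmetric under a case/control label swap: it is large
whenever the two position distributions differ, in either direction.

Because no single window partition is known in advance, a grid of
candidate *segmentations* is enumerated: for each (window size w, shift
increment s) pair, one segmentation per offset in {0, s, ..., w - s}. The
default grid (8,1), (16,2), (32,4), (64,8) yields 32 candidates per gene;
the best (largest-LLR) segmentation is selected per gene, and for a gene
set the per-gene maxima are summed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DEFAULT_WS_PAIRS",
    "Segmentation",
    "PositionResult",
    "enumerate_segmentations",
    "window_counts",
    "multinomial_llr",
    "best_segmentation",
    "GenePositionPlan",
]

DEFAULT_WS_PAIRS: tuple[tuple[int, int], ...] = ((8, 1), (16, 2), (32, 4), (64, 8))

COUNT_MODES = ("mutations", "positions")


@dataclass(frozen=True)
class Segmentation:
    """A disjoint, exhaustive partition of a gene's codons into windows.

    Interior windows have length ``window_size``; when ``offset > 0`` a
    leading window of length ``offset`` is kept, and the trailing window
    may be shorter, so that every codon belongs to exactly one window.
    """

    window_size: int
    shift: int
    offset: int
    n_codons: int

    def __post_init__(self) -> None:
        w, s = self.window_size, self.shift
        if not 1 <= s <= w:
            raise ValueError(f"shift {s} must satisfy 1 <= s <= window size {w}")
        if w % s != 0:
            raise ValueError(f"shift {s} must divide window size {w}")
        if not 0 <= self.offset < w:
            raise ValueError("offset must lie in [0, window_size)")
        if self.n_codons < 1:
            raise ValueError("gene must have at least one codon")

    @property
    def n_windows(self) -> int:
        lead = 1 if self.offset > 0 else 0
        return lead + -(-(self.n_codons - self.offset) // self.window_size)

    @property
    def boundaries(self) -> list[tuple[int, int]]:
        edges = [0]
        start = self.offset if self.offset > 0 else 0
        if self.offset > 0:
            edges.append(min(self.offset, self.n_codons))
        while start < self.n_codons:
            start = min(start + self.window_size, self.n_codons)
            edges.append(start)
        return list(zip(edges[:-1], edges[1:]))

    def window_of(self, codons) -> np.ndarray:
        """Window index of each codon position (vectorized)."""
        c = np.asarray(codons, dtype=int)
        if c.size and (c.min() < 0 or c.max() >= self.n_codons):
            raise ValueError("codon position outside gene")
        lead = 1 if self.offset > 0 else 0
        return np.where(
            c < self.offset, 0, (c - self.offset) // self.window_size + lead
        )


def enumerate_segmentations(gene_length_codons, ws_pairs=DEFAULT_WS_PAIRS):
    """All candidate segmentations of a gene for a (w, s) grid.

    Each (w, s) pair contributes w/s segmentations (offsets 0, s, ..., w-s),
    so the default grid gives 8 + 8 + 8 + 8 = 32 per gene regardless of gene
    length. Genes shorter than a window size still receive that family's
    segmentations; coinciding duplicates are deliberately retained.
    """
    if gene_length_codons < 1:
        raise ValueError("gene length must be >= 1 codon")
    segs = []
    for w, s in ws_pairs:
        for offset in range(0, w, s):
            segs.append(Segmentation(w, s, offset, gene_length_codons))
    return segs


def window_counts(
    segmentation,
    case_codons,
    ctrl_codons,
    case_copies=None,
    ctrl_copies=None,
    count_mode="mutations",
):
    """Aggregated per-window mutation counts for cases and controls.

    ``case_codons``/``ctrl_codons`` give the codon position of each variant
    observed in the group, with ``*_copies`` the allele copies at that
    codon. In ``mutations`` mode every allele copy adds one to its window's
    count; in ``positions`` mode each distinct mutated codon adds one per
    group regardless of how many carriers it has.
    """
    if count_mode not in COUNT_MODES:
        raise ValueError(f"count_mode must be one of {COUNT_MODES}")
    K = segmentation.n_windows
    out = []
    for codons, copies in ((case_codons, case_copies), (ctrl_codons, ctrl_copies)):
        codons = np.asarray(codons, dtype=int)
        if copies is None:
            copies = np.ones(codons.size)
        copies = np.asarray(copies, dtype=float)
        keep = copies > 0
        codons, copies = codons[keep], copies[keep]
        if count_mode == "positions":
            codons = np.unique(codons)
            copies = np.ones(codons.size)
        wins = segmentation.window_of(codons)
        out.append(np.bincount(wins, weights=copies, minlength=K))
    return out[0], out[1]


def multinomial_llr(x_case, x_ctrl):
    """Smoothed multinomial log-likelihood-ratio over window counts."""
    xc = np.asarray(x_case, dtype=float)
    xt = np.asarray(x_ctrl, dtype=float)
    if xc.shape != xt.shape or xc.ndim != 1 or xc.size < 1:
        raise ValueError("counts must be equal-length 1-D vectors with K >= 1")
    if np.any(xc < 0) or np.any(xt < 0):
        raise ValueError("window counts must be non-negative")
    K = xc.size
    xp = xc + xt
    th_c = (xc + 1.0) / (xc.sum() + K)
    th_t = (xt + 1.0) / (xt.sum() + K)
    th_p = (xp + 1.0) / (xp.sum() + K)
    return float(np.sum(xc * np.log(th_c / th_p) + xt * np.log(th_t / th_p)))


@dataclass
class PositionResult:
    """Best segmentation and statistic for one gene (or summed over a group)."""

    llr: float
    segmentations: dict  # gene -> Segmentation chosen on the observed labels
    per_gene_llr: dict


def best_segmentation(
    gene_length_codons,
    codon_positions,
    dosage,
    labels,
    ws_pairs=DEFAULT_WS_PAIRS,
    count_mode="mutations",
):
    """Reference (per-call) segmentation selection for a single gene.

    Evaluates :func:`multinomial_llr` for every enumerated segmentation and
    returns ``(llr, segmentation)`` for the maximizer; ties resolve to the
    first segmentation in enumeration order. ``dosage`` is the samples x
    codon-positions allele-count matrix restricted to this gene's mutated
    codons; ``labels`` is boolean with True = case.
    """
    labels = np.asarray(labels, dtype=bool)
    dosage = np.asarray(dosage, dtype=float)
    pos = np.asarray(codon_positions, dtype=int)
    segs = enumerate_segmentations(gene_length_codons, ws_pairs)
    if pos.size == 0:
        return 0.0, segs[0] if segs else None
    case_tot = dosage[labels].sum(axis=0)
    ctrl_tot = dosage[~labels].sum(axis=0)
    best_llr, best_seg = -np.inf, None
    for seg in segs:
        xc, xt = window_counts(seg, pos, pos, case_tot, ctrl_tot, count_mode)
        llr = multinomial_llr(xc, xt)
        if llr > best_llr:
            best_llr, best_seg = llr, seg
    return best_llr, best_seg


class GenePositionPlan:
    """Precomputed window bookkeeping for scoring many label permutations.

    For one gene, maps its mutated codons into the windows of every
    candidate segmentation once; :meth:`llr_rows` then evaluates the
    per-segmentation multinomial LLR for a whole batch of per-codon group
    counts with a handful of array operations. Windows containing no
    mutated codon contribute zero to the LLR sum (their counts are zero),
    so only occupied windows are materialized; the full window number K of
    each segmentation still enters the smoothed parameter denominators.
    """

    def __init__(self, gene_length_codons, codon_positions, ws_pairs=DEFAULT_WS_PAIRS):
        self.n_codons = int(gene_length_codons)
        self.positions = np.asarray(codon_positions, dtype=int)
        self.segmentations = enumerate_segmentations(self.n_codons, ws_pairs)
        m = self.positions.size
        self.m = m
        if m == 0:
            return
        gather, starts, k_col, seg_starts = [], [], [], []
        base = 0
        for seg in self.segmentations:
            wins = seg.window_of(self.positions)
            order = np.argsort(wins, kind="stable")
            sorted_wins = wins[order]
            new = np.ones(m, dtype=bool)
            new[1:] = sorted_wins[1:] != sorted_wins[:-1]
            col_starts = np.nonzero(new)[0] + base
            seg_starts.append(len(starts))
            starts.extend(col_starts.tolist())
            k_col.extend([seg.n_windows] * col_starts.size)
            gather.append(order)
            base += m
        self.gather = np.concatenate(gather)
        self.col_starts = np.asarray(starts, dtype=np.intp)
        self.k_col = np.asarray(k_col, dtype=float)
        self.seg_col_starts = np.asarray(seg_starts, dtype=np.intp)

    def llr_rows(self, case_counts, ctrl_counts=None, total_counts=None):
        """Per-segmentation LLR matrix for batched group counts.

        ``case_counts``/``ctrl_counts`` are (rows x mutated codons)
        integer count matrices (allele copies in ``mutations`` mode,
        mutated-codon indicators in ``positions`` mode). In mutations
        mode the control counts are determined by the fixed per-codon
        totals, so ``ctrl_counts`` may be omitted in favour of a 1-D
        ``total_counts`` vector. Returns an array of shape
        (rows, n_segmentations).

        The LLR is evaluated in the expanded form

            sum_w [ x_c ln(x_c+1) + x_t ln(x_t+1) - x_p ln(x_p+1) ]
            - X_c ln(X_c+K) - X_t ln(X_t+K) + X_p ln(X_p+K),

        so the per-window part is a table lookup on small integer counts
        and only the totals term needs per-segmentation logarithms.
        Windows with no mutated codon contribute nothing to the sum and
        are never materialized.
        """
        n_rows = case_counts.shape[0]
        n_segs = len(self.segmentations)
        if self.m == 0:
            return np.zeros((n_rows, n_segs))
        case_counts = np.asarray(np.rint(case_counts), dtype=np.int64)
        xc = np.add.reduceat(case_counts[:, self.gather], self.col_starts, axis=1)
        tot_c = case_counts.sum(axis=1, keepdims=True)
        if ctrl_counts is None:
            if total_counts is None:
                raise ValueError("need ctrl_counts or total_counts")
            total = np.asarray(np.rint(total_counts), dtype=np.int64)
            tot_win = np.add.reduceat(total[self.gather], self.col_starts)
            xt = tot_win[None, :] - xc
            tot_t = int(total.sum()) - tot_c
        else:
            ctrl_counts = np.asarray(np.rint(ctrl_counts), dtype=np.int64)
            xt = np.add.reduceat(ctrl_counts[:, self.gather], self.col_starts, axis=1)
            tot_t = ctrl_counts.sum(axis=1, keepdims=True)
        top = int(tot_c.max() + tot_t.max()) + 1
        table = np.arange(top + 1, dtype=float)
        table *= np.log1p(table)  # k -> k ln(k+1)
        term = table[xc] + table[xt] - table[xc + xt]
        llr = np.add.reduceat(term, self.seg_col_starts, axis=1)
        k = np.array([s.n_windows for s in self.segmentations], dtype=float)[None, :]
        llr -= tot_c * np.log(tot_c + k)
        llr -= tot_t * np.log(tot_t + k)
        llr += (tot_c + tot_t) * np.log(tot_c + tot_t + k)
        return llr

    def best_rows(self, case_counts, ctrl_counts=None, total_counts=None):
        """Maximum LLR over segmentations per row, with the argmax index.

        Ties resolve to the first segmentation in enumeration order.
        """
        per_seg = self.llr_rows(case_counts, ctrl_counts, total_counts)
        idx = np.argmax(per_seg, axis=1)
        return per_seg[np.arange(per_seg.shape[0]), idx], idx
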