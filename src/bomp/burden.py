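"""Directional mutation-burden statistic.

Each individual's burden is a (possibly weighted) sum of genotype
contributions over all variants of the functional group; for a gene set
the burden is aggregated across every member gene. The burden is then
dichotomized at a threshold T: a sample "exceeds" when its burden is >= T.
With k_case of n_case cases and k_ctrl of n_ctrl controls exceeding, the
statistic is a log ratio of Bernoulli likelihoods, comparing separate
case/control exceedance probabilities against a pooled one. Probabilities
are add-one smoothed,

    p_case = (k_case + 1) / (n_case + 2),   p_ctrl = (k_ctrl + 1) / (n_ctrl + 2),
    p_pool = (k_case + k_ctrl + 1) / (n_case + n_ctrl + 2),

while the likelihood exponents use the raw counts. The statistic is
directional: the magnitude of the log ratio is signed by the comparison
of the smoothed probabilities — positive when cases exceed more often,
negated when controls do, and exactly zero at equality — so a higher
burden in cases scores high, a higher burden in controls scores low, and
perfectly balanced data score zero.

T is chosen per functional group by scanning every distinct positive
observed burden and keeping the threshold that maximizes the signed
statistic (smallest threshold on ties).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BurdenResult",
    "individual_burden",
    "smoothed_bernoulli_llr",
    "optimize_burden_threshold",
    "burden_llr_rows",
]


@dataclass
class BurdenResult:
    """Outcome of the burden-threshold optimization for one label assignment."""

    threshold: float | None
    n_case_exceed: int
    n_ctrl_exceed: int
    p_case: float
    p_ctrl: float
    p_pooled: float
    llr: float


def individual_burden(genotype_row, weights, genetic_model="additive"):
    """Weighted burden of one individual over a group's variants."""
    from .weights import effective_genotype_score

    row = np.asarray(genotype_row)
    w = np.asarray(weights, dtype=float)
    if row.shape != w.shape:
        raise ValueError(f"genotype row {row.shape} / weights {w.shape} length mismatch")
    return float(effective_genotype_score(row, w, genetic_model).sum())


def _bernoulli_ll(k, n, p):
    return k * np.log(p) + (n - k) * np.log1p(-p)


def smoothed_bernoulli_llr(k_case, n_case, k_ctrl, n_ctrl):
    """Signed smoothed Bernoulli log-likelihood-ratio at fixed counts."""
    for k, n in ((k_case, n_case), (k_ctrl, n_ctrl)):
        if n < 1:
            raise ValueError("group sizes must be >= 1")
        if not 0 <= k <= n:
            raise ValueError(f"exceedance count {k} outside [0, {n}]")
    p_case = (k_case + 1.0) / (n_case + 2.0)
    p_ctrl = (k_ctrl + 1.0) / (n_ctrl + 2.0)
    p_pool = (k_case + k_ctrl + 1.0) / (n_case + n_ctrl + 2.0)
    raw = (
        _bernoulli_ll(k_case, n_case, p_case)
        + _bernoulli_ll(k_ctrl, n_ctrl, p_ctrl)
        - _bernoulli_ll(k_case, n_case, p_pool)
        - _bernoulli_ll(k_ctrl, n_ctrl, p_pool)
    )
    if p_case > p_ctrl:
        return abs(raw)
    if p_case < p_ctrl:
        return -abs(raw)
    return 0.0


def optimize_burden_threshold(burdens_case, burdens_ctrl) -> BurdenResult:
    """Scan all distinct positive observed burdens for the maximizing threshold.

    Only observed values can change the exceedance counts, so the scan over
    distinct positive burdens is equivalent to a scan over all real
    thresholds. Ties are broken toward the smallest (most inclusive)
    threshold. If no sample carries a positive burden the statistic is 0
    and the threshold undefined.
    """
    bc = np.asarray(burdens_case, dtype=float)
    bt = np.asarray(burdens_ctrl, dtype=float)
    if bc.size == 0 and bt.size == 0:
        raise ValueError("both case and control groups are empty")
    if not (np.all(np.isfinite(bc)) and np.all(np.isfinite(bt))):
        raise ValueError("burdens must be finite")
    n_case, n_ctrl = bc.size, bt.size
    candidates = np.unique(np.concatenate([bc, bt]))
    candidates = candidates[candidates > 0]
    if candidates.size == 0:
        p_case = 1.0 / (n_case + 2.0) if n_case else np.nan
        p_ctrl = 1.0 / (n_ctrl + 2.0) if n_ctrl else np.nan
        return BurdenResult(None, 0, 0, p_case, p_ctrl,
                            1.0 / (n_case + n_ctrl + 2.0), 0.0)
    best = None
    for t in candidates:  # ascending: on ties, the smallest T wins via strict >
        k_case = int((bc >= t).sum())
        k_ctrl = int((bt >= t).sum())
        llr = smoothed_bernoulli_llr(k_case, max(n_case, 1), k_ctrl, max(n_ctrl, 1))
        if best is None or llr > best.llr:
            best = BurdenResult(
                float(t), k_case, k_ctrl,
                (k_case + 1.0) / (n_case + 2.0),
                (k_ctrl + 1.0) / (n_ctrl + 2.0),
                (k_case + k_ctrl + 1.0) / (n_case + n_ctrl + 2.0),
                float(llr),
            )
    return best


def burden_llr_rows(burdens, label_rows):
    """Optimized burden statistic for many case/control label assignments.

    Vectorized engine used by the permutation test: every row of
    ``label_rows`` (boolean, True = case) is scored with the full
    threshold re-optimization. Returns ``(llr, threshold)`` arrays of
    length ``label_rows.shape[0]``; thresholds are NaN where no positive
    burden exists. Equivalent to calling :func:`optimize_burden_threshold`
    per row (cross-checked in the test suite).
    """
    b = np.asarray(burdens, dtype=float)
    labels = np.asarray(label_rows, dtype=bool)
    n_rows, n = labels.shape
    if b.size != n:
        raise ValueError("burden vector and label rows length mismatch")

    order = np.argsort(-b, kind="stable")
    bs = b[order]
    # candidate thresholds: last prefix index of each distinct positive value
    positive = bs > 0
    last_of_value = np.ones(n, dtype=bool)
    if n > 1:
        last_of_value[:-1] = bs[:-1] != bs[1:]
    cand = np.nonzero(positive & last_of_value)[0]
    if cand.size == 0:
        return np.zeros(n_rows), np.full(n_rows, np.nan)

    k_case = np.cumsum(labels[:, order], axis=1, dtype=np.int64)[:, cand]
    n_at = (cand + 1).astype(np.int64)
    k_ctrl = n_at[None, :] - k_case
    n_case = labels.sum(axis=1, dtype=np.int64)[:, None]
    n_ctrl = n - n_case

    p_case = (k_case + 1.0) / (n_case + 2.0)
    p_ctrl = (k_ctrl + 1.0) / (n_ctrl + 2.0)
    p_pool = (k_case + k_ctrl + 1.0) / (n + 2.0)
    raw = (
        _bernoulli_ll(k_case, n_case, p_case)
        + _bernoulli_ll(k_ctrl, n_ctrl, p_ctrl)
        - _bernoulli_ll(k_case, n_case, p_pool)
        - _bernoulli_ll(k_ctrl, n_ctrl, p_pool)
    )
    signed = np.sign(p_case - p_ctrl) * np.abs(raw)

    # max over thresholds; ties resolved toward the smallest threshold,
    # i.e. the last candidate column (candidates are in descending order)
    rev = signed[:, ::-1]
    best_rev = np.argmax(rev, axis=1)
    best_col = cand.size - 1 - best_rev
    llr = signed[np.arange(n_rows), best_col]
    thresholds = bs[cand][best_col]
    return llr, thresholds
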