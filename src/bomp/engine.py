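"""Hybrid test engine: statistic combination, permutation p-values, FDR.

The burden and position-distribution log-likelihood ratios are combined
into a single hybrid statistic (sum of the two log ratios by default; a
max rule is available, matching the "burden OR position" reading). P-values
for all three statistics come from one shared stream of case/control label
permutations: for every permutation the *full* pipeline — burden-threshold
optimization and per-gene segmentation selection — is re-run, and

    p = (r + 1) / (B + 1),   r = #{null statistics >= observed},

with ties counting toward r, so p always lies on the grid
{1/(B+1), ..., 1}. When sample strata are provided (e.g. ancestry groups),
labels are permuted only within each stratum, preserving the per-stratum
case counts in every draw.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .burden import burden_llr_rows
from .core import FunctionalGroup, GenotypeMatrix, SampleTable
from .position import DEFAULT_WS_PAIRS, GenePositionPlan
from .weights import WeightConfig, variant_weights

logger = logging.getLogger(__name__)

__all__ = ["BompConfig", "BompResult", "bomp_statistic", "permutation_test", "bh_adjust"]

COMBINE_RULES = ("sum", "max")


@dataclass
class BompConfig:
    """Run configuration for the hybrid test.

    permutations
        Number of label permutations B (default 10,000).
    combine_rule
        ``sum`` (default) adds the two log-likelihood ratios; ``max`` takes
        the larger.
    count_mode
        ``mutations`` counts every allele copy per window; ``positions``
        counts distinct mutated codons per group.
    ws_pairs
        (window size, shift increment) grid for segmentation enumeration.
    weights
        Per-variant weighting and genetic model (burden statistic only).
    stratified
        Permute labels within sample strata when True.
    """

    permutations: int = 10_000
    combine_rule: str = "sum"
    count_mode: str = "mutations"
    ws_pairs: tuple = DEFAULT_WS_PAIRS
    weights: WeightConfig = field(default_factory=WeightConfig)
    stratified: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.combine_rule not in COMBINE_RULES:
            raise ValueError(f"combine_rule must be one of {COMBINE_RULES}")
        if self.permutations < 1:
            raise ValueError("permutations must be >= 1")


@dataclass
class BompResult:
    """Hybrid-test outcome for one functional group."""

    group: str
    llr_burden: float
    llr_position: float
    llr_combined: float
    p_burden: float
    p_position: float
    p_combined: float
    n_permutations: int
    burden_threshold: float | None
    segmentations: dict
    n_genes: int = 0
    n_variants: int = 0


def bomp_statistic(llr_burden, llr_position, combine_rule="sum"):
    """Combine the burden and position log-likelihood ratios."""
    if combine_rule == "sum":
        return llr_burden + llr_position
    if combine_rule == "max":
        return np.maximum(llr_burden, llr_position)
    raise ValueError(f"combine_rule must be one of {COMBINE_RULES}")


def _permuted_labels(status, strata, n_perm, rng):
    """(B+1) x n boolean label matrix; row 0 is the observed assignment.

    Permutations are uniform within strata and preserve the per-stratum
    case counts exactly.
    """
    n = status.size
    labels = np.tile(status, (n_perm + 1, 1))
    if strata is None:
        rng.permuted(labels[1:], axis=1, out=labels[1:])
        return labels
    for value in np.unique(strata):
        block = np.nonzero(strata == value)[0]
        k = int(status[block].sum())
        if k == 0 or k == block.size:
            warnings.warn(
                f"stratum {value!r} is all-case or all-control; it contributes "
                "no permutation variability",
                stacklevel=3,
            )
        sub = labels[1:, block]
        rng.permuted(sub, axis=1, out=sub)
        labels[1:, block] = sub
    return labels


def _gene_codon_dosage(gm: GenotypeMatrix, gene):
    """Collapse a gene's variant columns to its distinct mutated codons.

    Returns (codon_positions, samples x codons dosage matrix). Codons with
    no observed alternate allele in the study are dropped; they carry zero
    counts and cannot affect any statistic.
    """
    idx = gene.variant_indices
    if idx.size == 0:
        return np.empty(0, dtype=int), np.empty((gm.n_samples, 0))
    codons = np.array([gm.variants[j].codon_index for j in idx], dtype=int)
    uniq, inverse = np.unique(codons, return_inverse=True)
    dosage = np.zeros((uniq.size, gm.n_samples))
    np.add.at(dosage, inverse, gm.values[:, idx].T.astype(float))
    dosage = dosage.T
    observed = dosage.sum(axis=0) > 0
    return uniq[observed], dosage[:, observed]


def permutation_test(
    gm: GenotypeMatrix,
    samples: SampleTable,
    group: FunctionalGroup,
    config: BompConfig | None = None,
    B: int | None = None,
    seed=None,
    rng: np.random.Generator | None = None,
) -> BompResult:
    """Hybrid likelihood test of one functional group with permutation p-values.

    ``seed`` (or an explicit ``rng``) controls the permutation stream; the
    same seed and inputs give a bit-identical result. All three statistics
    (burden, position, combined) are scored against the same permutations.
    """
    config = config or BompConfig()
    B = int(B if B is not None else config.permutations)
    if B < 1:
        raise ValueError("number of permutations must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    if list(samples.samples) != list(gm.samples):
        raise ValueError("sample table and genotype matrix sample order differ")
    if not group.genes:
        raise ValueError(f"group {group.name} has no genes")

    status = samples.status
    strata = samples.stratum if config.stratified else None
    if config.stratified and samples.stratum is None:
        raise ValueError("stratified permutation requested but no strata given")
    labels = _permuted_labels(status, strata, B, rng)

    # ---- burden statistic (weights are label-invariant: the allele-frequency
    # estimate uses pooled counts, so per-sample burdens are computed once) ----
    idx = group.variant_indices
    counts = gm.column_allele_counts()[idx] if idx.size else np.empty(0)
    scores = gm.scores()[idx] if idx.size else np.empty(0)
    w = variant_weights(counts, gm.n_samples, scores, config.weights)
    if config.weights.genetic_model == "dominant":
        geff = (gm.values[:, idx] >= 1).astype(float)
    else:
        geff = gm.values[:, idx].astype(float)
    burdens = geff @ w if idx.size else np.zeros(gm.n_samples)
    llr_b, thresholds = burden_llr_rows(burdens, labels)

    # ---- position statistic: per-gene best segmentation, summed over genes ----
    plans, dosages, spans = [], [], []
    for gene in group.genes:
        pos, dose = _gene_codon_dosage(gm, gene)
        plans.append(GenePositionPlan(gene.length_codons, pos, config.ws_pairs))
        dosages.append(dose)
        spans.append(dose.shape[1])
    llr_p = np.zeros(labels.shape[0])
    chosen = {}
    if sum(spans):
        dose_all = np.concatenate([d for d in dosages if d.shape[1]], axis=1)
        case_dose = labels.astype(float) @ dose_all
        total_dose = dose_all.sum(axis=0)
        positions_mode = config.count_mode == "positions"
        if positions_mode:
            ctrl_dose = total_dose[None, :] - case_dose
            case_cnt = (case_dose > 0).astype(np.int64)
            ctrl_cnt = (ctrl_dose > 0).astype(np.int64)
        else:
            case_cnt, ctrl_cnt = case_dose, None
        offset = 0
        for gene, plan, span in zip(group.genes, plans, spans):
            if span == 0:
                continue
            sl = slice(offset, offset + span)
            if positions_mode:
                best, arg = plan.best_rows(case_cnt[:, sl], ctrl_cnt[:, sl])
            else:
                best, arg = plan.best_rows(case_cnt[:, sl],
                                           total_counts=total_dose[sl])
            llr_p += best
            chosen[gene.gene] = plan.segmentations[int(arg[0])]
            offset += span

    llr_c = bomp_statistic(llr_b, llr_p, config.combine_rule)

    def pval(stat_rows):
        r = int(np.sum(stat_rows[1:] >= stat_rows[0]))
        return (r + 1.0) / (B + 1.0)

    thr = thresholds[0]
    return BompResult(
        group=group.name,
        llr_burden=float(llr_b[0]),
        llr_position=float(llr_p[0]),
        llr_combined=float(llr_c[0]),
        p_burden=pval(llr_b),
        p_position=pval(llr_p),
        p_combined=pval(llr_c),
        n_permutations=B,
        burden_threshold=None if np.isnan(thr) else float(thr),
        segmentations=chosen,
        n_genes=len(group.genes),
        n_variants=int(idx.size),
    )


def bh_adjust(p_values):
    """Benjamini-Hochberg step-up FDR adjustment.

    Returns adjusted values in the input order: adjusted(i) is the minimum
    over j >= i (in sorted order) of p(j) * m / j, capped at 1.
    """
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise ValueError("need a non-empty 1-D vector of p-values")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
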