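"""Per-variant weights and genetic models.

The burden statistic can upweight variants by (estimated) rarity, by a
bioinformatics impact score in [0, 1], or by the product of the two. The
allele-frequency weight follows the Madsen-Browning convention: the weight
is the reciprocal of the binomial standard deviation of the allele count,
``1 / sqrt(2 N q (1 - q))``, evaluated at a beta-smoothed frequency
estimate so that unobserved and fully observed alleles stay inside (0, 1).

Weights enter the burden statistic only; the position-distribution
statistic always uses unweighted mutation counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WeightConfig",
    "estimate_allele_frequency",
    "af_weight",
    "effective_genotype_score",
    "variant_weights",
]

WEIGHT_MODES = ("none", "af", "score", "product")
GENETIC_MODELS = ("additive", "dominant")


@dataclass
class WeightConfig:
    """Weighting and genetic-model configuration.

    mode
        ``none`` (raw counts), ``af`` (allele-frequency weight), ``score``
        (bioinformatics score), or ``product`` (af weight x score).
    genetic_model
        ``additive`` (each allele copy contributes) or ``dominant``
        (heterozygotes and homozygotes contribute equally).
    beta_prior
        (alpha, beta) pseudocounts of the beta prior used when estimating
        allele frequencies; default Beta(1, 1).
    """

    mode: str = "none"
    genetic_model: str = "additive"
    beta_prior: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        if self.mode not in WEIGHT_MODES:
            raise ValueError(f"mode must be one of {WEIGHT_MODES}, got {self.mode!r}")
        if self.genetic_model not in GENETIC_MODELS:
            raise ValueError(
                f"genetic_model must be one of {GENETIC_MODELS}, "
                f"got {self.genetic_model!r}"
            )
        a, b = self.beta_prior
        if a <= 0 or b <= 0:
            raise ValueError("beta prior pseudocounts must be positive")


def estimate_allele_frequency(a_case, a_ctrl, n_samples, prior=(1.0, 1.0)):
    """Beta-smoothed estimate of a variant's population allele frequency.

    q_hat = (a_case + a_ctrl + alpha) / (2 N + alpha + beta), where N is the
    total number of individuals (cases plus controls) and (alpha, beta) are
    beta-prior pseudocounts. Always strictly inside (0, 1).
    """
    n_samples = np.asarray(n_samples)
    if np.any(n_samples <= 0):
        raise ValueError("n_samples must be >= 1")
    a, b = prior
    if a <= 0 or b <= 0:
        raise ValueError("beta prior pseudocounts must be positive")
    total = np.asarray(a_case, dtype=float) + np.asarray(a_ctrl, dtype=float)
    if np.any(total < 0):
        raise ValueError("allele counts must be non-negative")
    return (total + a) / (2.0 * n_samples + a + b)


def af_weight(q_hat, n_samples):
    """Madsen-Browning allele-frequency weight 1 / sqrt(2 N q (1 - q)).

    Strictly decreasing in q_hat on (0, 0.5], so rarer variants receive
    larger weight.
    """
    q = np.asarray(q_hat, dtype=float)
    if np.any((q <= 0) | (q >= 1)):
        raise ValueError("q_hat must lie strictly inside (0, 1)")
    return 1.0 / np.sqrt(2.0 * np.asarray(n_samples, dtype=float) * q * (1.0 - q))


def effective_genotype_score(g, score, genetic_model="additive"):
    """Contribution of one genotype to an individual burden.

    Additive: ``g * score`` (homozygotes count twice). Dominant:
    ``score`` whenever at least one alternate allele is carried.
    """
    g_arr = np.asarray(g)
    if np.any((g_arr < 0) | (g_arr > 2)):
        raise ValueError("genotype values must lie in {0, 1, 2}")
    if genetic_model == "additive":
        return g_arr * np.asarray(score, dtype=float)
    if genetic_model == "dominant":
        return (g_arr >= 1) * np.asarray(score, dtype=float)
    raise ValueError(f"unknown genetic model {genetic_model!r}")


def variant_weights(total_allele_counts, n_samples, scores=None, config=None):
    """Weight vector for a set of variants under a :class:`WeightConfig`.

    ``total_allele_counts`` are case+control alternate-allele counts (the
    allele-frequency estimate uses the pooled count, so weights are
    invariant under case/control label permutation). Missing scores
    (``None``/NaN) default to 1.0 when a score-based mode is requested.
    """
    config = config or WeightConfig()
    counts = np.asarray(total_allele_counts, dtype=float)
    if config.mode == "none":
        return np.ones_like(counts)
    w = np.ones_like(counts)
    if config.mode in ("af", "product"):
        q = estimate_allele_frequency(counts, 0.0, n_samples, config.beta_prior)
        w = w * af_weight(q, n_samples)
    if config.mode in ("score", "product"):
        if scores is None:
            s = np.ones_like(counts)
        else:
            s = np.asarray(scores, dtype=float).copy()
            s[np.isnan(s)] = 1.0
        if np.any((s < 0) | (s > 1)):
            raise ValueError("bioinformatics scores must lie in [0, 1]")
        w = w * s
    return w
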