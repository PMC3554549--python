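"""Orchestration: file-based association runs and simulation-based power.

`run_association` is the end-to-end path behind the command line: load
VCF + gene models + gene sets + phenotypes (+ optional scores), test every
functional group with the hybrid permutation test, and emit one result row
per group with a Benjamini-Hochberg FDR across the tested groups.

`estimate_power` repeatedly simulates case-control studies under a
scenario (each replicate with an independently derived seed), runs the
full test on each, and reports the fraction of replicates whose combined
p-value reaches the significance level.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import io as bio
from .engine import BompConfig, BompResult, bh_adjust, permutation_test
from .simulate import (
    AA_LIKE,
    CATEGORY_10_1_1_SAMPLER,
    Scenario,
    simulate_study,
)
from .weights import WeightConfig

logger = logging.getLogger(__name__)

__all__ = [
    "PowerEstimate",
    "estimate_power",
    "run_association",
    "rare_single_gene_scenario",
    "candidate_gene_set_scenario",
    "null_scenario",
    "SIM_CONFIG",
]

#: Test configuration used for all simulation studies: allele-frequency
#: weighting under the additive genetic model.
SIM_CONFIG = BompConfig(weights=WeightConfig(mode="af", genetic_model="additive"))


def rare_single_gene_scenario(n_case=1000, n_ctrl=1000, population=100_000,
                              afs=AA_LIKE) -> Scenario:
    """Single 500-codon candidate gene under the rare-deleterious etiology.

    The population is sized so the 1%-prevalence affected pool can supply
    the requested cases (100,000 individuals for a 1000-case draw).
    """
    return Scenario(
        name="rare_single_gene", afs=afs, population=population,
        n_case=n_case, n_ctrl=n_ctrl, n_genes=1, n_causal=1, etiology="rare",
    )


def candidate_gene_set_scenario(n_genes=100, n_causal=25, n_case=100, n_ctrl=100,
                                population=20_000, afs=AA_LIKE,
                                sampler=CATEGORY_10_1_1_SAMPLER) -> Scenario:
    """Large candidate gene set with mixed etiologies.

    Defaults give the 100-gene, 200-individual design with a 1:3 causal to
    non-causal gene ratio; causal etiologies are drawn 10:1:1 from
    {rare / low-frequency / key-region} : {common} : {protective-containing},
    uniformly within each category.
    """
    return Scenario(
        name="candidate_gene_set", afs=afs, population=population,
        n_case=n_case, n_ctrl=n_ctrl, n_genes=n_genes, n_causal=n_causal,
        etiology_sampler=sampler,
    )


def null_scenario(n_case=100, n_ctrl=100, population=10_000, n_genes=1,
                  afs=AA_LIKE) -> Scenario:
    """No-etiology scenario: the trait is standard normal for everyone."""
    return Scenario(
        name="null_study", afs=afs, population=population,
        n_case=n_case, n_ctrl=n_ctrl, n_genes=n_genes, n_causal=0,
        etiology="null",
    )


@dataclass
class PowerEstimate:
    """Monte-Carlo power estimate with its binomial standard error."""

    scenario: str
    n_replicates: int
    alpha: float
    power: float
    se: float
    p_values: np.ndarray

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (f"{self.scenario}: power {self.power:.3f} +/- {self.se:.3f} "
                f"at alpha {self.alpha} ({self.n_replicates} replicates)")


def estimate_power(scenario: Scenario, n_replicates, alpha=0.05, B=199,
                   seed=0, config: BompConfig | None = None) -> PowerEstimate:
    """Rejection rate of the hybrid test over simulated case-control studies.

    Each replicate derives its own random stream from ``seed``, simulates
    one study under the scenario, runs the full permutation test with B
    permutations, and records the combined p-value. Identical seed and
    scenario give an identical estimate.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    config = config or SIM_CONFIG
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    pvals = np.empty(n_replicates)
    t0 = time.time()
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        study = simulate_study(scenario, rng)
        res = permutation_test(study.genotypes, study.samples, study.group,
                               config, B=B, rng=rng)
        pvals[r] = res.p_combined
    power = float(np.mean(pvals <= alpha))
    se = float(np.sqrt(power * (1 - power) / n_replicates))
    logger.info("%s: %d replicates in %.1f s, power %.3f",
                scenario.name, n_replicates, time.time() - t0, power)
    return PowerEstimate(scenario.name, n_replicates, alpha, power, se, pvals)


def run_association(vcf, genes=None, sets=None, pheno=None, scores=None,
                    config: BompConfig | None = None, out=None,
                    seed=None) -> pd.DataFrame:
    """Test every functional group in a study and adjust across groups.

    Returns (and optionally writes) one row per group: the three
    log-likelihood ratios, their permutation p-values, the BH FDR over the
    tested groups' combined p-values, and the optimized burden threshold.
    Gene-set genes that resolve to no gene model and no variants are kept
    with empty variant lists and logged.
    """
    config = config or BompConfig()
    t0 = time.time()
    samples = bio.read_phenotypes(pheno)
    gene_models = bio.read_gene_models(genes) if genes else None
    score_map = bio.read_scores(scores) if scores else None
    gm = bio.read_vcf_genotypes(vcf, samples, gene_models, score_map)

    if sets:
        gene_sets = bio.read_gene_sets(sets)
    else:
        # no GMT: test each gene with loaded variants as its own group
        seen = sorted({v.gene for v in gm.variants})
        gene_sets = [(g, "single gene", [g]) for g in seen]
    groups = bio.build_groups(gene_sets, gm, gene_models)
    groups = [g for g in groups if g.genes]
    if not groups:
        raise ValueError("no resolvable functional group to test")

    rng = np.random.default_rng(config.seed if seed is None else seed)
    results: list[BompResult] = []
    for group in groups:
        results.append(permutation_test(gm, samples, group, config, rng=rng))
    fdr = bh_adjust([r.p_combined for r in results])
    logger.info(
        "tested %d groups (%d samples, %d variants) in %.1f s",
        len(groups), gm.n_samples, gm.n_variants, time.time() - t0,
    )
    if out:
        bio.write_results_tsv(results, fdr, out)
    frame = pd.DataFrame(
        {
            "group": [r.group for r in results],
            "n_genes": [r.n_genes for r in results],
            "n_variants": [r.n_variants for r in results],
            "llr_burden": [r.llr_burden for r in results],
            "llr_position": [r.llr_position for r in results],
            "llr_combined": [r.llr_combined for r in results],
            "p_burden": [r.p_burden for r in results],
            "p_position": [r.p_position for r in results],
            "p_combined": [r.p_combined for r in results],
            "fdr": fdr,
            "burden_threshold": [r.burden_threshold for r in results],
        }
    )
    return frame
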