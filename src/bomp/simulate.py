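"""Synthetic populations, disease etiologies, and extreme-phenotype studies.

The generator emulates the conditions of etiology-driven case-control
power studies without forward-in-time population simulation: per-site
minor allele frequencies are drawn from a mixture over frequency bands
(an ``AA-like`` model with a wide rare/low-frequency/common spectrum, and
an ``EA-like`` model consisting almost entirely of rare variants),
genotypes are Binomial(2, MAF) at linkage equilibrium, and a Gaussian
liability trait is built by shifting each individual's mean by the summed
per-variant effects of the causal variants it carries:

    phi ~ Normal( sum_j g_j * effect_j , 1 ),

so carriers of no causal variant draw from a standard normal. Case-control
studies use an extreme-phenotype design: the top ``prevalence`` fraction
(default 1%) of the population by trait is the affected pool and the
bottom ``control_tail`` fraction (default 25%) the unaffected pool; cases
and controls are sampled from those pools without replacement and
intermediate individuals are never selected.

Eight disease etiologies parameterize which variants are causal: rare
(MAF < 0.01), low-frequency (0.01-0.05), key-region (rare variants
confined to designated gene segments), common (one causal variant with
MAF > 0.05), and the same four with protective modifier variants added.
A ``null_fraction`` of qualifying variants is randomly assigned zero
effect, so that e.g. all causal variants are rare but not all rare
variants are causal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .core import FunctionalGroup, GeneMembers, GenotypeMatrix, SampleTable, VariantRecord

logger = logging.getLogger(__name__)

__all__ = [
    "AfsComponent",
    "AfsModel",
    "AA_LIKE",
    "EA_LIKE",
    "EtiologyConfig",
    "ETIOLOGIES",
    "EtiologySampler",
    "MIXED_RARE_SAMPLER",
    "CATEGORY_10_1_1_SAMPLER",
    "GeneLayout",
    "Population",
    "SimulatedStudy",
    "Scenario",
    "sample_site_frequencies",
    "simulate_genotypes",
    "assign_causal_effects",
    "simulate_trait",
    "draw_case_control_study",
    "build_gene_set_population",
    "simulate_study",
    "export_study",
]


# --------------------------------------------------------------------------
# allele-frequency spectra
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AfsComponent:
    """One mixture component: with probability ``weight`` a site's MAF is
    log-uniform on [lo, hi)."""

    weight: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi <= 0.5):
            raise ValueError(f"MAF band ({self.lo}, {self.hi}) must lie in (0, 0.5]")
        if self.weight < 0:
            raise ValueError("component weight must be non-negative")


@dataclass(frozen=True)
class AfsModel:
    """Site-frequency-spectrum model for one simulated population.

    ``sites_per_gene`` is the number of segregating sites placed on a
    default-length gene; genes of other lengths get a proportional count.
    """

    name: str
    components: tuple[AfsComponent, ...]
    sites_per_gene: int = 150
    gene_length_codons: int = 500

    def __post_init__(self) -> None:
        total = sum(c.weight for c in self.components)
        if not self.components or abs(total - 1.0) > 1e-9:
            raise ValueError("component weights must sum to 1")
        if self.sites_per_gene < 1 or self.gene_length_codons < 1:
            raise ValueError("sites_per_gene and gene_length_codons must be >= 1")


#: Wide spectrum with rare, low-frequency and common mass.
AA_LIKE = AfsModel(
    "AA-like",
    (
        AfsComponent(0.60, 1e-4, 0.01),
        AfsComponent(0.25, 0.01, 0.05),
        AfsComponent(0.15, 0.05, 0.5),
    ),
)

#: Almost entirely rare variants; >= 90% of sites below MAF 0.001.
EA_LIKE = AfsModel(
    "EA-like",
    (
        AfsComponent(0.95, 1e-4, 1e-3),
        AfsComponent(0.05, 1e-3, 0.01),
    ),
)


def sample_site_frequencies(afs_model, n_sites, rng):
    """Draw per-site minor allele frequencies from the configured mixture."""
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(rng)
    weights = np.array([c.weight for c in afs_model.components])
    comp = rng.choice(len(weights), size=n_sites, p=weights)
    lo = np.array([c.lo for c in afs_model.components])[comp]
    hi = np.array([c.hi for c in afs_model.components])[comp]
    u = rng.random(n_sites)
    return np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo)))


def simulate_genotypes(maf_vector, n_individuals, rng):
    """Genotypes ~ Binomial(2, MAF), independent across sites and individuals.

    Sampled as two independent haplotype draws per site (each allele
    present with probability MAF), processed in column chunks to bound
    memory for large populations.
    """
    if n_individuals < 2:
        raise ValueError("n_individuals must be >= 2")
    maf = np.asarray(maf_vector, dtype=float)
    if np.any((maf <= 0) | (maf > 0.5)):
        raise ValueError("MAFs must lie in (0, 0.5]")
    rng = np.random.default_rng(rng)
    out = np.empty((n_individuals, maf.size), dtype=np.int8)
    chunk = max(1, int(8_000_000 // max(n_individuals, 1)))
    for start in range(0, maf.size, chunk):
        p = maf[start:start + chunk]
        shape = (n_individuals, p.size)
        hap = (rng.random(shape) < p).astype(np.int8)
        hap += rng.random(shape) < p
        out[:, start:start + chunk] = hap
    return out


# --------------------------------------------------------------------------
# disease etiologies
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EtiologyConfig:
    """Causal-variant rules of one simulated disease model.

    ``causal_maf_range`` is half-open [lo, hi). ``effect_deleterious`` is
    the per-allele-copy mean trait shift of a causal variant; a
    ``null_fraction`` of qualifying variants is assigned zero effect.
    ``single_causal`` restricts the etiology to one causal variant (the
    common-variant model). Key-region genes consist of ``n_segments``
    segments of ``segment_length`` codons, with causal variants confined
    to ``n_key_segments`` randomly designated segments. Protective models
    additionally give a ``protective_fraction`` of the remaining variants
    below ``protective_maf_max`` a negative effect.
    """

    name: str
    causal_maf_range: tuple[float, float] = (0.0, 0.01)
    effect_deleterious: float = 0.5
    null_fraction: float = 0.25
    single_causal: bool = False
    key_region: bool = False
    n_segments: int = 100
    segment_length: int = 10
    n_key_segments: int = 10
    protective: bool = False
    effect_protective: float = -0.5
    protective_maf_max: float = 0.05
    protective_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.name != "null" and self.effect_deleterious <= 0:
            raise ValueError("deleterious effect size must be positive")
        if self.protective and self.effect_protective >= 0:
            raise ValueError("protective effect size must be negative")
        if not 0 <= self.null_fraction <= 1:
            raise ValueError("null_fraction must lie in [0, 1]")

    @property
    def gene_length_codons(self) -> int | None:
        """Key-region genes have a fixed layout; others follow the AFS model."""
        if self.key_region:
            return self.n_segments * self.segment_length
        return None


def _base_etiologies():
    rare = EtiologyConfig("rare", (0.0, 0.01), 0.5)
    low = EtiologyConfig("low_frequency", (0.01, 0.05), 0.25)
    key = EtiologyConfig("key_region", (0.0, 0.01), 1.0, key_region=True)
    common = EtiologyConfig("common", (0.05, 0.5000001), 0.25, single_causal=True)
    out = {e.name: e for e in (rare, low, key, common)}
    for base in (rare, low, key, common):
        out[base.name + "_protect"] = replace(
            base, name=base.name + "_protect", protective=True
        )
    out["null"] = EtiologyConfig("null", (0.0, 0.0), 1.0, null_fraction=1.0)
    return out


#: The eight disease etiologies plus the "null" (no-effect) model.
ETIOLOGIES: dict[str, EtiologyConfig] = _base_etiologies()


def assign_causal_effects(mafs, codon_positions, etiology, rng, key_segments=None):
    """Per-variant trait effects under an etiology's causality rules.

    Variants with MAF inside the etiology's causal range (and, for
    key-region models, inside the designated segments) qualify; a
    ``null_fraction`` of qualifying variants get effect zero and the rest
    the deleterious effect. For single-causal (common-variant) models one
    qualifying variant is chosen uniformly. Protective models then assign
    the protective effect to a fraction of the non-qualifying variants
    below ``protective_maf_max``.
    """
    if isinstance(etiology, str):
        etiology = ETIOLOGIES[etiology]
    rng = np.random.default_rng(rng)
    maf = np.asarray(mafs, dtype=float)
    pos = np.asarray(codon_positions, dtype=int)
    effects = np.zeros(maf.size)
    if etiology.name == "null":
        return effects

    lo, hi = etiology.causal_maf_range
    eligible = (maf >= lo) & (maf < hi)
    if etiology.key_region:
        if key_segments is None:
            raise ValueError("key-region etiology requires designated segments")
        seg_of = pos // etiology.segment_length
        eligible &= np.isin(seg_of, np.asarray(key_segments))
    idx = np.nonzero(eligible)[0]
    if idx.size == 0:
        warnings.warn(
            f"etiology {etiology.name!r}: no variant qualifies; all effects zero",
            stacklevel=2,
        )
    elif etiology.single_causal:
        effects[rng.choice(idx)] = etiology.effect_deleterious
    else:
        nulled = rng.random(idx.size) < etiology.null_fraction
        effects[idx[~nulled]] = etiology.effect_deleterious

    if etiology.protective:
        cand = np.nonzero(~eligible & (maf < etiology.protective_maf_max))[0]
        if cand.size:
            chosen = cand[rng.random(cand.size) < etiology.protective_fraction]
            effects[chosen] = etiology.effect_protective
    return effects


def simulate_trait(genotypes, effect_vector, rng):
    """Gaussian liability trait with per-variant mean shifts.

    ``phi ~ Normal(sum_j g_j effect_j, 1)`` per individual; with an
    all-zero effect vector every individual draws from a standard normal.
    """
    rng = np.random.default_rng(rng)
    g = np.atleast_2d(np.asarray(genotypes, dtype=float))
    eff = np.asarray(effect_vector, dtype=float)
    if not np.all(np.isfinite(eff)):
        raise ValueError("effects must be finite")
    mean = g @ eff
    phi = mean + rng.standard_normal(mean.size)
    return phi if np.asarray(genotypes).ndim == 2 else float(phi[0])


# --------------------------------------------------------------------------
# gene layouts, populations, studies
# --------------------------------------------------------------------------

@dataclass
class GeneLayout:
    """One simulated gene: site positions, frequencies and true effects."""

    name: str
    length_codons: int
    codon_positions: np.ndarray
    mafs: np.ndarray
    effects: np.ndarray
    etiology: str
    key_segments: np.ndarray | None = None


@dataclass
class Population:
    """An explicit simulated population: genotypes at every site plus traits."""

    genotypes: np.ndarray  # (n_individuals, total sites) int8
    traits: np.ndarray
    layouts: list[GeneLayout]

    @property
    def effects(self) -> np.ndarray:
        return np.concatenate([g.effects for g in self.layouts])


@dataclass
class SimulatedStudy:
    """A drawn case-control study, ready for the association engine."""

    genotypes: GenotypeMatrix
    samples: SampleTable
    group: FunctionalGroup
    effects: np.ndarray
    traits: np.ndarray
    monomorphic: np.ndarray
    layouts: list[GeneLayout]


@dataclass(frozen=True)
class EtiologySampler:
    """Draws an etiology name from weighted categories (uniform within each)."""

    categories: tuple[tuple[float, tuple[str, ...]], ...]

    def draw(self, rng) -> str:
        rng = np.random.default_rng(rng)
        weights = np.array([w for w, _ in self.categories], dtype=float)
        cat = rng.choice(len(weights), p=weights / weights.sum())
        names = self.categories[cat][1]
        return names[rng.integers(len(names))]


#: Equal mix of the three etiologies dominated by rare variants.
MIXED_RARE_SAMPLER = EtiologySampler(
    ((1.0, ("rare", "low_frequency", "key_region")),)
)

#: 10 : 1 : 1 over {rare / low-frequency / key-region} : {common} :
#: {protective-containing}, uniform within each category.
CATEGORY_10_1_1_SAMPLER = EtiologySampler(
    (
        (10.0, ("rare", "low_frequency", "key_region")),
        (1.0, ("common",)),
        (1.0, ("rare_protect", "low_frequency_protect",
               "key_region_protect", "common_protect")),
    )
)


@dataclass
class Scenario:
    """A complete simulation scenario: population, genes, etiologies, design."""

    name: str = "scenario"
    afs: AfsModel = AA_LIKE
    population: int = 50_000
    n_case: int = 100
    n_ctrl: int = 100
    prevalence: float = 0.01
    control_tail: float = 0.25
    n_genes: int = 1
    n_causal: int = 1
    etiology: str = "rare"
    etiology_sampler: EtiologySampler | None = None

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1 or not 0 < self.control_tail < 1:
            raise ValueError("prevalence and control_tail must lie in (0, 1)")
        if self.n_causal > self.n_genes:
            raise ValueError("n_causal cannot exceed n_genes")


def _build_layouts(scenario: Scenario, rng) -> list[GeneLayout]:
    """Sample gene layouts (sites, frequencies, effects) for a scenario."""
    causal = np.zeros(scenario.n_genes, dtype=bool)
    if scenario.n_causal:
        causal[rng.choice(scenario.n_genes, scenario.n_causal, replace=False)] = True
    layouts = []
    afs = scenario.afs
    for g in range(scenario.n_genes):
        if causal[g]:
            name = (
                scenario.etiology_sampler.draw(rng)
                if scenario.etiology_sampler is not None
                else scenario.etiology
            )
        else:
            name = "null"
        et = ETIOLOGIES[name]
        length = et.gene_length_codons or afs.gene_length_codons
        n_sites = min(length, max(1, round(afs.sites_per_gene * length
                                           / afs.gene_length_codons)))
        mafs = sample_site_frequencies(afs, n_sites, rng)
        positions = np.sort(rng.choice(length, size=n_sites, replace=False))
        key_segments = None
        if et.key_region:
            key_segments = np.sort(rng.choice(et.n_segments, et.n_key_segments,
                                              replace=False))
        effects = assign_causal_effects(mafs, positions, et, rng, key_segments)
        layouts.append(GeneLayout(f"gene{g + 1:03d}", length, positions, mafs,
                                  effects, name, key_segments))
    return layouts


def build_gene_set_population(scenario: Scenario, rng) -> Population:
    """Explicitly materialize a population: all genotypes, effects, traits.

    Per-gene genotype blocks are independent and concatenated per
    individual; the trait is generated from the union of all causal
    effects. Suitable for small populations; the power path uses
    :func:`simulate_study`, which draws non-causal genotypes only for the
    sampled study individuals.
    """
    if scenario.n_genes < 1:
        raise ValueError("scenario must contain at least one gene")
    rng = np.random.default_rng(rng)
    layouts = _build_layouts(scenario, rng)
    blocks = [simulate_genotypes(g.mafs, scenario.population, rng) for g in layouts]
    genotypes = np.concatenate(blocks, axis=1)
    effects = np.concatenate([g.effects for g in layouts])
    traits = simulate_trait(genotypes, effects, rng)
    return Population(genotypes, traits, layouts)


def _extreme_pools(traits, prevalence, control_tail):
    n = traits.size
    n_affected = int(n * prevalence)
    n_unaffected = int(n * control_tail)
    order = np.argsort(traits, kind="stable")
    return order[::-1][:n_affected], order[:n_unaffected]


def draw_case_control_study(
    population: Population,
    n_case,
    n_ctrl,
    prevalence=0.01,
    control_tail=0.25,
    rng=None,
    group_name="gene_set",
) -> SimulatedStudy:
    """Extreme-phenotype sampling of a case-control study from a population.

    The top ``prevalence`` fraction of individuals by trait form the
    affected pool and the bottom ``control_tail`` fraction the unaffected
    pool; cases and controls are sampled without replacement from their
    pools. Sites monomorphic within the study are retained but flagged.
    """
    rng = np.random.default_rng(rng)
    affected, unaffected = _extreme_pools(population.traits, prevalence, control_tail)
    if affected.size < n_case:
        raise ValueError(
            f"affected pool has {affected.size} individuals, cannot draw {n_case} cases"
        )
    if unaffected.size < n_ctrl:
        raise ValueError(
            f"unaffected pool has {unaffected.size} individuals, "
            f"cannot draw {n_ctrl} controls"
        )
    case_idx = rng.choice(affected, n_case, replace=False)
    ctrl_idx = rng.choice(unaffected, n_ctrl, replace=False)
    rows = np.concatenate([case_idx, ctrl_idx])
    values = population.genotypes[rows]
    traits = population.traits[rows]
    status = np.concatenate([np.ones(n_case, bool), np.zeros(n_ctrl, bool)])
    return _assemble_study(values, status, traits, population.layouts, group_name)


def _assemble_study(values, status, traits, layouts, group_name) -> SimulatedStudy:
    n = values.shape[0]
    names = [f"{'case' if s else 'ctrl'}{i + 1:05d}" for i, s in enumerate(status)]
    samples = SampleTable(names, status)
    case_counts = values[status].sum(axis=0)
    ctrl_counts = values[~status].sum(axis=0)
    variants, members, col = [], [], 0
    for layout in layouts:
        idx = []
        for j, codon in enumerate(layout.codon_positions):
            variants.append(
                VariantRecord(
                    id=f"{layout.name}:{int(codon) * 3 + 1}",
                    gene=layout.name,
                    codon_index=int(codon),
                    case_allele_count=int(case_counts[col]),
                    control_allele_count=int(ctrl_counts[col]),
                )
            )
            idx.append(col)
            col += 1
        members.append(GeneMembers(layout.name, layout.length_codons,
                                   np.asarray(idx, dtype=int)))
    gm = GenotypeMatrix(names, variants, values)
    group = FunctionalGroup(group_name, members)
    mono = gm.column_allele_counts() == 0
    effects = np.concatenate([g.effects for g in layouts])
    return SimulatedStudy(gm, samples, group, effects, traits, mono, layouts)


def simulate_study(scenario: Scenario, rng, group_name=None) -> SimulatedStudy:
    """Draw one case-control study under a scenario (power-path sampler).

    Traits depend only on causal-site genotypes and sites are independent,
    so population genotypes are materialized at causal sites only; after
    the extreme-phenotype draw, non-causal genotypes are sampled just for
    the selected study individuals. This is distributionally exact under
    the generator's linkage-equilibrium assumption and makes large
    populations affordable.
    """
    rng = np.random.default_rng(rng)
    layouts = _build_layouts(scenario, rng)
    pop = scenario.population
    causal_cols = [np.nonzero(g.effects != 0)[0] for g in layouts]
    causal_effects = np.concatenate(
        [g.effects[c] for g, c in zip(layouts, causal_cols)]
    )
    if causal_effects.size:
        causal_mafs = np.concatenate(
            [g.mafs[c] for g, c in zip(layouts, causal_cols)]
        )
        pop_causal = simulate_genotypes(causal_mafs, pop, rng)
        mean = pop_causal.astype(np.float32) @ causal_effects.astype(np.float32)
    else:
        pop_causal = np.empty((pop, 0), dtype=np.int8)
        mean = np.zeros(pop)
    traits = mean + rng.standard_normal(pop)

    affected, unaffected = _extreme_pools(traits, scenario.prevalence,
                                          scenario.control_tail)
    if affected.size < scenario.n_case:
        raise ValueError(
            f"affected pool has {affected.size} individuals, cannot draw "
            f"{scenario.n_case} cases"
        )
    if unaffected.size < scenario.n_ctrl:
        raise ValueError(
            f"unaffected pool has {unaffected.size} individuals, cannot draw "
            f"{scenario.n_ctrl} controls"
        )
    case_idx = rng.choice(affected, scenario.n_case, replace=False)
    ctrl_idx = rng.choice(unaffected, scenario.n_ctrl, replace=False)
    rows = np.concatenate([case_idx, ctrl_idx])
    n_study = rows.size

    blocks, causal_offset = [], 0
    for layout, ccols in zip(layouts, causal_cols):
        block = np.empty((n_study, layout.mafs.size), dtype=np.int8)
        noncausal = np.setdiff1d(np.arange(layout.mafs.size), ccols)
        if noncausal.size:
            block[:, noncausal] = simulate_genotypes(
                layout.mafs[noncausal], n_study, rng
            )
        if ccols.size:
            block[:, ccols] = pop_causal[
                rows[:, None], causal_offset + np.arange(ccols.size)[None, :]
            ]
            causal_offset += ccols.size
        blocks.append(block)
    values = np.concatenate(blocks, axis=1)
    status = np.concatenate(
        [np.ones(scenario.n_case, bool), np.zeros(scenario.n_ctrl, bool)]
    )
    return _assemble_study(values, status, traits[rows], layouts,
                           group_name or scenario.name)


# --------------------------------------------------------------------------
# export
# --------------------------------------------------------------------------

def export_study(study: SimulatedStudy, outdir, prefix="study"):
    """Write a simulated study as VCF + phenotype/gene-model/GMT/truth files.

    Produces ``<prefix>.vcf`` (one contig per gene, variant positions at
    the first base of their codon), ``<prefix>.pheno.tsv``,
    ``<prefix>.genes.tsv`` (6-column gene models), ``<prefix>.sets.gmt``
    (the study's functional group) and ``<prefix>.truth.tsv`` (true
    per-variant effects). Returns the paths as a dict.
    """
    import pysam
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {k: outdir / f"{prefix}.{ext}" for k, ext in
             [("vcf", "vcf"), ("pheno", "pheno.tsv"), ("genes", "genes.tsv"),
              ("gmt", "sets.gmt"), ("truth", "truth.tsv")]}

    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for layout in study.layouts:
        header.contigs.add(layout.name, length=layout.length_codons * 3)
    for s in study.genotypes.samples:
        header.add_sample(s)
    gm = study.genotypes
    with pysam.VariantFile(str(paths["vcf"]), "w", header=header) as vcf:
        for j, v in enumerate(gm.variants):
            rec = vcf.new_record(
                contig=v.gene, start=v.codon_index * 3, stop=v.codon_index * 3 + 1,
                alleles=("A", "C"), id=v.id,
            )
            for i, s in enumerate(gm.samples):
                g = int(gm.values[i, j])
                rec.samples[s]["GT"] = ((0, 0), (0, 1), (1, 1))[g]
            vcf.write(rec)

    with open(paths["pheno"], "w") as fh:
        fh.write("sample\tstatus\tstratum\n")
        for s, is_case in zip(study.samples.samples, study.samples.status):
            stratum = "all" if study.samples.stratum is None else "?"
            fh.write(f"{s}\t{'case' if is_case else 'control'}\t{stratum}\n")

    with open(paths["genes"], "w") as fh:
        fh.write("gene\tchrom\tstart\tend\tstrand\tframe\n")
        for layout in study.layouts:
            fh.write(f"{layout.name}\t{layout.name}\t0\t"
                     f"{layout.length_codons * 3}\t+\t0\n")

    with open(paths["gmt"], "w") as fh:
        genes = "\t".join(layout.name for layout in study.layouts)
        fh.write(f"{study.group.name}\tsimulated functional group\t{genes}\n")

    with open(paths["truth"], "w") as fh:
        fh.write("variant\tgene\tcodon\tmaf\teffect\n")
        col = 0
        for layout in study.layouts:
            for codon, maf, eff in zip(layout.codon_positions, layout.mafs,
                                       layout.effects):
                v = gm.variants[col]
                fh.write(f"{v.id}\t{layout.name}\t{int(codon)}\t{maf:.6g}\t{eff:g}\n")
                col += 1
    return paths
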