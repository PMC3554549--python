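"""Core data model for case-control sequence association testing.

The substrate of every statistic in this package is a samples x variants
matrix of alternate-allele counts together with a sample phenotype table
and one or more *functional groups* (a single gene, or a gene set whose
member genes are tested jointly). Variant positions are expressed as
0-based codon indices within each gene's concatenated coding sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VariantRecord",
    "GenotypeMatrix",
    "SampleTable",
    "GeneMembers",
    "FunctionalGroup",
    "GeneModel",
    "map_variant_to_codon",
]


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic variant mapped into a gene's coding sequence.

    Parameters
    ----------
    id : str
        Variant identifier (e.g. ``chrom:pos:ref:alt``).
    gene : str
        Gene the variant falls in.
    codon_index : int
        0-based codon offset within the gene's concatenated CDS.
    case_allele_count, control_allele_count : int
        Alternate-allele counts observed in cases and in controls.
    score : float or None
        Optional bioinformatics impact score in [0, 1]; ``None`` when no
        score file was supplied for the variant.
    """

    id: str
    gene: str
    codon_index: int
    case_allele_count: int
    control_allele_count: int
    score: float | None = None

    def __post_init__(self) -> None:
        if self.codon_index < 0:
            raise ValueError(f"codon_index must be >= 0, got {self.codon_index}")
        if self.case_allele_count < 0 or self.control_allele_count < 0:
            raise ValueError("allele counts must be non-negative")
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must lie in [0, 1], got {self.score}")

    @property
    def total_allele_count(self) -> int:
        return self.case_allele_count + self.control_allele_count


class GenotypeMatrix:
    """Samples x variants table of alternate-allele counts in {0, 1, 2}."""

    def __init__(self, samples, variants, values):
        values = np.asarray(values, dtype=np.int8)
        if values.shape != (len(samples), len(variants)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"{len(samples)} samples x {len(variants)} variants"
            )
        if values.size and (values.min() < 0 or values.max() > 2):
            raise ValueError("genotype values must lie in {0, 1, 2}")
        self.samples: list[str] = list(samples)
        self.variants: list[VariantRecord] = list(variants)
        self.values: np.ndarray = values
        self._sample_index = {s: i for i, s in enumerate(self.samples)}
        if len(self._sample_index) != len(self.samples):
            raise ValueError("duplicate sample identifiers")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def column_allele_counts(self) -> np.ndarray:
        """Total alternate-allele count per variant column."""
        return self.values.sum(axis=0, dtype=np.int64)

    def sample_rows(self, samples) -> np.ndarray:
        idx = [self._sample_index[s] for s in samples]
        return self.values[idx]

    def scores(self, default: float | None = None) -> np.ndarray:
        """Per-variant score vector; missing scores become ``default`` (or NaN)."""
        fill = math.nan if default is None else float(default)
        return np.array(
            [fill if v.score is None else v.score for v in self.variants], dtype=float
        )


@dataclass
class SampleTable:
    """Sample phenotype (and optional stratum) assignments.

    ``status`` is a boolean vector, ``True`` for cases. ``stratum`` carries
    group labels used for stratified permutation, or ``None`` when the study
    is unstratified.
    """

    samples: list[str]
    status: np.ndarray
    stratum: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.status = np.asarray(self.status, dtype=bool)
        if len(self.samples) != self.status.size:
            raise ValueError("samples and status length mismatch")
        if self.stratum is not None:
            self.stratum = np.asarray(self.stratum)
            if self.stratum.size != len(self.samples):
                raise ValueError("samples and stratum length mismatch")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one case and one control")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample identifiers in sample table")

    @property
    def n_cases(self) -> int:
        return int(self.status.sum())

    @property
    def n_controls(self) -> int:
        return int((~self.status).sum())


@dataclass
class GeneMembers:
    """One gene inside a functional group: coding length plus the indices of
    its variant columns in the study's :class:`GenotypeMatrix`."""

    gene: str
    length_codons: int
    variant_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        if self.length_codons < 1:
            raise ValueError(f"gene {self.gene}: coding length must be >= 1 codon")
        self.variant_indices = np.asarray(self.variant_indices, dtype=int)


@dataclass
class FunctionalGroup:
    """The unit of association testing: a gene or a set of genes."""

    name: str
    genes: list[GeneMembers]

    def __post_init__(self) -> None:
        names = [g.gene for g in self.genes]
        if len(set(names)) != len(names):
            raise ValueError(f"group {self.name}: duplicate gene ids")

    @property
    def variant_indices(self) -> np.ndarray:
        if not self.genes:
            return np.empty(0, dtype=int)
        return np.concatenate([g.variant_indices for g in self.genes])

    @property
    def n_variants(self) -> int:
        return int(sum(g.variant_indices.size for g in self.genes))


def map_variant_to_codon(cds_offset_bases: int, gene_length_bases: int) -> int:
    """Map a 0-based offset within a gene's concatenated CDS to a codon index.

    A trailing partial codon (gene length not divisible by 3) is still
    indexed, so a 1500-base gene has codons 0..499 and a 1501-base gene
    codons 0..500.
    """
    if gene_length_bases < 1:
        raise ValueError("gene_length_bases must be >= 1")
    if not 0 <= cds_offset_bases < gene_length_bases:
        raise ValueError(
            f"cds offset {cds_offset_bases} outside gene of "
            f"{gene_length_bases} bases"
        )
    return cds_offset_bases // 3


class GeneModel:
    """A gene's coding model: ordered CDS intervals on one chromosome.

    Intervals are 0-based half-open on the genome. The concatenated CDS
    offset is strand-aware: on the minus strand exons are walked from the
    highest-coordinate interval down and positions within each interval are
    reversed, so offset 0 is always the first coding base of the mRNA.
    """

    def __init__(self, gene: str, chrom: str, strand: str, intervals):
        if strand not in {"+", "-"}:
            raise ValueError(f"gene {gene}: strand must be '+' or '-', got {strand!r}")
        ivals = sorted((int(a), int(b)) for a, b in intervals)
        for a, b in ivals:
            if b <= a:
                raise ValueError(f"gene {gene}: empty or inverted interval ({a}, {b})")
        for (_, b1), (a2, _) in zip(ivals, ivals[1:]):
            if a2 < b1:
                raise ValueError(f"gene {gene}: overlapping CDS intervals")
        self.gene = gene
        self.chrom = chrom
        self.strand = strand
        self.intervals = ivals
        walk = ivals if strand == "+" else ivals[::-1]
        self._walk = walk
        self._cumlen = np.concatenate(
            [[0], np.cumsum([b - a for a, b in walk])]
        ).astype(int)

    @property
    def length_bases(self) -> int:
        return int(self._cumlen[-1])

    @property
    def length_codons(self) -> int:
        return -(-self.length_bases // 3)

    def cds_offset(self, chrom: str, pos0: int) -> int | None:
        """0-based CDS offset of genomic position ``pos0``, or None if the
        position is outside every coding interval of the gene."""
        if chrom != self.chrom:
            return None
        for i, (a, b) in enumerate(self._walk):
            if a <= pos0 < b:
                within = pos0 - a if self.strand == "+" else b - 1 - pos0
                return int(self._cumlen[i]) + within
        return None

    def codon_of(self, chrom: str, pos0: int) -> int | None:
        off = self.cds_offset(chrom, pos0)
        if off is None:
            return None
        return map_variant_to_codon(off, self.length_bases)
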