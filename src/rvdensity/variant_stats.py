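"""Per-gene, per-population, per-stratum allele-frequency and rarity counts.

A "variant" for a population is a site polymorphic within that population's
sample; minor allele frequencies are computed within the same sample, so the
pooled analysis recomputes MAF on the combined sample. A rare variant is a
segregating site with MAF strictly below the threshold (default 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from rvdensity.genotype_io import GenotypeMatrix

DEFAULT_RARE_MAF = 0.05


@dataclass
class GeneVariantSummary:
    """Counts for one gene within one population sample and stratum.

    ``maf_per_site`` lists the MAF of each segregating site (all > 0;
    monomorphic-in-population sites are excluded from every count).
    """

    gene: str
    population: str
    stratum: str
    n_chromosomes: int
    total_variants: int
    rare_variants: int
    maf_per_site: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.maf_per_site = np.asarray(self.maf_per_site, dtype=float)
        if not (0 <= self.rare_variants <= self.total_variants):
            raise ValueError(
                f"gene {self.gene}: rare_variants must lie in [0, total_variants]"
            )
        # counts-only summaries (e.g. re-read from TSV) may omit the MAFs
        if self.maf_per_site.size and len(self.maf_per_site) != self.total_variants:
            raise ValueError(f"gene {self.gene}: one MAF per segregating site required")


def site_maf(allele_count_column: np.ndarray, n_chromosomes: int) -> float:
    """Minor allele frequency min(p, 1-p) from a diploid alt-count column."""
    if n_chromosomes <= 0:
        raise ValueError("n_chromosomes must be positive")
    p = float(np.sum(allele_count_column)) / n_chromosomes
    return min(p, 1.0 - p)


def is_rare(maf: float, threshold: float = DEFAULT_RARE_MAF) -> bool:
    """True iff 0 < maf < threshold (strict; monomorphic sites are not variants)."""
    if not 0.0 <= maf <= 0.5:
        raise ValueError(f"MAF must lie in [0, 0.5], got {maf}")
    return 0.0 < maf < threshold


def _stratum_mafs(
    matrix: GenotypeMatrix, stratum: str
) -> tuple[np.ndarray, np.ndarray]:
    """(column mask of segregating sites in stratum, their MAFs)."""
    n = matrix.n_chromosomes
    cols = matrix.class_mask(stratum)
    totals = matrix.allele_counts.sum(axis=0)
    p = totals / n
    maf = np.minimum(p, 1.0 - p)
    seg = cols & (totals > 0) & (totals < n)
    return seg, maf


def summarize_gene(
    matrix: GenotypeMatrix,
    stratum: str = "all",
    threshold: float = DEFAULT_RARE_MAF,
    population: str = "",
) -> GeneVariantSummary:
    """Count segregating and rare sites for one gene/population/stratum."""
    seg, maf = _stratum_mafs(matrix, stratum)
    mafs = maf[seg]
    return GeneVariantSummary(
        gene=matrix.gene,
        population=population,
        stratum=stratum,
        n_chromosomes=matrix.n_chromosomes,
        total_variants=int(seg.sum()),
        rare_variants=int(np.sum(mafs < threshold)),
        maf_per_site=mafs,
    )


def rare_site_mask(
    matrix: GenotypeMatrix,
    stratum: str = "all",
    threshold: float = DEFAULT_RARE_MAF,
) -> np.ndarray:
    """Boolean mask over ALL matrix columns marking rare sites in ``stratum``.

    A column is marked iff it belongs to the stratum, is polymorphic within
    this sample, and has MAF strictly below ``threshold``. Feed this to the
    individual-level measures so that rarity is defined on the same
    population sample.
    """
    seg, maf = _stratum_mafs(matrix, stratum)
    return seg & (maf < threshold)
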