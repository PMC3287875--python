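"""Individual-level rare-variant density measures and their comparison.

Two per-gene measures are computed within a population sample: the
proportion of individuals carrying at least one rare variant for the gene,
and the average number of rare variants per individual. "Carrying" is
defined with respect to the population-level minor allele at each rare
site, so a site where the reference allele is the rare one counts
reference-allele carriers. By default the per-individual count is the
number of rare sites at which the individual carries the minor allele
(site presence); an allele-dosage variant is available for sensitivity
analysis. Two populations are compared over an identical gene list with a
classic paired t test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from rvdensity.genotype_io import GenotypeMatrix

logger = logging.getLogger(__name__)

COUNTING_MODES = ("presence", "dosage")


@dataclass
class IndividualDensitySummary:
    gene: str
    population: str
    prop_carriers: float
    mean_rare_per_individual: float


def _minor_allele_matrix(matrix: GenotypeMatrix, rare_site_mask: np.ndarray) -> np.ndarray:
    """Per-individual minor-allele copy counts at the masked rare sites."""
    rare_site_mask = np.asarray(rare_site_mask, dtype=bool)
    if rare_site_mask.shape != (matrix.n_variants,):
        raise ValueError("rare_site_mask must have one entry per variant column")
    counts = matrix.allele_counts[:, rare_site_mask].astype(np.int16)
    if counts.shape[1] == 0:
        return counts
    p = counts.sum(axis=0) / matrix.n_chromosomes
    minor_is_ref = p > 0.5
    counts[:, minor_is_ref] = 2 - counts[:, minor_is_ref]
    return counts


def carrier_proportion(matrix: GenotypeMatrix, rare_site_mask: np.ndarray) -> float:
    """Fraction of individuals with >= 1 minor allele at >= 1 rare site."""
    if matrix.n_samples == 0:
        raise ValueError(f"gene {matrix.gene}: no individuals")
    minor = _minor_allele_matrix(matrix, rare_site_mask)
    if minor.shape[1] == 0:
        return 0.0
    return float(np.mean((minor > 0).any(axis=1)))


def mean_rare_count(
    matrix: GenotypeMatrix,
    rare_site_mask: np.ndarray,
    counting: str = "presence",
) -> float:
    """Average number of rare variants per individual for one gene.

    ``counting="presence"`` (default) counts rare sites at which the
    individual carries the minor allele; ``"dosage"`` counts minor-allele
    copies.
    """
    if counting not in COUNTING_MODES:
        raise ValueError(f"counting must be one of {COUNTING_MODES}, got {counting!r}")
    if matrix.n_samples == 0:
        raise ValueError(f"gene {matrix.gene}: no individuals")
    minor = _minor_allele_matrix(matrix, rare_site_mask)
    if minor.shape[1] == 0:
        return 0.0
    per_ind = (minor > 0).sum(axis=1) if counting == "presence" else minor.sum(axis=1)
    return float(np.mean(per_ind))


def summarize_individual_density(
    matrix: GenotypeMatrix,
    rare_site_mask: np.ndarray,
    population: str = "",
    counting: str = "presence",
) -> IndividualDensitySummary:
    """Both individual-level measures for one gene/population."""
    return IndividualDensitySummary(
        gene=matrix.gene,
        population=population,
        prop_carriers=carrier_proportion(matrix, rare_site_mask),
        mean_rare_per_individual=mean_rare_count(matrix, rare_site_mask, counting),
    )


def paired_gene_test(
    values_a: np.ndarray, values_b: np.ndarray
) -> tuple[float, float]:
    """Two-sided paired t test on per-gene differences between two populations.

    Both vectors must cover the same ordered gene list. Returns (t, p) with
    df = n_genes - 1. If every difference is zero, (0, 1). If the
    differences have zero variance but nonzero mean, the p-value is reported
    at the smallest positive normal float with a logged warning rather than
    as NaN.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired test needs 1-D vectors over the same gene list")
    n = len(a)
    if n < 2:
        raise ValueError("paired test needs at least 2 genes")
    d = a - b
    if np.all(d == 0.0):
        return 0.0, 1.0
    sd = float(np.std(d, ddof=1))
    mean = float(np.mean(d))
    if sd == 0.0:
        logger.warning(
            "paired_gene_test: zero-variance nonzero differences; p below machine floor"
        )
        t = math.inf if mean > 0 else -math.inf
        return t, float(np.finfo(float).tiny)
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    return t, p
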