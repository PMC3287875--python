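"""Watterson's theta, nucleotide diversity and Tajima's D per gene.

Two estimators of the scaled mutation rate are contrasted: Watterson's
theta_W = S / a1, driven by the number of segregating sites S, and the
nucleotide diversity pi, the mean number of pairwise differences between
sampled chromosomes. Under the standard neutral model both estimate the
same quantity; an excess of rare variants (population expansion, purifying
or positive selection) depresses pi relative to theta_W and yields a
negative Tajima's D,

    D = (pi - S/a1) / sqrt(e1*S + e2*S*(S-1)),

with the variance coefficients of Tajima (1989):

    a1 = sum_{i=1}^{n-1} 1/i          a2 = sum_{i=1}^{n-1} 1/i^2
    b1 = (n+1) / (3(n-1))             b2 = 2(n^2+n+3) / (9n(n-1))
    c1 = b1 - 1/a1                    c2 = b2 - (n+2)/(a1*n) + a2/a1^2
    e1 = c1/a1                        e2 = c2/(a1^2 + a2)

where n is the number of sampled chromosomes. D is undefined (NaN) for
S = 0 or n < 4 and is propagated as missing, never as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from rvdensity.genotype_io import GenotypeMatrix


@dataclass(frozen=True)
class TajimaCoefficients:
    """Constants of the D denominator for a sample of ``n`` chromosomes."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


@lru_cache(maxsize=4096)
def tajima_coefficients(n: int) -> TajimaCoefficients:
    """Tajima (1989) normalization coefficients for ``n`` chromosomes (n >= 2)."""
    if n < 2:
        raise ValueError(f"need at least 2 chromosomes, got n={n}")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaCoefficients(n, a1, a2, b1, b2, c1, c2, e1, e2)


def watterson_theta(S: int, n: int) -> float:
    """Watterson's estimator S / a1(n) for ``S`` segregating sites, ``n`` chromosomes."""
    if n < 2:
        raise ValueError(f"need at least 2 chromosomes, got n={n}")
    if S < 0:
        raise ValueError(f"segregating-site count must be >= 0, got {S}")
    if S == 0:
        return 0.0
    return S / tajima_coefficients(n).a1


def nucleotide_diversity(allele_counts: np.ndarray, n: int | None = None) -> float:
    """Nucleotide diversity pi as summed unbiased per-site heterozygosity.

    pi = sum_sites (n/(n-1)) * 2 p (1-p), which equals the mean pairwise
    Hamming distance over all C(n,2) chromosome pairs.

    Parameters
    ----------
    allele_counts
        Either a 2-D diploid count matrix (samples x sites, entries 0/1/2),
        or a 1-D vector of per-site total alt-allele counts (then ``n`` is
        required).
    n
        Number of chromosomes; inferred as ``2 * n_samples`` for matrix input.
    """
    counts = np.asarray(allele_counts)
    if counts.ndim == 2:
        if n is None:
            n = 2 * counts.shape[0]
        site_totals = counts.sum(axis=0)
    elif counts.ndim == 1:
        if n is None:
            raise ValueError("n (chromosome count) required for per-site count input")
        site_totals = counts
    else:
        raise ValueError("allele_counts must be 1-D or 2-D")
    if n < 2:
        raise ValueError(f"need at least 2 chromosomes, got n={n}")
    p = site_totals / n
    return float(np.sum(n / (n - 1.0) * 2.0 * p * (1.0 - p)))


def tajimas_d(pi: float, S: int, n: int) -> float:
    """Tajima's D; NaN when undefined (S = 0 or n < 4)."""
    if n < 2:
        raise ValueError(f"need at least 2 chromosomes, got n={n}")
    if S < 0 or pi < 0:
        raise ValueError("S and pi must be non-negative")
    if S == 0 or n < 4:
        return math.nan
    c = tajima_coefficients(n)
    var = c.e1 * S + c.e2 * S * (S - 1)
    return (pi - S / c.a1) / math.sqrt(var)


@dataclass
class TajimaResult:
    """Diversity summary for one gene within one population sample and stratum."""

    gene: str
    population: str
    stratum: str
    n: int          # chromosomes
    S: int          # segregating sites
    theta_w: float
    pi: float
    D: float        # NaN when undefined


def gene_tajima(
    matrix: GenotypeMatrix, stratum: str = "all", population: str = ""
) -> TajimaResult:
    """Compute S, theta_W, pi and D for one gene/population/stratum.

    Columns are filtered to ``stratum`` and sites monomorphic within this
    sample are excluded before counting.
    """
    n = matrix.n_chromosomes
    if n < 2:
        raise ValueError(f"gene {matrix.gene}: need at least 1 diploid sample")
    cols = matrix.class_mask(stratum)
    totals = matrix.allele_counts[:, cols].sum(axis=0)
    seg = (totals > 0) & (totals < n)
    S = int(seg.sum())
    pi = nucleotide_diversity(totals[seg], n)
    return TajimaResult(
        gene=matrix.gene,
        population=population,
        stratum=stratum,
        n=n,
        S=S,
        theta_w=watterson_theta(S, n),
        pi=pi,
        D=tajimas_d(pi, S, n),
    )
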