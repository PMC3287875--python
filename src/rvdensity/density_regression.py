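"""Through-origin regression of rare on total variant counts across genes.

Per population j the model is

    rare_i(j) = B(j) * total_i(j) + e_i(j)

with no intercept: a gene with zero variants has zero rare variants by
construction. The slope B = sum(x*y) / sum(x^2) characterizes the genome-wide
rare-variant density; slopes of two populations are compared with
t = (B_a - B_b) / sqrt(SE_a^2 + SE_b^2) against the standard normal (with
thousands of genes per fit the normal and t references are
indistinguishable). Genes far from the pooled fit are density outliers:
above the line, an excess of rare variants; below it, an excess of common
variants.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class SlopeEstimate:
    population: str
    stratum: str
    B: float
    SE: float
    n_genes: int


@dataclass
class SlopeComparison:
    population_a: str
    population_b: str
    t: float
    p_value: float


@dataclass
class OutlierReport:
    gene: str
    observed_rare: float
    predicted_rare: float
    residual: float      # observed - predicted
    direction: str       # "positive" (rare excess) or "negative" (common excess)


def fit_through_origin(
    x: np.ndarray,
    y: np.ndarray,
    population: str = "",
    stratum: str = "all",
) -> SlopeEstimate:
    """Least-squares slope of y = B*x with no intercept.

    B = sum(xy)/sum(x^2); SE uses the textbook through-origin estimator with
    residual degrees of freedom n_genes - 1 (one parameter estimated). With a
    single gene the slope is the point ratio and SE is NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    sxx = float(np.sum(x * x))
    if sxx == 0.0:
        raise ValueError("all total-variant counts are zero; slope undefined")
    B = float(np.sum(x * y)) / sxx
    n = len(x)
    if n < 2:
        se = math.nan
    else:
        rss = float(np.sum((y - B * x) ** 2))
        se = math.sqrt(rss / (n - 1) / sxx)
    return SlopeEstimate(population=population, stratum=stratum, B=B, SE=se, n_genes=n)


def compare_slopes(a: SlopeEstimate, b: SlopeEstimate) -> SlopeComparison:
    """Two-sided test of B_a = B_b using the SE of the slope difference."""
    if a.stratum != b.stratum:
        raise ValueError(
            f"slope estimates are on different strata ({a.stratum!r} vs {b.stratum!r})"
        )
    se_diff = math.sqrt(a.SE**2 + b.SE**2)
    if se_diff == 0.0:
        if a.B == b.B:
            return SlopeComparison(a.population, b.population, 0.0, 1.0)
        logger.warning(
            "compare_slopes: zero SEs with unequal slopes (%s vs %s); p = 0",
            a.population, b.population,
        )
        t = math.inf if a.B > b.B else -math.inf
        return SlopeComparison(a.population, b.population, t, 0.0)
    t = (a.B - b.B) / se_diff
    p = 2.0 * float(stats.norm.sf(abs(t)))
    return SlopeComparison(a.population, b.population, t, p)


def pairwise_slope_matrix(
    estimates: Sequence[SlopeEstimate],
) -> list[SlopeComparison]:
    """All unordered pairwise slope comparisons, sorted by population label."""
    if len(estimates) < 2:
        raise ValueError("need at least 2 slope estimates")
    ordered = sorted(estimates, key=lambda e: e.population)
    return [compare_slopes(a, b) for a, b in combinations(ordered, 2)]


def pooled_outliers(
    fit: SlopeEstimate,
    x: np.ndarray,
    y: np.ndarray,
    genes: Sequence[str],
    k: int = 4,
) -> list[OutlierReport]:
    """The k genes with largest positive and k with largest negative residual.

    Residuals are observed - predicted under the (pooled) through-origin
    fit. Ties are broken by gene name ascending; results are deterministic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (len(x) == len(y) == len(genes)):
        raise ValueError("x, y and genes must have equal length")
    if k < 0:
        raise ValueError("k must be non-negative")
    if k > len(genes):
        logger.warning("pooled_outliers: k=%d exceeds %d genes; truncating", k, len(genes))
        k = len(genes)
    residuals = y - fit.B * x
    order = sorted(range(len(genes)), key=lambda i: (-residuals[i], genes[i]))
    reports = []
    for i in order[:k]:
        reports.append(
            OutlierReport(genes[i], float(y[i]), float(fit.B * x[i]),
                          float(residuals[i]), "positive")
        )
    neg_order = sorted(range(len(genes)), key=lambda i: (residuals[i], genes[i]))
    for i in neg_order[:k]:
        reports.append(
            OutlierReport(genes[i], float(y[i]), float(fit.B * x[i]),
                          float(residuals[i]), "negative")
        )
    return reports
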