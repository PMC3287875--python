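"""Cross-population aggregation of per-gene statistics and D-threshold flags.

For each gene, per-population Tajima's D values (for a chosen stratum) are
summarized by their mean and sample variance across populations, alongside
cross-population means of the variant counts: the mean number of variants,
the mean fraction of variants that are rare, and the mean fraction of rare
variants that are nonsynonymous (the count columns always use all SNPs,
whatever the D stratum). Genes whose D falls strictly below a negative
threshold in some population are flagged as putative selection candidates;
genes flagged in two or more populations are marked shared. The average of
per-gene cross-population D variances measures how consistently a stratum
ranks genes across populations.

Because D can be undefined (no segregating sites in a stratum for some
population), two aggregation policies exist: ``"available"`` (default)
averages over populations with defined D, while ``"strict"`` invalidates
the mean and variance whenever any population's D is undefined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from rvdensity.tajima import TajimaResult
from rvdensity.variant_stats import GeneVariantSummary

POLICIES = ("available", "strict")


@dataclass
class GeneCrossPopSummary:
    """One gene's statistics aggregated across populations (one stratum)."""

    gene: str
    stratum: str
    mean_D: float            # NaN when undefined under the policy
    var_D: float             # sample variance (df = n-1); NaN when < 2 defined
    mean_total_variants: float
    prop_rare: float         # NaN when no population has variants
    prop_rare_nonsyn: float  # NaN when no population has rare variants
    n_pops_defined: int


def aggregate_gene(
    tajima_results: Sequence[TajimaResult],
    summaries: Sequence[GeneVariantSummary],
    policy: str = "available",
) -> GeneCrossPopSummary:
    """Aggregate one gene's per-population rows.

    Parameters
    ----------
    tajima_results
        One :class:`TajimaResult` per population, all for the same gene and
        stratum (the stratum whose D is being aggregated).
    summaries
        :class:`GeneVariantSummary` rows for the same gene covering the
        ``all`` and ``nonsynonymous`` strata of each population; the count
        columns are computed from these.
    policy
        ``"available"`` or ``"strict"`` (see module docstring).
    """
    if policy not in POLICIES:
        raise ValueError(f"policy must be one of {POLICIES}, got {policy!r}")
    if not tajima_results:
        raise ValueError("aggregate_gene needs at least one population row")
    gene = tajima_results[0].gene
    stratum = tajima_results[0].stratum
    if any(r.gene != gene or r.stratum != stratum for r in tajima_results):
        raise ValueError("tajima_results must cover a single gene and stratum")
    if any(s.gene != gene for s in summaries):
        raise ValueError("summaries must cover the same gene")

    d = np.array([r.D for r in tajima_results], dtype=float)
    defined = d[~np.isnan(d)]
    n_def = len(defined)
    if policy == "strict" and n_def < len(d):
        mean_d = var_d = math.nan
    else:
        mean_d = float(np.mean(defined)) if n_def >= 1 else math.nan
        var_d = float(np.var(defined, ddof=1)) if n_def >= 2 else math.nan

    by_pop: dict[str, dict[str, GeneVariantSummary]] = {}
    for s in summaries:
        by_pop.setdefault(s.population, {})[s.stratum] = s
    totals, ratios, ns_ratios = [], [], []
    for pop, strata in sorted(by_pop.items()):
        if "all" not in strata:
            raise ValueError(f"gene {gene}: missing stratum 'all' summary for {pop!r}")
        s_all = strata["all"]
        totals.append(s_all.total_variants)
        if s_all.total_variants > 0:
            ratios.append(s_all.rare_variants / s_all.total_variants)
        if "nonsynonymous" in strata and s_all.rare_variants > 0:
            ns_ratios.append(strata["nonsynonymous"].rare_variants / s_all.rare_variants)
    if not totals:
        raise ValueError(f"gene {gene}: no variant summaries supplied")

    return GeneCrossPopSummary(
        gene=gene,
        stratum=stratum,
        mean_D=mean_d,
        var_D=var_d,
        mean_total_variants=float(np.mean(totals)),
        prop_rare=float(np.mean(ratios)) if ratios else math.nan,
        prop_rare_nonsyn=float(np.mean(ns_ratios)) if ns_ratios else math.nan,
        n_pops_defined=n_def,
    )


def flag_selection_candidates(
    tajima_results: Iterable[TajimaResult],
    stratum: str,
    threshold: float,
) -> dict[str, set[str]]:
    """Populations in which each gene's D lies strictly below ``threshold``.

    Only genes flagged in at least one population appear in the result;
    undefined D never flags. Shared genes are those whose population set has
    size >= 2 (see :func:`shared_genes`).
    """
    flags: dict[str, set[str]] = {}
    for r in tajima_results:
        if r.stratum != stratum:
            continue
        if not math.isnan(r.D) and r.D < threshold:
            flags.setdefault(r.gene, set()).add(r.population)
    return flags


def shared_genes(flags: Mapping[str, set[str]]) -> set[str]:
    """Genes flagged in more than one population."""
    return {g for g, pops in flags.items() if len(pops) >= 2}


def stratum_dispersion(summaries: Iterable[GeneCrossPopSummary]) -> float:
    """Average across genes of the cross-population variance of D.

    NaN when no gene has a defined variance. A lower average for the
    nonsynonymous stratum than the synonymous one indicates cross-population
    consistency of the genes' D signal.
    """
    vars_ = [s.var_D for s in summaries if not math.isnan(s.var_D)]
    return float(np.mean(vars_)) if vars_ else math.nan
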