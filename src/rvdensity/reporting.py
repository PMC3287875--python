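"""Tabular report assembly: deterministic TSVs mirroring the summary tables.

Module TSVs carry full double precision; rounding happens only here.
"NA" is the literal missing token in every table. The report layer performs
no computation beyond rounding, sorting, and the per-block "Average" row.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from rvdensity.cross_population import GeneCrossPopSummary, shared_genes
from rvdensity.density_regression import SlopeEstimate, compare_slopes
from rvdensity.genotype_io import POOLED_LABEL


def write_tsv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
    return path


def make_table1(
    slope_estimates: Sequence[SlopeEstimate],
    mean_d: Mapping[tuple[str, str], float],
) -> pd.DataFrame:
    """Population summary: slope, SE, adjacent-pair p, mean D per stratum.

    Rows are sorted by ascending slope (stable tie-break on the population
    label), the pooled sample last by construction since pooling inflates
    the slope. ``p_next`` tests each row's slope against the next row's;
    the full pairwise matrix lives in its own TSV. ``mean_d`` maps
    ``(population, stratum)`` to the across-gene mean of defined D values;
    the pooled row's D cells are left NA.
    """
    ordered = sorted(slope_estimates, key=lambda e: (e.B, e.population))
    rows = []
    for i, est in enumerate(ordered):
        p_next = (
            compare_slopes(est, ordered[i + 1]).p_value if i + 1 < len(ordered) else math.nan
        )
        pooled = est.population == POOLED_LABEL
        rows.append(
            {
                "population": est.population,
                "slope": round(est.B, 3),
                "SE": round(est.SE, 3),
                "p_next": p_next,
                "mean_D_nonsynonymous": (
                    math.nan if pooled
                    else _round3(mean_d.get((est.population, "nonsynonymous"), math.nan))
                ),
                "mean_D_synonymous": (
                    math.nan if pooled
                    else _round3(mean_d.get((est.population, "synonymous"), math.nan))
                ),
            }
        )
    return pd.DataFrame(rows)


def _round3(x: float) -> float:
    return round(x, 3) if not math.isnan(x) else x


_TABLE2_COLS = [
    "mean_D",
    "var_D",
    "mean_total_variants",
    "prop_rare",
    "prop_rare_nonsyn",
]


def make_table2(
    crosspop: Mapping[str, Sequence[GeneCrossPopSummary]],
    flags: Mapping[str, Mapping[str, set[str]]],
) -> pd.DataFrame:
    """Flagged-gene blocks per stratum with a per-block Average row.

    ``crosspop`` maps stratum -> cross-population summaries for every gene;
    ``flags`` maps stratum -> (gene -> flagging populations). Each block
    lists the flagged genes (name-sorted) with the five aggregate columns
    rounded to 2 decimals, a shared-gene marker, and closes with the mean of
    the defined values per column.
    """
    rows = []
    for stratum in ("nonsynonymous", "synonymous"):
        summaries = {s.gene: s for s in crosspop.get(stratum, [])}
        stratum_flags = flags.get(stratum, {})
        shared = shared_genes(stratum_flags)
        block = []
        for gene in sorted(stratum_flags):
            s = summaries.get(gene)
            if s is None:
                continue
            block.append(
                {
                    "stratum": stratum,
                    "gene": gene,
                    **{c: getattr(s, c) for c in _TABLE2_COLS},
                    "populations_flagged": ";".join(sorted(stratum_flags[gene])),
                    "shared": gene in shared,
                }
            )
        if block:
            avg = {"stratum": stratum, "gene": "Average",
                   "populations_flagged": "", "shared": ""}
            for c in _TABLE2_COLS:
                vals = [b[c] for b in block if not math.isnan(b[c])]
                avg[c] = float(np.mean(vals)) if vals else math.nan
            block.append(avg)
        for b in block:
            for c in _TABLE2_COLS:
                if not math.isnan(b[c]):
                    b[c] = round(b[c], 2)
        rows.extend(block)
    return pd.DataFrame(
        rows,
        columns=["stratum", "gene", *_TABLE2_COLS, "populations_flagged", "shared"],
    )
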