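"""End-to-end orchestration: inputs -> per-gene statistics -> reports.

The pipeline reads (or simulates and writes, then re-reads) a VCF plus
annotation and sample-map TSVs, computes per-gene/population/stratum
variant summaries and Tajima's D, fits the rare-to-total through-origin
regressions with all pairwise slope comparisons and pooled-fit outliers,
computes the individual-level carrier measures with all pairwise paired-t
comparisons, aggregates statistics across populations with D-threshold
selection flags, and writes deterministic TSV outputs plus the two
population/gene summary tables.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from rvdensity import cross_population, reporting
from rvdensity.density_regression import (
    SlopeEstimate,
    fit_through_origin,
    pairwise_slope_matrix,
    pooled_outliers,
)
from rvdensity.genotype_io import (
    POOLED_LABEL,
    STRATA,
    GenotypeMatrix,
    read_annotation,
    read_population_map,
    read_vcf,
    split_by_population,
)
from rvdensity.individual_density import (
    paired_gene_test,
    summarize_individual_density,
)
from rvdensity.synthetic_data import SimulationConfig, simulate_dataset, write_dataset
from rvdensity.tajima import TajimaResult, gene_tajima
from rvdensity.variant_stats import (
    DEFAULT_RARE_MAF,
    GeneVariantSummary,
    rare_site_mask,
    summarize_gene,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage."""


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    Exactly one of (``vcf``+``annotation``+``samples``) or ``simulation``
    must be provided. Thresholds follow the conventional defaults: rare MAF
    below 0.05, selection-candidate D below -2 for nonsynonymous and -1.8
    for synonymous SNPs.
    """

    out_dir: str | Path
    vcf: str | Path | None = None
    annotation: str | Path | None = None
    samples: str | Path | None = None
    simulation: SimulationConfig | str | Path | None = None
    rare_maf: float = DEFAULT_RARE_MAF
    nonsyn_d_threshold: float = -2.0
    syn_d_threshold: float = -1.8
    outlier_k: int = 4
    missing_d_policy: str = "available"
    counting: str = "presence"
    missing_genotypes: str = "strict"
    seed: int | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        file_mode = self.vcf is not None
        if file_mode and (self.annotation is None or self.samples is None):
            raise ValueError("file input requires vcf, annotation and samples paths")
        if file_mode == (self.simulation is not None):
            raise ValueError("exactly one of file inputs or a simulation config required")
        if not 0.0 < self.rare_maf <= 0.5:
            raise ValueError("rare_maf must lie in (0, 0.5]")
        if self.missing_d_policy not in cross_population.POLICIES:
            raise ValueError(f"missing_d_policy must be one of {cross_population.POLICIES}")
        if self.outlier_k < 0:
            raise ValueError("outlier_k must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "simulation" in data and isinstance(data["simulation"], dict):
            data["simulation"] = SimulationConfig(**data["simulation"])
        return cls(**data)


@dataclass
class PipelineResult:
    out_dir: Path
    tables: dict[str, pd.DataFrame]
    paths: dict[str, Path]
    metrics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Stage computations (DataFrame producers), reused by the CLI subcommands
# ---------------------------------------------------------------------------

@dataclass
class _PerGeneRows:
    summaries: list[GeneVariantSummary]
    tajima: list[TajimaResult]
    individual: list  # IndividualDensitySummary


def analyze_matrices(
    matrices: Sequence[GenotypeMatrix],
    population_map: Mapping[str, str],
    rare_maf: float = DEFAULT_RARE_MAF,
    counting: str = "presence",
) -> _PerGeneRows:
    """Single pass over genes: summaries, Tajima results, individual measures."""
    rows = _PerGeneRows([], [], [])
    for matrix in matrices:
        per_pop = split_by_population(matrix, population_map)
        for pop, sub in per_pop.items():
            for stratum in STRATA:
                rows.summaries.append(
                    summarize_gene(sub, stratum, threshold=rare_maf, population=pop)
                )
                rows.tajima.append(gene_tajima(sub, stratum, population=pop))
            if pop != POOLED_LABEL:
                mask = rare_site_mask(sub, "all", threshold=rare_maf)
                rows.individual.append(
                    summarize_individual_density(sub, mask, population=pop, counting=counting)
                )
    return rows


def summaries_frame(rows: Sequence[GeneVariantSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": s.gene, "population": s.population, "stratum": s.stratum,
                "n_chromosomes": s.n_chromosomes,
                "total_variants": s.total_variants, "rare_variants": s.rare_variants,
            }
            for s in rows
        ]
    )


def tajima_frame(rows: Sequence[TajimaResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene, "population": r.population, "stratum": r.stratum,
                "n": r.n, "S": r.S, "theta_w": r.theta_w, "pi": r.pi, "D": r.D,
            }
            for r in rows
        ]
    )


def individual_frame(rows: Sequence) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene, "population": r.population,
                "prop_carriers": r.prop_carriers,
                "mean_rare_per_individual": r.mean_rare_per_individual,
            }
            for r in rows
        ]
    )


def fit_all_slopes(summary_df: pd.DataFrame) -> list[SlopeEstimate]:
    """Through-origin fit per (population, stratum) over the gene universe."""
    estimates = []
    for (pop, stratum), grp in summary_df.groupby(["population", "stratum"], sort=True):
        grp = grp.sort_values("gene")
        estimates.append(
            fit_through_origin(
                grp["total_variants"].to_numpy(float),
                grp["rare_variants"].to_numpy(float),
                population=pop,
                stratum=stratum,
            )
        )
    return estimates


def slope_frames(
    estimates: Sequence[SlopeEstimate],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(slopes.tsv frame, slope_comparisons.tsv frame with Bonferroni column)."""
    slopes = pd.DataFrame(
        [
            {"population": e.population, "stratum": e.stratum,
             "B": e.B, "SE": e.SE, "n_genes": e.n_genes}
            for e in estimates
        ]
    )
    comp_rows = []
    for stratum in sorted({e.stratum for e in estimates}):
        ests = [e for e in estimates if e.stratum == stratum]
        if len(ests) < 2:
            continue
        comps = pairwise_slope_matrix(ests)
        m = len(comps)
        for c in comps:
            comp_rows.append(
                {
                    "stratum": stratum,
                    "population_a": c.population_a, "population_b": c.population_b,
                    "t": c.t, "p": c.p_value,
                    "p_bonferroni": min(1.0, c.p_value * m),
                }
            )
    return slopes, pd.DataFrame(comp_rows)


def outlier_frame(
    summary_df: pd.DataFrame, estimates: Sequence[SlopeEstimate], k: int
) -> pd.DataFrame:
    """Pooled-fit outliers on the all-SNP stratum."""
    pooled = [e for e in estimates if e.population == POOLED_LABEL and e.stratum == "all"]
    if not pooled:
        raise PipelineError("no pooled all-stratum slope estimate available")
    grp = summary_df[
        (summary_df["population"] == POOLED_LABEL) & (summary_df["stratum"] == "all")
    ].sort_values("gene")
    reports = pooled_outliers(
        pooled[0],
        grp["total_variants"].to_numpy(float),
        grp["rare_variants"].to_numpy(float),
        grp["gene"].tolist(),
        k=k,
    )
    return pd.DataFrame(
        [
            {"gene": r.gene, "observed_rare": r.observed_rare,
             "predicted_rare": r.predicted_rare, "residual": r.residual,
             "direction": r.direction}
            for r in reports
        ]
    )


def individual_comparison_frame(individual_df: pd.DataFrame) -> pd.DataFrame:
    """Paired t comparisons of both measures for every population pair."""
    rows = []
    pops = sorted(individual_df["population"].unique())
    for measure in ("prop_carriers", "mean_rare_per_individual"):
        wide = individual_df.pivot(index="gene", columns="population", values=measure)
        if wide.isna().any().any():
            raise PipelineError("individual measures must cover the same gene set")
        for a, b in combinations(pops, 2):
            t, p = paired_gene_test(wide[a].to_numpy(), wide[b].to_numpy())
            rows.append(
                {
                    "measure": measure, "population_a": a, "population_b": b,
                    "mean_a": float(wide[a].mean()), "mean_b": float(wide[b].mean()),
                    "t": t, "p": p,
                }
            )
    return pd.DataFrame(rows)


def aggregate_stage(
    tajima_rows: Sequence[TajimaResult],
    summary_rows: Sequence[GeneVariantSummary],
    policy: str,
    nonsyn_d_threshold: float,
    syn_d_threshold: float,
) -> tuple[dict, dict, pd.DataFrame, pd.DataFrame, dict[str, float]]:
    """Cross-population aggregation, flags and dispersion for both strata."""
    t_by: dict[tuple[str, str], list[TajimaResult]] = {}
    for r in tajima_rows:
        if r.population == POOLED_LABEL:
            continue
        t_by.setdefault((r.gene, r.stratum), []).append(r)
    s_by: dict[str, list[GeneVariantSummary]] = {}
    for s in summary_rows:
        if s.population == POOLED_LABEL or s.stratum == "synonymous":
            continue
        s_by.setdefault(s.gene, []).append(s)

    crosspop: dict[str, list] = {}
    for stratum in ("nonsynonymous", "synonymous"):
        crosspop[stratum] = [
            cross_population.aggregate_gene(t_by[(gene, stratum)], s_by[gene], policy=policy)
            for gene in sorted(s_by)
        ]
    thresholds = {"nonsynonymous": nonsyn_d_threshold, "synonymous": syn_d_threshold}
    flags = {
        stratum: cross_population.flag_selection_candidates(
            tajima_rows, stratum, thresholds[stratum]
        )
        for stratum in thresholds
    }
    dispersion = {
        stratum: cross_population.stratum_dispersion(crosspop[stratum])
        for stratum in crosspop
    }

    crosspop_df = pd.DataFrame(
        [
            {
                "gene": s.gene, "stratum": s.stratum, "mean_D": s.mean_D,
                "var_D": s.var_D, "mean_total_variants": s.mean_total_variants,
                "prop_rare": s.prop_rare, "prop_rare_nonsyn": s.prop_rare_nonsyn,
                "n_pops_defined": s.n_pops_defined, "policy": policy,
            }
            for stratum in ("nonsynonymous", "synonymous")
            for s in crosspop[stratum]
        ]
    )
    flag_rows = []
    for stratum, fl in flags.items():
        shared = cross_population.shared_genes(fl)
        for gene in sorted(fl):
            flag_rows.append(
                {
                    "gene": gene, "stratum": stratum,
                    "populations": ";".join(sorted(fl[gene])),
                    "n_populations": len(fl[gene]), "shared": gene in shared,
                }
            )
    flags_df = pd.DataFrame(
        flag_rows, columns=["gene", "stratum", "populations", "n_populations", "shared"]
    )
    return crosspop, flags, crosspop_df, flags_df, dispersion


def mean_d_by_population(tajima_df: pd.DataFrame) -> dict[tuple[str, str], float]:
    """Across-gene mean of defined D per (population, stratum), pooled excluded."""
    sub = tajima_df[tajima_df["population"] != POOLED_LABEL]
    out = {}
    for (pop, stratum), grp in sub.groupby(["population", "stratum"]):
        d = grp["D"].dropna()
        out[(pop, stratum)] = float(d.mean()) if len(d) else math.nan
    return out


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full pipeline and write all outputs under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("rvdensity")
    root.addHandler(handler)
    root.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    try:
        return _run(config, out)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out: Path) -> PipelineResult:
    paths: dict[str, Path] = {}

    def stage(name):
        logger.info("stage: %s", name)

    # -- inputs -------------------------------------------------------------
    stage("inputs")
    try:
        if config.simulation is not None:
            sim = config.simulation
            if isinstance(sim, (str, Path)):
                sim = SimulationConfig.from_yaml(sim)
            if config.seed is not None:
                sim = SimulationConfig(**{**sim.to_dict(), "seed": config.seed})
            dataset = simulate_dataset(sim)
            input_paths = write_dataset(dataset, out / "inputs")
            vcf_path = input_paths["vcf"]
            ann_path = input_paths["annotation"]
            map_path = input_paths["samples"]
        else:
            vcf_path, ann_path, map_path = (
                Path(config.vcf), Path(config.annotation), Path(config.samples)
            )
        annotation = read_annotation(ann_path)
        population_map = read_population_map(map_path)
        matrices = read_vcf(
            vcf_path, annotation, population_map, missing=config.missing_genotypes
        )
    except Exception as exc:
        raise PipelineError(f"stage 'inputs' failed: {exc}") from exc
    if not matrices:
        raise PipelineError("stage 'inputs' failed: no annotated variants loaded")
    input_hashes = {p.name: _sha256(p) for p in (vcf_path, ann_path, map_path)}

    # -- per-gene statistics ------------------------------------------------
    stage("per-gene statistics")
    try:
        rows = analyze_matrices(
            matrices, population_map, rare_maf=config.rare_maf, counting=config.counting
        )
        summary_df = summaries_frame(rows.summaries)
        tajima_df = tajima_frame(rows.tajima)
        individual_df = individual_frame(rows.individual)
    except Exception as exc:
        raise PipelineError(f"stage 'per-gene statistics' failed: {exc}") from exc
    paths["summaries"] = reporting.write_tsv(summary_df, out / "summaries.tsv")
    paths["tajima"] = reporting.write_tsv(tajima_df, out / "tajima.tsv")
    paths["individual"] = reporting.write_tsv(individual_df, out / "individual_density.tsv")

    # -- regressions --------------------------------------------------------
    stage("density regression")
    try:
        estimates = fit_all_slopes(summary_df)
        slopes_df, comparisons_df = slope_frames(estimates)
        outliers_df = outlier_frame(summary_df, estimates, config.outlier_k)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage 'density regression' failed: {exc}") from exc
    paths["slopes"] = reporting.write_tsv(slopes_df, out / "slopes.tsv")
    paths["slope_comparisons"] = reporting.write_tsv(
        comparisons_df, out / "slope_comparisons.tsv"
    )
    paths["outliers"] = reporting.write_tsv(outliers_df, out / "outliers.tsv")

    # -- individual-level comparisons --------------------------------------
    stage("individual density")
    try:
        ind_comp_df = individual_comparison_frame(individual_df)
    except Exception as exc:
        raise PipelineError(f"stage 'individual density' failed: {exc}") from exc
    paths["individual_comparisons"] = reporting.write_tsv(
        ind_comp_df, out / "individual_comparisons.tsv"
    )

    # -- cross-population aggregation --------------------------------------
    stage("cross-population aggregation")
    try:
        crosspop, flags, crosspop_df, flags_df, dispersion = aggregate_stage(
            rows.tajima,
            rows.summaries,
            config.missing_d_policy,
            config.nonsyn_d_threshold,
            config.syn_d_threshold,
        )
    except Exception as exc:
        raise PipelineError(f"stage 'cross-population aggregation' failed: {exc}") from exc
    paths["gene_crosspop"] = reporting.write_tsv(crosspop_df, out / "gene_crosspop.tsv")
    paths["selection_flags"] = reporting.write_tsv(flags_df, out / "selection_flags.tsv")

    # -- reports ------------------------------------------------------------
    stage("reports")
    try:
        all_estimates = [e for e in estimates if e.stratum == "all"]
        table1 = reporting.make_table1(all_estimates, mean_d_by_population(tajima_df))
        table2 = reporting.make_table2(crosspop, flags)
    except Exception as exc:
        raise PipelineError(f"stage 'reports' failed: {exc}") from exc
    paths["population_summary"] = reporting.write_tsv(table1, out / "population_summary.tsv")
    paths["table2"] = reporting.write_tsv(table2, out / "table2.tsv")

    metrics = {
        "n_genes": int(summary_df["gene"].nunique()),
        "n_populations": int(len({p for p in population_map.values()})),
        "dispersion": {k: (None if math.isnan(v) else float(v)) for k, v in dispersion.items()},
        "missing_d_policy": config.missing_d_policy,
        "counting": config.counting,
        "rare_maf": config.rare_maf,
        "seed": config.seed,
        "input_sha256": input_hashes,
    }
    with open(out / "run_summary.yaml", "w") as fh:
        yaml.safe_dump(metrics, fh, sort_keys=False)
    paths["run_summary"] = out / "run_summary.yaml"
    logger.info("run complete: %d genes, %d populations", metrics["n_genes"],
                metrics["n_populations"])

    tables = {
        "summaries": summary_df,
        "tajima": tajima_df,
        "individual": individual_df,
        "individual_comparisons": ind_comp_df,
        "slopes": slopes_df,
        "slope_comparisons": comparisons_df,
        "outliers": outliers_df,
        "gene_crosspop": crosspop_df,
        "selection_flags": flags_df,
        "population_summary": table1,
        "table2": table2,
    }
    return PipelineResult(out_dir=out, tables=tables, paths=paths, metrics=metrics)
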