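"""Genotype, annotation and sample-map input with per-gene matrix assembly.

The unit of analysis is the biallelic SNP. Genotypes arrive as a VCF v4.2
with GT calls for every sample; variant-to-gene assignment and the
synonymous/nonsynonymous class come exclusively from a tab-separated
annotation table (never from positional overlap), and samples are assigned
to populations by a second tab-separated map. The central container,
:class:`GenotypeMatrix`, holds one gene's diploid alt-allele counts as a
``samples x variants`` integer matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

FUNCTIONAL_CLASSES = ("synonymous", "nonsynonymous")
STRATA = ("all", "synonymous", "nonsynonymous")

#: Label reserved for the union of all population samples.
POOLED_LABEL = "pooled"


class GenotypeIOError(ValueError):
    """Raised for malformed genotype, annotation or sample-map input."""


@dataclass
class GenotypeMatrix:
    """Diploid alt-allele counts for one gene.

    Parameters
    ----------
    gene
        Gene symbol the variants belong to.
    sample_ids
        Ordered sample identifiers (matrix rows).
    variant_ids
        Ordered variant identifiers (matrix columns).
    allele_counts
        ``(n_samples, n_variants)`` integer matrix with entries in
        ``{0, 1, 2}`` — the number of alternate alleles per diploid sample.
    functional_class
        Per-variant class, each ``"synonymous"`` or ``"nonsynonymous"``.
    """

    gene: str
    sample_ids: list[str]
    variant_ids: list[str]
    allele_counts: np.ndarray
    functional_class: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.allele_counts = np.asarray(self.allele_counts, dtype=np.int8)
        if self.allele_counts.ndim != 2:
            raise GenotypeIOError("allele_counts must be 2-D (samples x variants)")
        n_samples, n_variants = self.allele_counts.shape
        if n_samples != len(self.sample_ids) or n_variants != len(self.variant_ids):
            raise GenotypeIOError(
                f"gene {self.gene}: matrix shape {self.allele_counts.shape} does not "
                f"match {len(self.sample_ids)} samples x {len(self.variant_ids)} variants"
            )
        if self.allele_counts.size and (
            self.allele_counts.min() < 0 or self.allele_counts.max() > 2
        ):
            raise GenotypeIOError(f"gene {self.gene}: allele counts must lie in {{0,1,2}}")
        if self.functional_class is None:
            self.functional_class = np.full(n_variants, "nonsynonymous", dtype=object)
        self.functional_class = np.asarray(self.functional_class, dtype=object)
        if self.functional_class.shape != (n_variants,):
            raise GenotypeIOError(f"gene {self.gene}: one functional class per variant required")
        bad = set(self.functional_class) - set(FUNCTIONAL_CLASSES)
        if bad:
            raise GenotypeIOError(f"gene {self.gene}: unknown functional class {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    @property
    def n_chromosomes(self) -> int:
        """Number of sampled chromosomes (2 per diploid individual)."""
        return 2 * self.n_samples

    def class_mask(self, stratum: str) -> np.ndarray:
        """Boolean mask over variant columns for ``stratum``.

        ``"all"`` selects every column; ``"synonymous"`` /
        ``"nonsynonymous"`` select columns of that class.
        """
        if stratum == "all":
            return np.ones(self.n_variants, dtype=bool)
        if stratum not in FUNCTIONAL_CLASSES:
            raise GenotypeIOError(f"unknown stratum {stratum!r}")
        return self.functional_class == stratum

    def take_samples(self, indices: np.ndarray, gene: str | None = None) -> "GenotypeMatrix":
        """Row-subset matrix for the given sample indices (column-identical)."""
        return GenotypeMatrix(
            gene=gene or self.gene,
            sample_ids=[self.sample_ids[i] for i in indices],
            variant_ids=list(self.variant_ids),
            allele_counts=self.allele_counts[np.asarray(indices, dtype=int), :],
            functional_class=self.functional_class.copy(),
        )


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a variant annotation table.

    Expects a UTF-8 TSV with header columns ``variant_id``, ``gene``,
    ``functional_class``. Class strings are normalized case-insensitively to
    ``synonymous`` / ``nonsynonymous``.

    Returns a DataFrame indexed by ``variant_id`` with columns ``gene`` and
    ``functional_class``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"variant_id", "gene", "functional_class"}
    missing = required - set(df.columns)
    if missing:
        raise GenotypeIOError(f"annotation {path}: missing columns {sorted(missing)}")
    dup = df["variant_id"][df["variant_id"].duplicated()]
    if len(dup):
        raise GenotypeIOError(
            f"annotation {path}: duplicate variant_id {dup.iloc[0]!r}"
        )
    if df["gene"].isna().any() or (df["gene"].str.len() == 0).any():
        raise GenotypeIOError(f"annotation {path}: empty gene name")
    df["functional_class"] = df["functional_class"].str.lower().str.strip()
    unknown = set(df["functional_class"]) - set(FUNCTIONAL_CLASSES)
    if unknown:
        raise GenotypeIOError(
            f"annotation {path}: unknown functional class label(s) {sorted(unknown)}"
        )
    return df.set_index("variant_id")


def read_population_map(path: str | Path) -> dict[str, str]:
    """Read the sample-to-population map (TSV: ``sample_id``, ``population``).

    Every sample belongs to exactly one population and every population must
    have at least two samples.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "population"}
    missing = required - set(df.columns)
    if missing:
        raise GenotypeIOError(f"sample map {path}: missing columns {sorted(missing)}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise GenotypeIOError(f"sample map {path}: duplicate sample_id {dup.iloc[0]!r}")
    counts = df["population"].value_counts()
    small = counts[counts < 2]
    if len(small):
        raise GenotypeIOError(
            f"sample map {path}: population(s) with fewer than 2 samples: "
            f"{sorted(small.index)}"
        )
    if POOLED_LABEL in counts.index:
        raise GenotypeIOError(
            f"sample map {path}: population label {POOLED_LABEL!r} is reserved"
        )
    return dict(zip(df["sample_id"], df["population"]))


def read_vcf(
    path: str | Path,
    annotation: pd.DataFrame,
    population_map: Mapping[str, str],
    missing: str = "strict",
) -> list[GenotypeMatrix]:
    """Load a VCF into per-gene :class:`GenotypeMatrix` objects.

    Only biallelic SNPs annotated in ``annotation`` are retained;
    multiallelic or non-SNP records are rejected with a logged warning, as
    are variants whose id is absent from the annotation. Samples not present
    in ``population_map`` are dropped with a logged warning.

    Parameters
    ----------
    missing
        ``"strict"`` (default): any missing genotype call is a hard error
        naming the sample and variant. ``"drop"``: a variant with one or
        more missing calls is dropped, logged per variant.
    """
    if missing not in ("strict", "drop"):
        raise GenotypeIOError(f"missing policy must be 'strict' or 'drop', got {missing!r}")
    vcf = VCF(str(path), gts012=True)
    all_samples = list(vcf.samples)
    kept_samples = [s for s in all_samples if s in population_map]
    dropped = [s for s in all_samples if s not in population_map]
    if dropped:
        logger.warning(
            "VCF %s: dropping %d sample(s) absent from the population map (e.g. %s)",
            path, len(dropped), dropped[0],
        )
    if not kept_samples:
        raise GenotypeIOError(f"VCF {path}: no sample overlaps the population map")
    if kept_samples != all_samples:
        vcf.set_samples(kept_samples)
        kept_samples = list(vcf.samples)

    ann_gene = annotation["gene"]
    ann_class = annotation["functional_class"]
    # per-gene accumulators, in order of first appearance in the VCF
    genes: dict[str, dict[str, list]] = {}
    n_records = 0
    for record in vcf:
        n_records += 1
        vid = record.ID
        if len(record.ALT) != 1 or len(record.REF) != 1 or len(record.ALT[0]) != 1:
            logger.warning(
                "VCF %s: rejecting multiallelic/non-SNP record %s at %s:%d",
                path, vid, record.CHROM, record.POS,
            )
            continue
        if vid is None or vid not in ann_gene.index:
            logger.warning(
                "VCF %s: dropping unannotated variant %s at %s:%d",
                path, vid, record.CHROM, record.POS,
            )
            continue
        if "GT" not in record.FORMAT:
            raise GenotypeIOError(
                f"VCF {path}: record {vid} at {record.CHROM}:{record.POS} has no GT field"
            )
        gts = record.gt_types  # gts012: 0/1/2 = alt-allele count, 3 = missing
        miss = gts == 3
        if miss.any():
            if missing == "strict":
                i = int(np.flatnonzero(miss)[0])
                raise GenotypeIOError(
                    f"VCF {path}: missing genotype for sample {kept_samples[i]!r} "
                    f"at variant {vid!r}"
                )
            logger.warning("VCF %s: dropping variant %s with missing call(s)", path, vid)
            continue
        gene = ann_gene.loc[vid]
        bucket = genes.setdefault(gene, {"ids": [], "cols": [], "cls": []})
        bucket["ids"].append(vid)
        bucket["cols"].append(gts.astype(np.int8))
        bucket["cls"].append(ann_class.loc[vid])

    if n_records == 0:
        logger.warning("VCF %s: no records", path)
    matrices = []
    for gene, bucket in genes.items():
        matrices.append(
            GenotypeMatrix(
                gene=gene,
                sample_ids=list(kept_samples),
                variant_ids=bucket["ids"],
                allele_counts=np.column_stack(bucket["cols"]),
                functional_class=np.array(bucket["cls"], dtype=object),
            )
        )
    return matrices


def split_by_population(
    matrix: GenotypeMatrix, population_map: Mapping[str, str]
) -> dict[str, GenotypeMatrix]:
    """Partition a gene matrix by population, plus a pooled entry.

    Returns a mapping ``population label -> GenotypeMatrix`` containing one
    column-identical submatrix per population and a ``"pooled"`` entry with
    all samples. Columns monomorphic within a population are retained here;
    they are excluded downstream where per-sample statistics are computed.
    """
    missing = [s for s in matrix.sample_ids if s not in population_map]
    if missing:
        raise GenotypeIOError(
            f"gene {matrix.gene}: sample {missing[0]!r} absent from population map"
        )
    labels = [population_map[s] for s in matrix.sample_ids]
    out: dict[str, GenotypeMatrix] = {}
    for pop in sorted(set(labels)):
        idx = np.flatnonzero(np.array(labels, dtype=object) == pop)
        out[pop] = matrix.take_samples(idx)
    out[POOLED_LABEL] = matrix.take_samples(np.arange(matrix.n_samples))
    return out
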