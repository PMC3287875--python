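import numpy as np
import pytest

from rvdensity.genotype_io import GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20110929)


def make_matrix(counts, classes=None, gene="G1", sample_prefix="s", variant_prefix="v"):
    """GenotypeMatrix from a nested list of diploid alt counts (samples x variants)."""
    counts = np.asarray(counts, dtype=np.int8)
    n_samples, n_variants = counts.shape
    if classes is None:
        classes = ["nonsynonymous"] * n_variants
    return GenotypeMatrix(
        gene=gene,
        sample_ids=[f"{sample_prefix}{i + 1}" for i in range(n_samples)],
        variant_ids=[f"{variant_prefix}{j + 1}" for j in range(n_variants)],
        allele_counts=counts,
        functional_class=np.array(classes, dtype=object),
    )


def random_matrix(rng, n_samples, n_variants, gene="G1"):
    """Random diploid matrix with a mix of frequencies and classes."""
    hap = rng.random((2 * n_samples, n_variants)) < rng.uniform(0.02, 0.6, n_variants)
    counts = hap[0::2].astype(np.int8) + hap[1::2].astype(np.int8)
    classes = np.where(rng.random(n_variants) < 0.5, "nonsynonymous", "synonymous")
    return make_matrix(counts, list(classes), gene=gene)


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def write_vcf(path, samples, records, contigs=("chr1",)):
    """Write a small VCF; each record is (chrom, pos, vid, ref, alt, gts)."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for chrom, pos, vid, ref, alt, gts in records:
            fh.write(f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")
    return path


def write_tsv(path, header, rows):
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    return path
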