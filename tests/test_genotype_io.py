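"""Input validation, per-gene assembly and population partitioning."""

import numpy as np
import pytest

from rvdensity.genotype_io import (
    GenotypeIOError,
    GenotypeMatrix,
    read_annotation,
    read_population_map,
    read_vcf,
    split_by_population,
)
from rvdensity.synthetic_data import (
    PopulationConfig,
    SimulationConfig,
    simulate_dataset,
    write_dataset,
)

from conftest import make_matrix, write_tsv, write_vcf

GTS_OK = ["0/0", "0/1", "1/1"]


@pytest.fixture
def annotation_file(tmp_path):
    return write_tsv(
        tmp_path / "ann.tsv",
        ["variant_id", "gene", "functional_class"],
        [
            ["v1", "A", "synonymous"],
            ["v2", "A", "Nonsynonymous"],
            ["v3", "B", "nonsynonymous"],
            ["v4", "B", "synonymous"],
            ["v5", "B", "synonymous"],
        ],
    )


@pytest.fixture
def samples_file(tmp_path):
    return write_tsv(
        tmp_path / "samples.tsv",
        ["sample_id", "population"],
        [["s1", "P1"], ["s2", "P1"], ["s3", "P2"], ["s4", "P2"]],
    )


class TestReadAnnotation:
    def test_reads_and_normalizes_class_case(self, annotation_file):
        ann = read_annotation(annotation_file)
        assert len(ann) == 5
        assert ann.loc["v2", "functional_class"] == "nonsynonymous"
        assert ann.loc["v1", "gene"] == "A"

    def test_duplicate_variant_id_names_the_id(self, tmp_path):
        path = write_tsv(
            tmp_path / "dup.tsv",
            ["variant_id", "gene", "functional_class"],
            [["v1", "A", "synonymous"], ["v1", "A", "synonymous"]],
        )
        with pytest.raises(GenotypeIOError, match="v1"):
            read_annotation(path)

    def test_unknown_class_rejected(self, tmp_path):
        path = write_tsv(
            tmp_path / "bad.tsv",
            ["variant_id", "gene", "functional_class"],
            [["v1", "A", "missense"]],
        )
        with pytest.raises(GenotypeIOError, match="missense"):
            read_annotation(path)


class TestReadPopulationMap:
    def test_reads_map(self, samples_file):
        popmap = read_population_map(samples_file)
        assert popmap == {"s1": "P1", "s2": "P1", "s3": "P2", "s4": "P2"}

    def test_singleton_population_rejected(self, tmp_path):
        path = write_tsv(
            tmp_path / "m.tsv", ["sample_id", "population"],
            [["s1", "P1"], ["s2", "P1"], ["s3", "P2"]],
        )
        with pytest.raises(GenotypeIOError, match="P2"):
            read_population_map(path)


class TestReadVcf:
    samples = ["s1", "s2", "s3", "s4"]

    def test_empty_vcf_gives_empty_gene_list(self, tmp_path, annotation_file, samples_file):
        vcf = write_vcf(tmp_path / "empty.vcf", self.samples, [])
        ann = read_annotation(annotation_file)
        popmap = read_population_map(samples_file)
        assert read_vcf(vcf, ann, popmap) == []

    def test_groups_variants_by_annotated_gene(self, tmp_path, annotation_file, samples_file):
        records = [
            ("chr1", 10, "v1", "A", "T", ["0/0", "0/1", "0/0", "0/0"]),
            ("chr1", 20, "v2", "C", "G", ["0/1", "1/1", "0/0", "0/1"]),
            ("chr1", 30, "v3", "G", "A", ["0/0", "0/0", "0/1", "0/0"]),
        ]
        vcf = write_vcf(tmp_path / "three.vcf", self.samples, records)
        matrices = read_vcf(
            vcf, read_annotation(annotation_file), read_population_map(samples_file)
        )
        by_gene = {m.gene: m for m in matrices}
        assert set(by_gene) == {"A", "B"}
        assert by_gene["A"].n_variants == 2
        assert by_gene["B"].n_variants == 1
        np.testing.assert_array_equal(by_gene["A"].allele_counts,
                                      [[0, 1], [1, 2], [0, 0], [0, 1]])
        assert list(by_gene["A"].functional_class) == ["synonymous", "nonsynonymous"]

    def test_multiallelic_record_rejected(self, tmp_path, annotation_file, samples_file, caplog):
        gts = ["0/0", "0/1", "0/0", "0/0"]
        records = [
            ("chr1", 10, "v1", "A", "T", gts),
            ("chr1", 20, "v2", "C", "G", gts),
            ("chr1", 30, "v3", "G", "A,C", ["0/0", "0/2", "0/1", "0/0"]),
            ("chr1", 40, "v4", "T", "C", gts),
            ("chr1", 50, "v5", "A", "G", gts),
        ]
        vcf = write_vcf(tmp_path / "multi.vcf", self.samples, records)
        with caplog.at_level("WARNING"):
            matrices = read_vcf(
                vcf, read_annotation(annotation_file), read_population_map(samples_file)
            )
        assert sum(m.n_variants for m in matrices) == 4
        assert sum("multiallelic" in r.message for r in caplog.records) == 1

    def test_unannotated_variant_dropped(self, tmp_path, annotation_file, samples_file):
        records = [
            ("chr1", 10, "v1", "A", "T", ["0/0", "0/1", "0/0", "0/0"]),
            ("chr1", 20, "vX", "C", "G", ["0/1", "0/0", "0/0", "0/0"]),
        ]
        vcf = write_vcf(tmp_path / "unann.vcf", self.samples, records)
        matrices = read_vcf(
            vcf, read_annotation(annotation_file), read_population_map(samples_file)
        )
        assert sum(m.n_variants for m in matrices) == 1

    def test_missing_call_is_hard_error_in_strict_mode(
        self, tmp_path, annotation_file, samples_file
    ):
        records = [("chr1", 10, "v1", "A", "T", ["0/0", "./.", "0/0", "0/0"])]
        vcf = write_vcf(tmp_path / "miss.vcf", self.samples, records)
        with pytest.raises(GenotypeIOError, match="s2.*v1"):
            read_vcf(vcf, read_annotation(annotation_file),
                     read_population_map(samples_file), missing="strict")

    def test_missing_call_drops_variant_in_drop_mode(
        self, tmp_path, annotation_file, samples_file
    ):
        records = [
            ("chr1", 10, "v1", "A", "T", ["0/0", "./.", "0/0", "0/0"]),
            ("chr1", 20, "v2", "C", "G", ["0/1", "0/0", "0/0", "0/0"]),
        ]
        vcf = write_vcf(tmp_path / "miss2.vcf", self.samples, records)
        matrices = read_vcf(vcf, read_annotation(annotation_file),
                            read_population_map(samples_file), missing="drop")
        assert sum(m.n_variants for m in matrices) == 1

    def test_phased_and_unphased_calls_count_alike(self, tmp_path, annotation_file, samples_file):
        records = [("chr1", 10, "v1", "A", "T", ["0|1", "0/1", "1|1", "0/0"])]
        vcf = write_vcf(tmp_path / "phase.vcf", self.samples, records)
        (m,) = read_vcf(vcf, read_annotation(annotation_file),
                        read_population_map(samples_file))
        np.testing.assert_array_equal(m.allele_counts[:, 0], [1, 1, 2, 0])


class TestSplitByPopulation:
    def test_two_populations_plus_pooled(self):
        m = make_matrix([[0, 1], [1, 0], [2, 0], [0, 0]])
        popmap = {"s1": "P1", "s2": "P1", "s3": "P2", "s4": "P2"}
        parts = split_by_population(m, popmap)
        assert set(parts) == {"P1", "P2", "pooled"}
        assert parts["pooled"].n_samples == 4
        np.testing.assert_array_equal(parts["P1"].allele_counts, [[0, 1], [1, 0]])
        np.testing.assert_array_equal(parts["P2"].allele_counts, [[2, 0], [0, 0]])

    def test_single_population_equals_pooled(self):
        m = make_matrix([[0, 1], [1, 0]])
        parts = split_by_population(m, {"s1": "P1", "s2": "P1"})
        np.testing.assert_array_equal(parts["P1"].allele_counts,
                                      parts["pooled"].allele_counts)
        assert parts["P1"].sample_ids == parts["pooled"].sample_ids

    def test_seven_population_panel_pools_697_samples(self):
        sizes = {"CEPH": 90, "DenverChinese": 107, "HanChinese": 109, "Japanese": 105,
                 "Luhya": 108, "Tuscan": 66, "Yoruba": 112}
        popmap = {}
        for pop, n in sizes.items():
            for i in range(n):
                popmap[f"{pop}_{i}"] = pop
        samples = list(popmap)
        m = GenotypeMatrix(
            gene="G", sample_ids=samples, variant_ids=["v1"],
            allele_counts=np.zeros((len(samples), 1), dtype=np.int8),
            functional_class=np.array(["synonymous"], dtype=object),
        )
        parts = split_by_population(m, popmap)
        assert parts["pooled"].n_samples == 697
        assert {p: parts[p].n_samples for p in sizes} == sizes

    def test_partition_is_disjoint_and_covers_pooled(self, rng):
        from conftest import random_matrix
        m = random_matrix(rng, 12, 5)
        popmap = {s: f"P{i % 3}" for i, s in enumerate(m.sample_ids)}
        parts = split_by_population(m, popmap)
        pop_samples = [s for p, sub in parts.items() if p != "pooled"
                       for s in sub.sample_ids]
        assert len(pop_samples) == len(set(pop_samples))
        assert set(pop_samples) == set(parts["pooled"].sample_ids)

    def test_unmapped_sample_is_hard_error(self):
        m = make_matrix([[0], [1]])
        with pytest.raises(GenotypeIOError, match="s2"):
            split_by_population(m, {"s1": "P1"})


class TestRoundTrip:
    def test_written_dataset_reloads_identically(self, tmp_path):
        config = SimulationConfig(
            seed=7, n_genes=4,
            populations=[PopulationConfig("A", 5, 1.0), PopulationConfig("B", 4, 1.5)],
            theta_per_gene=4.0, p_nonsyn=0.5,
        )
        dataset = simulate_dataset(config)
        paths = write_dataset(dataset, tmp_path / "ds")
        ann = read_annotation(paths["annotation"])
        popmap = read_population_map(paths["samples"])
        matrices = read_vcf(paths["vcf"], ann, popmap)
        by_gene = {m.gene: m for m in matrices}
        for original in dataset.matrices:
            if original.n_variants == 0:
                assert original.gene not in by_gene
                continue
            loaded = by_gene[original.gene]
            assert loaded.sample_ids == original.sample_ids
            assert loaded.variant_ids == original.variant_ids
            np.testing.assert_array_equal(loaded.allele_counts, original.allele_counts)
            assert list(loaded.functional_class) == list(original.functional_class)
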