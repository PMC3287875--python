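"""Generator distributional checks, determinism and the coalescent calibrator."""

import filecmp

import numpy as np
import pytest

from rvdensity.genotype_io import read_annotation, read_population_map, read_vcf
from rvdensity.synthetic_data import (
    PopulationConfig,
    SimulationConfig,
    _place_derived,
    draw_sfs_counts,
    draw_sfs_site,
    sample_coalescent_times,
    sfs_site_distribution,
    simulate_coalescent_gene,
    simulate_dataset,
    simulate_gene,
    write_dataset,
)
from rvdensity.tajima import tajima_coefficients


def two_pop_config(**kwargs):
    defaults = dict(
        seed=3, n_genes=5,
        populations=[PopulationConfig("A", 6, 1.0), PopulationConfig("B", 4, 1.8)],
        theta_per_gene=4.0, p_nonsyn=0.5,
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


class TestSfsDraw:
    def test_pair_sample_only_allows_singletons(self, rng):
        assert all(draw_sfs_site(2, 1.0, rng) == 1 for _ in range(20))

    def test_large_skew_concentrates_on_singletons(self):
        # direct computation of the normalized distribution, alpha = 12
        p = sfs_site_distribution(100, 12.0)
        assert p[0] >= 0.99

    def test_neutral_tilt_reproduces_watterson_singleton_share(self, rng):
        # expected singleton fraction at alpha=1 is (1/1) / a1(n)
        draws = draw_sfs_counts(100, 1.0, 100_000, rng)
        expected = 1.0 / tajima_coefficients(100).a1
        assert np.mean(draws == 1) == pytest.approx(expected, abs=0.01)

    def test_invalid_alpha_rejected(self, rng):
        with pytest.raises(ValueError):
            draw_sfs_site(10, 0.5, rng)


class TestSimulateGene:
    def test_zero_theta_gives_no_sites(self):
        config = two_pop_config(theta_per_gene=0.0)
        m = simulate_gene(config, 0, "A")
        assert m.n_variants == 0

    def test_placement_matrix_rows_sum_to_drawn_counts(self, rng):
        k = rng.integers(1, 20, size=50)
        hap = _place_derived(k, 20, rng)
        np.testing.assert_array_equal(hap.sum(axis=1), k)
        assert set(np.unique(hap)) <= {0, 1}

    def test_column_totals_lie_in_polymorphic_range(self):
        config = two_pop_config(theta_per_gene=8.0)
        m = simulate_gene(config, 2, "A")
        totals = m.allele_counts.sum(axis=0)
        assert ((totals >= 1) & (totals <= m.n_chromosomes - 1)).all()

    def test_mean_segregating_sites_matches_watterson_expectation(self):
        # E[S] = theta * a1(n); Monte Carlo over genes
        config = SimulationConfig(
            seed=11, n_genes=1500,
            populations=[PopulationConfig("A", 25, 1.0)], theta_per_gene=5.0,
        )
        s = [simulate_gene(config, g, "A").n_variants for g in range(config.n_genes)]
        expected = 5.0 * tajima_coefficients(50).a1
        assert np.mean(s) == pytest.approx(expected, rel=0.05)

    def test_same_seed_reproduces_gene_regardless_of_call_order(self):
        config = two_pop_config()
        m1 = simulate_gene(config, 3, "B")
        _ = simulate_gene(config, 1, "A")
        m2 = simulate_gene(config, 3, "B")
        np.testing.assert_array_equal(m1.allele_counts, m2.allele_counts)
        assert m1.variant_ids == m2.variant_ids


class TestCoalescent:
    def test_pair_tmrca_expectation(self, rng):
        times = np.array([sample_coalescent_times(2, rng).sum() for _ in range(10_000)])
        assert times.mean() == pytest.approx(1.0, rel=0.03)

    def test_mean_segregating_sites_matches_watterson_expectation(self, rng):
        s = [simulate_coalescent_gene(10, 5.0, rng).n_variants for _ in range(5000)]
        expected = 5.0 * tajima_coefficients(10).a1  # ~14.14
        assert np.mean(s) == pytest.approx(expected, rel=0.03)

    def test_vanishing_theta_gives_no_sites(self, rng):
        assert all(
            simulate_coalescent_gene(10, 1e-6, rng).n_variants == 0 for _ in range(100)
        )

    def test_site_columns_are_polymorphic(self, rng):
        m = simulate_coalescent_gene(20, 5.0, rng)
        totals = m.allele_counts.sum(axis=0)
        assert ((totals >= 1) & (totals <= 19)).all()

    def test_odd_chromosome_count_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_coalescent_gene(5, 1.0, rng)


class TestWriteDataset:
    def test_same_seed_gives_byte_identical_files(self, tmp_path):
        for d in ("run1", "run2"):
            write_dataset(simulate_dataset(two_pop_config()), tmp_path / d)
        for name in ("genotypes.vcf", "annotation.tsv", "samples.tsv", "provenance.yaml"):
            assert filecmp.cmp(tmp_path / "run1" / name, tmp_path / "run2" / name,
                               shallow=False), name

    def test_different_seed_changes_genotypes(self, tmp_path):
        write_dataset(simulate_dataset(two_pop_config(seed=3)), tmp_path / "a")
        write_dataset(simulate_dataset(two_pop_config(seed=4)), tmp_path / "b")
        assert not filecmp.cmp(tmp_path / "a" / "genotypes.vcf",
                               tmp_path / "b" / "genotypes.vcf", shallow=False)

    def test_variant_free_dataset_writes_header_only_vcf(self, tmp_path):
        config = two_pop_config(theta_per_gene=0.0)
        paths = write_dataset(simulate_dataset(config), tmp_path / "empty")
        lines = paths["vcf"].read_text().splitlines()
        assert all(line.startswith("#") for line in lines)
        ann = read_annotation(paths["annotation"])
        popmap = read_population_map(paths["samples"])
        assert read_vcf(paths["vcf"], ann, popmap) == []

    def test_population_blocks_are_private(self):
        """Each variant segregates only within its source population."""
        dataset = simulate_dataset(two_pop_config(theta_per_gene=6.0))
        popmap = dataset.population_map
        for m in dataset.matrices:
            rows_a = [i for i, s in enumerate(m.sample_ids) if popmap[s] == "A"]
            rows_b = [i for i, s in enumerate(m.sample_ids) if popmap[s] == "B"]
            for j, vid in enumerate(m.variant_ids):
                col = m.allele_counts[:, j]
                if "_A_" in vid:
                    assert col[rows_b].sum() == 0 and col[rows_a].sum() > 0
                else:
                    assert col[rows_a].sum() == 0 and col[rows_b].sum() > 0
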