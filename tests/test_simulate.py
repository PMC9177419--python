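"""Generator contracts: determinism, analytic laws, ground-truth integrity."""

import numpy as np
import pytest

from jvscan.containers import GT_HET
from jvscan.layout import GenomeLayout, Inversion
from jvscan.simulate import (
    SimConfig,
    make_scaffold_map,
    simulate_ase,
    simulate_chrseq,
    simulate_diverged_cds,
    simulate_f2,
    simulate_gametes,
    simulate_island_panel,
    simulate_parent,
    simulate_population,
)


@pytest.fixture
def strata_layout():
    return GenomeLayout(
        (("chrA", 100_000_000),),
        (
            Inversion("chrA", 5_000_000, 30_000_000, 1),
            Inversion("chrA", 35_000_000, 60_000_000, 2),
            Inversion("chrA", 65_000_000, 90_000_000, 3),
        ),
    )


class TestParent:
    def test_marker_density_ranks_follow_stratum_divergence(self, strata_layout):
        cfg = SimConfig(
            layout=strata_layout,
            map_lengths={"chrA": 1.0},
            suppressed=(),
            markers_per_chromosome=3000,
            stratum_divergence={1: 0.0064, 2: 0.0052, 3: 0.0090},
            seed=1,
        )
        markers, parent, truth = simulate_parent(cfg)
        pos = markers["pos"].to_numpy()
        counts = {
            s: int(((pos >= inv.start) & (pos < inv.end)).sum())
            for s, inv in zip((1, 2, 3), strata_layout.inversions)
        }
        # equal-length inversions: counts must rank s3 > s1 > s2
        assert counts[3] > counts[1] > counts[2]

    def test_parent_het_everywhere(self, strata_layout):
        cfg = SimConfig(layout=strata_layout, suppressed=(),
                        markers_per_chromosome=100, seed=2)
        _, parent, _ = simulate_parent(cfg)
        assert (parent.codes == GT_HET).all()

    def test_fixed_seed_reproducible(self, strata_layout):
        cfg = SimConfig(layout=strata_layout, suppressed=(),
                        markers_per_chromosome=50, seed=7)
        m1, _, t1 = simulate_parent(cfg)
        m2, _, t2 = simulate_parent(cfg)
        assert m1.equals(m2)
        np.testing.assert_array_equal(t1.j_allele, t2.j_allele)

    def test_out_of_range_divergence_rejected(self, strata_layout):
        with pytest.raises(ValueError):
            SimConfig(layout=strata_layout,
                      stratum_divergence={1: 0.3}, seed=0)

    def test_zero_markers_rejected(self, strata_layout):
        with pytest.raises(ValueError):
            SimConfig(layout=strata_layout, markers_per_chromosome=0)


class TestGametes:
    def test_zero_map_gives_zero_crossovers(self, single_chrom_layout):
        cfg = SimConfig(layout=single_chrom_layout, map_lengths={"chrA": 0.0},
                        suppressed=(), markers_per_chromosome=50, seed=3)
        markers, _, truth = simulate_parent(cfg)
        _, gtruth = simulate_gametes(markers, truth, cfg, 50, "sperm")
        assert all(
            len(bk["chrA"]) == 0 for bk in gtruth.crossovers.values()
        )

    def test_poisson_mean_one_morgan(self, single_chrom_layout):
        cfg = SimConfig(layout=single_chrom_layout, map_lengths={"chrA": 1.0},
                        suppressed=(), markers_per_chromosome=20, seed=4)
        markers, _, truth = simulate_parent(cfg)
        _, gtruth = simulate_gametes(markers, truth, cfg, 1000, "sperm")
        counts = np.array([len(b["chrA"]) for b in gtruth.crossovers.values()])
        # Poisson(1): sample mean within 3 standard errors of 1.0
        assert abs(counts.mean() - 1.0) < 3.0 / np.sqrt(1000)

    def test_noise_free_calls_match_haplotype_truth(self, single_chrom_layout):
        cfg = SimConfig(layout=single_chrom_layout, map_lengths={"chrA": 0.0},
                        suppressed=(), gene_conversion_rate=0.0,
                        error_rate=0.0, missing_rate=0.0,
                        markers_per_chromosome=40, seed=5)
        markers, _, truth = simulate_parent(cfg)
        gametes, _ = simulate_gametes(markers, truth, cfg, 10, "oocyte")
        # no recombination, no noise: each gamete is pure J or pure V
        j = truth.j_allele
        for g in range(10):
            col = gametes.calls[:, g]
            assert (col == j).all() or (col == 1 - j).all()

    def test_breakpoints_strictly_between_markers(self, single_chrom_layout):
        cfg = SimConfig(layout=single_chrom_layout, map_lengths={"chrA": 3.0},
                        suppressed=(), markers_per_chromosome=50, seed=6)
        markers, _, truth = simulate_parent(cfg)
        _, gtruth = simulate_gametes(markers, truth, cfg, 50, "sperm")
        positions = set(markers["pos"].tolist())
        for bk in gtruth.crossovers.values():
            assert not positions & set(bk["chrA"])


class TestPopulation:
    def test_balanced_lethal_locks_chr1_heterozygosity(self):
        cfg = SimConfig(markers_per_chromosome=30, seed=8)
        table = simulate_population(cfg, 20, "balanced_lethal", 0.5)
        chr1 = (table.markers["chrom"] == "chr1").to_numpy()
        assert (table.codes[chr1] == GT_HET).all()

    def test_panmictic_het_matches_binomial(self):
        cfg = SimConfig(markers_per_chromosome=500, seed=9)
        table = simulate_population(cfg, 50, "panmictic", 0.5)
        het = (table.codes == GT_HET).mean()
        n = table.codes.size
        # HWE at p=0.5: P(het) = 0.5
        assert abs(het - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_single_individual_rejected(self):
        cfg = SimConfig(markers_per_chromosome=10, seed=10)
        with pytest.raises(ValueError):
            simulate_population(cfg, 1, "panmictic", 0.5)

    def test_island_panel_locks_only_listed_populations(self):
        cfg = SimConfig(markers_per_chromosome=40, seed=11)
        table, labels = simulate_island_panel(
            cfg, {"SAR": 6, "SIC": 6}, locked_populations=("SAR",)
        )
        chr1 = (table.markers["chrom"] == "chr1").to_numpy()
        sar = [i for i, l in enumerate(labels) if l == "SAR"]
        sic = [i for i, l in enumerate(labels) if l == "SIC"]
        assert (table.codes[np.ix_(chr1, sar)] == GT_HET).all()
        assert not (table.codes[np.ix_(chr1, sic)] == GT_HET).all()


class TestChrSeq:
    def test_noiseless_depth_separates_truth(self, small_layout):
        smap = make_scaffold_map(small_layout, 30, seed=1)
        cov = simulate_chrseq(smap, 3, contamination=0.0, noise_sigma=0.0,
                              seed=2)
        for scaffold in cov.scaffolds:
            best = cov.depths.loc[scaffold].idxmax()
            assert cov.sample_chrom[best] == smap[scaffold]

    def test_reproducible_matrix(self, small_layout):
        smap = make_scaffold_map(small_layout, 10, seed=3)
        a = simulate_chrseq(smap, 2, 0.1, 0.3, seed=4)
        b = simulate_chrseq(smap, 2, 0.1, 0.3, seed=4)
        assert a.depths.equals(b.depths)

    def test_single_sample_per_chromosome_rejected(self, small_layout):
        smap = make_scaffold_map(small_layout, 5, seed=5)
        with pytest.raises(ValueError):
            simulate_chrseq(smap, 1)


class TestF2:
    def test_zero_map_reproduces_f1_pattern(self, single_chrom_layout):
        cfg = SimConfig(layout=single_chrom_layout, map_lengths={"chrA": 0.0},
                        suppressed=(), markers_per_chromosome=30, seed=12)
        _, f2, _ = simulate_f2(cfg, 40)
        # each segregant = one whole haplotype from each parent meiosis:
        # genotype constant along the chromosome
        for j in range(f2.n_individuals):
            assert len(set(f2.codes[:, j].tolist())) == 1

    def test_recombinant_count_matches_expectation(self, single_chrom_layout):
        cfg = SimConfig(layout=single_chrom_layout,
                        map_lengths={"chrA": 0.005}, suppressed=(),
                        markers_per_chromosome=20, seed=13)
        _, _, truth = simulate_f2(cfg, 2000)
        n_events = sum(
            len(g["chrA"]) for pair in truth.crossovers.values() for g in pair
        )
        lam = 2000 * 2 * 0.005  # segregants x meioses x Morgans
        assert abs(n_events - lam) < 3 * np.sqrt(lam)

    def test_non_informative_parent_markers_excluded(self, single_chrom_layout):
        from conftest import make_genotypes

        cfg = SimConfig(layout=single_chrom_layout, markers_per_chromosome=5,
                        suppressed=(), seed=14)
        parents = make_genotypes(
            [[0, 2], [0, 2], [1, 2], [0, 2]], chrom="chrA",
            names=["p1", "p2"],
        )
        with pytest.warns(UserWarning, match="non-informative"):
            kept, _, _ = simulate_f2(cfg, 5, parents=parents)
        assert kept.n_markers == 3


class TestAse:
    def test_depth_split_across_variants(self):
        table, _ = simulate_ase(5, 0.5, depth=200, variants_per_gene=3, seed=1)
        per_gene = table.groupby("gene")[["j_count", "v_count"]].sum().sum(axis=1)
        assert (per_gene == 200).all()

    def test_extreme_bias_rejected(self):
        with pytest.raises(ValueError):
            simulate_ase(3, 1.0, depth=10)

    def test_binomial_law(self):
        table, _ = simulate_ase(500, 0.7, depth=100, variants_per_gene=1,
                                seed=2)
        frac = (table["j_count"] / 100).mean()
        assert abs(frac - 0.7) < 3 * np.sqrt(0.7 * 0.3 / (100 * 500))


class TestDivergedCds:
    def test_zero_age_gives_identical_sequences(self):
        a, b = simulate_diverged_cds(1000, 0.0, seed=3)
        assert a == b

    def test_in_frame_and_acgt_only(self):
        a, b = simulate_diverged_cds(100, 1e5, seed=4)
        assert len(a) == len(b) == 300
        assert set(a) <= set("ACGT")
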