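"""Population scans: site filters, heterozygosity, IBS, FST, J/V calls."""

import itertools

import numpy as np
import pandas as pd
import pytest

from jvscan.containers import GT_HET, GT_HOM_ALT, GT_HOM_REF, GT_MISSING
from jvscan.layout import GenomeLayout
from jvscan.popgen import (
    PopulationPanel,
    classify_jv,
    filter_sites,
    het_window_scan,
    hudson_fst,
    ibs_matrix,
    obs_exp_het,
)
from jvscan.simulate import SimConfig, simulate_island_panel, simulate_population

from conftest import make_genotypes


def panel_from(codes, pops=None, **kw):
    table = make_genotypes(codes, **kw)
    return PopulationPanel(table, pops or ["P"] * table.n_individuals)


class TestFilterSites:
    def test_low_maf_site_removed(self):
        # 1 alt allele among 26 -> MAF 0.038 < 0.04
        codes = np.zeros((2, 13), dtype=np.int8)
        codes[0, 0] = GT_HET
        codes[1, :6] = GT_HET  # healthy MAF companion site
        panel = filter_sites(panel_from(codes))
        assert panel.table.n_markers == 1

    def test_fully_heterozygous_site_removed(self):
        codes = np.full((2, 10), GT_HET, dtype=np.int8)
        codes[1, 0] = GT_HOM_REF
        panel = filter_sites(panel_from(codes))
        # site 0: obs het 1.0 > 0.99 -> dropped; site 1: 0.9 kept
        assert panel.table.n_markers == 1

    def test_low_presence_site_removed(self):
        codes = np.tile(np.array([[GT_HET]], dtype=np.int8), (2, 10))
        codes[0, :3] = GT_MISSING  # present in 70% < 75%
        codes[1, 0] = GT_HOM_REF   # keep site 1 below max-obs-het
        panel = filter_sites(panel_from(codes))
        assert panel.table.n_markers == 1

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        codes = rng.choice([-1, 0, 1, 2], size=(100, 20),
                           p=[0.1, 0.4, 0.3, 0.2]).astype(np.int8)
        once = filter_sites(panel_from(codes))
        twice = filter_sites(once)
        assert once.table.n_markers == twice.table.n_markers

    def test_empty_result_is_error(self):
        codes = np.full((3, 10), GT_HET, dtype=np.int8)
        with pytest.raises(ValueError, match="no sites"):
            filter_sites(panel_from(codes))


class TestHetWindowScan:
    def _scan(self, codes):
        layout = GenomeLayout((("chr1", 10_000),))
        panel = panel_from(codes, spacing=100)
        return het_window_scan(panel, layout, window=10_000)

    def test_strictly_above_threshold_counted(self):
        codes = np.full((1, 10), GT_HET, dtype=np.int8)
        codes[0, 0] = GT_HOM_REF  # het in 9 of 10 = 90% > 80%
        assert self._scan(codes)["het_sites"].iloc[0] == 1

    def test_exactly_at_threshold_not_counted(self):
        codes = np.full((1, 10), GT_HET, dtype=np.int8)
        codes[0, :2] = GT_HOM_REF  # het in exactly 80%
        assert self._scan(codes)["het_sites"].iloc[0] == 0

    def test_empty_window_counts_zero(self):
        layout = GenomeLayout((("chr1", 30_000),))
        panel = panel_from(np.full((1, 5), GT_HET, dtype=np.int8))
        scan = het_window_scan(panel, layout, window=10_000)
        assert scan["het_sites"].tolist() == [1, 0, 0]

    def test_missing_excluded_from_denominator(self):
        codes = np.full((1, 10), GT_HET, dtype=np.int8)
        codes[0, :5] = GT_MISSING  # 5/5 non-missing het -> 100%
        assert self._scan(codes)["het_sites"].iloc[0] == 1


class TestObsExpHet:
    def test_hwe_fixed_point(self):
        cfg = SimConfig(markers_per_chromosome=2500, seed=1)
        table = simulate_population(cfg, 100, "panmictic", 0.5)
        panel = PopulationPanel(table, ["P"] * 100)
        result = obs_exp_het(panel)
        for _, row in result.iterrows():
            assert row["observed_het"] == pytest.approx(0.5, abs=0.02)
            assert row["expected_het"] == pytest.approx(0.5, abs=0.02)

    def test_balanced_lethal_signature(self):
        cfg = SimConfig(markers_per_chromosome=200, seed=2)
        table = simulate_population(cfg, 28, "balanced_lethal", 0.5)
        result = obs_exp_het(PopulationPanel(table, ["SAR"] * 28))
        chr1 = result[result["chrom"] == "chr1"].iloc[0]
        assert chr1["observed_het"] == 1.0
        assert chr1["expected_het"] == pytest.approx(0.5, abs=1e-12)

    def test_monomorphic_sites_contribute_zero(self):
        codes = np.zeros((4, 6), dtype=np.int8)
        codes[0, :3] = GT_HET
        result = obs_exp_het(panel_from(codes))
        row = result.iloc[0]
        # one polymorphic site out of four dilutes both means
        assert row["observed_het"] == pytest.approx(0.5 / 4)

    def test_requires_two_individuals(self):
        with pytest.raises(ValueError):
            obs_exp_het(panel_from(np.zeros((2, 1), dtype=np.int8)))


class TestIbs:
    def test_sharing_convention_exhaustive(self):
        share = {(0, 0): 1.0, (1, 1): 1.0, (2, 2): 1.0,
                 (0, 1): 0.5, (1, 0): 0.5, (1, 2): 0.5, (2, 1): 0.5,
                 (0, 2): 0.0, (2, 0): 0.0}
        for (a, b), s in share.items():
            codes = np.array([[a, b]], dtype=np.int8)
            dist, _ = ibs_matrix(panel_from(codes))
            assert dist.iloc[0, 1] == pytest.approx(1 - s)

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(3)
        codes = rng.choice([0, 1, 2], size=(50, 6)).astype(np.int8)
        dist, newick = ibs_matrix(panel_from(codes))
        np.testing.assert_allclose(dist.values, dist.values.T)
        assert (np.diag(dist.values) == 0).all()
        assert newick and newick.count("(") >= 1

    def test_disjoint_pair_flagged(self):
        codes = np.array([[0, -1], [-1, 1]], dtype=np.int8)
        with pytest.warns(UserWarning, match="no shared sites"):
            dist, newick = ibs_matrix(panel_from(codes))
        assert np.isnan(dist.iloc[0, 1])
        assert newick is None


class TestFst:
    def _two_pop(self, codes1, codes2):
        codes = np.concatenate([codes1, codes2], axis=1).astype(np.int8)
        pops = ["A"] * codes1.shape[1] + ["B"] * codes2.shape[1]
        return panel_from(codes, pops=pops)

    def test_fixed_difference_gives_one(self):
        panel = self._two_pop(np.zeros((5, 8)), np.full((5, 8), 2))
        _, genome = hudson_fst(panel, "A", "B")
        assert genome == pytest.approx(1.0)

    def test_identical_frequencies_give_zero(self):
        rng = np.random.default_rng(4)
        block = rng.choice([0, 1, 2], size=(2000, 30), p=[0.25, 0.5, 0.25])
        panel = self._two_pop(block[:, :15], block[:, 15:])
        _, genome = hudson_fst(panel, "A", "B")
        assert abs(genome) < 0.02

    def test_drift_parameterised_fst_recovered(self):
        # island model: subpopulation frequencies Beta-distributed with
        # E[FST] = F
        rng = np.random.default_rng(5)
        F, p0, n, sites = 0.2, 0.5, 50, 10_000
        a = p0 * (1 - F) / F
        b = (1 - p0) * (1 - F) / F
        p1 = rng.beta(a, b, size=sites)
        p2 = rng.beta(a, b, size=sites)
        g1 = rng.binomial(1, p1[:, None], size=(sites, n)) + rng.binomial(
            1, p1[:, None], size=(sites, n)
        )
        g2 = rng.binomial(1, p2[:, None], size=(sites, n)) + rng.binomial(
            1, p2[:, None], size=(sites, n)
        )
        panel = self._two_pop(g1, g2)
        _, genome = hudson_fst(panel, "A", "B")
        assert genome == pytest.approx(F, abs=0.02)


class TestClassifyJv:
    def test_fully_het_panel_is_jv(self):
        assert classify_jv(np.full(50, GT_HET)) == "J/V"

    def test_fully_hom_panel_is_jj(self):
        assert classify_jv(np.full(50, GT_HOM_REF)) == "J/J"

    def test_half_het_is_unclassified(self):
        g = np.array([GT_HET, GT_HOM_REF] * 25)
        assert classify_jv(g) == "unclassified"

    def test_too_few_markers_unclassified(self):
        assert classify_jv(np.full(10, GT_HET)) == "unclassified"


class TestIslandContrast:
    def test_locked_chromosome_separates_by_tenfold(self):
        """Window-scan contrast between locked and panmictic islands."""
        layout = GenomeLayout((("chr1", 2_000_000), ("chr2", 1_000_000)))
        cfg = SimConfig(
            layout=layout,
            map_lengths={"chr1": 0.005, "chr2": 1.0},
            suppressed=("chr1",),
            markers_per_chromosome=400,
            gene_conversion_tract=1000,
            seed=6,
        )
        table, labels = simulate_island_panel(
            cfg, {"SAR": 14, "COR": 10, "SIC": 14, "TUN": 10},
            locked_populations=("SAR", "COR"),
        )
        panel = filter_sites(PopulationPanel(table, labels))
        means = {}
        for pop in ("SAR", "COR", "SIC", "TUN"):
            scan = het_window_scan(panel.subset_population(pop), layout,
                                   window=100_000)
            for chrom, grp in scan.groupby("chrom"):
                means[(pop, chrom)] = grp["het_sites"].mean()
        locked = [means[(p, "chr1")] for p in ("SAR", "COR")]
        rest = [v for k, v in means.items()
                if k not in {("SAR", "chr1"), ("COR", "chr1")}]
        assert min(locked) >= 10 * max(max(rest), 1e-9)
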