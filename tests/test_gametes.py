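"""Marker filtering, minimum-recombination phasing, imputation and
crossover/gene-conversion classification."""

import numpy as np
import pandas as pd
import pytest

from jvscan.containers import (
    CALL_MISSING,
    GT_HET,
    GT_HOM_REF,
    GameteMatrix,
    HaplotypeAssignment,
)
from jvscan.gametes import (
    _switch_edges,
    call_events,
    exhaustive_min_switches,
    filter_gamete_markers,
    impute_bins,
    phase_mpr,
    summarize_recombination,
)
from jvscan.layout import GenomeLayout
from jvscan.pipeline import run_gamete_pipeline
from jvscan.simulate import SimConfig, simulate_gametes, simulate_parent

from conftest import make_gametes, make_genotypes, make_markers


def attained_switches(assignment: HaplotypeAssignment) -> int:
    ei, ej, ed = _switch_edges(assignment.haplotypes)
    return int((ed != 0).sum())


class TestFilter:
    def _parent(self, n, codes=None, chrom="chr1", spacing=1000):
        if codes is None:
            codes = [[GT_HET]] * n
        return make_genotypes(codes, chrom=chrom, spacing=spacing,
                              names=["parent"])

    def test_close_cluster_fully_removed(self):
        # markers at 1000 and 1150 are 150 bp apart: both must go
        markers = pd.DataFrame(
            {"chrom": "chr1", "pos": [1000, 1150, 5000, 9000],
             "ref": "A", "alt": "T"}
        )
        calls = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0], [1, 0, 1]],
                         dtype=np.int8)
        gametes = GameteMatrix(markers, ["g0", "g1", "g2"], ["sperm"] * 3,
                               calls)
        parent = make_genotypes([[GT_HET]] * 4, names=["parent"])
        parent.markers["pos"] = [1000, 1150, 5000, 9000]
        kept, _ = filter_gamete_markers(parent, gametes)
        assert kept["pos"].tolist() == [5000, 9000]

    def test_het_in_one_sperm_removes_marker(self):
        calls = np.zeros((2, 5), dtype=np.int8)
        calls[:, ::2] = 1
        calls[0, 3] = 2  # het call in a haploid sperm
        gametes = make_gametes(calls)
        kept, _ = filter_gamete_markers(self._parent(2), gametes)
        assert kept["pos"].tolist() == [1000]

    def test_non_segregating_marker_removed(self):
        calls = np.array([[0, 0, 0, 0], [0, 1, 0, 1]], dtype=np.int8)
        gametes = make_gametes(calls)
        kept, _ = filter_gamete_markers(self._parent(2), gametes)
        assert kept["pos"].tolist() == [1000]

    def test_parent_homozygous_marker_removed(self):
        calls = np.array([[0, 1, 0], [1, 0, 1]], dtype=np.int8)
        gametes = make_gametes(calls)
        parent = self._parent(2, [[GT_HOM_REF], [GT_HET]])
        kept, _ = filter_gamete_markers(parent, gametes)
        assert kept["pos"].tolist() == [1000]

    def test_no_survivors_is_an_error(self):
        calls = np.zeros((2, 3), dtype=np.int8)
        gametes = make_gametes(calls)
        with pytest.raises(ValueError, match="no markers survive"):
            filter_gamete_markers(self._parent(2), gametes)

    def test_oocyte_het_calls_become_missing(self):
        calls = np.array([[0, 1, 0, 2], [1, 0, 1, 0]], dtype=np.int8)
        gametes = make_gametes(
            calls, types=["sperm", "sperm", "sperm", "oocyte"]
        )
        _, filtered = filter_gamete_markers(self._parent(2), gametes)
        assert filtered.n_markers == 2  # oocyte het does not drop the marker
        assert filtered.calls[0, 3] == CALL_MISSING


class TestPhasing:
    def test_no_recombination_gives_constant_haplotypes(self):
        rng = np.random.default_rng(0)
        j = rng.integers(0, 2, size=12).astype(np.int8)
        calls = np.stack([j, 1 - j, j, j], axis=1)
        assignment = phase_mpr(make_gametes(calls))
        assert attained_switches(assignment) == 0
        for g in range(4):
            assert len(set(assignment.haplotypes[:, g])) == 1

    def test_single_crossover_attains_minimum_one(self):
        # truth: one crossover in one gamete of four, five markers
        calls = np.array(
            [
                [0, 1, 0, 0],
                [0, 1, 0, 0],
                [0, 1, 0, 1],
                [0, 1, 0, 1],
                [0, 1, 0, 1],
            ],
            dtype=np.int8,
        )
        gametes = make_gametes(calls)
        assignment = phase_mpr(gametes)
        assert attained_switches(assignment) == 1
        assert exhaustive_min_switches(gametes) == 1

    @pytest.mark.parametrize("trial", range(40))
    def test_matches_exhaustive_minimum_on_random_instances(self, trial):
        rng = np.random.default_rng(1000 + trial)
        m = int(rng.integers(3, 16))
        g = int(rng.integers(2, 9))
        calls = rng.integers(0, 2, size=(m, g)).astype(np.int8)
        calls[rng.random((m, g)) < rng.uniform(0, 0.3)] = -1
        for row in range(m):
            if (calls[row] < 0).all():
                calls[row, 0] = 0
        gametes = make_gametes(calls)
        assignment = phase_mpr(gametes)
        assert attained_switches(assignment) == exhaustive_min_switches(gametes)

    def test_recovers_simulated_phase(self, single_chrom_layout):
        cfg = SimConfig(layout=single_chrom_layout, map_lengths={"chrA": 1.0},
                        suppressed=(), markers_per_chromosome=200,
                        error_rate=0.005, missing_rate=0.05, seed=21)
        markers, _, truth = simulate_parent(cfg)
        gametes, _ = simulate_gametes(markers, truth, cfg, 45, "sperm")
        assignment = phase_mpr(gametes)
        agree = (assignment.phase == truth.j_allele).mean()
        # label swap gives the complementary agreement
        assert max(agree, 1 - agree) > 0.99

    def test_label_swap_leaves_event_counts_unchanged(self, single_chrom_layout):
        cfg = SimConfig(layout=single_chrom_layout, map_lengths={"chrA": 1.0},
                        suppressed=(), markers_per_chromosome=80, seed=22)
        markers, _, truth = simulate_parent(cfg)
        gametes, _ = simulate_gametes(markers, truth, cfg, 20, "sperm")
        calls_a = call_events(
            impute_bins(phase_mpr(gametes)), single_chrom_layout
        )
        swapped = GameteMatrix(
            gametes.markers.copy(), list(gametes.gamete_ids),
            list(gametes.gamete_types),
            np.where(gametes.calls >= 0, 1 - gametes.calls, -1).astype(np.int8),
        )
        calls_b = call_events(
            impute_bins(phase_mpr(swapped)), single_chrom_layout
        )
        a = calls_a.events.groupby("kind").size().to_dict()
        b = calls_b.events.groupby("kind").size().to_dict()
        assert a == b

    def test_all_missing_marker_dropped_with_warning(self):
        calls = np.array([[0, 1], [-1, -1], [1, 0]], dtype=np.int8)
        with pytest.warns(UserWarning, match="no calls"):
            assignment = phase_mpr(make_gametes(calls))
        assert len(assignment.markers) == 2

    def test_fewer_than_two_gametes_rejected(self):
        with pytest.raises(ValueError):
            phase_mpr(make_gametes(np.array([[0], [1]], dtype=np.int8)))


class TestImputation:
    def _assignment(self, haps):
        haps = np.asarray(haps, dtype=np.int8)
        n = haps.shape[0]
        return HaplotypeAssignment(
            make_markers(n), [f"g{i}" for i in range(haps.shape[1])],
            ["sperm"] * haps.shape[1], np.zeros(n, dtype=np.int8), haps
        )

    def test_isolated_flip_corrected(self):
        # J J V J J -> J J J J J
        out = impute_bins(self._assignment([[0], [0], [1], [0], [0]]))
        assert out.haplotypes[:, 0].tolist() == [0, 0, 0, 0, 0]

    def test_all_missing_gamete_unchanged(self):
        out = impute_bins(self._assignment([[-1]] * 6))
        assert (out.haplotypes == -1).all()

    def test_noise_free_vector_is_fixed_point(self):
        haps = [[0], [0], [0], [1], [1], [1]]
        out = impute_bins(self._assignment(haps))
        assert out.haplotypes[:, 0].tolist() == [0, 0, 0, 1, 1, 1]

    def test_missing_filled_by_surrounding_majority(self):
        out = impute_bins(self._assignment([[0], [0], [-1], [0], [0]]))
        assert out.haplotypes[2, 0] == 0

    def test_missing_at_boundary_stays_missing(self):
        out = impute_bins(self._assignment([[0], [0], [-1], [1], [1]]))
        assert out.haplotypes[2, 0] == -1

    def test_even_or_small_window_rejected(self):
        a = self._assignment([[0], [1]])
        with pytest.raises(ValueError):
            impute_bins(a, window=4)
        with pytest.raises(ValueError):
            impute_bins(a, window=1)


class TestEventCalling:
    def _assignment(self, haps, spacing, chrom="chrA"):
        haps = np.asarray(haps, dtype=np.int8).reshape(-1, 1)
        n = haps.shape[0]
        return HaplotypeAssignment(
            make_markers(n, chrom=chrom, spacing=spacing), ["g0"], ["sperm"],
            np.zeros(n, dtype=np.int8), haps
        )

    def test_single_switch_is_one_crossover(self, single_chrom_layout):
        a = self._assignment([0, 0, 0, 0, 1, 1, 1, 1], spacing=10_000_000)
        calls = call_events(a, GenomeLayout((("chrA", 80_000_000),)))
        assert len(calls.events) == 1
        ev = calls.events.iloc[0]
        assert ev["kind"] == "crossover"
        assert (ev["start"], ev["end"]) == (30_000_000, 40_000_000)

    def test_short_internal_track_is_gene_conversion(self):
        # V-track spanning 0.5 Mb on a 100-Mb chromosome: 0.5% < 1%
        layout = GenomeLayout((("chrA", 100_000_000),))
        a = self._assignment([0, 0, 0, 1, 1, 0, 0, 0], spacing=250_000)
        calls = call_events(a, layout)
        kinds = calls.events["kind"].tolist()
        assert kinds == ["gene_conversion"]

    def test_long_internal_track_is_two_crossovers(self):
        # V-track spanning 2 Mb (2% of 100 Mb) flanked by J
        layout = GenomeLayout((("chrA", 100_000_000),))
        a = self._assignment([0, 0, 1, 1, 1, 0, 0], spacing=1_000_000)
        calls = call_events(a, layout)
        assert calls.events["kind"].tolist() == ["crossover", "crossover"]

    def test_constant_gamete_has_no_events(self):
        layout = GenomeLayout((("chrA", 100_000_000),))
        a = self._assignment([0, 0, 0, 0], spacing=1_000_000)
        assert call_events(a, layout).events.empty

    def test_terminal_short_track_counts_as_crossover(self):
        layout = GenomeLayout((("chrA", 100_000_000),))
        a = self._assignment([1, 0, 0, 0, 0], spacing=1_000_000)
        calls = call_events(a, layout)
        assert calls.events["kind"].tolist() == ["crossover"]

    def test_unknown_chromosome_rejected(self):
        a = self._assignment([0, 1], spacing=1000, chrom="weird")
        with pytest.raises(KeyError):
            call_events(a, GenomeLayout((("chrA", 10_000),)))


class TestSummaries:
    def test_zero_crossover_fraction_formatting(self, single_chrom_layout):
        events = pd.DataFrame(
            [["g44", "chrA", 100, 200, "crossover"]],
            columns=["gamete", "chrom", "start", "end", "kind"],
        )
        from jvscan.containers import CrossoverCallSet

        calls = CrossoverCallSet(
            events, [f"g{i}" for i in range(45)], ["sperm"] * 45
        )
        markers = make_markers(10, chrom="chrA", spacing=1_000_000)
        summary, _, _ = summarize_recombination(
            calls, markers, single_chrom_layout
        )
        row = summary.iloc[0]
        assert row["n_zero"] == 44
        assert row["percent_zero"] == 98

    def test_cv_of_equal_windows_is_zero(self, single_chrom_layout):
        from jvscan.containers import CrossoverCallSet

        calls = CrossoverCallSet(
            pd.DataFrame([["g0", "chrA", 0, 1, "crossover"]],
                         columns=["gamete", "chrom", "start", "end", "kind"]),
            ["g0"], ["sperm"],
        )
        # 5 markers in each 20-Mb window
        markers = pd.DataFrame({
            "chrom": "chrA",
            "pos": np.concatenate([np.arange(5) * 1000 + w * 20_000_000
                                   for w in range(5)]),
            "ref": "A", "alt": "T",
        })
        _, density, cv = summarize_recombination(
            calls, markers, single_chrom_layout
        )
        assert cv["cv"].iloc[0] == 0.0

    def test_cv_sample_standard_deviation(self):
        from jvscan.containers import CrossoverCallSet

        layout = GenomeLayout((("chrA", 40_000_000),))
        calls = CrossoverCallSet(
            pd.DataFrame([["g0", "chrA", 0, 1, "crossover"]],
                         columns=["gamete", "chrom", "start", "end", "kind"]),
            ["g0"], ["sperm"],
        )
        pos = np.concatenate([
            np.arange(50) * 100, 20_000_000 + np.arange(150) * 100
        ])
        markers = pd.DataFrame({"chrom": "chrA", "pos": pos,
                                "ref": "A", "alt": "T"})
        _, _, cv = summarize_recombination(calls, markers, layout)
        # windows {50, 150}: sample SD / mean = 70.71 / 100
        assert cv["cv"].iloc[0] == pytest.approx(0.7071, abs=1e-3)


class TestSuppressionContrast:
    def test_suppressed_chromosome_shows_no_crossovers(self):
        """Chromosome 1 at 0.005 Morgans vs chromosome 3 at 1.1 Morgans."""
        cfg = SimConfig(markers_per_chromosome=120, seed=31)
        markers, parent, truth = simulate_parent(cfg)
        rng = np.random.default_rng(31)
        gametes, _ = simulate_gametes(markers, truth, cfg, 45, "sperm",
                                      seed=rng)
        assignment, calls = run_gamete_pipeline(parent, gametes, cfg.layout)
        summary, _, _ = summarize_recombination(
            calls, assignment.markers, cfg.layout
        )
        s = summary.set_index("chrom")
        assert s.loc["chr1", "fraction_zero"] >= 0.9
        assert s.loc["chr3", "median_crossovers"] >= 1
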