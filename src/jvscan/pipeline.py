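"""End-to-end workflows: the gamete pipeline and the synthetic replay.

``demo_replay`` regenerates, from a single seed, a synthetic study with
the same design as the real one -- 45 sperm and 28 oocytes from a J/V
line, a four-island wild panel in which two islands carry the
balanced-lethal chromosome-1 system, 13 expression-tested genes, three
dated inversion strata and the knockdown phenotype comparison -- and
runs every analysis stage on it.
"""

from __future__ import annotations

import json
import numpy as np
import pandas as pd

from jvscan import __version__
from jvscan.ase import analyze_gene_bias
from jvscan.chrseq import assign_scaffolds, normalize_coverage
from jvscan.containers import GameteMatrix, GenotypeTable
from jvscan.gametes import (
    call_events,
    filter_gamete_markers,
    impute_bins,
    phase_mpr,
    summarize_recombination,
)
from jvscan.layout import GenomeLayout
from jvscan.phenotype import FiveNumberSummary, compare_summaries
from jvscan.popgen import (
    PopulationPanel,
    classify_jv,
    filter_sites,
    het_window_scan,
    hudson_fst,
    obs_exp_het,
)
from jvscan.simulate import (
    SimConfig,
    make_scaffold_map,
    simulate_ase,
    simulate_chrseq,
    simulate_diverged_cds,
    simulate_gametes,
    simulate_island_panel,
    simulate_parent,
)
from jvscan.strata import date_strata

# bursa-canal length as a percentage of whole-worm length, n = 4 per
# group, reported as five-number summaries of the knockdown experiment
GLP_KNOCKDOWN_SUMMARY = FiveNumberSummary(
    n=4, minimum=10.28, q1=10.375, median=10.845, q3=11.31, maximum=11.4
)
CONTROL_SUMMARY = FiveNumberSummary(
    n=4, minimum=7.95, q1=8.06, median=8.26, q3=8.6, maximum=8.85
)

# true J-allele proportions for the 13 expression-tested genes: seven
# genes with haplotype-biased expression (five J-biased, two V-biased),
# six unbiased
ASE_DEMO_BIASES = (
    0.95, 0.88, 0.85, 0.82, 0.80, 0.18, 0.12,
    0.5, 0.5, 0.5, 0.5, 0.5, 0.5,
)


def run_gamete_pipeline(
    parent: GenotypeTable,
    gametes: GameteMatrix,
    layout: GenomeLayout,
    min_gap: int = 200,
    impute_window: int = 5,
    min_track_fraction: float = 0.01,
):
    """Filter, phase, impute and call events in one pass.

    Returns ``(assignment, calls)`` where ``assignment`` is the imputed
    haplotype assignment and ``calls`` the classified event set.
    """
    _, filtered = filter_gamete_markers(parent, gametes, min_gap=min_gap)
    assignment = phase_mpr(filtered)
    imputed = impute_bins(assignment, window=impute_window)
    calls = call_events(imputed, layout, min_track_fraction=min_track_fraction)
    return imputed, calls


def _merge_gametes(a: GameteMatrix, b: GameteMatrix) -> GameteMatrix:
    if not a.markers[["chrom", "pos"]].equals(b.markers[["chrom", "pos"]]):
        raise ValueError("gamete matrices must share a marker set")
    return GameteMatrix(
        a.markers.copy(),
        a.gamete_ids + b.gamete_ids,
        a.gamete_types + b.gamete_types,
        np.concatenate([a.calls, b.calls], axis=1),
    )


def demo_replay(
    seed: int = 0,
    n_sperm: int = 45,
    n_oocytes: int = 28,
    markers_per_chromosome: int = 150,
    out_dir: str | None = None,
) -> dict:
    """Synthetic replay of the whole study design at desk scale.

    Regenerates identically for a fixed seed. Returns a report dict; if
    ``out_dir`` is given, also writes the report JSON, the stage tables
    and a manifest there.
    """
    rng = np.random.default_rng(seed)
    config = SimConfig(
        markers_per_chromosome=markers_per_chromosome,
        seed=seed,
    )
    layout = config.layout
    report: dict = {"seed": seed, "version": __version__}

    # -- gamete recombination: suppressed chr1 vs recombining chr3 ------
    markers, parent, truth = simulate_parent(config, seed=rng)
    sperm, _ = simulate_gametes(markers, truth, config, n_sperm, "sperm", seed=rng)
    oocytes, _ = simulate_gametes(
        markers, truth, config, n_oocytes, "oocyte", seed=rng
    )
    gametes = _merge_gametes(sperm, oocytes)
    assignment, calls = run_gamete_pipeline(parent, gametes, layout)
    summary, density, cv = summarize_recombination(
        calls, assignment.markers, layout
    )
    chr1 = summary[summary["chrom"] == "chr1"]
    chr3 = summary[summary["chrom"] == "chr3"]
    report["gametes"] = {
        "n_sperm": n_sperm,
        "n_oocytes": n_oocytes,
        "chr1_zero_crossover_fraction": {
            row["gamete_type"]: row["fraction_zero"]
            for _, row in chr1.iterrows()
        },
        "chr3_median_crossovers": {
            row["gamete_type"]: row["median_crossovers"]
            for _, row in chr3.iterrows()
        },
        "snv_density_cv": dict(zip(cv["chrom"], cv["cv"])),
    }

    # -- wild panel: two locked islands, two panmictic ------------------
    sizes = {"SAR": 28, "COR": 8, "SIC": 27, "TUN": 7}
    table, labels = simulate_island_panel(config, sizes, seed=rng)
    panel = filter_sites(PopulationPanel(table, labels))
    hohe = obs_exp_het(panel)
    scan_frames = []
    for pop in sizes:
        scan = het_window_scan(panel.subset_population(pop), layout)
        scan["population"] = pop
        scan_frames.append(scan)
    scans = pd.concat(scan_frames, ignore_index=True)
    mean_counts = (
        scans.groupby(["population", "chrom"])["het_sites"].mean().reset_index()
    )
    chr1_markers = (panel.table.markers["chrom"] == "chr1").to_numpy()
    jv_calls = {
        name: classify_jv(panel.table.codes[chr1_markers, i])
        for i, name in enumerate(panel.table.individuals)
    }
    jv_by_pop = (
        pd.DataFrame(
            {"population": labels, "call": [jv_calls[n] for n in panel.table.individuals]}
        )
        .groupby(["population", "call"])
        .size()
        .reset_index(name="n")
    )
    _, fst = hudson_fst(panel, "SAR", "SIC")
    report["popgen"] = {
        "ho_he": hohe.to_dict(orient="records"),
        "mean_het_window_counts": mean_counts.to_dict(orient="records"),
        "jv_classification": jv_by_pop.to_dict(orient="records"),
        "fst_SAR_SIC": fst,
    }

    # -- haplotype-biased expression ------------------------------------
    variants, _ = simulate_ase(
        n_genes=len(ASE_DEMO_BIASES),
        bias=ASE_DEMO_BIASES,
        depth=200,
        seed=rng,
    )
    ase_table = analyze_gene_bias(variants)
    report["ase"] = {
        "n_genes": len(ase_table),
        "n_significant": int((ase_table["p_bonferroni"] < 0.05).sum()),
        "table": ase_table.to_dict(orient="records"),
    }

    # -- scaffold assignment -------------------------------------------
    scaffold_map = make_scaffold_map(layout, 40, seed=rng)
    coverage = simulate_chrseq(
        scaffold_map, samples_per_chromosome=4, noise_sigma=0.3, seed=rng
    )
    result = assign_scaffolds(normalize_coverage(coverage))
    assigned = result.table[result.table["chromosome"] != ""]
    accuracy = float(
        np.mean(
            [
                scaffold_map[s] == c
                for s, c in zip(assigned["scaffold"], assigned["chromosome"])
            ]
        )
    )
    report["chrseq"] = {
        "n_scaffolds": len(result.table),
        "assignment_accuracy": accuracy,
        "codes": result.table["code"].value_counts().to_dict(),
    }

    # -- strata dating --------------------------------------------------
    mu = 1.0e-8
    ages = {1: 320_000, 2: 260_000, 3: 450_000}
    stratum_cds = {
        s: [simulate_diverged_cds(40_000, age, mu=mu, seed=rng)]
        for s, age in ages.items()
    }
    strata_table = date_strata(stratum_cds, mu)
    report["strata"] = {
        "mu": mu,
        "true_ages": ages,
        "estimates": strata_table.to_dict(orient="records"),
    }

    # -- knockdown phenotype -------------------------------------------
    report["phenotype"] = compare_summaries(
        GLP_KNOCKDOWN_SUMMARY, CONTROL_SUMMARY
    )

    if out_dir is not None:
        from jvscan.io import ensure_dir, write_events_bed

        ensure_dir(out_dir)
        with open(f"{out_dir}/report.json", "w") as handle:
            json.dump(report, handle, indent=2, default=_jsonify)
        summary.to_csv(f"{out_dir}/gamete_summary.tsv", sep="\t", index=False)
        hohe.to_csv(f"{out_dir}/ho_he.tsv", sep="\t", index=False)
        scans.to_csv(f"{out_dir}/het_windows.tsv", sep="\t", index=False)
        ase_table.to_csv(f"{out_dir}/ase.tsv", sep="\t", index=False)
        strata_table.to_csv(f"{out_dir}/strata.tsv", sep="\t", index=False)
        write_events_bed(calls, f"{out_dir}/events.bed")
        write_manifest(
            f"{out_dir}/manifest.json",
            {"command": "demo", "seed": seed,
             "markers_per_chromosome": markers_per_chromosome,
             "n_sperm": n_sperm, "n_oocytes": n_oocytes},
        )
    return report


def write_manifest(path: str, params: dict) -> None:
    """Record the parameters and package version of a run."""
    manifest = {"jvscan_version": __version__, **params}
    with open(path, "w") as handle:
        json.dump(manifest, handle, indent=2, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
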