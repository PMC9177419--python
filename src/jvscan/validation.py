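"""Truth-based evaluation of the gamete pipeline on simulated data.

These helpers quantify how well the crossover-calling pipeline recovers
known simulated truth. Two recovery notions are reported:

* **detection** -- a true crossover breakpoint is detected when some
  called event's flanking-marker interval contains it. Two crossovers
  closer than ~1% of the chromosome produce a short intervening track
  that the classification rule deliberately labels a gene conversion;
  the pair is then detected by that conversion event although neither
  breakpoint yields a called crossover.
* **strict** -- the breakpoint lies inside a called *crossover* interval
  (each called crossover is consumed by at most one true breakpoint).

Denominators count breakpoints within the marker-covered span of the
chromosome (between the outermost retained markers); breakpoints beyond
the terminal markers produce no genotypic signal and are unobservable to
any method. Both totals are reported.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from jvscan.containers import GameteMatrix
from jvscan.gametes import exhaustive_min_switches, phase_mpr, _switch_edges
from jvscan.layout import GenomeLayout
from jvscan.pipeline import run_gamete_pipeline
from jvscan.simulate import SimConfig, simulate_gametes, simulate_parent


def evaluate_crossover_recovery(
    seeds,
    n_gametes: int = 100,
    n_markers: int = 200,
    map_morgans: float = 1.0,
    error_rate: float = 0.005,
    missing_rate: float = 0.05,
    chromosome_length: int = 100_000_000,
) -> dict:
    """Run the pipeline on replicate simulated datasets and score it.

    Returns a dict with pooled detection/strict recovery rates, the false
    crossover rate per gamete, and the number of true gene-conversion
    tracts whose both boundaries were called crossovers (misclassified
    tracts; must be zero).
    """
    layout = GenomeLayout((("chrA", chromosome_length),))
    n_true = n_true_span = detected = strict = false = 0
    conv_violations = n_tracts = 0
    for seed in seeds:
        cfg = SimConfig(
            layout=layout,
            map_lengths={"chrA": map_morgans},
            suppressed=(),
            markers_per_chromosome=n_markers,
            error_rate=error_rate,
            missing_rate=missing_rate,
            stratum_divergence={1: 0.01},
            background_divergence=0.005,
            seed=int(seed),
        )
        markers, parent, truth = simulate_parent(cfg)
        gametes, gtruth = simulate_gametes(markers, truth, cfg, n_gametes,
                                           "sperm")
        assignment, calls = run_gamete_pipeline(parent, gametes, layout)
        pos = assignment.markers["pos"].to_numpy()
        lo, hi = pos[0], pos[-1]
        events = calls.events
        for gid in gametes.gamete_ids:
            ev = events[events["gamete"] == gid]
            evx = ev[ev["kind"] == "crossover"]
            true_b = gtruth.crossovers[gid]["chrA"]
            n_true += len(true_b)
            used = set()
            for b in true_b:
                in_span = lo <= b <= hi
                n_true_span += in_span
                if any(s <= b <= e for s, e in zip(ev["start"], ev["end"])):
                    detected += in_span
                for k, (s, e) in enumerate(zip(evx["start"], evx["end"])):
                    if k not in used and s <= b <= e:
                        used.add(k)
                        strict += in_span
                        break
            false += len(evx) - len(used)
            for t0, t1 in gtruth.conversions[gid]["chrA"]:
                n_tracts += 1
                left = any(s <= t0 <= e for s, e in zip(evx["start"], evx["end"]))
                right = any(s <= t1 <= e for s, e in zip(evx["start"], evx["end"]))
                if left and right:
                    conv_violations += 1
    total_gametes = n_gametes * len(list(seeds))
    return {
        "n_true_crossovers": n_true,
        "n_true_in_span": n_true_span,
        "detection_recovery": detected / n_true_span if n_true_span else 1.0,
        "strict_recovery": strict / n_true_span if n_true_span else 1.0,
        "false_per_gamete": false / total_gametes,
        "n_conversion_tracts": n_tracts,
        "conversions_called_crossover": conv_violations,
        "n_gametes": total_gametes,
    }


def mpr_oracle_agreement(n_instances: int = 200, seed: int = 0,
                         max_markers: int = 20, max_gametes: int = 10) -> dict:
    """Compare the phasing search with the exhaustive minimum.

    Random haploid call matrices (markers <= ``max_markers``, gametes <=
    ``max_gametes``, missing rates up to 30%) are phased; the attained
    total switch count is compared with brute-force enumeration over all
    phasings.
    """
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_instances):
        m = int(rng.integers(3, max_markers + 1))
        g = int(rng.integers(2, max_gametes + 1))
        calls = rng.integers(0, 2, size=(m, g)).astype(np.int8)
        calls[rng.random((m, g)) < rng.uniform(0, 0.3)] = -1
        for row in range(m):
            if (calls[row] < 0).all():
                calls[row, 0] = 0
        markers = pd.DataFrame(
            {"chrom": "c", "pos": np.arange(m) * 1000, "ref": "A", "alt": "T"}
        )
        gametes = GameteMatrix(
            markers, [f"g{i}" for i in range(g)], ["sperm"] * g, calls
        )
        assignment = phase_mpr(gametes)
        _, _, ed = _switch_edges(assignment.haplotypes)
        attained = int((ed != 0).sum())
        if attained == exhaustive_min_switches(gametes):
            agree += 1
    return {"n_instances": n_instances, "agreement": agree / n_instances}
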