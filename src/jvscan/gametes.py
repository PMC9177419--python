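"""Single-gamete crossover calling.

From a heterozygous parent and haploid genotypes of its single sperm
cells and oocytes: filter unreliable markers, phase the two parental
haplotypes (J and V) by minimum recombination, impute noisy calls by
local majority, and classify haplotype switches into crossovers versus
short gene-conversion tracts.

Phasing criterion
-----------------
The phase chosen is the per-marker allele -> haplotype mapping that
minimises the total number of haplotype switches summed over gametes
(maximum parsimony of recombination). Between two consecutive non-missing
calls of a gamete at markers ``i < j`` a switch occurs iff
``call_i XOR call_j != phase_i XOR phase_j``, so the objective depends on
the phase only through XORs along "edges" (i, j). The minimum is found
exactly by a sliding-window dynamic programme over marker phases whose
window covers the longest edge span; when missing data create spans too
long for the DP (window beyond 20 markers) a seeded hill-climbing search
over single-marker and suffix flips is used instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from jvscan.containers import (
    CALL_ALT,
    CALL_HET,
    CALL_MISSING,
    CALL_REF,
    GT_HET,
    CrossoverCallSet,
    GameteMatrix,
    GenotypeTable,
    HaplotypeAssignment,
)
from jvscan.layout import GenomeLayout

# DP state space guard: fall back to local search when the sliding-window
# state space times the instance size exceeds this many elementary ops
_DP_BUDGET = 40_000_000


# -- marker filtering ---------------------------------------------------


def filter_gamete_markers(
    parent: GenotypeTable,
    gametes: GameteMatrix,
    min_gap: int = 200,
    min_informative: int = 3,
) -> tuple[pd.DataFrame, GameteMatrix]:
    """Remove abnormal markers before phasing.

    A marker is retained iff it is (a) heterozygous in the parent, (b)
    segregating -- both alleles observed among non-missing gamete calls,
    assessed only when at least ``min_informative`` non-missing calls
    exist, (c) not within ``min_gap`` bp of another marker (every member
    of a close cluster is dropped), and (d) never called heterozygous in
    any sperm cell (haploid cells cannot be het; such calls flag
    amplification artefacts). Rules are evaluated on the input marker
    set, so their order is irrelevant. Residual het calls in oocytes at
    retained markers are set to missing.
    """
    markers = gametes.markers
    key = ["chrom", "pos"]
    parent_idx = parent.markers.reset_index().merge(markers[key], on=key)
    if len(parent_idx) < len(markers):
        raise ValueError("parent genotypes unavailable at some gamete markers")
    parent_codes = parent.codes[parent_idx["index"].to_numpy(), 0]
    het_in_parent = parent_codes == GT_HET

    calls = gametes.calls
    informative = (calls == CALL_REF) | (calls == CALL_ALT)
    n_informative = informative.sum(axis=1)
    has_ref = (calls == CALL_REF).any(axis=1)
    has_alt = (calls == CALL_ALT).any(axis=1)
    segregating = (n_informative >= min_informative) & has_ref & has_alt

    spaced = np.ones(len(markers), dtype=bool)
    chrom = markers["chrom"].to_numpy()
    pos = markers["pos"].to_numpy()
    same_chrom = chrom[1:] == chrom[:-1]
    close = same_chrom & (np.diff(pos) < min_gap)
    spaced[:-1] &= ~close
    spaced[1:] &= ~close

    sperm = np.array([t == "sperm" for t in gametes.gamete_types])
    het_in_sperm = (calls[:, sperm] == CALL_HET).any(axis=1)

    keep = het_in_parent & segregating & spaced & ~het_in_sperm
    if not keep.any():
        raise ValueError("no markers survive gamete-marker filtering")
    filtered = gametes.subset_markers(keep)
    filtered.calls[filtered.calls == CALL_HET] = CALL_MISSING
    return filtered.markers, filtered


# -- phasing ------------------------------------------------------------


def _switch_edges(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Edges (i, j, d): consecutive informative calls per gamete.

    ``d`` is the XOR of the two calls; a switch occurs on the edge iff
    ``phase_i XOR phase_j != d``.
    """
    ei, ej, ed = [], [], []
    for g in range(calls.shape[1]):
        idx = np.flatnonzero(calls[:, g] >= 0)
        if len(idx) < 2:
            continue
        ei.append(idx[:-1])
        ej.append(idx[1:])
        ed.append(calls[idx[:-1], g] ^ calls[idx[1:], g])
    if not ei:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty, empty.astype(np.int8)
    return (
        np.concatenate(ei),
        np.concatenate(ej),
        np.concatenate(ed).astype(np.int8),
    )


def _phase_cost(phase: np.ndarray, edges) -> int:
    ei, ej, ed = edges
    return int(((phase[ei] ^ phase[ej]) != ed).sum())


def _phase_dp(n_markers: int, edges, window: int) -> np.ndarray:
    """Exact minimum-switch phase via a sliding-window DP.

    State after marker ``m``: the phases of markers ``m-window+1 .. m``
    packed into an integer (bit k = phase of marker ``m-k``). Every edge
    ends within the window of its right marker, so its cost can be added
    when that marker is placed.
    """
    ei, ej, ed = edges
    n_states = 1 << window
    states = np.arange(n_states, dtype=np.int64)
    hi = 1 << (window - 1)
    # cost of edges ending at marker m, as a function of the state at m
    by_end: dict[int, list[tuple[int, int]]] = {}
    for i, j, d in zip(ei, ej, ed):
        by_end.setdefault(int(j), []).append((int(j - i), int(d)))

    def edge_cost(m: int) -> np.ndarray:
        cost = np.zeros(n_states, dtype=np.int64)
        for offset, d in by_end.get(m, []):
            viol = (((states >> offset) ^ states) & 1) != d
            cost += viol
        return cost

    first = min(window - 1, n_markers - 1)
    cost = np.zeros(n_states, dtype=np.int64)
    for m in range(first + 1):
        # initial block: all its edges scored against the full state
        for offset, d in by_end.get(m, []):
            bit_i = first - (m - offset)
            bit_j = first - m
            viol = (((states >> bit_i) ^ (states >> bit_j)) & 1) != d
            cost += viol
    if first < window - 1:  # fewer markers than the window
        best = int(np.argmin(cost))
        phase = np.zeros(n_markers, dtype=np.int8)
        for m in range(n_markers):
            phase[m] = (best >> (first - m)) & 1
        return phase
    back = np.zeros((n_markers, n_states), dtype=np.int8)
    for m in range(window, n_markers):
        shifted = states >> 1
        stay = cost[shifted]
        flip = cost[shifted | hi]
        take_hi = flip < stay
        cost = np.where(take_hi, flip, stay) + edge_cost_shifted(m, states, by_end)
        back[m] = take_hi
    best = int(np.argmin(cost))
    phase = np.zeros(n_markers, dtype=np.int8)
    # unwind: state at marker m holds phases of m-window+1 .. m
    state = best
    for m in range(n_markers - 1, window - 1, -1):
        phase[m] = state & 1
        oldest = back[m, state]
        state = (state >> 1) | (int(oldest) << (window - 1))
    for k in range(window):
        phase[window - 1 - k] = (state >> k) & 1
    return phase


def edge_cost_shifted(m, states, by_end) -> np.ndarray:
    cost = np.zeros(len(states), dtype=np.int64)
    for offset, d in by_end.get(m, []):
        viol = (((states >> offset) ^ states) & 1) != d
        cost += viol
    return cost


def _phase_hillclimb(n_markers: int, calls: np.ndarray, edges) -> np.ndarray:
    """Seeded local search fallback for very long missing runs.

    Seeds from the gametes with fewest missing calls (missing filled by
    carry-forward), then greedily applies the best single-marker or
    suffix flip until no move reduces the switch count.
    """
    ei, ej, ed = edges
    n_missing = (calls < 0).sum(axis=0)
    seeds = np.argsort(n_missing, kind="stable")[:8]
    best_phase, best_cost = None, None
    for g in seeds:
        phase = calls[:, g].astype(np.int8).copy()
        # fill missing by carry-forward, then backward, default 0
        last = 0
        for m in range(n_markers):
            if phase[m] < 0:
                phase[m] = last
            else:
                last = phase[m]
        improved = True
        while improved:
            improved = False
            viol = ((phase[ei] ^ phase[ej]) != ed).astype(np.int64)
            sat = 1 - viol
            flip_delta = (
                np.bincount(ei, weights=sat, minlength=n_markers)
                + np.bincount(ej, weights=sat, minlength=n_markers)
                - np.bincount(ei, weights=viol, minlength=n_markers)
                - np.bincount(ej, weights=viol, minlength=n_markers)
            )
            diff = np.zeros(n_markers + 1)
            np.add.at(diff, ei + 1, sat - viol)
            np.add.at(diff, ej + 1, -(sat - viol))
            suffix_delta = np.cumsum(diff)[1:]
            m1 = int(np.argmin(flip_delta))
            m2 = int(np.argmin(suffix_delta))
            if flip_delta[m1] <= suffix_delta[m2] and flip_delta[m1] < 0:
                phase[m1] ^= 1
                improved = True
            elif suffix_delta[m2] < 0:
                phase[m2:] ^= 1
                improved = True
        cost = _phase_cost(phase, edges)
        if best_cost is None or cost < best_cost:
            best_phase, best_cost = phase, cost
    return best_phase if best_phase is not None else np.zeros(n_markers, np.int8)


def phase_mpr(gametes: GameteMatrix) -> HaplotypeAssignment:
    """Phase markers into J/V haplotypes by minimum total recombination.

    Markers at which every gamete is missing are dropped with a warning.
    The phase is canonicalised so that the first marker of each
    chromosome maps its reference allele to J (a global J/V label swap
    per chromosome is an equivalent optimum).
    """
    if gametes.n_gametes < 2:
        raise ValueError("phasing requires at least 2 gametes")
    all_missing = (gametes.calls < 0).all(axis=1)
    if all_missing.any():
        warnings.warn(
            f"dropping {int(all_missing.sum())} markers with no calls",
            stacklevel=2,
        )
        gametes = gametes.subset_markers(~all_missing)
    markers = gametes.markers
    phase = np.zeros(len(markers), dtype=np.int8)
    chrom = markers["chrom"].to_numpy()
    for name in markers["chrom"].drop_duplicates():
        sel = np.flatnonzero(chrom == name)
        calls = gametes.calls[sel]
        if len(sel) < 2:
            phase[sel] = 0
            continue
        edges = _switch_edges(calls)
        if len(edges[0]) == 0:
            phase[sel] = 0
            continue
        span = int((edges[1] - edges[0]).max())
        window = max(2, span + 1)
        budget = (1 << window) * max(len(edges[0]), len(sel))
        if budget <= _DP_BUDGET:
            p = _phase_dp(len(sel), edges, window)
        else:
            p = _phase_hillclimb(len(sel), calls, edges)
        if p[0] == 1:  # canonical label: ref -> J at the first marker
            p = p ^ 1
        phase[sel] = p
    haplotypes = np.where(
        gametes.calls >= 0, gametes.calls ^ phase[:, None], -1
    ).astype(np.int8)
    return HaplotypeAssignment(
        markers,
        list(gametes.gamete_ids),
        list(gametes.gamete_types),
        phase,
        haplotypes,
    )


def min_switches(gametes: GameteMatrix) -> int:
    """Total switch count attained by :func:`phase_mpr` (all chromosomes)."""
    assignment = phase_mpr(gametes)
    total = 0
    chrom = assignment.markers["chrom"].to_numpy()
    for name in assignment.markers["chrom"].drop_duplicates():
        sel = chrom == name
        edges = _switch_edges(np.where(assignment.haplotypes[sel] >= 0,
                                       assignment.haplotypes[sel], -1))
        ei, ej, ed = edges
        total += int((ed != 0).sum())
    return total


def exhaustive_min_switches(gametes: GameteMatrix) -> int:
    """Brute-force minimum switch count over all phasings (test oracle).

    Enumerates all 2^(M-1) phasings per chromosome (the label swap is
    fixed); only feasible for small marker counts.
    """
    total = 0
    chrom = gametes.markers["chrom"].to_numpy()
    for name in gametes.markers["chrom"].drop_duplicates():
        sel = chrom == name
        calls = gametes.calls[sel]
        edges = _switch_edges(calls)
        ei, ej, ed = edges
        m = int(sel.sum())
        if len(ei) == 0:
            continue
        if m > 22:
            raise ValueError("exhaustive search limited to 22 markers")
        masks = np.arange(1 << (m - 1), dtype=np.int64) << 1  # phase[0] = 0
        cost = np.zeros(len(masks), dtype=np.int64)
        for i, j, d in zip(ei, ej, ed):
            cost += (((masks >> int(i)) ^ (masks >> int(j))) & 1) != d
        total += int(cost.min())
    return total


# -- imputation ---------------------------------------------------------


def impute_bins(
    assignment: HaplotypeAssignment, window: int = 5
) -> HaplotypeAssignment:
    """Correct and fill haplotype calls by local voting.

    An informative call is corrected (flipped) only when every other
    informative marker in its centred window of ``window`` markers
    carries the opposite haplotype: this fixes isolated allele-flip
    errors without shifting genuine track boundaries, where the vote is
    split. Windows shrink symmetrically near chromosome ends, which
    preserves short terminal tracks. A missing call is filled by the
    strict majority of the ``window - 1`` informative markers
    surrounding the gap; ties leave it missing.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    half = window // 2
    haps = assignment.haplotypes.copy()
    chrom = assignment.markers["chrom"].to_numpy()
    for name in assignment.markers["chrom"].drop_duplicates():
        sel = np.flatnonzero(chrom == name)
        block = assignment.haplotypes[sel]
        out = block.copy()
        for g in range(block.shape[1]):
            col = block[:, g]
            info = np.flatnonzero(col >= 0)
            if len(info) == 0:
                continue
            vals = col[info]
            csum = np.concatenate([[0], np.cumsum(vals)])
            n = len(info)
            for rank, idx in enumerate(info):
                h = min(half, rank, n - 1 - rank)
                if h == 0:
                    continue
                lo, hi_ = rank - h, rank + h + 1
                ones = csum[hi_] - csum[lo]
                size = hi_ - lo
                own = vals[rank]
                same_others = (ones if own == 1 else size - ones) - 1
                if same_others == 0:  # unique supporter of its haplotype
                    out[idx, g] = 1 - own
            gaps = np.flatnonzero(col < 0)
            for idx in gaps:
                rank = int(np.searchsorted(info, idx))
                lo = max(0, rank - half)
                hi_ = min(n, rank + half)
                ones = csum[hi_] - csum[lo]
                size = hi_ - lo
                if size == 0:
                    continue
                if 2 * ones > size:
                    out[idx, g] = 1
                elif 2 * ones < size:
                    out[idx, g] = 0
        haps[sel] = out
    return HaplotypeAssignment(
        assignment.markers,
        list(assignment.gamete_ids),
        list(assignment.gamete_types),
        assignment.phase,
        haps,
    )


# -- event calling ------------------------------------------------------


@dataclass
class _Track:
    hap: int
    first: int  # marker index into the chromosome block
    last: int


def call_events(
    assignment: HaplotypeAssignment,
    layout: GenomeLayout,
    min_track_fraction: float = 0.01,
) -> CrossoverCallSet:
    """Classify haplotype switches into crossovers and gene conversions.

    Maximal constant-haplotype tracks are computed per gamete per
    chromosome; a track's span is the distance from its first to its last
    informative marker. An internal track spanning less than
    ``min_track_fraction`` of the chromosome length, flanked on both
    sides by the other haplotype, is one gene-conversion event (shortest
    first; its flanks then merge). Every boundary between remaining
    tracks is one crossover, localised to the interval between the
    flanking informative markers. A sub-threshold track at a chromosome
    end has only one flank and counts as a crossover, not a conversion.
    """
    chrom = assignment.markers["chrom"].to_numpy()
    pos = assignment.markers["pos"].to_numpy()
    events = []
    for name in assignment.markers["chrom"].drop_duplicates():
        if name not in layout.names:
            raise KeyError(f"chromosome {name} absent from layout")
        threshold = min_track_fraction * layout.length(name)
        sel = np.flatnonzero(chrom == name)
        p = pos[sel]
        for g, gid in enumerate(assignment.gamete_ids):
            col = assignment.haplotypes[sel, g]
            info = np.flatnonzero(col >= 0)
            if len(info) == 0:
                continue
            vals = col[info]
            change = np.flatnonzero(np.diff(vals)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change - 1, [len(vals) - 1]])
            tracks = [
                _Track(int(vals[s]), int(info[s]), int(info[e]))
                for s, e in zip(starts, ends)
            ]
            span = lambda t: p[t.last] - p[t.first]
            while len(tracks) >= 3:
                internal = [
                    (span(tracks[k]), k) for k in range(1, len(tracks) - 1)
                ]
                short = [(s, k) for s, k in internal if s < threshold]
                if not short:
                    break
                _, k = min(short)
                left, mid, right = tracks[k - 1], tracks[k], tracks[k + 1]
                events.append(
                    (gid, name, int(p[left.last]), int(p[right.first]),
                     "gene_conversion")
                )
                tracks[k - 1] = _Track(left.hap, left.first, right.last)
                del tracks[k:k + 2]
            for k in range(len(tracks) - 1):
                events.append(
                    (
                        gid,
                        name,
                        int(p[tracks[k].last]),
                        int(p[tracks[k + 1].first]),
                        "crossover",
                    )
                )
    table = pd.DataFrame(
        events, columns=["gamete", "chrom", "start", "end", "kind"]
    )
    if not table.empty:
        table = table.sort_values(["gamete", "chrom", "start"]).reset_index(
            drop=True
        )
    return CrossoverCallSet(
        table, list(assignment.gamete_ids), list(assignment.gamete_types)
    )


# -- summaries ----------------------------------------------------------


def summarize_recombination(
    calls: CrossoverCallSet,
    markers: pd.DataFrame,
    layout: GenomeLayout,
    window: int = 20_000_000,
):
    """Crossover-count distributions and marker-density uniformity.

    Returns ``(gamete_summary, window_density, cv_table)``:

    * ``gamete_summary`` -- per gamete type and chromosome: number of
      gametes, mean/median crossover count, gametes with zero crossovers
      (count, fraction and rounded percent);
    * ``window_density`` -- marker counts per ``window``-bp window;
    * ``cv_table`` -- per chromosome, the coefficient of variation
      (sample standard deviation / mean) of the window counts.
    """
    if calls.events.empty and not calls.gamete_ids:
        raise ValueError("empty call set")
    chromosomes = list(markers["chrom"].drop_duplicates())
    counts = calls.count_matrix(chromosomes)
    types = dict(zip(calls.gamete_ids, calls.gamete_types))
    counts["gamete_type"] = counts["gamete"].map(types)
    rows = []
    for (gtype, name), grp in counts.groupby(["gamete_type", "chrom"], sort=False):
        c = grp["crossovers"].to_numpy()
        n_zero = int((c == 0).sum())
        rows.append(
            {
                "gamete_type": gtype,
                "chrom": name,
                "n_gametes": len(c),
                "mean_crossovers": float(c.mean()),
                "median_crossovers": float(np.median(c)),
                "n_zero": n_zero,
                "fraction_zero": n_zero / len(c),
                "percent_zero": int(round(100 * n_zero / len(c))),
            }
        )
    gamete_summary = pd.DataFrame(rows)

    from jvscan.layout import make_windows

    windows = make_windows(layout, window)
    windows = windows[windows["chrom"].isin(chromosomes)].reset_index(drop=True)
    density = []
    for row in windows.itertuples(index=False):
        n = int(
            (
                (markers["chrom"] == row.chrom)
                & (markers["pos"] >= row.start)
                & (markers["pos"] < row.end)
            ).sum()
        )
        density.append(n)
    window_density = windows.assign(markers=density)
    cv_rows = []
    for name, grp in window_density.groupby("chrom", sort=False):
        vals = grp["markers"].to_numpy(float)
        mean = vals.mean()
        sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
        cv_rows.append(
            {"chrom": name, "cv": sd / mean if mean > 0 else np.nan}
        )
    return gamete_summary, window_density, pd.DataFrame(cv_rows)
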