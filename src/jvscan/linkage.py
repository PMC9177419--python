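"""F2 linkage-map construction.

Markers are filtered by the mapping-cross rules (homozygous-opposite
parents, call rate, spacing, Mendelian 1:2:1 segregation), pairwise
recombination fractions are estimated by maximum likelihood for an F2
intercross (EM over the two-locus genotype table, which handles the
phase-ambiguous double heterozygotes), markers are grouped by
single-linkage under r/LOD thresholds, ordered by greedy seriation with
2-opt refinement, and adjacent recombination fractions are converted to
map distances with the Haldane (default) or Kosambi map function.

For crosses where one parent is heterozygous and the other homozygous at
the mapped markers (the het x hom configuration of a locked-heterozygous
chromosome), a backcross coding is available: each segregant is scored
het / hom and the recombination fraction is the direct recombinant
fraction.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from jvscan.containers import (
    GT_HET,
    GT_HOM_ALT,
    GT_HOM_REF,
    GT_MISSING,
    GenotypeTable,
)

# expected recombinant gametes per two-locus genotype class (F2 intercross);
# -1 marks the phase-ambiguous double heterozygote
_REC_GAMETES = np.array(
    [
        [0, 1, 2],
        [1, -1, 1],
        [2, 1, 0],
    ]
)


def filter_f2_markers(
    parents: GenotypeTable,
    f2: GenotypeTable,
    call_rate: float = 0.98,
    min_gap: int = 200,
    segregation_alpha: float = 0.001,
) -> tuple[pd.DataFrame, GenotypeTable]:
    """Apply the mapping-cross marker filters.

    Retained markers are homozygous for opposite alleles in the two
    parents, genotyped in at least ``call_rate`` of the segregants, at
    least ``min_gap`` bp from their neighbours (all members of a closer
    cluster are dropped) and consistent with 1:2:1 Mendelian segregation
    (chi-square p >= ``segregation_alpha``).
    """
    if parents.n_individuals != 2:
        raise ValueError("exactly two parents required")
    key = ["chrom", "pos"]
    pidx = parents.markers.reset_index().merge(f2.markers[key], on=key)
    if len(pidx) < f2.n_markers:
        raise ValueError("parents not genotyped at all F2 markers")
    pcodes = parents.codes[pidx["index"].to_numpy()]
    opposite = (
        ((pcodes[:, 0] == GT_HOM_REF) & (pcodes[:, 1] == GT_HOM_ALT))
        | ((pcodes[:, 0] == GT_HOM_ALT) & (pcodes[:, 1] == GT_HOM_REF))
    )

    called = (f2.codes != GT_MISSING).sum(axis=1) / f2.n_individuals
    well_called = called >= call_rate

    spaced = np.ones(f2.n_markers, dtype=bool)
    chrom = f2.markers["chrom"].to_numpy()
    pos = f2.markers["pos"].to_numpy()
    close = (chrom[1:] == chrom[:-1]) & (np.diff(pos) < min_gap)
    spaced[:-1] &= ~close
    spaced[1:] &= ~close

    mendelian = np.ones(f2.n_markers, dtype=bool)
    for m in range(f2.n_markers):
        row = f2.codes[m]
        n = np.array(
            [
                (row == GT_HOM_REF).sum(),
                (row == GT_HET).sum(),
                (row == GT_HOM_ALT).sum(),
            ]
        )
        total = n.sum()
        if total == 0:
            mendelian[m] = False
            continue
        expected = total * np.array([0.25, 0.5, 0.25])
        _, p = stats.chisquare(n, expected)
        mendelian[m] = p >= segregation_alpha

    keep = opposite & well_called & spaced & mendelian
    if not keep.any():
        raise ValueError("no markers survive F2 filtering")
    filtered = f2.subset_markers(keep)
    return filtered.markers, filtered


def estimate_rf(
    f2: GenotypeTable,
    m1: int,
    m2: int,
    coding: str = "intercross",
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> float:
    """Maximum-likelihood recombination fraction between two markers."""
    r, _, _ = _rf_with_lod(f2.codes[m1], f2.codes[m2], coding, tol, max_iter)
    return r


def _rf_with_lod(g1, g2, coding="intercross", tol=1e-8, max_iter=2000):
    both = (g1 != GT_MISSING) & (g2 != GT_MISSING)
    n_joint = int(both.sum())
    if n_joint < 10:
        raise ValueError("fewer than 10 jointly genotyped segregants")
    a, b = g1[both], g2[both]
    for g in (a, b):
        if len(np.unique(g)) < 2:
            raise ValueError("monomorphic marker; recombination fraction undefined")
    if coding == "backcross":
        het1, het2 = a == GT_HET, b == GT_HET
        rec = int((het1 != het2).sum())
        r = min(0.5, rec / n_joint)
        lod = _backcross_lod(rec, n_joint, r)
        return r, lod, n_joint
    if coding != "intercross":
        raise ValueError(f"unknown coding {coding!r}")
    counts = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            counts[i, j] = ((a == i) & (b == j)).sum()
    r = 0.25
    for _ in range(max_iter):
        # E-step: expected recombinant gametes; double hets contribute
        # 2 r^2 / ((1-r)^2 + r^2) each
        amb = counts[1, 1]
        det = float((counts * np.where(_REC_GAMETES < 0, 0, _REC_GAMETES)).sum())
        denom = (1 - r) ** 2 + r**2
        exp_rec = det + amb * (2 * r**2 / denom if denom > 0 else 0.0)
        new_r = exp_rec / (2 * n_joint)
        if abs(new_r - r) < tol:
            r = new_r
            break
        r = new_r
    r = float(min(max(r, 0.0), 0.5))
    lod = _intercross_lod(counts, r)
    return r, lod, n_joint


def _class_probs(r: float) -> np.ndarray:
    pp, pr = (1 - r) / 2, r / 2
    p = np.empty((3, 3))
    p[0, 0] = p[2, 2] = pp**2
    p[0, 2] = p[2, 0] = pr**2
    p[0, 1] = p[1, 0] = p[1, 2] = p[2, 1] = 2 * pp * pr
    p[1, 1] = 2 * (pp**2 + pr**2)
    return p


def _intercross_lod(counts: np.ndarray, r: float) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = counts * (np.log10(_class_probs(r)) - np.log10(_class_probs(0.5)))
    return float(np.nansum(np.where(counts > 0, ll, 0.0)))


def _backcross_lod(rec: int, n: int, r: float) -> float:
    nonrec = n - rec
    def ll(rr):
        out = 0.0
        if rec:
            out += rec * np.log10(rr) if rr > 0 else -np.inf
        if nonrec:
            out += nonrec * np.log10(1 - rr) if rr < 1 else -np.inf
        return out
    return float(ll(r) - ll(0.5))


def pairwise_rf(
    f2: GenotypeTable, coding: str = "intercross"
) -> tuple[np.ndarray, np.ndarray]:
    """Recombination fraction and LOD for every marker pair."""
    m = f2.n_markers
    rf = np.full((m, m), np.nan)
    lod = np.zeros((m, m))
    np.fill_diagonal(rf, 0.0)
    for i in range(m):
        for j in range(i + 1, m):
            try:
                r, ld, _ = _rf_with_lod(f2.codes[i], f2.codes[j], coding)
            except ValueError:
                continue
            rf[i, j] = rf[j, i] = r
            lod[i, j] = lod[j, i] = ld
    return rf, lod


def form_groups(
    rf: np.ndarray,
    lod: np.ndarray,
    max_rf: float = 0.35,
    min_lod: float = 3.0,
) -> list[list[int]]:
    """Single-linkage grouping: linked iff r <= max_rf and LOD >= min_lod."""
    linked = (rf <= max_rf) & (lod >= min_lod)
    np.fill_diagonal(linked, True)
    linked &= ~np.isnan(rf)
    n_comp, labels = connected_components(
        csr_matrix(linked), directed=False
    )
    groups = [[] for _ in range(n_comp)]
    for idx, lab in enumerate(labels):
        groups[lab].append(idx)
    groups.sort(key=len, reverse=True)
    return groups


def haldane(r: np.ndarray | float):
    """Haldane map function: d(cM) = -50 ln(1 - 2r)."""
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore"):
        d = -50.0 * np.log1p(-2.0 * np.clip(r, 0, 0.5))
    return d if d.shape else float(d)


def kosambi(r: np.ndarray | float):
    """Kosambi map function: d(cM) = 25 ln((1+2r)/(1-2r))."""
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore"):
        d = 25.0 * (np.log1p(2.0 * r) - np.log1p(-2.0 * np.clip(r, 0, 0.5)))
    return d if d.shape else float(d)


_MAP_FUNCTIONS = {"haldane": haldane, "kosambi": kosambi}


def order_and_map(
    group: list[int],
    rf: np.ndarray,
    map_function: str = "haldane",
) -> pd.DataFrame:
    """Order a linkage group and convert adjacent r to cumulative cM.

    Ordering: greedy nearest-neighbour seriation from the tightest pair,
    extending whichever end has the closer unplaced marker, then 2-opt
    segment reversals until the sum of adjacent recombination fractions
    stops improving. Adjacent r = 0.5 gives an infinite distance, which
    is flagged with a warning.
    """
    if map_function not in _MAP_FUNCTIONS:
        raise ValueError(f"unknown map function {map_function!r}")
    if len(group) < 2:
        return pd.DataFrame({"marker": group, "cM": [0.0] * len(group)})
    sub = rf[np.ix_(group, group)]
    sub = np.where(np.isnan(sub), 0.5, sub)
    order = _seriate(sub)
    order = _two_opt(order, sub)
    adj = np.array([sub[order[k], order[k + 1]] for k in range(len(order) - 1)])
    dist = _MAP_FUNCTIONS[map_function](adj)
    dist = np.atleast_1d(dist)
    if np.isinf(dist).any():
        warnings.warn(
            "adjacent markers with r = 0.5 after ordering; infinite distance",
            stacklevel=2,
        )
    cm = np.concatenate([[0.0], np.cumsum(dist)])
    return pd.DataFrame(
        {"marker": [group[k] for k in order], "cM": cm}
    )


def _seriate(sub: np.ndarray) -> list[int]:
    m = len(sub)
    masked = sub + np.diag([np.inf] * m)
    i, j = np.unravel_index(np.argmin(masked), masked.shape)
    path = [int(i), int(j)]
    remaining = set(range(m)) - set(path)
    while remaining:
        rem = list(remaining)
        head_d = [sub[path[0], k] for k in rem]
        tail_d = [sub[path[-1], k] for k in rem]
        if min(head_d) < min(tail_d):
            k = rem[int(np.argmin(head_d))]
            path.insert(0, k)
        else:
            k = rem[int(np.argmin(tail_d))]
            path.append(k)
        remaining.discard(k)
    return path


def _path_cost(order: list[int], sub: np.ndarray) -> float:
    return float(
        sum(sub[order[k], order[k + 1]] for k in range(len(order) - 1))
    )


def _two_opt(order: list[int], sub: np.ndarray) -> list[int]:
    best = list(order)
    best_cost = _path_cost(best, sub)
    improved = True
    while improved:
        improved = False
        for i in range(len(best) - 1):
            for j in range(i + 1, len(best)):
                cand = best[:i] + best[i:j + 1][::-1] + best[j + 1:]
                cost = _path_cost(cand, sub)
                if cost < best_cost - 1e-12:
                    best, best_cost = cand, cost
                    improved = True
    return best


def build_linkage_map(
    f2: GenotypeTable,
    coding: str = "intercross",
    max_rf: float = 0.35,
    min_lod: float = 3.0,
    map_function: str = "haldane",
) -> pd.DataFrame:
    """Full map construction on filtered F2 genotypes.

    Returns a table mirroring the published map format: one row per
    marker with columns ``group``, ``marker`` (chrom:pos), ``chrom``,
    ``pos`` and cumulative ``cM`` within its group.
    """
    rf, lod = pairwise_rf(f2, coding=coding)
    groups = form_groups(rf, lod, max_rf=max_rf, min_lod=min_lod)
    frames = []
    for gnum, group in enumerate(groups, start=1):
        ordered = order_and_map(group, rf, map_function=map_function)
        sub = f2.markers.iloc[ordered["marker"].to_numpy()]
        frames.append(
            pd.DataFrame(
                {
                    "group": f"L.{gnum}",
                    "marker": [
                        f"{c}:{p}" for c, p in zip(sub["chrom"], sub["pos"])
                    ],
                    "chrom": sub["chrom"].to_numpy(),
                    "pos": sub["pos"].to_numpy(),
                    "cM": ordered["cM"].to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
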