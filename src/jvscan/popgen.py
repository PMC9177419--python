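"""Population-level detection of the locked-heterozygosity signature.

A balanced-lethal chromosome shows up in wild populations as observed
heterozygosity far above its Hardy--Weinberg expectation, and as
dense stretches of sites heterozygous in most individuals. The scans
here implement the site filters, >80%-heterozygosity window counts,
observed vs expected heterozygosity, identity-by-state distances,
Hudson's FST and the J/V genotype classifier used to separate
locked-heterozygous island populations from panmictic ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from jvscan.containers import GT_HET, GT_HOM_ALT, GT_MISSING, GenotypeTable
from jvscan.layout import GenomeLayout, make_windows


@dataclass
class PopulationPanel:
    """A genotype table with per-individual population labels."""

    table: GenotypeTable
    populations: list[str]

    def __post_init__(self) -> None:
        if len(self.populations) != self.table.n_individuals:
            raise ValueError("one population label per individual required")
        if any(not p for p in self.populations):
            raise ValueError("population labels must be non-empty")

    def site_stats(self) -> pd.DataFrame:
        """Per-site minor allele frequency, observed het, presence."""
        codes = self.table.codes
        n_called = (codes != GT_MISSING).sum(axis=1)
        n_het = (codes == GT_HET).sum(axis=1)
        n_alt = (codes == GT_HOM_ALT).sum(axis=1) * 2 + n_het
        with np.errstate(invalid="ignore", divide="ignore"):
            p_alt = np.where(n_called > 0, n_alt / (2 * n_called), np.nan)
            obs_het = np.where(n_called > 0, n_het / n_called, np.nan)
        maf = np.minimum(p_alt, 1 - p_alt)
        return pd.DataFrame(
            {
                "maf": maf,
                "obs_het": obs_het,
                "presence": n_called / self.table.n_individuals,
            }
        )

    def subset_sites(self, mask: np.ndarray) -> "PopulationPanel":
        return PopulationPanel(self.table.subset_markers(mask), list(self.populations))

    def subset_population(self, name: str) -> "PopulationPanel":
        keep = [i for i, p in zip(self.table.individuals, self.populations) if p == name]
        pops = [p for p in self.populations if p == name]
        return PopulationPanel(self.table.subset_individuals(keep), pops)


def filter_sites(
    panel: PopulationPanel,
    min_presence: float = 0.75,
    min_maf: float = 0.04,
    max_obs_het: float = 0.99,
) -> PopulationPanel:
    """Apply the population-panel site filters.

    Sites are kept iff genotyped in at least ``min_presence`` of all
    individuals, with minor allele frequency at least ``min_maf`` (drops
    singletons that mask structure) and observed heterozygosity at most
    ``max_obs_het`` (drops likely paralogue collapses). All statistics
    are computed on the input panel, so the rules commute and the filter
    is idempotent.
    """
    if panel.table.n_markers == 0:
        raise ValueError("empty panel")
    stats = panel.site_stats()
    keep = (
        (stats["presence"] >= min_presence)
        & (stats["maf"] >= min_maf)
        & (stats["obs_het"] <= max_obs_het)
    ).to_numpy()
    if not keep.any():
        raise ValueError("no sites survive population filtering")
    return panel.subset_sites(keep)


def het_window_scan(
    panel: PopulationPanel,
    layout: GenomeLayout,
    window: int = 10_000,
    het_fraction: float = 0.8,
) -> pd.DataFrame:
    """Count persistently heterozygous sites per genomic window.

    A site counts when strictly more than ``het_fraction`` of its
    non-missing genotypes are heterozygous. Returns the window table with
    a ``het_sites`` column.
    """
    codes = panel.table.codes
    n_called = (codes != GT_MISSING).sum(axis=1)
    n_het = (codes == GT_HET).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_called > 0, n_het / np.maximum(n_called, 1), 0.0)
    hot = (frac > het_fraction) & (n_called > 0)
    markers = panel.table.markers
    windows = make_windows(layout, window)
    counts = np.zeros(len(windows), dtype=int)
    offsets = {}
    cursor = 0
    for name, length in layout.chromosomes:
        offsets[name] = cursor
        cursor += -(-length // window)  # windows on this chromosome
    chrom = markers["chrom"].to_numpy()
    pos = markers["pos"].to_numpy()
    for name in markers["chrom"].drop_duplicates():
        if name not in offsets:
            continue
        sel = chrom == name
        idx = offsets[name] + pos[sel] // window
        np.add.at(counts, idx.astype(int), hot[sel].astype(int))
    return windows.assign(het_sites=counts)


def obs_exp_het(
    panel: PopulationPanel,
    unbiased: bool = False,
) -> pd.DataFrame:
    """Observed vs Hardy--Weinberg expected heterozygosity per chromosome
    per population.

    Ho is the mean over sites of the het fraction among non-missing
    genotypes; He is the mean over sites of 2p(1-p) with p estimated from
    non-missing genotypes (optionally with the small-sample factor
    2n/(2n-1)). Groups with zero polymorphic sites are omitted with a
    warning.
    """
    if panel.table.n_individuals < 2:
        raise ValueError("at least two individuals required")
    rows = []
    markers = panel.table.markers
    for pop in dict.fromkeys(panel.populations):
        sub = panel.subset_population(pop)
        codes = sub.table.codes
        for chrom in markers["chrom"].drop_duplicates():
            sel = (markers["chrom"] == chrom).to_numpy()
            c = codes[sel]
            n_called = (c != GT_MISSING).sum(axis=1)
            ok = n_called > 0
            n_het = (c == GT_HET).sum(axis=1)
            n_alt = (c == GT_HOM_ALT).sum(axis=1) * 2 + n_het
            with np.errstate(invalid="ignore", divide="ignore"):
                p = n_alt[ok] / (2 * n_called[ok])
                ho_site = n_het[ok] / n_called[ok]
            polymorphic = (p > 0) & (p < 1)
            if not (polymorphic.any() or (ho_site > 0).any()):
                warnings.warn(
                    f"{pop}/{chrom}: no polymorphic sites; omitted",
                    stacklevel=2,
                )
                continue
            he_site = 2 * p * (1 - p)
            if unbiased:
                two_n = 2 * n_called[ok]
                he_site = he_site * two_n / np.maximum(two_n - 1, 1)
            rows.append(
                {
                    "population": pop,
                    "chrom": chrom,
                    "observed_het": float(ho_site.mean()),
                    "expected_het": float(he_site.mean()),
                    "n_sites": int(ok.sum()),
                }
            )
    return pd.DataFrame(rows)


# -- identity by state --------------------------------------------------

# allele-sharing score between genotype codes (0/1/2 alt copies):
# 1 identical, 0.5 one shared allele, 0 none shared
_SHARING = np.array(
    [
        [1.0, 0.5, 0.0],
        [0.5, 1.0, 0.5],
        [0.0, 0.5, 1.0],
    ]
)


def ibs_matrix(panel: PopulationPanel):
    """Pairwise identity-by-state distances and an average-linkage tree.

    distance(i, j) = 1 - mean allele sharing over jointly genotyped
    sites (sharing 1 for identical genotypes, 0.5 for one shared allele,
    0 for opposite homozygotes). Returns ``(distance DataFrame, newick
    string)``; pairs with zero jointly genotyped sites get NaN and a
    warning, and the tree is built only when all distances are defined.
    """
    if panel.table.n_individuals < 2:
        raise ValueError("at least two individuals required")
    codes = panel.table.codes
    n = panel.table.n_individuals
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = (codes[:, i] != GT_MISSING) & (codes[:, j] != GT_MISSING)
            if not both.any():
                warnings.warn(
                    f"no shared sites between {panel.table.individuals[i]} "
                    f"and {panel.table.individuals[j]}",
                    stacklevel=2,
                )
                dist[i, j] = dist[j, i] = np.nan
                continue
            share = _SHARING[codes[both, i], codes[both, j]]
            dist[i, j] = dist[j, i] = 1.0 - float(share.mean())
    frame = pd.DataFrame(
        dist, index=panel.table.individuals, columns=panel.table.individuals
    )
    newick = None
    if not np.isnan(dist).any():
        linkage = hierarchy.average(squareform(dist, checks=False))
        from skbio.tree import TreeNode

        tree = TreeNode.from_linkage_matrix(linkage, panel.table.individuals)
        newick = str(tree)
    return frame, newick


def hudson_fst(
    panel: PopulationPanel,
    pop1: str,
    pop2: str,
) -> tuple[pd.DataFrame, float]:
    """Hudson's FST per site and its genome-wide ratio of averages.

    Per site, with sample allele frequencies p1, p2 from n1, n2 diploid
    individuals::

        N = (p1 - p2)^2 - p1(1-p1)/(2n1 - 1) - p2(1-p2)/(2n2 - 1)
        D = p1(1-p2) + p2(1-p1)

    Sites monomorphic across the union, or with fewer than two genotyped
    individuals in either population, are skipped. The genome-wide value
    is sum(N)/sum(D).
    """
    sub1 = panel.subset_population(pop1).table
    sub2 = panel.subset_population(pop2).table

    def freqs(codes):
        n_called = (codes != GT_MISSING).sum(axis=1)
        n_alt = (codes == GT_HOM_ALT).sum(axis=1) * 2 + (codes == GT_HET).sum(
            axis=1
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_called > 0, n_alt / (2 * n_called), np.nan)
        return p, n_called

    p1, n1 = freqs(sub1.codes)
    p2, n2 = freqs(sub2.codes)
    ok = (n1 >= 2) & (n2 >= 2)
    poly = ok & ~((p1 == 0) & (p2 == 0)) & ~((p1 == 1) & (p2 == 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (
            (p1 - p2) ** 2
            - p1 * (1 - p1) / np.maximum(2 * n1 - 1, 1)
            - p2 * (1 - p2) / np.maximum(2 * n2 - 1, 1)
        )
        den = p1 * (1 - p2) + p2 * (1 - p1)
    table = panel.table.markers[["chrom", "pos"]].copy()
    table["fst"] = np.where(poly & (den > 0), num / den, np.nan)
    genome = float(np.nansum(np.where(poly, num, 0.0)) / np.nansum(
        np.where(poly, den, 0.0)
    ))
    return table, genome


def classify_jv(
    genotypes: np.ndarray,
    het_threshold: float = 0.8,
    min_markers: int = 20,
) -> str:
    """Classify one individual's haplotype genotype from a J/V marker panel.

    ``genotypes`` are the individual's codes at the panel markers (the
    chromosome-1 markers heterozygous in the reference J/V line). A het
    fraction of at least ``het_threshold`` across genotyped panel markers
    gives ``"J/V"``; at most ``1 - het_threshold`` gives ``"J/J"``;
    anything between, or fewer than ``min_markers`` genotyped markers,
    gives ``"unclassified"``.
    """
    genotypes = np.asarray(genotypes)
    called = genotypes != GT_MISSING
    if int(called.sum()) < min_markers:
        return "unclassified"
    frac = float((genotypes[called] == GT_HET).mean())
    if frac >= het_threshold:
        return "J/V"
    if frac <= 1 - het_threshold:
        return "J/J"
    return "unclassified"
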