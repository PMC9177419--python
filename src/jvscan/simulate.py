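"""Synthetic-data generators with recorded ground truth.

Every pipeline input can be generated here: a diploid parent whose two
phased haplotypes (J and V) diverge inside three inversion strata;
single gametes with Poisson crossovers, short gene-conversion tracts and
genotyping noise; a balanced-lethal population (every survivor
heterozygous on chromosome 1) next to a Hardy--Weinberg population;
chromosome-sorted sequencing depth with amplification noise and
contamination; an F2 intercross; haplotype-biased expression counts; and
synonymously diverged coding-sequence pairs for the strata clock.

All generators are pure functions of (config, seed): a fixed seed gives
byte-identical output. Crossover interference is not modelled (counts
are Poisson with mean equal to the genetic map length in Morgans), which
keeps the expected behaviour analytic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from jvscan.containers import (
    GT_HET,
    GT_MISSING,
    CoverageMatrix,
    GameteMatrix,
    GenotypeTable,
)
from jvscan.layout import GenomeLayout, default_layout


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SimConfig:
    """Simulation knobs.

    ``map_lengths`` give the genetic length of each chromosome in
    Morgans; chromosomes named in ``suppressed`` are forced to the
    residual map length (default 0.005 Morgans, i.e. the 0.5 cM measured
    for the suppressed chromosome). Per-stratum J/V divergence defaults
    follow the strata clock (dS = 2 mu T with mu = 1e-8 per generation
    and ages 320k / 260k / 450k generations for strata 1--3).
    """

    layout: GenomeLayout = field(default_factory=default_layout)
    map_lengths: dict = field(
        default_factory=lambda: {
            "chr1": 1.0,
            "chr2": 0.9,
            "chr3": 1.1,
            "chr4": 0.8,
        }
    )
    suppressed: tuple = ("chr1",)
    residual_map_length: float = 0.005
    telomere_fraction: float | None = None
    gene_conversion_rate: float = 0.2
    gene_conversion_tract: int = 50_000
    error_rate: float = 0.005
    missing_rate: float = 0.05
    markers_per_chromosome: int = 200
    stratum_divergence: dict = field(
        default_factory=lambda: {1: 0.0064, 2: 0.0052, 3: 0.0090}
    )
    background_divergence: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.gene_conversion_rate,):
            if rate < 0:
                raise ValueError("gene conversion rate must be >= 0")
        for rate in (self.error_rate, self.missing_rate):
            if not 0 <= rate <= 1:
                raise ValueError("error/missing rates must lie in [0, 1]")
        for div in self.stratum_divergence.values():
            if not 0 < div <= 0.25:
                raise ValueError("stratum divergence must lie in (0, 0.25]")
        if self.markers_per_chromosome < 1:
            raise ValueError("at least one marker per chromosome required")
        min_len = min(length for _, length in self.layout.chromosomes)
        if self.gene_conversion_tract >= 0.01 * min_len:
            warnings.warn(
                "gene-conversion tract length is not safely below 1% of the "
                "shortest chromosome; tracts may be classified as crossovers",
                stacklevel=2,
            )

    def effective_map_length(self, chromosome: str) -> float:
        if chromosome in self.suppressed:
            return self.residual_map_length
        return float(self.map_lengths.get(chromosome, 1.0))


@dataclass
class SimTruth:
    """Ground truth recorded by the generators (recovery-test oracle)."""

    seed: int | None = None
    # parent: allele carried by the J haplotype at each marker (0/1)
    j_allele: np.ndarray | None = None
    # per gamete id: {chromosome: sorted crossover breakpoints (bp floats)}
    crossovers: dict | None = None
    # per gamete id: {chromosome: list of (start, end) conversion tracts}
    conversions: dict | None = None
    # scaffold -> chromosome
    scaffold_map: dict | None = None
    # per gene: true J-allele proportion
    ase_bias: dict | None = None


# -- parent -------------------------------------------------------------


def simulate_parent(config: SimConfig, seed=None):
    """Place heterozygous markers and phase them into J/V haplotypes.

    Marker density within each inversion stratum is proportional to the
    stratum's J/V divergence; outside the strata it follows the (lower)
    background divergence. The parent is heterozygous at every marker.

    Returns ``(markers, parent, truth)`` where ``parent`` is a
    one-individual :class:`GenotypeTable` that is het everywhere and
    ``truth.j_allele`` records which allele sits on the J haplotype.
    """
    rng = _rng(config.seed if seed is None else seed)
    rows = []
    for name, length in config.layout.chromosomes:
        n = config.markers_per_chromosome
        segments = _divergence_segments(config, name, length)
        weights = np.array([(end - start) * div for start, end, div in segments])
        counts = rng.multinomial(n, weights / weights.sum())
        positions: list[int] = []
        for (start, end, _), k in zip(segments, counts):
            if k == 0:
                continue
            pos = np.unique(rng.integers(start, end, size=k))
            while len(pos) < k:
                extra = rng.integers(start, end, size=k - len(pos))
                pos = np.unique(np.concatenate([pos, extra]))
            positions.extend(int(p) for p in pos)
        positions = sorted(set(positions))
        for p in positions:
            rows.append((name, p))
    markers = pd.DataFrame(rows, columns=["chrom", "pos"])
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=len(markers))
    alt_idx = (ref_idx + rng.integers(1, 4, size=len(markers))) % 4
    markers["ref"] = bases[ref_idx]
    markers["alt"] = bases[alt_idx]
    j_allele = rng.integers(0, 2, size=len(markers)).astype(np.int8)
    parent = GenotypeTable(
        markers,
        ["parent"],
        np.full((len(markers), 1), GT_HET, dtype=np.int8),
    )
    truth = SimTruth(seed=config.seed, j_allele=j_allele)
    return parent.markers, parent, truth


def _divergence_segments(config: SimConfig, chromosome: str, length: int):
    """Partition a chromosome into (start, end, divergence) segments."""
    inversions = sorted(
        config.layout.inversions_on(chromosome), key=lambda inv: inv.start
    )
    segments = []
    cursor = 0
    for inv in inversions:
        if inv.start > cursor:
            segments.append((cursor, inv.start, config.background_divergence))
        segments.append(
            (inv.start, inv.end, config.stratum_divergence.get(inv.stratum, 0.005))
        )
        cursor = inv.end
    if cursor < length:
        segments.append((cursor, length, config.background_divergence))
    return segments


# -- gametes ------------------------------------------------------------


def simulate_gametes(
    markers: pd.DataFrame,
    truth: SimTruth,
    config: SimConfig,
    n_gametes: int,
    gamete_type: str = "sperm",
    seed=None,
):
    """Draw haploid gametes from the phased parent.

    Per gamete and chromosome the crossover count is Poisson with mean
    equal to the chromosome's genetic map length; breakpoints are uniform
    (restricted to the telomeric ``telomere_fraction`` of the chromosome
    if configured). Gene-conversion tracts are Poisson with the
    configured per-gamete rate and a fixed tract length. Calls are then
    perturbed by symmetric allele flips (``error_rate``) and missingness
    (``missing_rate``), independently per cell.

    Breakpoints are placed at half-integer coordinates, hence strictly
    between markers.
    """
    if n_gametes < 1:
        raise ValueError("n_gametes must be >= 1")
    if gamete_type not in {"sperm", "oocyte"}:
        raise ValueError("gamete_type must be 'sperm' or 'oocyte'")
    rng = _rng(config.seed + 1 if seed is None else seed)
    j_allele = truth.j_allele
    if j_allele is None:
        raise ValueError("truth must carry the parental phase (j_allele)")
    chroms = markers["chrom"].to_numpy()
    pos = markers["pos"].to_numpy()
    n_markers = len(markers)
    calls = np.zeros((n_markers, n_gametes), dtype=np.int8)
    ids = [f"{gamete_type}_{i + 1:03d}" for i in range(n_gametes)]
    xo_truth: dict = {}
    gc_truth: dict = {}
    for g, gid in enumerate(ids):
        xo_truth[gid] = {}
        gc_truth[gid] = {}
        hap = np.empty(n_markers, dtype=np.int8)
        for name, length in config.layout.chromosomes:
            sel = chroms == name
            morgans = config.effective_map_length(name)
            n_xo = rng.poisson(morgans)
            breakpoints = _draw_breakpoints(rng, n_xo, length, config)
            n_gc = rng.poisson(config.gene_conversion_rate)
            tracts = []
            span = max(1, length - config.gene_conversion_tract)
            for _ in range(n_gc):
                start = float(rng.integers(0, span)) + 0.5
                tracts.append((start, start + config.gene_conversion_tract))
            start_hap = int(rng.integers(0, 2))
            p = pos[sel]
            flips = np.searchsorted(breakpoints, p) % 2
            h = start_hap ^ flips
            for t0, t1 in tracts:
                inside = (p > t0) & (p < t1)
                h = np.where(inside, 1 - h, h)
            hap[sel] = h
            xo_truth[gid][name] = [float(b) for b in breakpoints]
            gc_truth[gid][name] = tracts
        allele = np.where(hap == 0, j_allele, 1 - j_allele).astype(np.int8)
        if config.error_rate > 0:
            flip = rng.random(n_markers) < config.error_rate
            allele = np.where(flip, 1 - allele, allele).astype(np.int8)
        if config.missing_rate > 0:
            miss = rng.random(n_markers) < config.missing_rate
            allele = np.where(miss, -1, allele).astype(np.int8)
        calls[:, g] = allele
    gametes = GameteMatrix(
        markers.copy(), ids, [gamete_type] * n_gametes, calls
    )
    out_truth = SimTruth(
        seed=truth.seed,
        j_allele=j_allele,
        crossovers=xo_truth,
        conversions=gc_truth,
    )
    return gametes, out_truth


def _draw_breakpoints(rng, n_xo, length, config) -> np.ndarray:
    if n_xo == 0:
        return np.empty(0)
    if config.telomere_fraction:
        tel = int(length * config.telomere_fraction)
        left = rng.random(n_xo) < 0.5
        raw = np.where(
            left,
            rng.integers(0, tel, size=n_xo),
            rng.integers(length - tel, length, size=n_xo),
        )
    else:
        raw = rng.integers(0, length, size=n_xo)
    return np.sort(raw.astype(float) + 0.5)


# -- populations --------------------------------------------------------


def simulate_population(
    config: SimConfig,
    n_individuals: int,
    model: str = "balanced_lethal",
    allele_freq: float = 0.5,
    seed=None,
    error_rate: float = 0.0,
):
    """Genotypes for a wild population panel.

    ``model="balanced_lethal"``: both chromosome-1 homozygotes die as
    embryos, so every surviving individual is heterozygous at every
    chromosome-1 J/V marker; other chromosomes follow Hardy--Weinberg at
    ``allele_freq``. ``model="panmictic"``: all chromosomes follow
    Hardy--Weinberg.
    """
    if n_individuals < 2:
        raise ValueError("n_individuals must be >= 2")
    if not 0 < allele_freq < 1:
        raise ValueError("allele_freq must lie in (0, 1)")
    if model not in {"balanced_lethal", "panmictic"}:
        raise ValueError(f"unknown population model {model!r}")
    rng = _rng(config.seed + 2 if seed is None else seed)
    markers, _, _ = simulate_parent(config, seed=rng)
    n_markers = len(markers)
    p = allele_freq
    alleles = rng.random((n_markers, n_individuals, 2)) < p
    codes = alleles.sum(axis=2).astype(np.int8)  # 0/1/2 copies of alt
    if model == "balanced_lethal":
        locked = markers["chrom"].isin(config.suppressed).to_numpy()
        codes[locked, :] = GT_HET
    if error_rate > 0:
        err = rng.random(codes.shape) < error_rate
        codes = np.where(err, rng.integers(0, 3, size=codes.shape), codes)
    codes = codes.astype(np.int8)
    individuals = [f"ind_{i + 1:03d}" for i in range(n_individuals)]
    return GenotypeTable(markers, individuals, codes)


def simulate_island_panel(
    config: SimConfig,
    sizes: dict,
    locked_populations: tuple = ("SAR", "COR"),
    allele_freq: float = 0.5,
    jv_marker_freq: float = 0.02,
    seed=None,
):
    """A multi-island wild panel sharing one marker set.

    ``sizes`` maps population name -> number of individuals. Populations
    named in ``locked_populations`` carry the balanced-lethal chromosome-1
    system (every individual heterozygous at chromosome-1 markers); in
    the remaining populations the chromosome-1 J/V markers are nearly
    fixed for the J allele (alternate-allele frequency
    ``jv_marker_freq``, emulating J/J-homozygous islands). All other
    chromosomes follow Hardy--Weinberg at ``allele_freq`` everywhere.

    Returns ``(GenotypeTable, population labels)``.
    """
    rng = _rng(config.seed + 4 if seed is None else seed)
    markers, _, _ = simulate_parent(config, seed=rng)
    n_markers = len(markers)
    locked_sites = markers["chrom"].isin(config.suppressed).to_numpy()
    columns, labels, names = [], [], []
    for pop, n in sizes.items():
        freq = np.full(n_markers, allele_freq)
        if pop not in locked_populations:
            freq[locked_sites] = jv_marker_freq
        alleles = rng.random((n_markers, n, 2)) < freq[:, None, None]
        codes = alleles.sum(axis=2).astype(np.int8)
        if pop in locked_populations:
            codes[locked_sites, :] = GT_HET
        columns.append(codes)
        labels.extend([pop] * n)
        names.extend([f"{pop}_{i + 1:03d}" for i in range(n)])
    table = GenotypeTable(markers, names, np.concatenate(columns, axis=1))
    return table, labels


# -- chromosome sequencing ----------------------------------------------


def make_scaffold_map(layout: GenomeLayout, n_scaffolds: int, seed=None) -> dict:
    """Random truth assignment of scaffolds to chromosomes.

    Scaffold counts per chromosome are proportional to chromosome length.
    """
    rng = _rng(seed)
    names = layout.names
    lengths = np.array([layout.length(n) for n in names], dtype=float)
    chroms = rng.choice(len(names), size=n_scaffolds, p=lengths / lengths.sum())
    return {f"scaffold_{i + 1:04d}": names[c] for i, c in enumerate(chroms)}


def simulate_chrseq(
    scaffold_map: dict,
    samples_per_chromosome: int = 4,
    contamination: float = 0.0,
    noise_sigma: float = 0.0,
    background: float = 0.01,
    seed=None,
) -> CoverageMatrix:
    """Depth matrix for laser-captured single-chromosome sequencing.

    A scaffold's depth in a sample is lognormal around 1 if the sample's
    chromosome matches the scaffold's true chromosome, else lognormal
    around ``background``. With probability ``contamination`` a sample
    additionally carries a second chromosome's signal (a stray chromosome
    captured alongside the intended one).
    """
    if samples_per_chromosome < 2:
        raise ValueError(
            "at least 2 samples per chromosome required for reproducibility"
        )
    rng = _rng(seed)
    chromosomes = sorted(set(scaffold_map.values()))
    scaffolds = list(scaffold_map)
    columns = {}
    sample_chrom = {}
    truth_chrom = np.array([scaffold_map[s] for s in scaffolds])
    for chrom in chromosomes:
        for k in range(samples_per_chromosome):
            name = f"{chrom}_s{k + 1}"
            sample_chrom[name] = chrom
            signal = np.where(truth_chrom == chrom, 1.0, background)
            # draw contamination variates unconditionally so that runs at
            # different contamination rates share one random stream (the
            # contaminated sample set is then nested across rates)
            u_cont = rng.random()
            other = rng.choice([c for c in chromosomes if c != chrom])
            if u_cont < contamination:
                signal = np.maximum(signal, np.where(truth_chrom == other, 1.0, 0.0))
            if noise_sigma > 0:
                signal = signal * rng.lognormal(0.0, noise_sigma, size=len(signal))
            columns[name] = signal
    depths = pd.DataFrame(columns, index=scaffolds)
    lengths = pd.Series(
        rng.integers(200_000, 5_000_000, size=len(scaffolds)), index=scaffolds
    )
    return CoverageMatrix(depths, pd.Series(sample_chrom), lengths)


# -- F2 intercross ------------------------------------------------------


def simulate_f2(
    config: SimConfig,
    n_segregants: int,
    seed=None,
    parents: GenotypeTable | None = None,
    missing_rate: float = 0.0,
):
    """An F2 intercross between two fully homozygous, divergent strains.

    Parent 1 is homozygous reference and parent 2 homozygous alternate at
    every map marker (markers where supplied parents are not opposite
    homozygotes are excluded with a warning). Each segregant is the union
    of two independent F1 gametes drawn under the genetic map.

    Returns ``(parents, f2, truth)``.
    """
    rng = _rng(config.seed + 3 if seed is None else seed)
    if parents is None:
        markers, _, _ = simulate_parent(config, seed=rng)
        codes = np.zeros((len(markers), 2), dtype=np.int8)
        codes[:, 1] = 2
        parents = GenotypeTable(markers, ["parent1", "parent2"], codes)
    else:
        informative = (
            ((parents.codes[:, 0] == 0) & (parents.codes[:, 1] == 2))
            | ((parents.codes[:, 0] == 2) & (parents.codes[:, 1] == 0))
        )
        if not informative.all():
            warnings.warn(
                f"excluding {int((~informative).sum())} non-informative "
                "parent markers",
                stacklevel=2,
            )
            parents = parents.subset_markers(informative)
    markers = parents.markers
    chroms = markers["chrom"].to_numpy()
    pos = markers["pos"].to_numpy()
    n_markers = len(markers)
    codes = np.empty((n_markers, n_segregants), dtype=np.int8)
    xo_truth: dict = {}
    ids = [f"f2_{i + 1:03d}" for i in range(n_segregants)]
    # allele of parent 2 (alt) marks its haplotype
    p2_hom = parents.codes[:, 1] == 2
    for j, sid in enumerate(ids):
        total = np.zeros(n_markers, dtype=np.int8)
        xo_truth[sid] = []
        for _ in range(2):  # two F1 gametes
            gamete = np.empty(n_markers, dtype=np.int8)
            bks = {}
            for name, length in config.layout.chromosomes:
                sel = chroms == name
                if not sel.any():
                    continue
                n_xo = rng.poisson(config.effective_map_length(name))
                breakpoints = _draw_breakpoints(rng, n_xo, length, config)
                start = int(rng.integers(0, 2))
                flips = np.searchsorted(breakpoints, pos[sel]) % 2
                gamete[sel] = start ^ flips  # 1 = parent-2 haplotype
                bks[name] = [float(b) for b in breakpoints]
            total += gamete
            xo_truth[sid].append(bks)
        # copies of the parent-2 allele; parent-2 allele is alt where p2 hom-alt
        alt_copies = np.where(p2_hom, total, 2 - total)
        codes[:, j] = alt_copies
    if missing_rate > 0:
        miss = rng.random(codes.shape) < missing_rate
        codes = np.where(miss, GT_MISSING, codes).astype(np.int8)
    f2 = GenotypeTable(markers.copy(), ids, codes)
    truth = SimTruth(seed=config.seed, crossovers=xo_truth)
    return parents, f2, truth


# -- allele-specific expression ----------------------------------------


def simulate_ase(
    n_genes: int,
    bias,
    depth: int,
    variants_per_gene: int = 3,
    tissue: str = "whole_worm",
    seed=None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Per-variant J/V allele counts for expression-bias testing.

    ``bias`` (scalar or per-gene array) is the true probability that a
    read carries the J allele; the gene's total read depth is split
    evenly across its exonic variants and each variant's J count is
    binomial.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    bias_arr = np.broadcast_to(np.asarray(bias, dtype=float), (n_genes,))
    if ((bias_arr <= 0) | (bias_arr >= 1)).any():
        raise ValueError("bias must lie strictly inside (0, 1)")
    rng = _rng(seed)
    rows = []
    truth_bias = {}
    for g in range(n_genes):
        gene = f"gene_{g + 1:04d}"
        truth_bias[gene] = float(bias_arr[g])
        base = depth // variants_per_gene
        extra = depth % variants_per_gene
        for v in range(variants_per_gene):
            v_depth = base + (1 if v < extra else 0)
            j = int(rng.binomial(v_depth, bias_arr[g])) if v_depth else 0
            rows.append((gene, f"{gene}_v{v + 1}", j, v_depth - j, tissue))
    table = pd.DataFrame(
        rows, columns=["gene", "variant", "j_count", "v_count", "tissue"]
    )
    return table, SimTruth(ase_bias=truth_bias)


# -- diverged coding sequence for the strata clock ----------------------

_FOURFOLD_PREFIXES = ("GC", "GG", "GT", "CC", "AC", "TC")
_BASES = np.array(list("ACGT"))


def simulate_diverged_cds(
    n_codons: int,
    generations: float,
    mu: float = 1.0e-8,
    seed=None,
) -> tuple[str, str]:
    """Two haplotype CDS copies diverged for ``generations`` at rate ``mu``.

    The ancestor is built from fourfold-degenerate codon families whose
    first two positions never change synonymously (GCN, GGN, GTN, CCN,
    ACN, TCN), so every synonymous site is the third codon position.
    Each haplotype's third positions then evolve under Jukes--Cantor for
    ``generations`` at ``mu`` substitutions per site per generation;
    first and second positions are held fixed, restricting all divergence
    to synonymous sites.
    """
    rng = _rng(seed)
    prefixes = rng.choice(len(_FOURFOLD_PREFIXES), size=n_codons)
    third = rng.integers(0, 4, size=n_codons)

    def mutate(third_pos):
        # JC: P(site differs from ancestor) = 3/4 (1 - exp(-4/3 mu t))
        p_diff = 0.75 * (1.0 - np.exp(-4.0 / 3.0 * mu * generations))
        hit = rng.random(n_codons) < p_diff
        shift = rng.integers(1, 4, size=n_codons)
        return np.where(hit, (third_pos + shift) % 4, third_pos)

    def build(third_pos):
        codons = [
            _FOURFOLD_PREFIXES[p] + _BASES[t]
            for p, t in zip(prefixes, third_pos)
        ]
        return "".join(codons)

    return build(mutate(third)), build(mutate(third))
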