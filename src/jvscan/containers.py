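"""In-memory containers shared by all pipeline stages.

Genotype codes
--------------
Diploid genotypes are small ints: ``0`` hom-ref, ``1`` het, ``2`` hom-alt,
``-1`` missing (the ``0/0``, ``0/1``, ``1/1``, ``./.`` dialect of the
genotype tables). Haploid gamete calls use ``0`` ref, ``1`` alt, ``2``
het-anomaly (a heterozygous call in a haploid cell, an artefact of
whole-genome amplification) and ``-1`` missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# diploid genotype codes
GT_HOM_REF = 0
GT_HET = 1
GT_HOM_ALT = 2
GT_MISSING = -1

# haploid gamete call codes
CALL_REF = 0
CALL_ALT = 1
CALL_HET = 2
CALL_MISSING = -1

# haplotype labels after phasing
HAP_J = 0
HAP_V = 1
HAP_MISSING = -1

MARKER_COLUMNS = ["chrom", "pos", "ref", "alt"]


def validate_markers(markers: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonically sort a marker table.

    Markers are biallelic SNVs with columns ``chrom``, ``pos``, ``ref``,
    ``alt``. They are sorted by (chromosome in order of first appearance,
    position); positions must be unique within a chromosome.
    """
    missing = [c for c in MARKER_COLUMNS if c not in markers.columns]
    if missing:
        raise ValueError(f"marker table lacks columns {missing}")
    markers = markers.reset_index(drop=True)
    order = {c: i for i, c in enumerate(markers["chrom"].drop_duplicates())}
    key = markers["chrom"].map(order)
    markers = (
        markers.assign(_key=key)
        .sort_values(["_key", "pos"], kind="stable")
        .drop(columns="_key")
        .reset_index(drop=True)
    )
    dup = markers.duplicated(subset=["chrom", "pos"])
    if dup.any():
        where = markers.loc[dup, ["chrom", "pos"]].iloc[0]
        raise ValueError(
            f"duplicate marker position {where['chrom']}:{where['pos']}"
        )
    return markers


@dataclass
class GenotypeTable:
    """Diploid genotypes: markers x individuals.

    ``codes`` is an int8 array of shape (n_markers, n_individuals) using
    the module-level genotype codes.
    """

    markers: pd.DataFrame
    individuals: list[str]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.markers = validate_markers(self.markers)
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.markers), len(self.individuals)):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.markers)} markers x {len(self.individuals)} individuals"
            )
        valid = {GT_HOM_REF, GT_HET, GT_HOM_ALT, GT_MISSING}
        if not set(np.unique(self.codes)) <= valid:
            raise ValueError("genotype codes must be in {0, 1, 2, -1}")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def subset_markers(self, mask: np.ndarray) -> "GenotypeTable":
        mask = np.asarray(mask)
        return GenotypeTable(
            self.markers.loc[mask].reset_index(drop=True),
            list(self.individuals),
            self.codes[mask],
        )

    def subset_individuals(self, names: list[str]) -> "GenotypeTable":
        idx = [self.individuals.index(n) for n in names]
        return GenotypeTable(self.markers.copy(), list(names), self.codes[:, idx])


@dataclass
class GameteMatrix:
    """Haploid calls for single gametes: markers x gametes.

    ``gamete_types`` holds ``"sperm"`` or ``"oocyte"`` per gamete.
    """

    markers: pd.DataFrame
    gamete_ids: list[str]
    gamete_types: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.markers = validate_markers(self.markers)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if len(self.gamete_ids) != len(set(self.gamete_ids)):
            raise ValueError("gamete ids must be unique")
        if len(self.gamete_types) != len(self.gamete_ids):
            raise ValueError("one gamete type per gamete id required")
        bad = set(self.gamete_types) - {"sperm", "oocyte"}
        if bad:
            raise ValueError(f"unknown gamete types {bad}")
        if self.calls.shape != (len(self.markers), len(self.gamete_ids)):
            raise ValueError("calls shape does not match markers x gametes")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_gametes(self) -> int:
        return len(self.gamete_ids)

    def subset_markers(self, mask: np.ndarray) -> "GameteMatrix":
        mask = np.asarray(mask)
        return GameteMatrix(
            self.markers.loc[mask].reset_index(drop=True),
            list(self.gamete_ids),
            list(self.gamete_types),
            self.calls[mask],
        )


@dataclass
class HaplotypeAssignment:
    """Phased haplotype calls for gametes.

    ``phase`` maps each marker's alleles onto the J/V labels: ``phase[m]``
    is the allele (0 = ref, 1 = alt) carried by the J haplotype at marker
    ``m``. ``haplotypes`` holds per-gamete calls in {0 = J, 1 = V, -1 =
    missing}. A global label swap (J <-> V per chromosome) yields an
    equivalent assignment.
    """

    markers: pd.DataFrame
    gamete_ids: list[str]
    gamete_types: list[str]
    phase: np.ndarray
    haplotypes: np.ndarray

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=np.int8)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.phase.shape != (len(self.markers),):
            raise ValueError("phase must hold one allele per marker")
        if self.haplotypes.shape != (len(self.markers), len(self.gamete_ids)):
            raise ValueError("haplotypes shape does not match markers x gametes")


EVENT_COLUMNS = ["gamete", "chrom", "start", "end", "kind"]


@dataclass
class CrossoverCallSet:
    """Recombination events called per gamete.

    ``events`` has one row per event with columns ``gamete``, ``chrom``,
    ``start``, ``end`` (the half-open interval between the flanking
    informative markers) and ``kind`` in {"crossover", "gene_conversion"}.
    Gene-conversion events never contribute to crossover counts.
    """

    events: pd.DataFrame
    gamete_ids: list[str] = field(default_factory=list)
    gamete_types: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.events.empty:
            self.events = pd.DataFrame(columns=EVENT_COLUMNS)
        missing = [c for c in EVENT_COLUMNS if c not in self.events.columns]
        if missing:
            raise ValueError(f"event table lacks columns {missing}")
        bad = set(self.events["kind"].unique()) - {"crossover", "gene_conversion"}
        if bad:
            raise ValueError(f"unknown event kinds {bad}")

    def crossover_counts(self) -> pd.DataFrame:
        """Per-gamete, per-chromosome crossover counts (conversions excluded).

        Includes zero rows for every known gamete x chromosome present in
        the event table's chromosomes.
        """
        xo = self.events[self.events["kind"] == "crossover"]
        counts = (
            xo.groupby(["gamete", "chrom"], sort=False)
            .size()
            .rename("crossovers")
            .reset_index()
        )
        return counts

    def count_matrix(self, chromosomes: list[str]) -> pd.DataFrame:
        """Dense gamete x chromosome crossover-count table (zeros filled)."""
        counts = self.crossover_counts()
        base = pd.DataFrame(
            [(g, c) for g in self.gamete_ids for c in chromosomes],
            columns=["gamete", "chrom"],
        )
        out = base.merge(counts, how="left", on=["gamete", "chrom"])
        out["crossovers"] = out["crossovers"].fillna(0).astype(int)
        return out


@dataclass
class CoverageMatrix:
    """Chromosome-sequencing depth of scaffolds across samples.

    ``depths`` is indexed by scaffold with one column per sample;
    ``sample_chrom`` maps each sample to its claimed chromosome identity;
    ``scaffold_lengths`` gives scaffold lengths in bp.
    """

    depths: pd.DataFrame
    sample_chrom: pd.Series
    scaffold_lengths: pd.Series

    def __post_init__(self) -> None:
        if (self.depths.values < 0).any():
            raise ValueError("depths must be non-negative")
        missing = set(self.depths.columns) - set(self.sample_chrom.index)
        if missing:
            raise ValueError(f"samples without chromosome label: {missing}")
        missing = set(self.depths.index) - set(self.scaffold_lengths.index)
        if missing:
            raise ValueError(f"scaffolds without length: {missing}")

    @property
    def samples(self) -> list[str]:
        return list(self.depths.columns)

    @property
    def scaffolds(self) -> list[str]:
        return list(self.depths.index)
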