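"""Genome layout: chromosome lengths, inversion strata and window tiling.

All coordinates are 0-based half-open throughout the package; VCF
positions are converted on read/write.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
import yaml


@dataclass(frozen=True)
class Inversion:
    """An inversion interval belonging to an evolutionary stratum."""

    chromosome: str
    start: int
    end: int
    stratum: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid inversion interval [{self.start}, {self.end})"
            )


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes with lengths (bp) plus inversion strata.

    Parameters
    ----------
    chromosomes:
        Ordered ``(name, length_bp)`` pairs.
    inversions:
        Inversion intervals, each tagged with a stratum id. Stratum ids
        must be unique and intervals must lie within their chromosome.
    """

    chromosomes: tuple[tuple[str, int], ...]
    inversions: tuple[Inversion, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("layout needs at least one chromosome")
        names = [name for name, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        strata = [inv.stratum for inv in self.inversions]
        if len(set(strata)) != len(strata):
            raise ValueError("stratum ids must be unique")
        for inv in self.inversions:
            if inv.chromosome not in names:
                raise ValueError(f"inversion on unknown chromosome {inv.chromosome}")
            if inv.end > self.length(inv.chromosome):
                raise ValueError(
                    f"inversion [{inv.start}, {inv.end}) exceeds "
                    f"{inv.chromosome} length"
                )

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    def length(self, chromosome: str) -> int:
        for name, length in self.chromosomes:
            if name == chromosome:
                return length
        raise KeyError(chromosome)

    def inversions_on(self, chromosome: str) -> list[Inversion]:
        return [inv for inv in self.inversions if inv.chromosome == chromosome]

    def stratum_at(self, chromosome: str, pos: int) -> int | None:
        """Stratum id covering ``pos`` on ``chromosome``, or ``None``."""
        for inv in self.inversions_on(chromosome):
            if inv.start <= pos < inv.end:
                return inv.stratum
        return None

    # -- serialisation ---------------------------------------------------

    def to_yaml(self, path: str) -> None:
        doc = {
            "chromosomes": [
                {"name": name, "length": int(length)}
                for name, length in self.chromosomes
            ],
            "inversions": [
                {
                    "chromosome": inv.chromosome,
                    "start": int(inv.start),
                    "end": int(inv.end),
                    "stratum": int(inv.stratum),
                }
                for inv in self.inversions
            ],
        }
        with open(path, "w") as handle:
            yaml.safe_dump(doc, handle, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "GenomeLayout":
        with open(path) as handle:
            doc = yaml.safe_load(handle)
        chromosomes = tuple(
            (entry["name"], int(entry["length"])) for entry in doc["chromosomes"]
        )
        inversions = tuple(
            Inversion(
                entry["chromosome"],
                int(entry["start"]),
                int(entry["end"]),
                int(entry["stratum"]),
            )
            for entry in doc.get("inversions", [])
        )
        return cls(chromosomes, inversions)


def default_layout() -> GenomeLayout:
    """Desk-scale analogue of the four-chromosome planarian genome.

    Chromosome 1 carries more than 40% of the genome and three inversions,
    each longer than 20 Mb, one per evolutionary stratum. The proportions
    mirror the study system (333 / 120 / 100 / 90 Mb).
    """
    return GenomeLayout(
        chromosomes=(
            ("chr1", 333_000_000),
            ("chr2", 120_000_000),
            ("chr3", 100_000_000),
            ("chr4", 90_000_000),
        ),
        inversions=(
            Inversion("chr1", 30_000_000, 110_000_000, 1),
            Inversion("chr1", 130_000_000, 190_000_000, 2),
            Inversion("chr1", 210_000_000, 300_000_000, 3),
        ),
    )


def make_windows(layout: GenomeLayout, size: int) -> pd.DataFrame:
    """Tile every chromosome with half-open windows of ``size`` bp.

    The final window of each chromosome is truncated at the chromosome
    length, so the union of windows covers each chromosome exactly.

    Returns a DataFrame with columns ``chrom``, ``start``, ``end``.
    """
    if size <= 0:
        raise ValueError("window size must be positive")
    rows = []
    for name, length in layout.chromosomes:
        start = 0
        while start < length:
            rows.append((name, start, min(start + size, length)))
            start += size
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])
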