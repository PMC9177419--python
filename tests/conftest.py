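import numpy as np
import pandas as pd
import pytest

from jvscan.containers import GameteMatrix, GenotypeTable
from jvscan.layout import GenomeLayout, Inversion


@pytest.fixture
def single_chrom_layout() -> GenomeLayout:
    return GenomeLayout((("chrA", 100_000_000),))


@pytest.fixture
def small_layout() -> GenomeLayout:
    """Two small chromosomes with one inversion stratum each on chrA."""
    return GenomeLayout(
        (("chrA", 10_000_000), ("chrB", 5_000_000)),
        (
            Inversion("chrA", 1_000_000, 4_000_000, 1),
            Inversion("chrA", 5_000_000, 9_000_000, 2),
        ),
    )


def make_markers(n: int, chrom: str = "chr1", spacing: int = 1000) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.arange(n) * spacing,
            "ref": "A",
            "alt": "T",
        }
    )


def make_gametes(calls, chrom="chr1", spacing=1000, types=None) -> GameteMatrix:
    """Build a GameteMatrix from a (markers x gametes) call array."""
    calls = np.asarray(calls, dtype=np.int8)
    n_markers, n_gametes = calls.shape
    types = types or ["sperm"] * n_gametes
    return GameteMatrix(
        make_markers(n_markers, chrom, spacing),
        [f"g{i}" for i in range(n_gametes)],
        types,
        calls,
    )


def make_genotypes(codes, chrom="chr1", spacing=1000, names=None) -> GenotypeTable:
    codes = np.asarray(codes, dtype=np.int8)
    names = names or [f"ind{i}" for i in range(codes.shape[1])]
    return GenotypeTable(make_markers(codes.shape[0], chrom, spacing), names, codes)
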