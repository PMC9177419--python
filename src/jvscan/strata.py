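"""Evolutionary-strata dating from haplotype divergence.

Once recombination stops, the two haplotypes of an inversion stratum
accumulate substitutions independently, so synonymous divergence dS
between the phased J and V copies of the coding sequence, together with
the per-generation mutation rate mu, dates the stratum:

    T = dS / (2 mu)   generations

(divergence accumulates on both haplotypes). dS and dN are computed by
Nei--Gojobori (1986) counting with Jukes--Cantor correction; the raw
proportions pS and pN are reported alongside. The per-generation
mutation rate is estimated at genotype level from pedigree trios, and a
premature-stop scan tallies haplotype-specific coding degeneration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from jvscan.containers import (
    GT_HET,
    GT_HOM_ALT,
    GT_HOM_REF,
    GT_MISSING,
    GenotypeTable,
)

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_STOPS = set(standard_dna_table.stop_codons)


def _codon_str(idx: int) -> str:
    return _BASES[idx >> 4] + _BASES[(idx >> 2) & 3] + _BASES[idx & 3]


def _aa(codon: str) -> str | None:
    if codon in _STOPS:
        return None
    return standard_dna_table.forward_table[codon]


def _build_tables():
    """Per-codon synonymous site fractions and per-pair path-averaged
    synonymous/nonsynonymous difference counts."""
    syn_sites = np.zeros(64)
    is_stop = np.zeros(64, dtype=bool)
    for idx in range(64):
        codon = _codon_str(idx)
        if codon in _STOPS:
            is_stop[idx] = True
            continue
        aa = _aa(codon)
        s = 0.0
        for pos in range(3):
            for b in _BASES:
                if b == codon[pos]:
                    continue
                mut = codon[:pos] + b + codon[pos + 1:]
                # mutation to a stop codon counts as nonsynonymous
                if mut not in _STOPS and _aa(mut) == aa:
                    s += 1.0 / 3.0
        syn_sites[idx] = s

    syn_diff = np.zeros((64, 64))
    nonsyn_diff = np.zeros((64, 64))
    for i in range(64):
        if is_stop[i]:
            continue
        ci = _codon_str(i)
        for j in range(64):
            if is_stop[j] or j == i:
                continue
            cj = _codon_str(j)
            positions = [k for k in range(3) if ci[k] != cj[k]]
            paths = []
            for order in permutations(positions):
                cur = ci
                steps = []
                blocked = False
                for pos in order:
                    nxt = cur[:pos] + cj[pos] + cur[pos + 1:]
                    if nxt in _STOPS:
                        blocked = True
                    steps.append((cur, nxt))
                    cur = nxt
                paths.append((blocked, steps))
            usable = [steps for blocked, steps in paths if not blocked]
            if not usable:  # every path crosses a stop; use them all
                usable = [steps for _, steps in paths]
            s = n = 0.0
            for steps in usable:
                for cur, nxt in steps:
                    if (
                        nxt not in _STOPS
                        and cur not in _STOPS
                        and _aa(cur) == _aa(nxt)
                    ):
                        s += 1
                    else:
                        n += 1
            syn_diff[i, j] = s / len(usable)
            nonsyn_diff[i, j] = n / len(usable)
    return syn_sites, syn_diff, nonsyn_diff, is_stop


_SYN_SITES, _SYN_DIFF, _NONSYN_DIFF, _IS_STOP = _build_tables()


def _codon_indices(seq: str, name: str) -> np.ndarray:
    if len(seq) % 3 != 0:
        raise ValueError(f"{name}: length not divisible by 3")
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    lut = np.full(256, -1, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        lut[ord(b)] = i
    codes = lut[arr]
    if (codes < 0).any():
        bad = seq[int(np.argmax(lut[arr] < 0))]
        raise ValueError(f"{name}: gap or ambiguous base {bad!r}")
    codes = codes.reshape(-1, 3)
    return codes[:, 0] * 16 + codes[:, 1] * 4 + codes[:, 2]


@dataclass
class DivergenceResult:
    """Nei--Gojobori divergence between two aligned coding sequences."""

    p_syn: float
    p_nonsyn: float
    d_syn: float
    d_nonsyn: float
    syn_sites: float
    nonsyn_sites: float
    n_codons: int
    saturated: bool = False


def nei_gojobori(cds1: str, cds2: str) -> DivergenceResult:
    """Synonymous and nonsynonymous divergence (Nei--Gojobori 1986).

    Sequences must be equal-length, gapless, in frame. Synonymous and
    nonsynonymous site counts are averaged over the two sequences;
    differences in multi-substitution codons are averaged over all
    minimal mutational paths (paths through stop codons are excluded
    when any stop-free path exists). pS and pN are corrected to dS and
    dN with the Jukes--Cantor formula d = -3/4 ln(1 - 4/3 p); p >= 0.75
    is saturated and yields NaN with the ``saturated`` flag set. Codon
    pairs where either codon is a stop are skipped.
    """
    if len(cds1) != len(cds2):
        raise ValueError("sequences must be the same length")
    c1 = _codon_indices(cds1, "cds1")
    c2 = _codon_indices(cds2, "cds2")
    ok = ~(_IS_STOP[c1] | _IS_STOP[c2])
    c1, c2 = c1[ok], c2[ok]
    n_codons = len(c1)
    if n_codons == 0:
        raise ValueError("no comparable codons")
    syn_sites = float((_SYN_SITES[c1].sum() + _SYN_SITES[c2].sum()) / 2.0)
    nonsyn_sites = 3.0 * n_codons - syn_sites
    sd = float(_SYN_DIFF[c1, c2].sum())
    nd = float(_NONSYN_DIFF[c1, c2].sum())
    p_syn = sd / syn_sites if syn_sites > 0 else 0.0
    p_nonsyn = nd / nonsyn_sites if nonsyn_sites > 0 else 0.0
    d_syn, sat_s = _jukes_cantor(p_syn)
    d_nonsyn, sat_n = _jukes_cantor(p_nonsyn)
    return DivergenceResult(
        p_syn=p_syn,
        p_nonsyn=p_nonsyn,
        d_syn=d_syn,
        d_nonsyn=d_nonsyn,
        syn_sites=syn_sites,
        nonsyn_sites=nonsyn_sites,
        n_codons=n_codons,
        saturated=sat_s or sat_n,
    )


def _jukes_cantor(p: float) -> tuple[float, bool]:
    if p >= 0.75:
        return float("nan"), True
    return float(-0.75 * np.log1p(-4.0 * p / 3.0)), False


def date_stratum(d_syn: float, mu: float) -> float:
    """Age in generations: T = dS / (2 mu).

    The factor 2 reflects substitutions accumulating independently on
    both haplotypes since recombination ceased.
    """
    if mu <= 0:
        raise ValueError("mutation rate must be positive")
    if d_syn < 0:
        raise ValueError("dS must be non-negative")
    return d_syn / (2.0 * mu)


def estimate_mutation_rate(
    parents: GenotypeTable,
    offspring: GenotypeTable,
    callable_sites: int,
) -> tuple[float, int]:
    """Per-generation de novo mutation rate from pedigree genotypes.

    A candidate is any offspring allele absent from both parents at a
    genotyped site. With ``callable_sites`` callable positions and ``k``
    offspring, mu = candidates / (2 * callable_sites * k) per nucleotide
    per generation. Genotype-level only; read-level filters (depth,
    strand bias) are out of scope.

    Returns ``(mu, candidate_count)``.
    """
    if callable_sites <= 0:
        raise ValueError("callable site count must be positive")
    if parents.n_individuals != 2:
        raise ValueError("exactly two parents required")
    key = ["chrom", "pos"]
    pidx = parents.markers.reset_index().merge(offspring.markers[key], on=key)
    if len(pidx) < offspring.n_markers:
        raise ValueError("parents not genotyped at all offspring markers")
    pcodes = parents.codes[pidx["index"].to_numpy()]

    def alleles(codes):
        has_ref = (codes == GT_HOM_REF) | (codes == GT_HET)
        has_alt = (codes == GT_HOM_ALT) | (codes == GT_HET)
        return has_ref, has_alt

    p_ref, p_alt = alleles(pcodes)
    parents_have_ref = p_ref.any(axis=1)
    parents_have_alt = p_alt.any(axis=1)
    o_ref, o_alt = alleles(offspring.codes)
    informative = offspring.codes != GT_MISSING
    novel = (
        (o_ref & ~parents_have_ref[:, None])
        | (o_alt & ~parents_have_alt[:, None])
    ) & informative
    candidates = int(novel.sum())
    mu = candidates / (2.0 * callable_sites * offspring.n_individuals)
    if candidates == 0:
        warnings.warn(
            "no de novo candidates: the estimate is 0 and only an upper "
            "bound on the rate is meaningful",
            stacklevel=2,
        )
    return mu, candidates


# -- premature stops ----------------------------------------------------


def premature_stop_scan(cds: pd.DataFrame) -> pd.DataFrame:
    """Count coding sequences with premature in-frame stop codons.

    ``cds`` needs columns ``gene``, ``haplotype`` (J or V), ``chrom`` and
    ``seq``. A CDS counts once if any in-frame TAA/TAG/TGA occurs before
    the final codon; sequences with internal N are skipped with a
    warning. Counts are grouped by chromosome and haplotype.
    """
    rows = []
    for rec in cds.itertuples(index=False):
        seq = rec.seq.upper()
        if "N" in seq:
            warnings.warn(f"skipping {rec.gene} ({rec.haplotype}): contains N",
                          stacklevel=2)
            continue
        if len(seq) % 3 != 0:
            raise ValueError(f"{rec.gene}: length not divisible by 3")
        codons = [seq[i:i + 3] for i in range(0, len(seq) - 3, 3)]
        premature = any(c in _STOPS for c in codons)
        rows.append(
            {
                "chrom": rec.chrom,
                "haplotype": rec.haplotype,
                "gene": rec.gene,
                "premature_stop": premature,
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        return pd.DataFrame(columns=["chrom", "haplotype", "n_cds", "n_premature"])
    out = (
        table.groupby(["chrom", "haplotype"], sort=False)
        .agg(n_cds=("gene", "size"), n_premature=("premature_stop", "sum"))
        .reset_index()
    )
    out["n_premature"] = out["n_premature"].astype(int)
    return out


def read_cds_fasta(path: str) -> pd.DataFrame:
    """Read phased CDS records from FASTA.

    Headers follow ``gene|haplotype|chromosome`` (e.g.
    ``>glp-1|J|chr1``).
    """
    from Bio import SeqIO

    rows = []
    for record in SeqIO.parse(path, "fasta"):
        parts = record.id.split("|")
        if len(parts) != 3:
            raise ValueError(
                f"header {record.id!r} must be gene|haplotype|chromosome"
            )
        gene, hap, chrom = parts
        rows.append(
            {"gene": gene, "haplotype": hap, "chrom": chrom, "seq": str(record.seq)}
        )
    return pd.DataFrame(rows)


@dataclass
class StratumEstimate:
    """Dated divergence of one inversion stratum."""

    stratum: int
    d_syn: float
    d_nonsyn: float
    mu: float
    age_generations: float


def date_strata(
    stratum_cds: dict,
    mu: float,
) -> pd.DataFrame:
    """Date each stratum from its phased J/V coding sequence.

    ``stratum_cds`` maps stratum id -> iterable of ``(cds_j, cds_v)``
    pairs; per stratum, synonymous differences and sites are pooled over
    gene pairs before the Jukes--Cantor correction, then T = dS/(2 mu).
    """
    rows = []
    for stratum, pairs in stratum_cds.items():
        sd = ss = nd = ns = 0.0
        for cds_j, cds_v in pairs:
            res = nei_gojobori(cds_j, cds_v)
            sd += res.p_syn * res.syn_sites
            ss += res.syn_sites
            nd += res.p_nonsyn * res.nonsyn_sites
            ns += res.nonsyn_sites
        p_syn = sd / ss if ss > 0 else 0.0
        p_nonsyn = nd / ns if ns > 0 else 0.0
        d_syn, _ = _jukes_cantor(p_syn)
        d_nonsyn, _ = _jukes_cantor(p_nonsyn)
        rows.append(
            {
                "stratum": stratum,
                "p_syn": p_syn,
                "d_syn": d_syn,
                "d_nonsyn": d_nonsyn,
                "mu": mu,
                "age_generations": date_stratum(d_syn, mu),
            }
        )
    return pd.DataFrame(rows)
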