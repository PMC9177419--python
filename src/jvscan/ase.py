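"""Haplotype-biased expression testing.

Per gene, J- and V-allele read counts are aggregated over all exonic
biallelic variants and tested for deviation from equal expression with
an exact two-sided binomial test; p-values are Bonferroni-corrected over
the genes tested in the run (corrected values above 1 are capped at 1).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats


def aggregate_counts(
    variants: pd.DataFrame,
    gene_map: dict | None = None,
) -> pd.DataFrame:
    """Sum per-variant J/V counts into per-gene counts.

    ``variants`` needs columns ``gene``, ``variant``, ``j_count``,
    ``v_count`` (and optionally ``tissue``). ``gene_map`` optionally maps
    variant id -> gene id; a variant mapped to a different gene than its
    own row claims is a conflict and raises. Genes whose total count is
    zero are excluded with a warning.
    """
    required = {"gene", "variant", "j_count", "v_count"}
    missing = required - set(variants.columns)
    if missing:
        raise ValueError(f"variant table lacks columns {sorted(missing)}")
    if (variants[["j_count", "v_count"]] < 0).any().any():
        raise ValueError("allele counts must be non-negative")
    if gene_map is not None:
        claimed = variants["variant"].map(gene_map)
        conflict = claimed.notna() & (claimed != variants["gene"])
        if conflict.any():
            bad = variants.loc[conflict, ["variant", "gene"]]
            raise ValueError(
                "variants mapped to conflicting genes: "
                + ", ".join(
                    f"{v} ({g} vs {gene_map[v]})"
                    for v, g in zip(bad["variant"], bad["gene"])
                )
            )
    keys = ["gene"] + (["tissue"] if "tissue" in variants.columns else [])
    genes = (
        variants.groupby(keys, sort=False)[["j_count", "v_count"]]
        .sum()
        .reset_index()
    )
    total = genes["j_count"] + genes["v_count"]
    if (total == 0).any():
        zero = genes.loc[total == 0, "gene"].tolist()
        warnings.warn(f"excluding zero-count genes: {zero}", stacklevel=2)
        genes = genes[total > 0].reset_index(drop=True)
    return genes


def binomial_bias_test(
    genes: pd.DataFrame,
    method: str = "minlike",
) -> pd.DataFrame:
    """Exact two-sided binomial p-value per gene under a 0.5 null.

    ``method="minlike"`` (default) sums the probabilities of all outcomes
    no more likely than the observed count, the standard exact two-sided
    convention; ``method="double"`` doubles the smaller one-sided tail
    (capped at 1). Genes with zero total count are skipped with a warning.
    """
    if method not in {"minlike", "double"}:
        raise ValueError(f"unknown method {method!r}")
    out = genes.copy()
    total = out["j_count"] + out["v_count"]
    if (total == 0).any():
        warnings.warn("skipping zero-count genes", stacklevel=2)
        out = out[total > 0].reset_index(drop=True)
    pvals = []
    for j, v in zip(out["j_count"], out["v_count"]):
        n = int(j + v)
        if method == "minlike":
            p = stats.binomtest(int(j), n, 0.5, alternative="two-sided").pvalue
        else:
            tail = stats.binom.cdf(min(j, v), n, 0.5)
            p = min(1.0, 2.0 * tail)
        pvals.append(float(p))
    out["p_raw"] = pvals
    return out


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni correction: corrected = min(1, p * m).

    ``m`` defaults to the number of p-values supplied (the genes tested
    in the run).
    """
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = len(p)
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, p * m)


def analyze_gene_bias(
    variants: pd.DataFrame,
    method: str = "minlike",
    m: int | None = None,
) -> pd.DataFrame:
    """Aggregate, test and correct in one step.

    Returns per gene: counts, raw two-sided binomial p and the
    Bonferroni-corrected p (correction per tissue when a tissue column is
    present, mirroring one experiment per tissue).
    """
    genes = aggregate_counts(variants)
    tested = binomial_bias_test(genes, method=method)
    if "tissue" in tested.columns and m is None:
        tested["p_bonferroni"] = tested.groupby("tissue", sort=False)[
            "p_raw"
        ].transform(lambda s: bonferroni(s.to_numpy()))
    else:
        tested["p_bonferroni"] = bonferroni(tested["p_raw"].to_numpy(), m=m)
    return tested
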