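"""Scaffold-to-chromosome assignment from single-chromosome sequencing depth.

Individually laser-captured mitotic chromosomes are amplified and
sequenced; a scaffold belongs to a chromosome when it is covered
reproducibly (in at least ``min_samples`` samples of that chromosome) and
specifically (its depth in those samples dwarfs its depth in samples of
the other chromosomes). The resulting per-scaffold codes follow the
published coding: 1--4 for the four chromosomes, 0 for unassignable, 5
for scaffolds claimed by two or more chromosomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from jvscan.containers import CoverageMatrix

CODE_UNASSIGNED = 0
CODE_AMBIGUOUS = 5


@dataclass
class AssignmentResult:
    """Per-scaffold chromosome codes plus support statistics.

    ``table`` has one row per scaffold: ``code`` (1--4, 0 or 5),
    ``chromosome`` (name, or empty for 0/5), per-chromosome enrichment
    scores and supporting-sample counts. ``chrom_codes`` maps chromosome
    name -> numeric code.
    """

    table: pd.DataFrame
    chrom_codes: dict


def normalize_coverage(matrix: CoverageMatrix) -> CoverageMatrix:
    """Scale each sample to a length-weighted mean depth of 1.

    The weighting keeps short scaffolds from dominating the scale factor.
    All-zero samples are excluded with a warning.
    """
    lengths = matrix.scaffold_lengths.loc[matrix.depths.index].to_numpy(float)
    weights = lengths / lengths.sum()
    keep = []
    scaled = {}
    for sample in matrix.samples:
        depth = matrix.depths[sample].to_numpy(float)
        mean = float(np.sum(depth * weights))
        if mean == 0:
            warnings.warn(f"sample {sample} has zero depth; excluded", stacklevel=2)
            continue
        keep.append(sample)
        scaled[sample] = depth / mean
    if not keep:
        raise ValueError("no sample has non-zero depth")
    depths = pd.DataFrame(scaled, index=matrix.depths.index)
    return CoverageMatrix(
        depths, matrix.sample_chrom.loc[keep], matrix.scaffold_lengths
    )


def assign_scaffolds(
    matrix: CoverageMatrix,
    min_samples: int = 2,
    enrichment: float = 5.0,
    detect_floor: float = 0.2,
) -> AssignmentResult:
    """Assign each scaffold to a chromosome, or to code 0 / 5.

    A chromosome ``c`` claims a scaffold iff the scaffold's normalized
    depth reaches ``detect_floor`` in at least ``min_samples`` samples of
    ``c`` (reproducibility) and the median depth across ``c``'s samples
    is at least ``enrichment`` times the median across all samples of the
    other chromosomes (specificity). Exactly one claiming chromosome
    gives that chromosome's code; none gives 0; two or more give 5.
    """
    chroms = sorted(matrix.sample_chrom.unique())
    chrom_codes = {c: i + 1 for i, c in enumerate(chroms)}
    sample_groups = {
        c: [s for s in matrix.samples if matrix.sample_chrom[s] == c]
        for c in chroms
    }
    for c, group in sample_groups.items():
        if len(group) < min_samples:
            raise ValueError(
                f"chromosome {c} has {len(group)} samples; "
                f"min_samples={min_samples} required"
            )
    depth = matrix.depths
    rows = []
    for scaffold in matrix.scaffolds:
        d = depth.loc[scaffold]
        passing = []
        support = {}
        for c in chroms:
            own = d[sample_groups[c]].to_numpy(float)
            other_samples = [s for s in matrix.samples if matrix.sample_chrom[s] != c]
            other = d[other_samples].to_numpy(float)
            n_detect = int((own >= detect_floor).sum())
            med_own = float(np.median(own))
            med_other = float(np.median(other)) if len(other) else 0.0
            score = med_own / med_other if med_other > 0 else np.inf
            reproducible = n_detect >= min_samples
            specific = med_own >= enrichment * med_other
            support[f"enrichment_{c}"] = score
            support[f"n_detect_{c}"] = n_detect
            if reproducible and specific:
                passing.append(c)
        if len(passing) == 1:
            code, name = chrom_codes[passing[0]], passing[0]
        elif len(passing) == 0:
            code, name = CODE_UNASSIGNED, ""
        else:
            code, name = CODE_AMBIGUOUS, ""
        rows.append({"scaffold": scaffold, "code": code, "chromosome": name, **support})
    return AssignmentResult(pd.DataFrame(rows), chrom_codes)


def reconcile_assignments(
    chrseq: AssignmentResult,
    contact_map: dict,
) -> tuple[dict, pd.DataFrame]:
    """Merge depth-based codes with a contact-based scaffold->chromosome map.

    Where a confident depth assignment (code 1--4) disagrees with the
    contact map, the contact map wins and the conflict is recorded with
    both calls. Depth codes 0/5 carry no claim, so contact assignments
    fill them in silently. Scaffolds assigned by neither method are
    omitted with a warning.
    """
    merged: dict = {}
    conflicts = []
    chrseq_call = dict(
        zip(chrseq.table["scaffold"], chrseq.table["chromosome"])
    )
    all_scaffolds = list(
        dict.fromkeys(list(chrseq_call) + list(contact_map))
    )
    for scaffold in all_scaffolds:
        depth_chrom = chrseq_call.get(scaffold, "")
        contact_chrom = contact_map.get(scaffold)
        if contact_chrom is not None:
            merged[scaffold] = contact_chrom
            if depth_chrom and depth_chrom != contact_chrom:
                conflicts.append(
                    {
                        "scaffold": scaffold,
                        "chrseq": depth_chrom,
                        "contact": contact_chrom,
                        "resolved": contact_chrom,
                    }
                )
        elif depth_chrom:
            merged[scaffold] = depth_chrom
        else:
            warnings.warn(
                f"scaffold {scaffold} assigned by neither method; omitted",
                stacklevel=2,
            )
    return merged, pd.DataFrame(
        conflicts, columns=["scaffold", "chrseq", "contact", "resolved"]
    )
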