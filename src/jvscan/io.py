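"""Readers and writers for the genotype, gamete, coverage and event formats.

Formats are deliberately plain: a TSV genotype dialect (``0/0``, ``0/1``,
``1/1``, ``./.``), a GT-only subset of VCF v4.2, BED6 for events and
windows, and TSV matrices for coverage. Internally everything is 0-based
half-open; VCF is converted from/to its 1-based convention on the way
through.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from jvscan.containers import (
    CALL_ALT,
    CALL_HET,
    CALL_MISSING,
    CALL_REF,
    GT_HET,
    GT_HOM_ALT,
    GT_HOM_REF,
    GT_MISSING,
    CoverageMatrix,
    CrossoverCallSet,
    GameteMatrix,
    GenotypeTable,
)

_GT_FROM_TEXT = {
    "0/0": GT_HOM_REF,
    "0|0": GT_HOM_REF,
    "0/1": GT_HET,
    "1/0": GT_HET,
    "0|1": GT_HET,
    "1|0": GT_HET,
    "1/1": GT_HOM_ALT,
    "1|1": GT_HOM_ALT,
    "./.": GT_MISSING,
    ".|.": GT_MISSING,
    ".": GT_MISSING,
}

_GT_TO_TEXT = {
    GT_HOM_REF: "0/0",
    GT_HET: "0/1",
    GT_HOM_ALT: "1/1",
    GT_MISSING: "./.",
}

_CALL_FROM_TEXT = {
    "0": CALL_REF,
    "1": CALL_ALT,
    "0/1": CALL_HET,
    "1/0": CALL_HET,
    ".": CALL_MISSING,
}

_CALL_TO_TEXT = {
    CALL_REF: "0",
    CALL_ALT: "1",
    CALL_HET: "0/1",
    CALL_MISSING: ".",
}


class ParseError(ValueError):
    """Malformed input line; the message names the offending line number."""


def read_genotypes(path: str, format: str = "auto") -> GenotypeTable:
    """Read a diploid genotype table from TSV or VCF.

    ``format`` is ``"tsv"``, ``"vcf"`` or ``"auto"`` (by extension).
    Unphased ``1/0`` is treated identically to ``0/1``; multi-allelic
    records are rejected.
    """
    if format == "auto":
        format = "vcf" if path.endswith((".vcf", ".vcf.gz")) else "tsv"
    if format == "tsv":
        return _read_genotypes_tsv(path)
    if format == "vcf":
        return _read_genotypes_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_genotypes_tsv(path: str) -> GenotypeTable:
    with open(path) as handle:
        header = handle.readline()
        if not header.strip():
            raise ParseError(f"{path}:1: empty header")
        cols = header.rstrip("\n").split("\t")
        if cols[:4] != ["chrom", "pos", "ref", "alt"]:
            raise ParseError(
                f"{path}:1: header must start with chrom/pos/ref/alt"
            )
        individuals = cols[4:]
        rows, codes = [], []
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 4 + len(individuals):
                raise ParseError(
                    f"{path}:{lineno}: expected {4 + len(individuals)} "
                    f"fields, found {len(fields)}"
                )
            chrom, pos, ref, alt = fields[:4]
            if "," in alt:
                raise ParseError(f"{path}:{lineno}: multi-allelic record")
            try:
                pos_i = int(pos)
            except ValueError as err:
                raise ParseError(f"{path}:{lineno}: bad position {pos!r}") from err
            try:
                row_codes = [_GT_FROM_TEXT[g] for g in fields[4:]]
            except KeyError as err:
                raise ParseError(
                    f"{path}:{lineno}: bad genotype {err.args[0]!r}"
                ) from err
            rows.append((chrom, pos_i, ref, alt))
            codes.append(row_codes)
    markers = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    arr = (
        np.asarray(codes, dtype=np.int8)
        if codes
        else np.empty((0, len(individuals)), dtype=np.int8)
    )
    # canonical sort happens in the container; keep codes aligned
    order = _marker_sort_order(markers)
    return GenotypeTable(markers.iloc[order], individuals, arr[order])


def _marker_sort_order(markers: pd.DataFrame) -> np.ndarray:
    chrom_rank = {c: i for i, c in enumerate(markers["chrom"].drop_duplicates())}
    key = markers["chrom"].map(chrom_rank).to_numpy()
    return np.lexsort((markers["pos"].to_numpy(), key))


def _read_genotypes_vcf(path: str) -> GenotypeTable:
    from cyvcf2 import VCF

    vcf = VCF(path)
    individuals = list(vcf.samples)
    rows, codes = [], []
    for record in vcf:
        if len(record.ALT) != 1:
            raise ParseError(
                f"{path}: multi-allelic record at {record.CHROM}:{record.POS}"
            )
        # VCF POS is 1-based; internal coordinates are 0-based
        rows.append((record.CHROM, record.POS - 1, record.REF, record.ALT[0]))
        row = []
        for geno in record.genotypes:
            a, b = geno[0], geno[1]
            if a < 0 or b < 0:
                row.append(GT_MISSING)
            elif a == 0 and b == 0:
                row.append(GT_HOM_REF)
            elif a == 1 and b == 1:
                row.append(GT_HOM_ALT)
            else:
                row.append(GT_HET)
        codes.append(row)
    markers = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    arr = (
        np.asarray(codes, dtype=np.int8)
        if codes
        else np.empty((0, len(individuals)), dtype=np.int8)
    )
    order = _marker_sort_order(markers)
    return GenotypeTable(markers.iloc[order], individuals, arr[order])


def write_genotypes_tsv(table: GenotypeTable, path: str) -> None:
    with open(path, "w") as handle:
        handle.write("\t".join(["chrom", "pos", "ref", "alt"] + table.individuals))
        handle.write("\n")
        markers = table.markers
        for i in range(table.n_markers):
            row = markers.iloc[i]
            genos = [_GT_TO_TEXT[int(c)] for c in table.codes[i]]
            handle.write(
                "\t".join(
                    [row["chrom"], str(int(row["pos"])), row["ref"], row["alt"]]
                    + genos
                )
            )
            handle.write("\n")


def write_genotypes_vcf(table: GenotypeTable, path: str) -> None:
    """Write a minimal GT-only VCF v4.2 (1-based positions)."""
    with open(path, "w") as handle:
        handle.write("##fileformat=VCFv4.2\n")
        handle.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        handle.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.individuals)
            + "\n"
        )
        markers = table.markers
        for i in range(table.n_markers):
            row = markers.iloc[i]
            genos = [_GT_TO_TEXT[int(c)] for c in table.codes[i]]
            handle.write(
                "\t".join(
                    [
                        row["chrom"],
                        str(int(row["pos"]) + 1),
                        ".",
                        row["ref"],
                        row["alt"],
                        ".",
                        ".",
                        ".",
                        "GT",
                    ]
                    + genos
                )
            )
            handle.write("\n")


def merge_replicates(
    table: GenotypeTable,
    groups: dict[str, str],
    how: str = "consensus",
) -> GenotypeTable:
    """Merge replicate samples of the same segregant into one column.

    ``groups`` maps each individual name to its segregant id. ``how`` is
    ``"consensus"`` (majority non-missing genotype per marker; ties become
    missing) or ``"first"`` (first replicate's call wins, missing filled
    from later replicates).
    """
    if how not in {"consensus", "first"}:
        raise ValueError("how must be 'consensus' or 'first'")
    seen: dict[str, list[int]] = {}
    for idx, name in enumerate(table.individuals):
        seg = groups.get(name, name)
        seen.setdefault(seg, []).append(idx)
    segregants = list(seen)
    merged = np.full((table.n_markers, len(segregants)), GT_MISSING, dtype=np.int8)
    for j, seg in enumerate(segregants):
        cols = table.codes[:, seen[seg]]
        if how == "first":
            for col in cols.T:
                fill = merged[:, j] == GT_MISSING
                merged[fill, j] = col[fill]
        else:
            counts = np.stack(
                [(cols == code).sum(axis=1) for code in (0, 1, 2)], axis=1
            )
            best = counts.argmax(axis=1)
            top = counts.max(axis=1)
            runner = np.sort(counts, axis=1)[:, -2]
            ok = (top > 0) & (top > runner)
            merged[ok, j] = best[ok]
    return GenotypeTable(table.markers.copy(), segregants, merged)


# -- gamete matrices ----------------------------------------------------


def read_gametes_tsv(path: str, metadata_path: str) -> GameteMatrix:
    """Read a haploid gamete call matrix plus its gamete-type sidecar.

    The matrix has columns chrom/pos/ref/alt then one column per gamete
    with calls in {``0``, ``1``, ``0/1``, ``.``}; the metadata TSV has
    columns ``gamete`` and ``type`` (sperm or oocyte).
    """
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    types = dict(zip(meta["gamete"], meta["type"]))
    with open(path) as handle:
        cols = handle.readline().rstrip("\n").split("\t")
        if cols[:4] != ["chrom", "pos", "ref", "alt"]:
            raise ParseError(f"{path}:1: header must start with chrom/pos/ref/alt")
        gamete_ids = cols[4:]
        rows, calls = [], []
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 4 + len(gamete_ids):
                raise ParseError(f"{path}:{lineno}: wrong field count")
            try:
                row_calls = [_CALL_FROM_TEXT[c] for c in fields[4:]]
            except KeyError as err:
                raise ParseError(
                    f"{path}:{lineno}: bad call {err.args[0]!r}"
                ) from err
            rows.append((fields[0], int(fields[1]), fields[2], fields[3]))
            calls.append(row_calls)
    markers = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    arr = (
        np.asarray(calls, dtype=np.int8)
        if calls
        else np.empty((0, len(gamete_ids)), dtype=np.int8)
    )
    order = _marker_sort_order(markers)
    try:
        gamete_types = [types[g] for g in gamete_ids]
    except KeyError as err:
        raise ParseError(f"{metadata_path}: no type for gamete {err.args[0]!r}")
    return GameteMatrix(markers.iloc[order], gamete_ids, gamete_types, arr[order])


def write_gametes_tsv(gametes: GameteMatrix, path: str, metadata_path: str) -> None:
    with open(path, "w") as handle:
        handle.write(
            "\t".join(["chrom", "pos", "ref", "alt"] + gametes.gamete_ids) + "\n"
        )
        for i in range(gametes.n_markers):
            row = gametes.markers.iloc[i]
            txt = [_CALL_TO_TEXT[int(c)] for c in gametes.calls[i]]
            handle.write(
                "\t".join(
                    [row["chrom"], str(int(row["pos"])), row["ref"], row["alt"]]
                    + txt
                )
                + "\n"
            )
    pd.DataFrame(
        {"gamete": gametes.gamete_ids, "type": gametes.gamete_types}
    ).to_csv(metadata_path, sep="\t", index=False)


# -- events and windows -------------------------------------------------


def write_events_bed(events: CrossoverCallSet, path: str) -> None:
    """Write events as BED6: name = ``<gamete>:<kind>``, score 0, strand '.'."""
    with open(path, "w") as handle:
        for row in events.events.itertuples(index=False):
            handle.write(
                f"{row.chrom}\t{int(row.start)}\t{int(row.end)}\t"
                f"{row.gamete}:{row.kind}\t0\t.\n"
            )


def write_windows_bed(windows: pd.DataFrame, path: str, value: str | None = None) -> None:
    with open(path, "w") as handle:
        for row in windows.itertuples(index=False):
            name = str(getattr(row, value)) if value else "."
            handle.write(f"{row.chrom}\t{int(row.start)}\t{int(row.end)}\t{name}\n")


# -- coverage matrices --------------------------------------------------


def read_coverage_tsv(path: str, metadata_path: str) -> CoverageMatrix:
    """Read a scaffold x sample depth matrix and its sample metadata.

    The matrix TSV has columns ``scaffold``, ``length`` then one column
    per sample; the metadata TSV has columns ``sample`` and ``chromosome``.
    """
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "scaffold" or df.columns[1] != "length":
        raise ParseError(f"{path}: first columns must be scaffold, length")
    df = df.set_index("scaffold")
    lengths = df["length"]
    depths = df.drop(columns="length").astype(float)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str).set_index("sample")
    return CoverageMatrix(depths, meta["chromosome"], lengths)


def write_coverage_tsv(matrix: CoverageMatrix, path: str, metadata_path: str) -> None:
    out = matrix.depths.copy()
    out.insert(0, "length", matrix.scaffold_lengths.loc[out.index])
    out.index.name = "scaffold"
    out.to_csv(path, sep="\t")
    matrix.sample_chrom.rename("chromosome").rename_axis("sample").to_csv(
        metadata_path, sep="\t"
    )


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
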