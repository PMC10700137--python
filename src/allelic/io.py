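"""On-disk dialects: long/wide count TSVs, BED, CpG, contact and truth tables.

All tables are plain TSV with headers; intervals are 0-based half-open
(BED convention) and the TSS of a minus-strand interval is ``end - 1``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .epigenome import GenomicInterval
from .tables import AlleleCountTable

LONG_COLUMNS = [
    "gene_id",
    "sample_id",
    "clone",
    "condition",
    "replicate",
    "allele",
    "count",
]


def write_counts(table: AlleleCountTable, path) -> None:
    """Write the long-format counts dialect."""
    parts = []
    for allele in ("a1", "a2", "total"):
        long = (
            table.counts[allele]
            .rename_axis("gene_id")
            .reset_index()
            .melt(id_vars="gene_id", var_name="sample_id", value_name="count")
        )
        long["allele"] = allele
        parts.append(long)
    df = pd.concat(parts, ignore_index=True)
    meta = table.samples[["clone", "condition", "replicate"]]
    df = df.join(meta, on="sample_id")
    df[LONG_COLUMNS].to_csv(path, sep="\t", index=False)


def write_counts_wide(table: AlleleCountTable, prefix) -> dict[str, Path]:
    """Write three wide matrices (total/a1/a2) plus a metadata TSV."""
    prefix = Path(prefix)
    paths = {}
    for allele in ("total", "a1", "a2"):
        p = prefix.with_name(prefix.name + f".{allele}.tsv")
        table.counts[allele].rename_axis("gene_id").to_csv(p, sep="\t")
        paths[allele] = p
    meta_path = prefix.with_name(prefix.name + ".samples.tsv")
    table.samples.rename_axis("sample_id").to_csv(meta_path, sep="\t")
    paths["samples"] = meta_path
    return paths


def read_counts(path) -> AlleleCountTable:
    """Read the long-format counts dialect (auto-detected by header)."""
    df = pd.read_csv(path, sep="\t", dtype={"count": object})
    missing = set(LONG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(
            f"{path}: not a long-format counts file (missing {sorted(missing)})"
        )
    bad_allele = ~df["allele"].isin(["a1", "a2", "total"])
    if bad_allele.any():
        line = int(np.flatnonzero(bad_allele)[0]) + 2  # 1-based incl. header
        raise ValueError(
            f"{path}:{line}: unknown allele label {df['allele'][bad_allele].iloc[0]!r}"
        )
    counts_num = pd.to_numeric(df["count"], errors="coerce")
    nonint = counts_num.isna() | (counts_num != counts_num.round())
    if nonint.any():
        line = int(np.flatnonzero(nonint)[0]) + 2
        raise ValueError(f"{path}:{line}: non-integer count {df['count'].iloc[line - 2]!r}")
    df["count"] = counts_num.astype(np.int64)
    dup = df.duplicated(subset=["gene_id", "sample_id", "allele"])
    if dup.any():
        line = int(np.flatnonzero(dup)[0]) + 2
        raise ValueError(f"{path}:{line}: duplicate (gene, sample, allele) row")

    samples = (
        df[["sample_id", "clone", "condition", "replicate"]]
        .drop_duplicates("sample_id")
        .set_index("sample_id")
    )
    counts = {}
    for allele in ("a1", "a2", "total"):
        sub = df[df["allele"] == allele]
        counts[allele] = (
            sub.pivot(index="gene_id", columns="sample_id", values="count")
            .loc[:, samples.index]
            .fillna(0)
            .astype(np.int64)
        )
    genes = counts["total"].index
    counts = {k: v.reindex(genes).fillna(0).astype(np.int64) for k, v in counts.items()}
    return AlleleCountTable(counts, samples)


def read_counts_wide(total_path, a1_path, a2_path, samples_path) -> AlleleCountTable:
    """Read the wide dialect: three matrices plus sample metadata."""
    counts = {}
    for allele, p in (("total", total_path), ("a1", a1_path), ("a2", a2_path)):
        counts[allele] = pd.read_csv(p, sep="\t", index_col="gene_id")
    samples = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
    genes = counts["total"].index
    cols = counts["total"].columns
    counts = {k: v.loc[genes, cols] for k, v in counts.items()}
    return AlleleCountTable(counts, samples)


def read_bed(path) -> list[GenomicInterval]:
    """Read a BED3+/BED6 file into sorted intervals (0-based half-open)."""
    intervals = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            name = fields[3] if len(fields) > 3 else "."
            try:
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 else "+"
            intervals.append(GenomicInterval(fields[0], start, end, name, score, strand))
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


def write_bed(intervals, path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score}\t{iv.strand}\n"
            )


def write_contacts(matrix: np.ndarray, path, bin_size: int = 10_000) -> None:
    """Upper-triangle contact TSV plus a JSON sidecar stating the bin size."""
    n = matrix.shape[0]
    iu = np.triu_indices(n)
    pd.DataFrame(
        {"bin_i": iu[0], "bin_j": iu[1], "value": matrix[iu]}
    ).to_csv(path, sep="\t", index=False)
    Path(str(path) + ".json").write_text(
        json.dumps({"bin_size": bin_size, "n_bins": n}) + "\n"
    )


def read_contacts(path) -> tuple[np.ndarray, int]:
    df = pd.read_csv(path, sep="\t")
    meta = json.loads(Path(str(path) + ".json").read_text())
    n = int(meta["n_bins"])
    mat = np.zeros((n, n))
    mat[df["bin_i"], df["bin_j"]] = df["value"]
    mat[df["bin_j"], df["bin_i"]] = df["value"]
    return mat, int(meta["bin_size"])


def write_cpg_table(table: pd.DataFrame, path) -> None:
    cols = [
        c
        for c in ("chrom", "pos", "gene_id", "allele", "condition",
                  "count_methylated", "count_unmethylated")
        if c in table.columns
    ]
    table[cols].to_csv(path, sep="\t", index=False)


def read_cpg_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
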