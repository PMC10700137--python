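"""Allelic methylation, differential methylation, region classes,
TF-binding/methylation anticorrelation and aggregate peak-pair contacts.

The differential methylation caller is a deliberately simple, exact and
oracle-testable replacement for smoothed-dispersion testers: per CpG a
two-sided Fisher exact test on the pooled methylated/unmethylated 2x2 table
between conditions, Benjamini-Hochberg adjusted, with the same decision
threshold (FDR < 1e-5) used downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .de import adjust_bh


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    @property
    def tss(self) -> int:
        return self.start if self.strand != "-" else self.end - 1


def methylation_frequency(table: pd.DataFrame) -> pd.DataFrame:
    """Per-CpG methylation frequency f = M / (M + U) with coverage.

    Zero-coverage CpGs get NaN frequency and ``defined = False``.
    """
    m = table["count_methylated"].to_numpy(dtype=float)
    u = table["count_unmethylated"].to_numpy(dtype=float)
    if np.any(m < 0) or np.any(u < 0):
        raise ValueError("negative methylation counts")
    cov = m + u
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(cov > 0, m / cov, np.nan)
    out = table.copy()
    out["coverage"] = cov.astype(int)
    out["frequency"] = f
    out["defined"] = cov > 0
    return out


_CPG_KEY = ["chrom", "pos", "allele"]


def call_dml(
    wt_table: pd.DataFrame,
    ko_table: pd.DataFrame,
    min_coverage: int = 10,
    fdr: float = 1e-5,
) -> pd.DataFrame:
    """Differentially methylated loci between two conditions (or alleles).

    CpGs are matched on (chrom, pos, allele) and pooled over replicates;
    each matched CpG with coverage >= ``min_coverage`` in both tables gets a
    two-sided Fisher exact p on [[M, U]_WT, [M, U]_KO], BH-adjusted across
    tested CpGs.  ``is_dml`` flags q < ``fdr``.
    """
    key_cols = [c for c in _CPG_KEY if c in wt_table.columns and c in ko_table.columns]
    if not key_cols:
        raise ValueError("tables lack CpG key columns (chrom, pos[, allele])")

    def pool(t: pd.DataFrame) -> pd.DataFrame:
        return t.groupby(key_cols, as_index=False)[
            ["count_methylated", "count_unmethylated"]
        ].sum()

    wt = pool(wt_table)
    ko = pool(ko_table)
    merged = wt.merge(ko, on=key_cols, suffixes=("_wt", "_ko"))
    if merged.empty:
        raise ValueError("no overlapping CpGs between the two tables")
    cov_wt = merged["count_methylated_wt"] + merged["count_unmethylated_wt"]
    cov_ko = merged["count_methylated_ko"] + merged["count_unmethylated_ko"]
    tested = (cov_wt >= min_coverage) & (cov_ko >= min_coverage)

    with np.errstate(divide="ignore", invalid="ignore"):
        f_wt = merged["count_methylated_wt"] / cov_wt
        f_ko = merged["count_methylated_ko"] / cov_ko
    merged["delta_f"] = f_ko - f_wt

    pvals = np.full(len(merged), np.nan)
    idx = np.flatnonzero(tested.to_numpy())
    mw = merged["count_methylated_wt"].to_numpy()
    uw = merged["count_unmethylated_wt"].to_numpy()
    mk = merged["count_methylated_ko"].to_numpy()
    uk = merged["count_unmethylated_ko"].to_numpy()
    for i in idx:
        _, pvals[i] = sps.fisher_exact(
            [[mw[i], uw[i]], [mk[i], uk[i]]], alternative="two-sided"
        )
    merged["p"] = pvals
    merged["q"] = adjust_bh(pvals)
    merged["tested"] = tested
    merged["is_dml"] = merged["q"] < fdr
    return merged


def classify_methylation_regions(
    freqs: pd.DataFrame,
    tss_intervals: list[GenomicInterval],
    min_coverage: int = 10,
    merge_gap: int = 200,
    size_range: tuple[int, int] = (350, 2000),
    tss_flank: int = 100,
) -> pd.DataFrame:
    """Segment CpGs into fully / low / un-methylated promoter regions.

    CpGs covered more than ``min_coverage`` times are banded by frequency
    (fully > 0.95; low 0.10-0.50; un < 0.10); consecutive same-band CpGs
    within ``merge_gap`` bp merge into a region.  Regions are retained when
    their span lies within ``size_range`` and they overlap any TSS +/-
    ``tss_flank`` window.
    """
    empty = pd.DataFrame(
        columns=["chrom", "start", "end", "band", "n_cpgs", "mean_frequency"]
    )
    if freqs.empty:
        return empty
    f = freqs[freqs["coverage"] > min_coverage].copy()

    def band(x: float) -> str | None:
        if x > 0.95:
            return "fully"
        if 0.10 <= x <= 0.50:
            return "low"
        if x < 0.10:
            return "un"
        return None

    f["band"] = f["frequency"].map(band)
    f = f.dropna(subset=["band"]).sort_values(["chrom", "pos"])

    regions = []
    for (chrom, b), sub in f.groupby(["chrom", "band"]):
        pos = sub["pos"].to_numpy()
        fr = sub["frequency"].to_numpy()
        start_i = 0
        for i in range(1, len(pos) + 1):
            if i == len(pos) or pos[i] - pos[i - 1] > merge_gap:
                regions.append(
                    {
                        "chrom": chrom,
                        "start": int(pos[start_i]),
                        "end": int(pos[i - 1]) + 1,
                        "band": b,
                        "n_cpgs": i - start_i,
                        "mean_frequency": float(fr[start_i:i].mean()),
                    }
                )
                start_i = i
    out = pd.DataFrame(regions)
    if out.empty:
        return empty
    span = out["end"] - out["start"]
    out = out[(span >= size_range[0]) & (span <= size_range[1])]
    if out.empty:
        return empty

    def overlaps_tss(row) -> bool:
        for iv in tss_intervals:
            if iv.chrom != row["chrom"]:
                continue
            lo, hi = iv.tss - tss_flank, iv.tss + tss_flank + 1
            if row["start"] < hi and lo < row["end"]:
                return True
        return False

    return out[out.apply(overlaps_tss, axis=1)].reset_index(drop=True)


def tf_meth_anticorrelation(
    peaks: pd.DataFrame,
    allelic_freqs: pd.DataFrame,
    lfc_threshold: float = 1.0,
    delta_threshold: float = 0.25,
) -> tuple[pd.DataFrame, dict]:
    """Join allele-biased TF peaks with allele-biased CpG methylation.

    ``peaks`` carries chrom/start/end and ``allelic_lfc`` = log2(a2/a1)
    binding signal; ``allelic_freqs`` carries chrom/pos and ``delta_f`` =
    f_a2 - f_a1.  Peaks with |lfc| > 1 are overlapped with CpGs with
    |delta_f| > 0.25; a pair is concordantly anticorrelated when the biased
    binding and the biased methylation point to opposite alleles.
    """
    sel_peaks = peaks[np.abs(peaks["allelic_lfc"]) > lfc_threshold]
    sel_cpgs = allelic_freqs[np.abs(allelic_freqs["delta_f"]) > delta_threshold]
    if not sel_peaks["start"].is_monotonic_increasing:
        warnings.warn("peak intervals were unsorted; sorting", stacklevel=2)
        sel_peaks = sel_peaks.sort_values(["chrom", "start"])
    rows = []
    for _, pk in sel_peaks.iterrows():
        hits = sel_cpgs[
            (sel_cpgs["chrom"] == pk["chrom"])
            & (sel_cpgs["pos"] >= pk["start"])
            & (sel_cpgs["pos"] < pk["end"])
        ]
        for _, cg in hits.iterrows():
            rows.append(
                {
                    "chrom": pk["chrom"],
                    "peak_start": pk["start"],
                    "peak_end": pk["end"],
                    "pos": cg["pos"],
                    "allelic_lfc": pk["allelic_lfc"],
                    "delta_f": cg["delta_f"],
                    "concordant_anticorrelation": np.sign(pk["allelic_lfc"])
                    != np.sign(cg["delta_f"]),
                }
            )
    joined = pd.DataFrame(rows)
    summary = {
        "n_pairs": len(joined),
        "fraction_concordant": (
            float(joined["concordant_anticorrelation"].mean())
            if len(joined)
            else np.nan
        ),
    }
    return joined, summary


def aggregate_peak_contacts(
    matrix: np.ndarray,
    peaks,
    window: int = 5,
    distance_range: tuple[int, int] | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Aggregate contact submatrices at peak-pair anchors vs matched background.

    Foreground: bin pairs (i < j) within ``distance_range`` where both bins
    contain a peak.  Background: an equal number of random pairs with
    neither bin containing a peak, sampled per foreground distance
    (nearest-distance fallback with a warning when a distance has no
    peak-free pairs).  Aggregates are means of (2*window+1)^2 submatrices
    centred on the pairs; enrichment is the ratio of the centre means.
    """
    mat = np.asarray(matrix, dtype=float)
    n = mat.shape[0]
    if mat.shape[0] != mat.shape[1]:
        raise ValueError("contact matrix must be square")
    has_peak = np.zeros(n, dtype=bool)
    has_peak[np.asarray(list(peaks), dtype=int)] = True
    if distance_range is None:
        distance_range = (1, n)
    lo_d, hi_d = distance_range

    valid = np.arange(window, n - window)
    fg = [
        (i, j)
        for i in valid
        for j in valid
        if i < j and lo_d <= j - i <= hi_d and has_peak[i] and has_peak[j]
    ]
    if not fg:
        raise ValueError("no foreground pairs (no peak-pair bins in range)")

    bg_by_dist: dict[int, list[tuple[int, int]]] = {}
    for i in valid:
        for j in valid:
            if i < j and not has_peak[i] and not has_peak[j]:
                bg_by_dist.setdefault(j - i, []).append((i, j))
    if not bg_by_dist:
        raise ValueError("no background pairs available")

    rng = np.random.default_rng(seed)
    bg = []
    for i, j in fg:
        d = j - i
        if d not in bg_by_dist:
            nearest = min(bg_by_dist, key=lambda x: abs(x - d))
            warnings.warn(
                f"no peak-free pairs at distance {d}; using distance {nearest}",
                stacklevel=2,
            )
            d = nearest
        pool = bg_by_dist[d]
        bg.append(pool[rng.integers(len(pool))])

    def aggregate(pairs) -> np.ndarray:
        acc = np.zeros((2 * window + 1, 2 * window + 1))
        for i, j in pairs:
            acc += mat[i - window : i + window + 1, j - window : j + window + 1]
        return acc / len(pairs)

    fg_agg = aggregate(fg)
    bg_agg = aggregate(bg)
    enrichment = float(fg_agg[window, window] / bg_agg[window, window])
    return fg_agg, bg_agg, enrichment
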