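"""Allelic copy-number QC and single-cell allele frequency."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


def chromosome_cpm_flags(
    coverage: pd.DataFrame, low: float = 0.8, high: float = 1.2
) -> pd.DataFrame:
    """Flag chromosomes with unequal allelic copy number from coverage CPM.

    ``coverage`` is a long frame (chrom, allele, count).  Each allele's
    counts are CPM-normalised across chromosomes; a chromosome is flagged
    when the a2/a1 CPM ratio falls strictly below ``low`` (0.8) or strictly
    above ``high`` (1.2).  A chromosome with zero a1 CPM is flagged with an
    infinite ratio sentinel.
    """
    wide = coverage.pivot_table(
        index="chrom", columns="allele", values="count", aggfunc="sum"
    ).fillna(0.0)
    for allele in ("a1", "a2"):
        if allele not in wide.columns:
            raise ValueError(f"coverage table lacks allele {allele!r}")
        total = wide[allele].sum()
        if total <= 0:
            raise ValueError(f"allele {allele!r} has zero genome-wide counts")
        wide[f"cpm_{allele}"] = 1e6 * wide[allele] / total
    with np.errstate(divide="ignore"):
        ratio = np.where(
            wide["cpm_a1"] > 0, wide["cpm_a2"] / wide["cpm_a1"], np.inf
        )
    flagged = (ratio < low) | (ratio > high)
    return pd.DataFrame(
        {
            "cpm_a1": wide["cpm_a1"],
            "cpm_a2": wide["cpm_a2"],
            "ratio_a2_a1": ratio,
            "flagged": flagged,
        },
        index=wide.index,
    )


def rna_copy_number_flags(
    allele_bias_de: pd.DataFrame,
    chrom_of: pd.Series,
    pseudocount: float = 1.0,
    p_threshold: float = 0.01,
    lfc_threshold: float = 0.5,
    log_ratio_bound: float = 1.0,
) -> pd.DataFrame:
    """RNA-based copy-number flags from allele-biased DE gene counts.

    ``allele_bias_de`` holds per-gene allele-2-vs-allele-1 test results
    within one condition (columns ``p`` and ``log2fc``); a gene is biased
    toward an allele when p < 0.01 and |log2FC| > 0.5.  Per chromosome,
    ``L = log2((n_a2_biased + pc) / (n_a1_biased + pc))``; flagged when
    |L| > 1.  Chromosomes with no tested genes are skipped with a warning.
    """
    with np.errstate(invalid="ignore"):
        sig = (allele_bias_de["p"] < p_threshold) & (
            allele_bias_de["log2fc"].abs() > lfc_threshold
        )
    biased_a2 = sig & (allele_bias_de["log2fc"] > 0)
    biased_a1 = sig & (allele_bias_de["log2fc"] < 0)
    chrom = chrom_of.reindex(allele_bias_de.index)
    tested = allele_bias_de["p"].notna()
    rows = []
    for c in pd.unique(chrom.dropna()):
        on_c = chrom == c
        if not (on_c & tested).any():
            warnings.warn(f"chromosome {c}: no tested genes, skipped", stacklevel=2)
            continue
        n1 = int((biased_a1 & on_c).sum())
        n2 = int((biased_a2 & on_c).sum())
        L = np.log2((n2 + pseudocount) / (n1 + pseudocount))
        rows.append(
            {
                "chrom": c,
                "n_a1_biased": n1,
                "n_a2_biased": n2,
                "log2_bias_ratio": L,
                "flagged": abs(L) > log_ratio_bound,
            }
        )
    return pd.DataFrame(rows).set_index("chrom")


@dataclass
class CellAlleleExpression:
    """Per-cell, per-gene, per-allele detection counts (cells x genes x 2)."""

    counts: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3 or self.counts.shape[2] != 2:
            raise ValueError("counts must have shape (cells, genes, 2)")
        if np.any(self.counts < 0):
            raise ValueError("detection counts must be non-negative")

    def detected(self) -> np.ndarray:
        return self.counts >= 1

    def gene_index(self, gene) -> int:
        return self.gene_ids.index(gene)


def cell_allele_frequency(
    cells: CellAlleleExpression, gene, min_cells: int = 10
) -> tuple[float | None, str]:
    """Detection-based allele frequency of one gene across cells.

    AF = |cells detecting a1| / |cells detecting a1 OR a2| (a union, so
    cells detecting both alleles count once).  Undefined (None) when fewer
    than ``min_cells`` cells express either allele.
    """
    det = cells.detected()[:, cells.gene_index(gene), :]
    either = det[:, 0] | det[:, 1]
    n_expressing = int(either.sum())
    if n_expressing < min_cells:
        return None, f"only {n_expressing} expressing cells (< {min_cells})"
    af = float(det[:, 0].sum() / n_expressing)
    return af, ""
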