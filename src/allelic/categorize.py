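"""Decision tree assigning genes to allelic expression-change categories.

A gene downregulated after the knockout is placed in exactly one of:

* ``bi_to_mono_A1`` / ``bi_to_mono_A2`` — biallelic in WT, silenced on one
  allele in KO (the subscript names the allele that remains active);
* ``mono_A1_to_none`` / ``mono_A2_to_none`` — monoallelic in WT, the single
  active allele silenced in KO;
* ``bi_to_bi_down`` — downregulated without allelic specificity;
* ``unclassified`` otherwise.

Candidates for the monoallelic categories must pass the allele-specific
(interaction) test (p < 0.05, |log2FC| > 0.5) and be supported by the
standard test (q < 0.01) or either per-allele test (p < 0.01).  The
monoallelic gates then use the WT allelic balance:

* bi-to-mono^A2: WT log2(a2/a1) > -1 and WT a1/(a1+a2) > 0.1 and allele-1
  log2FC < 0;
* bi-to-mono^A1: WT log2(a2/a1) < 1 and WT a2/(a1+a2) > 0.1 and allele-2
  log2FC < 0 (asymmetric with the A2 gate: no lower ratio bound; kept
  verbatim, see docs/methods.md);
* mono^A2-to-none: WT log2(a2/a1) > 1 and allele-2 log2FC < 0;
* mono^A1-to-none: WT log2(a2/a1) < -1 and allele-1 log2FC < 0.

Mono gates are evaluated before bi gates.  A strict flag marks bi-to-mono
genes whose silenced allele shows log2FC < -2 (near-complete loss).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .de import DESuiteResult
from .tables import AlleleCountTable


@dataclass(frozen=True)
class Thresholds:
    """Gate values of the categorization decision tree."""

    standard_q: float = 0.01
    allelic_p: float = 0.01
    as_p: float = 0.05
    as_abs_lfc: float = 0.5
    strict_lfc: float = -2.0
    wt_ratio_bound: float = 1.0
    wt_frac_min: float = 0.1
    n_controls: int = 300
    pseudocount: float = 1.0

    def __post_init__(self):
        for name in ("standard_q", "allelic_p", "as_p"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1)")
        if not (0 < self.wt_frac_min < 0.5):
            raise ValueError("wt_frac_min must lie in (0, 0.5)")

    def with_(self, **kwargs) -> "Thresholds":
        return replace(self, **kwargs)


CATEGORY_LABELS = (
    "bi_to_bi_down",
    "bi_to_mono_A1",
    "bi_to_mono_A2",
    "mono_A1_to_none",
    "mono_A2_to_none",
    "control",
    "unclassified",
)


def compute_wt_allele_stats(
    table: AlleleCountTable,
    size_factors: pd.Series,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """WT allelic balance per gene from normalized allelic counts.

    Returns ``wt_mean_a1``, ``wt_mean_a2``, ``wt_log2_ratio`` (pseudocount
    inside the log ratio only) and ``wt_frac_a1`` / ``wt_frac_a2`` (raw
    means; NaN when both means are zero).
    """
    wt = table.condition_mask("WT")
    if not np.any(wt):
        raise ValueError("no WT samples in table")
    sf = size_factors
    means = {}
    for allele in ("a1", "a2"):
        cols = [f"{s}|{allele}" for s in table.sample_ids[wt]]
        norm = table.counts[allele].loc[:, table.sample_ids[wt]].to_numpy(
            dtype=float
        ) / sf.loc[cols].to_numpy()[None, :]
        means[allele] = norm.mean(axis=1)
    m1, m2 = means["a1"], means["a2"]
    total = m1 + m2
    with np.errstate(divide="ignore", invalid="ignore"):
        frac1 = np.where(total > 0, m1 / total, np.nan)
    ratio = np.log2((m2 + pseudocount) / (m1 + pseudocount))
    ratio = np.where(total > 0, ratio, np.nan)
    return pd.DataFrame(
        {
            "wt_mean_a1": m1,
            "wt_mean_a2": m2,
            "wt_log2_ratio": ratio,
            "wt_frac_a1": frac1,
            "wt_frac_a2": 1.0 - frac1,
        },
        index=table.genes,
    )


def assign_categories(
    suite: DESuiteResult,
    wt_stats: pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Run the decision tree; one mutually exclusive label per gene.

    Returns a frame with ``category``, ``strict_bi_to_mono``, ``reason`` and
    the gate statistics used.  Genes with undefined WT allelic stats are
    unclassified with a reason code; upregulated genes are never
    categorized.
    """
    genes = suite.genes
    if not wt_stats.index.equals(genes):
        wt_stats = wt_stats.reindex(genes)
    t = thresholds

    std = suite.standard
    a1 = suite.allele1
    a2 = suite.allele2
    asr = suite.allele_specific

    std_q = std["q"].to_numpy()
    std_lfc = std["log2fc"].to_numpy()
    p1 = a1["p"].to_numpy()
    p2 = a2["p"].to_numpy()
    l1 = a1["log2fc"].to_numpy()
    l2 = a2["log2fc"].to_numpy()
    as_p = asr["p"].to_numpy()
    as_lfc = asr["log2fc"].to_numpy()
    ratio = wt_stats["wt_log2_ratio"].to_numpy()
    frac1 = wt_stats["wt_frac_a1"].to_numpy()
    frac2 = wt_stats["wt_frac_a2"].to_numpy()

    with np.errstate(invalid="ignore"):
        support = (
            np.less(std_q, t.standard_q)
            | np.less(p1, t.allelic_p)
            | np.less(p2, t.allelic_p)
        )
        candidate = (
            np.less(as_p, t.as_p)
            & np.greater(np.abs(as_lfc), t.as_abs_lfc)
            & support
        )
        mono_a2_none = np.greater(ratio, t.wt_ratio_bound) & np.less(l2, 0)
        mono_a1_none = np.less(ratio, -t.wt_ratio_bound) & np.less(l1, 0)
        bi_mono_a2 = (
            np.greater(ratio, -t.wt_ratio_bound)
            & np.greater(frac1, t.wt_frac_min)
            & np.less(l1, 0)
        )
        bi_mono_a1 = (
            np.less(ratio, t.wt_ratio_bound)
            & np.greater(frac2, t.wt_frac_min)
            & np.less(l2, 0)
        )
        nonallelic_down = (np.less(std_q, t.standard_q) & np.less(std_lfc, 0)) | (
            np.less(p1, t.allelic_p) & np.less(l1, 0)
        ) | (np.less(p2, t.allelic_p) & np.less(l2, 0))

    category = np.full(len(genes), "unclassified", dtype=object)
    reason = np.full(len(genes), "", dtype=object)

    nan_stats = np.isnan(ratio) | np.isnan(frac1)
    reason[nan_stats] = "undefined_wt_allelic_stats"

    cand = candidate & ~nan_stats
    # mono gates first (the WT ratio bounds make them disjoint from bi gates)
    category[cand & mono_a2_none] = "mono_A2_to_none"
    category[cand & mono_a1_none & (category == "unclassified")] = "mono_A1_to_none"

    open_ = cand & (category == "unclassified")
    both_bi = open_ & bi_mono_a1 & bi_mono_a2
    # gate conflict: assign to the side whose allele fell harder
    category[both_bi & (l1 <= l2)] = "bi_to_mono_A2"
    category[both_bi & (l1 > l2)] = "bi_to_mono_A1"
    reason[both_bi] = "both_bi_gates_passed"
    only = open_ & ~both_bi
    category[only & bi_mono_a1] = "bi_to_mono_A1"
    category[only & bi_mono_a2] = "bi_to_mono_A2"

    down_left = (category == "unclassified") & nonallelic_down & ~nan_stats
    category[down_left] = "bi_to_bi_down"

    silenced_lfc = np.where(
        category == "bi_to_mono_A1",
        l2,
        np.where(category == "bi_to_mono_A2", l1, np.nan),
    )
    with np.errstate(invalid="ignore"):
        strict = np.less(silenced_lfc, t.strict_lfc)

    return pd.DataFrame(
        {
            "category": category,
            "strict_bi_to_mono": strict,
            "reason": reason,
            "std_q": std_q,
            "std_log2fc": std_lfc,
            "allele1_p": p1,
            "allele1_log2fc": l1,
            "allele2_p": p2,
            "allele2_log2fc": l2,
            "as_p": as_p,
            "as_log2fc": as_lfc,
            "wt_log2_ratio": ratio,
            "wt_frac_a1": frac1,
        },
        index=genes,
    )


def select_controls(
    suite: DESuiteResult,
    thresholds: Thresholds = Thresholds(),
    seed: int = 0,
) -> pd.Index:
    """Seeded uniform sample of unchanged genes for the control category.

    Eligible genes show no evidence of change: standard q > 0.5,
    |standard log2FC| < 0.1 and allele-specific p > 0.5.
    """
    std = suite.standard
    asr = suite.allele_specific
    with np.errstate(invalid="ignore"):
        eligible = (
            (std["q"].to_numpy() > 0.5)
            & (np.abs(std["log2fc"].to_numpy()) < 0.1)
            & (asr["p"].to_numpy() > 0.5)
        )
    pool = suite.genes[np.nan_to_num(eligible.astype(float)) > 0]
    n = thresholds.n_controls
    if len(pool) < n:
        raise ValueError(
            f"control pool has {len(pool)} genes, fewer than requested {n}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=n, replace=False)
    return pool[np.sort(chosen)]
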