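"""Cross-clone consistency, parental origin, escapees and set enrichment."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans

from .categorize import Thresholds
from .de import DESuiteResult
from .simulate import CrossInfo
from .tables import AlleleCountTable


def cluster_allelic_fc(
    lfc_matrix: pd.DataFrame, k: int = 14, seed: int = 0, n_init: int = 10
) -> pd.Series:
    """K-means (Lloyd) clustering of a gene x (clone-allele) log2FC matrix.

    Untested entries (NaN) are imputed as 0 (no change).  ``k`` defaults to
    14, the subcluster count used for the four-clone bi-to-mono matrix.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > lfc_matrix.shape[0]:
        raise ValueError("k exceeds the number of genes")
    X = lfc_matrix.to_numpy(dtype=float)
    X = np.nan_to_num(X, nan=0.0)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(X)
    return pd.Series(labels, index=lfc_matrix.index, name="cluster")


def lost_allele(
    suite: DESuiteResult, thresholds: Thresholds = Thresholds()
) -> pd.Series:
    """The allele whose expression was lost, per gene.

    Operational rule: allelic p < 0.01 and log2FC below the strict
    silencing threshold (-2).  Genes where neither or both alleles qualify
    get NA.
    """
    t = thresholds
    with np.errstate(invalid="ignore"):
        lost1 = (suite.allele1["p"] < t.allelic_p) & (
            suite.allele1["log2fc"] < t.strict_lfc
        )
        lost2 = (suite.allele2["p"] < t.allelic_p) & (
            suite.allele2["log2fc"] < t.strict_lfc
        )
    out = pd.Series(pd.NA, index=suite.genes, dtype="object")
    out[lost1 & ~lost2] = "a1"
    out[lost2 & ~lost1] = "a2"
    return out


def classify_cross_clone_consistency(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    cross_a: CrossInfo,
    cross_b: CrossInfo,
    lost_a: pd.Series,
    lost_b: pd.Series,
) -> pd.DataFrame:
    """Same-allele vs reversed-allele classification for shared bi-to-mono genes.

    Restricted to genes called bi-to-mono in both clones with a defined lost
    allele.  ``mode`` is ``same_allele`` when the identical strain allele is
    lost in both clones.  Parental origin of each loss follows from the
    clone's cross (allele 2 = CAST, so the loss is maternal iff the CAST
    parent is the mother, etc.).  For reciprocal crosses a reversed-allele
    change with consistent parental origin is imprinting-like; for clones of
    the same cross a reversed-allele change is random-monoallelic-like.
    """
    bi = ("bi_to_mono_A1", "bi_to_mono_A2")
    shared = calls_a.index[calls_a["category"].isin(bi)].intersection(
        calls_b.index[calls_b["category"].isin(bi)]
    )
    reciprocal = cross_a.maternal_strain != cross_b.maternal_strain
    rows = []
    for g in shared:
        la, lb = lost_a.get(g), lost_b.get(g)
        if pd.isna(la) or pd.isna(lb):
            rows.append(
                {"gene_id": g, "mode": pd.NA, "excluded_reason": "lost allele undefined"}
            )
            continue
        origin_a = cross_a.parental_origin(la)
        origin_b = cross_b.parental_origin(lb)
        mode = "same_allele" if la == lb else "reversed_allele"
        consistent = origin_a == origin_b
        if mode == "reversed_allele":
            label = (
                "imprinting_like"
                if (reciprocal and consistent)
                else "random_monoallelic_like"
            )
        else:
            label = "strain_consistent" if reciprocal else "same_allele_change"
        rows.append(
            {
                "gene_id": g,
                "mode": mode,
                "lost_allele_a": la,
                "lost_allele_b": lb,
                "parental_origin_a": origin_a,
                "parental_origin_b": origin_b,
                "origin_consistent": consistent,
                "interpretation": label,
                "excluded_reason": "",
            }
        )
    return pd.DataFrame(rows).set_index("gene_id") if rows else pd.DataFrame(
        columns=[
            "mode",
            "lost_allele_a",
            "lost_allele_b",
            "parental_origin_a",
            "parental_origin_b",
            "origin_consistent",
            "interpretation",
            "excluded_reason",
        ]
    )


def identify_escapees(
    table: AlleleCountTable,
    suite: DESuiteResult,
    cross: CrossInfo,
    thresholds: Thresholds = Thresholds(),
    min_xi_counts: float = 10.0,
    frac_bounds: tuple[float, float] = (0.1, 0.9),
) -> pd.DataFrame:
    """X-inactivation escapees in a female clone, and the regulated subset.

    A chrX gene escapes when its WT inactive-X allele shows normalized
    counts > 10 and an allelic fraction strictly between 0.1 and 0.9.  An
    escapee is knockout-regulated when its Xi-allele log2FC (KO/WT) falls
    below the strict silencing threshold (-2).
    """
    if cross.xi_allele is None:
        raise ValueError(f"{cross.clone_id}: not an XCI-informative clone")
    if table.gene_info is None or "chrom" not in table.gene_info.columns:
        raise ValueError("table lacks gene annotation with chromosomes")
    xi = cross.xi_allele
    xa = "a1" if xi == "a2" else "a2"
    x_genes = table.gene_info.index[table.gene_info["chrom"] == "chrX"]

    wt = table.condition_mask("WT")
    sf = suite.size_factors_allelic

    def wt_mean(allele: str) -> pd.Series:
        cols = [f"{s}|{allele}" for s in table.sample_ids[wt]]
        norm = table.counts[allele].loc[x_genes, table.sample_ids[wt]].to_numpy(
            dtype=float
        ) / sf.loc[cols].to_numpy()[None, :]
        return pd.Series(norm.mean(axis=1), index=x_genes)

    xi_mean = wt_mean(xi)
    xa_mean = wt_mean(xa)
    total = xi_mean + xa_mean
    with np.errstate(invalid="ignore", divide="ignore"):
        xi_fraction = (xi_mean / total).where(total > 0)
    lo, hi = frac_bounds
    is_escapee = (
        (xi_mean > min_xi_counts) & (xi_fraction > lo) & (xi_fraction < hi)
    ).fillna(False)
    xi_lfc = suite.frame("allele1" if xi == "a1" else "allele2")["log2fc"].reindex(
        x_genes
    )
    is_regulated = is_escapee & (xi_lfc < thresholds.strict_lfc).fillna(False)
    return pd.DataFrame(
        {
            "xi_allele": xi,
            "xi_mean": xi_mean,
            "xi_fraction": xi_fraction,
            "xi_log2fc": xi_lfc,
            "is_escapee": is_escapee,
            "is_msl2_regulated": is_regulated,
        },
        index=x_genes,
    )


def fisher_enrichment(query_set, annotation_set, universe):
    """Two-sided Fisher's exact test of query vs annotation membership.

    Returns ``(odds_ratio, p_two_sided, table)`` where ``table`` is the 2x2
    array [[both, query only], [annotation only, neither]].  The sample odds
    ratio uses a 0.5 Haldane correction only when a cell is zero.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query_set) & universe
    anno = set(annotation_set) & universe
    a = len(query & anno)
    b = len(query - anno)
    c = len(anno - query)
    d = len(universe) - a - b - c
    table = np.array([[a, b], [c, d]])
    _, p = sps.fisher_exact(table, alternative="two-sided")
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return float(odds), float(p), table


def haploinsufficiency_summary(
    category_calls: pd.DataFrame,
    hi_table: pd.DataFrame,
    universe,
) -> pd.DataFrame:
    """Per-category haploinsufficiency burden.

    ``hi_table`` lists ``gene_id``, ``hi_score`` in [0, 1] and a
    ``triplosensitive`` 0/1 flag; a gene is counted haploinsufficient when
    present in the table.  Reports the HI fraction, score quantiles and a
    Fisher enrichment against the universe.
    """
    if hi_table["gene_id"].duplicated().any():
        dups = hi_table.loc[hi_table["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene ids in HI table: {dups[:5]}")
    universe = list(universe)
    hi_genes = set(hi_table["gene_id"]) & set(universe)
    scores = hi_table.set_index("gene_id")["hi_score"]
    rows = []
    for cat, sub in category_calls.groupby("category"):
        genes = list(sub.index)
        in_hi = [g for g in genes if g in hi_genes]
        frac = len(in_hi) / len(genes) if genes else np.nan
        qs = (
            scores.reindex(in_hi).quantile([0.25, 0.5, 0.75])
            if in_hi
            else pd.Series([np.nan] * 3, index=[0.25, 0.5, 0.75])
        )
        odds, p, _ = fisher_enrichment(genes, hi_genes, universe)
        rows.append(
            {
                "category": cat,
                "n_genes": len(genes),
                "n_hi": len(in_hi),
                "frac_hi": frac,
                "hi_score_q25": qs.loc[0.25],
                "hi_score_median": qs.loc[0.5],
                "hi_score_q75": qs.loc[0.75],
                "odds_ratio": odds,
                "fisher_p": p,
            }
        )
    return pd.DataFrame(rows).set_index("category")
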