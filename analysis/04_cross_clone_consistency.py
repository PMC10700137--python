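"""Cross-clone consistency of bi-to-mono genes: imprinting-like vs
random-monoallelic-like.

Compares the reciprocal male clones (parent-of-origin informative) and the
two same-direction CaBl clones, k-means-clusters the allele-specific
log2FC matrix across all four clones, and writes the classification
summaries.
"""

import pandas as pd

from allelic import Thresholds, assign_categories, compute_wt_allele_stats
from allelic.cross import classify_cross_clone_consistency, cluster_allelic_fc, lost_allele

from common import CONFIG, SEED, get_suites, outdir


def main():
    tables, truth, suites = get_suites()
    out = outdir()
    thresholds = Thresholds()
    crosses = {c.clone_id: c for c in CONFIG.crosses}

    calls, lost = {}, {}
    for clone, suite in suites.items():
        wt = compute_wt_allele_stats(tables[clone], suite.size_factors_allelic)
        calls[clone] = assign_categories(suite, wt, thresholds)
        lost[clone] = lost_allele(suite, thresholds)

    for a, b, label in (
        ("male_CaBl", "male_BlCa", "reciprocal_males"),
        ("male_CaBl", "female_CaBl", "same_cross_CaBl"),
    ):
        res = classify_cross_clone_consistency(
            calls[a], calls[b], crosses[a], crosses[b], lost[a], lost[b]
        )
        res.to_csv(out / f"consistency_{label}.tsv", sep="\t")
        counts = res["interpretation"].value_counts()
        print(f"{label} ({a} vs {b}): {len(res)} shared bi-to-mono genes")
        print(counts.to_string(), "\n")
        if label == "reciprocal_males":
            imp = truth["origin_mode"] == "imprinted_maternal"
            found = res.index.intersection(truth.index[imp])
            frac = (
                (res.loc[found, "interpretation"] == "imprinting_like").mean()
                if len(found)
                else float("nan")
            )
            print(
                f"planted imprinted-maternal genes recovered as imprinting-like: "
                f"{frac:.1%} of {len(found)} shared\n"
            )

    # four-clone allele-specific log2FC matrix for bi-to-mono genes
    bi = pd.Index(
        sorted(
            set().union(
                *[
                    calls[c].index[
                        calls[c]["category"].str.startswith("bi_to_mono")
                    ]
                    for c in suites
                ]
            )
        )
    )
    mat = pd.DataFrame(
        {c: suites[c].allele_specific["log2fc"].reindex(bi) for c in suites}
    )
    labels = cluster_allelic_fc(mat, k=14, seed=SEED)
    labels.to_frame().join(mat.round(3)).to_csv(out / "bi_to_mono_clusters.tsv", sep="\t")
    print(f"k-means (k=14) on {len(bi)} union bi-to-mono genes; cluster sizes:")
    print(labels.value_counts().sort_index().to_string())


if __name__ == "__main__":
    main()
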