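"""Assign allelic expression-change categories per clone.

Runs the decision tree on every clone, selects the seeded control set, and
compares calls against the planted truth.  Writes the per-clone confusion
summary and the full calls for male CaBl.
"""

import pandas as pd

from allelic import Thresholds, assign_categories, compute_wt_allele_stats, select_controls
from allelic.simulate import expected_category

from common import CONFIG, SEED, get_suites, outdir


def main():
    tables, truth, suites = get_suites()
    out = outdir()
    thresholds = Thresholds(n_controls=200)
    crosses = {c.clone_id: c for c in CONFIG.crosses}

    confusion = {}
    for clone, suite in suites.items():
        wt = compute_wt_allele_stats(tables[clone], suite.size_factors_allelic)
        calls = assign_categories(suite, wt, thresholds)
        controls = select_controls(suite, thresholds, seed=SEED)
        calls.loc[
            calls.index.isin(controls) & (calls["category"] == "unclassified"),
            "category",
        ] = "control"
        planted = expected_category(truth, crosses[clone])
        confusion[clone] = (
            pd.crosstab(planted, calls["category"]).reindex(
                planted.unique(), fill_value=0
            )
        )
        if clone == "male_CaBl":
            calls.round(4).to_csv(out / "categories_male_CaBl.tsv", sep="\t")
        recov = {}
        for cat in ("bi_to_mono_A1", "bi_to_mono_A2", "mono_A1_to_none",
                    "mono_A2_to_none"):
            mask = planted == cat
            if mask.any():
                recov[cat] = round(float((calls.loc[mask, "category"] == cat).mean()), 3)
        print(f"{clone}: exact-subclass recovery {recov}")

    summary = pd.concat(confusion, names=["clone", "planted"])
    summary.to_csv(out / "category_confusion.tsv", sep="\t")
    print("\nconfusion matrices written to category_confusion.tsv")


if __name__ == "__main__":
    main()
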