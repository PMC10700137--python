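"""Fit the four differential-expression modes for every clone.

The standard test misses most monoallelic transitions; the allele-specific
(interaction) test recovers them.  Writes per-clone significant-gene counts
and the full result table for the male CaBl clone.
"""

import pandas as pd

from common import get_suites, outdir


def main():
    tables, truth, suites = get_suites()
    out = outdir()

    rows = []
    for clone, suite in suites.items():
        rows.append(
            {
                "clone": clone,
                "tested": int(suite.standard["tested"].sum()),
                "standard_q_lt_0.01": int((suite.standard["q"] < 0.01).sum()),
                "allele1_p_lt_0.01": int((suite.allele1["p"] < 0.01).sum()),
                "allele2_p_lt_0.01": int((suite.allele2["p"] < 0.01).sum()),
                "as_p_lt_0.05": int((suite.allele_specific["p"] < 0.05).sum()),
            }
        )
    summary = pd.DataFrame(rows).set_index("clone")
    summary.to_csv(out / "de_summary.tsv", sep="\t")
    print(summary.to_string())

    suite = suites["male_CaBl"]
    merged = pd.concat(
        {m: suite.frame(m)[["log2fc", "p", "q"]] for m in
         ("standard", "allele1", "allele2", "allele_specific")},
        axis=1,
    )
    merged.columns = ["_".join(c) for c in merged.columns]
    merged.round(4).to_csv(out / "de_male_CaBl.tsv", sep="\t")

    # how many allele-specific hits the standard analysis would have missed
    asr = suite.allele_specific
    hits = (asr["p"] < 0.05) & (asr["log2fc"].abs() > 0.5)
    missed = hits & (suite.standard["q"] >= 0.01)
    print(
        f"\nmale_CaBl: {int(hits.sum())} allele-specific hits, "
        f"{int(missed.sum())} of them not significant in the standard test "
        "(the hybrid system's added value)."
    )


if __name__ == "__main__":
    main()
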