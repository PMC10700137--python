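"""Simulate the four-clone hybrid knockout experiment and describe the panel.

Writes the ground-truth gene table and a per-clone sanity summary
(assignable-read fraction, allelic balance) to results/analysis/.
"""

import pandas as pd

from common import CONFIG, get_experiment, outdir


def main():
    tables, truth = get_experiment()
    out = outdir()
    truth.to_csv(out / "truth.tsv", sep="\t")

    print(f"panel: {len(truth)} genes")
    print(truth.groupby(["category", "origin_mode"]).size().to_string(), "\n")

    rows = []
    for clone, t in tables.items():
        a1 = t.counts["a1"].to_numpy().sum()
        a2 = t.counts["a2"].to_numpy().sum()
        tot = t.counts["total"].to_numpy().sum()
        rows.append(
            {
                "clone": clone,
                "n_samples": len(t.sample_ids),
                "assignable_frac": round((a1 + a2) / tot, 4),
                "a2_over_a1": round(a2 / a1, 4),
            }
        )
    summary = pd.DataFrame(rows).set_index("clone")
    summary.to_csv(out / "simulation_summary.tsv", sep="\t")
    print(summary.to_string())
    print(
        f"\nassignable fraction tracks the configured assign_rate "
        f"({CONFIG.assign_rate}); a2/a1 near 1 genome-wide (the X skews "
        "female clones slightly)."
    )


if __name__ == "__main__":
    main()
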