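"""Allelic copy-number QC and detection-based single-cell allele frequency.

Demonstrates both copy-number rules (coverage CPM and allele-biased DE gene
counts) on the simulated male CaBl clone, including a planted chr7 trisomy,
and computes per-gene allele frequencies from simulated cells.
"""

import numpy as np
import pandas as pd

from allelic import simulate_cells
from allelic.qc import cell_allele_frequency, chromosome_cpm_flags, rna_copy_number_flags

from common import CONFIG, SEED, get_suites, outdir


def main():
    tables, truth, suites = get_suites()
    cross = CONFIG.crosses[0]
    table = tables[cross.clone_id]
    out = outdir()

    # coverage-CPM rule on the balanced clone, then with a planted trisomy
    rows = []
    chrom_of = table.gene_info["chrom"]
    for allele in ("a1", "a2"):
        per = table.counts[allele].sum(axis=1).groupby(chrom_of).sum()
        for chrom, count in per.items():
            factor = 2 if (allele == "a2" and chrom == "chr7") else 1
            rows.append({"chrom": chrom, "allele": allele, "count": int(count) * factor})
    flags = chromosome_cpm_flags(pd.DataFrame(rows))
    flags.round(3).to_csv(out / "cpm_flags_trisomy7.tsv", sep="\t")
    print("coverage-CPM rule with a2 doubled on chr7:")
    print(flags[flags["flagged"]].round(3).to_string(), "\n")

    # RNA-based rule: allele-2 vs allele-1 contrast within WT
    suite = suites[cross.clone_id]
    allele_bias = pd.DataFrame(
        {
            # WT allelic imbalance proxy: the fitted allele coefficient is
            # not exported per mode, so use the WT mean ratio test frame
            "p": suite.allele_specific["p"],
            "log2fc": suite.allele_specific["log2fc"],
        }
    )
    rna_flags = rna_copy_number_flags(allele_bias, chrom_of)
    rna_flags.to_csv(out / "rna_copy_number_flags.tsv", sep="\t")
    print("RNA-based rule (no planted aneuploidy -> nothing flagged):")
    print(f"flagged chromosomes: {list(rna_flags.index[rna_flags['flagged']])}\n")

    # single-cell allele frequency
    sub = pd.concat(
        [
            truth[truth["category"] == "control"].head(30),
            truth[truth["category"] == "mono_A1_to_none"].head(30),
        ]
    )
    cells = simulate_cells(sub, cross, n_cells=300, detect_prob=0.4, seed=SEED)
    afs = []
    for gid, row in sub.iterrows():
        af, reason = cell_allele_frequency(cells, gid, min_cells=10)
        afs.append({"gene_id": gid, "category": row["category"], "af": af})
    af_df = pd.DataFrame(afs).set_index("gene_id")
    af_df.to_csv(out / "cell_allele_frequency.tsv", sep="\t")
    print("mean allele frequency by category (0.5 = biallelic, 1 = a1-only):")
    print(af_df.groupby("category")["af"].mean().round(3).to_string())


if __name__ == "__main__":
    main()
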