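"""Allelic promoter methylation after the knockout.

Simulates bisulfite data for the male CaBl clone, calls differential
methylation (KO vs WT, per allele), classifies promoter methylation
regions, and checks the anticorrelation between allelic TF binding and
allelic methylation at bi-to-mono genes.
"""

import numpy as np
import pandas as pd

from allelic import simulate_methylation
from allelic.epigenome import (
    GenomicInterval,
    call_dml,
    classify_methylation_regions,
    methylation_frequency,
    tf_meth_anticorrelation,
)

from common import CONFIG, SEED, get_experiment, outdir


def main():
    tables, truth = get_experiment()
    cross = CONFIG.crosses[0]  # male CaBl
    out = outdir()
    meth = simulate_methylation(truth, cross, coverage=50, seed=SEED)

    # differential methylation, KO vs WT per allele
    dml = call_dml(
        meth[meth["condition"] == "WT"], meth[meth["condition"] == "KO"],
        min_coverage=10, fdr=1e-5,
    )
    dml_pos = dml[dml["is_dml"] & (dml["delta_f"] > 0)]
    silenced = truth[f"silenced_allele_{cross.clone_id}"]
    pos_map = meth.drop_duplicates(["chrom", "pos", "allele"])[
        ["chrom", "pos", "allele", "gene_id"]
    ]
    dml_annot = dml.merge(pos_map, on=["chrom", "pos", "allele"])
    on_silenced = dml_annot["allele"] == dml_annot["gene_id"].map(silenced)
    print(
        f"{len(dml_pos)} gained-methylation DML of {int(dml['tested'].sum())} "
        f"tested CpGs; {on_silenced[dml_annot['is_dml']].mean():.1%} of DML "
        "lie on the silenced allele"
    )
    dml_annot[dml_annot["is_dml"]].round(4).to_csv(
        out / "dml_male_CaBl.tsv", sep="\t", index=False
    )

    # promoter methylation region classes.  WT promoters of regulated genes
    # are unmethylated ("un" band, f ~ 0.05); the KO silenced allele sits at
    # f ~ 0.6, between the "low" (0.10-0.50) and "fully" (> 0.95) bands, so
    # those promoters drop OUT of every class after the knockout.
    tss = [
        GenomicInterval(r["chrom"], int(r["tss"]), int(r["tss"]) + 1)
        for _, r in truth.loc[silenced != ""].iterrows()
    ]
    by_condition = {}
    for condition in ("WT", "KO"):
        sil = meth[
            (meth["condition"] == condition)
            & (meth["allele"] == meth["gene_id"].map(silenced))
        ]
        freqs = methylation_frequency(
            sil.groupby(["chrom", "pos"], as_index=False)[
                ["count_methylated", "count_unmethylated"]
            ].sum()
        )
        by_condition[condition] = classify_methylation_regions(
            freqs, tss, size_range=(350, 2000)
        )
    nonempty = {k: v for k, v in by_condition.items() if not v.empty}
    regions = (
        pd.concat(nonempty, names=["condition"]).reset_index(level=0)
        if nonempty
        else pd.DataFrame()
    )
    regions.to_csv(out / "methylation_regions.tsv", sep="\t", index=False)
    print(
        "silenced-allele promoter region classes: "
        f"WT {by_condition['WT']['band'].value_counts().to_dict()}, "
        f"KO {by_condition['KO']['band'].value_counts().to_dict()} "
        "(gained intermediate methylation leaves every band)"
    )

    # TF binding vs methylation anticorrelation at bi-to-mono promoters
    rng = np.random.default_rng(SEED)
    bi = truth[truth["category"].str.startswith("bi_to_mono")]
    peaks = pd.DataFrame(
        {
            "chrom": bi["chrom"],
            "start": bi["tss"] - 300,
            "end": bi["tss"] + 300,
            # binding is lost on the silenced allele: a2/a1 log2FC positive
            # when a1 is silenced, negative when a2 is silenced
            "allelic_lfc": np.where(
                silenced.loc[bi.index] == "a1", 2.0, -2.0
            ) + rng.normal(0, 0.2, len(bi)),
        }
    )
    wt_ko = meth[meth["condition"] == "KO"]
    piv = wt_ko.pivot_table(
        index=["chrom", "pos"], columns="allele",
        values="count_methylated", aggfunc="sum",
    )
    cov = wt_ko.pivot_table(
        index=["chrom", "pos"], columns="allele",
        values="count_unmethylated", aggfunc="sum",
    )
    delta = (piv["a2"] / (piv["a2"] + cov["a2"])) - (
        piv["a1"] / (piv["a1"] + cov["a1"])
    )
    cpg_deltas = delta.rename("delta_f").reset_index()
    joined, summary = tf_meth_anticorrelation(peaks, cpg_deltas)
    print(
        f"anticorrelation join: {summary['n_pairs']} peak-CpG pairs, "
        f"{summary['fraction_concordant']:.1%} concordant "
        "(methylation gained on the allele that lost binding)"
    )
    joined.round(4).to_csv(out / "tf_meth_anticorrelation.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
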