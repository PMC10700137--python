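"""Core in-memory containers for allele-resolved count data.

Counts from a hybrid (F1) cross are kept as three gene x sample integer
matrices: reads assigned to allele 1 (reference strain, e.g. C57BL/6 or
129S1), reads assigned to allele 2 (CAST), and the total (allele-assigned
plus SNP-uninformative reads).  The allelic sum can therefore never exceed
the total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ALLELES = ("a1", "a2", "total")

REQUIRED_SAMPLE_COLS = ("clone", "condition", "replicate")


@dataclass
class AlleleCountTable:
    """Gene x sample counts for alleles a1, a2 and totals, plus sample metadata.

    Parameters
    ----------
    counts
        Mapping with keys ``"a1"``, ``"a2"``, ``"total"``; each value is a
        genes x samples DataFrame of non-negative integers sharing the same
        index (gene ids) and columns (sample ids).
    samples
        DataFrame indexed by sample id with at least columns ``clone``,
        ``condition`` (``WT``/``KO``) and ``replicate``.
    """

    counts: dict[str, pd.DataFrame]
    samples: pd.DataFrame
    gene_info: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        missing = set(ALLELES) - set(self.counts)
        if missing:
            raise ValueError(f"missing count matrices: {sorted(missing)}")
        ref = self.counts["total"]
        for key in ALLELES:
            m = self.counts[key]
            if not m.index.equals(ref.index) or not m.columns.equals(ref.columns):
                raise ValueError("count matrices must share genes and samples")
            vals = m.to_numpy()
            if np.any(vals < 0):
                raise ValueError(f"negative counts in {key!r} matrix")
            if not np.issubdtype(vals.dtype, np.integer):
                if not np.allclose(vals, np.round(vals)):
                    raise ValueError(f"non-integer counts in {key!r} matrix")
                self.counts[key] = m.astype(np.int64)
        for col in REQUIRED_SAMPLE_COLS:
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata lacks column {col!r}")
        if not self.samples.index.equals(ref.columns):
            raise ValueError("sample metadata index must match count columns")
        allelic = self.counts["a1"].to_numpy() + self.counts["a2"].to_numpy()
        if np.any(allelic > self.counts["total"].to_numpy()):
            raise ValueError("allelic sum a1 + a2 exceeds total for some entries")

    @property
    def genes(self) -> pd.Index:
        return self.counts["total"].index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts["total"].columns

    def condition_mask(self, condition: str) -> np.ndarray:
        return (self.samples["condition"] == condition).to_numpy()

    def allele_layout(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Flatten to one column per sample x allele.

        Returns the genes x (2 * n_samples) count matrix with columns
        ``<sample>|a1`` then ``<sample>|a2`` and a matching column metadata
        frame (sample, allele, condition, clone, replicate).
        """
        blocks = []
        meta_rows = []
        for allele in ("a1", "a2"):
            block = self.counts[allele].copy()
            block.columns = [f"{s}|{allele}" for s in block.columns]
            blocks.append(block)
            for s in self.sample_ids:
                row = self.samples.loc[s]
                meta_rows.append(
                    {
                        "column": f"{s}|{allele}",
                        "sample": s,
                        "allele": allele,
                        "condition": row["condition"],
                        "clone": row["clone"],
                        "replicate": row["replicate"],
                    }
                )
        mat = pd.concat(blocks, axis=1)
        meta = pd.DataFrame(meta_rows).set_index("column")
        return mat, meta

    def subset_genes(self, genes) -> "AlleleCountTable":
        return AlleleCountTable(
            counts={k: v.loc[genes] for k, v in self.counts.items()},
            samples=self.samples.copy(),
            gene_info=None if self.gene_info is None else self.gene_info.loc[genes],
        )
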