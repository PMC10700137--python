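"""Synthetic allele-resolved datasets with known ground truth.

Emulates a hybrid (F1) knockout experiment of the kind used to study
regulators of biallelic expression: clonal cell lines from reciprocal
crosses (reference strain x CAST), wild-type and knockout conditions with
replicate RNA-seq, negative-binomial allelic counts with a planted effect
per gene category, SNP-assignment loss (only a fraction of reads are
allele-informative), X-inactivation with escapee genes in female clones,
allelic promoter methylation gain at silenced alleles, contact-matrix
enrichment at peak pairs, and per-cell allele detection.

Planted gene categories (the subscript names the allele that REMAINS
active after the knockout):

``control``
    biallelic, unaffected.
``bi_to_bi_down``
    biallelic, both alleles downregulated comparably.
``bi_to_mono_A1`` / ``bi_to_mono_A2``
    biallelic in WT; the other allele is silenced in KO.
``mono_A1_to_none`` / ``mono_A2_to_none``
    monoallelic in WT; the single active allele is silenced in KO.
``escapee`` / ``escapee_msl2_regulated``
    X-linked genes expressed from the inactive X of female clones; the
    regulated subset loses the Xi allele in KO.

Genes may additionally carry a parental-origin mode (imprinted-like or
random-monoallelic-like) that decides, per clone, which strain allele is
silenced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import AlleleCountTable

CATEGORIES = (
    "control",
    "bi_to_bi_down",
    "bi_to_mono_A1",
    "bi_to_mono_A2",
    "mono_A1_to_none",
    "mono_A2_to_none",
    "escapee",
    "escapee_msl2_regulated",
)

ORIGIN_MODES = ("none", "imprinted_maternal", "imprinted_paternal", "random_per_clone")

#: WT allelic share of the minor allele of a monoallelic gene.  Real
#: monoallelic genes retain a small assignable background (antisense reads,
#: residual mis-assignment); an exactly zero allele would make the
#: interaction contrast inestimable.
MONO_MINOR_SHARE = 0.03

AUTOSOMES = tuple(f"chr{i}" for i in range(1, 20))


@dataclass(frozen=True)
class CrossInfo:
    """One clonal line from an F1 cross.

    ``xi_allele`` names the inactive-X allele of a female clone (``"a1"`` or
    ``"a2"``); male clones must use ``None``.
    """

    clone_id: str
    maternal_strain: str
    paternal_strain: str
    sex: str  # "male" | "female"
    xi_allele: str | None = None

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")
        if self.maternal_strain == self.paternal_strain:
            raise ValueError("maternal and paternal strains must differ")
        if self.sex == "male" and self.xi_allele is not None:
            raise ValueError("xi_allele must be None for male clones")
        if self.xi_allele not in (None, "a1", "a2"):
            raise ValueError("xi_allele must be 'a1', 'a2' or None")

    def allele_of_strain(self, strain: str) -> str:
        # a2 is CAST by convention; a1 the reference strain
        return "a2" if strain == "CAST" else "a1"

    @property
    def maternal_allele(self) -> str:
        return self.allele_of_strain(self.maternal_strain)

    @property
    def paternal_allele(self) -> str:
        return "a1" if self.maternal_allele == "a2" else "a2"

    def parental_origin(self, allele: str) -> str:
        return "maternal" if allele == self.maternal_allele else "paternal"


#: The four clonal NPC lines of the motivating experiment: reciprocal male
#: crosses and female lines with reciprocal X inactivation (CAST Xi in
#: female CaBl; CAST Xa in 9sCa).
STUDY_CROSSES = (
    CrossInfo("male_CaBl", "CAST", "BL6", "male"),
    CrossInfo("male_BlCa", "BL6", "CAST", "male"),
    CrossInfo("female_CaBl", "CAST", "BL6", "female", xi_allele="a2"),
    CrossInfo("female_9sCa", "129S1", "CAST", "female", xi_allele="a1"),
)


@dataclass
class SimConfig:
    """Study-condition parameters for the count simulator.

    Defaults mirror the replicate structure and effect sizes of the
    motivating experiment: six replicates per condition, near-complete
    silencing (log2FC -3, beyond the -2 "complete loss" threshold) of the
    affected allele of monoallelic-transition genes, and a moderate
    biallelic downregulation (-0.7) for bi-to-bi-down genes.
    """

    n_genes_per_category: int = 300
    #: extra unchanged (control-category) genes emulating the genome-wide
    #: majority of non-regulated genes.  The motivating experiment found
    #: ~2,500 differential genes among >20,000 quantified (~12% changed);
    #: median-of-ratios normalization relies on that unchanged majority, and
    #: a panel dominated by planted effects would bias every fold change.
    n_background: int = 8000
    n_replicates: int = 6
    base_mean: float = 500.0
    dispersion: float = 0.05
    silencing_lfc: float = -3.0
    down_lfc: float = -0.7
    assign_rate: float = 0.25
    library_size_factors: np.ndarray | None = None
    crosses: tuple[CrossInfo, ...] = STUDY_CROSSES
    categories: tuple[str, ...] = CATEGORIES
    n_imprinted_maternal: int = 0
    n_imprinted_paternal: int = 0
    n_random_mono: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.base_mean <= 0:
            raise ValueError("base_mean must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not (0 < self.assign_rate <= 1):
            raise ValueError("assign_rate must lie in (0, 1]")
        if not (self.silencing_lfc <= self.down_lfc <= 0):
            raise ValueError("require silencing_lfc <= down_lfc <= 0")
        unknown = set(self.categories) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories: {sorted(unknown)}")


# ---------------------------------------------------------------------------
# truth construction
# ---------------------------------------------------------------------------

def _build_truth(config: SimConfig) -> pd.DataFrame:
    """Gene panel with planted category, origin mode and annotation."""
    rows = []

    def add(category: str, origin_mode: str, n: int):
        for _ in range(n):
            rows.append({"category": category, "origin_mode": origin_mode})

    for cat in config.categories:
        add(cat, "none", config.n_genes_per_category)
    if "control" in config.categories:
        add("control", "none", config.n_background)
    add("bi_to_mono_A1", "imprinted_maternal", config.n_imprinted_maternal)
    add("bi_to_mono_A1", "imprinted_paternal", config.n_imprinted_paternal)
    add("bi_to_mono_A1", "random_per_clone", config.n_random_mono)

    truth = pd.DataFrame(rows)
    truth.index = [f"g{i:05d}" for i in range(len(truth))]
    truth.index.name = "gene_id"

    is_x = truth["category"].str.startswith("escapee")
    chroms = np.where(
        is_x, "chrX", [AUTOSOMES[i % len(AUTOSOMES)] for i in range(len(truth))]
    )
    truth["chrom"] = chroms
    truth["tss"] = 100_000 + 10_000 * np.arange(len(truth))
    truth["strand"] = "+"

    # per-gene Xi expressed fraction for escapees
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 987_654)))
    xi_frac = rng.uniform(0.15, 0.45, size=len(truth))
    truth["xi_fraction"] = np.where(is_x, xi_frac, np.nan)
    return truth


def _gene_rng(seed: int, gene_index: int) -> np.random.Generator:
    # counter-based substream: adding genes never perturbs earlier genes
    return np.random.default_rng(np.random.SeedSequence((seed, gene_index)))


def _resolve_gene(
    truth_row: pd.Series, cross: CrossInfo, rng: np.random.Generator
) -> tuple[dict, dict, str | None]:
    """Return (WT allelic shares, KO log2FC per allele, silenced allele)."""
    cat = truth_row["category"]
    mode = truth_row["origin_mode"]
    shares = {"a1": 0.5, "a2": 0.5}
    lfc = {"a1": 0.0, "a2": 0.0}
    silenced = None

    if cat.startswith("escapee"):
        if cross.sex == "male":
            # single (maternal) X; unaffected by KO
            shares = {cross.maternal_allele: 1.0, cross.paternal_allele: 0.0}
            return shares, lfc, None
        xi = cross.xi_allele
        xa = "a1" if xi == "a2" else "a2"
        phi = float(truth_row["xi_fraction"])
        shares = {xi: phi, xa: 1.0 - phi}
        if cat == "escapee_msl2_regulated":
            silenced = xi
        return shares, lfc, silenced

    if cat == "bi_to_bi_down":
        lfc = {"a1": truth_row["down_lfc"], "a2": truth_row["down_lfc"]}
        return shares, lfc, None

    if cat in ("bi_to_mono_A1", "bi_to_mono_A2"):
        if mode == "none":
            silenced = "a2" if cat == "bi_to_mono_A1" else "a1"
        elif mode == "imprinted_maternal":
            silenced = cross.maternal_allele
        elif mode == "imprinted_paternal":
            silenced = cross.paternal_allele
        elif mode == "random_per_clone":
            silenced = "a1" if rng.random() < 0.5 else "a2"
        return shares, lfc, silenced

    if cat in ("mono_A1_to_none", "mono_A2_to_none"):
        major = "a1" if cat == "mono_A1_to_none" else "a2"
        minor = "a2" if major == "a1" else "a1"
        shares = {major: 1.0 - MONO_MINOR_SHARE, minor: MONO_MINOR_SHARE}
        silenced = major
        return shares, lfc, silenced

    return shares, lfc, None  # control


def expected_category(truth: pd.DataFrame, cross: CrossInfo) -> pd.Series:
    """The category each gene should be called in a given clone.

    For genes with a parental-origin mode the silenced strain-allele (and
    hence the A1/A2 subclass) depends on the clone's cross; this resolves it
    deterministically from the planted truth.
    """
    out = []
    for gid, row in truth.iterrows():
        cat = row["category"]
        mode = row["origin_mode"]
        if cat in ("bi_to_mono_A1", "bi_to_mono_A2") and mode != "none":
            if mode == "imprinted_maternal":
                silenced = cross.maternal_allele
            elif mode == "imprinted_paternal":
                silenced = cross.paternal_allele
            else:  # random_per_clone: replay the per-gene substream
                gi = truth.index.get_loc(gid)
                rng = _gene_rng(int(row["seed_root"]), gi)
                clone_idx = int(row[f"clone_index_{cross.clone_id}"])
                silenced = _replay_random_silenced(rng, clone_idx)
            cat = "bi_to_mono_A1" if silenced == "a2" else "bi_to_mono_A2"
        out.append(cat)
    return pd.Series(out, index=truth.index, name="expected_category")


def _replay_random_silenced(rng: np.random.Generator, clone_idx: int) -> str:
    for _ in range(clone_idx):
        rng.random()
    return "a1" if rng.random() < 0.5 else "a2"


# ---------------------------------------------------------------------------
# count sampling
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    if not np.any(pos):
        return out
    if alpha < 1e-12:
        out[pos] = rng.poisson(mu[pos])
    else:
        n = 1.0 / alpha
        p = n / (n + mu[pos])
        out[pos] = rng.negative_binomial(n, p)
    return out


def simulate_experiment(
    config: SimConfig,
) -> tuple[dict[str, AlleleCountTable], pd.DataFrame]:
    """Draw allele-resolved count tables for every clone in the config.

    Returns ``(tables, truth)`` where ``tables`` maps clone id to an
    :class:`AlleleCountTable` and ``truth`` records each gene's planted
    category, origin mode, per-clone silenced allele and annotation.

    For each gene, clone, condition and allele the allelic mean is
    ``base_mean * assign_rate * share * 2**lfc`` (lfc applied in KO only),
    scaled by the per-sample library size factor; unassigned reads with mean
    ``base_mean * (1 - assign_rate) * pooled_fold`` are added so the total
    always bounds the allelic sum.  Counts are NB with shared dispersion
    (variance = mu + alpha * mu^2).  A fixed seed gives byte-identical
    output; each gene has its own counter-based substream.
    """
    truth = _build_truth(config)
    truth["down_lfc"] = config.down_lfc
    truth["silencing_lfc"] = config.silencing_lfc
    truth["seed_root"] = config.seed

    n_rep = config.n_replicates
    n_samples = 2 * n_rep
    if config.library_size_factors is None:
        lib_sf = np.ones(n_samples)
    else:
        lib_sf = np.asarray(config.library_size_factors, dtype=float)
        if lib_sf.shape != (n_samples,):
            raise ValueError(
                f"library_size_factors must have length {n_samples} "
                "(WT then KO replicates)"
            )
        if np.any(lib_sf <= 0):
            raise ValueError("library size factors must be positive")

    conditions = ["WT"] * n_rep + ["KO"] * n_rep

    tables: dict[str, AlleleCountTable] = {}
    for clone_idx, cross in enumerate(config.crosses):
        sample_ids = [
            f"{cross.clone_id}_{cond}_r{(i % n_rep) + 1}"
            for i, cond in enumerate(conditions)
        ]
        samples = pd.DataFrame(
            {
                "clone": cross.clone_id,
                "condition": conditions,
                "replicate": [(i % n_rep) + 1 for i in range(n_samples)],
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
        is_ko = np.asarray([c == "KO" for c in conditions])

        a1 = np.zeros((len(truth), n_samples), dtype=np.int64)
        a2 = np.zeros_like(a1)
        tot = np.zeros_like(a1)
        silenced_col = []
        for gi, (gid, row) in enumerate(truth.iterrows()):
            rng = _gene_rng(config.seed, gi)
            # burn clone_idx uniforms so random_per_clone is replayable and
            # clones use distinct draws of the same substream
            shares, base_lfc, silenced = _resolve_gene(
                row, cross, _SkipAhead(rng, clone_idx)
            )
            lfc = dict(base_lfc)
            if silenced is not None:
                lfc[silenced] = lfc[silenced] + config.silencing_lfc
            fold = {a: np.where(is_ko, 2.0 ** lfc[a], 1.0) for a in ("a1", "a2")}
            mu_a1 = config.base_mean * config.assign_rate * shares["a1"] * fold["a1"]
            mu_a2 = config.base_mean * config.assign_rate * shares["a2"] * fold["a2"]
            pooled = shares["a1"] * fold["a1"] + shares["a2"] * fold["a2"]
            mu_un = config.base_mean * (1.0 - config.assign_rate) * pooled
            rng_c = np.random.default_rng(
                np.random.SeedSequence((config.seed, gi, clone_idx))
            )
            a1[gi] = _nb_draw(rng_c, mu_a1 * lib_sf, config.dispersion)
            a2[gi] = _nb_draw(rng_c, mu_a2 * lib_sf, config.dispersion)
            un = _nb_draw(rng_c, mu_un * lib_sf, config.dispersion)
            tot[gi] = a1[gi] + a2[gi] + un
            silenced_col.append(silenced if silenced is not None else "")
        truth[f"silenced_allele_{cross.clone_id}"] = silenced_col
        truth[f"clone_index_{cross.clone_id}"] = clone_idx

        counts = {
            "a1": pd.DataFrame(a1, index=truth.index, columns=sample_ids),
            "a2": pd.DataFrame(a2, index=truth.index, columns=sample_ids),
            "total": pd.DataFrame(tot, index=truth.index, columns=sample_ids),
        }
        gene_info = truth[["chrom", "tss", "strand"]].copy()
        tables[cross.clone_id] = AlleleCountTable(counts, samples, gene_info)
    return tables, truth


class _SkipAhead:
    """Wrap a Generator so the k-th clone uses the k-th uniform draw."""

    def __init__(self, rng: np.random.Generator, skip: int):
        self._rng = rng
        self._skip = skip
        self._used = False

    def random(self) -> float:
        if not self._used:
            for _ in range(self._skip):
                self._rng.random()
            self._used = True
        return self._rng.random()


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------

def simulate_methylation(
    truth: pd.DataFrame,
    cross: CrossInfo,
    coverage: int = 50,
    n_cpgs_per_gene: int = 12,
    span: int = 550,
    f_low: float = 0.05,
    f_high: float = 0.6,
    n_replicates: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-CpG allelic methylation counts around each gene's TSS.

    Active alleles (and both alleles of controls, in both conditions) are
    methylated at background frequency ``f_low``; the allele that is silenced
    in the knockout gains promoter methylation ``f_high`` in KO samples,
    emulating methylation appearing exclusively on the allele that lost
    CG-motif transcription-factor binding.  Methylated counts are
    Binomial(coverage, f), drawn per replicate (``n_replicates`` bisulfite
    libraries per condition; downstream testing pools them).
    """
    if coverage < 1:
        raise ValueError("coverage must be >= 1")
    if not (0 <= f_low <= 1 and 0 <= f_high <= 1):
        raise ValueError("methylation frequencies must lie in [0, 1]")
    sil_col = f"silenced_allele_{cross.clone_id}"
    if sil_col not in truth.columns:
        raise ValueError(f"truth lacks {sil_col}; simulate counts first")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 24_601)))
    rows = []
    offsets = np.linspace(-span // 2, span // 2, n_cpgs_per_gene).astype(int)
    for gid, row in truth.iterrows():
        silenced = row[sil_col]
        for off in offsets:
            pos = int(row["tss"]) + int(off)
            for condition in ("WT", "KO"):
                for allele in ("a1", "a2"):
                    f = (
                        f_high
                        if (condition == "KO" and allele == silenced)
                        else f_low
                    )
                    for rep in range(1, n_replicates + 1):
                        m = int(rng.binomial(coverage, f))
                        rows.append(
                            {
                                "chrom": row["chrom"],
                                "pos": pos,
                                "gene_id": gid,
                                "allele": allele,
                                "condition": condition,
                                "replicate": rep,
                                "count_methylated": m,
                                "count_unmethylated": coverage - m,
                            }
                        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

def simulate_contacts(
    peaks,
    n_bins: int,
    enrichment: float,
    baseline: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Symmetric binned contact matrix with planted peak-pair enrichment.

    Every bin pair gets ``baseline``; pairs where both bins contain at least
    one peak get ``baseline * enrichment``.  Optional symmetric Gaussian
    noise.
    """
    if n_bins < 20:
        raise ValueError("n_bins must be >= 20")
    if enrichment <= 0:
        raise ValueError("enrichment must be positive")
    peaks = np.asarray(list(peaks), dtype=int)
    if peaks.size and (peaks.min() < 0 or peaks.max() >= n_bins):
        raise ValueError("peak bins must lie in [0, n_bins)")
    mat = np.full((n_bins, n_bins), float(baseline))
    has_peak = np.zeros(n_bins, dtype=bool)
    has_peak[peaks] = True
    pair = np.outer(has_peak, has_peak)
    mat[pair] = baseline * enrichment
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, noise_sd, size=mat.shape)
        noise = (noise + noise.T) / 2.0
        mat = np.maximum(mat + noise, 0.0)
    return mat


# ---------------------------------------------------------------------------
# single cells
# ---------------------------------------------------------------------------

def simulate_cells(
    truth: pd.DataFrame,
    cross: CrossInfo,
    n_cells: int,
    detect_prob: float,
    condition: str = "WT",
    seed: int = 0,
):
    """Bernoulli per-cell allele detection for every gene.

    Expressed alleles are detected with probability ``detect_prob``;
    silenced alleles (WT share below the monoallelic background, or the
    planted silenced allele in KO) are never detected.
    """
    from .qc import CellAlleleExpression

    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    if not (0 < detect_prob <= 1):
        raise ValueError("detect_prob must lie in (0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 31_415)))
    genes = truth.index.to_list()
    sil_col = f"silenced_allele_{cross.clone_id}"
    counts = np.zeros((n_cells, len(genes), 2), dtype=np.int64)
    for gi, (gid, row) in enumerate(truth.iterrows()):
        shares, _, silenced = _resolve_gene(row, cross, _SkipAhead(rng, 0))
        if sil_col in truth.columns and row[sil_col]:
            silenced = row[sil_col]
        for ai, allele in enumerate(("a1", "a2")):
            expressed = shares[allele] > MONO_MINOR_SHARE
            if condition == "KO" and allele == silenced:
                expressed = False
            if expressed:
                counts[:, gi, ai] = rng.random(n_cells) < detect_prob
    return CellAlleleExpression(
        counts=counts,
        cell_ids=[f"cell{i:05d}" for i in range(n_cells)],
        gene_ids=genes,
    )
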