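"""End-to-end orchestration of the synthetic experiment and all analyses.

A run simulates (or loads) allele-resolved counts, fits the DE suite per
clone, categorizes genes, picks controls, classifies cross-clone
consistency, calls escapees in female clones, simulates and tests allelic
methylation, and runs copy-number QC.  Every stage's outputs are TSVs under
the output directory; a JSON manifest records seeds, thresholds and output
checksums so a run can be reproduced byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cross as cross_mod
from .categorize import Thresholds, assign_categories, compute_wt_allele_stats, select_controls
from .de import run_de_suite
from .epigenome import call_dml
from .qc import chromosome_cpm_flags
from .simulate import SimConfig, expected_category, simulate_experiment, simulate_methylation

log = logging.getLogger("allelic")


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0
    stages: tuple[str, ...] = (
        "simulate",
        "de",
        "categorize",
        "consistency",
        "escapees",
        "methylation",
        "qc",
    )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimConfig(**raw.get("sim", {}))
        thresholds = Thresholds(**raw.get("thresholds", {}))
        return cls(
            sim=sim,
            thresholds=thresholds,
            seed=int(raw.get("seed", 0)),
            stages=tuple(raw.get("stages", cls.stages)),
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the requested stages; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(df: pd.DataFrame, name: str, **kwargs):
        p = outdir / name
        df.to_csv(p, sep="\t", **kwargs)
        written.append(p)
        return p

    try:
        log.info("stage=simulate seed=%d", config.sim.seed)
        tables, truth = simulate_experiment(config.sim)
        save(truth, "truth.tsv")

        suites = {}
        calls = {}
        if "de" in config.stages or "categorize" in config.stages:
            for clone, table in tables.items():
                log.info("stage=de clone=%s", clone)
                suite = run_de_suite(table)
                suites[clone] = suite
                for mode in ("standard", "allele1", "allele2", "allele_specific"):
                    save(suite.frame(mode), f"de_{clone}_{mode}.tsv")

        if "categorize" in config.stages:
            for clone, table in tables.items():
                log.info("stage=categorize clone=%s", clone)
                suite = suites[clone]
                wt_stats = compute_wt_allele_stats(
                    table, suite.size_factors_allelic, config.thresholds.pseudocount
                )
                cc = assign_categories(suite, wt_stats, config.thresholds)
                try:
                    controls = select_controls(suite, config.thresholds, config.seed)
                    cc.loc[
                        cc.index.isin(controls) & (cc["category"] == "unclassified"),
                        "category",
                    ] = "control"
                except ValueError as exc:
                    log.warning("stage=categorize clone=%s controls skipped: %s", clone, exc)
                calls[clone] = cc
                save(cc, f"categories_{clone}.tsv")

        if "consistency" in config.stages and len(calls) >= 2:
            clone_ids = list(calls)
            crosses = {c.clone_id: c for c in config.sim.crosses}
            for i in range(len(clone_ids)):
                for j in range(i + 1, len(clone_ids)):
                    a, b = clone_ids[i], clone_ids[j]
                    log.info("stage=consistency pair=%s,%s", a, b)
                    res = cross_mod.classify_cross_clone_consistency(
                        calls[a],
                        calls[b],
                        crosses[a],
                        crosses[b],
                        cross_mod.lost_allele(suites[a], config.thresholds),
                        cross_mod.lost_allele(suites[b], config.thresholds),
                    )
                    save(res, f"consistency_{a}_vs_{b}.tsv")

        if "escapees" in config.stages:
            for cross in config.sim.crosses:
                if cross.xi_allele is None or cross.clone_id not in suites:
                    continue
                log.info("stage=escapees clone=%s", cross.clone_id)
                esc = cross_mod.identify_escapees(
                    tables[cross.clone_id], suites[cross.clone_id], cross,
                    config.thresholds,
                )
                save(esc, f"escapees_{cross.clone_id}.tsv")

        if "methylation" in config.stages:
            cross0 = config.sim.crosses[0]
            log.info("stage=methylation clone=%s", cross0.clone_id)
            meth = simulate_methylation(truth, cross0, seed=config.seed)
            save(meth, "methylation.tsv", index=False)
            wt = meth[meth["condition"] == "WT"]
            ko = meth[meth["condition"] == "KO"]
            dml = call_dml(wt, ko)
            save(dml, "dml.tsv", index=False)

        if "qc" in config.stages:
            clone0 = config.sim.crosses[0].clone_id
            log.info("stage=qc clone=%s", clone0)
            table = tables[clone0]
            cov_rows = []
            gene_chrom = table.gene_info["chrom"]
            for allele in ("a1", "a2"):
                per_chrom = (
                    table.counts[allele].sum(axis=1).groupby(gene_chrom).sum()
                )
                for chrom, count in per_chrom.items():
                    cov_rows.append(
                        {"chrom": chrom, "allele": allele, "count": int(count)}
                    )
            flags = chromosome_cpm_flags(pd.DataFrame(cov_rows))
            save(flags, "chromosome_cpm_flags.tsv")
    except Exception as exc:  # pragma: no cover - error path
        raise RuntimeError(f"pipeline aborted: {exc}") from exc

    manifest = {
        "seed": config.seed,
        "sim": {
            k: v
            for k, v in asdict(config.sim).items()
            if k not in ("crosses", "library_size_factors")
        },
        "crosses": [asdict(c) for c in config.sim.crosses],
        "thresholds": asdict(config.thresholds),
        "stages": list(config.stages),
        "outputs": {p.name: _sha256(p) for p in written},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
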