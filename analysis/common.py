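"""Shared study configuration for the numbered analysis scripts.

All scripts analyse the same seeded synthetic experiment: the four clonal
NPC lines (reciprocal male crosses, two females with reciprocal X
inactivation), 100 genes per planted category plus 60 imprinted-like and
60 random-monoallelic-like genes over a 2,000-gene unchanged background,
six replicates per condition.  Simulation is deterministic, and the fitted
DE suites are cached under scratch/ so later scripts do not refit.
"""

from __future__ import annotations

import pickle
from pathlib import Path

from allelic import SimConfig, STUDY_CROSSES, run_de_suite, simulate_experiment

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results" / "analysis"
SCRATCH = ROOT / "scratch"

SEED = 42

CONFIG = SimConfig(
    n_genes_per_category=100,
    n_background=2000,
    n_imprinted_maternal=60,
    n_random_mono=60,
    crosses=STUDY_CROSSES,
    seed=SEED,
)


def get_experiment():
    return simulate_experiment(CONFIG)


def get_suites():
    """Fit (or load cached) DE suites for every clone."""
    SCRATCH.mkdir(exist_ok=True)
    cache = SCRATCH / f"suites_seed{SEED}.pkl"
    if cache.exists():
        with open(cache, "rb") as fh:
            return pickle.load(fh)
    tables, truth = get_experiment()
    suites = {clone: run_de_suite(t) for clone, t in tables.items()}
    with open(cache, "wb") as fh:
        pickle.dump((tables, truth, suites), fh)
    return tables, truth, suites


def outdir() -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    return RESULTS
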