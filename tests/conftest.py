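import pandas as pd
import pytest

from allelic import CrossInfo, SimConfig, run_de_suite, simulate_experiment


@pytest.fixture(scope="session")
def male_cabl():
    return CrossInfo("male_CaBl", "CAST", "BL6", "male")


@pytest.fixture(scope="session")
def male_blca():
    return CrossInfo("male_BlCa", "BL6", "CAST", "male")


@pytest.fixture(scope="session")
def small_config(male_cabl):
    return SimConfig(
        n_genes_per_category=40,
        n_background=400,
        crosses=(male_cabl,),
        categories=(
            "control",
            "bi_to_bi_down",
            "bi_to_mono_A1",
            "bi_to_mono_A2",
            "mono_A1_to_none",
            "mono_A2_to_none",
        ),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return simulate_experiment(small_config)


@pytest.fixture(scope="session")
def small_table(small_experiment):
    tables, _ = small_experiment
    return tables["male_CaBl"]


@pytest.fixture(scope="session")
def small_truth(small_experiment):
    _, truth = small_experiment
    return truth


@pytest.fixture(scope="session")
def small_suite(small_table):
    return run_de_suite(small_table)


def make_suite_frames(genes, **cols):
    """Build a DESuiteResult-like object from explicit per-mode columns.

    ``cols`` maps '<mode>_<field>' to a list; unspecified fields get
    benign defaults.
    """
    import numpy as np

    from allelic.de import DESuiteResult, adjust_bh

    n = len(genes)
    frames = {}
    for mode in ("standard", "allele1", "allele2", "allele_specific"):
        frame = pd.DataFrame(
            {
                "base_mean": cols.get(f"{mode}_base_mean", [100.0] * n),
                "log2fc": cols.get(f"{mode}_log2fc", [0.0] * n),
                "se": cols.get(f"{mode}_se", [0.1] * n),
                "p": cols.get(f"{mode}_p", [1.0] * n),
                "tested": True,
            },
            index=pd.Index(genes, name="gene_id"),
        )
        if f"{mode}_q" in cols:
            frame["q"] = cols[f"{mode}_q"]
        else:
            frame["q"] = adjust_bh(np.asarray(frame["p"], dtype=float))
        frames[mode] = frame
    return DESuiteResult(
        standard=frames["standard"],
        allele1=frames["allele1"],
        allele2=frames["allele2"],
        allele_specific=frames["allele_specific"],
        size_factors_total=None,
        size_factors_allelic=None,
    )
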