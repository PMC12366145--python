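import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from famdev.simulate import GeneratorParams, simulate_cohort

settings.register_profile(
    "suite", settings(deadline=None, derandomize=True, max_examples=50,
                      suppress_health_check=[HealthCheck.too_slow]))
settings.load_profile("suite")


@pytest.fixture(scope="session")
def sim_cohort():
    """Medium simulated cohort under default study conditions."""
    params = GeneratorParams(n_families=500, seed=7)
    cohort, truth = simulate_cohort(params)
    return cohort, truth


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no planted effects and no ascertainment."""
    params = GeneratorParams(n_families=800, seed=11, ascertainment=None,
                             gene_model=[], carrier_rate_ptv=0.0,
                             carrier_rate_mis=0.0, missingness={})
    cohort, truth = simulate_cohort(params)
    return cohort, truth


def write_tsv(path, header, rows):
    lines = ["\t".join(header)] + ["\t".join(str(c) for c in r) for r in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def trio_pedigree(tmp_path):
    header = ["family_id", "individual_id", "father_id", "mother_id", "sex",
              "affected", "age_years", "cohort"]
    rows = [
        ["FAM1", "FAM1.p", "FAM1.fa", "FAM1.mo", "male", "true", "8", "korean"],
        ["FAM1", "FAM1.s", "FAM1.fa", "FAM1.mo", "female", "false", "11", "korean"],
        ["FAM1", "FAM1.fa", "0", "0", "male", "false", "41", "korean"],
        ["FAM1", "FAM1.mo", "0", "0", "female", "false", "39", "korean"],
    ]
    return write_tsv(tmp_path / "ped.tsv", header, rows)
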