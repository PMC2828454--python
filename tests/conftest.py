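import numpy as np
import pytest

from pncca import (
    preprocess,
    simulate_genotypes,
    simulate_longitudinal,
    summarize,
    tiny_design,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small signal-bearing cohort run through preprocessing."""
    design = tiny_design(signal=True, n_subjects=80, q_snps=30, seed=42)
    G = simulate_genotypes(design)
    records, truth = simulate_longitudinal(design, G)
    records, G, report = preprocess(records, G, seed=7)
    return {"design": design, "G": G, "records": records, "truth": truth, "report": report}


@pytest.fixture(scope="session")
def tiny_summaries(tiny_cohort):
    covs = {p: ["trt", "sex"] for p in tiny_cohort["records"]["phenotype"].unique()}
    return summarize(tiny_cohort["records"], covariates=covs)
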