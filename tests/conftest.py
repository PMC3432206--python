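import numpy as np
import pytest

from snprisk import (
    SimulationConfig,
    assign_phenotypes,
    sample_case_control,
    simulate_genotypes,
    split_train_test,
)


def make_case_control(
    n_snps=60,
    cohort=8000,
    causal=None,
    alpha=-1.2,
    seed=0,
    ld_rho=0.0,
    n_cases=400,
    n_controls=420,
    maf_range=(0.05, 0.5),
):
    """Simulated case-control sample with known truth, for reuse in tests."""
    cfg = SimulationConfig(
        n_snps=n_snps,
        cohort_size=cohort,
        maf_range=maf_range,
        ld_rho=ld_rho,
        causal_effects=causal or {},
        baseline_log_odds=alpha,
        seed=seed,
    )
    ds = assign_phenotypes(simulate_genotypes(cfg), cfg)
    return cfg, ds, sample_case_control(ds, n_cases, n_controls, seed=seed + 1)


@pytest.fixture(scope="session")
def signal_sample():
    """Case-control sample with four planted causal SNPs."""
    causal = {5: 0.5, 20: 0.45, 35: -0.5, 50: 0.55}
    cfg, cohort, sample = make_case_control(causal=causal, seed=11)
    return cfg, cohort, sample


@pytest.fixture(scope="session")
def signal_split(signal_sample):
    _, _, sample = signal_sample
    train, test = split_train_test(sample, (260, 270), seed=3)
    return train, test


@pytest.fixture(scope="session")
def null_sample():
    """Case-control sample with no causal SNPs."""
    cfg, cohort, sample = make_case_control(causal={}, alpha=-1.0, seed=29)
    return cfg, cohort, sample
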