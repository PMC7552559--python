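import numpy as np
import pytest

from telomr.simulate import (SimulationConfig, SNPSpec, calibration_config,
                             simulate_cohort)


@pytest.fixture(scope="session")
def strong_cohort():
    """600/600 cohort with two strong instruments, a weak SNP, a rare SNP and
    a monomorphic SNP; linear causal effect. Shared read-only across tests."""
    cfg = SimulationConfig(
        n_cases=600,
        n_controls=600,
        snps=(
            SNPSpec("iv_a", 0.30, delta=-0.30),
            SNPSpec("iv_b", 0.25, delta=-0.30),
            SNPSpec("null_snp", 0.40, delta=0.0),
            SNPSpec("rare_snp", 0.01),
            SNPSpec("mono_snp", 0.0),
        ),
        exposure_mean=0.0,
        exposure_sd=0.6,
        causal_shape="linear",
        theta=0.3,
        seed=202,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def linear_truth_cohort():
    """Large no-covariate cohort under a linear causal effect (theta = 0.3)."""
    return simulate_cohort(
        calibration_config(5000, 5000, causal_shape="linear", theta=0.3, seed=77)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(915)
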