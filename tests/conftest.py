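import numpy as np
import pandas as pd
import pytest

from mrchain import SimulationConfig, simulate_study


def make_records(rows):
    """Canonical summary-stats frame from (snp, chr, pos, ea, oa, eaf, beta, se, p, n)."""
    return pd.DataFrame(
        rows, columns=["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]
    )


@pytest.fixture
def toy_records():
    return make_records(
        [
            ("rs1", "1", 1_000_000, "A", "G", 0.30, 0.10, 0.020, 1e-8, 5000),
            ("rs2", "2", 2_000_000, "C", "T", 0.45, -0.08, 0.015, 1e-7, 5000),
            ("rs3", "3", 3_000_000, "G", "A", None, 0.05, 0.010, 1e-6, 5000),
        ]
    )


@pytest.fixture
def random_records():
    rng = np.random.default_rng(42)
    n = 100
    alleles = [("A", "G"), ("C", "T"), ("G", "C"), ("T", "A")]
    rows = []
    for i in range(n):
        ea, oa = alleles[i % 4]
        rows.append(
            (
                f"rs{i}",
                str(1 + i % 22),
                int(rng.integers(1, 10**8)),
                ea,
                oa,
                float(rng.uniform(0.01, 0.99)) if i % 5 else None,
                float(rng.normal(0, 0.1)),
                float(rng.uniform(0.001, 0.05)),
                float(rng.uniform(1e-12, 1.0)),
                int(rng.integers(1000, 500_000)),
            )
        )
    return make_records(rows)


#: Conditions of the synthetic chain scenario used across mediation /
#: recovery tests: three cohorts of 5,000, 50 strong instruments each for
#: exposure and mediator, a 10% outcome prevalence, and the causal chain
#: theta_xm=0.3, theta_my=0.4, theta_xy=0.1.
CHAIN_KWARGS = dict(
    n_exposure=5000,
    n_mediator=5000,
    n_outcome=5000,
    m_snps=100,
    n_causal=50,
    n_causal_mediator=50,
    h2_exposure=0.6,
    h2_mediator=0.6,
    theta_xm=0.3,
    theta_my=0.4,
    theta_xy=0.1,
    outcome_prevalence=0.10,
)


@pytest.fixture(scope="session")
def chain_study():
    return simulate_study(SimulationConfig(**CHAIN_KWARGS, seed=12345))
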