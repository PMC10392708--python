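import numpy as np
import pandas as pd
import pytest

from tilscore import ExpressionMatrix, SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    """A compact cohort: two small overlapping panels, 13 cell types."""
    return SynthConfig(n_samples=40, n_endog_a=80, n_endog_b=70, n_common=30,
                       n_hk_a=6, n_hk_b=6, markers_per_type=3, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def efron_loglik_reference(beta, times, events, x) -> float:
    """Independent direct evaluation of the Efron-tie Cox partial log-likelihood."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    x = np.asarray(x, dtype=float)
    ll = 0.0
    for t in np.unique(times[events == 1]):
        D = np.where((times == t) & (events == 1))[0]
        R = np.where(times >= t)[0]
        d = len(D)
        ll += beta * x[D].sum()
        s_risk = np.exp(beta * x[R]).sum()
        s_tied = np.exp(beta * x[D]).sum()
        for l in range(d):
            ll -= np.log(s_risk - (l / d) * s_tied)
    return ll


def make_matrix(values, genes=None, samples=None, probe_class=None,
                scale="normalized", panel_id="P") -> ExpressionMatrix:
    """Helper to build small expression matrices in tests."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    pc = pd.Series(probe_class or ["endogenous"] * len(genes), index=genes)
    return ExpressionMatrix(values=pd.DataFrame(values, index=genes, columns=samples),
                            probe_class=pc, panel_id=panel_id, scale=scale)
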