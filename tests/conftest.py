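import numpy as np
import pandas as pd
import pytest

from mhshock import metareg
from mhshock.synthdata import (SyntheticConfig, generate_baseline,
                               generate_indicators, generate_surveys)


@pytest.fixture(scope="session")
def small_cfg():
    return SyntheticConfig(n_locations=6, n_studies=40, seed=101, n_draws=200)


@pytest.fixture(scope="session")
def sim_data(small_cfg):
    indicators = generate_indicators(small_cfg)
    surfaces, populations, severity = generate_baseline(small_cfg)
    studies, truth = generate_surveys(small_cfg, indicators, surfaces)
    return {"indicators": indicators, "surfaces": surfaces,
            "populations": populations, "severity": severity,
            "studies": studies, "truth": truth}


@pytest.fixture(scope="session")
def mdd_fits(sim_data):
    """Both meta-regression steps fitted on the MDD slice of the shared
    simulated dataset."""
    studies = sim_data["studies"]
    frame = metareg.build_model_frame(studies[studies["disorder"] == "MDD"],
                                      sim_data["indicators"])
    step1 = metareg.fit_indicator_model(frame, disorder="MDD", n_draws=200,
                                        seed=7)
    index = metareg.compute_impact_index(
        frame[list(metareg.INDICATOR_NAMES)], step1, per_draw=False)
    step2 = metareg.fit_final_model(frame, index, disorder="MDD", n_draws=200,
                                    seed=8)
    return {"frame": frame, "step1": step1, "index": index, "step2": step2}


def make_coeffs(values, roles, pvalues=None, n_draws=1000, draws=None,
                re_var_intercept=0.0, re_var_indicator=0.0):
    """Hand-built coefficient set with constant (or supplied) draws, for
    exercising index/shift arithmetic at known point values."""
    names = list(values)
    beta = np.array([values[n] for n in names], dtype=float)
    if draws is None:
        draws = np.tile(beta, (n_draws, 1))
    pv = np.array([pvalues.get(n, 0.001) if pvalues else 0.001 for n in names])
    return metareg.CoefficientSet(
        disorder="MDD", names=names, beta=beta,
        cov=np.eye(len(names)) * 1e-12, draws=np.asarray(draws, float),
        re_var_intercept=re_var_intercept, re_var_indicator=re_var_indicator,
        roles=dict(roles), pvalues=pv, loglik=0.0, aic=0.0, n_obs=0)
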