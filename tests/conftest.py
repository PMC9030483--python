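import numpy as np
import pandas as pd
import pytest

from rppdecay import (
    CohortTable,
    GeneratorConfig,
    ModelParams,
    fit_model,
    prepare_observations,
    simulate_cohort,
)
from rppdecay.pipeline import config_from_params


def make_cohort(volumes: dict[str, dict[int, float]], bmi: dict[str, float] | None = None):
    """Build a small cohort table from {patient: {pod: volume}} by hand."""
    pids = sorted(volumes)
    bmi = bmi or {}
    patients = pd.DataFrame(
        {
            "patient_id": pids,
            "age": 66.0,
            "weight_kg": 83.0,
            "height_cm": 177.0,
            "bmi": [bmi.get(p, 26.5) for p in pids],
            "bmi_group": [
                "normal" if bmi.get(p, 26.5) < 25
                else ("overweight" if bmi.get(p, 26.5) < 30 else "obese")
                for p in pids
            ],
            "op_duration_min": 300.0,
            "insufflation_min": 280.0,
            "total_gas_L": 970.0,
            "decompressed": True,
        }
    )
    rows = [
        {"patient_id": p, "pod": pod, "volume_mL": v, "censored": v == 0}
        for p in pids
        for pod, v in sorted(volumes[p].items())
    ]
    return CohortTable(patients, pd.DataFrame(rows), followup_rule="complete")


@pytest.fixture(scope="session")
def truth_params() -> ModelParams:
    """The default calibration viewed as model parameters."""
    cfg = GeneratorConfig()
    return ModelParams(
        mu_alpha=cfg.pop_intercept_mean,
        mu_beta=cfg.pop_slope_mean,
        sigma_alpha=cfg.sd_intercept,
        sigma_beta=cfg.sd_slope,
        rho=cfg.intercept_slope_corr,
        delta=cfg.group_effect("overweight"),
        eta=cfg.group_effect("obese"),
        sigma_y=cfg.residual_sd,
    )


@pytest.fixture(scope="session")
def small_fit(truth_params):
    """One reduced-size fit shared across tests that need real draws."""
    cfg = config_from_params(truth_params, 80, seed=11)
    table = simulate_cohort(cfg)
    obs = prepare_observations(table, cfg.detection_limit_mL)
    draws = fit_model(
        obs, seed=11, n_warmup=600, n_samples=1200, check_convergence=False
    )
    return draws


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(7)
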