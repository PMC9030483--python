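"""Posterior-predictive credible intervals for a new patient's RPP volume.

For each posterior draw of the population parameters, a new patient's
(intercept, slope) pair is simulated from the random-effects law,
residual noise added, and the result back-transformed to mL with the
zero floor.  Quantiles over all simulated volumes give the credible
(prediction) interval; tabulating them over BMI strata and PODs yields
the clinician-facing reference table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import BmiGroup
from .fit import PosteriorDraws

__all__ = ["CredibleTable", "predictive_interval", "make_credible_table"]

DEFAULT_PODS = (3, 4, 5, 6, 7)


@dataclass(frozen=True)
class CredibleTable:
    """Predictive interval grid keyed by (bmi_group, pod), volumes in mL."""

    frame: pd.DataFrame
    level: float

    def __post_init__(self) -> None:
        required = {"bmi_group", "pod", "lower_mL", "upper_mL"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"credible table missing columns: {sorted(missing)}")
        if (self.frame["lower_mL"] < 0).any() or (self.frame["upper_mL"] < 0).any():
            raise ValueError("credible limits must be non-negative")
        if (self.frame["lower_mL"] > self.frame["upper_mL"]).any():
            raise ValueError("lower_mL must not exceed upper_mL")

    def lookup(self, group: BmiGroup | str, pod: int) -> tuple[float, float]:
        g = BmiGroup(group).value
        row = self.frame[(self.frame["bmi_group"] == g) & (self.frame["pod"] == pod)]
        if row.empty:
            raise KeyError(f"no row for ({g}, POD {pod})")
        return float(row["lower_mL"].iloc[0]), float(row["upper_mL"].iloc[0])

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.frame.to_csv(path, index=False)
        return path


def _simulate_predictive_volumes(
    draws: PosteriorDraws,
    group: BmiGroup | str,
    pod: int,
    n_total: int,
    rng: np.random.Generator,
) -> np.ndarray:
    group = BmiGroup(group)
    params = draws.param_matrix()
    n_draws = len(params)
    per_draw = max(1, int(np.ceil(n_total / n_draws)))
    rep = lambda col: np.repeat(params[col].to_numpy(), per_draw)  # noqa: E731
    mu_a, mu_b = rep("mu_alpha"), rep("mu_beta")
    sa, sb, rho, sy = rep("sigma_alpha"), rep("sigma_beta"), rep("rho"), rep("sigma_y")
    if group is BmiGroup.NORMAL:
        g = rep("gamma") if "gamma" in params.columns else 0.0
    elif group is BmiGroup.OVERWEIGHT:
        g = rep("delta")
    else:
        g = rep("eta")
    n = len(mu_a)
    z1, z2, z3 = rng.standard_normal((3, n))
    alpha = mu_a + sa * z1
    beta = mu_b + sb * (rho * z1 + np.sqrt(np.clip(1.0 - rho**2, 0.0, None)) * z2)
    y = alpha + beta * (pod - 3.0) + g + sy * z3
    return np.maximum(np.expm1(y), 0.0)


def predictive_interval(
    draws: PosteriorDraws,
    group: BmiGroup | str,
    pod: int,
    level: float = 0.95,
    *,
    n_total: int = 400_000,
    seed: int = 0,
    force: bool = False,
) -> tuple[float, float]:
    """Central predictive interval (in mL) for a new patient of *group* at *pod*.

    Refuses to use a non-converged posterior unless ``force=True``.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must lie in (0, 1), got {level!r}")
    if not draws.converged and not force:
        raise RuntimeError(
            "posterior draws flagged as non-converged; pass force=True to override"
        )
    rng = np.random.default_rng(seed)
    volumes = _simulate_predictive_volumes(draws, group, pod, n_total, rng)
    lo, hi = np.quantile(volumes, [(1 - level) / 2, (1 + level) / 2])
    return float(lo), float(hi)


def make_credible_table(
    draws: PosteriorDraws,
    pods: tuple[int, ...] = DEFAULT_PODS,
    level: float = 0.95,
    *,
    n_total: int = 400_000,
    seed: int = 0,
    force: bool = False,
    allow_extrapolation: bool = False,
) -> CredibleTable:
    """Predictive interval for every (BMI group, POD) combination.

    Days before the first scan (POD < 3) are outside the fitted range
    and are rejected unless ``allow_extrapolation=True``.
    """
    pods = tuple(int(p) for p in pods)
    if not allow_extrapolation and any(p < 3 for p in pods):
        raise ValueError(
            "PODs before day 3 extrapolate outside the fitted design; "
            "pass allow_extrapolation=True to override"
        )
    rows = []
    ss = np.random.SeedSequence(seed)
    for group in BmiGroup:
        for pod in pods:
            sub_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            lo, hi = predictive_interval(
                draws, group, pod, level, n_total=n_total, seed=sub_seed, force=force
            )
            rows.append(
                {"bmi_group": group.value, "pod": pod, "lower_mL": lo, "upper_mL": hi}
            )
    return CredibleTable(frame=pd.DataFrame(rows), level=level)
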