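"""Region-of-practical-equivalence (ROPE) decisions on posterior draws.

A parameter is judged against a region of +/- 0.1 reference standard
deviations around zero (the Kruschke-Liddell convention): if the 95%
highest-density interval (HDI) lies entirely outside the region the
null is rejected; entirely inside, practical equivalence is accepted;
otherwise the test is undecided.  The reference SD defaults to the SD
of the pooled non-censored log-shifted volumes (the "general
population" spread on the model scale).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import arviz as az
import numpy as np

from .fit import PosteriorDraws
from .model import TransformedObservation

__all__ = ["RopeDecision", "RopeResult", "rope_test", "reference_sd"]

ROPE_HALF_WIDTH_SDS = 0.1


class RopeDecision(str, enum.Enum):
    REJECT_NULL = "reject_null"
    ACCEPT_EQUIVALENCE = "accept_equivalence"
    UNDECIDED = "undecided"


@dataclass(frozen=True)
class RopeResult:
    parameter: str
    hdi_low: float
    hdi_high: float
    rope_low: float
    rope_high: float
    decision: RopeDecision


def reference_sd(obs: list[TransformedObservation]) -> float:
    """SD of all non-censored transformed volumes, pooled across PODs."""
    y = np.array([o.y for o in obs if not o.censored])
    if len(y) < 2:
        raise ValueError("need >= 2 non-censored observations for a reference SD")
    return float(np.std(y, ddof=1))


def decide(hdi_low: float, hdi_high: float, rope_low: float, rope_high: float) -> RopeDecision:
    """The HDI-vs-ROPE decision rule on explicit interval endpoints."""
    if hdi_high < rope_low or hdi_low > rope_high:
        return RopeDecision.REJECT_NULL
    if rope_low <= hdi_low and hdi_high <= rope_high:
        return RopeDecision.ACCEPT_EQUIVALENCE
    return RopeDecision.UNDECIDED


def rope_test(
    draws: PosteriorDraws,
    parameter: str,
    reference_sd: float,
    *,
    hdi_prob: float = 0.95,
) -> RopeResult:
    """HDI + ROPE equivalence test for one parameter of the posterior."""
    if parameter not in draws.param_names:
        raise KeyError(
            f"unknown parameter {parameter!r}; available: {draws.param_names}"
        )
    if reference_sd <= 0:
        raise ValueError("reference_sd must be strictly positive")
    samples = draws.stacked(parameter)
    if np.ptp(samples) == 0:
        hdi_low = hdi_high = float(samples[0])  # point-mass posterior
    else:
        hdi = az.hdi(draws.idata.posterior[parameter], hdi_prob=hdi_prob)[parameter]
        hdi_low, hdi_high = (float(v) for v in hdi.to_numpy())
    half = ROPE_HALF_WIDTH_SDS * reference_sd
    return RopeResult(
        parameter=parameter,
        hdi_low=hdi_low,
        hdi_high=hdi_high,
        rope_low=-half,
        rope_high=half,
        decision=decide(hdi_low, hdi_high, -half, half),
    )
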