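"""The hierarchical censored log-linear decay model.

Response transform
------------------
Volumes are shifted one unit right before the log so that a volume of
0 mL maps to y = 0:  y = log(V + 1).  The day covariate is centered at
the first scan, x = POD - 3, so the patient intercept is the expected
log-volume at the first CT.

Observation model
-----------------
For observation i of patient j,

    y_i ~ Normal(alpha_j + beta_j * x_i + g(BMI group_i), sigma_y^2)

with correlated patient effects

    (alpha_j, beta_j) ~ BVN((mu_alpha, mu_beta),
                            [[sa^2, rho sa sb], [rho sa sb, sb^2]]).

A recorded 0 mL is a left-censored reading: the latent y is only known
to lie at or below c = log(detection limit + 1).

Two likelihoods are provided.  :func:`censored_loglik` conditions on the
patient effects (the literal per-observation law above).
:func:`marginal_loglik` integrates the patient effects out analytically:
each patient's scan vector is multivariate normal, and censored
components contribute the normal CDF of their conditional law given the
uncensored components.  The marginal form is what the MCMC fit uses —
it reduces the posterior to the population parameters only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg, stats
from scipy.special import log_ndtr

from .cohort import BmiGroup, CohortTable

__all__ = [
    "log_shift",
    "inverse_log_shift",
    "ModelParams",
    "RandomEffects",
    "TransformedObservation",
    "prepare_observations",
    "censored_loglik",
    "marginal_loglik",
    "closed_form_predictive",
    "draw_new_patient_y",
    "ObservationSet",
]

_LOG_2PI = np.log(2.0 * np.pi)


def log_shift(volume_mL):
    """Shifted log transform y = log(V + 1); maps the minimum (0 mL) to 0."""
    v = np.asarray(volume_mL, dtype=float)
    if np.any(v < 0):
        raise ValueError("volumes must be non-negative")
    out = np.log1p(v)
    return float(out) if np.isscalar(volume_mL) else out


def inverse_log_shift(y):
    """Back-transform V = max(exp(y) - 1, 0)."""
    out = np.maximum(np.expm1(np.asarray(y, dtype=float)), 0.0)
    return float(out) if np.isscalar(y) else out


@dataclass(frozen=True)
class ModelParams:
    """Population parameters of the decay model.

    ``mu_alpha`` is the mean log-volume at POD 3 for the reference
    stratum, ``mu_beta`` the mean per-day decay slope.  ``gamma``,
    ``delta``, ``eta`` are the normal-weight / overweight / obese fixed
    effects; under the default reference coding gamma == 0 and mu_alpha
    is the normal-weight POD-3 mean.
    """

    mu_alpha: float
    mu_beta: float
    sigma_alpha: float
    sigma_beta: float
    rho: float
    delta: float = 0.0
    eta: float = 0.0
    gamma: float = 0.0
    sigma_y: float = 1.0

    def __post_init__(self) -> None:
        vals = [
            self.mu_alpha, self.mu_beta, self.sigma_alpha, self.sigma_beta,
            self.rho, self.delta, self.eta, self.gamma, self.sigma_y,
        ]
        if not all(np.isfinite(vals)):
            raise ValueError(f"non-finite model parameter in {self}")
        for name in ("sigma_alpha", "sigma_beta", "sigma_y"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must lie in [-1, 1], got {self.rho}")

    def group_effect(self, group: BmiGroup | str) -> float:
        group = BmiGroup(group)
        return {
            BmiGroup.NORMAL: self.gamma,
            BmiGroup.OVERWEIGHT: self.delta,
            BmiGroup.OBESE: self.eta,
        }[group]

    def random_effects_cov(self) -> np.ndarray:
        off = self.rho * self.sigma_alpha * self.sigma_beta
        return np.array(
            [[self.sigma_alpha**2, off], [off, self.sigma_beta**2]]
        )

    def replace(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class RandomEffects:
    """Per-patient (intercept, slope) pairs aligned with patient indices."""

    alpha: np.ndarray
    beta: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "alpha", np.asarray(self.alpha, dtype=float))
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float))
        if self.alpha.shape != self.beta.shape:
            raise ValueError("alpha and beta must have the same shape")


@dataclass(frozen=True)
class TransformedObservation:
    """One model-ready scan: y = log(V+1), x = POD - 3, censoring status.

    For a censored row ``y`` equals ``censor_bound`` and is interpreted
    as "at or below the bound", not as an exact value.
    """

    patient_index: int
    y: float
    x_day: float
    bmi_group: BmiGroup
    censored: bool
    censor_bound: float


def prepare_observations(
    table: CohortTable, detection_limit_mL: float = 0.05
) -> list[TransformedObservation]:
    """Transform a cohort's measurement rows into model observations.

    Patient indices follow the row order of ``table.patients``.  Zero
    volumes become left-censored observations with bound
    ``log(detection_limit + 1)``.
    """
    if detection_limit_mL <= 0:
        raise ValueError("detection_limit_mL must be strictly positive")
    index_of = {pid: i for i, pid in enumerate(table.patients["patient_id"])}
    group_of = {
        pid: BmiGroup(g)
        for pid, g in zip(table.patients["patient_id"], table.patients["bmi_group"])
    }
    bound = float(np.log1p(detection_limit_mL))
    obs = []
    for row in table.measurements.itertuples(index=False):
        if row.patient_id not in index_of:
            raise ValueError(f"measurement references unknown patient {row.patient_id!r}")
        censored = bool(row.censored)
        obs.append(
            TransformedObservation(
                patient_index=index_of[row.patient_id],
                y=bound if censored else float(np.log1p(row.volume_mL)),
                x_day=float(row.pod - 3),
                bmi_group=group_of[row.patient_id],
                censored=censored,
                censor_bound=bound,
            )
        )
    return obs


def censored_loglik(
    params: ModelParams,
    re: RandomEffects,
    obs: list[TransformedObservation],
) -> float:
    """Log-likelihood conditional on the patient random effects.

    Non-censored rows contribute the normal log-density at y; censored
    rows the log lower-tail probability at their bound.  The mean of row
    i is ``alpha_j + beta_j * x + group effect``.
    """
    n_re = len(re.alpha)
    total = 0.0
    sy = params.sigma_y
    for o in obs:
        j = o.patient_index
        if not 0 <= j < n_re:
            raise ValueError(f"no random-effect pair for patient index {j}")
        mean = re.alpha[j] + re.beta[j] * o.x_day + params.group_effect(o.bmi_group)
        if o.censored:
            total += log_ndtr((o.censor_bound - mean) / sy)
        else:
            z = (o.y - mean) / sy
            total += -0.5 * (_LOG_2PI + z * z) - np.log(sy)
    if not np.isfinite(total) and np.isnan(total):
        raise ValueError("non-finite parameter or observation in censored_loglik")
    return float(total)


# ---------------------------------------------------------------------------
# marginal likelihood with the random effects integrated out


class ObservationSet:
    """Observations grouped by (day pattern, censoring pattern) for fast
    repeated marginal-likelihood evaluation.

    Patients sharing the same scan days and the same censoring mask share
    one scan-vector covariance; within a bucket everything vectorizes.
    """

    def __init__(self, obs: list[TransformedObservation]):
        if not obs:
            raise ValueError("empty observation collection")
        per_patient: dict[int, list[TransformedObservation]] = {}
        for o in obs:
            per_patient.setdefault(o.patient_index, []).append(o)
        self.n_patients = len(per_patient)
        self.n_obs = len(obs)
        buckets: dict[tuple, dict] = {}
        for j, rows in per_patient.items():
            rows = sorted(rows, key=lambda o: o.x_day)
            x = tuple(o.x_day for o in rows)
            cens = tuple(o.censored for o in rows)
            groups = {o.bmi_group for o in rows}
            if len(groups) != 1:
                raise ValueError(f"patient {j} has inconsistent BMI groups")
            key = (x, cens)
            b = buckets.setdefault(key, {"y": [], "group": [], "bound": [], "pid": []})
            b["y"].append([o.y for o in rows])
            b["bound"].append([o.censor_bound for o in rows])
            b["group"].append(groups.pop())
            b["pid"].append(j)
        code = {BmiGroup.NORMAL: 0, BmiGroup.OVERWEIGHT: 1, BmiGroup.OBESE: 2}
        self.buckets = []
        for (x, cens), b in sorted(buckets.items()):
            x = np.asarray(x)
            cens_mask = np.asarray(cens, dtype=bool)
            self.buckets.append(
                {
                    "x": x,
                    "cens": cens_mask,
                    "o_idx": np.flatnonzero(~cens_mask),
                    "m_idx": np.flatnonzero(cens_mask),
                    "Y": np.asarray(b["y"], dtype=float),
                    "bound": np.asarray(b["bound"], dtype=float),
                    "group": np.asarray([g.value for g in b["group"]]),
                    "group_code": np.asarray([code[g] for g in b["group"]]),
                    "pid": np.asarray(b["pid"]),
                }
            )

    def group_effect_vector(self, params: ModelParams, groups: np.ndarray) -> np.ndarray:
        out = np.empty(len(groups))
        for g in (BmiGroup.NORMAL, BmiGroup.OVERWEIGHT, BmiGroup.OBESE):
            out[groups == g.value] = params.group_effect(g)
        return out

    @property
    def group_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for b in self.buckets:
            for g, c in zip(*np.unique(b["group"], return_counts=True)):
                sizes[g] = sizes.get(g, 0) + int(c)
        return sizes


def _scan_cov(params: ModelParams, x: np.ndarray) -> np.ndarray:
    Z = np.column_stack([np.ones_like(x), x])
    return Z @ params.random_effects_cov() @ Z.T + params.sigma_y**2 * np.eye(len(x))


def marginal_loglik(
    params: ModelParams, obs: list[TransformedObservation] | ObservationSet
) -> float:
    """Log-likelihood with patient effects integrated out analytically.

    Per patient, the scan vector is multivariate normal; censored
    components contribute the (possibly multivariate) normal CDF of
    their conditional distribution given the uncensored components.
    """
    oset = obs if isinstance(obs, ObservationSet) else ObservationSet(obs)
    ge = np.array(
        [
            params.group_effect(BmiGroup.NORMAL),
            params.group_effect(BmiGroup.OVERWEIGHT),
            params.group_effect(BmiGroup.OBESE),
        ]
    )
    sa2 = params.sigma_alpha**2
    sb2 = params.sigma_beta**2
    sab = params.rho * params.sigma_alpha * params.sigma_beta
    sy2 = params.sigma_y**2
    total = 0.0
    for b in oset.buckets:
        x, o_idx, m_idx = b["x"], b["o_idx"], b["m_idx"]
        Y = b["Y"]
        k = len(x)
        # scan-vector covariance: sa^2 + sab (x_i + x_j) + sb^2 x_i x_j + sy^2 I
        sigma = sa2 + sab * (x[:, None] + x[None, :]) + sb2 * np.outer(x, x)
        sigma = sigma + sy2 * np.eye(k)
        mean_base = params.mu_alpha + params.mu_beta * x
        M = mean_base[None, :] + ge[b["group_code"]][:, None]
        if len(o_idx):
            Soo = sigma[np.ix_(o_idx, o_idx)]
            sign, logdet = np.linalg.slogdet(Soo)
            if sign <= 0:
                return -np.inf
            Soo_inv = np.linalg.inv(Soo)
            R = Y[:, o_idx] - M[:, o_idx]  # (n_p, k_o)
            quad = np.einsum("ij,jk,ik->i", R, Soo_inv, R)
            total += np.sum(-0.5 * (len(o_idx) * _LOG_2PI + logdet + quad))
            if len(m_idx):
                A = sigma[np.ix_(m_idx, o_idx)] @ Soo_inv  # (k_m, k_o)
                mu_c = M[:, m_idx] + R @ A.T  # (n_p, k_m)
                S_c = sigma[np.ix_(m_idx, m_idx)] - A @ sigma[np.ix_(o_idx, m_idx)]
        else:
            mu_c = M[:, m_idx]
            S_c = sigma[np.ix_(m_idx, m_idx)]
        if len(m_idx):
            bounds = b["bound"][:, m_idx]
            if len(m_idx) == 1:
                s = np.sqrt(S_c[0, 0])
                total += np.sum(log_ndtr((bounds[:, 0] - mu_c[:, 0]) / s))
            else:
                mvn = stats.multivariate_normal(mean=np.zeros(len(m_idx)), cov=S_c)
                for i in range(Y.shape[0]):
                    total += np.log(max(mvn.cdf(bounds[i] - mu_c[i]), 1e-300))
    return float(total)


def closed_form_predictive(
    params: ModelParams, group: BmiGroup | str, pod: int
) -> tuple[float, float]:
    """Normal law of y = log(V+1) for a NEW patient of *group* at *pod*.

    mean = mu_alpha + mu_beta (pod-3) + group effect;
    variance = sa^2 + 2 rho sa sb (pod-3) + sb^2 (pod-3)^2 + sy^2.
    """
    if pod < 0 or int(pod) != pod:
        raise ValueError(f"pod must be a non-negative integer, got {pod!r}")
    x = float(pod - 3)
    mean = params.mu_alpha + params.mu_beta * x + params.group_effect(group)
    sa, sb = params.sigma_alpha, params.sigma_beta
    variance = (
        sa**2 + 2.0 * params.rho * sa * sb * x + (sb * x) ** 2 + params.sigma_y**2
    )
    return float(mean), float(variance)


def draw_new_patient_y(
    params: ModelParams,
    group: BmiGroup | str,
    pod: int,
    size: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate y for new patients: draw (alpha, beta), add residual noise.

    Monte-Carlo counterpart of :func:`closed_form_predictive`.
    """
    chol = linalg.cholesky(params.random_effects_cov(), lower=True)
    z = rng.standard_normal((size, 2)) @ chol.T
    alpha = params.mu_alpha + z[:, 0]
    beta = params.mu_beta + z[:, 1]
    x = float(pod - 3)
    eps = params.sigma_y * rng.standard_normal(size)
    return alpha + beta * x + params.group_effect(group) + eps
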