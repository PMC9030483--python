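"""Descriptive layer: cohort summary table, POD ANOVA, correlations, zero fractions.

Conventions
-----------
* Quantiles use linear interpolation (the common "type 7" rule).
* A patient whose scans stopped because residual gas had already
  resolved (conditional follow-up) is imputed as 0 mL at later days for
  summary and zero-fraction purposes; a scan missing for any other
  reason stays missing.
* The one-way ANOVA compares scans across post-operative days,
  available-case, on the log-shifted scale by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable

__all__ = [
    "SummaryRow",
    "AnovaResult",
    "CorrelationMatrix",
    "volumes_at_pod",
    "summarize_cohort",
    "anova_rpp",
    "correlation_matrix",
    "zero_rpp_fraction",
]

#: patient-level variables included in summaries and correlation plots
DEMOGRAPHIC_VARS = [
    "age",
    "weight_kg",
    "height_cm",
    "bmi",
    "op_duration_min",
    "insufflation_min",
    "total_gas_L",
]


@dataclass(frozen=True)
class SummaryRow:
    variable: str
    n: int
    mean: float
    sd: float
    median: float
    iqr_low: float
    iqr_high: float


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float


@dataclass(frozen=True)
class CorrelationMatrix:
    variables: list[str]
    corr: pd.DataFrame
    pvalues: pd.DataFrame
    #: variables whose pairs are undefined (zero variance in complete cases)
    degenerate: list[str]


def volumes_at_pod(
    table: CohortTable, pod: int, *, resolved_as_zero: bool = True
) -> pd.Series:
    """Per-patient volume at *pod*, imputing resolved patients as 0 mL.

    Returns a float Series indexed by patient_id.  NaN marks patients
    with no information at *pod* (no scan and no earlier zero reading).
    """
    m = table.measurements
    at_pod = m[m["pod"] == pod].set_index("patient_id")["volume_mL"]
    out = at_pod.reindex(table.patients["patient_id"]).astype(float)
    if resolved_as_zero:
        prior = m[(m["pod"] < pod) & m["censored"]]
        resolved = out.index.isin(prior["patient_id"])
        out[np.asarray(resolved) & out.isna().to_numpy()] = 0.0
    return out


def _summary_row(variable: str, values: np.ndarray) -> SummaryRow:
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) == 0:
        raise ValueError(f"no observed values for variable {variable!r}")
    q25, q50, q75 = np.quantile(values, [0.25, 0.5, 0.75])  # linear interpolation
    return SummaryRow(
        variable=variable,
        n=len(values),
        mean=float(np.mean(values)),
        sd=float(np.std(values, ddof=1)) if len(values) > 1 else 0.0,
        median=float(q50),
        iqr_low=float(q25),
        iqr_high=float(q75),
    )


def summarize_cohort(
    table: CohortTable, *, resolved_as_zero: bool = True
) -> list[SummaryRow]:
    """Demographics plus per-POD RPP summaries (mean, SD, median, IQR).

    ``n`` counts available (non-missing) values per variable.
    """
    if table.n_patients == 0:
        raise ValueError("cannot summarize an empty cohort")
    rows = [
        _summary_row(var, table.patients[var].to_numpy())
        for var in DEMOGRAPHIC_VARS
        if var in table.patients.columns
    ]
    for pod in table.pods():
        vols = volumes_at_pod(table, pod, resolved_as_zero=resolved_as_zero)
        rows.append(_summary_row(f"rpp_pod{pod}_mL", vols.to_numpy()))
    return rows


def summary_frame(rows: list[SummaryRow]) -> pd.DataFrame:
    return pd.DataFrame([row.__dict__ for row in rows])


def anova_rpp(table: CohortTable, scale: str = "log_shift") -> AnovaResult:
    """One-way ANOVA of scan volumes grouped by post-operative day.

    Available-case: every recorded scan (including censored zeros, as
    0 mL) enters the group of its POD.  ``scale`` is ``log_shift``
    (log(V + 1), default) or ``raw``.
    """
    if scale not in ("raw", "log_shift"):
        raise ValueError(f"scale must be 'raw' or 'log_shift', got {scale!r}")
    m = table.measurements
    groups = []
    for pod in table.pods():
        v = m.loc[m["pod"] == pod, "volume_mL"].to_numpy(dtype=float)
        if len(v) >= 2:
            groups.append(np.log1p(v) if scale == "log_shift" else v)
    if len(groups) < 2:
        raise ValueError("ANOVA requires >= 2 PODs with >= 2 observations each")
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    grand = np.concatenate(groups)
    ss_between = sum(len(g) * (g.mean() - grand.mean()) ** 2 for g in groups)
    if ss_between <= 1e-12 * max(1.0, float(np.var(grand)) * n_total):
        # no between-group variability (e.g. identical values everywhere)
        return AnovaResult(0.0, k - 1, n_total - k, 1.0)
    f_stat, p_value = stats.f_oneway(*groups)
    return AnovaResult(float(f_stat), k - 1, n_total - k, float(p_value))


def correlation_matrix(
    table: CohortTable, method: str = "pearson", *, resolved_as_zero: bool = True
) -> CorrelationMatrix:
    """Pairwise correlations among demographics, operative data and per-POD RPP.

    Missing scans are handled pairwise-complete.  Variables that are
    constant over the complete cases of a pair yield NaN entries and are
    reported in ``degenerate`` (with a warning) rather than silently
    zeroed.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    data = table.patients.set_index("patient_id")[
        [v for v in DEMOGRAPHIC_VARS if v in table.patients.columns]
    ].copy()
    for pod in table.pods():
        data[f"rpp_pod{pod}_mL"] = volumes_at_pod(
            table, pod, resolved_as_zero=resolved_as_zero
        )
    variables = list(data.columns)
    p = len(variables)
    corr = np.eye(p)
    pvals = np.zeros((p, p))
    degenerate: set[str] = set()
    func = stats.pearsonr if method == "pearson" else stats.spearmanr
    for i in range(p):
        for j in range(i + 1, p):
            pair = data.iloc[:, [i, j]].dropna().to_numpy(dtype=float)
            if len(pair) < 3:
                raise ValueError(
                    f"need >= 3 complete cases for ({variables[i]}, {variables[j]})"
                )
            x, y = pair[:, 0], pair[:, 1]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                if np.ptp(x) == 0:
                    degenerate.add(variables[i])
                if np.ptp(y) == 0:
                    degenerate.add(variables[j])
                corr[i, j] = corr[j, i] = np.nan
                pvals[i, j] = pvals[j, i] = np.nan
                continue
            r, pv = func(x, y)
            corr[i, j] = corr[j, i] = r
            pvals[i, j] = pvals[j, i] = pv
    if degenerate:
        warnings.warn(
            f"correlation undefined for constant variables: {sorted(degenerate)}",
            stacklevel=2,
        )
    return CorrelationMatrix(
        variables=variables,
        corr=pd.DataFrame(corr, index=variables, columns=variables),
        pvalues=pd.DataFrame(pvals, index=variables, columns=variables),
        degenerate=sorted(degenerate),
    )


def zero_rpp_fraction(
    table: CohortTable, pod: int, *, resolved_as_zero: bool = True
) -> float:
    """Fraction of informative patients with no detectable RPP at *pod*.

    Patients whose scans stopped after an earlier zero reading count as
    zero (their pneumoperitoneum had resolved); patients with no
    information at *pod* are excluded from the denominator.
    """
    vols = volumes_at_pod(table, pod, resolved_as_zero=resolved_as_zero)
    vols = vols.dropna()
    if len(vols) == 0:
        raise ValueError(f"no information at POD {pod}")
    return float((vols == 0.0).mean())
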