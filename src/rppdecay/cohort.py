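"""Cohort containers: patient-level covariates and longitudinal RPP scans.

A cohort is a pair of long-format tables: one row per patient
(demographics, operative parameters, BMI stratum) and one row per
(patient, post-operative day) CT volumetry reading.  Volumes are in mL;
a recorded volume of exactly 0 means no detectable residual gas, i.e. a
left-censored reading.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BmiGroup",
    "FollowupRule",
    "CohortTable",
    "assign_bmi_group",
    "apply_followup_rule",
    "PATIENT_COLUMNS",
    "MEASUREMENT_COLUMNS",
]

PATIENT_COLUMNS = [
    "patient_id",
    "age",
    "weight_kg",
    "height_cm",
    "bmi",
    "bmi_group",
    "op_duration_min",
    "insufflation_min",
    "total_gas_L",
    "decompressed",
]

MEASUREMENT_COLUMNS = ["patient_id", "pod", "volume_mL", "censored"]


class BmiGroup(str, enum.Enum):
    """WHO body-mass-index strata used as fixed effects in the decay model."""

    NORMAL = "normal"
    OVERWEIGHT = "overweight"
    OBESE = "obese"


class FollowupRule(str, enum.Enum):
    """How later scans depend on earlier findings.

    CONDITIONAL mirrors the study design: a POD-5 (resp. POD-7) scan is
    only performed if residual gas was still visible at the preceding
    scan.  COMPLETE scans everyone at every scheduled day.
    INDEPENDENT_MISSING drops scan rows independently at random, a
    device for sensitivity analyses of the follow-up mechanism.
    """

    CONDITIONAL = "conditional"
    COMPLETE = "complete"
    INDEPENDENT_MISSING = "independent_missing"


def assign_bmi_group(bmi: float) -> BmiGroup:
    """Classify a BMI (kg/m^2) into normal / overweight / obese.

    WHO convention: normal < 25, overweight in [25, 30), obese >= 30.

    Raises
    ------
    ValueError
        If ``bmi`` is not strictly positive.
    """
    if not np.isfinite(bmi) or bmi <= 0:
        raise ValueError(f"bmi must be a positive finite number, got {bmi!r}")
    if bmi < 25.0:
        return BmiGroup.NORMAL
    if bmi < 30.0:
        return BmiGroup.OVERWEIGHT
    return BmiGroup.OBESE


@dataclass
class CohortTable:
    """A simulated or real cohort: patients plus longitudinal scans.

    Attributes
    ----------
    patients : pandas.DataFrame
        One row per patient, columns :data:`PATIENT_COLUMNS`.
    measurements : pandas.DataFrame
        One row per (patient, POD) reading, columns
        :data:`MEASUREMENT_COLUMNS`.  ``censored`` is True exactly when
        ``volume_mL == 0``.
    """

    patients: pd.DataFrame
    measurements: pd.DataFrame
    followup_rule: FollowupRule = field(default=FollowupRule.CONDITIONAL)

    def __post_init__(self) -> None:
        self.followup_rule = FollowupRule(self.followup_rule)
        self.validate()

    def validate(self) -> None:
        missing = set(PATIENT_COLUMNS) - set(self.patients.columns)
        if missing:
            raise ValueError(f"patients table missing columns: {sorted(missing)}")
        missing = set(MEASUREMENT_COLUMNS) - set(self.measurements.columns)
        if missing:
            raise ValueError(f"measurements table missing columns: {sorted(missing)}")
        m = self.measurements
        if len(m):
            if (m["volume_mL"] < 0).any():
                raise ValueError("volume_mL must be non-negative")
            if not (m["censored"] == (m["volume_mL"] == 0)).all():
                raise ValueError("censored flag must hold exactly when volume_mL == 0")
            if m.duplicated(subset=["patient_id", "pod"]).any():
                raise ValueError("at most one measurement per (patient_id, pod)")
            unknown = set(m["patient_id"]) - set(self.patients["patient_id"])
            if unknown:
                raise ValueError(
                    f"measurements reference unknown patients: {sorted(unknown)[:5]}"
                )

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def pods(self) -> list[int]:
        return sorted(self.measurements["pod"].unique())

    # ------------------------------------------------------------------ I/O

    def to_csv(self, out_dir: str | Path) -> tuple[Path, Path]:
        """Write ``patients.csv`` and ``measurements.csv`` under *out_dir*."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        p_path = out / "patients.csv"
        m_path = out / "measurements.csv"
        self.patients.to_csv(p_path, index=False)
        self.measurements.to_csv(m_path, index=False)
        return p_path, m_path

    @classmethod
    def from_csv(
        cls, data_dir: str | Path, followup_rule: FollowupRule | str = FollowupRule.CONDITIONAL
    ) -> "CohortTable":
        data = Path(data_dir)
        patients = pd.read_csv(data / "patients.csv")
        measurements = pd.read_csv(data / "measurements.csv")
        measurements["censored"] = measurements["censored"].astype(bool)
        return cls(patients, measurements, followup_rule=FollowupRule(followup_rule))


def apply_followup_rule(
    table: CohortTable,
    rule: FollowupRule | str,
    *,
    missing_prob: float = 0.1,
    seed: int | None = None,
) -> CohortTable:
    """Restrict a cohort's measurements according to a follow-up rule.

    Under ``conditional``, any scan whose most recent preceding scan (for
    the same patient) read 0 mL is removed, along with everything after
    it: once residual gas has resolved, no further scans take place.
    ``complete`` is the identity.  ``independent_missing`` drops each
    measurement row independently with probability *missing_prob*.
    Remaining rows are never altered.
    """
    rule = FollowupRule(rule)
    m = table.measurements
    if rule is FollowupRule.COMPLETE:
        keep = np.ones(len(m), dtype=bool)
    elif rule is FollowupRule.INDEPENDENT_MISSING:
        rng = np.random.default_rng(seed)
        keep = rng.random(len(m)) >= missing_prob
    elif rule is FollowupRule.CONDITIONAL:
        ms = m.sort_values(["patient_id", "pod"], kind="stable")
        # keep rows up to and including each patient's first zero reading
        zero = ms["censored"].to_numpy(dtype=np.int64)
        pid = ms["patient_id"].to_numpy()
        is_start = np.r_[True, pid[1:] != pid[:-1]]
        excl = np.r_[0, np.cumsum(zero)[:-1]]  # zeros strictly before each row
        group_idx = np.cumsum(is_start) - 1
        prior_zero = (excl - excl[is_start][group_idx]) > 0
        keep = pd.Series(~prior_zero, index=ms.index).reindex(m.index).to_numpy()
    else:  # pragma: no cover - enum is exhaustive
        raise ValueError(f"unknown follow-up rule: {rule!r}")
    return CohortTable(
        table.patients.copy(), m.loc[keep].reset_index(drop=True), followup_rule=rule
    )
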