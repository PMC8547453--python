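"""Cohort assembly: relative weight change, exclusion rules, and group labels.

Subjects from a lifestyle-intervention cohort are labelled ``weight_loss``
when they lost more than 1% of baseline body weight per month between the
baseline and follow-up measurements, and ``no_weight_loss`` when their weight
stayed essentially stable (gained less than 0.1%, never lost).  Subjects whose
recorded weight series never changes are excluded: repeated identical values
are the signature of a stale self-reported weight rather than a real
measurement.  The group label is the target covariate of every downstream
association model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

__all__ = [
    "SubjectRecord",
    "relative_weight_change",
    "exclude_zero_variance",
    "assign_group",
    "select_cohort",
    "GROUP_WEIGHT_LOSS",
    "GROUP_NO_WEIGHT_LOSS",
    "GROUP_EXCLUDED",
    "GROUP_UNASSIGNED",
]

GROUP_WEIGHT_LOSS = "weight_loss"
GROUP_NO_WEIGHT_LOSS = "no_weight_loss"
GROUP_EXCLUDED = "excluded"
GROUP_UNASSIGNED = "unassigned"

#: machine-readable exclusion reason codes
REASON_ZERO_VARIANCE = "zero_variance_weight_series"
REASON_UNASSESSABLE = "weight_series_too_short"


@dataclass
class SubjectRecord:
    """Per-subject covariates and weight trajectory.

    ``sex`` is a binary category (``"female"``/``"male"``), ``age`` in years,
    ``baseline_bmi`` in kg/m2, weights in kg, ``months_between`` in months.
    ``weight_series`` optionally holds the full ordered series of recorded
    weights (kg) used by the zero-variance exclusion rule.
    """

    subject_id: str
    sex: str
    age: float
    baseline_bmi: float
    baseline_weight: float
    followup_weight: float
    months_between: float
    weight_series: Sequence[float] | None = None
    group: str = GROUP_UNASSIGNED
    rate: float | None = None
    exclusion_reason: str = field(default="")


def relative_weight_change(
    baseline_weight: float, followup_weight: float, months: float
) -> float:
    """Relative weight change in percent of baseline body weight per month.

    Computed as ``100 * (followup - baseline) / baseline / months``; negative
    values mean weight loss.

    Raises
    ------
    ValueError
        If ``baseline_weight`` or ``months`` is not strictly positive.
    """
    if not baseline_weight > 0:
        raise ValueError(
            f"baseline_weight must be positive, got {baseline_weight!r}"
        )
    if not months > 0:
        raise ValueError(f"months must be positive, got {months!r}")
    return 100.0 * (followup_weight - baseline_weight) / baseline_weight / months


def exclude_zero_variance(weight_series: Sequence[float]) -> tuple[bool, str]:
    """Flag a weight series recorded as a constant.

    Returns ``(excluded, reason)``.  A series with fewer than two entries
    cannot be assessed and is flagged with :data:`REASON_UNASSESSABLE` but not
    excluded.  Exclusion uses exact equality of the recorded values: the rule
    targets repeated self-report of a stale value, not near-constant weight.
    """
    series = list(weight_series)
    if len(series) < 2:
        return False, REASON_UNASSESSABLE
    if all(w == series[0] for w in series[1:]):
        return True, REASON_ZERO_VARIANCE
    return False, ""


def assign_group(
    rate: float,
    loss_threshold: float = -1.0,
    stable_threshold: float = 0.1,
) -> str:
    """Assign the weight-loss group label from a percent-per-month rate.

    ``rate < loss_threshold`` (default more than 1% of body weight lost per
    month) gives ``weight_loss``; ``0 <= rate < stable_threshold`` (stable or
    only marginally gaining) gives ``no_weight_loss``; anything in between or
    above is ``unassigned``.
    """
    if rate < loss_threshold:
        return GROUP_WEIGHT_LOSS
    if 0.0 <= rate < stable_threshold:
        return GROUP_NO_WEIGHT_LOSS
    return GROUP_UNASSIGNED


def select_cohort(
    meta: pd.DataFrame,
    loss_threshold: float = -1.0,
    stable_threshold: float = 0.1,
) -> pd.DataFrame:
    """Apply the rate computation, exclusion and grouping rules to a table.

    Parameters
    ----------
    meta:
        DataFrame with columns ``subject_id, sex, age, baseline_bmi,
        baseline_weight, followup_weight, months_between`` and optionally
        ``weight_series`` (semicolon-joined kg values).

    Returns
    -------
    A copy of ``meta`` with ``rate``, ``group`` and ``exclusion_reason``
    columns added.  Excluded subjects have ``group == "excluded"`` and no
    rate-based label.
    """
    required = [
        "subject_id",
        "baseline_weight",
        "followup_weight",
        "months_between",
    ]
    missing = [c for c in required if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata is missing required columns: {missing}")

    out = meta.copy()
    rates: list[float] = []
    groups: list[str] = []
    reasons: list[str] = []
    for _, row in out.iterrows():
        reason = ""
        excluded = False
        if "weight_series" in out.columns and isinstance(
            row.get("weight_series"), str
        ) and row["weight_series"]:
            series = [float(x) for x in str(row["weight_series"]).split(";")]
            excluded, reason = exclude_zero_variance(series)
            if reason == REASON_UNASSESSABLE:
                reason = ""  # too short to assess: keep, do not exclude
        rate = relative_weight_change(
            row["baseline_weight"], row["followup_weight"], row["months_between"]
        )
        rates.append(rate)
        if excluded:
            groups.append(GROUP_EXCLUDED)
            reasons.append(reason)
        else:
            groups.append(assign_group(rate, loss_threshold, stable_threshold))
            reasons.append("")
    out["rate"] = rates
    out["group"] = groups
    out["exclusion_reason"] = reasons
    return out
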