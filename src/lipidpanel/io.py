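"""Reading, writing and validating long-format cohort panels.

A cohort panel is a tidy :class:`pandas.DataFrame` with one row per
(child, visit). Mandatory columns are ``child_id``, ``sex``, ``week`` and
``visit_index``; growth outcomes (``waz``, ``laz``, ``wlz``) and any number
of ``lipid_*`` / ``me_*`` feature columns are optional but at least one
value column must be present.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: default clinic visit schedule, weeks of age
DEFAULT_VISIT_WEEKS = (12, 24, 52, 78, 104)

GROWTH_COLUMNS = ("waz", "laz", "wlz")
MANDATORY_COLUMNS = ("child_id", "sex", "week")

#: z-scores outside this band are implausible and flagged, not rejected
ZSCORE_FLAG_RANGE = (-6.0, 6.0)


class SchemaError(ValueError):
    """Raised when a cohort CSV does not satisfy the documented schema."""


@dataclass
class ValidationReport:
    n_rows: int = 0
    n_children: int = 0
    flagged_zscores: int = 0
    messages: list[str] = field(default_factory=list)


def feature_columns(panel: pd.DataFrame, prefix: str = "lipid_") -> list[str]:
    """Columns of *panel* starting with *prefix*, in column order."""
    return [c for c in panel.columns if c.startswith(prefix)]


def weeks_to_visit_index(weeks: pd.Series, schedule=None) -> pd.Series:
    """Map calendar weeks onto 1-based visit indices.

    If *schedule* is None the sorted unique weeks present in the data define
    the schedule (week 12 -> 1, ..., week 104 -> 5 on the default design).
    """
    if schedule is None:
        schedule = sorted(pd.unique(weeks.dropna()))
    mapping = {w: i + 1 for i, w in enumerate(schedule)}
    unknown = set(weeks.dropna()) - set(mapping)
    if unknown:
        raise SchemaError(f"weeks not on the visit schedule: {sorted(unknown)}")
    return weeks.map(mapping).astype(int)


def validate_panel(panel: pd.DataFrame) -> ValidationReport:
    """Validate a cohort panel in place; raise :class:`SchemaError` on hard errors."""
    missing = [c for c in MANDATORY_COLUMNS if c not in panel.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")
    value_cols = [c for c in panel.columns if c in GROWTH_COLUMNS] + feature_columns(
        panel
    ) + feature_columns(panel, "me_")
    if not value_cols:
        raise SchemaError(
            "panel has no value columns (waz/laz/wlz or lipid_*/me_*)"
        )
    dup = panel.duplicated(subset=["child_id", "week"])
    if dup.any():
        raise SchemaError(
            f"duplicate (child_id, week) rows: {panel.loc[dup, ['child_id', 'week']].values.tolist()}"
        )
    report = ValidationReport(
        n_rows=len(panel), n_children=panel["child_id"].nunique()
    )
    lo, hi = ZSCORE_FLAG_RANGE
    for col in GROWTH_COLUMNS:
        if col in panel.columns:
            bad = ((panel[col] < lo) | (panel[col] > hi)).sum()
            if bad:
                report.flagged_zscores += int(bad)
                report.messages.append(
                    f"{bad} {col} values outside [{lo}, {hi}] flagged"
                )
    if report.messages:
        warnings.warn("; ".join(report.messages))
    return report


def read_cohort_csv(path, schedule=None) -> pd.DataFrame:
    """Read and validate a cohort panel CSV.

    ``visit_index`` is recomputed from ``week`` when absent.
    """
    panel = pd.read_csv(path, float_precision="round_trip")
    if "visit_index" not in panel.columns and "week" in panel.columns:
        panel["visit_index"] = weeks_to_visit_index(panel["week"], schedule)
    validate_panel(panel)
    return panel.sort_values(["child_id", "visit_index"]).reset_index(drop=True)


def write_cohort_csv(panel: pd.DataFrame, path) -> None:
    validate_panel(panel)
    panel.to_csv(path, index=False)
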