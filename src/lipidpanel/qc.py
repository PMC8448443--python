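"""Feature-level quality control for raw lipidomics intensity tables.

Four conjunctive filters are applied, in a fixed order so that per-step
attrition can be reported:

1. mass accuracy   — drop features whose mean mass deviation exceeds 5 ppm;
2. blank ratio     — drop features whose mean study intensity is less than
                     5x the mean blank intensity;
3. zero fraction   — drop features with zeros in more than 10% of study samples;
4. dilution series — drop features whose intensity correlates with the QC
                     dilution factor at r < 0.9.

All rules use strict inequalities, so a feature sitting exactly on a
threshold is retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: filter names in application order
FILTER_ORDER = ("ppm", "blank_ratio", "zero_fraction", "dilution_r")

DEFAULT_THRESHOLDS = {
    "ppm": 5.0,
    "blank_ratio": 5.0,
    "zero_fraction": 0.10,
    "dilution_r": 0.9,
}

SAMPLE_ROLES = ("study", "blank", "qc_dilution")


@dataclass
class RawFeatureTable:
    """Feature x sample intensity matrix with QC metadata.

    Parameters
    ----------
    intensities
        DataFrame indexed by feature id, columns are sample ids; values >= 0.
    feature_meta
        DataFrame indexed by feature id with columns ``expected_mass`` and
        ``observed_mass`` (mean recorded mass), both in Da.
    sample_meta
        DataFrame indexed by sample id with column ``role`` in
        ``{'study', 'blank', 'qc_dilution'}`` and, for dilution samples,
        a positive ``dilution_factor``.
    """

    intensities: pd.DataFrame
    feature_meta: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self):
        if (self.intensities.values < 0).any():
            raise ValueError("intensities must be nonnegative")
        bad_roles = set(self.sample_meta["role"]) - set(SAMPLE_ROLES)
        if bad_roles:
            raise ValueError(f"unknown sample roles: {bad_roles}")
        if not (self.sample_meta["role"] == "study").any():
            raise ValueError("at least one study sample is required")
        qc = self.sample_meta["role"] == "qc_dilution"
        if qc.any():
            df = self.sample_meta.loc[qc, "dilution_factor"]
            if df.isna().any() or (df <= 0).any():
                raise ValueError(
                    "every qc_dilution sample needs a positive dilution_factor"
                )

    def samples(self, role: str) -> list:
        return list(self.sample_meta.index[self.sample_meta["role"] == role])

    @property
    def n_features(self) -> int:
        return self.intensities.shape[0]


@dataclass
class FilterReport:
    """Per-feature QC metrics, pass flags and thresholds used."""

    metrics: pd.DataFrame  # ppm_deviation, blank_ratio, zero_fraction, dilution_r
    passes: pd.DataFrame  # boolean, one column per filter + 'overall'
    thresholds: dict
    attrition: dict = field(default_factory=dict)  # filter -> n removed at that step
    not_evaluable: list = field(default_factory=list)

    def survivors(self) -> list:
        return list(self.passes.index[self.passes["overall"]])


def compute_qc_metrics(raw: RawFeatureTable) -> FilterReport:
    """Compute the four QC metrics for every feature (no filtering).

    Filters that cannot be evaluated (no blanks, or fewer than three dilution
    points) are marked not-evaluable and pass by default.
    """
    study = raw.samples("study")
    blanks = raw.samples("blank")
    qc = raw.samples("qc_dilution")
    not_evaluable = []

    expected = raw.feature_meta["expected_mass"].astype(float)
    observed = raw.feature_meta["observed_mass"].astype(float)
    ppm = (observed - expected).abs() / expected * 1e6

    x_study = raw.intensities[study]
    study_mean = x_study.mean(axis=1)
    if blanks:
        blank_mean = raw.intensities[blanks].mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            blank_ratio = study_mean / blank_mean
        # all-zero blanks: signal is infinitely above background
        blank_ratio = blank_ratio.replace(np.nan, np.inf).where(
            blank_mean > 0, np.inf
        )
    else:
        blank_ratio = pd.Series(np.inf, index=raw.intensities.index)
        not_evaluable.append("blank_ratio")
        warnings.warn("no blank samples: blank_ratio filter not evaluable")

    zero_fraction = (x_study == 0).mean(axis=1)

    if len(qc) >= 3:
        factors = raw.sample_meta.loc[qc, "dilution_factor"].astype(float).values
        x_qc = raw.intensities[qc].values
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dilution_r = pd.Series(
                [
                    stats.pearsonr(row, factors)[0] if np.std(row) > 0 else 0.0
                    for row in x_qc
                ],
                index=raw.intensities.index,
            )
        dilution_r = dilution_r.fillna(0.0)
    else:
        dilution_r = pd.Series(1.0, index=raw.intensities.index)
        not_evaluable.append("dilution_r")
        warnings.warn(
            "fewer than 3 dilution points: dilution_r filter not evaluable"
        )

    metrics = pd.DataFrame(
        {
            "ppm_deviation": ppm,
            "blank_ratio": blank_ratio,
            "zero_fraction": zero_fraction,
            "dilution_r": dilution_r,
        }
    )
    return FilterReport(
        metrics=metrics,
        passes=pd.DataFrame(index=metrics.index),
        thresholds=dict(DEFAULT_THRESHOLDS),
        not_evaluable=not_evaluable,
    )


def apply_qc_filters(
    raw: RawFeatureTable, thresholds: dict | None = None
) -> tuple[RawFeatureTable, FilterReport]:
    """Filter *raw* with the four QC rules; return survivors and the report.

    The survivor set is order-invariant (rules are conjunctive); attrition is
    attributed sequentially in :data:`FILTER_ORDER`.
    """
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    if any(v <= 0 for v in thr.values()):
        raise ValueError("thresholds must be positive")

    report = compute_qc_metrics(raw)
    report.thresholds = thr
    m = report.metrics
    passes = pd.DataFrame(
        {
            "ppm": ~(m["ppm_deviation"] > thr["ppm"]),
            "blank_ratio": ~(m["blank_ratio"] < thr["blank_ratio"]),
            "zero_fraction": ~(m["zero_fraction"] > thr["zero_fraction"]),
            "dilution_r": ~(m["dilution_r"] < thr["dilution_r"]),
        }
    )
    passes["overall"] = passes[list(FILTER_ORDER)].all(axis=1)
    report.passes = passes

    alive = pd.Series(True, index=m.index)
    for name in FILTER_ORDER:
        removed = alive & ~passes[name]
        report.attrition[name] = int(removed.sum())
        alive &= passes[name]

    survivors = list(m.index[alive])
    if not survivors:
        warnings.warn("no features survive QC filtering")
    filtered = RawFeatureTable(
        intensities=raw.intensities.loc[survivors],
        feature_meta=raw.feature_meta.loc[survivors],
        sample_meta=raw.sample_meta,
    )
    return filtered, report


def report_to_frame(report: FilterReport) -> pd.DataFrame:
    """Flat per-feature table (metrics + pass flags) for CSV export."""
    return report.metrics.join(report.passes.add_suffix("_pass"))


def write_raw_table(raw: RawFeatureTable, directory) -> list:
    """Write a raw feature table as three CSVs in *directory*."""
    import os

    os.makedirs(directory, exist_ok=True)
    paths = []
    for name, frame in (
        ("intensities.csv", raw.intensities),
        ("feature_meta.csv", raw.feature_meta),
        ("sample_meta.csv", raw.sample_meta),
    ):
        path = os.path.join(directory, name)
        frame.to_csv(path)
        paths.append(path)
    return paths


def read_raw_table(directory) -> RawFeatureTable:
    """Read a raw feature table written by :func:`write_raw_table`."""
    import os

    return RawFeatureTable(
        intensities=pd.read_csv(os.path.join(directory, "intensities.csv"), index_col=0),
        feature_meta=pd.read_csv(os.path.join(directory, "feature_meta.csv"), index_col=0),
        sample_meta=pd.read_csv(os.path.join(directory, "sample_meta.csv"), index_col=0),
    )
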