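"""Assay-validation arithmetic: recovery, RSD, accuracy, precision,
acceptance flags, and linearity fitting.

Conventions follow standard analytical-method validation practice:

* recovery = 100 x calculated / expected (undefined — "NC" — for
  0%-expected samples),
* RSD = 100 x sample standard deviation (n-1 denominator) / mean,
* overall accuracy = grand mean of the replicate-average recoveries,
* intermediate precision = RSD of the replicate-average recoveries,
* acceptance: RSD < 20% and recovery within 80-120%.

Linearity of calculated vs expected integrity is fit by generalized
least squares; with a compound-symmetry structure, observations sharing
a replicate (experiment) label are equicorrelated, and with independent
errors the fit reduces to ordinary least squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "RSD_LIMIT",
    "RECOVERY_RANGE",
    "SampleSummary",
    "StudySummary",
    "LinearityFit",
    "percent_recovery",
    "rsd",
    "overall_accuracy",
    "intermediate_precision",
    "summarize_study",
    "linearity_fit",
]

RSD_LIMIT = 20.0
RECOVERY_RANGE = (80.0, 120.0)


def percent_recovery(calculated: float, expected: float) -> float:
    """100 x calculated/expected; NaN (the NC marker) when expected is 0."""
    if expected < 0:
        raise ValueError("expected integrity must be non-negative")
    if expected == 0:
        return math.nan
    return 100.0 * calculated / expected


def rsd(values: Sequence[float]) -> float:
    """Percent relative standard deviation, with the n-1 (sample)
    standard deviation.  NaN (NC) when the mean is zero."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError("RSD requires at least 2 values")
    mean = arr.mean()
    if mean == 0:
        return math.nan
    return 100.0 * arr.std(ddof=1) / mean


def overall_accuracy(recoveries: Sequence[float]) -> float:
    """Grand mean of replicate-average percent recoveries (NC entries,
    encoded as NaN, are excluded)."""
    arr = np.asarray(list(recoveries), dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("no calculable recoveries")
    return float(arr.mean())


def intermediate_precision(recoveries: Sequence[float]) -> float:
    """RSD of replicate-average percent recoveries (NC excluded)."""
    arr = np.asarray(list(recoveries), dtype=float)
    arr = arr[~np.isnan(arr)]
    return rsd(arr)


@dataclass(frozen=True)
class SampleSummary:
    """Per-sample validation summary over a dilution series."""

    sample: str
    expected_percent: float
    estimates: tuple[float, ...]  # per-dilution integrity estimates (%)
    mean_percent: float
    rsd_percent: float
    recovery_percent: float  # NaN = NC (expected 0%)
    rsd_ok: bool
    recovery_ok: bool

    @property
    def is_nc(self) -> bool:
        return math.isnan(self.recovery_percent)


@dataclass(frozen=True)
class StudySummary:
    """Whole-study summary: per-sample rows plus the accuracy/precision
    footer computed from per-(sample, replicate) average recoveries."""

    samples: tuple[SampleSummary, ...]
    replicate_recoveries: pd.DataFrame  # columns: sample, replicate, recovery
    overall_accuracy: float
    intermediate_precision: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample": s.sample,
                "expected_percent": s.expected_percent,
                "mean_percent": round(s.mean_percent, 1),
                "rsd_percent": "NC" if math.isnan(s.rsd_percent) else round(s.rsd_percent, 1),
                "recovery_percent": "NC" if s.is_nc else round(s.recovery_percent, 1),
                "rsd_ok": "" if math.isnan(s.rsd_percent) else s.rsd_ok,
                "recovery_ok": "" if s.is_nc else s.recovery_ok,
            }
            for s in self.samples
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        frame = self.to_frame()
        footer = pd.DataFrame(
            [
                {"sample": "Overall accuracy", "expected_percent": "",
                 "mean_percent": "", "rsd_percent": "",
                 "recovery_percent": round(self.overall_accuracy, 1),
                 "rsd_ok": "", "recovery_ok": ""},
                {"sample": "Intermediate precision", "expected_percent": "",
                 "mean_percent": "", "rsd_percent": "",
                 "recovery_percent": round(self.intermediate_precision, 1),
                 "rsd_ok": "", "recovery_ok": ""},
            ]
        )
        pd.concat([frame, footer], ignore_index=True).to_csv(path, index=False)


def summarize_study(
    results: pd.DataFrame,
    expected: Mapping[str, float],
    value_col: str = "integrity_percent",
) -> StudySummary:
    """Aggregate per-well integrity estimates into a validation summary.

    ``results`` needs columns ``sample``, ``replicate``, ``dilution`` and
    ``value_col`` (NaN for NA wells; NA wells are dropped from averages).
    Per sample: the per-dilution means across replicates form the
    dilution-series estimates, from which the mean integrity, RSD and
    recovery are computed and flagged against the acceptance criteria.
    Per (sample, replicate): the replicate-average recovery feeds the
    overall accuracy (grand mean) and intermediate precision (RSD).
    Samples with 0% expected integrity are marked NC and excluded from
    the accuracy/precision footer.  Output is invariant to row order.
    """
    required = {"sample", "replicate", "dilution", value_col}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"results missing columns: {sorted(missing)}")
    df = results.sort_values(["sample", "replicate", "dilution"], kind="stable")
    summaries = []
    rep_rows = []
    for sample in sorted(expected):
        exp = float(expected[sample])
        grp = df[df["sample"] == sample].dropna(subset=[value_col])
        if grp.empty:
            raise ValueError(f"no usable results for sample group '{sample}'")
        per_dilution = grp.groupby("dilution", sort=True)[value_col].mean()
        estimates = tuple(float(v) for v in per_dilution)
        mean_pct = float(np.mean(estimates))
        rsd_pct = rsd(estimates) if len(estimates) >= 2 else math.nan
        rec = percent_recovery(mean_pct, exp)
        summaries.append(
            SampleSummary(
                sample=sample,
                expected_percent=exp,
                estimates=estimates,
                mean_percent=mean_pct,
                rsd_percent=rsd_pct,
                recovery_percent=rec,
                rsd_ok=bool(rsd_pct < RSD_LIMIT) if not math.isnan(rsd_pct) else False,
                recovery_ok=(
                    bool(RECOVERY_RANGE[0] <= rec <= RECOVERY_RANGE[1])
                    if not math.isnan(rec)
                    else False
                ),
            )
        )
        for rep, rgrp in grp.groupby("replicate", sort=True):
            rep_mean = float(rgrp[value_col].mean())
            rep_rows.append(
                {
                    "sample": sample,
                    "replicate": rep,
                    "recovery": percent_recovery(rep_mean, exp),
                }
            )
    rep_df = pd.DataFrame(rep_rows)
    usable = rep_df["recovery"].dropna()
    return StudySummary(
        samples=tuple(summaries),
        replicate_recoveries=rep_df,
        overall_accuracy=overall_accuracy(usable),
        intermediate_precision=intermediate_precision(usable),
    )


@dataclass(frozen=True)
class LinearityFit:
    """Calculated-vs-expected linear fit."""

    slope: float
    intercept: float
    pseudo_r2: float
    residuals: np.ndarray
    structure: str
    rho: float = 0.0  # estimated within-replicate correlation


def linearity_fit(
    expected: Sequence[float],
    observed: Sequence[float],
    replicate: Optional[Sequence] = None,
    structure: str = "compound_symmetry",
) -> LinearityFit:
    """Fit observed = intercept + slope * expected by GLS.

    ``structure="compound_symmetry"`` treats observations sharing a
    replicate label as equicorrelated, with the correlation estimated
    from OLS residual cross-products (feasible GLS); ``"independence"``
    (or a missing replicate vector) reduces to ordinary least squares.
    The pseudo-R2 is 1 - RSS/TSS on the observation scale.
    """
    x = np.asarray(list(expected), dtype=float)
    y = np.asarray(list(observed), dtype=float)
    if x.shape != y.shape:
        raise ValueError("expected and observed must have equal length")
    if np.unique(x).size < 2:
        raise ValueError("degenerate design: need at least 2 distinct expected levels")
    X = sm.add_constant(x)

    if structure not in ("compound_symmetry", "independence"):
        raise ValueError(f"unknown correlation structure {structure!r}")
    if structure == "independence" or replicate is None:
        fit = sm.OLS(y, X).fit()
        structure_used, rho = "independence", 0.0
    else:
        labels = np.asarray(list(replicate))
        if labels.shape[0] != x.shape[0]:
            raise ValueError("replicate labels must match observations")
        resid = sm.OLS(y, X).fit().resid
        s2 = float(np.mean(resid**2))
        cross, pairs = 0.0, 0
        for lab in np.unique(labels):
            r = resid[labels == lab]
            n = r.size
            if n > 1:
                cross += (r.sum() ** 2 - (r**2).sum()) / 2.0
                pairs += n * (n - 1) // 2
        rho = float(np.clip(cross / (pairs * s2), 0.0, 0.99)) if pairs and s2 > 0 else 0.0
        sigma = np.eye(x.size)
        for lab in np.unique(labels):
            idx = np.flatnonzero(labels == lab)
            sigma[np.ix_(idx, idx)] = rho
        np.fill_diagonal(sigma, 1.0)
        fit = sm.GLS(y, X, sigma=sigma).fit()
        structure_used = "compound_symmetry"

    yhat = fit.predict(X)
    resid = y - yhat
    tss = float(np.sum((y - y.mean()) ** 2))
    pseudo_r2 = 1.0 - float(np.sum(resid**2)) / tss if tss > 0 else math.nan
    return LinearityFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        pseudo_r2=pseudo_r2,
        residuals=resid,
        structure=structure_used,
        rho=rho,
    )
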