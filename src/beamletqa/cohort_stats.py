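"""Per-fraction, per-patient and cohort summaries with fits and correlations.

Rolls fraction-level comparison results up to patient means (sample
standard deviation, n-1 denominator) and to cohort-level descriptive
regressions:

* mean skipped firing positions vs. total planned firing positions
  (larger plans expose more opportunities to skip — an approximately
  linear, noisy relationship);
* mean MU reduction vs. mean skipped positions (exactly proportional
  through the machine's single MU-per-firing-position constant, so the
  fit's R^2 is 1 to numerical precision);
* Pearson correlation between the mean percent of positions skipped and
  the plan's average leaf transition rate (a modulation-dependence probe;
  skips driven by transient hardware faults show no strong correlation).

Cohort percent-skipped is reported as the mean of per-patient percentages
(primary) alongside the ratio of means.  Display rounding — percentages
2 d.p., MU and rates 1 d.p., count means 1 d.p. — happens only in the
table formatter; stored values are unrounded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .compare import ComparisonResult
from .leaf_metrics import TransitionProfile

__all__ = [
    "FractionSummary",
    "PatientSummary",
    "LinearFitResult",
    "CohortSummary",
    "summarize_fraction",
    "summarize_patient",
    "linear_fit",
    "cohort_summary",
    "fractions_table",
    "patients_table",
    "format_cohort_table",
]

logger = logging.getLogger(__name__)


@dataclass
class FractionSummary:
    patient_id: str
    fraction: int
    n_plan_events: int
    n_skipped: int
    percent_skipped: float
    mu_reduction: float
    percent_mu_reduction: float


@dataclass
class PatientSummary:
    patient_id: str
    n_fractions: int
    n_plan_events: int
    mean_skipped: float
    sd_skipped: float
    min_skipped: int
    max_skipped: int
    mean_percent_skipped: float
    sd_percent_skipped: float
    mean_mu_reduction: float
    max_transition_rate: float = math.nan
    avg_transition_rate: float = math.nan


@dataclass
class LinearFitResult:
    slope: float
    intercept: float
    r_squared: float
    pearson_r: float
    n_points: int


@dataclass
class CohortSummary:
    patients: list[PatientSummary]
    fit_skipped_vs_total: Optional[LinearFitResult]
    fit_mu_vs_skipped: Optional[LinearFitResult]
    corr_skiprate_vs_transition: Optional[float]


def summarize_fraction(result: ComparisonResult) -> FractionSummary:
    """Flatten one fraction's comparison into the summary row."""
    mu = result.mu_report
    return FractionSummary(
        patient_id=result.patient_id,
        fraction=result.fraction,
        n_plan_events=mu.n_plan_events,
        n_skipped=mu.n_skipped,
        percent_skipped=mu.percent_skipped,
        mu_reduction=mu.mu_reduction,
        percent_mu_reduction=mu.percent_reduction,
    )


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    """Mean and sample SD (n-1); SD is 0 by convention for n=1."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 1:
        return float(arr[0]), 0.0
    return float(arr.mean()), float(arr.std(ddof=1))


def summarize_patient(
    fractions: Sequence[FractionSummary],
    profile: Optional[TransitionProfile] = None,
) -> PatientSummary:
    """Aggregate a patient's fraction summaries (mean/SD/min/max).

    ``profile`` is the *plan's* transition profile; its rates are copied
    into the summary for the modulation-vs-skip-rate correlation.

    Raises
    ------
    ValueError
        On an empty collection or mixed patient ids.
    """
    if not fractions:
        raise ValueError("summarize_patient requires at least one fraction")
    ids = {f.patient_id for f in fractions}
    if len(ids) > 1:
        raise ValueError(f"fractions span multiple patients: {sorted(ids)}")
    if len(fractions) == 1:
        logger.warning(
            "patient %s has a single fraction; SD reported as 0", fractions[0].patient_id
        )
    skips = [f.n_skipped for f in fractions]
    mean_sk, sd_sk = _mean_sd(skips)
    mean_pct, sd_pct = _mean_sd([f.percent_skipped for f in fractions])
    mean_mu, _ = _mean_sd([f.mu_reduction for f in fractions])
    return PatientSummary(
        patient_id=fractions[0].patient_id,
        n_fractions=len(fractions),
        n_plan_events=fractions[0].n_plan_events,
        mean_skipped=mean_sk,
        sd_skipped=sd_sk,
        min_skipped=min(skips),
        max_skipped=max(skips),
        mean_percent_skipped=mean_pct,
        sd_percent_skipped=sd_pct,
        mean_mu_reduction=mean_mu,
        max_transition_rate=profile.max_rate if profile else math.nan,
        avg_transition_rate=profile.avg_rate if profile else math.nan,
    )


def linear_fit(points: Iterable[tuple[float, float]]) -> LinearFitResult:
    """Ordinary least-squares line through (x, y) points.

    ``r_squared = 1 - SS_res/SS_tot`` equals the squared Pearson
    correlation for simple linear regression; ``pearson_r`` carries the
    sign of the slope.

    Raises
    ------
    ValueError
        With fewer than two points or all x identical (degenerate fit).
    """
    pts = list(points)
    if len(pts) < 2:
        raise ValueError("linear_fit requires at least two points")
    x = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: all x values identical")
    res = stats.linregress(x, y)
    return LinearFitResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        pearson_r=float(res.rvalue),
        n_points=len(pts),
    )


def cohort_summary(patients: Sequence[PatientSummary]) -> CohortSummary:
    """Build the cohort-level fits and modulation correlation.

    With fewer than two patients the fits are omitted with a warning; the
    transition-rate correlation additionally requires the patients to
    carry plan transition profiles.
    """
    patients = list(patients)
    fit_skipped = fit_mu = None
    if len(patients) >= 2:
        fit_skipped = linear_fit(
            [(p.n_plan_events, p.mean_skipped) for p in patients]
        )
        fit_mu = linear_fit(
            [(p.mean_skipped, p.mean_mu_reduction) for p in patients]
        )
    else:
        logger.warning("cohort has %d patient(s); regression fits omitted", len(patients))

    corr = None
    rates = [p.avg_transition_rate for p in patients]
    if len(patients) >= 2 and not any(math.isnan(r) for r in rates):
        pct = [p.mean_percent_skipped for p in patients]
        if np.ptp(rates) > 0 and np.ptp(pct) > 0:
            corr = float(stats.pearsonr(pct, rates).statistic)
    return CohortSummary(
        patients=patients,
        fit_skipped_vs_total=fit_skipped,
        fit_mu_vs_skipped=fit_mu,
        corr_skiprate_vs_transition=corr,
    )


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------

def fractions_table(fractions: Sequence[FractionSummary]) -> pd.DataFrame:
    """Per-fraction summaries as a DataFrame (CSV-ready)."""
    return pd.DataFrame(
        {
            "patient_id": [f.patient_id for f in fractions],
            "fraction": [f.fraction for f in fractions],
            "n_plan_events": [f.n_plan_events for f in fractions],
            "n_skipped": [f.n_skipped for f in fractions],
            "percent_skipped": [f.percent_skipped for f in fractions],
            "mu_reduction": [f.mu_reduction for f in fractions],
            "percent_mu_reduction": [f.percent_mu_reduction for f in fractions],
        }
    )


def patients_table(patients: Sequence[PatientSummary]) -> pd.DataFrame:
    """Per-patient summaries as a DataFrame (CSV-ready)."""
    return pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in patients],
            "n_fractions": [p.n_fractions for p in patients],
            "n_plan_events": [p.n_plan_events for p in patients],
            "mean_skipped": [p.mean_skipped for p in patients],
            "sd_skipped": [p.sd_skipped for p in patients],
            "min_skipped": [p.min_skipped for p in patients],
            "max_skipped": [p.max_skipped for p in patients],
            "mean_percent_skipped": [p.mean_percent_skipped for p in patients],
            "sd_percent_skipped": [p.sd_percent_skipped for p in patients],
            "mean_mu_reduction": [p.mean_mu_reduction for p in patients],
            "max_transition_rate": [p.max_transition_rate for p in patients],
            "avg_transition_rate": [p.avg_transition_rate for p in patients],
        }
    )


def _msr(values: Sequence[float], digits: int) -> str:
    """'Mean +/- StdDev (range)' cell at the given display precision."""
    mean, sd = _mean_sd(values)
    lo, hi = min(values), max(values)
    return f"{mean:.{digits}f} ± {sd:.{digits}f} ({lo:.{digits}f}–{hi:.{digits}f})"


def format_cohort_table(summary: CohortSummary) -> str:
    """Plain-text cohort statistics table, 'Mean +/- StdDev (range)' rows.

    Counts and MU at 1 d.p., rates 1 d.p., percentages 2 d.p.
    """
    p = summary.patients
    rows: list[tuple[str, str]] = [
        ("Firing positions in the treatment plan", _msr([x.n_plan_events for x in p], 1)),
        ("Average skipped firing positions in delivery", _msr([x.mean_skipped for x in p], 1)),
        ("Relative to total firing positions (%)", _msr([x.mean_percent_skipped for x in p], 2)),
        ("Average MU reduction per fraction (MU)", _msr([x.mean_mu_reduction for x in p], 1)),
    ]
    if not any(math.isnan(x.max_transition_rate) for x in p):
        rows.insert(1, ("Maximum leaf transition rate (leaves/sec)",
                        _msr([x.max_transition_rate for x in p], 1)))
        rows.insert(2, ("Average leaf transition rate (leaves/sec)",
                        _msr([x.avg_transition_rate for x in p], 1)))
    width = max(len(r[0]) for r in rows)
    lines = [f"{'Parameter':<{width}}  Mean ± StdDev (range)"]
    lines.extend(f"{name:<{width}}  {cell}" for name, cell in rows)
    if summary.fit_mu_vs_skipped is not None:
        lines.append("")
        lines.append(
            "Fit mean MU reduction vs mean skipped positions: "
            f"R^2 = {summary.fit_mu_vs_skipped.r_squared:.3f}"
        )
        lines.append(
            "Fit mean skipped positions vs total plan positions: "
            f"R^2 = {summary.fit_skipped_vs_total.r_squared:.2f}, "
            f"Pearson r = {summary.fit_skipped_vs_total.pearson_r:.2f}"
        )
    if summary.corr_skiprate_vs_transition is not None:
        lines.append(
            "Pearson r, mean % skipped vs average transition rate: "
            f"{summary.corr_skiprate_vs_transition:.2f}"
        )
    return "\n".join(lines)
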