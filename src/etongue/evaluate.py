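"""Model-quality metrics and the single-electrode comparison framework.

The electronic tongue is judged the way multicomponent calibrations are
judged in analytical chemistry: root-mean-squared error of the recovered
concentrations, obtained-vs-expected regressions whose slope/intercept/
correlation should approach 1/0/1 (with 95% confidence intervals), and
percentage relative errors on application samples — side by side with the
"conventional" determination that interpolates each ion on its own
electrode's calibration curve while ignoring interference.  A paired
Student t-test checks whether predictions and nominal concentrations
differ systematically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .activity import ActivityModelParams, IonSpec, activity_coefficient
from .characterize import CalibrationFit
from .errors import InputError

__all__ = [
    "RmseResult",
    "ComparisonRegression",
    "ErrorReport",
    "PairedTTest",
    "rmse",
    "comparison_regression",
    "single_ise_baseline",
    "relative_errors",
    "paired_t_test",
]


@dataclass(frozen=True)
class RmseResult:
    per_ion: Mapping[str, float]  # mol/L
    pooled: float  # mol/L


def rmse(
    predicted: np.ndarray,
    expected: np.ndarray,
    ion_names: Sequence[str] = ("ClO4", "S"),
) -> RmseResult:
    """Root-mean-squared concentration error per ion, plus pooled.

    The pooled value (over every sample-ion pair) is the scalar criterion
    used to rank candidate network architectures.
    """
    p = np.atleast_2d(np.asarray(predicted, dtype=float))
    e = np.atleast_2d(np.asarray(expected, dtype=float))
    if p.shape != e.shape:
        raise InputError(f"shape mismatch: {p.shape} vs {e.shape}")
    if p.size == 0:
        raise InputError("rmse of an empty set is undefined")
    sq = (p - e) ** 2
    per_ion = {
        name: float(np.sqrt(sq[:, j].mean())) for j, name in enumerate(ion_names)
    }
    return RmseResult(per_ion=per_ion, pooled=float(np.sqrt(sq.mean())))


@dataclass(frozen=True)
class ComparisonRegression:
    """OLS of obtained (y) on expected (x) with t-based confidence intervals."""

    ion: str
    subset: str
    slope: float
    slope_ci: tuple[float, float]
    intercept: float
    intercept_ci: tuple[float, float]
    r: float
    n: int
    contains_unity_slope: bool
    contains_zero_intercept: bool


def comparison_regression(
    predicted: np.ndarray,
    expected: np.ndarray,
    confidence: float = 0.95,
    ion: str = "",
    subset: str = "",
) -> ComparisonRegression:
    y = np.asarray(predicted, dtype=float).ravel()
    x = np.asarray(expected, dtype=float).ravel()
    if len(x) != len(y) or len(x) < 3:
        raise InputError("comparison regression needs >= 3 paired values")
    if np.ptp(x) == 0:
        raise InputError("expected values have zero variance")
    res = stats.linregress(x, y)
    df = len(x) - 2
    tcrit = stats.t.ppf(0.5 + confidence / 2.0, df)
    s_lo, s_hi = res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr
    i_lo = res.intercept - tcrit * res.intercept_stderr
    i_hi = res.intercept + tcrit * res.intercept_stderr
    return ComparisonRegression(
        ion=ion,
        subset=subset,
        slope=float(res.slope),
        slope_ci=(float(s_lo), float(s_hi)),
        intercept=float(res.intercept),
        intercept_ci=(float(i_lo), float(i_hi)),
        r=float(res.rvalue),
        n=len(x),
        contains_unity_slope=bool(s_lo <= 1.0 <= s_hi),
        contains_zero_intercept=bool(i_lo <= 0.0 <= i_hi),
    )


def single_ise_baseline(
    potentials: pd.DataFrame,
    fits: Mapping[str, CalibrationFit],
    electrode_for_ion: Mapping[str, str],
    ions: Sequence[IonSpec],
    params: ActivityModelParams,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Conventional one-electrode determination of each ion.

    Inverts ``E = e0 + s·log10(a + a0)`` for the designated electrode of
    each ion — interference from the other ion is deliberately ignored, as
    in routine single-ISE practice — and converts the activity back to a
    concentration assuming that ion (plus its counter-ion) dominates the
    ionic strength.  Returns (concentrations, extrapolation flags).
    """
    ions_by_name = {ion.name: ion for ion in ions}
    conc = pd.DataFrame(index=potentials.index)
    flags = pd.DataFrame(index=potentials.index)
    for ion_name, sensor_id in electrode_for_ion.items():
        if sensor_id not in potentials.columns:
            raise InputError(f"potential matrix lacks electrode {sensor_id!r}")
        fit = fits[sensor_id]
        ion = ions_by_name[ion_name]
        E = potentials[sensor_id].to_numpy(dtype=float)
        a_total = 10.0 ** ((E - fit.e0_hat) / fit.slope)
        a = np.maximum(a_total - fit.flattening_activity, 1e-15)
        w = 0.5 * (ion.charge**2 + abs(ion.charge))
        c = a.copy()
        for _ in range(30):
            I = params.fixed_background_ionic_strength + w * c
            gamma = np.array(
                [activity_coefficient(ion.charge, float(i), params) for i in I]
            )
            c = a / gamma
        conc[ion_name] = c
        lo, hi = fit.activity_range
        # flag readings below the detection limit (inferred activity under
        # the flattening level) or beyond the calibrated span
        flags[ion_name] = (a < fit.flattening_activity) | (a_total > 2.0 * hi)
    return conc, flags


@dataclass(frozen=True)
class ErrorReport:
    table: pd.DataFrame  # sample_id, ion, expected, predicted, rel_err_pct, method
    aggregate: Mapping[str, Mapping[str, float]]  # method -> ion -> aggregate %
    n_excluded: int
    aggregate_fn: str = "mean"


def relative_errors(
    predicted: np.ndarray,
    expected: np.ndarray,
    ion_names: Sequence[str] = ("ClO4", "S"),
    method: str = "ET",
    sample_ids: Sequence[str] | None = None,
    aggregate: str = "mean",
    min_expected: float = 0.0,
) -> ErrorReport:
    """Percentage relative errors, defined only where the expected value > 0.

    Rows with expected concentration at or below ``min_expected`` are
    excluded from the aggregates and counted in ``n_excluded``.
    """
    p = np.atleast_2d(np.asarray(predicted, dtype=float))
    e = np.atleast_2d(np.asarray(expected, dtype=float))
    if p.shape != e.shape:
        raise InputError("predicted and expected shapes differ")
    if sample_ids is None:
        sample_ids = [str(i + 1) for i in range(p.shape[0])]
    rows = []
    n_excluded = 0
    for i, sid in enumerate(sample_ids):
        for j, name in enumerate(ion_names):
            if e[i, j] <= max(min_expected, 0.0):
                n_excluded += 1
                continue
            rows.append(
                {
                    "sample_id": sid,
                    "ion": name,
                    "expected_M": e[i, j],
                    "predicted_M": p[i, j],
                    "rel_err_pct": 100.0 * abs(p[i, j] - e[i, j]) / e[i, j],
                    "method": method,
                }
            )
    table = pd.DataFrame(rows)
    agg_fn = np.mean if aggregate == "mean" else np.median
    agg: dict[str, dict[str, float]] = {method: {}}
    for name in ion_names:
        vals = table.loc[table["ion"] == name, "rel_err_pct"]
        agg[method][name] = float(agg_fn(vals)) if len(vals) else math.nan
    agg[method]["pooled"] = (
        float(agg_fn(table["rel_err_pct"])) if len(table) else math.nan
    )
    return ErrorReport(
        table=table, aggregate=agg, n_excluded=n_excluded, aggregate_fn=aggregate
    )


@dataclass(frozen=True)
class PairedTTest:
    t: float
    df: int
    critical: float
    confidence: float
    significant: bool  # True when the difference is statistically significant


def paired_t_test(
    predicted: np.ndarray, nominal: np.ndarray, confidence: float = 0.95
) -> PairedTTest:
    """Student's paired-samples t-test of predictions against nominal values.

    ``t = mean(d) / (sd(d)/sqrt(n))`` on the paired differences; the
    two-tailed critical value comes from the t distribution with n-1
    degrees of freedom.  ``|t| < critical`` means no significant bias.
    """
    p = np.asarray(predicted, dtype=float).ravel()
    m = np.asarray(nominal, dtype=float).ravel()
    if len(p) != len(m) or len(p) < 2:
        raise InputError("paired t-test needs >= 2 pairs of equal length")
    d = p - m
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0:
        t = 0.0 if d.mean() == 0 else math.copysign(math.inf, d.mean())
    else:
        t = float(d.mean() / (sd / math.sqrt(n)))
    df = n - 1
    critical = float(stats.t.ppf(0.5 + confidence / 2.0, df))
    return PairedTTest(
        t=t,
        df=df,
        critical=critical,
        confidence=confidence,
        significant=bool(abs(t) > critical),
    )
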