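"""IUPAC-style electrode characterization from calibration-format data.

Estimates, per electrode: the response slope (mV/decade) and standard
potential, the detection limit (intersection of the extrapolated linear
branch with the low-concentration plateau), potentiometric selectivity
coefficients by the fixed-interference (mixed solution) method or by a
direct nonlinear fit of the Nikolsky-Eisenmann response, and the
between-session reproducibility of the slope.

All estimators work on the *activity* scale internally: measured potentials
are regressed against log10 of the primary-ion activity, consistent with the
response law, and detection limits are converted back to concentrations at
the ionic strength of the series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .activity import ActivityModelParams, IonSpec, activity_coefficient
from .errors import EstimationError, InputError
from .sensors import SensorPanel, SensorSpec, array_response, sample_activities
from .tables import conc_column, make_sample_table

__all__ = [
    "CalibrationFit",
    "SelectivityEstimate",
    "fit_calibration",
    "detection_limit",
    "selectivity_coefficient",
    "slope_reproducibility",
    "calibration_sessions",
    "characterize_panel",
]


@dataclass(frozen=True)
class CalibrationFit:
    """Linear-response parameters of one electrode's calibration."""

    sensor_id: str
    slope: float  # mV/decade
    e0_hat: float  # mV
    linear_range: tuple[float, float]  # mol/L (concentration scale)
    r2: float
    residual_sd: float  # mV
    flattening_activity: float  # mol/L on the activity scale (a0)
    activity_range: tuple[float, float]  # activities of the linear region
    n_points: int = 0


@dataclass(frozen=True)
class SelectivityEstimate:
    sensor_id: str
    interferent: str
    log_k_pot: float
    method: str
    identifiable: bool = True
    per_level: tuple[tuple[float, float], ...] = ()  # (level M, log k)


def _primary_activities(
    concentrations: np.ndarray | None,
    table: pd.DataFrame | None,
    ion: IonSpec,
    params: ActivityModelParams,
    ions: Sequence[IonSpec],
) -> tuple[np.ndarray, np.ndarray]:
    """(concentration, activity) arrays of the primary ion."""
    if table is not None:
        conc = table[conc_column(ion)].to_numpy(dtype=float)
        idx = [k for k, i in enumerate(ions) if i.name == ion.name][0]
        act = sample_activities(table, ions, params)[:, idx]
        return conc, act
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc < 0):
        raise InputError("concentrations must be >= 0")
    w = 0.5 * (ion.charge**2 + abs(ion.charge))
    act = np.array(
        [
            activity_coefficient(
                ion.charge, params.fixed_background_ionic_strength + w * c, params
            )
            * c
            for c in conc
        ]
    )
    return conc, act


def _smooth_fit(E: np.ndarray, a: np.ndarray) -> tuple[float, float, float, float]:
    """Fit E = e0 + s·log10(a + a0); returns (e0, s, a0, sse)."""
    order = np.argsort(a)
    a, E = a[order], E[order]
    top = slice(len(a) // 2, None) if len(a) >= 4 else slice(None)
    init = linregress(np.log10(a[top]), E[top])
    s0, e00 = init.slope, init.intercept
    if s0 == 0:
        s0 = -1.0
    a0_guess = 10.0 ** ((E[0] - e00) / s0) - a[0]
    la_min, la_max = np.log10(a.min()) - 8.0, np.log10(a.max()) + 2.0
    la0 = np.clip(
        np.log10(a0_guess) if a0_guess > 0 else la_min, la_min + 1e-9, la_max - 1e-9
    )

    def model(x, e0, s, la0):
        return e0 + s * np.log10(x + 10.0**la0)

    popt, _ = curve_fit(
        model,
        a,
        E,
        p0=(e00, s0, la0),
        bounds=([-np.inf, -np.inf, la_min], [np.inf, np.inf, la_max]),
        maxfev=20000,
    )
    resid = E - model(a, *popt)
    return popt[0], popt[1], 10.0 ** popt[2], float(resid @ resid)


def fit_calibration(
    potentials: np.ndarray,
    concentrations: np.ndarray | None = None,
    *,
    table: pd.DataFrame | None = None,
    ion: IonSpec,
    params: ActivityModelParams,
    sensor_id: str = "",
    ions: Sequence[IonSpec] | None = None,
) -> CalibrationFit:
    """Slope/intercept of the Nernstian branch of a calibration series.

    The full low-end-curvature response ``E = e0 + s·log10(a + a0)`` is
    fitted so that the slope is unbiased by points near the flattening
    region; the reported linear range and r² refer to the points with
    activity above ten times the fitted flattening activity.
    """
    from .design import DEFAULT_IONS  # local import to avoid a cycle

    ions = ions or DEFAULT_IONS
    E = np.asarray(potentials, dtype=float)
    conc, act = _primary_activities(concentrations, table, ion, params, ions)
    if len(E) != len(act):
        raise InputError("potentials and concentrations differ in length")
    if len(E) < 2:
        raise InputError("at least two calibration points are required")
    order = np.argsort(act)
    act, conc, E = act[order], conc[order], E[order]

    a0 = act.min() * 1e-9
    resid_sd = 0.0
    if len(E) >= 4:
        try:
            e0_hat, slope, a0, sse = _smooth_fit(E, act)
            dof = max(len(E) - 3, 1)
            resid_sd = math.sqrt(sse / dof)
        except RuntimeError as exc:  # curve_fit failure: fall back to plain OLS
            e0_hat = slope = None  # type: ignore[assignment]
    else:
        e0_hat = slope = None  # type: ignore[assignment]
    if slope is None:
        ols = linregress(np.log10(act), E)
        slope, e0_hat = ols.slope, ols.intercept
        resid_sd = float(np.std(E - (e0_hat + slope * np.log10(act)), ddof=0))

    linear = act > 10.0 * a0
    if linear.sum() < 2:
        if a0 > act.max() / 10.0:
            raise EstimationError(
                f"sensor {sensor_id!r}: no linear region above the flattening point"
            )
        linear = np.zeros_like(linear)
        linear[-3:] = True
    ols_lin = linregress(np.log10(act[linear]), E[linear])
    r2 = float(ols_lin.rvalue**2) if linear.sum() > 2 else 1.0
    return CalibrationFit(
        sensor_id=sensor_id,
        slope=float(slope),
        e0_hat=float(e0_hat),
        linear_range=(float(conc[linear].min()), float(conc[linear].max())),
        r2=min(r2, 1.0),
        residual_sd=float(resid_sd),
        flattening_activity=float(a0),
        activity_range=(float(act[linear].min()), float(act[linear].max())),
        n_points=int(len(E)),
    )


def _segment_construction(E: np.ndarray, a: np.ndarray) -> tuple[float, float]:
    """Two-segment IUPAC construction: (flattening activity, sse)."""
    n = len(a)
    best: tuple[float, float] | None = None
    loga = np.log10(a)
    for k in range(2, n - 1):  # k plateau points, n-k line points (each >= 2)
        level = float(E[:k].mean())
        line = linregress(loga[k:], E[k:])
        if line.slope == 0:
            continue
        sse = float(((E[:k] - level) ** 2).sum()) + float(
            ((E[k:] - (line.intercept + line.slope * loga[k:])) ** 2).sum()
        )
        a0 = 10.0 ** ((level - line.intercept) / line.slope)
        if best is None or sse < best[1]:
            best = (a0, sse)
    if best is None:
        raise EstimationError("series too short for the two-segment construction")
    return best


def detection_limit(
    potentials: np.ndarray,
    concentrations: np.ndarray | None = None,
    *,
    table: pd.DataFrame | None = None,
    ion: IonSpec,
    params: ActivityModelParams,
    method: str = "auto",
    ions: Sequence[IonSpec] | None = None,
) -> float:
    """IUPAC detection limit (mol/L) of a calibration series.

    The limit is the abscissa where the extrapolated linear-response branch
    meets the extrapolated low-concentration plateau.  Two constructions are
    available — ``segments`` (two independent straight segments, exact for
    ideally piecewise-linear data) and ``smooth`` (asymptote intersection of
    the fitted curved response, exact for responses with an additive
    background activity).  ``auto`` keeps whichever explains the data with
    the smaller squared error.
    """
    from .design import DEFAULT_IONS

    ions = ions or DEFAULT_IONS
    E = np.asarray(potentials, dtype=float)
    conc, act = _primary_activities(concentrations, table, ion, params, ions)
    order = np.argsort(act)
    act, conc, E = act[order], conc[order], E[order]
    if len(E) < 4:
        raise InputError("at least four points are required for a detection limit")

    candidates: dict[str, tuple[float, float]] = {}
    if method in ("auto", "smooth"):
        try:
            _, _, a0, sse = _smooth_fit(E, act)
            candidates["smooth"] = (a0, sse)
        except RuntimeError:
            pass
    if method in ("auto", "segments"):
        try:
            candidates["segments"] = _segment_construction(E, act)
        except EstimationError:
            pass
    if not candidates:
        raise EstimationError("no detection-limit construction converged")
    a0 = min(candidates.values(), key=lambda t: t[1])[0]
    if a0 > act.max() / 3.0 or a0 < act.min() / 10.0:
        raise EstimationError(
            "series lies entirely in one response regime; "
            "the flattening point is not bracketed"
        )
    # convert the flattening activity back to a concentration using the
    # series' own concentration/activity relation
    loga, logc = np.log10(act), np.log10(conc)
    if a0 <= act[0]:
        return float(conc[0] * a0 / act[0])
    return float(10.0 ** np.interp(np.log10(a0), loga, logc))


def selectivity_coefficient(
    runs: pd.DataFrame,
    potentials: pd.DataFrame | np.ndarray,
    sensor: SensorSpec,
    interferent: IonSpec,
    *,
    params: ActivityModelParams,
    ions: Sequence[IonSpec] | None = None,
    method: str = "fixed_interference",
    blank_flattening_activity: float | None = None,
) -> SelectivityEstimate:
    """log10 selectivity coefficient from mixed-solution runs.

    ``fixed_interference``: each fixed-level run is fitted for its flattening
    activity; after subtracting the electrode's own blank flattening (from a
    zero-level run in ``runs`` or from ``blank_flattening_activity``), the
    remainder divided by ``a_j^{z_i/z_j}`` is the selectivity coefficient.
    Runs whose interference term does not measurably exceed the blank are
    flagged unidentifiable.

    ``nonlinear_fit``: one joint least-squares fit of the full
    Nikolsky-Eisenmann response over every run, with the coefficient free.
    """
    from .design import DEFAULT_IONS

    ions = ions or DEFAULT_IONS
    if isinstance(potentials, pd.DataFrame):
        E_all = potentials[sensor.id].to_numpy(dtype=float)
    else:
        E_all = np.asarray(potentials, dtype=float)
    if len(E_all) != len(runs):
        raise InputError("potentials and runs differ in length")
    primary = sensor.primary_ion
    p = sensor.exponent(interferent)
    pidx = [k for k, i in enumerate(ions) if i.name == primary.name][0]
    jidx = [k for k, i in enumerate(ions) if i.name == interferent.name][0]
    acts = sample_activities(runs, ions, params)
    a_i, a_j = acts[:, pidx], acts[:, jidx]
    c_j = runs[conc_column(interferent)].to_numpy(dtype=float)

    levels = np.unique(c_j)
    blank_a0 = blank_flattening_activity
    if 0.0 in levels and blank_a0 is None:
        mask = c_j == 0.0
        _, _, blank_a0, _ = _smooth_fit(E_all[mask], a_i[mask])

    if method == "nonlinear_fit":
        la_min = np.log10(a_i.min()) - 8.0

        def model(X, e0, s, la0, lk):
            ai, aj = X
            term = np.where(aj > 0, 10.0**lk * np.where(aj > 0, aj, 1.0) ** p, 0.0)
            return e0 + s * np.log10(ai + 10.0**la0 + term)

        init_fix = selectivity_coefficient(
            runs, E_all, sensor, interferent, params=params, ions=ions,
            method="fixed_interference", blank_flattening_activity=blank_a0,
        )
        lk0 = init_fix.log_k_pot if np.isfinite(init_fix.log_k_pot) else -3.0
        top = linregress(np.log10(a_i[a_i > 0][-5:]), E_all[a_i > 0][-5:])
        la0_0 = np.log10(blank_a0) if blank_a0 else la_min + 4
        popt, _ = curve_fit(
            model,
            (a_i, a_j),
            E_all,
            p0=(top.intercept, top.slope, la0_0, lk0),
            maxfev=40000,
        )
        return SelectivityEstimate(
            sensor_id=sensor.id,
            interferent=interferent.name,
            log_k_pot=float(popt[3]),
            method="nonlinear_fit",
        )

    if method != "fixed_interference":
        raise InputError(f"unknown selectivity method {method!r}")

    per_level: list[tuple[float, float]] = []
    unidentifiable_levels = 0
    for level in levels[levels > 0]:
        mask = c_j == level
        _, _, a0_run, _ = _smooth_fit(E_all[mask], a_i[mask])
        t = a0_run - (blank_a0 or 0.0)
        floor = 0.05 * (blank_a0 or a0_run * 1e-9)
        if t <= floor:
            unidentifiable_levels += 1
            continue
        # the flattening level is set by the plateau branch, so the relevant
        # interferent activity is the one at low primary-ion content (adding
        # primary ion raises the ionic strength and depresses a_j)
        plateau = mask & (a_i <= a0_run)
        if not plateau.any():
            low = np.argsort(np.where(mask, a_i, np.inf))[:3]
            plateau = np.zeros_like(mask)
            plateau[low] = True
        a_j_run = float(a_j[plateau].mean())
        per_level.append((float(level), float(np.log10(t) - p * np.log10(a_j_run))))
    if not per_level:
        return SelectivityEstimate(
            sensor_id=sensor.id,
            interferent=interferent.name,
            log_k_pot=-np.inf,
            method="fixed_interference",
            identifiable=False,
        )
    log_k = float(np.mean([lk for _, lk in per_level]))
    return SelectivityEstimate(
        sensor_id=sensor.id,
        interferent=interferent.name,
        log_k_pot=log_k,
        method="fixed_interference",
        identifiable=unidentifiable_levels == 0,
        per_level=tuple(per_level),
    )


def slope_reproducibility(fits: Sequence[CalibrationFit | float]) -> float:
    """Relative standard deviation (%) of the slope across sessions."""
    slopes = np.array(
        [f.slope if isinstance(f, CalibrationFit) else float(f) for f in fits]
    )
    if len(slopes) < 2:
        raise InputError("at least two sessions are required")
    return float(100.0 * slopes.std(ddof=1) / abs(slopes.mean()))


def calibration_sessions(
    sensor: SensorSpec,
    params: ActivityModelParams,
    n_sessions: int,
    seed: int,
    ions: Sequence[IonSpec] | None = None,
    cal_table: pd.DataFrame | None = None,
) -> list[CalibrationFit]:
    """Repeated single-ion calibrations with per-session drift and noise."""
    from .design import DEFAULT_IONS, single_ion_calibration

    ions = ions or DEFAULT_IONS
    if cal_table is None:
        cal_table = single_ion_calibration(sensor.primary_ion, ions=ions)
    rng = np.random.default_rng(seed)
    fits = []
    for _ in range(n_sessions):
        offset = rng.normal(0.0, sensor.drift_sd_per_session)
        noise_seed = int(rng.integers(2**31 - 1))
        E = array_response(
            [sensor],
            cal_table,
            ions,
            params,
            noise_seed=noise_seed if sensor.noise_sd > 0 else None,
            e0_offsets={sensor.id: offset},
        )[sensor.id].to_numpy()
        fits.append(
            fit_calibration(
                E, table=cal_table, ion=sensor.primary_ion, params=params,
                sensor_id=sensor.id, ions=ions,
            )
        )
    return fits


def characterize_panel(
    panel: SensorPanel,
    *,
    calibration_background: float = 0.05,
    noise_seed: int | None = None,
    noiseless: bool = True,
    selectivity_method: str = "fixed_interference",
) -> pd.DataFrame:
    """Full characterization table: slope, detection limit, selectivities.

    Simulates each electrode's single-ion calibration (in a background
    electrolyte of the given ionic strength) and its mixed-solution runs
    (without background, as in unbuffered measurements), then runs the
    estimators.  With ``noiseless`` the recovered values equal the panel's
    generating parameters, which is the package's primary self-consistency
    check.
    """
    from dataclasses import replace

    from .design import (
        DEFAULT_IONS,
        default_fixed_levels,
        generate_selectivity_runs,
        single_ion_calibration,
    )

    ions = tuple(panel.ions)
    cal_params = replace(
        panel.activity, fixed_background_ionic_strength=calibration_background
    )
    mix_params = replace(panel.activity, fixed_background_ionic_strength=0.0)
    sensors = (
        tuple(replace(s, noise_sd=0.0, drift_sd_per_session=0.0) for s in panel.sensors)
        if noiseless
        else panel.sensors
    )
    rows = []
    rng = np.random.default_rng(noise_seed)
    for sensor in sensors:
        cal = single_ion_calibration(sensor.primary_ion, ions=ions)
        seed = int(rng.integers(2**31 - 1)) if sensor.noise_sd > 0 else None
        E = array_response([sensor], cal, ions, cal_params, noise_seed=seed)[sensor.id]
        fit = fit_calibration(
            E.to_numpy(), table=cal, ion=sensor.primary_ion, params=cal_params,
            sensor_id=sensor.id, ions=ions,
        )
        lod = detection_limit(
            E.to_numpy(), table=cal, ion=sensor.primary_ion, params=cal_params,
            ions=ions,
        )
        row: dict[str, object] = {
            "sensor": sensor.id,
            "primary_ion": sensor.primary_ion.name,
            "slope_mV_per_decade": fit.slope,
            "e0_mV": fit.e0_hat,
            "r2": fit.r2,
            "detection_limit_M": lod,
        }
        for name in sensor.selectivity:
            interferent = panel.ion(name)
            levels = [0.0] + default_fixed_levels(sensor, interferent, mix_params)
            runs = generate_selectivity_runs(
                sensor, interferent, levels, mix_params, ions=ions
            )
            seed = int(rng.integers(2**31 - 1)) if sensor.noise_sd > 0 else None
            E_runs = array_response(
                [sensor], runs, ions, mix_params, noise_seed=seed
            )
            est = selectivity_coefficient(
                runs, E_runs, sensor, interferent, params=mix_params, ions=ions,
                method=selectivity_method,
            )
            row[f"log_k_{name}"] = est.log_k_pot
        rows.append(row)
    return pd.DataFrame(rows)
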