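"""Forward response model of ion-selective electrodes (ISEs).

Each electrode follows the Nikolsky-Eisenmann law

    E = e0 + s · log10( a_i + a_bg + Σ_j k_pot_ij · a_j^(z_i/z_j) )

where ``a_i`` is the primary-ion activity, ``a_j`` the activities of
interfering ions weighted by their potentiometric selectivity coefficients
``k_pot_ij`` (stored as log10 values), and ``z_i/z_j`` the *signed* charge
ratio — for the anion pairs here both exponents are positive (perchlorate
primary with sulfide interfering: 1/2; sulfide primary with perchlorate
interfering: 2).  The additive background activity ``a_bg`` produces the
low-concentration flattening of real calibration curves and ties the
electrode's detection limit to a concrete mechanism: the IUPAC two-segment
construction applied to this response recovers exactly ``a_bg``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .activity import (
    ActivityModelParams,
    IonSpec,
    SolutionState,
    activity_coefficient,
)
from .errors import ConfigError, InputError, ModelError
from .tables import conc_column

__all__ = [
    "SensorSpec",
    "SensorPanel",
    "electrode_potential",
    "array_response",
    "sample_activities",
]


@dataclass(frozen=True)
class SensorSpec:
    """One electrode's response law and noise characteristics.

    ``e0`` (mV) and ``slope`` (mV/decade, negative for anions) are the
    intercept and sensitivity of the response; ``selectivity`` maps
    interfering-ion names to log10 of the selectivity coefficient;
    ``background_activity`` (mol/L, activity scale) sets the low-end
    flattening and hence the detection limit; ``noise_sd`` (mV) is additive
    per-reading measurement noise and ``drift_sd_per_session`` (mV) the
    session-to-session standard deviation of ``e0``.
    """

    id: str
    primary_ion: IonSpec
    e0: float
    slope: float
    selectivity: Mapping[str, float] = field(default_factory=dict)
    background_activity: float = 1e-12
    noise_sd: float = 0.0
    drift_sd_per_session: float = 0.0

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ConfigError(f"sensor {self.id!r}: slope must be nonzero")
        if self.background_activity <= 0:
            raise ConfigError(
                f"sensor {self.id!r}: background_activity must be positive"
            )
        if self.noise_sd < 0 or self.drift_sd_per_session < 0:
            raise ConfigError(f"sensor {self.id!r}: noise magnitudes must be >= 0")

    def exponent(self, interferent: IonSpec) -> float:
        """Signed charge-ratio exponent z_i / z_j for an interfering ion."""
        return self.primary_ion.charge / interferent.charge


@dataclass(frozen=True)
class SensorPanel:
    """A declared set of ions plus the electrodes that sense them."""

    ions: tuple[IonSpec, ...]
    sensors: tuple[SensorSpec, ...]
    activity: ActivityModelParams = field(default_factory=ActivityModelParams)
    calibration_reference_ionic_strength: float = 0.05

    def __post_init__(self) -> None:
        names = [ion.name for ion in self.ions]
        if len(set(names)) != len(names):
            raise ConfigError("ion names must be unique within a panel")
        by_name = {ion.name: ion for ion in self.ions}
        ids = [s.id for s in self.sensors]
        if len(set(ids)) != len(ids):
            raise ConfigError("sensor ids must be unique within a panel")
        for sensor in self.sensors:
            if sensor.primary_ion.name not in by_name:
                raise ConfigError(
                    f"sensor {sensor.id!r}: primary ion {sensor.primary_ion.name!r} "
                    "not declared in the panel"
                )
            for name in sensor.selectivity:
                if name not in by_name:
                    raise ConfigError(
                        f"sensor {sensor.id!r}: selectivity key {name!r} "
                        "is not a declared ion"
                    )

    def ion(self, name: str) -> IonSpec:
        for ion in self.ions:
            if ion.name == name:
                return ion
        raise InputError(f"ion {name!r} not declared in the panel")

    def sensor(self, sensor_id: str) -> SensorSpec:
        for s in self.sensors:
            if s.id == sensor_id:
                return s
        raise InputError(f"sensor {sensor_id!r} not in the panel")

    def with_noise(self, noise_sd: float, drift_sd: float | None = None) -> "SensorPanel":
        """Copy of the panel with every sensor's noise levels overridden."""
        sensors = tuple(
            replace(
                s,
                noise_sd=noise_sd,
                drift_sd_per_session=(
                    s.drift_sd_per_session if drift_sd is None else drift_sd
                ),
            )
            for s in self.sensors
        )
        return replace(self, sensors=sensors)


def _response_argument(
    sensor: SensorSpec,
    activities: Mapping[str, float],
    ions_by_name: Mapping[str, IonSpec],
) -> float:
    a_i = activities.get(sensor.primary_ion.name, 0.0)
    arg = a_i + sensor.background_activity
    for name, log_k in sensor.selectivity.items():
        a_j = activities.get(name, 0.0)
        if a_j > 0:
            arg += 10.0**log_k * a_j ** sensor.exponent(ions_by_name[name])
    return arg


def electrode_potential(
    sensor: SensorSpec,
    solution: SolutionState,
    params: ActivityModelParams,
) -> float:
    """Noise-free potential (mV) of one electrode in one solution."""
    names = {ion.name for ion in solution.concentrations}
    if sensor.primary_ion.name not in names:
        raise InputError(
            f"solution does not declare primary ion {sensor.primary_ion.name!r}"
        )
    activities = {
        ion.name: a for ion, a in solution.activities(params).items()
    }
    ions_by_name = {ion.name: ion for ion in solution.concentrations}
    arg = _response_argument(sensor, activities, ions_by_name)
    if arg <= 0:
        raise ModelError(
            f"sensor {sensor.id!r}: non-positive Nikolsky-Eisenmann argument {arg!r}"
        )
    return sensor.e0 + sensor.slope * np.log10(arg)


def _gamma_columns(
    table: pd.DataFrame, ions: Sequence[IonSpec], params: ActivityModelParams
) -> tuple[np.ndarray, np.ndarray]:
    """Per-row ionic strength and per-row, per-ion activity coefficients."""
    conc = np.column_stack(
        [table[conc_column(ion)].to_numpy(dtype=float) for ion in ions]
    ) if len(table) else np.zeros((0, len(ions)))
    if np.any(conc < 0) or not np.all(np.isfinite(conc)):
        raise InputError("concentrations must be finite and >= 0")
    weights = np.array([0.5 * (ion.charge**2 + abs(ion.charge)) for ion in ions])
    I = params.fixed_background_ionic_strength + conc @ weights
    if params.formalism == "ideal":
        gamma = np.ones_like(conc)
    else:
        sqrt_i = np.sqrt(I)
        if params.formalism == "davies":
            base = sqrt_i / (1.0 + sqrt_i) - params.davies_linear_term * I
        else:
            base = sqrt_i / (1.0 + params.B * params.ion_size_angstrom * sqrt_i)
        z2 = np.array([ion.charge**2 for ion in ions], dtype=float)
        gamma = 10.0 ** (-params.A * base[:, None] * z2[None, :])
    return I, gamma * conc  # returns activities, not gammas


def sample_activities(
    table: pd.DataFrame, ions: Sequence[IonSpec], params: ActivityModelParams
) -> np.ndarray:
    """Per-sample activities (n_samples, n_ions) for a sample table."""
    _, activities = _gamma_columns(table, ions, params)
    return activities


def array_response(
    sensors: Sequence[SensorSpec],
    samples: pd.DataFrame,
    ions: Sequence[IonSpec],
    params: ActivityModelParams,
    noise_seed: int | None = None,
    e0_offsets: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Potential matrix (mV): one row per sample, one column per sensor.

    With all ``noise_sd`` zero the result is deterministic; otherwise a seed
    is mandatory so that every matrix is reproducible.  ``e0_offsets`` adds a
    per-sensor constant (session drift) to the intercepts.
    """
    if not sensors:
        raise InputError("at least one sensor is required")
    noisy = any(s.noise_sd > 0 for s in sensors)
    if noisy and noise_seed is None:
        raise InputError("noise_seed is required when any sensor has noise_sd > 0")
    for sensor in sensors:
        if conc_column(sensor.primary_ion) not in samples.columns and len(samples):
            raise InputError(
                f"sample table lacks the primary ion of sensor {sensor.id!r}"
            )
    ions_by_name = {ion.name: ion for ion in ions}
    activities = sample_activities(samples, ions, params)
    index = (
        pd.Index(samples["sample_id"], name="sample_id")
        if "sample_id" in samples.columns
        else samples.index
    )
    out = pd.DataFrame(index=index, columns=[s.id for s in sensors], dtype=float)
    rng = np.random.default_rng(noise_seed) if noisy else None
    for sensor in sensors:
        j = [k for k, ion in enumerate(ions) if ion.name == sensor.primary_ion.name]
        arg = activities[:, j[0]] + sensor.background_activity if j else None
        if arg is None:
            raise InputError(
                f"sensor {sensor.id!r}: primary ion not among declared ions"
            )
        for name, log_k in sensor.selectivity.items():
            if name not in ions_by_name:
                raise InputError(
                    f"sensor {sensor.id!r}: interferent {name!r} not declared"
                )
            jj = [k for k, ion in enumerate(ions) if ion.name == name][0]
            a_j = activities[:, jj]
            p = sensor.exponent(ions_by_name[name])
            term = np.zeros_like(a_j)
            pos = a_j > 0
            term[pos] = 10.0**log_k * a_j[pos] ** p
            arg = arg + term
        if np.any(arg <= 0):
            raise ModelError(f"sensor {sensor.id!r}: non-positive response argument")
        e = sensor.e0 + sensor.slope * np.log10(arg)
        if e0_offsets and sensor.id in e0_offsets:
            e = e + e0_offsets[sensor.id]
        if rng is not None and sensor.noise_sd > 0:
            e = e + rng.normal(0.0, sensor.noise_sd, size=len(e))
        elif rng is not None:
            rng.normal(0.0, 1.0, size=len(e))  # keep stream alignment across sensors
        out[sensor.id] = e
    return out
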