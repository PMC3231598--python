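"""Ionic strength and single-ion activity coefficients.

Potentiometric sensors respond to ion *activities*, not analytical
concentrations.  This module converts between the two using ionic-strength
based mean-activity formalisms of the Debye-Hückel family:

* ``davies`` (default): ``log10 γ = -A z² (√I/(1+√I) - 0.3 I)``, adequate up
  to ionic strengths of roughly 0.5 M and therefore covering both the 0.05 M
  background electrolyte used for single-ion calibrations and the dilute,
  unbuffered mixture measurements.
* ``extended_debye_huckel``: ``log10 γ = -A z² √I / (1 + B·å·√I)`` with an
  ion-size parameter å in ångström.
* ``ideal``: γ ≡ 1, useful for algebraic toy problems and oracle tests.

Ionic strength bookkeeping includes the monovalent counter-ion (Na⁺) that
accompanies each fully dissociated sodium salt: a concentration ``c`` of an
ion with charge ``z`` contributes ``½ c (z² + |z|)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .errors import ConfigError, InputError

__all__ = [
    "IonSpec",
    "ActivityModelParams",
    "SolutionState",
    "ionic_strength",
    "activity_coefficient",
]

_FORMALISMS = ("davies", "extended_debye_huckel", "ideal")


@dataclass(frozen=True)
class IonSpec:
    """An ionic species with a signed charge (perchlorate -1, sulfide -2)."""

    name: str
    charge: int

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ConfigError(f"ion {self.name!r}: charge must be nonzero")
        if not self.name:
            raise ConfigError("ion name must be a nonempty identifier")


@dataclass(frozen=True)
class ActivityModelParams:
    """Parameters of the activity-coefficient model.

    ``A`` is the Debye-Hückel constant (L^1/2 mol^-1/2; 0.511 at 25 °C).
    ``fixed_background_ionic_strength`` represents an inert background
    electrolyte (e.g. 0.05 mol/L lithium acetate) that contributes to the
    ionic strength but is not tracked as a named ion.
    """

    formalism: str = "davies"
    A: float = 0.511
    B: float = 0.328  # extended DH: L^1/2 mol^-1/2 Å^-1 at 25 °C
    ion_size_angstrom: float = 4.0
    davies_linear_term: float = 0.3
    fixed_background_ionic_strength: float = 0.0

    def __post_init__(self) -> None:
        if self.formalism not in _FORMALISMS:
            raise ConfigError(
                f"unknown activity formalism {self.formalism!r}; "
                f"expected one of {_FORMALISMS}"
            )
        if self.A <= 0:
            raise ConfigError("Debye-Hückel constant A must be positive")
        if self.fixed_background_ionic_strength < 0:
            raise ConfigError("fixed_background_ionic_strength must be >= 0")


def ionic_strength(
    concentrations: Mapping[IonSpec, float], params: ActivityModelParams
) -> float:
    """Total ionic strength (mol/L) of a solution of sodium salts.

    ``I = I_background + ½ Σ c_i (z_i² + |z_i|)`` — the ``|z_i|`` term is the
    Na⁺ counter-ion released per formula unit of each salt.
    """
    I = params.fixed_background_ionic_strength
    for ion, c in concentrations.items():
        if not math.isfinite(c) or c < 0:
            raise InputError(
                f"concentration of {ion.name!r} must be finite and >= 0, got {c!r}"
            )
        I += 0.5 * c * (ion.charge**2 + abs(ion.charge))
    return I


def activity_coefficient(
    charge: int, I: float, params: ActivityModelParams
) -> float:
    """Single-ion activity coefficient γ at ionic strength ``I`` (mol/L)."""
    if I < 0:
        raise InputError(f"ionic strength must be >= 0, got {I!r}")
    if charge == 0 or I == 0.0 or params.formalism == "ideal":
        return 1.0
    sqrt_i = math.sqrt(I)
    if params.formalism == "davies":
        log10_gamma = -params.A * charge**2 * (
            sqrt_i / (1.0 + sqrt_i) - params.davies_linear_term * I
        )
    else:  # extended_debye_huckel
        log10_gamma = (
            -params.A
            * charge**2
            * sqrt_i
            / (1.0 + params.B * params.ion_size_angstrom * sqrt_i)
        )
    return 10.0**log10_gamma


@dataclass
class SolutionState:
    """Concentrations (mol/L) of the declared ions in a single solution."""

    concentrations: dict[IonSpec, float]
    volume: float = 0.025  # L

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise InputError("solution volume must be positive")

    def ionic_strength(self, params: ActivityModelParams) -> float:
        return ionic_strength(self.concentrations, params)

    def activities(self, params: ActivityModelParams) -> dict[IonSpec, float]:
        """Per-ion activities ``a = γ(z, I) · c`` (mol/L)."""
        I = self.ionic_strength(params)
        return {
            ion: activity_coefficient(ion.charge, I, params) * c
            for ion, c in self.concentrations.items()
        }
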