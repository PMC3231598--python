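"""Synthetic experiment generation: calibrations, mixture designs, spikes.

Everything the analysis pipeline consumes is produced here as a pure
function of (configuration, seed):

* single-ion calibration series built by cumulative microvolume additions
  of standard solutions into a measuring vessel;
* the 79-sample two-ion mixture design assembled from seven addition
  sequences spanning 5.0e-6 ... 3.3e-4 mol/L per ion, with single-ion and
  combined runs, and its 59/20 train/test split that keeps range extremes
  in the training subset;
* wastewater-like application samples spiked from a 0.01 M standard;
* mixed-solution (fixed-interference) selectivity runs.

Concentration arithmetic is a strict mass balance: adding a volume ``v`` of
a stock at ``c_s`` to ``V`` litres at ``c`` gives ``(cV + c_s v)/(V + v)``,
and every ion present is diluted by the same step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .activity import ActivityModelParams, IonSpec, activity_coefficient
from .errors import ConfigError, InputError
from .sensors import SensorSpec
from .tables import conc_column, make_sample_table

__all__ = [
    "PERCHLORATE",
    "SULFIDE",
    "DEFAULT_IONS",
    "ALLOWED_STOCKS",
    "AdditionStep",
    "AdditionSequence",
    "DesignConfig",
    "SpikeConfig",
    "cumulative_additions",
    "default_design_sequences",
    "generate_design",
    "split_train_test",
    "generate_spiked_samples",
    "generate_selectivity_runs",
    "default_fixed_levels",
    "single_ion_calibration",
]

PERCHLORATE = IonSpec("ClO4", -1)
SULFIDE = IonSpec("S", -2)
DEFAULT_IONS: tuple[IonSpec, ...] = (PERCHLORATE, SULFIDE)

#: Standard-solution concentrations available in the laboratory protocol.
ALLOWED_STOCKS: tuple[float, ...] = (1e-4, 1e-3, 1e-2, 1e-1, 1.0)

C_MIN = 5.0e-6  # mol/L, lower end of the mixture design per ion
C_MAX = 3.3e-4  # mol/L, upper end of the mixture design per ion


@dataclass(frozen=True)
class AdditionStep:
    """One microvolume addition of a (possibly mixed) standard solution.

    ``stock`` maps ion names to the stock's concentration of that ion; a
    multi-ion entry represents a combined standard containing both salts.
    """

    stock: Mapping[str, float]
    volume: float  # L

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ConfigError("addition volume must be positive")
        for name, c in self.stock.items():
            if c < 0:
                raise ConfigError(f"stock concentration of {name!r} must be >= 0")
            if c > 0 and not any(
                math.isclose(c, s, rel_tol=1e-9) for s in ALLOWED_STOCKS
            ):
                raise ConfigError(
                    f"stock concentration {c!r} for {name!r} is not one of the "
                    f"allowed standards {ALLOWED_STOCKS}"
                )


@dataclass(frozen=True)
class AdditionSequence:
    id: int
    steps: tuple[AdditionStep, ...]
    initial_volume: float = 0.025  # L
    initial_concentrations: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.initial_volume <= 0:
            raise ConfigError("initial volume must be positive")


def cumulative_additions(
    seq: AdditionSequence, ions: Sequence[IonSpec] = DEFAULT_IONS
) -> pd.DataFrame:
    """Sample table with one row per addition step (mass-balance exact)."""
    if not seq.steps:
        raise InputError("addition sequence has no steps")
    volume = seq.initial_volume
    conc = {ion.name: float(seq.initial_concentrations.get(ion.name, 0.0)) for ion in ions}
    rows = []
    for step in seq.steps:
        new_volume = volume + step.volume
        for ion in ions:
            added = step.stock.get(ion.name, 0.0) * step.volume
            conc[ion.name] = (conc[ion.name] * volume + added) / new_volume
        volume = new_volume
        rows.append([conc[ion.name] for ion in ions])
    table = make_sample_table(ions, np.array(rows), sequence_id=seq.id)
    table["volume_L"] = [
        seq.initial_volume + sum(s.volume for s in seq.steps[: k + 1])
        for k in range(len(seq.steps))
    ]
    return table


def _stock_for_target(target: float, headroom: float = 25.0) -> float:
    """Smallest allowed standard at least ``headroom``× the target level."""
    for s in ALLOWED_STOCKS:
        if s >= headroom * target:
            return s
    return ALLOWED_STOCKS[-1]


def _volume_for_target(volume: float, c_old: float, c_stock: float, target: float) -> float:
    if not (c_stock > target > c_old):
        raise ConfigError(
            f"cannot reach {target!r} from {c_old!r} with a {c_stock!r} M stock"
        )
    return volume * (target - c_old) / (c_stock - target)


def sequence_from_targets(
    seq_id: int,
    program: Sequence[tuple[tuple[str, ...], float]],
    *,
    initial_volume: float = 0.025,
    initial_concentrations: Mapping[str, float] | None = None,
    ions: Sequence[IonSpec] = DEFAULT_IONS,
) -> AdditionSequence:
    """Translate a ladder of target concentrations into solved addition volumes.

    Each program entry names the ion (or ions, for a combined standard) to
    raise and the concentration it should reach after that step, accounting
    for the dilution of everything already in the vessel.
    """
    volume = initial_volume
    conc = {ion.name: 0.0 for ion in ions}
    if initial_concentrations:
        conc.update(initial_concentrations)
    steps: list[AdditionStep] = []
    for target_ions, target in program:
        stock_c = _stock_for_target(target)
        # all raised ions share one addition volume (a mixed standard); they
        # must sit at a common pre-step concentration for an exact solve
        c_olds = {conc[name] for name in target_ions}
        if len(c_olds) != 1:
            raise ConfigError(
                "combined additions require equal pre-step concentrations"
            )
        c_old = c_olds.pop()
        v = _volume_for_target(volume, c_old, stock_c, target)
        new_volume = volume + v
        for name in conc:
            conc[name] = conc[name] * volume / new_volume
        for name in target_ions:
            conc[name] += stock_c * v / new_volume
        volume = new_volume
        steps.append(AdditionStep({name: stock_c for name in target_ions}, v))
    return AdditionSequence(
        id=seq_id,
        steps=tuple(steps),
        initial_volume=initial_volume,
        initial_concentrations=dict(initial_concentrations or {}),
    )


def _interleave(a: list, b: list) -> list:
    out = []
    for k in range(max(len(a), len(b))):
        if k < len(a):
            out.append(a[k])
        if k < len(b):
            out.append(b[k])
    return out


def default_design_sequences(
    c_min: float = C_MIN, c_max: float = C_MAX
) -> tuple[AdditionSequence, ...]:
    """The seven shipped addition sequences (12+12+12+11+11+11+10 = 79 rows).

    Sequences 1-2 ramp one ion alone (axis points of the design), sequence 3
    ramps a combined standard of both (diagonal), 4-5 hold one ion near the
    low end while ramping the other, 6-7 alternate unequal additions to fill
    the off-diagonal interior.
    """
    ladder12 = np.geomspace(c_min, c_max, 12)
    ladder10 = np.geomspace(c_min, c_max, 10)

    def prog(name: str, targets) -> list[tuple[tuple[str, ...], float]]:
        return [((name,), float(t)) for t in targets]

    programs: list[list[tuple[tuple[str, ...], float]]] = [
        prog("ClO4", ladder12),
        prog("S", ladder12),
        [(("ClO4", "S"), float(t)) for t in ladder12],
        [(("S",), 1.5e-5)] + prog("ClO4", ladder10),
        [(("ClO4",), 1.5e-5)] + prog("S", ladder10),
        _interleave(
            prog("ClO4", np.geomspace(2e-5, c_max, 6)),
            prog("S", np.geomspace(1e-5, 1.2e-4, 5)),
        ),
        _interleave(
            prog("S", np.geomspace(2e-5, c_max, 5)),
            prog("ClO4", np.geomspace(8e-6, 1e-4, 5)),
        ),
    ]
    return tuple(
        sequence_from_targets(i + 1, program) for i, program in enumerate(programs)
    )


@dataclass(frozen=True)
class DesignConfig:
    sequences: tuple[AdditionSequence, ...] | None = None  # None → shipped default
    c_min: float = C_MIN
    c_max: float = C_MAX
    expected_rows: int | None = 79


def generate_design(
    config: DesignConfig | None = None, ions: Sequence[IonSpec] = DEFAULT_IONS
) -> pd.DataFrame:
    """The full mixture design as a sample table (roles unassigned)."""
    config = config or DesignConfig()
    sequences = config.sequences or default_design_sequences(config.c_min, config.c_max)
    tables = [cumulative_additions(seq, ions) for seq in sequences]
    table = pd.concat(tables, ignore_index=True)
    table["sample_id"] = [f"D{k + 1:02d}" for k in range(len(table))]
    if config.expected_rows is not None and len(table) != config.expected_rows:
        raise ConfigError(
            f"design produced {len(table)} rows, expected {config.expected_rows}"
        )
    tol = 1e-9
    for ion in ions:
        c = table[conc_column(ion)].to_numpy()
        nz = c[c > 0]
        if nz.size == 0:
            raise ConfigError(f"design never adds ion {ion.name!r}")
        if nz.min() < config.c_min * (1 - tol) or nz.max() > config.c_max * (1 + tol):
            raise ConfigError(
                f"design leaves the declared range for ion {ion.name!r}"
            )
        if not (
            math.isclose(nz.min(), config.c_min, rel_tol=1e-6)
            and math.isclose(nz.max(), config.c_max, rel_tol=1e-6)
        ):
            raise ConfigError(
                f"design does not span the declared range for ion {ion.name!r}"
            )
    return table


def _extreme_mask(table: pd.DataFrame, ions: Sequence[IonSpec]) -> np.ndarray:
    """Rows attaining a per-ion (nonzero) design minimum or maximum."""
    mask = np.zeros(len(table), dtype=bool)
    for ion in ions:
        c = table[conc_column(ion)].to_numpy()
        nz = c[c > 0]
        for extreme in (nz.min(), nz.max()):
            mask |= np.isclose(c, extreme, rtol=1e-9, atol=0.0)
    return mask


def split_train_test(
    table: pd.DataFrame,
    seed: int,
    n_test: int = 20,
    ions: Sequence[IonSpec] = DEFAULT_IONS,
) -> pd.DataFrame:
    """Assign train/test roles: extremes forced to train, remainder shuffled."""
    table = table.copy()
    forced = _extreme_mask(table, ions)
    free = np.flatnonzero(~forced)
    if len(free) < n_test:
        raise InputError(
            f"cannot reserve {n_test} test rows: only {len(free)} non-extreme rows"
        )
    rng = np.random.default_rng(seed)
    test_idx = rng.choice(free, size=n_test, replace=False)
    roles = np.full(len(table), "train", dtype=object)
    roles[test_idx] = "test"
    table["role"] = roles
    return table


@dataclass(frozen=True)
class SpikeConfig:
    n_samples: int = 6
    baseline_range: tuple[float, float] = (0.3e-6, 3.4e-5)  # mol/L per ion
    spike_stock: float = 1e-2  # mol/L standard used for the additions
    max_concentration: float = 5.0e-4  # mol/L cap after spiking
    min_final: float = 5.0e-5  # lowest final spike target
    initial_volume: float = 0.025  # L

    def __post_init__(self) -> None:
        lo, hi = self.baseline_range
        if not (0 <= lo < hi):
            raise ConfigError("baseline range must satisfy 0 <= low < high")
        if self.max_concentration <= hi:
            raise ConfigError("max_concentration must exceed the baseline range")


def generate_spiked_samples(
    config: SpikeConfig | None = None,
    seed: int = 0,
    ions: Sequence[IonSpec] = DEFAULT_IONS,
) -> pd.DataFrame:
    """Wastewater-like application samples after standard-addition spiking.

    Each sample starts from a random baseline concentration of both ions and
    receives one spike per ion from the 0.01 M standard; final per-ion levels
    are log-spaced between ``min_final`` and ``max_concentration``, with the
    pairing between the two ions permuted per seed.
    """
    config = config or SpikeConfig()
    rng = np.random.default_rng(seed)
    lo, hi = config.baseline_range
    n = config.n_samples
    targets = np.geomspace(config.min_final, config.max_concentration, n)
    per_ion_targets = {ion.name: rng.permutation(targets) for ion in ions}
    rows = []
    for i in range(n):
        baseline = {ion.name: float(rng.uniform(lo, hi)) for ion in ions}
        volume = config.initial_volume
        conc = dict(baseline)
        for ion in ions:
            target = float(per_ion_targets[ion.name][i])
            v = _volume_for_target(volume, conc[ion.name], config.spike_stock, target)
            new_volume = volume + v
            for name in conc:
                conc[name] *= volume / new_volume
            conc[ion.name] += config.spike_stock * v / new_volume
            volume = new_volume
        rows.append([conc[ion.name] for ion in ions])
    out = make_sample_table(
        ions, np.array(rows), sequence_id="spike", role="application"
    )
    out["sample_id"] = [f"W{k + 1}" for k in range(n)]
    cap = config.max_concentration * (1 + 1e-9)
    if np.any(np.array(rows) > cap):
        raise ConfigError("spiking exceeded the declared maximum concentration")
    return out


def _concentration_for_activity(
    target_activity: float,
    ion: IonSpec,
    params: ActivityModelParams,
    extra_ionic_strength: float = 0.0,
) -> float:
    """Invert a = γ(I(c))·c by fixed-point iteration (converges in a few steps)."""
    c = target_activity
    for _ in range(30):
        I = (
            params.fixed_background_ionic_strength
            + extra_ionic_strength
            + 0.5 * c * (ion.charge**2 + abs(ion.charge))
        )
        c = target_activity / activity_coefficient(ion.charge, I, params)
    return c


def generate_selectivity_runs(
    sensor: SensorSpec,
    interferent: IonSpec,
    fixed_levels: Sequence[float],
    params: ActivityModelParams,
    ions: Sequence[IonSpec] = DEFAULT_IONS,
    n_points: int = 13,
    decades_below: float = 2.0,
    decades_above: float = 2.0,
) -> pd.DataFrame:
    """Mixed-solution method runs: fixed interferent, ramped primary ion.

    For each fixed level the primary-ion grid is centred (in log space) on
    the expected flattening concentration — where the interference term plus
    the sensor's own background activity equals the primary activity — and
    spans ``decades_below`` + ``decades_above`` decades around it, so both
    the plateau and the linear branch are observable.  A level of exactly 0
    degenerates to a plain single-ion calibration.
    """
    if len(fixed_levels) == 0:
        raise InputError("at least one fixed interferent level is required")
    if interferent.name not in {ion.name for ion in ions}:
        raise InputError(f"interferent {interferent.name!r} not declared")
    primary = sensor.primary_ion
    tables = []
    for run_idx, level in enumerate(fixed_levels):
        if level < 0:
            raise InputError("fixed interferent level must be >= 0")
        flattening = sensor.background_activity
        extra_I = 0.5 * level * (interferent.charge**2 + abs(interferent.charge))
        if level > 0 and interferent.name in sensor.selectivity:
            gamma_j = activity_coefficient(
                interferent.charge,
                params.fixed_background_ionic_strength + extra_I,
                params,
            )
            a_j = gamma_j * level
            flattening += (
                10.0 ** sensor.selectivity[interferent.name]
                * a_j ** sensor.exponent(interferent)
            )
        c_flat = _concentration_for_activity(flattening, primary, params, extra_I)
        grid = np.geomspace(
            c_flat * 10.0**-decades_below, c_flat * 10.0**decades_above, n_points
        )
        conc = np.zeros((n_points, len(ions)))
        for j, ion in enumerate(ions):
            if ion.name == primary.name:
                conc[:, j] = grid
            elif ion.name == interferent.name:
                conc[:, j] = level
        t = make_sample_table(ions, conc, sequence_id=run_idx, role="selectivity")
        t["sample_id"] = [f"{sensor.id}-L{run_idx}-{k + 1}" for k in range(n_points)]
        t["fixed_level_M"] = level
        tables.append(t)
    return pd.concat(tables, ignore_index=True)


def default_fixed_levels(
    sensor: SensorSpec,
    interferent: IonSpec,
    params: ActivityModelParams,
    factors: Sequence[float] = (100.0, 1000.0),
    max_level: float = 1.0,
    min_level: float = 1e-5,
) -> list[float]:
    """Interferent levels at which the flattening shift is clearly measurable.

    Levels are chosen so the interference term is ``factor`` times the
    sensor's own background activity, then clipped to the available stock
    range; duplicates after clipping collapse to one level.  For weakly
    interfering electrode/ion pairs this pushes toward the 1 M stock, which
    is exactly what the fixed-interference method requires in practice.
    """
    if interferent.name not in sensor.selectivity:
        raise InputError(
            f"sensor {sensor.id!r} declares no selectivity toward {interferent.name!r}"
        )
    k = 10.0 ** sensor.selectivity[interferent.name]
    p = sensor.exponent(interferent)
    levels = []
    for factor in factors:
        a_j = (factor * sensor.background_activity / k) ** (1.0 / p)
        c = _concentration_for_activity(a_j, interferent, params)
        levels.append(float(np.clip(c, min_level, max_level)))
    unique: list[float] = []
    for lv in levels:
        if not any(math.isclose(lv, u, rel_tol=1e-6) for u in unique):
            unique.append(lv)
    return unique


def single_ion_calibration(
    ion: IonSpec,
    n_points: int = 10,
    c_min: float = 1e-6,
    c_max: float = 1e-3,
    initial_volume: float = 0.025,
    ions: Sequence[IonSpec] = DEFAULT_IONS,
    sequence_id: object = "cal",
) -> pd.DataFrame:
    """Single-ion calibration series built by cumulative standard additions."""
    targets = np.geomspace(c_min, c_max, n_points)
    seq = sequence_from_targets(
        0, [((ion.name,), float(t)) for t in targets], initial_volume=initial_volume,
        ions=ions,
    )
    table = cumulative_additions(seq, ions)
    table["sequence_id"] = sequence_id
    table["role"] = "calibration"
    table["sample_id"] = [f"C-{ion.name}-{k + 1}" for k in range(len(table))]
    return table
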