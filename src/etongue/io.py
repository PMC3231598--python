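"""File formats: sensor panel YAML, tabular CSV, model JSON.

All tabular exchange uses plain CSV with dot-decimal, full-precision
floats, so every artifact round-trips exactly and is regenerable from
(config, seed) alone.  The trained network is serialized as JSON carrying
layer sizes, transfer names, weight matrices and the input/output scaling.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .activity import ActivityModelParams, IonSpec, activity_coefficient
from .ann import AffineScaler, MLPModel
from .errors import ConfigError, ParseError
from .sensors import SensorPanel, SensorSpec

__all__ = [
    "default_panel_path",
    "load_panel",
    "read_sample_table",
    "write_sample_table",
    "read_potentials",
    "write_potentials",
    "save_model",
    "load_model",
]

_FLOAT_FMT = "%.17g"


def default_panel_path() -> Path:
    return Path(resources.files("etongue").joinpath("data/default_panel.yaml"))


def load_panel(path: str | Path | None = None) -> SensorPanel:
    """Load a sensor panel from YAML (``None`` loads the shipped default).

    Each sensor entry needs ``id``, ``primary_ion``, ``e0_mV``,
    ``slope_mV_per_decade`` and either ``background_activity_M`` directly or
    ``detection_limit_M``, from which the background activity is derived at
    the calibration reference ionic strength.
    """
    path = Path(path) if path is not None else default_panel_path()
    if not path.exists():
        raise ConfigError(f"panel file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ParseError(f"panel file {path}: {exc}") from exc
    if not isinstance(raw, dict) or "ions" not in raw or "sensors" not in raw:
        raise ConfigError(f"panel file {path} must declare 'ions' and 'sensors'")
    act_raw = raw.get("activity", {})
    activity = ActivityModelParams(
        formalism=act_raw.get("formalism", "davies"),
        A=float(act_raw.get("A", 0.511)),
        B=float(act_raw.get("B", 0.328)),
        ion_size_angstrom=float(act_raw.get("ion_size_angstrom", 4.0)),
    )
    i_ref = float(raw.get("calibration_reference_ionic_strength_M", 0.05))
    ions = tuple(
        IonSpec(name=str(e["name"]), charge=int(e["charge"])) for e in raw["ions"]
    )
    by_name = {ion.name: ion for ion in ions}
    sensors = []
    for e in raw["sensors"]:
        try:
            primary = by_name[str(e["primary_ion"])]
            if "background_activity_M" in e:
                a_bg = float(e["background_activity_M"])
            else:
                lod = float(e["detection_limit_M"])
                gamma = activity_coefficient(primary.charge, i_ref, activity)
                a_bg = gamma * lod
            sensors.append(
                SensorSpec(
                    id=str(e["id"]),
                    primary_ion=primary,
                    e0=float(e["e0_mV"]),
                    slope=float(e["slope_mV_per_decade"]),
                    selectivity={
                        str(k): float(v) for k, v in (e.get("log_k_pot") or {}).items()
                    },
                    background_activity=a_bg,
                    noise_sd=float(e.get("noise_sd_mV", 0.0)),
                    drift_sd_per_session=float(e.get("drift_sd_per_session_mV", 0.0)),
                )
            )
        except KeyError as exc:
            raise ConfigError(
                f"panel file {path}: sensor entry {e.get('id', '?')!r} "
                f"lacks required key {exc}"
            ) from exc
    return SensorPanel(
        ions=ions,
        sensors=tuple(sensors),
        activity=activity,
        calibration_reference_ionic_strength=i_ref,
    )


def write_sample_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_sample_table(path: str | Path) -> pd.DataFrame:
    try:
        table = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, FileNotFoundError, UnicodeDecodeError) as exc:
        raise ParseError(f"sample table {path}: {exc}") from exc
    if "sample_id" not in table.columns:
        raise ParseError(f"sample table {path}: missing 'sample_id' column")
    for col in table.columns:
        if col.startswith("c_") and not np.issubdtype(table[col].dtype, np.number):
            bad = table[pd.to_numeric(table[col], errors="coerce").isna()].index
            if len(bad):
                raise ParseError(
                    f"sample table {path}: non-numeric value in column {col!r} "
                    f"at data line {int(bad[0]) + 2}"
                )
            table[col] = table[col].astype(float)
    table["sample_id"] = table["sample_id"].astype(str)
    return table


def write_potentials(potentials: pd.DataFrame, path: str | Path) -> None:
    potentials.to_csv(path, index=True, float_format=_FLOAT_FMT)


def read_potentials(path: str | Path) -> pd.DataFrame:
    try:
        out = pd.read_csv(path, index_col=0, float_precision="round_trip")
    except (pd.errors.ParserError, FileNotFoundError, UnicodeDecodeError) as exc:
        raise ParseError(f"potential matrix {path}: {exc}") from exc
    out.index = out.index.astype(str)
    return out


def save_model(model: MLPModel, path: str | Path) -> None:
    payload = {
        "layer_sizes": list(model.layer_sizes),
        "hidden_transfer": model.hidden_transfer,
        "output_transfer": model.output_transfer,
        "W1": model.W1.tolist(),
        "b1": model.b1.tolist(),
        "W2": model.W2.tolist(),
        "b2": model.b2.tolist(),
        "input_scaling": {
            "lo": model.input_scaler.lo.tolist(),
            "hi": model.input_scaler.hi.tolist(),
        }
        if model.input_scaler
        else None,
        "output_scaling": {
            "lo": model.output_scaler.lo.tolist(),
            "hi": model.output_scaler.hi.tolist(),
        }
        if model.output_scaler
        else None,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> MLPModel:
    try:
        payload = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, FileNotFoundError) as exc:
        raise ParseError(f"model file {path}: {exc}") from exc

    def scaler(entry):
        if entry is None:
            return None
        return AffineScaler(
            lo=np.asarray(entry["lo"], dtype=float),
            hi=np.asarray(entry["hi"], dtype=float),
        )

    return MLPModel(
        layer_sizes=tuple(payload["layer_sizes"]),
        hidden_transfer=payload["hidden_transfer"],
        output_transfer=payload["output_transfer"],
        W1=np.asarray(payload["W1"], dtype=float),
        b1=np.asarray(payload["b1"], dtype=float),
        W2=np.asarray(payload["W2"], dtype=float),
        b2=np.asarray(payload["b2"], dtype=float),
        input_scaler=scaler(payload["input_scaling"]),
        output_scaler=scaler(payload["output_scaling"]),
    )
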