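"""End-to-end orchestration: simulate → characterize → train → evaluate.

One master seed deterministically derives every stage seed, so a pipeline
run is a pure function of (configuration, seed): re-running with the same
inputs reproduces every CSV byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ann import MLPModel, TrainingConfig, forward, multi_restart_train
from .characterize import (
    CalibrationFit,
    detection_limit,
    fit_calibration,
    selectivity_coefficient,
)
from .design import (
    DEFAULT_IONS,
    SpikeConfig,
    default_fixed_levels,
    generate_design,
    generate_selectivity_runs,
    generate_spiked_samples,
    single_ion_calibration,
    split_train_test,
)
from .errors import ConfigError
from .evaluate import (
    comparison_regression,
    paired_t_test,
    relative_errors,
    rmse,
    single_ise_baseline,
)
from .io import load_panel, save_model, write_potentials, write_sample_table
from .sensors import array_response
from .tables import concentration_matrix

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_pipeline_config"]


@dataclass(frozen=True)
class PipelineConfig:
    panel_path: str | None = None  # None → shipped default panel
    outdir: str = "etongue_run"
    seed: int = 1
    noise_sd_mV: float | None = None  # override every sensor's noise level
    calibration_background_M: float = 0.05
    hidden_units: int = 8
    hidden_transfer: str = "tansig"
    n_restarts: int = 5
    max_epochs: int = 300
    n_test: int = 20
    confidence: float = 0.95
    baseline_electrodes: Mapping[str, str] = field(
        default_factory=lambda: {"ClO4": "P1", "S": "S3"}
    )
    spike: SpikeConfig = field(default_factory=SpikeConfig)
    min_expected_for_errors: float = 1e-5  # mol/L floor for relative errors
    make_plots: bool = True


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    spike = SpikeConfig(**raw.pop("spike", {})) if "spike" in raw else SpikeConfig()
    known = PipelineConfig.__dataclass_fields__
    unknown = set(raw) - set(known)
    if unknown:
        raise ConfigError(f"unknown pipeline config keys: {sorted(unknown)}")
    return PipelineConfig(spike=spike, **raw)


@dataclass
class PipelineResult:
    config: PipelineConfig
    design: pd.DataFrame
    potentials: pd.DataFrame
    characterization: pd.DataFrame
    calibration_fits: dict[str, CalibrationFit]
    model: MLPModel
    comparison: pd.DataFrame
    spiked: pd.DataFrame
    spiked_predictions: pd.DataFrame
    errors: pd.DataFrame
    error_aggregates: dict[str, dict[str, float]]
    ttests: pd.DataFrame
    outdir: Path


def _stage_seeds(master: int, n: int = 8) -> list[int]:
    return [
        int(s.generate_state(1)[0] % (2**31 - 1))
        for s in np.random.SeedSequence(master).spawn(n)
    ]


def run_pipeline(config: PipelineConfig | None = None) -> PipelineResult:
    """Run the whole study and write its report bundle to ``config.outdir``."""
    config = config or PipelineConfig()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel = load_panel(config.panel_path)
    if config.noise_sd_mV is not None:
        panel = panel.with_noise(config.noise_sd_mV)
    ions = tuple(panel.ions)
    ion_names = [ion.name for ion in ions]
    noisy = any(s.noise_sd > 0 for s in panel.sensors)
    (
        seed_split,
        seed_train_noise,
        seed_cal_noise,
        seed_ann,
        seed_spike,
        seed_spike_noise,
        *_,
    ) = _stage_seeds(config.seed)
    mix_params = replace(panel.activity, fixed_background_ionic_strength=0.0)
    cal_params = replace(
        panel.activity,
        fixed_background_ionic_strength=config.calibration_background_M,
    )

    # --- stage 1: mixture design and array response -------------------------
    design = split_train_test(generate_design(ions=ions), seed_split,
                              n_test=config.n_test, ions=ions)
    potentials = array_response(
        panel.sensors, design, ions, mix_params,
        noise_seed=seed_train_noise if noisy else None,
    )

    # --- stage 2: per-electrode characterization ----------------------------
    cal_rng = np.random.default_rng(seed_cal_noise)
    fits: dict[str, CalibrationFit] = {}
    char_rows = []
    for sensor in panel.sensors:
        cal = single_ion_calibration(sensor.primary_ion, ions=ions)
        seed = int(cal_rng.integers(2**31 - 1)) if sensor.noise_sd > 0 else None
        E = array_response([sensor], cal, ions, cal_params, noise_seed=seed)[sensor.id]
        fit = fit_calibration(
            E.to_numpy(), table=cal, ion=sensor.primary_ion, params=cal_params,
            sensor_id=sensor.id, ions=ions,
        )
        lod = detection_limit(
            E.to_numpy(), table=cal, ion=sensor.primary_ion, params=cal_params,
            ions=ions,
        )
        fits[sensor.id] = fit
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
            seed = int(cal_rng.integers(2**31 - 1)) if sensor.noise_sd > 0 else None
            E_runs = array_response([sensor], runs, ions, mix_params, noise_seed=seed)
            est = selectivity_coefficient(
                runs, E_runs, sensor, interferent, params=mix_params, ions=ions
            )
            row[f"log_k_{name}"] = est.log_k_pot
        char_rows.append(row)
    characterization = pd.DataFrame(char_rows)

    # --- stage 3: inverse-model training ------------------------------------
    train_mask = (design["role"] == "train").to_numpy()
    test_mask = (design["role"] == "test").to_numpy()
    X = potentials.to_numpy(dtype=float)
    Y = concentration_matrix(design, ions)
    template = MLPModel(
        layer_sizes=(len(panel.sensors), config.hidden_units, len(ions)),
        hidden_transfer=config.hidden_transfer,
    )
    tconfig = TrainingConfig(
        n_restarts=config.n_restarts, max_epochs=config.max_epochs, seed=seed_ann
    )
    model, restarts = multi_restart_train(
        template, X[train_mask], Y[train_mask], X[test_mask], Y[test_mask], tconfig
    )

    # --- stage 4: obtained-vs-expected comparison ---------------------------
    comp_rows = []
    for subset, mask in (("train", train_mask), ("test", test_mask)):
        pred = forward(model, X[mask])
        res = rmse(pred, Y[mask], ion_names=ion_names)
        for j, name in enumerate(ion_names):
            reg = comparison_regression(
                pred[:, j], Y[mask][:, j], confidence=config.confidence,
                ion=name, subset=subset,
            )
            comp_rows.append(
                {
                    "ion": name,
                    "subset": subset,
                    "rmse_M": res.per_ion[name],
                    "slope": reg.slope,
                    "slope_lo": reg.slope_ci[0],
                    "slope_hi": reg.slope_ci[1],
                    "intercept": reg.intercept,
                    "intercept_lo": reg.intercept_ci[0],
                    "intercept_hi": reg.intercept_ci[1],
                    "r": reg.r,
                    "contains_unity_slope": reg.contains_unity_slope,
                    "contains_zero_intercept": reg.contains_zero_intercept,
                }
            )
    comparison = pd.DataFrame(comp_rows)

    # --- stage 5: spiked application samples, ET vs single-ISE --------------
    spiked = generate_spiked_samples(config.spike, seed_spike, ions=ions)
    spiked_potentials = array_response(
        panel.sensors, spiked, ions, mix_params,
        noise_seed=seed_spike_noise if noisy else None,
    )
    nominal = concentration_matrix(spiked, ions)
    et_pred, extrapolating = forward(
        model, spiked_potentials.to_numpy(dtype=float), return_extrapolation_flags=True
    )
    base_pred, base_flags = single_ise_baseline(
        spiked_potentials, fits, config.baseline_electrodes, ions, mix_params
    )
    et_report = relative_errors(
        et_pred, nominal, ion_names=ion_names, method="ET",
        sample_ids=spiked["sample_id"], min_expected=config.min_expected_for_errors,
    )
    base_report = relative_errors(
        base_pred[ion_names].to_numpy(), nominal, ion_names=ion_names,
        method="single_ISE", sample_ids=spiked["sample_id"],
        min_expected=config.min_expected_for_errors,
    )
    errors = pd.concat([et_report.table, base_report.table], ignore_index=True)
    aggregates = {**et_report.aggregate, **base_report.aggregate}
    ttests = pd.DataFrame(
        [
            {
                "ion": name,
                "method": "ET",
                **asdict(paired_t_test(et_pred[:, j], nominal[:, j], config.confidence)),
            }
            for j, name in enumerate(ion_names)
        ]
    )
    spiked_predictions = pd.DataFrame(
        {
            "sample_id": spiked["sample_id"],
            **{f"nominal_{n}": nominal[:, j] for j, n in enumerate(ion_names)},
            **{f"ET_{n}": et_pred[:, j] for j, n in enumerate(ion_names)},
            **{f"ISE_{n}": base_pred[n].to_numpy() for n in ion_names},
            "extrapolating": extrapolating,
        }
    )

    # --- stage 6: report bundle ---------------------------------------------
    write_sample_table(design, outdir / "design.csv")
    write_potentials(potentials, outdir / "potentials.csv")
    characterization.to_csv(outdir / "characterization.csv", index=False,
                            float_format="%.17g")
    save_model(model, outdir / "model.json")
    comparison.to_csv(outdir / "comparison.csv", index=False, float_format="%.17g")
    write_sample_table(spiked, outdir / "spiked_samples.csv")
    write_potentials(spiked_potentials, outdir / "spiked_potentials.csv")
    spiked_predictions.to_csv(outdir / "spiked_predictions.csv", index=False,
                              float_format="%.17g")
    errors.to_csv(outdir / "errors.csv", index=False, float_format="%.17g")
    ttests.to_csv(outdir / "ttests.csv", index=False, float_format="%.17g")
    log = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "config": _config_dict(config),
        "restart_test_rmse": list(restarts.test_rmse),
        "error_aggregates": aggregates,
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=1, default=str))
    if config.make_plots:
        _make_plots(outdir, design, spiked, comparison, errors, ions)
    return PipelineResult(
        config=config,
        design=design,
        potentials=potentials,
        characterization=characterization,
        calibration_fits=fits,
        model=model,
        comparison=comparison,
        spiked=spiked,
        spiked_predictions=spiked_predictions,
        errors=errors,
        error_aggregates=aggregates,
        ttests=ttests,
        outdir=outdir,
    )


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["baseline_electrodes"] = dict(config.baseline_electrodes)
    return d


def _make_plots(outdir, design, spiked, comparison, errors, ions):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .tables import conc_column

    fig, ax = plt.subplots(figsize=(5, 5))
    for seq, sub in design.groupby("sequence_id"):
        ax.plot(sub[conc_column(ions[0])], sub[conc_column(ions[1])], "o",
                label=f"seq {seq}", alpha=0.7)
    ax.set_xlabel(f"[{ions[0].name}] / M")
    ax.set_ylabel(f"[{ions[1].name}] / M")
    ax.set_title("Mixture design")
    ax.legend(fontsize=7)
    fig.savefig(outdir / "design.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    for (method, ion), sub in errors.groupby(["method", "ion"]):
        ax.bar(
            [f"{method}\n{ion}"], [sub["rel_err_pct"].mean()],
            yerr=[sub["rel_err_pct"].std(ddof=0)], capsize=4,
        )
    ax.set_ylabel("relative error / %")
    ax.set_title("Spiked samples: electronic tongue vs single ISE")
    fig.savefig(outdir / "errors.png", dpi=120)
    plt.close(fig)
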