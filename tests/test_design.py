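"""Synthetic experiment generation: mass balance, design shape, splits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from etongue.design import (
    ALLOWED_STOCKS,
    DEFAULT_IONS,
    AdditionSequence,
    AdditionStep,
    SpikeConfig,
    cumulative_additions,
    default_fixed_levels,
    generate_selectivity_runs,
    generate_spiked_samples,
    single_ion_calibration,
    split_train_test,
)
from etongue.errors import ConfigError, InputError

CLO4, S = DEFAULT_IONS


class TestCumulativeAdditions:
    def test_single_step_mass_balance(self):
        # 25 mL water + 25 mL of 1e-4 M stock -> 5e-5 M
        seq = AdditionSequence(
            id=1, steps=(AdditionStep({"ClO4": 1e-4}, 0.025),), initial_volume=0.025
        )
        out = cumulative_additions(seq)
        assert out["c_ClO4"].iloc[0] == pytest.approx(5e-5, rel=1e-12)

    def test_zero_stock_is_pure_dilution(self):
        seq = AdditionSequence(
            id=1,
            steps=(AdditionStep({"ClO4": 0.0}, 0.005),),
            initial_volume=0.025,
            initial_concentrations={"ClO4": 1e-4, "S": 2e-4},
        )
        out = cumulative_additions(seq)
        factor = 0.025 / 0.030
        assert out["c_ClO4"].iloc[0] == pytest.approx(1e-4 * factor, rel=1e-12)
        assert out["c_S"].iloc[0] == pytest.approx(2e-4 * factor, rel=1e-12)

    @settings(max_examples=40, derandomize=True)
    @given(data=st.data())
    def test_moles_conserved_across_every_step(self, data):
        n_steps = data.draw(st.integers(1, 8))
        steps = []
        for _ in range(n_steps):
            stock = data.draw(st.sampled_from(ALLOWED_STOCKS))
            ion = data.draw(st.sampled_from(["ClO4", "S"]))
            vol = data.draw(st.floats(1e-6, 5e-3))
            steps.append(AdditionStep({ion: stock}, vol))
        seq = AdditionSequence(id=9, steps=tuple(steps), initial_volume=0.025)
        out = cumulative_additions(seq)
        added = {"ClO4": 0.0, "S": 0.0}
        volume = 0.025
        for k, step in enumerate(steps):
            for ion, c in step.stock.items():
                added[ion] += c * step.volume
            volume += step.volume
            for ion in ("ClO4", "S"):
                moles = out[f"c_{ion}"].iloc[k] * volume
                assert moles == pytest.approx(added[ion], rel=1e-12, abs=1e-30)

    def test_empty_sequence_rejected(self):
        with pytest.raises(InputError):
            cumulative_additions(
                AdditionSequence(id=1, steps=(), initial_volume=0.025)
            )

    def test_disallowed_stock_rejected(self):
        with pytest.raises(ConfigError):
            AdditionStep({"ClO4": 3.3e-3}, 1e-4)


class TestMixtureDesign:
    def test_design_has_79_samples(self, design):
        assert len(design) == 79
        assert design["sample_id"].is_unique
        assert design["sequence_id"].nunique() == 7

    def test_per_ion_range_spans_5em6_to_33em5(self, design):
        for ion in DEFAULT_IONS:
            c = design[f"c_{ion.name}"].to_numpy()
            nz = c[c > 0]
            assert nz.min() == pytest.approx(5.0e-6, rel=1e-9)
            assert nz.max() == pytest.approx(3.3e-4, rel=1e-9)
            assert np.all(nz >= 5.0e-6 * (1 - 1e-9))
            assert np.all(nz <= 3.3e-4 * (1 + 1e-9))

    def test_design_covers_axes_and_interior(self, design):
        c1 = design["c_ClO4"].to_numpy()
        c2 = design["c_S"].to_numpy()
        assert ((c1 > 0) & (c2 == 0)).any()  # perchlorate-only sequences
        assert ((c1 == 0) & (c2 > 0)).any()  # sulfide-only sequences
        both = (c1 > 0) & (c2 > 0)
        ratio = c2[both] / c1[both]
        assert both.sum() > 30
        assert ratio.min() < 0.5 and ratio.max() > 2.0  # off-diagonal coverage

    def test_two_stock_levels_per_ion(self, design):
        # the shipped sequences draw on exactly two standards per ion
        from etongue.design import default_design_sequences

        stocks = {"ClO4": set(), "S": set()}
        for seq in default_design_sequences():
            for step in seq.steps:
                for ion, c in step.stock.items():
                    stocks[ion].add(c)
        assert stocks["ClO4"] == {1e-3, 1e-2}
        assert stocks["S"] == {1e-3, 1e-2}


class TestSplit:
    def test_59_train_20_test(self, design):
        split = split_train_test(design, seed=123)
        assert (split["role"] == "train").sum() == 59
        assert (split["role"] == "test").sum() == 20

    def test_extremes_forced_into_training_subset(self, design):
        split = split_train_test(design, seed=7)
        for ion in DEFAULT_IONS:
            c = split[f"c_{ion.name}"].to_numpy()
            nz = c[c > 0]
            for extreme in (nz.min(), nz.max()):
                rows = np.isclose(c, extreme, rtol=1e-9)
                assert (split.loc[rows, "role"] == "train").all()

    def test_split_is_seed_reproducible(self, design):
        a = split_train_test(design, seed=99)
        b = split_train_test(design, seed=99)
        pd.testing.assert_frame_equal(a, b)
        c = split_train_test(design, seed=100)
        assert not a["role"].equals(c["role"])

    def test_too_many_test_rows_rejected(self, design):
        with pytest.raises(InputError):
            split_train_test(design, seed=1, n_test=75)


class TestSpikedSamples:
    def test_six_application_samples_capped_at_5em4(self):
        t = generate_spiked_samples(seed=5)
        assert len(t) == 6
        assert (t["role"] == "application").all()
        conc = t[["c_ClO4", "c_S"]].to_numpy()
        assert conc.max() <= 5.0e-4 * (1 + 1e-9)
        assert conc.max() == pytest.approx(5.0e-4, rel=1e-6)

    def test_seed_reproducible(self):
        a = generate_spiked_samples(seed=8)
        b = generate_spiked_samples(seed=8)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_baseline_range_rejected(self):
        with pytest.raises(ConfigError):
            SpikeConfig(baseline_range=(2e-5, 1e-5))


class TestSelectivityRuns:
    def test_fixed_level_constant_and_primary_increasing(self, clean_panel, mix_params):
        p1 = clean_panel.sensor("P1")
        runs = generate_selectivity_runs(p1, S, [1e-3], mix_params, n_points=10)
        assert len(runs) == 10
        assert (runs["c_S"] == 1e-3).all()
        assert runs["c_ClO4"].is_monotonic_increasing

    def test_grid_brackets_expected_flattening(self, clean_panel, mix_params):
        # the flattening of a noise-free run sits near k_pot · a_j^(zi/zj)
        p1 = clean_panel.sensor("P1")
        runs = generate_selectivity_runs(p1, S, [1e-2], mix_params)
        from etongue.activity import activity_coefficient
        from etongue.sensors import sample_activities

        acts = sample_activities(runs, clean_panel.ions, mix_params)
        a_j = acts[:, 1].mean()
        flattening = 10.0 ** p1.selectivity["S"] * a_j**0.5
        a_i = acts[:, 0]
        assert a_i.min() < flattening / 50
        assert a_i.max() > flattening * 50

    def test_zero_level_degenerates_to_plain_calibration(self, clean_panel, mix_params):
        p1 = clean_panel.sensor("P1")
        runs = generate_selectivity_runs(p1, S, [0.0], mix_params)
        assert (runs["c_S"] == 0.0).all()

    def test_empty_levels_rejected(self, clean_panel, mix_params):
        with pytest.raises(InputError):
            generate_selectivity_runs(clean_panel.sensor("P1"), S, [], mix_params)

    def test_default_levels_scale_interference_above_background(
        self, clean_panel, mix_params
    ):
        s3 = clean_panel.sensor("S3")
        levels = default_fixed_levels(s3, CLO4, mix_params)
        assert all(1e-5 <= lv <= 1.0 for lv in levels)


def test_single_ion_calibration_is_monotone_and_spans_range():
    t = single_ion_calibration(CLO4)
    assert len(t) == 10
    assert t["c_ClO4"].iloc[0] == pytest.approx(1e-6, rel=1e-9)
    assert t["c_ClO4"].iloc[-1] == pytest.approx(1e-3, rel=1e-9)
    assert t["c_ClO4"].is_monotonic_increasing
    assert (t["c_S"] == 0).all()
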