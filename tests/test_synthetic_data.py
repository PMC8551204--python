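"""Synthetic-data generator: adaptation laws, signal realism, cohorts."""

import math
from dataclasses import replace

import numpy as np
import pytest

import splitgait as sg
from splitgait import synthetic_data as sd
from splitgait.synthetic_data import ParamLaw, exponential_series

from conftest import strip_noise


class TestAdaptationLaw:
    def test_degenerate_start_at_plateau_is_constant(self):
        y = exponential_series(40, start=0.3, plateau=0.3, tau=10.0)
        assert np.allclose(y, 0.3)

    def test_closed_form_of_exponential_law(self):
        y = exponential_series(30, start=1.0, plateau=0.0, tau=10.0)
        assert y[0] == pytest.approx(1.0)
        assert y[20] == pytest.approx(math.exp(-2.0), abs=1e-12)

    def test_non_positive_tau_rejected(self):
        with pytest.raises(ValueError):
            exponential_series(10, 1.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            ParamLaw(base={"baseline_slow": 0.0, "baseline_fast": 0.0},
                     split_start=0.0, split_plateau=0.0, split_tau=-1.0,
                     after_start=0.0, after_tau=5.0, noise_sd=0.0)

    def test_negative_noise_sd_rejected(self):
        with pytest.raises(ValueError):
            ParamLaw(base={"baseline_slow": 0.0, "baseline_fast": 0.0},
                     split_start=0.0, split_plateau=0.0, split_tau=1.0,
                     after_start=0.0, after_tau=5.0, noise_sd=-0.1)


class TestStepTruth:
    def test_same_seed_is_bit_identical(self, short_protocol):
        a = sg.generate_step_truth(short_protocol, seed=5)
        b = sg.generate_step_truth(short_protocol, seed=5)
        assert a.table.equals(b.table)

    def test_different_seed_changes_only_noise(self, short_protocol):
        noisy_a = sg.generate_step_truth(short_protocol, seed=5)
        noisy_b = sg.generate_step_truth(short_protocol, seed=6)
        assert not noisy_a.table["step_length"].equals(noisy_b.table["step_length"])
        clean = strip_noise(sd.default_laws())
        a = sg.generate_step_truth(short_protocol, clean, seed=5)
        b = sg.generate_step_truth(short_protocol, clean, seed=6)
        assert a.table.equals(b.table)

    def test_feet_alternate(self, clean_truth):
        for cond in clean_truth.protocol.names:
            feet = clean_truth.condition_steps(cond)["foot"].to_numpy()
            assert all(feet[i] != feet[i + 1] for i in range(len(feet) - 1))

    def test_durations_positive_and_on_grid(self, clean_truth):
        t = clean_truth.table
        assert (t["duration"] > 0.2).all()
        samples = t["duration"] * clean_truth.fs_grid
        assert np.allclose(samples, samples.round(), atol=1e-6)

    def test_split_series_follows_exponential_law(self, short_protocol):
        laws = strip_noise(sd.default_laws())
        truth = sg.generate_step_truth(short_protocol, laws, seed=0)
        split = truth.condition_steps("split")
        fast = split[split["foot"] == "fast"]["step_length"].to_numpy()
        law = laws["step_length"]["fast"]
        expected = exponential_series(len(fast), law.split_start,
                                      law.split_plateau, law.split_tau)
        assert np.allclose(fast, expected, atol=1e-12)


class TestSynthesizeTrial:
    def test_one_forward_maximum_per_programmed_strike(self, clean_split_trial):
        trial = clean_split_trial
        for name, side in (("heel_l", "left"), ("heel_r", "right")):
            x = trial.markers[name]["ap"]
            maxima = np.flatnonzero((x[1:-1] > x[:-2]) & (x[1:-1] > x[2:])) + 1
            programmed = [t for t, s in zip(trial.truth_events["strike_times"],
                                            trial.truth_events["strike_sides"])
                          if s == side]
            assert len(maxima) == len(programmed)
            err = np.abs(maxima / trial.fs_marker - np.asarray(programmed))
            assert err.max() <= 1.0 / trial.fs_marker

    def test_constant_programmed_step_width_recovered(self, short_protocol,
                                                      clean_signal_params):
        laws = strip_noise(sd.default_laws())
        truth = sg.generate_step_truth(short_protocol, laws, seed=3)
        trial = sd.synthesize_trial(truth, "baseline_slow", clean_signal_params, seed=4)
        steps, _ = sg.process_trial(trial, filter_cutoff_hz=None)
        widths = steps.loc[steps["valid"], "step_width"]
        assert np.allclose(widths, 0.145, atol=1e-6)

    def test_cop_under_loaded_foot_during_single_stance(self, clean_truth,
                                                        clean_split_trial):
        trial = clean_split_trial
        steps = trial.truth_events["steps"]
        t_cop = trial.t_cop
        for k in range(min(10, len(steps) - 1)):
            po = steps["t_strike"].iloc[k] + steps["double_stance_time"].iloc[k]
            end = steps["t_strike"].iloc[k] + steps["duration"].iloc[k]
            j0, j1 = np.searchsorted(t_cop, [po + 1e-6, end - 1e-6])
            stance_left = steps["leading_side"].iloc[k] == "left"
            loaded = trial.load_left if stance_left else trial.load_right
            unloaded = trial.load_right if stance_left else trial.load_left
            assert loaded[j0:j1].all()
            assert not unloaded[j0:j1].any()
            swing_cop = (trial.cop_right_ml if stance_left else trial.cop_left_ml)
            assert np.all(np.isnan(swing_cop[j0:j1]))

    def test_dropout_markers_masked(self, clean_truth, clean_signal_params):
        params = replace(clean_signal_params, dropouts=(("hip_l", 5.0, 0.15),))
        trial = sd.synthesize_trial(clean_truth, "split", params, seed=9)
        i0 = int(5.0 * trial.fs_marker)
        i1 = int(5.15 * trial.fs_marker)
        assert trial.marker_mask["hip_l"][i0:i1].all()
        assert np.all(np.isnan(trial.markers["hip_l"]["ml"][i0:i1]))

    def test_same_seed_reproducible(self, clean_truth):
        params = sg.SignalParams(marker_noise_sd=0.002)
        a = sd.synthesize_trial(clean_truth, "after", params, seed=7)
        b = sd.synthesize_trial(clean_truth, "after", params, seed=7)
        assert np.array_equal(a.markers["heel_l"]["ap"], b.markers["heel_l"]["ap"])
        assert np.array_equal(a.cop_left_ml, b.cop_left_ml, equal_nan=True)

    def test_too_short_condition_rejected(self):
        with pytest.raises(ValueError):
            sg.generate_step_truth(sg.default_protocol(baseline_s=0.5))


class TestCohort:
    def test_empty_cohort(self):
        assert sg.generate_cohort(0, 0, seed=1) == []

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            sg.generate_cohort(-1, 5, seed=1)

    def test_reference_cohort_sample_sizes(self, short_protocol):
        cohort = sg.generate_cohort(31, 21, seed=1, protocol=short_protocol)
        assert len(cohort) == 52
        groups = [s.group for s in cohort]
        assert groups.count("younger") == 31
        assert groups.count("older") == 21

    def test_group_asymmetry_structure(self, short_protocol):
        gp = sg.GroupParams(subject_sd={"com": 0.0, "cop_disp": 0.0})
        cohort = sg.generate_cohort(2, 2, gp, seed=3, protocol=short_protocol)
        for subj in cohort:
            laws = subj.truth.laws["com"]
            asym = laws["slow"].split_plateau - laws["fast"].split_plateau
            if subj.group == "younger":
                assert asym == pytest.approx(0.020, abs=1e-12)
            else:
                assert asym == pytest.approx(0.0, abs=1e-12)
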