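"""Symmetry series, plateau detection, aftereffects, percent conversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splitgait.adaptation import (PlateauResult, aftereffect_magnitude,
                                  percent_change, plateau_magnitude,
                                  steps_to_plateau, symmetry)
from splitgait.synthetic_data import exponential_series


def plateau_oracle(y, last_n=50, k_sd=2.0, consec=9):
    """Exhaustive window scan, independent of the vectorized implementation."""
    y = np.asarray(y, dtype=float)
    tail = y[-last_n:]
    p, s = tail.mean(), tail.std(ddof=1)
    band = k_sd * s if s > 0 else 1e-12
    for i in range(len(y) - consec + 1):
        if all(abs(y[i + j] - p) <= band for j in range(consec)):
            return i + 1, True
    return len(y), False


class TestSymmetry:
    def test_elementwise_difference(self):
        assert symmetry([0.3], [0.1])[0] == pytest.approx(0.2)

    def test_identical_series_all_zero(self):
        x = np.random.default_rng(0).normal(size=30)
        assert np.allclose(symmetry(x, x), 0.0)

    def test_antisymmetry_under_foot_swap(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=20), rng.normal(size=20)
        assert np.allclose(symmetry(a, b), -symmetry(b, a))

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            symmetry([1.0, 2.0], [1.0])


class TestStepsToPlateau:
    def test_constant_series_plateaus_at_step_one(self):
        res = steps_to_plateau(np.full(80, 0.2))
        assert res.steps_to_plateau == 1
        assert res.converged
        assert res.plateau_sd < 1e-12

    def test_constructed_series_with_known_entry_point(self):
        """Values up to 1-based step 36 violate the band; 37 onward stay inside."""
        y = np.zeros(120)
        y[-50:] = np.tile([1.0, -1.0], 25)  # plateau mean 0, SD ~ 1
        y[:36] = 5.0  # outside 2 SD through 1-based index 36
        expected, conv = plateau_oracle(y)
        res = steps_to_plateau(y)
        assert (res.steps_to_plateau, res.converged) == (expected, conv)
        assert res.steps_to_plateau == 37

    def test_noise_free_exponential_matches_scan_and_closed_form(self):
        for tau in (5.0, 10.0, 20.0):
            y = exponential_series(200, 1.0, 0.0, tau)
            res = steps_to_plateau(y)
            oracle = plateau_oracle(y)
            assert (res.steps_to_plateau, res.converged) == oracle
            # closed form: first k (0-based) with exp(-k/tau) <= band
            tail = y[-50:]
            band = 2.0 * tail.std(ddof=1)
            p = tail.mean()
            k_analytic = int(np.ceil(-tau * np.log(band + p))) if band + p < 1 else 0
            assert res.steps_to_plateau == k_analytic + 1

    def test_monotone_in_time_constant(self):
        """Slower adaptation takes longer to reach a pinned plateau band.

        A stationary alternating ripple fixes the plateau SD; for a pure
        exponential the band itself would decay with tau and the index
        saturates near the series end instead.
        """
        n = 300
        ripple = 1e-3 * (-1.0) ** np.arange(n)
        taus = [4.0, 8.0, 16.0, 32.0]
        steps = [steps_to_plateau(exponential_series(n, 1.0, 0.0, t) + ripple
                                  ).steps_to_plateau
                 for t in taus]
        assert all(a < b for a, b in zip(steps, steps[1:]))

    def test_invariant_to_constant_shift(self):
        rng = np.random.default_rng(3)
        y = np.concatenate([rng.normal(2.0, 1.0, 40), rng.normal(0.0, 0.3, 80)])
        r0 = steps_to_plateau(y)
        r1 = steps_to_plateau(y + 17.3)
        assert r0.steps_to_plateau == r1.steps_to_plateau

    def test_nonconvergence_reports_length_without_raising(self):
        # spikes every 6 steps exceed the 2-SD band in every 9-step window
        y = np.zeros(90)
        y[::6] = 1.0
        res = steps_to_plateau(y)
        assert not res.converged
        assert res.steps_to_plateau == len(y)
        assert np.isnan(res.magnitude)

    def test_too_short_series_raises(self):
        with pytest.raises(ValueError):
            steps_to_plateau(np.zeros(58))

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_agrees_with_bruteforce_on_random_series(self, seed):
        rng = np.random.default_rng(seed)
        kind = seed % 3
        n = int(rng.integers(59, 200))
        if kind == 0:
            y = rng.normal(size=n)
        elif kind == 1:  # AR(1)
            y = np.zeros(n)
            eps = rng.normal(size=n)
            for i in range(1, n):
                y[i] = 0.8 * y[i - 1] + eps[i]
        else:
            y = exponential_series(n, 2.0, 0.0, 12.0) + 0.2 * rng.normal(size=n)
        res = steps_to_plateau(y)
        assert (res.steps_to_plateau, res.converged) == plateau_oracle(y)


class TestPlateauMagnitude:
    def test_constant_series(self):
        y = np.full(80, 0.2)
        res = steps_to_plateau(y)
        assert plateau_magnitude(y, res) == pytest.approx(0.2)

    def test_window_of_ones_yields_one(self):
        y = np.concatenate([np.full(20, 5.0), np.ones(70)])
        res = steps_to_plateau(y)
        assert res.steps_to_plateau == 21
        assert plateau_magnitude(y, res) == pytest.approx(1.0)

    def test_nonconverged_yields_nan(self):
        res = PlateauResult(steps_to_plateau=90, plateau_mean=0.0, plateau_sd=1.0,
                            magnitude=np.nan, converged=False)
        assert np.isnan(plateau_magnitude(np.zeros(90), res))

    def test_alternative_modes(self):
        y = np.concatenate([np.full(20, 5.0), np.ones(70)])
        res = steps_to_plateau(y)
        assert plateau_magnitude(y, res, mode="instant") == pytest.approx(1.0)
        assert plateau_magnitude(y, res, mode="plateau") == pytest.approx(1.0)
        with pytest.raises(ValueError):
            plateau_magnitude(y, res, mode="nope")


class TestAftereffect:
    def test_mean_of_first_ten(self):
        assert aftereffect_magnitude(np.arange(1.0, 21.0)) == pytest.approx(5.5)

    def test_zeros(self):
        assert aftereffect_magnitude(np.zeros(15)) == 0.0

    def test_short_series_raises(self):
        with pytest.raises(ValueError):
            aftereffect_magnitude(np.zeros(9))

    def test_exponential_aftereffect_closed_form(self):
        amp, tau = 0.8, 6.0
        y = exponential_series(40, amp, 0.0, tau)
        r = np.exp(-1.0 / tau)
        analytic = amp * (1 - r**10) / (10 * (1 - r))
        assert aftereffect_magnitude(y) == pytest.approx(analytic, abs=1e-12)


class TestPercentChange:
    def test_simple_ratio(self):
        assert percent_change(0.07, 0.70) == pytest.approx(10.0)

    def test_zero_delta(self):
        assert percent_change(0.0, 0.5) == 0.0

    def test_sign_preserved(self):
        assert percent_change(-0.07, 0.70) == pytest.approx(-10.0)

    def test_zero_reference_flagged_missing(self):
        assert np.isnan(percent_change(1.0, 0.0))
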