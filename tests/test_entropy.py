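"""Phase construction, polar histograms and the entropy statistic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from groovetap.entropy import (
    PhaseAngleSeries,
    PhaseHistogram,
    entropy_table,
    phase_angles,
    polar_histogram,
    shannon_entropy,
    trial_entropy,
)
from groovetap.io_formats import TapTrial


def brute_force_entropy(probs):
    """Independent oracle: naive loop over bins, log base 10."""
    h = 0.0
    for p in probs:
        if p > 0:
            h -= p * math.log10(p)
    return h


class TestPhaseAngles:
    def test_iois_at_reference_period_map_to_zero(self):
        s = phase_angles(np.array([0.5, 0.5, 0.5]), reference_period=0.5)
        np.testing.assert_allclose(s.angles, 0.0, atol=1e-12)

    def test_ioi_at_one_and_a_half_periods_maps_to_pi(self):
        s = phase_angles(np.array([0.75]), reference_period=0.5)
        assert s.angles[0] == pytest.approx(np.pi)

    def test_onsets_on_beat_grid_map_to_zero(self):
        trial = TapTrial("p", "s", "high", "pre",
                         onsets=np.arange(0, 10, 0.5))
        s = phase_angles(trial, reference_period=0.5, mode="onset_phase")
        np.testing.assert_allclose(np.minimum(s.angles, 2 * np.pi - s.angles),
                                   0.0, atol=1e-9)

    def test_median_ioi_fallback(self):
        s = phase_angles(np.array([0.4, 0.5, 0.6]))
        assert s.reference_period == pytest.approx(0.5)

    def test_angles_always_in_range(self):
        s = phase_angles(np.array([0.1, 0.9999999, 2.3, 0.5]), reference_period=0.5)
        assert np.all((s.angles >= 0) & (s.angles < 2 * np.pi))


class TestPolarHistogram:
    def test_identical_angles_occupy_one_bin(self):
        s = PhaseAngleSeries(np.full(7, 1.234), 0.5, "ioi_phase")
        h = polar_histogram(s)
        assert h.counts.max() == 7
        assert (h.counts > 0).sum() == 1

    def test_bin_edges_half_open(self):
        width = 2 * np.pi / 400
        s = PhaseAngleSeries(np.array([0.0, width, 2 * width]), 0.5, "ioi_phase")
        h = polar_histogram(s)
        assert h.counts[0] == 1 and h.counts[1] == 1 and h.counts[2] == 1

    def test_counts_conserved(self, rng):
        s = PhaseAngleSeries(rng.uniform(0, 2 * np.pi, 321), 0.5, "ioi_phase")
        h = polar_histogram(s)
        assert h.total == 321
        assert h.probabilities.sum() == pytest.approx(1.0)

    def test_zero_angles_error(self):
        s = PhaseAngleSeries(np.empty(0), 0.5, "ioi_phase")
        with pytest.raises(ValueError):
            polar_histogram(s)


class TestShannonEntropy:
    def test_uniform_400_bins_is_2_602(self):
        h = PhaseHistogram.from_probabilities([1 / 400] * 400, n_events=400)
        assert round(shannon_entropy(h).H, 3) == 2.602

    def test_single_bin_is_zero(self):
        counts = np.zeros(400)
        counts[37] = 12
        assert shannon_entropy(PhaseHistogram(counts)).H == 0.0

    def test_two_equal_bins_is_log10_2(self):
        counts = np.zeros(400)
        counts[[3, 250]] = 5
        assert shannon_entropy(PhaseHistogram(counts)).H == pytest.approx(
            math.log10(2), abs=1e-12
        )

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            counts = rng.integers(0, 50, size=rng.integers(2, 500))
            if counts.sum() == 0:
                counts[0] = 1
            h = PhaseHistogram(counts)
            assert shannon_entropy(h).H == pytest.approx(
                brute_force_entropy(h.probabilities), abs=1e-12
            )

    @given(st.lists(st.integers(0, 100), min_size=2, max_size=400).filter(
        lambda c: sum(c) > 0))
    @settings(derandomize=True, max_examples=200)
    def test_bounds_and_permutation_invariance(self, counts):
        h = shannon_entropy(PhaseHistogram(np.array(counts)))
        assert 0 <= h.H <= math.log10(len(counts)) + 1e-12
        perm = np.random.default_rng(0).permutation(counts)
        assert shannon_entropy(PhaseHistogram(perm)).H == pytest.approx(h.H, abs=1e-12)

    def test_rotation_by_bin_width_invariant(self, rng):
        angles = rng.uniform(0, 2 * np.pi, 500)
        width = 2 * np.pi / 400
        h1 = shannon_entropy(polar_histogram(
            PhaseAngleSeries(angles, 0.5, "ioi_phase")))
        rotated = np.mod(angles + 7 * width, 2 * np.pi)
        h2 = shannon_entropy(polar_histogram(
            PhaseAngleSeries(rotated, 0.5, "ioi_phase")))
        assert h2.H == pytest.approx(h1.H, abs=1e-9)


class TestTrialEntropy:
    def test_periodic_tapper_has_zero_entropy(self):
        onsets = np.arange(0, 30, 0.5)
        trial = TapTrial("p", "s", "high", "pre", onsets=onsets)
        assert trial_entropy(trial, reference_period=0.5).H == 0.0

    def test_uniform_phases_converge_to_max(self, rng):
        # 10^4 i.i.d. uniform phases: H approaches log10(400) = 2.602
        angles = PhaseAngleSeries(rng.uniform(0, 2 * np.pi, 10_000), 0.5, "ioi_phase")
        h = shannon_entropy(polar_histogram(angles))
        assert abs(h.H - 2.602) < 0.02

    def test_five_event_toy_trial_hand_computed(self):
        # raw IOIs [0.5 x4, 0.25, 0.75]; warm-up drops 3, leaving
        # [0.5, 0.25, 0.75] -> phases {0, pi, pi} (0.75 is 1.5 periods)
        # -> bins with probabilities {1/3, 2/3}:
        # H = -(1/3)log(1/3) - (2/3)log(2/3) = log10(3) - (2/3)log10(2)
        onsets = np.array([0.0, 0.5, 1.0, 1.5, 2.0, 2.25, 3.0])
        trial = TapTrial("p", "s", "high", "pre", onsets=onsets)
        res = trial_entropy(trial, reference_period=0.5)
        assert res.n_events == 3
        expected = math.log10(3) - (2 / 3) * math.log10(2)
        assert res.H == pytest.approx(expected, abs=1e-12)

    def test_no_kept_iois_returns_none(self):
        trial = TapTrial("p", "s", "high", "pre", onsets=np.array([0.0, 0.5, 1.0]))
        assert trial_entropy(trial, reference_period=0.5) is None

    def test_log_h_floor_flags_robotic_trials(self):
        onsets = np.arange(0, 30, 0.5)
        trial = TapTrial("p", "s", "high", "pre", onsets=onsets)
        res = trial_entropy(trial, reference_period=0.5)
        assert res.floored
        assert res.log_H == pytest.approx(math.log(1e-6))

    def test_entropy_table_schema(self, small_cohort):
        table = entropy_table(small_cohort.tap_trials,
                              small_cohort.reference_periods)
        assert set(table.columns) >= {"participant_id", "groove", "time_point",
                                      "H", "log_H", "n_events"}
        assert (table["H"] >= 0).all()
        assert (table["H"] <= math.log10(400)).all()
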