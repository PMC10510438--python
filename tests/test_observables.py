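"""Configurational statistics: tilt, density, block averaging, summaries."""

import math
import statistics

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vsdye import (
    AtomTrack,
    OrientationSeries,
    VoltageCondition,
    block_average,
    density_profile,
    range_of_motion,
    summarize_condition,
    tilt_angle,
)
from vsdye.observables import ConditionSummary


class TestTiltAngle:
    @pytest.mark.parametrize(
        "axis, normal, expected",
        [
            ((0, 0, 1), (0, 0, 1), 0.0),
            ((1, 0, 0), (0, 0, 1), 90.0),
            ((1, 0, 1), (0, 0, 1), 45.0),
            ((0, 0, -1), (0, 0, 1), 180.0),  # unfolded convention
        ],
    )
    def test_closed_form_angles(self, axis, normal, expected):
        assert tilt_angle(axis, normal) == pytest.approx(expected, abs=1e-12)

    @given(
        scale_a=st.floats(1e-3, 1e3),
        scale_n=st.floats(1e-3, 1e3),
        ax=st.tuples(*[st.floats(-1, 1) for _ in range(3)]),
    )
    def test_invariant_to_positive_rescaling(self, scale_a, scale_n, ax):
        a = np.asarray(ax)
        if np.linalg.norm(a) < 1e-6:
            return
        base = tilt_angle(a, (0, 0, 1))
        scaled = tilt_angle(scale_a * a, scale_n * np.array([0, 0, 1.0]))
        assert scaled == pytest.approx(base, abs=1e-9)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="nonzero"):
            tilt_angle((0, 0, 0), (0, 0, 1))


class TestDensityProfile:
    def test_identical_samples_occupy_one_unit_peak_bin(self):
        p = density_profile([7.5] * 10, bin_width=0.5, normalization="unit_peak")
        assert len(p.density) == 1
        assert p.density[0] == 1.0

    def test_count_mode_conserves_samples(self, rng):
        x = rng.normal(0.0, 3.0, size=5000)
        p = density_profile(x, bin_width=0.5, normalization="count")
        assert p.density.sum() == 5000

    def test_occupied_bin_weighted_mean_recovers_distribution_mean(self, rng):
        # amino-nitrogen-like distribution: normal(7.5 A, 2.4 A)
        x = rng.normal(7.5, 2.4, size=10**5)
        p = density_profile(x, bin_width=0.5, normalization="count")
        wmean = float((p.bin_centers * p.density).sum() / p.density.sum())
        se = 2.4 / math.sqrt(10**5)
        # half a bin of discretization slack on top of the 3-SE sampling band
        assert abs(wmean - 7.5) < 3 * se + 0.25

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError, match="at least one sample"):
            density_profile([], bin_width=0.5)


def _brute_force_block(series, n_blocks):
    """Independent oracle: explicit per-block slicing and stdlib statistics."""
    n = len(series)
    size = n // n_blocks
    blocks = []
    for i in range(n_blocks):
        a = i * size
        b = (i + 1) * size if i < n_blocks - 1 else n
        blocks.append(sum(series[a:b]) / (b - a))
    mean = sum(series) / n
    se = statistics.stdev(blocks) / math.sqrt(n_blocks)
    return mean, se


class TestBlockAverage:
    def test_constant_series_has_zero_se(self):
        mean, se = block_average([3.3] * 50, n_blocks=5)
        assert mean == 3.3 and se == 0.0

    def test_six_frames_three_blocks_hand_arithmetic(self):
        mean, se = block_average([1, 2, 3, 4, 5, 6], n_blocks=3)
        assert mean == pytest.approx(3.5)
        # block means (1.5, 3.5, 5.5); sample SD 2; SE 2/sqrt(3)
        assert se == pytest.approx(2.0 / math.sqrt(3.0))

    def test_iid_series_se_matches_sampling_theory(self, rng):
        x = rng.standard_normal(10**5)
        _, se = block_average(x, n_blocks=10)
        target = 1.0 / math.sqrt(10**5)
        assert target / 2 < se < target * 2

    @given(
        data=st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=100),
        n_blocks=st.integers(2, 10),
    )
    def test_agrees_with_brute_force_oracle(self, data, n_blocks):
        if n_blocks > len(data):
            return
        mean, se = block_average(data, n_blocks)
        mean_o, se_o = _brute_force_block(data, n_blocks)
        assert mean == pytest.approx(mean_o, rel=1e-9, abs=1e-9)
        assert se == pytest.approx(se_o, rel=1e-9, abs=1e-9)

    def test_singleton_blocks_reduce_to_iid_se_formula(self, rng):
        x = rng.standard_normal(40)
        mean, se = block_average(x, n_blocks=40)
        assert mean == pytest.approx(x.mean())
        assert se == pytest.approx(x.std(ddof=1) / math.sqrt(40))

    @pytest.mark.parametrize("n_blocks", [1, 0, 101])
    def test_invalid_block_counts_rejected(self, n_blocks):
        with pytest.raises(ValueError):
            block_average(list(range(100)), n_blocks)


def _tracks_and_orient(n, means, tilt_deg):
    frames = np.arange(n)
    tracks = [
        AtomTrack(label=lab, frames=frames, z=np.full(n, m))
        for lab, m in means.items()
    ]
    t = math.radians(tilt_deg)
    vec = np.array([math.sin(t), 0.0, math.cos(t)])
    orient = OrientationSeries(frames=frames, vectors=np.tile(vec, (n, 1)))
    return tracks, orient


class TestSummarizeCondition:
    def test_zero_noise_summary_is_exact_with_zero_sd(self):
        cond = VoltageCondition(0.0, "excited")
        tracks, orient = _tracks_and_orient(
            100, {"S": 18.8, "N1": 15.7, "N2": 7.5, "C_tail": 4.0}, 48.3
        )
        s = summarize_condition(tracks, orient, cond)
        for lab, m in [("S", 18.8), ("N1", 15.7), ("N2", 7.5), ("C_tail", 4.0)]:
            assert s.z_stats[lab] == (pytest.approx(m), pytest.approx(0.0))
        assert s.tilt_stats[0] == pytest.approx(48.3, abs=1e-9)
        assert s.tilt_stats[1] == pytest.approx(0.0, abs=1e-9)

    def test_frame_count_bookkeeping(self):
        cond = VoltageCondition(0.0, "ground")
        tracks, orient = _tracks_and_orient(10_000, {"S": 22.1}, 25.9)
        assert summarize_condition(tracks, orient, cond).n_frames == 10_000

    def test_length_mismatch_rejected(self):
        cond = VoltageCondition(0.0, "ground")
        tracks, _ = _tracks_and_orient(100, {"S": 22.1}, 25.9)
        _, orient = _tracks_and_orient(99, {"S": 22.1}, 25.9)
        with pytest.raises(ValueError, match="length mismatch"):
            summarize_condition(tracks, orient, cond)


def _summary(v_mp, state, label, mean):
    return ConditionSummary(
        cond=VoltageCondition(v_mp, state),
        n_frames=1,
        z_stats={label: (mean, 0.0)},
        tilt_stats=(0.0, 0.0),
    )


class TestRangeOfMotion:
    def test_excited_amino_nitrogen_shift_between_extreme_voltages(self):
        s = [_summary(-500.0, "excited", "N2", 6.3),
             _summary(500.0, "excited", "N2", 7.6)]
        assert range_of_motion(s, "N2") == pytest.approx(1.3)

    def test_ground_sulfur_shift_between_extreme_voltages(self):
        s = [_summary(-500.0, "ground", "S", 21.8),
             _summary(0.0, "ground", "S", 22.1),
             _summary(500.0, "ground", "S", 22.2)]
        assert range_of_motion(s, "S") == pytest.approx(0.4)

    def test_equal_means_give_zero(self):
        s = [_summary(-500.0, "ground", "S", 22.0),
             _summary(500.0, "ground", "S", 22.0)]
        assert range_of_motion(s, "S") == 0.0

    def test_absent_label_rejected(self):
        s = [_summary(-500.0, "ground", "S", 22.0),
             _summary(500.0, "ground", "S", 22.0)]
        with pytest.raises(KeyError, match="N2"):
            range_of_motion(s, "N2")
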