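import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_trajectory
from optomotor.features import (
    FEATURE_COLUMNS,
    ReplicateFit,
    ReplicatePath,
    extract_features,
    fit_replicates,
    rotation_asymmetry,
    segment_to_path,
    tortuosity,
    turning_velocity,
    walking_pace,
)
from optomotor.fictrac import align
from optomotor.simulate import ArchetypeParams, Archetype, simulate_trajectory
from optomotor.stimuli import Direction, Epoch, Schedule, StimulusSpec, build_schedule


def _ramp_path(slope: float, direction: Direction, duration: float = 10.0, fs: float = 50.0) -> ReplicatePath:
    t = np.arange(0, duration, 1 / fs)
    return ReplicatePath(t=t, y=slope * t, direction=direction)


def _const_path(ymax: float, direction: Direction) -> ReplicatePath:
    """Path whose sign-corrected maximum accumulated rotation is exactly ymax."""
    t = np.linspace(0, 10, 101)  # grid contains the mid-epoch peak exactly
    y = direction.sign * ymax * np.sin(np.pi * t / 10.0)
    y[0] = 0.0
    return ReplicatePath(t=t, y=y, direction=direction)


class TestSegmentToPath:
    @pytest.mark.parametrize("rate,expected_end", [(0.5, 5.0), (-0.5, -5.0), (0.0, 0.0)])
    def test_linear_heading_ramp(self, rate, expected_end, single_stimulus_schedule):
        t = np.arange(0, 85, 0.02)
        traj = make_trajectory(rate * t)
        segs = align(traj, single_stimulus_schedule, t0=0.0)
        path = segment_to_path(segs[0])
        assert path.t[0] == 0.0 and path.y[0] == 0.0
        assert path.y[-1] == pytest.approx(expected_end, abs=0.02 * abs(rate) + 1e-12)

    def test_constant_heading_gives_zero_path(self, single_stimulus_schedule):
        traj = make_trajectory(np.full(50 * 85, 1.7))
        path = segment_to_path(align(traj, single_stimulus_schedule, t0=0.0)[0])
        assert np.all(path.y == 0.0)


class TestFitReplicates:
    def test_exact_line_recovered(self):
        fits = fit_replicates([_ramp_path(0.5, Direction.LEFT)])
        assert fits[0].slope == pytest.approx(0.5, abs=1e-12)
        assert fits[0].r_squared == pytest.approx(1.0, abs=1e-12)

    def test_ols_matches_normal_equations_oracle(self):
        # brute-force normal equations on random small paths
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = rng.integers(5, 60)
            t = np.sort(rng.uniform(0, 10, size=n))
            t[0] = 0.0
            y = rng.normal(0, 1, size=n)
            y[0] = 0.0
            A = np.column_stack([np.ones(n), t])
            beta = np.linalg.solve(A.T @ A, A.T @ y)
            resid = y - A @ beta
            ss_tot = np.sum((y - y.mean()) ** 2)
            r2 = 1.0 - resid @ resid / ss_tot
            fit = fit_replicates([ReplicatePath(t=t, y=y, direction=Direction.LEFT)])[0]
            assert abs(fit.slope - beta[1]) < 1e-10
            assert abs(fit.r_squared - r2) < 1e-10

    def test_noise_around_zero_has_near_zero_slope_and_r2(self):
        t = np.arange(0, 10, 0.02)
        y = 0.01 * np.where(np.arange(len(t)) % 2 == 0, 1.0, -1.0)
        y[0] = 0.0
        fit = fit_replicates([ReplicatePath(t=t, y=y, direction=Direction.LEFT)])[0]
        assert abs(fit.slope) < 1e-3
        assert fit.r_squared < 0.05

    def test_short_path_flagged_invalid(self):
        short = ReplicatePath(t=np.array([0.0, 0.1]), y=np.array([0.0, 0.1]), direction=Direction.LEFT)
        with pytest.warns(UserWarning, match="excluded"):
            fits = fit_replicates([short, _ramp_path(0.3, Direction.RIGHT)])
        assert not fits[0].valid and fits[1].valid

    def test_identical_paths_identical_fits(self):
        fits = fit_replicates([_ramp_path(0.4, Direction.LEFT)] * 8)
        assert len({(f.slope, f.r_squared) for f in fits}) == 1


def _mk_fits(slopes, r2s=None):
    r2s = r2s if r2s is not None else [1.0] * len(slopes)
    return [ReplicateFit(s, r, Direction.LEFT, 100) for s, r in zip(slopes, r2s)]


class TestTurningVelocityAndTortuosity:
    @pytest.mark.parametrize(
        "slopes,expected",
        [
            ([0.5] * 4 + [-0.5] * 4, 0.0),
            ([0.5] * 4 + [-0.1] * 4, 0.2),
            ([0.3] * 8, 0.3),
        ],
    )
    def test_turning_velocity(self, slopes, expected):
        assert turning_velocity(_mk_fits(slopes)) == pytest.approx(expected)

    def test_turning_velocity_order_invariant(self):
        slopes = [0.5, -0.2, 0.3, -0.4, 0.1]
        rng = np.random.default_rng(0)
        base = turning_velocity(_mk_fits(slopes))
        for _ in range(5):
            rng.shuffle(slopes)
            assert turning_velocity(_mk_fits(slopes)) == pytest.approx(base)

    @pytest.mark.parametrize(
        "r2s,expected", [([1.0] * 8, 1.0), ([1, 1, 1, 1, 0, 0, 0, 0], 0.5), ([0.7], 0.7)]
    )
    def test_tortuosity_is_mean_r_squared(self, r2s, expected):
        assert tortuosity(_mk_fits([0.1] * len(r2s), r2s)) == pytest.approx(expected)

    def test_invalid_fits_excluded(self):
        fits = _mk_fits([0.5, 0.5]) + [ReplicateFit(np.nan, np.nan, Direction.LEFT, 2, valid=False)]
        assert turning_velocity(fits) == pytest.approx(0.5)
        assert tortuosity(fits) == pytest.approx(1.0)

    def test_no_valid_fits_undefined(self):
        fits = [ReplicateFit(np.nan, np.nan, Direction.LEFT, 1, valid=False)]
        assert np.isnan(turning_velocity(fits)) and np.isnan(tortuosity(fits))


class TestRotationAsymmetry:
    def test_symmetric_responses(self):
        res = rotation_asymmetry([_const_path(2.0, Direction.LEFT), _const_path(2.0, Direction.RIGHT)])
        assert res.y_sym == pytest.approx(0.0)
        assert res.bias_direction is None
        assert res.ymax == pytest.approx(2.0)

    def test_right_biased_response(self):
        res = rotation_asymmetry([_const_path(1.0, Direction.LEFT), _const_path(3.0, Direction.RIGHT)])
        assert res.y_sym == pytest.approx(2.0 / 3.0)
        assert res.bias_direction is Direction.RIGHT
        assert res.ymax == pytest.approx(2.0)

    def test_one_sided_extreme(self):
        res = rotation_asymmetry([_const_path(0.0, Direction.LEFT), _const_path(2.0, Direction.RIGHT)])
        assert res.y_sym == pytest.approx(1.0)
        assert res.bias_direction is Direction.RIGHT

    def test_both_directions_zero_is_degenerate_zero(self):
        res = rotation_asymmetry([_const_path(0.0, Direction.LEFT), _const_path(0.0, Direction.RIGHT)])
        assert res.y_sym == 0.0 and res.degenerate

    def test_missing_direction_rejected(self):
        with pytest.raises(ValueError):
            rotation_asymmetry([_const_path(1.0, Direction.LEFT)])

    @given(
        ymax_l=st.floats(0.0, 10.0),
        ymax_r=st.floats(0.0, 10.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_y_sym_bounds_and_identities(self, ymax_l, ymax_r):
        res = rotation_asymmetry([_const_path(ymax_l, Direction.LEFT), _const_path(ymax_r, Direction.RIGHT)])
        assert 0.0 <= res.y_sym <= 1.0
        if max(ymax_l, ymax_r) > 1e-6:
            if abs(ymax_l - ymax_r) < 1e-12:
                assert res.y_sym == pytest.approx(0.0, abs=1e-9)
            if min(ymax_l, ymax_r) == 0.0:
                assert res.y_sym == pytest.approx(1.0)


class TestWalkingPace:
    def _uniform_rotation_traj(self, rot_per_frame: float, fs: float, diameter: float, n: int = 3000):
        inc = np.zeros((n, 3))
        inc[:, 0] = rot_per_frame
        traj = make_trajectory(np.zeros(n), frame_rate=fs, ball_diameter=diameter, increments=inc)
        return traj

    def test_arc_length_arithmetic(self):
        # 0.1 rad/frame at 30 fps on a 5 cm ball -> 0.1 * 30 * 2.5 = 7.5 cm/s
        traj = self._uniform_rotation_traj(0.1, 30.0, 5.0)
        sched = build_schedule([StimulusSpec(0.0625, 16.0)], 10.0, 4, isi=0.0)
        segs = align(traj, sched, t0=0.0)
        assert walking_pace(segs) == pytest.approx(7.5, rel=1e-3)

    def test_stationary_ball_zero_pace(self):
        traj = self._uniform_rotation_traj(0.0, 30.0, 5.0)
        sched = build_schedule([StimulusSpec(0.0625, 16.0)], 10.0, 4, isi=0.0)
        assert walking_pace(align(traj, sched, t0=0.0)) == 0.0

    def test_pace_linear_in_diameter(self):
        sched = build_schedule([StimulusSpec(0.0625, 16.0)], 10.0, 4, isi=0.0)
        p1 = walking_pace(align(self._uniform_rotation_traj(0.05, 30.0, 5.0), sched, t0=0.0))
        p2 = walking_pace(align(self._uniform_rotation_traj(0.05, 30.0, 10.0), sched, t0=0.0))
        assert p2 == pytest.approx(2 * p1)

    def test_fallback_to_speed_column(self):
        n = 3000
        traj = make_trajectory(np.zeros(n), frame_rate=30.0, ball_diameter=5.0)
        traj.rotation_increment = None
        traj.movement_speed = np.full(n, 0.1)
        sched = build_schedule([StimulusSpec(0.0625, 16.0)], 10.0, 4, isi=0.0)
        assert walking_pace(align(traj, sched, t0=0.0)) == pytest.approx(7.5, rel=1e-3)


class TestExtractFeatures:
    def test_perfect_follower_features(self, single_stimulus_schedule):
        params = ArchetypeParams(Archetype.FOLLOWER, 0.5, 0.0, 0.0, 2.0, 0.0)
        traj = simulate_trajectory(params, single_stimulus_schedule, seed=0, t0=2.0)
        row = extract_features(traj, single_stimulus_schedule, t0=2.0).iloc[0]
        assert row["rotation_asymmetry"] == pytest.approx(0.0, abs=0.01)
        assert row["tortuosity"] == pytest.approx(1.0, abs=1e-6)
        assert row["abs_turning_velocity"] == pytest.approx(0.0, abs=1e-6)
        assert row["ymax"] == pytest.approx(5.0, rel=0.01)

    def test_pure_left_turner_features(self, single_stimulus_schedule):
        params = ArchetypeParams(Archetype.BIASED_TURNER, 0.0, 0.0, 0.8, 3.0, 0.0)
        traj = simulate_trajectory(params, single_stimulus_schedule, seed=0, t0=2.0)
        row = extract_features(traj, single_stimulus_schedule, t0=2.0).iloc[0]
        assert row["rotation_asymmetry"] == pytest.approx(1.0, abs=1e-6)
        assert row["abs_turning_velocity"] == pytest.approx(0.8, rel=1e-3)
        assert row["bias_direction"] == "LEFT"

    def test_full_battery_yields_one_row_per_stimulus(self):
        from optomotor.stimuli import default_battery

        sched = build_schedule(default_battery(), epoch_duration=2.0, repeats=2, isi=1.0, order_seed=0)
        params = ArchetypeParams(Archetype.FOLLOWER, 0.5, 0.1, 0.0, 2.0, 0.05)
        traj = simulate_trajectory(params, sched, seed=1, t0=1.0)
        table = extract_features(traj, sched, t0=1.0)
        assert len(table) == 12
        assert set(FEATURE_COLUMNS) <= set(table.columns)
        assert table["full_coverage"].all()

    def test_mirror_symmetry(self, single_stimulus_schedule):
        params = ArchetypeParams(Archetype.BIASED_TURNER, 0.3, 0.2, 0.4, 2.5, 0.0)
        traj = simulate_trajectory(params, single_stimulus_schedule, seed=3, t0=2.0)
        row = extract_features(traj, single_stimulus_schedule, t0=2.0).iloc[0]

        # reflect the world left<->right: negate yaw and swap epoch directions
        mirrored = make_trajectory(
            -traj.integrated_heading,
            frame_rate=traj.frame_rate,
            ball_diameter=traj.ball_diameter,
            increments=traj.rotation_increment * np.array([1.0, 1.0, -1.0]),
        )
        swapped = Schedule(
            stimuli=tuple(
                (spec, tuple(Epoch(Direction(-e.direction.value), e.onset, e.duration) for e in epochs))
                for spec, epochs in single_stimulus_schedule.stimuli
            ),
            inter_stimulus_interval=single_stimulus_schedule.inter_stimulus_interval,
            epoch_duration=single_stimulus_schedule.epoch_duration,
            repeats=single_stimulus_schedule.repeats,
            order_seed=single_stimulus_schedule.order_seed,
        )
        mrow = extract_features(mirrored, swapped, t0=2.0).iloc[0]
        assert mrow["ymax_left"] == pytest.approx(row["ymax_right"], abs=1e-9)
        assert mrow["ymax_right"] == pytest.approx(row["ymax_left"], abs=1e-9)
        assert mrow["bias_direction"] != row["bias_direction"] or row["bias_direction"] == "NONE"
        for col in ("rotation_asymmetry", "tortuosity", "walking_pace", "abs_turning_velocity"):
            assert mrow[col] == pytest.approx(row[col], abs=1e-9)
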