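"""Binning, transition deltas, the PI formula, and population statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import photokin as pk
from photokin.photokinesis import (
    BinnedActivity,
    TransitionDelta,
    compare_populations,
    extract_transition_deltas,
    photokinesis_index,
)


def _track(times, x, y, well="w0", fr=None):
    times = np.asarray(times, dtype=float)
    fr = fr or 1.0 / (times[1] - times[0])
    return pk.LocomotorTrack(well, fr, times, np.asarray(x, float), np.asarray(y, float))


def _binned(distances, bin_s=30.0, well="w0"):
    d = np.asarray(distances, float)
    return BinnedActivity(well, bin_s, bin_s * np.arange(len(d)), d)


class TestBinActivity:
    def test_piecewise_speeds_sum_by_brute_force(self):
        # 2 mm/s for 30 s then 0.5 mm/s for 30 s, sampled at 1 Hz along x
        t = np.arange(61.0)
        speed = np.where(t < 30, 2.0, 0.5)
        x = np.concatenate([[0.0], np.cumsum(speed[:-1])])
        binned = pk.bin_activity(_track(t, x, np.zeros_like(x)), jitter_mm=0.0)
        np.testing.assert_allclose(binned.distance_mm, [60.0, 15.0])

    def test_stationary_larva_has_zero_bins(self):
        t = np.arange(90.0)
        binned = pk.bin_activity(_track(t, np.ones_like(t), np.ones_like(t)))
        np.testing.assert_array_equal(binned.distance_mm, [0.0, 0.0])

    def test_jitter_threshold_suppresses_small_steps(self):
        t = np.arange(31.0)
        x = 0.05 * np.arange(31.0)  # 0.05-mm steps, below the 0.1-mm default
        assert pk.bin_activity(_track(t, x, np.zeros_like(x))).distance_mm[0] == 0.0
        assert pk.bin_activity(_track(t, x, np.zeros_like(x)), jitter_mm=0.0).distance_mm[
            0
        ] == pytest.approx(1.5)

    def test_trailing_partial_bin_dropped(self):
        t = np.arange(75.0)
        x = np.arange(75.0)
        binned = pk.bin_activity(_track(t, x, np.zeros_like(x)), jitter_mm=0.0)
        assert len(binned.distance_mm) == 2

    def test_degenerate_tracks_raise(self):
        with pytest.raises(ValueError):
            pk.bin_activity(_track([0.0], [0.0], [0.0], fr=1.0))
        bad = pk.LocomotorTrack.__new__(pk.LocomotorTrack)
        object.__setattr__(bad, "well_id", "w")
        object.__setattr__(bad, "frame_rate", 1.0)
        object.__setattr__(bad, "time_s", np.array([0.0, 2.0, 1.0]))
        object.__setattr__(bad, "x_mm", np.zeros(3))
        object.__setattr__(bad, "y_mm", np.zeros(3))
        with pytest.raises(ValueError):
            pk.bin_activity(bad)


class TestTransitionDeltas:
    def test_single_transition_delta(self):
        # ON 0-60, OFF 60-120; bins [10, 10, 20, 20]
        sched = pk.make_schedule(0, 60, 1)
        delta = extract_transition_deltas(_binned([10, 10, 20, 20]), sched)
        assert delta.delta_on_off == pytest.approx(10.0)
        assert delta.n_on_off == 1 and delta.n_off_on == 0

    def test_flat_activity_gives_zero_deltas(self, assay_schedule):
        binned = _binned(np.full(120, 7.0))
        delta = extract_transition_deltas(binned, assay_schedule)
        assert delta.delta_on_off == 0.0 and delta.delta_off_on == 0.0
        assert delta.n_on_off == 3 and delta.n_off_on == 2

    def test_deltas_average_across_transitions(self):
        # two ON->OFF transitions with post-pre changes 8 and 12
        sched = pk.LightSchedule(
            (
                (pk.ON, 0, 30),
                (pk.OFF, 30, 60),
                (pk.ON, 60, 90),
                (pk.OFF, 90, 120),
            )
        )
        binned = _binned([10, 18, 10, 22])
        delta = extract_transition_deltas(binned, sched)
        assert delta.delta_on_off == pytest.approx(10.0)

    def test_acclimation_boundary_excluded_by_default(self, assay_schedule):
        d = np.zeros(120)
        binned = _binned(d)
        assert extract_transition_deltas(binned, assay_schedule).n_off_on == 2
        assert (
            extract_transition_deltas(
                binned, assay_schedule, skip_acclimation=False
            ).n_off_on
            == 3
        )

    def test_misaligned_transitions_raise(self):
        sched = pk.make_schedule(0, 45, 1)
        with pytest.raises(ValueError):
            extract_transition_deltas(_binned([1, 2, 3]), sched)


class TestPhotokinesisIndex:
    @pytest.mark.parametrize(
        "d1,d2,expected",
        [(5.0, 0.0, 1.0), (2.0, 2.0, 0.0), (1.0, 3.0, -0.5)],
    )
    def test_printed_formula(self, d1, d2, expected):
        delta = TransitionDelta("w", d1, d2, 1, 1)
        rec = photokinesis_index(delta)
        assert rec.valid and rec.pi == pytest.approx(expected)

    def test_near_zero_denominator_flagged_invalid(self):
        rec = photokinesis_index(TransitionDelta("w", 1e-9, -1e-9, 1, 1))
        assert not rec.valid and "epsilon" in rec.reason

    def test_missing_transition_type_flagged(self):
        rec = photokinesis_index(TransitionDelta("w", 1.0, float("nan"), 1, 0))
        assert not rec.valid and "OFF->ON" in rec.reason

    @settings(max_examples=200, deadline=None)
    @given(
        d1=st.floats(0.0, 1e4),
        d2=st.floats(0.0, 1e4),
        scale=st.floats(1e-3, 1e3),
    )
    def test_antisymmetry_bounds_and_scale_invariance(self, d1, d2, scale):
        rec = photokinesis_index(TransitionDelta("w", d1, d2, 1, 1))
        swapped = photokinesis_index(TransitionDelta("w", d2, d1, 1, 1))
        scaled = photokinesis_index(TransitionDelta("w", scale * d1, scale * d2, 1, 1))
        if rec.valid:
            assert -1.0 <= rec.pi <= 1.0
            assert swapped.valid and swapped.pi == pytest.approx(-rec.pi, abs=1e-12)
            if scaled.valid:
                assert scaled.pi == pytest.approx(rec.pi, rel=1e-9, abs=1e-9)


class TestScorePopulation:
    def test_noiseless_populations_score_plus_minus_one(self, assay_schedule):
        for params, sign in [
            (pk.surface_like_params(noise_sd=0.0), 1.0),
            (pk.cave_like_params(noise_sd=0.0), -1.0),
        ]:
            tracks = [
                pk.simulate_track(params, assay_schedule, seed=i, well_id=f"w{i}")
                for i in range(5)
            ]
            table, summary = pk.score_population(tracks, assay_schedule)
            assert np.allclose(table["pi"], sign, atol=1e-3)
            assert summary["n_excluded"] == 0

    def test_invalid_fish_are_counted_not_dropped_silently(self, short_schedule):
        good = pk.simulate_track(
            pk.surface_like_params(), short_schedule, seed=0, well_id="good"
        )
        frozen = pk.simulate_track(
            pk.PopulationParams(baseline_speed=0.0, transient_gain=0.0, noise_sd=0.0),
            short_schedule,
            seed=1,
            well_id="frozen",
        )
        table, summary = pk.score_population([good, frozen], short_schedule)
        assert summary["n_excluded"] == 1
        assert not table.set_index("well_id").loc["frozen", "valid"]

    def test_per_transition_variant_matches_on_symmetric_data(self, short_schedule):
        tracks = [
            pk.simulate_track(
                pk.surface_like_params(noise_sd=0.0), short_schedule, seed=0
            )
        ]
        t_avg, _ = pk.score_population(tracks, short_schedule)
        t_per, _ = pk.score_population(tracks, short_schedule, per_transition=True)
        assert t_per["pi"].iloc[0] == pytest.approx(t_avg["pi"].iloc[0], abs=1e-3)

    def test_empty_input_raises(self, short_schedule):
        with pytest.raises(ValueError):
            pk.score_population([], short_schedule)


class TestComparePopulations:
    def test_identical_groups_give_f_zero_p_one(self):
        g = [1.0, 2.0, 3.0]
        report = compare_populations({"a": g, "b": g, "c": g})
        assert report.statistic == pytest.approx(0.0)
        assert report.p_value == pytest.approx(1.0)

    def test_anova_f_matches_brute_force_sums_of_squares(self, rng):
        groups = {f"g{i}": rng.normal(i * 0.3, 1.0, 8 + i) for i in range(3)}
        report = compare_populations(groups)
        data = [np.asarray(v) for v in groups.values()]
        grand = np.concatenate(data).mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in data)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in data)
        k, n = len(data), sum(len(g) for g in data)
        f_brute = (ss_between / (k - 1)) / (ss_within / (n - k))
        assert report.statistic == pytest.approx(f_brute, abs=1e-10)

    def test_welch_used_for_two_groups(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(1, 2, 15)
        report = compare_populations({"a": a, "b": b})
        assert report.test == "welch_t"
        from scipy.stats import ttest_ind

        t, p = ttest_ind(a, b, equal_var=False)
        assert report.statistic == pytest.approx(t)
        assert report.p_value == pytest.approx(p)

    def test_tukey_adjusted_p_never_below_raw(self, rng):
        for _ in range(20):
            groups = {f"g{i}": rng.normal(rng.normal(), 1.0, 6) for i in range(4)}
            report = compare_populations(groups)
            for pair in report.pairwise:
                assert pair["p_adj"] >= pair["p_raw"] - 1e-12

    def test_normality_reported_but_not_switching_test(self, rng):
        groups = {"a": rng.exponential(1, 20), "b": rng.exponential(1, 20)}
        report = compare_populations(groups)
        assert report.test == "welch_t"
        assert all("shapiro_p" in g for g in report.groups.values())

    def test_small_groups_raise(self):
        with pytest.raises(ValueError):
            compare_populations({"a": [1.0, 2.0], "b": [1.0, 2.0, 3.0]})


class TestPipelineInvariants:
    def test_scale_invariance_of_pi_through_pipeline(self, short_schedule):
        track = pk.simulate_track(pk.surface_like_params(), short_schedule, seed=3)
        t1, _ = pk.score_population([track], short_schedule, jitter_mm=0.0)
        scaled = pk.LocomotorTrack(
            track.well_id,
            track.frame_rate,
            track.time_s,
            3.0 * track.x_mm,
            3.0 * track.y_mm,
        )
        t2, _ = pk.score_population([scaled], short_schedule, jitter_mm=0.0)
        assert t2["pi"].iloc[0] == pytest.approx(t1["pi"].iloc[0], rel=1e-9)

    def test_central_pi_monotone_in_triggered_gain(self, short_schedule):
        """Median PI rises with the dark-triggered gain and falls with the
        light-triggered gain (the PI ratio is heavy-tailed at low SNR, so the
        median is the stable central-tendency readout on a fixed seed grid)."""
        gains = [0.02, 0.3, 3.0]

        def medians(make_params):
            out = []
            for gain in gains:
                params = make_params(transient_gain=gain, noise_sd=2.5)
                tracks = [
                    pk.simulate_track(
                        params,
                        short_schedule,
                        seed=pk.substream(11, f"{params.label}:{gain}:{i}"),
                        well_id=f"w{i}",
                    )
                    for i in range(80)
                ]
                table, _ = pk.score_population(tracks, short_schedule)
                out.append(float(table.loc[table["valid"], "pi"].median()))
            return out

        surf = medians(pk.surface_like_params)
        cave = medians(pk.cave_like_params)
        assert surf[0] < surf[1] < surf[2]
        assert cave[0] > cave[1] > cave[2]

    def test_identical_inputs_give_identical_tables(self, short_schedule):
        tracks = [
            pk.simulate_track(pk.surface_like_params(), short_schedule, seed=i)
            for i in range(3)
        ]
        t1, _ = pk.score_population(tracks, short_schedule)
        t2, _ = pk.score_population(tracks, short_schedule)
        assert t1.equals(t2)
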