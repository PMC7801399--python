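"""State machine and phenotype extraction from light/dark-box profiles."""

import numpy as np
import pytest

from anxmediate import synthdata
from anxmediate.behavior import (
    DARK,
    LIGHT,
    PARTIAL,
    StateSequence,
    TrackingProfile,
    compute_phenotypes,
    compute_states,
    count_transitions,
    extract_phenotypes,
)


def _profile(area, fr=30.0):
    n = len(area)
    return TrackingProfile(
        t=np.arange(n) / fr,
        area_fraction=np.asarray(area, dtype=float),
        x=np.full(n, 50.0),
        y=np.full(n, 50.0),
        frame_rate=fr,
    )


class TestComputeStates:
    @pytest.mark.parametrize(
        "area, expected",
        [
            ([1, 1, 0, 0], [LIGHT, LIGHT, DARK, DARK]),
            ([1, 0.5, 0], [LIGHT, PARTIAL, DARK]),
        ],
    )
    def test_direct_thresholding(self, area, expected):
        seq = compute_states(_profile(area), theta_hi=0.95, theta_lo=0.05, min_dwell=1)
        assert seq.states.tolist() == expected

    def test_debounce_absorbs_single_frame_flicker(self):
        seq = compute_states(_profile([1, 1, 0, 1, 1, 1]), min_dwell=2)
        assert seq.states.tolist() == [LIGHT] * 6

    def test_first_run_exempt_from_debounce(self):
        seq = compute_states(_profile([1, 0, 0, 0, 0, 0]), min_dwell=3)
        assert seq.states.tolist() == [LIGHT] + [DARK] * 5

    def test_nan_area_names_frame(self):
        area = [1.0, 1.0, np.nan, 1.0]
        prof = _profile([1, 1, 1, 1])
        prof.area_fraction = np.asarray(area)
        with pytest.raises(ValueError, match="frame 2"):
            compute_states(prof)

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValueError):
            compute_states(_profile([1, 0]), theta_hi=0.05, theta_lo=0.95)


class TestCountTransitions:
    @pytest.mark.parametrize(
        "states, expected",
        [
            ([LIGHT, LIGHT, DARK, DARK, LIGHT, PARTIAL, DARK], (2, 0)),
            ([LIGHT, DARK, PARTIAL, DARK, PARTIAL, DARK], (1, 2)),
            ([LIGHT] * 6, (0, 0)),
            # excursion through PARTIAL still counts as one full transition
            ([LIGHT, PARTIAL, DARK], (1, 0)),
            # trailing partial poke that never returns to dark is not counted
            ([LIGHT, DARK, PARTIAL], (1, 0)),
        ],
    )
    def test_hand_traced_sequences(self, states, expected):
        assert count_transitions(np.asarray(states, dtype=np.int8)) == expected

    def test_appending_excursion_increments_full_count(self, rng):
        base = [LIGHT] * 10 + [DARK] * 5 + [LIGHT] * 8
        n0, _ = count_transitions(np.asarray(base, dtype=np.int8))
        extended = base + [DARK] * 5
        n1, _ = count_transitions(np.asarray(extended, dtype=np.int8))
        assert n1 == n0 + 1


class TestComputePhenotypes:
    def test_never_leaving_light(self):
        fr = 30.0
        n = int(300 * fr)
        plan = synthdata.TransitionPlan([("light", n)], [100.0], fr)
        prof = synthdata.gen_tracking_profile(plan, rng=1)
        pv = extract_phenotypes(prof)
        assert pv.time_light == 300.0
        assert pv.n_full_transitions == 0
        assert pv.latency_first_transition == 300.0
        assert pv.avg_time_light == 300.0
        assert pv.avg_speed == pytest.approx(pv.distance_light / 300.0)

    def test_two_transitions_light_dwell_arithmetic(self):
        fr = 30.0
        segs = [("light", 3000), ("dark", 2000), ("light", 1500), ("dark", 2500)]
        plan = synthdata.TransitionPlan(segs, [60.0, 60.0], fr)
        prof = synthdata.gen_tracking_profile(plan, rng=2)
        pv = extract_phenotypes(prof)
        assert pv.n_full_transitions == 2
        assert pv.time_light == pytest.approx(150.0)
        assert pv.avg_time_light == pytest.approx(75.0)
        assert pv.latency_first_transition == pytest.approx(100.0)

    def test_constant_speed_distance_oracle(self):
        # 100 mm/s for 2 s of light: ideal path length 200 mm, recovered
        # within one frame displacement (the polyline has n-1 steps)
        fr = 30.0
        plan = synthdata.TransitionPlan([("light", 60), ("dark", 8940)], [100.0], fr)
        prof = synthdata.gen_tracking_profile(plan, rng=3)
        pv = extract_phenotypes(prof)
        assert pv.distance_light == pytest.approx(plan.planted_distance, rel=1e-9)
        assert abs(pv.distance_light - 200.0) <= 100.0 / fr + 1e-9

    def test_centroid_confined_to_light_box_when_visible(self):
        plan = synthdata.TransitionPlan([("light", 2000), ("dark", 7000)], [80.0], 30.0)
        prof = synthdata.gen_tracking_profile(plan, rng=4)
        vis = prof.area_fraction >= 0.5
        assert np.all((prof.x[vis] >= 0) & (prof.x[vis] <= synthdata.BOX_WIDTH_MM))
        assert np.all((prof.y[vis] >= 0) & (prof.y[vis] <= synthdata.BOX_LENGTH_MM))
        assert prof.area_fraction[0] >= 0.95  # placed into the light


class TestPlantedRecovery:
    def test_random_plans_recovered_exactly(self, rng):
        spec = synthdata.CohortSpec(seed=5)
        for _ in range(100):
            n_full = int(rng.integers(0, 13))
            n_partial = int(rng.integers(0, 25)) if n_full else 0
            time_light = float(rng.uniform(25, 200))
            speed = float(rng.uniform(30, 110))
            plan = synthdata.build_plan(
                n_full, n_partial, time_light, speed, 30.0, 300.0, rng
            )
            prof = synthdata.gen_tracking_profile(plan, spec, rng=rng)
            pv = extract_phenotypes(prof)
            assert (pv.n_full_transitions, pv.n_partial_transitions) == plan.planted_counts
            assert pv.time_light == plan.planted_time_light
            assert pv.latency_first_transition == plan.planted_latency
            assert pv.distance_light == pytest.approx(plan.planted_distance, abs=1e-6)

    def test_subthreshold_noise_leaves_counts_invariant(self, rng):
        spec = synthdata.CohortSpec(seed=6)
        for _ in range(20):
            plan = synthdata.build_plan(
                int(rng.integers(1, 8)), int(rng.integers(0, 10)),
                float(rng.uniform(40, 150)), 60.0, 30.0, 300.0, rng,
            )
            noisy = synthdata.gen_tracking_profile(plan, spec, area_noise=0.04, rng=rng)
            pv = extract_phenotypes(noisy)
            assert (pv.n_full_transitions, pv.n_partial_transitions) == plan.planted_counts
            assert pv.time_light == plan.planted_time_light
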