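"""Generators: hand template, percept sessions, synergy EMG, observer search."""

import numpy as np
import pytest

from smbench.emg_features import (
    MOVE_FRAMES,
    REST_FRAMES,
    enumerate_postures,
)
from smbench.percept_maps import cumulative_coverage, percept_area
from smbench.percept_clustering import build_dissimilarity_matrix
from smbench.synthetic_data import (
    SyntheticUser,
    ThresholdObserver,
    default_synergy_model,
    forward_wfl,
    generate_emg_dataset,
    generate_hand_template,
    generate_percept_sessions,
    isens_60contact_model,
    percutaneous_16ch_model,
    simulate_threshold_search,
)


class TestHandTemplate:
    def test_deterministic_and_nonempty(self):
        a = generate_hand_template(128, seed=0)
        b = generate_hand_template(128, seed=0)
        np.testing.assert_array_equal(a.mask, b.mask)
        assert a.total_hand_area_px > 0

    def test_digit_zones_disjoint_and_labelled(self, template):
        digits = {"thumb", "index", "middle", "ring", "little"}
        seen = set(np.unique(template.region_labels))
        assert digits <= seen
        # each pixel carries exactly one region label by construction;
        # digit zones must all be hand pixels distal to the wrist
        for d in digits:
            zone = template.region_labels == d
            assert zone.any()
            assert np.all(template.mask[zone])

    def test_wrist_to_middle_fingertip_is_19cm(self, template):
        middle_rows = np.flatnonzero(
            np.any(template.region_labels == "middle", axis=1)
        )
        length_px = template.wrist_row - middle_rows.min()
        assert length_px * template.cm_per_pixel == pytest.approx(19.0)

    def test_panels_partition_hand_mask(self, template):
        on_hand = template.panel_labels != "background"
        np.testing.assert_array_equal(on_hand, template.mask)


class TestPerceptSessions:
    def test_deterministic_under_seed(self, small_template):
        m = percutaneous_16ch_model()
        a = generate_percept_sessions(m, small_template, 2, seed=9)
        b = generate_percept_sessions(m, small_template, 2, seed=9)
        for sa, sb in zip(a, b):
            assert len(sa.drawings) == len(sb.drawings)
            for da, db in zip(sa.drawings, sb.drawings):
                np.testing.assert_array_equal(da.mask, db.mask)

    def test_zero_jitter_certain_evoke_gives_identical_sessions(self, small_template):
        m = percutaneous_16ch_model(
            jitter_frac=0.0, area_sigma=0.0, p_proprioceptive=0.0, p_painful=0.0
        )
        sessions = generate_percept_sessions(m, small_template, 2, seed=0)
        assert all(len(s.drawings) == 16 for s in sessions)
        for da, db in zip(sessions[0].drawings, sessions[1].drawings):
            np.testing.assert_array_equal(da.mask, db.mask)

    def test_dense_model_has_more_overlap_than_sparse(self, template):
        def mean_similarity(model, seed):
            s = generate_percept_sessions(model, template, 1, seed=seed)[0]
            Dm = build_dissimilarity_matrix(s.drawings, include=None)
            triu = Dm.D[np.triu_indices(Dm.n, 1)]
            return float(1.0 - triu.mean())  # mean pairwise Jaccard overlap

        sims_sparse = [mean_similarity(percutaneous_16ch_model(), s) for s in range(5)]
        sims_dense = [mean_similarity(isens_60contact_model(), s) for s in range(5)]
        assert np.mean(sims_dense) > np.mean(sims_sparse)

    def test_area_parameter_calibrated(self, template):
        m = percutaneous_16ch_model(
            area_fraction_mean=0.03, area_sigma=0.0,
            p_proprioceptive=0.0, p_painful=0.0,
        )
        sessions = generate_percept_sessions(m, template, 7, seed=0)
        areas = [percept_area(d, template) for s in sessions for d in s.drawings]
        assert len(areas) >= 100
        assert np.mean(areas) == pytest.approx(0.03, rel=0.2)

    def test_tested_contacts_include_silent_ones(self, template):
        m = isens_60contact_model()
        s = generate_percept_sessions(m, template, 1, seed=1)[0]
        assert len(s.tested_contacts) == 60
        assert len(s.drawings) < 60  # radial cuff mostly silent

    def test_coverage_resolution_stable(self):
        # the generator parameters are resolution-independent, so coverage
        # fractions agree across raster resolutions to within 1%
        covs = {}
        for res in (128, 512):
            t = generate_hand_template(res)
            s = generate_percept_sessions(
                percutaneous_16ch_model(), t, 1, seed=1
            )[0]
            covs[res] = cumulative_coverage(s.drawings, t)
        assert abs(covs[128] - covs[512]) <= 0.01

    def test_drawings_clipped_to_hand(self, template):
        s = generate_percept_sessions(percutaneous_16ch_model(), template, 1, seed=2)[0]
        hand = template.hand_region
        for d in s.drawings:
            assert not np.any(d.mask & ~hand)


class TestEmgGeneration:
    def test_full_protocol_yields_320_trials(self, emg_trials):
        assert len(emg_trials) == 320
        assert len({t.posture for t in emg_trials}) == 32

    def test_rest_window_wfl_sits_at_noise_floor(self, synergy_model, emg_trials):
        t = emg_trials[0]
        rest = t.wfl[:, REST_FRAMES].mean(axis=1)
        expect = 2 / np.sqrt(np.pi) * synergy_model.gains * synergy_model.noise_floor
        np.testing.assert_allclose(rest, expect, rtol=0.35)

    def test_driven_channel_modulates_only_for_its_dof(self, synergy_model):
        # supinator (ch 12) drives +supination only
        pro = generate_emg_dataset(
            synergy_model, postures=[(-1, 0, 0, 0)], reps=3, seed=0
        )
        sup = generate_emg_dataset(
            synergy_model, postures=[(1, 0, 0, 0)], reps=3, seed=0
        )

        def ratio(trials, ch):
            move = np.mean([t.wfl[ch, MOVE_FRAMES].mean() for t in trials])
            rest = np.mean([t.wfl[ch, REST_FRAMES].mean() for t in trials])
            return move / rest

        assert ratio(sup, 12) > 2.0
        assert ratio(pro, 12) == pytest.approx(1.0, abs=0.3)

    def test_dead_channels_never_modulate(self, synergy_model, emg_trials):
        for ch in synergy_model.dead_channels:
            move = np.mean([t.wfl[ch, MOVE_FRAMES].mean() for t in emg_trials[:40]])
            rest = np.mean([t.wfl[ch, REST_FRAMES].mean() for t in emg_trials[:40]])
            assert move / rest == pytest.approx(1.0, abs=0.1)

    def test_wfl_increases_with_activation(self, synergy_model):
        trials = generate_emg_dataset(
            synergy_model, postures=[(0, 1, 0, 0)], reps=1, seed=3
        )
        wfl = trials[0].wfl[13]  # ECRL during wrist extension
        assert wfl[MOVE_FRAMES[-5:]].mean() > 3 * wfl[REST_FRAMES].mean()

    def test_bitwise_reproducible(self, synergy_model):
        a = generate_emg_dataset(synergy_model, postures=[(0, 0, 0, 1)], reps=2, seed=5)
        b = generate_emg_dataset(synergy_model, postures=[(0, 0, 0, 1)], reps=2, seed=5)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.raw, tb.raw)


class TestSyntheticUser:
    def test_at_target_emits_near_floor_frame(self, synergy_model):
        user = SyntheticUser(synergy_model, noise=0.0, seed=0)
        state = np.array([0.3, -0.2, 0.1, 0.0])
        frame = user(state, state)
        floor = forward_wfl(synergy_model, np.zeros(4))
        np.testing.assert_allclose(frame, floor, rtol=1e-9)

    def test_deterministic_given_seed(self, synergy_model):
        f1 = SyntheticUser(synergy_model, seed=4)(np.zeros(4), np.ones(4))
        f2 = SyntheticUser(synergy_model, seed=4)(np.zeros(4), np.ones(4))
        np.testing.assert_array_equal(f1, f2)

    def test_larger_error_gives_larger_mean_frame(self, synergy_model):
        # errors below the saturation point of the kp=2 policy
        user = SyntheticUser(synergy_model, noise=0.0, seed=0)
        means = [
            user(np.zeros(4), np.full(4, err)).mean()
            for err in (0.05, 0.15, 0.3, 0.5)
        ]
        assert np.all(np.diff(means) > 0)


class TestThresholdSearch:
    def test_found_pulse_width_within_resolution(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            amp_step = 0.1
            resolution = float(rng.choice([5.0, 10.0]))
            T = float(rng.uniform(1.0, 200.0))
            obs = ThresholdObserver(charge_threshold=T)
            res = simulate_threshold_search(
                obs, amplitude_step_ma=amp_step, pw_resolution_us=resolution,
                pw_max_us=255.0,
            )
            assert res.detected
            true_pw = obs.min_pulse_width(res.amplitude_ma)
            assert res.pulse_width_us >= true_pw  # always detectable
            assert res.pulse_width_us - true_pw <= resolution

    def test_threshold_above_charge_limit_gives_no_percept(self):
        obs = ThresholdObserver(charge_threshold=1e6)
        res = simulate_threshold_search(obs)
        assert not res.detected
        assert res.amplitude_ma is None and res.pulse_width_us is None

    def test_query_count_bounded_by_bisection_depth(self):
        obs = ThresholdObserver(charge_threshold=128.0 * 0.5)
        res = simulate_threshold_search(
            obs, amplitude_step_ma=0.1, pw_resolution_us=5.0, pw_max_us=256.0
        )
        staircase_steps = 10  # at most amplitude_max / step queries
        assert res.n_queries <= int(np.ceil(np.log2(256 / 5.0))) + staircase_steps


class TestEndToEndRehearsals:
    def test_dense_system_yields_more_clusters_and_coverage(self, template):
        """More, denser stimulation contacts produce more unique percept
        locations (cutoff 0.7) and larger cumulative hand coverage."""
        from smbench.percept_clustering import cluster_curve

        counts = {"sparse": [], "dense": []}
        covs = {"sparse": [], "dense": []}
        for seed in range(5):
            for name, model in (
                ("sparse", percutaneous_16ch_model()),
                ("dense", isens_60contact_model()),
            ):
                sessions = generate_percept_sessions(model, template, 1, seed=seed)
                for s in sessions:
                    counts[name].append(
                        cluster_curve(s.drawings).count_at(0.7)
                    )
                    covs[name].append(cumulative_coverage(s.drawings, template))
        assert np.mean(counts["dense"]) > np.mean(counts["sparse"])
        assert np.mean(covs["dense"]) > np.mean(covs["sparse"])
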