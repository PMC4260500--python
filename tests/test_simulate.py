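"""Forward-model contracts: determinism, the workload signature against a
periodogram oracle, and artifact injection."""

import numpy as np
import pytest
from scipy.signal import welch

from wmlbci.events import SessionSchedule
from wmlbci.forward import ForwardModel, inject_artifacts, simulate_session
from wmlbci.preprocess import extract_interval_pairs
from wmlbci.schedules import ReactionTimes, build_nback_block
from wmlbci.workload import RatingModel, WorkloadProfile


def slow_nback_schedule(n_trials=16, seed=0):
    """n-back variant with long intervals (8-s ISI, ~4-s responses) so that
    activation and rest segments are long enough for periodogram oracles."""
    return build_nback_block(1, n_trials, seed, isi_s=8.0,
                             rt=ReactionTimes(4.0, 0.02, 3.8, 4.2))


class TestDeterminism:
    def test_same_seed_same_config_bit_identical(self):
        sched = build_nback_block(2, 16, 3)
        fm = ForwardModel(rate=128.0)
        a, ra = simulate_session(sched, fm, seed=11)
        b, rb = simulate_session(sched, fm, seed=11)
        assert np.array_equal(a.signal, b.signal)
        assert [r.rating for r in ra] == [r.rating for r in rb]

    def test_different_seed_differs(self):
        sched = build_nback_block(2, 16, 3)
        fm = ForwardModel(rate=128.0)
        a, _ = simulate_session(sched, fm, seed=11)
        b, _ = simulate_session(sched, fm, seed=12)
        assert not np.array_equal(a.signal, b.signal)

    def test_zero_signature_is_independent_of_workload(self):
        """With k_a = k_t = 0 the rendered signal is identical whatever the
        latent load profile (null forward model)."""
        sched = build_nback_block(2, 16, 4)
        fm = ForwardModel(rate=128.0, k_a=0.0, k_t=0.0)
        lo = WorkloadProfile(base_load={("nback", 2): 0.05})
        hi = WorkloadProfile(base_load={("nback", 2): 0.95})
        a, _ = simulate_session(sched, fm, profile=lo, seed=5, artifacts=False)
        b, _ = simulate_session(sched, fm, profile=hi, seed=5, artifacts=False)
        assert np.array_equal(a.signal, b.signal)


class TestSignature:
    def test_alpha_erd_matches_analytic_expectation(self):
        """With alpha amplitude factor (1 - k_a) = 0.6 between full load and
        rest, parietal alpha band power should show ~(0.36 - 1) = -64% ERD;
        oracle is a Welch periodogram on the generated segments."""
        sched = slow_nback_schedule()
        fm = ForwardModel(rate=128.0, k_a=0.4, k_t=0.0, pink_amp=0.0,
                          am_depth=0.05, freq_jitter_hz=0.02, drift_amp=0.0)
        profile = WorkloadProfile(base_load={("nback", 1): 1.0}, floor=0.0,
                                  learning_decay_rate=0.0)
        rec, _ = simulate_session(sched, fm, profile=profile, seed=2,
                                  artifacts=False)
        pairs = extract_interval_pairs(rec, "nback")
        pz = rec.channel_index("Pz")

        def alpha_power(i0, i1):
            f, pxx = welch(rec.signal[pz, i0:i1], fs=rec.rate,
                           nperseg=min(256, i1 - i0))
            return pxx[(f >= 8) & (f <= 13)].mean()

        pa = np.mean([alpha_power(p.activation.i0, p.activation.i1) for p in pairs])
        pr = np.mean([alpha_power(p.rest.i0, p.rest.i1) for p in pairs])
        erd = (pa - pr) / pr * 100.0
        assert erd == pytest.approx(-64.0, abs=8.0)

    def test_signature_direction_frontal_theta_up_parietal_alpha_down(self, nback_recording):
        rec, _ = nback_recording
        pairs = extract_interval_pairs(rec, "nback")
        fz, pz = rec.channel_index("Fz"), rec.channel_index("Pz")
        lv = {1: [], 3: []}
        for p in pairs:
            if p.level in lv:
                lv[p.level].append(p)

        def band_mean(ps, ch, lohi):
            vals = []
            for p in ps:
                f, pxx = welch(rec.signal[ch, p.activation.i0:p.activation.i1],
                               fs=rec.rate, nperseg=min(64, p.activation.n_samples()))
                vals.append(pxx[(f >= lohi[0]) & (f <= lohi[1])].mean())
            return np.mean(vals)

        assert band_mean(lv[3], fz, (4, 7)) > band_mean(lv[1], fz, (4, 7))
        assert band_mean(lv[3], pz, (8, 13)) < band_mean(lv[1], pz, (8, 13))


class TestOverloadReversal:
    def test_extreme_load_inverts_the_alpha_modulation(self):
        """Above the overload threshold the signature flips (disengagement):
        alpha is enhanced rather than suppressed during activation."""
        sched = slow_nback_schedule(seed=9)
        fm = ForwardModel(rate=128.0, k_a=0.6, k_t=0.0, pink_amp=0.0,
                          am_depth=0.05, freq_jitter_hz=0.02, drift_amp=0.0)
        base = dict(base_load={("nback", 1): 1.0}, floor=0.0,
                    learning_decay_rate=0.0)
        normal = WorkloadProfile(**base)
        reversed_ = WorkloadProfile(**base, overload_reversal=True,
                                    reversal_threshold=0.5)
        rec_n, _ = simulate_session(sched, fm, profile=normal, seed=4,
                                    artifacts=False)
        rec_r, _ = simulate_session(sched, fm, profile=reversed_, seed=4,
                                    artifacts=False)
        pz = rec_n.channel_index("Pz")
        pairs = extract_interval_pairs(rec_n, "nback")
        i0, i1 = pairs[0].activation.i0, pairs[-1].activation.i1
        var_n = rec_n.signal[pz, i0:i1].var()
        var_r = rec_r.signal[pz, i0:i1].var()
        assert var_r > var_n  # (1 + k_a W) vs (1 - k_a W) amplitude


class TestArtifacts:
    def test_zero_amplitudes_leave_recording_unchanged(self):
        sched = build_nback_block(1, 8, 0)
        fm = ForwardModel(rate=128.0, blink_rate_hz=0.0, blink_amp=0.0, emg_amp=0.0)
        rec, _ = simulate_session(sched, fm, seed=1, artifacts=False)
        out = inject_artifacts(rec, fm, seed=2)
        assert np.array_equal(out.signal, rec.signal)
        assert len(out.events) == len(rec.events)

    def test_emg_bursts_raise_2060hz_power_around_keypresses(self):
        sched = build_nback_block(1, 24, 1)
        fm = ForwardModel(rate=256.0, blink_rate_hz=0.0, emg_amp=8.0)
        rec, _ = simulate_session(sched, fm, seed=3, artifacts=True)
        fz = rec.channel_index("Fz")
        kp = [e.onset_s for e in rec.events if e.kind == "keypress"]

        def hf_power(t0, t1):
            seg = rec.signal[fz, int(t0 * rec.rate):int(t1 * rec.rate)]
            f, pxx = welch(seg, fs=rec.rate, nperseg=min(128, len(seg)))
            return pxx[(f >= 20) & (f <= 60)].mean()

        near = np.mean([hf_power(t - 0.1, t + 0.1) for t in kp])
        # keypress-free: just after each stimulus-free mid-rest point
        far = np.mean([hf_power(t + 0.45, t + 0.65) for t in kp[:-1]])
        assert near > 2.0 * far

    def test_blinks_inflate_veog_variance(self):
        sched = build_nback_block(1, 24, 1)
        quiet = ForwardModel(rate=128.0, blink_rate_hz=0.0, emg_amp=0.0)
        blinky = ForwardModel(rate=128.0, blink_rate_hz=0.5, emg_amp=0.0)
        rec_q, _ = simulate_session(sched, quiet, seed=4, artifacts=True)
        rec_b, _ = simulate_session(sched, blinky, seed=4, artifacts=True)
        assert rec_b.get("VEOG").var() > 2.0 * rec_q.get("VEOG").var()

    def test_aliasing_guard_rejects_low_rate(self):
        with pytest.raises(ValueError):
            ForwardModel(rate=100.0)


class TestRatingsCoupling:
    def test_rating_prompts_filled_with_generated_ratings(self):
        sched = build_nback_block(2, 16, 5)
        rec, ratings = simulate_session(sched, ForwardModel(rate=128.0), seed=6)
        prompts = [e for e in rec.events if e.kind == "rating_prompt"]
        assert prompts and all(e.payload["value"] in range(1, 8) for e in prompts)
        assert all(1 <= r.rating <= 7 for r in ratings)

    def test_container_roundtrip(self, tmp_path):
        sched = build_nback_block(1, 6, 0)
        rec, _ = simulate_session(sched, ForwardModel(rate=128.0), seed=7)
        rec.to_dir(tmp_path)
        from wmlbci.recording import EEGRecording

        back = EEGRecording.from_dir(tmp_path)
        assert back.channels == rec.channels
        assert back.rate == rec.rate
        assert np.allclose(back.signal, rec.signal, atol=1e-5)
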