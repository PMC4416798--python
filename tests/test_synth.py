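"""Synthetic experiment generator: session plans, speed profiles, onset
detection, forward-projected recordings and whole-subject simulation."""

import numpy as np
import pytest

from gaitdecode import synth
from gaitdecode.headmodel import Dipole, forward_potentials
from gaitdecode.io import quantize_bdf, read_bdf, write_bdf
from gaitdecode.synth import (Carrier, GeneratorConfig, SourceSpec,
                              default_sources, detect_onsets_encoder,
                              make_session_plan, render_speed_profile,
                              simulate_recording, simulate_subject)

KMH = 1 / 3.6


class TestSessionPlan:
    def test_cued_design(self):
        plan = make_session_plan("cued")
        assert len(plan.block_speeds) == 19
        assert plan.n_transitions == 18
        assert sum(plan.block_durations) == pytest.approx(380.0)
        assert plan.block_speeds[:6] == (0, 1, 2, 1, 2, 1)

    def test_uncued_reproducible_and_truncated(self):
        a = make_session_plan("uncued", seed=7)
        b = make_session_plan("uncued", seed=7)
        assert a == b
        assert sum(a.block_durations) == pytest.approx(380.0)
        assert a.block_speeds == synth.SPEED_ORDER[:len(a.block_speeds)]

    def test_uncued_plateaus_floored(self):
        plan = make_session_plan("uncued", seed=3)
        for prev, cur, dur in zip(plan.block_speeds, plan.block_speeds[1:],
                                  plan.block_durations[1:-1]):
            ramp = 4.0 if cur > prev else 8.0
            assert dur - ramp >= synth.UNCUED_PLATEAU_FLOOR - 1e-9


class TestSpeedProfile:
    def test_ramp_durations(self):
        prof = render_speed_profile(make_session_plan("cued"), fs=128.0)
        up = next(t for t in prof.transitions if t.to_kmh > t.from_kmh)
        down = next(t for t in prof.transitions if t.to_kmh < t.from_kmh)
        assert up.ramp_s == 4.0 and down.ramp_s == 8.0
        # speed really moves linearly over exactly the ramp span
        sel = (prof.t >= up.t_start) & (prof.t <= up.t_start + 4.0)
        assert prof.speed[sel][0] == pytest.approx(up.from_kmh * KMH, abs=1e-2)
        assert prof.speed[sel][-1] == pytest.approx(up.to_kmh * KMH, abs=1e-2)

    def test_plateaus_flat(self):
        prof = render_speed_profile(make_session_plan("cued"))
        d = np.diff(prof.speed)
        in_ramp = np.zeros(len(prof.t) - 1, bool)
        for tr in prof.transitions:
            in_ramp |= (prof.t[:-1] >= tr.t_start - 1e-9) & \
                       (prof.t[:-1] < tr.t_start + tr.ramp_s)
        assert np.all(d[~in_ramp] == 0.0)

    def test_transition_count(self):
        plan = make_session_plan("cued")
        prof = render_speed_profile(plan)
        assert len(prof.transitions) == plan.n_transitions


class TestOnsetDetection:
    def test_constant_profile_has_no_events(self):
        prof = synth.SpeedProfile(t=np.arange(0, 100, 1 / 64.0),
                                  speed=np.full(6400, 0.3),
                                  transitions=(), fs=64.0)
        assert len(detect_onsets_encoder(prof)) == 0

    def test_crossing_time_is_analytic(self):
        prof = render_speed_profile(make_session_plan("cued"), fs=256.0)
        ev = detect_onsets_encoder(prof, threshold=0.12)
        slope_up = KMH / 4.0
        first = next(t for t in prof.transitions if t.to_kmh > t.from_kmh)
        assert ev.iloc[0]["onset_s"] == pytest.approx(
            first.t_start + 0.12 / slope_up, abs=1e-9)

    def test_cued_session_yields_18_events(self):
        prof = render_speed_profile(make_session_plan("cued"))
        assert len(detect_onsets_encoder(prof)) == 18


class TestSimulateRecording:
    def test_silence(self, montage, headmodel):
        plan = make_session_plan("cued")
        rec = simulate_recording(plan, [], montage, headmodel, fs=64.0,
                                 seed=0, sensor_noise_uv=0.0)
        assert np.all(rec.signal == 0.0)
        assert len(rec.events) == 18

    def test_rank_one_structure(self, montage, headmodel):
        src = SourceSpec("cortical", Dipole((-30., 0., 40.), (0., 1., 0.)), 10.0,
                         carriers=(Carrier((9., 12.), 1.0, 0.0),))
        rec = simulate_recording(make_session_plan("cued"), [src], montage,
                                 headmodel, fs=64.0, seed=1, sensor_noise_uv=0.0)
        u, s, _ = np.linalg.svd(rec.signal[:, :4000], full_matrices=False)
        assert s[1] < 1e-9 * s[0]
        gain = forward_potentials(Dipole((-30., 0., 40.), (0., 10., 0.)),
                                  montage, headmodel)
        c = np.abs(np.corrcoef(u[:, 0], gain)[0, 1])
        assert c > 1 - 1e-9

    def test_implanted_erd_depth_measurable(self, montage, headmodel):
        """The parietal source's 10 Hz log-power drops by the configured depth
        (±1 dB) in the 0–2 s post-onset window, measured with the package's
        own spectral estimator."""
        from gaitdecode.timefreq import TFConfig, wavelet_tf
        gen = GeneratorConfig(fs=256.0)
        src = SourceSpec(
            "cortical", Dipole(synth.PARIETAL_LOCATION, (0., 1., 0.)), 16.0,
            carriers=(Carrier((8.0, 15.0), 1.0, gen.mu_erd_db),),
            params={"env_depth": 0.0})
        rec = simulate_recording(make_session_plan("cued"), [src], montage,
                                 headmodel, fs=256.0, seed=2,
                                 sensor_noise_uv=0.0)
        gain = forward_potentials(Dipole(synth.PARIETAL_LOCATION, (0., 16., 0.)),
                                  montage, headmodel)
        best = int(np.argmax(np.abs(gain)))
        cfg = TFConfig.batch()
        onsets = rec.events["onset_s"].to_numpy()
        drops = []
        for on in onsets:
            i0 = int((on - 4.0) * 256)
            epoch = rec.signal[best, i0:i0 + 2048]
            tf = wavelet_tf(epoch, cfg, 256.0)
            times = cfg.times(2048, 256.0)
            mu_bin = int(np.argmin(np.abs(cfg.freqs - 10.0)))
            inside = tf[mu_bin, (times >= 0.4) & (times <= 1.6)].mean()
            outside = tf[mu_bin, (times <= -1.0)].mean()
            drops.append(outside - inside)
        assert np.mean(drops) == pytest.approx(gen.mu_erd_db, abs=1.0)

    def test_power_conservation(self, montage, headmodel):
        """Per-channel variance ≈ sum of projected source variances plus
        sensor noise, pooled over several sessions of independent sources."""
        gen = GeneratorConfig(fs=128.0)
        rng = np.random.default_rng(5)
        srcs = default_sources(gen, rng, headmodel)
        plan = make_session_plan("cued")
        prof = render_speed_profile(plan)
        ev = detect_onsets_encoder(prof)["onset_s"].to_numpy()
        obs = np.zeros(64)
        pred = np.zeros(64)
        n_rep = 3
        for seed in range(n_rep):
            rec = simulate_recording(plan, srcs, montage, headmodel, fs=128.0,
                                     seed=seed, sensor_noise_uv=gen.sensor_noise_uv)
            obs += rec.signal.var(axis=1) / n_rep
            t = np.arange(rec.n_samples) / 128.0
            speed = np.interp(t, prof.t, prof.speed)
            wrng = np.random.default_rng(seed)  # same stream as the simulator
            p = np.full(64, gen.sensor_noise_uv ** 2)
            for s in srcs:
                g = forward_potentials(
                    Dipole(s.dipole.location, s.dipole.moment * s.amplitude),
                    montage, headmodel)
                w = synth.render_source_waveform(s, t, 128.0, speed, ev, wrng)
                p += g ** 2 * w.var()
            pred += p / n_rep
        assert np.abs(obs - pred).max() / pred.max() < 0.02


class TestSubject:
    @pytest.fixture(scope="class")
    def subject(self):
        gen = GeneratorConfig(fs=128.0)
        return simulate_subject(gen, seed=11, subject_id="S1")

    def test_session_counts(self, subject):
        assert len(subject) == 10
        conds = [r.condition for r in subject]
        assert conds.count("cued") == 7 and conds.count("uncued") == 3

    def test_uncued_interleaved_after_2_or_3_cued(self, subject):
        conds = [r.condition for r in subject]
        runs, run = [], 0
        for c in conds:
            if c == "cued":
                run += 1
            else:
                runs.append(run)
                run = 0
        assert all(2 <= r <= 3 for r in runs)

    def test_seeded_determinism_and_distinct_noise(self, subject):
        gen = GeneratorConfig(fs=128.0)
        again = simulate_subject(gen, seed=11, subject_id="S1")
        assert np.array_equal(subject[0].signal, again[0].signal)
        other = simulate_subject(gen, seed=12, subject_id="S1")
        # same cued plans (event times equal) but different realisations
        assert np.allclose(subject[0].events["onset_s"],
                           other[0].events["onset_s"])
        assert not np.allclose(subject[0].signal, other[0].signal)

    def test_bdf_round_trip_bit_compatible(self, subject, tmp_path, montage):
        rec = subject[0]
        path = tmp_path / "s.bdf"
        write_bdf(rec, path)
        back = read_bdf(path, montage)
        n = rec.n_samples
        lim = max(np.abs(rec.signal).max(), 1e-6)
        _, expected = quantize_bdf(rec.signal, (-lim, lim))
        assert back.fs == rec.fs
        assert np.allclose(back.signal[:, :n], expected, atol=1e-6 * lim)
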