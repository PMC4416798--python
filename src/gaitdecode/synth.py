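"""Synthetic treadmill-walking EEG experiments.

Generates complete subjects (10 sessions of 380 s; 7 visually cued, 3
self-paced) with the statistical structure the decoding pipeline assumes:

* a treadmill speed profile stepping between 0, 1 and 2 km/h in the block
  order 0-1-2-1-2-1 repeated three times then rest, with 4 s acceleration and
  8 s deceleration ramps;
* speed-change onsets detected the way the real encoder worked — first
  crossing of a ±0.12 m/s relative-speed threshold;
* cortical sources (parietal and, optionally, motor) whose mu (8–15 Hz) and
  beta (16–31 Hz) carriers desynchronise by a configurable depth after each
  onset;
* structured nuisance sources: 1/f background activity, eye blinks, EMG
  bursts, and a step-locked harmonic artifact active only while walking;
* white sensor noise.

Every source is a dipole forward-projected through the 4-shell head model, so
the spatial statistics seen by ICA and dipole fitting are faithful to the
generative model the analysis assumes.  All magnitudes are free parameters of
the generator (the corresponding real-world quantities are unknown); the
defaults live in :class:`GeneratorConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .headmodel import Dipole, HeadModel, Montage, forward_potentials
from .io import Recording

KMH = 1.0 / 3.6  # km/h -> m/s

#: block speed order of one session (km/h): three repetitions then rest
SPEED_ORDER = (0, 1, 2, 1, 2, 1) * 3 + (0,)

#: self-paced plateau statistics (s): mean/SD after acceleration, after deceleration
UNCUED_PLATEAU_ACCEL = (17.4, 5.35)
UNCUED_PLATEAU_DECEL = (12.8, 6.51)
UNCUED_PLATEAU_FLOOR = 6.0

#: stepping fundamental (Hz) at 1 and 2 km/h
STEP_RATE_KMH = {1.0: 0.75, 2.0: 0.95}


@dataclass(frozen=True)
class SessionPlan:
    condition: str                      # cued | uncued
    block_speeds: tuple[int, ...]       # km/h
    block_durations: tuple[float, ...]  # s, ramp included at block start
    accel_ramp: float = 4.0
    decel_ramp: float = 8.0
    total_duration: float = 380.0

    def __post_init__(self) -> None:
        if self.condition not in ("cued", "uncued"):
            raise ValueError("condition must be cued or uncued")
        if abs(sum(self.block_durations) - self.total_duration) > 1e-6:
            raise ValueError("block durations must sum to the session length")

    @property
    def n_transitions(self) -> int:
        return len(self.block_speeds) - 1


@dataclass(frozen=True)
class Transition:
    t_start: float
    from_kmh: float
    to_kmh: float
    ramp_s: float


@dataclass(frozen=True)
class SpeedProfile:
    t: np.ndarray          # s
    speed: np.ndarray      # belt speed, m/s
    transitions: tuple[Transition, ...]
    fs: float


def make_session_plan(condition: str, seed: int | None = None) -> SessionPlan:
    """Build one session plan.

    Cued sessions are the deterministic 19 × 20 s block design.  Self-paced
    (uncued) sessions keep the speed order but draw plateau durations from
    the goniometer statistics of the original experiment, truncated so the
    session still lasts exactly 380 s.
    """
    if condition == "cued":
        return SessionPlan("cued", SPEED_ORDER, (20.0,) * len(SPEED_ORDER))
    rng = np.random.default_rng(seed)
    total = 380.0
    speeds = [SPEED_ORDER[0]]
    durs = [20.0]
    elapsed = 20.0
    for prev, cur in zip(SPEED_ORDER, SPEED_ORDER[1:]):
        up = cur > prev
        ramp = 4.0 if up else 8.0
        mu, sd = UNCUED_PLATEAU_ACCEL if up else UNCUED_PLATEAU_DECEL
        plateau = max(float(rng.normal(mu, sd)), UNCUED_PLATEAU_FLOOR)
        dur = ramp + plateau
        speeds.append(cur)
        if elapsed + dur >= total:
            durs.append(total - elapsed)
            elapsed = total
            break
        durs.append(dur)
        elapsed += dur
    if elapsed < total:
        durs[-1] += total - elapsed
    return SessionPlan("uncued", tuple(speeds), tuple(durs))


def render_speed_profile(plan: SessionPlan, fs: float = 64.0) -> SpeedProfile:
    """Piecewise-linear belt speed over the session, plus the ramp events."""
    n = int(round(plan.total_duration * fs)) + 1
    t = np.arange(n) / fs
    speed = np.full(n, plan.block_speeds[0] * KMH)
    transitions = []
    t_block = np.cumsum((0.0,) + plan.block_durations)
    for k in range(1, len(plan.block_speeds)):
        frm, to = plan.block_speeds[k - 1], plan.block_speeds[k]
        if to == frm:
            continue
        ramp = plan.accel_ramp if to > frm else plan.decel_ramp
        t0 = t_block[k]
        transitions.append(Transition(t0, float(frm), float(to), ramp))
        seg = (t >= t0) & (t < t0 + ramp)
        speed[seg] = (frm + (to - frm) * (t[seg] - t0) / ramp) * KMH
        speed[t >= t0 + ramp] = to * KMH
    return SpeedProfile(t=t, speed=speed, transitions=tuple(transitions), fs=fs)


def detect_onsets_encoder(profile: SpeedProfile, threshold: float = 0.12,
                          lag: float = 0.0, noise_sd: float = 0.0,
                          seed: int | None = None) -> pd.DataFrame:
    """Emulated encoder onset detection.

    The relative speed (subject minus belt plateau) during each ramp is
    scanned for the first crossing of ±``threshold`` m/s; with a noiseless
    linear ramp the crossing time is found exactly by linear interpolation.
    One event per transition.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for tr in profile.transitions:
        sel = (profile.t >= tr.t_start) & (profile.t <= tr.t_start + tr.ramp_s + 1.0 / profile.fs)
        rel = np.abs(profile.speed[sel] - tr.from_kmh * KMH)
        if noise_sd > 0:
            rel = rel + rng.normal(0.0, noise_sd, rel.size)
        tt = profile.t[sel]
        above = np.nonzero(rel >= threshold)[0]
        if above.size == 0:
            continue
        i = above[0]
        if i > 0 and noise_sd == 0 and rel[i] > rel[i - 1]:
            frac = (threshold - rel[i - 1]) / (rel[i] - rel[i - 1])
            onset = tt[i - 1] + frac / profile.fs
        else:
            onset = tt[i]
        rows.append({"onset_s": onset + lag, "from_kmh": tr.from_kmh,
                     "to_kmh": tr.to_kmh})
    return pd.DataFrame(rows, columns=["onset_s", "from_kmh", "to_kmh"])


# ---------------------------------------------------------------------------
# sources


@dataclass(frozen=True)
class Carrier:
    """One band-limited oscillatory carrier of a cortical source."""
    band: tuple[float, float]   # Hz
    amplitude: float = 1.0      # relative to the source amplitude
    erd_db: float = 0.0         # power drop (dB) inside the ERD window


@dataclass(frozen=True)
class SourceSpec:
    kind: str                     # cortical | background | blink | emg | step
    dipole: Dipole
    amplitude: float              # nA·m, overall scale of the unit-variance waveform
    carriers: tuple[Carrier, ...] = ()
    erd_window: tuple[float, float] = (0.0, 2.0)   # s relative to onset
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for c in self.carriers:
            if c.erd_db < 0:
                raise ValueError("ERD depth must be non-negative (a power drop)")


def _slow_envelope(rng, n: int, fs: float, depth: float = 0.6,
                   cutoff: float = 0.25) -> np.ndarray:
    """Slow positive amplitude envelope (waxing/waning of rhythms)."""
    sos = sps.butter(2, cutoff, btype="lowpass", fs=fs, output="sos")
    z = sps.sosfiltfilt(sos, rng.standard_normal(n))
    z /= max(z.std(), 1e-12)
    return np.clip(1.0 + depth * z, 0.1, None)


def _band_noise(rng, n: int, fs: float, band: tuple[float, float],
                env_depth: float = 0.15, env_cutoff: float = 0.4) -> np.ndarray:
    lo, hi = band
    hi = min(hi, 0.45 * fs)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    if env_depth > 0:
        x *= _slow_envelope(rng, n, fs, depth=env_depth, cutoff=env_cutoff)
    return x / max(x.std(), 1e-12)

def _pink_noise(rng, n: int, fs: float) -> np.ndarray:
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    x = np.fft.irfft(spec * f ** -0.5, n)
    x *= _slow_envelope(rng, n, fs)
    return x / x.std()


def erd_envelope(t: np.ndarray, onsets: np.ndarray, depth_db: float,
                 window: tuple[float, float], transition: float = 0.5) -> np.ndarray:
    """Amplitude gain over time: unity, dipping to −``depth_db``/2 in amplitude
    (−``depth_db`` in power) inside ``window`` after each onset, with raised-
    cosine edges of length ``transition``."""
    g_min = 10.0 ** (-depth_db / 20.0)
    dip = np.zeros_like(t)
    for on in onsets:
        a, b = on + window[0], on + window[1]
        ramp_in = np.clip((t - (a - transition / 2)) / transition, 0.0, 1.0)
        ramp_out = np.clip(((b + transition / 2) - t) / transition, 0.0, 1.0)
        dip = np.maximum(dip, np.minimum(ramp_in, ramp_out))
    return 1.0 - (1.0 - g_min) * dip


def _stepping_rate(speed_ms: np.ndarray) -> np.ndarray:
    """Instantaneous stepping fundamental (Hz) as a function of belt speed."""
    kmh = speed_ms / KMH
    r1, r2 = STEP_RATE_KMH[1.0], STEP_RATE_KMH[2.0]
    rate = r1 + (r2 - r1) * (kmh - 1.0)
    rate = np.clip(rate, 0.6 * r1, 1.2 * r2)
    return np.where(kmh > 0.05, rate, 0.0)


def render_source_waveform(src: SourceSpec, t: np.ndarray, fs: float,
                           speed: np.ndarray, onsets: np.ndarray,
                           rng: np.random.Generator) -> np.ndarray:
    """Unit-scale waveform of one source over the session time grid."""
    n = t.size
    if src.kind == "cortical":
        w = np.zeros(n)
        for c in src.carriers:
            env = erd_envelope(t, onsets, c.erd_db, src.erd_window)
            w += c.amplitude * env * _band_noise(
                rng, n, fs, c.band,
                env_depth=src.params.get("env_depth", 0.15),
                env_cutoff=src.params.get("env_cutoff", 0.4))
        return w
    if src.kind == "background":
        return _pink_noise(rng, n, fs)
    if src.kind == "blink":
        mean_iv = src.params.get("mean_interval", 4.0)
        tau = src.params.get("pulse_tau", 0.07)
        w = np.zeros(n)
        kt = np.arange(0, int(10 * tau * fs)) / fs
        kernel = kt * np.exp(-kt / tau)
        kernel /= kernel.max()
        pos = rng.exponential(mean_iv)
        while pos < t[-1]:
            i = int(pos * fs)
            seg = min(kernel.size, n - i)
            w[i:i + seg] += kernel[:seg]
            pos += max(rng.exponential(mean_iv), 0.5)
        return w / max(w.std(), 1e-12)
    if src.kind == "emg":
        base = src.params.get("rest_level", 0.2)
        burst_rate = src.params.get("burst_rate", 0.25)  # bursts per second while walking
        env = np.full(n, base)
        walking = speed > 0.05
        expected = burst_rate * walking.sum() / fs
        for _ in range(rng.poisson(expected)):
            idx = rng.choice(np.nonzero(walking)[0])
            dur = rng.uniform(0.3, 1.5)
            half = int(dur * fs / 2)
            lo, hi = max(0, idx - half), min(n, idx + half)
            win = np.hanning(hi - lo)
            env[lo:hi] = np.maximum(env[lo:hi], base + win)
        hp = sps.butter(4, 20.0, btype="highpass", fs=fs, output="sos")
        noise = sps.sosfiltfilt(hp, rng.standard_normal(n))
        w = env * noise
        return w / max(w.std(), 1e-12)
    if src.kind == "step":
        n_harm = src.params.get("n_harmonics", 5)
        rate = _stepping_rate(speed)
        phase = 2.0 * np.pi * np.cumsum(rate) / fs
        gate = np.clip(speed / 0.1, 0.0, 1.0)
        w = np.zeros(n)
        for h in range(1, n_harm + 1):
            w += np.cos(h * phase + rng.uniform(0, 2 * np.pi)) / h
        w *= gate
        return w / max(w.std(), 1e-12)
    raise ValueError(f"unknown source kind {src.kind!r}")


# ---------------------------------------------------------------------------
# recording- and subject-level simulation


@dataclass(frozen=True)
class GeneratorConfig:
    """Free parameters of the generator.

    Amplitudes are in nA·m (the waveforms have unit variance); sensor noise
    is the white-noise SD per channel in µV.  The defaults implant a −3 dB mu
    and −1.5 dB beta desynchronisation in a parietal source over 0–2 s after
    each speed-change onset, with a weaker (−1 dB) motor source present in a
    configurable subset of subjects.
    """
    fs: float = 2048.0
    profile_fs: float = 64.0
    n_sessions: int = 10
    n_cued: int = 7
    sensor_noise_uv: float = 1.0
    parietal_amp: float = 16.0
    motor_amp: float = 9.0
    background_amp: float = 10.0
    n_background: int = 5
    blink_amp: float = 50.0
    emg_amp: float = 12.0
    step_amp: float = 10.0
    mu_erd_db: float = 3.0
    beta_erd_db: float = 1.5
    motor_erd_db: float = 1.0
    include_motor: bool = True
    onset_threshold: float = 0.12   # m/s

    def with_(self, **kw) -> "GeneratorConfig":
        return replace(self, **kw)


#: parietal ERD source location, mm head frame (posterior midline-left, 55 mm radius)
PARIETAL_LOCATION = (-34.5, 7.7, 42.1)
#: motor ERD source location, mm head frame
MOTOR_LOCATION = (-25.0, -24.0, 46.0)


def default_sources(config: GeneratorConfig, rng: np.random.Generator,
                    model: HeadModel) -> list[SourceSpec]:
    """The default source population of one synthetic subject."""
    sources = [SourceSpec(
        kind="cortical",
        dipole=Dipole(PARIETAL_LOCATION, _random_tangentialish(rng, PARIETAL_LOCATION)),
        amplitude=config.parietal_amp,
        carriers=(Carrier((8.0, 15.0), 1.0, config.mu_erd_db),
                  Carrier((16.0, 31.0), 0.7, config.beta_erd_db)),
    )]
    if config.include_motor:
        sources.append(SourceSpec(
            kind="cortical",
            dipole=Dipole(MOTOR_LOCATION, _random_tangentialish(rng, MOTOR_LOCATION)),
            amplitude=config.motor_amp,
            carriers=(Carrier((8.0, 15.0), 1.0, config.motor_erd_db),
                      Carrier((16.0, 31.0), 0.7, config.motor_erd_db)),
        ))
    for _ in range(config.n_background):
        u = rng.standard_normal(3)
        loc = u / np.linalg.norm(u) * rng.uniform(20.0, 0.75 * model.brain_radius)
        if loc[2] < 5.0:
            loc[2] = 5.0 + abs(loc[2]) * 0.5
        sources.append(SourceSpec("background", Dipole(loc, rng.standard_normal(3)),
                                  config.background_amp))
    sources.append(SourceSpec("blink", Dipole((60.0, 0.0, -10.0), (30.0, 0.0, 20.0)),
                              config.blink_amp))
    for ysign in (+1.0, -1.0):
        sources.append(SourceSpec("emg", Dipole((-50.0, 28.0 * ysign, -18.0),
                                                rng.standard_normal(3)),
                                  config.emg_amp))
    sources.append(SourceSpec("step", Dipole((0.0, 0.0, -30.0), (0.0, 0.0, 30.0)),
                              config.step_amp, params={"n_harmonics": 5}))
    return sources


def _random_tangentialish(rng: np.random.Generator, loc) -> np.ndarray:
    """Random unit moment with a tangential bias, scaled to 1 (relative units)."""
    loc = np.asarray(loc, float)
    r = loc / np.linalg.norm(loc)
    v = rng.standard_normal(3)
    v -= 0.7 * (v @ r) * r
    return v / np.linalg.norm(v)


def simulate_recording(plan: SessionPlan, sources: list[SourceSpec],
                       montage: Montage, model: HeadModel,
                       fs: float = 2048.0, seed: int | None = None,
                       sensor_noise_uv: float = 1.0,
                       onset_threshold: float = 0.12,
                       profile_fs: float = 64.0,
                       condition: str | None = None,
                       session_id: int = 0, subject_id: str = "S0") -> Recording:
    """Render one session: forward-projected sources plus sensor noise."""
    rng = np.random.default_rng(seed)
    profile = render_speed_profile(plan, profile_fs)
    events = detect_onsets_encoder(profile, threshold=onset_threshold)
    n = int(round(plan.total_duration * fs))
    t = np.arange(n) / fs
    speed = np.interp(t, profile.t, profile.speed)
    onsets = events["onset_s"].to_numpy()

    sig = np.zeros((64, n))
    for src in sources:
        if src.amplitude == 0.0:
            continue
        gain = forward_potentials(
            Dipole(src.dipole.location, src.dipole.moment * src.amplitude),
            montage, model)
        w = render_source_waveform(src, t, fs, speed, onsets, rng)
        sig += np.outer(gain, w)
    if sensor_noise_uv > 0:
        sig += rng.normal(0.0, sensor_noise_uv, sig.shape)

    events = events.copy()
    events["onset_sample"] = np.round(events["onset_s"] * fs).astype(int)
    events = events[["onset_s", "onset_sample", "from_kmh", "to_kmh"]]
    prof_df = pd.DataFrame({"time_s": profile.t, "belt_speed_ms": profile.speed})
    return Recording(signal=sig, fs=fs, montage=montage, events=events,
                     condition=condition or plan.condition,
                     session_id=session_id, subject_id=subject_id,
                     profile=prof_df)


def session_conditions(n_sessions: int, n_cued: int,
                       rng: np.random.Generator) -> list[str]:
    """Interleave uncued sessions after every 2–3 cued ones."""
    n_uncued = n_sessions - n_cued
    if n_uncued == 0:
        return ["cued"] * n_cued
    if n_cued < 2 * n_uncued:
        # too few cued sessions for the 2–3 rule; spread them evenly
        groups = np.full(n_uncued, n_cued // n_uncued)
    else:
        while True:
            groups = rng.integers(2, 4, size=n_uncued)  # cued before each uncued
            if groups.sum() <= n_cued:
                break
    order = []
    for g in groups:
        order += ["cued"] * int(g) + ["uncued"]
    order += ["cued"] * (n_cued - int(groups.sum()))
    return order


def simulate_subject(config: GeneratorConfig, seed: int,
                     montage: Montage | None = None,
                     model: HeadModel | None = None,
                     subject_id: str = "S0") -> list[Recording]:
    """Simulate all sessions of one subject, deterministically from ``seed``."""
    montage = montage or Montage.default()
    model = model or HeadModel()
    ss = np.random.SeedSequence(seed)
    subj_rng = np.random.default_rng(ss.spawn(1)[0])
    sources = default_sources(config, subj_rng, model)
    conditions = session_conditions(config.n_sessions, config.n_cued, subj_rng)
    session_seeds = ss.spawn(config.n_sessions)
    recordings = []
    for k, (cond, sseed) in enumerate(zip(conditions, session_seeds)):
        plan_seed = int(sseed.generate_state(1)[0] % (2 ** 31))
        plan = make_session_plan(cond, seed=plan_seed if cond == "uncued" else None)
        rec = simulate_recording(
            plan, sources, montage, model, fs=config.fs, seed=sseed,
            sensor_noise_uv=config.sensor_noise_uv,
            onset_threshold=config.onset_threshold,
            profile_fs=config.profile_fs,
            session_id=k, subject_id=subject_id)
        recordings.append(rec)
    return recordings
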