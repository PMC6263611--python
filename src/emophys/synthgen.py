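"""Synthetic multichannel physiological recordings with ground truth.

Generates labelled 4-channel (ECG, GSR, EMG, PPG) recordings at 200 Hz whose
statistical structure mimics an affective-computing acquisition: four emotion
classes (pleasure, fear, sadness, anger) that differ in heart rate, heart-rate
variability, skin-conductance-response rate and facial-EMG burst activity.
Every record carries ground-truth fiducial times (ECG R waves, PPG pulse
peaks) so downstream detectors can be scored exactly.

The waveform models are deliberately simple and fully parameterised:

* ECG — one PQRST template per beat, built from five Gaussian bumps at fixed
  offsets relative to the R time, placed at RR intervals drawn from a
  truncated normal; plus sinusoidal baseline drift and white noise.
* PPG — one asymmetric pulse per beat, delayed from the R time by the pulse
  transit time.
* GSR — a tonic conductance level plus Poisson-placed skin-conductance
  responses (fast rise, slow decay) and noise.
* EMG — white noise amplitude-modulated by Poisson-placed burst envelopes.

All generators are deterministic given their seed (one root seed per dataset,
per-channel substreams derived from it).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

EMOTIONS = ("pleasure", "fear", "sadness", "anger")

# PQRST template: per-wave (offset s, amplitude, width s) relative to R.
# Offsets/amplitudes chosen so all five characteristic waves exist and are
# locatable by the detector windows (P before Q, T well after S).
ECG_TEMPLATE = {
    "P": (-0.20, 0.15, 0.025),
    "Q": (-0.04, -0.10, 0.010),
    "R": (0.00, 1.00, 0.012),
    "S": (0.04, -0.20, 0.010),
    "T": (0.25, 0.30, 0.045),
}


@dataclass(frozen=True)
class EmotionRegime:
    """Class-conditional signal statistics for one emotion.

    Rates are per minute; ``hr_mean``/``hr_sd`` are in beats/min, where
    ``hr_sd`` describes between-beat variability (mapped internally onto the
    standard deviation of the RR interval).
    """

    emotion: str
    hr_mean: float
    hr_sd: float
    scr_rate: float
    gsr_tonic: float
    emg_burst_rate: float
    emg_gain: float
    ppg_amp_mean: float = 1.0
    ppg_amp_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.emotion not in EMOTIONS:
            raise ValueError(f"unknown emotion {self.emotion!r}; expected one of {EMOTIONS}")
        if not 30.0 < self.hr_mean < 200.0:
            raise ValueError("hr_mean must lie in (30, 200) bpm")
        for name in ("hr_sd", "scr_rate", "gsr_tonic", "emg_burst_rate", "ppg_amp_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


#: Default per-emotion regimes. Chosen so the four classes separate mainly
#: through heart rate / HRV, SCR rate and EMG burst activity.
DEFAULT_REGIMES: dict[str, EmotionRegime] = {
    "pleasure": EmotionRegime("pleasure", hr_mean=70.0, hr_sd=4.0, scr_rate=4.0,
                              gsr_tonic=8.0, emg_burst_rate=4.0, emg_gain=1.5),
    "fear": EmotionRegime("fear", hr_mean=95.0, hr_sd=8.0, scr_rate=10.0,
                          gsr_tonic=12.0, emg_burst_rate=10.0, emg_gain=3.0),
    "sadness": EmotionRegime("sadness", hr_mean=60.0, hr_sd=2.0, scr_rate=2.0,
                             gsr_tonic=6.0, emg_burst_rate=2.0, emg_gain=1.0),
    "anger": EmotionRegime("anger", hr_mean=85.0, hr_sd=6.0, scr_rate=7.0,
                           gsr_tonic=10.0, emg_burst_rate=8.0, emg_gain=2.5),
}


@dataclass
class SignalRecord:
    """A multichannel sampled recording with labels and ground truth.

    ``channels`` maps channel name (ecg, gsr, emg, ppg) to an equal-length
    sample array; ``label_intervals`` is a list of ``(start_s, end_s,
    emotion)``; ``truth`` optionally maps channel name to ground-truth
    fiducial times in seconds (R times for ecg, pulse-peak times for ppg).
    """

    fs: float
    channels: dict[str, np.ndarray]
    label_intervals: list[tuple[float, float, str]] = field(default_factory=list)
    truth: dict[str, np.ndarray] = field(default_factory=dict)
    seed: int = 0
    record_id: str = "rec0"

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise ValueError("all channels must have the same length")
        dur = self.duration_s
        for start, end, emo in self.label_intervals:
            if not (0 <= start < end <= dur + 1e-9):
                raise ValueError(f"label interval ({start}, {end}) outside record duration {dur}")
            if emo not in EMOTIONS:
                raise ValueError(f"unknown emotion label {emo!r}")
        for ch, times in self.truth.items():
            t = np.asarray(times, dtype=float)
            if t.size and (t.min() < 0 or t.max() > dur + 1e-9):
                raise ValueError(f"truth times for {ch!r} outside record duration")
            if t.size > 1 and not np.all(np.diff(t) > 0):
                raise ValueError(f"truth times for {ch!r} must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


def _check_duration(duration_s: float, fs: float) -> int:
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if fs <= 0:
        raise ValueError("fs must be positive")
    return int(round(duration_s * fs))


def _rr_sd_from_hr_sd(hr_mean: float, hr_sd: float) -> float:
    # delta method: RR = 60/HR, so sd(RR) ~ 60 * sd(HR) / HR^2
    return 60.0 * hr_sd / hr_mean**2


def _draw_beat_times(duration_s: float, hr_mean: float, hr_sd: float,
                     rng: np.random.Generator) -> np.ndarray:
    rr_mean = 60.0 / hr_mean
    rr_sd = _rr_sd_from_hr_sd(hr_mean, hr_sd)
    times = []
    t = rr_mean * float(rng.uniform(0.4, 0.9))  # random phase of first beat
    while t < duration_s - 0.35:  # keep the T wave inside the record
        times.append(t)
        t += max(0.3, float(rng.normal(rr_mean, rr_sd)))
    return np.asarray(times)


def generate_ecg(duration_s: float, fs: float, regime: EmotionRegime,
                 drift_amp: float = 0.1, drift_freq_hz: float = 0.15,
                 noise_sd: float = 0.02, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Synthesise an ECG trace; returns ``(waveform, r_times)``.

    The waveform is a sum of per-beat PQRST templates at RR intervals of
    ``max(0.3 s, N(60/hr_mean, sd))``, plus sinusoidal baseline wander of
    amplitude ``drift_amp`` at ``drift_freq_hz`` and white noise.
    """
    n = _check_duration(duration_s, fs)
    if drift_freq_hz >= 0.5:
        raise ValueError("drift_freq_hz must be below 0.5 Hz (baseline wander band)")
    rng = np.random.default_rng(seed)
    r_times = _draw_beat_times(duration_s, regime.hr_mean, regime.hr_sd, rng)
    t = np.arange(n) / fs
    x = np.zeros(n)
    for rt in r_times:
        for offset, amp, width in ECG_TEMPLATE.values():
            x += amp * np.exp(-0.5 * ((t - rt - offset) / width) ** 2)
    x += drift_amp * np.sin(2 * np.pi * drift_freq_hz * t + float(rng.uniform(0, 2 * np.pi)))
    if noise_sd > 0:
        x += rng.normal(0.0, noise_sd, n)
    return x, r_times


def generate_ppg(duration_s: float, fs: float, regime: EmotionRegime,
                 r_times: np.ndarray, delay_s: float = 0.25,
                 noise_sd: float = 0.01, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Synthesise a PPG trace with one pulse per beat at ``r_times + delay_s``."""
    n = _check_duration(duration_s, fs)
    if delay_s < 0:
        raise ValueError("delay_s must be non-negative")
    r_times = np.asarray(r_times, dtype=float)
    if r_times.size and (r_times.min() < 0 or r_times.max() > duration_s):
        raise ValueError("r_times outside record duration")
    rng = np.random.default_rng(seed)
    pulse_times = r_times + delay_s
    pulse_times = pulse_times[pulse_times < duration_s - 0.1]
    t = np.arange(n) / fs
    x = np.zeros(n)
    amps = regime.ppg_amp_mean + regime.ppg_amp_sd * rng.standard_normal(pulse_times.size)
    for pt, amp in zip(pulse_times, amps):
        dt = t - pt
        # asymmetric pulse peaking exactly at pt: steep systolic upstroke
        # (sigma 30 ms), slower diastolic decay (sigma 100 ms)
        x += amp * np.where(dt < 0, np.exp(-0.5 * (dt / 0.03) ** 2),
                            np.exp(-0.5 * (dt / 0.10) ** 2))
    if noise_sd > 0:
        x += rng.normal(0.0, noise_sd, n)
    return x, pulse_times


def generate_gsr(duration_s: float, fs: float, regime: EmotionRegime,
                 noise_sd: float = 0.02, seed: int = 0) -> np.ndarray:
    """Synthesise skin conductance: tonic level plus Poisson SCR events.

    Each skin-conductance response is a bump with ~1 s rise and ~4 s decay.
    """
    n = _check_duration(duration_s, fs)
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    x = np.full(n, float(regime.gsr_tonic))
    n_events = rng.poisson(regime.scr_rate * duration_s / 60.0)
    event_times = np.sort(rng.uniform(0.0, duration_s, n_events))
    for et in event_times:
        dt = t - et
        scr = np.where(dt >= 0, (np.exp(-dt / 4.0) - np.exp(-dt / 1.0)), 0.0)
        x += 0.8 * scr / 0.47  # normalise bump peak to ~0.8 conductance units
    if noise_sd > 0:
        x += rng.normal(0.0, noise_sd, n)
    return x


def generate_emg(duration_s: float, fs: float, regime: EmotionRegime,
                 seed: int = 0) -> np.ndarray:
    """Synthesise facial EMG: noise carrier modulated by Poisson burst envelopes."""
    n = _check_duration(duration_s, fs)
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    envelope = np.ones(n)
    n_bursts = rng.poisson(regime.emg_burst_rate * duration_s / 60.0)
    burst_times = rng.uniform(0.0, duration_s, n_bursts)
    for bt in burst_times:
        width = float(rng.uniform(0.2, 0.6))
        envelope += regime.emg_gain * np.exp(-0.5 * ((t - bt) / width) ** 2)
    carrier = rng.standard_normal(n)
    return 0.05 * envelope * carrier


def _jitter_regime(regime: EmotionRegime, rng: np.random.Generator,
                   hr_jitter: float = 2.0, rate_jitter: float = 0.15) -> EmotionRegime:
    """Per-participant random perturbation of a class regime."""
    return replace(
        regime,
        hr_mean=float(np.clip(regime.hr_mean + rng.normal(0, hr_jitter), 35, 195)),
        hr_sd=max(0.0, regime.hr_sd * float(rng.uniform(1 - rate_jitter, 1 + rate_jitter))),
        scr_rate=regime.scr_rate * float(rng.uniform(1 - rate_jitter, 1 + rate_jitter)),
        gsr_tonic=regime.gsr_tonic * float(rng.uniform(1 - rate_jitter, 1 + rate_jitter)),
        emg_burst_rate=regime.emg_burst_rate * float(rng.uniform(1 - rate_jitter, 1 + rate_jitter)),
        emg_gain=regime.emg_gain * float(rng.uniform(1 - rate_jitter, 1 + rate_jitter)),
    )


def generate_record(duration_per_emotion_s: float, fs: float,
                    regimes: dict[str, EmotionRegime], seed: int,
                    record_id: str = "rec0", drift_amp: float = 0.1,
                    noise_sd: float = 0.02, emg_into_ecg_gain: float = 0.05,
                    ppg_delay_s: float = 0.25) -> SignalRecord:
    """One participant record: a contiguous labelled interval per emotion.

    ``emg_into_ecg_gain`` adds a scaled copy of the EMG channel into the ECG
    channel as cross-channel interference (exercises the LMS canceller).
    """
    ss = np.random.SeedSequence(seed)
    sub = ss.spawn(len(EMOTIONS) * 4)
    ecg_parts, gsr_parts, emg_parts, ppg_parts = [], [], [], []
    r_all, p_all, intervals = [], [], []
    offset = 0.0
    for i, emo in enumerate(EMOTIONS):
        reg = regimes[emo]
        s_ecg, s_gsr, s_emg, s_ppg = (int(s.generate_state(1)[0] % (2**31))
                                      for s in sub[4 * i:4 * i + 4])
        ecg, r_times = generate_ecg(duration_per_emotion_s, fs, reg,
                                    drift_amp=drift_amp, noise_sd=noise_sd, seed=s_ecg)
        ppg, p_times = generate_ppg(duration_per_emotion_s, fs, reg, r_times,
                                    delay_s=ppg_delay_s, noise_sd=noise_sd / 2, seed=s_ppg)
        gsr = generate_gsr(duration_per_emotion_s, fs, reg, noise_sd=noise_sd, seed=s_gsr)
        emg = generate_emg(duration_per_emotion_s, fs, reg, seed=s_emg)
        ecg = ecg + emg_into_ecg_gain * emg
        ecg_parts.append(ecg)
        gsr_parts.append(gsr)
        emg_parts.append(emg)
        ppg_parts.append(ppg)
        r_all.append(r_times + offset)
        p_all.append(p_times + offset)
        intervals.append((offset, offset + duration_per_emotion_s, emo))
        offset += duration_per_emotion_s
    return SignalRecord(
        fs=fs,
        channels={
            "ecg": np.concatenate(ecg_parts),
            "gsr": np.concatenate(gsr_parts),
            "emg": np.concatenate(emg_parts),
            "ppg": np.concatenate(ppg_parts),
        },
        label_intervals=intervals,
        truth={"ecg": np.concatenate(r_all), "ppg": np.concatenate(p_all)},
        seed=seed,
        record_id=record_id,
    )


def generate_dataset(n_participants: int, segments_per_emotion: int,
                     regimes: dict[str, EmotionRegime] | None = None,
                     fs: float = 200.0, seed: int = 0,
                     segment_length_s: float = 20.0,
                     drift_amp: float = 0.1, noise_sd: float = 0.02,
                     emg_into_ecg_gain: float = 0.05) -> list[SignalRecord]:
    """Generate one record per participant with per-participant regime jitter.

    Each record holds ``segments_per_emotion × segment_length_s`` of signal
    per emotion, so segmentation at ``segment_length_s`` yields
    ``n_participants × 4 × segments_per_emotion`` labelled segments.
    """
    if n_participants < 1 or segments_per_emotion < 1:
        raise ValueError("n_participants and segments_per_emotion must be >= 1")
    regimes = dict(regimes or DEFAULT_REGIMES)
    root = np.random.SeedSequence(seed)
    records = []
    for p, ss in enumerate(root.spawn(n_participants)):
        jit_seed, rec_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
        rng = np.random.default_rng(jit_seed)
        part_regimes = {emo: _jitter_regime(reg, rng) for emo, reg in regimes.items()}
        records.append(generate_record(
            segments_per_emotion * segment_length_s, fs, part_regimes,
            seed=rec_seed, record_id=f"p{p:02d}", drift_amp=drift_amp,
            noise_sd=noise_sd, emg_into_ecg_gain=emg_into_ecg_gain,
        ))
    return records
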