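"""Synthetic paired EEG-fNIRS recordings with benchmark-like structure.

One simulated subject mimics the session/trial layout of the public hybrid
BCI recordings (3 sessions, 20 balanced binary trials per session, 1 min of
rest before and after the trial block) together with the class-dependent
signal physics each modality contributes:

* **EEG** — 1/f background noise plus an 8-12 Hz rhythm carried by lateral
  channels.  During the task the rhythm is attenuated on one hemisphere
  (event-related desynchronization): class 0 attenuates the left channels,
  class 1 the right, with depth ``eeg_effect_size``.  Ocular activity leaks
  into frontal channels from two simulated EOG references.
* **fNIRS** — a canonical double-gamma hemodynamic response (impulse peak
  ~5 s, undershoot ~15 s) convolved with an adaptation-weighted neural drive
  (3 s plateau then exponential decay, mirroring the EEG desynchronization
  envelope).  The noise-free HbO response peaks ~7.7 s after onset —
  the delayed response the 11-segment pairing downstream exploits.  HbR is
  -1/3 of HbO.  Noise: 0.1 Hz Mayer wave, slow drift, and in-band
  low-frequency physiological fluctuation.

Both modalities are generated directly at the post-downsampling rates
(200 Hz EEG, 10 Hz fNIRS); ``raw_rates=True`` generates at the acquisition
rates (1000 / 12.5 Hz) for exercising the downsampling step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal
from scipy.stats import gamma as _gamma_dist

from .montage import MontageSpec, make_montage

#: plateau (s) and decay constant (s) of the neural drive shared by the EEG
#: desynchronization envelope and the hemodynamic drive.
NEURAL_PLATEAU_S = 3.0
NEURAL_TAU_S = 2.0
TASK_DURATION_S = 10.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and signal-physics knobs for one simulated subject."""

    n_sessions: int = 3
    trials_per_session: int = 20
    eeg_fs: float = 200.0
    fnirs_fs: float = 10.0
    trial_span: tuple[float, float] = (-5.0, 25.0)
    #: relative attenuation of 8-12 Hz amplitude on the affected hemisphere
    eeg_effect_size: float = 0.7
    #: peak task-related change in HbO, micromolar
    fnirs_effect_size: float = 1.0
    #: RMS of the 1/f EEG background, microvolt
    eeg_noise_uv: float = 3.5
    #: RMS of the 8-12 Hz rhythm at the most lateral channels, microvolt
    alpha_amplitude_uv: float = 5.0
    eog_amplitude_uv: float = 40.0
    eog_leak: float = 0.15
    #: RMS of in-band (0.01-0.1 Hz) physiological fNIRS noise, micromolar
    fnirs_noise_um: float = 0.75
    mayer_amplitude_um: float = 0.4
    drift_amplitude_um: float = 0.4
    rest_period_s: float = 60.0
    inter_trial_interval_s: float = 35.0
    raw_rates: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.eeg_fs <= 0 or self.fnirs_fs <= 0:
            raise ValueError("sampling rates must be positive")
        lo, hi = self.trial_span
        if lo > -5.0 or hi < 20.0:
            raise ValueError(
                "trial_span must cover at least [-5, 20] s (baseline window and "
                f"hemodynamic pairing), got {self.trial_span}"
            )
        if self.eeg_effect_size < 0 or self.fnirs_effect_size < 0:
            raise ValueError("effect sizes must be nonnegative")
        if self.inter_trial_interval_s < hi - lo:
            raise ValueError("onset spacing must be at least the trial span width")


@dataclass
class SimulatedStudy:
    """One subject's simulated recordings plus the trial table."""

    montage: MontageSpec
    eeg: list[np.ndarray]          # per session: (n_eeg, T_eeg) microvolt
    eog: list[np.ndarray]          # per session: (2, T_eeg)
    fnirs: list[np.ndarray]        # per session: (n_fnirs, T_fnirs, 2) micromolar
    trials: pd.DataFrame           # columns: session, onset, label
    eeg_fs: float
    fnirs_fs: float
    config: SimulationConfig = field(default=None)


def neural_drive(t: np.ndarray) -> np.ndarray:
    """Adaptation-weighted task drive: plateau then exponential decay, 0-10 s."""
    r = np.where(t <= NEURAL_PLATEAU_S, 1.0, np.exp(-(t - NEURAL_PLATEAU_S) / NEURAL_TAU_S))
    return np.where((t >= 0) & (t <= TASK_DURATION_S), r, 0.0)


def hrf_double_gamma(t: np.ndarray) -> np.ndarray:
    """Canonical double-gamma hemodynamic impulse response (shapes 6/16, ratio 1/6)."""
    t = np.asarray(t, dtype=float)
    h = _gamma_dist.pdf(t, 6.0, scale=1.0) - _gamma_dist.pdf(t, 16.0, scale=1.0) / 6.0
    return np.where(t >= 0, h, 0.0)


def hemodynamic_response(t: np.ndarray, dt: float = 0.05) -> np.ndarray:
    """Noise-free HbO response to one trial, normalized to unit peak.

    Evaluated by convolving the double-gamma kernel with the neural drive on a
    fine grid and interpolating to ``t`` (seconds after trial onset).
    """
    grid = np.arange(0.0, 40.0, dt)
    resp = np.convolve(neural_drive(grid), hrf_double_gamma(grid))[: grid.size] * dt
    resp /= resp.max()
    return np.interp(t, grid, resp, left=0.0, right=0.0)


def _one_over_f_noise(rng: np.random.Generator, n_ch: int, n: int, fs: float, rms: float) -> np.ndarray:
    """Spectrally shaped white noise with a 1/f power spectrum."""
    white = rng.standard_normal((n_ch, n))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.zeros_like(f)
    shaping[1:] = f[1:] ** -0.5
    shaped = np.fft.irfft(spec * shaping, n=n, axis=1)
    shaped *= rms / shaped.std(axis=1, keepdims=True)
    return shaped


def _alpha_carrier(rng: np.random.Generator, n_ch: int, n: int, fs: float) -> np.ndarray:
    """Unit-RMS narrowband 8-12 Hz processes, one per channel."""
    white = rng.standard_normal((n_ch, n))
    sos = signal.butter(4, [8.0, 12.0], btype="bandpass", fs=fs, output="sos")
    carrier = signal.sosfilt(sos, white, axis=1)
    carrier /= carrier.std(axis=1, keepdims=True)
    return carrier


def _lfo_noise(rng: np.random.Generator, n_ch: int, n: int, fs: float, rms: float) -> np.ndarray:
    """Low-frequency physiological noise inside the 0.01-0.1 Hz band.

    Broadband noise would be removed almost entirely by the hemodynamic
    bandpass; what limits real fNIRS decoding is slow vascular fluctuation in
    the same band as the response, so the noise is shaped to live there
    (correlation time of tens of seconds).
    """
    white = rng.standard_normal((n_ch, n))
    sos = signal.butter(2, [0.01, min(0.1, 0.45 * fs)], btype="bandpass", fs=fs,
                        output="sos")
    slow = signal.sosfilt(sos, white, axis=1)
    std = slow.std(axis=1, keepdims=True)
    return slow * (rms / np.where(std > 0, std, 1.0))


def _blink_train(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Sparse blink-like pulses (unit amplitude, ~300 ms wide)."""
    out = np.zeros(n)
    width = max(int(0.3 * fs), 3)
    pulse = np.hanning(width)
    t = 0.0
    while True:
        t += rng.exponential(4.0)
        idx = int(t * fs)
        if idx + width >= n:
            break
        out[idx:idx + width] += pulse * rng.uniform(0.7, 1.3)
    return out


def _balanced_labels(rng: np.random.Generator, n_trials: int) -> np.ndarray:
    labels = np.array([0, 1] * (n_trials // 2) + [0] * (n_trials % 2))
    rng.shuffle(labels)
    return labels


def simulate_subject(config: SimulationConfig, montage: MontageSpec | None = None) -> SimulatedStudy:
    """Generate one subject; bit-identical for a fixed config (incl. seed)."""
    if montage is None:
        montage = make_montage(seed=config.seed)
    rng = np.random.default_rng(config.seed)
    eeg_fs = 1000.0 if config.raw_rates else config.eeg_fs
    fnirs_fs = 12.5 if config.raw_rates else config.fnirs_fs

    session_len = 2 * config.rest_period_s + config.trials_per_session * config.inter_trial_interval_s
    n_eeg_samp = int(round(session_len * eeg_fs))
    n_fnirs_samp = int(round(session_len * fnirs_fs))

    ex = montage.eeg_pos3d[:, 0]
    ey = montage.eeg_pos3d[:, 1]
    alpha_weight = 0.25 + 0.75 * np.abs(ex) / max(np.abs(ex).max(), 1e-12)
    eeg_left = ex < -1e-9
    eeg_right = ex > 1e-9
    frontal_leak = config.eog_leak * np.clip(ey, 0.0, None)

    fx = montage.fnirs_pos3d[:, 0]
    fnirs_gain = 0.25 + 0.75 * np.abs(fx) / max(np.abs(fx).max(), 1e-12)
    fnirs_left = fx < -1e-9
    fnirs_right = fx > 1e-9

    eeg_sessions, eog_sessions, fnirs_sessions = [], [], []
    rows = []
    for sess in range(config.n_sessions):
        labels = _balanced_labels(rng, config.trials_per_session)
        onsets = config.rest_period_s + np.arange(config.trials_per_session) * config.inter_trial_interval_s
        for onset, label in zip(onsets, labels):
            rows.append((sess, float(onset), int(label)))

        t_eeg = np.arange(n_eeg_samp) / eeg_fs
        envelope = np.ones((montage.n_eeg, n_eeg_samp))
        for onset, label in zip(onsets, labels):
            drive = neural_drive(t_eeg - onset)
            side = eeg_left if label == 0 else eeg_right
            envelope[side] *= 1.0 - config.eeg_effect_size * drive[None, :]
        carrier = _alpha_carrier(rng, montage.n_eeg, n_eeg_samp, eeg_fs)
        alpha = config.alpha_amplitude_uv * alpha_weight[:, None] * carrier * envelope
        background = _one_over_f_noise(rng, montage.n_eeg, n_eeg_samp, eeg_fs, config.eeg_noise_uv) \
            if config.eeg_noise_uv > 0 else 0.0
        eog = np.stack([
            config.eog_amplitude_uv * _blink_train(rng, n_eeg_samp, eeg_fs),
            config.eog_amplitude_uv * 0.8 * _blink_train(rng, n_eeg_samp, eeg_fs),
        ])
        eeg = alpha + background + frontal_leak[:, None] * (eog[0] + 0.5 * eog[1])
        eeg_sessions.append(eeg.astype(np.float32))
        eog_sessions.append(eog.astype(np.float32))

        t_f = np.arange(n_fnirs_samp) / fnirs_fs
        hbo = np.zeros((montage.n_fnirs, n_fnirs_samp))
        for onset, label in zip(onsets, labels):
            resp = hemodynamic_response(t_f - onset)
            side = fnirs_left if label == 0 else fnirs_right
            hbo[side] += config.fnirs_effect_size * fnirs_gain[side, None] * resp[None, :]
        hbr = -hbo / 3.0
        if config.mayer_amplitude_um > 0:
            phases = rng.uniform(0, 2 * np.pi, montage.n_fnirs)
            amps = config.mayer_amplitude_um * rng.uniform(0.5, 1.5, montage.n_fnirs)
            mayer = amps[:, None] * np.sin(2 * np.pi * 0.1 * t_f[None, :] + phases[:, None])
            hbo = hbo + mayer
            hbr = hbr + 0.3 * mayer
        if config.drift_amplitude_um > 0:
            dp = rng.uniform(0, 2 * np.pi, (montage.n_fnirs, 2))
            da = config.drift_amplitude_um * rng.uniform(0.5, 1.5, (montage.n_fnirs, 2))
            for k, f0 in enumerate((0.004, 0.009)):
                drift = da[:, k:k + 1] * np.sin(2 * np.pi * f0 * t_f[None, :] + dp[:, k:k + 1])
                hbo = hbo + drift
                hbr = hbr + drift * 0.5
        if config.fnirs_noise_um > 0:
            hbo = hbo + _lfo_noise(rng, montage.n_fnirs, n_fnirs_samp, fnirs_fs,
                                   config.fnirs_noise_um)
            hbr = hbr + _lfo_noise(rng, montage.n_fnirs, n_fnirs_samp, fnirs_fs,
                                   0.5 * config.fnirs_noise_um)
        fnirs_sessions.append(np.stack([hbo, hbr], axis=-1).astype(np.float32))

    trials = pd.DataFrame(rows, columns=["session", "onset", "label"])
    return SimulatedStudy(
        montage=montage,
        eeg=eeg_sessions,
        eog=eog_sessions,
        fnirs=fnirs_sessions,
        trials=trials,
        eeg_fs=eeg_fs,
        fnirs_fs=fnirs_fs,
        config=config,
    )


def null_config(**overrides) -> SimulationConfig:
    """Config with both effect sizes zero (class-independent signals)."""
    cfg = SimulationConfig(eeg_effect_size=0.0, fnirs_effect_size=0.0)
    return replace(cfg, **overrides)
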