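"""Signal conditioning for raw EEG and fNIRS recordings.

EEG: zero-phase Butterworth bandpass (0.5-50 Hz, order 6), common average
reference, then removal of ocular activity.  Ocular removal is implemented as
least-squares regression on the EOG reference channels: it is deterministic
and satisfies the operational contract that the cleaned EEG is uncorrelated
with every EOG reference.  (An ICA backend could be slotted behind the same
interface, but component selection rules would be an extra free choice.)

fNIRS: modified Beer-Lambert law (when raw optical intensities are supplied;
simulated concentrations bypass it), bandpass 0.01-0.1 Hz, then per-trial
baseline correction against the -5..-2 s pre-trial window.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

#: molar extinction coefficients (1/(mM*cm)) at 760 and 850 nm for HbO, HbR,
#: from standard compiled tables; rows = wavelength, columns = (HbO, HbR).
DEFAULT_EXTINCTION = np.array([[1.4866, 3.8437],
                               [2.5264, 1.7986]])
DEFAULT_DPF = 6.0
DEFAULT_DISTANCE_CM = 3.0

EEG_BAND = (0.5, 50.0)
FNIRS_BAND = (0.01, 0.1)
BASELINE_WINDOW = (-5.0, -2.0)


@dataclass(frozen=True)
class RawEEG:
    data: np.ndarray      # (channels, samples), microvolt
    fs: float
    names: tuple[str, ...] = ()
    eog: np.ndarray | None = None


@dataclass(frozen=True)
class RawFNIRS:
    data: np.ndarray      # (channels, samples, 2) HbO/HbR, micromolar
    fs: float

    def __post_init__(self):
        if self.data.shape[-1] != 2:
            raise ValueError("last axis must hold the two chromophores (HbO, HbR)")


def bandpass_zero_phase(x: np.ndarray, fs: float, low: float, high: float,
                        order: int = 6) -> np.ndarray:
    """Forward-backward Butterworth bandpass; shape-preserving, zero phase.

    ``order`` is the order of the designed filter (applied twice).  Edge
    transients are suppressed with reflective padding of 3x the filter order.
    """
    if not 0 < low < high:
        raise ValueError(f"need 0 < low < high, got ({low}, {high})")
    if high >= fs / 2:
        raise ValueError(f"high cutoff {high} Hz must be below Nyquist {fs / 2} Hz")
    if order % 2:
        raise ValueError("filter order must be even")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    padlen = min(3 * order * 2, np.asarray(x).shape[-1] - 1)
    return signal.sosfiltfilt(sos, x, axis=-1, padtype="even", padlen=padlen)


def common_average_reference(eeg: np.ndarray) -> np.ndarray:
    """Subtract the instantaneous across-channel mean from every channel."""
    eeg = np.asarray(eeg)
    if eeg.shape[0] < 2:
        raise ValueError("common average reference needs at least 2 channels")
    return eeg - eeg.mean(axis=0, keepdims=True)


def remove_ocular(eeg: np.ndarray, eog: np.ndarray) -> np.ndarray:
    """Project out the EOG subspace (plus a constant) from every EEG channel.

    The residual of each EEG channel has zero correlation with each EOG
    reference (ordinary least squares with an intercept).
    """
    eeg = np.asarray(eeg, dtype=float)
    eog = np.atleast_2d(np.asarray(eog, dtype=float))
    if eeg.shape[1] != eog.shape[1]:
        raise ValueError("EEG and EOG must have the same number of samples")
    eog_dm = eog - eog.mean(axis=1, keepdims=True)
    coef, *_ = np.linalg.lstsq(eog_dm.T, eeg.T, rcond=None)     # (n_eog, n_ch)
    return eeg - coef.T @ eog_dm


def mbll(intensity: np.ndarray, fs: float, dpf: float = DEFAULT_DPF,
         distance_cm: float = DEFAULT_DISTANCE_CM,
         extinction: np.ndarray = DEFAULT_EXTINCTION,
         i0: np.ndarray | float | None = None) -> np.ndarray:
    """Modified Beer-Lambert law: optical intensities to HbO/HbR changes.

    ``intensity``: (channels, samples, 2 wavelengths), strictly positive;
    the per-channel temporal mean serves as the reference intensity unless an
    explicit ``i0`` is supplied.  Returns
    (channels, samples, 2) concentration changes in micromolar (positions of
    the last axis: HbO, HbR).  Bypass this op when concentrations are
    simulated directly.
    """
    intensity = np.asarray(intensity, dtype=float)
    if np.any(intensity <= 0):
        raise ValueError("optical intensities must be strictly positive")
    extinction = np.asarray(extinction, dtype=float)
    if abs(np.linalg.det(extinction)) < 1e-12:
        raise np.linalg.LinAlgError("extinction matrix is singular")
    if i0 is None:
        i0 = intensity.mean(axis=1, keepdims=True)
    delta_od = -np.log(intensity / i0)                      # (ch, T, wavelength)
    inv = np.linalg.inv(extinction * dpf * distance_cm)     # (chromo x wavelength)^-1
    conc_mm = delta_od @ inv.T                              # mM
    return conc_mm * 1e3                                    # micromolar


def mbll_forward(concentration_um: np.ndarray, fs: float, dpf: float = DEFAULT_DPF,
                 distance_cm: float = DEFAULT_DISTANCE_CM,
                 extinction: np.ndarray = DEFAULT_EXTINCTION,
                 i0: float = 1.0) -> np.ndarray:
    """Forward model (concentrations to intensities); inverse of :func:`mbll`
    up to the temporal-mean referencing, used for round-trip validation."""
    delta_od = (np.asarray(concentration_um) * 1e-3) @ (np.asarray(extinction) * dpf * distance_cm).T
    return i0 * np.exp(-delta_od)


def baseline_correct(trial_signal: np.ndarray, fs: float, span_start: float,
                     window: tuple[float, float] = BASELINE_WINDOW) -> np.ndarray:
    """Subtract the per-channel mean over ``window`` (seconds, trial-relative).

    ``trial_signal`` covers a span starting at ``span_start`` seconds relative
    to the trial onset; time is the last axis.
    """
    x = np.asarray(trial_signal, dtype=float)
    lo, hi = window
    n = x.shape[-1]
    i0 = int(round((lo - span_start) * fs))
    i1 = int(round((hi - span_start) * fs))
    if i0 < 0 or i1 > n or i0 >= i1:
        raise ValueError(f"baseline window {window} falls outside the covered span")
    base = x[..., i0:i1].mean(axis=-1, keepdims=True)
    return x - base


def downsample(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Anti-aliased (polyphase) resampling along the last axis.

    Output length is ``round(n * fs_out / fs_in)``.  Identity when the rates
    match; supports non-integer ratios such as 12.5 -> 10 Hz.
    """
    if fs_out <= 0:
        raise ValueError("output rate must be positive")
    if fs_in < fs_out:
        raise ValueError("downsample cannot increase the sampling rate")
    if fs_in == fs_out:
        return np.asarray(x)
    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    return signal.resample_poly(np.asarray(x, dtype=float), frac.numerator,
                                frac.denominator, axis=-1)


def preprocess_eeg(eeg: np.ndarray, eog: np.ndarray, fs: float,
                   band: tuple[float, float] = EEG_BAND, order: int = 6) -> np.ndarray:
    """Bandpass -> common average reference -> ocular removal."""
    x = bandpass_zero_phase(eeg, fs, *band, order=order)
    x = common_average_reference(x)
    eog_f = bandpass_zero_phase(eog, fs, *band, order=order)
    return remove_ocular(x, eog_f)


def preprocess_fnirs(conc: np.ndarray, fs: float,
                     band: tuple[float, float] = FNIRS_BAND, order: int = 6) -> np.ndarray:
    """Bandpass the HbO/HbR concentration time series (channels, T, 2).

    Baseline correction is applied later, per trial.  When starting from raw
    intensities, apply :func:`mbll` first.
    """
    conc = np.asarray(conc)
    return np.stack([bandpass_zero_phase(conc[..., k], fs, *band, order=order)
                     for k in range(conc.shape[-1])], axis=-1)


def preprocess_study(study) -> "object":
    """Run the full conditioning pipeline on a simulated/loaded study in place
    conventions: returns a new study-like object with conditioned signals."""
    from dataclasses import replace as _replace

    eeg_clean = [preprocess_eeg(e, o, study.eeg_fs) for e, o in zip(study.eeg, study.eog)]
    fnirs_clean = [preprocess_fnirs(f, study.fnirs_fs) for f in study.fnirs]
    return _replace(study, eeg=[e.astype(np.float32) for e in eeg_clean],
                    fnirs=[f.astype(np.float32) for f in fnirs_clean])
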