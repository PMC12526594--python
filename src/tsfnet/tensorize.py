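"""From conditioned signals to paired 3D tensors.

Each trial is cut into 3 s windows sliding at 1 s steps over the instruction
and task period (-2..10 s), giving 10 EEG windows per trial.  Channel values
are projected to a plane with the azimuthal equidistant projection (vertex at
the origin, radial distance = polar angle, azimuth preserved) and rasterized
onto a 16 x 16 grid with piecewise-cubic scattered-data interpolation
(Clough-Tocher on a Delaunay triangulation), zero outside the convex hull of
the sensors.  Because the hemodynamic response lags neural activity, every
EEG window is paired with the time-matched fNIRS window plus the 10
subsequent ones, stacked on a leading segment axis.

Coordinate conventions: grid row 0 is anterior, the time axis starts at the
window onset, and windows are labelled by their right edge in seconds
relative to trial onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
from scipy.interpolate import CloughTocher2DInterpolator
from scipy.spatial import Delaunay, QhullError

from .montage import MontageSpec
from .preprocess import baseline_correct

GRID_SIZE = 16
EEG_WINDOW_SPAN = (-2.0, 10.0)
WINDOW_LENGTH_S = 3.0
WINDOW_STEP_S = 1.0
FNIRS_LOOKAHEAD = 10
#: fNIRS segmentation must extend to 10 s + lookahead * step = 20 s
FNIRS_WINDOW_SPAN = (-2.0, EEG_WINDOW_SPAN[1] + FNIRS_LOOKAHEAD * WINDOW_STEP_S)

MANIFEST = {
    "grid_row0": "anterior",
    "time_axis0": "window start",
    "window_label": "right edge, seconds relative to trial onset",
    "fnirs_last_axis": ("HbO", "HbR"),
}


def segment_windows(trial_signal: np.ndarray, fs: float, start: float, end: float,
                    length: float = WINDOW_LENGTH_S, step: float = WINDOW_STEP_S) -> list[np.ndarray]:
    """Slice sliding windows out of a trial signal covering [start, end] s.

    Windows start at ``start, start+step, ...`` while onset + length <= end;
    each has ``round(length * fs)`` samples along the last axis.
    """
    if start >= end:
        raise ValueError("window span must satisfy start < end")
    if length > end - start:
        raise ValueError("window length exceeds the covered span")
    x = np.asarray(trial_signal)
    n_win = int(round(length * fs))
    windows = []
    onset = start
    while onset + length <= end + 1e-9:
        i0 = int(round((onset - start) * fs))
        if i0 + n_win > x.shape[-1]:
            raise ValueError("trial signal too short for the requested windows")
        windows.append(x[..., i0:i0 + n_win])
        onset += step
    if not windows:
        raise ValueError("window parameters produce an empty window set")
    return windows


def window_onsets(start: float, end: float, length: float = WINDOW_LENGTH_S,
                  step: float = WINDOW_STEP_S) -> np.ndarray:
    onsets = []
    onset = start
    while onset + length <= end + 1e-9:
        onsets.append(onset)
        onset += step
    return np.asarray(onsets)


def project_positions(pos3d: np.ndarray) -> np.ndarray:
    """Azimuthal equidistant projection of unit vectors, vertex at the origin.

    Radial distance in the plane equals the polar angle (great-circle distance
    from the vertex); azimuth is preserved.
    """
    pos = np.asarray(pos3d, dtype=float)
    z = np.clip(pos[:, 2], -1.0, 1.0)
    if np.any(z <= -1.0 + 1e-12):
        raise ValueError("cannot project the antipode of the vertex")
    theta = np.arccos(z)
    rho = np.hypot(pos[:, 0], pos[:, 1])
    scale = np.where(rho > 0, theta / np.where(rho > 0, rho, 1.0), 0.0)
    return np.column_stack([pos[:, 0] * scale, pos[:, 1] * scale])


class GridRasterizer:
    """Scattered-data interpolation of channel values onto a square grid.

    The projection plane is scaled so that the outermost sensor's radius maps
    to a grid radius of (grid_size - 1) / 2 cells, using the full grid extent;
    grid row 0 is anterior (+y).
    """

    def __init__(self, coords2d: np.ndarray, grid_size: int = GRID_SIZE):
        coords2d = np.asarray(coords2d, dtype=float)
        if coords2d.shape[0] < 4:
            raise ValueError("need at least 4 sensors to rasterize")
        try:
            self._tri = Delaunay(coords2d)
        except QhullError as err:
            raise ValueError("sensor positions are collinear; cannot triangulate") from err
        self.coords2d = coords2d
        self.grid_size = grid_size
        r_max = np.linalg.norm(coords2d, axis=1).max()
        half = (grid_size - 1) / 2.0
        cell = r_max / half
        idx = np.arange(grid_size)
        x = (idx - half) * cell               # column -> +x (right)
        y = (half - idx) * cell               # row 0 -> +y (anterior)
        gx, gy = np.meshgrid(x, y, indexing="xy")
        self._cells = np.column_stack([gx.ravel(), gy.ravel()])

    def __call__(self, values: np.ndarray) -> np.ndarray:
        """Interpolate (n_channels, ...) values to (grid, grid, ...)."""
        values = np.asarray(values, dtype=float)
        interp = CloughTocher2DInterpolator(self._tri, values, fill_value=0.0)
        out = interp(self._cells)
        return out.reshape(self.grid_size, self.grid_size, *values.shape[1:])

    def at_points(self, values: np.ndarray, points: np.ndarray) -> np.ndarray:
        interp = CloughTocher2DInterpolator(self._tri, np.asarray(values, dtype=float),
                                            fill_value=0.0)
        return interp(np.asarray(points, dtype=float))


def rasterize_to_grid(channel_values: np.ndarray, coords2d: np.ndarray,
                      grid_size: int = GRID_SIZE) -> np.ndarray:
    """One-shot functional form of :class:`GridRasterizer`."""
    return GridRasterizer(coords2d, grid_size)(channel_values)


def pair_fnirs_segments(fnirs_windows, eeg_window_index: int,
                        lookahead: int = FNIRS_LOOKAHEAD) -> np.ndarray:
    """Stack windows [k, k+1, ..., k+lookahead] on a new leading axis.

    Raises if coverage is insufficient; windows are never silently truncated.
    """
    n = len(fnirs_windows)
    k = eeg_window_index
    if k < 0 or k + lookahead >= n:
        raise ValueError(
            f"need fNIRS windows up to index {k + lookahead}, have {n}; "
            "trial span does not cover the pairing horizon"
        )
    return np.stack([np.asarray(fnirs_windows[k + d]) for d in range(lookahead + 1)], axis=0)


@dataclass(frozen=True)
class EegSample:
    """One 16 x 16 x 600 EEG window (microvolt) with its metadata."""

    tensor: np.ndarray
    trial: int
    window_right_edge: float

    def __post_init__(self):
        if self.tensor.shape != (GRID_SIZE, GRID_SIZE, 600):
            raise ValueError(f"EEG tensor must be 16x16x600, got {self.tensor.shape}")
        if not np.isfinite(self.tensor).all():
            raise ValueError("EEG tensor contains non-finite values")


@dataclass(frozen=True)
class FnirsSample:
    """One 11 x 16 x 16 x 30 x 2 fNIRS segment stack (micromolar)."""

    tensor: np.ndarray

    def __post_init__(self):
        if self.tensor.shape != (FNIRS_LOOKAHEAD + 1, GRID_SIZE, GRID_SIZE, 30, 2):
            raise ValueError(f"fNIRS tensor must be 11x16x16x30x2, got {self.tensor.shape}")


_META_FIELDS = ("labels", "subject", "session", "trial", "trial_row",
                "window_index", "window_right_edge")


@dataclass
class SampleSet:
    """Aligned (EEG tensor, fNIRS tensor, label) samples with metadata.

    Samples are stored window-major to exploit the heavy overlap of the
    sliding segmentation: ``eeg_trials`` holds each trial's rasterized
    -2..10 s grid time course once, ``fnirs_trials`` each trial's 20 distinct
    3-s fNIRS windows once.  Per-sample tensors — the 16 x 16 x 600 EEG
    window and the 11 x 16 x 16 x 30 x 2 fNIRS stack — are materialized on
    demand (``eeg_batch`` / ``fnirs_batch`` / the ``eeg`` / ``fnirs``
    properties), so the stored pairing stays a bijection between EEG windows
    and fNIRS segment stacks of one trial.
    """

    eeg_trials: np.ndarray         # (n_trials, 16, 16, 2400) microvolt
    fnirs_trials: np.ndarray       # (n_trials, 20, 16, 16, 30, 2) micromolar
    labels: np.ndarray
    subject: np.ndarray
    session: np.ndarray
    trial: np.ndarray
    trial_row: np.ndarray          # per-sample index into *_trials
    window_index: np.ndarray
    window_right_edge: np.ndarray
    eeg_step: int = 200            # samples per 1 s window step at 200 Hz
    eeg_window: int = 600          # samples per 3 s window
    manifest: dict = field(default_factory=lambda: dict(MANIFEST))

    def __post_init__(self):
        n = len(self.labels)
        for name in _META_FIELDS:
            if len(getattr(self, name)) != n:
                raise ValueError("metadata arrays must be pairwise aligned")
        if not np.isin(self.labels, [0, 1]).all():
            raise ValueError("labels must be binary")

    def __len__(self) -> int:
        return len(self.labels)

    # -- per-sample materialization -----------------------------------------
    def eeg_batch(self, idx) -> np.ndarray:
        idx = np.asarray(idx)
        out = np.empty((len(idx), GRID_SIZE, GRID_SIZE, self.eeg_window), dtype=np.float32)
        for i, s in enumerate(idx):
            k = int(self.window_index[s]) * self.eeg_step
            out[i] = self.eeg_trials[self.trial_row[s], :, :, k:k + self.eeg_window]
        return out

    def fnirs_batch(self, idx) -> np.ndarray:
        idx = np.asarray(idx)
        rows = self.trial_row[idx]
        segs = self.window_index[idx, None] + np.arange(FNIRS_LOOKAHEAD + 1)[None, :]
        return self.fnirs_trials[rows[:, None], segs]

    def fnirs_unique_windows(self, idx) -> tuple[np.ndarray, np.ndarray]:
        """Distinct fNIRS windows of the batch plus the (B, 11) index map.

        ``windows[seg_map[b, d]]`` is segment ``d`` of sample ``b``; duplicate
        windows across overlapping stacks are stored once.
        """
        idx = np.asarray(idx)
        rows = self.trial_row[idx]
        urows, inv = np.unique(rows, return_inverse=True)
        n_win = self.fnirs_trials.shape[1]
        windows = self.fnirs_trials[urows].reshape(-1, *self.fnirs_trials.shape[2:])
        segs = self.window_index[idx, None] + np.arange(FNIRS_LOOKAHEAD + 1)[None, :]
        seg_map = inv[:, None] * n_win + segs
        return windows, seg_map

    @property
    def eeg(self) -> np.ndarray:
        return self.eeg_batch(np.arange(len(self)))

    @property
    def fnirs(self) -> np.ndarray:
        return self.fnirs_batch(np.arange(len(self)))

    def __getitem__(self, i: int):
        eeg = EegSample(self.eeg_batch([i])[0], int(self.trial[i]),
                        float(self.window_right_edge[i]))
        fnirs = FnirsSample(self.fnirs_batch([i])[0])
        return eeg, fnirs, int(self.labels[i]), int(self.subject[i]), \
            int(self.session[i]), int(self.window_index[i])

    # -- set operations ------------------------------------------------------
    def subset(self, idx) -> "SampleSet":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        rows = self.trial_row[idx]
        urows, inv = np.unique(rows, return_inverse=True)
        meta = {name: getattr(self, name)[idx] for name in _META_FIELDS}
        meta["trial_row"] = inv
        out = SampleSet(self.eeg_trials[urows], self.fnirs_trials[urows],
                        **meta, eeg_step=self.eeg_step, eeg_window=self.eeg_window,
                        manifest=dict(self.manifest))
        bank = getattr(self, "_patch_bank", None)
        if bank is not None:  # precomputed conv patches are shared, not copied
            out._patch_bank = bank
            out._patch_idx = self._patch_idx[idx]
        return out

    @property
    def sessions(self) -> np.ndarray:
        return np.unique(self.session)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        with h5py.File(path, "w") as f:
            f.create_dataset("eeg_trials", data=self.eeg_trials)
            f.create_dataset("fnirs_trials", data=self.fnirs_trials)
            for name in _META_FIELDS:
                f.create_dataset(name, data=getattr(self, name))
            f.attrs["eeg_step"] = self.eeg_step
            f.attrs["eeg_window"] = self.eeg_window
            for key, val in self.manifest.items():
                f.attrs["manifest_" + key] = str(val)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "SampleSet":
        with h5py.File(path, "r") as f:
            arrays = {name: f[name][()] for name in _META_FIELDS}
            out = cls(eeg_trials=f["eeg_trials"][()], fnirs_trials=f["fnirs_trials"][()],
                      **arrays, eeg_step=int(f.attrs["eeg_step"]),
                      eeg_window=int(f.attrs["eeg_window"]),
                      manifest={k.removeprefix("manifest_"): f.attrs[k]
                                for k in f.attrs if k.startswith("manifest_")})
        return out


def build_samples(study, montage: MontageSpec | None = None, subject: int = 0) -> SampleSet:
    """Tensorize a conditioned study into aligned EEG/fNIRS sample pairs.

    Per trial: 10 EEG windows (16 x 16 x 600 at 200 Hz) each paired with an
    11-segment fNIRS stack (11 x 16 x 16 x 30 x 2 at 10 Hz).  fNIRS trials are
    baseline-corrected against the -5..-2 s window before rasterization.
    Ordering is deterministic: (subject, session, trial, window).
    """
    montage = montage or study.montage
    eeg_fs, fnirs_fs = study.eeg_fs, study.fnirs_fs
    ras_eeg = GridRasterizer(project_positions(montage.eeg_pos3d))
    ras_fnirs = GridRasterizer(project_positions(montage.fnirs_pos3d))

    e_lo, e_hi = EEG_WINDOW_SPAN
    f_lo, f_hi = FNIRS_WINDOW_SPAN
    n_win = len(window_onsets(e_lo, e_hi))
    edges = window_onsets(e_lo, e_hi) + WINDOW_LENGTH_S

    eeg_trials, fnirs_trials, meta = [], [], []
    trials = study.trials.sort_values(["session", "onset"]).reset_index(drop=True)
    trial_counter: dict[int, int] = {}
    for _, row in trials.iterrows():
        sess, onset, label = int(row["session"]), float(row["onset"]), int(row["label"])
        t_idx = trial_counter.get(sess, 0)
        trial_counter[sess] = t_idx + 1

        sig_e = study.eeg[sess]
        i0 = int(round((onset + e_lo) * eeg_fs))
        i1 = i0 + int(round((e_hi - e_lo) * eeg_fs))
        if i0 < 0 or i1 > sig_e.shape[-1]:
            raise ValueError(f"trial at {onset}s (session {sess}) exceeds EEG coverage")
        grid_e = ras_eeg(sig_e[:, i0:i1]).astype(np.float32)      # (16,16,2400)

        sig_f = study.fnirs[sess]
        span_lo = -5.0
        j0 = int(round((onset + span_lo) * fnirs_fs))
        j1 = int(round((onset + f_hi) * fnirs_fs))
        if j0 < 0 or j1 > sig_f.shape[1]:
            raise ValueError(f"trial at {onset}s (session {sess}) exceeds fNIRS coverage")
        trial_f = baseline_correct(np.moveaxis(sig_f[:, j0:j1], 2, 1), fnirs_fs, span_lo)
        trial_f = np.moveaxis(trial_f, 1, 2)                      # (ch, T, 2)
        k0 = int(round((f_lo - span_lo) * fnirs_fs))
        grid_f = ras_fnirs(trial_f[:, k0:, :]).astype(np.float32)  # (16,16,Tf,2)
        fnirs_windows = segment_windows(np.moveaxis(grid_f, 3, 0), fnirs_fs, f_lo, f_hi)
        fnirs_windows = [np.moveaxis(w, 0, -1) for w in fnirs_windows]  # (16,16,30,2)
        # the pairing horizon must exist for the last window; fail loudly if not
        pair_fnirs_segments(fnirs_windows, n_win - 1)

        row_id = len(eeg_trials)
        eeg_trials.append(grid_e)
        fnirs_trials.append(np.stack(fnirs_windows))
        for k in range(n_win):
            meta.append((label, subject, sess, t_idx, row_id, k, edges[k]))

    labels, subj, sess_a, trial_a, rows, widx, wedge = map(np.asarray, zip(*meta))
    eeg_step = int(round(WINDOW_STEP_S * eeg_fs))
    return SampleSet(
        eeg_trials=np.stack(eeg_trials), fnirs_trials=np.stack(fnirs_trials),
        labels=labels.astype(np.int64), subject=subj.astype(np.int64),
        session=sess_a.astype(np.int64), trial=trial_a.astype(np.int64),
        trial_row=rows.astype(np.int64), window_index=widx.astype(np.int64),
        window_right_edge=wedge.astype(np.float64),
        eeg_step=eeg_step, eeg_window=int(round(WINDOW_LENGTH_S * eeg_fs)),
    )
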