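"""Sensor geometry for the paired EEG-fNIRS recordings.

Positions live on the unit sphere (head radius 1, +z through the vertex,
+y through the nasion, +x through the right preauricular point).  The layout
is schematic rather than a tabulated standard montage: sensors are placed on
concentric rings of the upper hemisphere with enforced left/right mirror
pairs, which is all the downstream stages need (azimuthal projection,
hemispheric lateralization of simulated effects).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_NORM_TOL = 1e-9


@dataclass(frozen=True)
class MontageSpec:
    """Named sensor positions for one subject.

    ``eeg_pos3d`` and ``fnirs_pos3d`` are (n, 3) unit vectors; fNIRS
    positions are the source-detector channel midpoints projected back to
    the scalp sphere.
    """

    eeg_names: tuple[str, ...]
    eeg_pos3d: np.ndarray
    eog_names: tuple[str, ...]
    fnirs_names: tuple[str, ...]
    fnirs_pos3d: np.ndarray

    def __post_init__(self):
        for pos, names, kind in ((self.eeg_pos3d, self.eeg_names, "EEG"),
                                 (self.fnirs_pos3d, self.fnirs_names, "fNIRS")):
            pos = np.asarray(pos, dtype=float)
            if pos.shape != (len(names), 3):
                raise ValueError(f"{kind} positions must be ({len(names)}, 3), got {pos.shape}")
            norms = np.linalg.norm(pos, axis=1)
            if not np.allclose(norms, 1.0, atol=_NORM_TOL):
                raise ValueError(f"{kind} positions must lie on the unit sphere")
        all_names = list(self.eeg_names) + list(self.eog_names) + list(self.fnirs_names)
        if len(set(all_names)) != len(all_names):
            raise ValueError("channel names must be unique")

    @property
    def n_eeg(self) -> int:
        return len(self.eeg_names)

    @property
    def n_fnirs(self) -> int:
        return len(self.fnirs_names)

    def mirror_pairs(self, kind: str = "eeg", tol: float = 1e-6) -> list[tuple[int, int]]:
        """Index pairs (left, right) of sensors mirrored across the x=0 plane."""
        pos = self.eeg_pos3d if kind == "eeg" else self.fnirs_pos3d
        pairs = []
        for i, p in enumerate(pos):
            if p[0] >= -tol:  # left member has x < 0
                continue
            mirrored = p * np.array([-1.0, 1.0, 1.0])
            d = np.linalg.norm(pos - mirrored, axis=1)
            j = int(np.argmin(d))
            if d[j] < tol:
                pairs.append((i, j))
        return pairs


def _ring_layout(n: int, prefix: str, seed: int, theta_max: float) -> tuple[list[str], np.ndarray]:
    """Vertex sensor plus mirror-symmetric pairs on upper-hemisphere rings.

    Pair azimuths follow a low-discrepancy (golden ratio) sequence jittered
    deterministically by ``seed``; both members of a pair receive the same
    jitter so mirror symmetry is exact.
    """
    rng = np.random.default_rng(seed)
    names = [f"{prefix}z00"]
    pos = [(0.0, 0.0, 1.0)]
    n_rest = n - 1
    n_pairs = n_rest // 2
    n_mid = n_rest - 2 * n_pairs
    golden = (np.sqrt(5.0) - 1.0) / 2.0
    k = 0
    for i in range(n_pairs):
        k += 1
        theta = theta_max * np.sqrt((i + 1) / n_pairs)
        phi = np.pi * ((i * golden) % 1.0) * 0.9 + 0.05 * np.pi
        phi += rng.uniform(-0.02, 0.02)
        x = np.sin(theta) * np.sin(phi)
        y = np.sin(theta) * np.cos(phi)
        z = np.cos(theta)
        names.append(f"{prefix}l{k:02d}")
        pos.append((-x, y, z))
        names.append(f"{prefix}r{k:02d}")
        pos.append((x, y, z))
    for i in range(n_mid):
        theta = 0.5 * theta_max
        names.append(f"{prefix}z{i + 1:02d}")
        pos.append((0.0, np.sin(theta), np.cos(theta)))
    arr = np.asarray(pos, dtype=float)
    arr /= np.linalg.norm(arr, axis=1, keepdims=True)
    return names, arr


def make_montage(n_eeg: int = 30, n_fnirs: int = 36, seed: int = 0) -> MontageSpec:
    """Build a schematic mirror-symmetric montage.

    Parameters default to the 30 EEG / 36 fNIRS channel counts of the
    benchmark recordings.  Deterministic for a fixed seed; every layout
    contains a vertex sensor at (0, 0, 1) and at least one mirror pair.
    """
    if n_eeg < 4 or n_fnirs < 4:
        raise ValueError("need at least 4 EEG and 4 fNIRS channels for a symmetric layout")
    eeg_names, eeg_pos = _ring_layout(n_eeg, "E", seed, theta_max=1.35)
    fnirs_names, fnirs_pos = _ring_layout(n_fnirs, "F", seed + 1, theta_max=1.20)
    return MontageSpec(
        eeg_names=tuple(eeg_names),
        eeg_pos3d=eeg_pos,
        eog_names=("EOGh", "EOGv"),
        fnirs_names=tuple(fnirs_names),
        fnirs_pos3d=fnirs_pos,
    )
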