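"""Self-describing HDF5 container for simulated/processed subjects.

Layout (one file per subject)::

    /eeg/session0..K      (n_eeg, T) float32, microvolt
    /eog/session0..K      (2, T)
    /fnirs/session0..K    (n_fnirs, T, 2) float32, micromolar (HbO, HbR)
    /trials/{session,onset,label}
    /montage/{eeg_names,eeg_pos3d,eog_names,fnirs_names,fnirs_pos3d}

Root attributes carry the sampling rates and, when available, the JSON of the
simulation config.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .montage import MontageSpec
from .simulate import SimulatedStudy, SimulationConfig


def _write_names(group: h5py.Group, key: str, names) -> None:
    group.create_dataset(key, data=np.array(list(names), dtype=h5py.string_dtype()))


def save_study(study: SimulatedStudy, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["eeg_fs"] = study.eeg_fs
        f.attrs["fnirs_fs"] = study.fnirs_fs
        if study.config is not None:
            cfg = dataclasses.asdict(study.config)
            cfg["trial_span"] = list(cfg["trial_span"])
            f.attrs["config_json"] = json.dumps(cfg)
        for kind, sessions in (("eeg", study.eeg), ("eog", study.eog), ("fnirs", study.fnirs)):
            g = f.create_group(kind)
            for k, arr in enumerate(sessions):
                g.create_dataset(f"session{k}", data=np.asarray(arr, dtype=np.float32))
        g = f.create_group("trials")
        g.create_dataset("session", data=study.trials["session"].to_numpy(np.int64))
        g.create_dataset("onset", data=study.trials["onset"].to_numpy(np.float64))
        g.create_dataset("label", data=study.trials["label"].to_numpy(np.int64))
        m = f.create_group("montage")
        _write_names(m, "eeg_names", study.montage.eeg_names)
        _write_names(m, "eog_names", study.montage.eog_names)
        _write_names(m, "fnirs_names", study.montage.fnirs_names)
        m.create_dataset("eeg_pos3d", data=study.montage.eeg_pos3d)
        m.create_dataset("fnirs_pos3d", data=study.montage.fnirs_pos3d)
    return path


def load_study(path: str | Path) -> SimulatedStudy:
    with h5py.File(path, "r") as f:
        montage = MontageSpec(
            eeg_names=tuple(s.decode() if isinstance(s, bytes) else str(s)
                            for s in f["montage/eeg_names"][()]),
            eeg_pos3d=f["montage/eeg_pos3d"][()],
            eog_names=tuple(s.decode() if isinstance(s, bytes) else str(s)
                            for s in f["montage/eog_names"][()]),
            fnirs_names=tuple(s.decode() if isinstance(s, bytes) else str(s)
                              for s in f["montage/fnirs_names"][()]),
            fnirs_pos3d=f["montage/fnirs_pos3d"][()],
        )
        sessions = sorted(f["eeg"], key=lambda s: int(s.removeprefix("session")))
        eeg = [f["eeg"][k][()] for k in sessions]
        eog = [f["eog"][k][()] for k in sessions]
        fnirs = [f["fnirs"][k][()] for k in sessions]
        trials = pd.DataFrame({
            "session": f["trials/session"][()],
            "onset": f["trials/onset"][()],
            "label": f["trials/label"][()],
        })
        config = None
        if "config_json" in f.attrs:
            raw = json.loads(f.attrs["config_json"])
            raw["trial_span"] = tuple(raw["trial_span"])
            config = SimulationConfig(**raw)
        return SimulatedStudy(
            montage=montage, eeg=eeg, eog=eog, fnirs=fnirs, trials=trials,
            eeg_fs=float(f.attrs["eeg_fs"]), fnirs_fs=float(f.attrs["fnirs_fs"]),
            config=config,
        )


def export_trials_csv(study: SimulatedStudy, path: str | Path) -> Path:
    path = Path(path)
    study.trials.to_csv(path, index=False)
    return path
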