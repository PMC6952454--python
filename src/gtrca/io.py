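"""File I/O: the native HDF5 container, optional EDF/FIF/MAT loaders, and
CSV/JSON exports of fitted models.

Native layout (all arrays row-major float64)::

    /condition/{id, f_stim, phase}
    /subjects/<id>/{X, fs, channel_labels, onsets, tau}
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .datasets import ConditionInfo, EpochSet, GroupDataset, SubjectRecording, epoch
from .group import GtrcaModel

__all__ = [
    "save_group",
    "load_group",
    "load_edf",
    "load_fif_epochs",
    "load_ssvep_mat",
    "save_model",
    "load_model_arrays",
    "export_model_csv",
    "write_json_report",
]


def save_group(path: str | Path, group: GroupDataset) -> None:
    """Write a GroupDataset to the native HDF5 container."""
    with h5py.File(path, "w") as f:
        cond = f.create_group("condition")
        cond.create_dataset("id", data=int(group.condition.condition_id))
        cond.create_dataset("f_stim", data=float(group.condition.f_stim))
        cond.create_dataset("phase", data=float(group.condition.phase))
        subs = f.create_group("subjects")
        for i, (rec, _) in enumerate(group.subjects):
            g = subs.create_group(f"{i:04d}_{rec.subject_id}")
            g.create_dataset("X", data=rec.X)
            g.create_dataset("fs", data=float(rec.fs))
            g.create_dataset("onsets", data=rec.onsets)
            g.create_dataset("tau", data=int(rec.tau))
            g.create_dataset(
                "channel_labels",
                data=np.asarray(rec.channel_labels, dtype=h5py.string_dtype()),
            )


def load_group(path: str | Path) -> GroupDataset:
    """Read a GroupDataset back; epochs are re-sliced from the continuous
    data, so a write/read round trip is bit-exact."""
    with h5py.File(path, "r") as f:
        cond = ConditionInfo(
            condition_id=int(f["condition/id"][()]),
            f_stim=float(f["condition/f_stim"][()]),
            phase=float(f["condition/phase"][()]),
        )
        subjects = []
        for key in sorted(f["subjects"]):
            g = f["subjects"][key]
            rec = SubjectRecording(
                subject_id=key.split("_", 1)[1] if "_" in key else key,
                X=g["X"][()],
                fs=float(g["fs"][()]),
                onsets=g["onsets"][()],
                tau=int(g["tau"][()]),
                channel_labels=[s.decode() if isinstance(s, bytes) else str(s)
                                for s in g["channel_labels"][()]],
            )
            subjects.append((rec, epoch(rec)))
    return GroupDataset(subjects=subjects, condition=cond)


def load_edf(path: str | Path, subject_id: str, tau: int,
             annotation: str | None = None) -> SubjectRecording:
    """Load a continuous EDF recording; annotations provide the onsets.

    ``annotation`` selects which annotation description marks a trial onset
    (all annotations when None).  Requires :mod:`mne`.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    onsets = []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        if annotation is None or desc == annotation:
            onsets.append(int(round(onset * raw.info["sfreq"])))
    if not onsets:
        raise ValueError(f"no trial-onset annotations found in {path}")
    return SubjectRecording(
        subject_id=subject_id,
        X=raw.get_data(),
        fs=float(raw.info["sfreq"]),
        onsets=np.asarray(onsets),
        tau=tau,
        channel_labels=list(raw.ch_names),
    )


def load_fif_epochs(path: str | Path) -> EpochSet:
    """Load pre-epoched trials from a FIF epochs file.  Requires :mod:`mne`."""
    import mne

    ep = mne.read_epochs(str(path), preload=True, verbose="error")
    return EpochSet(trials=ep.get_data(copy=True), fs=float(ep.info["sfreq"]))


def load_ssvep_mat(path: str | Path, subject_id: str, fs: float = 250.0,
                   condition: int = 0) -> SubjectRecording:
    """Load one condition from the 35-subject SSVEP benchmark's per-subject
    MAT layout (channels x samples x conditions x blocks).

    The benchmark ships only epoched data; the continuous recording is the
    horizontal concatenation of the trial windows, with onsets at the
    window boundaries.
    """
    from scipy.io import loadmat

    mat = loadmat(str(path))
    arrays = [v for k, v in mat.items() if isinstance(v, np.ndarray) and v.ndim == 4]
    if not arrays:
        raise ValueError(f"no channels x samples x conditions x blocks array in {path}")
    data = arrays[0]
    n, tau, C, K = data.shape
    if not (0 <= condition < C):
        raise ValueError(f"condition {condition} out of range [0, {C})")
    trials = data[:, :, condition, :].transpose(2, 0, 1)  # (K, n, tau)
    X = np.hstack(list(trials))
    return SubjectRecording(
        subject_id=subject_id,
        X=X,
        fs=fs,
        onsets=np.arange(K) * tau,
        tau=tau,
    )


def save_model(path: str | Path, model: GtrcaModel, condition_id: int = 0) -> None:
    """Append a fitted group model to an HDF5 container under
    ``/models/gtrca/<condition>/``."""
    with h5py.File(path, "a") as f:
        key = f"models/gtrca/{int(condition_id):04d}"
        if key in f:
            del f[key]
        g = f.create_group(key)
        g.create_dataset("stacked_w", data=model.stacked_w)
        g.create_dataset("eigenvalues", data=model.eigenvalues)
        g.create_dataset("offsets", data=model.offsets)
        g.create_dataset("group_mean_trc", data=model.group_mean_trc)
        for a, (w, m, y) in enumerate(zip(model.filters, model.maps, model.mean_trcs)):
            sg = g.create_group(f"subject_{a:04d}")
            sg.create_dataset("w", data=w)
            sg.create_dataset("map", data=m)
            sg.create_dataset("mean_trc", data=y)


def load_model_arrays(path: str | Path, condition_id: int = 0) -> dict:
    """Read back the arrays written by :func:`save_model` (the block
    matrices and summaries are recomputable from the data and not stored)."""
    with h5py.File(path, "r") as f:
        g = f[f"models/gtrca/{int(condition_id):04d}"]
        out = {
            "stacked_w": g["stacked_w"][()],
            "eigenvalues": g["eigenvalues"][()],
            "offsets": g["offsets"][()],
            "group_mean_trc": g["group_mean_trc"][()],
            "filters": [], "maps": [], "mean_trcs": [],
        }
        for key in sorted(k for k in g if k.startswith("subject_")):
            out["filters"].append(g[key]["w"][()])
            out["maps"].append(g[key]["map"][()])
            out["mean_trcs"].append(g[key]["mean_trc"][()])
    return out


def _frame_to_csv(path: Path, frame: pd.DataFrame, header_meta: dict) -> None:
    with open(path, "w") as fh:
        for k, v in header_meta.items():
            fh.write(f"# {k}: {v}\n")
        frame.to_csv(fh, index=False)


def export_model_csv(model: GtrcaModel, group: GroupDataset, out_dir: str | Path,
                     meta: dict | None = None) -> dict[str, Path]:
    """Write filters, scalp maps, components and eigenvalues as CSV.

    One column per subject; filter/map rows are channel labels, component
    rows are sample indices.  ``meta`` key/value pairs are embedded as
    comment headers.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = meta or {}
    ids = [rec.subject_id for rec, _ in group.subjects]

    ns = set(group.channel_counts())
    if len(ns) == 1:
        labels = group.subjects[0][0].channel_labels
        filt = pd.DataFrame({"channel": labels})
        maps = pd.DataFrame({"channel": labels})
        for sid, w, m in zip(ids, model.filters, model.maps):
            filt[sid] = w
            maps[sid] = m
    else:  # ragged channel counts: pad with NaN
        nmax = max(ns)
        filt = pd.DataFrame({"channel": [f"ch{i:02d}" for i in range(nmax)]})
        maps = filt.copy()
        for sid, w, m in zip(ids, model.filters, model.maps):
            filt[sid] = np.pad(w, (0, nmax - len(w)), constant_values=np.nan)
            maps[sid] = np.pad(m, (0, nmax - len(m)), constant_values=np.nan)

    trcs = pd.DataFrame({"sample": np.arange(group.tau)})
    for sid, y in zip(ids, model.mean_trcs):
        trcs[sid] = y
    trcs["group_mean"] = model.group_mean_trc
    eig = pd.DataFrame({"rank": np.arange(len(model.eigenvalues)),
                        "eigenvalue": model.eigenvalues})

    paths = {}
    for name, frame in [("filters", filt), ("maps", maps), ("trcs", trcs), ("eigenvalues", eig)]:
        p = out_dir / f"{name}.csv"
        _frame_to_csv(p, frame, meta)
        paths[name] = p
    return paths


def write_json_report(path: str | Path, payload: dict, meta: dict | None = None) -> None:
    """Serialize a result dict (plus provenance metadata) as JSON."""
    out = dict(meta or {})
    out.update(payload)

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(out, indent=2, default=_default, sort_keys=True) + "\n")
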