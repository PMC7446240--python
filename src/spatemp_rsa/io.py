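"""Readers and writers for the pipeline's on-disk formats.

* RDMs — square CSV with a header row and index column of condition
  labels; symmetry is validated on read.
* Epoched channel data — a directory of per-trial delimited-text
  matrices plus a JSON sidecar (labels, sampling rate, time origin), or a
  single HDF5 container.
* Event tables — TSV with ``onset_s``, ``duration_s``, ``condition``.
* Meshes — Wavefront OBJ (vertices/faces).
* RDM timecourses — HDF5 (windows x n x n) with labels and window starts.

All numeric round trips are loss-bounded to about 1e-12 relative.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import trimesh

from .types import RDM, ChannelEpochs, RdmTimecourse, SurfaceMesh

__all__ = [
    "read_rdm",
    "write_rdm",
    "read_epochs",
    "write_epochs",
    "read_events",
    "write_events",
    "read_mesh_obj",
    "write_mesh_obj",
    "read_rdm_timecourse",
    "write_rdm_timecourse",
]

_ASYM_TOL = 1e-9


def write_rdm(rdm: RDM, path: str | Path) -> None:
    """Write an RDM as labeled square CSV (full precision)."""
    df = pd.DataFrame(rdm.values, index=rdm.labels, columns=rdm.labels)
    df.to_csv(path, float_format="%.17g")


def read_rdm(path: str | Path, kind: str = "data_crossnobis") -> RDM:
    """Read a labeled square CSV RDM, validating shape and symmetry."""
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"RDM file {path} is not square: shape {df.shape}")
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError(f"RDM file {path} has mismatched row/column labels")
    values = df.to_numpy(dtype=float)
    asym = np.max(np.abs(values - values.T)) if values.size else 0.0
    if asym > _ASYM_TOL:
        raise ValueError(
            f"RDM file {path} is asymmetric beyond tolerance "
            f"(max |a - a.T| = {asym:.3g})"
        )
    return RDM(values, [str(c) for c in df.columns], kind=kind)


def write_epochs(epochs: ChannelEpochs, path: str | Path, fmt: str = "dir") -> None:
    """Write epochs as a per-trial CSV directory (+ JSON sidecar) or HDF5."""
    path = Path(path)
    if fmt == "dir":
        path.mkdir(parents=True, exist_ok=True)
        for t in range(epochs.n_trials):
            np.savetxt(path / f"trial{t:04d}.csv", epochs.data[t], delimiter=",")
        sidecar = {
            "labels": epochs.labels,
            "fs": epochs.fs,
            "t0_ms": epochs.t0_ms,
            "n_trials": epochs.n_trials,
        }
        (path / "epochs.json").write_text(json.dumps(sidecar, indent=2))
    elif fmt == "h5":
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=epochs.data)
            f.create_dataset(
                "labels", data=np.array(epochs.labels, dtype=h5py.string_dtype())
            )
            f.attrs["fs"] = epochs.fs
            f.attrs["t0_ms"] = epochs.t0_ms
    else:
        raise ValueError(f"unknown epochs format {fmt!r}; expected 'dir' or 'h5'")


def read_epochs(path: str | Path) -> ChannelEpochs:
    """Read epochs written by :func:`write_epochs` (either format)."""
    path = Path(path)
    if path.is_dir():
        sidecar = json.loads((path / "epochs.json").read_text())
        data = np.stack(
            [
                np.loadtxt(path / f"trial{t:04d}.csv", delimiter=",", ndmin=2)
                for t in range(sidecar["n_trials"])
            ]
        )
        return ChannelEpochs(data, sidecar["fs"], sidecar["t0_ms"], sidecar["labels"])
    with h5py.File(path, "r") as f:
        return ChannelEpochs(
            f["data"][()],
            float(f.attrs["fs"]),
            float(f.attrs["t0_ms"]),
            [s.decode() if isinstance(s, bytes) else str(s) for s in f["labels"][()]],
        )


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_events(path: str | Path) -> pd.DataFrame:
    ev = pd.read_csv(path, sep="\t")
    required = {"onset_s", "duration_s", "condition"}
    if not required.issubset(ev.columns):
        raise ValueError(f"event table {path} must have columns {sorted(required)}")
    return ev


def write_mesh_obj(mesh: SurfaceMesh, path: str | Path) -> None:
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    Path(path).write_text(tm.export(file_type="obj"))


def read_mesh_obj(path: str | Path) -> SurfaceMesh:
    tm = trimesh.load(str(path), file_type="obj", process=False)
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))


def write_rdm_timecourse(tc: RdmTimecourse, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("rdms", data=np.stack([r.values for r in tc.rdms]))
        f.create_dataset("window_starts_ms", data=tc.window_starts_ms)
        f.create_dataset(
            "labels", data=np.array(tc.labels, dtype=h5py.string_dtype())
        )
        f.attrs["band"] = tc.band
        f.attrs["width_ms"] = tc.width_ms


def read_rdm_timecourse(path: str | Path) -> RdmTimecourse:
    with h5py.File(path, "r") as f:
        values = f["rdms"][()]
        starts = f["window_starts_ms"][()]
        labels = [
            s.decode() if isinstance(s, bytes) else str(s) for s in f["labels"][()]
        ]
        band = str(f.attrs["band"])
        width = float(f.attrs["width_ms"])
    rdms = [RDM(v, labels, "data_crossnobis") for v in values]
    return RdmTimecourse(starts, rdms, band=band, width_ms=width)
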