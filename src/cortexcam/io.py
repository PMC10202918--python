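"""HDF5 / CSV containers for cohorts, volumes and heatmaps.

Cohort container layout::

    /surface/vertices            (n_vertices, 3)
    /surface/regions             (n_vertices,)
    /subjects/<id>/trials        (n_trials, n_vertices, n_time)
    /subjects/<id>/sensors       optional (n_trials, n_channels, n_time)
        attrs: fs_hz, t_start_ms, t_end_ms, group

Volume container::

    /volumes/values              (N, H, W[, D])
    /volumes/labels              (N,) 0 control / 1 patient
    /volumes/subject_ids, /volumes/trial_ids

Heatmaps go to ``/heatmaps/<method>/<sample_id>`` with model/sample
provenance attributes.  Every file carries the generating seed and config
hash as root attributes when provided.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

import h5py

from .cnn import VolumeDataset
from .synthdata import SourceTrialSet, SurfaceGeometry

__all__ = [
    "save_cohort",
    "load_surface",
    "load_subject_trials",
    "iter_saved_subjects",
    "save_volumes",
    "load_volumes",
    "save_heatmaps",
]


def _set_meta(f: h5py.File, meta: dict | None) -> None:
    for k, v in (meta or {}).items():
        f.attrs[k] = v


def save_cohort(
    path: str,
    surface: SurfaceGeometry,
    cohort: pd.DataFrame,
    trial_sets,
    csv_path: str | None = None,
    meta: dict | None = None,
) -> None:
    """Write surface + per-subject trials (any iterable of SourceTrialSet)
    and the cohort metadata table."""
    with h5py.File(path, "w") as f:
        _set_meta(f, meta)
        g = f.create_group("surface")
        g.create_dataset("vertices", data=surface.vertex_coords)
        g.create_dataset("regions", data=surface.region_labels)
        subs = f.create_group("subjects")
        for ts in trial_sets:
            sg = subs.create_group(ts.subject_id)
            sg.create_dataset("trials", data=ts.data, compression="gzip", shuffle=True)
            sg.attrs["fs_hz"] = ts.fs_hz
            sg.attrs["t_start_ms"] = ts.t_start_ms
            sg.attrs["t_end_ms"] = ts.t_end_ms
            sg.attrs["group"] = ts.group
    if csv_path is not None:
        cohort.to_csv(csv_path, index=False)


def load_surface(path: str) -> SurfaceGeometry:
    with h5py.File(path, "r") as f:
        return SurfaceGeometry(
            vertex_coords=f["surface/vertices"][()],
            region_labels=f["surface/regions"][()],
        )


def load_subject_trials(path: str, subject_id: str) -> SourceTrialSet:
    with h5py.File(path, "r") as f:
        sg = f[f"subjects/{subject_id}"]
        return SourceTrialSet(
            data=sg["trials"][()],
            t_start_ms=float(sg.attrs["t_start_ms"]),
            t_end_ms=float(sg.attrs["t_end_ms"]),
            fs_hz=float(sg.attrs["fs_hz"]),
            subject_id=subject_id,
            group=str(sg.attrs["group"]),
        )


def iter_saved_subjects(path: str):
    """Yield SourceTrialSet per stored subject, one at a time."""
    with h5py.File(path, "r") as f:
        ids = sorted(f["subjects"].keys())
    for sid in ids:
        yield load_subject_trials(path, sid)


def save_volumes(path: str, ds: VolumeDataset, meta: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        _set_meta(f, meta)
        g = f.create_group("volumes")
        g.create_dataset("values", data=ds.X[..., 0], compression="gzip", shuffle=True)
        g.create_dataset("labels", data=ds.y)
        g.create_dataset(
            "subject_ids", data=np.array([s.encode() for s in ds.subject_ids])
        )
        g.create_dataset("trial_ids", data=ds.trial_ids)


def load_volumes(path: str) -> VolumeDataset:
    with h5py.File(path, "r") as f:
        g = f["volumes"]
        return VolumeDataset(
            X=g["values"][()][..., None].astype(np.float32),
            y=g["labels"][()],
            subject_ids=np.array([s.decode() for s in g["subject_ids"][()]], dtype=object),
            trial_ids=g["trial_ids"][()],
        )


def save_heatmaps(path: str, heatmaps: list, meta: dict | None = None) -> None:
    """Append RelevanceVolume objects under /heatmaps/<method>/<sample_id>."""
    with h5py.File(path, "a") as f:
        _set_meta(f, meta)
        root = f.require_group("heatmaps")
        for hm in heatmaps:
            g = root.require_group(hm.method)
            d = g.create_dataset(hm.sample_id, data=hm.values)
            d.attrs["model_id"] = hm.model_id
            d.attrs["sample_id"] = hm.sample_id
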