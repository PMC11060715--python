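"""File I/O: recordings, tidy result tables, and schema validation.

Recordings travel either as an HDF5 container (one file: ROI + neuropil
matrices, centroids, speed, ground-truth attributes) or as delimited
tables (frames x neurons CSV for traces, 3-column centroid table, 1-column
speed table).  All analysis outputs are tidy CSV — one row per
unit-of-observation — so they drop straight into any downstream
statistics environment.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synthetic import GroundTruth, SpeedTrace, SyntheticRecording
from .traces import RoiTraceSet

__all__ = [
    "SchemaError",
    "save_recording_h5",
    "load_recording_h5",
    "save_recording_tables",
    "load_trace_tables",
    "save_ground_truth_json",
    "load_ground_truth_json",
    "raster_to_table",
    "edges_to_table",
    "assemblies_to_tables",
]


class SchemaError(ValueError):
    """An input file does not match the expected schema."""


def save_ground_truth_json(gt: GroundTruth, path: str | Path) -> None:
    d = dataclasses.asdict(gt)
    d["assembly_memberships"] = [sorted(m) for m in gt.assembly_memberships]
    Path(path).write_text(json.dumps(d, indent=2, sort_keys=True))


def load_ground_truth_json(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    d["assembly_memberships"] = tuple(frozenset(m) for m in d["assembly_memberships"])
    d["movement_bouts"] = tuple(tuple(b) for b in d.get("movement_bouts", ()))
    return GroundTruth(**d)


def save_recording_h5(rec: SyntheticRecording, path: str | Path) -> None:
    """Write a synthetic recording (and its ground truth) to one HDF5 file."""
    with h5py.File(path, "w") as f:
        f.create_dataset("roi_fluorescence", data=rec.roi_fluorescence)
        f.create_dataset("neuropil_fluorescence", data=rec.neuropil_fluorescence)
        f.create_dataset("clean_fluorescence", data=rec.clean_fluorescence)
        f.create_dataset("roi_centroids", data=rec.roi_centroids)
        f.create_dataset("speed", data=rec.speed.speed)
        f.create_dataset("moving_true", data=rec.speed.moving_true)
        f.create_dataset("true_spike_raster", data=rec.true_spike_raster)
        for i, frames in enumerate(rec.assembly_event_frames):
            f.create_dataset(f"assembly_event_frames/{i}", data=frames)
        gt = dataclasses.asdict(rec.ground_truth)
        gt["assembly_memberships"] = [sorted(m) for m in rec.ground_truth.assembly_memberships]
        f.attrs["ground_truth_json"] = json.dumps(gt, sort_keys=True)


def load_recording_h5(path: str | Path) -> SyntheticRecording:
    with h5py.File(path, "r") as f:
        gt_d = json.loads(f.attrs["ground_truth_json"])
        gt_d["assembly_memberships"] = tuple(frozenset(m) for m in gt_d["assembly_memberships"])
        gt_d["movement_bouts"] = tuple(tuple(b) for b in gt_d.get("movement_bouts", ()))
        gt = GroundTruth(**gt_d)
        n_assemblies = len(gt.assembly_memberships)
        event_frames = [
            f[f"assembly_event_frames/{i}"][()] for i in range(n_assemblies)
        ]
        return SyntheticRecording(
            roi_fluorescence=f["roi_fluorescence"][()],
            neuropil_fluorescence=f["neuropil_fluorescence"][()],
            clean_fluorescence=f["clean_fluorescence"][()],
            roi_centroids=f["roi_centroids"][()],
            speed=SpeedTrace(
                speed=f["speed"][()],
                moving_true=f["moving_true"][()],
                frame_rate_hz=gt.frame_rate_hz,
                bouts=gt.movement_bouts,
            ),
            true_spike_raster=f["true_spike_raster"][()],
            assembly_event_frames=event_frames,
            ground_truth=gt,
        )


def _check_trace_frame(df: pd.DataFrame, path: Path) -> None:
    if df.shape[1] == 0:
        raise SchemaError(f"{path}: no neuron columns")
    bad = np.flatnonzero(~np.isfinite(df.to_numpy()).all(axis=1))
    if bad.size:
        raise SchemaError(f"{path}: non-finite value at frame index {int(bad[0])}")


def save_recording_tables(rec: SyntheticRecording, out_dir: str | Path) -> None:
    """Delimited-table export: raw.csv, neuropil.csv, centroids.csv, speed.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n = rec.roi_fluorescence.shape[0]
    cols = [f"n{i}" for i in range(n)]
    pd.DataFrame(rec.roi_fluorescence.T, columns=cols).to_csv(out / "raw.csv", index=False)
    pd.DataFrame(rec.neuropil_fluorescence.T, columns=cols).to_csv(
        out / "neuropil.csv", index=False
    )
    pd.DataFrame(
        {"id": range(n), "x_um": rec.roi_centroids[:, 0], "y_um": rec.roi_centroids[:, 1]}
    ).to_csv(out / "centroids.csv", index=False)
    pd.DataFrame({"speed_mms": rec.speed.speed}).to_csv(out / "speed.csv", index=False)
    save_ground_truth_json(rec.ground_truth, out / "ground_truth.json")


def load_trace_tables(
    raw_path: str | Path,
    neuropil_path: str | Path,
    frame_rate_hz: float,
    centroids_path: str | Path | None = None,
) -> RoiTraceSet:
    """Read a frames x neurons raw/neuropil CSV pair into a RoiTraceSet."""
    raw_path, neuropil_path = Path(raw_path), Path(neuropil_path)
    if not neuropil_path.exists():
        raise SchemaError(f"{neuropil_path}: neuropil table missing")
    raw = pd.read_csv(raw_path)
    npil = pd.read_csv(neuropil_path)
    _check_trace_frame(raw, raw_path)
    _check_trace_frame(npil, neuropil_path)
    if list(raw.columns) != list(npil.columns):
        raise SchemaError(
            f"{neuropil_path}: neuron columns do not match {raw_path} "
            f"({list(npil.columns)[:3]}... vs {list(raw.columns)[:3]}...)"
        )
    centroids = None
    if centroids_path is not None:
        cdf = pd.read_csv(centroids_path)
        for col in ("id", "x_um", "y_um"):
            if col not in cdf.columns:
                raise SchemaError(f"{centroids_path}: missing column {col!r}")
        centroids = cdf.sort_values("id")[["x_um", "y_um"]].to_numpy()
    return RoiTraceSet(
        raw=raw.to_numpy().T,
        neuropil=npil.to_numpy().T,
        frame_rate_hz=frame_rate_hz,
        centroids=centroids,
    )


def raster_to_table(raster) -> pd.DataFrame:
    """Sparse event export: one row per event (neuron, onset_frame, duration)."""
    rows = []
    for i, onsets in enumerate(raster.onsets):
        for onset in onsets:
            end = onset
            T = raster.active.shape[1]
            while end < T and raster.active[i, end]:
                end += 1
            rows.append((i, int(onset), int(end - onset)))
    return pd.DataFrame(rows, columns=["neuron", "onset_frame", "duration_frames"])


def edges_to_table(graph, null) -> pd.DataFrame:
    """Edge list: (i, j, r, threshold, distance_um) per significant pair."""
    rows = []
    for i, j, d in graph.graph.edges(data=True):
        rows.append(
            (i, j, d["r"], d["threshold"], d.get("distance_um", np.nan))
        )
    return pd.DataFrame(rows, columns=["i", "j", "r", "threshold", "distance_um"])


def assemblies_to_tables(model) -> tuple[pd.DataFrame, dict]:
    """Long membership table + JSON-ready metadata."""
    rows = [
        (a, n) for a, members in enumerate(model.memberships) for n in sorted(members)
    ]
    table = pd.DataFrame(rows, columns=["assembly_id", "neuron_id"])
    meta = {
        "z_max": None if np.isnan(model.z_max) else float(model.z_max),
        "n_pcs": int(model.n_pcs),
        "n_assemblies": model.n_assemblies,
        "synchrony_p": None
        if model.synchrony_p is None
        else [float(p) for p in model.synchrony_p],
        "merge_log": [
            {"pair": list(pair), "dot": float(dot)} for pair, dot in model.merge_log
        ],
        "flags": list(model.flags),
    }
    return table, meta
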