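"""Readers and writers for the pipeline's on-disk formats.

Primary interchange format is plain text: TSV for maps, timeseries, network
matrices and edge vectors; CSV for behavioral tables; single-column text
plus a JSON sidecar for electrodermal traces; BIDS-events-style TSV
(columns ``onset``, ``duration`` in seconds, 0-based) for trial onsets.
Spatial maps and 4-D data can optionally be read from / written to NIfTI.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import NodeTimeseries, SpatialMapSet
from .netmats import NetMat
from .scr import ScrRecording

__all__ = [
    "write_spatial_maps", "read_spatial_maps",
    "write_timeseries", "read_timeseries",
    "write_netmat", "read_netmat",
    "write_edge_vector", "read_edge_vector",
    "write_scr_trace", "read_scr_trace",
    "write_events", "read_events",
    "write_maps_nifti", "read_maps_nifti",
]


def write_spatial_maps(mapset: SpatialMapSet, path) -> None:
    df = pd.DataFrame(mapset.maps, index=mapset.component_ids)
    df.insert(0, "kept", mapset.kept_flags.astype(int))
    df.to_csv(path, sep="\t", index_label="component")


def read_spatial_maps(path) -> SpatialMapSet:
    df = pd.read_csv(path, sep="\t", index_col="component")
    kept = df.pop("kept").to_numpy(bool)
    return SpatialMapSet(df.to_numpy(float), [str(i) for i in df.index], kept_flags=kept)


def write_timeseries(ts: NodeTimeseries, path) -> None:
    # artifact columns are tagged in the header so cleanup stays self-describing
    cols = [
        f"{l}:artifact" if a else l
        for l, a in zip(ts.node_labels, ts.artifact_flags)
    ]
    pd.DataFrame(ts.data, columns=cols).to_csv(path, sep="\t", index=False)


def read_timeseries(path, tr_seconds: float = 1.0) -> NodeTimeseries:
    df = pd.read_csv(path, sep="\t")
    labels = [c.removesuffix(":artifact") for c in df.columns]
    flags = np.array([c.endswith(":artifact") for c in df.columns])
    return NodeTimeseries(df.to_numpy(float), labels, flags, tr_seconds)


def write_netmat(nm: NetMat, path) -> None:
    df = pd.DataFrame(nm.z, index=nm.node_labels, columns=nm.node_labels)
    with open(path, "w") as fh:
        fh.write(f"# scaling={nm.scaling}\tn_timepoints={nm.n_timepoints_effective}\n")
        df.to_csv(fh, sep="\t", index_label="node")


def read_netmat(path) -> NetMat:
    with open(path) as fh:
        header = fh.readline().strip().lstrip("# ")
        meta = dict(kv.split("=") for kv in header.split("\t"))
        df = pd.read_csv(fh, sep="\t", index_col="node")
    return NetMat(
        df.to_numpy(float), [str(c) for c in df.columns],
        int(meta["n_timepoints"]), meta["scaling"],
    )


def write_edge_vector(values: np.ndarray, edge_labels: list[str], path) -> None:
    pd.DataFrame([np.asarray(values)], columns=edge_labels).to_csv(path, sep="\t", index=False)


def read_edge_vector(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    return df.to_numpy(float)[0], [str(c) for c in df.columns]


def write_scr_trace(samples: np.ndarray, fs_hz: float, path) -> None:
    path = Path(path)
    np.savetxt(path, np.asarray(samples), fmt="%.8g")
    path.with_suffix(path.suffix + ".json").write_text(json.dumps({"fs_hz": fs_hz}))


def read_scr_trace(path, events: pd.DataFrame | None = None) -> ScrRecording:
    path = Path(path)
    samples = np.loadtxt(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return ScrRecording(samples, float(meta["fs_hz"]), events)


def write_events(events: pd.DataFrame, path) -> None:
    cols = ["onset", "duration"] + [c for c in events.columns if c not in ("onset", "duration")]
    events[cols].to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"onset", "duration"} <= set(df.columns):
        raise ValueError("events file needs 'onset' and 'duration' columns")
    return df


def write_maps_nifti(mapset: SpatialMapSet, path) -> None:
    """Write maps as a 4-D NIfTI (x, y, z, component), row-major voxel order."""
    import nibabel as nib

    shape = mapset.grid_shape or (mapset.n_voxels, 1, 1)
    vol = mapset.maps.T.reshape(*shape, mapset.n_components)
    nib.save(nib.Nifti1Image(vol, np.eye(4)), str(path))


def read_maps_nifti(path, component_ids=None) -> SpatialMapSet:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    n_comp = data.shape[-1]
    maps = data.reshape(-1, n_comp).T
    ids = component_ids or [f"IC{i + 1}" for i in range(n_comp)]
    return SpatialMapSet(maps, ids, grid_shape=data.shape[:-1])
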