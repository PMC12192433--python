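"""Shared data containers for the connectivity pipeline.

These are thin, validated wrappers around numpy arrays with the labels and
flags the pipeline needs to keep straight: which components are canonical
networks versus artifacts, which voxel grid a map lives on, and how edges
of a network matrix are ordered when flattened.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Canonical network labels for the 17 retained components, in fixed order:
#: three default-mode subnetworks, left/right frontoparietal, two attention
#: control networks, salience, limbic, two reward networks, cerebellum-basal
#: ganglia, higher visual, visual, sensorimotor-language and two
#: somatosensory networks.
CANONICAL_NETWORKS = (
    "DMN1", "DMN2", "DMN3", "LFP", "RFP", "ACN1", "ACN2", "SN", "LIMB",
    "REW1", "REW2", "CBG", "HVIS", "VIS", "SML", "SSN1", "SSN2",
)


@dataclass
class SpatialMapSet:
    """A set of group-level spatial component maps (components x voxels).

    Parameters
    ----------
    maps
        Real matrix, one row per component.
    component_ids
        One label per component.
    kept_flags
        True for components retained as canonical networks, False for
        artifactual components. May be unset (all True) before matching.
    match_r
        Spatial correlation of each component against its best-matching
        reference map; NaN before matching has been run.
    match_label
        Label of the best-matching reference component, or None.
    grid_shape
        Original 3-D grid shape if the maps were flattened from a volume
        (row-major voxel ordering); None for abstract voxel vectors.
    """

    maps: np.ndarray
    component_ids: list[str]
    kept_flags: np.ndarray = None
    match_r: np.ndarray = None
    match_label: list = None
    grid_shape: tuple | None = None

    def __post_init__(self):
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 2:
            raise ValueError("maps must be a 2-D (component x voxel) matrix")
        n = self.maps.shape[0]
        if len(self.component_ids) != n:
            raise ValueError("need one component_id per map row")
        if self.kept_flags is None:
            self.kept_flags = np.ones(n, dtype=bool)
        self.kept_flags = np.asarray(self.kept_flags, dtype=bool)
        if self.match_r is None:
            self.match_r = np.full(n, np.nan)
        self.match_r = np.asarray(self.match_r, dtype=float)
        if self.match_label is None:
            self.match_label = [None] * n
        norms = np.linalg.norm(self.maps, axis=1)
        if np.any(norms == 0):
            bad = [self.component_ids[i] for i in np.flatnonzero(norms == 0)]
            raise ValueError(f"all-zero component map(s): {bad}")

    @property
    def n_components(self) -> int:
        return self.maps.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.maps.shape[1]


@dataclass
class NodeTimeseries:
    """Per-subject, per-condition node timeseries (time x node).

    ``artifact_flags`` marks columns that correspond to artifactual
    components; they ride along through stage-1 dual regression and are
    consumed (regressed out, then dropped) by the netmats cleanup step.
    """

    data: np.ndarray
    node_labels: list[str]
    artifact_flags: np.ndarray = None
    tr_seconds: float = 1.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (time x node)")
        if len(self.node_labels) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.node_labels)} labels for {self.data.shape[1]} columns"
            )
        if self.artifact_flags is None:
            self.artifact_flags = np.zeros(self.data.shape[1], dtype=bool)
        self.artifact_flags = np.asarray(self.artifact_flags, dtype=bool)

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]

    def kept(self) -> "NodeTimeseries":
        """Return only the non-artifact columns (order preserved)."""
        keep = ~self.artifact_flags
        return NodeTimeseries(
            self.data[:, keep],
            [l for l, k in zip(self.node_labels, keep) if k],
            np.zeros(int(keep.sum()), dtype=bool),
            self.tr_seconds,
        )


def edge_index(n_nodes: int) -> list[tuple[int, int]]:
    """Row-major upper-triangle edge ordering: (0,1), (0,2), ..., (n-2,n-1)."""
    return [(i, j) for i in range(n_nodes) for j in range(i + 1, n_nodes)]


def edge_labels(node_labels: list[str]) -> list[str]:
    """Pair labels in ``A__B`` style matching :func:`edge_index` order."""
    return [f"{node_labels[i]}__{node_labels[j]}" for i, j in edge_index(len(node_labels))]
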