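"""Projection of voxel scalar metrics onto skeleton mesh vertices.

For every vertex the scalar volume is sampled by trilinear interpolation
along the vertex normal, from -half_thickness to +half_thickness, and the
maximum (study default) or mean of the samples becomes the vertex value.
Per-tract per-subject mean FA and barycentric vertex area weights also
live here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .errors import ConfigError, ProjectionError
from .mesh import SkeletonMesh
from .tensor import ScalarVolume


@dataclass
class VertexDataset:
    """Subjects x vertices matrix of metric values projected onto one tract."""

    tract: str
    subject_ids: list
    values: np.ndarray

    def __post_init__(self):
        self.subject_ids = list(self.subject_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ConfigError("values must be a 2-D subjects x vertices matrix")
        if self.values.shape[0] != len(self.subject_ids):
            raise ConfigError("row count must equal number of subjects")
        if np.any(~np.isfinite(self.values)):
            raise ConfigError("vertex dataset contains missing cells")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"v{i}" for i in range(self.n_vertices)]
        return pd.DataFrame(self.values, index=pd.Index(self.subject_ids, name="subject_id"), columns=cols)

    def subset(self, subject_ids) -> "VertexDataset":
        """Rows restricted to ``subject_ids``, in the given order."""
        pos = {s: i for i, s in enumerate(self.subject_ids)}
        idx = [pos[s] for s in subject_ids]
        return VertexDataset(self.tract, list(subject_ids), self.values[idx])


def _sample_offsets(half_thickness: np.ndarray, step: float):
    """Per-vertex symmetric offsets [-h, h] spaced at most ``step`` apart.

    Always includes both endpoints and 0, so the h -> 0 limit degenerates to
    a single sample at the vertex.
    """
    n_half = np.maximum(1, np.ceil(half_thickness / step).astype(int))
    offsets, owner = [], []
    for i, (h, k) in enumerate(zip(half_thickness, n_half)):
        t = np.linspace(-h, h, 2 * k + 1)
        offsets.append(t)
        owner.append(np.full(t.size, i))
    return np.concatenate(offsets), np.concatenate(owner)


def project_metric(volume: ScalarVolume, mesh: SkeletonMesh, mode: str = "max",
                   step: float | None = None) -> np.ndarray:
    """Project a scalar volume onto the mesh vertices.

    Parameters
    ----------
    mode : {"max", "mean"}
        Reduction over the samples along the normal segment; "max" is the
        study default.
    step : float, optional
        Sampling step in mm; defaults to a quarter of the smallest voxel
        dimension.

    Returns
    -------
    (V,) array of projected values.

    Raises
    ------
    ProjectionError
        If any vertex's whole segment falls outside the volume; the
        offending indices are attached to the exception.
    """
    if mode not in ("max", "mean"):
        raise ConfigError(f"mode must be 'max' or 'mean', got {mode!r}")
    if step is None:
        step = 0.25 * float(volume.voxel_sizes.min())
    if step <= 0:
        raise ConfigError("step must be positive")

    offsets, owner = _sample_offsets(mesh.half_thickness, step)
    points = mesh.vertices[owner] + offsets[:, None] * mesh.normals[owner]
    inv = np.linalg.inv(volume.affine)
    ijk = points @ inv[:3, :3].T + inv[:3, 3]
    samples = map_coordinates(
        volume.data, ijk.T, order=1, mode="constant", cval=np.nan
    )

    df = pd.DataFrame({"v": owner, "s": samples})
    reduced = df.groupby("v")["s"].max() if mode == "max" else df.groupby("v")["s"].mean()
    values = reduced.to_numpy()
    outside = np.flatnonzero(~np.isfinite(values))
    if outside.size:
        raise ProjectionError(
            f"{outside.size} vertices have no in-volume sample", vertices=outside
        )
    return values


def tract_mean_fa(dataset: VertexDataset) -> pd.Series:
    """Unweighted per-subject mean over vertices (atlas-space tract mean)."""
    if dataset.n_vertices == 0 or dataset.n_subjects == 0:
        raise ConfigError("empty vertex dataset")
    return pd.Series(
        dataset.values.mean(axis=1),
        index=pd.Index(dataset.subject_ids, name="subject_id"),
        name=dataset.tract,
    )


def triangle_areas(mesh: SkeletonMesh) -> np.ndarray:
    """Euclidean area of each triangle (mm^2)."""
    v = mesh.vertices
    t = mesh.triangles
    cross = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
    return 0.5 * np.linalg.norm(cross, axis=1)


def vertex_area_weights(mesh: SkeletonMesh) -> np.ndarray:
    """Barycentric vertex areas: one third of each incident triangle.

    The weights sum exactly to the mesh surface area; degenerate triangles
    contribute zero and trigger a warning.
    """
    areas = triangle_areas(mesh)
    if np.any(areas == 0):
        warnings.warn(
            f"{int(np.count_nonzero(areas == 0))} degenerate triangles "
            f"contribute zero area", stacklevel=2,
        )
    w = np.zeros(mesh.n_vertices)
    np.add.at(w, mesh.triangles.ravel(), np.repeat(areas / 3.0, 3))
    return w
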