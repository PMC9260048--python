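"""Cortical surface geometry: meshes, scalar maps, E-field seed regions.

The stimulated "seed" is the set of surface vertices where the simulated
TMS-induced electric field magnitude |E| meets a threshold (default
0.9 V/m). Seed area is reported in mm^2, computed from the mesh triangles:
a face contributes its area only when all three of its vertices are
suprathreshold, which is conservative at the seed boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .networks import NETWORKS, validate_network

log = logging.getLogger(__name__)

#: Default |E| threshold, V/m, used to delimit the stimulated patch.
DEFAULT_THRESHOLD = 0.9


class EmptySeedError(ValueError):
    """No vertex reaches the E-field threshold."""


@dataclass(frozen=True)
class SurfaceMesh:
    """Triangulated cortical surface (single hemisphere).

    Parameters
    ----------
    vertices : (V, 3) float array
        Vertex coordinates in millimetres.
    faces : (F, 3) int array
        Triangles as vertex-index triples (0-based).
    hemisphere : str
        Hemisphere label; the pipeline models the left ("L") hemisphere.
    """

    vertices: np.ndarray
    faces: np.ndarray
    hemisphere: str = "L"

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("vertices must be (V, 3)")
        if f.ndim != 2 or f.shape[1] != 3:
            raise ValueError("faces must be (F, 3)")
        if v.shape[0] < 4:
            raise ValueError("a surface mesh needs at least 4 vertices")
        if f.min(initial=0) < 0 or f.max(initial=-1) >= v.shape[0]:
            raise ValueError("face indices out of range")
        if (
            (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
        ).any():
            raise ValueError("a face repeats a vertex")
        referenced = np.zeros(v.shape[0], dtype=bool)
        referenced[f.ravel()] = True
        if not referenced.all():
            raise ValueError("every vertex must be referenced by >=1 face")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]


@dataclass(frozen=True)
class ScalarMap:
    """Per-vertex scalar field, here |E| in V/m, aligned to a mesh."""

    values: np.ndarray
    mesh_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if not np.isfinite(v).all():
            raise ValueError("scalar map values must be finite")
        if (v < 0).any():
            raise ValueError("|E| values must be nonnegative")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class SeedRegion:
    """Suprathreshold E-field patch: vertex ids, threshold and area."""

    vertex_ids: np.ndarray
    threshold: float
    area_mm2: float

    def __post_init__(self) -> None:
        ids = np.asarray(self.vertex_ids, dtype=np.int64).ravel()
        if ids.size == 0:
            raise ValueError("seed region must be nonempty")
        if (np.diff(ids) <= 0).any():
            raise ValueError("vertex_ids must be strictly increasing")
        if self.area_mm2 < 0:
            raise ValueError("area must be nonnegative")
        object.__setattr__(self, "vertex_ids", ids)

    @property
    def n_vertices(self) -> int:
        return self.vertex_ids.size


@dataclass(frozen=True)
class Parcellation:
    """Vertex-level parcellation plus a parcel -> network lookup."""

    vertex_parcel: np.ndarray
    parcel_network: dict[int, str]

    def __post_init__(self) -> None:
        vp = np.asarray(self.vertex_parcel, dtype=np.int64).ravel()
        parcels = set(np.unique(vp).tolist())
        missing = parcels - set(self.parcel_network)
        if missing:
            raise ValueError(f"parcels without a network: {sorted(missing)}")
        for net in self.parcel_network.values():
            validate_network(net)
        present = {self.parcel_network[p] for p in parcels}
        if present != set(NETWORKS):
            raise ValueError(
                "all eight networks must be present; missing "
                f"{sorted(set(NETWORKS) - present)}"
            )
        object.__setattr__(self, "vertex_parcel", vp)

    @property
    def n_vertices(self) -> int:
        return self.vertex_parcel.shape[0]

    def vertex_network_codes(self) -> np.ndarray:
        """Network index (position in the fixed order) per vertex."""
        lut = np.empty(int(self.vertex_parcel.max()) + 1, dtype=np.int64)
        for pid, net in self.parcel_network.items():
            if pid <= self.vertex_parcel.max():
                lut[pid] = NETWORKS.index(net)
        return lut[self.vertex_parcel]


def face_areas(mesh: SurfaceMesh) -> np.ndarray:
    """Area of every triangle of the mesh, mm^2.

    Degenerate (collinear) faces get area 0 and a logged warning rather
    than raising: real surface extracts contain sliver triangles.
    """
    tri = mesh.vertices[mesh.faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    n_degenerate = int((areas == 0.0).sum())
    if n_degenerate:
        log.warning("%d degenerate (zero-area) faces in mesh", n_degenerate)
    return areas


def extract_seed(
    emap: ScalarMap, mesh: SurfaceMesh, threshold: float = DEFAULT_THRESHOLD
) -> SeedRegion:
    """Threshold an E-field map into a seed region.

    A vertex is suprathreshold when its value is >= ``threshold``
    (inclusive, so the printed 0.9 V/m boundary stays inside the seed).
    The reported area sums faces whose three vertices are all
    suprathreshold.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if len(emap) != mesh.n_vertices:
        raise ValueError("scalar map does not match mesh vertex count")
    supra = emap.values >= threshold
    ids = np.flatnonzero(supra)
    if ids.size == 0:
        raise EmptySeedError(
            f"no vertex reaches the {threshold} V/m threshold "
            f"(max |E| = {emap.values.max():.4g} V/m)"
        )
    keep = supra[mesh.faces].all(axis=1)
    area = float(face_areas(mesh)[keep].sum())
    return SeedRegion(vertex_ids=ids, threshold=float(threshold), area_mm2=area)


def threshold_sweep(
    emap: ScalarMap,
    mesh: SurfaceMesh,
    thresholds: "list[float] | np.ndarray",
    on_empty: str = "zero",
) -> pd.DataFrame:
    """Seed size and area over a range of E-field thresholds.

    Returns a DataFrame with columns (threshold, n_vertices, area_mm2);
    both counts and areas are monotonically non-increasing in threshold.
    Thresholds above the map maximum yield zero rows with a warning by
    default (``on_empty="zero"``) or raise (``on_empty="error"``).
    """
    thr = np.asarray(thresholds, dtype=float).ravel()
    if thr.size == 0:
        raise ValueError("threshold list must be nonempty")
    if (np.diff(thr) <= 0).any():
        raise ValueError("thresholds must be strictly increasing")
    if on_empty not in ("zero", "error"):
        raise ValueError("on_empty must be 'zero' or 'error'")
    areas = face_areas(mesh)
    rows = []
    for t in thr:
        supra = emap.values >= t
        n = int(supra.sum())
        if n == 0:
            if on_empty == "error":
                raise EmptySeedError(
                    f"no vertex reaches the {t} V/m threshold"
                )
            warnings.warn(
                f"threshold {t} V/m above map maximum; empty seed",
                stacklevel=2,
            )
            rows.append((float(t), 0, 0.0))
            continue
        keep = supra[mesh.faces].all(axis=1)
        rows.append((float(t), n, float(areas[keep].sum())))
    return pd.DataFrame(rows, columns=["threshold", "n_vertices", "area_mm2"])
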