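"""Dense-connectome functional connectivity and network engagement.

A dense connectome is the vertex x vertex Pearson-correlation matrix of
resting-state time series. The FC of a stimulated seed is the plain
arithmetic mean, over seed vertices, of their correlation to every other
vertex ("average FC ... to every other node"); Fisher-z averaging is used
only where it is standard, i.e. when averaging whole correlation matrices
across runs or across subjects.

Network engagement is the spider-plot statistic: each suprathreshold seed
vertex is assigned to the canonical network to which its mean FC is
maximal, and the engagement profile is the percentage of seed vertices
assigned to each of the eight networks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .networks import NETWORKS, N_NETWORKS
from .surface import Parcellation, SeedRegion

_Z_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class DenseConnectome:
    """Vertex x vertex Pearson-r matrix for one subject or a group."""

    matrix: np.ndarray
    connectome_id: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("connectome matrix must be square")
        if not np.allclose(m, m.T, atol=1e-8):
            raise ValueError("connectome matrix must be symmetric")
        if not np.allclose(np.diagonal(m), 1.0, atol=1e-8):
            raise ValueError("connectome diagonal must be 1")
        if m.min() < -1 - 1e-8 or m.max() > 1 + 1e-8:
            raise ValueError("correlations must lie in [-1, 1]")
        object.__setattr__(self, "matrix", m)

    @property
    def n_vertices(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class SeedFCMap:
    """Seed-averaged FC: one r per vertex of the surface.

    Seed vertices are not excluded from the map domain (the seed's column
    average runs over the full dense connectome, self-correlations
    included); use ``mask_seed`` for display purposes.
    """

    values: np.ndarray
    seed: SeedRegion
    source: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if v.min() < -1 - 1e-8 or v.max() > 1 + 1e-8:
            raise ValueError("seed FC values must lie in [-1, 1]")
        object.__setattr__(self, "values", v)

    def mask_seed(self) -> np.ndarray:
        """Copy of the map with seed vertices set to NaN (display only)."""
        out = self.values.copy()
        out[self.seed.vertex_ids] = np.nan
        return out


@dataclass(frozen=True)
class EngagementProfile:
    """Percentage of seed vertices assigned to each canonical network."""

    percent: np.ndarray  # aligned with networks.NETWORKS
    n_seed_vertices: int

    def __post_init__(self) -> None:
        p = np.asarray(self.percent, dtype=float).ravel()
        if p.shape[0] != N_NETWORKS:
            raise ValueError(f"expected {N_NETWORKS} percentages")
        if (p < 0).any() or (p > 100).any():
            raise ValueError("percentages must lie in [0, 100]")
        if abs(p.sum() - 100.0) > 1e-9:
            raise ValueError("percentages must sum to 100")
        if self.n_seed_vertices < 1:
            raise ValueError("profile needs at least one seed vertex")
        object.__setattr__(self, "percent", p)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(NETWORKS, self.percent.tolist()))


def _fisher_mean(mats: Sequence[np.ndarray]) -> np.ndarray:
    """Fisher-z average of correlation matrices; diagonal forced to 1."""
    acc = np.zeros_like(np.asarray(mats[0], dtype=np.float64))
    for m in mats:
        acc += np.arctanh(np.clip(np.asarray(m, dtype=np.float64),
                                  -_Z_CLIP, _Z_CLIP))
    out = np.tanh(acc / len(mats))
    np.fill_diagonal(out, 1.0)
    return out


def average_fc_runs(runs: Sequence[DenseConnectome]) -> DenseConnectome:
    """Average per-run connectomes of one subject in Fisher-z space."""
    if len(runs) == 0:
        raise ValueError("need at least one run")
    shapes = {r.matrix.shape for r in runs}
    if len(shapes) != 1:
        raise ValueError(f"run shape mismatch: {sorted(shapes)}")
    return DenseConnectome(
        _fisher_mean([r.matrix for r in runs]), connectome_id="run-average"
    )


def group_average_fc(subject_fc: Sequence[DenseConnectome]) -> DenseConnectome:
    """Fisher-z group average of per-subject connectomes."""
    if len(subject_fc) == 0:
        raise ValueError("need at least one subject")
    shapes = {s.matrix.shape for s in subject_fc}
    if len(shapes) != 1:
        raise ValueError(f"subject shape mismatch: {sorted(shapes)}")
    return DenseConnectome(
        _fisher_mean([s.matrix for s in subject_fc]),
        connectome_id="group-average",
    )


def seed_fc_map(connectome: DenseConnectome, seed: SeedRegion) -> SeedFCMap:
    """Seed-averaged FC map: mean r from the seed to every vertex.

    Plain arithmetic mean over seed rows, no Fisher transform.
    """
    ids = seed.vertex_ids
    if ids.max() >= connectome.n_vertices:
        raise ValueError("seed vertex id out of range for connectome")
    values = connectome.matrix[ids, :].mean(axis=0, dtype=np.float64)
    return SeedFCMap(values=values, seed=seed, source=connectome.connectome_id)


def vertex_network_fc(
    connectome: DenseConnectome, vertex: int, parcellation: Parcellation
) -> np.ndarray:
    """Mean FC of one vertex to each canonical network.

    For each network, the arithmetic mean of r(vertex, j) over vertices j
    of that network, excluding j = vertex itself (self-correlation would
    bias the vertex's own network upward).
    """
    if not (0 <= vertex < connectome.n_vertices):
        raise ValueError(f"vertex {vertex} out of range")
    codes = parcellation.vertex_network_codes()
    row = connectome.matrix[vertex].astype(np.float64)
    sums = np.bincount(codes, weights=row, minlength=N_NETWORKS)
    counts = np.bincount(codes, minlength=N_NETWORKS).astype(float)
    own = codes[vertex]
    sums[own] -= row[vertex]
    counts[own] -= 1
    if (counts == 0).any():
        empty = [NETWORKS[i] for i in np.flatnonzero(counts == 0)]
        raise ValueError(f"network(s) with no vertices: {empty}")
    return sums / counts


def assign_vertices(
    connectome: DenseConnectome,
    seed: SeedRegion,
    parcellation: Parcellation,
) -> np.ndarray:
    """Assign each seed vertex to its maximum-FC network.

    Signed argmax over the eight mean network FC values; exact ties break
    to the earlier network in the fixed canonical order (np.argmax's
    first-wins convention). Returns network indices, one per seed vertex.
    """
    ids = seed.vertex_ids
    if ids.max() >= connectome.n_vertices:
        raise ValueError("seed vertex id out of range for connectome")
    codes = parcellation.vertex_network_codes()
    counts = np.bincount(codes, minlength=N_NETWORKS).astype(np.float64)
    if (counts == 0).any():
        empty = [NETWORKS[i] for i in np.flatnonzero(counts == 0)]
        raise ValueError(f"network(s) with no vertices: {empty}")
    # one-hot membership (V x 8); rows of the seed block give per-network sums
    member = np.zeros((connectome.n_vertices, N_NETWORKS))
    member[np.arange(connectome.n_vertices), codes] = 1.0
    rows = connectome.matrix[ids, :].astype(np.float64)
    sums = rows @ member
    # exclude each seed vertex's self-correlation from its own network
    own = codes[ids]
    sums[np.arange(ids.size), own] -= rows[np.arange(ids.size), ids]
    net_counts = np.tile(counts, (ids.size, 1))
    net_counts[np.arange(ids.size), own] -= 1
    if (net_counts == 0).any():
        raise ValueError(
            "a seed vertex is its network's only vertex; network mean FC "
            "undefined after self-exclusion"
        )
    means = sums / net_counts
    return np.argmax(means, axis=1)


def engagement_profile(assignments: Iterable[int]) -> EngagementProfile:
    """Counts of network assignments as percentages of seed vertices."""
    a = np.asarray(list(assignments), dtype=np.int64)
    if a.size == 0:
        raise ValueError("no assignments given")
    if a.min() < 0 or a.max() >= N_NETWORKS:
        raise ValueError("assignment out of network range")
    counts = np.bincount(a, minlength=N_NETWORKS)
    return EngagementProfile(
        percent=100.0 * counts / a.size, n_seed_vertices=int(a.size)
    )


def most_engaged(profile: EngagementProfile) -> str:
    """Network with the largest engagement percentage (fixed-order ties)."""
    return NETWORKS[int(np.argmax(profile.percent))]
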