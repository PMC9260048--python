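"""Synthetic study cohort: template surface, E-field surrogates, connectomes.

The real study paired subject-specific simulated TMS E-field maps with
resting-state dense connectomes. This module generates a desk-scale
surrogate cohort with the same analyzable structure:

* a shared template surface (icosphere, radius in mm);
* a contiguous parcellation whose parcels map onto the eight canonical
  networks;
* per-subject E-field maps: a Gaussian-of-Euclidean-distance bump around a
  coil focus, with subject-varying amplitude, width and focus position
  standing in for inter-subject differences in skull/cortical geometry;
* per-subject dense connectomes from a latent network-factor time-series
  model, guaranteed symmetric/unit-diagonal/PSD, with multi-run averaging.

Subject geometry variability is represented entirely through the E-field
realizations on the shared mesh: downstream analyses see geometry only via
the E-field map, so per-subject meshes are unnecessary at this scale.

Inter-subject FC variability is controlled by a single knob
(``fc_perturbation_scale``): the latent factors, global signal and vertex
noise of each run are drawn once per cohort and shared across subjects,
while each subject perturbs the factor loadings vertex-wise. Setting the
knob to zero therefore makes every subject's connectome identical — the
degenerate cohorts used to isolate geometry-driven from FC-driven
variability are exact, not approximate.

Vertex signals are mixtures of network factors with spatially decaying
weights (``boundary_mixing_mm``): a vertex deep inside a parcel loads
almost purely on its own network, while vertices near parcel boundaries
load on the neighbouring networks too. This is what makes a vertex's
maximum-FC network genuinely ambiguous at boundaries — and hence lets
individual FC perturbations flip assignments, the connectivity-driven
variability the framework is designed to measure. With the mixing length
set to zero the generator reduces exactly to the pure one-network-per-
vertex factor model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import trimesh

from .connectivity import DenseConnectome, EngagementProfile, average_fc_runs
from .networks import NETWORKS, N_NETWORKS, network_index
from .surface import (
    DEFAULT_THRESHOLD,
    Parcellation,
    ScalarMap,
    SeedRegion,
    SurfaceMesh,
    extract_seed,
)

log = logging.getLogger(__name__)

# spawn_key name spaces for master_seed-derived RNG streams
_KEY_PARCELLATION = 0
_KEY_SUBJECT_PARAMS = 1
_KEY_FC_BASE = 2
_KEY_FC_SUBJECT = 3

# icosphere vertex counts by subdivision level
_ICOSPHERE_VERTICES = {0: 12, 1: 42, 2: 162, 3: 642, 4: 2562, 5: 10242, 6: 40962}


@dataclass(frozen=True)
class CoilPlacement:
    """A nominal coil placement: focus point and Gaussian field parameters.

    ``nominal_amplitude`` is the peak |E| (V/m) at the focus vertex for a
    subject with identity parameters; ``nominal_sigma`` the Gaussian width
    (mm) of the field's fall-off with Euclidean distance from the focus.
    """

    label: str
    focus_point: np.ndarray
    nominal_amplitude: float
    nominal_sigma: float

    def __post_init__(self) -> None:
        if self.nominal_amplitude <= 0 or self.nominal_sigma <= 0:
            raise ValueError("amplitude and sigma must be positive")
        object.__setattr__(
            self, "focus_point", np.asarray(self.focus_point, dtype=float)
        )


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject multiplicative E-field factors, jitter and FC spread."""

    amplitude_factor: float = 1.0
    sigma_factor: float = 1.0
    focus_jitter: np.ndarray = field(
        default_factory=lambda: np.zeros(3)
    )
    fc_perturbation_scale: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude_factor <= 0 or self.sigma_factor <= 0:
            raise ValueError("factors must be positive")
        if self.fc_perturbation_scale < 0:
            raise ValueError("fc_perturbation_scale must be >= 0")
        j = np.asarray(self.focus_jitter, dtype=float)
        if j.shape != (3,) or not np.isfinite(j).all():
            raise ValueError("focus_jitter must be a finite 3-vector")
        object.__setattr__(self, "focus_jitter", j)


IDENTITY_PARAMS = SubjectParams()


@dataclass(frozen=True)
class CohortSpec:
    """Everything that defines a synthetic cohort.

    Defaults are the packaged study conditions: 40 subjects on a level-4
    icosphere (2562 vertices, radius 20 mm), 32 parcels over the eight
    networks, four 200-sample runs per subject.
    """

    master_seed: int
    n_subjects: int = 40
    mesh_subdivision: int = 4
    mesh_radius_mm: float = 20.0
    n_parcels: int = 32
    n_timepoints: int = 200
    n_runs: int = 4
    within_network_loading: float = 0.8
    shared_loading: float = 0.4
    noise_sd: float = 0.6
    amplitude_spread: float = 0.12  # sd of log amplitude factor
    sigma_spread: float = 0.10  # sd of log width factor
    focus_jitter_sd: float = 2.0  # mm, per axis
    fc_perturbation_scale: float = 0.15
    planted_network: str | None = None
    planted_placement: str | None = None
    planted_loading_factor: float = 3.0
    planted_radius_mm: float | None = None
    boundary_mixing_mm: float = 2.0  # spatial network-mixing length, mm
    run_average_order: str = "fc"  # "fc": average run FCs; "timeseries"

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.n_parcels < N_NETWORKS:
            raise ValueError(f"need at least {N_NETWORKS} parcels")
        if self.n_timepoints <= self.n_parcels:
            raise ValueError("n_timepoints must exceed n_parcels")
        if self.n_runs < 1:
            raise ValueError("need at least one run")
        if self.run_average_order not in ("fc", "timeseries"):
            raise ValueError("run_average_order must be 'fc' or 'timeseries'")
        if self.boundary_mixing_mm < 0:
            raise ValueError("boundary_mixing_mm must be >= 0")
        if self.planted_network is not None:
            network_index(self.planted_network)


def build_template_mesh(subdivision: int, radius: float = 20.0) -> SurfaceMesh:
    """Icosphere template surface (stand-in for the 32k CIFTI hemisphere)."""
    if subdivision < 2:
        raise ValueError("subdivision level must be >= 2")
    if subdivision > 6:
        raise ValueError("subdivision level > 6 is not supported (desk scale)")
    ico = trimesh.creation.icosphere(subdivisions=subdivision, radius=radius)
    mesh = SurfaceMesh(
        vertices=np.asarray(ico.vertices, dtype=float),
        faces=np.asarray(ico.faces, dtype=np.int64),
        hemisphere="L",
    )
    assert mesh.n_vertices == _ICOSPHERE_VERTICES[subdivision]
    return mesh


def build_parcellation(
    mesh: SurfaceMesh, n_parcels: int, rng: np.random.Generator
) -> Parcellation:
    """Spatially contiguous parcels via farthest-point seeding.

    Parcel seeds are chosen by iterative farthest-point sampling from a
    random start vertex; every vertex joins its nearest seed (Euclidean).
    Parcels are dealt to the eight networks round-robin in parcel-id
    order, so each network receives at least one parcel.
    """
    if n_parcels < N_NETWORKS:
        raise ValueError(f"need at least {N_NETWORKS} parcels")
    v = mesh.vertices
    seeds = [int(rng.integers(mesh.n_vertices))]
    d = np.linalg.norm(v - v[seeds[0]], axis=1)
    for _ in range(n_parcels - 1):
        nxt = int(np.argmax(d))
        seeds.append(nxt)
        d = np.minimum(d, np.linalg.norm(v - v[nxt], axis=1))
    dist = np.linalg.norm(v[:, None, :] - v[seeds][None, :, :], axis=2)
    vertex_parcel = np.argmin(dist, axis=1).astype(np.int64)
    parcel_network = {p: NETWORKS[p % N_NETWORKS] for p in range(n_parcels)}
    return Parcellation(vertex_parcel=vertex_parcel, parcel_network=parcel_network)


def plant_network(
    parcellation: Parcellation,
    mesh: SurfaceMesh,
    center: np.ndarray,
    radius_mm: float,
    network: str,
) -> Parcellation:
    """Reassign every parcel intersecting a disc around ``center`` to one
    network, so a seed region there is dominated by that network.

    Raises if the reassignment would leave any of the eight networks
    without a parcel.
    """
    network_index(network)
    d = np.linalg.norm(mesh.vertices - np.asarray(center, dtype=float), axis=1)
    hit = np.unique(parcellation.vertex_parcel[d <= radius_mm])
    mapping = dict(parcellation.parcel_network)
    for p in hit:
        mapping[int(p)] = network
    return Parcellation(
        vertex_parcel=parcellation.vertex_parcel, parcel_network=mapping
    )


def seed_radius_mm(
    amplitude: float, sigma: float, threshold: float = DEFAULT_THRESHOLD
) -> float:
    """Closed-form isocontour radius of the Gaussian field surrogate.

    The |E| = threshold contour of A*exp(-d^2 / (2 sigma^2)) lies at
    d = sigma * sqrt(2 ln(A / threshold)).
    """
    if amplitude <= threshold:
        return 0.0
    return float(sigma * np.sqrt(2.0 * np.log(amplitude / threshold)))


def simulate_efield(
    mesh: SurfaceMesh,
    placement: CoilPlacement,
    params: SubjectParams = IDENTITY_PARAMS,
) -> ScalarMap:
    """Gaussian-of-distance surrogate for a simulated TMS E-field map.

    value(v) = A exp(-||v - c||^2 / (2 sigma^2)) with A and sigma the
    placement nominals scaled by the subject factors, and c the jittered
    focus projected to its nearest mesh vertex (so the peak equals A
    exactly at one vertex).
    """
    centroid = mesh.vertices.mean(axis=0)
    radius = np.linalg.norm(mesh.vertices - centroid, axis=1).max()
    if np.linalg.norm(placement.focus_point - centroid) > 2 * radius:
        raise ValueError("focus point too far from the mesh")
    amplitude = placement.nominal_amplitude * params.amplitude_factor
    sigma = placement.nominal_sigma * params.sigma_factor
    if amplitude <= DEFAULT_THRESHOLD:
        log.warning(
            "peak |E| %.3f V/m is at or below the default %.1f V/m "
            "threshold; the seed may be empty",
            amplitude,
            DEFAULT_THRESHOLD,
        )
    target = placement.focus_point + params.focus_jitter
    focus_vertex = int(
        np.argmin(np.linalg.norm(mesh.vertices - target, axis=1))
    )
    c = mesh.vertices[focus_vertex]
    d2 = ((mesh.vertices - c) ** 2).sum(axis=1)
    values = amplitude * np.exp(-d2 / (2.0 * sigma**2))
    return ScalarMap(values=values, mesh_id=placement.label)


def _network_loadings(spec: CohortSpec) -> np.ndarray:
    w = np.full(N_NETWORKS, spec.within_network_loading)
    if spec.planted_network is not None:
        w[network_index(spec.planted_network)] *= spec.planted_loading_factor
    return w


def network_mixing_weights(
    mesh: SurfaceMesh, parcellation: Parcellation, mixing_mm: float
) -> np.ndarray:
    """(V, 8) spatial mixing of network factors into vertex signals.

    Weight of network m at vertex i is exp(-d^2 / (2 lambda^2)) with d the
    Euclidean distance from i to the nearest vertex belonging to m, rows
    normalized to sum 1. A vertex's own network always has d = 0; with
    ``mixing_mm`` 0 the result is the one-hot membership matrix.
    """
    codes = parcellation.vertex_network_codes()
    v = mesh.vertices
    onehot = np.zeros((mesh.n_vertices, N_NETWORKS))
    onehot[np.arange(mesh.n_vertices), codes] = 1.0
    if mixing_mm == 0:
        return onehot
    w = np.empty((mesh.n_vertices, N_NETWORKS))
    for m in range(N_NETWORKS):
        members = v[codes == m]
        # min distance from every vertex to network m, chunked to cap memory
        dmin = np.full(mesh.n_vertices, np.inf)
        for start in range(0, members.shape[0], 512):
            chunk = members[start : start + 512]
            d = np.linalg.norm(v[:, None, :] - chunk[None, :, :], axis=2)
            dmin = np.minimum(dmin, d.min(axis=1))
        w[:, m] = np.exp(-(dmin**2) / (2.0 * mixing_mm**2))
    return w / w.sum(axis=1, keepdims=True)


def _loading_matrix(
    spec: CohortSpec,
    parcellation: Parcellation,
    mixing: "np.ndarray | None",
) -> np.ndarray:
    """Deterministic (V, 8) loading matrix C (before subject perturbation)."""
    w = _network_loadings(spec)
    if mixing is None:
        codes = parcellation.vertex_network_codes()
        c = np.zeros((parcellation.n_vertices, N_NETWORKS))
        c[np.arange(parcellation.n_vertices), codes] = w[codes]
        return c
    return mixing * w[None, :]


def _draw_base_signals(
    spec: CohortSpec, n_vertices: int
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Cohort-level latent signals, one (factors, global, noise) per run."""
    out = []
    for run in range(spec.n_runs):
        rng = np.random.default_rng(
            np.random.SeedSequence(spec.master_seed, spawn_key=(_KEY_FC_BASE, run))
        )
        factors = rng.standard_normal((N_NETWORKS, spec.n_timepoints))
        g = rng.standard_normal(spec.n_timepoints)
        eps = rng.standard_normal((n_vertices, spec.n_timepoints))
        out.append((factors, g, eps))
    return out


def _pearson(x: np.ndarray) -> np.ndarray:
    xc = x - x.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(xc, axis=1, keepdims=True)
    xs = xc / norm
    r = xs @ xs.T
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return r


def simulate_subject_fc(
    parcellation: Parcellation,
    spec: CohortSpec,
    params: SubjectParams,
    rng: np.random.Generator,
    base_signals: "list[tuple[np.ndarray, np.ndarray, np.ndarray]] | None" = None,
    mixing: "np.ndarray | None" = None,
) -> DenseConnectome:
    """One subject's run-averaged dense connectome from the factor model.

    Vertex i follows x_i(t) = sum_m c_im f_m(t) + w_shared g(t)
    + noise_sd eps_i(t), where the loading row c_i is the spatially mixed
    network loading (``mixing``; pure own-network when None) plus the
    subject's Gaussian perturbation delta_i of scale
    ``fc_perturbation_scale``. The returned matrix is the Pearson
    correlation, averaged over runs in Fisher-z space (or computed on the
    run-concatenated time series when the spec says so).
    """
    if spec.n_timepoints <= 3:
        raise ValueError("need more than 3 timepoints")
    n_vertices = parcellation.n_vertices
    if base_signals is None:
        base_signals = _draw_base_signals(spec, n_vertices)
    loading = _loading_matrix(spec, parcellation, mixing)
    if params.fc_perturbation_scale > 0:
        loading = loading + rng.normal(
            0.0, params.fc_perturbation_scale, (n_vertices, N_NETWORKS)
        )
    series = []
    for factors, g, eps in base_signals:
        x = loading @ factors + spec.shared_loading * g + spec.noise_sd * eps
        series.append(x)
    if spec.run_average_order == "timeseries":
        demeaned = [x - x.mean(axis=1, keepdims=True) for x in series]
        return DenseConnectome(_pearson(np.concatenate(demeaned, axis=1)))
    runs = [DenseConnectome(_pearson(x)) for x in series]
    return average_fc_runs(runs)


def draw_subject_params(spec: CohortSpec, subject: int) -> SubjectParams:
    """Subject parameters from the subject's own master_seed-derived stream.

    Multiplicative factors are log-normal (median 1); a spread of exactly
    zero yields the identity factor bitwise, so zero-variability cohorts
    degenerate exactly to the template.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(
            spec.master_seed, spawn_key=(_KEY_SUBJECT_PARAMS, subject)
        )
    )
    amp = float(np.exp(rng.normal(0.0, spec.amplitude_spread))) \
        if spec.amplitude_spread > 0 else 1.0
    sig = float(np.exp(rng.normal(0.0, spec.sigma_spread))) \
        if spec.sigma_spread > 0 else 1.0
    jitter = rng.normal(0.0, spec.focus_jitter_sd, 3) \
        if spec.focus_jitter_sd > 0 else np.zeros(3)
    return SubjectParams(
        amplitude_factor=amp,
        sigma_factor=sig,
        focus_jitter=jitter,
        fc_perturbation_scale=spec.fc_perturbation_scale,
    )


def default_placements(radius: float = 20.0) -> list[CoilPlacement]:
    """The two packaged coil placements.

    "F3-like" (dlPFC-like) and "Fp1-like" (OFC-like) foci on the template
    sphere. Amplitudes and widths are calibrated so that the 0.9 V/m
    thresholded areas land near the study's reported mean patch sizes
    (dlPFC ~54 mm^2, OFC ~16 mm^2) on the default level-4 mesh.
    """
    f3_dir = np.array([-0.53, 0.46, 0.71])
    fp1_dir = np.array([-0.26, 0.96, -0.04])
    return [
        CoilPlacement(
            label="dlpfc",
            focus_point=radius * f3_dir / np.linalg.norm(f3_dir),
            nominal_amplitude=1.5,
            nominal_sigma=4.85,
        ),
        CoilPlacement(
            label="ofc",
            focus_point=radius * fp1_dir / np.linalg.norm(fp1_dir),
            nominal_amplitude=1.25,
            nominal_sigma=3.75,
        ),
    ]


@dataclass
class SubjectRecord:
    """Materialized per-subject data (small cohorts only)."""

    subject_id: int
    efield_maps: dict[str, ScalarMap]
    fc_runs: list[DenseConnectome]
    params: SubjectParams


class Cohort:
    """A generated synthetic cohort.

    Per-subject E-field maps are cheap and computed on demand; per-subject
    run-averaged connectomes are computed lazily and cached as float32
    (at the default mesh scale each is ~25 MB).
    """

    def __init__(
        self,
        spec: CohortSpec,
        placements: Sequence[CoilPlacement],
        mesh: SurfaceMesh,
        parcellation: Parcellation,
    ) -> None:
        self.spec = spec
        self.placements = {p.label: p for p in placements}
        if len(self.placements) != len(placements):
            raise ValueError("placement labels must be unique")
        self.mesh = mesh
        self.parcellation = parcellation
        self._base_signals: list | None = None
        self._mixing: np.ndarray | None = None
        self._mixing_done = False
        self._subject_params: dict[int, SubjectParams] = {}
        self._fc_cache: dict[int, DenseConnectome] = {}
        self._group_fc: DenseConnectome | None = None

    # -- subjects ---------------------------------------------------------
    @property
    def subject_ids(self) -> range:
        return range(self.spec.n_subjects)

    def subject_params(self, subject: int) -> SubjectParams:
        self._check_subject(subject)
        if subject not in self._subject_params:
            self._subject_params[subject] = draw_subject_params(
                self.spec, subject
            )
        return self._subject_params[subject]

    def _check_subject(self, subject: int) -> None:
        if not (0 <= subject < self.spec.n_subjects):
            raise ValueError(f"unknown subject {subject}")

    # -- E-fields ---------------------------------------------------------
    def template_efield(self, placement_label: str) -> ScalarMap:
        return simulate_efield(
            self.mesh, self._placement(placement_label), IDENTITY_PARAMS
        )

    def subject_efield(self, subject: int, placement_label: str) -> ScalarMap:
        return simulate_efield(
            self.mesh,
            self._placement(placement_label),
            self.subject_params(subject),
        )

    def _placement(self, label: str) -> CoilPlacement:
        try:
            return self.placements[label]
        except KeyError:
            raise ValueError(
                f"unknown placement {label!r}; have {sorted(self.placements)}"
            ) from None

    # -- connectomes ------------------------------------------------------
    def _base(self) -> list:
        if self._base_signals is None:
            self._base_signals = _draw_base_signals(
                self.spec, self.mesh.n_vertices
            )
        return self._base_signals

    def mixing_weights(self) -> "np.ndarray | None":
        """Spatial network-mixing matrix (None when the length is zero)."""
        if not self._mixing_done:
            if self.spec.boundary_mixing_mm > 0:
                self._mixing = network_mixing_weights(
                    self.mesh, self.parcellation, self.spec.boundary_mixing_mm
                )
            self._mixing_done = True
        return self._mixing

    def subject_fc(self, subject: int) -> DenseConnectome:
        self._check_subject(subject)
        if subject not in self._fc_cache:
            rng = np.random.default_rng(
                np.random.SeedSequence(
                    self.spec.master_seed, spawn_key=(_KEY_FC_SUBJECT, subject)
                )
            )
            fc = simulate_subject_fc(
                self.parcellation,
                self.spec,
                self.subject_params(subject),
                rng,
                base_signals=self._base(),
                mixing=self.mixing_weights(),
            )
            self._fc_cache[subject] = DenseConnectome(
                fc.matrix.astype(np.float32),
                connectome_id=f"subject-{subject}",
            )
        return self._fc_cache[subject]

    def group_fc(self) -> DenseConnectome:
        """Fisher-z group average of all subjects' connectomes.

        The real study used an external, much larger group-average
        connectome; here the cohort's own average plays that role.
        """
        if self._group_fc is None:
            if self.spec.fc_perturbation_scale == 0:
                # all subject connectomes are identical by construction;
                # the Fisher average of identical matrices is that matrix
                fc = self.subject_fc(0)
                self._group_fc = DenseConnectome(
                    fc.matrix, connectome_id="group-average"
                )
                return self._group_fc
            n = self.spec.n_subjects
            acc = np.zeros(
                (self.mesh.n_vertices, self.mesh.n_vertices), dtype=np.float64
            )
            for s in self.subject_ids:
                m = self.subject_fc(s).matrix.astype(np.float64)
                acc += np.arctanh(np.clip(m, -(1 - 1e-7), 1 - 1e-7))
            out = np.tanh(acc / n)
            np.fill_diagonal(out, 1.0)
            self._group_fc = DenseConnectome(
                out.astype(np.float32), connectome_id="group-average"
            )
        return self._group_fc

    # -- materialization --------------------------------------------------
    def subject_record(self, subject: int) -> SubjectRecord:
        params = self.subject_params(subject)
        return SubjectRecord(
            subject_id=subject,
            efield_maps={
                label: self.subject_efield(subject, label)
                for label in self.placements
            },
            fc_runs=[self.subject_fc(subject)],
            params=params,
        )

    def iter_records(self) -> Iterator[SubjectRecord]:
        for s in self.subject_ids:
            yield self.subject_record(s)


def generate_cohort(
    spec: CohortSpec, placements: "Sequence[CoilPlacement] | None" = None
) -> Cohort:
    """Build the full synthetic cohort bundle.

    The template E-field uses identity subject parameters (all factors 1,
    zero jitter), emulating the study's fixed template-head field; subject
    fields and connectomes come from independent master_seed-derived
    streams, so the bundle is fully reproducible.
    """
    if placements is None:
        placements = default_placements(spec.mesh_radius_mm)
    if len(placements) == 0:
        raise ValueError("need at least one coil placement")
    mesh = build_template_mesh(spec.mesh_subdivision, spec.mesh_radius_mm)
    rng = np.random.default_rng(
        np.random.SeedSequence(spec.master_seed, spawn_key=(_KEY_PARCELLATION,))
    )
    parcellation = build_parcellation(mesh, spec.n_parcels, rng)
    if spec.planted_network is not None:
        if spec.planted_placement is None:
            raise ValueError("planted_network requires planted_placement")
        placement = {p.label: p for p in placements}[spec.planted_placement]
        radius = spec.planted_radius_mm
        if radius is None:
            radius = (
                seed_radius_mm(
                    placement.nominal_amplitude, placement.nominal_sigma
                )
                + 3.0 * max(spec.focus_jitter_sd, 1.0)
            )
        parcellation = plant_network(
            parcellation, mesh, placement.focus_point, radius,
            spec.planted_network,
        )
    return Cohort(spec, placements, mesh, parcellation)


def membership_profile(
    parcellation: Parcellation, seed: SeedRegion
) -> EngagementProfile:
    """Geometric (infinite-data) engagement expectation for a seed.

    In the factor model a vertex's mean FC is maximal to its own network
    in the infinite-sample limit, so the expected engagement profile is
    simply the network membership distribution of the seed vertices.
    """
    codes = parcellation.vertex_network_codes()[seed.vertex_ids]
    counts = np.bincount(codes, minlength=N_NETWORKS)
    return EngagementProfile(
        percent=100.0 * counts / seed.n_vertices,
        n_seed_vertices=seed.n_vertices,
    )


def expected_profile(
    parcellation: Parcellation,
    spec: CohortSpec,
    seed: SeedRegion,
    mixing: "np.ndarray | None" = None,
) -> EngagementProfile:
    """Factor-model (population-limit) engagement expectation for a seed.

    Under the generator, the population covariance of the vertex signals
    is Sigma = C C' + w_shared^2 J + noise_sd^2 I with C the deterministic
    loading matrix (no subject perturbation). The expected assignment of a
    seed vertex is the argmax over networks of its population mean
    correlation to the network's vertices (self-excluded, mirroring the
    pipeline's convention). Closed form — no sampling — so it serves as an
    independent oracle for parameter-recovery checks. With zero mixing it
    reduces to the seed's network-membership distribution.
    """
    c = _loading_matrix(spec, parcellation, mixing)
    codes = parcellation.vertex_network_codes()
    s = np.sqrt((c**2).sum(axis=1) + spec.shared_loading**2 + spec.noise_sd**2)
    u = c / s[:, None]  # normalized loadings
    inv_s = 1.0 / s
    counts = np.bincount(codes, minlength=N_NETWORKS).astype(float)
    # per-network sums of u_j and 1/s_j (for the shared-signal term)
    u_sums = np.zeros((N_NETWORKS, N_NETWORKS))
    invs_sums = np.zeros(N_NETWORKS)
    for m in range(N_NETWORKS):
        sel = codes == m
        u_sums[m] = u[sel].sum(axis=0)
        invs_sums[m] = inv_s[sel].sum()
    ids = seed.vertex_ids
    g2 = spec.shared_loading**2
    assignments = np.empty(ids.size, dtype=np.int64)
    for a, i in enumerate(ids):
        # mean_m r(i, j) = [u_i . sum_j u_j + g^2/s_i sum_j 1/s_j] / n_m
        num = u_sums @ u[i] + g2 * inv_s[i] * invs_sums
        n_m = counts.copy()
        own = codes[i]
        num[own] -= u[i] @ u[i] + g2 * inv_s[i] ** 2  # drop self-correlation
        n_m[own] -= 1
        assignments[a] = int(np.argmax(num / n_m))
    counts_seed = np.bincount(assignments, minlength=N_NETWORKS)
    return EngagementProfile(
        percent=100.0 * counts_seed / ids.size, n_seed_vertices=int(ids.size)
    )
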