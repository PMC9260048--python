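"""Synthetic cohort generator: mesh, parcellation, E-fields, connectomes."""

import numpy as np
import pytest

from efnet import (
    CohortSpec,
    CoilPlacement,
    SubjectParams,
    build_parcellation,
    build_template_mesh,
    default_placements,
    extract_seed,
    face_areas,
    generate_cohort,
    membership_profile,
    seed_radius_mm,
    simulate_efield,
    simulate_subject_fc,
)
from efnet.networks import NETWORKS
from efnet.synthetic import IDENTITY_PARAMS, draw_subject_params

from conftest import eight_network_parcellation


class TestTemplateMesh:
    @pytest.mark.parametrize(
        "level,n_vertices,n_faces", [(2, 162, 320), (3, 642, 1280), (4, 2562, 5120)]
    )
    def test_icosphere_combinatorics(self, level, n_vertices, n_faces):
        mesh = build_template_mesh(level, radius=100.0)
        assert mesh.n_vertices == n_vertices
        assert mesh.n_faces == n_faces

    def test_total_area_close_to_sphere(self):
        mesh = build_template_mesh(4, radius=100.0)
        sphere = 4 * np.pi * 100.0**2
        assert face_areas(mesh).sum() == pytest.approx(sphere, rel=0.03)

    def test_level_bounds_rejected(self):
        with pytest.raises(ValueError):
            build_template_mesh(1)
        with pytest.raises(ValueError):
            build_template_mesh(7)

    def test_all_faces_positive_area(self):
        mesh = build_template_mesh(3, radius=10.0)
        assert (face_areas(mesh) > 0).all()


class TestParcellation:
    def test_eight_parcels_one_per_network(self, small_mesh):
        rng = np.random.default_rng(0)
        parc = build_parcellation(small_mesh, 8, rng)
        nets = sorted(parc.parcel_network.values())
        assert nets == sorted(NETWORKS)

    def test_partition_covers_all_vertices(self, small_mesh):
        rng = np.random.default_rng(1)
        parc = build_parcellation(small_mesh, 16, rng)
        assert parc.n_vertices == small_mesh.n_vertices
        counts = np.bincount(parc.vertex_parcel, minlength=16)
        assert counts.sum() == small_mesh.n_vertices
        assert (counts > 0).all()

    def test_deterministic_given_seed(self, small_mesh):
        a = build_parcellation(small_mesh, 12, np.random.default_rng(9))
        b = build_parcellation(small_mesh, 12, np.random.default_rng(9))
        assert np.array_equal(a.vertex_parcel, b.vertex_parcel)
        assert a.parcel_network == b.parcel_network

    def test_too_few_parcels_rejected(self, small_mesh):
        with pytest.raises(ValueError):
            build_parcellation(small_mesh, 7, np.random.default_rng(0))


class TestEfieldSurrogate:
    def placement(self, radius=10.0, amplitude=1.5, sigma=2.5):
        direction = np.array([0.0, 0.0, 1.0])
        return CoilPlacement(
            label="test",
            focus_point=radius * direction,
            nominal_amplitude=amplitude,
            nominal_sigma=sigma,
        )

    def test_peak_equals_amplitude_at_focus_vertex(self, small_mesh):
        p = self.placement()
        emap = simulate_efield(small_mesh, p, IDENTITY_PARAMS)
        assert emap.values.max() == pytest.approx(p.nominal_amplitude)
        focus_vertex = int(np.argmax(emap.values))
        d = np.linalg.norm(small_mesh.vertices[focus_vertex] - p.focus_point)
        assert d <= 2.0  # nearest-vertex projection at level-2 resolution

    def test_isocontour_closed_form(self, small_mesh):
        p = self.placement()
        emap = simulate_efield(small_mesh, p, IDENTITY_PARAMS)
        r09 = seed_radius_mm(p.nominal_amplitude, p.nominal_sigma, 0.9)
        assert r09 == pytest.approx(
            p.nominal_sigma * np.sqrt(2 * np.log(p.nominal_amplitude / 0.9))
        )
        c = small_mesh.vertices[int(np.argmax(emap.values))]
        d = np.linalg.norm(small_mesh.vertices - c, axis=1)
        supra = emap.values >= 0.9
        assert d[supra].max() <= r09 + 1e-9
        assert (d[~supra] > r09 - 1e-9).all()

    def test_decreases_with_distance_from_focus(self, small_mesh):
        emap = simulate_efield(small_mesh, self.placement(), IDENTITY_PARAMS)
        c = small_mesh.vertices[int(np.argmax(emap.values))]
        d = np.linalg.norm(small_mesh.vertices - c, axis=1)
        order = np.argsort(d)
        assert (np.diff(emap.values[order]) <= 1e-12).all()

    def test_weak_field_logs_warning(self, small_mesh, caplog):
        p = self.placement(amplitude=0.5)
        with caplog.at_level("WARNING"):
            simulate_efield(small_mesh, p, IDENTITY_PARAMS)
        assert "seed may be empty" in caplog.text

    def test_far_focus_rejected(self, small_mesh):
        p = CoilPlacement(
            label="far", focus_point=[100, 0, 0],
            nominal_amplitude=1.5, nominal_sigma=2.0,
        )
        with pytest.raises(ValueError, match="too far"):
            simulate_efield(small_mesh, p, IDENTITY_PARAMS)


def fc_spec(**kw):
    base = dict(
        master_seed=77,
        n_subjects=2,
        mesh_subdivision=2,
        n_parcels=8,
        n_timepoints=64,
        n_runs=1,
        boundary_mixing_mm=0.0,  # pure one-network-per-vertex regime
        fc_perturbation_scale=0.0,
    )
    base.update(kw)
    return CohortSpec(**base)


class TestSubjectFC:
    def test_common_factor_limit_within_network_r_to_one(self):
        parc = eight_network_parcellation(40)
        spec = fc_spec(noise_sd=1e-6, shared_loading=0.0)
        fc = simulate_subject_fc(
            parc, spec, IDENTITY_PARAMS, np.random.default_rng(0)
        )
        codes = parc.vertex_network_codes()
        same = codes[:, None] == codes[None, :]
        off = ~np.eye(40, dtype=bool)
        assert fc.matrix[same & off].min() > 0.999

    def test_null_case_correlations_near_zero(self):
        parc = eight_network_parcellation(40)
        spec = fc_spec(within_network_loading=0.0, shared_loading=0.0,
                       n_timepoints=256)
        fc = simulate_subject_fc(
            parc, spec, IDENTITY_PARAMS, np.random.default_rng(0)
        )
        off = ~np.eye(40, dtype=bool)
        assert abs(fc.matrix[off].mean()) < 3 / np.sqrt(256)

    @pytest.mark.parametrize("wsh", [0.0, 0.4])
    def test_within_network_r_matches_factor_formula(self, wsh):
        # population r = (w^2 + w_sh^2) / (w^2 + w_sh^2 + sd^2); with no
        # shared signal this is the plain one-factor w^2/(w^2 + sd^2)
        parc = eight_network_parcellation(64)
        w, sd = 0.8, 0.6
        spec = fc_spec(
            within_network_loading=w, shared_loading=wsh, noise_sd=sd,
            n_timepoints=500,
        )
        fc = simulate_subject_fc(
            parc, spec, IDENTITY_PARAMS, np.random.default_rng(3)
        )
        expected = (w**2 + wsh**2) / (w**2 + wsh**2 + sd**2)
        codes = parc.vertex_network_codes()
        same = codes[:, None] == codes[None, :]
        off = ~np.eye(64, dtype=bool)
        assert fc.matrix[same & off].mean() == pytest.approx(expected, abs=0.05)

    def test_connectome_invariants(self):
        parc = eight_network_parcellation(50)
        spec = fc_spec(boundary_mixing_mm=0.0, fc_perturbation_scale=0.2,
                       n_runs=3)
        fc = simulate_subject_fc(
            parc, spec, SubjectParams(fc_perturbation_scale=0.2),
            np.random.default_rng(4),
        )
        m = fc.matrix
        assert np.abs(m - m.T).max() < 1e-12
        assert (np.diagonal(m) == 1.0).all()
        assert np.linalg.eigvalsh(m).min() >= -1e-8

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(ValueError):
            fc_spec(n_timepoints=3, n_parcels=8)


class TestCohort:
    def test_same_master_seed_identical_bundle(self):
        spec = fc_spec(n_subjects=3, fc_perturbation_scale=0.1)
        a, b = generate_cohort(spec), generate_cohort(spec)
        assert np.array_equal(a.mesh.vertices, b.mesh.vertices)
        assert np.array_equal(
            a.parcellation.vertex_parcel, b.parcellation.vertex_parcel
        )
        for s in range(3):
            ea = a.subject_efield(s, "dlpfc").values
            eb = b.subject_efield(s, "dlpfc").values
            assert np.array_equal(ea, eb)
            assert np.array_equal(a.subject_fc(s).matrix, b.subject_fc(s).matrix)

    def test_zero_variability_degenerates_to_template(self):
        spec = fc_spec(
            n_subjects=3,
            amplitude_spread=0.0,
            sigma_spread=0.0,
            focus_jitter_sd=0.0,
        )
        cohort = generate_cohort(spec)
        template = cohort.template_efield("ofc").values
        for s in range(3):
            assert np.array_equal(cohort.subject_efield(s, "ofc").values, template)

    def test_distinct_subjects_distinct_streams(self):
        spec = CohortSpec(master_seed=5, n_subjects=4, mesh_subdivision=2,
                          n_timepoints=64)
        params = [draw_subject_params(spec, s) for s in range(4)]
        factors = {p.amplitude_factor for p in params}
        assert len(factors) == 4  # no shared stream

    def test_default_cohort_nonempty_seeds_both_targets(self):
        # packaged defaults, subset of subjects for speed
        spec = CohortSpec(master_seed=42, n_subjects=40)
        cohort = generate_cohort(spec)
        for s in list(cohort.subject_ids)[::5]:
            for target in ("dlpfc", "ofc"):
                emap = cohort.subject_efield(s, target)
                seed = extract_seed(emap, cohort.mesh, 0.9)
                assert seed.n_vertices >= 1

    def test_membership_profile_sums_to_100(self, small_cohort):
        seed = extract_seed(
            small_cohort.subject_efield(0, "dlpfc"), small_cohort.mesh
        )
        prof = membership_profile(small_cohort.parcellation, seed)
        assert prof.percent.sum() == pytest.approx(100.0)

    def test_default_placement_calibration_areas(self):
        """Thresholded template areas sit in the study-like mm^2 range."""
        mesh = build_template_mesh(4, 20.0)
        dlpfc, ofc = default_placements(20.0)
        a_dl = extract_seed(simulate_efield(mesh, dlpfc), mesh).area_mm2
        a_ofc = extract_seed(simulate_efield(mesh, ofc), mesh).area_mm2
        assert 30 < a_dl < 90
        assert 5 < a_ofc < 40
        assert a_dl > a_ofc
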