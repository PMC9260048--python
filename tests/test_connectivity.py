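"""Seed FC, vertex network FC, engagement profiles — against hand values
and naive double-loop oracles."""

import numpy as np
import pytest

from efnet import (
    DenseConnectome,
    EngagementProfile,
    SeedRegion,
    assign_vertices,
    average_fc_runs,
    engagement_profile,
    group_average_fc,
    most_engaged,
    seed_fc_map,
    vertex_network_fc,
)
from efnet.networks import NETWORKS

from conftest import eight_network_parcellation


def random_connectome(n, rng):
    """Random valid correlation matrix (from random time series)."""
    x = rng.standard_normal((n, n + 8))
    return DenseConnectome(np.corrcoef(x))


def make_seed(ids):
    return SeedRegion(vertex_ids=np.asarray(ids), threshold=0.9, area_mm2=1.0)


class TestFisherAveraging:
    def test_single_run_identity_up_to_clipping(self):
        fc = random_connectome(10, np.random.default_rng(0))
        out = average_fc_runs([fc])
        assert np.allclose(out.matrix, fc.matrix, atol=1e-12)

    def test_opposite_entries_cancel(self):
        a = np.eye(3)
        a[0, 1] = a[1, 0] = 0.6
        b = np.eye(3)
        b[0, 1] = b[1, 0] = -0.6
        out = average_fc_runs([DenseConnectome(a), DenseConnectome(b)])
        assert out.matrix[0, 1] == pytest.approx(0.0, abs=1e-15)

    def test_hand_fisher_mean(self):
        a = np.eye(2)
        a[0, 1] = a[1, 0] = 0.3
        b = np.eye(2)
        b[0, 1] = b[1, 0] = 0.5
        out = average_fc_runs([DenseConnectome(a), DenseConnectome(b)])
        expected = np.tanh((np.arctanh(0.3) + np.arctanh(0.5)) / 2)
        assert out.matrix[0, 1] == pytest.approx(expected)
        assert expected == pytest.approx(0.40479, abs=5e-5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            average_fc_runs(
                [random_connectome(4, np.random.default_rng(0)),
                 random_connectome(5, np.random.default_rng(1))]
            )

    def test_group_idempotent_on_identical_subjects(self):
        fc = random_connectome(8, np.random.default_rng(2))
        out = group_average_fc([fc, fc, fc])
        assert np.allclose(out.matrix, fc.matrix, atol=1e-12)

    def test_group_commutes_with_subject_order(self):
        rng = np.random.default_rng(3)
        subs = [random_connectome(6, rng) for _ in range(4)]
        a = group_average_fc(subs).matrix
        b = group_average_fc(subs[::-1]).matrix
        assert np.allclose(a, b, atol=1e-15)

    def test_three_subject_hand_value(self):
        mats = []
        for r in (0.1, 0.2, 0.3):
            m = np.eye(2)
            m[0, 1] = m[1, 0] = r
            mats.append(DenseConnectome(m))
        out = group_average_fc(mats)
        expected = np.tanh(np.mean(np.arctanh([0.1, 0.2, 0.3])))
        assert out.matrix[0, 1] == pytest.approx(expected)
        assert expected == pytest.approx(0.20140, abs=5e-5)


class TestSeedFCMap:
    def test_two_vertex_seed_hand_mean(self):
        m = np.array([[1, 0.5, 0.2], [0.5, 1, 0.4], [0.2, 0.4, 1]])
        fc_map = seed_fc_map(DenseConnectome(m), make_seed([0, 1]))
        assert fc_map.values[2] == pytest.approx(0.3)

    def test_singleton_seed_is_matrix_row(self):
        fc = random_connectome(7, np.random.default_rng(4))
        fc_map = seed_fc_map(fc, make_seed([3]))
        assert np.allclose(fc_map.values, fc.matrix[3])

    def test_seed_vertices_included_with_self_correlation(self):
        m = np.array([[1, 0.5, 0.2], [0.5, 1, 0.4], [0.2, 0.4, 1]])
        fc_map = seed_fc_map(DenseConnectome(m), make_seed([0, 1]))
        assert fc_map.values[0] == pytest.approx(0.75)  # (1 + .5)/2

    def test_mask_seed_for_display(self):
        fc = random_connectome(5, np.random.default_rng(5))
        fc_map = seed_fc_map(fc, make_seed([1, 2]))
        masked = fc_map.mask_seed()
        assert np.isnan(masked[[1, 2]]).all()
        assert np.isfinite(np.delete(masked, [1, 2])).all()

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(6)
        fc = random_connectome(30, rng)
        ids = np.sort(rng.choice(30, 9, replace=False))
        fc_map = seed_fc_map(fc, make_seed(ids))
        for j in range(30):
            naive = sum(fc.matrix[i, j] for i in ids) / len(ids)
            assert fc_map.values[j] == pytest.approx(naive, abs=1e-12)


class TestVertexNetworkFC:
    def test_hand_means_with_self_exclusion(self):
        # labels A A B B; row of vertex 0 = [1, .6, .2, .4]
        m = np.eye(4)
        m[0, 1:] = m[1:, 0] = [0.6, 0.2, 0.4]
        m[1, 2] = m[2, 1] = 0.1
        m[1, 3] = m[3, 1] = 0.1
        m[2, 3] = m[3, 2] = 0.1
        from efnet import Parcellation

        # vertices 0,1 share network 0 ("A"); 2,3 share network 1 ("B")
        parc = Parcellation(
            vertex_parcel=np.array([0, 0, 1, 1, 2, 3, 4, 5, 6, 7]),
            parcel_network={i: NETWORKS[i] for i in range(8)},
        )
        big = np.eye(10)
        big[:4, :4] = m
        fc = DenseConnectome(big)
        vals = vertex_network_fc(fc, 0, parc)
        assert vals[0] == pytest.approx(0.6)  # own network, self excluded
        assert vals[1] == pytest.approx(0.3)  # mean of .2, .4

    def test_zero_row_gives_zeros(self):
        fc = DenseConnectome(np.eye(16))
        parc = eight_network_parcellation(16)
        vals = vertex_network_fc(fc, 0, parc)
        assert np.allclose(np.delete(vals, 0), 0.0)

    def test_constant_off_diagonal_row(self):
        c = 0.37
        m = np.full((16, 16), c)
        np.fill_diagonal(m, 1.0)
        fc = DenseConnectome(m)
        parc = eight_network_parcellation(16)
        vals = vertex_network_fc(fc, 5, parc)
        assert np.allclose(vals, c)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(8)
        fc = random_connectome(40, rng)
        parc = eight_network_parcellation(40, rng)
        codes = parc.vertex_network_codes()
        for vertex in (0, 17, 39):
            vals = vertex_network_fc(fc, vertex, parc)
            for n in range(8):
                js = [j for j in range(40) if codes[j] == n and j != vertex]
                naive = sum(fc.matrix[vertex, j] for j in js) / len(js)
                assert vals[n] == pytest.approx(naive, abs=1e-12)


class TestAssignmentsAndProfiles:
    def test_argmax_assignment(self):
        rng = np.random.default_rng(9)
        fc = random_connectome(32, rng)
        parc = eight_network_parcellation(32, rng)
        seed = make_seed(np.arange(0, 32, 5))
        got = assign_vertices(fc, seed, parc)
        for a, v in zip(got, seed.vertex_ids):
            expected = int(np.argmax(vertex_network_fc(fc, int(v), parc)))
            assert a == expected

    def test_tie_breaks_to_earlier_network(self):
        profile = EngagementProfile(
            percent=np.array([0, 0, 0, 50, 0, 50, 0, 0.0]), n_seed_vertices=4
        )
        assert most_engaged(profile) == "VAN"  # VAN before FPN in fixed order

    def test_profile_counting(self):
        van, fpn = NETWORKS.index("VAN"), NETWORKS.index("FPN")
        prof = engagement_profile([van, van, fpn, van])
        assert prof.as_dict()["VAN"] == 75.0
        assert prof.as_dict()["FPN"] == 25.0
        assert prof.percent.sum() == pytest.approx(100.0)

    def test_uniform_assignment(self):
        prof = engagement_profile(list(range(8)))
        assert np.allclose(prof.percent, 12.5)

    def test_empty_assignments_rejected(self):
        with pytest.raises(ValueError):
            engagement_profile([])

    def test_profiles_invariant_to_parcel_relabeling(self):
        from efnet import Parcellation

        rng = np.random.default_rng(10)
        fc = random_connectome(32, rng)
        parc = eight_network_parcellation(32, rng)
        seed = make_seed(np.arange(10))
        base = engagement_profile(assign_vertices(fc, seed, parc))
        # split each parcel into two ids mapping to the same network
        doubled = Parcellation(
            vertex_parcel=parc.vertex_parcel * 2
            + (np.arange(32) % 2).astype(np.int64) * 1,
            parcel_network={
                2 * p + b: net
                for p, net in parc.parcel_network.items()
                for b in (0, 1)
            },
        )
        relabeled = engagement_profile(assign_vertices(fc, seed, doubled))
        assert np.array_equal(base.percent, relabeled.percent)
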