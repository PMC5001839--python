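import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from chromokin.excitons import (
    ExcitonBasis,
    ExcitonParameters,
    dipole_coupling,
    exciton_states,
    neighbor_graph,
    pairwise_rates,
    site_hamiltonian,
    spectral_overlap,
    transfer_rate,
)
from chromokin.geometry import (
    ClusterType,
    Pigment,
    PigmentClass,
    PigmentCluster,
    rotate_vesicle,
)

PARAMS = ExcitonParameters()


def _pigment(mg, dipole, cluster="X", pclass=PigmentClass.B875, index=0):
    dipole = np.asarray(dipole, dtype=float)
    dipole = dipole / np.linalg.norm(dipole)
    mg = np.asarray(mg, dtype=float)
    return Pigment(
        cluster_id=cluster,
        pigment_class=pclass,
        ring_index=index,
        mg_position=mg,
        nb_position=mg - dipole,
        nd_position=mg + dipole,
    )


class TestDipoleCoupling:
    def test_parallel_perpendicular_to_separation(self):
        p1 = _pigment([0, 0, 0], [0, 0, 1])
        p2 = _pigment([10, 0, 0], [0, 0, 1])
        assert dipole_coupling(p1, p2) == pytest.approx(348.0)

    def test_head_to_tail(self):
        p1 = _pigment([0, 0, 0], [1, 0, 0])
        p2 = _pigment([10, 0, 0], [1, 0, 0])
        assert dipole_coupling(p1, p2) == pytest.approx(-696.0)

    def test_orthogonal_vanishes(self):
        p1 = _pigment([0, 0, 0], [1, 0, 0])  # parallel to r
        p2 = _pigment([10, 0, 0], [0, 1, 0])  # perpendicular to r and to d1
        assert dipole_coupling(p1, p2) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric(self, rng):
        p1 = _pigment(rng.normal(size=3), rng.normal(size=3))
        p2 = _pigment(rng.normal(size=3) + 20, rng.normal(size=3))
        assert dipole_coupling(p1, p2) == pytest.approx(dipole_coupling(p2, p1))

    @given(st.floats(5.0, 200.0))
    def test_inverse_cube_scaling(self, r):
        p1 = _pigment([0, 0, 0], [0, 0, 1])
        near = _pigment([r, 0, 0], [0, 0, 1])
        far = _pigment([2 * r, 0, 0], [0, 0, 1])
        assert dipole_coupling(p1, far) == pytest.approx(dipole_coupling(p1, near) / 8.0, rel=1e-12)

    def test_zero_separation_error(self):
        p1 = _pigment([0, 0, 0], [0, 0, 1])
        p2 = _pigment([0, 0, 0], [0, 1, 0])
        with pytest.raises(ValueError, match="coincident"):
            dipole_coupling(p1, p2)


class TestSiteHamiltonian:
    def test_lh2_trace(self, reference_vesicle):
        lh2 = reference_vesicle.clusters_of(ClusterType.LH2)[0]
        H = site_hamiltonian(lh2, PARAMS)
        assert H.shape == (18, 18)
        assert np.trace(H) == pytest.approx(9 * (12459 + 12625))

    def test_lh2_nearest_neighbor_alternation(self, reference_vesicle):
        lh2 = reference_vesicle.clusters_of(ClusterType.LH2)[0]
        H = site_hamiltonian(lh2, PARAMS)
        assert H[0, 1] == pytest.approx(363.0)
        assert H[1, 2] == pytest.approx(320.0)
        assert H[17, 0] == pytest.approx(320.0)

    def test_lh1_nearest_neighbor_alternation(self, reference_vesicle):
        lh1 = reference_vesicle.clusters_of(ClusterType.LH1)[0]
        H = site_hamiltonian(lh1, PARAMS)
        assert H.shape == (28, 28)
        assert H[0, 1] == pytest.approx(806.0)
        assert H[1, 2] == pytest.approx(377.0)
        np.testing.assert_allclose(np.diag(H), 12344.0)

    def test_rc_special_pair(self, reference_vesicle):
        rc = reference_vesicle.clusters_of(ClusterType.RC)[0]
        H = site_hamiltonian(rc, PARAMS)
        assert H.shape == (4, 4)
        assert H[0, 1] == pytest.approx(500.0)
        assert np.diag(H).tolist() == [12092.0, 12092.0, 12581.0, 12581.0]

    def test_symmetry(self, reference_vesicle):
        for cluster in reference_vesicle.clusters[:5]:
            H = site_hamiltonian(cluster, PARAMS)
            np.testing.assert_allclose(H, H.T)

    def test_odd_ring_rejected(self):
        pigments = [
            _pigment([math.cos(a), math.sin(a), 0], [1, 0, 0], cluster="odd",
                     pclass=PigmentClass.B875, index=i)
            for i, a in enumerate(np.linspace(0, 2 * math.pi, 5, endpoint=False))
        ]
        cluster = PigmentCluster("odd", ClusterType.LH1, pigments)
        with pytest.raises(ValueError, match="odd ring length"):
            site_hamiltonian(cluster, PARAMS)

    def test_two_pigment_closed_form(self):
        # eigenvalues of [[E, V], [V, E]] are E +/- V
        E, V = 12000.0, 250.0
        H = np.array([[E, V], [V, E]])
        basis = exciton_states(H, PARAMS)
        np.testing.assert_allclose(basis.energies, [E - V, E + V])


class TestExcitonStates:
    def test_diagonal_hamiltonian(self):
        H = np.diag([3.0, 1.0, 2.0])
        basis = exciton_states(H, PARAMS)
        np.testing.assert_allclose(basis.energies, [1.0, 2.0, 3.0])
        np.testing.assert_allclose(np.abs(basis.coefficients), np.eye(3)[:, [1, 2, 0]], atol=1e-12)

    def test_equal_energies_uniform_weights(self):
        basis = exciton_states(np.diag([5.0, 5.0, 5.0, 5.0]), PARAMS)
        np.testing.assert_allclose(basis.boltzmann_weights, 0.25)

    def test_orthonormal_coefficients(self, reference_vesicle):
        lh1 = reference_vesicle.clusters_of(ClusterType.LH1)[0]
        basis = exciton_states(site_hamiltonian(lh1, PARAMS), PARAMS)
        np.testing.assert_allclose(basis.coefficients @ basis.coefficients.T, np.eye(28), atol=1e-10)

    def test_weights_normalized_and_ordered(self, reference_vesicle):
        lh2 = reference_vesicle.clusters_of(ClusterType.LH2)[0]
        basis = exciton_states(site_hamiltonian(lh2, PARAMS), PARAMS)
        assert basis.boltzmann_weights.sum() == pytest.approx(1.0)
        assert np.all(np.diff(basis.boltzmann_weights) <= 1e-15)
        assert np.all(np.diff(basis.energies) >= 0)

    def test_lowest_exciton_below_site_energies(self, reference_vesicle):
        lh2 = reference_vesicle.clusters_of(ClusterType.LH2)[0]
        basis = exciton_states(site_hamiltonian(lh2, PARAMS), PARAMS)
        assert basis.energies[0] < 12459.0

    def test_four_ring_closed_form(self):
        # alternating ring of four sites: exact eigenvalues from the 2x2
        # Bloch blocks are mean +/- sqrt(delta^2 + (v1 +/- v2)^2)
        e1, e2, v1, v2 = 12459.0, 12625.0, 363.0, 320.0
        H = np.array(
            [
                [e1, v1, 0, v2],
                [v1, e2, v2, 0],
                [0, v2, e1, v1],
                [v2, 0, v1, e2],
            ]
        )
        mean, delta = (e1 + e2) / 2, (e1 - e2) / 2
        expected = sorted(
            mean + s * math.hypot(delta, v) for s in (1, -1) for v in (v1 + v2, v1 - v2)
        )
        np.testing.assert_allclose(exciton_states(H, PARAMS).energies, expected)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            exciton_states(np.array([[1.0, 2.0], [3.0, 4.0]]), PARAMS)


class TestSpectralOverlap:
    def test_equal_energies_closed_form(self):
        value = spectral_overlap(12500.0, 12500.0, 188.0, 188.0)
        assert value == pytest.approx(1.0 / (2 * 188.0 * math.sqrt(math.pi)), rel=1e-12)
        assert value == pytest.approx(1.5005e-3, rel=1e-3)

    def test_vanishes_at_large_separation(self):
        assert spectral_overlap(12500.0, 20000.0, 188.0, 188.0) < 1e-60

    def test_symmetric_without_shift(self):
        a = spectral_overlap(12400.0, 12600.0, 188.0, 188.0, shift_s=0.0)
        b = spectral_overlap(12600.0, 12400.0, 188.0, 188.0, shift_s=0.0)
        assert a == pytest.approx(b, rel=1e-14)

    @pytest.mark.parametrize("lineshape", ["normalized", "literal"])
    @pytest.mark.parametrize("delta,sd,sa,shift", [
        (0.0, 188.0, 188.0, 0.0),
        (150.0, 188.0, 235.0, 0.0),
        (-300.0, 235.0, 235.0, 100.0),
        (500.0, 188.0, 235.0, -50.0),
    ])
    def test_matches_quadrature(self, lineshape, delta, sd, sa, shift):
        mu, nu = 12500.0 + delta, 12500.0

        if lineshape == "normalized":
            def line(E, center, sigma):
                return math.exp(-((E - center) ** 2) / (2 * sigma**2)) / (math.sqrt(2 * math.pi) * sigma)
        else:
            def line(E, center, sigma):
                return math.exp(-(((E - center) / sigma) ** 2)) / (math.sqrt(2 * math.pi) * sigma)

        numeric, _ = quad(
            lambda E: line(E, mu - shift, sd) * line(E, nu, sa), 8000, 17000, limit=300
        )
        closed = spectral_overlap(mu, nu, sd, sa, shift_s=shift, lineshape=lineshape)
        if lineshape == "literal":
            # the printed prefactor does not normalize the printed exponent;
            # our literal branch integrates the printed product exactly as is
            numeric *= 1.0  # same convention on both sides
        assert closed == pytest.approx(numeric, rel=1e-10)

    def test_bad_linewidth(self):
        with pytest.raises(ValueError):
            spectral_overlap(1.0, 1.0, -1.0, 188.0)


def _scalar_cluster(cid, ctype, mg, dipole, energy):
    p = _pigment(mg, dipole, cluster=cid, pclass=PigmentClass.B875)
    p.site_energy = energy
    return PigmentCluster(cid, ctype, [p])


def _scalar_basis(cid, energy, sigma):
    return ExcitonBasis(cid, np.array([energy]), np.eye(1), np.array([1.0]), sigma)


class TestTransferRate:
    def test_fixed_lh1_to_rc(self, reference_vesicle):
        lh1 = reference_vesicle.clusters_of(ClusterType.LH1)[0]
        rc = next(c for c in reference_vesicle.clusters_of(ClusterType.RC)
                  if c.complex_id == lh1.complex_id)
        b1 = exciton_states(site_hamiltonian(lh1, PARAMS), PARAMS, linewidth=235.0)
        b2 = exciton_states(site_hamiltonian(rc, PARAMS), PARAMS, linewidth=235.0)
        assert transfer_rate(lh1, rc, b1, b2, PARAMS) == pytest.approx(1 / 35e-12)
        assert transfer_rate(rc, lh1, b2, b1, PARAMS) == pytest.approx(1 / 8e-12)

    def test_scalar_case_hand_formula(self):
        d1 = _scalar_cluster("a", ClusterType.LH2, [0, 0, 0], [0, 0, 1], 12500.0)
        d2 = _scalar_cluster("b", ClusterType.LH2, [20, 0, 0], [0, 0, 1], 12500.0)
        b1 = _scalar_basis("a", 12500.0, 188.0)
        b2 = _scalar_basis("b", 12500.0, 188.0)
        V = 348000.0 / 20**3
        J = 1.0 / (2 * 188.0 * math.sqrt(math.pi))
        expected = 2 * math.pi / 5.3088e-12 * V**2 * J
        assert transfer_rate(d1, d2, b1, b2, PARAMS) == pytest.approx(expected, rel=1e-12)

    def test_detailed_balance_equal_energies(self):
        d1 = _scalar_cluster("a", ClusterType.LH2, [0, 0, 0], [0, 1, 1], 12500.0)
        d2 = _scalar_cluster("b", ClusterType.LH2, [25, 3, 0], [1, 0, 1], 12500.0)
        b1 = _scalar_basis("a", 12500.0, 188.0)
        b2 = _scalar_basis("b", 12500.0, 188.0)
        k12 = transfer_rate(d1, d2, b1, b2, PARAMS)
        k21 = transfer_rate(d2, d1, b2, b1, PARAMS)
        assert k12 == pytest.approx(k21, rel=1e-12)

    def test_same_cluster_rejected(self, reference_vesicle):
        lh2 = reference_vesicle.clusters_of(ClusterType.LH2)[0]
        basis = exciton_states(site_hamiltonian(lh2, PARAMS), PARAMS)
        with pytest.raises(ValueError, match="distinct"):
            transfer_rate(lh2, lh2, basis, basis, PARAMS)


class TestNeighborGraph:
    def test_far_apart_no_edge(self, mini_vesicle):
        shifted = rotate_vesicle(mini_vesicle, np.eye(3), translation=np.array([1e4, 0, 0]))
        lh2_a = mini_vesicle.clusters_of(ClusterType.LH2)[0]
        lh2_b = shifted.clusters_of(ClusterType.LH2)[1]
        lh2_b.cluster_id = "LH2_far"
        for p in lh2_b.pigments:
            p.cluster_id = "LH2_far"
        import dataclasses

        model = dataclasses.replace(mini_vesicle, clusters=[lh2_a, lh2_b], n_lh2=2, n_l_dimers=0,
                                    n_dimeric=0, n_monomeric=0)
        g = neighbor_graph(model, cutoff=70.0)
        assert g.number_of_edges() == 0

    def test_symmetric(self, mini_vesicle):
        g = neighbor_graph(mini_vesicle, cutoff=70.0)
        for u, v in g.edges:
            assert g.has_edge(v, u)

    def test_every_rc_paired_with_its_lh1(self, reference_vesicle):
        g = neighbor_graph(reference_vesicle, cutoff=70.0)
        by_id = {c.cluster_id: c for c in reference_vesicle.clusters}
        for rc in reference_vesicle.clusters_of(ClusterType.RC):
            partners = [
                n for n in g.neighbors(rc.cluster_id)
                if by_id[n].cluster_type is ClusterType.LH1 and by_id[n].complex_id == rc.complex_id
            ]
            assert len(partners) == 1

    def test_bad_cutoff(self, mini_vesicle):
        with pytest.raises(ValueError):
            neighbor_graph(mini_vesicle, cutoff=0.0)


class TestRigidMotionInvariance:
    def test_rates_invariant_under_rotation_translation(self, mini_vesicle):
        from scipy.spatial.transform import Rotation

        R = Rotation.random(random_state=np.random.RandomState(42)).as_matrix()
        moved = rotate_vesicle(mini_vesicle, R, translation=np.array([123.0, -77.0, 9.0]))
        rates_a, _, _ = pairwise_rates(mini_vesicle, PARAMS)
        rates_b, _, _ = pairwise_rates(moved, PARAMS)
        assert set(rates_a) == set(rates_b)
        for key, ka in rates_a.items():
            assert rates_b[key] == pytest.approx(ka, rel=1e-8)
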