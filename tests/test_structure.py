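"""Paracrystal structure factors: in-plane lattice and vertical stack."""

import numpy as np
import pytest

import islandsas as isl
from islandsas.oracle import realize_lattice
from islandsas.structure import StackModel, island_island_sf, stack_sf


@pytest.fixture(scope="module")
def lattice():
    return isl.ParacrystalLattice2D(a=150.0, g_a=0.3)


class TestZhangRelation:
    def test_values(self):
        assert isl.zhang_g_from_eta(0.0) == 0.0
        assert isl.zhang_g_from_eta(1.0) == pytest.approx(0.294958, abs=1e-6)

    def test_monotone(self):
        eta = np.linspace(0.0, 10.0, 50)
        g = np.array([isl.zhang_g_from_eta(e) for e in eta])
        assert np.all(np.diff(g) > 0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            isl.zhang_g_from_eta(-0.1)


class TestIslandIslandSF:
    def test_tends_to_one_at_large_q(self, lattice):
        q = 10.0 / lattice.sigma_a
        assert island_island_sf(np.array([q]), lattice)[0] == pytest.approx(
            1.0, abs=1e-4
        )

    def test_large_distortion_gives_unity(self):
        lat = isl.ParacrystalLattice2D(a=150.0, g_a=3.0)
        q = np.array([0.05, 0.1, 0.3])
        assert np.allclose(island_island_sf(q, lat), 1.0, atol=1e-4)

    def test_first_peak_at_reciprocal_lattice_position(self):
        """Azimuthally averaged S_dd peaks at 4 pi / (sqrt(3) a), the first
        reciprocal-lattice shell of the hexagonal lattice."""
        lat = isl.ParacrystalLattice2D(a=150.0, g_a=0.1)
        q = np.linspace(0.02, 0.08, 1201)
        s = island_island_sf(q, lat)
        q_peak = q[np.argmax(s)]
        assert q_peak == pytest.approx(4 * np.pi / (np.sqrt(3) * 150.0), rel=0.02)

    def test_fundamental_domain_average_equals_full_circle(self, lattice):
        psi = np.linspace(0.0, 2 * np.pi, 100001)[:-1]
        for q in (0.004, 0.02, 0.05, 0.2):
            dense = island_island_sf(q, lattice, azimuth=psi).mean()
            avg = island_island_sf(np.array([q]), lattice)[0]
            assert avg == pytest.approx(dense, rel=2e-4)

    def test_nonnegative_and_real(self, lattice):
        q = np.geomspace(1e-4, 1.0, 200)
        s = island_island_sf(q, lattice)
        assert np.all(s >= 0)

    def test_forward_direction_rejected(self, lattice):
        with pytest.raises(ValueError):
            island_island_sf(0.0, lattice)

    def test_matches_finite_lattice_pair_sum(self, lattice):
        """Monte Carlo pair sum over explicit 32x32 paracrystal realizations
        agrees with the infinite-lattice formula for q >= 2 pi/(N_a a)."""
        rng = np.random.default_rng(7)
        n_a, n_real = 32, 160
        qs = np.array([0.05, 0.08, 0.12, 0.2])
        psi = np.linspace(0, 2 * np.pi, 25)[:-1]
        qvec = qs[:, None, None] * np.stack(
            [np.cos(psi), np.sin(psi)], axis=-1
        )  # (nq, npsi, 2)
        est = np.zeros((n_real, qs.size))
        for i in range(n_real):
            r = realize_lattice(lattice, n_a, rng)
            phases = np.exp(1j * np.einsum("qpk,mk->qpm", qvec, r))
            est[i] = (np.abs(phases.sum(-1)) ** 2).mean(-1) / len(r)
        mc = est.mean(0)
        err = est.std(0, ddof=1) / np.sqrt(n_real)
        ana = island_island_sf(qs, lattice)
        # the finite pair sum carries O(1/N_a) rim corrections on top of the
        # Monte Carlo error
        assert np.all(np.abs(mc - ana) < 4 * err + 0.06 * ana + 0.02)


class TestStackSF:
    def test_single_bilayer_is_unity(self):
        stack = StackModel(n_bilayers=1)
        q = np.linspace(0.01, 0.6, 50)
        assert np.allclose(stack_sf(q, stack), 1.0)

    def test_pt_peaks_at_lamellar_bragg_positions(self):
        stack = StackModel(n_bilayers=10, c=65.0, theory="PT", g_cperp=0.05,
                           poly_width=0.0)
        q = np.linspace(0.05, 0.25, 4001)
        s = stack_sf(q, stack)
        for h in (1, 2):
            q_bragg = 2 * np.pi * h / 65.0
            window = (q > q_bragg * 0.9) & (q < q_bragg * 1.1)
            q_peak = q[window][np.argmax(s[window])]
            assert q_peak == pytest.approx(q_bragg, rel=0.01)

    def test_pt_equals_direct_stack_sum(self):
        """PT closed form vs the explicit double sum over cumulative-Gaussian
        stack realizations."""
        stack = StackModel(n_bilayers=6, c=60.0, theory="PT", g_cperp=0.08,
                           poly_width=0.0)
        rng = np.random.default_rng(11)
        n_real = 10000
        qs = np.array([0.05, 0.105, 0.2])
        est = np.zeros((n_real, qs.size))
        for i in range(n_real):
            z = np.concatenate(
                ([0.0], np.cumsum(60.0 + 0.08 * 60.0 * rng.standard_normal(5)))
            )
            est[i] = np.abs(np.exp(1j * np.outer(qs, z)).sum(1)) ** 2 / 6.0
        mc, err = est.mean(0), est.std(0, ddof=1) / np.sqrt(n_real)
        ana = stack_sf(qs, stack)
        assert np.all(np.abs(mc - ana) < 4 * err)

    def test_mct_and_pt_agree_at_first_bragg_peak_via_zhang(self):
        """The Zhang relation equates the PT and MCT nearest-neighbour
        damping at q = 2 pi / c; for a two-bilayer stack (only the m = 1
        pair term) the two theories then coincide there."""
        eta1 = 0.08
        c = 65.0
        mct = StackModel(n_bilayers=2, c=c, theory="MCT", eta1=eta1,
                         poly_width=0.0)
        pt = StackModel(n_bilayers=2, c=c, theory="PT",
                        g_cperp=isl.zhang_g_from_eta(eta1), poly_width=0.0)
        q = 2 * np.pi / c
        assert stack_sf(q, mct) == pytest.approx(stack_sf(q, pt), rel=1e-3)

    def test_zhang_conversion_applied_on_construction(self):
        s = StackModel(n_bilayers=5, eta1=1.0)
        assert s.g_cperp == pytest.approx(0.294958, abs=1e-6)
        s2 = StackModel(n_bilayers=5, g_cperp=0.294958)
        assert s2.eta1 == pytest.approx(1.0, rel=1e-4)

    def test_polydispersity_weights_normalised_and_limit(self):
        stack = StackModel(n_bilayers=8, poly_width=0.3)
        ns, w = stack.n_weights()
        assert w.sum() == pytest.approx(1.0)
        assert np.all(ns >= 1)
        mono = StackModel(n_bilayers=8, poly_width=0.0)
        q = np.linspace(0.02, 0.3, 100)
        assert np.allclose(
            stack_sf(q, StackModel(n_bilayers=8, poly_width=1e-9)),
            stack_sf(q, mono),
            rtol=1e-6,
        )

    def test_polydispersity_suppresses_intrinsic_oscillations(self):
        """The monodisperse paracrystal stack factor oscillates at low q;
        a wider discrete Gaussian over N damps those oscillations."""
        q = np.linspace(0.02, 0.075, 400)  # below the first Bragg peak

        def oscillation_amplitude(width):
            s = stack_sf(q, StackModel(n_bilayers=10, c=65.0, g_cperp=0.05,
                                       poly_width=width))
            return np.abs(np.diff(s)).sum()

        amps = [oscillation_amplitude(w) for w in (0.0, 0.05, 0.15)]
        assert amps[0] > amps[1] > amps[2]

    def test_tends_to_one_at_large_q(self):
        for theory, kw in (("PT", {"g_cperp": 0.06}), ("MCT", {"eta1": 0.3})):
            stack = StackModel(n_bilayers=10, c=65.0, theory=theory, **kw)
            assert stack_sf(5.0, stack) == pytest.approx(1.0, abs=0.02)
            assert np.all(stack_sf(np.linspace(0.01, 1.0, 300), stack) >= 0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            StackModel(n_bilayers=0)
        with pytest.raises(ValueError):
            StackModel(n_bilayers=2, eta1=-1.0)
        with pytest.raises(ValueError):
            StackModel(n_bilayers=2, g_cperp=-0.1)
        with pytest.raises(ValueError):
            StackModel(n_bilayers=2, theory="XY")
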