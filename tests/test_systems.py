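"""Island archetype builders and stoichiometric relations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

import islandsas as isl
from islandsas.systems import torus_lipid_half_height, torus_segment_volumes


class TestIslandDensity:
    def test_printed_values(self):
        assert isl.island_density(1.5) == pytest.approx(0.51, abs=0.005)
        assert isl.island_density(150.0) == pytest.approx(5.132e-5, rel=1e-3)

    def test_vanishes_for_dilute_lattice(self):
        assert isl.island_density(1e9) < 1e-17

    @given(st.floats(min_value=0.1, max_value=1e4))
    @settings(max_examples=50, deadline=None)
    def test_reciprocal_of_unit_cell_area(self, a):
        n_d = isl.island_density(a)
        assert n_d * (np.sqrt(3.0) / 2.0) * a**2 == pytest.approx(1.0, rel=1e-12)


class TestDomainStoichiometry:
    def test_zero_radius_gives_zero_guest(self):
        assert isl.domain_concentration(3.0, 150.0, 0.0, 57.0, 60.0) == 0.0

    def test_reference_composition(self):
        c = isl.domain_concentration(3.0, 150.0, 60.0, 57.0, 60.0)
        assert c == pytest.approx(3.94, abs=0.005)

    def test_area_fraction_identity(self):
        """The guest area share equals the domain surface fraction
        n_d pi R1^2."""
        a, r1, a_h, a_g = 150.0, 60.0, 57.0, 60.0
        c_h = 3.0
        c_g = isl.domain_concentration(c_h, a, r1, a_h, a_g)
        share = c_g * a_g / (c_g * a_g + c_h * a_h)
        assert share == pytest.approx(
            isl.island_density(a) * np.pi * r1**2, rel=1e-12
        )

    def test_domain_diameter_bounded_by_lattice(self):
        with pytest.raises(ValueError):
            isl.domain_concentration(3.0, 150.0, 75.0, 57.0, 60.0)


class TestDomainBuilder:
    def test_reference_system_composition(self, xray):
        system = isl.build_domain_system(
            isl.DPPC, isl.DOPC, 150.0, 60.0, 0.3, 3.0, xray
        )
        concs = dict(system.concentrations)
        assert concs[3.0] == isl.DPPC.volume
        guest = [c for c, v in system.concentrations if v == isl.DOPC.volume][0]
        assert guest == pytest.approx(3.94, abs=0.005)
        assert system.island.radii == (60.0,)

    def test_lattice_exclusion_boundary(self, xray):
        isl.build_domain_system(isl.DPPC, isl.DOPC, 150.0, 74.9, 0.3, 3.0, xray)
        with pytest.raises(ValueError):
            isl.build_domain_system(isl.DPPC, isl.DOPC, 150.0, 75.0, 0.3, 3.0, xray)


class TestProteinStoichiometry:
    def test_anchored_removes_no_lipid(self):
        c = isl.protein_concentration(3.0, 150.0, np.pi * 29.01**2, xi=0.0)
        assert c == pytest.approx(3.0 * 57.0 / (np.sqrt(3.0) * 150.0**2), rel=1e-12)

    def test_transmembrane_value_by_direct_substitution(self):
        a_p = np.pi * 29.01**2
        c = isl.protein_concentration(3.0, 150.0, a_p, xi=1.0)
        assert c == pytest.approx(
            3.0 * 57.0 / (np.sqrt(3.0) * 150.0**2 - 2.0 * a_p), rel=1e-12
        )

    def test_monotone_decreasing_in_lattice_parameter(self):
        a_p = np.pi * 29.01**2
        cs = [isl.protein_concentration(3.0, a, a_p, xi=1.0)
              for a in (120.0, 150.0, 200.0, 300.0)]
        assert all(x > y for x, y in zip(cs, cs[1:]))

    def test_footprint_exhausting_cell_rejected(self):
        with pytest.raises(ValueError):
            isl.protein_concentration(3.0, 50.0, np.pi * 40.0**2, xi=1.0)


class TestTransmembraneBuilder:
    def test_bacteriorhodopsin_geometry(self, xray, dppc_profile):
        p = isl.PROTEINS["bacteriorhodopsin"]
        island = isl.build_transmembrane_protein(
            p.radius, p.delta, p.phi_i, p.phi_e, p.length, p.sld(xray),
            dppc_profile,
        )
        assert island.radii == pytest.approx((8.01, 29.01))
        prof = island.shell_profiles[0]
        assert prof.total_thickness == pytest.approx(45.5)
        assert prof.z_base == pytest.approx(-45.5 / 2.0)

    def test_half_embedding_offsets_by_quarter_length(self, xray, dppc_profile):
        p = isl.PROTEINS["atpase"]
        island = isl.build_transmembrane_protein(
            p.radius, p.delta, p.phi_i, p.phi_e, p.length, p.sld(xray),
            dppc_profile, embed="half",
        )
        assert island.shell_profiles[0].z_base == pytest.approx(-p.length / 4.0)

    def test_atpase_total_radius(self):
        assert isl.PROTEINS["atpase"].outer_radius == pytest.approx(42.8, abs=0.05)

    def test_matched_sld_gives_zero_contrast(self):
        """With phi_i = phi_e and the occupancy-mixed SLD equal to the local
        bilayer SLD, the island scatters nothing (uniform one-level host)."""
        host = isl.SLDLevelProfile((40.0,), (1.0,), (0.0, 0.0), -20.0, 0.5)
        phi = 0.4
        rho_p = (1.0 - (1 - phi) * 0.5) / phi  # mix == host level SLD
        island = isl.build_transmembrane_protein(
            10.0, 5.0, phi, phi, 40.0, rho_p, host
        )
        amp = isl.island_amplitude(island, host, 0.1, 0.05)
        assert abs(amp) < 1e-12


class TestPeripheralBuilder:
    @pytest.mark.parametrize("xi", [0.0, 0.5, 1.0])
    def test_cytochrome_c_builds_in_all_geometries(self, xi, xray, dppc_profile):
        p = isl.PROTEINS["cytochrome_c"]
        island = isl.build_peripheral_protein(p, xi, dppc_profile, xray)
        assert island.radii == pytest.approx((0.262, 15.262))
        expected_levels = {0.0: 6, 0.5: 4, 1.0: 1}[xi]
        assert island.shell_profiles[0].n_levels == expected_levels

    def test_anchored_extends_above_monotopic(self, xray, dppc_profile):
        p = isl.PROTEINS["cytochrome_c"]

        def top(island):
            prof = island.shell_profiles[0]
            return prof.z_base + prof.total_thickness

        anchored = isl.build_peripheral_protein(p, 0.0, dppc_profile, xray)
        monotopic = isl.build_peripheral_protein(p, 0.5, dppc_profile, xray)
        assert top(anchored) > top(monotopic)
        assert top(anchored) == pytest.approx(48.9 / 2.0 + p.length)

    def test_solvent_matched_anchored_protein_is_invisible(self, xray, dppc_profile):
        p = isl.PROTEINS["cytochrome_c"]
        ghost = isl.ProteinParams(
            "ghost", p.mw, p.volume, p.radius, p.delta, p.phi_i, p.phi_e,
            p.length, isl.profiles.ELECTRON_DENSITY_WATER, xray.rho_solvent,
        )
        island = isl.build_peripheral_protein(ghost, 0.0, dppc_profile, xray)
        q = np.linspace(0.01, 0.4, 30)
        amp = isl.island_amplitude(island, dppc_profile, q, q / 2.0)
        assert np.max(np.abs(amp)) < 1e-18

    def test_invalid_xi_rejected(self, xray, dppc_profile):
        with pytest.raises(ValueError):
            isl.build_peripheral_protein(
                isl.PROTEINS["cytochrome_c"], 0.3, dppc_profile, xray
            )


class TestPoreBuilder:
    def test_radii_follow_host_region_thicknesses(self, dppc_profile):
        island = isl.build_pore(20.0, dppc_profile)
        assert island.radii == pytest.approx((20.0, 32.0, 46.2))
        assert island.shell_profiles[0] is None  # water hole

    @pytest.mark.parametrize("r_w", [8.0, 20.0, 30.0])
    def test_shell_volumes_match_torus_segments(self, r_w, dppc_profile):
        """Volume-equality conditions checked against independent adaptive
        quadrature of the torus half-height profile."""
        island = isl.build_pore(r_w, dppc_profile)
        rt = dppc_profile.total_thickness / 2.0
        d1 = dppc_profile.thicknesses[0]
        (r0, r1), (_, r2) = island.shell_bounds()[1:]

        def lipid_volume(lo, hi):
            return quad(
                lambda r: 4 * np.pi * r
                * torus_lipid_half_height(np.array(r), r_w, rt)[()],
                lo, hi, limit=400,
            )[0]

        rim = island.shell_profiles[1]
        got = rim.total_thickness * np.pi * (r1**2 - r0**2)
        assert got == pytest.approx(lipid_volume(r0, r1), rel=1e-8)

        outer = island.shell_profiles[2]
        got_total = outer.total_thickness * np.pi * (r2**2 - r1**2)
        assert got_total == pytest.approx(lipid_volume(r1, r2), rel=1e-8)
        # head band: lipid within vertical distance D1 of the curved surface
        head = quad(
            lambda r: 4 * np.pi * r
            * min(d1, torus_lipid_half_height(np.array(r), r_w, rt)[()]),
            r1, r2, limit=400,
        )[0]
        got_head = 2 * outer.thicknesses[0] * np.pi * (r2**2 - r1**2)
        assert got_head == pytest.approx(head, rel=1e-8)

    def test_pore_suppresses_low_q_intensity(self, pore_system, dppc_system):
        """Below the first form-factor minimum the pore curve lies under the
        pore-free bilayer curve (X-ray contrast)."""
        q = np.linspace(0.01, 0.04, 12)
        with_pore = isl.per_bilayer_cross_section(pore_system, q)
        free = isl.per_bilayer_cross_section(dppc_system, q)
        assert np.all(with_pore < free)

    def test_excess_shrinks_continuously_with_pore_radius(self, dppc_profile):
        """Less material is displaced as R_w shrinks: the forward excess
        amplitude decreases in magnitude, continuously."""
        r_ws = (30.0, 20.0, 10.0, 3.0, 0.5)
        fwd = []
        for r_w in r_ws:
            island = isl.build_pore(r_w, dppc_profile)
            fwd.append(abs(isl.island_amplitude(island, dppc_profile, 0.0, 0.0)))
        assert all(x > y for x, y in zip(fwd, fwd[1:]))

    def test_contracts(self, dppc_profile, xray):
        with pytest.raises(ValueError):
            isl.build_pore(0.0, dppc_profile)
        single = isl.SLDLevelProfile((40.0,), (1.0,), (0.0, 0.0), -20.0, 0.0)
        with pytest.raises(ValueError):
            isl.build_pore(20.0, single)

    def test_segment_volumes_partition(self, dppc_profile):
        total, head, chain = torus_segment_volumes(32.0, 46.2, 20.0, 24.45, 12.0)
        assert total == pytest.approx(head + chain, rel=1e-12)
        assert head > 0 and chain > 0
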