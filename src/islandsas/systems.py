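"""Builders for the island archetypes and their stoichiometric relations.

Four archetypes of in-plane inhomogeneity are supported:

* lipid *domains* -- a single cylindrical shell carrying the guest lipid's
  five-level profile as excess over the host bilayer;
* *transmembrane proteins* -- two shells (core + shell of a core-shell
  cylinder) with occupancy-mixed protein/water SLDs;
* *peripheral proteins* -- anchored (xi = 0), monotopic (xi = 1/2) or
  transmembrane (xi = 1) placements of the same core-shell cylinder;
* *water pores* -- the inner surface of a torus mapped onto a three-shell
  cylinder island by volume-equality conditions.

Stoichiometry: the hexagonal lattice parameter ``a`` fixes the island surface
density ``n_d = 2/(sqrt(3) a^2)`` and thereby the guest (or protein)
concentration implied by a given host lipid concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .amplitudes import Island
from .intensity import AVOGADRO_MM_A3, MembraneSystem
from .profiles import ProbeContrast, SLDLevelProfile
from .structure import ParacrystalLattice2D, StackModel

__all__ = [
    "LipidSpecies",
    "ProteinParams",
    "DPPC",
    "DOPC",
    "PROTEINS",
    "island_density",
    "volume_fraction",
    "domain_concentration",
    "protein_concentration",
    "build_domain_system",
    "build_transmembrane_protein",
    "build_peripheral_protein",
    "build_pore",
]


@dataclass(frozen=True)
class LipidSpecies:
    """Half-profile (three regions: polar head, CH2-rich, CH3-rich) plus
    molecular area and volume of one lipid species.

    ``rho_x`` are electron densities [e/A^3], ``rho_n`` neutron SLDs in pure
    D2O [1/A^2]; region index order is head, CH2, CH3.
    """

    name: str
    area: float            # a_l [A^2]
    volume: float          # v_l [A^3]
    thicknesses: tuple[float, float, float]
    rho_x: tuple[float, float, float]
    rho_n: tuple[float, float, float]
    sigmas: tuple[float, float, float]

    def region_slds(self, probe: ProbeContrast) -> tuple[float, float, float]:
        if probe.kind == "xray":
            return tuple(float(probe.sld_from_electron_density(r)) for r in self.rho_x)
        return self.rho_n

    def bilayer_profile(self, probe: ProbeContrast) -> SLDLevelProfile:
        """Symmetric five-level bilayer (head, CH2, CH3, CH2, head) with the
        CH3 region centred on the mid-plane z = 0."""
        d1, d2, d3 = self.thicknesses
        r1, r2, r3 = self.region_slds(probe)
        s1, s2, s3 = self.sigmas
        return SLDLevelProfile(
            thicknesses=(d1, d2, d3, d2, d1),
            slds=(r1, r2, r3, r2, r1),
            sigmas=(s1, s2, s3, s3, s2, s1),
            z_base=-(d1 + d2 + d3 / 2.0),
            rho_solvent=probe.rho_solvent,
        )


DPPC = LipidSpecies(
    name="DPPC",
    area=57.0,
    volume=1140.0,
    thicknesses=(12.0, 10.7, 3.50),
    rho_x=(0.412, 0.317, 0.245),
    rho_n=(4.203e-6, -0.349e-6, -0.602e-6),
    sigmas=(2.49, 2.39, 2.01),
)

DOPC = LipidSpecies(
    name="DOPC",
    area=60.0,
    volume=1270.0,
    thicknesses=(11.9, 9.9, 5.87),
    rho_x=(0.408, 0.302, 0.264),
    rho_n=(4.294e-6, -0.265e-6, -0.446e-6),
    sigmas=(3.50, 3.48, 4.02),
)


@dataclass(frozen=True)
class ProteinParams:
    """Core-shell cylinder parameterisation of one protein.

    ``rho_x`` is the protein electron density [e/A^3], ``rho_n`` its neutron
    SLD [1/A^2]; ``phi_i``/``phi_e`` are polypeptide occupancy fractions of
    the core and shell regions, ``length`` the cylinder length L [A].
    """

    name: str
    mw: float
    volume: float          # V_p [A^3]
    radius: float          # core radius R [A]
    delta: float           # shell thickness [A]
    phi_i: float
    phi_e: float
    length: float          # L [A]
    rho_x: float
    rho_n: float

    @property
    def outer_radius(self) -> float:
        return self.radius + self.delta

    @property
    def footprint(self) -> float:
        """Area toward the xy plane, a_p = pi (R + delta)^2 [A^2]."""
        return np.pi * self.outer_radius**2

    def sld(self, probe: ProbeContrast) -> float:
        if probe.kind == "xray":
            return float(probe.sld_from_electron_density(self.rho_x))
        return self.rho_n


PROTEINS = {
    "aquaporin": ProteinParams(
        "aquaporin", 102505.0, 133006.0, 5.78, 28.6, 0.211, 0.904, 41.4,
        0.411, 2.828e-6,
    ),
    "bacteriorhodopsin": ProteinParams(
        "bacteriorhodopsin", 73690.0, 96506.0, 8.01, 21.0, 0.0195, 0.870, 45.5,
        0.411, 2.732e-6,
    ),
    "atpase": ProteinParams(
        "atpase", 109942.0, 138965.0, 18.2, 24.6, 1.00, 0.0557, 107.0,
        0.420, 3.009e-6,
    ),
    "cytochrome_c": ProteinParams(
        "cytochrome_c", 11721.0, 14839.0, 0.262, 15.0, 0.718, 0.886, 22.8,
        0.420, 3.119e-6,
    ),
}


# ---------------------------------------------------------------------------
# stoichiometry
# ---------------------------------------------------------------------------

def island_density(a: float) -> float:
    """Island surface density n_d = 2 / (sqrt(3) a^2) [1/A^2]."""
    if a <= 0:
        raise ValueError("lattice parameter must be positive")
    return 2.0 / (np.sqrt(3.0) * a**2)


def volume_fraction(
    concentrations_mm: list[float] | tuple[float, ...],
    volumes: list[float] | tuple[float, ...],
) -> float:
    """c_V = N_A sum_i C_i v_i, C in mM and v in A^3 (dimensionless)."""
    c = np.asarray(concentrations_mm, dtype=float)
    v = np.asarray(volumes, dtype=float)
    if np.any(c < 0) or np.any(v < 0):
        raise ValueError("concentrations and volumes must be nonnegative")
    return float(AVOGADRO_MM_A3 * np.sum(c * v))


def domain_concentration(
    c_host: float, a: float, r1: float, a_host: float, a_guest: float
) -> float:
    """Guest-lipid concentration implied by the unit-cell area balance.

    Per unit cell the domain occupies pi R1^2 (guest lipid) and the remainder
    (sqrt(3)/2 a^2 - pi R1^2) is host lipid; both leaflets contribute equally,
    so the leaflet factor cancels:

    C_guest = C_host (a_host / a_guest) pi R1^2 / [sqrt(3)/2 a^2 - pi R1^2].
    """
    if a <= 2.0 * r1:
        raise ValueError("lattice parameter must exceed the domain diameter")
    cell = np.sqrt(3.0) / 2.0 * a**2
    dom = np.pi * r1**2
    if cell - dom <= 0:
        raise ValueError("no host area left in the unit cell")
    return float(c_host * (a_host / a_guest) * dom / (cell - dom))


def protein_concentration(c_b: float, a: float, a_p: float, xi: float = 1.0) -> float:
    """Protein concentration C_p = C_b a_lipid / [sqrt(3) a^2 - 2 xi a_p].

    ``a_p`` is the protein footprint toward the xy plane (outer radius); the
    embedding fraction xi scales how much lipid the protein displaces
    (xi = 0: anchored, removes none; xi = 1: transmembrane).
    """
    if not 0.0 <= xi <= 1.0:
        raise ValueError("xi must lie in [0, 1]")
    denom = np.sqrt(3.0) * a**2 - 2.0 * xi * a_p
    if denom <= 0:
        raise ValueError("protein footprint exceeds the available cell area")
    return c_b * DPPC.area / denom


# ---------------------------------------------------------------------------
# lipid domains
# ---------------------------------------------------------------------------

def build_domain_system(
    host: LipidSpecies,
    guest: LipidSpecies,
    a: float,
    r1: float,
    g_a: float,
    c_host: float,
    probe: ProbeContrast,
    stack: StackModel | None = None,
) -> MembraneSystem:
    """Guest-lipid domains of radius ``r1`` in a host bilayer, on a hexagonal
    paracrystal of parameter ``a`` and distortion ``g_a``."""
    island = Island(
        radii=(r1,), shell_profiles=(guest.bilayer_profile(probe),)
    )
    lattice = ParacrystalLattice2D(a=a, g_a=g_a)
    c_guest = domain_concentration(c_host, a, r1, host.area, guest.area)
    return MembraneSystem(
        bilayer=host.bilayer_profile(probe),
        probe=probe,
        stack=stack or StackModel(),
        island=island,
        lattice=lattice,
        concentrations=((c_host, host.volume), (c_guest, guest.volume)),
    )


# ---------------------------------------------------------------------------
# proteins
# ---------------------------------------------------------------------------

def _protein_level_sld(phi: float, rho_p: float, rho_solvent: float) -> float:
    """Occupancy-mixed SLD of a protein region (rest of the space is water)."""
    if not 0.0 <= phi <= 1.0:
        raise ValueError("occupancy fraction must lie in [0, 1]")
    return phi * rho_p + (1.0 - phi) * rho_solvent


def build_transmembrane_protein(
    radius: float,
    delta: float,
    phi_i: float,
    phi_e: float,
    length: float,
    rho_p: float,
    bilayer: SLDLevelProfile,
    embed: str = "full",
) -> Island:
    """Two-shell island (core radius R, outer R + delta) for a transmembrane
    protein of length L, positioned at z = -L/2 (``embed='full'``) or
    z = -L/4 (``embed='half'``, protein half-embedded in the bilayer)."""
    if radius <= 0 or delta <= 0 or length <= 0:
        raise ValueError("R, delta and L must be positive")
    if embed not in ("full", "half"):
        raise ValueError("embed must be 'full' or 'half'")
    z0 = -length / 2.0 if embed == "full" else -length / 4.0
    rho0 = bilayer.rho_solvent
    shells = []
    for phi in (phi_i, phi_e):
        shells.append(
            SLDLevelProfile(
                thicknesses=(length,),
                slds=(_protein_level_sld(phi, rho_p, rho0),),
                sigmas=(0.0, 0.0),
                z_base=z0,
                rho_solvent=rho0,
            )
        )
    return Island(radii=(radius, radius + delta), shell_profiles=tuple(shells))


def build_peripheral_protein(
    protein: ProteinParams,
    xi: float,
    bilayer: SLDLevelProfile,
    probe: ProbeContrast,
) -> Island:
    """Core-shell protein island in anchored (xi = 0), monotopic (xi = 1/2)
    or transmembrane (xi = 1) geometry.

    Anchored: each shell keeps the five bilayer levels and adds a sixth
    protein level of thickness L sitting on the upper surface.  Monotopic:
    each shell keeps the three lower bilayer levels and the fourth level is
    the protein.  Transmembrane: single protein level at z = -L/2.
    """
    rho_p = protein.sld(probe)
    rho0 = bilayer.rho_solvent
    if xi == 1.0:
        return build_transmembrane_protein(
            protein.radius, protein.delta, protein.phi_i, protein.phi_e,
            protein.length, rho_p, bilayer, embed="full",
        )
    if bilayer.n_levels != 5:
        raise ValueError("peripheral geometries require a 5-level bilayer")
    D = bilayer.thicknesses
    rho = bilayer.slds
    sig = bilayer.sigmas
    z_top = bilayer.z_base + bilayer.total_thickness
    shells = []
    if xi == 0.0:  # anchored: bilayer + protein level above the surface
        for phi in (protein.phi_i, protein.phi_e):
            shells.append(
                SLDLevelProfile(
                    thicknesses=D + (protein.length,),
                    slds=rho + (_protein_level_sld(phi, rho_p, rho0),),
                    sigmas=sig[:5] + (sig[5], 0.0),
                    z_base=bilayer.z_base,
                    rho_solvent=rho0,
                )
            )
    elif xi == 0.5:  # monotopic: lower three bilayer levels + protein
        for phi in (protein.phi_i, protein.phi_e):
            shells.append(
                SLDLevelProfile(
                    thicknesses=D[:3] + (protein.length,),
                    slds=rho[:3] + (_protein_level_sld(phi, rho_p, rho0),),
                    sigmas=sig[:3] + (sig[3], 0.0),
                    z_base=bilayer.z_base,
                    rho_solvent=rho0,
                )
            )
    else:
        raise ValueError("xi must be one of 0, 0.5, 1")
    return Island(
        radii=(protein.radius, protein.outer_radius),
        shell_profiles=tuple(shells),
    )


# ---------------------------------------------------------------------------
# torus pores
# ---------------------------------------------------------------------------

def _sqrt_int(u: np.ndarray | float, rt: float) -> float:
    """Primitive of sqrt(rt^2 - u^2)."""
    u = np.clip(u, -rt, rt)
    return 0.5 * (u * np.sqrt(np.maximum(rt**2 - u**2, 0.0)) + rt**2 * np.arcsin(u / rt))


def _u_sqrt_int(u: np.ndarray | float, rt: float) -> float:
    """Primitive of u sqrt(rt^2 - u^2)."""
    u = np.clip(u, -rt, rt)
    return -((np.maximum(rt**2 - u**2, 0.0)) ** 1.5) / 3.0


def torus_lipid_half_height(r: np.ndarray | float, r_w: float, rt: float):
    """Half-height z_s(r) of the lipid column at radius r for a toroidal pore
    of radius ``r_w`` in a bilayer of half-thickness ``rt``.

    The pore wall is the inner surface of a torus with tube radius rt and
    centreline radius R_c = r_w + rt: lipid occupies |z| < z_s(r) with
    z_s = sqrt(rt^2 - (R_c - r)^2) for r_w <= r <= R_c, 0 inside the pore and
    rt (the flat bilayer) beyond R_c.
    """
    r = np.asarray(r, dtype=float)
    rc = r_w + rt
    inner = np.sqrt(np.maximum(rt**2 - (rc - r) ** 2, 0.0))
    return np.where(r < r_w, 0.0, np.where(r <= rc, inner, rt))


def _torus_band_volume(r1: float, r2: float, r_w: float, rt: float, cap: float) -> float:
    """Volume of lipid with |z| between max(0, z_s - cap)... specifically the
    volume integral of 2 min(cap, z_s(r)) over the annulus [r1, r2].

    ``cap = rt`` gives the total lipid volume (z_s never exceeds rt).
    Evaluated in closed form from the primitives of sqrt(rt^2 - u^2).
    """
    rc = r_w + rt
    cap = min(cap, rt)
    vol = 0.0
    # region A: r in [max(r1, r_w), min(r2, rc)] on the curved wall
    ra, rb = max(r1, r_w), min(r2, rc)
    if rb > ra:
        # z_s <= cap while (rc - r) >= sqrt(rt^2 - cap^2)
        u_cap = np.sqrt(max(rt**2 - cap**2, 0.0))
        r_star = rc - u_cap  # z_s(r_star) = cap
        # curved part: z_s < cap for r < r_star
        lo, hi = ra, min(rb, r_star)
        if hi > lo:
            # integral of 2 z_s(r) 2 pi r dr, substitute u = rc - r
            u1, u2 = rc - lo, rc - hi  # u1 > u2
            i_s = _sqrt_int(u1, rt) - _sqrt_int(u2, rt)
            i_us = _u_sqrt_int(u1, rt) - _u_sqrt_int(u2, rt)
            vol += 4.0 * np.pi * (rc * i_s - i_us)
        # capped part: min(cap, z_s) = cap for r > r_star
        lo = max(ra, r_star)
        if rb > lo:
            vol += 2.0 * cap * np.pi * (rb**2 - lo**2)
    # region B: flat bilayer beyond the torus
    if r2 > rc:
        lo = max(r1, rc)
        vol += 2.0 * cap * np.pi * (r2**2 - lo**2)
    return float(vol)


def torus_segment_volumes(r1: float, r2: float, r_w: float, rt: float, d_head: float):
    """(total, head, chain) lipid volumes in the annulus [r1, r2] of a
    toroidal pore: the head band is the lipid within vertical distance
    ``d_head`` of the curved surface (per leaflet), the chain region the rest."""
    total = _torus_band_volume(r1, r2, r_w, rt, rt)
    chain = 0.0
    if rt > d_head:
        # chain half-height is max(0, z_s - d_head): reuse the band primitive
        # via total minus the head band of thickness d_head.
        head = _torus_band_volume(r1, r2, r_w, rt, d_head)
        chain = total - head
    else:
        head = total
    return total, head, chain


def build_pore(r_w: float, bilayer: SLDLevelProfile) -> Island:
    """Map a toroidal water pore of radius ``r_w`` onto a three-shell island.

    Radii: R1 = R_w (water hole through the bilayer), R2 = R_w + D_1,
    R3 = R_w + D_1 + D_2 + D_3 (D_j the host half-profile thicknesses).  The
    rim shell carries a single level whose thickness solves the lipid-volume
    equality with the torus segment over [R1, R2]; the outer shell carries a
    symmetric head/chain/head three-level profile solving the volume
    equalities of the head band and chain core over [R2, R3].
    """
    if r_w <= 0:
        raise ValueError("pore radius must be positive")
    if bilayer.n_levels != 5:
        raise ValueError("the pore mapping requires the 5-level symmetric bilayer")
    d1, d2, d3 = bilayer.thicknesses[:3]
    rho1, rho2, rho3 = bilayer.slds[:3]
    s1, s2, _ = bilayer.sigmas[:3]
    rt = bilayer.total_thickness / 2.0
    r1_, r2_, r3_ = r_w, r_w + d1, r_w + d1 + d2 + d3

    # rim shell: one level of thickness-weighted mean bilayer SLD
    d_arr = np.asarray(bilayer.thicknesses)
    rho_mean = float(np.dot(d_arr, bilayer.slds) / d_arr.sum())
    v_tot, _, _ = torus_segment_volumes(r1_, r2_, r_w, rt, d1)
    t_rim = v_tot / (np.pi * (r2_**2 - r1_**2))
    if t_rim <= 0 or t_rim > bilayer.total_thickness:
        raise ValueError("pore radius too small for the level solving")
    rim = SLDLevelProfile(
        thicknesses=(t_rim,),
        slds=(rho_mean,),
        sigmas=(s1, s1),
        z_base=-t_rim / 2.0,
        rho_solvent=bilayer.rho_solvent,
    )

    # outer shell: symmetric head / chain / head levels
    _, v_head, v_chain = torus_segment_volumes(r2_, r3_, r_w, rt, d1)
    area = np.pi * (r3_**2 - r2_**2)
    t_head = v_head / (2.0 * area)
    t_chain = v_chain / area
    if t_head <= 0 or t_chain <= 0:
        raise ValueError("pore radius too small for the level solving")
    rho_chain = (2.0 * d2 * rho2 + d3 * rho3) / (2.0 * d2 + d3)
    outer = SLDLevelProfile(
        thicknesses=(t_head, t_chain, t_head),
        slds=(rho1, rho_chain, rho1),
        sigmas=(s1, s2, s2, s1),
        z_base=-(t_chain / 2.0 + t_head),
        rho_solvent=bilayer.rho_solvent,
    )

    return Island(radii=(r1_, r2_, r3_), shell_profiles=(None, rim, outer))
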