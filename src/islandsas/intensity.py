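"""Orientationally averaged macroscopic scattering intensity of a membrane
system.

The analytic pipeline assembles, per unit bilayer area, (i) a coherent
flat-sheet term -- the 1D transform of the laterally averaged excess SLD
profile, carrying the 2 pi / q^2 factor that results from replacing the sheet
transform by its Dirac-delta limit for an infinite plane, multiplied by the
stacking structure factor -- and (ii) a diffuse island term, the zenith and
azimuth average of the squared island amplitude weighted by the in-plane
paracrystal structure factor.  No bilayer radius R_b appears anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .amplitudes import Island, island_amplitude
from .profiles import ProbeContrast, SLDLevelProfile
from .structure import ParacrystalLattice2D, StackModel, island_island_sf, stack_sf

__all__ = [
    "AVOGADRO_MM_A3",
    "MembraneSystem",
    "ScatteringCurve",
    "per_bilayer_cross_section",
    "macroscopic_intensity",
    "bilayer_volume",
]

#: Number density [1/A^3] of a 1 mM solute: N_A * 1e-3 mol/L / (1e27 A^3/L).
AVOGADRO_MM_A3 = 6.02214076e-7

# The azimuthally averaged paracrystal factor depends only on (a, g_a) and the
# q_par grid; during a global fit it is shared between the SAXS and SANS
# curves and unchanged under perturbations of profile parameters, so a small
# memo table pays off.  Keyed by exact byte content; bounded size.
_SDD_CACHE: dict = {}
_SDD_CACHE_MAX = 32


def _cached_sdd(lattice, q_par: np.ndarray, n_azimuth: int) -> np.ndarray:
    key = (lattice.a, lattice.g_a, n_azimuth, q_par.shape, q_par.tobytes())
    hit = _SDD_CACHE.get(key)
    if hit is None:
        hit = island_island_sf(q_par, lattice, n_azimuth=n_azimuth)
        if len(_SDD_CACHE) >= _SDD_CACHE_MAX:
            _SDD_CACHE.pop(next(iter(_SDD_CACHE)))
        _SDD_CACHE[key] = hit
    return hit


@dataclass(frozen=True)
class ScatteringCurve:
    """A (q, I, sigma) scattering curve with probe metadata."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    probe: ProbeContrast | None = None
    label: str = ""
    comments: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        if q.ndim != 1 or q.size == 0:
            raise ValueError("q must be a nonempty 1D array")
        if i.shape != q.shape:
            raise ValueError("intensity and q must have equal length")
        if np.any(q <= 0):
            raise ValueError("all q values must be positive")
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "intensity", i)
        if self.sigma is not None:
            s = np.asarray(self.sigma, dtype=float)
            if s.shape != q.shape:
                raise ValueError("sigma and q must have equal length")
            if np.any(s <= 0):
                raise ValueError("uncertainties must be positive")
            object.__setattr__(self, "sigma", s)

    def __len__(self) -> int:
        return self.q.size


@dataclass(frozen=True)
class MembraneSystem:
    """A bilayer (+ optional island lattice + stack) under one probe.

    The unit of simulation and fitting.  ``concentrations`` holds
    (molar concentration [mM], molecular volume [A^3]) pairs of every species
    in solution, from which the scattering-matter volume fraction c_V follows.
    """

    bilayer: SLDLevelProfile
    probe: ProbeContrast
    stack: StackModel = field(default_factory=StackModel)
    island: Island | None = None
    lattice: ParacrystalLattice2D | None = None
    concentrations: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if (self.island is None) != (self.lattice is None):
            raise ValueError("island and lattice must be given together")
        if self.island is not None:
            self.lattice.validate_against(self.island.r_max)

    @property
    def n_d(self) -> float:
        """Island surface density [1/A^2] (0 for an island-free bilayer)."""
        return 0.0 if self.lattice is None else self.lattice.density

    @property
    def volume_fraction(self) -> float:
        """c_V = N_A sum_i C_i v_i (dimensionless)."""
        return float(
            sum(AVOGADRO_MM_A3 * c * v for c, v in self.concentrations)
        )


def bilayer_volume(system: MembraneSystem) -> float:
    """Volume of the bilayer-with-islands per unit area [A].

    Combines the island-free bilayer thickness with the cylindrical-shell
    thicknesses weighted by the island surface density; a water pore removes
    material, an anchored protein adds it.
    """
    t_b = system.bilayer.total_thickness
    if system.island is None:
        return t_b
    t = t_b
    for area, prof in zip(
        system.island.shell_areas(), system.island.shell_profiles
    ):
        t_k = 0.0 if prof is None else prof.total_thickness
        t += system.n_d * area * (t_k - t_b)
    return t


def _mean_island_amplitude(system: MembraneSystem, q: np.ndarray) -> np.ndarray:
    """sum_k A_k(q) pi (R_k^2 - R_{k-1}^2): the q_par -> 0 island amplitude."""
    island = system.island
    amps = island.shell_excess_amplitudes(system.bilayer, q)
    total = np.zeros(q.shape, dtype=complex)
    for area, a_k in zip(island.shell_areas(), amps):
        total = total + area * a_k
    return total


def per_bilayer_cross_section(
    system: MembraneSystem,
    q: float | np.ndarray,
    n_zenith: int = 64,
    n_azimuth: int = 16,
) -> np.ndarray:
    """Reduced (per unit bilayer area, dimensionless) cross section.

    Sigma(q) = (2 pi / q^2) S_stack(q) |A_b(q) + n_d A_I(q, q_par=0)|^2
             + n_d < |A_I(q cos b, q sin b)|^2 S_dd(q sin b, psi) >_{b,psi}

    The zenith average is a Gauss-Legendre rule in the zenith angle beta on
    the open interval (0, pi/2) -- the singular forward direction q_par = 0
    is never a node -- and the azimuth average is delegated to
    :func:`islandsas.structure.island_island_sf` (composite rule over the
    paracrystal's fundamental azimuthal domain); ``n_azimuth`` is its
    per-segment node count.
    """
    q = np.asarray(q, dtype=float)
    scalar = q.ndim == 0
    q = np.atleast_1d(q)
    if np.any(q <= 0):
        raise ValueError("q must be positive")

    a_sheet = system.bilayer.excess_amplitude(q)
    if system.island is not None:
        a_sheet = a_sheet + system.n_d * _mean_island_amplitude(system, q)
    total = (2.0 * np.pi / q**2) * stack_sf(q, system.stack) * np.abs(a_sheet) ** 2

    if system.island is not None:
        # Gauss-Legendre in the zenith angle itself: the azimuthally averaged
        # paracrystal factor grows like 1/q_par toward the forward direction
        # (an integrable endpoint singularity in cos beta, but smooth in beta
        # once weighted by sin beta d beta).
        x, w = np.polynomial.legendre.leggauss(n_zenith)
        beta = 0.25 * np.pi * (x + 1.0)  # (0, pi/2)
        mu = np.cos(beta)
        wmu = 0.25 * np.pi * w * np.sin(beta)
        s = np.sqrt(1.0 - mu**2)
        q_perp = q[:, None] * mu[None, :]          # (nq, nz)
        q_par = q[:, None] * s[None, :]
        amp2 = np.abs(
            island_amplitude(system.island, system.bilayer, q_perp, q_par)
        ) ** 2                                      # (nq, nz)
        sdd = _cached_sdd(system.lattice, q_par, n_azimuth)
        diffuse = (amp2 * sdd) @ wmu
        total = total + system.n_d * diffuse

    return total[0] if scalar else total


def macroscopic_intensity(
    system: MembraneSystem,
    q: float | np.ndarray,
    kappa: float = 1.0,
    background: float = 0.0,
    n_zenith: int = 64,
    n_azimuth: int = 16,
) -> np.ndarray:
    """Macroscopic differential scattering cross section [1/A].

    I(q) = kappa (c_V / t) Sigma(q) + B, with t the bilayer volume per unit
    area, so the bilayer radius never enters.  Multiply by 1e8 for 1/cm.
    """
    if kappa <= 0:
        raise ValueError("scale factor kappa must be positive")
    if background < 0:
        raise ValueError("flat background must be nonnegative")
    cross = per_bilayer_cross_section(system, q, n_zenith, n_azimuth)
    return (
        kappa * system.volume_fraction / bilayer_volume(system) * cross
        + background
    )
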