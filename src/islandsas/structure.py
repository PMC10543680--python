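"""Paracrystal structure factors: in-plane island lattice and vertical stack.

In-plane order is a distorted 2D hexagonal lattice (paracrystal) with lattice
parameter ``a`` and distortion ``g_a = sigma_a / a``; the infinite-lattice
interference function factorises over the two unit-cell directions.  Vertical
order is a 1D stack of ``N`` bilayers described either by paracrystal theory
(PT, Gaussian spacing disorder) or by the modified Caille theory (MCT,
thermal bending fluctuations parameterised by eta_1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ParacrystalLattice2D",
    "StackModel",
    "island_island_sf",
    "stack_sf",
    "zhang_g_from_eta",
]

_EULER_GAMMA = float(np.euler_gamma)


def zhang_g_from_eta(eta1: float) -> float:
    """Vertical distortion factor implied by the Caille parameter.

    g_cperp = (0.087 eta_1)^(1/2); the constant 0.087 is
    (gamma + ln pi) / (2 pi^2), which makes the PT and MCT nearest-neighbour
    damping agree at the first lamellar Bragg position.
    """
    if eta1 < 0:
        raise ValueError("eta1 must be nonnegative")
    return float(np.sqrt(0.087 * eta1))


@dataclass(frozen=True)
class ParacrystalLattice2D:
    """Distorted 2D hexagonal lattice of islands.

    ``a`` is the average island-island distance (unit-cell vectors at 60
    degrees, unit-cell area sqrt(3)/2 a^2); ``g_a`` the relative Gaussian
    distortion (sigma_a = g_a a).  ``n_a`` is the average number of islands
    per lattice direction, used only by finite-lattice diagnostics.
    """

    a: float
    g_a: float
    n_a: int = 0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("lattice parameter a must be positive")
        if self.g_a < 0:
            raise ValueError("distortion factor g_a must be nonnegative")

    @property
    def sigma_a(self) -> float:
        return self.g_a * self.a

    @property
    def cell_area(self) -> float:
        return np.sqrt(3.0) / 2.0 * self.a**2

    @property
    def density(self) -> float:
        """Island surface density n_d = 2 / (sqrt(3) a^2) [1/A^2]."""
        return 1.0 / self.cell_area

    def unit_vectors(self) -> np.ndarray:
        """Unit-cell vectors a1, a2 (rows), at 60 degrees."""
        return self.a * np.array([[1.0, 0.0], [0.5, np.sqrt(3.0) / 2.0]])

    def validate_against(self, r_max: float) -> None:
        """Enforce the exclusion a > 2 R_max (islands cannot interpenetrate)."""
        if self.a <= 2.0 * r_max:
            raise ValueError(
                f"lattice parameter a = {self.a} must exceed twice the island "
                f"radius R_max = {r_max}"
            )


def _direction_factor(u: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Re[(1 + Phi)/(1 - Phi)] for Phi = exp(-x) exp(i u), the infinite
    1D-paracrystal interference function along one lattice direction.

    ``x = q_par^2 sigma_a^2 / 2`` is the damping exponent; written with
    expm1 so the factor stays accurate for arbitrarily small q_par.
    """
    one_minus = -np.expm1(-x)                  # 1 - eps, exact for tiny x
    eps = np.exp(-x)
    den = one_minus**2 + 4.0 * eps * np.sin(0.5 * u) ** 2
    return one_minus * (1.0 + eps) / den


def island_island_sf(
    q_par: float | np.ndarray,
    lattice: ParacrystalLattice2D,
    azimuth: float | np.ndarray | None = None,
    n_azimuth: int = 32,
) -> np.ndarray:
    """Infinite-paracrystal island-island structure factor S_dd.

    For a fixed azimuth ``psi`` this is the product over the two lattice
    directions of Re[(1 + Phi_k)/(1 - Phi_k)] with
    Phi_k = exp(i q_par a_k . u_hat - q_par^2 sigma_a^2 / 2).

    With ``azimuth=None`` the value is azimuthally averaged.  The product
    form is invariant under inversion and under the reflection swapping the
    two growth axes (psi -> pi/3 - psi) -- but *not* under the full sixfold
    rotation, because the paracrystal's growth directions a1, a2 are special.
    The fundamental azimuthal domain is therefore [pi/6, 2pi/3], and the
    average uses a composite Gauss-Legendre rule with a Lorentzian-stretched
    window around psi = pi/2, where the factor of the direction perpendicular
    to the probe develops a narrow ridge at small q_par (long-wavelength
    sliding of lattice rows).

    ``q_par = 0`` is rejected: the forward direction is handled analytically
    by the intensity assembly.
    """
    q = np.asarray(q_par, dtype=float)
    if np.any(q <= 0):
        raise ValueError("q_par must be positive")
    sig = lattice.sigma_a
    x_damp = 0.5 * q**2 * sig**2
    if azimuth is not None:
        psi = np.asarray(azimuth, dtype=float)
        u1 = q * lattice.a * np.cos(psi)
        u2 = q * lattice.a * np.cos(psi - np.pi / 3.0)
        return _direction_factor(u1, x_damp) * _direction_factor(u2, x_damp)
    return _azimuthal_average(q, x_damp, lattice.a, n_azimuth)


def _azimuthal_average(q: np.ndarray, x_damp: np.ndarray, a: float,
                       n_nodes: int) -> np.ndarray:
    """Average of Z1(psi) Z2(psi) over the fundamental domain [pi/6, 2pi/3].

    Three Gauss-Legendre segments: two plain ones on [pi/6, psi_w] and
    [pi - psi_w ... 2pi/3] flanks, and a central window [pi/2 -/+ dw] whose
    nodes follow the Lorentzian half-width (1 - eps)/sqrt(eps) of Z1 in
    u1 = q a cos(psi) via a tangent substitution, so the ridge at psi = pi/2
    stays resolved for arbitrarily small q_par.
    """
    shape = q.shape
    qf = np.atleast_1d(q).ravel()[:, None]
    ef = np.atleast_1d(x_damp).ravel()[:, None]
    x, w = np.polynomial.legendre.leggauss(n_nodes)
    lo, hi = np.pi / 6.0, 2.0 * np.pi / 3.0
    dw = np.pi / 12.0  # central window half-width (15 degrees)
    total = np.zeros(qf.shape[0])

    def add_plain(p_lo, p_hi):
        nonlocal total
        psi = 0.5 * (p_hi - p_lo) * x + 0.5 * (p_hi + p_lo)
        wts = 0.5 * (p_hi - p_lo) * w
        u1 = qf * a * np.cos(psi)
        u2 = qf * a * np.cos(psi - np.pi / 3.0)
        total += (_direction_factor(u1, ef) * _direction_factor(u2, ef)) @ wts

    add_plain(lo, np.pi / 2.0 - dw)
    add_plain(np.pi / 2.0 + dw, hi)

    # central window: u1 = gamma tan(v), gamma the Lorentzian half-width
    one_minus = -np.expm1(-ef)
    gamma = np.maximum(one_minus / np.sqrt(np.maximum(np.exp(-ef), 1e-300)), 1e-300)
    u1w = qf * a * np.sin(dw)
    v0 = np.arctan(u1w / gamma)
    v = v0 * x  # (nq, n_nodes)
    u1 = gamma * np.tan(v)
    dpsi_dv = (gamma / np.cos(v) ** 2) / np.sqrt(
        np.maximum((qf * a) ** 2 - u1**2, 1e-300)
    )
    psi = np.pi / 2.0 + np.arcsin(np.clip(u1 / (qf * a), -1.0, 1.0))
    u2 = qf * a * np.cos(psi - np.pi / 3.0)
    z = _direction_factor(u1, ef) * _direction_factor(u2, ef)
    total += np.einsum("ij,ij,j->i", z, v0 * dpsi_dv, w)

    return (total / (hi - lo)).reshape(shape)


@dataclass(frozen=True)
class StackModel:
    """Vertical stack of N bilayers with spacing c.

    ``theory`` selects paracrystal ("PT", parameterised by the distortion
    ``g_cperp``) or modified Caille ("MCT", parameterised by the Caille
    parameter ``eta1``).  If only one of ``g_cperp``/``eta1`` is given the
    other is filled in through the Zhang relation.  ``poly_width`` is the
    relative width of a discrete Gaussian distribution over N; N = 1 means a
    single bilayer and a structure factor identically 1.
    """

    n_bilayers: int = 1
    c: float = 65.0
    theory: str = "PT"
    g_cperp: float | None = None
    eta1: float | None = None
    poly_width: float = 0.3

    def __post_init__(self) -> None:
        if self.n_bilayers < 1:
            raise ValueError("need at least one bilayer per stack")
        if self.c <= 0:
            raise ValueError("stacking distance c must be positive")
        if self.theory not in ("PT", "MCT"):
            raise ValueError("theory must be 'PT' or 'MCT'")
        if self.poly_width < 0:
            raise ValueError("poly_width must be nonnegative")
        g, e = self.g_cperp, self.eta1
        if g is not None and g < 0:
            raise ValueError("g_cperp must be nonnegative")
        if e is not None and e < 0:
            raise ValueError("eta1 must be nonnegative")
        if g is None and e is not None:
            object.__setattr__(self, "g_cperp", zhang_g_from_eta(e))
        elif e is None and g is not None:
            object.__setattr__(self, "eta1", g**2 / 0.087)
        elif g is None and e is None:
            object.__setattr__(self, "g_cperp", 0.0)
            object.__setattr__(self, "eta1", 0.0)

    def n_weights(self) -> tuple[np.ndarray, np.ndarray]:
        """Discrete Gaussian weights over N, truncated at +/- 3 widths and
        at N >= 1, renormalised to sum to 1."""
        n0 = self.n_bilayers
        if self.poly_width == 0 or n0 == 1:
            return np.array([n0]), np.array([1.0])
        w = self.poly_width * n0
        lo = max(1, int(np.floor(n0 - 3 * w)))
        hi = int(np.ceil(n0 + 3 * w))
        ns = np.arange(lo, hi + 1)
        wts = np.exp(-0.5 * ((ns - n0) / w) ** 2)
        return ns, wts / wts.sum()


def _stack_sum(q: np.ndarray, n: int, stack: StackModel) -> np.ndarray:
    """Unnormalised S_N(q) = N + 2 sum_{m<N} (N-m) Re[phi_T(q)^m]."""
    if n == 1:
        return np.full(q.shape, 1.0)
    m = np.arange(1, n)
    phase = np.cos(np.outer(q, m) * stack.c)
    if stack.theory == "PT":
        damp = np.exp(-0.5 * np.outer(q**2, m) * (stack.g_cperp * stack.c) ** 2)
    else:  # MCT, Caille correlation: exp(-s gamma) (pi m)^(-s), s = eta1 (qc/2pi)^2
        s = stack.eta1 * (q * stack.c / (2.0 * np.pi)) ** 2
        damp = np.exp(-s[:, None] * (_EULER_GAMMA + np.log(np.pi * m)[None, :]))
    return n + 2.0 * (phase * damp) @ (n - m).astype(float)


def stack_sf(q_perp: float | np.ndarray, stack: StackModel) -> np.ndarray:
    """Per-bilayer stacking structure factor S(q)/<N> (dimensionless, -> 1).

    Polydispersity over N averages the unnormalised paracrystal/MCT sums with
    discrete Gaussian weights and divides by the mean N, which suppresses the
    intrinsic low-q oscillations of the monodisperse expression.
    """
    q = np.asarray(q_perp, dtype=float)
    if np.any(q <= 0):
        raise ValueError("q_perp must be positive")
    scalar = q.ndim == 0
    q = np.atleast_1d(q)
    ns, wts = stack.n_weights()
    total = np.zeros(q.shape)
    for n, w in zip(ns, wts):
        total += w * _stack_sum(q, int(n), stack)
    total /= float(np.sum(wts * ns))
    return total[0] if scalar else total
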