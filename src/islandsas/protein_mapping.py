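"""Core-shell cylinder parameterisation of protein form factors.

An arbitrary protein P(q) curve (e.g. computed from atomic coordinates by an
external tool) is reduced to five numbers -- core radius R, shell thickness
delta, occupancy fractions phi_i / phi_e, cylinder length L -- that the
island builders in :mod:`islandsas.systems` consume.  The cylinder length is
a derived parameter: the occupied volume

    phi_i pi R^2 L + phi_e pi [(R + delta)^2 - R^2] L = V_p

must close on the protein molecular volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np
from scipy.special import j1

from .intensity import ScatteringCurve

__all__ = [
    "CoreShellCylinderParams",
    "core_shell_cylinder_pq",
    "fit_core_shell",
]


@dataclass(frozen=True)
class CoreShellCylinderParams:
    radius: float          # core radius R [A]
    delta: float           # shell thickness [A]
    phi_i: float
    phi_e: float
    length: float          # L [A]
    volume: float          # V_p [A^3]
    rho_p: float           # protein SLD [1/A^2]

    def __post_init__(self) -> None:
        if not (0.0 <= self.phi_i <= 1.0 and 0.0 <= self.phi_e <= 1.0):
            raise ValueError("occupancy fractions must lie in [0, 1]")
        if self.radius <= 0 or self.delta <= 0 or self.length <= 0:
            raise ValueError("R, delta and L must be positive")

    @property
    def outer_radius(self) -> float:
        return self.radius + self.delta

    def occupied_volume(self) -> float:
        core = np.pi * self.radius**2
        ring = np.pi * (self.outer_radius**2 - self.radius**2)
        return (self.phi_i * core + self.phi_e * ring) * self.length


def derived_length(radius: float, delta: float, phi_i: float, phi_e: float,
                   volume: float) -> float:
    """Cylinder length implied by the volume-closure invariant."""
    core = np.pi * radius**2
    ring = np.pi * ((radius + delta) ** 2 - radius**2)
    occ = phi_i * core + phi_e * ring
    if occ <= 0:
        raise ValueError("occupied cross-section must be positive")
    return volume / occ


def _two_j1_over_x(x: np.ndarray) -> np.ndarray:
    small = np.abs(x) < 1e-4
    safe = np.where(small, 1.0, x)
    return np.where(small, 1.0 - x**2 / 8.0, 2.0 * j1(safe) / safe)


def core_shell_cylinder_pq(
    params: CoreShellCylinderParams,
    rho_solv: float,
    q: float | np.ndarray,
    n_zenith: int = 256,
) -> np.ndarray:
    """Orientationally averaged form factor of the core-shell cylinder.

    Contrasts are the occupancy-mixed SLDs minus the solvent:
    drho_core = phi_i (rho_p - rho_solv), drho_shell = phi_e (rho_p - rho_solv).
    Normalisation: P(0) equals the squared total excess scattering length.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("q must be nonnegative")
    scalar = q.ndim == 0
    q = np.atleast_1d(q)
    drho = params.rho_p - rho_solv
    v_core = np.pi * params.radius**2 * params.length
    v_ring = np.pi * (params.outer_radius**2 - params.radius**2) * params.length

    x, w = np.polynomial.legendre.leggauss(n_zenith)
    mu = 0.5 * (x + 1.0)
    wmu = 0.5 * w
    s = np.sqrt(1.0 - mu**2)
    arg_z = np.outer(q, mu) * (params.length / 2.0)
    axial = np.sinc(arg_z / np.pi)
    rad_core = _two_j1_over_x(np.outer(q, s) * params.radius)
    rad_out = _two_j1_over_x(np.outer(q, s) * params.outer_radius)
    v_out = np.pi * params.outer_radius**2 * params.length
    amp = axial * (
        params.phi_i * drho * v_core * rad_core
        + params.phi_e * drho * (v_out * rad_out - v_core * rad_core)
    )
    pq = (amp**2) @ wmu
    return pq[0] if scalar else pq


def fit_core_shell(
    pq_curve: ScatteringCurve,
    volume: float,
    rho_p: float,
    rho_solv: float,
    bounds: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    n_starts: int = 5,
    pin_length: float | None = None,
    start: dict[str, float] | None = None,
) -> CoreShellCylinderParams:
    """Least-squares core-shell cylinder fit of a P(q) curve.

    The objective is unweighted least squares on log P (shape-only: an overall
    log-scale factor is fitted alongside), with the cylinder length derived
    from the volume closure unless ``pin_length`` is given.  The shape-only
    objective is multimodal (core and shell roles can swap), so supply a
    ``start`` near the expected geometry when one is known; the remaining
    starts (seeded) are random restarts.  Non-convergence or a degenerate
    (flat) input curve raises with diagnostics.
    """
    q = pq_curve.q
    p_obs = pq_curve.intensity
    if q.size < 20 or q.max() / q.min() < 10.0:
        raise ValueError("need >= 20 points spanning at least one decade in q")
    if np.any(p_obs <= 0):
        raise ValueError("form factor values must be positive for a log fit")
    log_obs = np.log(p_obs)
    if log_obs.max() - log_obs.min() < 0.1:
        raise ValueError("degenerate (flat) curve: no shape information to fit")

    bounds = bounds or {}
    b_r = bounds.get("radius", (0.1, 200.0))
    b_d = bounds.get("delta", (0.5, 200.0))
    b_phi = (1e-4, 1.0)

    def model_logp(r, d, fi, fe):
        length = pin_length or derived_length(r, d, fi, fe, volume)
        p = CoreShellCylinderParams(r, d, fi, fe, length, volume, rho_p)
        return np.log(np.maximum(core_shell_cylinder_pq(p, rho_solv, q), 1e-300))

    def residual(pars):
        v = pars.valuesdict()
        return (
            model_logp(v["radius"], v["delta"], v["phi_i"], v["phi_e"])
            + v["log_scale"]
            - log_obs
        )

    rng = np.random.default_rng(seed)
    best = None
    for i_start in range(n_starts):
        if i_start == 0 and start is not None:
            r0 = start.get("radius", np.sqrt(b_r[0] * b_r[1]))
            d0 = start.get("delta", np.sqrt(b_d[0] * b_d[1]))
            fi0 = start.get("phi_i", 0.5)
            fe0 = start.get("phi_e", 0.5)
        elif i_start == 0:  # deterministic mid-bounds start
            r0, d0 = np.sqrt(b_r[0] * b_r[1]), np.sqrt(b_d[0] * b_d[1])
            fi0 = fe0 = 0.5
        else:  # seeded random restarts
            r0, d0 = rng.uniform(*b_r), rng.uniform(*b_d)
            fi0, fe0 = rng.uniform(0.05, 0.95, size=2)
        pars = lmfit.Parameters()
        pars.add("radius", value=r0, min=b_r[0], max=b_r[1])
        pars.add("delta", value=d0, min=b_d[0], max=b_d[1])
        pars.add("phi_i", value=fi0, min=b_phi[0], max=b_phi[1])
        pars.add("phi_e", value=fe0, min=b_phi[0], max=b_phi[1])
        pars.add("log_scale", value=0.0, min=-20.0, max=20.0)
        res = lmfit.minimize(residual, pars, method="least_squares",
                             max_nfev=6000, ftol=1e-12, xtol=1e-12, gtol=1e-12)
        if best is None or res.chisqr < best.chisqr:
            best = res
        if best.chisqr < 1e-12 * q.size:  # essentially exact: stop restarting
            break
    if best is None or not best.success:
        raise RuntimeError(f"core-shell cylinder fit did not converge: {best}")
    v = best.params.valuesdict()
    length = pin_length or derived_length(
        v["radius"], v["delta"], v["phi_i"], v["phi_e"], volume
    )
    return CoreShellCylinderParams(
        v["radius"], v["delta"], v["phi_i"], v["phi_e"], length, volume, rho_p
    )
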