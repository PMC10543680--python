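"""Multi-level erf-smoothed scattering-length-density profiles along z.

A lipid bilayer (or one cylindrical shell of an in-plane inhomogeneity) is
described by a stack of ``N`` constant-SLD levels with error-function
transitions between them.  The 1D Fourier transform of the excess SLD over a
reference (solvent or host bilayer) has a closed form: each transition
contributes a Gaussian-damped phase term, which is what makes simulation and
global fitting of scattering curves fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import erf

__all__ = [
    "R_E_ANGSTROM",
    "SLD_H2O_NEUTRON",
    "SLD_D2O_NEUTRON",
    "ELECTRON_DENSITY_WATER",
    "ProbeContrast",
    "SLDLevelProfile",
    "profile_excess_amplitude",
]

#: Classical electron radius expressed in angstroms (0.28e-12 cm).
R_E_ANGSTROM = 2.8e-5

#: Coherent neutron SLD of light and heavy water [1/A^2].
SLD_H2O_NEUTRON = -0.56e-6
SLD_D2O_NEUTRON = 6.36e-6

#: Electron density of water [e/A^3].
ELECTRON_DENSITY_WATER = 0.333


@dataclass(frozen=True)
class ProbeContrast:
    """Radiation probe and the solvent reference it implies.

    Parameters
    ----------
    kind:
        ``"xray"`` or ``"neutron"``.
    x_d:
        Solvent deuteration fraction in [0, 1] (neutrons only).  The solvent
        SLD interpolates linearly between pure H2O and pure D2O.
    """

    kind: str
    x_d: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("xray", "neutron"):
            raise ValueError(f"unknown probe kind {self.kind!r}")
        if not 0.0 <= self.x_d <= 1.0:
            raise ValueError("deuteration fraction x_d must lie in [0, 1]")

    @property
    def rho_solvent(self) -> float:
        """Solvent SLD in 1/A^2."""
        if self.kind == "xray":
            return self.sld_from_electron_density(ELECTRON_DENSITY_WATER)
        return (1.0 - self.x_d) * SLD_H2O_NEUTRON + self.x_d * SLD_D2O_NEUTRON

    @staticmethod
    def sld_from_electron_density(rho_e: float | np.ndarray) -> float | np.ndarray:
        """Convert an electron density [e/A^3] to an X-ray SLD [1/A^2]."""
        return np.asarray(rho_e, dtype=float) * R_E_ANGSTROM

    @staticmethod
    def electron_density_from_sld(sld: float | np.ndarray) -> float | np.ndarray:
        """Inverse of :meth:`sld_from_electron_density` (exact round trip)."""
        return np.asarray(sld, dtype=float) / R_E_ANGSTROM


@dataclass(frozen=True)
class SLDLevelProfile:
    """An N-level SLD profile along z with erf-smoothed transitions.

    Level ``j`` (1-based) occupies ``[z_j, z_j + D_j]`` with
    ``z_{j+1} = z_j + D_j`` and ``z_1 = z_base``.  Transition ``j`` (between
    level ``j-1`` and level ``j``, with levels 0 and N+1 being the solvent)
    has smoothness ``sigmas[j-1]``; there are ``N + 1`` transitions.  The
    profile tends to ``rho_solvent`` for z -> +/- infinity.

    All lengths are in angstroms, SLDs in 1/A^2.
    """

    thicknesses: tuple[float, ...]
    slds: tuple[float, ...]
    sigmas: tuple[float, ...]
    z_base: float
    rho_solvent: float

    def __post_init__(self) -> None:
        D = np.asarray(self.thicknesses, dtype=float)
        rho = np.asarray(self.slds, dtype=float)
        sig = np.asarray(self.sigmas, dtype=float)
        if D.ndim != 1 or D.size == 0:
            raise ValueError("profile needs at least one level")
        if rho.shape != D.shape:
            raise ValueError("slds and thicknesses must have equal length")
        if sig.shape != (D.size + 1,):
            raise ValueError(
                "sigmas must have n_levels + 1 entries (one per transition)"
            )
        if np.any(D <= 0):
            raise ValueError("all level thicknesses must be positive")
        if np.any(sig < 0):
            raise ValueError("transition smoothness must be nonnegative")
        object.__setattr__(self, "thicknesses", tuple(float(x) for x in D))
        object.__setattr__(self, "slds", tuple(float(x) for x in rho))
        object.__setattr__(self, "sigmas", tuple(float(x) for x in sig))

    # -- geometry ---------------------------------------------------------

    @property
    def n_levels(self) -> int:
        return len(self.thicknesses)

    @property
    def total_thickness(self) -> float:
        return float(np.sum(self.thicknesses))

    def level_positions(self) -> np.ndarray:
        """Lower edges z_1..z_N of the levels (z_{j+1} = z_j + D_j)."""
        D = np.asarray(self.thicknesses)
        return self.z_base + np.concatenate(([0.0], np.cumsum(D)[:-1]))

    def transition_positions(self) -> np.ndarray:
        """Positions of the N+1 transitions (z_1..z_N plus the upper edge)."""
        D = np.asarray(self.thicknesses)
        return self.z_base + np.concatenate(([0.0], np.cumsum(D)))

    def transition_steps(self) -> np.ndarray:
        """SLD jumps at each transition; they sum to zero (returns to solvent)."""
        rho = np.concatenate(
            ([self.rho_solvent], np.asarray(self.slds), [self.rho_solvent])
        )
        return np.diff(rho)

    # -- evaluation -------------------------------------------------------

    def evaluate_sld(self, z: float | np.ndarray) -> np.ndarray:
        """SLD at height(s) ``z``.

        sigma = 0 transitions use the exact step-function branch.
        """
        z = np.asarray(z, dtype=float)
        zt = self.transition_positions()
        steps = self.transition_steps()
        sig = np.asarray(self.sigmas)
        out = np.full(z.shape, self.rho_solvent, dtype=float)
        for zj, dj, sj in zip(zt, steps, sig):
            if sj == 0.0:
                out = out + dj * (z >= zj)
            else:
                out = out + dj * 0.5 * (1.0 + erf((z - zj) / (np.sqrt(2.0) * sj)))
        return out

    def excess_amplitude(self, q_perp: float | np.ndarray) -> np.ndarray:
        """Closed-form 1D Fourier transform of the excess SLD over solvent.

        A(q) = integral [rho(z) - rho_solvent] exp(i q z) dz
             = (i/q) sum_j drho_j exp(i q z_j) exp(-q^2 sigma_j^2 / 2).

        The q -> 0 limit, -sum_j drho_j z_j = sum_j (rho_j - rho0) D_j, is
        taken via a series branch for |q| below a switch-over threshold.

        Parameters
        ----------
        q_perp:
            Nonnegative momentum transfer(s) along z, in 1/A.
        """
        q = np.asarray(q_perp, dtype=float)
        if np.any(q < 0):
            raise ValueError("q_perp must be nonnegative")
        zt = self.transition_positions()
        steps = self.transition_steps()
        sig2 = np.asarray(self.sigmas) ** 2

        qc = q[..., None]
        small = np.abs(q) < 1e-4
        out = np.empty(q.shape, dtype=complex)

        if np.any(~small):
            qs = np.where(small, 1.0, q)[..., None]  # dummy 1.0 avoids 0-div
            terms = steps * np.exp(1j * qs * zt - 0.5 * qs**2 * sig2)
            full = (1j / qs[..., 0]) * terms.sum(axis=-1)
            out[...] = full
        if np.any(small):
            # series in q: A = a0 + i q a1 + q^2 a2 + O(q^3)
            a0 = -np.sum(steps * zt)
            a1 = -0.5 * np.sum(steps * (zt**2 + sig2))
            a2 = np.sum(steps * (zt**3 / 6.0 + zt * sig2 / 2.0))
            ser = a0 + 1j * qc[..., 0] * a1 + qc[..., 0] ** 2 * a2
            out = np.where(small, ser, out)
        return out


def profile_excess_amplitude(
    profile: SLDLevelProfile,
    reference: SLDLevelProfile | None,
    q_perp: float | np.ndarray,
) -> np.ndarray:
    """Fourier transform of ``profile`` minus ``reference`` (solvent if None).

    Both profiles must share the same solvent SLD so the excess over the
    reference is well defined.  Used for island shell amplitudes, which are
    defined as the excess over the host bilayer profile.
    """
    amp = profile.excess_amplitude(q_perp)
    if reference is None:
        return amp
    if not np.isclose(profile.rho_solvent, reference.rho_solvent, rtol=0, atol=0.0):
        raise ValueError("profile and reference must share the solvent SLD")
    return amp - reference.excess_amplitude(q_perp)
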