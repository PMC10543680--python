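"""In-plane transforms of discs/annuli and total island scattering amplitudes.

An island is a set of concentric cylindrical shells embedded in the host
bilayer; shell ``k`` spans radii ``(R_{k-1}, R_k]`` (``R_0 = 0``) and carries
its own z-profile.  Its scattering amplitude factorises into the 1D transform
of the shell's excess SLD profile (see :mod:`islandsas.profiles`) times the
2D transform of the annulus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import j1

from .profiles import SLDLevelProfile, profile_excess_amplitude

__all__ = ["Island", "disc_ft", "annulus_ft", "island_amplitude"]

# Below this value of x = q_par * R the ratio 2 J1(x)/x is evaluated by its
# Taylor series to avoid cancellation; validated against high-precision
# evaluation in the tests.
_SERIES_X = 1e-4


def _two_j1_over_x(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < _SERIES_X
    safe = np.where(small, 1.0, x)
    out = 2.0 * j1(safe) / safe
    # 2 J1(x)/x = 1 - x^2/8 + x^4/192 - ...
    ser = 1.0 - x**2 / 8.0 + x**4 / 192.0
    return np.where(small, ser, out)


def disc_ft(q_par: float | np.ndarray, R: float) -> np.ndarray:
    """2D Fourier transform of a disc indicator of radius ``R`` [A^2].

    Equals ``2 pi R J1(q R) / q``; the q -> 0 limit is ``pi R^2``.
    """
    if R <= 0:
        raise ValueError("disc radius must be positive")
    q = np.asarray(q_par, dtype=float)
    if np.any(q < 0):
        raise ValueError("q_par must be nonnegative")
    return np.pi * R**2 * _two_j1_over_x(q * R)


def annulus_ft(q_par: float | np.ndarray, R_in: float, R_out: float) -> np.ndarray:
    """2D Fourier transform of the annulus ``R_in < r <= R_out`` [A^2].

    At q = 0 this is the annulus area pi (R_out^2 - R_in^2).
    """
    if R_in < 0 or R_in >= R_out:
        raise ValueError("need 0 <= R_in < R_out")
    outer = disc_ft(q_par, R_out)
    if R_in == 0.0:
        return outer
    return outer - disc_ft(q_par, R_in)


@dataclass(frozen=True)
class Island:
    """Concentric cylindrical shells of SLD inhomogeneity in a bilayer.

    ``shell_profiles[k]`` is the full SLD profile of shell ``k`` (``None``
    denotes a water hole, i.e. solvent throughout); the scattering-relevant
    quantity is always its excess over the host bilayer profile.  Shell
    profiles carry their own vertical placement through ``z_base``.
    """

    radii: tuple[float, ...]
    shell_profiles: tuple[SLDLevelProfile | None, ...]

    def __post_init__(self) -> None:
        R = np.asarray(self.radii, dtype=float)
        if R.ndim != 1 or R.size == 0:
            raise ValueError("island needs at least one shell")
        if R[0] <= 0 or np.any(np.diff(R) <= 0):
            raise ValueError("shell radii must satisfy 0 < R_1 < ... < R_Ns")
        if len(self.shell_profiles) != R.size:
            raise ValueError("one profile (or None) per shell is required")
        object.__setattr__(self, "radii", tuple(float(x) for x in R))

    @property
    def n_shells(self) -> int:
        return len(self.radii)

    @property
    def r_max(self) -> float:
        return self.radii[-1]

    def shell_bounds(self) -> list[tuple[float, float]]:
        inner = (0.0,) + self.radii[:-1]
        return list(zip(inner, self.radii))

    def shell_areas(self) -> np.ndarray:
        """In-plane areas pi (R_k^2 - R_{k-1}^2) of the shells [A^2]."""
        R2 = np.concatenate(([0.0], np.square(self.radii)))
        return np.pi * np.diff(R2)

    def shell_excess_amplitudes(
        self, host: SLDLevelProfile, q_perp: float | np.ndarray
    ) -> list[np.ndarray]:
        """1D amplitudes A_k(q_perp) of each shell's excess over the host."""
        amps = []
        for prof in self.shell_profiles:
            if prof is None:  # water hole: rho_k(z) = rho_solvent
                amps.append(-host.excess_amplitude(q_perp))
            else:
                amps.append(profile_excess_amplitude(prof, host, q_perp))
        return amps


def island_amplitude(
    island: Island,
    host: SLDLevelProfile,
    q_perp: float | np.ndarray,
    q_par: float | np.ndarray,
) -> np.ndarray:
    """Total island amplitude sum_k A_k(q_perp) S_k(q_par) [A^3-consistent].

    ``q_perp`` and ``q_par`` broadcast against each other.  The amplitude is
    linear in the shell excess contrasts and vanishes when every shell equals
    the host profile.
    """
    q_perp = np.asarray(q_perp, dtype=float)
    q_par = np.asarray(q_par, dtype=float)
    amps = island.shell_excess_amplitudes(host, q_perp)
    total = np.zeros(np.broadcast(q_perp, q_par).shape, dtype=complex)
    for (r_in, r_out), a_k in zip(island.shell_bounds(), amps):
        total = total + a_k * annulus_ft(q_par, r_in, r_out)
    return total
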