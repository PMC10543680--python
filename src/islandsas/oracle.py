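"""Brute-force finite-system reference intensity.

Validates the analytic pipeline by explicit averaging: a finite bilayer disc
of radius ``R_b`` carries an explicit paracrystal realization of island
centres (cumulative Gaussian-jittered hexagonal steps) and, optionally, an
explicit stack of bilayers; the squared scattering amplitude -- exact partial
amplitudes times the finite-disc sheet transform, no asymptotic
delta-function replacement -- is orientationally integrated and averaged over
realizations.  This is a test instrument, not a production path: it scales
with the island count and is meaningful for q >= 4 pi / R_b.

The orientational (zenith) integral needs care because the finite-sheet
transform oscillates on the scale 1/R_b: the region q_par < q_c is integrated
on a dense shared q_par grid, the remainder by Gauss-Legendre in cos(beta).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .amplitudes import disc_ft, island_amplitude
from .intensity import MembraneSystem
from .structure import ParacrystalLattice2D

__all__ = ["realize_lattice", "lattice_in_disc", "brute_force_intensity"]


def _cumulative_steps(step: np.ndarray, sigma: float, n_lo: int, n_hi: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Positions sum_{k} (step + jitter_k) for indices n_lo..n_hi (0 at n=0);
    jitter is isotropic Gaussian with standard deviation sigma per component."""
    idx = np.arange(n_lo, n_hi + 1)
    pos = np.zeros((idx.size, 2))
    up = np.cumsum(step + sigma * rng.standard_normal((max(n_hi, 0), 2)), axis=0)
    dn = -np.cumsum(step + sigma * rng.standard_normal((max(-n_lo, 0), 2)), axis=0)
    for i, n in enumerate(idx):
        if n > 0:
            pos[i] = up[n - 1]
        elif n < 0:
            pos[i] = dn[-n - 1]
    return pos


def realize_lattice(
    lattice: ParacrystalLattice2D,
    n_a: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """One paracrystal realization of an ``n_a`` x ``n_a`` island array.

    Ideal-paracrystal growth: centre(n1, n2) is the sum of n1 jittered
    a1-steps and n2 jittered a2-steps, each step Gaussian with standard
    deviation sigma_a per component.  Returns an (n_a^2, 2) array centred on
    the mean position.
    """
    if n_a < 1:
        raise ValueError("need at least one island per direction")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a1, a2 = lattice.unit_vectors()
    half = n_a // 2
    c1 = _cumulative_steps(a1, lattice.sigma_a, -half, n_a - 1 - half, rng)
    c2 = _cumulative_steps(a2, lattice.sigma_a, -half, n_a - 1 - half, rng)
    centers = (c1[:, None, :] + c2[None, :, :]).reshape(-1, 2)
    return centers - centers.mean(axis=0)


def lattice_in_disc(
    lattice: ParacrystalLattice2D,
    r_keep: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Paracrystal realization covering a disc: islands with centres outside
    radius ``r_keep`` are discarded."""
    n_a = 2 * int(np.ceil(1.3 * r_keep / (lattice.a * np.sqrt(3.0) / 2.0))) + 1
    centers = realize_lattice(lattice, n_a, seed)
    return centers[np.einsum("ij,ij->i", centers, centers) <= r_keep**2]


@dataclass
class OracleCurve:
    q: np.ndarray
    intensity: np.ndarray      # per-area reduced cross section, as the
    stderr: np.ndarray         # analytic per_bilayer_cross_section
    n_islands_mean: float


def brute_force_intensity(
    system: MembraneSystem,
    r_b: float,
    q_grid: np.ndarray,
    n_realizations: int = 32,
    seed: int = 0,
    n_zenith: int = 64,
    n_azimuth: int = 12,
    n_fine: int = 512,
    keep_margin: float | None = None,
) -> OracleCurve:
    """Monte Carlo finite-system reduced cross section (per unit sheet area).

    Each realization draws island centres (per bilayer) and stack
    displacements, then integrates |A(q)|^2 / N over the sphere of
    orientations exactly (dense q_par grid near the forward sheet peak plus
    Gauss-Legendre elsewhere).  Returns per-q mean and standard error over
    realizations, on the same scale as
    :func:`islandsas.intensity.per_bilayer_cross_section`.

    ``keep_margin`` is the rim exclusion for island centres (default: the
    island radius R_max, so islands lie entirely on the sheet).
    """
    q_grid = np.asarray(q_grid, dtype=float)
    if np.any(q_grid <= 0):
        raise ValueError("q must be positive")
    rng = np.random.default_rng(seed)
    sheet_area = np.pi * r_b**2
    stack = system.stack
    has_islands = system.island is not None
    if keep_margin is None:
        keep_margin = system.island.r_max if has_islands else 0.0

    # shared dense q_par grid for the sheet-peak region; the finite-sheet
    # transform oscillates with period ~pi/R_b, so resolve it with >= 16
    # nodes per oscillation
    q_c_all = np.minimum(0.8 * q_grid, 0.06)
    n_fine = max(n_fine, int(q_c_all.max() * r_b * 16.0 / np.pi) + 1)
    qf = np.linspace(1e-6, q_c_all.max(), n_fine)
    psi = np.arange(n_azimuth) * 2.0 * np.pi / n_azimuth
    xg, wg = np.polynomial.legendre.leggauss(n_zenith)

    samples = np.zeros((n_realizations, q_grid.size))
    m_counts = []
    for i_real in range(n_realizations):
        # stack displacements (cumulative Gaussian steps)
        n_bil = stack.n_bilayers
        if n_bil > 1:
            steps = stack.c + stack.g_cperp * stack.c * rng.standard_normal(n_bil - 1)
            z_n = np.concatenate(([0.0], np.cumsum(steps)))
        else:
            z_n = np.zeros(1)
        # island centres per bilayer, with a random global rotation
        if has_islands:
            phi0 = rng.uniform(0.0, 2.0 * np.pi)
            rot = np.array(
                [[np.cos(phi0), -np.sin(phi0)], [np.sin(phi0), np.cos(phi0)]]
            )
            centers = [
                lattice_in_disc(system.lattice, r_b - keep_margin, rng) @ rot.T
                for _ in range(n_bil)
            ]
            m_counts.extend(len(c) for c in centers)
            u = np.stack([np.cos(psi), np.sin(psi)], axis=1)     # (na, 2)
            # G on the shared fine grid: (nf, na) per bilayer
            g_fine = [
                np.exp(1j * qf[:, None, None] * (u @ c.T)[None, :, :]).sum(-1)
                for c in centers
            ]
        samples[i_real] = _integrate_realization(
            system, r_b, q_grid, q_c_all, qf, psi, xg, wg, z_n,
            centers if has_islands else None,
            g_fine if has_islands else None,
        ) / (sheet_area * n_bil)
    mean = samples.mean(axis=0)
    if n_realizations > 1:
        err = samples.std(axis=0, ddof=1) / np.sqrt(n_realizations)
    else:
        err = np.full(q_grid.shape, np.nan)
    return OracleCurve(q_grid, mean, err, float(np.mean(m_counts)) if m_counts else 0.0)


def _integrate_realization(system, r_b, q_grid, q_c_all, qf, psi, xg, wg,
                           z_n, centers, g_fine):
    """Full-sphere average of |A|^2 for one realization, per q."""
    out = np.empty(q_grid.size)
    bilayer = system.bilayer
    island = system.island
    u = np.stack([np.cos(psi), np.sin(psi)], axis=1)
    for iq, q in enumerate(q_grid):
        q_c = q_c_all[iq]
        mask = qf <= q_c
        qp = qf[mask]
        mu_f = np.sqrt(1.0 - (qp / q) ** 2)
        w_f = np.gradient(qp) * qp / (q**2 * mu_f)   # dmu = qpar dqpar/(q^2 mu)
        qperp_f = q * mu_f
        stack_f = np.exp(1j * np.outer(qperp_f, z_n)).sum(axis=1)
        ab_f = bilayer.excess_amplitude(qperp_f) * disc_ft(qp, r_b)
        if island is not None:
            ai_f = island_amplitude(island, bilayer, qperp_f, qp)
            val_f = 0.0
            for zb, g in zip(z_n, g_fine):
                amp = (
                    np.exp(1j * qperp_f * zb)[:, None]
                    * (ab_f[:, None] + ai_f[:, None] * g[mask])
                )
                # coherent across bilayers only through the common phase
                val_f = val_f + amp
            integ_f = (np.abs(val_f) ** 2).mean(axis=1)
        else:
            integ_f = np.abs(stack_f * ab_f) ** 2
        part_fine = float(np.sum(w_f * integ_f))

        # Gauss-Legendre region: mu in (0, mu_c)
        mu_c = np.sqrt(max(1.0 - (q_c / q) ** 2, 0.0))
        mu_g = 0.5 * (xg + 1.0) * mu_c
        w_g = 0.5 * wg * mu_c
        qperp_g = q * mu_g
        qpar_g = q * np.sqrt(1.0 - mu_g**2)
        ab_g = bilayer.excess_amplitude(qperp_g) * disc_ft(qpar_g, r_b)
        if island is not None:
            ai_g = island_amplitude(island, bilayer, qperp_g, qpar_g)
            val_g = 0.0
            for zb, c in zip(z_n, centers):
                g = np.exp(
                    1j * qpar_g[:, None, None] * (u @ c.T)[None, :, :]
                ).sum(-1)                                  # (nz, na)
                val_g = val_g + (
                    np.exp(1j * qperp_g * zb)[:, None]
                    * (ab_g[:, None] + ai_g[:, None] * g)
                )
            integ_g = (np.abs(val_g) ** 2).mean(axis=1)
        else:
            stack_g = np.exp(1j * np.outer(qperp_g, z_n)).sum(axis=1)
            integ_g = np.abs(stack_g * ab_g) ** 2
        out[iq] = part_fine + float(np.sum(w_g * integ_g))
    return out
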