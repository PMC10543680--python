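# Methods

`islandsas` computes small-angle X-ray and neutron scattering (SAXS/SANS)
from flat lipid bilayers that carry laterally correlated cylindrical
scattering-length-density (SLD) inhomogeneities — "islands": lipid domains,
toroidal water pores, and membrane proteins — and refits the resulting curves
to recover the structural parameters. This note records the model, its
assumptions, the numerical choices, and what the synthetic experiments do and
do not establish.

## The model

**Geometry.** The membrane is an infinite flat sheet (a planar idealisation
of a large unilamellar vesicle; curvature effects are out of scope). Islands
are concentric cylindrical shells perpendicular to the bilayer, with radii
`R_1 < … < R_Ns`; each shell carries its own z-profile. Stacks of `N`
bilayers with average spacing `c` are supported, with no correlation between
vertical and horizontal order.

**SLD profiles.** Every profile (bilayer or shell) is an `N_l`-level step
function of z smoothed by error-function transitions: transition `j` at
`z_j` with smoothness `σ_j` contributes
`Δρ_j · ½[1 + erf((z − z_j)/(√2 σ_j))]`, with levels 0 and `N_l + 1` being
the solvent. Its 1D Fourier transform is closed-form,

    A(q⊥) = (i/q⊥) Σ_j Δρ_j exp(i q⊥ z_j) exp(−q⊥² σ_j²/2),

with a series branch below `q⊥ = 10⁻⁴ Å⁻¹` to avoid cancellation. A lipid
species is described by a three-region half-profile (polar head, CH₂-rich,
CH₃-rich), mirrored into a symmetric five-level bilayer with the CH₃ region
centred on the mid-plane `z = 0`. X-ray electron densities (e Å⁻³) are
converted to SLD through the classical electron radius `r_e = 2.8 × 10⁻⁵ Å`;
neutron solvent SLD interpolates linearly between H₂O (−0.56 × 10⁻⁶ Å⁻²)
and D₂O (6.36 × 10⁻⁶ Å⁻²) with the deuteration fraction `x_D`, and water's
electron density is 0.333 e Å⁻³.

**Island amplitude.** Shell `k` contributes its excess over the host bilayer
profile times the annulus transform
`S̃_k(q∥) = 2π[R_k J₁(q∥R_k) − R_{k−1} J₁(q∥R_{k−1})]/q∥`; a water hole is a
shell whose profile is pure solvent. The amplitude is linear in the shell
contrasts.

**In-plane order.** Island centres form a distorted 2D hexagonal paracrystal:
positions grow by cumulative Gaussian-jittered steps along the two unit-cell
vectors (60° apart), each step with standard deviation `σ_a = g_a a` per
component. The lattice parameter fixes the island surface density
`n_d = 2/(√3 a²)`. The infinite-lattice interference function factorises over
the two growth directions,

    S_dd(q∥, ψ) = Π_k Re[(1 + Φ_k)/(1 − Φ_k)],
    Φ_k = exp(i q∥ a cos(ψ − ψ_k) − q∥² σ_a²/2).

A caution discovered while validating against the explicit finite-lattice
pair sum: this product form is **not** sixfold symmetric — the growth axes
are special. Its symmetry group is inversion plus the reflection that swaps
the two axes, so the azimuthal average must run over the fundamental domain
`[π/6, 2π/3]`, not a 60° sector. At small `q∥` the factor of the axis nearly
perpendicular to the scattering vector develops a narrow Lorentzian ridge at
`ψ = π/2` (rigid sliding of lattice rows), giving an azimuthally averaged
`S_dd ∝ 1/q∥`; the quadrature uses a tangent-stretched central window so the
ridge stays resolved at any `q∥`.

**Vertical order.** The stacking structure factor per bilayer is
`S(q⊥)/⟨N⟩` with `S = N + 2 Σ_m (N−m) cos(m q c) f_T(m, q)`, where
paracrystal theory (PT) has `f = exp(−m q² g_c⊥² c²/2)` and modified Caillé
theory (MCT) has `f = exp(−s γ)(πm)^(−s)`, `s = η₁ (qc/2π)²`, γ Euler's
constant. The Zhang relation `g_c⊥ = (0.087 η₁)^{1/2}` — the constant is
`(γ + ln π)/(2π²)` — equates the two nearest-neighbour dampings at the first
Bragg position. Polydispersity over `N` uses a discrete Gaussian (relative
width `poly_width`, default 0.3, truncated at ±3 widths and `N ≥ 1`),
averaging `Σ w_N S_N / Σ w_N N`; it suppresses the intrinsic low-q
oscillations of the monodisperse expression.

**Intensity assembly.** Per unit bilayer area the reduced cross section is

    Σ̃(q) = (2π/q²) S̄(q) |A_b(q) + n_d Σ_k A_k(q) π(R_k² − R_{k−1}²)|²
          + n_d ⟨ |A_I(q cos β, q sin β)|² S_dd(q sin β) ⟩_β

The first term is the coherent flat-sheet contribution: orientational
averaging of an extended sheet concentrates its transform into the forward
direction, leaving the Lorentz-type `2π/q²` factor, and the sheet amplitude
is the *laterally averaged* excess profile — bilayer plus mean island excess.
That mean-island piece is what produces both required limits: for small
dense islands the curve becomes the homogeneous surface-fraction mixture of
the two profiles, and for large separated islands the coherent and diffuse
terms together reproduce the area-fraction-weighted sum of two independent
sheet intensities. The second (diffuse) term is the zenith average of the
squared island amplitude weighted by the in-plane structure factor; the
forward direction `q∥ = 0` is handled only by the analytic coherent term and
is never a quadrature node. Whether a bilayer–island cross term survives the
flat-sheet reduction was settled by the finite-system Monte Carlo oracle:
it does, and it is exactly the cross term of the squared mean-sheet
amplitude above.

The macroscopic intensity is `I(q) = κ (c_V/t̄) Σ̃(q) + B` in Å⁻¹ (multiply
by 10⁸ for cm⁻¹), with `c_V = N_A Σ C_i v_i` the scattering-matter volume
fraction and `t̄` the bilayer volume per unit area (island-free thickness
plus `n_d`-weighted shell corrections). No sheet radius appears anywhere.

## Island archetypes

* **Lipid domains** — one shell of radius `R₁` carrying the guest lipid's
  five-level profile. The unit-cell area balance fixes the guest
  concentration: `C_g = C_h (a_h/a_g) πR₁² / (√3 a²/2 − πR₁²)`; both
  leaflets contribute equally, so the leaflet factor cancels.
* **Transmembrane proteins** — two shells (`R`, `R + δ`) with one level of
  thickness `L` each, SLDs mixed from protein and water by the occupancy
  fractions `φ_i` (core) and `φ_e` (shell); centred (`z = −L/2`) or
  half-embedded (`z = −L/4`). Protein concentration:
  `C_p = C_b a_lipid/(√3 a² − 2ξ a_p)`, `a_p = π(R + δ)²`.
* **Peripheral proteins** — anchored (ξ = 0: five bilayer levels plus a
  protein level resting on the surface), monotopic (ξ = ½: three lower
  bilayer levels plus the protein level), transmembrane (ξ = 1).
* **Toroidal pores** — pore radius `R_w`; the pore wall is the inner surface
  of a torus with tube radius equal to the bilayer half-thickness. Mapped to
  three shells with radii `R_w`, `R_w + D₁`, `R_w + D₁ + D₂ + D₃`: a water
  hole, a single-level rim whose thickness solves the lipid-volume equality
  with the torus segment (level SLD: thickness-weighted mean bilayer SLD —
  the rim is a bent mix of head and chain material), and a three-level
  head/chain/head outer shell solving the volume equalities of the head band
  (lipid within vertical distance `D₁` of the curved surface) and the chain
  core. All torus segment volumes are closed-form. Note the mapping does not
  vanish as `R_w → 0`: a horn-torus dimple still displaces lipid.

The protein parameterisation itself comes from `protein_mapping`: a
core-shell cylinder (R, δ, φ_i, φ_e) fitted to any externally computed P(q)
curve by unweighted log-intensity least squares with a free overall scale
(shape-only), the length `L` derived from the volume closure
`φ_i πR²L + φ_e π[(R+δ)² − R²]L = V_p`. The shape-only objective is
multimodal (core and shell roles can swap); supply a start near the expected
geometry, or rely on seeded random restarts.

## Fitting and synthetic experiments

`simulate_experiment` adds Gaussian noise with `σ(q) = ε √I(q)`; the default
ε gives 3% relative error at the curve maximum. The reference
simulate-and-refit protocol generates four curves (SAXS and SANS at
`x_D = 1`, pure DPPC and DOPC domains in DPPC at `a = 150 Å`, `R₁ = 60 Å`,
`g_a = 0.3`, 3 mM DPPC) on a 300-point grid over `q ∈ [0.005, 0.6] Å⁻¹` —
the dense coverage typical of synchrotron SAXS and reactor SANS — and
refits all 26 structural parameters (two half-profiles, `R₁`, `g_a`) shared
across the four curves by bounded least squares (multi-start, seeded),
with uncertainties from the Jacobian covariance.

A second protocol refits a transmembrane protein: bacteriorhodopsin as a
two-shell core–shell cylinder island in DPPC (same lattice and
concentration), sharing the host half-profile and fitting (R, δ, φ_i, φ_e,
L) with the protein SLD and volume held fixed.

Identifiability notes, measured on synthetic data at the default noise
(20-seed study): the per-curve scale factors must stay fixed when all SLDs
float (an exact per-probe scaling degeneracy otherwise). The medians of the
well-constrained parameters — `R₁` (59.99 ± 0.06), `g_a` (0.299 ± 0.003),
`D₁` (12.00 ± 0.02), the region electron densities — sit on truth within
their reported errors. The (D₂, D₃) pair is a near-singular covariance
block (the CH₂/CH₃ boundary is soft on the σ ≈ 2 Å scale): its actual
seed-to-seed spread is small (≈ 0.07/0.13 Å) but the Jacobian-based errors
for it are unreliable and should not be quoted. On sparse grids
(≲ 120 points) or with noise anchored to the global forward maximum, `D₁`
drifts by ångströms: the recovery tests show consistency of simulator and
fitter under dense, well-calibrated data, not identifiability for sparse or
narrow-range measurements, nor robustness to instrument systematics
(smearing, structured background, absolute-scale errors), none of which the
generator emulates.

## Numerical choices

* Zenith average: Gauss–Legendre in the zenith angle β on (0, π/2), 64 nodes
  by default. In cos β the azimuthally averaged `S_dd ∝ 1/q∥` endpoint
  behaviour destroys spectral convergence; in β the weighted integrand is
  smooth. Doubling the nodes changes reference curves by < 0.1%.
* Azimuthal average of `S_dd`: three Gauss–Legendre segments over the
  fundamental domain (default 32 nodes each in `structure`, 8 in the
  intensity hot path), with the tangent-stretched ridge window; validated to
  ≤ 2 × 10⁻⁴ against dense full-circle references down to `q∥ = 10⁻⁹ Å⁻¹`.
* Small-argument series for `J₁(x)/x` and the profile transform below
  `x = 10⁻⁴`, checked for smooth join.
* The paracrystal direction factor is computed with `expm1` so it stays
  exact for arbitrarily small damping exponents.
* σ = 0 transitions use an exact step branch, not a small-σ epsilon.

## The brute-force oracle

`islandsas.oracle.brute_force_intensity` computes the finite-system
intensity with no asymptotic replacements: explicit island centres
(cumulative-jitter paracrystal covering a disc of radius `R_b`), explicit
stack displacements, the exact finite-disc sheet transform, and full
orientational integration (a dense shared `q∥` grid across the forward sheet
peak — ≥16 nodes per `π/R_b` oscillation — plus Gauss–Legendre elsewhere),
averaged over seeded realizations. It validated the term structure of the
intensity assembly, including the presence of the bilayer–island cross term
and the sixfold-symmetry correction above. Agreement with the analytic
pipeline at `R_b = 3000 Å` (≈1450 islands) is at the few-percent level for
`q ≥ 4π/R_b`; the residual deviations are finite-size effects — the rim
exclusion of island centres (`R_max/R_b` density deficit) and the smearing
of sharp form-factor minima by the `π/R_b`-wide sheet peak — and shrink with
`R_b`. The oracle is a test instrument, not a production path.

## Problem sizes used in the shipped tests

Unit and property tests run in seconds. The heavy checks use: the
finite-lattice pair-sum oracle at 32×32 sites × 160 realizations; the
stacking oracle at `N = 5` × 96 realizations; oracle-vs-analytic intensity
at `R_b = 3000 Å` with 12 realizations per system (Monte Carlo error ≈ 1%);
one full simulate-and-refit of each four-curve protocol (domain and
protein); and the 20-seed recovery distribution on a 150-point grid.

## Known limitations

* Islands are identical within a system: no polydispersity over island size
  or type, no in-plane SLD gradients within a shell, no leaflet asymmetry in
  the builders (the profile machinery itself is asymmetric-capable).
* No instrument resolution smearing; the background is a flat constant.
* The MCT branch is validated for internal consistency (Zhang relation,
  limits) but not against an external lamellar MCT implementation.
* The torus-pore mapping conserves volumes, not scattering lengths; its rim
  SLD choice (thickness-weighted mean) is a modelling decision.
* Vertical and horizontal order are uncorrelated by construction; islands in
  different bilayers of a stack are uncorrelated in-plane.
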