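# Methods

This note documents the models, conventions and numerical choices behind
`dostherm`, in the spirit of the methods documentation of packages like
statsmodels or msprime: what is computed, under which assumptions, and what
the synthetic validation does and does not establish.

## Conventions and units

Internal units are fs (time), nm/ps (velocity), amu (mass), THz (frequency)
and kJ/mol (energy); all heat capacities are reported in J/(mol K) and
diffusion coefficients in 10⁻⁹ m²/s. Physical constants are CODATA 2018,
with R = 8.31446 J/(mol K).

The mass-weighted velocity autocorrelation function is

    C(t) = Σᵢ mᵢ ⟨vᵢ(0)·vᵢ(t)⟩ / Σᵢ mᵢ ⟨vᵢ²⟩,

so C(0) = 1 by construction. The vibrational density of states is the
one-sided cosine transform

    S(ν) = 4 ∫₀^∞ C(t) cos(2πνt) dt,

chosen so that (i) the inverse cosine transform returns C(t), and (ii) the
norm ∫₀^∞ S(ν) dν equals C(0) = 1 exactly under the trapezoidal rule. Other
2PT codes often carry a dimensional 12mk_BT-style prefactor; comparisons
against them must rescale. All downstream formulas use this normalized
convention consistently.

C(t) is computed by FFT over all time origins (stride 1); the longest lag is
capped at half the trajectory span so every lag retains at least half the
origins. An optional block-averaged standard error uses 5 contiguous blocks.
No window function is applied by default. Negative spectral ripple from the
finite transform is retained in all integrals (clipping would bias them);
a clipped copy exists only for plotting.

## Integration rules

The transform is evaluated with a DCT-I, which reproduces the trapezoidal
quadrature exactly on the grid ν_j = j/(2NΔt); the left Riemann sum is
obtained from the same transform via the exact identity

    Riemann − trapezoid = Δt·(g(0) − g(t_max))/2

applied per frequency. The left Riemann rule exists purely to demonstrate
the systematic inflation it causes at coarse sampling (a documented source
of ~40% errors in published heat capacities and diffusivities); it is never
the default, it triggers a logged warning in the CLI, and its inflated norm
is deliberately *not* renormalized — the inflation is the phenomenon.
Trapezoid-rule VDOS with a norm off by more than 5% (badly converged input)
is renormalized with a warning before heat-capacity weighting.

## Heat-capacity models

With f degrees of freedom per molecule and the harmonic weight
W(x) = x²eˣ/(eˣ−1)², x = βhν:

- **1PT**: c_V = f R ∫ S W dν. Bounded above by f R; reaches it only in the
  classical limit or for spectral mass at ν = 0.
- **quantum correction**: c_VΔ = f R ∫ S (W−1) dν ≤ 0; identically
  c_V(1PT) − f R.
- **anharmonic correction**: AC = c_V^cl − f R, the deviation of the
  classical (fluctuation-derived) heat capacity from f classical harmonic
  oscillators.
- **1PT+AC**: c_V^cl + c_VΔ = f R + AC + c_VΔ. Both assemblies are computed
  and must agree to 1e-9; the h → 0 limit is c_V^cl exactly
  (correspondence principle).
- **2PT**: the VDOS is split S = S_gas + S_solid (below) and
  c_V = f R [∫ S_solid W dν + ½ ∫ S_gas dν]. In the classical limit this
  lies in [f R/2, f R], and it never exceeds 1PT.
- **2PT+AC**: c_V^cl + f R ∫ S_solid (W−1) dν. The gas weight ½ is
  h-independent, so it drops out of the quantum correction; the h → 0 limit
  is again c_V^cl, and 2PT+AC − 1PT+AC = f R ∫ S_gas (1−W) dν ≥ 0, small
  because the gas component lives at low frequency where W ≈ 1.

An `hbar_scale` knob multiplies Planck's constant in every weight so the
classical-limit statements are directly testable; it is not a physical
parameter. W is evaluated overflow-safely: the e⁻ˣ form everywhere, the
asymptotic x²e⁻ˣ for x > 700, and the series 1 − x²/12 for x < 1e-8,
keeping W C¹-smooth across the switches.

## The GSTA time-domain route

The 1PT integral can be evaluated without ever forming the VDOS:
c_V = f R ∫₀^∞ C(t) γ(t) dt, where γ is the one-sided cosine transform of
W. Carrying out the transform analytically (contour integration over the
double poles of csch²) gives the closed form

    γ(t) = (4π²/βh) · csch²θ · (θ coth θ − 1),   θ = 2π²t/βh,

with γ(0) = 4π²/(3βh). The implementation validates this closed form
against direct numerical quadrature of the transform (to ~1e-7 relative) in
the test suite — the identity c_V(GSTA) ≡ c_V(1PT) is a Parseval statement
and is asserted on every synthetic system. The kernel decays as
exp(−4π²t/βh), a ~4 fs time constant at 298 K, so a 68 fs VACF already
gives the converged answer at room temperature; the default truncation
scales with βh (∝ 1/T) at other temperatures. The lag spacing must resolve
the kernel (≤ βh/20, ~8 fs at 298 K). At `hbar_scale = 0` the kernel
degenerates to a delta at t = 0 and the route returns f R·C(0) = f R.

## Two-phase decomposition

The gas component follows the hard-sphere 2PT form: in the unit-norm molar
convention (N_mol = 1),

    S_gas(ν) = s₀ / (1 + (π f s₀ ν / (6 f_m N_mol))²),   s₀ = S(0),

which satisfies S_gas(0) = s₀ exactly and integrates to 3 f_m N_mol/f — the
fluidity fraction of the three translational DOF. Rotation is not split
separately (its gas component vanishes). The fluidity f_m is either
supplied or solved from the hard-sphere universal equation

    2Δ⁻⁹ᐟ² f_m¹⁵ᐟ² − 6Δ⁻³ f_m⁵ − Δ⁻³ᐟ² f_m⁷ᐟ² + 6Δ⁻³ᐟ² f_m⁵ᐟ² + 2f_m − 2 = 0

by bracketed root-finding on [0, 1]; the polynomial has exactly one root
there for every Δ > 0 (asserted by sign-change counting in the tests). The
dimensionless diffusivity Δ is built from s₀, T, the molecular mass and the
number density (from a user-supplied thermodynamic state).

Degenerate geometry: where the Lorentzian would exceed the total VDOS
(sharp solid-like spectra, negative ripple bins), the gas is capped at the
non-negative part of the total and the lost integral restored by rescaling
the capped gas shape into the remaining low-frequency headroom, iterating
until converged — this keeps the pointwise partition S_gas + S_solid = S
and S_gas ≥ 0 exact, at the cost of a slightly distorted gas line shape
(warned). Pinning a large fluidity on a system with s₀ ≈ 0 (no diffusive
motion) is an unphysical combination and produces a degenerate, very broad
Lorentzian; the auto route would give f_m ≈ 0 there.

The decomposition takes the *molecule* count, never the atom count; a
regression test asserts that the two give different answers for polyatomic
systems, guarding against a historical analysis-tool bug.

## Classical heat capacity and cp/cv conversion

The classical isobaric heat capacity comes from NpT enthalpy fluctuations,
c_p^cl = Var(H)/(R T² N_mol) with H the total system enthalpy in kJ/mol
(the molar image of Var(H)/(k_B T²)); uncertainty is block-averaged over 5
blocks, and at least 100 frames are required. The isochoric conversion uses
c_p − c_V = T α_p² M/(ρ κ_T); α_p and κ_T are *inputs* (experimental or
user-computed), since estimating them needs NpT volume series outside this
package's scope. For an ideal-gas state the identity returns exactly R —
the test oracle. For organic liquids the term is tens of J/(mol K), never
the ~0.1 J/(mol K) of some flawed prior analyses; a regression test pins
this with experimental state points for methanol, ethanol, acetone and
toluene. Water is a deliberate exception (its anomalously small α_p at
25 °C gives c_p − c_V ≈ 0.5 J/(mol K)) and is excluded from that guard.

## Self-diffusion

Both routes use molecular center-of-mass motion (standard for molecular
self-diffusion), while heat capacities use the atomistic VACF; the split is
configurable. Green–Kubo: D = (k_BT/M) ∫₀^{t_max} C_com dt with the COM
VACF normalized at lag 0 — for an Ornstein–Uhlenbeck velocity this is the
Langevin result k_BTτ/M, the generator-truth oracle. Einstein: the
two-point form [MSD(t₂) − MSD(t₁)]/(6(t₂−t₁)) at the customary 8 and 12 ps,
origin-averaged; a least-squares fit over the window exists behind a flag.
Wrapped coordinates (single-step displacement beyond box/2) raise; a
near-quadratic MSD over the window triggers a ballistic-regime warning. No
finite-size correction is applied. Default VACF truncation is 10 ps; this
is known to be short of full convergence for real liquids, a property of
the estimator, not of the implementation.

## Synthetic systems

The generators produce trajectories whose every analysis target has a
closed form:

- `harmonic_ensemble` — exactly integrated sinusoids; each Cartesian DOF is
  one mode, frequencies apportioned to the requested weights by largest
  remainder (deterministic, so the ground truth is exact), energies drawn
  from the canonical exponential distribution and phases uniform, so
  equipartition holds at T and the classical c_V is f R.
- `ou_gas` — the exact discrete OU update
  v' = v e^(−Δt/τ) + √(k_BT/m)·√(1−e^(−2Δt/τ))·ξ, positions by midpoint
  integration; VACF = e^(−t/τ), Lorentzian VDOS, classical c_V = R/2 per
  DOF, D = k_BTτ/m.
- `mixture` — per molecule, 3 OU center-of-mass DOF plus 3(p−1) internal
  harmonic DOF on an orthonormal basis of the COM-free subspace of p
  equal-mass atoms; ground truth is additive. The "methanol-like" fixture
  (6-atom molecules, modes at 3/10/30/90/111 THz over an OU block with
  τ = 150 fs) qualitatively mirrors a hydrogen-bonded liquid's spectral
  layout for convergence studies.

Resolution guards reject Δt > τ/5 or Δt > period/10. Randomness comes from
the counter-based Philox generator keyed by the seed, so output is
bit-reproducible.

What the synthetic battery does **not** show: real liquids have
anharmonic mode coupling, non-exponential memory, cross-correlations and
finite-size effects that these independent-DOF constructions lack. Passing
tests establish the correctness of the estimators and their identities, not
force-field accuracy; benchmarking against experimental heat capacities
requires user-supplied MD trajectories.

## Problem sizes and tolerances

The validation battery uses 16–64 molecules and 4 000–24 000 frames at
0.5–4 fs sampling — enough that sampling error sits well below the asserted
tolerances (0.5 J/(mol K) for transform-pair identities, 3 standard errors
for stochastic recoveries, 1e-9 for exact algebraic assemblies, 1e-12 for
quadrature identities). The GSTA kernel oracle and the fluidity bisection
oracle are brute-force recomputations independent of the implementation
paths they check. Einstein/Green–Kubo comparisons use ≥ 8 independent seeds
and combined standard errors.
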