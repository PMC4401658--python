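# Methods

## Model

One receptor binding an ensemble of ligands is described as a random
energy landscape.  Each ligand exposes N_t binding states whose
energies are i.i.d. Gaussian with mean Ē and standard deviation ΔE
(the roughness); the native (strongest) state sits at the low end of
the spectrum.  The microscopic justification is the pairwise-contact
Hamiltonian E = Σ J_ij σ_ij: with many contact types the couplings are
effectively Gaussian draws, so state energies are Gaussian with
Var E = N·ΔJ² for N active contacts (`synth.sample_contact_energies`
demonstrates the scaling).  Correlations between state energies are
neglected — the independent-states (REM) approximation — so every
distributional statement below inherits that first-order assumption.

Units: k_B = R = 1; energies and temperatures in kcal/mol (room
temperature T = 0.593); RMSD in Å; times in units of dx²/D, i.e. the
diffusion coefficient only rescales reported times.

The trapping temperature is Tc = ΔE/√(2S) with S = log Ω the
configurational entropy (S = log N_t when a state count is given).  It
follows from the Gaussian microcanonical entropy S(E) = S − E²/(2ΔE²)
reaching zero at the spectrum edge, and separates the self-averaging
regime (T > Tc: Gaussian/log-normal centers) from the glassy regime
(T < Tc: exponential/power-law tails).

## Analytic densities (`landscape`)

Every law is exposed as a normalized density with an explicit support:

- free energy: center Gaussian(F̄, ΔE²); tail (1/Tc)·exp[(F−Fc)/Tc] on
  F ≤ Fc with a hard step at the cutoff Fc (no smoothing).  Fc defaults
  to the freezing level Ē − ΔE√(2S); the derived mean free energy F̄
  is the annealed value Ē − ΔE²/(2T) − T·S.
- log K: center Normal with σ = ΔE/T (location free: the theory fixes
  shape, not position); K tail ∝ K^(−1−T/Tc).  Pure power laws are not
  normalizable on (0, ∞), so tails live on a bounded support with
  default span 10⁶.
- ISR center: the magnitude of the standardized minimum of N_t
  standard normals, f(x) = N_t φ(x) Φ(x)^(N_t−1) / (1 − 2^(−N_t)) on
  [0, ∞), with the closed-form CDF (Φ(x)^N_t − 2^(−N_t))/(1 − 2^(−N_t))
  used for KS tests.  ISR tail: exp[−(x+1)]·(1−exp[−(x+1)])^(N_t−1),
  implemented literally with the +1 shift; its normalization is closed
  form.  The printed form of the tail law is typographically ambiguous
  between ±1 in the exponent; the +1 reading is used and only affects
  the bracket term near x = 0, not the unit log-slope of the far tail.
- times: center log-normal with σ = ΔE/T (median = τ0 by default);
  tail ∝ τ^(−1−T/Tc) on a bounded support.

`AnalyticDensity` tabulates the CDF on a grid (geometric spacing for
the multiplicative-scale families K and τ) for inverse-CDF sampling;
normalization is verified by adaptive quadrature to 1e−6 in the tests.

## Per-ligand metrics (`spectrum`)

Given a spectrum {(E_i, RMSD_i)} with native index n:

- F̄ and ΔF are the mean and population (divide-by-N) standard
  deviation of the non-native states — roughness is a population
  parameter, so no Bessel correction.
- affinity = F_n − F̄ (≤ 0 by construction).
- F_un = −T log Σ exp(−E_i/T) over non-native states; log K =
  (F_n − F_un)/T.  The Boltzmann log-sum is used rather than the
  arithmetic mean because log K is a free-energy difference; the
  arithmetic mean is already consumed by the affinity definition.
- ISR = |F_n − F̄|/ΔF, invariant under energy shift and scale.
- ΔF is the per-ligand spectrum spread, not the ensemble-level ΔE:
  it is the only choice computable ligand-by-ligand, and it reduces to
  ΔE in expectation under the generating model.

Poses within `exclusion_radius` (default 1 Å) of the native RMSD are
assigned to the native basin and dropped from the non-native ensemble,
so F̄/ΔF describe genuinely non-native competition; pass 0 to keep
every pose (used by the order-statistics checks, where the native is
the spectrum minimum itself).

Stratification: RMSD bins of width `bin_width` from the native pose
outward, each carrying F(b) = −T log Σ_b exp(−E_i/T); empty interior
bins are linearly interpolated; fewer than two occupied bins is an
error.  The resulting uniform grid of bin centers plus a constant D is
the kinetics input.

## Kinetics (`kinetics`)

The binding coordinate is RMSD with locally connected dynamics, i.e.
1-D overdamped diffusion on F(RMSD).  τ_off is the MFPT from the
native end (reflecting) to the non-native end (absorbing),

    tau = (1/D) ∫ dx e^{F(x)/T} ∫_i^x dx' e^{-F(x')/T},

evaluated by nested trapezoids (exact on flat profiles: L²/(2D));
τ_on swaps the boundary roles, implemented by mirroring the profile.
D(RMSD) is constant by default — no functional form is imposed by the
theory — and since its value for a docking ensemble is unknown, all
times are relative (τ0 = 1 internal unit).

The independent oracle is the birth–death chain with
midpoint-exponential rates k_{j→j±1} = (D/dx²)·exp(∓ΔF/(2T)), which
satisfy detailed balance.  The reflecting start node represents half a
grid cell (vertex-centered finite volume): its escape rate is doubled
and its stationary weight halved.  Without the half-cell correction
the chain MFPT converges only first-order to the continuum integral
(a boundary Riemann-sum artifact of order dx/width-of-the-start-well,
several percent on rough funnels at 500 points); with it the flat
chain reproduces L²/(2D) exactly and rough-funnel agreement with the
quadrature is ~1% at 500 points.  `chain_fpt_moments` solves the exact
first three FPT moments from the generator, and `sample_fpt` draws
continuous-time trajectories (reproducible per seed) whose mean and
variance match the exact solves.

Kinetic trapping drives the FPT law toward the single-exponential
limit: for a 1-D chain the FPT is a sequential (hypoexponential-like)
mixture, so its skewness is bounded by 2 and a deep interior trap
raises it from the flat-profile value (~1.96) toward 2 while fattening
the relative tail.  Heavier-than-exponential (power-law) kinetics
emerges at the ensemble level, from exponentially distributed trap
depths (below), not from a single profile.

## Synthetic ensembles (`synth`)

The spectrum generator emulates an exhaustive docking run per ligand:

- N_t = 100 non-native poses, energies Gaussian(Ē = −6, ΔE = 2)
  kcal/mol — chosen so ensemble affinities fall in the −4 to −12
  kcal/mol window typical of small-molecule docking scores;
- one native pose at RMSD 1 Å with energy min(spectrum) − gap,
  gap = |Normal(2, 0.5²)| kcal/mol, realizing a funnel-consistent
  discrete native level below the quasi-continuous tail;
- non-native RMSD = 1 + 0.8·(E − E_min) Å + Normal(0, 1²), clipped to
  (1, 10] Å — a linear energy–RMSD coupling with noise, the minimal
  model that yields a funneled F(RMSD) after stratification (steeper
  slope ⇒ higher ISR ⇒ faster on/slower off);
- default ensemble size 720 ligands.

Per-ligand RNG streams are keyed by (root seed, ligand index), so
ensembles are bit-reproducible and order-independent.

Two analytic-law samplers complement the microscopic generator.
`sample_rem_ensemble` draws per-ligand affinity from
Normal(−3ΔE, ΔE²) — the ligand-to-ligand variability asserted by the
Gaussian free-energy law, where each ligand carries its own coupling
realization — with log K = affinity/T.  This is the generator for
parameter-recovery studies: the composite fit must return σ = ΔE
(affinity) and ΔE/T (log K).  The min-of-spectrum generator cannot
serve here: the spread of per-ligand minima is the extreme-value
width (≈ 0.45·ΔE at N_t = 100), intrinsically narrower than ΔE, which
is why the pipeline reports both the spectrum-level fit and the
landscape-level recovery check.  `sample_exponential_dos_times` draws
trap depths Exp(Tc) and residence times τ0·exp(depth/T), giving the
power-law tail exponent 1 + T/Tc exactly in distribution.

Profiles: `flat`, `linear_funnel` (slope in kcal/mol/Å away from the
native end), and `rough_funnel` (linear plus seeded Gaussian bumps,
amplitude in kcal/mol, correlation length `roughness_scale` = 0.5 Å by
default, generated by Gaussian-smoothing white noise and rescaling).

What the generators do *not* emulate: correlated pose energies,
non-Gaussian score distributions, receptor flexibility, multiple
native basins, RMSD measured against a crystal structure rather than
the best-scoring pose.  Passing tests therefore validate the
statistical machinery under the model's own assumptions, not the
accuracy of any docking score on real complexes.

## Distribution fitting (`distfit`)

The composite model mirrors how one fits a drawn histogram: least
squares on bin probability densities, not likelihood.

1. Robust center (median, 1.4826·MAD) defines the window ±1.5 robust
   sigmas (the crossover is not dictated by theory; the robust window
   is the reproducible choice).
2. Gaussian LSQ inside the window; bins by Freedman–Diaconis unless
   overridden.
3. Each exponential tail is a log-linear LSQ over the outside bins
   that hold ≥ 5 counts and exceed 1.5× the fitted Gaussian — the bins
   where the data has genuinely departed from the center.  Fits are
   weighted by √count (Poisson noise of log density).  A tail is
   flagged unreliable when too few bins qualify or when a quadratic
   term shows the log-density is curved (a Gaussian tail posing as
   exponential).
4. Junctions move to the crossing points of the pieces (a quadratic
   root); if the pieces never cross, the junction stays at the window
   edge and the tail amplitude is matched to the Gaussian there.  The
   composite is then globally renormalized, preserving continuity.

`fit_power_tail` maps a positive variable to y = log x, where a
power law x^(−1−λ) becomes Exp(λ): the exponent is α = 1 + λ from the
weighted log-space slope over the upper `tail_fraction` (default 0.2)
of the sample, with the Hill estimator 1 + 1/mean(y − y_thr) as an
independent ML cross-check and the same curvature test to reject
log-normal-like curvature.  The estimator is exactly scale-invariant.

## Pipeline (`pipeline`, `cli`)

`run_pipeline` chains simulate → metrics → kinetics → fits, writing
TSVs, per-observable fit JSONs, and a summary JSON that echoes the
full config and the built-in checks: pooled non-native energy sd vs
ΔE, and landscape-level recovery of ΔE (affinity) and ΔE/T (log K)
within 5%.  Summaries contain no timestamps or absolute paths, so a
(config, seed) pair reproduces byte-identical output; stage timings go
to stderr logging only.  A stage failure (e.g. a one-ligand ensemble
reaching the ≥100-value fit requirement) is recorded as
`failed_stage` and reflected in the exit status of `bindscape run`.

Configs are flat key=value text with dotted sections
(`ensemble.landscape.roughness = 2.0`); unknown keys are rejected by
name.

## Problem sizes and numerical choices

Analysis runs use 10⁵ ligands for extreme-value KS checks (expected KS
distance ≈ 0.003), 5000 ligands for parameter recovery (fit σ accurate
to ~2%), 500-point grids for MFPT (quadrature converged to ≪ 0.5%),
and 300–720-ligand pipelines; the full test suite and the acceptance
script each complete in well under a minute on one CPU.  Degenerate
inputs fail loudly: zero non-native spread (ISR undefined), constant
samples, single-bin profiles, non-positive temperatures or diffusion
coefficients all raise typed errors.

## Known limitations

- Independent-states approximation throughout; correlated landscapes
  (GREM-like) are out of scope.
- The power-law tails require a bounded support to normalize; reported
  tail exponents are insensitive to the span, but absolute tail
  densities are not.
- Kinetics is strictly 1-D in RMSD with constant D; no time-dependent
  populations P(RMSD, t) are computed, only first-passage functionals.
- The per-profile FPT distribution cannot exceed exponential skewness;
  fat-tailed kinetics is an ensemble statement.
- Log K locations (and τ medians) are free parameters of the center
  laws; only widths and tail exponents are theory-constrained.
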