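# bindscape

Statistical energy-landscape analysis of biomolecular recognition.

When many different ligands are docked against one receptor (or one
ligand explores many binding sites), the binding observables —
affinity, equilibrium constant, intrinsic specificity, on/off kinetics
— are not single numbers but *distributions* across the ligand
ensemble.  Modelling the binding states of each ligand as a random
energy landscape (i.i.d. Gaussian state energies with mean Ē and
roughness ΔE) predicts universal shapes for these distributions, and
`bindscape` implements the whole analysis chain:

* **Analytic laws** (`bindscape.landscape`).  With trapping temperature
  T<sub>c</sub> = ΔE/√(2S) (S = log N<sub>t</sub> the configurational
  entropy), the free energy F is Gaussian with spread ΔE above
  T<sub>c</sub> and exponential, ∝ exp[(F−F<sub>c</sub>)/T<sub>c</sub>]
  for F ≤ F<sub>c</sub>, below it; the equilibrium constant K is
  log-normal near the mean (σ = ΔE/T) with a power-law tail
  K<sup>−1−T/T<sub>c</sub></sup>; the intrinsic specificity ratio
  ISR = |F<sub>n</sub> − F̄|/ΔF follows the extreme-value density of the
  standardized minimum of N<sub>t</sub> Gaussians,
  f(x) ∝ exp(−x²/2)·Φ(x)<sup>N<sub>t</sub>−1</sup>, with an exponential
  far tail; binding times are log-normal near the mean and power-law,
  τ<sup>−1−T/T<sub>c</sub></sup>, in the slow tail.  All densities are
  normalized, evaluable, and sampleable objects.
* **Per-ligand metrics** (`bindscape.spectrum`).  From a binding
  spectrum — the list of (pose energy, RMSD-to-native) states of one
  ligand — compute affinity F<sub>n</sub> − F̄, log K =
  (F<sub>n</sub> − F<sub>un</sub>)/T with F<sub>un</sub> the Boltzmann
  free energy of the non-native ensemble, the ISR, and the
  RMSD-stratified free-energy profile F(RMSD).
* **Kinetics** (`bindscape.kinetics`).  Mean first-passage times on
  F(RMSD) by the diffusion double integral (reflecting at the native
  end, absorbing at the non-native end for τ<sub>off</sub>; boundaries
  swapped for τ<sub>on</sub>), cross-checked against the exact
  birth–death-chain solve, plus stochastic first-passage-time sampling.
* **Distribution fitting** (`bindscape.distfit`).  The composite model
  the histograms call for — a Gaussian center with exponential tails
  joined at their crossing points — and a power-law tail exponent
  estimator (log-space slope with a Hill ML cross-check).
* **Synthetic ensembles** (`bindscape.synth`).  Generators that emulate
  docking data: Gaussian non-native spectra with a funneled
  energy–RMSD correlation and a native pose a gap below the spectrum
  minimum; a pairwise-contact Hamiltonian (Var E = N·ΔJ²); analytic-law
  samplers for parameter-recovery studies.

Energies and temperatures are in kcal/mol with k<sub>B</sub> = 1
(kT ≈ 0.593 kcal/mol at 298 K); times are in units of dx²/D.

## Worked example

```python
import numpy as np
import bindscape as bs

# a 720-ligand synthetic ensemble: Gaussian spectra, roughness 2 kcal/mol
spec = bs.EnsembleSpec(num_ligands=720, seed=7)
sp = bs.generate_spectrum(spec, 0)

m = bs.compute_metrics(sp, T=0.593)
print(f"ligand {m.ligand_id}: affinity = {m.affinity:.2f} kcal/mol, "
      f"logK = {m.logK:.2f}, ISR = {m.isr:.2f}")

prof = bs.stratify_profile(sp, T=0.593, bin_width=0.5)
kin = bs.kinetics_for_profile(prof, T=0.593)
print(f"tau_on = {kin.tau_on:.3g}, tau_off = {kin.tau_off:.3g}, "
      f"barrier_off = {kin.barrier_off:.2f} kcal/mol")

mets = [bs.compute_metrics(bs.generate_spectrum(spec, i), T=0.593)
        for i in range(spec.num_ligands)]
fit = bs.fit_composite(np.array([x.affinity for x in mets]),
                       variable_name="affinity")
print(f"affinity center: mu = {fit.mu:.2f}, sigma = {fit.sigma:.2f} kcal/mol")
```

prints

```
ligand L00000: affinity = -6.74 kcal/mol, logK = -3.97, ISR = 4.26
tau_on = 5.94, tau_off = 5.08e+05, barrier_off = 9.02 kcal/mol
affinity center: mu = -7.07, sigma = 0.91 kcal/mol
```

The first ligand binds about 6.7 kcal/mol below its own non-native
average and sits 4.3 non-native spreads below it (its intrinsic
specificity); its funneled profile makes binding fast (τ_on ≈ 6) and
escape slow (τ_off ≈ 5×10⁵, a 9 kcal/mol barrier).  Across the
ensemble the affinity histogram has a Gaussian center near −7 kcal/mol
whose width reflects the order statistics of each spectrum's minimum —
narrower than the 2 kcal/mol state-level roughness.

The same analysis is scriptable end to end:

```sh
bindscape run --config config.txt --outdir out/   # or: simulate, metrics,
                                                  # kinetics, fitdist, density eval
```

which writes the ensemble/metrics/kinetics TSVs, one fit JSON per
observable, and a deterministic `summary.json` with built-in
parameter-recovery checks.

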