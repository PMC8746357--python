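# Methods

This note records the models implemented in `retspec`, the defaults and the
reasoning behind them, what the synthetic fixtures do and do not emulate,
and the numerical conventions a user should know before trusting a number.

## Ensemble absorption spectra

A snapshot ensemble contributes one stick spectrum per snapshot: vertical
excitation energies (eV) with oscillator strengths. Each snapshot's sticks
are broadened with a Gaussian band shape in the peak-height convention,

    I(E) = Σ_i f_i · exp(−(E − E_i)² / 2σ²),

and the ensemble spectrum is the pointwise arithmetic mean of the
per-snapshot curves on a common energy grid. Because the Gaussian sum is
linear, averaging broadened spectra is identical to broadening all pooled
sticks with weight 1/N — a property the tests check to 1e-12.

Choices and their defaults:

* **σ = 0.15 eV**, interpreted as the Gaussian standard deviation. A width
  quoted without qualification could also mean FWHM; `width_is_fwhm=True`
  switches convention (σ = FWHM/2.3548). The default is the common usage in
  vertical-excitation broadening.
* **Oscillator-strength weighting** is on by default; an unweighted mode
  exists for sensitivity checks.
* **Energy grid 1.5–4.0 eV at 0.001 eV**. Averaging is done on an energy
  grid; a wavelength-grid mode is available because intensity-per-nm and
  intensity-per-eV maxima differ slightly for broad bands.
* **λ_max = hc/E_max with hc = 1239.84193 eV·nm**, which reproduces
  standard published (nm, eV) pairs at their printed 2-decimal precision.
* Ties in the argmax resolve toward the lowest energy; an identically flat
  spectrum is returned flagged `degenerate` rather than raising, and shift
  computation refuses degenerate summaries.

## Pocket geometry statistics

* **Pair distances** are plain Euclidean per-frame distances between two
  single-atom selections; the summary is the mean and the n−1 sample
  standard deviation.
* **Hydrogen-bond occupancy** uses the geometric criterion
  D···A ≤ 3.5 Å and D–H···A angle ≥ 120°, configurable. These are the most
  common defaults; the synthetic fixtures place contact and non-contact
  geometries well away from both thresholds, so fixture-derived occupancies
  are insensitive to the exact criterion.
* **Integrated water RDF**: each water oxygen contributes at its minimum
  distance to any chromophore *heavy* atom, and the curve is the
  frame-averaged cumulative count — not a density-normalised g(r), which is
  deliberately out of scope. A per-atom reference mode (`heavy_only=False`)
  exists. Oxygens, not whole waters, are counted.
* No periodic minimum-image correction by default, since the analyses
  operate on extracted pocket models; `use_box=True` enables orthorhombic
  minimum-image distances.

## Electrostatics and the tuning descriptor

The environment potential is the unscreened Coulomb sum
Φ(r) = 332.0637 Σ q_i/r_i kcal/(mol·e). This is a deliberate model
substitution for a Poisson–Boltzmann solve: with no dielectric screening
the absolute values are not comparable to solvated-continuum maps, but the
sign and locality structure — which end of the chromophore the environment
stabilises — is preserved, and only such sign/ordering statements are made
or tested.

* **Environment selection** is whole-residue: a residue enters if any atom
  lies within the cutoff (default 50 Å) of any chromophore atom, and the
  chromophore's own residue is excluded. Membership is monotone in the
  cutoff by construction.
* **Surface projection** samples each atom's Bondi vdW sphere (scale 1.0)
  with a Fibonacci lattice and discards points inside any other atom's
  sphere.
* **Tuning descriptor**: Φ averaged over the Schiff-base region atoms
  (default {C15, N15, H15}) minus Φ averaged over the β-ionone ring carbons
  (default {C1–C6}); both atom-name sets are configurable since the
  moieties, not exact atom lists, define the model. Δ < 0 predicts a blue
  shift relative to vacuum (ground-state stabilisation of the
  Schiff-base-localised positive charge). In the study pipeline the
  descriptor is averaged over 200 frames by default: the per-frame spread
  (sd ≈ 10 kcal/(mol·e) on the packaged fixtures) is large relative to the
  ~5 kcal/(mol·e) separation between isomer means, so the isomer ordering
  is an ensemble-mean statement, not a per-frame one.

## Restrained ESP charge fitting

Single-stage RESP-style fit: minimise the squared ESP residual pooled over
conformers plus the hyperbolic restraint a·Σ(√(q²+b²)−b) with b = 0.1 e,
subject to a total-charge constraint, exact equivalence within groups, and
frozen charges. The restraint weight (default a = 0.005) multiplies the
penalty directly with potentials in kcal/(mol·e); the restrained set is
supplied by the caller (conventionally the heavy atoms, with hydrogens
unrestrained but equivalence-constrained).

Numerics: equivalence groups and frozen charges are eliminated by variable
reduction (q = Tp + q0); the total charge adds one Lagrange multiplier,
with the constraint row scaled to the magnitude of the normal matrix so the
KKT condition number reflects genuine degeneracy rather than units. The
nonlinear restraint is handled by iterative re-linearisation (diagonal term
a/√(q²+b²) at the current iterate), converged when max|Δq| < 1e-6 e, capped
at 200 iterations (`converged=False` is reported, never raised). A KKT
condition number above 1e10 or a singular solve raises a rank-deficiency
error naming the offending atoms. With a = 0 and a self-consistent grid the
fit recovers the generating charges exactly; this is the well-posedness
test. A two-stage refit protocol is intentionally out of scope.

## Normal-mode Boltzmann sampling

Classical canonical sampling of independent harmonic modes: per-mode energy
E ~ Exponential(kT) (the classical 1-D oscillator energy distribution) and
a uniform phase φ splitting E into potential and kinetic parts,
Q = (√2E/ω)sinφ, Q̇ = √2E cosφ, mapped to Cartesians through the
orthonormal mass-weighted displacement vectors. The random-phase split is a
choice — an all-kinetic start would thermalise to the same ensemble but is
not what "sampling a Boltzmann distribution of energies" most naturally
means for an oscillator. No zero-point energy is added (a Wigner mode is
out of scope), so ⟨E⟩ = kT per mode exactly in expectation. Internal units
are amu/Å/ps with 1 kcal/mol = 418.4 amu·Å²/ps² (thermochemical calorie)
and kB = 0.0019872 kcal·mol⁻¹·K⁻¹. Rotational/translational modes must be
projected out upstream; the container enforces strictly positive
frequencies and orthonormal displacements rather than fixing them silently.

## Synthetic fixtures: what they emulate, what they do not

`generate_trajectory` builds a geometric scaffold, not physics: a static
retinal-like chromophore (Schiff base at the origin, polyene chain along
−x, six-carbon ring at the far end), acceptor atoms for the labelled pocket
residues, and a shell of waters with oxygen oriented toward the positively
charged Schiff base (cation solvation). Controlled statistics:

* labelled pair distances: independent truncated-Normal draws (> 1.5 Å)
  per frame along a fixed per-pair direction; an AR(1) autocorrelation knob
  exists but defaults off, since time-average summaries are insensitive to
  it;
* contact partners: per-frame Bernoulli draws placing the acceptor either
  in hydrogen-bond geometry (D···A uniform in 2.6–3.4 Å, near-linear angle)
  or clearly out of it (4.5–6.0 Å);
* per-snapshot S1 energies: Normal around the environment-specific mean
  with sd 0.08 eV — a free smoothing parameter chosen to make 100-snapshot
  broadened spectra smooth, not an estimate of any real ensemble's spread;
* water counts per isomer (6/5/3 for 9-cis/11-cis/all-trans) follow the
  qualitative ordering of pocket hydration across the isomer models.

Limitations to keep in mind: frames are uncorrelated in time (no diffusive
dynamics); the chromophore is internally rigid; the Y126 partner is driven
through its distance distribution only — a single atom cannot independently
realise both a ~3 Å mean distance and a modest hydrogen-bond occupancy, so
fixture Y126 occupancies are not meaningful; and fixture partial charges
are plausible force-field-like values, not fitted ones. Consequently,
passing recovery tests demonstrates that the *analysis operations* are
correct and statistically calibrated — not that the generator reproduces
real pocket dynamics.

## Problem sizes

Defaults used by the study recipe and the reproduction script: 100
spectrum snapshots per environment (a 1-ns trajectory sampled every 10 ps),
2000-frame ensembles for distance statistics, 5000 frames for occupancy
(binomial standard error ≈ 0.7 percentage points), 200 frames for the
ensemble tuning descriptor, and 10⁴ draws for equipartition checks. At
these sizes every recovery lands within 3 standard errors of its configured
parameter and the whole suite runs in seconds on one CPU.
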