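# retspec

Ensemble spectral-tuning analysis for retinal-protein binding pockets.

Visual pigments and other rhodopsins tune the absorption maximum of one and
the same chromophore — the retinal protonated Schiff base (RPSB) — over a
wide wavelength range purely through the protein environment. Computational
studies of this effect typically sample snapshots from a molecular-dynamics
trajectory, compute a vertical S0→S1 excitation per snapshot, and assemble
an ensemble absorption spectrum, then rationalise the resulting shifts
through the binding-pocket geometry and electrostatics. `retspec` packages
the *analysis layer* of that workflow — everything downstream of the MD and
electronic-structure engines — as a reusable, fully tested Python library
with a CLI, exercised end-to-end on synthetic three-isomer (9-cis, 11-cis,
all-trans) pocket ensembles.

## What it computes

* **Ensemble spectra** — per-snapshot stick spectra `(E_i, f_i)` are
  broadened with a Gaussian band shape,
  `I(E) = Σ_i f_i · exp(−(E−E_i)²/2σ²)` (default σ = 0.15 eV), averaged
  pointwise over snapshots, and summarised by the absorption maximum
  `λ_max = hc/E_max` (hc = 1239.84193 eV·nm). Shifts between spectra
  (protein vs vacuum, isomer vs isomer) are signed differences of `E_max`.
* **Pocket geometry** — pair-distance statistics (e.g. Schiff-base N to
  counterion O), geometric hydrogen-bond occupancies (D···A ≤ 3.5 Å,
  D–H···A ≥ 120° by default), and the integrated radial distribution
  function of waters around the chromophore (frame-averaged cumulative
  water count vs radius).
* **Electrostatics** — bare Coulomb potential `Φ = k Σ q_i/r_i`
  (k = 332.0637 kcal·Å/(mol·e²)) of the whole-residue environment within a
  cutoff, projected onto the chromophore's Bondi van der Waals surface, and
  the external point-charge tuning descriptor
  `Δ = Φ_SB − Φ_ring`: an environment more negative at the Schiff base than
  at the β-ionone ring (Δ < 0) stabilises S0 preferentially and predicts a
  blue shift.
* **Charge fitting** — single-stage restrained ESP (RESP-style) fitting of
  atomic point charges to reference potentials over stacked conformers,
  with a hyperbolic restraint `a(√(q²+b²)−b)` on selected atoms,
  equivalence groups, frozen charges, and an exact total-charge constraint.
* **Normal-mode sampling** — classical Boltzmann sampling of harmonic
  initial conditions: per-mode energy `E ~ Exp(kT)`, random phase split
  into position and velocity, satisfying equipartition `⟨E⟩ = kT`
  (0.59616 kcal/mol at 300 K).

The synthetic-data module generates pocket trajectories, stick-spectrum
tables, and ESP grids as pure functions of (config, seed); the packaged
fixture configs encode published binding-pocket statistics of the jumping
spider rhodopsin-1 isomer models, so downstream analyses act as
parameter-recovery exercises.

## Worked example

Generate a 9-cis pocket ensemble (2000 frames, 100 spectrum snapshots) and
analyse it:

```bash
retspec synth --isomer 9-cis --n-frames 2000 --n-snapshots 100 --seed 1 --out demo
retspec spectra --sticks demo/sticks_protein.tsv --out demo/protein
retspec spectra --sticks demo/sticks_vacuum.tsv  --out demo/vacuum
retspec distances --traj demo/trajectory.xyz --template demo/template.pdb \
    --a RET/1/N15 --b GLU/194/OE1 --out demo/d_e194.tsv
retspec hbonds --traj demo/trajectory.xyz --template demo/template.pdb \
    --acceptor MET/103/SD --out demo/occ.json
```

which prints

```
e_max = 2.565 eV (483 nm, 100 snapshots)
e_max = 2.385 eV (520 nm, 100 snapshots)
RET/1/N15···GLU/194/OE1: mean 6.945 Å, sd 0.305 Å
occupancy(MET/103/SD) = 39.0%
```

Read: the protein-environment ensemble peaks at 2.565 eV (483 nm) and the
vacuum ensemble at 2.385 eV — a 0.18 eV blue shift from embedding the
chromophore in the protein. The counterion stays ~6.9 Å from the Schiff
base (too far for a direct contact), while the Schiff base hydrogen-bonds
to the M103 sulfur in 39% of frames. All numbers recover the fixture's
configured statistics within sampling error.

`retspec study --out results/` runs the full three-isomer recipe (spectra,
shifts, distances, occupancies, integrated RDF, tuning descriptor) and
writes a single deterministic JSON report plus TSV artifacts.

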