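# gopull

Coarse-grained, structure-based (Gō-model) protein pulling simulations with
three free-energy/work estimators along the end-to-end reaction coordinate,
plus the trajectory analyses needed to characterize mechanical unfolding
pathways of α-helix bundles.

What's inside:

- **`structure_io`** — PDB reading (Cα chains with retained heavy atoms,
  altloc resolution by occupancy), PDB/XYZ writing, a Cα-geometry helix
  detector, and a deterministic synthetic helix-bundle generator so the whole
  pipeline is testable without downloading structures.
- **`go_model`** — native contact maps by the heavy-atom overlap criterion
  (van der Waals radii enlarged 1.24×, sequence separation ≥ 3) and the full
  force field: harmonic backbone bonds, a local chirality restraint, native
  Lennard-Jones contacts with uniform well depth 1 ε and minima at native
  distances, and purely repulsive interactions below 4 Å for all other pairs.
- **`langevin_engine`** — overdamped Langevin (Brownian) dynamics in reduced
  units (Å, ε, τ): kT = 0.3 ε, γ = 2m/τ, noise dispersion 2γkT, dt = 0.005 τ.
  Numba-compiled kernels with an explicitly seeded RNG give bit-reproducible
  trajectories. Includes 1D polynomial test systems for estimator validation.
- **`pulling_smd`** — constant-velocity pulling with elastic springs on both
  termini (defaults 0.12 ε/Å² and 0.005 Å/τ), force–extension traces,
  accumulated pulling work, and rupture-peak detection.
- **`boxed_md`** — boxed dynamics on the end-to-end coordinate: wall-hit
  counting with reflective velocity inversion, box-to-box rate constants from
  hits per residence time, and PMF assembly via ΔG = −kT·ln(k_fwd/k_bwd)
  with Poisson or residence-segment error bars.
- **`umbrella_wham`** — umbrella windows (seeded from pulling frames, first
  third discarded as equilibration) and a self-consistent WHAM solver with
  block-bootstrap PMF errors; physical-unit umbrella constants
  (kJ/mol·nm⁻²) are converted through ε = 110 pN·Å ≈ 6.62 kJ/mol.
- **`unfolding_analysis`** — helicity versus extension, per-helix-pair native
  contact fractions Q, attached-helix state classification (five-helix /
  three-helix / zero-helix …), detachment extensions, unfolding-event
  detection on PMF or force profiles, and a replica census that counts
  which three-helix intermediate survives.

## Command line

```bash
gopull fixture --helices 4 --len 15 --loop 4 --seed 1 -o bundle.pdb
gopull model bundle.pdb -o model.json          # contacts + topology + helices
gopull pull model.json --replicas 4 --seed 7 -o pull/
gopull bxd model.json --box-width 0.5 --events 600 --range 12 -o bxd/
gopull analyze pull/ model.json -o report/
```

`model` also works on real PDB files, e.g.
`gopull model 2L7A.pdb --residues 796-909 -o r3.json`.

## Units

Lengths in Å, energies in ε (110 pN·Å ≈ 6.62 kJ/mol), times in τ (~1 ns),
temperature as kT/ε (0.3 at room temperature). `gopull.units` holds the
conversions.
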