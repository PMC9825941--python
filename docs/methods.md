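# Methods

This note records the model behind `ensemblecd`, the parameter defaults
and why they were chosen, the numerical conventions, and what the
synthetic generators do and do not emulate.

## Model and assumptions

The package computes ensemble-averaged UV/ECD spectra in four coupled
steps.

**1. Essential dynamics.** Internal fluctuations are separated from
rigid-body motion by iteratively superposing every frame onto the mean
structure (mass-unweighted Kabsch fit; the covariance analysed afterwards
is positional, so mass weighting would be inconsistent). The 3n × 3n
covariance of the superposed analysis selection is built with the
population divisor 1/N — its eigenvalues are then mean-square fluctuations
in nm²; at MD frame counts the 1/(N−1) distinction is immaterial.
Eigenvalues are sorted descending (ties keep the original index order and
are logged), clamped at zero below −10⁻¹² relative round-off, and each
eigenvector's largest-magnitude component is made positive so projections
are reproducible across runs and platforms. The analysis selection
defaults to the peptide backbone, read as {N, CA, C} per residue:
hydrogens and the carbonyl oxygen are excluded, which keeps the covariance
focused on torsional rather than librational motion; the selection grammar
lets users include O or side-chain atoms if they prefer.

**2. Free-energy landscape.** The first two principal components are
histogrammed (default 100 × 100 bins over the data range, half-open bins
with the last bin closed) and converted to F = −RT ln(n/n_max) with
R = 8.31446 × 10⁻³ kJ/(mol K); temperatures are entered in °C and
converted once via T(K) = T(°C) + 273.15. Basins are the 4-connected
components of populated cells with F at or below a cutoff (default
3 kJ/mol, the window from which representative structures are drawn; pass
`inf` to assign every populated frame). Connected-component labelling was
chosen over watershed segmentation as the simplest rule that reproduces
visually separated basins; merging of basins that touch below the cutoff
is the known cost and is accepted. Basin weight P(i) is the member-frame
fraction of *all* frames, so ΣP(i) ≤ 1: the deficit (frames above the
cutoff) is logged and weights are renormalized only when spectra are
combined. ΔG°ᵢ = −RT ln(P(i)/P_ref) against the most populated basin
assumes negligible partial-molar-volume and vibrational-partition-function
differences between basins — the usual reading of relative conformer
free energies from constant-volume sampling.

Representatives: k = 1 returns the member frame nearest the basin
centroid in the essential plane; k > 1 runs k-means (fixed seed, default
0) and returns per-cluster medoids, the member minimizing the summed
in-cluster distance, ties broken toward the lowest frame index.
Representatives are exported as structures for external quantum-chemical
relaxation; the package does not itself perform the constrained geometry
optimization that should precede excited-state calculations.

**3. Solvation-shell clusters.** A constrained trajectory (solute frozen,
verified to within 10⁻⁶ nm; larger drift is an error, since the whole
construction presumes one fixed solute conformation) is reduced per frame
to the solute plus the N solvent molecules closest in the solute-shaped
ellipsoid metric m = Σₖ((Δ·uₖ)/aₖ)², with axes from the solute's
single-structure gyration tensor and semi-axes the maximum atom projection
per axis plus a padding (default 0 nm). The anisotropic metric keeps the
selected shell conformal with an elongated solute where a spherical cutoff
would over-collect at the waist. Distances are minimum-imaged in the cubic
box; molecules are kept whole and shifted as rigid units into the
solute-centred cell. The ranking site is the water oxygen when one is
recognizable, else the centre of geometry (configurable). Ties at the N-th
rank resolve to the lower molecule id.

Cluster ED runs on the slot-ordered solvent site coordinates (the frozen
solute would contribute exact zeros). Slot ordering by ascending metric is
what makes chemically identical solvent molecules comparable across
frames; its cost is that identity swaps between equal-metric molecules
appear as spurious coordinate jumps that blur the cluster covariance and
fragment the solvent landscape. This is visible in practice as many
small basins around the dominant ones; the hierarchical weights
p(j,i) = (basin-j fraction) × P(i) still sum correctly (Σⱼ p(j,i) = P(i)
at infinite cutoff, deficit reported otherwise), and recovery tests group
fragments by their generating state. Solvent covariances with trace below
10⁻²⁴ nm² per degree of freedom are treated as frozen (single basin).

**4. Spectra.** Stick spectra are broadened with Gaussians using
σ = HWHM/√(ln 2). The default HWHM is 0.4 eV — the value matching the
experimental resolution for the short cationic tripeptide the protocol was
developed on; 0.3 eV suits the larger elastin-like decapeptide. The molar
absorptivity prefactor is 2.870 × 10⁴ (ε in M⁻¹ cm⁻¹ with f
dimensionless and energies in eV); the CD prefactor is 1/(2.297 × 10⁻³⁹)
applied to rotatory strengths in raw cgs. Files carry R in 10⁻⁴⁰ cgs (the
near-universal excited-state-code output convention) and are rescaled
internally; `rotatory_units: raw_cgs` covers tables already in raw cgs.
The default grid is 2000 uniform energy points spanning 170–260 nm
(nm↔eV via 1239.84193 eV·nm). Weighted combination renormalizes by the
weight sum by default, since basin weights sum below 1; raw summation is
available for pre-normalized weights.

## Synthetic generators

The generators provide ground truth, not physics:

* `gen_conformer_trajectory` — a 9-bead three-residue backbone (N, CA, C
  beads) with two rigid reference shapes, a compact arc and an extended
  zig-zag, mimicking the folded/extended distinction at topology level
  only. Frames are drawn from a Markov chain (default: i.i.d. at the
  stationary distribution, default populations 0.7/0.3 — a realistic
  two-state split giving |ΔG| ≈ 2 kJ/mol at room temperature), plus
  isotropic Gaussian noise (σ = 0.01 nm, small against the ~0.1 nm
  conformer separation so basins are well resolved) and a uniformly random
  rigid motion per frame that the superposition stage must remove. True
  labels are returned for recovery tests.
* `gen_solvated_constrained` — the solute frozen at the centre of a
  periodic cubic box; rigid 3-site waters (0.0957 nm O–H, 104.5° H–O–H, so
  the oxygen-vs-centre-of-geometry site policy is exercised) at
  liquid-like density (default 600 molecules in a 2.7 nm box ≈ 30 nm⁻³),
  placed with a 0.15 nm minimum O–O distance by rejection sampling. A
  small switchable shell (default 8 molecules) jumps between two radii
  with a frame-level two-state occupancy, creating exactly two solvent
  basins with known weights; everything else is fixed up to a 0.004 nm
  jitter. What this does **not** emulate: solvent diffusion and exchange,
  hydrogen-bond structure, realistic shell occupancy fluctuations —
  passing tests show the bookkeeping (selection, slotting, weighting) is
  right, not that real constrained MD will give such clean landscapes.
* `gen_stick_spectrum` — reproducible random sticks (energies uniform on
  4.8–7.3 eV ≈ 170–260 nm, f uniform on [0, 0.3], R normal with σ = 10 in
  10⁻⁴⁰ cgs, magnitudes typical of peptide backbone transitions); the
  label is hashed into the stream so distinct conformations get distinct
  spectra at the same seed.

All generators are seed-deterministic (NumPy `default_rng`).

## Numerical choices and degenerate inputs

* Internal unit is nm; Å-based formats are converted only at the file
  boundary. Only cubic boxes are supported; triclinic input is an explicit
  error. The placeholder 1 Å × 1 Å × 1 Å cell some writers emit for
  non-periodic data is read as "no box".
* Minimum-image components lie in (−box/2, box/2]; the exact half-edge
  folds to the positive side.
* Superposition: iterative fit starts from the mean of the raw
  coordinates, making the procedure idempotent on an already-fitted
  trajectory; convergence when the mean moves < 10⁻⁶ nm RMS, capped at 50
  iterations (logged). Collinear or < 3-atom fit selections are a rank
  error; the proper-rotation branch is always taken.
* Degenerate landscape (all frames in one cell) is a warning and yields a
  single basin. A planar/linear solute gets its vanishing ellipsoid
  semi-axes floored at the padding (warned).
* Problem sizes in the shipped checks were chosen so the whole suite and
  the acceptance script run in well under a minute: the landscape-recovery
  check uses 10⁶ sampled points (sampling error ~0.01 kJ/mol, below the
  0.1 kJ/mol reporting grain), the cluster-cardinality check a 600-water
  box over 20 frames, and the half-width check a 10⁻⁴ eV grid.

## Known limitations

* Basin detection is 2-D only. For chromophore–solvent clusters the
  eigenvalue spectrum is intrinsically flat, so two principal components
  under-resolve the solvent repertoire; this is accepted as the standard
  compromise and surfaces as the fragmentation discussed above.
* Slot ordering is an approximation wherever solvent molecules trade
  places at equal metric values; the blurring grows with the number of
  near-threshold molecules.
* No kinetics: basin populations are equilibrium weights; transition
  rates between basins are out of scope.
* The package neither runs MD nor any electronic-structure method, and it
  does not perform the constrained relaxation of extracted structures;
  representatives and clusters are exported for external codes.
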