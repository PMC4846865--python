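# Methods

This note records the statistical models behind each analysis stage, the
conventions and numerical choices in force, what the synthetic generators do
and do not emulate, and the known limitations.

## Ensembles, selections, superposition

An ensemble is an ordered stack of coordinate frames (Å) over one topology.
Residue identity is PDB author numbering plus insertion code throughout; no
renumbering is applied, so residue references in output match the depositing
authors' numbering.  Alternate locations collapse to the highest-occupancy
conformer (ties by altloc letter).  Superposition is the Kabsch rigid-body
least-squares fit of a selection (typically all Cα) onto a reference frame,
with a determinant guard so reflections are never produced; a selection
whose reference coordinates are collinear (rank < 2 after centering) is
rejected.  Multi-model PDB is the interchange format (written via biotite at
the format's three-decimal precision); other trajectory formats can be added
behind the same `Ensemble` contract.

## Fluctuations and B-factors

RMSF is taken about the ensemble-mean position,
`RMSF_i = sqrt(⟨|r_i − ⟨r_i⟩|²⟩)` — the standard definition; using frame 1
as reference instead would inflate values by the frame-1 offset.  The
equivalent isotropic temperature factor is `B = (8π²/3)·RMSF²` (Å²), an
exact bijection on RMSF ≥ 0.  Distance monitors report per-frame Euclidean
distances with a centered running mean truncated at the series edges
(trailing averages would lag transitions; centered was chosen and is noted
here because either convention is defensible).  Snapshot RMSD matrices
superpose every snapshot pair on the analysis selection before the RMSD, so
rigid-body drift between simulations never contributes; block summaries are
unweighted means over all cross-snapshot pairs of a (simulation, simulation)
block, with diagonal blocks restricted to distinct pairs.  Groove-width
style monitors default to Cα–Cα distances with configurable atom names.

## Order parameters

Bond vectors are Cα→Cβ, or Cα→Hα for glycine (a glycine without an Hα is an
error, never a silent skip).  The iRED route builds the M×M matrix
`A_ij = ⟨P2(μ̂_i·μ̂_j)⟩`, eigendecomposes it, and computes
`S²_i = 1 − Σ λ_m e²_{m,i}` over all but the `n_excluded = 5`
largest-eigenvalue modes — the five reorientational modes of the standard
iRED separation.  The default of 5 is exposed as a parameter and recorded in
output, because the trajectories this package consumes are usually already
superposed; the cross-check estimator quantifies what exclusion costs.

**Finite-size bias.** For motions with no collective component the spectrum
has no reorientational gap: by the spherical-harmonic addition theorem the
static part of `A` is a rank-5 Gram matrix plus `(1−S²)·I`, so excluding 5
of M modes removes ≈ `(1−S²)·5/M` of genuinely internal variance and iRED
estimates sit above the direct estimator by that amount.  At M = 20 the bias
is ≈ 0.21 — not a defect of the implementation but of applying mode
exclusion to tiny vector sets.  Tests therefore compare iRED against the
analytic cone value at M = 400 (bias ≈ 0.011, inside the 0.02 tolerance)
and against the direct estimator at M = 100 (bias ≈ 0.043, inside 0.05).
The direct estimator `S² = (3 Σ_{ab} ⟨μ_a μ_b⟩² − 1)/2` is bias-free and
serves as the oracle.  Degenerate eigenvalues are ordered deterministically
and eigenvector signs fixed (first non-negligible component positive).
Values in (−1e−6, 0) clamp to 0.

## Correlation matrices and community networks

DCCM entries are normalised displacement covariances clamped to [−1, 1];
zero-variance residues yield missing (NaN) entries rather than 0, which
would fake perfect decorrelation.  Loop-pair averages are unweighted means
over all residue pairs of the rectangle; a loop against itself uses
off-diagonal pairs only.  LMI uses the Gaussian closed form on 3-D
displacement covariances, in nats; a singular marginal covariance makes the
entry missing (logged), a singular joint covariance with regular marginals
means perfect linear coupling and reports +inf (flagged, excluded from
nothing — an infinite LMI passes any threshold).  For bivariate Gaussian
motion with per-axis correlation r the closed form is `−(3/2)·ln(1−r²)`,
which the generator suite verifies at r ∈ {0.2, 0.5, 0.8}.

Networks keep edges with LMI ≥ 0.4 (on the nats scale — the threshold's
scale is recorded in every output header) and ensemble-mean inter-residue
distance ≤ a cutoff scanned over [8, 10] Å in 0.5 Å steps; the cutoff
minimising the community count is selected, ties resolved to the larger
cutoff.  Edges are unweighted for betweenness and modularity — correlation
gates which edges exist but does not weight them; a weighted mode exists for
the inter-community connectivity report.  Girvan–Newman removes the
highest-betweenness edge iteratively (ties by lexicographic node-pair order,
for determinism) and keeps the maximum-modularity partition over the whole
removal sequence, including the initial connected components; modularity
ties keep the coarsest partition.  An edgeless graph yields singleton
communities with a warning.

## Dihedrals

φ/ψ follow the IUPAC sign convention (validated against an independent
implementation) with angles wrapped to (−180°, 180°]; terminal residues
report the undefined angle as NaN.  Box occupancy counts frames whose
wrapped |Δφ| and |Δψ| are both ≤ the half-width (30° by default); box edges
are inclusive — the boundary has measure zero for continuous sampling, and
inclusivity makes constructed inputs deterministic.  Occupancies are
reported to 0.1 % granularity.

## Hydrogen bonds

A bond requires donor→acceptor heavy-atom distance ≤ 3.5 Å and
donor–hydrogen–acceptor angle ≥ 120°.  Donor/acceptor chemistry for the
standard amino acids is packaged (backbone N donates, carbonyl O/OXT
accepts; side-chain donors of S/T/Y/N/Q/K/R/H/W; acceptors of D/E/N/Q/S/T/Y
and H ring nitrogens).  Attached hydrogens and antecedent heavy atoms are
found by covalent distance within the residue (≤ 1.25 Å and ≤ 1.8 Å).  The
inclusive boundaries carry a numerical tolerance of 1e−4 Å / 1e−3°, which
absorbs single-precision coordinate storage and is far below any physical
scale.  Structures without hydrogens (crystal models) can use an explicitly
flagged proxy mode: distance criterion plus an antecedent–donor–acceptor
angle ≥ 90°; proxy detections are marked in every output, never silent.
Occupancy maps report, per residue pair, the occupancy of the most
persistent donor/acceptor atom combination; the interface summary (bond
count, mean occupancy) applies a configurable occupancy floor, default
10 %, recorded in output rather than hard-coded as truth.

## Surface areas and the mobility regression

SASA is Shrake–Rupley with a 1.4 Å probe and a deterministic 240-point
Fibonacci-spiral sphere per atom — same probe and point budget as classical
grid implementations, but with reproducible point placement.  Radii are a
single packaged Bondi element table; hydrogens are excluded by default so
structures with and without them are comparable.  Relative accessibility
divides by the same residue type's area in an extended (φ = −120°,
ψ = 120°) Ala-X-Ala tripeptide; the reference table ships as versioned
package data (`data/axa_reference.csv`) and is regenerated on demand by
`build_axa_reference()`, which constructs the tripeptides from ideal
internal coordinates with side chains grafted from ideal residue conformers.
Values above 1 are possible for distorted conformations and are not clipped.
Regression is ordinary least squares of RMSF on relative SASA (as a
fraction, not a percent — coefficients are reported with units) and
B-factor, with the design matrix rejected above condition number 1e10 and
the Pearson correlation between fitted and observed RMSF as the summary.

## Synthetic generators

The generators emulate exactly the statistical features the analyses
measure, and nothing else:

* `gaussian_ensemble` — i.i.d.-across-frames Gaussian residue displacements
  with per-axis covariance `ρ_ij σ_i σ_j`; each residue moves rigidly, so
  expected RMSF is `σ√3`, expected DCCM is ρ, expected LMI is
  `−(3/2)ln(1−ρ²)`.  Non-PSD covariances are rejected before sampling.
* `cone_vectors` — unit vectors uniform on a spherical cap of half-angle
  θ0, for which `S² = [cosθ0(1+cosθ0)/2]²`; per-residue random cone axes
  avoid artificial collective alignment.
* `dihedral_switch` — Bernoulli two-state (φ, ψ) switching with
  wrapped-normal jitter (the simplest circular noise with controllable
  spread).
* `hbond_script` — frame-by-frame donor–H–acceptor geometry realising
  prescribed bond presence, with non-bonded frames violating exactly one
  criterion, alternating distance (3.6 Å) and angle (100°) violations.

Every spec carries a mandatory seed; one named generator per spec makes
output bit-reproducible, and the demo pipeline fans a single global seed
into per-stage substreams.  What the generators deliberately do **not**
reproduce: temporal autocorrelation (all target statistics are ensemble
averages), anharmonic or multi-basin positional distributions, solvent,
and any force-field physics.  Passing tests therefore demonstrate that the
estimators are correct on data matching their own statistical assumptions —
not that a 500 ns solvated-protein simulation would be reproduced.  The
demo dataset plants a mobility contrast typical of a flexible-binding-loop
receptor (per-axis σ of 1.2 Å on the mobile hypervariable loop vs 0.25 Å
on the correlated germline pair, base level 0.4 Å, intra-pair ρ = 0.8)
at 2000 frames by default; these sizes keep the full pipeline comfortably
within interactive runtimes while leaving Monte-Carlo errors well inside
every stated tolerance.

## Problem sizes used in validation

Closed-form comparisons use 2×10⁴ frames (RMSF, covariance, DCCM averages)
or 5×10⁴ frames (cone S², LMI), where sampling error is a few parts in a
thousand; the iRED/cone comparison uses 400 vectors × 3000 frames for the
bias reasons above; community recovery uses 12 residues in two planted
blocks at 5000 frames; the regression recovery suite uses n = 200 residues
and 200–500 noisy replicates.

## Limitations

No time-correlation analysis (Lipari–Szabo fitting, relaxation rates) —
ensemble statistics only.  No nonlinear mutual information.  No
salt-bridge/π-stacking or water-mediated contacts.  SASA makes no
polar/apolar split and does not reproduce any particular commercial
implementation's areas (different radii sets shift absolute values by
~10 %; relative values are much more stable).  mmCIF input and DCD/XTC
trajectories are extension points, not implemented.
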