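# loopdyn

Conformational-ensemble flexibility analysis for protein binding loops, built
for the kind of question raised by αβ T cell receptors (TCRs): how mobile are
the six complementarity-determining-region (CDR) loops of a receptor, how are
their motions coupled, and can that mobility be anticipated from a crystal
structure alone?

`loopdyn` consumes structure ensembles (multi-model PDB: one topology, many
coordinate frames) and computes, per stage:

* **Fluctuation profiles** — per-residue Cα RMSF with the equivalent
  isotropic temperature factor, `B = (8π²/3)·RMSF²`; atom-pair distance
  monitors with running averages; all-pairs snapshot RMSD matrices with
  per-simulation block averages.
* **Generalized order parameters `S²`** — from Cα→Cβ bond vectors (Cα→Hα for
  glycine) via isotropic reorientational eigenmode dynamics (iRED), where
  `S²_i = 1 − Σ_m λ_m e²_{m,i}` over the internal modes of the matrix
  `⟨P2(μ̂_i·μ̂_j)⟩`, cross-checked by the direct second-rank estimator
  `S² = (3 Σ_{ab} ⟨μ_a μ_b⟩² − 1)/2`.
* **Correlation networks** — dynamic cross-correlation matrices (DCCM,
  `C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨Δr_i²⟩⟨Δr_j²⟩)`) with loop-pair block averages;
  linear mutual information (`I_ij = ½[ln det Σ_i + ln det Σ_j −
  ln det Σ_ij]`, nats); community detection by edge filtering (LMI ≥ 0.4,
  mean distance ≤ a cutoff scanned over 8–10 Å and chosen to minimise the
  community count, ties to the larger cutoff) followed by Girvan–Newman
  clustering at maximum modularity.
* **Dihedral sampling** — backbone φ/ψ time series and the circular
  box-occupancy statistic: the percentage of frames within ±30° of a
  reference (e.g. bound-state) conformation.
* **Hydrogen-bond occupancy** — bonds by the 3.5 Å donor–acceptor /
  ≥ 120° donor–H–acceptor criterion, aggregated into residue-pair occupancy
  maps across an ensemble, plus interloop bond counting on single
  structures.
* **Surface/mobility regression** — Shrake–Rupley SASA (1.4 Å probe,
  240-point deterministic Fibonacci sphere per atom), normalised to
  Ala-X-Ala tripeptide reference areas, and the ordinary-least-squares
  mobility model `RMSF = a·(relative SASA) + b·(B-factor) + c` with its
  Pearson correlation.

A first-class synthetic-ensemble module generates data with analytically
known ground truth for every one of those statistics (Gaussian positional
fluctuations with prescribed covariance, diffusion-in-a-cone bond vectors,
two-state dihedral switching, scripted hydrogen-bond geometries), so the
whole pipeline is testable end to end without any trajectory data.

## Worked example

```sh
loopdyn simulate --seed 11 --frames 500 --out demo/
loopdyn run demo/demo_config.yaml --out results_demo/
```

or from Python (this is `examples/01_fluctuation_profiles.py`):

```python
from loopdyn import (SelectionMask, generate_demo_data, read_ensemble,
                     resolve_loops, rmsf, superpose)

paths = generate_demo_data(seed=11, out_dir="demo", receptor="A6",
                           n_frames=500)
ensemble = read_ensemble(paths["ensemble"])
mask = SelectionMask.alpha_carbons(ensemble.topology)
profile = rmsf(superpose(ensemble, mask, 0), mask)
```

The demo builds a two-chain toy receptor embedding the real A6 CDR loop
sequences and plants a dynamic contrast (one mobile uncorrelated
hypervariable loop, one rigid correlated germline pair).  The script prints:

```
loop     length  max RMSF (A)
CDR1a         6          0.36
CDR1b         5          0.71
CDR2a         6          0.36
CDR2b         6          0.72
CDR3a        11          0.72
CDR3b        14          2.07
```

CDR3b (14 residues, planted per-axis σ = 1.2 Å) dominates the profile while
the correlated CDR1a/CDR2a pair (σ = 0.25 Å) stays rigid — the analysis
recovers the planted mobility ranking.  The other scripts in `examples/`
walk through order parameters against the cone oracle, DCCM/LMI community
recovery, dihedral box occupancy, hydrogen-bond occupancy maps, and the
SASA/B-factor regression, each printing the numbers it computes alongside
the planted truth.

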