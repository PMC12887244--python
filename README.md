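# spineprint

Functional-connectome fingerprinting of the cervical spinal cord.

Resting-state fMRI functional connectivity (FC) — the matrix of Pearson
correlations between regionally averaged BOLD time series — is stable
enough within a person, and variable enough between people, that an
individual can be recognized from it. `spineprint` implements the full
test–retest identifiability pipeline for *spinal-cord* FC (optionally
combined with a brain block), for researchers who have two runs of
parcelled time series per subject, or who want to study the statistics
themselves on simulated cohorts:

- **Parcellation** — the canonical 14-ROI spinal cross-section (gray
  matter: dorsal horn *dh*, intermediate zone *iz*, ventral horn *vh*;
  white matter: *cst*, *fc*, *fg*, *sl*; each bilateral) over any range
  of levels C2–C8 (42/70/98 ROIs for 3/5/7 levels), plus a 119-ROI brain
  block; robust (5th–95th percentile trimmed) parcel means and voxelwise
  tSNR from NIfTI volumes.
- **Fingerprinting** — for Ns subjects with FC vectors `c_i(r)`
  (upper-triangle unfolding, M = N(N−1)/2 edges), the identifiability
  matrix `I[i,j] = corr(c_i(1), c_j(2))`; `Iself` (mean diagonal),
  `Iothers` (mean off-diagonal), `Idiff = Iself − Iothers`; Cohen's
  `d = Idiff / sqrt((σ²self + σ²others)/2)`; identification accuracy
  (row-max on the diagonal) with chance level 100/Ns, and top-K curves.
- **Edge reliability** — per-edge one-way random
  `ICC(1,1) = (MSR − MSW)/(MSR + (k−1)MSW)` over the two runs, mapped to
  N×N, averaged over within-level 14×14 blocks, thresholded at the 95th
  percentile, and summarized per ROI as nodal strength.
- **PCA identifiability maximization** — joint PCA of all 2·Ns FC
  profiles, sweeping the reconstruction rank m to maximize Idiff.
- **Residualization** — per subject/run least squares `Y = Xβ + ε`
  removing the brain block's variance from the spinal block (or vice
  versa) before fingerprinting the residuals.
- **Synthetic cohorts** — a seeded latent-factor generator producing
  two-run cohorts with controllable subject distinctiveness
  (`lambda_subject`), run noise (`sigma_run`) and brain→spine coupling,
  so every stage is testable without any data download.

## Worked example

```python
import spineprint as sp
from spineprint.pipeline import cohort_vectors

parc = sp.build_spinal_parcellation(["C4", "C5", "C6"])   # 42 ROIs
spec = sp.CohortSpec(n_subjects=15, parcellation=parc, seed=1)
cohort = sp.generate_cohort(spec)                          # 15 x 2 runs, T=300

v1, v2 = cohort_vectors(cohort.runs)                       # FC edge vectors
res = sp.fingerprint(v1, v2)
print(f"Idiff = {res.idiff:.3f}, d = {res.cohens_d:.2f}, "
      f"accuracy = {res.accuracy:.1f}% (chance {res.chance:.1f}%)")
```

prints

```
Idiff = 0.041, d = 1.35, accuracy = 66.7% (chance 6.7%)
```

i.e. the simulated cohort carries an individual spinal FC signature:
self-similarity exceeds other-similarity by 0.041 correlation units
(a large 1.35-SD separation), and 10 of 15 subjects are identified
outright where random assignment would find one.

The same analyses as narrative scripts, each writing small tables under
`results/`:

```bash
python analysis/01_simulate_cohort.py --seed 1   # cohort TSVs (scratch/)
python analysis/02_fingerprint_spine.py          # identifiability matrix, Idiff
python analysis/03_edge_reliability.py           # ICC maps, nodal strength
python analysis/04_pca_sweep.py                  # Idiff-maximizing rank m*
python analysis/05_residualization.py            # brain->spine residual effect
```

A `spineprint` CLI wraps the same functions
(`spineprint simulate|extract|fc|fingerprint|pca-sweep|icc|residualize|run`);
see `spineprint --help`.

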