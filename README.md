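# fncpipe

Functional network connectivity (FNC) analysis of resting-state fMRI for
three-group designs, with a synthetic-cohort simulator that makes every
stage testable without scanner data.

The pipeline implements the classic group-ICA FNC workflow used to compare
patient groups — here framed around an idiopathic-generalized-epilepsy
design with healthy controls (HC), myoclonic-seizure (MS) and
absence-seizure (AS) patients:

1. **Preprocessing** — discard the first 5 volumes, exclude subjects with
   head motion exceeding 2 mm / 2°, smooth with an 8-mm-FWHM Gaussian
   kernel, and regress out white-matter and CSF mean signals and linear
   drift.
2. **Group spatial ICA** — temporally concatenate all subjects into a
   (Σt × voxels) matrix, select the model order by the minimum description
   length (MDL) criterion, reduce by PCA, and unmix with Infomax
   (natural-gradient ascent, logistic nonlinearity). Dual regression maps
   the group components back to subject-specific time courses and spatial
   maps.
3. **Network selection** — the twelve resting-state networks (RSNs:
   LFPN, RFPN, LDAN, RDAN, aDMN, pDMN, SRN, SN, CBN, SMN, AN, VN) are
   chosen among the components by optimal template matching.
4. **Voxelwise statistics** — per-RSN masks from a one-sample t-test
   (Bonferroni FWE, p < 0.05), then voxelwise one-way ANOVA and pairwise
   Welch contrasts between groups, FDR-corrected within each mask.
5. **FNC** — for each subject and each pair of networks (i, j), the
   statistic is the signed Pearson correlation at the lag that maximizes
   its absolute value,

   r_ij = r(ℓ*),  ℓ* = argmax_{|ℓ| ≤ 5 s} |r(ℓ)|,  z_ij = atanh(r_ij),

   scanned on a 1-s lag grid after linear resampling (TR = 2 s).
6. **Group inference** — per group, one-sample t-tests over edges with
   Benjamini–Hochberg FDR (positive/negative connection diagrams); across
   groups, per-edge one-way ANOVA (FDR over the 66 edges) with
   Tukey–Kramer post hoc comparisons (studentized range, valid for the
   unequal sizes 21/20/21), reported as AS−HC, MS−HC and AS−MS mean
   z-differences.

The **simulator** (`fncpipe.synth`) generates cohorts with known ground
truth: compact Gaussian-blob network maps, network time courses with
planted signed lagged correlations (realized by time-shifting shared
latent Gaussian factors), WM/CSF nuisance slabs, linear drift, white
noise and bounded-random-walk motion traces. Group effects are planted as
Fisher-z shifts of selected couplings and per-network amplitude scales,
so the pipeline's Table-style output can be checked against what was
planted.

## Worked example

Run the full default study design (62 subjects: 21 HC / 20 MS / 21 AS,
TR 2 s, 255 volumes, 24×24×18 grid at 3 mm, 12 networks, planted
visual–salience connectivity loss in both patient groups):

```bash
fncpipe init-config --out demo        # writes demo/config.yaml (seed 0)
fncpipe run-all --config demo/config.yaml --seed 7 --out demo
```

which prints (about a minute on one CPU):

```
config hash e1e036244b04
62 subjects analysed, 66 FNC edges per subject
4 connections significant (ANOVA, FDR q < 0.05)
```

`demo/significant_connections.tsv` then starts with

```
rsn_i  rsn_j  F      p        q        md_AS_HC  p_AS_HC  md_MS_HC  p_MS_HC
SN     VN     132.9  1.4e-22  9.2e-21  -0.253    0.000    -0.283    0.000
aDMN   VN     15.2   4.7e-06  1.6e-04  ...
```

The salience–visual (SN–VN) edge is the planted effect: the generator
lowered its coupling on the Fisher-z scale by 0.31 in AS and 0.43 in MS.
The recovered mean differences (−0.25, −0.28) are the planted decreases
attenuated by extraction noise, both patient contrasts are post hoc
significant, and AS−MS is not — the planted pattern. The remaining edges
are secondary consequences of the planted per-network amplitude changes
(e.g. reduced salience-network amplitude in AS), which alter the
signal-to-noise of the affected networks' time courses.

Other outputs in the run directory: the cohort manifest, per-subject FNC
edge list (`fnc_edges.tsv`), RSN↔component assignment, per-group
within-group connection tables (Figure-3-style positive/negative edges),
per-contrast edge lists, voxel-stats summary, and a JSON-lines run log.
Every table embeds the config hash; identical config + seed reproduces
the whole output tree bit-for-bit.

The library is usable directly, e.g.

```python
from fncpipe import synth, fnc
spec = synth.default_cohort_spec()
cohort = synth.simulate_cohort(spec, seed=1)
```

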