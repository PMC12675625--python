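# glymphpipe

Synthetic-phantom re-creation of a diffusion-MRI analysis chain for
prodromal α-synucleinopathy (iRBD) research: multi-shell microstructure
mapping with a three-compartment neurite model (ICVF / ODI / ISO),
skeleton-based voxelwise group statistics on white and gray matter
(TBSS / GBSS analogs) with TFCE permutation inference, the DTI-ALPS
perivascular-flow index, gait-derived clinical metrics, and mixed-data
phenotype clustering with bootstrap validation.

Real cohorts for such studies are private; everything here runs end-to-end
on generated phantoms and cohorts whose ground truth is known, so every
stage is testable: simulated signals are fitted back, planted group effects
are detected where (and only where) they were planted, and planted clinical
subgroups are recovered.

## The models in brief

**Diffusion signal.** Tissue voxels follow the three-compartment model
`S/S0 = (1−iso)·[icvf·S_intra + (1−icvf)·S_extra] + iso·e^{−b·d_iso}` with
Watson-dispersed sticks (dispersion reported as ODI = (2/π)·arctan(1/κ)),
a tortuosity-coupled hindered tensor (d_perp = d_par(1−icvf)), and free
water. Tensors are fitted by log-linear least squares on the low-b shell;
the neurite model by grid search plus local refinement on the full
multi-shell signal.

**DTI-ALPS.** With projection fibers along z, association fibers along y
and the perivascular space along x,

    ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)

— higher means better perivascular (glymphatic) flow. The phantom encodes
flow as a gain on x-axis diffusivity, so the planted index is known
exactly.

**Skeleton statistics.** Group skeleton = ridge voxels of the mean FA map
(threshold 0.2, local maximum along the structure-tensor perpendicular);
subject metrics are projected onto it (GM variant: 0.65 probability
threshold in >75 % of subjects, Gaussian σ = 2 mm hole-filling) and
compared across groups by Freedman–Lane permutation testing with
threshold-free cluster enhancement (TFCE) and covariates.

**Phenotype clustering.** Gower distance over mixed clinical variables,
k-medoids (PAM; exact enumeration at desk scale), silhouette /
Calinski–Harabasz k-selection, non-positive-silhouette subjects flagged
unassigned, and bootstrap stability as the mean adjusted Rand index (ARI)
over 1000 resamples.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Run the demo-scale end-to-end pipeline (12 + 12 simulated subjects for the
imaging arms, 52 controls + 44 patients for the clinical arm):

```bash
glymphpipe run --out demo/ --seed 7
```

prints (abridged):

```json
{
  "alps": {
    "mean_control": 1.4899873183174293,
    "mean_patient": 1.1825360360907224,
    "p_one_sided_control_gt_patient": 7.36428199042723e-11
  },
  "skeleton_stats": {
    "n_skeleton_voxels": 61,
    "n_significant": 9,
    "n_significant_outside_region": 0,
    "min_p_in_region": 0.001996007984031936
  },
  "cluster": {
    "k": 2,
    "cluster_sizes": {"0": 26, "1": 18},
    "ari_vs_planted": 1.0,
    "bootstrap_mean_ari": 0.9965496958540541
  }
}
```

Reading it: the phantoms plant perivascular gains of 1.6 (controls) vs 1.2
(patients), and the recovered ALPS means (1.49 vs 1.18, slightly shrunk by
ROI edge voxels and noise) separate the groups decisively. The TFCE
permutation test finds 9 significant skeleton voxels, all inside the
planted dispersion-deficit region and none outside. The clustering arm
selects k = 2, recovers the planted patient subgroups exactly
(ARI = 1.0), and the bootstrap says the partition is stable. The full
report (`demo/report.json`) records every threshold and derived seed;
rerunning with the same seed reproduces it byte-for-byte.

Individual stages are also exposed: `glymphpipe simulate | fit-dti |
fit-noddi | alps | skeleton | cluster` operate on NIfTI volumes with
FSL-style bval/bvec sidecars, YAML ROI/config files and CSV tables, so the
pieces can be used on any data in those formats.

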