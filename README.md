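# metacad

A feature-selection workbench for computer-aided detection (CAD) of
metaphase chromosomes in high-throughput scanning microscopy.

## The problem

Karyotyping needs fields of view ("ROIs") that contain a clinically
analyzable metaphase spread — roughly 46 small, bright, rod-shaped
chromosomes clustered in one area. Most scanned fields instead show only
interphase nuclei (large, round, dimmer) or several metaphase spreads
overlapping each other; both are unanalyzable. A CAD scheme must rank
fields by how likely they are to be analyzable, using cheap morphology
features computed from a segmented image.

`metacad` implements and compares the nine classical morphology features of
this task and the two-level classifier that combines the best of them:

1. number of labeled regions,
2. / 3. mean and SD of per-region mean intensity,
4. / 5. mean and SD of region area,
6. / 7. mean and SD of region circularity — for a region of area A with
   gravity center c, the circularity is A_o/A where A_o is the overlap
   between the region and the circle of equal area centered at c,
8. / 9. mean and SD of the radial distance from each region's gravity
   center to the global gravity center of all regions.

Feature performance is assessed with binormal ROC analysis: latent class
scores are modeled as Gaussian, giving TPF = Φ(a + b·Φ⁻¹(FPF)) and
AUC = Φ(a/√(1+b²)). The parameters (a, b) and the category cutpoints are
estimated by maximum likelihood on quantile-categorized scores
(Dorfman–Alf), with the nonparametric Mann–Whitney AUC as a model-free
cross-check. Paired AUC differences use DeLong's covariance estimator.
Features with AUC at or near 0.5 are screened out, and Pearson correlations
identify redundant pairs.

The two-level classifier feeds the mean region area, mean intensity and the
SD of region distance into a small neural network (score in [0, 1]), then
fuses that score with the min–max-normalized region count by the minimum
rule: an image must convince both stages.

Because no public dataset of scanned bone-marrow ROIs exists, the package
includes a fully seeded synthetic-scene generator (module `metacad.synth`)
that emulates the three field classes — single spread, interphase-only,
overlapped spreads — plus stain debris, and provides per-object ground
truth. All experiments in the test suite run on these scenes.

## Worked example

```bash
metacad run --out report/ --seed 1
```

prints

```
best single feature: n_regions (AUC 0.899)
fused classifier CV AUC: 0.915
on-line set: n_regions
off-line set: n_regions, std_area, std_dist, std_circ
```

and writes `feature_rocs.csv` (per-feature binormal parameters, AUC,
standard error, screening flag), `pvalues.csv` (pairwise DeLong tests over
retained features), `correlations.csv`, `roc_curves.csv`,
`classifier_roc.csv` and `recommendations.txt` into `report/`.

Reading the output: the number of labeled regions is the strongest single
discriminator (AUC ≈ 0.90) — an analyzable field yields ~30–50 separated
regions, an interphase field far fewer, and counting is barely perturbed by
debris or nucleus-size variation, which degrade the mean-type features.
That makes it the recommended feature for the time-critical on-line stage.
The fused two-level classifier improves on it (cross-validated AUC ≈ 0.91–
0.95 across seeds; resubstitution ≈ 0.94). The off-line recommendation
keeps the top feature and drops, from every correlated pair (|r| ≥ 0.5),
the weaker member.

The same pipeline is scriptable:

```python
from metacad import workbench
report = workbench.run_experiment(workbench.ExperimentConfig(seed=1))
print(report.feature_rocs[["feature", "auc", "se_auc", "retained"]])
```

Individual stages are exposed as `metacad simulate`, `metacad extract`,
`metacad evaluate` and `metacad classify`; see `--help` on each.

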