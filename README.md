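# tractstats

Tract-specific analysis of diffusion MRI metrics on white-matter skeleton
surfaces, plus a fully synthetic three-group cohort generator so the whole
pipeline runs and is testable without any external data.

What it does, end to end:

1. **synthetic cohort** — parametric medial skeleton sheets for eleven
   tracts (CC, bilateral CST / IFO / ILF / SLF / UNC), subject-level vertex
   FA fields with planted group decrements on geodesic disks, simulated
   single-shell DWI with Rician noise, white-matter lesion allocations, and
   neurocognitive scaled scores (mean 10, SD 3) with a controllable
   correlation to corpus-callosum mean FA;
2. **tensor metrics** — log-linear OLS diffusion tensor fit from DWI
   signals; fractional anisotropy and mean diffusivity;
3. **skeleton projection** — trilinear sampling of a scalar volume along
   each vertex normal out to the tract boundary (max or mean mode),
   per-tract per-subject mean FA, barycentric vertex area weights;
4. **cluster inference** — vertex-wise two-group GLM with age/sex
   covariates, supra-threshold cluster extraction on the mesh, and
   FWER-corrected cluster p-values from the permutation distribution of
   the maximal cluster mass pooled over all tracts (Freedman–Lane residual
   permutation; exhaustive label enumeration at tiny n);
5. **cohort statistics** — per-tract three-group ANOVA, Wilcoxon rank-sum
   tests, demographics tables (t / chi-squared, Bonferroni), lesion
   distribution summaries;
6. **association** — tract-mean-FA x neurocognitive-score Pearson
   correlations with Benjamini–Hochberg FDR control over the full
   99-pair family.

## CLI

```bash
# full pipeline (simulate -> analyze -> report -> correlate) from one config
tractstats run --config pipeline.json --out results/ --seed 1

# individual stages
tractstats simulate --out cohort/ --seed 1
tractstats project --fa subj_fa.nii.gz --mesh CC.vtk --mode max --out CC_subj.csv
tractstats analyze --subjects subjects.csv --tracts tracts/ \
    --group-a CTL --group-b SCD --perms 10000 --alpha 0.05 --cfp 0.01 \
    --seed 1 --out clusters.csv
tractstats report --subjects subjects.csv --summaries tracts/ --out report/
tractstats correlate --subjects subjects.csv --summaries tracts/ \
    --group SCD --q 0.05 --out associations.csv
```

Formats: skeleton meshes as VTK legacy ASCII polydata with point-data
arrays `normal` and `half_thickness`; volumes as NIfTI-1; subject tables,
vertex datasets, cluster and association tables as headed CSV; configs as
JSON. Every pipeline run writes a `provenance.json` with the config hash
and seed; identical config + seed reproduces byte-identical outputs.

## Layout

```
src/tractstats/
  mesh.py          skeleton meshes, adjacency, geodesic disks
  synthetic.py     cohort / lesion / DWI / score generators
  tensor.py        tensor fit, FA, MD
  projection.py    normal-line projection, tract means, vertex areas
  inference.py     vertex-wise GLM, clusters, permutation FWER
  cohort_stats.py  ANOVA, Wilcoxon, demographics tables, lesion summaries
  association.py   Pearson correlations + Benjamini-Hochberg
  io.py            VTK / NIfTI / CSV / JSON readers and writers
  pipeline.py      stage driver with provenance
  cli.py           click command line
```
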