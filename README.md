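# rehofc

Resting-state fMRI analysis of how the executive-function (EF) network
mediates episodic-memory (EM) performance: regional-homogeneity (ReHo)
seed discovery, seed-based functional connectivity (FC), group GLM with
gray-matter correction, behavior–connectivity regression with
conjunction, and three-step mediation — plus a synthetic-cohort
generator with planted ground truth so the whole chain is verifiable
end to end without any data download.

The package is aimed at methods developers and students who want a
compact, fully testable implementation of this classic analysis chain:
every stage is an importable function, every default is explicit, and
every claim the test suite makes is checked against planted truth or an
independent oracle.

## The chain

1. **Preprocess** each subject's 4D BOLD series: discard 10 volumes,
   linear detrend, band-pass 0.01–0.08 Hz, regress out six motion
   parameters + WM/CSF (optionally global) signals; scrub volumes with
   framewise displacement dRMS > 0.5 mm (one back, two forward) on the
   connectivity branch.
2. **ReHo**: Kendall's coefficient of concordance over each voxel's 27
   neighbors,

   `W = 12 Σ_t (R_t − k(n+1)/2)² / (k²(n³−n))`,

   normalized by the whole-brain mean, smoothed 8 mm FWHM; the
   covariate-adjusted group difference yields data-driven seed ROIs.
3. **Connectivity**: seed mean time course → voxelwise Pearson r →
   Fisher z = arctanh(r); group comparisons restricted to significantly
   positive connectivity.
4. **Inference**: per-voxel OLS `FC ~ group + age + gender + education
   + GM(voxel)` with the gray-matter covariate entering voxel-wise;
   cluster-extent correction with thresholds estimated by an
   AlphaSim-style Monte-Carlo simulation on the analysis mask.
5. **Behavior**: composite z-scores (EM from three delayed-recall
   tests, EF from three timed tests — higher EF = slower = worse);
   voxelwise regressions of FC on each composite; conjunction of the
   two significant maps.
6. **Mediation** (Baron–Kenny style), with FC strength over the
   conjunction cluster as mediator M:

   ```
   (1) EM = c  EF + e1
   (2) M  = a  EF + e2
   (3) EM = c' EF + b M + e3
   ```

   OLS guarantees c = c' + a·b exactly; mediation requires c, a, b
   significant, and is *full* if c' is insignificant, *partial* if
   |c'| < |c|; the mediated fraction is (a·b)/c.

## Worked example

`examples/` contains one short script per capability. Mediation on a
synthetic patient cohort (n = 79) calibrated so the generative mediated
fraction is 42.9%:

```
$ python examples/04_mediation.py
generative mediated fraction: 0.429

mediation over n=79 subjects (alpha=0.05)
  total     c  = -0.4206 (p=2.352e-07)
  path      a  = +0.3423 (p=7.874e-14)
  path      b  = -0.4917 (p=0.02753)
  direct    c' = -0.2523 (p=0.01773)
  indirect a*b = -0.1683
  indirect ratio (a*b)/c = 0.400 (40.0% of the total effect)
  classification: partial
```

The total EF→EM effect is negative (slower executive performance, worse
memory); 40% of it runs through the connectivity mediator, against a
planted 42.9% — the gap is one cohort's sampling noise.

The full chain on a default synthetic cohort (79 patients / 119
controls, 200 volumes; a few minutes on one core):

```
$ rehofc run-all --out out/ --seed 7
```

writes `out/summary.json`. With seed 7 the run discovers exactly the
two planted seed regions from the ReHo group difference (frontal seed,
111 voxels, peak t = 11.9; retrosplenial seed, 127 voxels, peak
t = 12.4), finds raised frontal-network connectivity and lowered
retrosplenial→posterior-cingulate connectivity in patients (peak
t = −9.0, 408 voxels), and the EM/EF behavior maps overlap in a
483-voxel conjunction cluster at the middle-cingulate target whose
extracted strength correlates positively with EF (r = 0.56) and
negatively with EM (r = −0.38) — the qualitative pattern the chain is
built to expose. In this draw the b-path misses significance
(p = 0.21), so the mediation is classified *none*: at n = 79 with an
image-measured mediator that path is genuinely marginal.

A pipeline run is configured by a single YAML file (see
`rehofc.config.PipelineConfig` for every knob and default); each stage
is also a subcommand (`simulate`, `clustersim`, `composites`,
`mediate`).

## Layout

```
src/rehofc/
  atlas.py         synthetic atlas: geometry, tissue masks, named regions
  synth.py         cohort generator with planted ground truth
  preprocess.py    detrend / band-pass / nuisance / dRMS / scrubbing
  reho.py          Kendall's W, ReHo maps, smoothing, seed selection
  connectivity.py  seed time courses, correlation maps, Fisher z
  stats.py         voxelwise GLMs, clusters, conjunction, partial corr
  clustersim.py    Monte-Carlo cluster-extent thresholds
  behavior.py      composite neuropsychological scores
  mediation.py     three-step mediation with classification
  pipeline.py      run_all orchestration, caching, summary JSON
  cli.py           thin click CLI (`rehofc`)
docs/methods.md    models, defaults, numerical choices, limitations
examples/          one narrative script per capability
```
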