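# motionshare

Simulation and analysis of intervertebral **motion-sharing biomarkers** for
passive recumbent lumbar flexion, as captured by quantitative fluoroscopy:

* **synthetic data** — motorised-table kinematics (6°/s² ramp, 6°/s plateau,
  40° peak, mirrored return, 15 Hz sampling), per-subject intervertebral
  angle series with configurable motion sharing and 0.52° instrument noise,
  variance-component observation matrices, and rendered image sequences with
  per-frame ground-truth vertebral poses;
* **tracking** — first-image registration from corner landmarks (with
  simulated repeated manual placement) and frame-to-frame rigid template
  tracking by normalized cross-correlation with sub-pixel/sub-degree
  refinement, failure flagging and re-tracking;
* **motion sharing** — proportional scaling of level angles by the gross
  L2–S1 angle, middle-80% amplitude trimming per motion phase, the per-frame
  proportion range (fRC), and the biomarkers
  **MSI** (mean of fRC) and **MSV** (population SD of fRC);
* **repeatability** — two-way random-effects ANOVA, single-measures ICC
  (absolute agreement by default) with F-based 95% CI, SEM (√error variance),
  minimal difference (SEM × 1.96 × √2), qualitative reliability bands, and a
  full report with group summaries and identity-line scatterplots;
* **CLI / pipeline** — deterministic end-to-end runs with provenance
  (version, config hash, seed) on every artifact.

## CLI

```bash
# one subject's angle time series (CSV)
motionshare simulate --seed 1 --outdir run/sim --shares 0.4,0.3,0.2,0.1

# biomarkers from an angle CSV
motionshare biomarkers --input run/sim/sequence.csv --trim amplitude --phases both

# render synthetic frames and track them back
motionshare render --input run/sim/sequence.csv --outdir run/frames
motionshare track --frames-dir run/frames --outdir run/tracked

# repeatability from long-format readings (subject, rater, biomarker, value)
motionshare repeatability --input readings.csv --outdir run/rep --pairs intra=DT1:DT2,inter=AxB:DT1

# full pipeline: simulate cohort -> biomarkers -> observer readings -> report
motionshare pipeline --seed 1 --outdir run/full [--config cfg.yaml]
```

Config files are YAML overriding the defaults in
`motionshare.pipeline.DEFAULT_CONFIG`; unknown keys are rejected.

## Conventions

Angles are degrees everywhere, flexion positive, expressed as change from the
first frame. Sequence CSVs have columns
`time_s, phase, gross_deg, l2l3_deg, l3l4_deg, l4l5_deg, l5s1_deg` with a
`#` provenance header. Image coordinates are pixels, origin top-left, x
right, y down.
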