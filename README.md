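# ktrscope

Quantitative single-cell analysis of kinase-translocation-reporter (KTR)
imaging for drug-persistence studies, with companion dose–response/synergy
analytics and tumor-section immune-infiltration morphometry.

## The problem

Breast-cancer cells treated with CDK4/6 inhibitors arrest, but a
subpopulation of *persister* cells re-activates CDK2 under drug and seeds
resistance. Live-cell KTR sensors report kinase activity as the ratio of
cytoplasmic to nuclear fluorescence (C/N): active kinase exports the
reporter from the nucleus, so C/N rises with activity. Measuring this per
cell over days of imaging requires a pipeline: illumination correction,
nuclear segmentation, lineage tracking through mitoses, ring-based C/N
quantification, and trace classification. `ktrscope` implements that
pipeline, plus the surrounding assay analytics, and ships a synthetic-data
generator with full ground truth so every stage can be benchmarked.

## What it computes

- **Segmentation** (`ktrscope.imgproc`): flat-field correction (2-D
  polynomial background surface); fixed-cell nuclei by Otsu thresholding of
  the DNA stain with watershed splitting; live-cell nuclei by multi-scale
  Laplacian-of-Gaussian blob detection on an H2B channel.
- **Tracking** (`ktrscope.tracker`): globally optimal frame-to-frame
  assignment (Hungarian algorithm on centroid distance), gap bridging over
  missed detections, and mitosis detection — two closely adjacent daughter
  nuclei whose combined nuclear intensity is comparable to the parent's.
- **Reporter quantification** (`ktrscope.reporters`): per-cell C/N ratio
  with the cytoplasm approximated as a ring 2–10 µm outside the nuclear
  mask, contested ring pixels excluded; degron (geminin/Cdt1) nuclear
  intensities and cell-cycle phase-transition calling.
- **Phenotyping** (`ktrscope.pheno`): persister classification — CDK2
  activity C/N > 1.0 sustained for more than 4 h within the 30–48 h window
  after treatment; EdU⁺ S-phase fractions; EU transcription summaries.
- **Pharmacology** (`ktrscope.pharm`): four-parameter logistic IC50 fits
  `y = bottom + (top − bottom) / (1 + (d/IC50)^h)`; Bliss-independence
  synergy (excess over `ya + yb − ya·yb`, mean-excess score × 100 with
  bootstrap CI); caliper tumor volume `width² × length / 2`.
- **Morphometry** (`ktrscope.morpho`): tumor mask, Euclidean
  margin-distance field, CD8⁺ spot detection, and cell densities in the
  tumor periphery (< 500 µm from the margin) versus core (> 500 µm).
- **Synthetic data** (`ktrscope.simgen`): movies of moving, dividing nuclei
  whose rendered sensor channels encode known activity trajectories
  (arrest vs sigmoidal persister re-activation), Hill-curve dose
  checkerboards with a controllable interaction term, and tumor sections
  with configurable periphery enrichment of immune cells.

## Worked example

```python
from ktrscope import simgen, imgproc, tracker, reporters, pheno, qc

cfg = simgen.SimConfig(rng_seed=1, n_cells=20, snr=None,
                       persister_fraction=0.5, division_rate_per_h=0.0)
stack, truth = simgen.simulate_timelapse(cfg, "cdk46i")

masks = imgproc.segment_movie(stack)
dets = imgproc.detections_table(masks, stack.channel("h2b"),
                                stack.frame_interval_h)
tracks, events = tracker.track_movie(dets)
readouts = reporters.quantify_movie(stack, masks)
traces = reporters.build_traces(tracks, readouts, treatment_time_h=0.0)

calls = pheno.classify_traces(traces)
print("persister fraction:", pheno.persister_fraction(calls))
print("CDK2 max abs error:",
      qc.trace_recovery_error(traces, truth.frames, tracks, "cdk2"))
```

Output:

```
persister fraction: 0.5
CDK2 max abs error: 0.002085668929373119
```

The constructed persister fraction (10 of 20 cells) is recovered exactly
from the rendered movie, and the extracted CDK2 activity traces deviate
from the ground-truth trajectories by at most ~0.002 C/N units.

A command-line interface mirrors the pipeline stages:

```bash
ktrscope simulate timelapse --out sim/ --scenario cdk46i
ktrscope segment --image sim/movie.ome.tif --out seg/ --mode live
ktrscope track --detections seg/detections.csv --out tracks.csv
ktrscope classify --traces-csv traces.csv --out persisters.json
```

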