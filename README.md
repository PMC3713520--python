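# cracquant

Quantification of store-operated calcium entry (SOCE) experiments:
segmentation and stoichiometry of Stim1–Orai1 (CRAC channel) clusters in
dual-channel TIRF images, and kinetic metrics of Fura-2 ratiometric calcium
traces. Written for cell biologists analyzing ER–PM junction imaging data,
with a synthetic-data generator that provides ground-truth fixtures for
validating every stage.

## What it computes

**Cluster analysis.** Upon ER store depletion, the Ca²⁺ sensor Stim1
clusters at ER–plasma-membrane junctions and recruits the channel subunit
Orai1; the clusters appear as diffraction-limited puncta in TIRF images of
cells co-expressing CFP-Stim1 and Orai1-YFP. The pipeline detects cluster
boundaries by *localized Otsu thresholding*: the image is uniformly scaled
to [0, 1] by percentile stretch, partitioned into tiles, each tile receives
its own Otsu threshold

σ²_B(t) = ω₀(t)·ω₁(t)·(μ₀(t) − μ₁(t))²  →  max over t,

and per-tile thresholds are bilinearly interpolated to every pixel. This
makes segmentation robust to the uneven illumination typical of TIRF,
where a single global threshold swallows the bright side of the field and
loses dim-side puncta. Connected components (8-connectivity, minimum area,
minimum prominence) become clusters; per cluster the pipeline reports area,
mean raw CFP and YFP intensity, and the CFP/YFP ratio — a per-cluster
Stim1:Orai1 stoichiometry readout. Clusters are pooled across cells and
compared between conditions with a two-sided Mann–Whitney U test (exact
enumeration for small samples).

**Fura-2 kinetics.** From ratio traces R(t) = (F340 − bg)/(F380 − bg) with
thapsigargin addition at t_tg and Ca²⁺ re-addition at t_ca, the pipeline
computes the baseline ratio, store-release peak ΔR_rel, SOCE amplitude, and
the maximal rate of initial rise after Ca²⁺ re-addition — the maximum
ordinary-least-squares slope over a sliding 5-point window (≈10 s at the
standard 2-s sampling cadence). For a logistic influx rise of amplitude ΔR
and steepness k the analytic maximum is ΔR·k/4, which the simulator exposes
as ground truth.

**Per-cell total fluorescence.** Cell bodies segmented from a YFP marker
(global Otsu + hole filling), then background-subtracted total intensity of
a target channel per cell — the readout used for fluorescent-cargo uptake
assays.

## Worked example

Run the default two-arm simulated experiment (9 cells per arm; the
perturbed arm has cluster areas scaled ×1.5 and the CFP:YFP amplitude
ratio scaled ×0.7 with CFP amplitudes held fixed):

```bash
cracquant clusters --out-dir out --seed 1
```

prints

```
pooled 1980 clusters -> out
  area_px: control vs perturbed p=9.97e-259 direction=+1
  ratio_cfp_yfp: control vs perturbed p=0 direction=-1
  mean_cfp: control vs perturbed p=0.128 direction=+1
  mean_yfp: control vs perturbed p=5.93e-11 direction=+1
```

Reading: ~990 clusters per arm were pooled; perturbed-arm clusters are
significantly larger (direction +1 on area) and significantly lower in
CFP/YFP ratio, while mean CFP intensity does not differ significantly
(p = 0.128) and mean YFP intensity rises — i.e. the stoichiometry change is
carried by the Orai1-YFP channel, exactly as constructed in the simulator.
`out/` contains the pooled cluster table, per-metric comparison report,
area histogram and a `run_log.yaml` echoing every effective parameter, the
seed and the configuration hash; reruns with the same configuration are
byte-identical.

The same interface drives real data: `cracquant simulate` writes TIFF
pairs plus a YAML manifest, and `cracquant clusters --config cfg.yaml`
accepts any manifest of CFP/YFP TIFF pairs. `cracquant fura2` and
`cracquant transferrin` run the trace and total-fluorescence analyses.

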