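# nestprofiler

Spatial immune profiling of chromogenic multiplex immunohistochemistry
(mIHC) slides, built around **tumor-nest / stroma tissue segmentation**.
Inside a tumor, neoplastic cells aggregate into *tumor cell nests*
surrounded by *intratumoral stroma*; immune cells distribute very unevenly
between the two compartments, and densities measured over the whole tumor
can hide — or even reverse — the prognostic signal carried by one
compartment (e.g. PD-1⁺ helper T cells inside nests). `nestprofiler`
implements the full analysis chain for head-and-neck-style mIHC panels:

1. **Tissue segmentation** — inverted single-marker grayscale images are
   classified into tissue vs. blank by a global threshold; the tumor-marker
   channel restricted to the tissue ROI is thresholded with the **Huang
   minimum-fuzziness method** to extract nests; the mask is cleaned by
   mathematical morphology (closing → fill holes → opening → despeckle);
   stroma is the exact set difference ROI ∖ nest.
2. **Image cytometry** — nuclei are detected on the hematoxylin channel
   (Otsu + distance-transform watershed), per-cell mean marker intensities
   are gated into leukocyte lineages by first-match-wins conjunction rules
   (helper T = CD45⁺CD3⁺CD8⁻Foxp3⁻, T_H1/T_H2 by Tbet/GATA3, TREG, CD8 T,
   B, NK, granulocyte, mast, CD68⁺CSF1R⁺ TAM split by CD163; PD-1 as an
   orthogonal flag), and each cell is assigned to nest or stroma by
   centroid containment. Region-stratified densities (cells/mm²),
   composition percentages, T_H1/T_H2 ratios and polarization classes
   (nest density / stroma density: >2 nest-polarized, <0.5
   stroma-polarized, else balanced) follow.
3. **Cohort statistics** — Kaplan–Meier curves, log-rank tests, Cox
   proportional-hazards regression (Efron ties), Spearman correlation
   matrices, Wilcoxon signed-rank and Kruskal–Wallis tests, and density
   cutoff rules (cohort mean, median, fixed external value such as
   43.1 cells/mm², or ROC/Youden-optimized), including two-marker
   stratification (e.g. both-high PD-1⁺ helper T × CD163⁺ TAM).
4. **Synthetic data** — a first-class generator produces slide-like marker
   stacks (disk-shaped nests, per-lineage Poisson cell placement, known
   masks and labels) and survival cohorts (log-normal density feature,
   exponential event times with a proportional-hazards group effect), so
   every stage is testable end to end with known ground truth.

## Worked example

Run the bundled demonstration (one simulated slide + a simulated
60-patient cohort whose hazard depends on the nest PD-1⁺ helper T density):

```bash
nestprofiler run --out demo_run --seed 7
nestprofiler report --manifest demo_run/manifest.json
```

or equivalently from Python:

```python
from nestprofiler.pipeline import demo_config, run_pipeline
manifest = run_pipeline(demo_config("demo_run", seed=7))
```

Key numbers from `demo_run/` at seed 7:

- `segmentation_report.json` — Huang nest threshold 72 on the tumor-marker
  channel; nest area 0.115 mm², stroma 0.703 mm².
- `region_stats.json` — T_H1/T_H2 ratio 4.5 in nests vs 0.44 in stroma:
  the generator's T_H1-skewed nests and T_H2-skewed stroma are recovered.
- `survival_report.json` — mean-density cutoff 31.07 cells/mm² splits the
  cohort 16 high / 44 low; log-rank χ² = 14.38, p = 1.5 × 10⁻⁴; the Cox
  model reports HR = 3.26 (95% CI 1.63–6.54, p = 8.4 × 10⁻⁴) for the
  high-density group — close to the simulated hazard ratio of 3.32 —
  while the four binary nuisance covariates (HPV status, sex, smoking,
  stage) stay non-significant, as simulated.

`demo_run/report/report.md` renders the composition bars, the
nest-vs-stroma density scatter (log axes with the 2.0 / 0.5 polarization
guides) and one KM plot per configured cutoff.

## Layout

```
src/nestprofiler/
  simulate.py      synthetic slides and survival cohorts with ground truth
  segmentation.py  tissue/blank, Huang nest extraction, morphology, ROIs
  cytometry.py     cell detection, marker quantification, gating, densities
  stats.py         KM / log-rank / Cox / Spearman / rank tests / cutoffs
  pipeline.py      end-to-end runs with manifests; report rendering
  cli.py           `nestprofiler simulate|segment|quantify|analyze|run|report`
  io.py            TIFF/PNG/CSV/YAML/JSON readers and writers
```
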