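# tilab

Quantifying tumour-infiltrating lymphocytes (TILs) from patch-level tissue
prediction maps, and testing the prognostic value of the resulting score.

## The problem

In H&E histology, lymphocytes that infiltrate tumour regions are a
prognostic signal in several cancers, including oral squamous cell
carcinoma. Pathologists grade TILs visually, which is subjective. Once a
patch classifier has labelled every 128×128-pixel patch of a whole-slide
image as tumour, lymphocyte, stroma, artefact or background, TIL abundance
can instead be measured objectively from the *spatial co-localization* of
the tumour and lymphocyte patches: lymphocytes count as infiltrating only
when they share neighbourhoods with tumour.

`tilab` is for computational-pathology researchers who have such prediction
maps (as CSV label tables or indexed rasters) and survival follow-up, and
want the scoring plus the downstream survival machinery in one tested
package.

## The score

The map is tiled into square grid-cells of physical side 0.28–1.26 mm. With
p<sup>l</sup><sub>ij</sub> and p<sup>t</sup><sub>ij</sub> the lymphocyte and
tumour areal fractions of cell (i, j):

- **Morisita–Horn co-localization**
  M = 2 ΣΣ p<sup>l</sup>p<sup>t</sup> / (ΣΣ (p<sup>l</sup>)² + ΣΣ (p<sup>t</sup>)²) ∈ [0, 1]
  — 1 when every cell holds equal fractions of both classes, 0 when every
  cell is single-class.
- **Shannon diversity**
  S = −ΣΣ (p<sup>l</sup> ln p<sup>l</sup> + p<sup>t</sup> ln p<sup>t</sup>) / (mn),
  maximal at ln 2 ≈ 0.7 when p<sup>l</sup> = p<sup>t</sup> = ½.
- **TILAb score**
  T = (C/2) · ΣΣ p<sup>l</sup> / ΣΣ p<sup>t</sup> when the map contains
  tumour (C = M or S), else T = 1. T breaks the symmetry of M and S: it
  rewards lymphocyte excess, grows monotonically with lymphocytic
  infiltration along the balanced sweep p<sup>t</sup> = 1 − p<sup>l</sup>,
  and is invariant to uniform density changes at a fixed
  lymphocyte-to-tumour ratio.

Downstream: per-section and per-slide scores, TIL+/− calls against
pathologist labels (accuracy/sensitivity/specificity/F1, AUC with DeLong
CI), Kaplan–Meier curves, log-rank tests, optimal cut-point stratification,
Cox proportional hazards (Efron/Breslow ties, Wald tests), Harrell's
c-index with CI, and seeded k-fold cross-validation. A synthetic-data
module generates prediction maps with controlled co-localization regimes
and cohorts with a known score–hazard link, so the whole pipeline is
testable without slide data.

## Worked example

```sh
tilab simulate map --seed 7 --out map.csv
tilab score --map map.csv --meta map.meta.json --cell-size-mm 0.28 --out report.json
cat report.sections.csv
```

```
slide_id,section_id,n_cells,morisita_horn,shannon,tilab,tilab_preclip
synthetic-uniform_mix-7,1,1024,0.7872290598735396,0.6417496675096115,0.3939048775123318,0.3939048775123318
```

The seeded map mixes 25% lymphocyte and 25% tumour patches uniformly, so at
the smallest grid-cell (0.28 mm, 4×4 patches) co-localization is high
(M ≈ 0.79; sampling noise in 16-patch cells keeps it below 1) and the TILAb
score sits near its balanced-mixture value of ½ × M ≈ 0.39.

```sh
tilab simulate cohort --seed 7 --out cohort.csv
tilab survival --cohort cohort.csv --split 60:40 --seed 7 --out surv.json
```

```
"split": {"cutpoint": 0.512, "modelling_p": 0.0032, "test_p": 0.0135, "test_c_index": 0.558, ...}
```

The simulated cohort plants a hazard jump at score 0.5 (low score = high
risk); the cut-point learned on the 60% modelling subset lands at 0.512 and
stratifies the held-out 40% significantly (log-rank p = 0.0135), with
KM step tables written next to `surv.json`.

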