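# Methods

## Scope and data model

The unit of analysis is the patch: a prediction map is a rectangular
lattice of categorical labels (tumour, lymphocyte, stroma, non-ROI
artefact, background), one per non-overlapping 128×128-pixel patch at the
analysis magnification, plus physical metadata (patch size in pixels,
microns per pixel). Probability maps are assumed already collapsed to
argmax labels upstream; this package consumes labels only. The label code
table (0=background … 4=non-ROI) is a fixed external contract. Background
is an explicit class so non-tissue area is distinguishable from unscanned
area; loaders default unlisted lattice positions to background.

Tissue sections are connected components of non-background patches,
numbered in row-major order of first occurrence. Default connectivity is 8:
fragments touching at a corner are one physical section. Non-ROI patches
count as tissue for section extent — they are part of the physical section
even though they contribute to neither score numerator.

## Grid construction

A grid-cell's side in patches is the nearest integer to the requested
physical size divided by the patch's physical side (with the default
metadata of 128 px at 0.55 µm/px, the 0.28 mm preset maps to 4 patches).
The lattice is tiled from the top-left; edge cells are truncated and kept,
because discarding them would bias small sections. Eight preset sizes start
at 0.28 mm and step by 0.14 mm (so the largest is 1.26 mm).

Per-cell fractions divide class counts by **all** patch positions in the
cell, whatever their class: the fractions are areal, and this guarantees
p_l + p_t ≤ 1. When a grid is restricted to one section, out-of-section
patches count in neither numerator nor denominator, the grid is cropped to
the section's bounding cells, and cells with no in-section patches are
marked invalid: they are excluded from every sum *and from the Shannon
divisor*, which therefore counts cells of the constructed (section) grid
rather than cells of a whole-slide tiling. This is the one
interpretation-sensitive choice in the Shannon index — the Morisita–Horn
index is indifferent to empty cells because they contribute nothing to its
sums — and it is fixed this way so that an identical section embedded in a
larger slide scores identically.

Slide-level scores use a single grid over the full lattice (all sections
jointly), not an average of section scores: the indices are defined through
global sums, and a joint grid is the only aggregation consistent with that.

## The indices and their conventions

Fractions are kept in [0, 1], not percent; this is what makes the
Morisita–Horn maximum exactly 1 and the Shannon maximum along the balanced
constraint exactly ln 2 ≈ 0.693 (reported as 0.7 to print precision).

Degenerate inputs: when a grid holds neither tumour nor lymphocyte
anywhere, M and S are defined as 0, and the TILAb score takes its
no-tumour branch value 1 with a warning flag in the report — a tumour-free
control slide must not be read silently as maximal infiltration.

The TILAb normalization factor ½ maps the uniform-composition sweep
(p_t = 1 − p_l in every cell) onto [0, 1]: along it T_MH = λ²/(λ²+(1−λ)²),
strictly increasing, reaching 1 only at the pure-lymphocyte endpoint via
the no-tumour branch. Off that sweep T can exceed 1 — e.g. one
lymphocyte-rich/low-tumour cell among many cells holding a trace of
lymphocyte and no tumour drives the lymphocyte-to-tumour ratio up much
faster than the co-localization falls. The default clip policy therefore
caps the reported score at 1; `clip="none"` is available and the pre-clip
value is always retained in reports, so the cap loses no information.

## TIL+/− classification

Calls threshold the section score, boundary counting as positive (fixed
for determinism). AUC is the Mann–Whitney probability with ties at ½; its
95% CI uses DeLong's structural-components variance — analytic and
seedless, preferred over a bootstrap for reproducibility. F1 is defined as
0 when precision + recall is 0; with single-class truth the undefined rate
is reported as missing rather than guessed.

## Survival machinery

Orientation: the TILAb score is protective, so subjects *below* a
cut-point form the high-risk group, and the concordance index defaults to
risk = −score (c > 0.5 then means predictive). Kaplan–Meier estimation is
delegated to lifelines; Cox fits to statsmodels' proportional-hazards
regression, Efron tie handling by default (more accurate with month-level
ties; Breslow available). Convergence is verified by the score norm at the
solution; monotone partial likelihood (complete separation) is flagged per
covariate with an unbounded CI instead of a misleadingly huge finite one.
The model-level test is the global Wald statistic β̂ᵀ I(β̂) β̂ on k df.
Categorical covariates are dummy-coded against the lexicographically first
level.

The two-group log-rank statistic is computed in vectorized form from the
per-event-time hypergeometric moments. The optimal cut-point scan evaluates
it at every midpoint between consecutive distinct scores whose split leaves
each group at least 10% of subjects (unconstrained maximally-selected
statistics degenerate at the score extremes); ties break toward the smaller
cut-point. No multiple-testing adjustment is applied over the scan — the
winning p-value is optimistic and should be validated on held-out data,
which is what the modelling/test split and the k-fold harness are for. The
significance threshold 0.05 annotates output; it never filters.

Harrell's c is computed by exact pair enumeration (usable pairs: the
shorter time carries the event; a censored subject at an event's exact time
counts as surviving past it; risk ties score ½), with a jackknife-based
normal 95% CI. Cross-validation shuffles subjects with a seeded generator
into k near-equal folds (k ≤ n/2, so every fold can host a two-group
test), learns the cut-point on the training folds and evaluates log-rank
and c-index on the held-out fold; folds with no events or a one-sided split
are flagged, never dropped.

## Synthetic data: what it emulates and what it does not

The map generator reproduces co-localization *regimes* — uniform mixing
(maximal co-localization in expectation), fully segregated compartments,
mixing confined to an interface band, and disc-shaped niches on stroma —
at controlled class fractions. Structured regimes realise the requested
fractions exactly (blob painting trims or extends the painted set by single
patches to hit the target count); `uniform_mix` scatters classes i.i.d. per
patch, so its fractions fluctuate at the multinomial scale. Default
metadata (128 px patches, 0.55 µm/px) makes the 0.28 mm preset exactly 4
patches. The generator does not imitate H&E texture, classifier error
structure, or the spatial autocorrelation of real tumour architecture, so
green tests certify the arithmetic and statistical machinery, not
performance on real slides.

The cohort generator draws exponential event times with hazard
λ₀·exp(β·z), where z is either an indicator of score below a threshold
(a planted hazard jump; low score = high risk, matching the protective
orientation) or the raw score, and censors uniformly on a window. Defaults
— λ₀ = 0.02 events/month (median ≈ 35 months, a plausible disease-free
survival scale) and a 60-month censoring window — mimic a five-year
follow-up study; n defaults to 200 subjects, the order of a
single-institution cohort.

## Calibration experiments and problem sizes

The statistical suite checks, at sizes chosen to keep the full run within a
few minutes on one CPU: log-rank type-I error within [0.03, 0.07] at
α = 0.05 over 1000 null cohorts of n = 100 (and, separately, under 1000
label permutations of one cohort); mean Cox estimate of a planted log-HR of
0.7 within 0.05 over 200 replicates at n = 500; and cut-point recovery of a
planted hazard jump (HR 4, n = 200) in ≥ 90 of 100 replicates. "Recovery"
means the learned cut-point falls within the ±5-percentile score window
around the planted threshold: the maximally-selected statistic genuinely
wanders a few order statistics around the true jump even at HR 4, so exact
adjacent-gap recovery is not an attainable standard, while a decile-wide
quantile window is the resolution at which the cut-point is scientifically
interpreted.

## Known limitations

- The Shannon divisor convention (valid cells of the constructed grid) is
  one of two defensible readings; both are exposed through the grid's
  validity mask, but only one is wired through the reports.
- Grid anchoring is fixed at the lattice top-left; scores of small sections
  can shift by a cell's worth of composition under sub-cell translations.
- The cut-point's unadjusted p-value is optimistic by construction; only
  held-out evaluations should be quoted.
- No competing risks, time-varying covariates, or probability-map inputs.
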