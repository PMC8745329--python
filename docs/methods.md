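# Methods

`thromboflow` models, images and analyses whole-blood thrombus formation in
a parallel-plate microfluidic chamber with microspots of collagen or
collagen plus tissue factor (TF), under arterial shear with in-situ
recalcification, where the perfusion can be switched from untreated to
inhibitor-treated blood at a chosen moment (0 or 2 minutes).  The package
has four computational layers: a kinetic simulator with switchable
pharmacology, a four-channel microscopy renderer with ground truth, a
segmentation chain, and the heatmap statistics.  This note records the
model, its assumptions, the tunable parameters, and the limits of what the
synthetic data can show.

## Flow arithmetic

The chamber is a shallow slit (height h = 50 µm, width w = 3.0 mm, length
30 mm).  For laminar Poiseuille flow between parallel plates the wall-shear
rate is γ = 6Q/(wh²); Q = 75 µL/min gives the 1000 s⁻¹ operating point.
Blood mixes 10:1 with recalcification medium (63 mM CaCl₂, 32 mM MgCl₂),
so final added concentrations are stock/11.  These are closed-form
relations; the only assumption is fully developed laminar slit flow
(h ≪ w holds by three orders of magnitude).

## Kinetic model

Six states per microspot over 0–10 min: platelet coverage P (→P1),
thrombus coverage T (→P2), PS-positive coverage S (→P6), fibrin coverage F
(→P7), and continuous contraction/multilayering levels on 0–3 (→P4, P5).
Coverages follow seeded logistic growth, dC/dt = r·a(t)·(C+c₀)(1−C/K),
integrated by forward Euler at dt = 0.01 min (rates ≈ 1/min, so r·dt ≈ 0.01
keeps the scheme well inside its stability region).

The activity a(t) mixes two receptor pathways:

* **GPVI (collagen receptor, via Syk)** — drive exp(−t/4 min): strongest in
  the first minutes, fading as the collagen surface is occupied.
* **Thrombin (PAR1/4)** — zero until the extrinsic TF/FVIIa initiation
  event fires (t_ext = 1 min, collagen/TF only), then rising with a 1-min
  time constant; on collagen-only spots a weak intrinsic drive (amplitude
  0.15) appears after 6 min.

Fibrin deposition starts a fixed delay (2.5 min) after the extrinsic
event, i.e. around 3.5–4 min on collagen/TF, and never within 10 min on
collagen alone.  Fibrin growth is partially coupled to thrombus coverage
(floor 0.3), so smaller thrombi make slower clots.

Inhibitor presets multiply pathway activities from their switch time
onward: PAR blockade leaves 15 % of the thrombin drive; GPVI Fab leaves
10 % of the GPVI drive and 2 % of the GPVI-gated PS channel; the Syk
inhibitor is slightly stronger (5 %/1.5 %) because Syk also serves other
ITAM receptors.  Two mechanisms are not plain rate factors:

* **FVIIa inhibition** removes the extrinsic initiation *event*.  Present
  from the start it prevents coagulation entirely; introduced at 2 min —
  after the event has fired — it changes nothing, reproducing the
  time-restricted role of the extrinsic route.  A rate factor applied from
  2 min could not do this, since fibrin only begins at ~4 min.
* **Integrin αIIbβ3 antagonism (tirofiban)** zeroes aggregation capacity
  and adds a first-order detachment (0.3/min) that dismantles existing
  thrombi — except where the extrinsic event has fired and early fibrin
  cross-links hold the thrombi together (collagen/TF), where detachment is
  suppressed.  Hence late tirofiban reverses growth on collagen but only
  freezes it on collagen/TF.

Rate constants (r, K, weights; see `KineticRates`) were chosen once so the
vehicle time courses have the right shape — thrombus coverage rising
through ~2 min to a plateau near 35 % on collagen/TF, clearly lower on
collagen alone, fibrin from ~4 min — and so the directional early/late
statements hold.  They are model configuration, not measurements, and no
attempt is made to fit them to published figures (figure data are not
tabulated anywhere).

**Variability.** Donor factors (log-normal, σ = 0.15) multiply the four
process rates and are shared across all runs of a donor — the paired
design.  Replicate factors (σ = 0.10) are drawn per physical run
(seed, donor, replicate) and deliberately do *not* depend on the condition:
the same blood sample perfused under two arms shares its noise.  σ values
are plausible placeholders; the assay's donor variability is published
only as error bars.  Contraction/multilayering share the aggregation
noise factor (same platelet-reactivity source).

## Renderer

Emulates the acquisition geometry: 8-bit monochrome frames, natively
1360 × 1024 px at 0.108 µm/px, channels brightfield, DiOC6 (platelets),
AF568-annexin A5 (PS), AF647-fibrin(ogen), at t = 2, 4, 6, 8, 10 min.
Tests and the demo pipeline run at ¼ scale (340 × 256, 0.432 µm/px); SAC
is scale-free and area cut points rescale by pixel area.

Thrombi are unions of platelet-sized disks (r = 1.5 µm) placed greedily
around 12 fixed cluster centres until the target pixel count is reached,
giving mask SAC within ±0.5 points of the kinetic coverage by
construction; single-platelet disks top the DiOC6 mask up to platelet
coverage.  The layout is drawn once per run, so thrombi grow — or, under
detachment, shrink — in place.  Contraction tightens the radial scatter
and paints a dark core (intensity 35 on a 110 thrombus level, fraction
≈ 0.25 per level); multilayering paints a bright DiOC6 core (235 over 160,
nominal fraction 0.25 per level).  The AF647 channel carries fibre
segments at 205 over a soluble-fibrinogen haze at 55 — the material the
fixed high threshold must reject.  Each channel gets a low-frequency
illumination gradient (±20) and Gaussian noise (σ = 4) before 8-bit
quantisation.

What the renderer does **not** emulate: optical blur and depth effects,
red-cell shadows, photobleaching, stage drift, debris, or any real
platelet morphology.  Passing recovery tests therefore show the chain is
self-consistent on images with known truth, not that it would meet the
same error bounds on real microscopy.

## Segmentation

Per channel: Fourier high-pass → horizontal-then-vertical morphological
opening → threshold → small-object removal (< 4 native px²) → optional
hole filling.  Brightfield is inverted first (thrombi are dark on bright).

The high-pass is Gaussian-edged, H(f) = 1 − exp(−f²/2σ²) with σ = 0.75 ×
cutoff (cycles/image), applied on a mirror-extended tile so image-wide
ramps do not leak into high frequencies as wrap-around ringing.  The
output is a signed residual (background near zero), keeping the filter
linear.  DC is removed exactly; a 1-cycle illumination gradient is
suppressed ≥ 90 % at cutoff 4; content at twice the cutoff passes ≥ 97 %.

Shipped defaults (cutoff 2 cycles/image and a fixed threshold of 15 above
the residual background for bf/DiOC6/AF568; a fixed high threshold of 120
with no high-pass for AF647) were tuned on the synthetic renderer.  Otsu
thresholding is available per channel but is not the default: rendered
thrombi are trimodal (background, platelet base, bright core), and Otsu
then splits core from base rather than foreground from background.
Fibrin/fibrinogen discrimination is purely the high fixed threshold —
fibres render at ~205, haze at ~55.  Thresholds are plain configuration;
the verification loop is: write QC overlays (mask contour in red over the
grayscale frame), inspect, edit the threshold, re-run.

Both orders (threshold before or after the morphological step) are
supported; the default cleans the grayscale image first, and a test checks
order insensitivity of SAC within 2 %.

## Parameters P1–P7

P1, P2, P6, P7 are SACs of the DiOC6, brightfield, AF568 and AF647 masks.
P3–P5 are ordinal scores assigned visually in the assay; here they are
explicit proxies:

* **P3 morphology (0–5):** largest 8-connected component by area class —
  ≥ 10,000 native px² big (5), ≥ 2,000 medium (4), ≥ 200 small aggregate
  (3); with only single-platelet components, total SAC decides: ≥ 5 %
  widespread singles (2), ≥ 0.2 % multiple singles (1), else 0.  The 0/1/2
  range uses SAC rather than a component count so the score is monotone
  under dilation (merging components can lower a count but never the
  coverage).
* **P4 contraction (0–3):** mean component solidity plus the fraction of
  thrombus pixels darker than 70 in brightfield; bins (solidity ≥ 0.85 &
  dark ≥ 0.44 → 3; 0.75/0.25 → 2; 0.65/0.08 → 1; else 1 if SAC ≥ 8 %,
  else 0).  The dark cuts sit at the midpoints of the renderer's
  ~0.25-per-level dark-core mapping; solidity acts mainly as a guard
  against ragged aggregates.
* **P5 multilayering (0–3):** fraction of thrombus pixels with DiOC6
  above 200; bins 0.50/0.25/0.08.

Across a mixed synthetic cohort the proxies track the simulator's true
levels with Spearman ρ ≥ 0.8.  They are reproducible rules, not replicas
of human judgement, and have not been calibrated against human-scored
images (none are published).

## Statistics

Order of operations: average duplicate/triplicate runs per donor → scale
each parameter to 0–10 → subtract → filter.  Scaling is one affine map per
parameter across all conditions, surfaces and timepoints (so panels are
comparable and the scaled mean equals the mean of scaled values); a
per-surface scope is available.  Condition comparisons use a two-sided
paired Student's t-test across donors per heatmap cell, t = mean(d)/(sd(d)/√n)
with the n−1 standard deviation; since scaling is affine with shared
bounds, t and p are identical whether computed on raw or scaled values.
Subtraction heatmaps show scaled treated-minus-reference means; with the
significance filter on, cells with p ≥ 0.05 are set to zero (shown as "no
relevant change"), while unfiltered deltas are retained in the CSVs.  Raw
per-cell p-values are used, as in the assay; Benjamini–Hochberg is an
off-by-default option.  The reference condition is explicit (default:
vehicle on the same surface) because published comparisons vary in their
reference.

Degenerate cells: zero-variance differences give p = 1 when the mean
difference is also zero (nothing to test) and p = 0 with a warning
otherwise.  Type-I calibration simulates null cohorts in which both arms
are vehicle runs from two disjoint replicate groups — independent physical
runs sharing donor noise, the faithful null for the paired design — and
checks that ~5 % of testable cells are flagged at α = 0.05.

## Problem sizes

Defaults were chosen to keep a full run on one CPU comfortable: ¼-scale
rasters for tests and the demo cohort (3 donors × duplicates × 2 surfaces
× a handful of conditions × 5 timepoints); 20 renders for recovery
checks; 2,000 vectorised cohorts for calibration.  Full-size rendering is
a flag away (`--full-size`) and changes no statistic, since every
quantity is coverage- or score-based.

## Known limitations

* One thrombin node cannot reproduce all relative magnitudes reported for
  the assay simultaneously: early FVIIa inhibition is described there as
  only insignificantly lowering thrombus coverage, while PAR blockade
  (downstream of thrombin) lowers it substantially and absence of TF slows
  everything.  In this model early FVIIa inhibition makes a collagen/TF
  run track collagen-only kinetics — a moderate P2 reduction.  Directional
  claims are preserved; this magnitude is not.
* GPVI blockade at 0 min catches up to vehicle thrombus coverage by 10 min
  on collagen/TF (thrombin takes over); the assay reports a more lasting
  reduction.
* Ordinal score proxies are tuned to this renderer's intensity model and
  would need recalibration for real images.
* The simulator's noise magnitudes are assumptions, not estimates.
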