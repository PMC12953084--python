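# Methods

This note documents the models, parameter choices and numerical
conventions behind each quantifier and generator, what the synthetic data
do and do not emulate, and the limitations a user should know before
applying the package to real micrographs or scanner exports.

## Donut-method AQP4 polarization

Aquaporin-4 normally concentrates at perivascular astrocyte endfeet; loss
of this polarization is a hallmark of glymphatic dysfunction. The score is

```
rate = (I_PAS − I_ASS) / I_global × 100
```

with three ROI conventions that the source description leaves open and
that we fix as follows:

- **ROI_PAS** is the annulus *outside* the GFAP-positive range: the binary
  dilation of the GFAP mask by 5 pixels (8-connectivity square structuring
  element, in pixels, not µm) minus the mask itself. Excluding
  GFAP-positive pixels keeps ROI_PAS and ROI_ASS disjoint, which the
  subtraction in the formula presupposes. Dilation clips at the image
  border.
- **ROI_ASS** (astrocyte cell-body space) is the union of soma cores,
  defined reproducibly as the morphological opening of each GFAP component
  with a disk of radius `soma_opening_radius_px` (default 8 px ≈ 4 µm at
  the default 0.5 µm/px) — a parameter-documented proxy for the manual ROI
  drawing used in practice.
- **ROI_global** is the entire image, following the usual phrasing of the
  method; whether it should instead be the union of cell-associated
  regions is a known sensitivity and can be probed by passing explicit
  masks.

Reported group values of the score run ≈39–72, so the raw ratio is
multiplied by 100. Intensities are **sums** over ROIs by default ("mean"
is exposed as an option); sums make the phantom's conservation law exact
and keep the score bounded in [−100, 100]. A zero global intensity raises
an explicit error, never a silent NaN. Per-section scores average the
section's three images; pooling across anatomical regions (anterior horn,
posterior horn, central canal) versus reporting them separately is left to
the caller — both are simple aggregations of the per-image results.

Segmentation is a global automatic threshold (Otsu by default, numeric
override available) on the GFAP channel, 8-connected components above
`min_cell_area_um2` (default 20 µm²), nucleus assignment by largest DAPI
overlap with the soma. Cells without a nucleus are excluded and logged;
touching cells merge into one label and are reported as such, never split
heuristically. The polarization score itself is image-level and therefore
insensitive to merges.

## Sholl morphometry

Crossings are counted on the topological skeleton of each cell, not the
raw mask, to avoid process-thickness artifacts. The circle of radius r is
realised as the set of skeleton pixels whose centre distance from the
nucleus centroid lies within half a pixel diagonal (√2/2 px) of r — wide
enough that a circle cannot slip diagonally through an 8-connected path —
and each 8-connected run of band pixels counts as one crossing. Radii
start at 5 µm and advance by 2 µm until past the farthest skeleton pixel
(the profile is zero from there on). Radii below one pixel are rejected.

## Nuclear translocation and ROS

Each DAPI nucleus seeds one cell; the cell mask is the marker-positive
region containing it. Because marker channels typically have three
intensity classes (background, cytoplasm, bright nuclei), the foreground
cut uses the lowest threshold of a three-class multi-Otsu, falling back to
binary Otsu on degenerate histograms; explicit masks bypass thresholding
entirely. The per-image value is the mean of per-cell nuclear fractions.
ROS is the mean DHE intensity over an ROI (whole image by default) with
optional, recorded background subtraction. Group values are reported as
fold change against the control-group mean, which maps the control mean to
exactly 1.

## MRI SI metrics and SIMR

Raw SI measurements (3 repeats × 3 ROIs × 3 segments per time point) are
averaged in that nesting order; unbalanced coverage raises rather than
silently reweighting. The peak is the sampled maximum after the
pre-injection baseline — no interpolation, earliest time on ties — so on
synthetic curves whose true peak falls between scan times the extracted
peak time is the sampled argmax (a documented discretization).

SIMR is a **group-level statistic of means**:
`(mean peak − mean initial) / (mean peak-time[h] × mean 5-min SI)`; the
mean of per-animal ratios is available as a diagnostic but is not the
canonical form. Peak time carries hours: back-calculation from the
reference group's summary values (1853 / (1 h × 4659) ≈ 0.40 h⁻¹) fixes
the unit, and the statistic is invariant under multiplicative rescaling of
all SI values. Since no peak-time row is published, the cohort generator's
group peak times (C 1.0 h, PDN 6.0 h, OMT 1.15 h, PMA 1.48 h; SD 10% of
the mean) are back-calculated from the published group SIMR values.

## Up-down 50% PWT

The filament series is the standard rodent Touch-Test sequence truncated
at the 26 g cutoff (0.4–26 g, 11 filaments); start filament defaults to
the middle of the series and the stop rule is four trials after the first
reversal, all configurable. The estimate is `10^(X_f + k·δ)/10⁴` with
forces handled in the conventional log10(force×10⁴) filament units and δ
the mean log10 spacing of the series. k is looked up from
`data/updown_k_table.csv`, keyed by the six-response window beginning one
trial before the first reversal; an unknown pattern raises an error naming
it. The table is generated (`scripts/make_k_table.py`) as the
maximum-likelihood location, in step units relative to the final filament,
of a normal tolerance distribution with spread one step — the derivation
underlying the published up-down tables; alternating patterns recover the
classical ±0.5. Sessions that run off the range before reversing are
assigned the boundary (26 g cutoff high, weakest filament low) and flagged
censored; estimates are clipped to the assignable range. Five test points
per paw are treated as five independent sessions averaged per animal.

## Synthetic generators

All generators are pure functions of their config, seed included.

**Astrocyte phantom.** Disk somata (6 µm radius) with 5 random-walk
processes (20 µm mean length) arranged around a central 6 µm vessel in a
256×256 field at 0.5 µm/px; DAPI nuclei at soma centres. The AQP4 channel
is painted *after* running the quantifier's own segmentation and ROI
construction on the noise-free geometry: with region sizes known, the
per-region intensity is solved so that the donut formula returns the
requested polarization exactly while conserving the total budget (10⁷
a.u.) over a uniform background floor (20 a.u.). A spare fraction (20% of
the residual budget) is painted into both ROIs so neither is empty at
moderate scores; the remainder is spread over the rest of the image as
dispersed AQP4. Requests the floor cannot support (|score| near 100 with
nonzero background) are rejected with guidance rather than silently
clipped. Noise is additive Gaussian (SD 5 a.u.) clipped at zero; the
background floor keeps the clipping bias negligible, which is why mean
recovery stays within ~0.1 score units of truth at default settings.

**Translocation phantom.** Non-overlapping cells (10 µm radius, 4 µm
nucleus); each cell's p65 budget (10⁵ a.u.) splits `nuclear_fraction` into
the nucleus and the rest into the cytoplasmic ring, with MMP-9 painted
over the ring. Allocation is exact before noise.

**SI curves.** Flat baseline at t = 0, linear rise to (t_p, S_p),
exponential decay with configurable half-life (default 2 h), sampled at
the standard scan times {0, 5, 15, 30, 60, 120, 180, 360} min; the
noise-free curve passes through (0, S₀) and (t_p, S_p) exactly. This is
deliberately the simplest identifiable shape — no pharmacokinetic
compartments are modelled.

**Von Frey sessions.** Response at force F is Bernoulli with
p = logistic((log10 F − log10 θ)/slope); slope 0 gives a deterministic
step responder. The session mechanics reuse the estimator-side protocol.

**Cohorts.** Per-animal endpoint draws from group normals at the published
four-group means/SDs (n = 10 per group by default); physically
non-negative measures truncate at 0. PWT group levels (healthy ≈20 g,
untreated neuropathy ≈6 g, treated 12–15 g) and the per-group nuclear
fraction / ROS levels used by the pipeline's report stage are declared as
plausible values, since none are published.

**What the phantoms do not emulate** — and hence what passing tests do
not establish about real data: realistic histology texture, intensity
gradients and autofluorescence, out-of-focus light, anisotropic or
correlated noise, densely overlapping astrocyte territories, MRI physics
and contrast-agent pharmacokinetics, and within-animal correlation
structure beyond shared group means. Tests against the phantoms validate
the arithmetic and the pipeline contracts, not biological performance.

## Statistics

Descriptives are mean ± SD (ddof = 1) with t-based 95% CIs;
single-observation groups are flagged, not erroneous. One-way ANOVA uses
the explicit between/within sum-of-squares decomposition (pairwise
contrasts: pooled-variance t, Bonferroni m = number of pairs). The two-way
repeated-measures design (group between, time within) is fitted as a
mixed ANOVA with Greenhouse–Geisser-corrected p-values reported alongside
the uncorrected ones, since the sphericity convention is rarely stated;
subjects with missing time points are excluded with a warning, never
imputed, and an all-constant response short-circuits to the exact null
result. The post-hoc family is restricted to between-group contrasts at
the same time point with m = (#group pairs) × (#time points), and m is
recorded in the output so the family can be audited. Because adjusting
the contrast CIs is a convention choice, both unadjusted and
Bonferroni-adjusted CIs are emitted. Significance stars follow the
0.05/0.01/0.001/0.0001 convention.

## Problem sizes

Default test and script sizes — 30 phantoms per polarization level,
256×256 fields, 1000 Monte-Carlo up-down sessions, 200 cohort/permutation
replicates — were chosen so each suite completes in minutes on one CPU
while keeping Monte-Carlo error well inside the stated tolerances (e.g.
±3 score units for polarization recovery against a ~0.03 standard error).

## Known limitations

- No 3-D/z-stack support, deconvolution or learned segmentation; 2-D
  single-plane images only.
- Touching astrocytes merge; per-cell measures (Sholl) then describe the
  merged object.
- DICOM reading is out of scope for the core path; SI enters as CSV.
- The up-down k-table derives from the normal-model MLE rather than a
  transcribed historical table; values agree with the classical anchors
  but may differ in the second decimal for rare patterns.
- The exact filament series and starting filament of any given study are
  seldom reported; defaults are declared in config and should be matched
  to the lab's series before comparing absolute PWT values.
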