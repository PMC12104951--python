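# Methods

`bowmetrics` reproduces, on fully synthetic data, an analysis chain for
measuring central Bowman's-layer thickness (BT) with ultra-high axial
resolution corneal OCT and relating it to central corneal thickness
(CCT) across diagnostic groups. This note records the models,
parameters and numerical choices, and what the synthetic data do and do
not establish.

## Image formation model

A B-scan is modelled in optical-path coordinates `[z, x]` (z deepens
downward, 0-based, sub-pixel positions as floats). The cornea is four
media — air, epithelium, Bowman's layer, stroma — separated by three
interfaces: the tear-film surface, the epithelium–Bowman interface
(epithelial basement membrane) and the Bowman–stroma interface. Each
interface is thinner than the axial resolution, so it is rendered as an
impulse line on the bulk reflectivity background and convolved axially
with a Gaussian point-spread function. The PSF full width at half
maximum is 1.7 µm in tissue; in optical-path units that is
1.7 × n_G ≈ 2.36 µm (group refractive index n_G = 1.387), i.e. σ ≈ 2.0
pixels at the default 0.5 µm optical sampling. Impulse areas are scaled
so the post-blur peak equals the configured interface reflectivity. By
default the epithelium–Bowman line is bright (0.7 relative to the
tear-film surface at 1.0) and the Bowman–stroma line noticeably fainter
(0.25), reflecting how the two boundaries present in vivo.

The anterior surface is a circular arc of radius 7.8 mm (a typical
cornea; ∞ gives a flat phantom); deeper interfaces are vertical offsets
of it by the layer optical thicknesses, so the per-column thickness is
constant. Over the 450 µm measurement window of a 7.8 mm surface the
cosine obliquity between the vertical and surface-normal thickness is
< 0.2 %, far below measurement noise; thickness is therefore defined
per column (verified numerically: flat vs curved agree within 0.1 µm).

Noise is multiplicative speckle: a Rayleigh field smoothed to the PSF
scale (axial σ = PSF σ, lateral σ = 0.75 px), standardised to mean 1
and SD `speckle_contrast` (default 0.5, the order of fully developed
speckle). Per-frame axial jitter is Gaussian with SD 1.5 px (0.75 µm
optical), emulating axial eye motion between frames. A capture holds 16
frames by default (the instrument acquires up to 50). These defaults
were fixed as plausible operating conditions; the full pipeline's
measured repeatability under them (≈ 0.01 µm SD over re-captures) sits
comfortably inside the instrument's published 0.3 µm bound, largely
because frame and 225-column averaging suppress the per-pixel noise.

What the generator does *not* emulate: scarring and local contrast
loss (the main clinical cause of segmentation failure), non-Rayleigh
detector noise, lateral eye motion, refraction at curved interfaces,
and any hardware physics (interferometry, dispersion, spectrometer
roll-off). Passing tests therefore demonstrate the correctness and
internal consistency of the computational chain under the stated image
model, not clinical performance on real captures.

## Synthetic cohorts

Three groups — healthy controls (HC, n=18), keratoconus (KC, n=24) and
corneal dystrophies (CD, n=20) — are drawn with the published
group-level means for BT, epithelial thickness (ET), CCT, Kmax, age and
sex mix. The published BT dispersions (0.49/0.43/0.64 µm) are quoted as
cohort standard errors (they are inconsistent with the published
min–max ranges if read as SDs), so the generator scales them by √n to
per-subject SDs; all other dispersions are used as SDs directly. Both
readings are configurable via `GroupParams`.

Per subject, true BT and CCT are drawn from a bivariate normal with
within-group correlation `bt_cct_corr`. Its default, 0.374, is the
value at which the pooled BT~CCT regression on ground truth explains
18 % of variance for the default three-group cohort; it is found by
bisection (`calibrate_bt_cct_corr`, 10⁴ subjects per evaluation with
common random numbers, where the corr→R² map is effectively noiseless
and monotone). The pooled R² mixes this within-group correlation with
the between-group structure (KC corneas are thinner in both BT and
CCT), which is why the within-group value is well below √0.18.

Each subject contributes one eye with three captures (the protocol
minimum); each capture is an independent noise realisation of the
subject's true geometry with its own sub-seed. One root seed fans out
through `numpy.random.SeedSequence` substreams, so the whole study is
byte-reproducible and stages can be re-run independently.

## Preprocessing

Frames whose signal statistic (99th-percentile intensity minus median
background) falls below 25 % of the stack's median statistic are
screened out; a stack-relative bar is used because a uniformly
attenuated frame keeps its internal contrast ratios and cannot be
caught by a per-frame threshold. Surviving frames are aligned in the
axial direction only: each laterally averaged depth profile is
circularly cross-correlated against a running-average reference (the
first frame seeds it, so its shift is 0), with parabolic sub-pixel
refinement of the correlation peak. Circular correlation makes pure
integer shifts recover exactly; wrap-around is negligible because the
profile ends (air above, bulk stroma below) are flat. Aligned frames
are averaged and rows lacking full overlap are cropped (`row_offset`
maps back to reference-frame coordinates), so the average is unbiased
everywhere it is reported. Lateral registration is deliberately absent.

## Graph-search segmentation

Each interface is a left-to-right path, one node per column, with a
hard step constraint |Δz| ≤ 2 px per column; the minimum-cost path
under summed node energies is found by dynamic programming (equivalent
to a shortest path on the column DAG; verified against Dijkstra on
random instances). Because a resolution-limited interface images as a
bright *line*, the pipeline energy is ridge-type (negative normalised
intensity): the energy minimum sits on the line centre, which is the
true interface position. Signed-gradient energies (dark→bright /
bright→dark) are also provided for step-type edges. Sub-pixel positions
come from a per-column parabolic fit of the energy about the integer
path, clamped to ±0.5 px — the published 0.3 µm repeatability is finer
than one pixel, implying sub-pixel localisation.

Paths are extracted iteratively; after each extraction a ±3 px band
around it is blocked. The step bound and band are sized against the PSF
(σ ≈ 2 px): the band swallows duplicate detections of one interface but
cannot reach the neighbouring interfaces (≥ 5 µm ≈ 14 px away). A
deterministic policy then replaces the human supervisor: the shallowest
strong path (≥ 50 % of the brightest path's mean intensity) is the tear
film; the strongest path 20–100 µm (geometric) below it is the
epithelium–Bowman interface; the strongest path 5–25 µm below that —
faintness allowed — is the Bowman–stroma interface. Other low-energy
paths (bulk speckle lanes, decoy reflections) remain unassigned.
Callers can block regions to emulate supervisor overrides. Any
unassigned interface marks the capture failed.

Quality grading 1–5 proxies the original subjective interpretability
rating with a fixed monotone map from the weakest interface's
contrast-to-noise ratio (mean path intensity over the robust axial-
derivative noise scale) and path roughness: CNR ≥ 200 and roughness
< 0.3 px → 5, ≥ 80/< 0.6 → 4, ≥ 30/< 1.2 → 3, else 2 or 1; failures
are capped at 2. The exact thresholds are a package choice (the
original grading is human); they are set so grades fall monotonically
with speckle contrast under default averaging, and only the monotone
gate/weight semantics matter downstream.

## Thickness measurement and aggregation

BT per column is the axial separation of the two Bowman boundaries
times the axial pixel pitch, divided by n_G to convert optical path to
geometric tissue distance; ET likewise from tear film to basement
membrane (one index for all layers — only one is published). The
capture value is the mean over the centred 450 µm window (a
"quasi-point" measurement; 225 columns at 2 µm), with the within-window
SD reported. Captures scoring < 3 are excluded; per eye, the default
aggregate is the weighted mean with weights 1/2/3 for scores 3/4/5. A
"best" mode (single highest-score capture, ties to lowest window SD) is
also provided because the acquisition protocol describes both
behaviours; the mode is recorded in the output.

## Cohort statistics

Group summaries (mean/SD/min/max per variable plus BT/ET and BT/CCT
ratios, always recomputed), one-way ANOVA with Tukey HSD pairwise
comparisons, OLS of BT on CCT (slope, intercept, R², p; in the single-
covariate case R² equals the squared Pearson r), and an ordinary GLM of
the BT/CCT ratio on diagnosis, age, sex, Kmax and ET with Type-II
per-factor p-values. "Fixed and random factors" in the source protocol
is ambiguous; both sex and diagnosis are treated as fixed effects. Tukey
handles the pairwise family; a Holm option covers the GLM factor family
(raw and adjusted p-values both reported). On saturated designs (tiny
cohorts) the factor tests are skipped rather than reported as NaN.
All of this is delegated to `scipy.stats` and `statsmodels`.

## Problem sizes and determinism

The standard study is 62 subjects × 3 captures × 16 frames of
440 × 500 px images (≈ 2 minutes end-to-end on one core); tests use
narrower fields (460 µm) and fewer frames where full geometry is not
the point. Repeatability is quoted over 10 re-captures of one 15 µm
phantom. Everything is seeded; identical config + seed reproduces
byte-identical reports, and every output table carries the SHA-256 hash
of the resolved configuration.

## Known limitations

- The ridge energy assumes interfaces brighter than their surroundings;
  a true step-edge boundary would need the gradient polarities.
- The labelling policy assumes the three interfaces are the brightest
  coherent paths in their depth bands; heavy scarring or a decoy line
  inside a band could mislabel (the original protocol used human
  supervisors for exactly this reason — the blocking override is the
  programmatic escape hatch).
- Group means and the calibrated BT–CCT correlation assume the
  published summary statistics; the generator reproduces summary
  structure, not corneal microanatomy.
- The measured BT carries a small positive bias (≈ +0.06 µm at default
  noise) from speckle asymmetry at the faint posterior boundary — an
  order of magnitude below the between-group differences of interest.
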