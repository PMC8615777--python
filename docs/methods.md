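# Methods

## Scope and model

`mycomorph` implements the quantitative morphological analysis applied to
submerged cocultures of two pellet-forming filamentous microorganisms — a
slow-developing, agglomerative species "A" (an *Aspergillus*-type fungus
whose fully evolved pellets reach ~10⁷ µm² projected area) and an aggressive,
nonagglomerative species "B" (a *Streptomyces*-type actinomycete with pellets
around 10⁴–10⁵ µm²). Each experiment consists of three parallel stirred-tank
vessels (monoculture A, monoculture B, coculture) sampled every 24 h;
broth samples are photographed under phase contrast and analysed per object.

The analysis chain is: segmentation → per-object descriptors → fractionation
(fully evolved pellets vs hyphae/clumps, with species attribution in the
coculture) → per-stratum statistics → coculture outcome call.

## Segmentation

Objects are dark on a bright background with an optional bright halo rim.
The default pipeline is a median filter (disk footprint, radius 2 px) for
edge smoothing, Otsu thresholding of the smoothed intensity (keeping pixels
*below* the threshold), and 8-connected component labeling in raster order.
The Sobel gradient magnitude is computed by the same module and exposed both
for boundary QC and as an alternative threshold channel, since interactive
packages differ in whether they threshold intensity or gradient. Hole
filling is available but off by default: with solid dark objects it is
unnecessary, and it would fill the open loop of a strongly curled hyphal
fragment, silently converting a filament into a compact blob.

Components below `min_object_area` (default 500 µm², converted to pixels via
scale², so the cut-off is magnification-invariant) are treated as
spores/debris and dropped. Border-touching components are excluded by
default because their projected area is censored. Operator edits — the
"semiautomatic" part of such workflows — are declarative CSV records
(`delete`, `merge`, `split` via watershed seed points, `species` tags), so a
human decision is reproducible and auditable rather than interactive.

## Descriptors

Per object: A = pixel count × scale²; P = Crofton perimeter (4 directions)
× scale; d_max/d_min from rotating calipers on the convex hull of boundary
pixel centers; C = 4πA/P²; E = d_max/d_min; Mo = 2√(πA)/(P·E) ≡ √C/E (the
identity holds to 10⁻¹² by construction and is asserted in tests). The
Crofton estimator matters: naive pixel-edge counting overestimates P of a
digital disk by up to ~27 %, which would push measured pellet Mo far below
its analytic value of 1. With Crofton, a rasterized smooth disk of radius
200 px measures Mo ≈ 0.996. C and Mo may exceed 1 by at most ε = 0.05
(digital bias); values are reported unclamped so estimator bias stays
visible. Elongation is defined as the Feret ratio; a one-parameter switch to
an ellipse-fit definition was considered and rejected because the Feret form
reproduces the known anchors (disk → 1, square → √2, 200×10 µm rod → ≈ 20).

Objects of fewer than 3 pixels, or with a degenerate (collinear) convex
hull, raise a degenerate-object error and are skipped with a log entry.

## Fractionation and species attribution

An object is a **fully evolved pellet** iff Mo ≥ 0.35 AND E ≤ 1.9 AND
A ≥ 10⁴ µm² (inclusive thresholds); everything else is **hyphae/clumps**.
These defaults reconstruct the separation implied by the measured bands
(pellets Mo 0.36–0.77, E up to ~1.86; hyphae/clumps Mo 0.1–0.35,
E 1.75–3.25); like an operator's filter limits they are per-experiment
configuration, and the built-in scenarios carry their own overrides (the
small-pellet spore scenario lowers `pellet_min_area` to 3×10³ µm²; the
simultaneous scenario lowers the species size threshold to 6×10⁵ µm²).

Monoculture objects inherit the vessel's organism. Coculture *pellets* are
attributed by projected area (≥ `species_area_threshold`, default 10⁶ µm² →
species A); calls within ±20 % of the threshold are flagged for review but
still receive the rule-based call — overlap is surfaced, never silently
resolved. The coculture *dispersed* fraction is species-undetermined unless
an operator override names the species; overrides always win and carry
`provenance = operator`.

## Statistics

Per (experiment, culture, time, species, fraction) stratum: means of A, E,
Mo over pooled per-object values (not per-image means) with Student-t
confidence half-widths t₁₋α/₂,ₙ₋₁·s/√n at α = 0.05. Strata with n < 30 are
emitted but flagged and excluded from outcome evidence; n = 1 yields an
undefined half-width. Coculture-vs-monoculture comparisons use Welch's
two-sided t-test with Welch–Satterthwaite degrees of freedom; the pooled-
variance variant is available by flag, Welch is the default because mono-
and coculture group variances differ systematically. p-values are reported
raw per timepoint (tiers p<0.05 / p<0.01 / p<0.001) without multiple-testing
correction, matching how such time courses are conventionally reported; a
log-scale option for area comparisons exists but is off by default.

## Outcome call

Evaluation window: sampling times strictly after
`second_introduction_h + 24 h` — the settling period absorbs preculture-
formed pellets of the eventual loser that persist briefly after inoculation.
At least two window timepoints are required, else an insufficient-data error
is raised.

For each species: **domination** by the competitor iff the species' coculture
pellet stratum is empty at every window timepoint while its monoculture has
pellets at ≥ 2 of them (a stratum present below n = 30 counts as *present* —
conservative). If no species is dominated, **advantage**: the species'
coculture pellet area is significantly smaller (p < 0.05, coculture mean
below monoculture mean) at a strict majority of the usable window
timepoints. Domination is evaluated first for both species and outranks
advantage; if both species qualify within one verdict tier the call is
`none` with a conflict flag. The rule is antisymmetric under species
relabeling by construction.

The quantifiers ("strict majority", the 24 h settling period, n-aware
absence) are this package's operationalization of notions that field
practice applies qualitatively; they are deliberately configurable.

Process-profile support: air flowrate (1.5–5.5 L min⁻¹) and stirring speed
(220–300 min⁻¹) logs are interpolated onto a common hourly grid and compared
by Pearson correlation per channel, averaged; constant channels are skipped
with a warning. The metric is symmetric and affine-invariant, matching the
visual-similarity argument it formalizes; monocultures whose scores differ
by ≤ 0.05 are a tie.

## Synthetic data generator

The generator is the test substrate; real micrographs of such experiments
are not publicly deposited, so its defaults are calibrated to *published
numbers* (size scales, descriptor bands, time-course trends), not to images.

* **Pellet**: filled disk (core radius r = √(A/π) from a log-normal area
  draw) plus a radial hair fringe — sparse triangular spikes, depth
  0.12 r, ~42 spikes at density 0.35, half-width 1.25°. The fringe inflates
  the perimeter so measured pellet Mo lands in the 0.4–0.7 band rather than
  at the smooth-disk value 1, without adding more than ~3 % area.
* **Clump**: union of 3–8 jittered ellipses, PCA-whitened so its generative
  elongation is set by `axis_ratio` alone, rescaled to the drawn area.
* **Hypha**: constant-thickness flat-capped tube along a curling random
  curve; `tortuosity` is the total heading turn (default 2–4.5 rad), chosen
  so measured fragment elongation stays in the observed 1.75–3.25 band
  rather than at the L/t ratio of a straight rod.
* Anisotropy is an area-preserving affine stretch, so the generative Feret
  elongation of a smooth object equals `axis_ratio` exactly — this is what
  makes elongation-recovery experiments well-posed.

Scenes place objects on a jittered grid (no unplanned overlaps; explicit
overlaps are permitted and flagged in the truth table), rasterize polygons
with an exact even-odd scanline fill (pixel-center convention, verified
against an independent rasterizer), and shade: background 200, objects 60,
optional bright halo rim, additive Gaussian noise (σ = 8 grey levels) —
deliberately *no* PSF/defocus optics, shading gradients or 3-D structure.
Rendering is bit-deterministic: each object's private RNG is seeded by
(scene seed, object index).

Magnification is per-scene metadata, as in real practice: each population is
rendered at the smallest calibration from {2, 4, 8, 16} µm/px at which its
largest object fits a placement cell (giant pellets coarse, hyphae fine), so
one sampling timepoint may produce several images; downstream statistics
pool objects per (vessel, time). Sub-seeds for scenes and profiles derive
from the master seed via CRC32 of "experiment|vessel|time|population|scene",
mixed with the Knuth multiplier and reduced mod 2³¹.

Three scenario templates encode the characteristic outcomes of the coculture
initiation strategies, with mean-area/elongation trajectories taken from the
published time courses: `simultaneous_preculture` (species-A pellets ~10×
smaller in coculture at every sampling, 1.3×10⁶ vs 1.3×10⁷ µm² at 24 h,
E 1.56 vs 1.08; B pellets statistically indistinguishable between vessels
from 48 h — advantage to B), `delayed_introduction` (coculture B pellets
exist only at the first sampling after their introduction — domination by
A), and `spore_inoculation` (no A pellets ever develop in the coculture —
domination by B). Strata whose sizes were not printed (e.g. monoculture-A
pellets in the spore scenario) use scale-consistent values of ~10⁶ µm².
Default counts are 35 objects per stratum, satisfying the ≥ 30-object rule.

**What passing tests do and do not show.** The generator reproduces the
statistical structure the analysis assumes (size distributions, descriptor
bands, presence/absence patterns, noise), so green tests demonstrate that
the pipeline recovers known truth under those assumptions. They do not
certify performance on real phase-contrast images with uneven illumination,
touching/overlapping aggregates, out-of-focus mycelium or halo artifacts
stronger than the simple rim model.

## Numerical choices and problem sizes

Otsu on a uniform image warns and returns zero objects instead of failing.
Both-zero-variance Welch input falls back to exact mean comparison (p = 1 or
0) with a warning. Labels are raster-ordered; merges keep the target label;
splits allocate fresh labels above the current maximum. Population means are
log-normal with mean/CV parameterization (σ² = ln(1+CV²), µ = ln m − σ²/2).

Tests and the acceptance script run the time-course scenarios at 5 of the 8
sampling times with 35 objects per stratum — enough for every statistical
rule to engage at the prescribed n ≥ 30 while keeping a full run in minutes
on one CPU. Determinism, band, recovery and calibration checks use fixed
seeds; the acceptance script derives all of its seeds from `--seed`.

## Known limitations

* Species attribution in cocultures rests on pellet size separation; when
  the two species' pellet sizes genuinely overlap, only operator overrides
  (or the review flags) resolve the ambiguity.
* No declumping of touching pellets beyond operator splits; no illumination
  correction; no tracking of individual objects across timepoints.
* The coculture dispersed fraction is species-undetermined by design, so
  per-species hyphae statistics exist only for monocultures.
* Scenario trajectories prescribe stratum means directly; there is no
  growth-kinetics model linking timepoints.
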