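# Methods

This note records the models implemented by the package, the parameter
choices that matter, what the synthetic data emulate (and do not), and the
numerical decisions taken where the design was genuinely open.

## Echo-integration and the Sv data model

Volume backscattering strength Sv (dB re 1 m⁻¹) lives on a ping × depth
lattice per frequency.  Missing data are NaN and propagate; they are never
imputed.  Echo-integration to ESDU cells (default 3 pings × 1.5 m) averages
in the linear domain: samples below the integration threshold (default
−100 dB) contribute **zero linear energy** but still count in the
denominator, and a cell whose samples are all missing *or* all thresholded
is missing.  The threshold-as-zero semantics is the standard
echo-integration convention; the alternative (excluding thresholded samples
from the denominator) would bias cell means upward in sparse water.
Vertical resampling uses proportional overlap, so raw bins that are not an
exact multiple of the ESDU bin are apportioned by intersection thickness
rather than silently truncated.  Depth bins are half-open `[top, bottom)`,
positive down; the surface exclusion removes any bin whose top is above
15 m, and each frequency is cut at its maximum usable depth (18 kHz:
1000 m, 38: 800, 70: 500, 120: 250, 200: 120 m — the deepest *fully
contained* bin is kept, so a 1.5 m lattice cut at 250 m ends at 249 m).

NASC (s_A, m² nmi⁻²) is `4π·1852² · Σ 10^(Sv/10) · Δz`.  A depth window owns
a bin when the bin's **top edge** falls inside it; disjoint windows
therefore partition the water column and their s_A values add exactly, which
the depth-category metrics rely on.

Solar periods (night / sunrise / day / sunset) come from solar elevation via
the NOAA low-precision solar position algorithm (~0.1° accuracy, no
refraction): day above +6°, night below −6°, and the ±6° band split into
sunrise/sunset by the sign of the elevation trend one minute ahead.  The ±6°
civil-twilight-style band is a documented choice — the period names are
standard but published cutoffs vary; only day and night cells feed the
summary metrics.

## Classification feature space and scoring

The features are per-cell dB differences relative to 38 kHz:
ΔSv = (Sv₁₈−Sv₃₈, Sv₇₀−Sv₃₈, Sv₁₂₀−Sv₃₈).  A triplet is missing iff any
contributing frequency is missing, keeping the three axes jointly valid.

Each echo-class is an **axis-aligned** ellipsoid: centroid μ_k and per-axis
sample SDs σ_k of the class's *echo-type mean triplets* (not of constituent
pixels) — the library level is what the hierarchical clustering operates on,
so the ellipsoid describes between-echo-type variability within a class.
σ is floored at 0.1 dB so a tiny or degenerate class cannot produce an
ellipsoid of zero volume.  The score is the sum of squared per-axis
z-scores, χ²(3)-distributed when the cell is drawn from the class's diagonal
Gaussian; full covariance is deliberately not used (the score is defined as
a sum of independent squared normals).  Assignment is argmin over classes,
with the strict boundary rule *min score ≥ threshold ⇒ unclassified* and
ties at the minimum going to the lowest class index.  The default threshold
is 25 (the χ²(3) 0.99998 quantile), with a sweep utility over 1–100 that
reports well-/mis-/not-classified percentages by cell count and by
backscatter share.

## Training

ROIs are rectangles on the ΔSv lattice restricted to the upper 250 m (the
120 kHz usable range).  Within each ROI, K-means (default k_roi = 3,
10 restarts, fixed seed) partitions the cells and the largest cluster is
retained as the echo-type, unless an explicit per-ROI `retain` override
names another cluster — the override is how an analyst keeps the
semi-supervised intent when the structure of interest is not the majority
mode.  k_roi = 3 is a configuration default: one cluster for the coherent
structure, leaving room for edge and background pixels.

The library of echo-type means is clustered with Ward linkage on Euclidean
distances — variance-minimizing behaviour suits compact 3-D means — and the
dendrogram is cut at k.  Class indices are renumbered 1..k by ascending
centroid ΔSv₁₈₋₃₈ so numbering is deterministic rather than a merge-order
artifact.  The cluster count is a majority vote of five validity indices
(silhouette, Calinski–Harabasz, Davies–Bouldin, Dunn, gap statistic with 20
uniform reference draws and the one-SE rule), ties to the smaller k.  Five
indices keep the vote semantics of larger index batteries at tractable
scope; the set is easy to extend.

Label quality is reported as a random forest's out-of-bag
correct-classification rate (500 trees, 1 feature per split = round(√3),
per-class error from the OOB decision function).  OOB error is
finite-sample-pessimistic under uninformative labels, so chance-level
checks are run on libraries of ≥ 300 echo-types per class.

Each class's dominant frequency is the argmax of the linear-domain mean Sv
of its member cells per frequency (ties to the lower frequency) — the
linear mean is the standard way frequency-response curves are drawn.

## Forward scattering models

All models output TS = 10·log10(σ_bs); Sv for one organism m⁻³ is
numerically TS, and the ΔSv triplet is formed exactly as Sv(f) − Sv(38).
Sound speed uses Mackenzie's 9-term polynomial in T, S, depth; ambient
pressure is atmospheric plus hydrostatic (ρ = 1026.5 kg m⁻³ by default).
ESR→cylinder geometry is volume-preserving given the length-to-width ratio.

- **DWBA bent cylinder** (weak scatterers: copepods, euphausiids): line
  integral of the distorted-wave Born approximation along a uniformly bent
  axis with radius of curvature 3 × body length (a common bent-krill
  convention), material term γ_κ − γ_ρ, 128-point trapezoid along the arc,
  and Gaussian tilt averaging by 64-node Gauss–Hermite quadrature of the
  cross-section.  Null contrast (g = h = 1) returns NaN (no scattered
  field).  Default orientation N(0°, 20°) about broadside; defaults g, h in
  1.02–1.06 by taxon, all overridable.
- **Randomly oriented fluid bent cylinder** (shrimp, salps): a reduced-TS
  high-pass form — the Rayleigh-regime cross-section (consistent with the
  DWBA small-ka limit, with a sinc² length directivity) blended with the
  geometric ray plateau σ_G = R²·a·ρ_c/4 as σ_R/(1 + σ_R/σ_G), averaged over
  the spherical-uniform tilt density cos θ by 64-node Gauss–Legendre.  The
  plateau constant is an approximation at the ray-solution level; the model
  is used for qualitative frequency-response shapes, and it agrees with the
  DWBA within 3 dB in the Rayleigh regime by construction.
- **High-pass dense fluid sphere** (gastropods):
  σ_bs = a²(ka)⁴α / (1 + (ka)⁴α/R²) with the Rayleigh coefficient α from the
  g, h contrasts and plateau R² from the plane-wave reflection coefficient:
  40 dB/decade below resonance, flat at large ka.
- **Gas bubble**: damped Minnaert resonator
  σ_bs = a²/(((f₀/f)² − 1)² + δ²), f₀ from ambient pressure, γ (default 1.4)
  and water density, surface tension ignored; damping δ = radiation (ka) +
  viscous (4μ/(ρωa²), μ = 1.05 mPa s).  Thermal damping is omitted — it
  broadens the resonance of sub-millimetre bubbles somewhat but does not
  move the peak, which is what classification depends on.  The ellipsoid
  variant raises f₀ by the equal-volume prolate-spheroid capacitance factor
  √(C/a_eq) (same gas stiffness, elongated geometry).
- **Hybrid gas + body** (siphonophore pneumatophores, small swimbladdered
  fish): incoherent sum of the bubble and DWBA-body cross-sections — phase
  coherence between a resonant inclusion and a weak body is not modelled.
  The gas inclusion defaults to an ESR of 5% of body length (a
  swimbladder-fraction convention) when not given explicitly.

A theoretical scatterer is "classified" by scoring its ΔSv triplet against
the fitted echo-class model exactly as a one-cell grid would be.

## Summary metrics

Total s_A integrates each ping from the grid top to the frequency's maximum
depth and reports mean ± SD across pings per (zone, day/night); sunrise and
sunset pings are excluded.  Averaging across pings (rather than hours or
transect segments) is a documented choice.  DVM strength is
1 − s_A,night/s_A,day over the mesopelagic realm (200 m to maximum depth),
reported for 18/38/70 kHz only (the higher frequencies do not reach the
mesopelagic).  Depth categories are 15–200 m (surface), 200–400 m
(intermediate), ≥ 400 m (deep); 120 kHz resolves only surface +
intermediate and 200 kHz only surface.  EKE is ½(u² + v²) element-wise.

## Synthetic scenes

The generator plants horizontal layers on the ESDU lattice with
per-frequency mean Sv, Gaussian dB noise, per-segment per-frequency mean
drift, partial occupancy, and a step change of depth band at solar-period
boundaries (sunrise joins the day band, sunset the night band).  Gaussian
dB noise matches the scoring model's normality assumption; a linear-domain
noise option is deliberately not the default.  Overlapping layers resolve
to the first declared layer, recorded in the truth grid.

The canonical scene has four layers whose ΔSv signatures mirror the
qualitative frequency-response shapes seen in mesopelagic communities (one
18-kHz-dominant falling response; three 38-kHz-peaked shapes with distinct
high-frequency slopes), separated by ≥ 6.4 dB, with 0.5 dB cell noise and
0.5 dB segment drift over 52 twelve-ping segments per layer (208
echo-types).  The segment drift is what gives the library its within-class
spread — real training libraries always have one — so the fitted σ are
~0.7–0.9 dB rather than degenerate.  What passing tests on this scene show:
the pipeline recovers planted structure under Gaussian, well-separated
conditions.  What they do not show: performance under heavy-tailed
(Rayleigh-amplitude) noise, range-dependent signal loss, overlapping layers
with mixed signatures, or calibration error between frequencies — real-data
behaviour must be validated against trawls or scattering models as usual.

## Numerical choices and limitations

- Problem sizes in the test and acceptance runs (10⁵ coverage draws,
  3 × 10⁴ oracle cells, a 624-ping scene) were chosen to finish in seconds
  while leaving Monte-Carlo error well inside the asserted tolerances.
- Ping-time alignment across frequencies requires exact equality on the
  shared ESDU index; no interpolation across pings is performed.
- Echo-integration keeps a trailing partial ping group; its cell simply
  averages fewer samples.
- The classified-grid serialization writes −1 for unclassified and an empty
  field for missing; model files are plain JSON with per-class μ, σ,
  dominant frequency and the threshold.
- K-means, the random forest, the gap statistic and the scene generator are
  all seeded; training derives one seed per ROI from the base seed, so runs
  are bit-reproducible.
- The scattering module is narrowband only (no FM spectra), has no elastic
  shell model (pteropods are approximated by the high-pass sphere at best),
  and the randomly oriented cylinder's geometric plateau constant is
  approximate as noted above.
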