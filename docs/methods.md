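# Methods

`ctmar` is a desk-scale, fully synthetic re-creation of the computational
chain used in clinical comparisons of CT metal-artefact-reduction (MAR)
methods: simulate dual-energy CT of metal-bearing anatomy, reconstruct the
four study arms (uncorrected mixed image; iterative sinogram-domain MAR;
high-keV virtual monoenergetic imaging; their combination), quantify
residual streaks with a polygon-trace Fourier metric, and compare arms with
nonparametric paired statistics.  This note records the models, the
parameters that matter, and the design choices that were genuinely open.

## Attenuation model and spectra

Every material follows a two-basis model

    mu(E) = a_pe * (E/E0)^-3  +  a_c * f_KN(E) / f_KN(E0),      E0 = 70 keV,

a photoelectric term and a Compton term with the total Klein–Nishina
cross-section shape.  Both basis functions equal 1 at the 70 keV reference,
so a material is fully described by its photoelectric/Compton split of
mu(70 keV).  Water is pinned to mu = 0.1928 cm^-1 at 70 keV, the fixed
point of all Hounsfield calibration in the package.  Coefficients are
stylized rather than tabulated: tissues sit at plausible HU, iodinated
blood carries a strong photoelectric excess (the k-edge surrogate that
makes its HU collapse at high keV), and the three implant metals are tiered
titanium < steel < amalgam so implant density can drive the iterative-MAR
cycle count.  The table is editable YAML (`physics.dump_material_table`).

Tube spectra are analytic Kramers bremsstrahlung on [20, kVp] keV with an
aluminium-equivalent inherent filtration (0.5 cm) and, for the 140 kV
setting, a 0.4 mm tin filter.  Only the relative hardening between the
100 kV and Sn140 kV beams matters to the artefact mechanisms, so no
manufacturer spectrum is emulated.  The effective energy of a
polyenergetic acquisition is its fluence-weighted mean (≈ 56 keV and
≈ 88 keV at the defaults) and is used only for HU calibration.

## Phantoms

Two anatomies mirror the implant strata of the clinical setting.  Hip
slices contain an elliptical pelvis, sacral/iliac bone, iodine-enhanced
vessels, and one or two metal femoral-head discs (diameter ≈ 13% of the
grid; titanium when unilateral, steel when bilateral).  Dental slices
contain a mandibular bone arc carrying 2–6 small amalgam inserts, a
vertebral body, an airway and neck vessels.  Cohorts keep one bilateral
case per ten hip cases, matching the strongly unilateral clinical mix.
All placement jitter derives from the phantom seed; cohort seeds derive
from a master seed via `SeedSequence((master, case_index, stream))`, so
every run is bit-reproducible.

Each phantom ships two fixed measurement sites: a closed elliptical
polygon through soft tissue that encloses the bone + implant region
without crossing any structure (the streak-metric trace), and an
artefact-remote ≥ 20×20 px soft-tissue patch for the noise ROI.  Keeping
the polygon off bone and air means its baseline (metal-free) trace is flat
up to noise, so the Fourier score isolates artefact energy rather than
anatomy.

## Simulation and reconstruction

Acquisition is 2D parallel-beam over 180 views in [0°, 180°), one ray per
detector at the image pixel pitch (scikit-image `radon`).  Detected
intensity follows Beer–Lambert summed over the spectrum; noisy mode draws
Poisson counts per ray with a one-count electronic floor before the log —
the photon-starvation mechanism.  The polychromatic sum itself produces
beam hardening (cupping, dark bands).  Default photons per ray are 2×10^5
(100 kV) and 4×10^5 (Sn140 kV), which make both artefact mechanisms
metrically and visually obvious at 256².  Reconstruction is filtered
back-projection (ramp filter by default).

The arm orchestrator applies a water beam-hardening precorrection to both
channels before any reconstruction — the polychromatic log value is mapped
through the spectrum's water attenuation curve to its monoenergetic
equivalent, exactly as scanner preprocessing does.  Water-like tissue then
reconstructs cupping-free while bone, iodine and metal retain their
residual hardening, which is the artefact under study.  Raw
`acquire → fbp` stays uncorrected so the simulator's hardening behaviour
remains observable.

## The four arms

* **NOMAR** — FBP of both channels, blended 0.5/0.5 into a 120
  kV-equivalent mixed image.
* **IMAR** — per-channel iterative MAR (below), then the same blend.
* **DEMAR** — image-domain two-basis decomposition of the channel pair
  (closed-form 2×2 per pixel, same basis functions as the simulator),
  virtual monoenergetic synthesis at 130 keV, then a frequency split that
  keeps the 130 keV low-pass and restores the high-pass of a 70 keV VMI
  from the same maps (σ = 2 px, λ = 1) — high-keV extrapolation alone
  amplifies noise.
* **IMAR+DEMAR** — decomposition and 130 keV synthesis applied to the
  IMAR-corrected channels.

Using the simulator's own basis functions for decomposition makes the
noiseless pipeline exact, which gives clean oracle tests; a water/bone
basis would only change coefficients, not the mechanism.

## Iterative MAR

Metal is segmented at 3000 HU (above any bone, far below simulated metal
plateaus) with a radius-1 closing; the mask's forward projection defines
the corrupted-ray trace (path > ¼ pixel).  Mask and trace are frozen after
the initial reconstruction — re-segmentation each cycle risks oscillation.
Each cycle builds a three-plateau prior (air/soft/bone class medians,
metal set to the soft plateau, σ = 1 px smoothing), normalizes the
sinogram by the prior's projections (ε floor = 10⁻⁴ of the median positive
projection), linearly interpolates the normalized data across the trace per
view (views fully inside the trace interpolate along the angle axis), and
re-multiplies.  Rays outside the trace are never altered — bit-identical
output is asserted in the tests.  A frequency split then recombines: low
frequencies from the corrected image, the original's high frequencies
restored in a feathered band around metal (σ_split = 4 px, r_edge = 6 px,
w_edge = 1 at the 256-px reference grid; both scales are rescaled with
grid size so the band stays proportional to the anatomy).

Cycle count follows implant density: titanium 3, steel 4, amalgam 6.  The
density tier also selects the iteration's prior source.  For titanium and
steel the next prior is built from the frequency-split output: the
restored content near a large implant is mostly real anatomy (acetabulum,
cortical bone) and priors sharpen cycle over cycle.  For amalgam the metal
neighbourhood is dominated by photon-starvation streaks; feeding the split
output back re-imports them into every prior and the cycle diverges, so
amalgam priors come from the bare NMAR-corrected image.  This is the one
place the implementation departs from a single fixed loop, and it is the
package's own reading of "cycles based on the anticipated density of the
implant": density decides not just how often but how conservatively to
iterate.  `build_prior` also exposes a `force_bone` argument (persistent
bone class) for experimentation; the default chain does not use it.

## Streak metric

HU values are read along the case polygon by bilinear interpolation after
arc-length resampling to a fixed N = 256 samples (a power of two, so band
indices are comparable across differently sized polygons; the clinical
procedure samples successive pixels, making N polygon-dependent).  The
one-sided DFT amplitudes |F_k| (no 1/N scaling) are grouped into the four
low-frequency bands {1,2}, {3,4}, {5–8}, {9–16}; the headline score is
their total, Σ|F_k| for k = 1..16, with DC always excluded (it encodes
mean HU, not streaks).  Streaks cross the trace as slow excursions and
land in these bands; image noise lands above them.  Multi-slice scoring
averages per-slice scores with the identical polygon propagated to every
arm and slice.  The noise ROI is the population HU standard deviation in
the phantom's reserved soft-tissue circle.

## Statistics

Paired contrasts (each arm vs NOMAR; IMAR vs DEMAR; IMAR vs IMAR+DEMAR)
use the Wilcoxon signed-rank test: zero differences dropped, mid-ranks for
ties, exact enumeration of all 2^n sign assignments for n ≤ 12, otherwise
a normal approximation with tie and continuity corrections; the result
records which branch ran.  The two-sided p is the symmetric tail
probability P(|T − E T| ≥ |t − E T|), which reduces to the doubled tail
for untied data.  The unpaired Mann–Whitney U (exact labeling enumeration
when min(n, m) ≤ 8 and the count of labelings is tractable) is exposed for
between-strata comparisons.  Inter-reader agreement uses unweighted
Cohen's kappa on the 5×5 contingency with the conventional bands (0–0.20
slight … 0.81–1.00 almost perfect, lower bounds inclusive); perfect
agreement on one constant category returns 1 with a warning.  A seeded
reader simulator (quantile-binned scores, ±1 perturbation with probability
0.2) stands in for human Likert raters so the qualitative pipeline is
testable end to end.  No multiple-testing correction is applied; α = 0.05.

## What the synthetic cohort does and does not show

The default study conditions are 20 hip + 30 dental phantoms at 256² and
180 views, one noise realization per case (five-slice averaging is
supported and unit-tested but not used for the cohort, keeping a full run
near six minutes on one CPU).  Under these conditions the pipeline
reproduces the clinical pattern qualitatively: hip median streak scores
order NOMAR > DEMAR > IMAR > IMAR+DEMAR (median reductions ≈ −18%, −30%,
−55%), the dental DEMAR reduction is far smaller than the hip one and not
significant, and dense-implant single cases can show DEMAR above NOMAR —
high-keV synthesis cannot remove starvation noise.

Magnitudes are smaller than clinical values and are not comparable: the
phantoms are 2D cartoons without contrast dynamics, scanner preprocessing
beyond water precorrection, spiral/cone-beam geometry, scatter, or vendor
reconstruction kernels, and the implant alloys are stand-ins (implant
composition is typically unknown clinically).  Passing tests demonstrate
that the implemented mechanisms interact the way the clinical comparison
reports, not that the package predicts clinical effect sizes.

## Numerical choices and degenerate inputs

Noiseless log line integrals are clamped at 40 (opaque rays are logged);
noisy counts are floored at one before the log.  An empty metal mask makes
IMAR an exact no-op FBP.  A trace covering the whole sinogram raises
("metal too large for inpainting").  An empty prior class falls back to
documented default plateaus (−1000 / 40 / 900 HU) with a warning.
Polygons must be simple and inside the image; trace length must be a power
of two ≥ 64.  All-zero paired differences give p = 1 with W = 0.  The
percent-reduction baseline must be positive.
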