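# ctmar

Desk-scale simulation and analysis pipeline for comparing CT
metal-artefact-reduction (MAR) strategies on dual-energy acquisitions.

Metal implants corrupt CT images through two mechanisms: **beam
hardening** (preferential absorption of low-energy photons, causing
cupping and dark bands) and **photon starvation** (near-zero counts behind
metal, causing extreme noise streaks).  Clinically, two remedies dominate:
*iterative MAR* (IMAR — sinogram inpainting via normalized interpolation,
NMAR, combined with a frequency split, FSMAR, over several cycles) and
*dual-energy MAR* (DEMAR — virtual monoenergetic images extrapolated to
130 keV from a 100 kV / Sn140 kV pair).  `ctmar` rebuilds that comparison
end to end on synthetic phantoms, for researchers who want a controlled,
fully reproducible testbed for MAR algorithms and artefact metrics rather
than patient data.

The package provides:

* digital hip-prosthesis and dental-implant phantoms with a two-basis
  attenuation model, mu(E) = a_pe (E/70 keV)^-3 + a_c f_KN(E)/f_KN(70 keV);
* a polyenergetic parallel-beam simulator with Poisson photon statistics
  and filtered back-projection;
* the four reconstruction arms NOMAR, IMAR, DEMAR, IMAR+DEMAR;
* the quantitative endpoint: HU values sampled along a polygon drawn
  around the implant region, Fourier-transformed; streaks appear as high
  amplitudes at low frequencies, and the score is the one-sided amplitude
  sum over harmonics k = 1..16 (bands {1,2}, {3,4}, {5–8}, {9–16}
  reported alongside; DC excluded);
* paired nonparametric statistics (exact/approximate Wilcoxon signed rank
  and Mann–Whitney U, Cohen's kappa with the conventional agreement bands)
  and a report generator for per-stratum arm comparisons.

## Worked example

```python
from ctmar import make_phantom, percent_reduction
from ctmar.pipeline import PipelineConfig, run_case

phantom = make_phantom("hip_unilateral", grid_size=256, seed=7)
result = run_case(phantom, PipelineConfig(), case_index=0, case_id="demo")
scores = {c.arm_label: c.mean_score for c in result["scores"]}
for arm in ("NOMAR", "DEMAR", "IMAR", "IMAR+DEMAR"):
    print(f"{arm:11s} streak score {scores[arm]:9.0f}"
          f"   ({percent_reduction(scores[arm], scores['NOMAR']):+.1f}% vs NOMAR)")
print(f"noise ROI sd {result['noise_sd']:.1f} HU")
```

prints

```
NOMAR       streak score     95505   (+0.0% vs NOMAR)
DEMAR       streak score     79190   (-17.1% vs NOMAR)
IMAR        streak score     57024   (-40.3% vs NOMAR)
IMAR+DEMAR  streak score     31151   (-67.4% vs NOMAR)
noise ROI sd 114.0 HU
```

One simulated unilateral hip case, acquired at 100 kV and Sn140 kV with
photon noise, reconstructed four ways and scored along the same propagated
polygon.  Dual-energy extrapolation alone removes the beam-hardening share
of the streaks (−17%), iterative inpainting removes more (−40%), and the
combination is strongest (−67%) — the qualitative pattern reported for
hip prostheses clinically.  The noise ROI value is the soft-tissue HU
standard deviation far from the implant.

Cohort-level runs aggregate this over 20 hip and 30 dental cases and emit
a per-stratum table of means ± SD, percent reductions and Wilcoxon
p-values:

```python
from ctmar.pipeline import PipelineConfig, run_cohort, summarize_cohort
scores = run_cohort(PipelineConfig(master_seed=1))
print(summarize_cohort(scores)["hip"].to_markdown())
```

A CLI wraps the same functionality (`ctmar phantom`, `ctmar simulate`,
`ctmar imar`, `ctmar run-arm`, `ctmar score`, `ctmar pipeline`); images
and sinograms travel as 32-bit TIFF with JSON sidecars, polygons as
JSON/CSV, and HU slices can be exported to or read from DICOM.

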