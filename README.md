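# octaflow

Quantification of parafoveal capillary nonperfusion ("flow void") on OCTA
en-face angiograms, and analysis of how visit-to-visit blood-pressure
variability relates to retinal microvascular injury.

## Who this is for

Optical coherence tomography angiography (OCTA) images retinal blood flow at
capillary resolution, layer by layer. In chronic kidney disease (CKD) — where
hypertension is nearly universal — the superficial vascular plexus (SVP)
shows focal nonperfusion long before any visible retinopathy. This package is
for researchers who want to (a) measure those flow-void areas reproducibly
from standard 3 × 3 mm, 304 × 304-pixel en-face angiograms, and (b) relate
them to longitudinal office blood-pressure records through the standard
covariate-controlled correlation analysis, with a fully synthetic data
generator so every stage can be validated against known ground truth.

## The algorithm and the analysis

**Image quantification.** Vessels are extracted by repeated global histogram
equalization and fixed-threshold binarization: intensity *v* maps to
*h(v) = round(255 · cdf(v) / MN)*, the equalized image is thresholded at 185,
and the next pass re-equalizes only the still-unclassified pixels — three
passes pull in first the bright trunk arterioles/venules and then the faint
interconnecting capillaries. The union mask is thinned to one-pixel
centerlines with Zhang–Suen thinning and blurred with a normalized L × L
Gaussian kernel (L = 35, σ = 0.3·((L−1)·0.5 − 1) + 0.8 = 5.6) into a
*perfusion map*. Low-perfusion connected components on that map are the flow
voids; the component containing the fovea center is the physiologic foveal
avascular zone (FAZ) and is reported separately. Areas are pixel counts
times the squared physical scale (3/304 mm per pixel by default), with the
parafoveal flow-void area summed over the 1-mm-wide annulus between radii
0.5 and 1.5 mm.

**Blood-pressure features.** From each patient's dated visit records in the
365 days strictly before enrollment: 1-year average and maximum SBP/DBP, the
within-patient standard deviation (sample SD — the visit-to-visit
variability metric), and the proportion of readings with SBP > 140 mmHg.
Patients with fewer than 3 in-window measurements are excluded.

**Statistics.** Group comparisons use Pearson's chi-squared (2 × 2, no
continuity correction) and independent-samples t tests (pooled, Welch, or
SPSS-style auto-selection); the core analysis is the partial correlation of
each BP parameter with each retinal outcome after least-squares
residualization on age, sex, diabetes, axial length, and intraocular
pressure, with p from *t = r·√((n−2−k)/(1−r²))*.

## Worked example

```python
import octaflow as of

# one synthetic SVP angiogram with a 0.25-mm² parafoveal lesion
cfg = of.ImageSimConfig(seed=7, lesions=(of.lesion_spec_for_area(0.25),))
img, truth = of.generate_vessel_image(cfg)
res = of.quantify_image(img)
print(f"true void {truth.parafoveal_void_area_mm2:.4f}  "
      f"measured {res.parafoveal_flow_void_area_mm2:.4f}  "
      f"FAZ {res.faz_area_mm2:.4f}")

# a synthetic CKD cohort with a planted BP-variability effect
sim = of.generate_cohort(of.CohortSimConfig(seed=11))
results = of.CohortStudy(sim.table).fit()
print(results.table2.set_index(["bp_parameter", "outcome"])
      .loc[("sd_sbp", "flow_void_area")])
```

prints

```
true void 0.2499  measured 0.2414  FAZ 0.3047
coefficient    0.293
p_value        0.000
n              256
k              5
```

The injected lesion is recovered within ~3%; the FAZ (drawn at 0.31 mm², the
scale seen in healthy eyes) within ~2%. The cohort generator plants a partial
correlation of 0.244 between within-patient SD of SBP and SVP flow-void area
— the fitted grid recovers it (r = +0.29 here; estimates vary by a standard
error of ≈ 1/√(n−k−2) ≈ 0.06 between cohorts) while DVP vessel density,
generated with no BP effect, stays null.

The same workflow is available from the shell:

```bash
octaflow simulate-cohort --out data --seed 3
octaflow analyze --cohort data/cohort.csv --bp data/bp_visits.csv --out report
octaflow simulate-images --out imgs --n-images 5 --lesion-area 0.25
octaflow quantify --images imgs --out metrics.csv
```

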