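# ptfmass

**Left-ventricular mass and septal wall thickness from non-gated ¹⁵O-water
cardiac PET.**

¹⁵O-water is the reference tracer for quantifying myocardial blood flow, but
it is freely diffusible: a minute after injection the images hold no
anatomical contrast, so LV mass (LVM) and wall thickness (WT) — the
screening parameters for LV hypertrophy — cannot be read from static images.
They *can* be read from the kinetic model itself. Fitting the single-tissue
water model

&nbsp;&nbsp;&nbsp;&nbsp;C(t) = PTF · F e^(−Ft/p) ⊗ C_A(t) + V_A C_A(t) + V_RV C_RV(t)

voxel-wise yields a parametric **perfusable-tissue-fraction (PTF)** map — a
high-contrast structural image of the time-averaged ventricle. `ptfmass`
delineates the LV wall on that map with radial profiles (36 rays per
short-axis slice; contours at 67% of the profile maximum), sums the enclosed
volume × 1.05 g/mL into LVM, measures mid-septal WT as the mean of the 5
profiles nearest the LV→RV line, and classifies hypertrophy (indexed LVM
> 81 g/m² women / > 85 g/m² men; WT bands at 12 and 15 mm).

The package is aimed at PET methodologists: it contains the full measurement
chain (basis-function kinetics → short-axis reorientation → contouring →
LVM/WT → classification), a digital cardiac phantom with analytic ground
truth for validating every stage, and the agreement-statistics battery
(regression, Bland–Altman, ICC(2,1), repeatability coefficient, ROC/Youden,
contingency metrics) used to characterise such methods.

## Worked example

Simulate a typical heart (9 mm wall, 108.3 g, 5 mm scanner PSF, clinical
noise) and push it through the whole chain:

```python
from ptfmass import PhantomSpec
from ptfmass.pipeline import run_phantom

spec = PhantomSpec(seed=7)          # 5 mm PSF, clinical noise, 2 mm voxels
res = run_phantom(spec)
print(f"true LVM  {res['true_lvm']:6.1f} g   measured LVM  {res['lvm']:6.1f} g")
print(f"true WT   {res['true_wt']:6.1f} mm  measured WT   {res['wt']:6.1f} mm")
print(f"indexed LVM {res['lvm_indexed']:.1f} g/m2 -> {res['classification']}")
```

prints

```
true LVM   108.3 g   measured LVM    94.9 g
true WT      9.0 mm  measured WT      7.4 mm
indexed LVM 47.4 g/m2 -> {'wt_class': 'normal', 'lvh_mass': False}
```

The measured values sit below truth: at this wall-to-resolution ratio the
67%-of-maximum criterion places the cavity-side contour inside the true
endocardium (see `docs/methods.md` for the quantitative account — the bias
shrinks on cleaner images and reverses for hotter surroundings or stronger
blur). Both values are far from the hypertrophy cutoffs, so the
classification is robust to it.

The same flow is available from the shell:

```bash
ptfmass simulate --out sim/ --seed 7          # phantom + dynamic scan + truth.json
ptfmass fit --dynamic sim/dynamic.nii.gz --sidecar sim/dynamic.json \
            --input-functions sim/input_functions.csv --out maps/
ptfmass segment --ptf maps/ptf.nii.gz --vrv maps/vrv.nii.gz \
                --sex male --height-cm 178 --weight-kg 82 --out report.json
ptfmass validate --n-phantoms 10 --out cohort/ --seed 1   # synthetic-cohort agreement study
```

Clinical data enter through `ptfmass report --config pipeline.yaml`, where the
config names a 4-D NIfTI (kBq/mL), a BIDS-style frame-timing sidecar
(`FrameTimesStart`/`FrameDuration`; the default protocol is 22 frames over
6 minutes), and either an input-function CSV or cavity ROI masks.

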