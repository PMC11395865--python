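# rapidwashout

Rapid wash-out maps for brain-tumor MRI follow-up.

After surgery and radiochemotherapy for glioblastoma (and in CNS lymphoma or
brain metastases), the central diagnostic problem is telling active tumor from
treatment-related change (radiation necrosis, pseudoprogression).  Contrast
kinetics help: actively perfused tumor tissue enhances early and *washes out*
contrast agent within minutes, while scar and necrotic tissue accumulate
contrast slowly (*wash-in* / late enhancement).  This package implements an
automated mapping of that difference from just two post-contrast T1-weighted
acquisitions ~15 minutes apart (early ≈ 5 min, late ≈ 20 min after injection):

1. read both series (DICOM or NIfTI),
2. N4 bias-field correction per series (3-fold shrink during estimation),
3. linear rescaling of both series to a common foreground mean,
4. rigid (6-DOF) registration of the late series onto the early grid
   (Mattes mutual information, multi-resolution, deterministic),
5. voxelwise subtraction `d = early − late`,
6. 8-bit encoding: the observed value range is halved into a symmetric clip
   range ±C and mapped linearly with `d = 0 ↦ 127` of 255; positive values
   (wash-out, tumor/vessel) ramp the **red** channel, negative values
   (wash-in, scar/necrosis) the **green** channel,
7. compartment segmentation and volumetry with the wash-out ratio
   `WO / (WO + WI)`,
8. optional hyperperfusion volumetry of a co-registered rCBV map at
   `rCBV > 1.2` with a 0.25 cm² minimum in-plane area criterion,
9. agreement statistics (ICC(2,k), Pearson r, Tukey HSD, paired t-tests,
   Likert summaries) for comparing wash-out with perfusion volumetry.

A built-in digital contrast-kinetics phantom (`rapidwashout.phantom`)
generates paired series from per-tissue enhancement curves with known masks,
bias fields, misalignment and noise, so the whole pipeline is testable
without patient data.

## Worked example

```python
import numpy as np
from rapidwashout import phantom, RunConfig, run_volumes

rng = np.random.default_rng(42)
t_true = phantom.random_rigid(rng, max_rotation_deg=5, max_translation_mm=5)
case = phantom.generate(seed=3, transform=t_true)   # early, late, rcbv + truth

res = run_volumes(case.early, case.late, rcbv=case.rcbv, config=RunConfig())
v = res.volumetry
print(f"wash-out {v.washout_mm3:.0f} mm3  wash-in {v.washin_mm3:.0f} mm3  "
      f"ratio {v.washout_ratio:.3f}")
print(f"perfusion (rCBV>1.2) {res.perfusion.volume_mm3:.0f} mm3")
print(f"registration recovered: {res.registration.success}")
```

prints

```
wash-out 2768 mm3  wash-in 3840 mm3  ratio 0.419
perfusion (rCBV>1.2) 1888 mm3
registration recovered: True
```

The phantom's true wash-out compartment (2 cm³ tumor sphere plus a small
vessel segment) voxelizes to 2768 mm³ — the measured wash-out volume matches
it exactly here; the wash-in volume is the slow-enhancing scar sphere; the
wash-out ratio is the per-case summary statistic (active fraction of the
total kinetically abnormal volume).  The perfusion volume is the
hyperperfused tumor sphere — the thin synthetic vessel falls below the
0.25 cm² in-plane area criterion and is filtered out.  The recovered rigid
transform is within a tenth of a voxel of the applied one.

The same pipeline runs from the shell:

```bash
rapidwashout phantom --out case0 --seed 0 --rotation-deg 5 --translation-mm 5
rapidwashout compute --early case0/early.nii.gz --late case0/late.nii.gz \
    --rcbv case0/rcbv.nii.gz --out case0_results
```

which writes the difference NIfTI, gray + RGB DICOM series, compartment
masks, a per-lesion CSV and a JSON provenance manifest (settings, scale
factors, transform, clip range, timings, output checksums).

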