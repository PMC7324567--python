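# cardioqsm

Quantitative susceptibility mapping (QSM) of the myocardium, for imaging
scientists studying iron in reperfused myocardial infarction. After a heart
attack treated by reperfusion, hemorrhage deposits iron in the infarct;
iron is paramagnetic and shifts the tissue magnetic susceptibility Δχ by of
order +0.03–0.16 ppm relative to remote myocardium — a contrast measurable
from the gradient-echo MRI signal phase where conventional T2*-based
reading is confounded by edema and fibrosis.

`cardioqsm` provides the full reconstruction and analysis chain as an
importable Python library (with a thin CLI), plus a synthetic cardiac
phantom that stands in for animal/patient data:

- **Forward model** — Fourier-domain dipole kernel `D = 1/3 − kz²/k²`,
  field simulation `FΦ = DFΔχ`, validated against the closed-form
  magnetized-sphere solution.
- **Phantom** — ellipsoidal myocardial shell, angular infarct wedge with a
  paramagnetic shift and shortened T2*, blood pool, matched bath or air
  background; noisy multi-echo complex echoes at the ex vivo protocol
  (5 TEs, 3.3–16.1 ms, 3 T).
- **Field preparation** — phase unwrapping, per-voxel weighted
  least-squares field fitting (ppm), magnitude-threshold masking, SNR
  weights.
- **Background removal** — projection onto dipole fields (PDF) by
  conjugate gradient.
- **Dipole inversion** — morphology-enabled, TV-regularized:
  `min_Δχ λ‖MGΔχ‖₁ + ‖W(F⁻¹DFΔχ − Φ)‖₂²`, solved by IRLS with inner
  conjugate gradient and a monotone objective.
- **Relaxometry** — voxelwise `S = A·e^(−TE/T2*)` fits, R2* = 1/T2*, error
  maps.
- **ROI analysis** — iso/hyper/hypointense region classification on T2*w
  images, susceptibility referencing to remote myocardium, FWHM infarct
  sizing, ROC curves with AUC and Youden's index.

## Worked example

`examples/02_phantom_reconstruction.py` simulates the default 64³ cardiac
phantom at amplitude SNR 40 (infarct Δχ = +0.07 ppm over remote myocardium)
and reconstructs it end to end:

```
$ python examples/02_phantom_reconstruction.py
true infarct-remote contrast:      0.0700 ppm
recovered contrast:                0.0649 ppm (-7.3 %)
voxelwise infarct-vs-remote AUC:   0.992
```

The recovered contrast agrees with the simulated truth to a few percent and
the ROC AUC near 1 shows voxelwise susceptibility cleanly separates infarct
from remote myocardium under the phantom's noise model. The other examples
demonstrate the sphere-oracle validation of the forward model, T2*
relaxometry, and the region/FWHM/ROC analyses.

The same pipeline is scriptable from a shell:

```bash
cardioqsm all --out results/phantom_run
cardioqsm recon --mag mag_e00.nii ... --phase phase_e00.nii ... \
    --sidecar series.yaml --out results/recon
```

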