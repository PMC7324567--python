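"""End-to-end susceptibility reconstruction of the synthetic cardiac phantom.

Simulates the ex vivo protocol (5 echoes, 3.3-16.1 ms, 3 T) on a 64-cube
phantom whose infarct wedge carries a +0.07 ppm paramagnetic shift over
remote myocardium at amplitude SNR 40, then reconstructs: mask -> unwrap ->
field fit -> dipole inversion -> referencing, and compares the recovered
infarct-remote contrast with the simulated truth.
"""

import tempfile

from cardioqsm.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig(
    phantom_n=64,
    snr=40.0,
    seed=1,
    # the default phantom sits in a susceptibility-matched bath: there are
    # no exterior field sources, so the background-removal projection is
    # skipped (see docs/methods.md on its over-removal of tissue field)
    apply_pdf=False,
)

with tempfile.TemporaryDirectory() as out:
    results = run_pipeline(config, out)

truth = 0.07  # ppm, infarct minus remote in the simulated heart
recovered = results["recovered_delta_chi"]
print(f"true infarct-remote contrast:      {truth:.4f} ppm")
print(f"recovered contrast:                {recovered:.4f} ppm "
      f"({(recovered - truth) / truth * 100:+.1f} %)")
print(f"voxelwise infarct-vs-remote AUC:   {results['roc'].auc:.3f}")
print()
print("The recovered contrast within a few percent of 0.07 ppm and an AUC")
print("near 1 show the inversion separates infarct from remote myocardium.")
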