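"""T2*-weighted region classification, FWHM sizing and ROC analysis.

Classifies iso/hyper/hypointense regions on the last-echo magnitude image,
references the true susceptibility map to remote myocardium, sizes the
infarct by full-width-at-half-maximum thresholding on a synthetic
enhancement image, and scores infarct-vs-remote classification by ROC.
"""

import numpy as np

import cardioqsm as cq
from cardioqsm.background import erode_mask
from cardioqsm.dipole import ScalarVolume
from cardioqsm.phantom import LABELS

spec = cq.default_spec(48, snr=40.0, seed=4)
truth = cq.build_phantom(spec)
series = cq.synthesize_echoes(truth, spec)
mask = cq.make_mask(series)

# iso / hyper / hypo regions on the last-echo T2*-weighted image
t2sw = cq.t2star_weighted_image(series, series.n_echoes - 1)
remote_seed = erode_mask((truth.labels == LABELS["remote"]) & mask, 1)
regions = cq.classify_t2sw_regions(t2sw, mask, remote_seed, k_sd=2.0)

# susceptibility referenced to remote myocardium
chi_ref = cq.reference_susceptibility(truth.chi_map, regions.remote)
stats = cq.region_stats(
    ScalarVolume(grid=spec.grid, values=chi_ref.values, units="ppm"), regions
)
print(stats.to_string(index=False))

# FWHM infarct sizing on a synthetic enhancement image (infarct enhances)
myocardium = np.isin(truth.labels, (LABELS["remote"], LABELS["infarct"])) & mask
enhancement = ScalarVolume(
    grid=spec.grid,
    values=np.where(truth.labels == LABELS["infarct"], 300.0, 100.0)
    + np.random.default_rng(0).normal(scale=5.0, size=spec.grid.shape),
    units="arbitrary",
)
fwhm = cq.fwhm_infarct_mask(enhancement, myocardium, regions.remote)
true_size = ((truth.labels == LABELS["infarct"]) & mask).sum()
print(f"\nFWHM infarct size: {fwhm.sum()} voxels (truth {true_size})")

# ROC of the T2*w intensity as an infarct classifier
eval_mask = myocardium
labels = (truth.labels == LABELS["infarct"])[eval_mask].astype(int)
roc = cq.roc_curve(-t2sw.values[eval_mask], labels)  # hypointense = positive
print(f"T2*w hypointensity AUC: {roc.auc:.3f}, Youden J: {roc.youden_j:.3f}")
print()
print("Hypointense voxels align with the hemorrhagic wedge; the FWHM rule")
print("recovers the infarct size and T2*w intensity separates the classes.")
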