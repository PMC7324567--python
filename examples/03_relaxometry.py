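"""T2* relaxometry on the synthetic phantom.

Fits the two-parameter monoexponential S = A exp(-TE/T2*) per voxel and
summarizes T2* in the remote myocardium and the (shortened-T2*) infarct.
"""

import numpy as np

import cardioqsm as cq
from cardioqsm.phantom import LABELS

spec = cq.default_spec(48, snr=40.0, seed=3)
truth = cq.build_phantom(spec)
series = cq.synthesize_echoes(truth, spec)
mask = cq.make_mask(series)

fit = cq.fit_t2star(series, mask)

remote = (truth.labels == LABELS["remote"]) & mask
infarct = (truth.labels == LABELS["infarct"]) & mask

print(f"echo times: {[f'{t * 1e3:.1f}' for t in spec.tes]} ms")
print(f"remote  T2*: fitted {np.median(fit.t2s_map.values[remote]):6.2f} ms "
      f"(truth {spec.t2s_remote} ms)")
print(f"infarct T2*: fitted {np.median(fit.t2s_map.values[infarct]):6.2f} ms "
      f"(truth {spec.t2s_infarct} ms)")
print(f"median relative fit residual: {np.median(fit.error_map.values[mask]):.4f}")
print()
print("The infarct's short T2* (hemorrhagic core) is recovered alongside the")
print("remote value; the error map stays at the noise level when the data")
print("follow the monoexponential model.")
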