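"""Region definition, susceptibility referencing, infarct sizing and ROC.

Regions follow the T2*-weighted reading of hemorrhagic infarction: remote
myocardium is isointense, edematous rim hyperintense, hemorrhagic core
hypointense.  The interactive segmentation of clinical practice is replaced
by a deterministic rule — voxels beyond k·SD of a known-remote reference
region are hyper/hypointense — while externally drawn masks can be supplied
unchanged.

Susceptibility values are referenced by subtracting the mean over a
reference region (the remote myocardium): the dipole kernel has no DC
component, so only susceptibility *differences* are observable.

Infarct sizing uses full-width-at-half-maximum thresholding on an
enhancement image, and classification performance is summarized by an ROC
curve with trapezoidal AUC and Youden's index at the optimal operating
point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dipole import ScalarVolume, SusceptibilityMap

__all__ = [
    "RegionSet",
    "RocResult",
    "classify_t2sw_regions",
    "reference_susceptibility",
    "fwhm_infarct_mask",
    "roc_curve",
    "region_stats",
]


@dataclass
class RegionSet:
    """Binary masks for the T2*w-derived regions on one grid."""

    remote: np.ndarray   # isointense
    hyper: np.ndarray
    hypo: np.ndarray

    @property
    def infarct(self) -> np.ndarray:
        return self.hyper | self.hypo

    @property
    def reference(self) -> np.ndarray:
        return self.remote

    def as_dict(self):
        return {
            "remote": self.remote,
            "hyper": self.hyper,
            "hypo": self.hypo,
            "infarct": self.infarct,
        }


@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_j: float
    optimal_threshold: float
    sensitivity_at_optimum: float
    specificity_at_optimum: float


def classify_t2sw_regions(
    t2sw: ScalarVolume,
    tissue_mask: np.ndarray,
    remote_seed_mask: np.ndarray,
    k_sd: float = 2.0,
) -> RegionSet:
    """Split tissue into iso/hyper/hypo by deviation from a remote reference.

    μ and σ (sample SD) come from ``remote_seed_mask`` — a region known a
    priori to be remote myocardium.  Voxels below μ − k·σ are hypointense,
    above μ + k·σ hyperintense, the remainder isointense.
    """
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    remote_seed_mask = np.asarray(remote_seed_mask, dtype=bool)
    if not remote_seed_mask.any():
        raise ValueError("remote seed mask is empty")
    vals = t2sw.values[remote_seed_mask]
    mu = vals.mean()
    sigma = vals.std(ddof=1) if vals.size > 1 else 0.0
    if sigma == 0.0:
        raise ValueError("remote reference region has zero variance")
    hypo = tissue_mask & (t2sw.values < mu - k_sd * sigma)
    hyper = tissue_mask & (t2sw.values > mu + k_sd * sigma)
    iso = tissue_mask & ~hypo & ~hyper
    return RegionSet(remote=iso, hyper=hyper, hypo=hypo)


def reference_susceptibility(
    chi: SusceptibilityMap, reference_mask: np.ndarray
) -> SusceptibilityMap:
    """Subtract the mean χ over the reference region (idempotent).

    Pairwise susceptibility differences are preserved exactly.
    """
    reference_mask = np.asarray(reference_mask, dtype=bool)
    if not reference_mask.any():
        raise ValueError("reference mask is empty")
    offset = chi.values[reference_mask].mean()
    return SusceptibilityMap(grid=chi.grid, values=chi.values - offset)


def fwhm_infarct_mask(
    lge_like: ScalarVolume,
    myocardium_mask: np.ndarray,
    remote_mask: np.ndarray,
    variant: str = "remote_anchor",
) -> np.ndarray:
    """Full-width-at-half-maximum infarct sizing on an enhancement image.

    ``remote_anchor`` (default): threshold = remote_mean + ½·(max over
    myocardium − remote_mean), robust to global intensity offsets.
    ``half_max``: threshold = ½·max.  Voxels at or above the threshold are
    infarct.  With no enhancement (max ≤ remote mean) an empty mask is
    returned with a warning.
    """
    myocardium_mask = np.asarray(myocardium_mask, dtype=bool)
    remote_mask = np.asarray(remote_mask, dtype=bool)
    if not myocardium_mask.any() or not remote_mask.any():
        raise ValueError("myocardium and remote masks must be nonempty")
    v = lge_like.values
    remote_mean = v[remote_mask].mean()
    vmax = v[myocardium_mask].max()
    if vmax <= remote_mean:
        warnings.warn(
            "no enhancement above the remote mean: empty infarct mask",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.zeros_like(myocardium_mask)
    if variant == "remote_anchor":
        threshold = remote_mean + 0.5 * (vmax - remote_mean)
    elif variant == "half_max":
        threshold = 0.5 * vmax
    else:
        raise ValueError(f"unknown FWHM variant {variant!r}")
    return myocardium_mask & (v >= threshold)


def roc_curve(values, labels) -> RocResult:
    """ROC analysis with "greater is positive" polarity.

    Thresholds sweep the unique values; a sample is called positive when its
    value is ≥ threshold.  AUC is the trapezoidal integral of sensitivity
    against 1 − specificity and equals the pairwise concordance probability
    with ties counted ½.  Youden's J = max(sens + spec − 1); at ties the
    lower threshold is reported.
    """
    values = np.asarray(values, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if values.shape != labels.shape:
        raise ValueError("values and labels must have the same length")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary {0, 1}")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    order = np.argsort(-values, kind="stable")
    v_sorted = values[order]
    y_sorted = labels[order]
    # cumulative positives/negatives at each unique threshold (value ≥ thr)
    distinct = np.r_[np.nonzero(np.diff(v_sorted))[0], len(v_sorted) - 1]
    tp = np.cumsum(y_sorted)[distinct]
    fp = np.cumsum(1 - y_sorted)[distinct]
    thresholds = v_sorted[distinct]

    sens = tp / n_pos
    fpr = fp / n_neg
    spec = 1.0 - fpr

    # prepend the "call nothing positive" operating point
    sens_curve = np.r_[0.0, sens]
    fpr_curve = np.r_[0.0, fpr]
    auc = float(np.trapezoid(sens_curve, fpr_curve))

    j = sens + spec - 1.0
    jmax = j.max()
    # ties on J: report the lowest qualifying threshold
    best = np.nonzero(np.isclose(j, jmax, rtol=0, atol=0) | (j == jmax))[0][-1]
    return RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        youden_j=float(jmax),
        optimal_threshold=float(thresholds[best]),
        sensitivity_at_optimum=float(sens[best]),
        specificity_at_optimum=float(spec[best]),
    )


def region_stats(map_volume: ScalarVolume, regions) -> pd.DataFrame:
    """Tidy per-region summary (n, mean, sample SD, median) of a named map.

    ``regions`` is a RegionSet or a mapping name → boolean mask.  Empty
    regions are reported with n = 0 and missing statistics.  The table is
    ready for any downstream statistics environment.
    """
    if isinstance(regions, RegionSet):
        regions = regions.as_dict()
    rows = []
    for name, mask in regions.items():
        mask = np.asarray(mask, dtype=bool)
        vals = map_volume.values[mask]
        if vals.size == 0:
            rows.append({"region": name, "n": 0, "mean": np.nan, "sd": np.nan,
                         "median": np.nan})
            continue
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        rows.append({
            "region": name,
            "n": int(vals.size),
            "mean": float(vals.mean()),
            "sd": sd,
            "median": float(np.median(vals)),
        })
    df = pd.DataFrame(rows)
    df.attrs["units"] = map_volume.units
    return df
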