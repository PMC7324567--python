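"""From multi-echo complex data to an unwrapped total field map in ppm.

Phase unwrapping is temporal: echo-to-echo phase increments are taken from
the complex conjugate product, which is wrap-free whenever the true
increment stays below π (the ex vivo ΔTE of 3.2 ms keeps myocardial fields
well inside this), and the first echo is unwrapped spatially with a
quality-guided algorithm so that strong background fields at short TE are
handled too.  The graph-cut SPURS algorithm of the original processing
chain is intentionally not reproduced: water-only phantoms carry no
chemical shift, and the unwrapping contract (output congruent to the input
modulo 2π, correct field recovery) is algorithm-agnostic.

The total field is then a per-voxel weighted linear least-squares fit of
φ(TE) = φ₀ + 2π f·TE with magnitude-squared weights (the maximum-likelihood
weighting for complex Gaussian noise), converted from Hz to ppm via
f / (γ̄ B₀) · 10⁶.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.restoration import unwrap_phase as _unwrap_spatial

from .dipole import FieldMap, ScalarVolume, VolumeGrid
from .phantom import ComplexEchoSeries

__all__ = [
    "FieldFitResult",
    "unwrap_phase",
    "fit_total_field",
    "make_mask",
    "compute_noise_weight",
]


@dataclass
class FieldFitResult:
    total_field: FieldMap          # ppm, kind="total"
    phi0_map: ScalarVolume         # radians
    residual_map: ScalarVolume     # weighted RMS fit residual, radians


def _require_mask(mask: np.ndarray, grid: VolumeGrid) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.shape:
        raise ValueError("mask shape does not match grid")
    if not mask.any():
        raise ValueError("mask is empty")
    return mask


def unwrap_phase(series: ComplexEchoSeries, mask: np.ndarray) -> np.ndarray:
    """Unwrap per-echo phase; returns radians, shape (n_echoes, *grid.shape).

    Echo 1 is unwrapped spatially (quality-guided, within the mask); later
    echoes add the temporal increments angle(S_j · conj(S_{j−1})).  For every
    masked voxel and echo, (unwrapped − wrapped) is an integer multiple of
    2π up to floating-point rounding.
    """
    if series.n_echoes < 2:
        raise ValueError("need at least 2 echoes to unwrap a multi-echo series")
    mask = _require_mask(mask, series.grid)
    mag1 = np.abs(series.echoes[0])
    if not (mag1[mask] > 0).any():
        raise ValueError("all-zero magnitude inside mask: no phase information")

    wrapped0 = np.angle(series.echoes[0])
    masked = np.ma.array(wrapped0, mask=~mask)
    unwrapped0 = np.ma.filled(_unwrap_spatial(masked), 0.0)
    unwrapped0[~mask] = wrapped0[~mask]

    out = np.empty((series.n_echoes,) + series.grid.shape, dtype=float)
    out[0] = unwrapped0
    for j in range(1, series.n_echoes):
        increment = np.angle(series.echoes[j] * np.conj(series.echoes[j - 1]))
        out[j] = out[j - 1] + increment
    return out


def fit_total_field(
    unwrapped: np.ndarray,
    series: ComplexEchoSeries,
    mask: np.ndarray,
) -> FieldFitResult:
    """Per-voxel weighted least squares of φ(TE) = φ₀ + 2π f TE.

    Weights are the squared echo magnitudes.  The slope is converted to ppm
    of the main field.  Outside the mask all outputs are zero.
    """
    if series.n_echoes < 2:
        raise ValueError(
            "field fitting needs at least 2 echoes: with a single echo the "
            "slope is not identifiable jointly with the receiver phase φ₀"
        )
    tes = np.asarray(series.tes, dtype=float)
    if np.any(np.diff(tes) <= 0):
        raise ValueError("echo times must be strictly increasing")
    mask = _require_mask(mask, series.grid)
    unwrapped = np.asarray(unwrapped, dtype=float)
    if unwrapped.shape != (series.n_echoes,) + series.grid.shape:
        raise ValueError("unwrapped phase volumes do not match the series")

    w = np.abs(series.echoes) ** 2  # (E, ...)
    t = tes.reshape(-1, 1, 1, 1)
    sw = w.sum(axis=0)
    swt = (w * t).sum(axis=0)
    swtt = (w * t * t).sum(axis=0)
    swp = (w * unwrapped).sum(axis=0)
    swtp = (w * t * unwrapped).sum(axis=0)

    det = sw * swtt - swt**2
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (sw * swtp - swt * swp) / det          # rad/s
        intercept = (swtt * swp - swt * swtp) / det    # rad
    bad = ~np.isfinite(slope) | ~np.isfinite(intercept)
    slope[bad] = 0.0
    intercept[bad] = 0.0

    resid = unwrapped - (intercept + slope * t)
    with np.errstate(divide="ignore", invalid="ignore"):
        rms = np.sqrt((w * resid**2).sum(axis=0) / sw)
    rms[~np.isfinite(rms)] = 0.0

    f_hz = slope / (2 * np.pi)
    ppm = f_hz / (series.gamma_bar * series.b0) * 1e6
    ppm[~mask] = 0.0
    intercept[~mask] = 0.0
    rms[~mask] = 0.0

    grid = series.grid
    return FieldFitResult(
        total_field=FieldMap(grid=grid, values=ppm, kind="total"),
        phi0_map=ScalarVolume(grid=grid, values=intercept, units="radians"),
        residual_map=ScalarVolume(grid=grid, values=rms, units="radians"),
    )


def make_mask(series: ComplexEchoSeries, rel_threshold: float = 0.15) -> np.ndarray:
    """Tissue mask by thresholding the echo-1 magnitude image.

    Threshold = rel_threshold × (99th percentile of the magnitude); the
    largest connected component is retained and eroded by 1 voxel to drop
    unreliable boundary phase.
    """
    if not 0.0 < rel_threshold < 1.0:
        raise ValueError("rel_threshold must lie in (0, 1)")
    mag = np.abs(series.echoes[0])
    threshold = rel_threshold * np.percentile(mag, 99)
    raw = mag > threshold
    if not raw.any():
        raise ValueError(
            f"empty mask: no voxels above threshold {threshold:.4g} "
            f"(rel_threshold={rel_threshold}, p99={np.percentile(mag, 99):.4g})"
        )
    labeled, n = ndimage.label(raw)
    if n > 1:
        sizes = ndimage.sum_labels(raw, labeled, index=np.arange(1, n + 1))
        raw = labeled == (1 + int(np.argmax(sizes)))
    eroded = ndimage.binary_erosion(raw)
    if not eroded.any():
        raise ValueError("mask vanished after 1-voxel erosion; object too thin")
    return eroded


def compute_noise_weight(series: ComplexEchoSeries, mask: np.ndarray) -> np.ndarray:
    """SNR weight W: root-sum-of-squares echo magnitude, mean 1 over the mask.

    W is zero outside the mask.  This is the data-fidelity weight of the
    dipole inversion and of background-field removal.
    """
    mask = _require_mask(mask, series.grid)
    rss = np.sqrt((np.abs(series.echoes) ** 2).sum(axis=0))
    w = np.where(mask, rss, 0.0)
    w /= w[mask].mean()
    return w
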