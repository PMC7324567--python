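"""Voxelwise T2*/R2* relaxometry from multi-echo magnitude data.

The signal model is the two-parameter monoexponential S(TE) = A·e^(−TE/T2*)
with A the amplitude at TE = 0.  Each in-mask voxel is initialized by a
weighted log-linear regression of ln S on TE (weights S², the
first-order-correct weighting for log-transformed noise) and refined by
damped Gauss–Newton on the nonlinear model.  Fitting uses the magnitude
data as acquired, without Rician-bias correction, so at very low SNR the
noise floor biases T2* upward.

T2* estimates are clamped to [1, 200] ms (clamped voxels are flagged);
R2* = 1/T2* in ms⁻¹.  The error map is the RMS fit residual relative to
the fitted amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dipole import ScalarVolume
from .phantom import ComplexEchoSeries

__all__ = ["T2StarFitResult", "fit_t2star", "t2star_weighted_image"]

T2S_BOUNDS_MS = (1.0, 200.0)


@dataclass
class T2StarFitResult:
    a_map: ScalarVolume        # signal units
    t2s_map: ScalarVolume      # ms
    r2s_map: ScalarVolume      # 1/ms
    error_map: ScalarVolume    # relative RMS residual
    clamped: np.ndarray        # voxels whose T2* hit the clamp bounds
    failed: np.ndarray         # voxels with no usable signal (NaN outputs)


def t2star_weighted_image(series: ComplexEchoSeries, echo_index: int) -> ScalarVolume:
    """Magnitude of the selected echo — the T2*-weighted image.

    Tissue with short T2* (hemorrhagic infarct core) is hypointense at late
    echoes; the final echo is the conventional choice for segmentation.
    """
    if not -series.n_echoes <= echo_index < series.n_echoes:
        raise IndexError(f"echo index {echo_index} out of range for {series.n_echoes} echoes")
    return ScalarVolume(
        grid=series.grid, values=np.abs(series.echoes[echo_index]), units="arbitrary"
    )


def fit_t2star(series: ComplexEchoSeries, mask: np.ndarray) -> T2StarFitResult:
    """Fit A and T2* per in-mask voxel by least squares on the magnitudes.

    Requires ≥ 2 echoes (≥ 3 recommended for a meaningful error map).
    Voxels with zero magnitude at every echo are flagged failed and carry
    NaN outputs rather than raising.
    """
    tes_ms = np.asarray(series.tes, dtype=float) * 1e3
    if len(tes_ms) < 2:
        raise ValueError("T2* fitting needs at least 2 echoes")
    if np.any(np.diff(tes_ms) <= 0):
        raise ValueError("echo times must be strictly increasing")
    mask = np.asarray(mask, dtype=bool)
    grid = series.grid
    if mask.shape != grid.shape:
        raise ValueError("mask shape does not match grid")

    mags = np.abs(series.echoes)  # (E, ...)
    flat = mags.reshape(len(tes_ms), -1)[:, mask.ravel()]  # (E, N)
    n_vox = flat.shape[1]
    te = tes_ms.reshape(-1, 1)

    usable = (flat > 0).all(axis=0)
    a_hat = np.full(n_vox, np.nan)
    r2_hat = np.full(n_vox, np.nan)
    err = np.full(n_vox, np.nan)

    if usable.any():
        s = flat[:, usable]
        # weighted log-linear initialization
        w = s**2
        ln_s = np.log(s)
        sw = w.sum(axis=0)
        swt = (w * te).sum(axis=0)
        swtt = (w * te * te).sum(axis=0)
        swy = (w * ln_s).sum(axis=0)
        swty = (w * te * ln_s).sum(axis=0)
        det = sw * swtt - swt**2
        slope = (sw * swty - swt * swy) / det
        intercept = (swtt * swy - swt * swty) / det
        a = np.exp(intercept)
        lo, hi = 1.0 / T2S_BOUNDS_MS[1], 1.0 / T2S_BOUNDS_MS[0]
        r2 = np.clip(-slope, lo, hi)  # 1/ms

        # damped Gauss–Newton refinement on (A, R2*)
        def cost(a, r2):
            return (((a * np.exp(-te * r2)) - s) ** 2).sum(axis=0)

        c = cost(a, r2)
        for _ in range(50):
            e = np.exp(-te * r2)
            r = a * e - s
            j1 = e
            j2 = -a * te * e
            a11 = (j1 * j1).sum(axis=0)
            a12 = (j1 * j2).sum(axis=0)
            a22 = (j2 * j2).sum(axis=0)
            g1 = (j1 * r).sum(axis=0)
            g2 = (j2 * r).sum(axis=0)
            det_n = a11 * a22 - a12**2
            det_n = np.where(np.abs(det_n) < 1e-300, np.nan, det_n)
            da = np.nan_to_num((a22 * g1 - a12 * g2) / det_n)
            dr = np.nan_to_num((a11 * g2 - a12 * g1) / det_n)
            # backtracking line search per voxel on the Gauss-Newton step
            step = np.ones_like(a)
            a_acc, r2_acc, c_acc = a, r2, c
            pending = np.ones_like(a, dtype=bool)
            for _bt in range(12):
                a_try = np.maximum(a - step * da, 1e-12)
                r2_try = np.clip(r2 - step * dr, lo, hi)
                c_try = cost(a_try, r2_try)
                take = pending & (c_try <= c)
                a_acc = np.where(take, a_try, a_acc)
                r2_acc = np.where(take, r2_try, r2_acc)
                c_acc = np.where(take, c_try, c_acc)
                pending = pending & ~take
                if not pending.any():
                    break
                step = np.where(pending, step * 0.5, step)
            a, r2, c = a_acc, r2_acc, c_acc
            if np.max(np.abs(da) / np.maximum(a, 1e-12)) < 1e-13 and (
                np.max(np.abs(dr)) < 1e-15
            ):
                break

        a_hat[usable] = a
        r2_hat[usable] = r2
        err[usable] = np.sqrt(c / len(tes_ms)) / a

    t2s_hat = 1.0 / r2_hat
    clamped_flat = usable & (
        (t2s_hat <= T2S_BOUNDS_MS[0]) | (t2s_hat >= T2S_BOUNDS_MS[1])
    )
    t2s_hat = np.clip(t2s_hat, *T2S_BOUNDS_MS)

    def to_volume(flat_vals, units):
        vol = np.zeros(grid.shape)
        vol[mask] = flat_vals
        return ScalarVolume(grid=grid, values=vol, units=units)

    clamped = np.zeros(grid.shape, dtype=bool)
    clamped[mask] = clamped_flat
    failed = np.zeros(grid.shape, dtype=bool)
    failed[mask] = ~usable

    return T2StarFitResult(
        a_map=to_volume(a_hat, "arbitrary"),
        t2s_map=to_volume(t2s_hat, "ms"),
        r2s_map=to_volume(1.0 / t2s_hat, "arbitrary"),
        error_map=to_volume(err, "arbitrary"),
        clamped=clamped,
        failed=failed,
    )
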