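"""NIfTI and sidecar I/O.

Volumes are stored as NIfTI-1 with an RAS+ affine built from the voxel size
(0-based voxel indexing).  Complex echo data travel as magnitude/phase
pairs (phase in radians in (−π, π]), the way scanners export them, with a
YAML sidecar carrying echo times (s), field strength (T), the B₀ direction
and any provenance the producer wants to attach.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .dipole import VolumeGrid
from .phantom import ComplexEchoSeries, PhantomTruth

__all__ = [
    "write_volume",
    "read_volume",
    "write_echo_series",
    "read_echo_series",
    "write_sidecar",
    "read_sidecar",
    "write_provenance",
]


def _affine(grid: VolumeGrid) -> np.ndarray:
    return np.diag(list(grid.voxel_size) + [1.0])


def write_volume(path, values: np.ndarray, grid: VolumeGrid) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float64), _affine(grid))
    nib.save(img, path)
    return path


def read_volume(path, b0_direction=(0.0, 0.0, 1.0)):
    """Read a NIfTI volume; returns (values, VolumeGrid).

    The B₀ direction is not representable in a NIfTI header and must come
    from the sidecar (default +z).
    """
    img = nib.load(str(path))
    values = np.asarray(img.dataobj, dtype=float)
    if values.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {values.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    grid = VolumeGrid(shape=values.shape, voxel_size=zooms, b0_direction=b0_direction)
    return values, grid, img.affine


def write_sidecar(path, data: dict) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
    return path


def read_sidecar(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_echo_series(out_dir, series: ComplexEchoSeries, extra_sidecar=None):
    """Write magnitude/phase NIfTI pairs plus a YAML sidecar; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mag_paths, phase_paths = [], []
    for j in range(series.n_echoes):
        mag_paths.append(write_volume(out_dir / f"mag_e{j:02d}.nii", np.abs(series.echoes[j]), series.grid))
        phase_paths.append(write_volume(out_dir / f"phase_e{j:02d}.nii", np.angle(series.echoes[j]), series.grid))
    sidecar = {
        "tes_s": [float(t) for t in series.tes],
        "b0_tesla": float(series.b0),
        "b0_direction": [float(c) for c in series.grid.b0_direction],
        "voxel_size_mm": [float(v) for v in series.grid.voxel_size],
        "phase_units": "radians",
    }
    if extra_sidecar:
        sidecar.update(extra_sidecar)
    sidecar_path = write_sidecar(out_dir / "series.yaml", sidecar)
    return mag_paths, phase_paths, sidecar_path


def read_echo_series(mag_paths, phase_paths, sidecar) -> ComplexEchoSeries:
    """Assemble a complex echo series from magnitude/phase files + sidecar.

    Validates matched counts, consistent shapes and affines across echoes,
    and that phase values are radians (|φ| ≤ π; degrees are rejected).
    """
    if isinstance(sidecar, (str, Path)):
        sidecar = read_sidecar(sidecar)
    if len(mag_paths) != len(phase_paths):
        raise ValueError("magnitude and phase file counts differ")
    if len(mag_paths) == 0:
        raise ValueError("no echoes provided")
    tes = sidecar.get("tes_s")
    if tes is None or len(tes) != len(mag_paths):
        raise ValueError("sidecar must list one echo time (tes_s) per echo")
    b0 = sidecar.get("b0_tesla")
    if b0 is None:
        raise ValueError("sidecar must carry the field strength b0_tesla")
    b0_dir = tuple(sidecar.get("b0_direction", (0.0, 0.0, 1.0)))

    echoes = []
    ref_grid = ref_affine = None
    for mp, pp in zip(mag_paths, phase_paths):
        mag, grid, affine = read_volume(mp, b0_direction=b0_dir)
        phase, grid_p, affine_p = read_volume(pp, b0_direction=b0_dir)
        if grid != grid_p or not np.allclose(affine, affine_p):
            raise ValueError(f"magnitude/phase geometry mismatch: {mp} vs {pp}")
        if np.nanmax(np.abs(phase)) > np.pi + 0.01:
            raise ValueError(
                f"{pp}: phase values exceed π — expected radians in (−π, π] "
                "(degrees or scaled integers are not accepted)"
            )
        if ref_grid is None:
            ref_grid, ref_affine = grid, affine
        elif grid != ref_grid or not np.allclose(affine, ref_affine):
            raise ValueError(f"{mp}: affine/shape differs from the first echo")
        echoes.append(mag * np.exp(1j * phase))

    return ComplexEchoSeries(
        grid=ref_grid,
        echoes=np.stack(echoes),
        tes=tuple(float(t) for t in tes),
        b0=float(b0),
    )


def write_truth(out_dir, truth: PhantomTruth):
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    grid = truth.chi_map.grid
    return {
        "chi": write_volume(out_dir / "truth_chi.nii", truth.chi_map.values, grid),
        "t2s": write_volume(out_dir / "truth_t2s.nii", truth.t2s_map.values, grid),
        "labels": write_volume(out_dir / "truth_labels.nii", truth.labels.astype(float), grid),
    }


def write_provenance(path, payload: dict) -> Path:
    """JSON provenance block recording everything that influenced an output."""
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
    return path
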