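"""Fourier-domain dipole physics shared by the whole pipeline.

A susceptibility distribution Δχ (ppm, relative to water) magnetized by the
main field B₀ perturbs the field by a convolution with the unit dipole
response.  In the Fourier domain the convolution is a pointwise multiply with
the kernel

    D(k) = 1/3 − kz² / |k|²,

where kz is the projection of the spatial frequency vector onto the B₀
direction.  The induced (normalized) field is Φ = F⁻¹ D F Δχ, in the same ppm
units as Δχ.  D(k=0) is set to 0: a uniform susceptibility offset produces no
observable field shift, so susceptibility maps are only ever defined up to a
reference region chosen afterwards.

All spatial frequencies are computed in physical units (cycles/mm) from the
grid shape and voxel size, so anisotropic voxels and oblique B₀ directions
are handled correctly.  Convolutions are circular (periodic boundary); users
of this module keep sources away from the grid boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "VolumeGrid",
    "KernelVolume",
    "ScalarVolume",
    "SusceptibilityMap",
    "FieldMap",
    "dipole_kernel",
    "simulate_field",
    "apply_forward_adjoint",
]

#: reduced gyromagnetic ratio of the proton, Hz/T
GAMMA_BAR = 42.576e6

_VALID_UNITS = {"ppm", "Hz", "radians", "ms", "arbitrary"}


@dataclass(frozen=True)
class VolumeGrid:
    """Acquisition geometry: voxel lattice, voxel size (mm), B₀ direction.

    ``b0_direction`` must be a unit vector; it need not be axis aligned
    (short-axis cardiac acquisitions have B₀ oblique to the heart).
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    b0_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self):
        shape = tuple(int(n) for n in self.shape)
        voxel = tuple(float(v) for v in self.voxel_size)
        b0 = np.asarray(self.b0_direction, dtype=float)
        if len(shape) != 3 or any(n < 2 for n in shape):
            raise ValueError(f"grid needs 3 dimensions of at least 2 voxels, got {shape}")
        if any(v <= 0 for v in voxel):
            raise ValueError(f"voxel_size components must be positive, got {voxel}")
        nrm = np.linalg.norm(b0)
        if abs(nrm - 1.0) > 1e-12:
            if nrm == 0:
                raise ValueError("b0_direction must be a nonzero vector")
            b0 = b0 / nrm
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size", voxel)
        object.__setattr__(self, "b0_direction", tuple(float(c) for c in b0))

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * v for n, v in zip(self.shape, self.voxel_size))

    def frequency_axes(self):
        """DFT frequency samples per axis, cycles/mm."""
        return [np.fft.fftfreq(n, d=v) for n, v in zip(self.shape, self.voxel_size)]

    def coordinate_axes(self, center: bool = True):
        """Voxel-center coordinates per axis in mm.

        The origin sits exactly on voxel n//2, so centered geometry is
        sampled symmetrically and on-axis points exist on the lattice.
        """
        axes = []
        for n, v in zip(self.shape, self.voxel_size):
            x = np.arange(n, dtype=float) * v
            if center:
                x -= x[n // 2]
            axes.append(x)
        return axes

    def with_b0(self, direction) -> "VolumeGrid":
        return replace(self, b0_direction=tuple(direction))


def _check_same_grid(a: VolumeGrid, b: VolumeGrid) -> None:
    if a != b:
        raise ValueError(f"grid mismatch: {a} vs {b}")


@dataclass
class ScalarVolume:
    """A real scalar field on a :class:`VolumeGrid` with a units tag."""

    grid: VolumeGrid
    values: np.ndarray
    units: str = "arbitrary"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if self.units not in _VALID_UNITS:
            raise ValueError(f"unknown units {self.units!r}; expected one of {_VALID_UNITS}")


@dataclass
class SusceptibilityMap(ScalarVolume):
    """Voxelwise Δχ in ppm relative to water."""

    units: str = "ppm"

    def __post_init__(self):
        super().__post_init__()
        if self.units != "ppm":
            raise ValueError("susceptibility maps are carried in ppm")


@dataclass
class FieldMap(ScalarVolume):
    """Normalized field perturbation Φ in ppm (δB/B₀ × 10⁶)."""

    units: str = "ppm"
    kind: str = "total"  # {"total", "background", "local"}

    def __post_init__(self):
        super().__post_init__()
        if self.units != "ppm":
            raise ValueError("field maps are carried in ppm")
        if self.kind not in {"total", "background", "local"}:
            raise ValueError(f"unknown field kind {self.kind!r}")


@dataclass
class KernelVolume:
    """The dipole kernel D sampled on the DFT frequency lattice of a grid."""

    grid: VolumeGrid
    values: np.ndarray = field(repr=False)


def dipole_kernel(grid: VolumeGrid) -> KernelVolume:
    """Sample D(k) = 1/3 − kz²/|k|² on the discrete frequency lattice.

    kz is the component of the frequency vector along ``grid.b0_direction``.
    The DC sample is set to 0 (uniform offsets are unobservable).  Values lie
    in [−2/3, 1/3] everywhere.
    """
    fx, fy, fz = grid.frequency_axes()
    kx, ky, kz_ax = np.meshgrid(fx, fy, fz, indexing="ij", sparse=True)
    bx, by, bz = grid.b0_direction
    kpar = kx * bx + ky * by + kz_ax * bz
    k2 = kx**2 + ky**2 + kz_ax**2
    with np.errstate(divide="ignore", invalid="ignore"):
        values = 1.0 / 3.0 - (kpar**2) / k2
    values[k2 == 0] = 0.0
    return KernelVolume(grid=grid, values=values)


def _apply_kernel(values: np.ndarray, kernel: KernelVolume) -> np.ndarray:
    return np.fft.ifftn(kernel.values * np.fft.fftn(values)).real


def simulate_field(chi: SusceptibilityMap, kernel: KernelVolume | None = None) -> FieldMap:
    """Forward field of a susceptibility map: Φ = F⁻¹(D · F(Δχ)), ppm.

    Linear in χ; circular convolution (periodic boundary).  The spatial mean
    of the output is zero by the D(0) = 0 convention.
    """
    if not np.all(np.isfinite(chi.values)):
        raise ValueError("susceptibility map contains non-finite values")
    if kernel is None:
        kernel = dipole_kernel(chi.grid)
    else:
        _check_same_grid(chi.grid, kernel.grid)
    return FieldMap(grid=chi.grid, values=_apply_kernel(chi.values, kernel), kind="total")


def apply_forward_adjoint(v: ScalarVolume, kernel: KernelVolume | None = None) -> ScalarVolume:
    """Apply F⁻¹ D F to a volume.

    D is real and even, so this operator is self-adjoint:
    ⟨Av, w⟩ = ⟨v, Aw⟩.  Solvers use it both as the forward map and as its
    adjoint.
    """
    if kernel is None:
        kernel = dipole_kernel(v.grid)
    else:
        _check_same_grid(v.grid, kernel.grid)
    return ScalarVolume(grid=v.grid, values=_apply_kernel(v.values, kernel), units=v.units)
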