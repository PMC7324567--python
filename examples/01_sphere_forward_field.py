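"""Forward dipole field of a uniformly magnetized sphere vs the closed form.

A sphere of susceptibility 1 ppm in a 64-cube: under the Lorentz-corrected
dipole kernel its interior field shift is exactly zero and its exterior
field is a point dipole.  The FFT-based forward model should reproduce both.
"""

import numpy as np

import cardioqsm as cq

grid = cq.VolumeGrid(shape=(64, 64, 64))  # 1 mm voxels, B0 along +z
chi = cq.sphere_chi_map(grid, radius_mm=8.0, chi_ppm=1.0)
field = cq.simulate_field(chi)
analytic, excluded = cq.sphere_analytic_field(grid, 8.0, 1.0)

ax = grid.coordinate_axes()
x, y, z = np.meshgrid(*ax, indexing="ij")
r = np.sqrt(x**2 + y**2 + z**2)

interior = r <= 6.0            # eroded interior
exterior = r >= 10.0           # outside a 2-voxel boundary shell
err = field.values[exterior] - analytic.values[exterior]
peak = np.nanmax(np.abs(analytic.values))

i0 = int(np.argmin(np.abs(ax[0])))
iz = int(np.argmin(np.abs(ax[2] - 16.0)))  # on-axis point at r = 2a

print(f"mean |field| inside the sphere:   {np.abs(field.values[interior]).mean():.5f} ppm")
print(f"exterior RMS error vs closed form: {np.sqrt(np.mean(err**2)) / peak * 100:.2f} % of peak")
print(f"field at the on-axis point r=2a:   {field.values[i0, i0, iz]:.5f} ppm "
      f"(closed form {1 / 12:.5f} ppm)")
print()
print("The interior mean near zero and the ~0.083 ppm pole value confirm the")
print("FFT dipole convolution matches the analytic magnetized-sphere solution.")
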