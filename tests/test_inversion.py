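"""Morphology-enabled dipole inversion: edge mask, TV operators, IRLS solver."""

import numpy as np
import pytest

import cardioqsm as cq
from cardioqsm.inversion import EdgeMask
from cardioqsm.phantom import ComplexEchoSeries


def _series_from_magnitude(grid, mag, tes=(3e-3, 6e-3)):
    echoes = np.stack([mag.astype(complex)] * len(tes))
    return ComplexEchoSeries(grid=grid, echoes=echoes, tes=tes, b0=3.0)


def _all_penalized(grid):
    return EdgeMask(grid=grid, values=np.ones((3,) + grid.shape))


class TestEdgeMask:
    def test_uniform_magnitude_penalizes_everywhere(self):
        grid = cq.VolumeGrid(shape=(12, 12, 12))
        series = _series_from_magnitude(grid, np.ones(grid.shape))
        m = cq.compute_edge_mask(series, np.ones(grid.shape, dtype=bool), 0.3)
        assert np.all(m.values == 1.0)

    def test_step_interface_is_unpenalized(self):
        grid = cq.VolumeGrid(shape=(16, 16, 16))
        mag = np.ones(grid.shape)
        mag[8:] = 5.0  # step along x between slices 7 and 8
        series = _series_from_magnitude(grid, mag)
        m = cq.compute_edge_mask(series, np.ones(grid.shape, dtype=bool), 0.1)
        assert np.all(m.values[0][7] == 0.0)  # forward difference sits at x=7
        assert np.all(m.values[0][:7] == 1.0) and np.all(m.values[0][8:] == 1.0)
        assert np.all(m.values[1] == 1.0) and np.all(m.values[2] == 1.0)

    def test_edge_fraction_is_respected(self, rng):
        grid = cq.VolumeGrid(shape=(24, 24, 24))
        mag = rng.uniform(1.0, 2.0, size=grid.shape)  # continuous: no ties
        series = _series_from_magnitude(grid, mag)
        mask = np.ones(grid.shape, dtype=bool)
        m = cq.compute_edge_mask(series, mask, edge_fraction=0.3)
        for ax in range(3):
            zero_frac = (m.values[ax][mask] == 0.0).mean()
            assert zero_frac == pytest.approx(0.30, abs=0.02)

    def test_invalid_fraction_rejected(self, small_series):
        with pytest.raises(ValueError):
            cq.compute_edge_mask(small_series, np.ones(small_series.grid.shape, bool), 1.5)


class TestSpatialGradient:
    def test_constant_volume_has_zero_gradient(self):
        grid = cq.VolumeGrid(shape=(8, 8, 8))
        g = cq.spatial_gradient(np.full(grid.shape, 3.3), grid)
        assert np.all(g == 0.0)

    def test_linear_ramp_gradient(self):
        grid = cq.VolumeGrid(shape=(8, 8, 8), voxel_size=(0.5, 1.0, 2.0))
        x = np.arange(8).reshape(-1, 1, 1) * 0.5 * np.ones(grid.shape)
        g = cq.spatial_gradient(1.7 * x, grid)
        assert np.allclose(g[0][:-1], 1.7)
        assert np.all(g[0][-1] == 0.0)
        assert np.all(g[1] == 0.0) and np.all(g[2] == 0.0)

    def test_adjoint_identity(self, rng):
        grid = cq.VolumeGrid(shape=(10, 12, 9), voxel_size=(0.9, 1.1, 1.4))
        v = rng.normal(size=grid.shape)
        w = rng.normal(size=(3,) + grid.shape)
        lhs = np.sum(cq.spatial_gradient(v, grid) * w)
        rhs = np.sum(v * cq.spatial_gradient_adjoint(w, grid))
        assert lhs == pytest.approx(rhs, rel=1e-10)


class TestEvaluateObjective:
    def test_zero_chi_zero_field(self):
        grid = cq.VolumeGrid(shape=(8, 8, 8))
        local = cq.FieldMap(grid=grid, values=np.zeros(grid.shape), kind="local")
        total, fid, reg = cq.evaluate_objective(
            np.zeros(grid.shape), local, np.ones(grid.shape), _all_penalized(grid), 1.0
        )
        assert total == 0.0 and fid == 0.0 and reg == 0.0

    def test_zero_chi_reduces_to_weighted_field_norm(self, rng):
        grid = cq.VolumeGrid(shape=(8, 8, 8))
        phi = rng.normal(size=grid.shape)
        w = rng.uniform(0.5, 2.0, size=grid.shape)
        local = cq.FieldMap(grid=grid, values=phi, kind="local")
        total, fid, reg = cq.evaluate_objective(
            np.zeros(grid.shape), local, w, _all_penalized(grid), 2.0
        )
        assert reg == 0.0
        assert fid == pytest.approx(np.sum((w * phi) ** 2), rel=1e-12)
        assert total == pytest.approx(fid, rel=1e-12)

    def test_matches_bruteforce_dft_evaluation(self, rng):
        """Independent check: explicit DFT matrix + elementwise loops on 8^3."""
        grid = cq.VolumeGrid(shape=(8, 8, 8), voxel_size=(0.9, 0.9, 1.2))
        n = 8
        chi = rng.normal(size=grid.shape)
        phi = rng.normal(size=grid.shape)
        w = rng.uniform(0.2, 1.5, size=grid.shape)
        m = (rng.uniform(size=(3,) + grid.shape) > 0.3).astype(float)
        lam = 0.7

        # forward field via explicit 1D DFT matrices (tensor product)
        F1 = np.exp(-2j * np.pi * np.outer(np.arange(n), np.arange(n)) / n)
        D = cq.dipole_kernel(grid).values
        chi_k = np.einsum("ai,bj,ck,ijk->abc", F1, F1, F1, chi)
        field_k = D * chi_k
        inv1 = np.conj(F1) / n
        fwd = np.einsum("ia,jb,kc,abc->ijk", inv1, inv1, inv1, field_k).real

        fid_bf = 0.0
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    fid_bf += (w[i, j, k] * (fwd[i, j, k] - phi[i, j, k])) ** 2
        reg_bf = 0.0
        h = grid.voxel_size
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    if i < n - 1:
                        reg_bf += m[0, i, j, k] * abs((chi[i + 1, j, k] - chi[i, j, k]) / h[0])
                    if j < n - 1:
                        reg_bf += m[1, i, j, k] * abs((chi[i, j + 1, k] - chi[i, j, k]) / h[1])
                    if k < n - 1:
                        reg_bf += m[2, i, j, k] * abs((chi[i, j, k + 1] - chi[i, j, k]) / h[2])

        local = cq.FieldMap(grid=grid, values=phi, kind="local")
        total, fid, reg = cq.evaluate_objective(
            chi, local, w, EdgeMask(grid=grid, values=m), lam
        )
        assert fid == pytest.approx(fid_bf, rel=1e-10)
        assert reg == pytest.approx(reg_bf, rel=1e-10)
        assert total == pytest.approx(lam * reg_bf + fid_bf, rel=1e-10)


class TestMediInvert:
    def test_zero_field_gives_zero_chi(self):
        grid = cq.VolumeGrid(shape=(16, 16, 16))
        mask = np.zeros(grid.shape, dtype=bool)
        mask[4:12, 4:12, 4:12] = True
        local = cq.FieldMap(grid=grid, values=np.zeros(grid.shape), kind="local")
        res = cq.medi_invert(local, mask.astype(float), _all_penalized(grid), mask)
        assert np.all(res.chi.values == 0.0)

    def test_objective_trace_is_monotone(self, rng):
        grid = cq.VolumeGrid(shape=(16, 16, 16))
        mask = np.zeros(grid.shape, dtype=bool)
        mask[3:13, 3:13, 3:13] = True
        chi_true = np.where(mask, rng.normal(scale=0.05, size=grid.shape), 0.0)
        phi = cq.simulate_field(cq.SusceptibilityMap(grid=grid, values=chi_true)).values
        phi += rng.normal(scale=0.005, size=grid.shape)
        local = cq.FieldMap(grid=grid, values=np.where(mask, phi, 0.0), kind="local")
        w = mask.astype(float)
        res = cq.medi_invert(
            local, w, _all_penalized(grid), mask,
            cq.InversionConfig(lambda_reg=1e-3, outer_iterations=8, cg_maxiter=30),
        )
        trace = np.asarray(res.objective_trace)
        assert len(trace) >= 2
        assert np.all(np.diff(trace) <= 1e-10 * trace[:-1])

    def test_unregularized_solution_is_linear_in_field(self):
        grid = cq.VolumeGrid(shape=(16, 16, 16))
        mask = np.zeros(grid.shape, dtype=bool)
        mask[3:13, 3:13, 3:13] = True
        rng = np.random.default_rng(4)
        chi_true = np.where(mask, rng.normal(scale=0.1, size=grid.shape), 0.0)
        phi = cq.simulate_field(cq.SusceptibilityMap(grid=grid, values=chi_true)).values
        cfg = cq.InversionConfig(lambda_reg=1e-15, outer_iterations=1, cg_maxiter=200)
        w = mask.astype(float)
        m = _all_penalized(grid)
        res1 = cq.medi_invert(
            cq.FieldMap(grid=grid, values=np.where(mask, phi, 0), kind="local"),
            w, m, mask, cfg,
        )
        res2 = cq.medi_invert(
            cq.FieldMap(grid=grid, values=np.where(mask, 2 * phi, 0), kind="local"),
            w, m, mask, cfg,
        )
        scale = np.abs(res2.chi.values).max()
        assert np.abs(res2.chi.values - 2 * res1.chi.values).max() < 1e-4 * scale

    def test_large_lambda_flattens_map(self):
        """lambda -> inf drives TV energy to near zero (constant in mask)."""
        grid = cq.VolumeGrid(shape=(16, 16, 16))
        mask = np.zeros(grid.shape, dtype=bool)
        mask[3:13, 3:13, 3:13] = True
        rng = np.random.default_rng(5)
        chi_true = np.where(mask, rng.normal(scale=0.1, size=grid.shape), 0.0)
        phi = cq.simulate_field(cq.SusceptibilityMap(grid=grid, values=chi_true)).values
        local = cq.FieldMap(grid=grid, values=np.where(mask, phi, 0), kind="local")
        w = mask.astype(float)
        m = _all_penalized(grid)
        res0 = cq.medi_invert(local, w, m, mask,
                              cq.InversionConfig(lambda_reg=1e-15, outer_iterations=1,
                                                 cg_maxiter=200))
        res_inf = cq.medi_invert(local, w, m, mask,
                                 cq.InversionConfig(lambda_reg=100.0, outer_iterations=8,
                                                    cg_maxiter=100))
        assert res_inf.regularizer < 0.01 * res0.regularizer

    def test_bandlimited_recovery_without_regularization(self, rng):
        """Away from the kernel zero cone, lambda=0 least squares is exact."""
        grid = cq.VolumeGrid(shape=(32, 32, 32))
        D = cq.dipole_kernel(grid).values
        spectrum = rng.normal(size=grid.shape) + 1j * rng.normal(size=grid.shape)
        spectrum[np.abs(D) < 0.15] = 0.0
        chi_true = np.fft.ifftn(spectrum).real
        chi_true /= np.abs(chi_true).max()
        phi = cq.simulate_field(cq.SusceptibilityMap(grid=grid, values=chi_true)).values
        mask = np.ones(grid.shape, dtype=bool)
        local = cq.FieldMap(grid=grid, values=phi, kind="local")
        res = cq.medi_invert(
            local, np.ones(grid.shape), _all_penalized(grid), mask,
            cq.InversionConfig(lambda_reg=1e-15, outer_iterations=1, cg_maxiter=400),
        )
        err = res.chi.values - chi_true
        assert np.sqrt(np.mean(err**2)) < 0.01 * np.sqrt(np.mean(chi_true**2))

    def test_sphere_susceptibility_recovery(self):
        """Weak TV recovers a 1 ppm sphere's interior value within 10%."""
        grid = cq.VolumeGrid(shape=(48, 48, 48))
        chi = cq.sphere_chi_map(grid, 8.0, 1.0)
        phi = cq.simulate_field(chi).values
        mask = np.ones(grid.shape, dtype=bool)
        local = cq.FieldMap(grid=grid, values=phi, kind="local")
        res = cq.medi_invert(
            local, np.ones(grid.shape), _all_penalized(grid), mask,
            cq.InversionConfig(lambda_reg=1e-5, outer_iterations=3, cg_maxiter=150),
        )
        ax = grid.coordinate_axes()
        x, y, z = np.meshgrid(*ax, indexing="ij")
        interior = np.sqrt(x**2 + y**2 + z**2) <= 6.0
        assert 0.9 <= res.chi.values[interior].mean() <= 1.1

    def test_nan_input_rejected(self):
        grid = cq.VolumeGrid(shape=(8, 8, 8))
        bad = np.zeros(grid.shape)
        bad[0, 0, 0] = np.nan
        local = cq.FieldMap(grid=grid, values=bad, kind="local")
        with pytest.raises(ValueError):
            cq.medi_invert(local, np.ones(grid.shape), _all_penalized(grid),
                           np.ones(grid.shape, dtype=bool))

    def test_total_field_kind_rejected(self):
        grid = cq.VolumeGrid(shape=(8, 8, 8))
        total = cq.FieldMap(grid=grid, values=np.zeros(grid.shape), kind="total")
        with pytest.raises(ValueError):
            cq.medi_invert(total, np.ones(grid.shape), _all_penalized(grid),
                           np.ones(grid.shape, dtype=bool))
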