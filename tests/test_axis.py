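"""Longitudinal-axis coordinates and gradient-vs-parcel variance partition."""

from dataclasses import replace

import numpy as np
import pytest

import hippoparc as hp
from hippoparc.axis import AxisVariancePartition, axis_coordinates, delta_fc
from hippoparc.connectivity import VoxelNetworkFC


def line_mask(n=10, axis=1, spacing=1.0):
    ijk = np.zeros((n, 3), dtype=int)
    ijk[:, axis] = np.arange(n)
    aff = np.diag([spacing] * 3 + [1.0])
    return hp.HippocampusMask(voxel_ijk=ijk, affine=aff, hemisphere=["L"] * n)


class TestAxisCoordinates:
    def test_line_gives_signed_distance(self):
        mask = line_mask(10, spacing=2.0)
        ax = axis_coordinates(mask, method="pca")
        # anterior = +y here, so the high-j end maps to coordinate 0
        expected = 2.0 * (9 - np.arange(10))
        assert np.allclose(np.sort(ax.coord), np.sort(expected))
        assert np.allclose(ax.coord, expected)

    def test_y_axis_equals_j_spacing_with_anterior_low(self):
        mask = line_mask(5, spacing=1.0)
        ax = axis_coordinates(mask, method="y_axis", anterior_direction=(0, -1, 0))
        assert np.allclose(ax.coord, np.arange(5, dtype=float))

    def test_rotation_invariance(self, noiseless_parcel_subject):
        mask = noiseless_parcel_subject.mask
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0],
                      [0, 0, 1.0]])
        aff_rot = mask.affine.copy()
        aff_rot[:3, :3] = R @ mask.affine[:3, :3]
        aff_rot[:3, 3] = R @ mask.affine[:3, 3]
        rotated = hp.HippocampusMask(voxel_ijk=mask.voxel_ijk, affine=aff_rot,
                                     hemisphere=mask.hemisphere, shape=mask.shape)
        a = axis_coordinates(mask, method="pca")
        b = axis_coordinates(rotated, method="pca", anterior_direction=R @ [0, 1, 0])
        assert np.allclose(a.coord, b.coord, atol=1e-8)

    def test_too_few_voxels(self):
        with pytest.raises(ValueError, match="at least 3"):
            axis_coordinates(line_mask(2))


class TestDeltaFC:
    def test_arithmetic_and_antisymmetry(self):
        fc = VoxelNetworkFC(z=np.array([[0.4, 0.1], [0.2, 0.2]]), labels=[1, 2],
                            valid=np.array([True, True]))
        d = delta_fc(fc, (1, 2))
        assert d[0] == pytest.approx(0.3)
        assert d[1] == pytest.approx(0.0)
        assert np.allclose(delta_fc(fc, (2, 1)), -d)

    def test_invalid_voxel_is_nan(self):
        fc = VoxelNetworkFC(z=np.array([[0.4, 0.1]]), labels=[1, 2],
                            valid=np.array([False]))
        assert np.isnan(delta_fc(fc, (1, 2))[0])


def normal_equations_r2(y, X):
    """Independent OLS oracle via the normal equations."""
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    tss = ((y - y.mean()) ** 2).sum()
    return 1.0 - (resid**2).sum() / tss


class TestVariancePartition:
    def test_perfect_step_function(self):
        parcel = np.repeat([0, 1], 25)
        axis = np.arange(50, dtype=float)
        delta = np.where(parcel == 0, 0.5, -0.3)
        res = AxisVariancePartition(delta, axis, parcel).fit()
        assert res.r2_parcel == pytest.approx(1.0, abs=1e-10)
        assert res.sp_gradient == pytest.approx(0.0, abs=1e-10)

    def test_perfect_linear_gradient(self):
        axis = np.linspace(0, 40, 60)
        parcel = (axis > 30).astype(int)
        delta = 0.8 - 0.02 * axis
        res = AxisVariancePartition(delta, axis, parcel).fit()
        assert res.r2_gradient == pytest.approx(1.0, abs=1e-10)
        assert res.sp_parcel == pytest.approx(0.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        n = 30
        axis = rng.uniform(0, 40, n)
        parcel = (rng.uniform(size=n) > 0.5).astype(int)
        delta = rng.normal(size=n)
        res = AxisVariancePartition(delta, axis, parcel).fit()
        ones = np.ones((n, 1))
        assert res.r2_gradient == pytest.approx(
            normal_equations_r2(delta, np.c_[ones, axis]), abs=1e-10)
        assert res.r2_parcel == pytest.approx(
            normal_equations_r2(delta, np.c_[ones, parcel]), abs=1e-10)
        assert res.r2_full == pytest.approx(
            normal_equations_r2(delta, np.c_[ones, axis, parcel]), abs=1e-10)
        assert res.r2_full >= res.sp_gradient - 1e-12
        assert res.r2_full >= res.sp_parcel - 1e-12

    def test_r2_invariant_to_axis_rescaling(self, rng):
        n = 40
        axis = rng.uniform(0, 40, n)
        parcel = (axis > 20).astype(int)
        delta = -0.02 * axis + 0.3 * parcel + 0.1 * rng.normal(size=n)
        a = AxisVariancePartition(delta, axis, parcel).fit()
        b = AxisVariancePartition(delta, 3.5 * axis - 7.0, parcel).fit()
        for attr in ("r2_gradient", "r2_parcel", "r2_full", "sp_gradient", "sp_parcel"):
            assert getattr(a, attr) == pytest.approx(getattr(b, attr), abs=1e-10)

    def test_single_parcel_flagged_gradient_only(self, rng):
        res = AxisVariancePartition(rng.normal(size=10), np.arange(10.0),
                                    np.zeros(10, int)).fit()
        assert res.gradient_only
        assert np.isnan(res.r2_parcel)
        assert "undefined" in res.summary()

    def test_binning_option_runs(self, rng):
        n = 60
        axis = rng.uniform(0, 40, n)
        parcel = (axis > 30).astype(int)
        delta = -0.02 * axis + 0.2 * parcel
        res = AxisVariancePartition(delta, axis, parcel, bins=8).fit()
        assert 0.5 < res.r2_gradient <= 1.0

    def test_nan_delta_rows_dropped(self):
        delta = np.array([0.1, np.nan, 0.3, 0.5])
        res = AxisVariancePartition(delta, np.arange(4.0),
                                    np.array([0, 0, 1, 1])).fit()
        assert res.n == 3


def test_mixed_mode_both_factors_explain_variance():
    """In mixed organisation both semi-partial r2 are positive (CI over seeds)."""
    from hippoparc.connectivity import exclusion_mask, network_timecourses, voxel_network_fc
    from hippoparc.synthetic import GeneratorSpec
    from hippoparc.wta import forced_choice

    sp_g, sp_p = [], []
    for seed in range(20):
        spec = GeneratorSpec(n_networks=4, vertices_per_network=12, axis_len=12,
                             n_timepoints=250, mode="mixed", lambda_mixed=0.5,
                             noise_sd=1.5, seed=seed)
        s = hp.make_subject(spec)
        include = exclusion_mask(s.atlas, s.mask, 20.0)
        fc = voxel_network_fc(
            s.bold_hippo, network_timecourses(s.bold_cortex, s.atlas, include))
        parc = forced_choice(fc, (1, 2))
        ax = axis_coordinates(s.mask)
        res = AxisVariancePartition(delta_fc(fc, (1, 2)), ax.coord, parc.labels).fit()
        sp_g.append(res.sp_gradient)
        sp_p.append(res.sp_parcel)
    for vals in (np.array(sp_g), np.array(sp_p)):
        lo = vals.mean() - 1.96 * vals.std(ddof=1) / np.sqrt(len(vals))
        assert lo > 0.0
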