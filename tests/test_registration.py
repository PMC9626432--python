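import numpy as np
import pytest

from irtkit import (
    CameraGeometry,
    PhantomSpec,
    RegistrationSettings,
    ThermalImage,
    check_convergence,
    deform_phantom,
    generate_phantom,
    mattes_mi,
    register,
    resample_image,
    resample_mask,
    transform_point,
    translate_phantom,
)
from irtkit.registration import (
    ConvergenceTrace,
    DeformationModel,
    grid_spacing_px,
)
from irtkit.roi_tools import ROIMask
from irtkit.errors import DimensionError, DomainError


def _binned_entropy(values, n_bins=32):
    v = np.asarray(values, float).ravel()
    b = np.minimum((v - v.min()) / (v.max() - v.min()) * n_bins, n_bins - 1)
    p = np.bincount(b.astype(int), minlength=n_bins).astype(float)
    p = p[p > 0] / p.sum()
    return float(-(p * np.log(p)).sum())


def _basis(t):
    """Reference cubic B-spline basis values, written out longhand."""
    return np.array(
        [
            (1 - t) ** 3 / 6,
            (3 * t**3 - 6 * t**2 + 4) / 6,
            (-3 * t**3 + 3 * t**2 + 3 * t + 1) / 6,
            t**3 / 6,
        ]
    )


class TestMattesMI:
    def test_self_similarity_equals_marginal_entropy(self, small_phantom):
        img, _ = small_phantom
        assert mattes_mi(img, img) == pytest.approx(_binned_entropy(img.values))

    def test_constant_moving_is_zero(self, small_phantom):
        img, _ = small_phantom
        const = np.full(img.shape, 30.0)
        assert mattes_mi(img, const) == 0.0
        assert mattes_mi(const, img) == 0.0

    def test_self_beats_permutation_bruteforce(self, rng):
        for _ in range(5):
            grid = rng.normal(28, 4, size=(8, 8))
            perm = rng.permutation(grid.ravel()).reshape(8, 8)
            assert mattes_mi(grid, grid) > mattes_mi(grid, perm)

    def test_symmetry(self, rng):
        a = rng.normal(25, 3, size=(20, 20))
        b = rng.normal(30, 2, size=(20, 20))
        assert abs(mattes_mi(a, b) - mattes_mi(b, a)) < 1e-6

    def test_nonnegative(self, rng):
        for _ in range(10):
            a = rng.normal(0, 1, size=(12, 12))
            b = rng.normal(0, 1, size=(12, 12))
            assert mattes_mi(a, b) >= 0.0

    def test_min_bins(self, rng):
        with pytest.raises(ValueError):
            mattes_mi(rng.normal(size=(4, 4)), rng.normal(size=(4, 4)), n_bins=3)

    def test_parzen_gradient_matches_finite_differences(self, rng):
        # analytic d(smooth MI)/dM_i against a central-difference oracle
        from irtkit.registration import _smooth_mi_and_alpha

        n, n_bins = 400, 16
        F = rng.normal(28, 4, size=n)
        M = F + rng.normal(0, 1.5, size=n)
        fstats = (F.min(), F.max() - F.min())
        # widen the moving range so perturbed values stay off the clip edges
        mstats = (M.min() - 2.0, M.max() - M.min() + 4.0)
        _, alpha = _smooth_mi_and_alpha(F, M, fstats, mstats, n_bins)
        eps = 1e-5
        for i in rng.choice(n, size=12, replace=False):
            up, dn = M.copy(), M.copy()
            up[i] += eps
            dn[i] -= eps
            mi_up, _ = _smooth_mi_and_alpha(F, up, fstats, mstats, n_bins)
            mi_dn, _ = _smooth_mi_and_alpha(F, dn, fstats, mstats, n_bins)
            fd = (mi_up - mi_dn) / (2 * eps)
            assert alpha[i] == pytest.approx(fd, rel=1e-4, abs=1e-8)


class TestDeformationModel:
    def test_identity_maps_points_exactly(self):
        model = DeformationModel.identity((40, 60), 5)
        for p in [(0, 0), (59, 39), (17.3, 22.8)]:
            assert transform_point(model, p) == p

    def test_out_of_domain_point(self):
        model = DeformationModel.identity((40, 60), 5)
        with pytest.raises(DomainError):
            transform_point(model, (61, 10))

    def test_single_coefficient_matches_basis_oracle(self):
        s = 4.0
        model = DeformationModel.identity((40, 40), s)
        p = (6.0, 9.0)
        ux, uy = p[0] / s, p[1] / s
        i0x, i0y = int(np.floor(ux)), int(np.floor(uy))
        wx = _basis(ux - i0x)
        wy = _basis(uy - i0y)
        for a in range(4):
            for b in range(4):
                model.coeff[:] = 0.0
                model.coeff[i0y + a, i0x + b] = (1.0, 0.0)
                got = model.displacement(np.array([p[0]]), np.array([p[1]]))[0]
                assert got[0] == pytest.approx(wy[a] * wx[b])
                assert got[1] == 0.0

    def test_partition_of_unity_gives_constant_field(self):
        model = DeformationModel.identity((30, 50), 6)
        model.coeff[..., 0] = -3.0
        model.coeff[..., 1] = 2.0
        field = model.dense_field()
        np.testing.assert_allclose(field[..., 0], -3.0, atol=1e-12)
        np.testing.assert_allclose(field[..., 1], 2.0, atol=1e-12)

    def test_save_load_round_trip(self, tmp_path, rng):
        model = DeformationModel.identity((30, 50), 6)
        model.coeff += rng.normal(0, 1, size=model.coeff.shape)
        p = tmp_path / "model.json"
        model.save(p)
        back = DeformationModel.load(p)
        probes = [(rng.uniform(0, 49), rng.uniform(0, 29)) for _ in range(10)]
        for pt in probes:
            assert transform_point(back, pt) == transform_point(model, pt)

    def test_grid_spacing_conversion(self):
        g = CameraGeometry(1.308, 1.5, 320, 240)
        s = RegistrationSettings(grid_spacing_mm=10)
        # 10 mm at 1.962 mm/px is ~5.1 px -> nearest integer, floor 2
        assert grid_spacing_px(s, g) == 5
        assert grid_spacing_px(RegistrationSettings(grid_spacing_mm=1), g) == 2


class TestResample:
    def test_identity_bitwise(self, small_phantom):
        img, _ = small_phantom
        model = DeformationModel.identity(img.shape, 5)
        out = resample_image(img, model)
        assert np.array_equal(out.values, img.values)

    def test_integer_translation_matches_index_shift(self, small_phantom):
        img, _ = small_phantom
        model = DeformationModel.identity(img.shape, 5)
        model.coeff[..., 0] = 3.0  # sample from x+3 => content shifts left
        out = resample_image(img, model, fill_value=0.0)
        np.testing.assert_allclose(
            out.values[:, :-3], img.values[:, 3:], atol=1e-9
        )

    def test_near_inverse_warp(self, clean_phantom):
        img, truth = clean_phantom
        warped, wtruth = deform_phantom(img, truth, 2, 40, seed=3)
        # warping by an approximation of the inverse field nearly restores
        # the original on the body interior
        back = resample_image(warped, _approx_inverse_model(wtruth), fill_value=22.0)
        interior = _eroded(truth.body_mask, 6)
        err = np.abs(back.values - img.values)[interior]
        assert err.mean() < 0.35

    def test_mask_binary_contract(self, small_phantom, rng):
        img, truth = small_phantom
        model = DeformationModel.identity(img.shape, 5)
        model.coeff += rng.normal(0, 1.5, size=model.coeff.shape)
        out = resample_mask(ROIMask(truth.body_mask.astype(np.uint8)), model)
        assert set(np.unique(out.values)) <= {0, 1}

    def test_mask_identity_and_shift(self, small_phantom):
        img, truth = small_phantom
        mask = ROIMask(truth.body_mask.astype(np.uint8))
        model = DeformationModel.identity(img.shape, 5)
        out = resample_mask(mask, model)
        assert np.array_equal(out.values, mask.values)
        model.coeff[..., 1] = 2.0
        out = resample_mask(mask, model)
        assert np.array_equal(out.values[:-2], mask.values[2:])

    def test_domain_mismatch(self, small_phantom):
        img, _ = small_phantom
        model = DeformationModel.identity((img.shape[0] + 2, img.shape[1]), 5)
        with pytest.raises(DimensionError):
            resample_image(img, model)


def _eroded(mask, n):
    from scipy import ndimage

    return ndimage.binary_erosion(mask, iterations=n)


def _approx_inverse_model(wtruth):
    """Model whose field approximately inverts a small truth warp."""
    h, w = wtruth.body_mask.shape
    model = DeformationModel.identity((h, w), 5)
    xs = (np.arange(model.coeff.shape[1]) - 1) * 5.0
    ys = (np.arange(model.coeff.shape[0]) - 1) * 5.0
    gx, gy = np.meshgrid(np.clip(xs, 0, w - 1), np.clip(ys, 0, h - 1))
    f = wtruth.displacement_field
    from scipy import ndimage

    model.coeff[..., 0] = -ndimage.map_coordinates(f[..., 0], [gy, gx], order=1)
    model.coeff[..., 1] = -ndimage.map_coordinates(f[..., 1], [gy, gx], order=1)
    return model


class TestRegister:
    SETTINGS = RegistrationSettings(n_resolutions=2, n_iterations=100, seed=1)

    def test_self_registration_near_identity(self, textured_phantom):
        img, _ = textured_phantom
        model, _ = register(img, img, RegistrationSettings(
            n_resolutions=2, n_iterations=60, seed=2))
        assert model.max_coefficient() < 0.5

    def test_known_warp_recovery(self, textured_phantom):
        img, truth = textured_phantom
        warped, wtruth = deform_phantom(img, truth, 3, 40, seed=7)
        model, trace = register(warped, img, self.SETTINGS)
        field = model.dense_field()
        mask = truth.body_mask
        err = np.linalg.norm(field - wtruth.displacement_field, axis=-1)[mask]
        base = np.linalg.norm(wtruth.displacement_field, axis=-1)[mask]
        assert err.mean() <= 0.5 * base.mean()

    def test_translation_recovery(self, textured_phantom):
        img, truth = textured_phantom
        moved, _ = translate_phantom(img, truth, 2, 2, seed=0)
        model, _ = register(moved, img, RegistrationSettings(
            n_resolutions=2, n_iterations=100, seed=3))
        field = model.dense_field()
        err = np.linalg.norm(field - np.array([-2.0, -2.0]), axis=-1)
        assert err[truth.body_mask].mean() < 1.0

    def test_mi_never_decreases(self, textured_phantom):
        img, truth = textured_phantom
        warped, _ = deform_phantom(img, truth, 2, 48, seed=9)
        for seed in (1, 2, 3):
            settings = RegistrationSettings(
                n_resolutions=1, n_iterations=40, seed=seed)
            model, _ = register(warped, img, settings)
            mi0 = mattes_mi(warped, img)
            mi1 = mattes_mi(warped, resample_image(img, model))
            assert mi1 >= mi0 - 1e-6

    def test_trace_stabilizes(self, textured_phantom):
        img, truth = textured_phantom
        warped, _ = deform_phantom(img, truth, 3, 40, seed=7)
        _, trace = register(warped, img, self.SETTINGS)
        assert len(trace) == 2 * 100
        assert check_convergence(trace).converged

    def test_deterministic_given_seed(self, textured_phantom):
        img, truth = textured_phantom
        warped, _ = deform_phantom(img, truth, 2, 40, seed=4)
        settings = RegistrationSettings(n_resolutions=1, n_iterations=30, seed=7)
        m1, t1 = register(warped, img, settings)
        m2, t2 = register(warped, img, settings)
        assert np.array_equal(m1.coeff, m2.coeff)
        assert np.array_equal(t1.values, t2.values)

    def test_shape_mismatch(self, textured_phantom):
        img, _ = textured_phantom
        other = ThermalImage(
            np.full((60, 80), 22.0), CameraGeometry(1.308, 1.5, 80, 60)
        )
        with pytest.raises(DimensionError):
            register(img, other)


class TestCheckConvergence:
    def test_constant_trace_converged(self):
        assert check_convergence(ConvergenceTrace(np.ones(50))).converged

    def test_linear_trace_not_converged(self):
        trace = ConvergenceTrace(np.linspace(0, 1, 50))
        assert not check_convergence(trace).converged

    def test_hand_evaluated_example(self):
        trace = ConvergenceTrace(
            np.array([0, 0.5, 0.9, 1, 1, 1, 1, 1, 1, 1.0])
        )
        res = check_convergence(trace, window_fraction=0.3, tol_fraction=0.01)
        assert res.converged

    def test_short_trace_warns(self):
        trace = ConvergenceTrace(np.array([1.0]))
        with pytest.warns(UserWarning):
            res = check_convergence(trace, window_fraction=2.0)
        assert res.converged

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            check_convergence(ConvergenceTrace(np.array([])))
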