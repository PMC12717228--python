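"""Two-stage artifact model: local fits, surfaces, lookup, correction."""

import numpy as np
import pytest

import pupilshift as ps
from pupilshift.psa_quantify import OffsetSeries
from pupilshift.psa_recalibration import (COEFF_NAMES, LookupDomain,
                                          local_fit_standard_errors,
                                          surface_exponents)


def series_from_poly(cx, cy, pupil, target=(0.0, 0.0), noise=0.0, rng=None):
    pupil = np.asarray(pupil, float)
    dx = np.polyval(cx[::-1], pupil)
    dy = np.polyval(cy[::-1], pupil)
    if noise:
        dx = dx + rng.normal(0, noise, len(pupil))
        dy = dy + rng.normal(0, noise, len(pupil))
    return OffsetSeries("left", target, pupil, dx, dy)


class TestFitLocal:
    def test_noiseless_polynomial_recovered_exactly(self):
        p = np.linspace(2, 6, 200)
        lf = ps.fit_local(series_from_poly((0.3, -0.1, 0.05),
                                           (-0.2, 0.4, 0.01), p))
        np.testing.assert_allclose(lf.coeffs_x, (0.3, -0.1, 0.05),
                                   atol=1e-10)
        np.testing.assert_allclose(lf.coeffs_y, (-0.2, 0.4, 0.01),
                                   atol=1e-10)

    def test_constant_offset(self):
        p = np.linspace(2, 6, 100)
        lf = ps.fit_local(series_from_poly((0.7, 0, 0), (0, 0, 0), p))
        np.testing.assert_allclose(lf.coeffs_x, (0.7, 0, 0), atol=1e-10)

    def test_noisy_coefficients_within_three_standard_errors(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(2, 6, 5000)
        truth_x, truth_y = (0.3, -0.1, 0.05), (-0.2, 0.4, 0.01)
        s = series_from_poly(truth_x, truth_y, p, noise=0.05, rng=rng)
        lf = ps.fit_local(s)
        se_x, se_y = local_fit_standard_errors(s)
        assert np.all(np.abs(lf.coeffs_x - truth_x) <= 3 * se_x)
        assert np.all(np.abs(lf.coeffs_y - truth_y) <= 3 * se_y)

    def test_rank_deficient_rejected(self):
        p = np.concatenate([np.full(10, 3.0), np.full(10, 4.0)])
        with pytest.raises(ps.InsufficientDataError):
            ps.fit_local(series_from_poly((0, 0.1, 0), (0, 0, 0), p))


class TestFitSurfaces:
    def _local_fits(self, coeff_fn, grid):
        out = []
        for tx, ty in grid.points:
            c = coeff_fn(tx, ty)
            out.append(ps.LocalFit((tx, ty), c[:3], c[3:],
                                   pupil_support=(2.0, 6.0)))
        return out

    def test_constant_coefficients_give_constant_surface(self, calib_grid):
        lfs = self._local_fits(lambda x, y: np.array([0.5, 0.1, 0, 0, 0, 0]),
                               calib_grid)
        surf = ps.fit_surfaces(lfs)
        vals = surf.evaluate("a0", np.array([-10.0, 0.0, 7.0]),
                             np.array([3.0, -2.0, 0.0]))
        np.testing.assert_allclose(vals, 0.5, atol=1e-9)

    def test_linear_in_x_recovered_by_quadratic(self, calib_grid):
        lfs = self._local_fits(
            lambda x, y: np.array([0.1 + 0.02 * x, 0, 0, 0, 0, 0]),
            calib_grid)
        surf = ps.fit_surfaces(lfs)
        xs = np.linspace(-13, 13, 7)
        np.testing.assert_allclose(surf.evaluate("a0", xs, np.zeros(7)),
                                   0.1 + 0.02 * xs, atol=1e-9)

    def test_quadratic_surface_zero_residual_on_nine_targets(self, calib_grid):
        # normal-equations oracle: 6-term model vs 9 exactly-quadratic values
        def fn(x, y):
            v = 0.1 + 0.01 * x - 0.02 * y + 1e-3 * x * y + 2e-3 * x ** 2 \
                - 1e-3 * y ** 2
            return np.array([v, 0, 0, 0, 0, 0])
        lfs = self._local_fits(fn, calib_grid)
        surf = ps.fit_surfaces(lfs)
        np.testing.assert_allclose(surf.residuals["a0"], 0.0, atol=1e-9)
        # independent oracle: solve the normal equations directly
        pts = calib_grid.as_array()
        exps = surface_exponents(2)
        X = np.stack([pts[:, 0] ** i * pts[:, 1] ** j for i, j in exps],
                     axis=1)
        v = np.array([fn(x, y)[0] for x, y in pts])
        beta = np.linalg.solve(X.T @ X, X.T @ v)
        np.testing.assert_allclose(surf.coeffs["a0"], beta, atol=1e-8)

    def test_too_few_targets_rejected(self):
        lfs = self._local_fits(lambda x, y: np.zeros(6),
                               ps.TargetGrid("calibration",
                                             [(-1, -1), (1, -1), (0, 0),
                                              (-1, 1), (1, 1)]))
        with pytest.raises(ps.InsufficientDataError, match="6"):
            ps.fit_surfaces(lfs)


class TestPredictOffset:
    def test_zero_surfaces_give_zero(self):
        exps = surface_exponents(2)
        surf = ps.CoefficientSurface(2, exps,
                                     {n: np.zeros(6) for n in COEFF_NAMES})
        dx, dy = ps.predict_offset(surf, 3.0, -2.0, 5.0)
        assert dx == 0.0 and dy == 0.0

    def test_hand_built_slope_model(self):
        exps = surface_exponents(2)
        coeffs = {n: np.zeros(6) for n in COEFF_NAMES}
        coeffs["a1"] = np.array([0.4, 0, 0, 0, 0, 0])
        surf = ps.CoefficientSurface(2, exps, coeffs)
        dx, dy = ps.predict_offset(surf, 5.0, 5.0, 5.0)
        assert dx == pytest.approx(2.0)
        assert dy == 0.0

    def test_matches_nested_polynomial_oracle(self, field):
        rng = np.random.default_rng(0)
        x = rng.uniform(-13, 13, 200)
        y = rng.uniform(-6, 6, 200)
        p = rng.uniform(2, 6, 200)
        dx, dy = ps.predict_offset(field.surfaces, x, y, p)
        exps = field.surfaces.exponents
        for i in rng.integers(0, 200, 20):
            c = {n: sum(cc * x[i] ** a * y[i] ** b
                        for cc, (a, b) in zip(field.surfaces.coeffs[n], exps))
                 for n in COEFF_NAMES}
            dxo = c["a0"] + c["a1"] * p[i] + c["a2"] * p[i] ** 2
            dyo = c["b0"] + c["b1"] * p[i] + c["b2"] * p[i] ** 2
            assert dx[i] == pytest.approx(dxo, abs=1e-12)
            assert dy[i] == pytest.approx(dyo, abs=1e-12)


class TestLookup:
    def _surf(self, **named):
        coeffs = {n: np.zeros(6) for n in COEFF_NAMES}
        for k, v in named.items():
            coeffs[k] = np.asarray(v, float)
        return ps.CoefficientSurface(2, surface_exponents(2), coeffs)

    def _domain(self):
        return LookupDomain(-5, 5, -3, 3, 2, 6)

    def test_zero_model_correction_is_identity(self):
        lut = ps.build_lookup(self._surf(), self._domain())
        assert np.allclose(lut.offset_dx, 0) and np.allclose(lut.offset_dy, 0)
        x, y = ps.correct_sample(lut, 1.234, -0.567, 4.0)
        assert x == pytest.approx(1.234) and y == pytest.approx(-0.567)

    def test_uniform_offset_everywhere(self):
        lut = ps.build_lookup(self._surf(a0=[1.0, 0, 0, 0, 0, 0]),
                              self._domain())
        inner = lut.offset_dx[5:-5, 5:-5, :]
        assert np.allclose(inner, 1.0, atol=1e-9)
        x, y = ps.correct_sample(lut, 2.0, 0.0, 4.0)
        assert x == pytest.approx(1.0, abs=1e-9)

    def test_correction_on_node_subtracts_stored_offset(self):
        lut = ps.build_lookup(self._surf(a0=[0.5, 0, 0, 0, 0, 0],
                                         b0=[-0.2, 0, 0, 0, 0, 0]),
                              self._domain())
        x, y = ps.correct_sample(lut, 1.0, 1.0, 4.0)
        assert x == pytest.approx(0.5, abs=1e-9)
        assert y == pytest.approx(1.2, abs=1e-9)

    def test_out_of_domain_pupil_uses_nearest(self):
        surf = self._surf(a1=[0.1, 0, 0, 0, 0, 0])
        lut = ps.build_lookup(surf, self._domain())
        x_hi, _ = ps.correct_sample(lut, 0.0, 0.0, 50.0)
        x_edge, _ = ps.correct_sample(lut, 0.0, 0.0, 6.0)
        assert x_hi == pytest.approx(x_edge)

    def test_deterministic_rebuild(self, field):
        dom = self._domain()
        a = ps.build_lookup(field.surfaces, dom)
        b = ps.build_lookup(field.surfaces, dom)
        np.testing.assert_array_equal(a.offset_dx, b.offset_dx)
        np.testing.assert_array_equal(a.offset_dy, b.offset_dy)

    def test_invalid_step_rejected(self):
        with pytest.raises(ps.InvalidInputError):
            ps.build_lookup(self._surf(), self._domain(), spatial_step=0.0)

    def test_round_trip_within_grid_step_bound(self, field):
        """Correcting the forward-mapped measurement recovers the true
        position within one grid step plus the field's local variation."""
        rng = np.random.default_rng(99)
        dom = LookupDomain(-15.5, 15.5, -8.4, 8.4, 2.0, 6.0)
        lut = ps.build_lookup(field.surfaces, dom)
        n = 1000
        tx = rng.uniform(-13.5, 13.5, n)
        ty = rng.uniform(-6.4, 6.4, n)
        p = rng.uniform(2.0, 6.0, n)
        dx, dy = field.offset(tx, ty, p)
        cx, cy = ps.correct_sample(lut, tx + dx, ty + dy, p)
        err = np.hypot(cx - tx, cy - ty)
        # Lipschitz bound of the offset field over the domain
        h = 0.1
        gx = np.abs(field.offset(tx + h, ty, p)[0] - dx) / h
        gy = np.abs(field.offset(tx, ty + h, p)[1] - dy) / h
        lip = max(gx.max(), gy.max())
        assert np.max(err) <= max(0.1, lip * 0.1) + 0.1

    def test_correction_bounded_by_max_stored_offset(self, field):
        lut = ps.build_lookup(field.surfaces, self._domain())
        rng = np.random.default_rng(5)
        x = rng.uniform(-10, 10, 500)
        y = rng.uniform(-6, 6, 500)
        p = rng.uniform(1, 8, 500)
        cx, cy = ps.correct_sample(lut, x, y, p)
        moved = np.hypot(cx - x, cy - y)
        assert np.max(moved) <= lut.max_abs_offset + 1e-12


class TestEndToEnd:
    def test_noiseless_surface_recovery_to_1e6(self, field, calib_grid):
        """Two-stage fit on noiseless simulated data recovers every
        ground-truth coefficient surface to 1e-6."""
        s, ep, _ = ps.simulate_plr_phase(
            field, calib_grid, noise_sd=0.0, blink_rate_per_min=0.0,
            dynamics=ps.PupilDynamics(wander_sd=0.0), seed=31)
        series = ps.compute_offsets(s, calib_grid, ep)
        lfs = [ps.fit_local(x) for x in series]
        surf = ps.fit_surfaces(lfs)
        for name in COEFF_NAMES:
            np.testing.assert_allclose(surf.coeffs[name],
                                       field.surfaces.coeffs[name],
                                       atol=1e-6)

    def test_validation_self_consistency(self, benchmark_model, valid_grid):
        """Validating on data generated by the model's own field yields
        near-total offset reduction."""
        f, model = benchmark_model
        vs, vep, _ = ps.simulate_plr_phase(f, valid_grid, noise_sd=0.0,
                                           blink_rate_per_min=0.0, seed=41)
        res = ps.validate_model(model, vs, valid_grid, vep)
        assert np.nanmedian(res.offset_after) <= 0.15
        assert np.nanmedian(res.offset_reductions) >= 0.9

    def test_validation_grid_role_enforced(self, benchmark_model, calib_grid):
        f, model = benchmark_model
        vs, vep, _ = ps.simulate_plr_phase(f, calib_grid, seed=43)
        with pytest.raises(ps.InvalidInputError):
            ps.validate_model(model, vs, calib_grid, vep)

    def test_model_json_round_trip(self, benchmark_model, tmp_path):
        _, model = benchmark_model
        path = tmp_path / "model.json"
        model.to_json(path)
        back = ps.PsaModel.from_json(path)
        assert back.eye == model.eye
        for name in COEFF_NAMES:
            np.testing.assert_allclose(back.surfaces.coeffs[name],
                                       model.surfaces.coeffs[name])
        np.testing.assert_array_equal(back.lookup.offset_dx,
                                      model.lookup.offset_dx)
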