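"""Diffusion smoothers: PM flux scheme, directional diffusion, baselines."""

import numpy as np
import pytest

import vesselkit as vk


def heat_step_5point(u, dt):
    """Explicit 5-point-Laplacian heat step with zero boundary flux."""
    lap = np.zeros_like(u)
    d0 = np.diff(u, axis=0)
    lap[:-1, :] += d0
    lap[1:, :] -= d0
    d1 = np.diff(u, axis=1)
    lap[:, :-1] += d1
    lap[:, 1:] -= d1
    return u + dt * lap


class TestPMDiffusivity:
    @pytest.mark.parametrize("variant", ["rational", "exponential"])
    def test_unit_at_zero_and_decreasing(self, variant):
        assert vk.pm_diffusivity(0.0, 5.0, variant) == 1.0
        g = vk.pm_diffusivity(np.linspace(0, 100, 200), 5.0, variant)
        assert np.all(np.diff(g) < 0)
        assert vk.pm_diffusivity(1e6, 5.0, variant) < 1e-6  # pass-all regime

    def test_rational_half_at_k(self):
        assert vk.pm_diffusivity(3.0, 3.0, "rational") == pytest.approx(0.5)

    def test_bad_parameters(self):
        with pytest.raises(ValueError):
            vk.pm_diffusivity(1.0, 0.0)
        with pytest.raises(ValueError):
            vk.pm_diffusivity(1.0, 1.0, "linear")


class TestPMDiffuse:
    def test_constant_unchanged_and_zero_iters_identity(self, rough_image):
        const = np.full((16, 16), 42.0)
        np.testing.assert_array_equal(vk.pm_diffuse(const, vk.PMParams(k=3, n_iter=50)), const)
        np.testing.assert_array_equal(vk.pm_diffuse(rough_image, vk.PMParams(k=3, n_iter=0)), rough_image)

    @pytest.mark.parametrize("variant", ["rational", "exponential"])
    def test_conserves_total_intensity(self, rough_image, variant):
        out = vk.pm_diffuse(rough_image, vk.PMParams(k=5, dt=0.2, n_iter=30, g_variant=variant))
        assert abs(out.sum() - rough_image.sum()) / rough_image.sum() < 1e-8

    def test_discrete_maximum_principle(self, rough_image):
        out = vk.pm_diffuse(rough_image, vk.PMParams(k=5, dt=0.25, n_iter=50))
        assert out.min() >= rough_image.min() - 1e-9
        assert out.max() <= rough_image.max() + 1e-9

    def test_matches_heat_equation_when_g_is_one(self, rough_image):
        # k -> infinity turns g into 1; the flux scheme must then agree
        # with a directly coded explicit heat iteration
        out = vk.pm_diffuse(rough_image, vk.PMParams(k=1e12, dt=0.2, n_iter=20))
        u = rough_image.copy()
        for _ in range(20):
            u = heat_step_5point(u, 0.2)
        assert np.sqrt(np.mean((out - u) ** 2)) < 1e-6

    def test_edges_preserved_at_small_k(self):
        # step edge of height 100: k=3 keeps the edge gradient, the k->inf
        # (heat) run destroys it
        img = np.zeros((32, 64))
        img[:, 32:] = 100.0
        sharp = vk.pm_diffuse(img, vk.PMParams(k=3.0, dt=0.15, n_iter=100))
        blurred = vk.pm_diffuse(img, vk.PMParams(k=1e12, dt=0.15, n_iter=100))
        g0 = np.abs(np.diff(img, axis=1)).max()
        assert np.abs(np.diff(sharp, axis=1)).max() > 0.5 * g0
        assert np.abs(np.diff(blurred, axis=1)).max() < 0.5 * g0

    def test_unstable_dt_rejected(self):
        with pytest.raises(ValueError, match="dt"):
            vk.PMParams(k=3.0, dt=0.3)


class TestDADBasis:
    def test_uniform_ramp_gradient_basis(self):
        cols = np.tile(np.arange(32, dtype=float), (32, 1))
        b = vk.dad_basis(cols, sigma_reg=1.0)
        interior = np.s_[6:-6, 6:-6]
        # v1 along columns (the gradient), v2 along rows
        np.testing.assert_allclose(np.abs(b.v1[1][interior]), 1.0, atol=1e-9)
        np.testing.assert_allclose(np.abs(b.u_v1[interior]), 1.0, atol=1e-9)
        np.testing.assert_allclose(b.u_v2[interior], 0.0, atol=1e-9)

    def test_constant_image_degenerate_basis(self):
        b = vk.dad_basis(np.full((16, 16), 9.0), sigma_reg=1.0)
        np.testing.assert_array_equal(b.u_v1, 0.0)
        np.testing.assert_array_equal(b.u_v2, 0.0)
        # fallback still produces an orthonormal basis
        dots = b.v1[0] * b.v2[0] + b.v1[1] * b.v2[1]
        np.testing.assert_allclose(dots, 0.0, atol=1e-6)

    def test_basis_orthonormal_on_random_image(self, rough_image):
        b = vk.dad_basis(rough_image, sigma_reg=0.8)
        np.testing.assert_allclose(np.hypot(b.v1[0], b.v1[1]), 1.0, atol=1e-6)
        np.testing.assert_allclose(np.hypot(b.v2[0], b.v2[1]), 1.0, atol=1e-6)
        np.testing.assert_allclose(b.v1[0] * b.v2[0] + b.v1[1] * b.v2[1], 0.0, atol=1e-6)

    def test_structure_direction_follows_bar_flanks(self, bar3):
        spec, img = bar3
        b = vk.dad_basis(img, sigma_reg=0.8)
        rows = np.arange(65, dtype=float)[:, None] * np.ones((1, 65))
        flank = (np.abs(np.abs(rows - 32.0) - spec.radius) < 0.6)
        flank[:, :5] = flank[:, -5:] = False
        # v2 (structure direction) within 5 degrees of the bar axis (columns)
        ang = np.degrees(np.arccos(np.clip(np.abs(b.v2[1][flank]), 0, 1)))
        assert np.mean(ang < 5.0) > 0.95


class TestDADDiffuse:
    def test_constant_unchanged(self):
        const = np.full((16, 16), 100.0)
        out = vk.dad_diffuse(const, vk.DADParams(k=7, n_iter=20))
        np.testing.assert_allclose(out, const, atol=1e-12)

    def test_attachment_pins_iterate_to_original(self):
        spec = vk.VesselPhantomSpec(radius=3.0)
        img = vk.add_gaussian_noise(vk.make_bar_phantom(spec, 48, 48), vk.NoiseSpec(20.0, 2))
        common = dict(k=7.0, alpha=0.5, dt=0.05, n_iter=200, sigma_reg=1.0)
        pinned = vk.dad_diffuse(img, vk.DADParams(beta=10.0, **common))
        free = vk.dad_diffuse(img, vk.DADParams(beta=0.0, **common))
        assert np.abs(pinned - img).max() < np.abs(free - img).max() / 10.0

    def test_degenerates_to_heat_equation(self, rough_image):
        # alpha=1 with identity phi1 and no attachment reconstructs the raw
        # gradient flux, i.e. the central-difference heat equation
        out = vk.dad_diffuse(
            rough_image,
            vk.DADParams(k=1.0, alpha=1.0, beta=0.0, dt=0.1, n_iter=10, sigma_reg=1.0, phi1_variant="identity"),
        )
        u = rough_image.copy()
        for _ in range(10):
            gr, gc = np.gradient(u)
            u = u + 0.1 * (np.gradient(gr, axis=0) + np.gradient(gc, axis=1))
        assert np.sqrt(np.mean((out - u) ** 2)) < 1e-6

    def test_zero_iters_identity_and_param_errors(self, rough_image):
        np.testing.assert_array_equal(vk.dad_diffuse(rough_image, vk.DADParams(k=7, n_iter=0)), rough_image)
        with pytest.raises(ValueError):
            vk.DADParams(k=7, alpha=0.0)
        with pytest.raises(ValueError):
            vk.DADParams(k=7, alpha=1.5)
        with pytest.raises(ValueError):
            vk.DADParams(k=7, dt=0.5)
        with pytest.raises(ValueError):
            vk.DADParams(k=7, sigma_reg=0.0)


class TestBaselines:
    def test_gaussian_normalized_and_constant_preserving(self):
        const = np.full((17, 17), 50.0)
        np.testing.assert_allclose(vk.gaussian_baseline(const, 2.0, 9), const, atol=1e-10)
        impulse = np.zeros((17, 17))
        impulse[8, 8] = 1.0
        resp = vk.gaussian_baseline(impulse, 2.0, 9)
        assert resp.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(resp, resp[::-1, ::-1], atol=1e-15)  # symmetric kernel
        assert resp[8, 8] == resp.max()

    def test_median_rejects_impulse_and_matches_bruteforce(self):
        flat = np.full((9, 9), 10.0)
        flat[4, 4] = 200.0
        np.testing.assert_array_equal(vk.median_baseline(flat, 3), np.full((9, 9), 10.0))

        img = np.random.default_rng(1).integers(0, 255, (7, 7)).astype(float)
        out = vk.median_baseline(img, 5)
        padded = np.pad(img, 2, mode="edge")
        for i in range(7):
            for j in range(7):
                window = padded[i : i + 5, j : j + 5].ravel()
                assert out[i, j] == np.sort(window)[12]

    def test_even_support_rejected(self):
        img = np.zeros((8, 8))
        with pytest.raises(ValueError):
            vk.gaussian_baseline(img, 1.0, 4)
        with pytest.raises(ValueError):
            vk.median_baseline(img, 4)
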