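"""Orientation grids and the marginalized image-node likelihood."""

import numpy as np
import pytest
from scipy.integrate import quad

from cryobife._quat import geodesic_distance, random_quaternion
from cryobife.likelihood import (
    MarginalizationConfig,
    OrientationGrid,
    build_uniform_orientation_grid,
    compute_likelihood_matrix,
    grid_spacing,
    image_node_log_likelihood,
    refine_orientation_grid,
)
from cryobife.path import Conformation, GroundTruthProfile, make_path
from cryobife.benchmarks import make_toy_rotor, toy_rotor_path
from cryobife.simulate import (
    ImagingParams,
    ParticleImage,
    ParticleStack,
    apply_ctf,
    generate_dataset,
    project,
)

IDENTITY = np.array([1.0, 0.0, 0.0, 0.0])


def _image_from_node(node, quat, defocus, box=32, px=2.2, snr=1e12):
    img = apply_ctf(project(node, quat, pixel_size=px, box_size=box), defocus, pixel_size=px)
    params = ImagingParams(
        orientation=quat, defocus=defocus, pixel_size=px, box_size=box, snr=snr
    )
    return ParticleImage(pixels=img, params=params)


class TestUniformGrid:
    def test_single_point_is_identity(self):
        g = build_uniform_orientation_grid(1)
        assert np.allclose(g.quaternions, [[1, 0, 0, 0]])
        assert g.weights[0] == 1.0

    def test_unit_norms_and_uniform_weights(self):
        g = build_uniform_orientation_grid(257, seed=3)
        assert np.allclose(np.linalg.norm(g.quaternions, axis=1), 1.0, atol=1e-12)
        assert np.allclose(g.weights, 1 / 257)

    def test_coverage_improves_with_size(self, rng):
        probes = random_quaternion(rng, 500)
        worst = {}
        for n in (64, 512):
            g = build_uniform_orientation_grid(n)
            dots = np.abs(probes @ g.quaternions.T)
            worst[n] = np.max(2 * np.arccos(np.clip(dots.max(axis=1), -1, 1)))
        assert worst[512] < worst[64]

    def test_seed_reproducible(self):
        a = build_uniform_orientation_grid(50, seed=9)
        b = build_uniform_orientation_grid(50, seed=9)
        assert np.array_equal(a.quaternions, b.quaternions)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError, match="weights"):
            OrientationGrid(np.array([[1.0, 0, 0, 0]]), np.array([0.5]))


class TestRefinedGrid:
    def test_default_round2_bookkeeping(self, rng):
        # ten seeds with 125 local points each: exactly 1250 quaternions
        seeds = random_quaternion(rng, 10)
        g = refine_orientation_grid(seeds, 125, half_width=0.1)
        assert len(g) == 1250
        assert np.allclose(np.linalg.norm(g.quaternions, axis=1), 1.0, atol=1e-12)

    def test_degenerate_refinement_returns_seed(self, rng):
        seed = random_quaternion(rng)
        g = refine_orientation_grid(seed[None, :], 1, half_width=0.2)
        assert len(g) == 1
        assert geodesic_distance(g.quaternions[0], seed) < 1e-12

    def test_points_stay_within_angle_cap(self, rng):
        seeds = random_quaternion(rng, 4)
        hw = 0.15
        g = refine_orientation_grid(seeds, 27, half_width=hw)
        dists = np.array(
            [geodesic_distance(q, seeds).min() for q in g.quaternions]
        )
        assert np.all(dists <= 3 * hw + 1e-9)

    def test_empty_seed_list_rejected(self):
        with pytest.raises(ValueError):
            refine_orientation_grid(np.empty((0, 4)), 5)


def _single_pose_config(defocus):
    return MarginalizationConfig(
        shift_extent_px=0,
        round1_grid_size=1,
        n_defocus_round1=1,
        defocus_range_um=(defocus, defocus),
    )


def numeric_marginal_log_likelihood(w, r, rel_tol=1e-9):
    """Brute-force triple integration over (scale, offset, noise sd).

    Integrates the Gaussian pixel likelihood against flat priors on the
    multiplicative scale and additive offset and a Jeffreys prior 1/sigma,
    by nested adaptive quadrature.  Independent of the closed form under
    test: it works directly with the density, only using crude moment
    estimates to place the integration windows.
    """
    w = w.ravel()
    r = r.ravel()
    N = w.size
    wt, rt = w - w.mean(), r - r.mean()
    srr = float((rt**2).sum())
    mu_hat = float((wt * rt).sum() / srr)
    rss = float((wt**2).sum() - (wt * rt).sum() ** 2 / srr)
    sig_hat = np.sqrt(rss / N)
    log_peak = -N * np.log(sig_hat)  # rough scale factor to keep exp in range

    d_mu = 8 * sig_hat / np.sqrt(srr)
    d_b = 8 * sig_hat / np.sqrt(N)
    b_hat = float(w.mean() - mu_hat * r.mean())

    def over_b(sigma, mu):
        resid0 = w - mu * r
        def f(b):
            ss = ((resid0 - b) ** 2).sum()
            return np.exp(-0.5 * ss / sigma**2 - N * np.log(sigma) - np.log(sigma) - log_peak)
        val, _ = quad(f, b_hat - d_b, b_hat + d_b, epsabs=0, epsrel=rel_tol, limit=200)
        return val

    def over_mu(sigma):
        val, _ = quad(
            lambda mu: over_b(sigma, mu),
            mu_hat - d_mu,
            mu_hat + d_mu,
            epsabs=0,
            epsrel=rel_tol,
            limit=200,
        )
        return val

    val, _ = quad(over_mu, sig_hat * 0.55, sig_hat * 2.5, epsabs=0, epsrel=rel_tol, limit=200)
    return np.log(val) - 0.5 * N * np.log(2 * np.pi) + log_peak


class TestAnalyticMarginalization:
    def test_matches_numeric_triple_integration(self, rng):
        # 8x8 image, single-pose grid: the closed form over (variance,
        # offset, normalization) must agree with nested quadrature
        box, px = 8, 3.0
        node = Conformation(
            bead_positions=rng.normal(scale=4.0, size=(3, 3)),
            bead_radii=np.full(3, 4.0),
            bead_electrons=np.full(3, 50.0),
        )
        defocus = 1.2
        ref = apply_ctf(project(node, IDENTITY, pixel_size=px, box_size=box), defocus, pixel_size=px)
        w = 1.4 * ref + 0.3 + rng.normal(scale=0.35 * ref.std(), size=ref.shape)
        image = ParticleImage(
            pixels=w,
            params=ImagingParams(
                orientation=IDENTITY, defocus=defocus, pixel_size=px, box_size=16
            ),
        )
        grid = build_uniform_orientation_grid(1)
        analytic = image_node_log_likelihood(image, node, grid, _single_pose_config(defocus))
        numeric = numeric_marginal_log_likelihood(w, ref)
        # relative tolerance 1e-4 on the likelihood itself = absolute 1e-4 in log
        assert analytic == pytest.approx(numeric, abs=1e-4)

    def test_offset_invariance(self, rng):
        node = make_toy_rotor(12, 10.0)
        q = random_quaternion(rng)
        img = _image_from_node(node, q, 1.0)
        grid = build_uniform_orientation_grid(4, seed=2)
        cfg = _single_pose_config(1.0)
        base = image_node_log_likelihood(img, node, grid, cfg)
        shifted = ParticleImage(pixels=img.pixels + 12.7, params=img.params)
        assert image_node_log_likelihood(shifted, node, grid, cfg) == pytest.approx(
            base, abs=1e-8
        )

    def test_intensity_scale_shifts_all_nodes_equally(self, rng):
        nodes = [make_toy_rotor(12, a) for a in (0.0, 40.0)]
        q = random_quaternion(rng)
        img = _image_from_node(nodes[0], q, 1.5)
        scaled = ParticleImage(pixels=3.0 * img.pixels, params=img.params)
        grid = build_uniform_orientation_grid(6, seed=1)
        cfg = _single_pose_config(1.5)
        deltas = [
            image_node_log_likelihood(scaled, n, grid, cfg)
            - image_node_log_likelihood(img, n, grid, cfg)
            for n in nodes
        ]
        assert deltas[0] == pytest.approx(deltas[1], abs=1e-6)

    def test_degenerate_reference_rejected(self):
        # beads so widely spread that, after centering, every bead falls
        # outside the box: the projection is identically zero
        node = Conformation(
            bead_positions=np.array([[-500.0, 0.0, 0.0], [500.0, 0.0, 0.0]]),
            bead_radii=np.array([2.0, 2.0]),
            bead_electrons=np.array([10.0, 10.0]),
        )
        img = ParticleImage(
            pixels=np.random.default_rng(0).normal(size=(16, 16)),
            params=ImagingParams(orientation=IDENTITY, pixel_size=2.0, box_size=16),
        )
        grid = build_uniform_orientation_grid(1)
        with pytest.raises(ValueError, match="degenerate"):
            image_node_log_likelihood(img, node, grid, _single_pose_config(1.0))


@pytest.fixture(scope="module")
def tiny_llmat_setup():
    path = toy_rotor_path(3, 12, 30.0)
    prof = GroundTruthProfile.tabulated(np.zeros(3))
    stack = generate_dataset(
        path, prof, 12, snr_range=(0.5, 1.0), defocus_range_um=(0.8, 2.0),
        seed=3, box_size=24,
    )
    cfg = MarginalizationConfig(
        shift_extent_px=1,
        round1_shift_extent_px=0,
        round1_grid_size=48,
        n_defocus_round1=3,
        defocus_range_um=(0.8, 2.0),
        round2_top_k=2,
        round2_local_size=8,
        n_defocus_round2=3,
    )
    return stack, path, cfg


class TestLikelihoodMatrix:
    def test_one_by_one_matrix_finite(self, rotor_path):
        prof = GroundTruthProfile.tabulated(np.zeros(4))
        stack = generate_dataset(rotor_path, prof, 1, seed=8, box_size=32,
                                 snr_range=(0.1, 0.1))
        single = make_path([rotor_path.nodes[0], rotor_path.nodes[1]])
        cfg = MarginalizationConfig(
            shift_extent_px=1, round1_grid_size=16, n_defocus_round1=2,
            round2_top_k=2, round2_local_size=8,
        )
        llm = compute_likelihood_matrix(stack, single, cfg)
        assert llm.values.shape == (1, 2)
        assert np.isfinite(llm.values).all()

    def test_default_top_k_is_ten(self):
        assert MarginalizationConfig().round2_top_k == 10
        assert MarginalizationConfig().round2_local_size == 125

    def test_permutation_equivariance(self, tiny_llmat_setup):
        stack, path, cfg = tiny_llmat_setup
        llm = compute_likelihood_matrix(stack, path, cfg)
        permuted_path = make_path([path.nodes[2], path.nodes[0], path.nodes[1]])
        llm_p = compute_likelihood_matrix(stack, permuted_path, cfg)
        assert np.allclose(llm_p.values, llm.values[:, [2, 0, 1]], atol=1e-9)

    def test_noiseless_grid_image_identifies_its_node(self):
        path = toy_rotor_path(4, 12, 30.0)
        grid_n = 40
        from cryobife.likelihood import build_uniform_orientation_grid

        grid = build_uniform_orientation_grid(grid_n, seed=0)
        images = []
        for m in (0, 2, 3):
            images.append(
                _image_from_node(path.nodes[m], grid.quaternions[7 + m], 1.75, box=32)
            )
        images[0] = ParticleImage(pixels=images[0].pixels, params=images[0].params,
                                  truth_node=0)
        stack = ParticleStack(images=images)
        cfg = MarginalizationConfig(
            shift_extent_px=1, round1_shift_extent_px=0, round1_grid_size=grid_n,
            n_defocus_round1=3, defocus_range_um=(0.5, 3.0),
            round2_top_k=2, round2_local_size=27,
        )
        llm = compute_likelihood_matrix(stack, path, cfg)
        assert list(llm.values.argmax(axis=1)) == [0, 2, 3]
        assert list(np.asarray(llm.round1_values).argmax(axis=1)) == [0, 2, 3]

    def test_round_trip_save_load(self, tiny_llmat_setup, tmp_path):
        stack, path, cfg = tiny_llmat_setup
        llm = compute_likelihood_matrix(stack, path, cfg)
        f = tmp_path / "ll.npz"
        llm.save(f)
        from cryobife.likelihood import LogLikelihoodMatrix

        back = LogLikelihoodMatrix.load(f)
        assert np.array_equal(back.values, llm.values)
        assert np.array_equal(back.round1_values, llm.round1_values)
        assert back.config == llm.config
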