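"""Marginalized image-node log-likelihoods with two-round orientation refinement.

For every image ``w_i`` and path node ``x_m`` the likelihood
``p(w_i | x_m)`` is a sum over a pose grid (orientation x in-plane shift x
defocus), weighted by the pose priors, of a per-pose marginal in which the
Gaussian noise variance, the additive intensity offset and the multiplicative
normalization have been integrated out in closed form.

Per-pose closed form.  With the pixel model ``w = mu * r + b + eps``,
``eps ~ N(0, sigma^2 I_N)``, flat priors on ``mu`` and ``b`` and a Jeffreys
prior ``1/sigma``, the marginal over ``(mu, b, sigma)`` is

    p(w | r) = (2 pi)^{-(N-2)/2} (N * Srr)^{-1/2} * (1/2) Gamma((N-2)/2)
               * (2 / RSS)^{(N-2)/2}

where ``Srr`` is the centered sum of squares of the reference and ``RSS`` is
the residual sum of squares of ``w`` after the optimal affine intensity
match to ``r``.  Its normalization over image space is independent of the
node, so values are directly comparable across nodes for a fixed image.
The closed form is validated against brute-force numerical triple
integration in the test-suite.

Orientation marginalization runs in two rounds: a uniform SO(3) grid
(round 1), then dense local grids around the best-scoring orientations of
each image-node pair with a particle-centered Gaussian defocus prior
(round 2).  All pose sums use log-sum-exp.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from ._quat import (
    geodesic_distance,
    quat_from_axis_angle,
    quat_multiply,
    quat_to_matrix,
    random_quaternion,
)
from .kernels import render_batch
from .path import Conformation, Path
from .simulate import ParticleImage, ParticleStack, ctf_2d

__all__ = [
    "OrientationGrid",
    "MarginalizationConfig",
    "LogLikelihoodMatrix",
    "build_uniform_orientation_grid",
    "grid_spacing",
    "refine_orientation_grid",
    "image_node_log_likelihood",
    "compute_likelihood_matrix",
]


@dataclass(frozen=True)
class OrientationGrid:
    """A set of unit quaternions with prior weights summing to one."""

    quaternions: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        q = np.atleast_2d(np.asarray(self.quaternions, dtype=float))
        w = np.atleast_1d(np.asarray(self.weights, dtype=float))
        if q.shape[1] != 4:
            raise ValueError("quaternions must have shape (n, 4)")
        norms = np.linalg.norm(q, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("orientation quaternions must have unit norm")
        if w.shape[0] != q.shape[0] or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")
        object.__setattr__(self, "quaternions", q)
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return self.quaternions.shape[0]


_SUPER_FIB_PHI = math.sqrt(2.0)
_SUPER_FIB_PSI = 1.533751168755204288118041


def build_uniform_orientation_grid(n: int, seed: int = 0) -> OrientationGrid:
    """Approximately uniform covering of SO(3) by ``n`` quaternions.

    Uses the super-Fibonacci spiral on S^3 (a low-discrepancy layering of the
    Hopf fibration), followed by a seeded random global rotation so that
    independently seeded grids are not axis-aligned with each other.  All
    points carry uniform weight ``1/n``.  ``n = 1`` returns the identity.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if n == 1:
        return OrientationGrid(np.array([[1.0, 0.0, 0.0, 0.0]]), np.array([1.0]))
    i = np.arange(n, dtype=float) + 0.5
    t = i / n
    r = np.sqrt(t)
    R = np.sqrt(1.0 - t)
    alpha = 2.0 * np.pi * i / _SUPER_FIB_PHI
    beta = 2.0 * np.pi * i / _SUPER_FIB_PSI
    q = np.column_stack([r * np.sin(alpha), r * np.cos(alpha), R * np.sin(beta), R * np.cos(beta)])
    rot = random_quaternion(np.random.default_rng(seed))
    q = quat_multiply(rot[None, :], q)
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    return OrientationGrid(q, np.full(n, 1.0 / n))


def grid_spacing(grid: OrientationGrid, n_sample: int = 128) -> float:
    """Mean nearest-neighbour geodesic distance (radians) of a grid.

    Estimated on a subsample for large grids; used as the default half-width
    of the round-2 local refinement boxes.
    """
    q = grid.quaternions
    n = q.shape[0]
    if n < 2:
        return np.pi / 2
    idx = np.linspace(0, n - 1, min(n, n_sample)).astype(int)
    dmin = np.empty(idx.size)
    for k, i in enumerate(idx):
        d = geodesic_distance(q[i][None, :], q)
        d[i] = np.inf
        dmin[k] = d.min()
    return float(dmin.mean())


def _local_offsets(local_size: int, half_width: float) -> np.ndarray:
    """The first ``local_size`` points of an odd Euler-angle cube, center first."""
    c = 1
    while c**3 < local_size:
        c += 2
    vals = np.linspace(-half_width, half_width, c) if c > 1 else np.array([0.0])
    ii, jj, kk = np.meshgrid(vals, vals, vals, indexing="ij")
    pts = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0], (pts**2).sum(axis=1)))
    return pts[order[:local_size]]


def refine_orientation_grid(
    top_orientations: np.ndarray, local_size: int, half_width: float = 0.1
) -> OrientationGrid:
    """Union of small local grids around each seed orientation.

    Each seed gets ``local_size`` body-frame Euler perturbations drawn from a
    cube of half-width ``half_width`` radians per axis (e.g. ``local_size =
    125`` gives the full 5 x 5 x 5 box), so the total count is exactly
    ``K * local_size``.  Every output quaternion lies within ``3 *
    half_width`` radians (sum of per-axis angles) of its seed.
    """
    tops = np.atleast_2d(np.asarray(top_orientations, dtype=float))
    if tops.shape[0] < 1:
        raise ValueError("need at least one seed orientation")
    if local_size < 1:
        raise ValueError("local_size must be at least 1")
    offsets = _local_offsets(local_size, half_width)
    q_off = np.empty((offsets.shape[0], 4))
    for j, (ax, ay, az) in enumerate(offsets):
        q = quat_from_axis_angle([1.0, 0.0, 0.0], ax)
        q = quat_multiply(q, quat_from_axis_angle([0.0, 1.0, 0.0], ay))
        q = quat_multiply(q, quat_from_axis_angle([0.0, 0.0, 1.0], az))
        q_off[j] = q
    out = quat_multiply(tops[:, None, :], q_off[None, :, :]).reshape(-1, 4)
    out /= np.linalg.norm(out, axis=1, keepdims=True)
    n = out.shape[0]
    return OrientationGrid(out, np.full(n, 1.0 / n))


@dataclass(frozen=True)
class MarginalizationConfig:
    """Grids and priors for the pose marginalization.

    Defocus values are micrometres, shifts are pixels, angles are radians.
    ``defocus_range_um = None`` derives the round-1 defocus grid from the
    per-particle metadata of the stack being scored.  The round-1 defocus
    prior is a broad Gaussian centered mid-range with scale half the range;
    round 2 uses a Gaussian centered at each particle's recorded defocus with
    scale ``defocus_scale_round2_um`` (Gauss-Hermite quadrature).
    """

    shift_extent_px: int = 4
    shift_step_px: int = 1
    round1_shift_extent_px: int | None = None
    round1_grid_size: int = 512
    n_defocus_round1: int = 5
    defocus_range_um: tuple[float, float] | None = None
    round2_top_k: int = 10
    round2_local_size: int = 125
    round2_half_width_rad: float | None = None
    round2_seed_mode: str = "pooled"
    n_defocus_round2: int = 3
    defocus_scale_round2_um: float = 0.3
    orientation_seed: int = 0
    ctf_amplitude: float = 0.1
    b_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.shift_extent_px < 0 or self.shift_step_px < 1:
            raise ValueError("invalid shift grid")
        if self.round1_shift_extent_px is not None and self.round1_shift_extent_px < 0:
            raise ValueError("invalid round-1 shift extent")
        if min(self.round1_grid_size, self.n_defocus_round1, self.round2_top_k,
               self.round2_local_size, self.n_defocus_round2) < 1:
            raise ValueError("grid sizes must be at least 1")
        if self.defocus_scale_round2_um <= 0:
            raise ValueError("defocus prior scale must be positive")
        if self.round2_seed_mode not in ("pooled", "per_node"):
            raise ValueError("round2_seed_mode must be 'pooled' or 'per_node'")

    def shift_offsets(self, extent: int | None = None) -> np.ndarray:
        if extent is None:
            extent = self.shift_extent_px
        return np.arange(-extent, extent + 1, self.shift_step_px)

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["defocus_range_um"] is not None:
            d["defocus_range_um"] = list(d["defocus_range_um"])
        return d


@dataclass
class LogLikelihoodMatrix:
    """I x M grid of ``log p(w_i | x_m)``: the imaging/inference interface.

    ``values`` holds the round-2 matrix used for inference; ``round1_values``
    keeps the round-1 matrix for diagnostics (the two rounds can be compared
    directly).  Rows share a common, node-independent normalization.
    """

    values: np.ndarray
    image_ids: list
    node_ids: list
    round1_values: np.ndarray | None = None
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be a 2D (images x nodes) array")
        if len(self.image_ids) != v.shape[0] or len(self.node_ids) != v.shape[1]:
            raise ValueError("image/node id lengths must match the matrix shape")
        self.values = v

    @property
    def n_images(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.node_ids)
        df.insert(0, "image_id", self.image_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def save(self, path) -> None:
        """Portable binary (npz) including the marginalization config record."""
        np.savez(
            path,
            values=self.values,
            round1_values=np.array([]) if self.round1_values is None else self.round1_values,
            image_ids=np.asarray(self.image_ids),
            node_ids=np.asarray(self.node_ids),
            config_json=np.array(json.dumps(self.config)),
        )

    @classmethod
    def load(cls, path) -> "LogLikelihoodMatrix":
        with np.load(path, allow_pickle=False) as z:
            r1 = z["round1_values"]
            return cls(
                values=z["values"],
                round1_values=None if r1.size == 0 else r1,
                image_ids=list(z["image_ids"]),
                node_ids=list(z["node_ids"]),
                config=json.loads(str(z["config_json"])),
            )


# ---------------------------------------------------------------------------
# per-pose closed form and helpers


def _pose_constant(n_pixels: int) -> float:
    n = n_pixels
    return (
        -0.5 * (n - 2) * math.log(2.0 * math.pi)
        + 0.5 * (n - 2) * math.log(2.0)
        + math.lgamma(0.5 * (n - 2))
        - math.log(2.0)
    )


def _pose_log_likelihood(n_pixels, sww_c, srr_c, swr_c):
    """Closed-form log marginal over (noise variance, offset, normalization)."""
    srr_c = np.asarray(srr_c, dtype=float)
    rss = sww_c - np.square(swr_c) / srr_c
    rss = np.maximum(rss, 1e-12 * sww_c)  # guard exact matches (noiseless inputs)
    return (
        _pose_constant(n_pixels)
        - 0.5 * np.log(n_pixels * srr_c)
        - 0.5 * (n_pixels - 2) * np.log(rss)
    )


def _sum_sq_from_rfft(F: np.ndarray, box: int) -> np.ndarray:
    """Sum of squared real-space pixels from an rfft2 spectrum (Parseval)."""
    mag = np.abs(F) ** 2
    total = 2.0 * mag.sum(axis=(-2, -1)) - mag[..., :, 0].sum(axis=-1)
    if box % 2 == 0:
        total -= mag[..., :, -1].sum(axis=-1)
    return total / (box * box)


def _shift_phase_matrix(box: int, offsets: np.ndarray) -> np.ndarray:
    """Phase factors evaluating circular-shift correlations at selected offsets.

    Column ``j`` holds ``exp(2 pi i k . d_j)`` over the flattened rfft2
    frequency grid, so that for Parseval-weighted spectra ``B`` (see
    ``_bank_matrix``) the matrix ``Re(B @ (W * E))`` gives the real-space
    inner products ``sum_p r(p) w(p + d_j)`` for every reference row.
    Evaluating a handful of shifts this way is cheaper than a full inverse
    FFT per reference.
    """
    ky = np.fft.fftfreq(box)
    kx = np.fft.rfftfreq(box)
    KY, KX = np.meshgrid(ky, kx, indexing="ij")
    dy, dx = np.meshgrid(offsets, offsets, indexing="ij")
    return np.exp(
        2j
        * np.pi
        * (
            KY.ravel()[:, None] * dy.ravel()[None, :]
            + KX.ravel()[:, None] * dx.ravel()[None, :]
        )
    )


def _defocus_round1(config: MarginalizationConfig, stack_defocus: np.ndarray):
    if config.defocus_range_um is not None:
        lo, hi = config.defocus_range_um
    else:
        lo, hi = float(np.min(stack_defocus)), float(np.max(stack_defocus))
    n = config.n_defocus_round1
    if n == 1 or hi <= lo:
        return np.array([0.5 * (lo + hi)]), np.array([0.0])
    vals = np.linspace(lo, hi, n)
    center, scale = 0.5 * (lo + hi), 0.5 * (hi - lo)
    logw = -0.5 * ((vals - center) / scale) ** 2
    logw -= logsumexp(logw)
    return vals, logw


def _defocus_round2(center_um: float, config: MarginalizationConfig):
    n = config.n_defocus_round2
    if n == 1:
        return np.array([center_um]), np.array([0.0])
    x, w = np.polynomial.hermite.hermgauss(n)
    vals = center_um + math.sqrt(2.0) * config.defocus_scale_round2_um * x
    vals = np.maximum(vals, 0.05)  # defocus must stay physical
    logw = np.log(w / math.sqrt(math.pi))
    return vals, logw


def _parseval_weights(box: int) -> np.ndarray:
    """Weights turning an rfft2 inner product into the real-space inner product."""
    wt = np.full((box, box // 2 + 1), 2.0)
    wt[:, 0] = 1.0
    if box % 2 == 0:
        wt[:, -1] = 1.0
    return wt / (box * box)


def _node_render_stats(node: Conformation, quats, defocus_vals, box, px, config):
    """Reference bank for one node: spectra matrix and intensity stats.

    Renders a projection per quaternion, applies the CTF per defocus value
    and returns ``(B, r_mean, srr_c)`` where ``B`` has shape
    ``(Q * D, box * (box//2 + 1))`` and holds the Parseval-weighted complex
    conjugate spectra (rows in (quaternion, defocus) order), ``r_mean`` and
    ``srr_c`` the per-reference mean and centered sum of squares, shape
    ``(Q, D)``.
    """
    projs = render_batch(
        node.bead_positions,
        node.bead_radii / 2.0,
        node.bead_electrons,
        quat_to_matrix(np.atleast_2d(quats)),
        px,
        box,
    )
    PF = np.fft.rfft2(projs)
    ctfs = np.stack(
        [ctf_2d(box, px, d, config.ctf_amplitude, config.b_factor) for d in defocus_vals]
    )
    RF = PF[:, None, :, :] * ctfs[None, :, :, :]
    n_pix = box * box
    r_mean = RF[..., 0, 0].real / n_pix
    srr = _sum_sq_from_rfft(RF, box)
    srr_c = srr - n_pix * r_mean**2
    B = (np.conj(RF) * _parseval_weights(box)).reshape(RF.shape[0] * RF.shape[1], -1)
    return B, r_mean, srr_c


def _score_bank(B, r_mean, srr_c, WE, w_mean, sww_c, n_pix):
    """Per-(orientation, defocus, shift) pose log-likelihoods for one image.

    ``WE = W_flat[:, None] * E`` combines the image spectrum with the shift
    phase matrix; ``B @ WE`` evaluates every reference-image inner product at
    every shift in one matrix product.  Returns shape ``(Q, D, S)``.
    """
    swr = (B @ WE).real.reshape(r_mean.shape + (WE.shape[1],))
    swr_c = swr - n_pix * w_mean * r_mean[..., None]
    srr_safe = np.maximum(srr_c, 1e-300)
    ll = _pose_log_likelihood(n_pix, sww_c, srr_safe[..., None], swr_c)
    return np.where(srr_c[..., None] <= 0, -np.inf, ll)


def image_node_log_likelihood(
    image: ParticleImage,
    node: Conformation,
    grid: OrientationGrid,
    config: MarginalizationConfig,
) -> float:
    """Marginal ``log p(w | x)`` for a single image-node pair over one grid.

    Sums the per-pose closed form over (orientation x shift x defocus) grid
    points weighted by their priors; the defocus grid follows the round-1
    prior (broad Gaussian over ``defocus_range_um``, or a single point when
    ``n_defocus_round1 = 1``).
    """
    w = image.pixels
    box = w.shape[0]
    px = image.params.pixel_size
    n_pix = box * box
    d_vals, d_logw = _defocus_round1(config, np.array([image.params.defocus]))
    B, r_mean, srr_c = _node_render_stats(node, grid.quaternions, d_vals, box, px, config)
    if np.all(srr_c <= 0):
        raise ValueError("degenerate reference: projections carry no contrast")
    offsets = config.shift_offsets()
    E = _shift_phase_matrix(box, offsets)
    Wf = np.fft.rfft2(w)
    w_mean = w.mean()
    sww_c = float(((w - w_mean) ** 2).sum())
    ll = _score_bank(B, r_mean, srr_c, Wf.ravel()[:, None] * E, w_mean, sww_c, n_pix)
    log_prior = (
        np.log(grid.weights)[:, None, None]
        + d_logw[None, :, None]
        - math.log(E.shape[1])
    )
    return float(logsumexp(ll + log_prior))


def compute_likelihood_matrix(
    stack: ParticleStack,
    path: Path,
    config: MarginalizationConfig | None = None,
    progress: bool = False,
) -> LogLikelihoodMatrix:
    """Two-round marginalized log-likelihoods for every image-node pair.

    Round 1 scores a shared uniform orientation grid with a broad defocus
    prior.  Round 2 builds local refinement grids (``round2_local_size``
    points per seed, cube half-width defaulting to the round-1
    nearest-neighbour spacing) around the ``round2_top_k`` best round-1
    orientations and rescores with a Gaussian defocus prior centered at the
    particle's recorded defocus.

    Seed selection (``round2_seed_mode``): in ``"pooled"`` mode (default)
    the seeds are the image's best orientations under its best-fitting node
    and every node is rescored on that one shared refined pose set, the way
    consensus-refinement pipelines carry one pose estimate per particle
    across maps; this keeps the refined pose set identical across nodes, so
    no node can gain an advantage merely from refining deeper around its own
    noise-fitting poses.  ``"per_node"`` refines independently per
    (image, node) pair.  Returns the round-2 matrix, with the round-1 matrix
    retained for diagnostics.
    """
    if config is None:
        config = MarginalizationConfig()
    if len(stack) == 0:
        raise ValueError("empty particle stack")
    box = stack.box_size
    px = stack.pixel_size
    n_pix = box * box
    M = path.n_nodes
    I = len(stack)

    grid1 = build_uniform_orientation_grid(config.round1_grid_size, config.orientation_seed)
    spacing = grid_spacing(grid1)
    half_width = (
        spacing if config.round2_half_width_rad is None else config.round2_half_width_rad
    )
    defocus_all = np.array([im.params.defocus for im in stack.images])
    d1_vals, d1_logw = _defocus_round1(config, defocus_all)
    extent1 = (
        config.shift_extent_px
        if config.round1_shift_extent_px is None
        else config.round1_shift_extent_px
    )
    E1 = _shift_phase_matrix(box, config.shift_offsets(extent1))
    E2 = _shift_phase_matrix(box, config.shift_offsets())
    G1 = len(grid1)
    K = min(config.round2_top_k, G1)
    L = config.round2_local_size

    bank = [
        _node_render_stats(node, grid1.quaternions, d1_vals, box, px, config)
        for node in path.nodes
    ]

    ll1 = np.empty((I, M))
    ll2 = np.empty((I, M))
    log_u_orient1 = -math.log(G1)
    log_u_shift1 = -math.log(E1.shape[1])
    log_u_shift2 = -math.log(E2.shape[1])

    pooled = config.round2_seed_mode == "pooled"
    o_scores = np.empty((M, G1))
    for i, im in enumerate(stack.images):
        w = im.pixels
        Wf = np.fft.rfft2(w).ravel()
        w_mean = w.mean()
        sww_c = float(((w - w_mean) ** 2).sum())
        d2_vals, d2_logw = _defocus_round2(im.params.defocus, config)
        WE1 = Wf[:, None] * E1
        WE2 = Wf[:, None] * E2
        for m in range(M):
            B, r_mean, srr_c = bank[m]
            pose = _score_bank(B, r_mean, srr_c, WE1, w_mean, sww_c, n_pix)
            # per-orientation marginal over defocus and shift
            o_scores[m] = logsumexp(
                pose + d1_logw[None, :, None] + log_u_shift1, axis=(1, 2)
            )
            ll1[i, m] = logsumexp(o_scores[m]) + log_u_orient1

        shared_local = None
        if pooled:
            seed_scores = o_scores[int(np.argmax(ll1[i]))]
            top_idx = np.argpartition(seed_scores, -K)[-K:]
            shared_local = refine_orientation_grid(
                grid1.quaternions[top_idx], L, half_width=half_width
            )
        for m, node in enumerate(path.nodes):
            if pooled:
                local = shared_local
            else:
                top_idx = np.argpartition(o_scores[m], -K)[-K:]
                local = refine_orientation_grid(
                    grid1.quaternions[top_idx], L, half_width=half_width
                )
            B2, r_mean2, srr_c2 = _node_render_stats(
                node, local.quaternions, d2_vals, box, px, config
            )
            pose2 = _score_bank(B2, r_mean2, srr_c2, WE2, w_mean, sww_c, n_pix)
            ll2[i, m] = logsumexp(
                pose2 + d2_logw[None, :, None] + log_u_shift2 - math.log(K * L)
            )
        if progress and (i + 1) % 100 == 0:
            print(f"  likelihood: {i + 1}/{I} images", flush=True)

    record = dict(config.to_dict())
    record["round1_spacing_rad"] = spacing
    record["box_size"] = box
    record["pixel_size"] = px
    return LogLikelihoodMatrix(
        values=ll2,
        round1_values=ll1,
        image_ids=list(range(I)),
        node_ids=list(range(M)),
        config=record,
    )
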