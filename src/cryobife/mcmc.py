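"""Posterior sampling of free-energy profiles by random-walk Metropolis.

The posterior over node values ``G = (G(s_1), ..., G(s_M))`` combines the
pre-computed image-node log-likelihoods with a weak smoothness prior

    p(G) = 1 / Gsq^2,   Gsq = sum_{m=1}^{M-1} (G(s_{m+1}) - G(s_m))^2,

(a standard-normal prior on the discrete differences, marginalized over its
precision).  Only differences of ``G`` are physical, so sampling is
gauge-fixed to ``sum_m G_m = 0``; reported profiles are shifted so the
minimum is zero.  Energies are in kBT throughout (``beta = 1``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.special import logsumexp

from .kernels import run_metropolis_chain
from .likelihood import LogLikelihoodMatrix

__all__ = [
    "FreeEnergyProfile",
    "MCMCConfig",
    "PosteriorSamples",
    "ProfileSummary",
    "log_prior",
    "log_posterior",
    "mcmc_sample",
    "expected_profile",
    "r_hat",
    "brute_force_posterior",
]

#: guard below which Gsq is clipped; the printed prior diverges at exactly
#: flat profiles (a measure-zero set), the guard keeps the density bounded.
PRIOR_GUARD = 1e-12


@dataclass(frozen=True)
class FreeEnergyProfile:
    """Free-energy values (kBT) at the M path nodes."""

    g_values: np.ndarray

    def __post_init__(self) -> None:
        g = np.atleast_1d(np.asarray(self.g_values, dtype=float))
        if g.ndim != 1 or g.size < 2:
            raise ValueError("a profile needs at least two node values")
        if not np.all(np.isfinite(g)):
            raise ValueError("profile values must be finite")
        object.__setattr__(self, "g_values", g)

    def recentered(self) -> "FreeEnergyProfile":
        """Gauge-fixed copy with sum(G) = 0."""
        return FreeEnergyProfile(self.g_values - self.g_values.mean())


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings.

    ``n_chains`` independent chains of ``n_steps`` single-node Metropolis
    moves; proposals perturb one uniformly chosen node by
    ``U[-step_half_width, step_half_width]`` kBT and re-center to the
    ``sum = 0`` gauge.  Initial profiles are drawn uniformly per node from
    ``init_range``.  ``burn_in_fraction = 0`` averages over every step (the
    reference behaviour); a nonzero fraction is available for short runs.
    """

    n_chains: int = 8
    n_steps: int = 200_000
    step_half_width: float = 0.5
    init_range: tuple[float, float] = (-2.0, 2.0)
    seed: int = 0
    burn_in_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be at least 1")
        if self.step_half_width <= 0:
            raise ValueError("step_half_width must be positive")
        if not 0.0 <= self.burn_in_fraction < 1.0:
            raise ValueError("burn_in_fraction must lie in [0, 1)")
        if self.n_chains < 1:
            raise ValueError("n_chains must be at least 1")


@dataclass
class PosteriorSamples:
    """MCMC draws: ``draws[r, i, m]`` = chain r, step i, node m (sum_m = 0)."""

    draws: np.ndarray
    acceptance_rate: np.ndarray
    config: MCMCConfig
    s_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.draws, dtype=float)
        if d.ndim != 3:
            raise ValueError("draws must have shape (chains, steps, nodes)")
        self.draws = d

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.draws.shape[2]


@dataclass
class ProfileSummary:
    """Posterior summary: mean profile (min = 0), 5-95% band, R-hat, spline."""

    mean_profile: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    r_hat: np.ndarray
    s_values: np.ndarray
    spline: CubicSpline = field(repr=False, default=None)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "node": np.arange(len(self.mean_profile)),
                "s": self.s_values,
                "mean": self.mean_profile,
                "ci5": self.ci_low,
                "ci95": self.ci_high,
                "r_hat": self.r_hat,
            }
        )


def _gsq(g: np.ndarray) -> float:
    d = np.diff(g)
    return float((d * d).sum())


def log_prior(profile: FreeEnergyProfile | np.ndarray) -> float:
    """Log of the smoothness prior ``1/Gsq^2`` (guarded at flat profiles)."""
    g = profile.g_values if isinstance(profile, FreeEnergyProfile) else np.asarray(profile, float)
    if g.size < 2:
        raise ValueError("prior needs at least two nodes")
    return -2.0 * np.log(max(_gsq(g), PRIOR_GUARD))


def log_posterior(
    profile: FreeEnergyProfile | np.ndarray, llmat: LogLikelihoodMatrix | np.ndarray
) -> float:
    """Unnormalized log posterior of a profile given the likelihood matrix.

    ``log p(G) + sum_i [ logsumexp_m(logL_im - G_m) - logsumexp_m(-G_m) ]``;
    the quadrature weights ``1/M`` and the partition factor cancel into a
    G-independent constant which is dropped.  Stable for ``-inf`` entries in
    the matrix (zero-likelihood nodes).
    """
    g = profile.g_values if isinstance(profile, FreeEnergyProfile) else np.asarray(profile, float)
    ll = llmat.values if isinstance(llmat, LogLikelihoodMatrix) else np.asarray(llmat, float)
    if ll.shape[1] != g.size:
        raise ValueError("profile length must match the matrix column count")
    like = logsumexp(ll - g[None, :], axis=1).sum() - ll.shape[0] * logsumexp(-g)
    return float(like + log_prior(g))


def _chain_seeds(master_seed: int, n_chains: int) -> np.ndarray:
    ss = np.random.SeedSequence(master_seed)
    return (ss.generate_state(n_chains) % np.uint32(2**31)).astype(np.int64)


def mcmc_sample(
    llmat: LogLikelihoodMatrix | np.ndarray,
    config: MCMCConfig | None = None,
    s_values: np.ndarray | None = None,
) -> PosteriorSamples:
    """Run independent Metropolis chains over gauge-fixed profiles.

    Every post-step state is stored (draws satisfy ``sum_m G_m = 0``); the
    run is fully reproducible from ``config.seed`` and chain results do not
    depend on execution order.
    """
    if config is None:
        config = MCMCConfig()
    ll = llmat.values if isinstance(llmat, LogLikelihoodMatrix) else np.asarray(llmat, float)
    if ll.ndim != 2 or ll.shape[1] < 2:
        raise ValueError("likelihood matrix must be 2D with at least two nodes")
    # row-rescale: exp(logL - rowmax) keeps factors in (0, 1]; the rescaling
    # constant is independent of G and cancels in acceptance ratios
    A = np.exp(ll - ll.max(axis=1, keepdims=True))
    R, N, M = config.n_chains, config.n_steps, ll.shape[1]
    draws = np.empty((R, N, M))
    acc = np.empty(R)
    seeds = _chain_seeds(config.seed, R)
    lo, hi = config.init_range
    for r in range(R):
        acc[r] = run_metropolis_chain(
            A, seeds[r], N, config.step_half_width, lo, hi, PRIOR_GUARD, draws[r]
        )
    return PosteriorSamples(draws=draws, acceptance_rate=acc, config=config, s_values=s_values)


def expected_profile(
    samples: PosteriorSamples, s_values: np.ndarray | None = None
) -> ProfileSummary:
    """Node-wise posterior mean, credible band, R-hat and interpolating spline.

    The mean over all retained draws is shifted so its minimum is zero; the
    node-wise empirical 5%/95% quantiles are shifted by the same constant so
    the band brackets the reported profile.  The spline is a natural cubic
    interpolant with knots at the nodes (it reproduces the node means
    exactly).
    """
    d = samples.draws
    if d.size == 0:
        raise ValueError("no posterior draws")
    burn = int(samples.config.burn_in_fraction * d.shape[1]) if samples.config else 0
    kept = d[:, burn:, :].reshape(-1, d.shape[2])
    mean = kept.mean(axis=0)
    q5, q95 = np.quantile(kept, [0.05, 0.95], axis=0)
    shift = mean.min()
    if s_values is None:
        s_values = (
            samples.s_values
            if samples.s_values is not None
            else np.arange(d.shape[2]) / (d.shape[2] - 1)
        )
    s_values = np.asarray(s_values, dtype=float)
    rh = (
        r_hat(d[:, burn:, :]) if samples.n_chains >= 2 else np.full(d.shape[2], np.nan)
    )
    mean_shifted = mean - shift
    return ProfileSummary(
        mean_profile=mean_shifted,
        ci_low=q5 - shift,
        ci_high=q95 - shift,
        r_hat=rh,
        s_values=s_values,
        spline=CubicSpline(s_values, mean_shifted, bc_type="natural"),
    )


def r_hat(samples: PosteriorSamples | np.ndarray) -> np.ndarray:
    """Per-node split R-hat (each chain halved; no rank normalization).

    Compares between-half-chain variance to within-half-chain variance;
    values at or below 1.1 indicate convergence.  When given
    ``PosteriorSamples`` the configured burn-in fraction is discarded first
    (the diagnostic describes the retained sample, following the usual
    warmup-discard convention); a raw draws array is used as passed.
    """
    if isinstance(samples, PosteriorSamples):
        burn = int(samples.config.burn_in_fraction * samples.draws.shape[1])
        d = samples.draws[:, burn:, :]
    else:
        d = np.asarray(samples, float)
    if d.ndim != 3 or d.shape[0] < 2:
        raise ValueError("r_hat needs at least two chains of draws")
    n = d.shape[1] // 2
    if n < 2:
        raise ValueError("chains are too short to split")
    halves = np.concatenate([d[:, :n, :], d[:, n : 2 * n, :]], axis=0)  # (2R, n, M)
    means = halves.mean(axis=1)
    W = halves.var(axis=1, ddof=1).mean(axis=0)
    B = n * means.var(axis=0, ddof=1)
    var_hat = (n - 1) / n * W + B / n
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.sqrt(var_hat / W)
    return np.where(W > 0, out, 1.0)  # constant chains: nothing to diagnose


def brute_force_posterior(
    llmat: LogLikelihoodMatrix | np.ndarray,
    grid_resolution: int = 201,
    half_range: float = 10.0,
) -> np.ndarray:
    """Node-marginal posterior means by dense quadrature (oracle, M <= 3).

    The ``sum = 0`` gauge leaves M-1 free coordinates; the posterior density
    (same guarded prior as the sampler) is evaluated on a regular grid over
    ``[-half_range, half_range]^(M-1)`` and node-wise means are returned.
    Intended as an independent check of the Metropolis sampler.
    """
    ll = llmat.values if isinstance(llmat, LogLikelihoodMatrix) else np.asarray(llmat, float)
    M = ll.shape[1]
    if M > 3:
        raise ValueError("brute-force quadrature is only supported for M <= 3")
    axis = np.linspace(-half_range, half_range, grid_resolution)
    if M == 2:
        free = axis[:, None]
    else:
        aa, bb = np.meshgrid(axis, axis, indexing="ij")
        free = np.column_stack([aa.ravel(), bb.ravel()])
    G = np.column_stack([free, -free.sum(axis=1)])  # (P, M), sum = 0
    rowmax = ll.max(axis=1, keepdims=True)
    A = np.exp(ll - rowmax)  # (I, M)
    logpost = np.empty(G.shape[0])
    chunk = 65536
    for lo in range(0, G.shape[0], chunk):
        g = G[lo : lo + chunk]
        q = np.exp(-g)  # (p, M)
        like = np.log(q @ A.T).sum(axis=1) - ll.shape[0] * np.log(q.sum(axis=1))
        gsq = np.maximum((np.diff(g, axis=1) ** 2).sum(axis=1), PRIOR_GUARD)
        logpost[lo : lo + chunk] = like - 2.0 * np.log(gsq)
    w = np.exp(logpost - logpost.max())
    w /= w.sum()
    return w @ G
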