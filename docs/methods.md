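# Methods

## Model

A conformational transition is represented by a discretized path: an ordered
set of M coarse-grained structures (nodes) `x_1 … x_M` with path parameters
`s_m = (m−1)/(M−1)`. The molecule's equilibrium ensemble restricted to the
path is Boltzmann-distributed under a free-energy profile `G(s)` (in kBT,
β = 1 throughout):

    ρ_G(s_m) = exp(−G(s_m)) / Z₁,   Z₁ = (1/M) Σ_k exp(−G(s_k)),

where the `1/M` node average is the package's quadrature rule for integrals
over `s` (a plain equispaced node average, deliberately not a trapezoid
rule, so endpoints carry the same weight as interior nodes).

Each particle image `w_i` is a noisy CTF-filtered projection of the molecule
in one (unobserved) conformation on the path. Marginalizing the latent node
gives the per-image likelihood `Σ_m p(w_i|x_m) ρ_G(s_m) / M`, and with a
smoothness prior `p(G) = 1/𝒢²`, `𝒢 = Σ_m (G_{m+1} − G_m)²` (a normal prior
on the discrete differences marginalized over its precision), the
posterior over profiles is

    p(G | w) ∝ p(G) Π_i [ Σ_m p(w_i | x_m) exp(−G_m) / (M Z₁) ].

Only differences of `G` matter; sampling is gauge-fixed to `Σ_m G_m = 0`
and reported profiles are shifted so their minimum is zero.

### Propriety of the posterior

The `1/𝒢²` prior is scale-free and heavy-tailed: on the gauge surface its
density falls as `ρ⁻⁴` in the profile amplitude `ρ = √𝒢` while the surface
volume grows as `ρ^{M−2}`, so the prior alone is not normalizable for
M ≥ 6, and near flat profiles it diverges (non-integrably for M ≤ 5). Two
consequences are handled explicitly:

* a guard clips `𝒢` at 1e−12 so the density stays bounded on the
  measure-zero flat set; the sampler and the brute-force quadrature oracle
  target the same guarded density, keeping their comparison well posed;
* the data must dominate the tails. With hundreds to thousands of images
  the aggregated likelihood penalty for unbounded or flat profiles is
  hundreds of nats and the posterior is effectively proper; with very few
  or nearly uninformative images the chains inherit the prior's drift and
  the credible bands widen accordingly. This is visible in the low-SNR
  experiments and is a property of the printed prior, not of the sampler.

## Image likelihood

`p(w|x)` is a sum over a pose grid — orientation × in-plane shift ×
defocus — of a per-pose marginal with the pose priors as weights. Per pose,
the pixel model is `w = μ r + b + ε`, `ε ~ N(0, σ²I)`, with `r` the
CTF-filtered projection of the node at that pose. The multiplicative
normalization `μ` and additive offset `b` take flat priors, the noise sd σ
a Jeffreys prior `1/σ`; all three integrate in closed form to

    p(w | r) = (2π)^{−(N−2)/2} (N S_rr)^{−1/2} · ½ Γ((N−2)/2) (2/RSS)^{(N−2)/2},

with `N` the pixel count, `S_rr` the centered sum of squares of `r` and
`RSS` the residual after the optimal affine intensity match. The
normalization over image space is node-independent, so entries are
comparable across nodes for a fixed image. The closed form is verified in
the tests against brute-force numerical triple integration on 8×8 images.

Cross-correlations over the shift grid are evaluated with Parseval-weighted
spectra against a small phase matrix (one BLAS product per image-node
block), which is cheaper than a full inverse FFT per reference when only a
handful of shifts is scanned.

### Two-round orientation handling

Round 1 scores a shared, approximately uniform SO(3) quaternion grid
(super-Fibonacci covering with a seeded global rotation; size configurable,
default 512) under a broad Gaussian defocus prior spanning the stack's
defocus range. Round 2 rebuilds the score on dense local grids — Euler-angle
cubes of `round2_local_size` points (default 125, i.e. 5×5×5) with
half-width equal to the round-1 nearest-neighbour spacing — around the
`round2_top_k` (default 10) best round-1 orientations, now with a Gaussian
defocus prior centered on each particle's recorded defocus (scale 0.3 μm,
integrated by Gauss–Hermite quadrature).

Seed pooling. By default the round-2 seeds are the image's best round-1
orientations under its best-fitting node, and **all** nodes are rescored on
that single shared refined pose set — the way consensus-refinement
pipelines carry one pose estimate per particle across candidate maps. The
alternative (`round2_seed_mode="per_node"`) refines independently around
each node's own seeds. At desk-scale grid sizes the per-node variant lets
each node deepen its own best noise fit, which injects node-dependent bias
into the matrix; scoring every node on an identical pose set removes that
asymmetry and measurably improves profile recovery. At production grid
sizes (tens of thousands of orientations) the two variants converge.

In-plane shifts default to a flat prior over ±4 px. Synthetic particles are
generated centered, so the benchmark configuration scans shifts only in
round 2 (±2 px) and scores round 1 at zero shift, which makes round 1 a
single inner product per reference.

All pose sums use log-sum-exp. Degenerate references (projections with no
contrast) raise rather than returning −∞ silently. A floor of
`1e−12 · S_ww` on RSS keeps noiseless self-matches finite.

## Forward model

Projection renders each residue bead as an integrable 2D Gaussian (sd =
radius/2, amplitude scaled by electron count and pixel area) after rotating
the electron-weighted-centered bead model; total intensity approximates
the total electron count. The CTF is applied in Fourier space:

    CTF(k) = −[√(1−A²) sin(πλ Δf k²) + A cos(πλ Δf k²)] e^{−Bk²/4},

with amplitude contrast A = 0.1, B-factor 1 Å² (read as Å²), electron
wavelength λ = 0.0197 Å (300 keV). The same convention is used by the
simulator and the likelihood; internal consistency is what matters, since
the exact convention is a free choice of the forward model. Noise is white
Gaussian with variance `Var_circle(signal)/SNR`, the variance measured in a
central circle of radius `round(box · 40/128)` px. Dataset generation draws
the node from the Boltzmann weights of the ground-truth profile,
orientations uniformly on SO(3) (Shoemake sampler), SNR log-uniformly and
defocus uniformly over their ranges, with zero in-plane shift (the
likelihood still scans shifts, so pre-centered particles are the
conservative choice). One `numpy` Generator seeded by the master seed
drives everything, so stacks are bit-reproducible.

## Synthetic benchmark design

The benchmark molecule is a rigid "toy rotor": a three-arm fixed base and a
moving arm that rotates on a 75° cone about +x in equal angular steps —
a desk-scale analogue of one protein domain rotating against a fixed
partner chain. Two geometric properties were chosen deliberately, and both
were necessary in practice:

* **Unequal arm lengths.** If the base had any rotational symmetry about
  the cone axis, path nodes would be global rotations of one another and
  therefore indistinguishable in projection ensembles.
* **Base mass off the cone axis.** A global rotation about the cone axis
  mimics the arm motion exactly; beads lying on that axis are invariant
  under it and contribute nothing to telling "conformational change" from
  "viewing-angle change". The base arms therefore point along −x, −y and a
  tilted +z direction, with only a quarter of the base on the axis.

Defaults: 24 beads (radius 4 Å, 60 electrons each, 3.8 Å spacing —
residue-like), 10 nodes at 15° steps, box 32 px at 2.2 Å/px, SNR
log-uniform in [0.01, 0.1], defocus uniform in [0.5, 3] μm, 1500 particles.
The ground truth is the analytic double-well profile
`exp(−G(s)) = exp(−(19s−6)²/8) + exp(−(19s−15)²/18)/3` evaluated at the
node parameters; node populations follow its Boltzmann weights. The 2D
benchmark uses a two-arm rotor (independent cone rotations ↔ the two model
indices) with the analytic two-basin surface, path lines CV1 (diagonal,
through both basins), CV2 (u = 10) and CV3 (v = 10) across the 20×20 model
grid.

What the generator does not emulate: structural noise within a node
(conformers off the path), ice/solvent background, detector MTF, dose
damage, particle-picking errors, or astigmatic/per-particle CTF error.
Passing benchmarks therefore demonstrate correctness of the inference
machinery under the stated image model, not robustness to every real-data
artifact; the file interfaces accept externally computed likelihood
matrices so real BioEM outputs can be plugged in unchanged.

## MCMC

Random-walk Metropolis on the node values: per step, one uniformly chosen
node is perturbed by δg ~ U[−0.5, 0.5] kBT, the profile is re-centered to
`Σ G = 0` (pure gauge: populations and prior are shift-invariant), and the
move is accepted on the log-posterior difference. Initial values are
uniform in [−2, 2] per node. R independent chains run from seeds spawned
off the master seed (`numpy.random.SeedSequence`); every post-step state is
stored. Defaults R = 8, 200,000 steps (production scale); the desk-scale
benchmarks use 4 chains × 20,000 steps with `burn_in_fraction = 0.1`. The
burn-in option exists precisely for such short chains, where the initial
transient is a visible fraction of the run; with 200,000 steps the default
of zero (average over everything) is the reference behaviour. Split R-hat
(each chain halved, no rank normalization; threshold 1.1) is computed on
the retained draws, following the usual warmup-discard convention.

Summaries: node-wise mean over retained draws (min-shifted to zero),
node-wise empirical 5%/95% quantiles shifted by the same constant, natural
cubic interpolating spline through the node means (knots at the nodes), and
per-node split R-hat.

The whole-step log-posterior is recomputed per proposal inside a
numba-compiled kernel (O(I·M) per step; ≈2 s for 4×20,000 steps at
I = 1500, M = 10). A dense-grid quadrature oracle (`brute_force_posterior`,
M ≤ 3 so the gauge surface has ≤ 2 dimensions) provides an independent
check of the sampler's node marginals.

## Problem sizes

Desk-scale defaults were chosen so the full closed loop — generate 1500
particles, two likelihood rounds, 4×20,000-step sampling — completes in
about three minutes on one CPU core: round-1 grid 384 orientations × 3
defocus values at zero shift; round-2 refinement 8 seeds × 27 local
orientations × 3 defocus values × 25 shifts. Production-scale settings (36,864-point
round-1 grid, 10×125 refinement, ±4 px shifts, 8×200,000-step chains)
are plain configuration values; nothing in the code is specific to the
small grids.

## Known limitations

* The likelihood treats pose grids as exhaustive; with very coarse grids
  the marginal is effectively a max over poses and residual pose error
  leaks into node comparisons. The pooled round-2 seeding mitigates the
  node-dependent part; the common-mode part inflates credible bands.
* The printed smoothness prior is improper in both tails (see above);
  inference quality degrades gracefully but visibly when the data are
  weak, and posterior means under near-uninformative matrices should be
  read as prior-dominated.
* Single-node Metropolis moves mix slowly along strongly correlated
  profile directions; for large M or very sharp posteriors more steps (or
  several restarts, as the R-hat diagnostic will demand) are needed.
* `brute_force_posterior` is limited to M ≤ 3 by design; it is an oracle,
  not an inference path.
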