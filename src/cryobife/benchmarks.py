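"""Desk-scale controlled experiments with known ground truth.

The benchmark object here is a "toy rotor": a rigid bead molecule with a
fixed multi-arm base and a moving arm that rotates about a fixed pivot in
equal angular steps, mimicking at small scale the single-domain rotation of
a two-chain chaperone (one chain fixed, the other rotated).  The base
geometry guarantees that different rotor angles are genuinely different
conformations and not global rotations of one another (see
``make_toy_rotor``).  Node populations follow the Boltzmann weights of an
analytic ground-truth profile, closing the validation loop:
generate -> likelihood -> sample -> compare to truth.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict

import numpy as np

from ._quat import quat_to_matrix
from .likelihood import MarginalizationConfig, compute_likelihood_matrix
from .mcmc import MCMCConfig, expected_profile, mcmc_sample
from .path import (
    Conformation,
    GroundTruthProfile,
    Path,
    ground_truth_1d,
    ground_truth_2d,
    make_path,
    path_cv_value,
    path_on_surface,
)
from .simulate import ParticleStack, generate_dataset

__all__ = [
    "make_toy_rotor",
    "make_toy_rotor_2d",
    "toy_rotor_path",
    "BenchmarkSpec",
    "BenchmarkReport",
    "get_benchmark",
    "run_benchmark",
    "histogram_profile",
    "compare_3d_vs_images",
    "BENCHMARKS",
]

_ARM_SPACING_A = 3.8     # bead spacing along an arm (Calpha-like)
_BEAD_RADIUS_A = 4.0     # coarse bead radius (effective residue-cluster size)
_BEAD_ELECTRONS = 60.0   # typical per-residue electron count
_CONE_HALF_ANGLE = np.deg2rad(75.0)


def _arm(direction: np.ndarray, n_beads: int) -> np.ndarray:
    steps = np.arange(1, n_beads + 1, dtype=float)[:, None]
    direction = direction / np.linalg.norm(direction)
    return steps * _ARM_SPACING_A * direction[None, :]


def make_toy_rotor(
    n_beads: int, rotation_deg: float, bead_radius: float = _BEAD_RADIUS_A
) -> Conformation:
    """Rigid rotor: a three-arm fixed base plus a moving arm on a cone.

    The moving arm points along ``(cos a, sin a cos t, sin a sin t)`` with
    cone half-angle ``a = 75 deg`` about +x and ``t = rotation_deg``; the
    base consists of three fixed arms of different lengths along -x, -y and
    a tilted +z direction.  Two properties of the base matter: its arms have
    unequal lengths (no global rotation maps one node onto another, so
    different rotation angles are genuinely different conformations, as for
    a domain rotating against a fixed partner chain), and most of its mass
    sits off the cone axis (a global rotation about +x that mimics the arm
    motion displaces the base strongly, so the mimicry is visible in
    projections).  RMSD between two rotors grows monotonically with their
    angular separation up to 180 degrees (chord length on the cone).
    """
    if n_beads < 3:
        raise ValueError("need at least three beads")
    n_moving = max(1, n_beads // 3)
    n_base_x = max(1, n_beads // 4)
    n_base_y = max(0, n_beads // 4)
    n_base_z = n_beads - n_moving - n_base_x - n_base_y
    t = np.deg2rad(rotation_deg)
    moving_dir = np.array(
        [
            np.cos(_CONE_HALF_ANGLE),
            np.sin(_CONE_HALF_ANGLE) * np.cos(t),
            np.sin(_CONE_HALF_ANGLE) * np.sin(t),
        ]
    )
    arms = [_arm(np.array([-1.0, 0.0, 0.0]), n_base_x)]
    if n_base_y > 0:
        arms.append(_arm(np.array([0.0, -1.0, 0.0]), n_base_y))
    if n_base_z > 0:
        arms.append(_arm(np.array([0.0, 0.3, 1.0]), n_base_z))
    arms.append(_arm(moving_dir, n_moving))
    pos = np.vstack(arms)
    return Conformation(
        bead_positions=pos,
        bead_radii=np.full(n_beads, bead_radius),
        bead_electrons=np.full(n_beads, _BEAD_ELECTRONS),
        label=f"rotor:{rotation_deg:g}deg",
    )


def make_toy_rotor_2d(n_beads: int, angle_u_deg: float, angle_v_deg: float) -> Conformation:
    """Three-arm rotor with two independently rotating arms (2D conformational space).

    Arm U rotates on a cone about +x (like the 1D rotor), arm V on a cone
    about +y; a third, fixed arm along -x - y anchors the frame.  The two
    angles play the role of the two domain-rotation coordinates of the 2D
    benchmark surface.
    """
    if n_beads < 6:
        raise ValueError("need at least six beads for the two-arm rotor")
    # unequal arm lengths so no global rotation can swap the two moving arms
    n_u = n_beads // 3 + 1
    n_v = max(1, n_beads // 3 - 1)
    n_fixed = n_beads - n_u - n_v
    tu = np.deg2rad(angle_u_deg)
    tv = np.deg2rad(angle_v_deg)
    dir_u = np.array(
        [
            np.cos(_CONE_HALF_ANGLE),
            np.sin(_CONE_HALF_ANGLE) * np.cos(tu),
            np.sin(_CONE_HALF_ANGLE) * np.sin(tu),
        ]
    )
    dir_v = np.array(
        [
            np.sin(_CONE_HALF_ANGLE) * np.cos(tv),
            np.cos(_CONE_HALF_ANGLE),
            np.sin(_CONE_HALF_ANGLE) * np.sin(tv),
        ]
    )
    dir_f = np.array([-1.0, -1.0, 0.0]) / np.sqrt(2.0)
    pos = np.vstack([_arm(dir_f, n_fixed), _arm(dir_u, n_u), _arm(dir_v, n_v)])
    return Conformation(
        bead_positions=pos,
        bead_radii=np.full(n_beads, _BEAD_RADIUS_A),
        bead_electrons=np.full(n_beads, _BEAD_ELECTRONS),
        label=f"rotor2d:{angle_u_deg:g},{angle_v_deg:g}",
    )


def toy_rotor_path(M: int, n_beads: int = 24, rotation_step_deg: float = 15.0) -> Path:
    """Path of M rotor conformations at equal angular steps."""
    return make_path([make_toy_rotor(n_beads, m * rotation_step_deg) for m in range(M)])


@dataclass(frozen=True)
class BenchmarkSpec:
    """Everything needed to reproduce one controlled experiment."""

    name: str
    M: int = 10
    n_beads: int = 24
    rotation_step_deg: float = 15.0
    ground_truth: str = "hsp90_1d"       # hsp90_1d | hsp90_2d:<CV1|CV2|CV3>
    n_images: int = 1500
    snr_range: tuple[float, float] = (0.01, 0.1)
    defocus_range_um: tuple[float, float] = (0.5, 3.0)
    box_size: int = 32
    pixel_size: float = 2.2
    seed: int = 1234
    marginalization: MarginalizationConfig = field(
        default_factory=lambda: MarginalizationConfig(
            shift_extent_px=2,
            round1_shift_extent_px=0,
            round1_grid_size=384,
            n_defocus_round1=3,
            defocus_range_um=(0.5, 3.0),
            round2_top_k=8,
            round2_local_size=27,
            n_defocus_round2=3,
        )
    )
    mcmc: MCMCConfig = field(
        default_factory=lambda: MCMCConfig(
            n_chains=4, n_steps=20_000, seed=1234, burn_in_fraction=0.1
        )
    )

    def build_path_and_truth(self) -> tuple[Path, GroundTruthProfile]:
        if self.ground_truth == "hsp90_1d":
            path = toy_rotor_path(self.M, self.n_beads, self.rotation_step_deg)
            truth = GroundTruthProfile.hsp90_1d(path.s_values)
            return path, truth
        if self.ground_truth.startswith("hsp90_2d:"):
            cv_id = self.ground_truth.split(":", 1)[1]
            uv = path_on_surface(cv_id, self.M)
            # model indices 1..20 map linearly onto the two rotor angles
            nodes = [
                make_toy_rotor_2d(
                    self.n_beads,
                    (u - 1.0) * self.rotation_step_deg,
                    (v - 1.0) * self.rotation_step_deg,
                )
                for u, v in uv
            ]
            path = make_path(nodes)
            truth = GroundTruthProfile.hsp90_2d_along_path(uv)
            return path, truth
        raise ValueError(f"unknown ground truth {self.ground_truth!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["marginalization"] = self.marginalization.to_dict()
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "BenchmarkSpec":
        data = dict(data)
        for key in ("snr_range", "defocus_range_um"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        marg = data.pop("marginalization", None)
        if marg is not None:
            if marg.get("defocus_range_um") is not None:
                marg = {**marg, "defocus_range_um": tuple(marg["defocus_range_um"])}
            data["marginalization"] = MarginalizationConfig(**marg)
        mcmc = data.pop("mcmc", None)
        if mcmc is not None:
            if "init_range" in mcmc and mcmc["init_range"] is not None:
                mcmc = {**mcmc, "init_range": tuple(mcmc["init_range"])}
            data["mcmc"] = MCMCConfig(**mcmc)
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "BenchmarkSpec":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class BenchmarkReport:
    """Outcome of one benchmark run, compared against the ground truth.

    ``rmse`` / ``coverage`` are restricted to nodes whose Boltzmann
    population is at least 5% of the maximum (sparsely populated nodes are
    barely constrained by the data, as the widening credible bands show).
    """

    spec: dict
    truth_profile: list
    mean_profile: list
    ci_low: list
    ci_high: list
    round1_mean_profile: list
    rmse: float
    round1_rmse: float
    coverage: float
    populated_nodes: list
    max_r_hat: float
    mean_band_width: float
    acceptance_rate: list
    runtime_s: dict

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            from .io import atomic_write_text

            atomic_write_text(path, text)
        return text


_POPULATION_CUTOFF = 0.05


def _min_shift(v: np.ndarray) -> np.ndarray:
    return v - v.min()


def run_benchmark(spec: BenchmarkSpec, progress: bool = False) -> BenchmarkReport:
    """Full loop: generate -> two-round likelihood -> sample -> summarize.

    The recovered expected profile (rounds 1 and 2) is compared to the
    min-shifted truth; both are shifted by their own minimum so the
    comparison is gauge-free.
    """
    t0 = time.perf_counter()
    path, truth = spec.build_path_and_truth()
    stack = generate_dataset(
        path,
        truth,
        spec.n_images,
        snr_range=spec.snr_range,
        defocus_range_um=spec.defocus_range_um,
        seed=spec.seed,
        pixel_size=spec.pixel_size,
        box_size=spec.box_size,
    )
    t1 = time.perf_counter()
    llmat = compute_likelihood_matrix(stack, path, spec.marginalization, progress=progress)
    t2 = time.perf_counter()
    samples = mcmc_sample(llmat, spec.mcmc, s_values=path.s_values)
    summary = expected_profile(samples)
    samples1 = mcmc_sample(
        np.asarray(llmat.round1_values), spec.mcmc, s_values=path.s_values
    )
    summary1 = expected_profile(samples1)
    t3 = time.perf_counter()

    truth_shifted = _min_shift(truth.values)
    pops = truth.boltzmann_weights()
    populated = np.flatnonzero(pops >= _POPULATION_CUTOFF * pops.max())
    err = summary.mean_profile - truth_shifted
    err1 = summary1.mean_profile - truth_shifted
    rmse = float(np.sqrt(np.mean(err[populated] ** 2)))
    rmse1 = float(np.sqrt(np.mean(err1[populated] ** 2)))
    inside = (truth_shifted[populated] >= summary.ci_low[populated]) & (
        truth_shifted[populated] <= summary.ci_high[populated]
    )
    return BenchmarkReport(
        spec=spec.to_dict(),
        truth_profile=[float(v) for v in truth_shifted],
        mean_profile=[float(v) for v in summary.mean_profile],
        ci_low=[float(v) for v in summary.ci_low],
        ci_high=[float(v) for v in summary.ci_high],
        round1_mean_profile=[float(v) for v in summary1.mean_profile],
        rmse=rmse,
        round1_rmse=rmse1,
        coverage=float(inside.mean()),
        populated_nodes=[int(m) for m in populated],
        max_r_hat=float(np.max(summary.r_hat)),
        mean_band_width=float(np.mean(summary.ci_high - summary.ci_low)),
        acceptance_rate=[float(a) for a in samples.acceptance_rate],
        runtime_s={
            "generate": t1 - t0,
            "likelihood": t2 - t1,
            "mcmc_and_summary": t3 - t2,
        },
    )


def histogram_profile(cv_values: np.ndarray, n_bins: int) -> np.ndarray:
    """Boltzmann free energies from a histogram of path-CV values.

    The number of bins equals the number of path nodes; empty bins get
    ``+inf`` free energy.  The profile is min-shifted.
    """
    counts, _ = np.histogram(np.asarray(cv_values, float), bins=n_bins, range=(0.0, 1.0))
    with np.errstate(divide="ignore"):
        g = -np.log(counts / counts.sum())
    return g - g[np.isfinite(g)].min()


def compare_3d_vs_images(
    ensemble,
    path: Path,
    stack: ParticleStack,
    lambda_cv: float = 50.0,
    mcmc_config: MCMCConfig | None = None,
    marginalization: MarginalizationConfig | None = None,
) -> dict:
    """Free-energy profile from 3D conformations vs from 2D particle images.

    The 3D route evaluates the RMSD path-CV for every ensemble member and
    histograms it (bins = nodes, Boltzmann inversion); the image route runs
    the full Bayesian inference on the particle stack over the same nodes.
    Both profiles are min-shifted for comparison.
    """
    cv_vals = np.array([path_cv_value(c, path, lambda_cv) for c in ensemble])
    g_hist = histogram_profile(cv_vals, path.n_nodes)
    llmat = compute_likelihood_matrix(stack, path, marginalization)
    samples = mcmc_sample(llmat, mcmc_config or MCMCConfig(n_chains=4, n_steps=20_000))
    summary = expected_profile(samples, s_values=path.s_values)
    return {
        "cv_values": cv_vals,
        "histogram_profile": g_hist,
        "bayesian_profile": summary.mean_profile,
        "summary": summary,
    }


BENCHMARKS: dict[str, BenchmarkSpec] = {
    "hsp90_1d_small": BenchmarkSpec(name="hsp90_1d_small"),
    "hsp90_1d_tiny": BenchmarkSpec(
        name="hsp90_1d_tiny",
        M=6,
        n_images=120,
        box_size=24,
        rotation_step_deg=15.0,
        marginalization=MarginalizationConfig(
            shift_extent_px=1,
            round1_grid_size=96,
            n_defocus_round1=3,
            round2_top_k=2,
            round2_local_size=8,
            n_defocus_round2=1,
        ),
        mcmc=MCMCConfig(n_chains=2, n_steps=4000),
    ),
    "hsp90_2d_cv1_small": BenchmarkSpec(
        name="hsp90_2d_cv1_small",
        ground_truth="hsp90_2d:CV1",
        M=10,
        n_beads=18,
        rotation_step_deg=7.0,
        n_images=600,
        box_size=32,
        marginalization=MarginalizationConfig(
            shift_extent_px=2,
            round1_shift_extent_px=0,
            round1_grid_size=384,
            n_defocus_round1=3,
            defocus_range_um=(0.5, 3.0),
            round2_top_k=8,
            round2_local_size=27,
            n_defocus_round2=3,
        ),
        mcmc=MCMCConfig(n_chains=4, n_steps=20_000, seed=1234, burn_in_fraction=0.1),
    ),
}


def get_benchmark(name: str, **overrides) -> BenchmarkSpec:
    if name not in BENCHMARKS:
        raise KeyError(f"unknown benchmark {name!r}; available: {sorted(BENCHMARKS)}")
    spec = BENCHMARKS[name]
    if overrides:
        from dataclasses import replace

        spec = replace(spec, **overrides)
    return spec
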