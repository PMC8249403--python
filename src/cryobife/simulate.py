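"""Forward model: synthetic cryo-EM particle images from path nodes.

Images are generated by (1) drawing a node index from the Boltzmann weights
of a ground-truth profile, (2) projecting the coarse-grained bead model under
a uniformly random SO(3) orientation, (3) applying a phase-contrast CTF in
Fourier space and (4) adding white Gaussian noise calibrated to a target SNR
measured against the signal variance inside a central circle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._quat import quat_to_matrix, random_quaternion
from .kernels import render_projection
from .path import Conformation, GroundTruthProfile, Path

__all__ = [
    "ImagingParams",
    "ParticleImage",
    "ParticleStack",
    "project",
    "ctf_2d",
    "apply_ctf",
    "noise_circle_radius",
    "add_noise",
    "sample_node_index",
    "generate_dataset",
]

#: electron wavelength in Angstroms at 300 keV accelerating voltage
ELECTRON_WAVELENGTH_A = 0.0197

DEFAULT_CTF_AMPLITUDE = 0.1
DEFAULT_B_FACTOR_A2 = 1.0


@dataclass(frozen=True)
class ImagingParams:
    """Per-particle imaging parameters.

    Units: ``defocus`` in micrometres, ``b_factor`` in A^2, ``pixel_size`` in
    A/px, ``in_plane_shift`` in pixels; ``snr`` is the dimensionless ratio of
    signal variance (central circle) to noise variance.
    """

    orientation: np.ndarray
    in_plane_shift: tuple[float, float] = (0.0, 0.0)
    defocus: float = 1.0
    ctf_amplitude: float = DEFAULT_CTF_AMPLITUDE
    b_factor: float = DEFAULT_B_FACTOR_A2
    pixel_size: float = 2.2
    box_size: int = 128
    snr: float = np.inf

    def __post_init__(self) -> None:
        q = np.asarray(self.orientation, dtype=float)
        if q.shape != (4,):
            raise ValueError("orientation must be a quaternion of shape (4,)")
        if abs(np.linalg.norm(q) - 1.0) > 1e-9:
            raise ValueError("orientation quaternion must have unit norm")
        if self.box_size < 16 or self.box_size % 2 != 0:
            raise ValueError("box_size must be even and at least 16")
        if self.defocus <= 0:
            raise ValueError("defocus must be positive")
        if not 0.0 <= self.ctf_amplitude <= 1.0:
            raise ValueError("ctf_amplitude must lie in [0, 1]")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        q = q.copy()
        q.flags.writeable = False
        object.__setattr__(self, "orientation", q)


@dataclass(frozen=True)
class ParticleImage:
    """A single boxed particle image plus its imaging metadata."""

    pixels: np.ndarray
    params: ImagingParams
    truth_node: int | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] != px.shape[1]:
            raise ValueError("pixels must form a square grid")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixels must be finite")
        object.__setattr__(self, "pixels", px)


@dataclass
class ParticleStack:
    """A set of particle images sharing box and pixel size, plus provenance."""

    images: list[ParticleImage]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.images:
            boxes = {im.pixels.shape[0] for im in self.images}
            pxs = {im.params.pixel_size for im in self.images}
            if len(boxes) != 1 or len(pxs) != 1:
                raise ValueError("all images in a stack must share box size and pixel size")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def box_size(self) -> int:
        return self.images[0].pixels.shape[0]

    @property
    def pixel_size(self) -> float:
        return self.images[0].params.pixel_size

    def pixel_array(self) -> np.ndarray:
        return np.stack([im.pixels for im in self.images])

    def metadata_frame(self) -> pd.DataFrame:
        """Per-particle metadata with RELION-style column names.

        Defocus is stored in Angstroms (``_rlnDefocusU``/``V``) as in RELION
        STAR files; simulator-truth columns are namespaced ``_cbife*``.
        """
        rows = []
        for im in self.images:
            p = im.params
            rows.append(
                {
                    "_rlnDefocusU": p.defocus * 1.0e4,
                    "_rlnDefocusV": p.defocus * 1.0e4,
                    "_rlnImagePixelSize": p.pixel_size,
                    "_cbifeSnr": p.snr,
                    "_cbifeTruthNode": -1 if im.truth_node is None else im.truth_node,
                    "_cbifeQuatW": p.orientation[0],
                    "_cbifeQuatX": p.orientation[1],
                    "_cbifeQuatY": p.orientation[2],
                    "_cbifeQuatZ": p.orientation[3],
                }
            )
        return pd.DataFrame(rows)


def project(
    conformation: Conformation,
    orientation: np.ndarray,
    shift: tuple[float, float] = (0.0, 0.0),
    pixel_size: float = 2.2,
    box_size: int = 128,
) -> np.ndarray:
    """Ideal (noise- and CTF-free) projection image of a bead model.

    The molecule is centered (electron-weighted centroid) at the box center,
    rotated by the unit quaternion, orthographically projected along the
    optical axis, and each bead is rendered as an integrable 2D Gaussian of
    standard deviation ``radius / 2`` scaled by its electron count.  Beads
    whose centers fall outside the box trigger a warning and are clipped.
    """
    q = np.asarray(orientation, dtype=float)
    if abs(np.linalg.norm(q) - 1.0) > 1e-9:
        raise ValueError("orientation quaternion must have unit norm")
    R = quat_to_matrix(q)
    sigma = conformation.bead_radii / 2.0
    out, clipped = render_projection(
        conformation.bead_positions,
        sigma,
        conformation.bead_electrons,
        R,
        pixel_size,
        box_size,
        shift=shift,
    )
    if clipped:
        warnings.warn(f"{clipped} bead center(s) fell outside the box and were clipped")
    return out


def ctf_2d(
    box_size: int,
    pixel_size: float,
    defocus_um: float,
    amplitude: float = DEFAULT_CTF_AMPLITUDE,
    b_factor: float = DEFAULT_B_FACTOR_A2,
) -> np.ndarray:
    """CTF sampled on the rfft2 frequency grid of a ``box_size`` image.

    ``CTF(k) = -[sqrt(1 - A^2) sin(pi lambda df k^2) + A cos(pi lambda df k^2)]
               * exp(-B k^2 / 4)``

    with spatial frequency ``k`` in 1/A, defocus ``df`` converted to A and
    the electron wavelength fixed at 0.0197 A (300 keV).  The same form is
    used by the simulator and the likelihood, which is what matters for
    internal consistency.
    """
    ky = np.fft.fftfreq(box_size, d=pixel_size)
    kx = np.fft.rfftfreq(box_size, d=pixel_size)
    k2 = ky[:, None] ** 2 + kx[None, :] ** 2
    gamma = np.pi * ELECTRON_WAVELENGTH_A * (defocus_um * 1.0e4) * k2
    env = np.exp(-b_factor * k2 / 4.0)
    return -(np.sqrt(1.0 - amplitude**2) * np.sin(gamma) + amplitude * np.cos(gamma)) * env


def apply_ctf(
    ideal: np.ndarray,
    defocus_um: float,
    ctf_amplitude: float = DEFAULT_CTF_AMPLITUDE,
    b_factor: float = DEFAULT_B_FACTOR_A2,
    pixel_size: float = 2.2,
) -> np.ndarray:
    """Apply the contrast transfer function to an ideal projection (linear op)."""
    ideal = np.asarray(ideal, dtype=float)
    if ideal.ndim != 2 or ideal.shape[0] != ideal.shape[1]:
        raise ValueError("image grid must be square")
    ctf = ctf_2d(ideal.shape[0], pixel_size, defocus_um, ctf_amplitude, b_factor)
    return np.fft.irfft2(np.fft.rfft2(ideal) * ctf, s=ideal.shape)


def noise_circle_radius(box_size: int) -> int:
    """Radius (px) of the central circle used to measure signal variance.

    40 px at box 128, scaled proportionally for other box sizes so the
    measured area fraction is box-size independent.
    """
    return int(round(box_size * 40.0 / 128.0))


def _circle_mask(box_size: int) -> np.ndarray:
    r = noise_circle_radius(box_size)
    c = box_size / 2.0
    yy, xx = np.mgrid[0:box_size, 0:box_size]
    return (yy - c) ** 2 + (xx - c) ** 2 <= r * r


def add_noise(image: np.ndarray, snr: float, rng_seed) -> np.ndarray:
    """Add white Gaussian noise with variance ``Var_circle(signal) / snr``.

    ``rng_seed`` may be an integer seed or a ``numpy.random.Generator``.
    Raises if the signal is constant inside the measurement circle (zero
    variance would make the SNR calibration undefined).
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    image = np.asarray(image, dtype=float)
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    var = float(image[_circle_mask(image.shape[0])].var())
    if var == 0.0:
        raise ValueError("signal variance inside the measurement circle is zero")
    if not np.isfinite(snr):
        return image.copy()
    sigma = np.sqrt(var / snr)
    return image + rng.normal(0.0, sigma, size=image.shape)


def sample_node_index(profile: GroundTruthProfile, rng_seed) -> int:
    """Draw a node index with Boltzmann probability ``exp(-G_m)/sum_k exp(-G_k)``."""
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    w = profile.boltzmann_weights()
    return int(rng.choice(len(w), p=w))


def generate_dataset(
    path: Path,
    profile: GroundTruthProfile,
    n_images: int,
    snr_range: tuple[float, float] = (0.001, 0.1),
    defocus_range_um: tuple[float, float] = (0.5, 3.0),
    seed: int = 0,
    pixel_size: float = 2.2,
    box_size: int = 128,
    ctf_amplitude: float = DEFAULT_CTF_AMPLITUDE,
    b_factor: float = DEFAULT_B_FACTOR_A2,
) -> ParticleStack:
    """Generate a synthetic particle stack from a path and a ground-truth profile.

    Per image: node ~ Boltzmann(profile), orientation uniform on SO(3), SNR
    log-uniform over ``snr_range``, defocus uniform over ``defocus_range_um``;
    the image is rendered as project -> apply_ctf -> add_noise.  Images carry
    zero in-plane shift (particles are centered); complete per-particle truth
    metadata is recorded.  Fully deterministic for a fixed seed.
    """
    if n_images < 1:
        raise ValueError("n_images must be at least 1")
    if len(profile.values) != path.n_nodes:
        raise ValueError("profile length must match the number of path nodes")
    if snr_range[0] <= 0 or snr_range[1] <= 0 or defocus_range_um[0] <= 0:
        raise ValueError("snr and defocus ranges must be positive")
    rng = np.random.default_rng(seed)
    weights = profile.boltzmann_weights()
    images: list[ParticleImage] = []
    log_lo, log_hi = np.log10(snr_range[0]), np.log10(snr_range[1])
    for _ in range(n_images):
        node = int(rng.choice(path.n_nodes, p=weights))
        quat = random_quaternion(rng)
        snr = 10.0 ** rng.uniform(log_lo, log_hi)
        defocus = rng.uniform(defocus_range_um[0], defocus_range_um[1])
        ideal = project(path.nodes[node], quat, pixel_size=pixel_size, box_size=box_size)
        convolved = apply_ctf(ideal, defocus, ctf_amplitude, b_factor, pixel_size)
        noisy = add_noise(convolved, snr, rng)
        params = ImagingParams(
            orientation=quat,
            defocus=defocus,
            ctf_amplitude=ctf_amplitude,
            b_factor=b_factor,
            pixel_size=pixel_size,
            box_size=box_size,
            snr=snr,
        )
        images.append(ParticleImage(pixels=noisy, params=params, truth_node=node))
    provenance = {
        "seed": int(seed),
        "n_images": int(n_images),
        "snr_range": [float(snr_range[0]), float(snr_range[1])],
        "defocus_range_um": [float(defocus_range_um[0]), float(defocus_range_um[1])],
        "pixel_size": float(pixel_size),
        "box_size": int(box_size),
        "ctf_amplitude": float(ctf_amplitude),
        "b_factor": float(b_factor),
        "profile_kind": profile.kind,
        "profile_values": [float(v) for v in profile.values],
    }
    return ParticleStack(images=images, provenance=provenance)
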