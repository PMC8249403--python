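"""Path collective variable: conformations, path nodes and ground-truth profiles.

A conformational path is an ordered sequence of coarse-grained bead models
(one bead per residue) discretizing a 1D collective variable ``s`` in
``[0, 1]`` at the equispaced nodes ``s_m = (m - 1) / (M - 1)``.  Free-energy
profiles ``G(s_m)`` are in units of kBT throughout (``beta = 1``); only
differences of ``G`` are physical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .residues import bead_parameters

__all__ = [
    "Conformation",
    "Path",
    "GroundTruthProfile",
    "make_path",
    "quadrature",
    "ground_truth_1d",
    "ground_truth_2d",
    "path_on_surface",
    "coarse_grain",
    "kabsch_rmsd",
    "path_cv_value",
    "select_nodes_by_metric",
]


def _readonly(a: np.ndarray) -> np.ndarray:
    a = np.ascontiguousarray(a, dtype=np.float64)
    a.flags.writeable = False
    return a


@dataclass(frozen=True)
class Conformation:
    """Residue-level coarse-grained bead model of one 3D conformation.

    Attributes
    ----------
    bead_positions
        ``(B, 3)`` coordinates in Angstroms.
    bead_radii
        Per-bead effective radius in Angstroms (> 0).
    bead_electrons
        Per-bead electron count (> 0, dimensionless).
    label
        Free-text identifier.
    """

    bead_positions: np.ndarray
    bead_radii: np.ndarray
    bead_electrons: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.bead_positions, dtype=float))
        radii = np.atleast_1d(np.asarray(self.bead_radii, dtype=float))
        elec = np.atleast_1d(np.asarray(self.bead_electrons, dtype=float))
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("bead_positions must have shape (B, 3)")
        if pos.shape[0] < 1:
            raise ValueError("a conformation needs at least one bead")
        if radii.shape[0] != pos.shape[0] or elec.shape[0] != pos.shape[0]:
            raise ValueError("bead_positions, bead_radii and bead_electrons must agree in length")
        if not np.all(np.isfinite(pos)):
            raise ValueError("bead positions must be finite")
        if np.any(radii <= 0):
            raise ValueError("bead radii must be positive")
        if np.any(elec <= 0):
            raise ValueError("bead electron counts must be positive")
        object.__setattr__(self, "bead_positions", _readonly(pos))
        object.__setattr__(self, "bead_radii", _readonly(radii))
        object.__setattr__(self, "bead_electrons", _readonly(elec))

    @property
    def n_beads(self) -> int:
        return self.bead_positions.shape[0]

    def center_of_mass(self) -> np.ndarray:
        """Electron-weighted centroid (electrons stand in for mass)."""
        w = self.bead_electrons
        return (self.bead_positions * w[:, None]).sum(axis=0) / w.sum()


@dataclass(frozen=True)
class Path:
    """Ordered path nodes ``x_1 .. x_M`` with parameters ``s_m = (m-1)/(M-1)``."""

    nodes: tuple[Conformation, ...]
    s_values: np.ndarray

    def __post_init__(self) -> None:
        nodes = tuple(self.nodes)
        if len(nodes) < 2:
            raise ValueError("a path needs at least two nodes")
        counts = {c.n_beads for c in nodes}
        if len(counts) != 1:
            raise ValueError("all path nodes must have the same bead count")
        s = np.asarray(self.s_values, dtype=float)
        expected = np.arange(len(nodes)) / (len(nodes) - 1)
        if s.shape != expected.shape or not np.array_equal(s, expected):
            raise ValueError("s_values must be exactly (m-1)/(M-1)")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "s_values", _readonly(s))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_beads(self) -> int:
        return self.nodes[0].n_beads


def make_path(conformations: Sequence[Conformation]) -> Path:
    """Assemble ordered conformations into a discretized path.

    Node ``m`` (1-based) receives parameter ``s_m = (m - 1) / (M - 1)``, so
    the endpoints sit at ``s = 0`` and ``s = 1``.
    """
    conformations = list(conformations)
    if len(conformations) < 2:
        raise ValueError("a path needs at least two conformations")
    s = np.arange(len(conformations)) / (len(conformations) - 1)
    return Path(nodes=tuple(conformations), s_values=s)


@dataclass(frozen=True)
class GroundTruthProfile:
    """Known free-energy values at the path nodes, used by the simulator.

    ``kind`` records provenance (analytic 1D/2D benchmark formula or a
    tabulated vector); ``values`` are ``G(s_m)`` in kBT with ``beta`` fixed
    at 1.  Only differences of ``values`` matter (gauge freedom).
    """

    kind: str
    values: np.ndarray
    beta: float = 1.0

    def __post_init__(self) -> None:
        v = np.atleast_1d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(v)):
            raise ValueError("ground-truth free energies must be finite")
        object.__setattr__(self, "values", _readonly(v))

    @classmethod
    def hsp90_1d(cls, s_values: np.ndarray) -> "GroundTruthProfile":
        return cls(kind="hsp90_1d", values=ground_truth_1d(np.asarray(s_values)))

    @classmethod
    def hsp90_2d_along_path(cls, uv_points: np.ndarray) -> "GroundTruthProfile":
        uv = np.asarray(uv_points, dtype=float)
        return cls(kind="hsp90_2d_along_path", values=ground_truth_2d(uv[:, 0], uv[:, 1]))

    @classmethod
    def tabulated(cls, values: np.ndarray) -> "GroundTruthProfile":
        return cls(kind="tabulated", values=np.asarray(values, dtype=float))

    def boltzmann_weights(self) -> np.ndarray:
        """Normalized node populations ``exp(-beta G_m) / sum_k exp(-beta G_k)``."""
        g = self.beta * self.values
        w = np.exp(-(g - g.min()))
        return w / w.sum()


def quadrature(node_values: Iterable[float]) -> float:
    """Equispaced M-node quadrature ``(1/M) sum_m f(s_m)`` for the unit interval.

    This is the path-integral discretization rule used throughout the
    inference (a plain node average, deliberately not a trapezoid rule).
    """
    v = np.atleast_1d(np.asarray(list(node_values) if not isinstance(node_values, np.ndarray) else node_values, dtype=float))
    if v.size == 0:
        raise ValueError("quadrature needs at least one node value")
    return float(v.mean())


def ground_truth_1d(s):
    """Benchmark 1D free-energy profile in kBT (double-well along ``s``).

    Defined through its Boltzmann density
    ``exp(-G(s)) = exp(-(19 s - 6)^2 / 8) + exp(-(19 s - 15)^2 / 18) / 3``
    with ``beta = 1``; the deeper basin sits near ``s = 6/19`` and a shallower
    one near ``s = 15/19``.
    """
    s = np.asarray(s, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("s must lie in [0, 1]")
    t = 19.0 * s
    dens = np.exp(-((t - 6.0) ** 2) / 8.0) + np.exp(-((t - 15.0) ** 2) / 18.0) / 3.0
    out = -np.log(dens)
    return float(out) if out.ndim == 0 else out


def ground_truth_2d(u, v):
    """Benchmark 2D free-energy surface in kBT over model indices ``(u, v)``.

    ``exp(-G(u, v)) = exp(-(u-6)^2/18 - (v-6)^2/10)
                    + exp(-(u-15)^2/18 - (v-15)^2/10)``:
    two Gaussian basins at (6, 6) and (15, 15) separated by a barrier of
    about 2 kBT along the diagonal.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    dens = np.exp(-((u - 6.0) ** 2) / 18.0 - ((v - 6.0) ** 2) / 10.0) + np.exp(
        -((u - 15.0) ** 2) / 18.0 - ((v - 15.0) ** 2) / 10.0
    )
    out = -np.log(dens)
    return float(out) if out.ndim == 0 else out


_GRID_LO, _GRID_HI = 1.0, 20.0  # model-index range of the 20x20 conformer grid


def path_on_surface(cv_id: str, M: int) -> np.ndarray:
    """(u, v) node coordinates for the named straight-line path on the 2D surface.

    ``CV1`` runs along the diagonal u = v (through both basins and the
    transition state); ``CV2`` fixes u = 10 and varies v; ``CV3`` varies u
    with v = 10 fixed.  Returns an ``(M, 2)`` array of equispaced points
    spanning the 20x20 model grid.
    """
    if M < 2:
        raise ValueError("M must be at least 2")
    t = np.linspace(_GRID_LO, _GRID_HI, M)
    mid = np.full(M, 10.0)
    if cv_id == "CV1":
        return np.column_stack([t, t])
    if cv_id == "CV2":
        return np.column_stack([mid, t])
    if cv_id == "CV3":
        return np.column_stack([t, mid])
    raise ValueError(f"unknown cv_id {cv_id!r}; expected CV1, CV2 or CV3")


def coarse_grain(atomic_structure, label: str | None = None) -> Conformation:
    """One bead per residue at the residue's center of mass.

    Parameters
    ----------
    atomic_structure
        A ``gemmi.Structure`` or a filesystem path to a PDB file.  All chains
        of the first model are used.
    label
        Optional label; defaults to the structure name.

    Bead radius and electron count come from the shipped per-residue table;
    residues that are not tabulated (ligands, waters, ...) raise rather than
    being silently dropped.
    """
    import gemmi

    if not isinstance(atomic_structure, gemmi.Structure):
        atomic_structure = gemmi.read_structure(str(atomic_structure))
    if len(atomic_structure) == 0:
        raise ValueError("structure has no models")
    model = atomic_structure[0]
    positions, radii, electrons = [], [], []
    for chain in model:
        for residue in chain:
            radius, count = bead_parameters(residue.name)
            coords = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in residue], dtype=float)
            if coords.size == 0:
                raise ValueError(f"residue {residue.name} has no atoms")
            weights = np.array([a.element.weight for a in residue], dtype=float)
            com = (coords * weights[:, None]).sum(axis=0) / weights.sum()
            positions.append(com)
            radii.append(radius)
            electrons.append(count)
    if not positions:
        raise ValueError("structure has no residues")
    return Conformation(
        bead_positions=np.array(positions),
        bead_radii=np.array(radii),
        bead_electrons=np.array(electrons),
        label=label if label is not None else atomic_structure.name,
    )


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD between two ``(B, 3)`` coordinate sets after optimal superposition.

    Both sets are centered and ``b`` is rotated onto ``a`` with the Kabsch
    (SVD) algorithm before computing the RMSD.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("coordinate sets must have the same shape")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    H = bc.T @ ac
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    diff = ac - bc @ R
    return float(np.sqrt((diff**2).sum() / a.shape[0]))


def path_cv_value(conformation: Conformation, path: Path, lambda_cv: float = 50.0) -> float:
    """Progress variable of a conformation along the path, in [0, 1].

    Softmax-weighted node index based on RMSD distances ``d_m`` to every node
    (computed after Kabsch superposition):

    ``s(x) = [sum_m (m - 1) exp(-lambda d_m^2)]
             / [(M - 1) sum_m exp(-lambda d_m^2)]``

    with ``lambda`` in 1/A^2 (default 50, a common choice when RMSD gaps
    between neighbouring nodes are of order 0.1-1 A).  In the large-lambda
    limit this returns the parameter of the nearest node.
    """
    if lambda_cv <= 0:
        raise ValueError("lambda_cv must be positive")
    if conformation.n_beads != path.n_beads:
        raise ValueError("conformation and path bead counts differ")
    d2 = np.array(
        [kabsch_rmsd(conformation.bead_positions, node.bead_positions) ** 2 for node in path.nodes]
    )
    logw = -lambda_cv * d2
    logw -= logw.max()  # stabilize the softmax
    w = np.exp(logw)
    m_idx = np.arange(path.n_nodes, dtype=float)
    return float((m_idx * w).sum() / ((path.n_nodes - 1) * w.sum()))


def select_nodes_by_metric(
    ensemble: Sequence[Conformation], metric: Sequence[float], M: int
) -> Path:
    """Pick M ensemble members whose metric values are closest to equispaced targets.

    Targets span the observed metric range; each target greedily claims the
    nearest not-yet-chosen member.  Typical use: build a path with equally
    spaced end-to-end distances between successive nodes.
    """
    ensemble = list(ensemble)
    metric = np.asarray(metric, dtype=float)
    if metric.shape[0] != len(ensemble):
        raise ValueError("metric length must match ensemble size")
    if not np.all(np.isfinite(metric)):
        raise ValueError("metric values must be finite")
    if len(ensemble) < M:
        raise ValueError("ensemble smaller than the requested number of nodes")
    targets = np.linspace(metric.min(), metric.max(), M)
    chosen: list[int] = []
    available = np.ones(len(ensemble), dtype=bool)
    for t in targets:
        dist = np.abs(metric - t)
        dist[~available] = np.inf
        k = int(np.argmin(dist))
        available[k] = False
        chosen.append(k)
    return make_path([ensemble[k] for k in chosen])
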