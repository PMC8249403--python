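"""Path collective variable: nodes, quadrature, ground truths, coarse-graining."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cryobife.path import (
    Conformation,
    ground_truth_1d,
    ground_truth_2d,
    kabsch_rmsd,
    make_path,
    path_cv_value,
    path_on_surface,
    quadrature,
    select_nodes_by_metric,
)
from cryobife.residues import RESIDUE_ELECTRONS, UnknownResidueError, bead_parameters


def _beads(n, offset=0.0, scale=1.0):
    pos = np.arange(3 * n, dtype=float).reshape(n, 3) * scale + offset
    return Conformation(pos, np.full(n, 2.0), np.full(n, 10.0))


class TestMakePath:
    def test_two_nodes_span_unit_interval(self):
        p = make_path([_beads(3), _beads(3, offset=1.0)])
        assert np.array_equal(p.s_values, [0.0, 1.0])

    def test_twenty_equispaced_nodes(self):
        p = make_path([_beads(4, offset=m) for m in range(20)])
        assert np.array_equal(p.s_values, np.arange(20) / 19.0)

    def test_mismatched_bead_counts_rejected(self):
        with pytest.raises(ValueError, match="bead count"):
            make_path([_beads(3), _beads(4), _beads(3)])

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            make_path([_beads(3)])


class TestQuadrature:
    def test_exact_for_constants(self):
        assert quadrature(np.full(7, 3.25)) == pytest.approx(3.25)

    @pytest.mark.parametrize("M", [2, 3, 10, 50])
    def test_linear_function_integrates_to_half(self, M):
        s = np.arange(M) / (M - 1)
        assert quadrature(s) == pytest.approx(0.5)

    def test_quadratic_three_nodes(self):
        # nodes 0, 0.5, 1 -> (0 + 0.25 + 1)/3
        assert quadrature(np.array([0.0, 0.5, 1.0]) ** 2) == pytest.approx(1.25 / 3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            quadrature([])

    @given(
        vals=st.lists(st.floats(-50, 50), min_size=2, max_size=12),
        a=st.floats(-3, 3),
        b=st.floats(-3, 3),
    )
    @settings(max_examples=50, deadline=None)
    def test_linearity(self, vals, a, b):
        v = np.asarray(vals)
        lhs = quadrature(a * v + b)
        assert lhs == pytest.approx(a * quadrature(v) + b, abs=1e-9)


class TestGroundTruthFormulas:
    @pytest.mark.parametrize(
        "s, expected",
        [
            (6 / 19, -np.log(1 + np.exp(-4.5) / 3)),
            (15 / 19, -np.log(np.exp(-81 / 8) + 1 / 3)),
            (0.0, -np.log(np.exp(-4.5) + np.exp(-12.5) / 3)),
        ],
    )
    def test_1d_printed_values(self, s, expected):
        assert ground_truth_1d(s) == pytest.approx(expected, rel=1e-12)

    def test_1d_outside_domain_rejected(self):
        with pytest.raises(ValueError):
            ground_truth_1d(1.5)

    def test_2d_basin_depth_near_zero(self):
        assert ground_truth_2d(6.0, 6.0) == pytest.approx(-np.log(1 + np.exp(-12.6)))
        assert abs(ground_truth_2d(6.0, 6.0)) < 1e-5

    def test_2d_basins_symmetric(self):
        assert ground_truth_2d(15.0, 15.0) == pytest.approx(ground_truth_2d(6.0, 6.0))

    def test_2d_diagonal_barrier(self):
        assert ground_truth_2d(10.5, 10.5) == pytest.approx(3.15 - np.log(2), rel=1e-12)

    @given(s=st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_1d_matches_density_definition(self, s):
        dens = np.exp(-((19 * s - 6) ** 2) / 8) + np.exp(-((19 * s - 15) ** 2) / 18) / 3
        assert ground_truth_1d(s) == pytest.approx(-np.log(dens), rel=1e-12)


class TestPathOnSurface:
    def test_cv1_is_diagonal(self):
        uv = path_on_surface("CV1", 20)
        assert np.allclose(uv[:, 0], uv[:, 1])
        assert uv[0, 0] == 1.0 and uv[-1, 0] == 20.0

    def test_cv2_fixes_u(self):
        uv = path_on_surface("CV2", 20)
        assert np.all(uv[:, 0] == 10.0)
        assert np.all(np.diff(uv[:, 1]) > 0)

    def test_cv3_fixes_v(self):
        uv = path_on_surface("CV3", 7)
        assert np.all(uv[:, 1] == 10.0)

    def test_cv1_two_nodes_are_endpoints(self):
        uv = path_on_surface("CV1", 2)
        assert np.allclose(uv, [[1.0, 1.0], [20.0, 20.0]])

    def test_unknown_cv_rejected(self):
        with pytest.raises(ValueError, match="cv_id"):
            path_on_surface("CV9", 5)


_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       1.300   2.400   0.000  1.00  0.00           O
ATOM      5  N   ALA A   2       3.300   1.500   0.000  1.00  0.00           N
ATOM      6  CA  ALA A   2       4.000   2.800   0.000  1.00  0.00           C
ATOM      7  CB  ALA A   2       5.500   2.600   0.100  1.00  0.00           C
ATOM      8  C   ALA A   2       3.600   3.700   1.200  1.00  0.00           C
ATOM      9  O   ALA A   2       3.300   3.200   2.300  1.00  0.00           O
END
"""

_PDB_LIGAND = _PDB.replace(
    "END\n",
    "HETATM   10 MG    MG A   3       9.000   9.000   9.000  1.00  0.00          MG\nEND\n",
)


class TestCoarseGrain:
    def test_one_bead_per_residue(self, tmp_path):
        import gemmi

        from cryobife.path import coarse_grain

        pdb = tmp_path / "toy.pdb"
        pdb.write_text(_PDB)
        conf = coarse_grain(pdb)
        assert conf.n_beads == 2
        assert conf.bead_electrons[0] == RESIDUE_ELECTRONS["GLY"]
        assert conf.bead_electrons[1] == RESIDUE_ELECTRONS["ALA"]
        # glycine bead sits at the mass-weighted center of its four atoms
        st = gemmi.read_structure(str(pdb))
        res = st[0][0][0]
        coords = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in res])
        weights = np.array([a.element.weight for a in res])
        com = (coords * weights[:, None]).sum(0) / weights.sum()
        assert np.allclose(conf.bead_positions[0], com)

    def test_unknown_residue_is_an_error(self, tmp_path):
        from cryobife.path import coarse_grain

        pdb = tmp_path / "lig.pdb"
        pdb.write_text(_PDB_LIGAND)
        with pytest.raises(UnknownResidueError):
            coarse_grain(pdb)

    def test_electron_counts_match_atomic_composition(self):
        # independent recomputation from residue formulas (C=6, H=1, N=7, O=8, S=16)
        formulas = {"GLY": (2, 3, 1, 1, 0), "TRP": (11, 10, 2, 1, 0), "MET": (5, 9, 1, 1, 1)}
        for name, (c, h, n, o, s) in formulas.items():
            expected = 6 * c + h + 7 * n + 8 * o + 16 * s
            _, electrons = bead_parameters(name)
            assert electrons == expected


def _random_rotation(rng):
    from cryobife._quat import quat_to_matrix, random_quaternion

    return quat_to_matrix(random_quaternion(rng))


class TestPathCV:
    def _path(self, M=5):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(6, 3)) * 4.0
        nodes = []
        for m in range(M):
            pos = base.copy()
            pos[3:] += np.array([1.5 * m, 0.0, 0.0])  # well-separated nodes
            nodes.append(Conformation(pos, np.full(6, 2.0), np.full(6, 10.0)))
        return make_path(nodes)

    def test_node_conformation_maps_to_node_parameter(self):
        path = self._path()
        for k in range(path.n_nodes):
            s = path_cv_value(path.nodes[k], path, lambda_cv=500.0)
            assert s == pytest.approx(k / (path.n_nodes - 1), abs=1e-6)

    def test_equidistant_between_two_nodes(self):
        # collinear query on the x-axis; the two nodes displace one bead by
        # +/- the same amount in y, so a 180-degree rotation about x maps one
        # node onto the other while fixing the query: the two RMSDs are equal
        # by symmetry and the progress variable must sit exactly halfway
        base = np.column_stack([np.arange(6.0), np.zeros(6), np.zeros(6)])
        up, down = base.copy(), base.copy()
        up[5, 1] += 2.0
        down[5, 1] -= 2.0
        mk = lambda p: Conformation(p, np.full(6, 2.0), np.full(6, 10.0))
        path = make_path([mk(up), mk(down)])
        assert path_cv_value(mk(base), path) == pytest.approx(0.5, abs=1e-9)

    def test_default_lambda_is_50_per_A2(self):
        import inspect

        assert inspect.signature(path_cv_value).parameters["lambda_cv"].default == 50.0

    def test_rigid_body_invariance(self, rng):
        path = self._path()
        query = path.nodes[2]
        s0 = path_cv_value(query, path)
        for _ in range(5):
            R = _random_rotation(rng)
            t = rng.normal(size=3) * 20
            moved = Conformation(
                query.bead_positions @ R.T + t, query.bead_radii, query.bead_electrons
            )
            assert path_cv_value(moved, path) == pytest.approx(s0, abs=1e-8)

    def test_kabsch_rmsd_zero_on_self(self, rng):
        x = rng.normal(size=(8, 3))
        R = _random_rotation(rng)
        assert kabsch_rmsd(x, x @ R.T + 5.0) == pytest.approx(0.0, abs=1e-9)


class TestSelectNodes:
    def test_exact_targets_select_exact_members(self):
        ensemble = [_beads(3, offset=float(k)) for k in range(10)]
        metric = np.arange(10.0)
        path = select_nodes_by_metric(ensemble, metric, 10)
        for node, k in zip(path.nodes, range(10)):
            assert np.allclose(node.bead_positions, ensemble[k].bead_positions)

    def test_matches_exhaustive_nearest_search(self, rng):
        metric = np.sort(rng.uniform(0, 30, size=40))
        ensemble = [_beads(3, offset=float(v)) for v in metric]
        M = 7
        path = select_nodes_by_metric(ensemble, metric, M)
        targets = np.linspace(metric.min(), metric.max(), M)
        chosen_metric = np.array([n.bead_positions[0, 0] for n in path.nodes])
        for t, c in zip(targets, chosen_metric):
            # no other member is strictly closer to this target
            assert np.min(np.abs(metric - t)) == pytest.approx(abs(c - t))

    def test_chosen_metric_monotone_along_s(self, rng):
        metric = rng.uniform(0, 10, size=30)
        ensemble = [_beads(3, offset=float(v)) for v in metric]
        path = select_nodes_by_metric(ensemble, metric, 6)
        vals = [n.bead_positions[0, 0] for n in path.nodes]
        assert np.all(np.diff(vals) >= 0)

    def test_small_ensemble_rejected(self):
        with pytest.raises(ValueError, match="smaller"):
            select_nodes_by_metric([_beads(3)], [0.0], 3)
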