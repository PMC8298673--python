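"""Distance-geometry solver, superposition, hydrogen placement."""

import numpy as np
import pytest

from graph2struct import (
    InputError,
    embed_distances,
    frac_to_cartesian,
    kabsch_superpose,
    parse_smiles,
)
from graph2struct.fixtures import build_ideal_geometry
from graph2struct.geometry import (
    place_hydrogens,
    select_hydrogen_anchors,
    sphere_grid,
    through_bond_anchors,
)
from graph2struct.graphs import CrystalRecord
from graph2struct.representations import bond_length_matrix


def _distance_matrix(points):
    return np.linalg.norm(points[:, None] - points[None, :], axis=-1)


class TestEmbedDistances:
    def test_unit_square(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]])
        d = _distance_matrix(pts)
        res = embed_distances(d)
        assert np.allclose(_distance_matrix(res.coordinates), d, atol=1e-8)
        assert res.converged

    def test_exact_recovery_random_points(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(4, 10)
            pts = rng.normal(size=(n, 3))
            res = embed_distances(_distance_matrix(pts))
            rep = kabsch_superpose(res.coordinates, pts, allow_reflection=True)
            assert rep.rmsd < 1e-6

    def test_noisy_distances_bounded_stress(self):
        """1% multiplicative noise on a rigid cube: stress stays at the
        noise scale and coordinates stay within 0.1 A RMSD."""
        pts = np.array(
            [[i, j, k] for i in (0.0, 1.5) for j in (0.0, 1.5) for k in (0.0, 1.5)]
        )
        d = _distance_matrix(pts)
        rng = np.random.default_rng(42)
        noise = 1.0 + 0.01 * rng.standard_normal(d.shape)
        noise = (noise + noise.T) / 2
        dn = d * noise
        np.fill_diagonal(dn, 0.0)
        res = embed_distances(dn)
        rep = kabsch_superpose(res.coordinates, pts, allow_reflection=True)
        assert rep.rmsd < 0.1
        # residual cannot exceed the total injected perturbation
        injected = ((dn - d)[np.triu_indices(8, k=1)] ** 2).sum()
        assert res.stress <= injected + 1e-12

    def test_stress_monotone_over_iterations(self):
        pts = np.random.default_rng(7).normal(size=(7, 3))
        d = _distance_matrix(pts) * 1.02  # inconsistent -> real iterations
        np.fill_diagonal(d, 0)
        d = (d + d.T) / 2
        res = embed_distances(d)
        hist = np.array(res.stress_history)
        assert np.all(np.diff(hist) <= 1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(InputError):
            embed_distances(np.zeros((2, 2)))
        bad = np.ones((4, 4))
        np.fill_diagonal(bad, 0)
        bad[0, 1] = 2.0  # asymmetric
        with pytest.raises(InputError, match="symmetric"):
            embed_distances(bad)
        neg = _distance_matrix(np.random.default_rng(1).normal(size=(4, 3)))
        neg[0, 1] = neg[1, 0] = -1.0
        with pytest.raises(InputError, match="positive"):
            embed_distances(neg)


class TestKabsch:
    @staticmethod
    def _rigid(points, seed):
        rng = np.random.default_rng(seed)
        a, b, c = rng.uniform(0, 2 * np.pi, 3)
        rz = np.array(
            [[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]]
        )
        ry = np.array(
            [[np.cos(b), 0, np.sin(b)], [0, 1, 0], [-np.sin(b), 0, np.cos(b)]]
        )
        rx = np.array(
            [[1, 0, 0], [0, np.cos(c), -np.sin(c)], [0, np.sin(c), np.cos(c)]]
        )
        return points @ (rz @ ry @ rx).T + rng.normal(size=3)

    def test_rigid_motion_rmsd_zero(self):
        rng = np.random.default_rng(3)
        for seed in range(20):
            p = rng.normal(size=(6, 3))
            q = self._rigid(p, seed)
            assert kabsch_superpose(p, q).rmsd < 1e-10

    def test_mirror_detection(self):
        p = np.random.default_rng(4).normal(size=(5, 3))
        q = p.copy()
        q[:, 0] *= -1
        no_ref = kabsch_superpose(p, q, allow_reflection=False)
        with_ref = kabsch_superpose(p, q, allow_reflection=True)
        assert no_ref.rmsd > 0.1
        assert with_ref.rmsd < 1e-10
        assert with_ref.reflection_used

    def test_reflection_never_hurts(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = rng.normal(size=(6, 3))
            q = rng.normal(size=(6, 3))
            a = kabsch_superpose(p, q, allow_reflection=False).rmsd
            b = kabsch_superpose(p, q, allow_reflection=True).rmsd
            assert b <= a + 1e-12

    def test_matches_brute_force_rotation_grid(self):
        """Hand-built 4-point case: the Kabsch optimum agrees with an
        exhaustive scan over discretized rotations."""
        from scipy.spatial.transform import Rotation

        p = np.array([[0.0, 0, 0], [1.4, 0, 0], [0.7, 1.1, 0], [0.4, 0.3, 1.2]])
        q = self._rigid(p, seed=11) + 0.05 * np.random.default_rng(12).normal(
            size=p.shape
        )
        report = kabsch_superpose(p, q)
        pc = p - p.mean(axis=0)
        qc = q - q.mean(axis=0)
        def rmsd_of(euler):
            r = Rotation.from_euler("zyx", euler).as_matrix()
            return np.sqrt(np.mean(np.sum((pc @ r.T - qc) ** 2, axis=1)))

        grid = np.linspace(0, 2 * np.pi, 24, endpoint=False)
        eulers = np.array(np.meshgrid(grid, grid, grid[:12])).reshape(3, -1).T
        vals = [rmsd_of(e) for e in eulers]
        start = eulers[int(np.argmin(vals))]
        from scipy.optimize import minimize as _min

        best = _min(rmsd_of, start, method="Nelder-Mead", options={"xatol": 1e-8}).fun
        assert report.rmsd <= best + 1e-9
        assert abs(report.rmsd - best) < 1e-3

    def test_rotation_is_orthogonal_det_pm1(self):
        p = np.random.default_rng(6).normal(size=(5, 3))
        q = np.random.default_rng(7).normal(size=(5, 3))
        for allow in (False, True):
            rep = kabsch_superpose(p, q, allow_reflection=allow)
            assert np.allclose(rep.rotation @ rep.rotation.T, np.eye(3), atol=1e-10)
            assert abs(abs(np.linalg.det(rep.rotation)) - 1) < 1e-10


class TestSphereGrid:
    def test_unit_norm_and_determinism(self):
        g1 = sphere_grid(512)
        g2 = sphere_grid(512)
        assert g1.shape == (512, 3)
        assert np.allclose(np.linalg.norm(g1, axis=1), 1.0)
        assert np.array_equal(g1, g2)

    def test_reasonable_coverage(self):
        g = sphere_grid(1024)
        # nearest-neighbour spacing should be tight and uniform-ish
        d = np.linalg.norm(g[:, None] - g[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        nn = d.min(axis=1)
        assert nn.max() < 0.2


class TestHydrogenPlacement:
    def test_exact_anchor_distances_recover_position(self, family_small, radii):
        """With exact anchor distances from a fixture geometry, each
        hydrogen lands within grid resolution of its true position."""
        g, geom = family_small[1]
        heavy = list(g.heavy_indices)
        scaffold = geom.coordinates[heavy]
        l_mat = bond_length_matrix(g, radii)
        anchor_sets, dists, true_pos = [], [], []
        for h, bonded in sorted(g.hydrogen_attachments.items()):
            b = heavy.index(bonded)
            anchors = through_bond_anchors(l_mat[b], scaffold, b)
            anchor_sets.append(anchors)
            dists.append(
                [np.linalg.norm(geom.coordinates[h] - scaffold[a]) for a in anchors]
            )
            true_pos.append(geom.coordinates[h])
        placed = place_hydrogens(scaffold, anchor_sets, np.array(dists), grid_size=8192)
        errs = np.linalg.norm(placed - np.array(true_pos), axis=1)
        assert np.median(errs) < 0.05

    def test_radius_honored_exactly(self):
        scaffold = np.array([[0.0, 0, 0], [1.5, 0, 0], [0, 1.5, 0], [0, 0, 1.5]])
        anchors = [[0, 1, 2, 3]]
        d = np.array([[1.09, 2.1, 2.1, 2.1]])
        placed = place_hydrogens(scaffold, anchors, d, grid_size=256)
        r = np.linalg.norm(placed[0] - scaffold[0])
        assert r == pytest.approx(1.09, abs=1e-12)

    def test_clash_penalty_separates_geminal_pair(self):
        scaffold = np.array([[0.0, 0, 0], [1.5, 0, 0], [3.0, 0.4, 0], [1.4, 1.4, 0.1]])
        anchors = [[0, 1, 2, 3], [0, 1, 2, 3]]
        d = np.array([[1.09, 2.1, 3.6, 2.2], [1.09, 2.1, 3.6, 2.2]])
        placed = place_hydrogens(scaffold, anchors, d, grid_size=2048)
        gap = np.linalg.norm(placed[0] - placed[1])
        assert gap > 0.8  # identical targets, but the pair does not collapse


class TestAnchors:
    def test_nearest_anchor_selection_matches_brute_force(self, family_small):
        g, geom = family_small[2]
        heavy = list(g.heavy_indices)
        infos = select_hydrogen_anchors(g, geom)
        for info in infos:
            h = info["hydrogen"]
            d_h = np.linalg.norm(geom.coordinates[heavy] - geom.coordinates[h], axis=1)
            bonded_pos = heavy.index(g.hydrogen_attachments[h])
            assert info["anchors"][0] == bonded_pos
            chosen = set(info["anchors"])
            assert bonded_pos in chosen
            assert len(chosen) == 4
            # anchors are drawn from the nearest heavies unless the
            # coplanarity swap advanced past one of them
            nearest4 = set(int(i) for i in np.argsort(d_h)[:4])
            extra = chosen - nearest4
            assert len(extra) <= 1

    def test_bonded_atom_always_first_with_its_distance(self, family_small):
        g, geom = family_small[2]
        heavy = list(g.heavy_indices)
        for info in select_hydrogen_anchors(g, geom):
            h = info["hydrogen"]
            b = info["anchors"][0]
            d = np.linalg.norm(geom.coordinates[h] - geom.coordinates[heavy[b]])
            assert info["distances"][0] == pytest.approx(d)
            assert info["distances"][0] < 1.3  # a bond, not a contact

    def test_collinear_chain_flags_coplanar(self):
        """A 4-heavy all-anti chain has a planar backbone: no non-coplanar
        quadruple exists, so the record is flagged, not rejected."""
        g = parse_smiles("CCCC")
        geom = build_ideal_geometry(g)
        infos = select_hydrogen_anchors(g, geom)
        assert any(info["coplanar_flag"] for info in infos)

    def test_through_bond_anchors_stable_under_jitter(self, family_small, radii):
        g, geom = family_small[3]
        heavy = list(g.heavy_indices)
        scaffold = geom.coordinates[heavy]
        l_mat = bond_length_matrix(g, radii)
        rng = np.random.default_rng(0)
        for b in range(len(heavy)):
            base = through_bond_anchors(l_mat[b], scaffold, b)
            jittered = through_bond_anchors(
                l_mat[b], scaffold + 1e-9 * rng.normal(size=scaffold.shape), b
            )
            assert base == jittered

    def test_anchor_order_independent_of_atom_order(self, family_small, radii):
        g, geom = family_small[4]
        perm = np.random.default_rng(1).permutation(g.n_atoms)
        gp, geop = g.permuted(perm), geom.permuted(perm)
        a = {
            tuple(np.round(info["distances"], 8)): info["coplanar_flag"]
            for info in select_hydrogen_anchors(g, geom)
        }
        b = {
            tuple(np.round(info["distances"], 8)): info["coplanar_flag"]
            for info in select_hydrogen_anchors(gp, geop)
        }
        assert a == b


class TestFracToCartesian:
    def test_identity_at_unit_cell(self):
        c = CrystalRecord(("Al", "Na", "K", "F"), 1.0, np.array([[0.3, 0.4, 0.5]]))
        assert np.allclose(frac_to_cartesian(c), [[0.3, 0.4, 0.5]])

    def test_body_center_scales(self):
        c = CrystalRecord(("Al", "Na", "K", "F"), 8.0, np.array([[0.5, 0.5, 0.5]]))
        assert np.allclose(frac_to_cartesian(c), [[4.0, 4.0, 4.0]])

    def test_distances_linear_in_lattice_constant(self, crystals):
        rec = crystals[0]
        small = CrystalRecord(rec.site_elements, 1.0, rec.fractional_coords)
        big = CrystalRecord(rec.site_elements, 7.5, rec.fractional_coords)
        ds = _distance_matrix(frac_to_cartesian(small))
        db = _distance_matrix(frac_to_cartesian(big))
        assert np.allclose(db, 7.5 * ds)
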