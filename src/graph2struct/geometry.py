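"""Cartesian reconstruction from distances, hydrogen placement, superposition.

The distance-geometry solver is two-stage: a classical (Torgerson) metric
embedding of the double-centered squared-distance matrix seeds an iterative
least-squares stress minimization of

    stress(R) = sum_{i<j} (||r_i - r_j|| - D_ij)^2 .

For exact Euclidean distance matrices the spectral stage is already exact
to numerical precision; the refinement stage is what absorbs regression
noise in predicted distances.  Hydrogens are placed after the heavy-atom
scaffold, each on a deterministic spherical grid around its bonded heavy
atom at the predicted bond distance, minimizing the residual to its three
remaining anchor distances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .graphs import GeometryRecord, InputError, MolecularGraph, CrystalRecord

__all__ = [
    "EmbeddingResult",
    "SuperpositionReport",
    "embed_distances",
    "kabsch_superpose",
    "sphere_grid",
    "place_hydrogens",
    "select_hydrogen_anchors",
    "through_bond_anchors",
    "frac_to_cartesian",
]


@dataclass(frozen=True)
class EmbeddingResult:
    """Output of the distance-geometry solve."""

    coordinates: np.ndarray
    stress: float
    converged: bool
    n_iterations: int
    stress_history: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("embedded coordinates must be finite")
        if self.stress < 0:
            raise ValueError("stress must be nonnegative")


@dataclass(frozen=True)
class SuperpositionReport:
    """Optimal rigid-body (optionally mirrored) superposition summary."""

    rmsd: float
    rotation: np.ndarray
    reflection_used: bool

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        object.__setattr__(self, "rotation", r)
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthogonal")

    def to_dict(self) -> dict:
        return {
            "rmsd": float(self.rmsd),
            "rotation": self.rotation.tolist(),
            "reflection_used": bool(self.reflection_used),
        }


# ---------------------------------------------------------------------------
# Distance-geometry embedding
# ---------------------------------------------------------------------------


def _classical_embedding(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (d**2) @ j
    w, v = np.linalg.eigh(b)
    idx = np.argsort(w)[::-1][:3]
    lam = np.clip(w[idx], 0.0, None)
    return v[:, idx] * np.sqrt(lam)


def _stress_and_grad(flat: np.ndarray, d: np.ndarray):
    n = d.shape[0]
    r = flat.reshape(n, 3)
    diff = r[:, None, :] - r[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    np.fill_diagonal(dist, 1.0)  # avoid 0/0; diagonal excluded below
    err = dist - d
    np.fill_diagonal(err, 0.0)
    stress = 0.5 * float((err**2).sum())  # each pair counted twice -> x0.5
    coef = err / dist
    np.fill_diagonal(coef, 0.0)
    grad = 2.0 * (coef[:, :, None] * diff).sum(axis=1)
    return stress, grad.ravel()


def embed_distances(
    d: np.ndarray, tol: float = 1e-10, max_iter: int = 500
) -> EmbeddingResult:
    """Solve the distance-geometry problem for a full distance matrix.

    Parameters
    ----------
    d
        Symmetric matrix with zero diagonal and positive off-diagonal
        entries; may be noisy (not exactly Euclidean).
    tol
        Relative stress-change convergence threshold of the refinement.
    max_iter
        Iteration cap of the stress minimizer.
    """
    d = np.asarray(d, dtype=np.float64)
    n = d.shape[0]
    if d.ndim != 2 or d.shape[1] != n:
        raise InputError("distance matrix must be square")
    if n < 3:
        raise InputError("need at least 3 points to embed")
    if not np.allclose(d, d.T, atol=1e-10):
        raise InputError("distance matrix must be symmetric")
    if np.any(np.diag(d) != 0):
        raise InputError("distance matrix must have zero diagonal")
    off = d[~np.eye(n, dtype=bool)]
    if np.any(off <= 0):
        raise InputError("off-diagonal distances must be positive")

    x0 = _classical_embedding(d)
    history = [
        _stress_and_grad(x0.ravel(), d)[0]
    ]

    def cb(xk):
        history.append(_stress_and_grad(xk, d)[0])

    res = minimize(
        _stress_and_grad,
        x0.ravel(),
        args=(d,),
        jac=True,
        method="L-BFGS-B",
        callback=cb,
        options={"maxiter": max_iter, "ftol": 1e-18, "gtol": 1e-14},
    )
    stress = float(res.fun)
    # convergence: relative stress change between the last accepted steps
    if len(history) >= 2 and history[-2] > 0:
        rel = abs(history[-1] - history[-2]) / max(history[-2], 1e-300)
    else:
        rel = 0.0
    converged = bool(res.success or rel < tol or stress < 1e-16)
    return EmbeddingResult(
        coordinates=res.x.reshape(n, 3),
        stress=stress,
        converged=converged,
        n_iterations=int(res.nit),
        stress_history=tuple(history),
    )


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------


def _kabsch_rotation(p: np.ndarray, q: np.ndarray, proper: bool):
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    r = vt.T @ u.T
    if proper and np.linalg.det(r) < 0:
        vt2 = vt.copy()
        vt2[-1] *= -1.0
        r = vt2.T @ u.T
    return r


def kabsch_superpose(
    p: np.ndarray, q: np.ndarray, allow_reflection: bool = False
) -> SuperpositionReport:
    """Minimum-RMSD rigid superposition of P onto Q (index correspondence).

    With ``allow_reflection`` the minimum over both hands is reported and
    flagged; distance information alone cannot fix chirality, so mirrored
    reconstructions are expected and evaluation defaults elsewhere use the
    reflection-minimized RMSD.
    """
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3:
        raise InputError("P and Q must be matching n x 3 arrays")
    if p.shape[0] < 3:
        raise InputError("need at least 3 points to superpose")
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)

    def rmsd_for(r):
        return float(np.sqrt(np.mean(np.sum((pc @ r.T - qc) ** 2, axis=1))))

    r_proper = _kabsch_rotation(pc, qc, proper=True)
    best = (rmsd_for(r_proper), r_proper, False)
    if allow_reflection:
        pm = pc.copy()
        pm[:, 0] *= -1.0  # mirror, then optimal proper rotation
        r_mirror = _kabsch_rotation(pm, qc, proper=True)
        flip = np.diag([-1.0, 1.0, 1.0])
        r_improper = r_mirror @ flip
        rmsd_m = rmsd_for(r_improper)
        if rmsd_m < best[0]:
            best = (rmsd_m, r_improper, True)
    return SuperpositionReport(rmsd=best[0], rotation=best[1], reflection_used=best[2])


# ---------------------------------------------------------------------------
# Hydrogen placement
# ---------------------------------------------------------------------------


def sphere_grid(n_points: int = 4096) -> np.ndarray:
    """Deterministic generalized-spiral unit-sphere grid (n_points x 3)."""
    k = np.arange(n_points, dtype=np.float64)
    z = 1.0 - 2.0 * (k + 0.5) / n_points
    phi = k * math.pi * (3.0 - math.sqrt(5.0))  # golden angle
    rho = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _tetrahedron_volume(points: np.ndarray) -> float:
    v = points[1:] - points[0]
    return abs(float(np.linalg.det(v))) / 6.0


def select_hydrogen_anchors(
    g: MolecularGraph,
    geom: GeometryRecord,
    coplanar_volume: float = 0.1,
):
    """Per-hydrogen anchor heavy atoms and reference distances (training time).

    For each hydrogen: its bonded heavy atom first, then the three heavy
    atoms nearest to the hydrogen in the reference geometry.  If the four
    anchors are coplanar (tetrahedron volume < ``coplanar_volume`` A^3),
    the farthest non-bonded anchor is swapped for the next-nearest
    candidate that breaks coplanarity; if none exists the coplanar set is
    kept and flagged.  Molecules with fewer than four heavy atoms fall
    back to the available anchors.  The three non-bonded anchors are
    ordered by their distance to the bonded heavy atom so that the order
    is reproducible at prediction time, when the hydrogen itself has no
    position yet.

    Returns a list of dicts with keys ``anchors`` (indices into
    ``g.heavy_indices`` order), ``distances`` (H-anchor, A) and
    ``coplanar_flag``.
    """
    heavy = list(g.heavy_indices)
    coords = geom.coordinates
    out = []
    for h, bonded in sorted(g.hydrogen_attachments.items()):
        b_pos = heavy.index(bonded)
        d_h = np.linalg.norm(coords[heavy] - coords[h], axis=1)
        order = [i for i in np.argsort(d_h, kind="stable") if i != b_pos]
        n_extra = min(3, len(order))
        chosen = list(order[:n_extra])
        coplanar_flag = False
        if n_extra == 3:
            pool = list(order[3:])
            while True:
                pts = coords[[heavy[b_pos]] + [heavy[i] for i in chosen]]
                if _tetrahedron_volume(pts) >= coplanar_volume:
                    break
                if not pool:
                    coplanar_flag = True
                    break
                # swap the farthest chosen anchor for the next candidate
                chosen = sorted(chosen, key=lambda i: d_h[i])[:-1] + [pool.pop(0)]
        # order non-bonded anchors by distance to the bonded heavy atom
        d_b = np.linalg.norm(
            coords[[heavy[i] for i in chosen]] - coords[heavy[b_pos]], axis=1
        )
        chosen = [chosen[int(i)] for i in np.argsort(d_b, kind="stable")]
        anchors = [b_pos] + chosen
        out.append(
            {
                "hydrogen": int(h),
                "anchors": [int(a) for a in anchors],
                "distances": np.array([d_h[a] for a in anchors]),
                "coplanar_flag": coplanar_flag,
            }
        )
    return out


def through_bond_anchors(
    l_from_bonded: np.ndarray,
    scaffold: np.ndarray,
    bonded_pos: int,
    coplanar_volume: float = 0.1,
) -> list[int]:
    """Hydrogen anchors by through-bond proximity to the bonded heavy atom.

    Candidates are ordered by (through-bond path length to the bonded
    atom, index) — a pure graph criterion, so the selection is identical
    at training and prediction time even when Euclidean distances are
    degenerate or noisy.  The third non-bonded anchor is advanced past
    candidates that would leave the quadruple coplanar (tetrahedron
    volume < ``coplanar_volume`` A^3, judged on the supplied scaffold
    coordinates); if no candidate breaks coplanarity the first is kept.
    """
    n = scaffold.shape[0]
    order = sorted(
        (i for i in range(n) if i != bonded_pos),
        key=lambda i: (l_from_bonded[i], i),
    )
    if len(order) < 3:
        return [bonded_pos] + [int(i) for i in order]
    chosen = list(order[:2])
    third = None
    for c in order[2:]:
        pts = scaffold[[bonded_pos] + chosen + [c]]
        if _tetrahedron_volume(pts) >= coplanar_volume:
            third = c
            break
    if third is None:
        third = order[2]
    return [bonded_pos] + [int(i) for i in chosen] + [int(third)]


def place_hydrogens(
    scaffold: np.ndarray,
    anchor_sets: list[list[int]],
    h_distances: np.ndarray,
    grid_size: int = 4096,
    clash_distance: float = 1.2,
    clash_weight: float = 10.0,
) -> np.ndarray:
    """Place each hydrogen on a spherical grid around its bonded heavy atom.

    Parameters
    ----------
    scaffold
        Embedded heavy-atom coordinates (canonical order), n_heavy x 3.
    anchor_sets
        Per hydrogen, the anchor indices into the scaffold; the first entry
        is the bonded heavy atom (sphere center).
    h_distances
        Per hydrogen, predicted distances to the anchors (same order);
        the first entry is the bond distance (sphere radius), which is
        honored exactly.

    Hydrogens are placed sequentially; a soft clash penalty against
    already-placed hydrogens breaks mirror-symmetric ties, remaining ties
    fall to the lowest grid index (numpy argmin).
    """
    grid = sphere_grid(grid_size)
    placed: list[np.ndarray] = []
    for anchors, dists in zip(anchor_sets, h_distances):
        anchors = list(anchors)
        dists = np.asarray(dists, dtype=float)
        center = scaffold[anchors[0]]
        radius = float(dists[0])
        cand = center + radius * grid
        cost = np.zeros(len(cand))
        for a, target in zip(anchors[1:], dists[1 : len(anchors)]):
            da = np.linalg.norm(cand - scaffold[a], axis=1)
            cost += (da - target) ** 2
        for hpos in placed:
            dh = np.linalg.norm(cand - hpos, axis=1)
            cost += clash_weight * np.clip(clash_distance - dh, 0.0, None) ** 2
        placed.append(cand[int(np.argmin(cost))])
    return np.array(placed).reshape(len(anchor_sets), 3)


# ---------------------------------------------------------------------------
# Crystals
# ---------------------------------------------------------------------------


def frac_to_cartesian(c: CrystalRecord) -> np.ndarray:
    """Cartesian site coordinates of a cubic cell: a * fractional."""
    return c.lattice_constant * c.fractional_coords
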