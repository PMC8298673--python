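"""Graph featurization: fixed-length, canonically sorted vectors.

Every molecular scheme builds an n_heavy x n_heavy matrix from the bonding
graph, sorts the atoms canonically so the vector is invariant to the input
atom order, zero-pads to ``n_max`` and flattens.  The same canonical
permutation is applied to the pairwise-distance labels, which is what makes
the regression targets index-invariant.

Schemes
-------
bond_order
    Heavy-atom bond orders, entries in {0, 1, 2, 3}.
bond_hop
    Number of bonds along the shortest connecting path.
bond_length
    Through-bond path length l_ij: the minimum over paths of the summed
    idealized bond lengths (covalent-radius sums) of the path edges.
graph_cm
    Coulomb-matrix analogue with l_ij in place of the Euclidean distance:
    0.5 Z^2.4 on the diagonal, Z_i Z_j / l_ij off it.
graph_bob
    graph_cm entries grouped into element-pair bags, each bag sorted
    descending and padded to the size observed in training.
flla
    Crystal stoichiometry tuple: (period, valence electrons) per site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .graphs import CrystalRecord, GeometryRecord, InputError, MolecularGraph
from .periodic import (
    SYMBOL_TO_Z,
    Z_TO_SYMBOL,
    CovalentRadiiTable,
    period_of,
    valence_electrons_of,
)

__all__ = [
    "SCHEMES",
    "OutOfVocabularyError",
    "RepresentationVector",
    "DistanceTargets",
    "BagSpec",
    "fit_bag_spec",
    "canonical_order",
    "canonical_sort",
    "bond_order_matrix",
    "bond_hop_matrix",
    "bond_length_matrix",
    "graph_cm_matrix",
    "scheme_matrix",
    "represent",
    "bond_order_rep",
    "bond_hop_rep",
    "bond_length_rep",
    "graph_cm_rep",
    "graph_bob_rep",
    "flla_rep",
    "distance_targets",
]

logger = logging.getLogger(__name__)

SCHEMES = ("bond_order", "bond_hop", "bond_length", "graph_cm", "graph_bob", "flla")


class OutOfVocabularyError(KeyError):
    """Query contains an element (pair) absent from the fitted bag layout."""


@dataclass(frozen=True)
class RepresentationVector:
    """Fixed-length featurization of one graph (or crystal stoichiometry)."""

    values: np.ndarray
    scheme: str
    n_max: int
    permutation: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=np.float64)
        )


@dataclass(frozen=True)
class DistanceTargets:
    """Canonically ordered heavy-atom pair distances, zero-padded to n_max.

    Entries are Angstrom for molecules and dimensionless fractional
    distances for crystals.  Entry order is the flattened upper triangle
    (i < j) of the n_max x n_max matrix in the canonical permutation;
    pairs involving padded (absent) atoms are exactly zero.
    """

    values: np.ndarray
    n_max: int
    permutation: tuple[int, ...]
    fractional: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        if v.shape != (self.n_max * (self.n_max - 1) // 2,):
            raise InputError("distance target length must be n_max(n_max-1)/2")
        n = len(self.permutation)
        mask = pair_mask(n, self.n_max)
        if not self.fractional and np.any((v[mask] <= 0.5)):
            raise InputError("molecular heavy-atom distances must exceed 0.5 A")
        if np.any(v[~mask] != 0.0):
            raise InputError("padded distance entries must be exactly zero")


def pair_mask(n: int, n_max: int) -> np.ndarray:
    """Boolean mask over upper-triangle slots marking real (non-padded) pairs."""
    iu, ju = np.triu_indices(n_max, k=1)
    return (iu < n) & (ju < n)


# ---------------------------------------------------------------------------
# Per-scheme heavy-atom matrices (pre-canonicalization)
# ---------------------------------------------------------------------------


def bond_order_matrix(g: MolecularGraph) -> np.ndarray:
    return g.heavy_bond_orders.astype(np.float64)


def _heavy_graph_csr(g: MolecularGraph, weights: np.ndarray | None = None):
    adj = (g.heavy_bond_orders > 0).astype(np.float64)
    if weights is not None:
        adj = adj * weights
    return csr_matrix(adj)


def bond_hop_matrix(g: MolecularGraph) -> np.ndarray:
    """Shortest-path bond counts between heavy atoms."""
    d = shortest_path(_heavy_graph_csr(g), method="D", unweighted=True)
    if np.isinf(d).any():
        raise InputError(
            "heavy-atom graph is disconnected; connect fragments with "
            "pseudo-edges (see add_fragment_pseudo_edges)"
        )
    return d


def bond_length_matrix(g: MolecularGraph, radii: CovalentRadiiTable) -> np.ndarray:
    """Through-bond path lengths l_ij in Angstrom.

    Each edge (a, b) weighs r_cov(a) + r_cov(b); l_ij is the minimum total
    weight over connecting paths, making l a true metric on the graph.
    """
    z = g.heavy_charges
    r = np.array([radii[int(zz)] for zz in z])
    w = r[:, None] + r[None, :]
    d = shortest_path(_heavy_graph_csr(g, weights=w), method="D")
    if np.isinf(d).any():
        raise InputError(
            "heavy-atom graph is disconnected; connect fragments with "
            "pseudo-edges (see add_fragment_pseudo_edges)"
        )
    # rounding removes float summation-order noise so canonically sorted
    # vectors are bit-identical under input permutations
    return np.round(d, 10)


def graph_cm_matrix(g: MolecularGraph, radii: CovalentRadiiTable) -> np.ndarray:
    """Coulomb-matrix analogue on through-bond path lengths."""
    z = g.heavy_charges.astype(np.float64)
    l = bond_length_matrix(g, radii)
    with np.errstate(divide="ignore"):
        m = np.outer(z, z) / l
    np.fill_diagonal(m, 0.5 * z**2.4)
    return m


def scheme_matrix(
    g: MolecularGraph, scheme: str, radii: CovalentRadiiTable
) -> np.ndarray:
    if scheme == "bond_order":
        return bond_order_matrix(g)
    if scheme == "bond_hop":
        return bond_hop_matrix(g)
    if scheme == "bond_length":
        return bond_length_matrix(g, radii)
    if scheme in ("graph_cm", "graph_bob"):
        return graph_cm_matrix(g, radii)
    raise InputError(f"unknown matrix scheme {scheme!r}")


# ---------------------------------------------------------------------------
# Canonical atom ordering
# ---------------------------------------------------------------------------


def canonical_order(matrix: np.ndarray, charges: np.ndarray | None = None):
    """Permutation sorting atoms by non-decreasing Euclidean row norm.

    Norm ties are broken by a column-order-invariant refinement: the
    initial key (row norm, descending-sorted row values, nuclear charge)
    is sharpened Weisfeiler-Lehman style with the sorted multiset of
    (entry, neighbor key rank) pairs until the partition stabilizes.
    Atoms a refinement cannot separate are structurally equivalent with
    respect to the matrix (automorphic in practice), so their relative
    order — stable by original index — does not change the sorted matrix.
    """
    n = matrix.shape[0]
    if n == 1:
        return np.zeros(1, dtype=np.int64)
    m = np.round(matrix, 10)
    norms = np.round(np.linalg.norm(m, axis=1), 10)
    z = (charges if charges is not None else np.zeros(n)).astype(int)
    base = [
        (float(norms[i]), tuple(np.sort(m[i])[::-1]), int(z[i]))
        for i in range(n)
    ]
    colors = _refine_colors(m, _dense_ranks(base))
    if len(set(colors)) == n:
        return np.array(sorted(range(n), key=lambda i: colors[i]), dtype=np.int64)

    # Individualization-refinement search: branch over the members of the
    # first still-tied class, refine, and keep the branch whose permuted
    # matrix signature is lexicographically smallest.  Exact over all
    # branches; automorphic branches give equal signatures, resolved
    # stably by original index.
    best: tuple | None = None

    def signature(perm: list[int]) -> tuple:
        sub = m[np.ix_(perm, perm)]
        return tuple(sub[np.triu_indices(n, k=1)]) + tuple(z[perm])

    def search(prefix: list[int], cols: list[int]) -> None:
        nonlocal best
        if len(prefix) == n:
            sig = signature(prefix)
            if best is None or sig < best[0]:
                best = (sig, list(prefix))
            return
        remaining = [i for i in range(n) if i not in prefix]
        cmin = min(cols[i] for i in remaining)
        cands = sorted(i for i in remaining if cols[i] == cmin)
        if len(cands) == 1:
            search(prefix + [cands[0]], cols)
            return
        for c in cands:
            ind = list(cols)
            ind[c] = -1 - len(prefix)  # fresh unique color, still minimal
            search(prefix + [c], _refine_colors(m, _dense_ranks_int(ind)))

    search([], colors)
    assert best is not None
    return np.array(best[1], dtype=np.int64)


def _refine_colors(m: np.ndarray, colors: list[int]) -> list[int]:
    """Weisfeiler-Lehman color propagation until the partition stabilizes."""
    n = len(colors)
    while True:
        keys = [
            (
                colors[i],
                tuple(
                    sorted((float(m[i, j]), colors[j]) for j in range(n) if j != i)
                ),
            )
            for i in range(n)
        ]
        new = _dense_ranks(keys)
        if new == colors:
            return colors
        colors = new


def _dense_ranks(keys: list) -> list[int]:
    order = {k: r for r, k in enumerate(sorted(set(keys)))}
    return [order[k] for k in keys]


def _dense_ranks_int(vals: list[int]) -> list[int]:
    order = {v: r for r, v in enumerate(sorted(set(vals)))}
    return [order[v] for v in vals]


def canonical_sort(
    rep_matrix: np.ndarray,
    distance_matrix: np.ndarray | None = None,
    charges: np.ndarray | None = None,
):
    """Reorder the representation matrix (and distance matrix) canonically.

    Returns ``(sorted_rep, sorted_dist, permutation)``; the SAME permutation
    is applied to both matrices so features and labels stay aligned.
    """
    if rep_matrix.shape[0] != rep_matrix.shape[1]:
        raise InputError("representation matrix must be square")
    perm = canonical_order(rep_matrix, charges)
    srep = rep_matrix[np.ix_(perm, perm)]
    sdist = None
    if distance_matrix is not None:
        if distance_matrix.shape != rep_matrix.shape:
            raise InputError("distance matrix shape mismatch")
        sdist = distance_matrix[np.ix_(perm, perm)]
    return srep, sdist, perm


def _pad_and_flatten(m: np.ndarray, n_max: int, diag: bool) -> np.ndarray:
    n = m.shape[0]
    if n > n_max:
        raise InputError(f"molecule has {n} heavy atoms, exceeds n_max={n_max}")
    padded = np.zeros((n_max, n_max))
    padded[:n, :n] = m
    iu, ju = np.triu_indices(n_max, k=0 if diag else 1)
    return padded[iu, ju]


# ---------------------------------------------------------------------------
# Public per-scheme representation builders
# ---------------------------------------------------------------------------


def _matrix_rep(
    g: MolecularGraph,
    scheme: str,
    n_max: int,
    radii: CovalentRadiiTable,
    diag: bool,
) -> RepresentationVector:
    m = scheme_matrix(g, scheme, radii)
    sm, _, perm = canonical_sort(m, charges=g.heavy_charges)
    return RepresentationVector(
        values=_pad_and_flatten(sm, n_max, diag=diag),
        scheme=scheme,
        n_max=n_max,
        permutation=tuple(int(p) for p in perm),
    )


def bond_order_rep(g, n_max, radii=None) -> RepresentationVector:
    return _matrix_rep(g, "bond_order", n_max, radii, diag=False)


def bond_hop_rep(g, n_max, radii=None) -> RepresentationVector:
    return _matrix_rep(g, "bond_hop", n_max, radii, diag=False)


def bond_length_rep(g, n_max, radii) -> RepresentationVector:
    return _matrix_rep(g, "bond_length", n_max, radii, diag=False)


def graph_cm_rep(g, n_max, radii) -> RepresentationVector:
    return _matrix_rep(g, "graph_cm", n_max, radii, diag=True)


# ---------------------------------------------------------------------------
# graph BoB
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BagSpec:
    """Fitted bag layout: ordered bag keys with their (training-set) sizes.

    Diagonal bags are keyed by a single element symbol, pair bags by the
    alphabetically unordered Z-sorted pair, e.g. ``("C", "O")``.
    """

    sizes: tuple[tuple[tuple[str, ...], int], ...]

    @property
    def length(self) -> int:
        return sum(s for _, s in self.sizes)

    def to_dict(self) -> dict:
        return {"|".join(k): int(s) for k, s in self.sizes}

    @classmethod
    def from_dict(cls, payload: dict) -> "BagSpec":
        sizes = tuple(
            (tuple(k.split("|")), int(s)) for k, s in payload.items()
        )
        return cls(sizes=tuple(sorted(sizes)))


def _bag_entries(g: MolecularGraph, radii: CovalentRadiiTable):
    m = graph_cm_matrix(g, radii)
    z = g.heavy_charges
    bags: dict[tuple[str, ...], list[float]] = {}
    n = len(z)
    for i in range(n):
        key = (Z_TO_SYMBOL[int(z[i])],)
        bags.setdefault(key, []).append(float(m[i, i]))
    for i in range(n):
        for j in range(i + 1, n):
            za, zb = sorted((int(z[i]), int(z[j])))
            key = (Z_TO_SYMBOL[za], Z_TO_SYMBOL[zb])
            bags.setdefault(key, []).append(float(m[i, j]))
    return bags


def fit_bag_spec(
    graphs: list[MolecularGraph], radii: CovalentRadiiTable
) -> BagSpec:
    """Bag keys and maximum bag sizes observed over a training set."""
    sizes: dict[tuple[str, ...], int] = {}
    for g in graphs:
        for key, vals in _bag_entries(g, radii).items():
            sizes[key] = max(sizes.get(key, 0), len(vals))
    return BagSpec(sizes=tuple(sorted(sizes.items())))


def graph_bob_rep(
    g: MolecularGraph,
    radii: CovalentRadiiTable,
    bags: BagSpec,
    n_max: int | None = None,
) -> RepresentationVector:
    """Bag-of-bonds form of the graph Coulomb matrix.

    Entries are grouped per element (pair), sorted descending within each
    bag and zero-padded to the fitted bag size.  Bags overflowing the
    fitted size are truncated (smallest entries dropped) with a warning.
    """
    entries = _bag_entries(g, radii)
    fitted = dict(bags.sizes)
    for key in entries:
        if key not in fitted:
            raise OutOfVocabularyError(
                f"element bag {'-'.join(key)} absent from the fitted bag layout"
            )
    chunks = []
    for key, size in bags.sizes:
        vals = sorted(entries.get(key, []), reverse=True)
        if len(vals) > size:
            logger.warning(
                "bag %s overflows fitted size %d (%d entries); truncating",
                "-".join(key), size, len(vals),
            )
            vals = vals[:size]
        chunks.append(np.pad(np.array(vals), (0, size - len(vals))))
    # distance labels follow the graph-CM canonical permutation
    _, _, perm = canonical_sort(
        graph_cm_matrix(g, radii), charges=g.heavy_charges
    )
    return RepresentationVector(
        values=np.concatenate(chunks) if chunks else np.zeros(0),
        scheme="graph_bob",
        n_max=n_max if n_max is not None else g.n_heavy,
        permutation=tuple(int(p) for p in perm),
    )


# ---------------------------------------------------------------------------
# FLLA (crystal stoichiometry)
# ---------------------------------------------------------------------------


def flla_rep(c: CrystalRecord) -> RepresentationVector:
    """(period, valence-electron count) per site, fixed A,B,C,D order."""
    vals = []
    for sym in c.site_elements:
        z = SYMBOL_TO_Z[sym]
        vals.extend([period_of(z), valence_electrons_of(z)])
    return RepresentationVector(
        values=np.array(vals, dtype=float),
        scheme="flla",
        n_max=4,
        permutation=(0, 1, 2, 3),
    )


# ---------------------------------------------------------------------------
# Dispatch + distance labels
# ---------------------------------------------------------------------------


def represent(
    g: MolecularGraph,
    scheme: str,
    n_max: int,
    radii: CovalentRadiiTable,
    bags: BagSpec | None = None,
) -> RepresentationVector:
    """Featurize one molecular graph with the named scheme."""
    if scheme == "graph_bob":
        if bags is None:
            raise InputError("graph_bob requires a fitted BagSpec")
        return graph_bob_rep(g, radii, bags, n_max=n_max)
    if scheme == "graph_cm":
        return graph_cm_rep(g, n_max, radii)
    if scheme == "bond_length":
        return bond_length_rep(g, n_max, radii)
    if scheme == "bond_hop":
        return bond_hop_rep(g, n_max)
    if scheme == "bond_order":
        return bond_order_rep(g, n_max)
    raise InputError(f"unknown representation scheme {scheme!r}")


def distance_targets(
    geometry: GeometryRecord,
    heavy_indices,
    permutation,
    n_max: int,
    fractional: bool = False,
) -> DistanceTargets:
    """Heavy-atom pair distances in the canonical order, padded to n_max."""
    coords = geometry.coordinates[list(heavy_indices)][list(permutation)]
    n = coords.shape[0]
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    padded = np.zeros((n_max, n_max))
    padded[:n, :n] = d
    iu, ju = np.triu_indices(n_max, k=1)
    return DistanceTargets(
        values=padded[iu, ju],
        n_max=n_max,
        permutation=tuple(int(p) for p in permutation),
        fractional=fractional,
    )
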