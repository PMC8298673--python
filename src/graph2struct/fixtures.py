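"""Synthetic structure families for testing and benchmarking without downloads.

The molecular generator emulates families of constitutional isomers: a
fixed heavy-atom stoichiometry, varying bonding connectivity, and — the
property the whole learning problem rests on — exactly ONE deterministic,
minimum-like geometry per graph.  Geometries are built from idealized
internal coordinates (bond lengths = sums of covalent radii, tetrahedral
angles, canonical anti/gauche torsions), so the map graph -> geometry is a
function with no conformational ambiguity, and identical seeds reproduce
byte-identical fixture sets.

The crystal generator emits distinct elpasolite-type ABC2D6 stoichiometries
with ideal fractional site positions and a lattice constant that is a
smooth closed-form function of per-element size proxies plus seeded
Gaussian noise.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np

from .graphs import CrystalRecord, GeometryRecord, InputError, MolecularGraph
from .periodic import (
    SYMBOL_TO_Z,
    CovalentRadiiTable,
    load_radii_table,
    period_of,
    valence_electrons_of,
)

__all__ = [
    "STANDARD_VALENCES",
    "build_ideal_geometry",
    "generate_fixture_family",
    "generate_crystal_fixtures",
    "crystal_size_proxy",
    "smooth_lattice_constant",
    "ELPASOLITE_SITE_MULTIPLICITIES",
]

STANDARD_VALENCES: dict[int, int] = {
    1: 1, 5: 3, 6: 4, 7: 3, 8: 2, 9: 1,
    14: 4, 15: 3, 16: 2, 17: 1, 35: 1, 53: 1,
}

_TET = math.radians(109.4712206)  # ideal tetrahedral angle


# ---------------------------------------------------------------------------
# Connectivity sampling
# ---------------------------------------------------------------------------


def _graph_hash(adj: np.ndarray, charges: np.ndarray) -> str:
    g = nx.Graph()
    for i, z in enumerate(charges):
        g.add_node(i, el=int(z))
    for i, j in zip(*np.nonzero(np.triu(adj))):
        g.add_edge(int(i), int(j))
    return nx.weisfeiler_lehman_graph_hash(g, node_attr="el", iterations=4)


def _tree_from_prufer(seq: tuple[int, ...], n: int) -> np.ndarray:
    tree = nx.from_prufer_sequence(list(seq))
    adj = np.zeros((n, n), dtype=np.int64)
    for i, j in tree.edges:
        adj[i, j] = adj[j, i] = 1
    return adj


def _valences_ok(adj: np.ndarray, charges: np.ndarray) -> bool:
    deg = adj.sum(axis=1)
    return all(
        deg[i] <= STANDARD_VALENCES[int(z)] for i, z in enumerate(charges)
    )


def _enumerate_trees(charges: np.ndarray) -> list[np.ndarray]:
    """All distinct valence-feasible heavy-atom trees (exhaustive, small n)."""
    n = len(charges)
    seen: dict[str, np.ndarray] = {}
    if n == 1:
        return [np.zeros((1, 1), dtype=np.int64)]
    if n == 2:
        return [np.array([[0, 1], [1, 0]], dtype=np.int64)]
    for seq in itertools.product(range(n), repeat=n - 2):
        adj = _tree_from_prufer(seq, n)
        if not _valences_ok(adj, charges):
            continue
        key = _graph_hash(adj, charges)
        seen.setdefault(key, adj)
    return list(seen.values())


def _add_ring_edge(
    adj: np.ndarray, charges: np.ndarray, rng: np.random.Generator
) -> np.ndarray | None:
    """Close one ring by adding an edge between atoms with spare valence."""
    deg = adj.sum(axis=1)
    n = len(charges)
    cands = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if adj[i, j] == 0
        and deg[i] < STANDARD_VALENCES[int(charges[i])]
        and deg[j] < STANDARD_VALENCES[int(charges[j])]
    ]
    # rings smaller than 3 atoms impossible by construction (no self/parallel)
    cands = [
        (i, j)
        for i, j in cands
        if nx.shortest_path_length(
            nx.from_numpy_array(adj.astype(float)), i, j
        )
        >= 2
    ]
    if not cands:
        return None
    i, j = cands[rng.integers(len(cands))]
    out = adj.copy()
    out[i, j] = out[j, i] = 1
    return out


def _stoichiometry_charges(stoichiometry: dict[str, int]) -> np.ndarray:
    charges: list[int] = []
    for sym in sorted(stoichiometry, key=lambda s: (-SYMBOL_TO_Z[s], s)):
        z = SYMBOL_TO_Z[sym]
        if z == 1:
            raise InputError("stoichiometry lists heavy atoms only")
        if z not in STANDARD_VALENCES:
            raise InputError(f"no standard valence for element {sym}")
        charges.extend([z] * stoichiometry[sym])
    return np.array(charges, dtype=np.int64)


def _with_hydrogens(heavy_adj: np.ndarray, heavy_z: np.ndarray) -> MolecularGraph:
    """Saturate free valences with explicit hydrogens (appended at the end)."""
    deg = heavy_adj.sum(axis=1)
    n_heavy = len(heavy_z)
    n_h_per = [STANDARD_VALENCES[int(z)] - int(d) for z, d in zip(heavy_z, deg)]
    n = n_heavy + sum(n_h_per)
    z = np.concatenate([heavy_z, np.ones(sum(n_h_per), dtype=np.int64)])
    bom = np.zeros((n, n), dtype=np.int64)
    bom[:n_heavy, :n_heavy] = heavy_adj
    h = n_heavy
    for i, k in enumerate(n_h_per):
        for _ in range(k):
            bom[i, h] = bom[h, i] = 1
            h += 1
    return MolecularGraph(z, bom)


# ---------------------------------------------------------------------------
# Deterministic idealized geometry
# ---------------------------------------------------------------------------


def _perp_reference(u: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = ref - np.dot(ref, u) * u
    return e1 / np.linalg.norm(e1)


_ROOT_DIRS = np.array(
    [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
) / math.sqrt(3.0)


def _child_direction(
    u_from_grand: np.ndarray, e1: np.ndarray, slot: int, phi0: float
) -> np.ndarray:
    """Direction of the slot-th child bond in the local tetrahedral frame.

    ``u_from_grand`` points from the grandparent to the parent; slot 0 at
    phi = phi0 is the anti torsion, subsequent slots are gauche.
    """
    e2 = np.cross(u_from_grand, e1)
    phi = math.radians(phi0 + 120.0 * slot)
    lat = math.cos(phi) * e1 + math.sin(phi) * e2
    half = math.pi - _TET  # 70.53 deg from the incoming bond direction
    return math.cos(half) * u_from_grand + math.sin(half) * lat


def _place_subtree(
    pos: np.ndarray,
    children: list[list[int]],
    parent_of: dict[int, int],
    start_atoms: list[int],
    lengths,
    phi0: float,
) -> None:
    """DFS placement of tree branches whose roots are already positioned."""
    stack = list(reversed(start_atoms))
    while stack:
        p = stack.pop()
        kids = children[p]
        if not kids:
            continue
        g = parent_of[p]
        u = pos[p] - pos[g]
        u = u / np.linalg.norm(u)
        gg = parent_of.get(g)
        if gg is not None:
            w = pos[gg] - pos[g]
            w_perp = w - np.dot(w, u) * u
            nrm = np.linalg.norm(w_perp)
            e1 = -w_perp / nrm if nrm > 1e-8 else _perp_reference(u)
        else:
            e1 = _perp_reference(u)
        for slot, c in enumerate(kids):
            d = _child_direction(u, e1, slot, phi0)
            pos[c] = pos[p] + lengths(p, c) * d
            stack.append(c)


def build_ideal_geometry(
    graph: MolecularGraph, radii: CovalentRadiiTable | None = None
) -> GeometryRecord:
    """Deterministic, minimum-like 3D geometry for a tree or single-ring graph.

    Bond lengths are sums of covalent radii; angles are tetrahedral; sibling
    torsions follow a canonical anti/gauche pattern.  The same graph always
    yields bit-identical coordinates.
    """
    radii = radii if radii is not None else load_radii_table()
    n = graph.n_atoms
    bom = graph.bond_order_matrix
    z = graph.nuclear_charges

    def lengths(i: int, j: int) -> float:
        return radii.bond_length(int(z[i]), int(z[j]))

    g_nx = nx.from_numpy_array((bom > 0).astype(float))
    cycles = nx.cycle_basis(g_nx)
    if len(cycles) > 1:
        raise InputError("ideal geometry supports at most one ring")

    best: tuple[float, np.ndarray] | None = None
    for phi0 in (0.0, 24.0, 48.0, 12.0, 36.0, 60.0):
        pos = np.zeros((n, 3))
        if not cycles:
            _embed_tree(graph, pos, lengths, phi0)
        else:
            _embed_monocycle(graph, cycles[0], pos, lengths, phi0)
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        dmin = float(d.min())
        if best is None or dmin > best[0]:
            best = (dmin, pos)
        if dmin > 0.6:
            break
    assert best is not None
    if best[0] < 0.31:
        raise InputError("could not build a clash-free idealized geometry")
    return GeometryRecord(z, best[1])


def _children_map(order_edges: list[tuple[int, int]], n: int):
    children: list[list[int]] = [[] for _ in range(n)]
    parent_of: dict[int, int] = {}
    for p, c in order_edges:
        children[p].append(c)
        parent_of[c] = p
    for kids in children:
        kids.sort()
    return children, parent_of


def _embed_tree(graph, pos, lengths, phi0: float) -> None:
    n = graph.n_atoms
    bom = graph.bond_order_matrix
    root = 0
    g_nx = nx.from_numpy_array((bom > 0).astype(float))
    edges = list(nx.bfs_edges(g_nx, root, sort_neighbors=sorted))
    children, parent_of = _children_map(edges, n)
    pos[root] = 0.0
    root_kids = children[root]
    for k, c in enumerate(root_kids):
        pos[c] = pos[root] + lengths(root, c) * _ROOT_DIRS[k]
    parent_of[root] = root  # sentinel; never dereferenced for frames
    start = list(root_kids)
    pf = dict(parent_of)
    pf.pop(root)
    _place_subtree(pos, children, pf, start, lengths, phi0)


def _embed_monocycle(graph, cycle: list[int], pos, lengths, phi0: float) -> None:
    n = graph.n_atoms
    bom = graph.bond_order_matrix
    # canonical ring order: start at the smallest index, walk toward its
    # smaller-indexed ring neighbor
    m = len(cycle)
    start = min(cycle)
    ring_set = set(cycle)
    i0 = cycle.index(start)
    nb = (cycle[(i0 - 1) % m], cycle[(i0 + 1) % m])
    step = 1 if nb[1] < nb[0] else -1
    ring = [cycle[(i0 + step * k) % m] for k in range(m)]

    side = float(np.mean([lengths(ring[k], ring[(k + 1) % m]) for k in range(m)]))
    radius = side / (2.0 * math.sin(math.pi / m))
    for k, a in enumerate(ring):
        theta = 2.0 * math.pi * k / m
        pos[a] = radius * np.array([math.cos(theta), math.sin(theta), 0.0])

    zhat = np.array([0.0, 0.0, 1.0])
    children: list[list[int]] = [[] for _ in range(n)]
    parent_of: dict[int, int] = {}
    starts: list[int] = []
    g_nx = nx.from_numpy_array((bom > 0).astype(float))
    for k, a in enumerate(ring):
        subs = sorted(i for i in np.flatnonzero(bom[a]) if i not in ring_set)
        d_out = pos[a] / np.linalg.norm(pos[a])
        for slot, s in enumerate(subs):
            sign = 1.0 if (k + slot) % 2 == 0 else -1.0
            d = 0.816 * d_out + 0.577 * sign * zhat
            d /= np.linalg.norm(d)
            pos[s] = pos[a] + lengths(a, s) * d
            parent_of[s] = a
            starts.append(s)
            # build the subtree hanging off s
            for p, c in nx.bfs_edges(
                g_nx.subgraph(set(range(n)) - ring_set), s, sort_neighbors=sorted
            ):
                children[p].append(c)
                parent_of[c] = p
    for kids in children:
        kids.sort()
    _place_subtree(pos, children, parent_of, starts, lengths, phi0)


# ---------------------------------------------------------------------------
# Public molecular generator
# ---------------------------------------------------------------------------


def generate_fixture_family(
    n_heavy: int,
    stoichiometry: dict[str, int],
    count: int,
    seed: int,
    unsaturation: int = 0,
    radii: CovalentRadiiTable | None = None,
) -> list[tuple[MolecularGraph, GeometryRecord]]:
    """Generate ``count`` distinct constitutional isomers of one stoichiometry.

    Parameters
    ----------
    n_heavy
        Number of heavy atoms (must match the stoichiometry; 4..9).
    stoichiometry
        Heavy-atom element multiset, e.g. ``{"C": 7, "O": 2}``.  Hydrogens
        are added automatically to saturate standard valences, so every
        member of a family shares the full sum formula.
    unsaturation
        0 emits acyclic (tree) skeletons, 1 emits single-ring skeletons.
        Mixing is not allowed because it would change the hydrogen count.
    seed
        Controls which connectivities are sampled; the graph -> geometry
        map itself is deterministic and seed-independent.
    """
    if not 4 <= n_heavy <= 9:
        raise InputError("n_heavy must be between 4 and 9")
    if unsaturation not in (0, 1):
        raise InputError("unsaturation must be 0 (trees) or 1 (single ring)")
    charges = _stoichiometry_charges(stoichiometry)
    if len(charges) != n_heavy:
        raise InputError("stoichiometry does not sum to n_heavy")
    radii = radii if radii is not None else load_radii_table()
    rng = np.random.default_rng(seed)

    found: dict[str, np.ndarray] = {}
    if n_heavy <= 7 and unsaturation == 0:
        # exhaustive: lets us report the exact maximum on over-requests
        pool = _enumerate_trees(charges)
        if count > len(pool):
            raise InputError(
                f"requested {count} isomers but only {len(pool)} distinct "
                "connectivities exist for this stoichiometry"
            )
        order = rng.permutation(len(pool))[:count]
        for k in order:
            found[str(k)] = pool[k]
    else:
        stall, max_stall = 0, 4000
        while len(found) < count:
            seq = tuple(rng.integers(0, n_heavy, size=n_heavy - 2))
            adj = _tree_from_prufer(seq, n_heavy)
            if unsaturation == 1:
                ringed = _add_ring_edge(adj, charges, rng)
                if ringed is None:
                    stall += 1
                    continue
                adj = ringed
            if not _valences_ok(adj, charges):
                stall += 1
                continue
            key = _graph_hash(adj, charges)
            if key in found:
                stall += 1
                if stall > max_stall:
                    raise InputError(
                        f"requested {count} isomers but sampling found only "
                        f"{len(found)} distinct connectivities"
                    )
                continue
            stall = 0
            found[key] = adj

    out = []
    for adj in found.values():
        graph = _with_hydrogens(adj, charges)
        out.append((graph, build_ideal_geometry(graph, radii)))
    return out


# ---------------------------------------------------------------------------
# Elpasolite crystal fixtures
# ---------------------------------------------------------------------------

# representative sites of the cubic ABC2D6 template, fixed Wyckoff order:
# A (4a), B (4b), C (8c x2), D (24e x6)
ELPASOLITE_SITE_MULTIPLICITIES = (1, 1, 2, 6)

DEFAULT_SITE_POOLS: dict[str, tuple[str, ...]] = {
    "A": ("B", "Al", "Ga", "In", "Tl", "Si", "Ge", "Sn", "Pb"),
    "B": ("Li", "Na", "K", "Rb", "Cs"),
    "C": ("Li", "Na", "K", "Rb", "Cs"),
    "D": ("F", "Cl", "Br", "I"),
}


def crystal_size_proxy(symbol: str) -> float:
    """Smooth per-element size proxy (A) from period and valence count.

    Monotone increasing in period and decreasing in valence-electron count,
    mimicking ionic-size trends while remaining an exact closed form the
    tests can check against.
    """
    z = SYMBOL_TO_Z[symbol]
    return 0.6 + 0.32 * period_of(z) - 0.03 * valence_electrons_of(z)


def smooth_lattice_constant(site_elements: tuple[str, str, str, str]) -> float:
    """Noise-free lattice constant of the fixture model (A)."""
    r_a, r_b, r_c, r_d = (crystal_size_proxy(s) for s in site_elements)
    return 2.2 + 0.7 * r_a + 0.6 * r_b + 0.9 * r_c + 2.2 * r_d


def _ideal_fractional_sites(x: float) -> np.ndarray:
    return np.array(
        [
            [0.0, 0.0, 0.0],          # A
            [0.5, 0.5, 0.5],          # B
            [0.25, 0.25, 0.25],       # C
            [0.75, 0.75, 0.75],       # C
            [x, 0.0, 0.0],            # D octahedron around A
            [1.0 - x, 0.0, 0.0],
            [0.0, x, 0.0],
            [0.0, 1.0 - x, 0.0],
            [0.0, 0.0, x],
            [0.0, 0.0, 1.0 - x],
        ]
    )


def generate_crystal_fixtures(
    count: int,
    seed: int,
    noise_scale: float = 0.1,
    site_pools: dict[str, tuple[str, ...]] | None = None,
) -> list[CrystalRecord]:
    """Generate distinct synthetic ABC2D6 records with seeded cell noise.

    The lattice constant is :func:`smooth_lattice_constant` plus Gaussian
    noise of standard deviation ``noise_scale`` (A); fractional sites are
    the ideal elpasolite positions with the anion parameter x set from the
    A-D size proxies (deterministic, noise-free).
    """
    pools = dict(DEFAULT_SITE_POOLS if site_pools is None else site_pools)
    combos = [
        (a, b, c, d)
        for a in pools["A"]
        for b in pools["B"]
        for c in pools["C"]
        for d in pools["D"]
        if b != c  # distinct roles for the two monovalent sites
    ]
    if count > len(combos):
        raise InputError(
            f"requested {count} distinct stoichiometries but the element "
            f"pool supports only {len(combos)}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(combos))[:count]
    records = []
    for idx in order:
        elems = combos[idx]
        a0 = smooth_lattice_constant(elems)
        a = a0 + noise_scale * rng.standard_normal()
        x = float(
            np.clip(
                (crystal_size_proxy(elems[0]) + crystal_size_proxy(elems[3])) / a0,
                0.18,
                0.30,
            )
        )
        records.append(
            CrystalRecord(
                site_elements=elems,
                lattice_constant=float(a),
                fractional_coords=_ideal_fractional_sites(x),
            )
        )
    return records
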