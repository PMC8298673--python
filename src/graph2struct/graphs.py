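"""Molecular-graph and geometry containers plus readers/writers.

A :class:`MolecularGraph` is the sole prediction-time input for molecules:
nuclear charges plus an integer bond-order matrix (0 none, 1 single,
2 double, 3 triple).  A :class:`GeometryRecord` carries Cartesian
coordinates in Angstrom and is used both for training labels and final
outputs.  SMILES and SDF parsing go through RDKit; XYZ is read and written
directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .periodic import SYMBOL_TO_Z, Z_TO_SYMBOL

__all__ = [
    "InputError",
    "UnsupportedFeatureError",
    "MolecularGraph",
    "GeometryRecord",
    "CrystalRecord",
    "parse_smiles",
    "read_xyz",
    "write_xyz",
    "read_sdf",
    "write_sdf",
    "add_fragment_pseudo_edges",
    "read_crystal_json",
    "write_crystal_json",
]


class InputError(ValueError):
    """Malformed or unparsable input."""


class UnsupportedFeatureError(ValueError):
    """Chemically valid input outside the supported feature set."""


@dataclass(frozen=True)
class MolecularGraph:
    """Bonding graph of one molecule, hydrogens explicit.

    Parameters
    ----------
    nuclear_charges
        Z per atom, positive integers.
    bond_order_matrix
        Symmetric integer matrix with entries in {0, 1, 2, 3} and zero
        diagonal.  Pseudo-edges (used to connect detached fragments of
        transition-state graphs) are entered as order 1.
    under_valent
        Indices of deliberately under-valent heavy atoms (e.g. the
        divalent carbon of a singlet carbene).  Informational; such atoms
        are handled like any other heavy atom downstream.
    """

    nuclear_charges: np.ndarray
    bond_order_matrix: np.ndarray
    under_valent: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        z = np.asarray(self.nuclear_charges, dtype=np.int64)
        bom = np.asarray(self.bond_order_matrix, dtype=np.int64)
        object.__setattr__(self, "nuclear_charges", z)
        object.__setattr__(self, "bond_order_matrix", bom)
        n = z.shape[0]
        if z.ndim != 1 or np.any(z < 1):
            raise InputError("nuclear charges must be positive integers")
        if bom.shape != (n, n):
            raise InputError("bond order matrix shape does not match atom count")
        if not np.array_equal(bom, bom.T):
            raise InputError("bond order matrix must be symmetric")
        if np.any(np.diag(bom) != 0):
            raise InputError("bond order matrix must have zero diagonal")
        if np.any((bom < 0) | (bom > 3)):
            raise InputError("bond orders must lie in {0, 1, 2, 3}")
        heavy = tuple(int(i) for i in np.flatnonzero(z > 1))
        if not heavy:
            raise InputError("graph has no heavy atoms")
        attachments: dict[int, int] = {}
        for h in np.flatnonzero(z == 1):
            partners = np.flatnonzero(bom[h])
            if len(partners) != 1 or bom[h, partners[0]] != 1:
                raise InputError(
                    f"hydrogen atom {h} must have exactly one single bond"
                )
            attachments[int(h)] = int(partners[0])
        object.__setattr__(self, "_heavy_indices", heavy)
        object.__setattr__(self, "_hydrogen_attachments", attachments)

    @property
    def n_atoms(self) -> int:
        return len(self.nuclear_charges)

    @property
    def heavy_indices(self) -> tuple[int, ...]:
        return self._heavy_indices  # type: ignore[attr-defined]

    @property
    def n_heavy(self) -> int:
        return len(self.heavy_indices)

    @property
    def hydrogen_attachments(self) -> dict[int, int]:
        """Map hydrogen index -> index of its bonded heavy atom."""
        return dict(self._hydrogen_attachments)  # type: ignore[attr-defined]

    @property
    def heavy_charges(self) -> np.ndarray:
        return self.nuclear_charges[list(self.heavy_indices)]

    @property
    def heavy_bond_orders(self) -> np.ndarray:
        idx = list(self.heavy_indices)
        return self.bond_order_matrix[np.ix_(idx, idx)]

    def permuted(self, perm: np.ndarray) -> "MolecularGraph":
        """Return the graph with atoms reordered by ``perm`` (new[i] = old[perm[i]])."""
        perm = np.asarray(perm)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        return MolecularGraph(
            nuclear_charges=self.nuclear_charges[perm],
            bond_order_matrix=self.bond_order_matrix[np.ix_(perm, perm)],
            under_valent=tuple(sorted(int(inv[i]) for i in self.under_valent)),
        )


@dataclass(frozen=True)
class GeometryRecord:
    """Elements plus Cartesian coordinates in Angstrom."""

    nuclear_charges: np.ndarray
    coordinates: np.ndarray

    def __post_init__(self) -> None:
        z = np.asarray(self.nuclear_charges, dtype=np.int64)
        xyz = np.asarray(self.coordinates, dtype=np.float64)
        object.__setattr__(self, "nuclear_charges", z)
        object.__setattr__(self, "coordinates", xyz)
        if xyz.shape != (z.shape[0], 3):
            raise InputError("coordinates must be n x 3")
        if not np.all(np.isfinite(xyz)):
            raise InputError("coordinates must be finite")

    def validate(self, min_dist: float = 0.3) -> None:
        """Check that no two atoms sit closer than ``min_dist`` Angstrom."""
        d = self.distance_matrix()
        np.fill_diagonal(d, np.inf)
        closest = float(d.min()) if d.size else np.inf
        if closest < min_dist:
            raise InputError(
                f"atoms closer than {min_dist} A (minimum distance {closest:.3f} A)"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.nuclear_charges)

    def distance_matrix(self) -> np.ndarray:
        diff = self.coordinates[:, None, :] - self.coordinates[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))

    def permuted(self, perm: np.ndarray) -> "GeometryRecord":
        perm = np.asarray(perm)
        return GeometryRecord(self.nuclear_charges[perm], self.coordinates[perm])


@dataclass(frozen=True)
class CrystalRecord:
    """One elpasolite-type ABC2D6 crystal: stoichiometry, cell and sites.

    ``fractional_coords`` lists the representative sites in a fixed
    Wyckoff order (A, B, C x2, D x6 for the elpasolite template).
    """

    site_elements: tuple[str, str, str, str]
    lattice_constant: float
    fractional_coords: np.ndarray

    def __post_init__(self) -> None:
        if len(self.site_elements) != 4:
            raise InputError("site_elements must be a 4-tuple (A, B, C, D)")
        for sym in self.site_elements:
            if sym not in SYMBOL_TO_Z:
                raise InputError(f"unknown element symbol {sym!r}")
        if not self.lattice_constant > 0:
            raise InputError("lattice constant must be positive")
        frac = np.asarray(self.fractional_coords, dtype=np.float64)
        object.__setattr__(self, "fractional_coords", frac)
        if frac.ndim != 2 or frac.shape[1] != 3:
            raise InputError("fractional coordinates must be m x 3")
        if np.any(frac < 0) or np.any(frac >= 1):
            raise InputError("fractional coordinates must lie in [0, 1)")

    def to_dict(self) -> dict:
        return {
            "site_elements": list(self.site_elements),
            "lattice_constant": float(self.lattice_constant),
            "fractional_coords": self.fractional_coords.tolist(),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "CrystalRecord":
        return cls(
            site_elements=tuple(payload["site_elements"]),
            lattice_constant=float(payload["lattice_constant"]),
            fractional_coords=np.asarray(payload["fractional_coords"], dtype=float),
        )


# ---------------------------------------------------------------------------
# SMILES / SDF via RDKit
# ---------------------------------------------------------------------------


def _graph_from_rdkit(mol) -> MolecularGraph:
    from rdkit import Chem

    for atom in mol.GetAtoms():
        if atom.GetFormalCharge() != 0:
            raise UnsupportedFeatureError(
                f"charged atom {atom.GetSymbol()}{atom.GetFormalCharge():+d} "
                "is not supported"
            )
    try:
        Chem.Kekulize(mol, clearAromaticFlags=True)
    except Exception as exc:  # pragma: no cover - rdkit raises various types
        raise UnsupportedFeatureError(f"cannot kekulize molecule: {exc}") from exc

    n = mol.GetNumAtoms()
    z = np.array([a.GetAtomicNum() for a in mol.GetAtoms()], dtype=np.int64)
    bom = np.zeros((n, n), dtype=np.int64)
    order_map = {
        Chem.BondType.SINGLE: 1,
        Chem.BondType.DOUBLE: 2,
        Chem.BondType.TRIPLE: 3,
    }
    for bond in mol.GetBonds():
        order = order_map.get(bond.GetBondType())
        if order is None:
            raise UnsupportedFeatureError(
                f"bond type {bond.GetBondType()} is not supported"
            )
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        bom[i, j] = bom[j, i] = order

    under_valent = tuple(
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetAtomicNum() == 6 and a.GetNumRadicalElectrons() > 0
    )
    # Radicals on elements other than carbon are outside scope.
    for a in mol.GetAtoms():
        if a.GetNumRadicalElectrons() > 0 and a.GetAtomicNum() != 6:
            raise UnsupportedFeatureError(
                f"radical on {a.GetSymbol()} is not supported"
            )
    return MolecularGraph(z, bom, under_valent=under_valent)


def parse_smiles(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a :class:`MolecularGraph`.

    Hydrogens are made explicit, aromatic systems are kekulized so all
    bond orders lie in {1, 2, 3}.  Charged species and non-carbon radicals
    raise :class:`UnsupportedFeatureError`; divalent (carbene-like)
    carbons are accepted and flagged ``under_valent``.
    """
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles, sanitize=True)
    if mol is None:
        raise InputError(f"unparsable SMILES string: {smiles!r}")
    mol = Chem.AddHs(mol)
    return _graph_from_rdkit(mol)


def write_sdf(
    path: str | Path, pairs: list[tuple[MolecularGraph, GeometryRecord]]
) -> None:
    """Write (graph, geometry) pairs as a V2000 SDF file."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for graph, geom in pairs:
            mol = Chem.RWMol()
            for z in graph.nuclear_charges:
                atom = Chem.Atom(int(z))
                atom.SetNoImplicit(True)
                mol.AddAtom(atom)
            order_map = {
                1: Chem.BondType.SINGLE,
                2: Chem.BondType.DOUBLE,
                3: Chem.BondType.TRIPLE,
            }
            bom = graph.bond_order_matrix
            for i, j in zip(*np.nonzero(np.triu(bom))):
                mol.AddBond(int(i), int(j), order_map[int(bom[i, j])])
            conf = Chem.Conformer(mol.GetNumAtoms())
            for i, (x, y, z_) in enumerate(geom.coordinates):
                conf.SetAtomPosition(i, Point3D(float(x), float(y), float(z_)))
            mol.AddConformer(conf)
            Chem.SanitizeMol(
                mol, Chem.SanitizeFlags.SANITIZE_ALL
                ^ Chem.SanitizeFlags.SANITIZE_PROPERTIES,
            )
            writer.write(mol)
    finally:
        writer.close()


def read_sdf(path: str | Path) -> list[tuple[MolecularGraph, GeometryRecord]]:
    """Read a V2000 SDF file into (graph, geometry) pairs.

    Bond orders come from the bond block, coordinates from the atom block.
    Aromatic bond entries (order 4) without kekulization information raise
    :class:`UnsupportedFeatureError`.
    """
    from rdkit import Chem

    path = Path(path)
    if not path.exists():
        raise InputError(f"SDF file not found: {path}")
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    out = []
    for i, mol in enumerate(supplier):
        if mol is None:
            raise InputError(f"molecule {i} in {path} could not be parsed")
        if mol.GetNumBonds() == 0 and mol.GetNumAtoms() > 1:
            raise InputError(f"molecule {i} in {path} has no bond block")
        if mol.GetNumConformers() == 0:
            raise InputError(f"molecule {i} in {path} has no coordinates")
        graph = _graph_from_rdkit(mol)
        coords = np.asarray(mol.GetConformer().GetPositions(), dtype=float)
        out.append((graph, GeometryRecord(graph.nuclear_charges, coords)))
    return out


def add_fragment_pseudo_edges(
    graph: MolecularGraph, reaction_centers: list[int]
) -> MolecularGraph:
    """Connect detached fragments to the reaction-center atoms.

    Transition-state graphs (attacking/leaving groups) are disconnected;
    a fully connected set of order-1 pseudo-edges is added between every
    atom of each detached fragment and every reaction-center atom.  The
    reaction centers must be supplied explicitly.
    """
    import networkx as nx

    if not reaction_centers:
        raise InputError("reaction_centers must be a nonempty index list")
    bom = graph.bond_order_matrix.copy()
    g_nx = nx.from_numpy_array((bom > 0).astype(float))
    components = list(nx.connected_components(g_nx))
    if len(components) == 1:
        return graph
    center_set = set(reaction_centers)
    main = next(c for c in components if center_set & c)
    for comp in components:
        if comp is main:
            continue
        for atom in comp:
            if graph.nuclear_charges[atom] == 1:
                continue  # hydrogens keep their single real bond
            for center in reaction_centers:
                if bom[atom, center] == 0:
                    bom[atom, center] = bom[center, atom] = 1
    return MolecularGraph(
        graph.nuclear_charges, bom, under_valent=graph.under_valent
    )


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------


def read_xyz(path: str | Path) -> GeometryRecord:
    """Read a single-structure XYZ file (count line, comment, atom lines)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise InputError(f"empty XYZ file: {path}")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise InputError(f"malformed XYZ count line: {lines[0]!r}") from None
    body = [ln for ln in lines[2 : 2 + n]]
    if len(body) != n:
        raise InputError(
            f"XYZ count line promises {n} atoms but {len(body)} lines follow"
        )
    charges, coords = [], []
    for ln in body:
        parts = ln.split()
        if len(parts) < 4:
            raise InputError(f"malformed XYZ atom line: {ln!r}")
        sym = parts[0]
        if sym not in SYMBOL_TO_Z:
            raise InputError(f"unknown element symbol {sym!r}")
        charges.append(SYMBOL_TO_Z[sym])
        coords.append([float(v) for v in parts[1:4]])
    return GeometryRecord(np.array(charges), np.array(coords))


def write_xyz(path: str | Path, record: GeometryRecord, comment: str = "") -> None:
    """Write a :class:`GeometryRecord` as a plain XYZ file."""
    lines = [str(record.n_atoms), comment.replace("\n", " ")]
    for z, (x, y, zz) in zip(record.nuclear_charges, record.coordinates):
        lines.append(f"{Z_TO_SYMBOL[int(z)]:<3s} {x: .10f} {y: .10f} {zz: .10f}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Crystal record JSON
# ---------------------------------------------------------------------------


def read_crystal_json(path: str | Path) -> list[CrystalRecord]:
    payload = json.loads(Path(path).read_text())
    return [CrystalRecord.from_dict(item) for item in payload]


def write_crystal_json(path: str | Path, records: list[CrystalRecord]) -> None:
    Path(path).write_text(
        json.dumps([r.to_dict() for r in records], indent=1) + "\n"
    )
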