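"""Element bookkeeping: symbols, covalent radii, periods and valence counts.

The covalent radii are pinned to a single published single-bond table
(shipped as a versioned JSON data file) so that every bond-length-derived
feature is reproducible bit for bit.  Period and valence-electron counts
cover the main group only, which is all the elpasolite stoichiometry
representation needs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

__all__ = [
    "SYMBOL_TO_Z",
    "Z_TO_SYMBOL",
    "CovalentRadiiTable",
    "load_radii_table",
    "period_of",
    "valence_electrons_of",
]

_SYMBOLS = (
    "H He "
    "Li Be B C N O F Ne "
    "Na Mg Al Si P S Cl Ar "
    "K Ca Sc Ti V Cr Mn Fe Co Ni Cu Zn Ga Ge As Se Br Kr "
    "Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te I Xe "
    "Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu "
    "Hf Ta W Re Os Ir Pt Au Hg Tl Pb Bi Po At Rn"
).split()

SYMBOL_TO_Z: dict[str, int] = {s: i + 1 for i, s in enumerate(_SYMBOLS)}
Z_TO_SYMBOL: dict[int, str] = {z: s for s, z in SYMBOL_TO_Z.items()}

# Noble-gas core sizes delimiting each period.
_PERIOD_EDGES = (0, 2, 10, 18, 36, 54, 86)


def period_of(z: int) -> int:
    """Periodic-table row of element ``z`` (main group and d block)."""
    for period, edge in enumerate(_PERIOD_EDGES[1:], start=1):
        if z <= edge:
            return period
    raise ValueError(f"element Z={z} beyond supported periods")


def valence_electrons_of(z: int) -> int:
    """Number of s+p valence electrons of a main-group element (1-8).

    Raises for d-block elements, where the count is not well defined in
    this simple scheme.
    """
    period = period_of(z)
    n_in_period = z - _PERIOD_EDGES[period - 1]
    period_size = _PERIOD_EDGES[period] - _PERIOD_EDGES[period - 1]
    if period_size == 18 and 3 <= n_in_period <= 12:
        raise ValueError(f"{Z_TO_SYMBOL[z]} (Z={z}) is not a main-group element")
    if n_in_period > 12:
        n_in_period -= 10  # skip the filled d shell
    return n_in_period


@dataclass(frozen=True)
class CovalentRadiiTable:
    """Map Z -> single-bond covalent radius in Angstrom.

    ``version`` identifies the published table the values are taken from.
    """

    radii: dict[int, float]
    version: str = "unversioned"
    _validated: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        for z, r in self.radii.items():
            if not (0.2 < r < 3.0):
                raise ValueError(f"radius {r} for Z={z} outside (0.2, 3.0) A")

    def __getitem__(self, z: int) -> float:
        try:
            return self.radii[z]
        except KeyError:
            sym = Z_TO_SYMBOL.get(z, f"Z={z}")
            raise KeyError(f"no covalent radius for element {sym}") from None

    def __contains__(self, z: int) -> bool:
        return z in self.radii

    def bond_length(self, z_a: int, z_b: int) -> float:
        """Idealized single-bond length: sum of the two covalent radii."""
        return self[z_a] + self[z_b]


def load_radii_table() -> CovalentRadiiTable:
    """Load the pinned covalent-radii table shipped with the package."""
    text = (
        resources.files("graph2struct.data").joinpath("covalent_radii.json").read_text()
    )
    payload = json.loads(text)
    radii = {SYMBOL_TO_Z[sym]: float(r) for sym, r in payload["radii"].items()}
    return CovalentRadiiTable(radii=radii, version=payload["version"])
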