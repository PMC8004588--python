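"""Hydrogen-suppressed molecular graphs and the weighted topological
matrices behind the 2D descriptors.

The graph substrate is deliberately minimal: heavy atoms with per-scheme
weights, bonds with orders (aromatic = 1.5), topological distances, the
Kier-Hall intrinsic state, and the heteroatom/bond-order weighted distance
matrix (Barysz matrix, Dz) from which the spectral descriptors are derived.

Atomic weighting schemes, keyed by the one-letter suffix used in descriptor
names:

====== =============================================
scheme property
====== =============================================
``m``  atomic mass
``v``  van der Waals volume (from Bondi radii)
``e``  Sanderson electronegativity
``p``  atomic polarizability
``s``  Kier-Hall intrinsic state (graph-dependent)
``Z``  atomic number
====== =============================================
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

__all__ = [
    "WEIGHT_SCHEMES",
    "Atom",
    "MolecularGraph",
    "PropertyTable",
    "default_properties",
    "from_smiles",
    "topological_distances",
    "intrinsic_state",
    "barysz_matrix",
    "atom_weights",
]

WEIGHT_SCHEMES = ("m", "v", "e", "p", "s", "Z")

_SUPPORTED_ELEMENTS = frozenset({"C", "N", "O", "S"})

#: carbon reference for the intrinsic-state weighting scheme: the value of a
#: singly connected sp3 carbon (delta = delta_v = 1), used where a
#: graph-independent carbon reference is required (Barysz diagonal/edges)
CARBON_INTRINSIC_STATE = 2.0


@dataclass(frozen=True)
class Atom:
    """Heavy atom with element identity and hydrogen count."""

    element: str
    Z: int
    n_hydrogens: int = 0

    def __post_init__(self) -> None:
        if self.element not in _SUPPORTED_ELEMENTS:
            raise ValueError(
                f"unsupported element {self.element!r}; the property table "
                f"covers {sorted(_SUPPORTED_ELEMENTS)}")


@dataclass(frozen=True)
class MolecularGraph:
    """Simple undirected hydrogen-suppressed graph.

    ``bonds`` are (i, j, order) with order in {1, 1.5, 2, 3}; aromatic bonds
    carry order 1.5.
    """

    atoms: tuple[Atom, ...]
    bonds: tuple[tuple[int, int, float], ...]

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen = set()
        for i, j, order in self.bonds:
            if i == j:
                raise ValueError(f"self-bond on atom {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) indexes outside 0..{n - 1}")
            if order not in (1.0, 1.5, 2.0, 3.0):
                raise ValueError(f"unsupported bond order {order}")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def degree(self) -> np.ndarray:
        """Heavy-atom connectivity delta_i."""
        d = np.zeros(self.n_atoms, dtype=int)
        for i, j, _ in self.bonds:
            d[i] += 1
            d[j] += 1
        return d

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_atoms, self.n_atoms))
        for i, j, _ in self.bonds:
            a[i, j] = a[j, i] = 1.0
        return a

    def permuted(self, perm: "np.ndarray | list[int]") -> "MolecularGraph":
        """Relabel atoms: new index ``perm[i]`` for old index ``i``."""
        perm = list(perm)
        inv = [0] * len(perm)
        for old, new in enumerate(perm):
            inv[new] = old
        atoms = tuple(self.atoms[inv[k]] for k in range(len(perm)))
        bonds = tuple(sorted(
            (min(perm[i], perm[j]), max(perm[i], perm[j]), order)
            for i, j, order in self.bonds))
        return MolecularGraph(atoms=atoms, bonds=bonds)


class PropertyTable:
    """Element property tabulation used for descriptor weighting.

    Values are stored raw; carbon-relative ratios are applied only inside
    the Barysz-matrix formula.  The packaged table is the single source of
    truth for the m/v/e/p schemes.
    """

    _NUMERIC = ("Z", "principal_quantum_number", "valence_electrons",
                "mass", "vdw_volume", "sanderson_en", "polarizability")

    def __init__(self, rows: Mapping[str, Mapping[str, float]]):
        if "C" not in rows:
            raise ValueError("property table must contain carbon")
        missing = _SUPPORTED_ELEMENTS - set(rows)
        if missing:
            raise ValueError(f"property table missing elements {sorted(missing)}")
        self._rows = {el: dict(vals) for el, vals in rows.items()}
        for el, vals in self._rows.items():
            for col in ("mass", "vdw_volume", "sanderson_en", "polarizability"):
                if vals[col] <= 0:
                    raise ValueError(f"non-positive {col} for {el}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "PropertyTable":
        rows: dict[str, dict[str, float]] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            for rec in csv.DictReader(fh):
                rows[rec["element"]] = {k: float(rec[k]) for k in cls._NUMERIC}
        return cls(rows)

    _SCHEME_COLUMN = {"m": "mass", "v": "vdw_volume", "e": "sanderson_en",
                      "p": "polarizability", "Z": "Z"}

    def value(self, element: str, scheme: str) -> float:
        return self._rows[element][self._SCHEME_COLUMN[scheme]]

    def carbon(self, scheme: str) -> float:
        if scheme == "s":
            return CARBON_INTRINSIC_STATE
        return self.value("C", scheme)

    def principal_quantum_number(self, element: str) -> int:
        return int(self._rows[element]["principal_quantum_number"])

    def valence_electrons(self, element: str) -> int:
        return int(self._rows[element]["valence_electrons"])


_DEFAULT_PROPERTIES: PropertyTable | None = None


def default_properties() -> PropertyTable:
    """The packaged element property table (cached)."""
    global _DEFAULT_PROPERTIES
    if _DEFAULT_PROPERTIES is None:
        _DEFAULT_PROPERTIES = PropertyTable.from_csv(
            Path(__file__).parent / "data" / "atomic_properties.csv")
    return _DEFAULT_PROPERTIES


def from_smiles(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a hydrogen-suppressed graph.

    Aromatic bonds carry order 1.5; implicit hydrogens are counted per atom
    so that intrinsic states can be computed.
    """
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    atoms = []
    for a in mol.GetAtoms():
        atoms.append(Atom(
            element=a.GetSymbol(),
            Z=a.GetAtomicNum(),
            n_hydrogens=a.GetTotalNumHs(),
        ))
    bonds = tuple(sorted(
        (min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
         max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
         b.GetBondTypeAsDouble())
        for b in mol.GetBonds()))
    return MolecularGraph(atoms=tuple(atoms), bonds=bonds)


def _sparse_adjacency(g: MolecularGraph, data: np.ndarray | None = None) -> csr_matrix:
    n = g.n_atoms
    ii, jj, vv = [], [], []
    for k, (i, j, _) in enumerate(g.bonds):
        v = 1.0 if data is None else data[k]
        ii += [i, j]
        jj += [j, i]
        vv += [v, v]
    return csr_matrix((vv, (ii, jj)), shape=(n, n))


def topological_distances(g: MolecularGraph) -> np.ndarray:
    """Matrix of minimum bond counts between all atom pairs."""
    if g.n_atoms == 1:
        return np.zeros((1, 1), dtype=int)
    adj = _sparse_adjacency(g)
    if connected_components(adj, directed=False, return_labels=False) != 1:
        raise ValueError("graph is disconnected")
    d = shortest_path(adj, method="D", directed=False, unweighted=True)
    return d.astype(int)


def intrinsic_state(
    g: MolecularGraph, properties: PropertyTable | None = None
) -> np.ndarray:
    """Kier-Hall intrinsic state I_i = ((2/L_i)^2 * delta_v_i + 1) / delta_i.

    L is the principal quantum number, delta the heavy-atom connectivity and
    delta_v = (valence electrons) - (attached hydrogens).
    """
    props = properties or default_properties()
    deg = g.degree()
    if np.any(deg == 0):
        raise ValueError("isolated atom: intrinsic state undefined (delta = 0)")
    out = np.empty(g.n_atoms)
    for i, atom in enumerate(g.atoms):
        L = props.principal_quantum_number(atom.element)
        delta_v = props.valence_electrons(atom.element) - atom.n_hydrogens
        out[i] = ((2.0 / L) ** 2 * delta_v + 1.0) / deg[i]
    return out


def atom_weights(
    g: MolecularGraph, scheme: str, properties: PropertyTable | None = None
) -> np.ndarray:
    """Per-atom weights for a scheme; ``s`` is graph-dependent."""
    if scheme not in WEIGHT_SCHEMES:
        raise ValueError(f"unknown weighting scheme {scheme!r}")
    props = properties or default_properties()
    if scheme == "s":
        return intrinsic_state(g, props)
    return np.array([props.value(a.element, scheme) for a in g.atoms])


def barysz_matrix(
    g: MolecularGraph, scheme: str, properties: PropertyTable | None = None
) -> np.ndarray:
    """Weighted topological distance matrix (Barysz matrix, Dz).

    Diagonal: ``1 - w_C / w_i``.  Off-diagonal (i, j): minimum over paths of
    the sum over path edges (k, l) of ``w_C**2 / (b_kl * w_k * w_l)`` with
    ``b_kl`` the bond order.  For an all-carbon, single-bonded graph this
    reduces to the plain topological distance matrix.
    """
    props = properties or default_properties()
    w = atom_weights(g, scheme, props)
    if np.any(w <= 0):
        raise ValueError("non-positive atom weight in Barysz matrix")
    wc = props.carbon(scheme)
    n = g.n_atoms
    if n == 1:
        return np.array([[1.0 - wc / w[0]]])
    edge_w = np.array([
        wc ** 2 / (order * w[i] * w[j]) for i, j, order in g.bonds])
    adj = _sparse_adjacency(g, edge_w)
    if connected_components(adj, directed=False, return_labels=False) != 1:
        raise ValueError("graph is disconnected")
    dz = shortest_path(adj, method="D", directed=False)
    np.fill_diagonal(dz, 1.0 - wc / w)
    return dz
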