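"""Light-weight molecular graphs for topological descriptor math.

Molecules are represented as heavy-atom graphs: hydrogens are never explicit
nodes, only per-atom counts, because electrotopological typing and the
delta/delta-v arithmetic read heavy-atom topology plus hydrogen counts.
SMILES/SDF parsing and aromaticity perception are delegated to RDKit (its
default aromaticity model); everything downstream reads only this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

#: Bond orders carried on graph edges.
BOND_ORDERS = ("single", "double", "triple", "aromatic")

_RDKIT_BOND = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}
_TO_RDKIT_BOND = {v: k for k, v in _RDKIT_BOND.items()}

#: Elements the descriptor engines accept (the common organic set).
SUPPORTED_ELEMENTS = frozenset(
    {"C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "B"}
)


class ParseError(ValueError):
    """Raised when a molecule file or SMILES string cannot be parsed."""


class DisconnectedGraphError(ValueError):
    """Raised for multi-fragment inputs where a single component is required."""

    def __init__(self, components: list[list[int]], name: str = ""):
        self.components = components
        label = f" in {name!r}" if name else ""
        super().__init__(
            f"disconnected molecular graph{label}: "
            f"{len(components)} components with atom index sets "
            + ", ".join(str(sorted(c)) for c in components)
        )


@dataclass(frozen=True)
class Atom:
    element: str
    formal_charge: int = 0
    n_h: int = 0
    aromatic: bool = False

    def __post_init__(self):
        if self.n_h < 0:
            raise ValueError("attached-hydrogen count must be >= 0")


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    order: str = "single"

    def __post_init__(self):
        if self.i == self.j:
            raise ValueError("a bond may not join an atom to itself")
        if self.order not in BOND_ORDERS:
            raise ValueError(f"unknown bond order {self.order!r}")


@dataclass
class MolecularGraph:
    """Heavy-atom graph with per-atom hydrogen counts.

    Invariants checked at construction: bond indices valid, no self-bonds,
    at most one bond per atom pair, aromatic bonds only between atoms
    flagged aromatic.
    """

    atoms: list[Atom]
    bonds: list[Bond]
    name: str = ""
    smiles: str = ""  # canonical echo when parsed from SMILES/SDF
    _adj: dict[int, list[tuple[int, str]]] = field(
        default_factory=dict, repr=False, compare=False
    )
    _rdmol: object = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        adj: dict[int, list[tuple[int, str]]] = {i: [] for i in range(n)}
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise ValueError(f"bond ({b.i},{b.j}) has an invalid atom index")
            key = (min(b.i, b.j), max(b.i, b.j))
            if key in seen:
                raise ValueError(f"duplicate bond between atoms {key}")
            seen.add(key)
            if b.order == "aromatic" and not (
                self.atoms[b.i].aromatic and self.atoms[b.j].aromatic
            ):
                raise ValueError(
                    f"aromatic bond ({b.i},{b.j}) between non-aromatic atoms"
                )
            adj[b.i].append((b.j, b.order))
            adj[b.j].append((b.i, b.order))
        object.__setattr__(self, "_adj", adj)

    def __len__(self) -> int:
        return len(self.atoms)

    def neighbors(self, i: int) -> list[tuple[int, str]]:
        """(neighbor index, bond order) pairs for heavy atom ``i``."""
        return self._adj[i]

    def components(self) -> list[list[int]]:
        unvisited = set(range(len(self.atoms)))
        comps = []
        while unvisited:
            stack = [min(unvisited)]
            comp = []
            while stack:
                k = stack.pop()
                if k not in unvisited:
                    continue
                unvisited.remove(k)
                comp.append(k)
                stack.extend(j for j, _ in self._adj[k])
            comps.append(comp)
        return comps


def heavy_degree(g: MolecularGraph, i: int) -> int:
    """Number of bonds from atom ``i`` to non-hydrogen neighbors."""
    if not 0 <= i < len(g.atoms):
        raise IndexError(f"atom index {i} out of range for {len(g.atoms)} atoms")
    return len(g.neighbors(i))


def graph_distance_matrix(g: MolecularGraph) -> np.ndarray:
    """Shortest-path bond counts between all heavy-atom pairs (BFS).

    Raises :class:`DisconnectedGraphError` for multi-component graphs.
    """
    comps = g.components()
    if len(comps) > 1:
        raise DisconnectedGraphError(comps, g.name)
    n = len(g.atoms)
    dist = np.full((n, n), -1, dtype=np.int64)
    for src in range(n):
        dist[src, src] = 0
        frontier = [src]
        d = 0
        while frontier:
            d += 1
            nxt = []
            for k in frontier:
                for j, _ in g.neighbors(k):
                    if dist[src, j] < 0:
                        dist[src, j] = d
                        nxt.append(j)
            frontier = nxt
    return dist


def _diagnose_smiles(smiles: str) -> str:
    """Best-effort location of the offending token in an unparseable SMILES."""
    stack = []
    pairs = {")": "(", "]": "["}
    for pos, ch in enumerate(smiles):
        if ch in "([":
            stack.append((ch, pos))
        elif ch in ")]":
            if not stack or stack[-1][0] != pairs[ch]:
                return f"unbalanced {ch!r} at position {pos}"
            stack.pop()
    if stack:
        ch, pos = stack[-1]
        return f"unclosed {ch!r} at position {pos}"
    return "rejected by the SMILES parser (valence or ring-closure problem)"


def from_rdkit(mol: Chem.Mol, name: str = "") -> MolecularGraph:
    """Convert a sanitized RDKit molecule into a :class:`MolecularGraph`."""
    atoms = [
        Atom(
            element=a.GetSymbol(),
            formal_charge=a.GetFormalCharge(),
            n_h=a.GetTotalNumHs(),
            aromatic=a.GetIsAromatic(),
        )
        for a in mol.GetAtoms()
    ]
    bonds = []
    for b in mol.GetBonds():
        order = _RDKIT_BOND.get(b.GetBondType())
        if order is None:
            raise ParseError(
                f"unsupported bond type {b.GetBondType()} in {name or 'molecule'}"
            )
        bonds.append(Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    smiles = Chem.MolToSmiles(mol)
    return MolecularGraph(
        atoms=atoms, bonds=bonds, name=name, smiles=smiles, _rdmol=mol
    )


def to_rdkit(g: MolecularGraph) -> Chem.Mol:
    """RDKit molecule for a graph: the parse-time mol when available, else a
    rebuild with explicit-H counts preserved."""
    if g._rdmol is not None:
        return g._rdmol
    rw = Chem.RWMol()
    for a in g.atoms:
        ra = Chem.Atom(a.element)
        ra.SetFormalCharge(a.formal_charge)
        ra.SetNumExplicitHs(a.n_h)
        ra.SetNoImplicit(True)
        ra.SetIsAromatic(a.aromatic)
        rw.AddAtom(ra)
    for b in g.bonds:
        rw.AddBond(b.i, b.j, _TO_RDKIT_BOND[b.order])
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return mol


def parse_smiles(
    smiles: str, name: str = "", largest_fragment: bool = False
) -> MolecularGraph:
    """Parse a SMILES string into a heavy-atom graph.

    Aromaticity is perceived by RDKit's default model and implicit hydrogens
    are counted onto their heavy atoms. Multi-fragment inputs (salts,
    mixtures) are rejected unless ``largest_fragment`` is set, in which case
    the component with the most heavy atoms is kept.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(
            f"cannot parse SMILES {smiles!r}: {_diagnose_smiles(smiles)}"
        )
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if len(frags) > 1:
        if not largest_fragment:
            raise DisconnectedGraphError(
                [list(ix) for ix in Chem.GetMolFrags(mol)], name or smiles
            )
        mol = max(frags, key=lambda m: m.GetNumAtoms())
    return from_rdkit(mol, name=name or smiles)


def read_smiles_file(path, largest_fragment: bool = False) -> list[MolecularGraph]:
    """Read a .smi file: one SMILES per line, optional whitespace-separated id."""
    graphs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smi = parts[0]
            name = parts[1].strip() if len(parts) > 1 else f"mol{lineno}"
            try:
                graphs.append(
                    parse_smiles(smi, name=name, largest_fragment=largest_fragment)
                )
            except ParseError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return graphs


def read_sdf(path, largest_fragment: bool = False) -> list[MolecularGraph]:
    """Read an SDF (V2000) file into graphs; record names come from the title."""
    graphs = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for k, mol in enumerate(supplier):
        if mol is None:
            raise ParseError(f"{path}: record {k + 1} could not be parsed")
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{k + 1}"
        frags = Chem.GetMolFrags(mol, asMols=True)
        if len(frags) > 1:
            if not largest_fragment:
                raise DisconnectedGraphError(
                    [list(ix) for ix in Chem.GetMolFrags(mol)], name
                )
            mol = max(frags, key=lambda m: m.GetNumAtoms())
        graphs.append(from_rdkit(mol, name=name))
    return graphs
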