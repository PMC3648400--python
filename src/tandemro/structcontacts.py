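"""Map top-ranked E-state symbols onto binding-site contacts.

Given a protein-ligand complex in PDB format, select the ligand atoms of a
requested E-state type (ssO ether oxygen, sssN amine nitrogen, aaO ring
oxygen, ...) and measure heavy-atom Euclidean distances to named protein
atoms (e.g. the Cys285 side-chain sulfur of PPARgamma). Distances are
between heavy atoms only — hydrogens are invisible to X-ray crystallography
— and are reported to 0.01 Angstrom.

PDB files carry no ligand bond orders, so E-state typing uses either bonds
inferred from geometry (RDKit proximity bonding) or, preferably, a
user-supplied SMILES template whose bond orders are transferred onto the
crystallographic ligand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import gemmi
import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from . import estate, molgraph

__all__ = ["ContactMeasurement", "LigandComplex", "load_complex",
           "measure_contacts", "parse_selection"]


class ComplexError(ValueError):
    """Problems locating or typing the ligand in a structure."""


@dataclass(frozen=True)
class ContactMeasurement:
    es_type: str
    ligand_atom: str          # PDB atom name
    residue: str              # e.g. "CYS285"
    protein_atom: str         # e.g. "SG"
    distance: float           # Angstrom, rounded to 0.01

    def __str__(self) -> str:
        return (f"{self.es_type} {self.ligand_atom} .. "
                f"{self.residue}:{self.protein_atom}  {self.distance:.2f} A")


@dataclass
class LigandComplex:
    """Protein atoms plus a bond-order-typed ligand graph."""

    structure: gemmi.Structure
    ligand_id: str
    ligand_graph: molgraph.MolecularGraph
    ligand_atom_names: list[str]       # parallel to ligand_graph.atoms
    ligand_positions: np.ndarray       # (n, 3) Angstrom
    atom_types: list[str]              # E-state type per ligand heavy atom

    def ligand_atoms_of_type(self, es_type: str) -> list[int]:
        return [i for i, t in enumerate(self.atom_types) if t == es_type]


def _pick_altloc(atoms, altloc: str | None):
    """Resolve alternate conformers: requested altloc, else highest occupancy."""
    by_name: dict[str, list] = {}
    for a in atoms:
        by_name.setdefault(a.name, []).append(a)
    picked = []
    for name, group in by_name.items():
        if len(group) == 1:
            picked.append(group[0])
            continue
        if altloc is not None:
            match = [a for a in group if a.altloc == altloc]
            if not match:
                raise ComplexError(
                    f"atom {name}: no altloc {altloc!r} "
                    f"(available: {sorted(a.altloc for a in group)})"
                )
            picked.append(match[0])
        else:
            picked.append(max(group, key=lambda a: (a.occ, -ord(a.altloc or " "))))
    return picked


def _ligand_pdb_block(residue, atoms) -> str:
    lines = []
    for k, a in enumerate(atoms, start=1):
        p = a.pos
        lines.append(
            f"HETATM{k:>5} {a.name:<4}{residue.name:>4} A{1:>4}    "
            f"{p.x:8.3f}{p.y:8.3f}{p.z:8.3f}{a.occ:6.2f}{0.0:6.2f}"
            f"          {a.element.name:>2}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def load_complex(
    pdb_path,
    ligand_id: str,
    ligand_smiles: str | None = None,
    altloc: str | None = None,
) -> LigandComplex:
    """Read a PDB complex and build an E-state-typed graph for one ligand.

    ``ligand_id`` is the hetero residue code (e.g. "BRL" for rosiglitazone
    in entry 2PRG). When ``ligand_smiles`` is given, its bond orders are
    transferred onto the crystallographic ligand (template matching), which
    is the reliable route for aromatic/charged ligands; otherwise bonds are
    inferred from interatomic distances. Raises listing the hetero residues
    found when the ligand code is absent.
    """
    st = gemmi.read_structure(str(pdb_path))
    st.setup_entities()
    model = st[0]

    ligand_res = None
    het_codes = set()
    for chain in model:
        for res in chain:
            if res.het_flag == "H" and res.name != "HOH":
                het_codes.add(res.name)
                if res.name == ligand_id and ligand_res is None:
                    ligand_res = res
    if ligand_res is None:
        raise ComplexError(
            f"ligand {ligand_id!r} not found; hetero residues present: "
            f"{sorted(het_codes) or 'none'}"
        )

    lig_atoms = _pick_altloc(
        [a for a in ligand_res if a.element.name != "H"], altloc
    )
    block = _ligand_pdb_block(ligand_res, lig_atoms)
    mol = Chem.MolFromPDBBlock(block, sanitize=False, removeHs=True,
                               proximityBonding=True)
    if mol is None:
        raise ComplexError(f"could not build a molecule for ligand {ligand_id!r}")
    if ligand_smiles is not None:
        template = Chem.MolFromSmiles(ligand_smiles)
        if template is None:
            raise ComplexError(f"bad ligand SMILES {ligand_smiles!r}")
        try:
            mol = AllChem.AssignBondOrdersFromTemplate(template, mol)
        except ValueError as exc:
            raise ComplexError(
                f"ligand SMILES does not match the crystallographic ligand: {exc}"
            ) from exc
    Chem.SanitizeMol(mol)
    graph = molgraph.from_rdkit(mol, name=ligand_id)
    names = [a.name for a in lig_atoms]
    positions = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in lig_atoms])
    types = estate.type_atoms(graph)
    return LigandComplex(
        structure=st,
        ligand_id=ligand_id,
        ligand_graph=graph,
        ligand_atom_names=names,
        ligand_positions=positions,
        atom_types=types,
    )


_SEL_RE = re.compile(r"^(?:([A-Za-z0-9])/)?([A-Za-z]{1,3})(\d+):([A-Za-z0-9']+)$")


def parse_selection(sel: str) -> tuple[str | None, str, int, str]:
    """Parse "CYS285:SG" or "A/CYS285:SG" into
    (chain or None, residue name, sequence number, atom name)."""
    m = _SEL_RE.match(sel.strip())
    if not m:
        raise ValueError(
            f"bad selection {sel!r}; expected [CHAIN/]RESNUM:ATOM "
            "like 'CYS285:SG' or 'A/CYS285:SG'"
        )
    chain = m.group(1).upper() if m.group(1) else None
    return chain, m.group(2).upper(), int(m.group(3)), m.group(4).upper()


def _resolve_protein_atom(
    cx: LigandComplex, sel: str, altloc: str | None, ambiguous: str = "error"
):
    chain_id, resname, seqnum, atomname = parse_selection(sel)
    hits = []
    for chain in cx.structure[0]:
        if chain_id is not None and chain.name.upper() != chain_id:
            continue
        for res in chain:
            if res.name == resname and res.seqid.num == seqnum:
                atoms = _pick_altloc(
                    [a for a in res if a.element.name != "H"], altloc
                )
                hits.extend(a for a in atoms if a.name == atomname)
    if not hits:
        raise ComplexError(f"selection {sel!r} matches no heavy atom")
    if len(hits) > 1:
        if ambiguous == "nearest":
            # contact semantics: the copy nearest the ligand is the one meant
            centroid = cx.ligand_positions.mean(axis=0)
            return min(
                hits,
                key=lambda a: np.linalg.norm(
                    np.array([a.pos.x, a.pos.y, a.pos.z]) - centroid
                ),
            )
        raise ComplexError(
            f"selection {sel!r} is ambiguous ({len(hits)} atoms across "
            "chains); qualify it as CHAIN/RES or pass ambiguous='nearest'"
        )
    return hits[0]


def measure_contacts(
    cx: LigandComplex,
    es_type: str,
    selections: list[str],
    altloc: str | None = None,
    ambiguous: str = "error",
) -> list[ContactMeasurement]:
    """Heavy-atom distances from every ligand atom of ``es_type`` to each
    selected protein atom, in Angstrom to 0.01. ``ambiguous="nearest"``
    resolves selections matching several chains to the copy nearest the
    ligand."""
    lig_idx = cx.ligand_atoms_of_type(es_type)
    if not lig_idx:
        raise ComplexError(
            f"ligand has no atom of E-state type {es_type!r}; "
            f"types present: {sorted(set(cx.atom_types))}"
        )
    out = []
    for sel in selections:
        pa = _resolve_protein_atom(cx, sel, altloc, ambiguous=ambiguous)
        ppos = np.array([pa.pos.x, pa.pos.y, pa.pos.z])
        _, resname, seqnum, atomname = parse_selection(sel)
        for i in lig_idx:
            d = float(np.linalg.norm(cx.ligand_positions[i] - ppos))
            out.append(
                ContactMeasurement(
                    es_type=es_type,
                    ligand_atom=cx.ligand_atom_names[i],
                    residue=f"{resname}{seqnum}",
                    protein_atom=atomname,
                    distance=round(d, 2),
                )
            )
    return out
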