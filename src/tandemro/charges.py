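"""Partial charges, the Jurs RNCG filter descriptor, and the descriptor matrix.

RNCG (relative negative charge) is the Stanton-Jurs CPSA quantity
|q_maxneg| / sum(|q_neg|): the fraction of a molecule's total negative
partial charge carried by its single most negative atom. It is the stage-1
"filter" descriptor of the tandem analysis — a bulk, charge-distribution
property — and needs only partial charges, no 3D surface.

Charges default to Gasteiger-Marsili (RDKit implementation) with hydrogen
charges folded onto their heavy atoms, so the charge vector is indexed like
the heavy-atom graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit.Chem import AllChem, Descriptors

from . import estate
from .molgraph import MolecularGraph, to_rdkit

logger = logging.getLogger(__name__)

__all__ = [
    "ChargeError",
    "assign_partial_charges",
    "rncg",
    "jurs_rncg",
    "DescriptorPool",
    "build_descriptor_matrix",
    "read_descriptor_matrix",
    "write_descriptor_matrix",
]


def read_descriptor_matrix(path) -> pd.DataFrame:
    """Read a TSV descriptor matrix (first column = compound id; leading
    '#' comment lines ignored)."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index.name = "id"
    return df


def write_descriptor_matrix(df: pd.DataFrame, path, comment: str = "") -> None:
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", float_format="%.6g")

#: polar atoms for the polar-atom-fraction pool descriptor
_POLAR_ELEMENTS = {"N", "O", "S", "P"}


class ChargeError(ValueError):
    """Charge assignment failed or a charge-based descriptor is undefined."""


def assign_partial_charges(g: MolecularGraph, method: str = "gasteiger") -> np.ndarray:
    """Per-heavy-atom partial charges (e), hydrogens folded onto heavy atoms."""
    if method != "gasteiger":
        raise ValueError(f"unknown charge model {method!r}")
    mol = to_rdkit(g)
    AllChem.ComputeGasteigerCharges(mol)
    q = np.empty(mol.GetNumAtoms())
    for a in mol.GetAtoms():
        qa = a.GetDoubleProp("_GasteigerCharge") + a.GetDoubleProp("_GasteigerHCharge")
        if not np.isfinite(qa):
            raise ChargeError(
                f"gasteiger charges did not converge for {g.name or g.smiles!r}"
            )
        q[a.GetIdx()] = qa
    return q


def rncg(charges: np.ndarray) -> float:
    """Relative negative charge: |most negative charge| / total negative charge.

    Lies in (0, 1]; equals 1 exactly when one atom carries all negative
    charge, and is invariant to positive rescaling of the charge vector.
    Undefined (raises) when no atom is negative.
    """
    q = np.asarray(charges, dtype=float)
    neg = q[q < 0]
    if neg.size == 0:
        raise ChargeError("RNCG undefined: no atom carries negative charge")
    return float(np.abs(neg).max() / np.abs(neg).sum())


def jurs_rncg(g: MolecularGraph, method: str = "gasteiger") -> float:
    """Jurs_RNCG of a molecule under the chosen charge model."""
    return rncg(assign_partial_charges(g, method=method))


@dataclass
class DescriptorPool:
    """Configuration of the descriptor-matrix columns.

    The ES Count/Sum pairs are always present (they are the stage-2 detector
    array); ``extras`` adds simple bulk competitors for the stage-1 screen,
    echoing the descriptor families that compete with Jurs_RNCG on real data
    (size, rings, polarity). ``charge_model`` is stamped into reports.
    """

    include_rncg: bool = True
    extras: tuple[str, ...] = (
        "HeavyAtomCount",
        "MolecularWeight",
        "RingBondCount",
        "PolarAtomFraction",
    )
    charge_model: str = "gasteiger"

    KNOWN_EXTRAS = (
        "HeavyAtomCount",
        "MolecularWeight",
        "RingBondCount",
        "PolarAtomFraction",
    )

    def __post_init__(self):
        unknown = set(self.extras) - set(self.KNOWN_EXTRAS)
        if unknown:
            raise ValueError(f"unknown pool descriptors: {sorted(unknown)}")

    @classmethod
    def from_file(cls, path) -> "DescriptorPool":
        """Load pool membership and charge model from a YAML config file.

        Recognised keys: ``extras`` (list), ``charge_model``, ``include_rncg``.
        """
        import yaml

        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        kwargs = {}
        if "extras" in cfg:
            kwargs["extras"] = tuple(cfg["extras"])
        if "charge_model" in cfg:
            kwargs["charge_model"] = str(cfg["charge_model"])
        if "include_rncg" in cfg:
            kwargs["include_rncg"] = bool(cfg["include_rncg"])
        return cls(**kwargs)


def _extra_descriptors(g: MolecularGraph, names: tuple[str, ...]) -> dict[str, float]:
    mol = to_rdkit(g)
    out: dict[str, float] = {}
    for name in names:
        if name == "HeavyAtomCount":
            out[name] = float(len(g.atoms))
        elif name == "MolecularWeight":
            out[name] = float(Descriptors.MolWt(mol))
        elif name == "RingBondCount":
            out[name] = float(sum(1 for b in mol.GetBonds() if b.IsInRing()))
        elif name == "PolarAtomFraction":
            out[name] = sum(a.element in _POLAR_ELEMENTS for a in g.atoms) / len(
                g.atoms
            )
    return out


def build_descriptor_matrix(
    mols: list[MolecularGraph],
    ids: list[str] | None = None,
    pool: DescriptorPool | None = None,
) -> pd.DataFrame:
    """Compounds x descriptors matrix: Jurs_RNCG, ES Count/Sum pairs, pool extras.

    The ES columns are the union of atom types over the whole set, zero-filled
    where a type is absent, so the matrix is rectangular with no missing
    cells. Molecules on which a descriptor fails (e.g. RNCG undefined) are
    excluded with a logged reason. Constant columns are retained but listed in
    ``df.attrs["constant_columns"]``; the charge model is stamped in
    ``df.attrs["charge_model"]``.
    """
    if not mols:
        raise ValueError("empty molecule list")
    pool = pool or DescriptorPool()
    ids = ids if ids is not None else [m.name or f"mol{k}" for k, m in enumerate(mols)]
    if len(ids) != len(mols):
        raise ValueError("ids and molecule list length mismatch")

    registry: set[str] = set()
    typed: dict[str, list[str]] = {}
    kept: list[tuple[str, MolecularGraph]] = []
    excluded: dict[str, str] = {}
    for cid, g in zip(ids, mols):
        try:
            types = estate.type_atoms(g)
        except estate.EStateError as exc:
            excluded[cid] = str(exc)
            logger.warning("excluding %s: %s", cid, exc)
            continue
        typed[cid] = types
        kept.append((cid, g))
        registry.update(types)

    reg = sorted(registry)
    rows = {}
    for cid, g in kept:
        try:
            row = {}
            if pool.include_rncg:
                row["Jurs_RNCG"] = jurs_rncg(g, method=pool.charge_model)
            row.update(estate.es_descriptor_vector(g, registry=reg))
            row.update(_extra_descriptors(g, pool.extras))
        except (estate.EStateError, ChargeError) as exc:
            excluded[cid] = str(exc)
            logger.warning("excluding %s: %s", cid, exc)
            continue
        rows[cid] = row

    if not rows:
        raise ValueError("no molecule survived descriptor computation")
    columns = (["Jurs_RNCG"] if pool.include_rncg else [])
    columns += [f"ES_{kind}_{t}" for t in reg for kind in ("Count", "Sum")]
    columns += list(pool.extras)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    df.index.name = "id"
    df.attrs["constant_columns"] = [
        c for c in df.columns if df[c].nunique(dropna=False) <= 1
    ]
    df.attrs["charge_model"] = pool.charge_model
    df.attrs["excluded"] = excluded
    return df
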