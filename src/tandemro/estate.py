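"""Electrotopological-state (E-state) atom typing and descriptor values.

Each heavy atom gets a bond-pattern symbol (s = single, d = double,
t = triple, a = aromatic; prefix letters ordered t, d, a, s to match the
canonical published names such as dssC, aasC, tsC) plus the element and an
H-count suffix: ssO is an oxygen with two single bonds, sssN a tertiary
amine nitrogen, aaO an aromatic-ring oxygen.

Per-atom values follow the Kier-Hall scheme:

    I = ((2/N)^2 * delta_v + 1) / delta          (intrinsic state)
    S_i = I_i + sum_j (I_i - I_j) / r_ij^2       (perturbed E-state)

with delta the heavy-atom degree, delta_v the valence-electron count minus
attached hydrogens (formal charge subtracts), N the principal quantum
number, and r_ij the topological distance plus one, so bonded neighbors sit
at r = 2. The perturbation runs over all heavy-atom pairs, no cutoff.
Pairwise perturbations are antisymmetric, so sum(S) == sum(I) always — a
cheap integrity check used throughout the test-suite.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np

from .molgraph import (
    SUPPORTED_ELEMENTS,
    MolecularGraph,
    graph_distance_matrix,
    heavy_degree,
)

__all__ = [
    "EStateError",
    "UnsupportedElementError",
    "type_atom",
    "type_atoms",
    "intrinsic_state",
    "estate_values",
    "es_descriptor_vector",
]

#: valence-electron counts for the supported organic element set
VALENCE_ELECTRONS = {
    "B": 3, "C": 4, "N": 5, "O": 6, "F": 7,
    "P": 5, "S": 6, "Cl": 7, "Br": 7, "I": 7,
}

#: principal quantum number of the valence shell
PRINCIPAL_QUANTUM = {
    "B": 2, "C": 2, "N": 2, "O": 2, "F": 2,
    "P": 3, "S": 3, "Cl": 3, "Br": 4, "I": 5,
}

_PREFIX_ORDER = {"t": 0, "d": 1, "a": 2, "s": 3}
_BOND_LETTER = {"single": "s", "double": "d", "triple": "t", "aromatic": "a"}


class EStateError(ValueError):
    """Raised when E-state values are undefined for the given graph."""


class UnsupportedElementError(EStateError):
    """Raised for atoms outside the supported organic element set."""


def type_atom(g: MolecularGraph, i: int) -> str:
    """E-state atom-type symbol for heavy atom ``i`` (e.g. ``"ssCH2"``).

    The prefix has one letter per bond to a heavy neighbor, sorted t, d, a, s;
    the hydrogen suffix appears only when the attached-H count is positive.
    """
    atom = g.atoms[i]
    if atom.element not in SUPPORTED_ELEMENTS:
        raise UnsupportedElementError(
            f"element {atom.element!r} (atom {i}) is outside the supported "
            f"organic set {sorted(SUPPORTED_ELEMENTS)}"
        )
    letters = sorted(
        (_BOND_LETTER[order] for _, order in g.neighbors(i)),
        key=_PREFIX_ORDER.__getitem__,
    )
    suffix = "" if atom.n_h == 0 else ("H" if atom.n_h == 1 else f"H{atom.n_h}")
    return "".join(letters) + atom.element + suffix


def type_atoms(g: MolecularGraph) -> list[str]:
    """Type every heavy atom of the graph."""
    return [type_atom(g, i) for i in range(len(g.atoms))]


def _delta_v(g: MolecularGraph, i: int) -> int:
    atom = g.atoms[i]
    if atom.element not in VALENCE_ELECTRONS:
        raise UnsupportedElementError(
            f"element {atom.element!r} (atom {i}) has no valence-electron entry"
        )
    return VALENCE_ELECTRONS[atom.element] - atom.n_h - atom.formal_charge


def intrinsic_state(g: MolecularGraph, i: int) -> float:
    """Kier-Hall intrinsic state I = ((2/N)^2 * delta_v + 1) / delta.

    For second-row elements (N = 2) this reduces to (delta_v + 1) / delta.
    Undefined for an atom with no heavy neighbor; such atoms only occur in
    single-heavy-atom molecules, which carry no topological information.
    """
    delta = heavy_degree(g, i)
    if delta < 1:
        raise EStateError(
            f"atom {i} ({g.atoms[i].element}) has no heavy neighbors; "
            "the intrinsic state requires delta >= 1"
        )
    dv = _delta_v(g, i)
    n = PRINCIPAL_QUANTUM[g.atoms[i].element]
    return ((2.0 / n) ** 2 * dv + 1.0) / delta


def estate_values(g: MolecularGraph) -> np.ndarray:
    """Per-atom E-state values S for a connected heavy-atom graph.

    S_i = I_i + sum_{j != i} (I_i - I_j) / (d_ij + 1)^2 with d the
    topological distance matrix. Raises for disconnected graphs, where the
    perturbation sum is undefined across components.
    """
    n = len(g.atoms)
    if n == 0:
        raise EStateError("empty molecular graph")
    I = np.array([intrinsic_state(g, i) for i in range(n)], dtype=float)
    d = graph_distance_matrix(g)
    r2 = (d + 1.0) ** 2
    diff = I[:, None] - I[None, :]
    np.fill_diagonal(r2, np.inf)
    return I + (diff / r2).sum(axis=1)


def intrinsic_states(g: MolecularGraph) -> np.ndarray:
    return np.array([intrinsic_state(g, i) for i in range(len(g.atoms))])


def es_descriptor_vector(
    g: MolecularGraph, registry: list[str] | None = None
) -> dict[str, float]:
    """ES_Count_*/ES_Sum_* descriptor pairs for one molecule.

    ``registry`` is an optional global list of type symbols; types absent
    from the molecule are then reported as 0/0, which is what makes a
    rectangular compound x descriptor matrix possible.
    """
    types = type_atoms(g)
    S = estate_values(g)
    counts: dict[str, int] = defaultdict(int)
    sums: dict[str, float] = defaultdict(float)
    for t, s in zip(types, S):
        counts[t] += 1
        sums[t] += float(s)
    symbols = registry if registry is not None else sorted(counts)
    out: dict[str, float] = {}
    for t in symbols:
        out[f"ES_Count_{t}"] = float(counts.get(t, 0))
        out[f"ES_Sum_{t}"] = float(sums.get(t, 0.0))
    return out
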