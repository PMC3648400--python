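"""Synthetic analog series with planted structural modifications.

Real agonist series of the kind the tandem analysis targets share a core
scaffold (here a thiazolidinedione head on a benzyl ether, the classic
glitazone layout) and vary in the tail: ether linkers (ssO), methylene
elongation (ssCH2), a tertiary amine (sssN) and, rarely, an aromatic-O
heterocycle (oxazole, aaO) carried by just a couple of compounds — the
"analog outlier" situation.

Activities are generated on the pEC50 scale as

    Y_i = beta0 + beta_bulk * RNCG_i + sum_k gamma_k * count_k(i) + eps_i,

with eps ~ Normal(0, sigma^2) and EC50 emitted as 10^(-Y). The bulk term
uses the series' own computed Jurs_RNCG (not an independent latent), so at
small sigma the stage-1 screen is guaranteed a genuine bulk descriptor to
find. Every moiety's declared E-state signature is re-derived from the
emitted molecule at generation time; a mismatch is a hard error, which
keeps the planted truth honest against the typing engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import charges, estate, molgraph

__all__ = ["Moiety", "AnalogSetSpec", "PlantedTruth", "GeneratedSet",
           "generate_analog_set", "planted_truth", "default_spec",
           "random_molecule_graph"]


def random_molecule_graph(
    rng: np.random.Generator, max_atoms: int = 12
) -> molgraph.MolecularGraph:
    """Random connected heavy-atom tree over the supported element set.

    Used to stress the descriptor arithmetic (conservation, oracle
    equivalence, typing totality) with varied elements, degrees, bond orders
    and H counts; chemical plausibility is deliberately not enforced, since
    the E-state formulas are defined for any typed graph.
    """
    n = int(rng.integers(2, max_atoms + 1))
    elements = rng.choice(["C", "C", "C", "N", "O", "S", "Cl", "P"], size=n)
    atoms = [
        molgraph.Atom(element=str(e), n_h=int(rng.integers(0, 3)))
        for e in elements
    ]
    bonds = []
    for i in range(1, n):
        j = int(rng.integers(0, i))  # random tree: connected, acyclic
        order = str(rng.choice(["single", "single", "single", "double"]))
        bonds.append(molgraph.Bond(i, j, order))
    return molgraph.MolecularGraph(atoms=atoms, bonds=bonds, name=f"rand{n}")


class GenerationError(RuntimeError):
    """A fragment is chemically incompatible with its site, or the emitted
    molecule's typing contradicts the declared moiety signature."""


@dataclass(frozen=True)
class Moiety:
    """A tail fragment with a declared E-state signature and planted effect.

    mode:
      ``count``    — 0..max_count copies per compound, uniform;
      ``optional`` — present with probability ``prob``;
      ``rare``     — present in exactly ``rare_count`` compounds of the set.
    ``gamma`` is the activity effect in log units per copy. ``gate`` marks
    moieties whose declared type is context-free (no other fragment can add
    or remove atoms of that type), which the generator verifies against the
    typing engine on every emitted molecule; linker carbons (ssCH2) are
    contributed by several fragments at once, so that moiety is not gated.
    """

    name: str
    unit: str          # SMILES fragment appended to the tail
    es_type: str       # E-state type the fragment contributes
    per_unit: int = 1  # copies of es_type added per fragment
    gamma: float = 0.0
    mode: str = "count"
    max_count: int = 3
    prob: float = 0.5
    rare_count: int = 2
    gate: bool = True


@dataclass(frozen=True)
class AnalogSetSpec:
    """Configuration of one synthetic analog series."""

    n: int = 150
    seed: int = 0
    scaffold: str = "O=C1NC(=O)SC1Cc1ccc({tail})cc1"
    base_tail: str = "OCC"  # constant ether linker, one ssO in every compound
    moieties: tuple[Moiety, ...] = (
        Moiety("ether", "OCC", "ssO", gamma=-1.5, mode="count", max_count=3),
        Moiety("methylene", "C", "ssCH2", gamma=0.0, mode="count", max_count=4,
               gate=False),
        Moiety("tert-amine", "CN(C)C", "sssN", gamma=+1.0, mode="optional",
               prob=0.4),
        # ring label 2: the fragment is spliced inside the scaffold's open ring 1
        Moiety("oxazole", "c2ocnc2", "aaO", gamma=+2.0, mode="rare",
               rare_count=2),
    )
    beta0: float = 6.0
    beta_bulk: float = 20.0   # on Jurs_RNCG; spans ~1.3 log units over the set
    sigma: float = 0.3

    def __post_init__(self):
        if self.n < 10:
            raise ValueError("analog sets need n >= 10")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def default_spec(seed: int = 0, **overrides) -> AnalogSetSpec:
    return replace(AnalogSetSpec(), seed=seed, **overrides)


@dataclass
class PlantedTruth:
    """What the detector should recover: ES types with effect signs."""

    signs: dict[str, str]                 # es_type -> "+" / "-"
    rare: dict[str, int] = field(default_factory=dict)  # es_type -> support

    def expected_top(self) -> dict[str, str]:
        return dict(self.signs)


@dataclass
class GeneratedSet:
    molecules: list[molgraph.MolecularGraph]
    activities: pd.DataFrame          # index id; ec50_molar, pEC50
    truth: PlantedTruth
    counts: pd.DataFrame              # per-compound moiety copy counts
    rncg: pd.Series

    @property
    def ids(self) -> list[str]:
        return list(self.activities.index)

    def to_files(self, prefix) -> None:
        """Write <prefix>.smi, <prefix>.activities.tsv, <prefix>.truth.json."""
        import json
        from pathlib import Path

        prefix = Path(prefix)
        with open(f"{prefix}.smi", "w") as fh:
            for g in self.molecules:
                fh.write(f"{g.smiles}\t{g.name}\n")
        out = self.activities[["ec50_molar"]].reset_index()
        out.to_csv(f"{prefix}.activities.tsv", sep="\t", index=False)
        with open(f"{prefix}.truth.json", "w") as fh:
            json.dump({"signs": self.truth.signs, "rare": self.truth.rare},
                      fh, indent=2, sort_keys=True)
            fh.write("\n")


def planted_truth(spec: AnalogSetSpec) -> PlantedTruth:
    """Expected top ES types with signs, derivable from the spec alone."""
    signs = {
        m.es_type: ("+" if m.gamma > 0 else "-")
        for m in spec.moieties
        if m.gamma != 0.0
    }
    rare = {
        m.es_type: m.rare_count
        for m in spec.moieties
        if m.mode == "rare" and m.gamma != 0.0
    }
    return PlantedTruth(signs=signs, rare=rare)


def _draw_copies(spec: AnalogSetSpec, rng: np.random.Generator) -> pd.DataFrame:
    cols = {}
    for m in spec.moieties:
        if m.mode == "count":
            cols[m.name] = rng.integers(0, m.max_count + 1, size=spec.n)
        elif m.mode == "optional":
            cols[m.name] = (rng.random(spec.n) < m.prob).astype(int)
        elif m.mode == "rare":
            picks = rng.choice(spec.n, size=min(m.rare_count, spec.n),
                               replace=False)
            v = np.zeros(spec.n, dtype=int)
            v[picks] = 1
            cols[m.name] = v
        else:
            raise ValueError(f"unknown moiety mode {m.mode!r}")
    return pd.DataFrame(cols, index=[f"cpd{k + 1:03d}" for k in range(spec.n)])


def _assemble(spec: AnalogSetSpec, copies: pd.Series) -> str:
    # chain fragments first (they end in sp3 carbon, safe to extend),
    # terminal fragments (amine, aryl) last
    chain, terminal = [], []
    for m in spec.moieties:
        c = int(copies[m.name])
        if c == 0:
            continue
        if m.unit[0].islower() or "(" in m.unit:
            if c > 1:
                raise GenerationError(
                    f"fragment {m.name!r} is terminal; cannot place {c} copies"
                )
            terminal.append(m.unit)
        else:
            chain.append(m.unit * c)
    tail = spec.base_tail + "".join(chain) + "".join(terminal)
    return spec.scaffold.format(tail=tail)


def generate_analog_set(spec: AnalogSetSpec) -> GeneratedSet:
    """Generate molecules, activities and the planted truth for one spec.

    Deterministic for a fixed spec (including its seed). The declared ES
    signature of every moiety is checked against the estate typing of each
    emitted molecule; EC50 round-trips to pEC50 exactly by construction.
    """
    rng = np.random.default_rng(spec.seed)
    copies = _draw_copies(spec, rng)
    base_g = molgraph.parse_smiles(
        spec.scaffold.format(tail=spec.base_tail), name="base"
    )
    base_counts = {
        m.es_type: estate.type_atoms(base_g).count(m.es_type)
        for m in spec.moieties
    }

    mols: list[molgraph.MolecularGraph] = []
    rncg_vals = np.empty(spec.n)
    type_counts = np.zeros((spec.n, len(spec.moieties)), dtype=int)
    for k, (cid, row) in enumerate(copies.iterrows()):
        smi = _assemble(spec, row)
        try:
            g = molgraph.parse_smiles(smi, name=cid)
        except molgraph.ParseError as exc:
            raise GenerationError(f"{cid}: fragment assembly failed: {exc}")
        types = estate.type_atoms(g)
        for j, m in enumerate(spec.moieties):
            got = types.count(m.es_type)
            if m.gate:
                want = base_counts[m.es_type] + m.per_unit * int(row[m.name])
                if got != want:
                    raise GenerationError(
                        f"{cid}: moiety {m.name!r} declares {m.es_type} x"
                        f"{m.per_unit} per copy but typing finds {got} "
                        f"(expected {want}) in {smi}"
                    )
            type_counts[k, j] = got
        rncg_vals[k] = charges.jurs_rncg(g)
        mols.append(g)

    gammas = np.array([m.gamma for m in spec.moieties])
    eps = rng.normal(0.0, spec.sigma, size=spec.n) if spec.sigma > 0 else 0.0
    y = spec.beta0 + spec.beta_bulk * rncg_vals + type_counts @ gammas + eps
    activities = pd.DataFrame(
        {"ec50_molar": np.power(10.0, -y), "pEC50": y}, index=copies.index
    )
    activities.index.name = "id"
    return GeneratedSet(
        molecules=mols,
        activities=activities,
        truth=planted_truth(spec),
        counts=copies,
        rncg=pd.Series(rncg_vals, index=copies.index, name="Jurs_RNCG"),
    )
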