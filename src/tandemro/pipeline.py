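"""End-to-end pipeline: molecules + activities in, paper-shaped reports out.

All tables are TSV (header row, '.' decimal); a JSON manifest records the
package version, charge model, seed, and a hash of the configuration so
that every report of a run can be traced to one invocation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__, charges, molgraph, tandem

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    molecules: str                     # .smi or .sdf path
    activities: str                    # CSV/TSV with id, ec50_molar
    out_dir: str = "tandemro_out"
    filter_descriptor: str = "Jurs_RNCG"
    top_k: int = 12
    sizes: list[int] | None = None
    near_rank: int = 4
    subset_order: str = "desc"
    seed: int = 0
    largest_fragment: bool = False
    pool_extras: tuple[str, ...] = charges.DescriptorPool().extras
    charge_model: str = "gasteiger"

    def validate(self) -> None:
        for p in (self.molecules, self.activities):
            if not Path(p).exists():
                raise ConfigError(f"input file not found: {p}")
        if self.top_k < 1:
            raise ConfigError("top-k must be >= 1")

    def digest(self) -> str:
        payload = json.dumps(
            dataclasses.asdict(self), sort_keys=True, default=str
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _read_molecules(cfg: RunConfig) -> list[molgraph.MolecularGraph]:
    path = Path(cfg.molecules)
    if path.suffix.lower() in {".sdf", ".mol"}:
        return molgraph.read_sdf(path, largest_fragment=cfg.largest_fragment)
    return molgraph.read_smiles_file(path, largest_fragment=cfg.largest_fragment)


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Run both tandem stages and write the report bundle.

    Outputs in ``cfg.out_dir``: descriptors.tsv, screen.tsv, dominance.tsv,
    monitor.tsv (rank / ES descriptor / sign), dependency.tsv and
    manifest.json. Any stage error aborts with a stage-named message and
    removes partial outputs.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    digest = cfg.digest()

    def _write(name: str, df) -> None:
        path = out / name
        with open(path, "w") as fh:
            fh.write(f"# tandemro {__version__} run {digest} "
                     f"charge_model={cfg.charge_model}\n")
            df.to_csv(fh, sep="\t", float_format="%.6g")
        written[name] = path

    stage = "input"
    try:
        mols = _read_molecules(cfg)
        activities = tandem.load_activities(cfg.activities)

        stage = "descriptors"
        pool = charges.DescriptorPool(
            extras=tuple(cfg.pool_extras), charge_model=cfg.charge_model
        )
        D = charges.build_descriptor_matrix(mols, pool=pool)
        _write("descriptors.tsv", D)

        stage = "screen"
        screen = tandem.screen_single_descriptors(D, activities)
        _write("screen.tsv", screen)

        stage = "dominance"
        n = len(D.index.intersection(activities.index))
        sizes = cfg.sizes or [s for s in range(10, n + 1, 10)]
        tally = tandem.DominanceScreen(
            D, activities, focal=cfg.filter_descriptor,
            sizes=sizes, near_rank=cfg.near_rank,
            subset_order=cfg.subset_order,
        ).fit()
        _write("dominance.tsv", tally.summary())

        stage = "prioritize"
        results = tandem.ContextEquationModel(
            D, activities, filter_descriptor=cfg.filter_descriptor
        ).fit()
        _write("monitor.tsv", results.summary(k=cfg.top_k))

        stage = "diagnose"
        report = results.dependency_diagnostics(k=cfg.top_k)
        dep = report.support.to_frame("support")
        dep["rare"] = dep.index.isin(report.rare_descriptors)
        dep["beta_combined"] = report.combined_coefficients
        dep["sign_flip"] = dep.index.isin(report.sign_flips)
        _write("dependency.tsv", dep)

        stage = "manifest"
        manifest = {
            "tandemro_version": __version__,
            "config": dataclasses.asdict(cfg),
            "config_hash": digest,
            "charge_model": cfg.charge_model,
            "seed": cfg.seed,
            "n_compounds": int(n),
            "n_descriptors": int(D.shape[1]),
            "excluded_molecules": D.attrs.get("excluded", {}),
            "excluded_activities": int(activities.attrs.get("n_excluded", 0)),
            "constant_columns": D.attrs.get("constant_columns", []),
        }
        path = out / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        written["manifest.json"] = path
    except Exception as exc:
        for p in written.values():
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return written
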