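"""End-to-end orchestration: one config, deterministic outputs, a manifest.

A run directory is write-once: the presence of ``manifest.json`` blocks a
rerun into the same directory.  Every stage failure is re-raised tagged
with the stage name; configuration problems raise :class:`ConfigError`
(CLI exit code 1) while runtime failures propagate (exit code 2).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

import tricall
from tricall.calls import (
    CallTable,
    read_call_table,
    write_call_table,
)
from tricall.clustering import (
    CLUSTERS,
    assign_clusters,
    cluster_modifier_profile,
    membership_frame,
    reconcile,
)
from tricall.contingency import cross_tabulate
from tricall.enrichment import AnnotationMap, bootstrap_enrichment
from tricall.motifs import (
    PromoterSet,
    hits_to_frame,
    match_catalog,
    prune_nested,
    read_catalog,
    scan_motifs,
)
from tricall.similarity import build_signature, rank_panel
from tricall import synthetic

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


@dataclasses.dataclass
class RunConfig:
    """Validated run configuration (raw mapping + resolved paths)."""

    raw: dict
    base_dir: Path
    outdir: Path
    seed: int

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        try:
            raw = yaml.safe_load(path.read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(raw, base_dir=path.parent)

    @classmethod
    def from_dict(cls, raw: dict, base_dir=".") -> "RunConfig":
        if "seed" not in raw:
            raise ConfigError("config must set a seed")
        if "outdir" not in raw:
            raise ConfigError("config must set an outdir")
        base = Path(base_dir)
        outdir = Path(raw["outdir"])
        if not outdir.is_absolute():
            outdir = base / outdir
        return cls(raw=raw, base_dir=base, outdir=outdir, seed=int(raw["seed"]))

    def resolve(self, rel) -> Path:
        p = Path(rel)
        p = p if p.is_absolute() else self.base_dir / p
        if not p.exists():
            raise ConfigError(f"referenced file does not exist: {p}")
        return p

    def config_hash(self) -> str:
        canonical = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_calls(cfg: RunConfig) -> CallTable:
    section = cfg.raw.get("calls", {})
    if "path" in section:
        table = read_call_table(cfg.resolve(section["path"]))
    elif "simulate" in section or not section:
        sim = section.get("simulate", {}) or {}
        table, _ = synthetic.plant_clusters(
            cluster_sizes=sim.get("cluster_sizes",
                                  {"A": 105, "B": 39, "C": 97, "D": 23}),
            single_sizes=sim.get("single_sizes", {}),
            n_background=int(sim.get("n_background", 2000)),
            seed=cfg.seed,
        )
    else:
        raise ConfigError("calls: need 'path' or 'simulate'")
    mapping = cfg.raw.get("contrast_map", {}) or {}
    if mapping:
        frame = table.to_frame().rename(columns=mapping)
        table = CallTable.from_frame(frame, provenance=table.provenance)
    return table


def run_all(cfg: RunConfig) -> dict:
    """Execute every configured stage; return the manifest."""
    outdir = cfg.outdir
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists():
        raise ConfigError(
            f"{manifest_path} already exists; run directories are write-once"
        )
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    def emit(name: str, path: Path) -> None:
        outputs[name] = _sha256(path)

    state: dict[str, Any] = {}

    def stage(name: str):
        class _Ctx:
            def __enter__(self):
                logger.info("stage %s: start", name)

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, ConfigError):
                    raise StageError(f"stage {name!r} failed: {exc}") from exc
                if exc is None:
                    logger.info("stage %s: done", name)
                return False

        return _Ctx()

    # -- calls -------------------------------------------------------------
    with stage("calls"):
        table = _load_calls(cfg)
        state["table"] = table
        path = outdir / "calls.tsv"
        write_call_table(table, path)
        emit("calls", path)

    # -- crosstab ----------------------------------------------------------
    section = cfg.raw.get("crosstab")
    if section:
        with stage("crosstab"):
            rows = section.get("rows")
            col = section.get("col")
            if not rows or not col:
                raise ConfigError("crosstab: need 'rows' and 'col'")
            missing = [c for c in [*rows, col]
                       if c not in table.contrast_names]
            if missing:
                raise ConfigError(
                    f"crosstab: contrasts missing from call table: {missing}"
                )
            result = cross_tabulate(table, rows, col)
            tsv = outdir / "crosstab.tsv"
            result.to_frame().to_csv(tsv, sep="\t", index=False)
            js = outdir / "crosstab.json"
            js.write_text(json.dumps(result.summary(), indent=2))
            emit("crosstab.tsv", tsv)
            emit("crosstab.json", js)

    # -- cluster -----------------------------------------------------------
    section = cfg.raw.get("cluster")
    if section:
        with stage("cluster"):
            inhibitors = section.get("inhibitors", ["EDE", "U73"])
            if len(inhibitors) != 2:
                raise ConfigError("cluster: exactly two inhibitors required")
            missing = [c for c in [*inhibitors, "SA", "W30B", "W30SA"]
                       if c not in table.contrast_names]
            if missing:
                raise ConfigError(
                    f"cluster: contrasts missing from call table: {missing}"
                )
            kwargs = {
                "d_excludes_inhibitor_up": bool(
                    section.get("d_excludes_inhibitor_up", True)),
                "c_excludes_w30sa_up": bool(
                    section.get("c_excludes_w30sa_up", False)),
            }
            assignments = [
                assign_clusters(table, inh, **kwargs) for inh in inhibitors
            ]
            rc = reconcile(*assignments)
            state["clusters"] = rc
            tsv = outdir / "cluster_members.tsv"
            membership_frame(rc).to_csv(tsv, sep="\t", index=False)
            js = outdir / "cluster_summary.json"
            js.write_text(json.dumps(rc.sizes(), indent=2))
            emit("cluster_members.tsv", tsv)
            emit("cluster_summary.json", js)
            modifier = section.get("modifier")
            if modifier:
                prof = cluster_modifier_profile(rc, table, modifier)
                mpath = outdir / f"cluster_modifier_{modifier}.tsv"
                prof.to_csv(mpath, sep="\t", index=False)
                emit(mpath.name, mpath)

    # -- enrichment --------------------------------------------------------
    section = cfg.raw.get("enrichment")
    if section:
        with stage("enrichment"):
            if "annotations" in section:
                ann = AnnotationMap.from_tsv(
                    cfg.resolve(section["annotations"]),
                    universe=state["table"].genes,
                )
            else:
                sim = section.get("simulate", {}) or {}
                ann, set_genes, _ = synthetic.simulate_annotations(
                    n_universe=int(sim.get("n_universe",
                                           state["table"].n_genes)),
                    background_freqs=sim.get("background_freqs", [0.1] * 5),
                    set_size=int(sim.get("set_size", 100)),
                    set_multipliers=sim.get("set_multipliers", [3, 1, 1, 1, 1]),
                    seed=cfg.seed,
                )
                state["simulated_set"] = set_genes
            spec = section.get("set", "simulated")
            if isinstance(spec, str) and spec.startswith("cluster:"):
                if "clusters" not in state:
                    raise ConfigError("enrichment: cluster stage did not run")
                gene_set = sorted(state["clusters"].stringent[spec.split(":", 1)[1]])
            elif spec == "simulated":
                if "simulated_set" not in state:
                    raise ConfigError("enrichment: no simulated set available")
                gene_set = state["simulated_set"]
            else:
                gene_set = cfg.resolve(spec).read_text().split()
            profile = bootstrap_enrichment(
                gene_set, ann,
                n_boot=int(section.get("n_boot", 100)), seed=cfg.seed,
            )
            path = outdir / "enrichment.tsv"
            profile.to_csv(path, sep="\t")
            emit("enrichment.tsv", path)

    # -- motifs ------------------------------------------------------------
    section = cfg.raw.get("motifs")
    if section:
        with stage("motifs"):
            if "fg" in section and "bg" in section:
                fg = PromoterSet.from_fasta(cfg.resolve(section["fg"]))
                bg = PromoterSet.from_fasta(cfg.resolve(section["bg"]))
            else:
                sim = section.get("simulate", {}) or {}
                fg, bg, _ = synthetic.simulate_promoters(
                    n_fg=int(sim.get("n_fg", 50)),
                    n_bg=int(sim.get("n_bg", 50)),
                    length=int(sim.get("length", 300)),
                    motif=sim.get("motif", "TTGACC"),
                    p_fg=float(sim.get("p_fg", 0.6)),
                    p_bg=float(sim.get("p_bg", 0.02)),
                    seed=cfg.seed,
                )
            hits = scan_motifs(
                fg, bg,
                kmin=int(section.get("kmin", 4)),
                kmax=int(section.get("kmax", 10)),
                alpha=float(section.get("alpha", 1e-5)),
            )
            if section.get("prune_nested"):
                hits = prune_nested(hits)
            if "catalog" in section:
                hits = match_catalog(hits,
                                     read_catalog(cfg.resolve(section["catalog"])))
            path = outdir / "motif_hits.tsv"
            hits_to_frame(hits).to_csv(path, sep="\t", index=False)
            emit("motif_hits.tsv", path)

    # -- similarity --------------------------------------------------------
    section = cfg.raw.get("similarity")
    if section:
        with stage("similarity"):
            n_top = int(section.get("n_top", 200))
            if "changes" in section:
                changes = pd.read_csv(cfg.resolve(section["changes"]), sep="\t",
                                      index_col=0).iloc[:, 0]
            else:
                sim = section.get("simulate", {}) or {}
                import numpy as np

                rng = np.random.default_rng(cfg.seed)
                n_genes = int(sim.get("n_genes", max(1000, 3 * n_top)))
                changes = pd.Series(
                    rng.normal(size=n_genes),
                    index=[f"G{i:05d}" for i in range(n_genes)],
                )
            sig = build_signature(changes, n_top=n_top)
            if "panel" in section:
                panel = pd.read_csv(cfg.resolve(section["panel"]), sep="\t",
                                    index_col=0)
            else:
                sim = section.get("simulate", {}) or {}
                panel, _ = synthetic.simulate_panel(
                    sig,
                    n_experiments=int(sim.get("n_experiments", 8)),
                    noise_step=float(sim.get("noise_step", 0.3)),
                    seed=cfg.seed,
                )
            ranking = rank_panel(sig, panel,
                                 mode=section.get("mode", "values"))
            path = outdir / "similarity.tsv"
            ranking.to_csv(path, sep="\t", index=False)
            emit("similarity.tsv", path)

    manifest = {
        "package_version": tricall.__version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "outputs": outputs,
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
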