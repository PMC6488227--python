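"""End-to-end orchestration: load inputs, build the seed network, cluster it,
rank miRNA families by spanning score, and (optionally) run the hallmark-style
gene-set enrichment — writing every stage's table, a manifest with parameters
and input checksums, and a plain-text log. Rerunning with the same config and
inputs reproduces byte-identical tables.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cluster import cluster_table, spectral_partition
from .errors import MirspanError, ValidationError
from .io import load_gmt, load_interactome, load_mirna_targets, load_seed_list
from .network import build_seed_network, map_seeds, network_summary, write_seed_network
from .ranking import (mirna_enrichment_profile, hallmark_enrichment,
                      rank_families, ranking_table, spanning_score)

log = logging.getLogger("mirspan")


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run."""

    interactome: str
    seeds: str
    targets: str | None = None
    gmt: str | None = None
    outdir: str = "mirspan_out"
    interactome_format: str = "edge_list"
    target_dialect: str = "simple"
    target_species: str = "9606"
    alpha: float = 0.05
    min_module_size: int = 3
    seed_incident_only: bool = False
    min_seed_links: int = 1
    universe: str = "interactome"  # or "targets": restrict to target-table gene space

    @classmethod
    def from_yaml(cls, path, **overrides):
        with open(path, "rt", encoding="utf-8") as f:
            raw = yaml.safe_load(f) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        known.update({k: v for k, v in overrides.items() if v is not None})
        if "interactome" not in known or "seeds" not in known:
            raise ValidationError("config must provide 'interactome' and 'seeds'")
        return cls(**known)

    def validate_paths(self):
        for name in ("interactome", "seeds", "targets", "gmt"):
            p = getattr(self, name)
            if p is not None and not Path(p).is_file():
                raise ValidationError(f"{name} file does not exist: {p}")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full flow; returns a dict of result objects and written
    paths. Any stage failure marks the manifest as partial and re-raises."""
    cfg.validate_paths()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.monotonic()
    manifest = {
        "tool": "mirspan",
        "version": __version__,
        "status": "running",
        "parameters": asdict(cfg),
        "inputs": {name: {"path": str(getattr(cfg, name)),
                          "sha256": _sha256(getattr(cfg, name))}
                   for name in ("interactome", "seeds", "targets", "gmt")
                   if getattr(cfg, name) is not None},
    }
    manifest_path = out / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=True))

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    results: dict = {"outdir": out}
    try:
        interactome = load_interactome(cfg.interactome, format=cfg.interactome_format)
        log.info("interactome: %d nodes, %d edges (%s)", interactome.n_nodes,
                 interactome.n_edges, interactome.source_counts)
        seedset = map_seeds(interactome, load_seed_list(cfg.seeds))
        log.info("seeds: %d mapped, %d unmapped", len(seedset.mapped),
                 len(seedset.unmapped))
        net = build_seed_network(interactome, seedset,
                                 seed_incident_only=cfg.seed_incident_only,
                                 min_seed_links=cfg.min_seed_links)
        summary = network_summary(net)
        log.info("seed network: %(n_nodes)d genes, %(n_edges)d interactions", summary)
        clustering = spectral_partition(net, min_module_size=cfg.min_module_size)
        log.info("clustering: %d modules, Q=%.4f", clustering.n_modules,
                 clustering.modularity)
        write_seed_network(net, out / "network_edges.tsv", out / "network_nodes.tsv",
                           clustering)
        pd.DataFrame([summary]).to_csv(out / "network_summary.tsv", sep="\t",
                                       index=False)
        cluster_table(net, clustering).to_csv(out / "modules.tsv", sep="\t",
                                              index=False)
        results.update(interactome=interactome, seedset=seedset, net=net,
                       summary=summary, clustering=clustering)

        if cfg.targets is not None:
            families = load_mirna_targets(cfg.targets, dialect=cfg.target_dialect,
                                          species=cfg.target_species)
            universe = None
            if cfg.universe == "targets":
                universe = interactome.nodes & set().union(
                    *(f.targets for f in families))
            scored = [spanning_score(
                f.family_id,
                mirna_enrichment_profile(f, interactome, net, clustering,
                                         universe=universe),
                alpha=cfg.alpha) for f in families]
            ranked = rank_families(scored)
            table = ranking_table(ranked, families)
            table.to_csv(out / "ranking.tsv", sep="\t", index=False)
            log.info("ranked %d families; top: %s", len(ranked),
                     ranked[0].family_id if ranked else "-")
            results.update(families=families, ranked=ranked, ranking_table=table)

        if cfg.gmt is not None:
            collection = load_gmt(cfg.gmt)
            hallmark = hallmark_enrichment(net.nodes, collection, interactome.nodes)
            hallmark.to_csv(out / "hallmark.tsv", sep="\t", index=False)
            log.info("hallmark enrichment over %d gene sets", len(hallmark))
            results["hallmark"] = hallmark

        manifest["status"] = "completed"
    except MirspanError:
        manifest["status"] = "failed-partial"
        raise
    finally:
        manifest["wall_time_s"] = round(time.monotonic() - t0, 3)
        manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=True))
        log.removeHandler(handler)
        handler.close()
    return results
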