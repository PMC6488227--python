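"""Synthetic inputs with the statistical structure the analysis assumes.

The generator emulates, at desk scale, the situation the pipeline is built
for: a modular disease-associated region (a planted-partition graph of
``n_blocks`` dense blocks) embedded in a much larger, sparse interactome
(``n_background`` background genes with low attachment probability), seed
genes drawn from the blocks, and miRNA families whose target sets have
controlled breadth across blocks. Because the background dominates the
universe while seeds concentrate in the blocks, the seed + first-neighbor
network is a small subnetwork of the interactome — the regime in which
per-module target enrichment is informative. Two regulators are planted with
equal target counts: a *broad* family whose targets spread evenly over
``broad_family_spread`` blocks and a *narrow* family confined to
``narrow_spread`` blocks (overflow beyond block capacity is placed on
background genes so the two families' K stay equal); the remaining decoy
families draw targets uniformly. Assay tables (ChIP-qPCR and comparative
qPCR Ct values) carry planted log2 effects plus Gaussian noise.

Every output is exactly reproducible from ``rng_seed``; a machine-readable
truth record accompanies the files and a self-audit verifies the two agree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np

from .errors import ValidationError
from .io import (GeneSetCollection, Interactome, MirnaFamily, write_gmt,
                 write_interactome)

from collections import OrderedDict


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic scenario (defaults are the study
    conditions the pipeline is exercised under; see docs/methods.md)."""

    rng_seed: int = 0
    n_blocks: int = 8
    block_size: int = 40
    p_within: float = 0.25
    p_between: float = 0.01
    n_background: int = 2880
    p_background: float = 2.0e-4
    n_seeds: int = 276
    seed_block_bias: float = 0.0
    n_unmapped_seeds: int = 0
    n_families: int = 153
    targets_per_family: int = 60
    broad_family_spread: int | None = None  # None -> n_blocks
    narrow_spread: int = 1
    decoy_target_rate: float = 1.0
    chip_n_per_group: int = 5
    chip_effect_log2: float = 2.0
    chip_noise_sd: float = 0.3
    chip_input_fraction: float = 0.1
    qpcr_n_per_group: int = 20
    qpcr_fold: float = 2.0
    qpcr_noise_sd: float = 0.2

    def __post_init__(self):
        for name in ("p_within", "p_between", "p_background", "seed_block_bias",
                     "decoy_target_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_blocks", "block_size", "n_seeds", "n_families",
                     "targets_per_family", "narrow_spread"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        if self.n_background < 0 or self.n_unmapped_seeds < 0:
            raise ValidationError("counts must be non-negative")
        spread = self.broad_family_spread
        if spread is not None and not 1 <= spread <= self.n_blocks:
            raise ValidationError("broad_family_spread must be in [1, n_blocks]")
        if self.narrow_spread > self.n_blocks:
            raise ValidationError("narrow_spread cannot exceed n_blocks")

    @property
    def spread(self) -> int:
        return self.n_blocks if self.broad_family_spread is None else self.broad_family_spread


BROAD_FAMILY_ID = "MIR-BROADSYN"
NARROW_FAMILY_ID = "MIR-NARROWSYN"


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic scenario, consistent with the emitted
    files (enforced by :func:`self_audit`)."""

    block_of: dict
    seeds: list
    broad_family_id: str
    narrow_family_id: str
    family_roles: dict
    family_spread: dict
    assay_effects: dict = field(default_factory=dict)


@dataclass
class SyntheticScenario:
    """In-memory bundle of everything one scenario produced."""

    config: SyntheticConfig
    interactome: Interactome
    seeds: list
    families: list
    gene_sets: GeneSetCollection
    chip_table: "object"
    qpcr_table: "object"
    truth: SyntheticTruth


def _block_gene_names(cfg: SyntheticConfig) -> list:
    return [[f"G{b + 1:02d}N{i:03d}" for i in range(cfg.block_size)]
            for b in range(cfg.n_blocks)]


def _background_gene_names(cfg: SyntheticConfig) -> list:
    return [f"BKG{i:05d}" for i in range(cfg.n_background)]


def _bernoulli_pairs(rng, genes_a, genes_b, p, same_group):
    """Sampled edges between two gene groups at probability p (vectorized)."""
    if p == 0.0 or not genes_a or not genes_b:
        return []
    a = np.asarray(genes_a, dtype=object)
    b = np.asarray(genes_b, dtype=object)
    if same_group:
        ii, jj = np.triu_indices(len(a), k=1)
        hit = rng.random(ii.size) < p
        return list(zip(a[ii[hit]], a[jj[hit]]))
    hit = rng.random((len(a), len(b))) < p
    ii, jj = np.nonzero(hit)
    return list(zip(a[ii], b[jj]))


def simulate_interactome(cfg: SyntheticConfig, rng=None):
    """Planted-partition interactome plus background genes.

    Returns (:class:`Interactome`, :class:`SyntheticTruth` with block labels;
    background genes carry block -1). Fatal if no edge is realized.
    """
    rng = np.random.default_rng(cfg.rng_seed) if rng is None else rng
    blocks = _block_gene_names(cfg)
    background = _background_gene_names(cfg)
    groups = blocks + ([background] if background else [])
    n_groups = len(groups)
    edges = []
    for i in range(n_groups):
        for j in range(i, n_groups):
            i_bg = i >= cfg.n_blocks
            j_bg = j >= cfg.n_blocks
            if i == j:
                p = cfg.p_background if i_bg else cfg.p_within
            elif i_bg or j_bg:
                p = cfg.p_background
            else:
                p = cfg.p_between
            edges.extend(_bernoulli_pairs(rng, groups[i], groups[j], p, i == j))
    if not edges:
        raise ValidationError("synthetic parameters produced an edgeless graph")
    graph = nx.Graph()
    for genes in groups:
        graph.add_nodes_from(genes)
    graph.add_edges_from(edges)
    block_of = {g: b for b, genes in enumerate(blocks) for g in genes}
    block_of.update({g: -1 for g in background})
    truth = SyntheticTruth(block_of=block_of, seeds=[],
                           broad_family_id=BROAD_FAMILY_ID,
                           narrow_family_id=NARROW_FAMILY_ID,
                           family_roles={}, family_spread={})
    return Interactome(graph=graph, source_counts={"kept": len(edges)}), truth


def _even_allocation(total: int, parts: int) -> list:
    base, extra = divmod(total, parts)
    return [base + (1 if i < extra else 0) for i in range(parts)]


def simulate_seeds_and_targets(cfg: SyntheticConfig, truth: SyntheticTruth,
                               rng=None):
    """Seed list (block-biased) and the miRNA family target table.

    The broad family's targets are allocated evenly (per-block counts differ
    by at most 1) over the first ``spread`` blocks; the narrow family fills
    its blocks to capacity and places the overflow on background genes; the
    remaining families draw ``decoy_target_rate`` of their targets uniformly
    from the whole gene universe and the rest uniformly from block genes.
    Returns (seeds, families, updated truth).
    """
    rng = np.random.default_rng(cfg.rng_seed + 1) if rng is None else rng
    blocks = _block_gene_names(cfg)
    block_genes = [g for genes in blocks for g in genes]
    background = _background_gene_names(cfg)
    all_genes = block_genes + background
    T = cfg.targets_per_family
    if T > len(all_genes):
        raise ValidationError("targets_per_family exceeds the synthetic genome size")
    if cfg.n_seeds > len(block_genes):
        raise ValidationError("n_seeds exceeds the number of block genes")

    # seeds: geometric tilt (1 - bias)^b across blocks, uniform within a block
    w = np.array([(1.0 - cfg.seed_block_bias) ** b for b in range(cfg.n_blocks)])
    per_gene = np.repeat(w / w.sum() / cfg.block_size, cfg.block_size)
    seeds = list(rng.choice(np.asarray(block_genes, dtype=object), size=cfg.n_seeds,
                            replace=False, p=per_gene, shuffle=False))
    seeds += [f"ABSENT{i:03d}" for i in range(cfg.n_unmapped_seeds)]

    families = []
    roles, spread_of = {}, {}

    # planted broad regulator: even allocation over `spread` blocks
    spread = cfg.spread
    counts = _even_allocation(T, spread)
    if max(counts) > cfg.block_size:
        raise ValidationError("broad family targets exceed block capacity")
    broad_targets = set()
    for b, c in enumerate(counts):
        broad_targets.update(rng.choice(np.asarray(blocks[b], dtype=object),
                                        size=c, replace=False, shuffle=False))
    families.append(MirnaFamily(BROAD_FAMILY_ID, [BROAD_FAMILY_ID], broad_targets))
    roles[BROAD_FAMILY_ID] = "broad"
    spread_of[BROAD_FAMILY_ID] = spread

    # planted narrow regulator: same K, confined to `narrow_spread` blocks;
    # overflow beyond block capacity goes to background genes
    narrow_blocks = list(range(cfg.n_blocks - cfg.narrow_spread, cfg.n_blocks))
    capacity = cfg.narrow_spread * cfg.block_size
    in_block = min(T, capacity)
    overflow = T - in_block
    if overflow > len(background):
        raise ValidationError(
            "narrow family overflow exceeds available background genes")
    narrow_targets = set()
    for b, c in zip(narrow_blocks, _even_allocation(in_block, cfg.narrow_spread)):
        narrow_targets.update(rng.choice(np.asarray(blocks[b], dtype=object),
                                         size=c, replace=False, shuffle=False))
    if overflow:
        narrow_targets.update(rng.choice(np.asarray(background, dtype=object),
                                         size=overflow, replace=False, shuffle=False))
    families.append(MirnaFamily(NARROW_FAMILY_ID, [NARROW_FAMILY_ID], narrow_targets))
    roles[NARROW_FAMILY_ID] = "narrow"
    spread_of[NARROW_FAMILY_ID] = cfg.narrow_spread

    # decoys: uniform draws (a 1 - decoy_target_rate share restricted to blocks)
    n_decoys = cfg.n_families - 2
    all_arr = np.asarray(all_genes, dtype=object)
    for i in range(n_decoys):
        fid = f"MIR-SYN{i:03d}"
        n_uniform = round(cfg.decoy_target_rate * T)
        chosen = set(rng.choice(all_arr, size=n_uniform, replace=False, shuffle=False))
        remaining = [g for g in block_genes if g not in chosen]
        need = T - len(chosen)
        if need > 0:
            chosen.update(rng.choice(np.asarray(remaining, dtype=object),
                                     size=need, replace=False, shuffle=False))
        families.append(MirnaFamily(fid, [fid], chosen))
        roles[fid] = "decoy"
        spread_of[fid] = 0

    truth.seeds = seeds
    truth.family_roles = roles
    truth.family_spread = spread_of
    return seeds, families, truth


def simulate_gene_sets(cfg: SyntheticConfig, rng=None) -> GeneSetCollection:
    """Hallmark-style collection: one gene set per block (block genes plus a
    sprinkling of background genes) and two uniform decoy sets."""
    rng = np.random.default_rng(cfg.rng_seed + 2) if rng is None else rng
    blocks = _block_gene_names(cfg)
    background = _background_gene_names(cfg)
    sets: "OrderedDict[str, tuple[str, set]]" = OrderedDict()
    for b, genes in enumerate(blocks):
        members = set(genes)
        if background:
            n_extra = min(len(genes) // 2, len(background))
            members.update(rng.choice(np.asarray(background, dtype=object),
                                      size=n_extra, replace=False, shuffle=False))
        sets[f"SYNSET_BLOCK{b + 1}"] = (f"synthetic process of block {b + 1}", members)
    all_genes = np.asarray([g for gg in blocks for g in gg] + background, dtype=object)
    for i in range(2):
        members = set(rng.choice(all_genes, size=min(50, all_genes.size),
                                 replace=False, shuffle=False))
        sets[f"SYNSET_RANDOM{i + 1}"] = ("synthetic uniform decoy set", members)
    return GeneSetCollection(sets=sets)


def simulate_assays(cfg: SyntheticConfig, rng=None):
    """ChIP-qPCR and comparative qPCR Ct tables with planted effects.

    ChIP: two patient groups, antibodies ZEB1/ZEB2/IgG over promoter and
    control regions, N = ``chip_n_per_group`` per cell. The first group's
    ZEB antibodies carry a planted ``chip_effect_log2`` enrichment on the
    promoter region over a 1% baseline percent input; IgG rows and control
    regions have no planted effect. qPCR: ``qpcr_fold``-fold planted
    expression difference of the first group relative to the second.
    Gaussian Ct noise has the configured sds (0 recovers effects exactly).
    Returns (chip DataFrame, qpcr DataFrame, effects dict).
    """
    import pandas as pd

    rng = np.random.default_rng(cfg.rng_seed + 3) if rng is None else rng
    groups = ["BAV", "TAV"]
    base_percent = 1.0
    dilution = math.log2(1.0 / cfg.chip_input_fraction)
    chip_rows = []
    for antibody in ["ZEB1", "ZEB2", "IGG"]:
        for region in ["promoter", "control"]:
            for group in groups:
                planted = (cfg.chip_effect_log2
                           if (group == "BAV" and antibody != "IGG"
                               and region == "promoter") else 0.0)
                percent = base_percent * 2.0 ** planted
                for i in range(cfg.chip_n_per_group):
                    ct_input = 30.0 + rng.normal(0.0, cfg.chip_noise_sd)
                    ct_ip = (ct_input - dilution - math.log2(percent / 100.0)
                             + rng.normal(0.0, cfg.chip_noise_sd))
                    chip_rows.append({
                        "sample_id": f"{group}{i + 1:02d}",
                        "group": group, "antibody": antibody, "region": region,
                        "ct_ip": round(ct_ip, 6), "ct_input": round(ct_input, 6),
                        "input_fraction": cfg.chip_input_fraction,
                    })
    qpcr_rows = []
    base_dct = 5.0
    for group in groups:
        dct = base_dct - (math.log2(cfg.qpcr_fold) if group == "BAV" else 0.0)
        for i in range(cfg.qpcr_n_per_group):
            ct_ref = 20.0 + rng.normal(0.0, cfg.qpcr_noise_sd)
            ct_target = ct_ref + dct + rng.normal(0.0, cfg.qpcr_noise_sd)
            qpcr_rows.append({
                "sample_id": f"{group}{i + 1:02d}", "group": group,
                "target": "MIR200C", "reference": "U6",
                "ct_target": round(ct_target, 6),
                "ct_reference": round(ct_ref, 6),
            })
    effects = {
        "chip_planted_percent_promoter_zeb_bav": base_percent * 2.0 ** cfg.chip_effect_log2,
        "chip_baseline_percent": base_percent,
        "qpcr_planted_fold_bav_vs_tav": cfg.qpcr_fold,
    }
    return pd.DataFrame(chip_rows), pd.DataFrame(qpcr_rows), effects


def simulate_scenario(cfg: SyntheticConfig) -> SyntheticScenario:
    """Generate the full scenario in memory (graph, seeds, families, gene
    sets, assay tables, truth), then self-audit it."""
    interactome, truth = simulate_interactome(cfg)
    seeds, families, truth = simulate_seeds_and_targets(cfg, truth)
    gene_sets = simulate_gene_sets(cfg)
    chip, qpcr, effects = simulate_assays(cfg)
    truth.assay_effects = effects
    scenario = SyntheticScenario(config=cfg, interactome=interactome, seeds=seeds,
                                 families=families, gene_sets=gene_sets,
                                 chip_table=chip, qpcr_table=qpcr, truth=truth)
    problems = self_audit(scenario)
    if problems:
        raise ValidationError("synthetic truth inconsistent with outputs",
                              details={"problems": problems})
    return scenario


def self_audit(scenario: SyntheticScenario) -> list:
    """Cross-check the truth record against the generated objects; returns a
    list of problem descriptions (empty when consistent)."""
    cfg, truth = scenario.config, scenario.truth
    problems = []
    nodes = scenario.interactome.nodes
    if set(truth.block_of) != nodes:
        problems.append("gene universe does not match truth block labels")
    mapped = [s for s in truth.seeds if not s.startswith("ABSENT")]
    if len(mapped) != cfg.n_seeds or not set(mapped) <= nodes:
        problems.append("seed list inconsistent with interactome")
    fam_by_id = {f.family_id: f for f in scenario.families}
    if len(fam_by_id) != cfg.n_families:
        problems.append("family count mismatch")
    broad = fam_by_id.get(truth.broad_family_id)
    if broad is None:
        problems.append("broad family missing")
    else:
        per_block = {}
        for g in broad.targets:
            per_block[truth.block_of[g]] = per_block.get(truth.block_of[g], 0) + 1
        counts = [per_block.get(b, 0) for b in range(cfg.spread)]
        if max(counts) - min(counts) > 1 or sum(per_block.values()) != len(broad.targets):
            problems.append("broad family targets not evenly spread")
        if len(broad.targets) != cfg.targets_per_family:
            problems.append("broad family target count mismatch")
    narrow = fam_by_id.get(truth.narrow_family_id)
    if narrow is None:
        problems.append("narrow family missing")
    else:
        narrow_blocks = set(range(cfg.n_blocks - cfg.narrow_spread, cfg.n_blocks))
        in_block = [g for g in narrow.targets if truth.block_of[g] >= 0]
        if {truth.block_of[g] for g in in_block} - narrow_blocks:
            problems.append("narrow family block targets outside its blocks")
        if len(narrow.targets) != cfg.targets_per_family:
            problems.append("narrow family target count mismatch")
    return problems


def write_scenario(scenario: SyntheticScenario, outdir) -> dict:
    """Write every scenario file (the exact formats the readers accept), a
    truth record, and a ready-to-run pipeline config; returns the path map."""
    import pandas as pd  # noqa: F401  (tables are pandas DataFrames)
    import yaml
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / fname for name, fname in [
        ("interactome", "interactome.tsv"), ("seeds", "seeds.txt"),
        ("targets", "targets.tsv"), ("gene_sets", "genesets.gmt"),
        ("chip", "chip.tsv"), ("qpcr", "qpcr.tsv"),
        ("truth_genes", "truth_genes.tsv"),
        ("truth_families", "truth_families.tsv"),
        ("manifest", "manifest.yaml"), ("run_config", "run.yaml"),
    ]}
    write_interactome(scenario.interactome, paths["interactome"])
    with open(paths["seeds"], "wt", encoding="utf-8") as f:
        f.write("# synthetic seed genes\n")
        for s in scenario.seeds:
            f.write(s + "\n")
    with open(paths["targets"], "wt", encoding="utf-8") as f:
        f.write("family_id\tgene_symbol\n")
        for fam in scenario.families:
            for g in sorted(fam.targets):
                f.write(f"{fam.family_id}\t{g}\n")
    write_gmt(scenario.gene_sets, paths["gene_sets"])
    scenario.chip_table.to_csv(paths["chip"], sep="\t", index=False)
    scenario.qpcr_table.to_csv(paths["qpcr"], sep="\t", index=False)
    with open(paths["truth_genes"], "wt", encoding="utf-8") as f:
        f.write("gene\tblock\n")
        for g in sorted(scenario.truth.block_of):
            f.write(f"{g}\t{scenario.truth.block_of[g]}\n")
    with open(paths["truth_families"], "wt", encoding="utf-8") as f:
        f.write("family_id\trole\tspread\tn_targets\n")
        for fam in scenario.families:
            f.write(f"{fam.family_id}\t{scenario.truth.family_roles[fam.family_id]}"
                    f"\t{scenario.truth.family_spread[fam.family_id]}"
                    f"\t{len(fam.targets)}\n")
    with open(paths["manifest"], "wt", encoding="utf-8") as f:
        yaml.safe_dump({"config": asdict(scenario.config),
                        "assay_effects": scenario.truth.assay_effects}, f,
                       sort_keys=True)
    with open(paths["run_config"], "wt", encoding="utf-8") as f:
        yaml.safe_dump({
            "interactome": str(paths["interactome"]),
            "seeds": str(paths["seeds"]),
            "targets": str(paths["targets"]),
            "target_dialect": "simple",
            "gmt": str(paths["gene_sets"]),
            "outdir": str(out / "results"),
            "alpha": 0.05,
            "min_module_size": 3,
        }, f, sort_keys=True)
    return paths
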