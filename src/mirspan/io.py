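"""Readers and writers for the external table formats.

Three inputs feed the pipeline: an interactome as a tab-separated gene-symbol
edge list (SIF also accepted), a miRNA-family -> target-gene table in either a
TargetScan-7-style dialect or a minimal two-column dialect, and a gene-set
collection in GMT format. Gene identity throughout the package is the
uppercased symbol; no alias resolution is attempted, so unmapped symbols are
reported rather than guessed.
"""

from __future__ import annotations

import re
from collections import OrderedDict
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .errors import InputError, ValidationError

_RNA_ALPHABET = frozenset("ACGU")
_WS = re.compile(r"\s")


def normalize_gene_id(symbol: str) -> str:
    """Uppercase a gene symbol after stripping flanking whitespace.

    Raises :class:`ValidationError` for empty tokens or tokens with internal
    whitespace. Normalization is idempotent.
    """
    token = str(symbol).strip()
    if not token:
        raise ValidationError("empty gene symbol")
    if _WS.search(token):
        raise ValidationError(f"gene symbol contains whitespace: {token!r}")
    return token.upper()


@dataclass
class Interactome:
    """Undirected, unweighted gene-association graph; the enrichment universe.

    ``source_counts`` records, per input-line category, how many lines were
    kept or dropped during parsing (kept / duplicate / self_loop / malformed /
    comment).
    """

    graph: nx.Graph
    source_counts: dict = field(default_factory=dict)

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set:
        return {tuple(sorted(e)) for e in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class MirnaFamily:
    """A miRNA family: mature members sharing a seed, plus their target set.

    ``seed_sequence`` is the 7-mer at mature positions 2-8 when known (families
    built by :func:`group_families_by_seed`); target tables loaded from disk
    may not carry sequences, in which case it is ``None``.
    """

    family_id: str
    members: list
    targets: set = field(default_factory=set)
    seed_sequence: str | None = None

    def __post_init__(self):
        if not self.members:
            raise ValidationError(f"family {self.family_id!r} has no members")
        if self.seed_sequence is not None:
            if len(self.seed_sequence) != 7 or not set(self.seed_sequence) <= _RNA_ALPHABET:
                raise ValidationError(
                    f"seed sequence must be an RNA 7-mer, got {self.seed_sequence!r}"
                )


@dataclass
class GeneSetCollection:
    """Named gene sets (name -> (description, genes)), e.g. hallmark-style."""

    sets: "OrderedDict[str, tuple[str, set]]"
    n_skipped: int = 0

    def __len__(self):
        return len(self.sets)

    def genes(self, name: str) -> set:
        return self.sets[name][1]


def _parse_edge_fields(fields, fmt):
    """Yield candidate (a, b) symbol pairs from one split line."""
    if fmt == "edge_list":
        if len(fields) < 2:
            raise InputError("fewer than 2 columns")
        yield fields[0], fields[1]
    else:  # sif: node, relation, node(s)
        if len(fields) < 3:
            raise InputError("SIF row needs >= 3 columns")
        for other in fields[2:]:
            yield fields[0], other


def load_interactome(path, format: str = "edge_list") -> Interactome:
    """Read an interactome from a tab-separated edge list or SIF file.

    Edges are undirected and deduplicated; self-loops are dropped; symbols are
    uppercased. Lines starting with ``#`` are skipped. Raises
    :class:`ValidationError` if no edge survives filtering (counts attached).
    """
    if format not in ("edge_list", "sif"):
        raise InputError(f"unknown interactome format {format!r}")
    counts = {"kept": 0, "duplicate": 0, "self_loop": 0, "malformed": 0, "comment": 0}
    graph = nx.Graph()
    try:
        handle = open(path, "rt", encoding="utf-8")
    except OSError as exc:
        raise InputError(f"cannot read interactome file {path}: {exc}") from exc
    with handle:
        for raw in handle:
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.lstrip().startswith("#"):
                counts["comment"] += 1
                continue
            fields = line.split("\t")
            try:
                for a_raw, b_raw in _parse_edge_fields(fields, format):
                    a, b = normalize_gene_id(a_raw), normalize_gene_id(b_raw)
                    if a == b:
                        counts["self_loop"] += 1
                    elif graph.has_edge(a, b):
                        counts["duplicate"] += 1
                    else:
                        graph.add_edge(a, b)
                        counts["kept"] += 1
            except (InputError, ValidationError):
                counts["malformed"] += 1
    if counts["kept"] == 0:
        raise ValidationError("no valid edges in interactome file", details=counts)
    return Interactome(graph=graph, source_counts=counts)


def write_interactome(interactome: Interactome, path) -> None:
    """Write an interactome as a sorted tab-separated edge list (round-trips
    through :func:`load_interactome` with an identical node and edge set)."""
    with open(path, "wt", encoding="utf-8") as out:
        for a, b in sorted(interactome.edges):
            out.write(f"{a}\t{b}\n")


_TS7_REQUIRED = {
    "family": "mir family",
    "gene": "gene symbol",
    "species": "species id",
}


def _match_ts7_columns(columns):
    """Map logical names to actual header names by case-insensitive substring."""
    found = {}
    for logical, needle in _TS7_REQUIRED.items():
        for col in columns:
            if needle in str(col).lower():
                found[logical] = col
                break
    missing = [v for k, v in _TS7_REQUIRED.items() if k not in found]
    if missing:
        raise InputError(
            f"TargetScan-style table is missing required columns matching {missing}; "
            f"found columns: {list(columns)}"
        )
    return found


def load_mirna_targets(path, dialect: str = "targetscan7", species: str = "9606"):
    """Read a miRNA -> target table; returns one :class:`MirnaFamily` per
    distinct family id, targets deduplicated and uppercased.

    ``targetscan7``: tab-separated with a header; columns are located
    case-insensitively by the substrings "miR family", "Gene Symbol",
    "Species ID", and rows are filtered to ``species`` (default human, 9606)
    before aggregation. ``simple``: two tab-separated columns
    (family_id, gene_symbol), header optional.
    """
    if dialect not in ("targetscan7", "simple"):
        raise InputError(f"unknown miRNA target dialect {dialect!r}")
    targets: "OrderedDict[str, set]" = OrderedDict()
    if dialect == "targetscan7":
        try:
            table = pd.read_csv(path, sep="\t", dtype=str)
        except OSError as exc:
            raise InputError(f"cannot read target table {path}: {exc}") from exc
        cols = _match_ts7_columns(table.columns)
        keep = table[cols["species"]].astype(str).str.strip() == str(species)
        for _, row in table[keep].iterrows():
            fam = str(row[cols["family"]]).strip()
            gene = normalize_gene_id(row[cols["gene"]])
            targets.setdefault(fam, set()).add(gene)
    else:
        try:
            handle = open(path, "rt", encoding="utf-8")
        except OSError as exc:
            raise InputError(f"cannot read target table {path}: {exc}") from exc
        with handle:
            for i, raw in enumerate(handle):
                line = raw.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise InputError(f"{path}: line {i + 1}: expected 2 columns")
                if i == 0 and fields[0].strip().lower() == "family_id":
                    continue  # optional header row
                fam = fields[0].strip()
                targets.setdefault(fam, set()).add(normalize_gene_id(fields[1]))
    return [MirnaFamily(family_id=fam, members=[fam], targets=tg)
            for fam, tg in sorted(targets.items())]


def group_families_by_seed(mature_mirnas) -> list:
    """Group mature miRNAs into families by identical seed (positions 2-8).

    ``mature_mirnas`` is a list of (name, mature RNA sequence) pairs; each
    sequence must be RNA over {A,C,G,U} of length >= 8. The family id is the
    sorted member names joined with "/"; target sets start empty. Every input
    miRNA lands in exactly one family.
    """
    by_seed: "OrderedDict[str, list]" = OrderedDict()
    for name, seq in mature_mirnas:
        seq = str(seq).strip().upper()
        if len(seq) < 8:
            raise ValidationError(f"mature sequence of {name!r} shorter than 8 nt")
        if not set(seq) <= _RNA_ALPHABET:
            raise ValidationError(f"mature sequence of {name!r} is not RNA over ACGU")
        by_seed.setdefault(seq[1:8], []).append(str(name))
    families = []
    for seed, names in by_seed.items():
        members = sorted(names)
        families.append(MirnaFamily(family_id="/".join(members), members=members,
                                    seed_sequence=seed))
    return sorted(families, key=lambda f: f.family_id)


def load_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file (name, description, genes..., tab-separated).

    Duplicate set names are fatal; lines with no genes are skipped and counted
    in ``n_skipped``; an empty collection is fatal.
    """
    sets: "OrderedDict[str, tuple[str, set]]" = OrderedDict()
    n_skipped = 0
    try:
        handle = open(path, "rt", encoding="utf-8")
    except OSError as exc:
        raise InputError(f"cannot read GMT file {path}: {exc}") from exc
    with handle:
        for raw in handle:
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3 or not any(f.strip() for f in fields[2:]):
                n_skipped += 1
                continue
            name, desc = fields[0].strip(), fields[1].strip()
            if name in sets:
                raise InputError(f"duplicate gene-set name {name!r} in {path}")
            genes = {normalize_gene_id(g) for g in fields[2:] if g.strip()}
            sets[name] = (desc, genes)
    if not sets:
        raise ValidationError(f"GMT file {path} contains no usable gene sets")
    return GeneSetCollection(sets=sets, n_skipped=n_skipped)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "wt", encoding="utf-8") as out:
        for name, (desc, genes) in collection.sets.items():
            out.write("\t".join([name, desc] + sorted(genes)) + "\n")


def load_seed_list(path) -> list:
    """Read a seed-gene list (one symbol per line, '#' comments allowed),
    preserving input order, without deduplication (map_seeds dedupes)."""
    seeds = []
    try:
        handle = open(path, "rt", encoding="utf-8")
    except OSError as exc:
        raise InputError(f"cannot read seed list {path}: {exc}") from exc
    with handle:
        for raw in handle:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            seeds.append(normalize_gene_id(line))
    if not seeds:
        raise ValidationError(f"seed list {path} is empty")
    return seeds
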