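"""PPI-overlay gene regulatory network construction and core extraction.

The GRN is the subgraph of a STRING-format protein association table induced
by a regulator together with its direct and putative-direct target genes:
an edge is retained when its combined confidence score reaches a threshold
(default 150 on STRING's 0-1000 scale, inclusive) and both endpoints belong
to the target set. Nodes with no retained edge are excluded — the graph is
defined by its edges. The "core section" around a seed (usually the
regulator itself) is the induced first-neighbor subgraph, including
neighbor-neighbor edges, implementing guilt-by-association. Edges are
undirected: the network carries no direction of regulation.

Graphs are plain :class:`networkx.Graph` objects with the conventions:
``graph["regulator_id"]`` names the distinguished node, every node has a
``status`` attribute (regulator / direct / putative_direct), every edge a
``score`` attribute.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import networkx as nx

from velvet_grn.target_classify import STATUS_DIRECT, STATUS_PUTATIVE, TargetRecord

logger = logging.getLogger(__name__)

GRN = nx.Graph  # type alias: see module docstring for the attribute contract


def read_string_links(path: str | Path) -> list[tuple[str, str, int]]:
    """Read a STRING links file (protein1 protein2 combined_score, whitespace).

    Edges are deduplicated under endpoint swap keeping the maximum score;
    self-loops are dropped. Non-integer scores raise an error naming the line.
    """
    best: dict[tuple[str, str], int] = {}
    with open(path) as fh:
        header = fh.readline().split()
        if header[:2] != ["protein1", "protein2"]:
            raise ValueError(f"{path}: expected header 'protein1 protein2 combined_score'")
        for lineno, line in enumerate(fh, 2):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            a, b, raw = parts
            try:
                score = int(raw)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer combined_score {raw!r}") from None
            if a == b:
                continue
            key = (a, b) if a < b else (b, a)
            if score > best.get(key, -1):
                best[key] = score
    return [(a, b, s) for (a, b), s in sorted(best.items())]


def read_alias(path: str | Path) -> dict[str, str]:
    """Read a two-column protein-id -> gene-id alias table (TSV, no header or with)."""
    alias: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: alias table needs 2 columns")
            if lineno == 1 and parts[0].lower() in ("protein_id", "protein", "string_protein_id"):
                continue
            alias[parts[0]] = parts[1]
    return alias


def map_edges_to_genes(
    edges: Iterable[tuple[str, str, int]], alias: dict[str, str]
) -> tuple[list[tuple[str, str, int]], int]:
    """Map protein-id edges to gene-id edges; unmapped or self-mapping edges drop.

    Re-deduplicates under swap after mapping (two protein pairs can collapse
    onto one gene pair), keeping the maximum score. Returns (edges, n_dropped).
    """
    best: dict[tuple[str, str], int] = {}
    dropped = 0
    for a, b, score in edges:
        ga, gb = alias.get(a), alias.get(b)
        if ga is None or gb is None or ga == gb:
            dropped += 1
            continue
        key = (ga, gb) if ga < gb else (gb, ga)
        if score > best.get(key, -1):
            best[key] = score
    if dropped:
        logger.info("map_edges_to_genes: dropped %d unmappable/self edges", dropped)
    return [(a, b, s) for (a, b), s in sorted(best.items())], dropped


def build_grn(
    target_statuses: dict[str, str] | Iterable[TargetRecord],
    edges: Iterable[tuple[str, str, int]],
    regulator_id: str,
    min_score: int = 150,
) -> nx.Graph:
    """Build the regulator-mediated GRN from gene-mapped scored edges.

    Retains edges with combined_score >= ``min_score`` whose endpoints both
    belong to {regulator} union direct union putative_direct targets. The
    node set is exactly the endpoints of retained edges.
    """
    if not isinstance(target_statuses, dict):
        target_statuses = {t.gene_id: t.status for t in target_statuses}
    allowed = {g for g, s in target_statuses.items() if s in (STATUS_DIRECT, STATUS_PUTATIVE)}
    allowed.add(regulator_id)
    g = nx.Graph(regulator_id=regulator_id, min_score=min_score)
    for a, b, score in edges:
        if score >= min_score and a in allowed and b in allowed and a != b:
            g.add_edge(a, b, score=score)
    for node in g.nodes:
        g.nodes[node]["status"] = (
            "regulator" if node == regulator_id else target_statuses[node])
    if g.number_of_nodes() == 0:
        logger.warning("build_grn: no edges passed the filters; empty GRN")
    return g


def core_section(grn: nx.Graph, seeds: Iterable[str]) -> nx.Graph:
    """Induced subgraph on the seeds and their first neighbors.

    Seeds absent from the network are logged and skipped; if none remain an
    error is raised. Neighbor-neighbor edges are retained (induced subgraph);
    node statuses carry over.
    """
    seeds = list(seeds)
    present = [s for s in seeds if s in grn]
    absent = [s for s in seeds if s not in grn]
    if absent:
        logger.warning("core_section: seeds absent from GRN skipped: %s", absent)
    if not present:
        raise ValueError(f"no core seeds present in the network: {seeds}")
    nodes = set(present)
    for s in present:
        nodes.update(grn.neighbors(s))
    core = grn.subgraph(nodes).copy()
    core.graph["core_seeds"] = ",".join(sorted(present))  # scalar: GraphML-safe
    return core


def common_grn_statuses(
    targets_a: Iterable[TargetRecord], targets_b: Iterable[TargetRecord]
) -> dict[str, str]:
    """Node statuses for the two-regulator common GRN.

    The node universe is the intersection of the two peak-associated gene
    sets; a gene is `direct` only when direct for both regulators, otherwise
    `putative_direct`.
    """
    status_a = {t.gene_id: t.status for t in targets_a if t.peak_associated}
    status_b = {t.gene_id: t.status for t in targets_b if t.peak_associated}
    common = set(status_a) & set(status_b)
    return {
        g: STATUS_DIRECT
        if status_a[g] == STATUS_DIRECT and status_b[g] == STATUS_DIRECT
        else STATUS_PUTATIVE
        for g in common
    }


def export_graph(grn: nx.Graph, basepath: str | Path) -> dict[str, Path]:
    """Write SIF, GraphML and a node-attribute TSV next to ``basepath``.

    Direct targets correspond to the rectangle node shape of the original
    visualization, putative-direct targets to the oval; here both are plain
    ``status`` attributes.
    """
    if grn.number_of_nodes() == 0:
        raise ValueError("refusing to export an empty graph")
    basepath = Path(basepath)
    basepath.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "sif": basepath.with_suffix(".sif"),
        "graphml": basepath.with_suffix(".graphml"),
        "nodes": basepath.with_name(basepath.name + "_nodes.tsv"),
    }
    with open(paths["sif"], "w") as fh:
        for a, b in sorted(map(lambda e: tuple(sorted(e)), grn.edges)):
            fh.write(f"{a}\tpp\t{b}\n")
    nx.write_graphml(grn, paths["graphml"])
    with open(paths["nodes"], "w") as fh:
        fh.write("gene_id\tstatus\tfunctional_category\n")
        for node in sorted(grn.nodes):
            attrs = grn.nodes[node]
            fh.write(f"{node}\t{attrs.get('status', '')}\t{attrs.get('functional_category', '')}\n")
    return paths


def read_graphml(path: str | Path) -> nx.Graph:
    """Read back an exported GraphML graph with integer edge scores."""
    g = nx.read_graphml(str(path))
    out = nx.Graph(**g.graph)
    for node, attrs in g.nodes(data=True):
        out.add_node(node, **attrs)
    for a, b, attrs in g.edges(data=True):
        if "score" in attrs:
            attrs["score"] = int(attrs["score"])
        out.add_edge(a, b, **attrs)
    return out
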