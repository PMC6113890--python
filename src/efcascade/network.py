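"""Signed regulatory-network assembly, motif detection, and reporting.

Nodes are TFs and their target genes; edges are signed (+ activation,
- repression) and carry an evidence reference back to the regulation call
they came from.  Synergistic calls for a TF pair become two co-annotated
edges sharing a ``synergy_group`` id, which keeps per-TF tallies
well-defined while the summary reports synergy as its own line.

Motifs are detected relative to a declared TF ordering (the developmental
order of the cascade, e.g. Pax6 -> Tbr2 -> Tbr1):

* feedforward chains: maximal all-positive paths that respect the ordering
* feedback edges: any edge from a later TF back to an earlier one
* autoregulation: signed self-edges
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

log = logging.getLogger(__name__)

EDGE_MODES = {
    "activates": "+",
    "represses": "-",
    "synergistic_activates": "+",
    "synergistic_represses": "-",
}


def build_network(
    calls: pd.DataFrame | Sequence[pd.DataFrame],
    node_roles: Mapping[str, str] | None = None,
) -> nx.DiGraph:
    """Assemble a signed digraph from regulation-call tables.

    Only calls whose mode maps to a sign become edges.  A synergy call for
    ``A+B`` is expanded to edges A->gene and B->gene sharing a synergy
    group id.  Duplicate (source, target) pairs with conflicting signs
    raise; duplicates with the same sign collapse to one edge.
    """
    node_roles = dict(node_roles or {})
    if isinstance(calls, pd.DataFrame):
        calls = [calls]
    graph = nx.DiGraph()
    for table in calls:
        for idx, row in enumerate(table.itertuples(index=False)):
            mode = str(row.mode)
            if mode not in EDGE_MODES:
                continue
            sign = EDGE_MODES[mode]
            tf_field = str(row.tf)
            gene = str(row.gene_id)
            synergy = mode.startswith("synergistic")
            sources = tf_field.split("+") if synergy else [tf_field]
            group = f"{tf_field}:{gene}" if synergy else ""
            for source in sources:
                evidence = f"{tf_field}->{gene}"
                if graph.has_edge(source, gene):
                    old = graph.edges[source, gene]["sign"]
                    if old != sign:
                        raise ValueError(
                            f"conflicting signs for edge {source}->{gene}: "
                            f"{old} vs {sign}"
                        )
                    continue
                graph.add_edge(
                    source,
                    gene,
                    sign=sign,
                    synergy=synergy,
                    synergy_group=group,
                    evidence=evidence,
                )
            graph.nodes[gene]["role"] = node_roles.get(gene, "EF")
            for source in sources:
                graph.nodes[source]["role"] = node_roles.get(source, "TF")
    # any edge source is a TF even when it is also somebody's target;
    # explicitly declared roles win over both defaults
    for u, _ in graph.edges:
        graph.nodes[u]["role"] = "TF"
    for node, role in node_roles.items():
        if node in graph:
            graph.nodes[node]["role"] = role
    return graph


@dataclass
class MotifReport:
    feedforward_chains: list[tuple[str, ...]] = field(default_factory=list)
    feedback_edges: list[tuple[str, str, str]] = field(default_factory=list)
    autoregulation: list[tuple[str, str]] = field(default_factory=list)


def _is_contiguous_subpath(short: tuple[str, ...], long: tuple[str, ...]) -> bool:
    if len(short) > len(long):
        return False
    return any(
        long[i : i + len(short)] == short for i in range(len(long) - len(short) + 1)
    )


def find_motifs(graph: nx.DiGraph, tf_order: Sequence[str]) -> MotifReport:
    """Detect cascade motifs relative to a declared upstream->downstream order.

    TFs present in the network as edge sources but missing from
    ``tf_order`` are excluded from the motif scan with a warning.
    """
    order = list(tf_order)
    pos = {tf: i for i, tf in enumerate(order)}
    sources = {u for u, _ in graph.edges}
    missing = sorted(sources - set(order))
    if missing:
        log.warning("TFs missing from tf_order excluded from motif scan: %s", missing)

    report = MotifReport()
    tf_edges = [
        (u, v, d["sign"])
        for u, v, d in graph.edges(data=True)
        if u in pos and v in pos
    ]
    for u, v, sign in sorted(tf_edges, key=lambda e: (pos[e[0]], pos[e[1]])):
        if u == v:
            report.autoregulation.append((u, sign))
        elif pos[u] > pos[v]:
            report.feedback_edges.append((u, v, sign))

    forward = nx.DiGraph()
    forward.add_nodes_from(order)
    for u, v, sign in tf_edges:
        if sign == "+" and pos[u] < pos[v]:
            forward.add_edge(u, v)
    paths: list[tuple[str, ...]] = []
    for u in order:
        for v in order:
            if pos[u] < pos[v]:
                for p in nx.all_simple_paths(forward, u, v):
                    paths.append(tuple(p))
    report.feedforward_chains = sorted(
        (
            p
            for p in paths
            if not any(q != p and _is_contiguous_subpath(p, q) for q in paths)
        ),
        key=lambda p: (pos[p[0]], len(p), p),
    )
    return report


def summarize(
    graph: nx.DiGraph,
    celltype_calls: pd.DataFrame | None = None,
    gradient_calls: pd.DataFrame | None = None,
) -> dict:
    """Tally regulation, cell-type, and gradient results.

    Returns a JSON-ready dict: per-TF activated/repressed counts, synergy
    tallies per TF pair, per-label gene counts, per-direction gradient
    counts, and the union count of genes that are cell-type-specific,
    graded, or regulated.  Missing inputs yield zero-count sections.
    """
    per_tf: dict[str, dict[str, int]] = {}
    synergy_groups: dict[str, set[str]] = {}
    regulated: set[str] = set()
    for u, v, d in graph.edges(data=True):
        regulated.add(v)
        if d.get("synergy"):
            group = d["synergy_group"]
            pair = group.split(":", 1)[0]
            synergy_groups.setdefault(pair, set()).add(group)
            per_tf.setdefault(u, {"activated": 0, "repressed": 0, "synergistic": 0})
            per_tf[u]["synergistic"] += 1
        else:
            per_tf.setdefault(u, {"activated": 0, "repressed": 0, "synergistic": 0})
            key = "activated" if d["sign"] == "+" else "repressed"
            per_tf[u][key] += 1

    specific_labels: dict[str, int] = {}
    specific_genes: set[str] = set()
    if celltype_calls is not None and len(celltype_calls):
        for r in celltype_calls.itertuples(index=False):
            specific_labels[r.label] = specific_labels.get(r.label, 0) + 1
            if r.label not in ("none", "conflicted", "mixed"):
                specific_genes.add(str(r.gene_id))
    else:
        log.info("summary: no cell-type calls provided")

    gradient_counts = {"high_rostral": 0, "high_caudal": 0, "none": 0}
    graded_genes: set[str] = set()
    if gradient_calls is not None and len(gradient_calls):
        for r in gradient_calls.itertuples(index=False):
            gradient_counts[r.direction] = gradient_counts.get(r.direction, 0) + 1
            if r.direction != "none":
                graded_genes.add(str(r.gene_id))
    else:
        log.info("summary: no gradient calls provided")

    return {
        "n_nodes": graph.number_of_nodes(),
        "n_edges": graph.number_of_edges(),
        "per_tf": {tf: per_tf[tf] for tf in sorted(per_tf)},
        "synergy_pairs": {
            pair: len(groups) for pair, groups in sorted(synergy_groups.items())
        },
        "celltype_labels": dict(sorted(specific_labels.items())),
        "n_celltype_specific": len(specific_genes),
        "gradients": gradient_counts,
        "n_graded": len(graded_genes),
        "n_regulated": len(regulated),
        "n_union": len(specific_genes | graded_genes | regulated),
    }


def render_report(summary: dict) -> str:
    """Human-readable Markdown rendering of a summary dict."""
    lines = ["# EF regulation summary", ""]
    lines.append(f"Network: {summary['n_nodes']} nodes, {summary['n_edges']} edges.")
    lines.append("")
    lines.append("## Regulation by TF")
    lines.append("")
    lines.append("| TF | activated | repressed | synergistic |")
    lines.append("|----|-----------|-----------|-------------|")
    for tf, counts in summary["per_tf"].items():
        lines.append(
            f"| {tf} | {counts['activated']} | {counts['repressed']} "
            f"| {counts['synergistic']} |"
        )
    for pair, n in summary["synergy_pairs"].items():
        lines.append(f"\n{pair} synergistically regulate {n} gene(s).")
    lines.append("")
    lines.append("## Cell-type labels")
    lines.append("")
    for label, n in summary["celltype_labels"].items():
        lines.append(f"- {label}: {n}")
    lines.append("")
    lines.append("## Rostrocaudal gradients")
    lines.append("")
    for direction, n in summary["gradients"].items():
        lines.append(f"- {direction}: {n}")
    lines.append("")
    lines.append(
        f"Union of cell-type-specific ({summary['n_celltype_specific']}), "
        f"graded ({summary['n_graded']}), or TF-regulated "
        f"({summary['n_regulated']}) genes: {summary['n_union']}."
    )
    lines.append("")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["source", "target", "sign", "synergy", "synergy_group", "evidence"]


def export_network(graph: nx.DiGraph, path: str | Path, fmt: str = "tsv") -> Path:
    """Write the network as TSV (lossless), SIF, or GraphML."""
    path = Path(path)
    edges = sorted(graph.edges(data=True), key=lambda e: (e[0], e[1]))
    if fmt == "tsv":
        rows = [
            {
                "source": u,
                "target": v,
                "sign": d["sign"],
                "synergy": bool(d.get("synergy", False)),
                "synergy_group": d.get("synergy_group", ""),
                "evidence": d.get("evidence", ""),
            }
            for u, v, d in edges
        ]
        pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for u, v, d in edges:
                keyword = "activates" if d["sign"] == "+" else "represses"
                fh.write(f"{u}\t{keyword}\t{v}\n")
    elif fmt == "graphml":
        clean = nx.DiGraph()
        for node, d in graph.nodes(data=True):
            clean.add_node(node, **{k: v for k, v in d.items() if v is not None})
        for u, v, d in edges:
            clean.add_edge(u, v, **{k: v for k, v in d.items() if v is not None})
        nx.write_graphml(clean, path)
    else:
        raise ValueError(f"unknown export format {fmt!r}")
    return path


def read_network_tsv(path: str | Path) -> nx.DiGraph:
    """Rebuild a network from its TSV export (round-trip inverse)."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    graph = nx.DiGraph()
    for r in df.itertuples(index=False):
        graph.add_edge(
            str(r.source),
            str(r.target),
            sign=str(r.sign),
            synergy=str(r.synergy) == "True",
            synergy_group=str(r.synergy_group),
            evidence=str(r.evidence),
        )
    return graph
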