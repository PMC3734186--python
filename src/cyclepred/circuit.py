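"""Threshold-rule inference of a TF -> TF regulatory circuit.

A directed edge regulator -> target is emitted when the regulator's
evidence in the target's promoter row passes:

1. the quantile-normalization score (NS) exceeds ``ns_threshold`` (0.9);
2. for TF-binding evidence, the log-transformed occupancy ratio exceeds
   ``tf_log_threshold`` (2);
3. for motif evidence, the raw aggregated matching score exceeds
   ``motif_score_threshold`` (0.5).

By default NS is read as a rank quantile: the fraction of genes whose
normalized value for that feature is strictly lower, so criterion (1)
demands the target's promoter rank in the top 10% for that feature.
(Normalized values themselves are not bounded by 1; ``ns_mode="value"``
compares the normalized value directly for the alternative reading.)

TF-binding columns name their regulator directly (TF features are genes);
motif columns only yield edges through an explicit motif -> TF map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from cyclepred.feature_io import KIND_MOTIF, KIND_TF, FeatureMatrix


@dataclass(frozen=True)
class CircuitEdge:
    """Directed regulator -> target call with its supporting evidence."""

    regulator: str
    target: str
    evidence: str  # "binding" or "motif"
    normalized_score: float
    raw_score: float


def read_tf_map(path) -> dict[str, str]:
    """Motif-id -> TF-gene-id map (TSV, two columns)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    motifs = df.iloc[:, 0]
    tfs = df.iloc[:, 1]
    if motifs.duplicated().any():
        dup = motifs[motifs.duplicated()].iloc[0]
        raise ValueError(f"motif {dup!r} mapped more than once")
    return dict(zip(motifs, tfs))


def quantile_ranks(m: FeatureMatrix) -> pd.DataFrame:
    """Per-cell rank quantile: fraction of genes strictly below, per feature."""
    vals = m.values.to_numpy(dtype=float)
    n = vals.shape[0]
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        # rank by strict domination; ties share the count of strictly-lower genes
        order = np.argsort(col, kind="stable")
        ranks = np.empty(n, dtype=float)
        sorted_col = col[order]
        counts = np.searchsorted(sorted_col, sorted_col, side="left")
        ranks[order] = counts
        out[:, j] = ranks / n
    return pd.DataFrame(out, index=m.values.index, columns=m.values.columns)


def infer_edges(
    raw: FeatureMatrix,
    normalized: FeatureMatrix,
    tf_map: dict[str, str],
    tf_set,
    log_base: float = 2.0,
    ns_threshold: float = 0.9,
    tf_log_threshold: float = 2.0,
    motif_score_threshold: float = 0.5,
    ns_mode: str = "rank",
) -> list[CircuitEdge]:
    """Apply the three criteria over every (feature, target) candidate.

    ``tf_set`` lists the target genes (typically the key cell-cycle TFs);
    both matrices must contain their rows.  A duplicate regulator/target
    pair supported by both evidence kinds yields two edges.
    """
    tf_set = list(tf_set)
    for g in tf_set:
        if g not in raw.values.index or g not in normalized.values.index:
            raise KeyError(f"target gene {g!r} absent from matrix")
    if ns_mode not in ("rank", "value"):
        raise ValueError(f"unknown ns_mode {ns_mode!r}")
    if ns_mode == "rank":
        ns = quantile_ranks(normalized)
    else:
        ns = normalized.values
    edges: list[CircuitEdge] = []
    log_den = math.log(log_base)
    for feature in raw.feature_ids:
        kind = raw.kinds[feature]
        if kind == KIND_TF:
            regulator, evidence = feature, "binding"
        elif kind == KIND_MOTIF:
            regulator = tf_map.get(feature)
            evidence = "motif"
            if regulator is None:
                continue  # unmapped motifs cannot produce edges
        else:  # pragma: no cover
            continue
        for target in tf_set:
            ns_score = float(ns.loc[target, feature])
            raw_score = float(raw.values.loc[target, feature])
            if ns_score <= ns_threshold:
                continue
            if evidence == "binding":
                if raw_score <= 0 or math.log(raw_score) / log_den <= tf_log_threshold:
                    continue
            else:
                if raw_score <= motif_score_threshold:
                    continue
            edges.append(
                CircuitEdge(
                    regulator=regulator,
                    target=target,
                    evidence=evidence,
                    normalized_score=ns_score,
                    raw_score=raw_score,
                )
            )
    edges.sort(key=lambda e: (e.regulator, e.target, e.evidence))
    return edges


def edge_report(
    raw: FeatureMatrix,
    normalized: FeatureMatrix,
    tf_map: dict[str, str],
    tf_set,
    log_base: float = 2.0,
    ns_mode: str = "rank",
) -> pd.DataFrame:
    """All candidate (regulator, target) pairs with their criterion values."""
    tf_set = list(tf_set)
    ns = quantile_ranks(normalized) if ns_mode == "rank" else normalized.values
    rows = []
    for feature in raw.feature_ids:
        kind = raw.kinds[feature]
        regulator = feature if kind == KIND_TF else tf_map.get(feature)
        if regulator is None:
            continue
        for target in tf_set:
            raw_score = float(raw.values.loc[target, feature])
            log_score = (
                math.log(raw_score) / math.log(log_base) if kind == KIND_TF and raw_score > 0 else float("nan")
            )
            rows.append(
                (
                    regulator,
                    target,
                    "binding" if kind == KIND_TF else "motif",
                    feature,
                    float(ns.loc[target, feature]),
                    raw_score,
                    log_score,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "regulator",
            "target",
            "evidence",
            "feature",
            "normalized_score",
            "raw_score",
            "log_occupancy",
        ],
    )


def to_graph(edges: list[CircuitEdge]) -> nx.MultiDiGraph:
    g = nx.MultiDiGraph()
    for e in sorted(edges, key=lambda e: (e.regulator, e.target, e.evidence)):
        g.add_node(e.regulator)
        g.add_node(e.target)
        g.add_edge(
            e.regulator,
            e.target,
            evidence=e.evidence,
            normalized_score=e.normalized_score,
            raw_score=e.raw_score,
        )
    return g


def graph_to_edges(g: nx.MultiDiGraph) -> list[CircuitEdge]:
    """Inverse of :func:`to_graph` (e.g. after re-reading a GraphML export)."""
    edges = [
        CircuitEdge(
            regulator=u,
            target=v,
            evidence=data["evidence"],
            normalized_score=float(data["normalized_score"]),
            raw_score=float(data["raw_score"]),
        )
        for u, v, data in g.edges(data=True)
    ]
    edges.sort(key=lambda e: (e.regulator, e.target, e.evidence))
    return edges


def export_graph(edges: list[CircuitEdge], path, format: str = "dot") -> None:
    """Write the circuit as DOT or GraphML with deterministic ordering."""
    if format == "dot":
        _write_dot(edges, path)
    elif format == "graphml":
        g = to_graph(edges)
        nx.write_graphml(g, path, named_key_ids=True)
    else:
        raise ValueError(f"unknown graph format {format!r}")


def _write_dot(edges: list[CircuitEdge], path) -> None:
    nodes = sorted({e.regulator for e in edges} | {e.target for e in edges})
    lines = ["digraph circuit {"]
    for node in nodes:
        lines.append(f'    "{node}";')
    for e in sorted(edges, key=lambda e: (e.regulator, e.target, e.evidence)):
        lines.append(
            f'    "{e.regulator}" -> "{e.target}" '
            f'[evidence="{e.evidence}", ns="{e.normalized_score:.6g}", raw="{e.raw_score:.6g}"];'
        )
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
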