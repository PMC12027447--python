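"""Typed heterogeneous biomolecular graph.

Eight node classes (miRNA, disease, drug, mRNA, protein, lncRNA, microbe,
circRNA) with integer labels 0-7, and up to sixteen co-occurrence
relations.  All relations are symmetric co-occurrence associations, so
edges are stored mirrored; isolated nodes are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import scipy.sparse as sp

NODE_TYPES: Tuple[str, ...] = (
    "miRNA",
    "disease",
    "drug",
    "mRNA",
    "protein",
    "lncRNA",
    "microbe",
    "circRNA",
)
NODE_TYPE_LABELS: Dict[str, int] = {t: i for i, t in enumerate(NODE_TYPES)}

# relation manifest: name -> (src_type, dst_type)
DEFAULT_RELATIONS: Dict[str, Tuple[str, str]] = {
    "miRNA-disease": ("miRNA", "disease"),
    "circRNA-disease": ("circRNA", "disease"),
    "circRNA-miRNA": ("circRNA", "miRNA"),
    "mRNA-disease": ("mRNA", "disease"),
    "lncRNA-disease": ("lncRNA", "disease"),
    "microbe-disease": ("microbe", "disease"),
    "drug-disease": ("drug", "disease"),
    "drug-protein": ("drug", "protein"),
    "miRNA-drug": ("miRNA", "drug"),
    "drug-microbe": ("drug", "microbe"),
    "mRNA-drug": ("mRNA", "drug"),
    "lncRNA-miRNA": ("lncRNA", "miRNA"),
    "lncRNA-mRNA": ("lncRNA", "mRNA"),
    "miRNA-mRNA": ("miRNA", "mRNA"),
    "lncRNA-protein": ("lncRNA", "protein"),
    "miRNA-protein": ("miRNA", "protein"),
}


@dataclass
class EdgeTable:
    """One typed association table feeding the graph builder."""

    src_type: str
    dst_type: str
    relation: str
    pairs: List[Tuple[str, str]]


@dataclass
class HeteroGraph:
    nodes: Dict[str, List[str]]
    edges: Dict[str, List[Tuple[str, str]]]
    relation_types: Dict[str, Tuple[str, str]]
    relation_ids: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for t in self.nodes:
            if t not in NODE_TYPE_LABELS:
                raise ValueError(f"unknown node type {t!r}")
        for t in NODE_TYPES:
            self.nodes.setdefault(t, [])
        if not self.relation_ids:
            self.relation_ids = {r: i for i, r in enumerate(sorted(self.edges))}
        self._index = {
            t: {v: i for i, v in enumerate(ids)} for t, ids in self.nodes.items()
        }
        offset = 0
        self._offset: Dict[str, int] = {}
        for t in NODE_TYPES:
            self._offset[t] = offset
            offset += len(self.nodes[t])
        self._n_total = offset

    @property
    def n_nodes(self) -> int:
        return self._n_total

    def node_type_labels(self) -> np.ndarray:
        """Integer type label (0-7) per global node index."""
        labels = np.empty(self.n_nodes, dtype=int)
        for t in NODE_TYPES:
            o = self._offset[t]
            labels[o : o + len(self.nodes[t])] = NODE_TYPE_LABELS[t]
        return labels

    def global_index(self, node_type: str, node_id: str) -> int:
        return self._offset[node_type] + self._index[node_type][node_id]

    def type_slice(self, node_type: str) -> slice:
        o = self._offset[node_type]
        return slice(o, o + len(self.nodes[node_type]))

    def adjacency(self) -> sp.csr_matrix:
        """Binary symmetric adjacency over the global node index."""
        rows, cols = [], []
        for rel, pairs in self.edges.items():
            st, dt = self.relation_types[rel]
            for s, d in pairs:
                i, j = self.global_index(st, s), self.global_index(dt, d)
                rows.extend((i, j))
                cols.extend((j, i))
        A = sp.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(self.n_nodes, self.n_nodes)
        )
        A.data[:] = 1.0  # collapse duplicates from multi-relation edges
        return A

    def degrees(self) -> np.ndarray:
        A = self.adjacency()
        return np.asarray(A.sum(axis=1)).ravel()


def build_graph(
    tables: Sequence[EdgeTable],
    nodes: Mapping[str, Iterable[str]] | None = None,
    relations: Mapping[str, Tuple[str, str]] | None = None,
) -> HeteroGraph:
    """Assemble the heterograph from typed edge tables.

    Node ids are ordered lexicographically within each type (union of
    declared nodes and edge endpoints).  Edge lists are deduplicated and
    canonicalized; relations are stored once and mirrored on demand by
    :meth:`HeteroGraph.adjacency`.
    """
    relations = dict(relations or DEFAULT_RELATIONS)
    node_sets: Dict[str, set] = {t: set() for t in NODE_TYPES}
    if nodes:
        for t, ids in nodes.items():
            if t not in NODE_TYPE_LABELS:
                raise ValueError(f"unknown node type {t!r}")
            node_sets[t].update(ids)
    edges: Dict[str, List[Tuple[str, str]]] = {}
    rel_types: Dict[str, Tuple[str, str]] = {}
    for table in tables:
        for t in (table.src_type, table.dst_type):
            if t not in NODE_TYPE_LABELS:
                raise ValueError(f"unknown node type {t!r}")
        if table.relation in rel_types and rel_types[table.relation] != (
            table.src_type,
            table.dst_type,
        ):
            raise ValueError(f"relation {table.relation!r} redeclared with new types")
        if table.relation in relations and relations[table.relation] != (
            table.src_type,
            table.dst_type,
        ):
            raise ValueError(
                f"relation {table.relation!r} conflicts with the manifest typing"
            )
        rel_types[table.relation] = (table.src_type, table.dst_type)
        seen = set(edges.get(table.relation, ()))
        out = edges.setdefault(table.relation, [])
        for s, d in table.pairs:
            if table.src_type != table.dst_type and s == d:
                raise ValueError(
                    f"self-loop {s!r} in cross-type relation {table.relation!r}"
                )
            if (s, d) in seen or (
                table.src_type == table.dst_type and (d, s) in seen
            ):
                continue
            seen.add((s, d))
            out.append((s, d))
            node_sets[table.src_type].add(s)
            node_sets[table.dst_type].add(d)
    if len(rel_types) > 16:
        raise ValueError("more than 16 relation types")
    node_lists = {t: sorted(node_sets[t]) for t in NODE_TYPES}
    rel_ids = {r: i for i, r in enumerate(sorted(rel_types))}
    return HeteroGraph(node_lists, edges, rel_types, rel_ids)


def init_features(
    graph: HeteroGraph,
    fused_mirna: Tuple[Sequence[str], np.ndarray],
    fused_disease: Tuple[Sequence[str], np.ndarray],
    embed_dim: int,
    seed: int,
) -> Dict[str, np.ndarray]:
    """Initial node feature table.

    miRNA and disease rows carry the fused (projected) similarity features;
    every other type is drawn i.i.d. N(0, 1/embed_dim) from a generator
    seeded with ``seed`` so the table is reproducible.
    """
    rng = np.random.default_rng(seed)
    feats: Dict[str, np.ndarray] = {}
    fused = {"miRNA": fused_mirna, "disease": fused_disease}
    for t in NODE_TYPES:
        n = len(graph.nodes[t])
        block = rng.normal(0.0, 1.0 / np.sqrt(embed_dim), size=(n, embed_dim))
        if t in fused:
            ids, X = fused[t]
            X = np.asarray(X, dtype=float)
            if X.shape != (len(ids), embed_dim):
                raise ValueError(
                    f"fused {t} features must be ({len(ids)},{embed_dim}), got {X.shape}"
                )
            index = {v: i for i, v in enumerate(graph.nodes[t])}
            unknown = [v for v in ids if v not in index]
            if unknown:
                raise ValueError(f"fused {t} ids not in graph: {unknown}")
            for row, v in enumerate(ids):
                block[index[v]] = X[row]
        feats[t] = block
    return feats


def stack_features(graph: HeteroGraph, feats: Mapping[str, np.ndarray]) -> np.ndarray:
    """Concatenate per-type feature blocks into global node order."""
    return np.vstack([feats[t] for t in NODE_TYPES])
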