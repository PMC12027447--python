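"""Desk-scale synthetic data with the structure the method assumes.

The generator emulates the shapes of the real corpora (a bipartite
miRNA-disease association matrix, typed multi-relational edge lists among
eight biomolecule classes, small MeSH-style DAG forests, short RNA
strings) with a planted latent-group signal: miRNAs, diseases and
auxiliary molecules each belong to one of ``n_latent_groups`` groups, and
a pair whose endpoints share a group is linked with ``intra_group_edge_prob``
versus ``inter_group_edge_prob`` otherwise.  Within-group diseases share
DAG ancestors and within-group miRNAs share a sequence template, so every
similarity channel carries the same planted signal the associations do.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np

from gonnmda import io as gio
from gonnmda.heterograph import (
    DEFAULT_RELATIONS,
    NODE_TYPES,
    EdgeTable,
    HeteroGraph,
    build_graph,
)
from gonnmda.similarity import DiseaseDAG, SignedAssociationTable


@dataclass
class SyntheticSpec:
    n_mirna: int = 60
    n_disease: int = 50
    n_drug: int = 20
    n_mrna: int = 20
    n_protein: int = 20
    n_lncrna: int = 20
    n_microbe: int = 20
    n_circrna: int = 20
    n_latent_groups: int = 4
    intra_group_edge_prob: float = 0.4
    inter_group_edge_prob: float = 0.02
    dag_depth: int = 3
    dag_branching: int = 2
    seq_length_range: Tuple[int, int] = (20, 23)
    mutation_rate: float = 0.1
    downregulation_rate: float = 0.2
    lam: float = 0.5
    seed: int = 7

    def __post_init__(self):
        if not (0.0 <= self.inter_group_edge_prob <= 1.0 <= 1.0) or not (
            0.0 <= self.intra_group_edge_prob <= 1.0
        ):
            raise ValueError("edge probabilities must be in [0,1]")
        if self.intra_group_edge_prob <= self.inter_group_edge_prob:
            raise ValueError("planted signal requires intra > inter")
        if self.dag_depth < 1:
            raise ValueError("dag_depth must be >= 1")
        lo, hi = self.seq_length_range
        if not (15 <= lo <= hi <= 30):
            raise ValueError("sequence length range must lie within [15, 30]")

    def counts(self) -> Dict[str, int]:
        return {
            "miRNA": self.n_mirna,
            "disease": self.n_disease,
            "drug": self.n_drug,
            "mRNA": self.n_mrna,
            "protein": self.n_protein,
            "lncRNA": self.n_lncrna,
            "microbe": self.n_microbe,
            "circRNA": self.n_circrna,
        }


_PREFIX = {
    "miRNA": "mir",
    "disease": "dis",
    "drug": "drg",
    "mRNA": "rna",
    "protein": "prt",
    "lncRNA": "lnc",
    "microbe": "mic",
    "circRNA": "cir",
}


def _ids(node_type: str, n: int) -> List[str]:
    return [f"{_PREFIX[node_type]}{i:03d}" for i in range(n)]


def _groups(n: int, n_groups: int) -> np.ndarray:
    # contiguous blocks, consistent with lexicographic id order
    return np.array([i * n_groups // n for i in range(n)])


@dataclass
class SyntheticData:
    spec: SyntheticSpec
    graph: HeteroGraph
    dags: Dict[str, DiseaseDAG]
    sequences: Dict[str, str]
    assoc: SignedAssociationTable
    assoc_matrix: np.ndarray  # (n_mirna, n_disease) binary
    groups: Dict[str, np.ndarray]
    tables: List[EdgeTable]

    @property
    def mirna_ids(self) -> List[str]:
        return self.graph.nodes["miRNA"]

    @property
    def disease_ids(self) -> List[str]:
        return self.graph.nodes["disease"]

    @property
    def positives(self) -> List[Tuple[str, str]]:
        m, d = self.mirna_ids, self.disease_ids
        return [(m[i], d[j]) for i, j in zip(*np.nonzero(self.assoc_matrix))]


def make_dag_forest(spec: SyntheticSpec) -> Dict[str, DiseaseDAG]:
    """One DAG per disease; within-group diseases share an ancestor chain.

    Each group owns a chain of ``dag_depth - 1`` ancestor terms; every
    disease of the group hangs under the chain's deepest term.  With
    ``dag_depth == 1`` each disease is its own root with no ancestors.
    """
    ids = _ids("disease", spec.n_disease)
    groups = _groups(spec.n_disease, spec.n_latent_groups)
    dags: Dict[str, DiseaseDAG] = {}
    for d, g in zip(ids, groups):
        if spec.dag_depth == 1:
            dags[d] = DiseaseDAG(d, frozenset({d}), frozenset(), spec.lam)
            continue
        chain = [f"grp{g}_anc{lvl}" for lvl in range(spec.dag_depth - 1)]
        nodes = {d, *chain}
        edges = {(chain[i], chain[i + 1]) for i in range(len(chain) - 1)}
        edges.add((chain[-1], d))
        dags[d] = DiseaseDAG(d, frozenset(nodes), frozenset(edges), spec.lam)
    return dags


def make_sequences(spec: SyntheticSpec) -> Dict[str, str]:
    """Within-group sequences from a shared template with point mutations."""
    rng = np.random.default_rng(spec.seed + 1)
    alphabet = np.array(list("ACGU"))
    ids = _ids("miRNA", spec.n_mirna)
    groups = _groups(spec.n_mirna, spec.n_latent_groups)
    lo, hi = spec.seq_length_range
    templates = {}
    for g in range(spec.n_latent_groups):
        length = int(rng.integers(lo, hi + 1))
        templates[g] = rng.choice(alphabet, size=length)
    seqs: Dict[str, str] = {}
    for m, g in zip(ids, groups):
        seq = templates[g].copy()
        mutate = rng.random(len(seq)) < spec.mutation_rate
        seq[mutate] = rng.choice(alphabet, size=int(mutate.sum()))
        seqs[m] = "".join(seq)
    return seqs


def _planted_pairs(
    rng: np.random.Generator,
    src_ids: List[str],
    dst_ids: List[str],
    src_groups: np.ndarray,
    dst_groups: np.ndarray,
    intra: float,
    inter: float,
) -> List[Tuple[str, str]]:
    same = src_groups[:, None] == dst_groups[None, :]
    prob = np.where(same, intra, inter)
    draw = rng.random(prob.shape) < prob
    return [(src_ids[i], dst_ids[j]) for i, j in zip(*np.nonzero(draw))]


def make_heterograph(
    spec: SyntheticSpec,
) -> Tuple[HeteroGraph, np.ndarray, Dict[str, np.ndarray], List[EdgeTable]]:
    """Planted-group heterograph over all eight node types.

    Every relation in the default 16-relation manifest is drawn with the
    same intra/inter group probabilities, so auxiliary molecules are wired
    to the same latent groups that drive the miRNA-disease associations.
    Returns the graph, the ground-truth binary association matrix, the
    group assignment per type, and the raw edge tables.
    """
    rng = np.random.default_rng(spec.seed + 2)
    counts = spec.counts()
    ids = {t: _ids(t, counts[t]) for t in NODE_TYPES}
    groups = {t: _groups(counts[t], spec.n_latent_groups) for t in NODE_TYPES}
    tables: List[EdgeTable] = []
    assoc_matrix = np.zeros((counts["miRNA"], counts["disease"]))
    for rel, (st, dt) in DEFAULT_RELATIONS.items():
        pairs = _planted_pairs(
            rng, ids[st], ids[dt], groups[st], groups[dt],
            spec.intra_group_edge_prob, spec.inter_group_edge_prob,
        )
        tables.append(EdgeTable(st, dt, rel, pairs))
        if rel == "miRNA-disease":
            mindex = {m: i for i, m in enumerate(ids["miRNA"])}
            dindex = {d: j for j, d in enumerate(ids["disease"])}
            for m, d in pairs:
                assoc_matrix[mindex[m], dindex[d]] = 1.0
    graph = build_graph(tables, nodes=ids)
    return graph, assoc_matrix, groups, tables


def make_signed_associations(
    spec: SyntheticSpec, assoc_matrix: np.ndarray
) -> SignedAssociationTable:
    """Attach up/down regulation flags to the planted associations."""
    rng = np.random.default_rng(spec.seed + 3)
    mids = _ids("miRNA", spec.n_mirna)
    dids = _ids("disease", spec.n_disease)
    rows = []
    for i, j in zip(*np.nonzero(assoc_matrix)):
        k = int(rng.random() < spec.downregulation_rate)
        rows.append((mids[i], dids[j], k))
    return SignedAssociationTable(rows)


def generate(spec: SyntheticSpec | None = None) -> SyntheticData:
    """Full deterministic fixture: graph, DAGs, sequences, associations."""
    spec = spec or SyntheticSpec()
    graph, assoc_matrix, groups, tables = make_heterograph(spec)
    return SyntheticData(
        spec=spec,
        graph=graph,
        dags=make_dag_forest(spec),
        sequences=make_sequences(spec),
        assoc=make_signed_associations(spec, assoc_matrix),
        assoc_matrix=assoc_matrix,
        groups=groups,
        tables=tables,
    )


def write_dataset(data: SyntheticData, out_dir: str | Path) -> None:
    """Write the fixture in the dialects the readers consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gio.write_fasta(data.sequences, out / "mirna_sequences.fasta")
    gio.write_dag_table(data.dags, out / "disease_dags.tsv")
    gio.write_signed_associations(data.assoc, out / "mirna_disease_signed.tsv")
    for table in data.tables:
        rows = [(s, d, table.relation) for s, d in table.pairs]
        name = table.relation.replace("-", "_")
        gio.write_edge_table(rows, out / f"edges_{name}.tsv")


def oracle_learnability_auc(data: SyntheticData, seed: int = 0) -> float:
    """AUC of a logistic regression on the planted group indicators.

    Certifies that the fixture carries learnable signal independently of
    the GONNMDA pipeline: features are the one-hot interaction of the
    miRNA group and the disease group for each pair of a balanced
    positive/negative sample.
    """
    from sklearn.linear_model import LogisticRegression

    from gonnmda.predictor import build_dataset

    dataset = build_dataset(
        data.positives, (data.mirna_ids, data.disease_ids), seed=seed
    )
    g = data.spec.n_latent_groups
    gm = data.groups["miRNA"]
    gd = data.groups["disease"]
    midx = {m: i for i, m in enumerate(data.mirna_ids)}
    didx = {d: i for i, d in enumerate(data.disease_ids)}
    X = np.zeros((len(dataset.pairs), g * g))
    y = dataset.labels
    for row, (m, d, _) in enumerate(dataset.pairs):
        X[row, gm[midx[m]] * g + gd[didx[d]]] = 1.0
    clf = LogisticRegression(max_iter=1000).fit(X, y)
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(y, clf.predict_proba(X)[:, 1]))
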