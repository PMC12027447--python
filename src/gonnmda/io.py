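"""Readers and writers for the plain-text input dialects.

FASTA for miRNA sequences (Biopython), TSV for DAG edges, signed
associations, typed edge tables, and persisted similarity matrices.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Mapping, Tuple

import pandas as pd
from Bio import SeqIO

from gonnmda.similarity import DiseaseDAG, SignedAssociationTable, SimilarityMatrix


def read_fasta(path: str | Path) -> Dict[str, str]:
    """Read miRNA sequences; DNA T is normalized to RNA U."""
    seqs = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper().replace("T", "U")
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(seqs):
            fh.write(f">{name}\n{seqs[name]}\n")


def read_dag_table(path: str | Path, lam: float = 0.5) -> Dict[str, DiseaseDAG]:
    """DAG edge TSV with columns (child, parent, root_disease).

    A row with an empty parent declares a root-only disease (no ancestors).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    dags: Dict[str, DiseaseDAG] = {}
    for root, grp in df.groupby("root_disease"):
        nodes = {root}
        edges = set()
        for _, row in grp.iterrows():
            if row["parent"]:
                nodes.update((row["parent"], row["child"]))
                edges.add((row["parent"], row["child"]))
        dags[root] = DiseaseDAG(root, frozenset(nodes), frozenset(edges), lam)
    return dags


def write_dag_table(dags: Mapping[str, DiseaseDAG], path: str | Path) -> None:
    rows = []
    for root in sorted(dags):
        dag = dags[root]
        if dag.edges:
            for p, c in sorted(dag.edges):
                rows.append({"child": c, "parent": p, "root_disease": root})
        else:
            rows.append({"child": root, "parent": "", "root_disease": root})
    pd.DataFrame(rows, columns=["child", "parent", "root_disease"]).to_csv(
        path, sep="\t", index=False
    )


def read_signed_associations(path: str | Path) -> SignedAssociationTable:
    """Signed association TSV with columns (mirna, disease, k)."""
    df = pd.read_csv(path, sep="\t", dtype={"mirna": str, "disease": str, "k": int})
    return SignedAssociationTable(
        [(r.mirna, r.disease, int(r.k)) for r in df.itertuples()]
    )


def write_signed_associations(table: SignedAssociationTable, path: str | Path) -> None:
    pd.DataFrame(table.rows, columns=["mirna", "disease", "k"]).to_csv(
        path, sep="\t", index=False
    )


def read_edge_table(path: str | Path) -> List[Tuple[str, str, str]]:
    """Typed edge TSV with columns (src_id, dst_id, relation)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [(r.src_id, r.dst_id, r.relation) for r in df.itertuples()]


def write_edge_table(rows, path: str | Path) -> None:
    pd.DataFrame(rows, columns=["src_id", "dst_id", "relation"]).to_csv(
        path, sep="\t", index=False
    )


def write_similarity(sim: SimilarityMatrix, path: str | Path) -> None:
    pd.DataFrame(sim.values, index=sim.ids, columns=sim.ids).to_csv(path, sep="\t")


def read_similarity(path: str | Path, name: str = "") -> SimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SimilarityMatrix(list(df.index), df.values, name=name)
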