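"""Similarity matrices for miRNAs and diseases.

Six matrices feed the fusion stage:

* ``DSS1`` / ``DSS2`` — disease semantic similarity from MeSH-style DAGs
  (two weighting schemes: edge-decay and information-content).
* ``DGS`` / ``MGS``  — Gaussian interaction-profile (GIP) kernel similarity
  for diseases and miRNAs.
* ``MFS``            — miRNA functional similarity from signed disease
  associations and disease semantic similarity.
* ``MQS``            — miRNA sequence similarity from Needleman-Wunsch
  global alignment scores, min-max normalized.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np
from Bio import Align

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiseaseDAG:
    """A disease and its ancestor closure in a MeSH-style hierarchy.

    ``nodes`` is the term set T_d (the disease itself plus every ancestor);
    ``edges`` are (parent, child) pairs within that closure; ``lam`` is the
    semantic contribution factor applied per edge when walking away from the
    disease term.
    """

    disease_id: str
    nodes: frozenset = field(default_factory=frozenset)
    edges: frozenset = field(default_factory=frozenset)
    lam: float = 0.5

    def __post_init__(self):
        if not (0.0 < self.lam < 1.0):
            raise ValueError(f"lambda must be in (0,1), got {self.lam}")
        if self.disease_id not in self.nodes:
            raise ValueError(f"disease {self.disease_id!r} not in its own node set")
        for p, c in self.edges:
            if p not in self.nodes or c not in self.nodes:
                raise ValueError(f"edge ({p!r},{c!r}) leaves the node set")
        self._check_acyclic_and_rooted()

    def children(self, term: str) -> List[str]:
        return [c for (p, c) in self.edges if p == term]

    def parents(self, term: str) -> List[str]:
        return [p for (p, c) in self.edges if c == term]

    def _check_acyclic_and_rooted(self) -> None:
        # Kahn toposort over the closure; leftovers indicate a cycle.
        nodes = set(self.nodes)
        indeg = {n: 0 for n in nodes}
        for _, c in self.edges:
            indeg[c] += 1
        queue = [n for n in nodes if indeg[n] == 0]
        seen = 0
        while queue:
            n = queue.pop()
            seen += 1
            for c in self.children(n):
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if seen != len(nodes):
            raise ValueError(f"cycle detected in DAG for {self.disease_id!r}")
        # every node must reach the disease term by following child edges
        # (equivalently: be an ancestor of it, or the term itself)
        reachable = {self.disease_id}
        frontier = [self.disease_id]
        while frontier:
            t = frontier.pop()
            for p in self.parents(t):
                if p not in reachable:
                    reachable.add(p)
                    frontier.append(p)
        stranded = nodes - reachable
        if stranded:
            raise ValueError(
                f"nodes {sorted(stranded)} have no path to root {self.disease_id!r}"
            )


@dataclass
class InteractionProfileSet:
    """Binary association profiles, one row IP(.) per entity."""

    entity_ids: List[str]
    profiles: np.ndarray

    def __post_init__(self):
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.ndim != 2 or self.profiles.shape[0] != len(self.entity_ids):
            raise ValueError("profiles must be 2-D with one row per entity")
        if not np.isin(self.profiles, (0.0, 1.0)).all():
            raise ValueError("profiles must be binary")


@dataclass
class SimilarityMatrix:
    """Square, symmetric, entity-indexed similarity matrix."""

    ids: List[str]
    values: np.ndarray
    name: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"values must be {n}x{n}, got {self.values.shape}")
        if not np.isfinite(self.values).all():
            raise ValueError("similarity matrix contains non-finite entries")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("similarity matrix is not symmetric within 1e-9")

    def loc(self, i: str, j: str) -> float:
        return float(self.values[self.ids.index(i), self.ids.index(j)])


@dataclass
class SignedAssociationTable:
    """(miRNA, disease, k) rows; k=0 upregulation, k=1 downregulation."""

    rows: List[Tuple[str, str, int]]

    def __post_init__(self):
        seen = set()
        for m, d, k in self.rows:
            if k not in (0, 1):
                raise ValueError(f"regulation flag must be 0 or 1, got {k!r}")
            if (m, d) in seen:
                raise ValueError(f"duplicate association ({m!r},{d!r})")
            seen.add((m, d))

    @property
    def mirnas(self) -> List[str]:
        return sorted({m for m, _, _ in self.rows})

    @property
    def diseases(self) -> List[str]:
        return sorted({d for _, d, _ in self.rows})


# ---------------------------------------------------------------------------
# disease semantic similarity
# ---------------------------------------------------------------------------


def semantic_value(dag: DiseaseDAG) -> Dict[str, float]:
    """Per-term semantic value D_d(t).

    The disease term itself has value 1; each ancestor term takes
    ``lam`` times the maximum value over its children within the closure,
    so contributions decay with distance from the disease.
    """
    values: Dict[str, float] = {dag.disease_id: 1.0}

    def _value(t: str) -> float:
        if t in values:
            return values[t]
        children = dag.children(t)
        if not children:
            # already excluded by the rooted check, defensive only
            raise ValueError(f"term {t!r} has no path toward {dag.disease_id!r}")
        v = max(dag.lam * _value(c) for c in children)
        values[t] = v
        return v

    for t in dag.nodes:
        _value(t)
    return values


def dss1(dags: Mapping[str, DiseaseDAG]) -> SimilarityMatrix:
    """Disease semantic similarity, edge-decay weighting.

    DSS1(di, dj) = sum over shared terms t of (D_di(t) + D_dj(t)),
    divided by (Ds1(di) + Ds1(dj)) where Ds1 is the total semantic value.
    """
    if not dags:
        raise ValueError("at least one DAG required")
    ids = sorted(dags)
    sv = {d: semantic_value(dags[d]) for d in ids}
    totals = {d: sum(sv[d].values()) for d in ids}
    n = len(ids)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            di, dj = ids[i], ids[j]
            shared = dags[di].nodes & dags[dj].nodes
            num = sum(sv[di][t] + sv[dj][t] for t in shared)
            values[i, j] = values[j, i] = num / (totals[di] + totals[dj])
    return SimilarityMatrix(ids, values, name="DSS1")


def dss2(dags: Mapping[str, DiseaseDAG], n_dag: int | None = None) -> SimilarityMatrix:
    """Disease semantic similarity, information-content weighting.

    Each term contributes -log(G(t) / N_DAG), where G(t) counts the DAGs
    containing t; terms common to every DAG contribute nothing.  The pair
    similarity mirrors the DSS1 ratio with these contributions.  The
    degenerate 0/0 off-diagonal case (all shared, zero information) is
    reported as 0 with a warning.
    """
    if not dags:
        raise ValueError("at least one DAG required")
    ids = sorted(dags)
    if n_dag is None:
        n_dag = len(dags)
    if n_dag < len(dags):
        raise ValueError("n_dag smaller than the number of DAGs supplied")
    counts: Dict[str, int] = {}
    for d in ids:
        for t in dags[d].nodes:
            counts[t] = counts.get(t, 0) + 1
    contrib = {}
    for t, g in counts.items():
        if g == 0:
            raise ValueError(f"term {t!r} present but counted 0 times")
        contrib[t] = -math.log(g / n_dag)
    totals = {d: sum(contrib[t] for t in dags[d].nodes) for d in ids}
    n = len(ids)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            di, dj = ids[i], ids[j]
            shared = dags[di].nodes & dags[dj].nodes
            num = sum(2.0 * contrib[t] for t in shared)
            den = totals[di] + totals[dj]
            if den <= 1e-300:
                if num > 0:  # impossible: num <= den by construction
                    raise ValueError("inconsistent DSS2 numerator/denominator")
                logger.warning(
                    "DSS2(%s,%s): zero information content, reporting 0", di, dj
                )
                values[i, j] = values[j, i] = 0.0
            else:
                values[i, j] = values[j, i] = num / den
    return SimilarityMatrix(ids, values, name="DSS2")


# ---------------------------------------------------------------------------
# Gaussian interaction-profile kernel
# ---------------------------------------------------------------------------


def gip_kernel(profiles: InteractionProfileSet, gamma: float = 1.0) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel similarity.

    S(i,j) = exp(-sigma * ||IP(i) - IP(j)||^2) with the data-adaptive
    bandwidth sigma = gamma / mean_k ||IP(k)||^2.
    """
    X = profiles.profiles
    if X.shape[0] < 1:
        raise ValueError("at least one profile required")
    mean_sq = float(np.mean(np.sum(X * X, axis=1)))
    if mean_sq == 0.0:
        raise ValueError("all profiles are zero; GIP bandwidth undefined")
    sigma = gamma / mean_sq
    sq = np.sum(X * X, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * X @ X.T
    np.maximum(d2, 0.0, out=d2)
    values = np.exp(-sigma * d2)
    np.fill_diagonal(values, 1.0)
    values = 0.5 * (values + values.T)
    return SimilarityMatrix(list(profiles.entity_ids), values)


# ---------------------------------------------------------------------------
# miRNA functional similarity
# ---------------------------------------------------------------------------


def mirna_functional_similarity(
    assoc: SignedAssociationTable,
    dss: SimilarityMatrix,
    dags: Mapping[str, DiseaseDAG],
    mirna_ids: Sequence[str] | None = None,
) -> SimilarityMatrix:
    """miRNA functional similarity from signed disease associations.

    Each miRNA is embedded over the full ordered disease universe: the
    signed semantic block holds (-1)^k * Ds1(d) at every associated disease
    d (zero elsewhere), and a cross-similarity block propagates that signed
    profile through the disease semantic similarity matrix.  The similarity
    is the cosine of the concatenated feature vectors, so it lies in
    [-1, 1]; a miRNA with no associations gets a zero off-diagonal row and
    is flagged.
    """
    disease_ids = list(dss.ids)
    idx = {d: i for i, d in enumerate(disease_ids)}
    for _, d, _ in assoc.rows:
        if d not in idx or d not in dags:
            raise ValueError(f"disease {d!r} missing from similarity/DAG inputs")
    if mirna_ids is None:
        mirna_ids = assoc.mirnas
    mirna_ids = list(mirna_ids)
    totals = {d: sum(semantic_value(dags[d]).values()) for d in disease_ids if d in dags}

    nm, nd = len(mirna_ids), len(disease_ids)
    signed = np.zeros((nm, nd))
    mpos = {m: i for i, m in enumerate(mirna_ids)}
    for m, d, k in assoc.rows:
        if m in mpos:
            signed[mpos[m], idx[d]] = (-1.0) ** k * totals[d]
    cross = signed @ dss.values
    feats = np.concatenate([signed, cross], axis=1)

    norms = np.linalg.norm(feats, axis=1)
    empty = norms == 0.0
    if empty.any():
        logger.warning(
            "miRNAs with no associated disease get zero similarity rows: %s",
            [mirna_ids[i] for i in np.flatnonzero(empty)],
        )
    safe = np.where(empty, 1.0, norms)
    unit = feats / safe[:, None]
    values = unit @ unit.T
    np.clip(values, -1.0, 1.0, out=values)
    np.fill_diagonal(values, 1.0)
    values = 0.5 * (values + values.T)
    return SimilarityMatrix(mirna_ids, values, name="MFS")


# ---------------------------------------------------------------------------
# miRNA sequence similarity
# ---------------------------------------------------------------------------


def _validate_rna(seq: str) -> str:
    seq = seq.upper().replace("T", "U")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ValueError(f"invalid nucleotide(s) {sorted(bad)} in sequence")
    return seq


def nw_score(
    a: str, b: str, match: float = 1.0, mismatch: float = -1.0, gap: float = -1.0
) -> float:
    """Needleman-Wunsch global alignment score with linear gap penalties."""
    a, b = _validate_rna(a), _validate_rna(b)
    if not a or not b:
        return gap * (len(a) + len(b))
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return float(aligner.score(a, b))


def mirna_sequence_similarity(
    seqs: Mapping[str, str],
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -1.0,
) -> SimilarityMatrix:
    """Min-max-normalized pairwise alignment scores; diagonal pinned to 1.

    Normalization runs over off-diagonal pairs only.  If every off-diagonal
    pair attains the same score the matrix is degenerate; all off-diagonal
    entries are set to 0.5 and a warning is logged.
    """
    if len(seqs) < 2:
        raise ValueError("at least two sequences required")
    ids = sorted(seqs)
    n = len(ids)
    scores = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            scores[i, j] = scores[j, i] = nw_score(
                seqs[ids[i]], seqs[ids[j]], match, mismatch, gap
            )
    off = ~np.eye(n, dtype=bool)
    lo, hi = scores[off].min(), scores[off].max()
    values = np.eye(n)
    if hi == lo:
        logger.warning("all alignment scores equal; off-diagonal MQS set to 0.5")
        values[off] = 0.5
    else:
        values[off] = (scores[off] - lo) / (hi - lo)
    return SimilarityMatrix(ids, values, name="MQS")
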