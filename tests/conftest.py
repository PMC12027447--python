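import numpy as np
import pytest

from gonnmda.similarity import DiseaseDAG


@pytest.fixture(scope="session")
def synthetic_data():
    """Default planted-group fixture, shared across tests (read-only)."""
    from gonnmda.synthetic import generate

    return generate()


@pytest.fixture
def chain_dag():
    """g -> p -> d ancestor chain for disease d."""
    return DiseaseDAG(
        "d", frozenset({"d", "p", "g"}), frozenset({("g", "p"), ("p", "d")}), 0.5
    )


@pytest.fixture
def shared_parent_dags():
    """d1, d2 each with the single shared parent p (DSS1 = 1/3 at lam=0.5)."""
    return {
        "d1": DiseaseDAG("d1", frozenset({"d1", "p"}), frozenset({("p", "d1")}), 0.5),
        "d2": DiseaseDAG("d2", frozenset({"d2", "p"}), frozenset({("p", "d2")}), 0.5),
    }


def brute_force_nw(a, b, match=1.0, mismatch=-1.0, gap=-1.0):
    """Independent alignment-score oracle: exhaustive recursion over all
    global alignments (exponential; only for short sequences)."""
    if not a and not b:
        return 0.0
    best = -np.inf
    if a and b:
        sub = match if a[0] == b[0] else mismatch
        best = max(best, sub + brute_force_nw(a[1:], b[1:], match, mismatch, gap))
    if a:
        best = max(best, gap + brute_force_nw(a[1:], b, match, mismatch, gap))
    if b:
        best = max(best, gap + brute_force_nw(a, b[1:], match, mismatch, gap))
    return best


def pair_counting_auc(y_true, y_score):
    """O(n^2) AUC oracle: positive-negative pair counting, midrank ties."""
    y_true = np.asarray(y_true)
    y_score = np.asarray(y_score)
    pos = y_score[y_true == 1]
    neg = y_score[y_true == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))
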