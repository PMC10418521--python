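"""Subject fingerprinting: scan-to-scan similarity and identification accuracy.

A subject is *identified* when a query FC vector's most similar other
vector in the cohort (by cosine similarity, or negated Euclidean
distance) belongs to the same subject.  This is per-query
nearest-neighbor matching, the standard fingerprinting protocol; exact
ties count as failure so the statistic is deterministic.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import cdist

from .types import ConnectivityVector, SimilarityMatrix

__all__ = [
    "cosine_similarity",
    "similarity_matrix",
    "identification_accuracy",
    "chance_level",
]


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """sim(a, b) = a.b / (||a|| ||b||), in [-1, 1].

    Invariant to positive rescaling of either argument; raises on zero
    vectors or mismatched lengths.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def _stack(vectors: Sequence[ConnectivityVector]) -> np.ndarray:
    if len(vectors) < 2:
        raise ValueError("need at least two vectors")
    lengths = {v.values.size for v in vectors}
    if len(lengths) > 1:
        raise ValueError(f"mixed vector lengths {sorted(lengths)}")
    return np.vstack([v.values for v in vectors])


def similarity_matrix(
    vectors: Sequence[ConnectivityVector], metric: str = "cosine"
) -> SimilarityMatrix:
    """Pairwise similarity of a list of FC vectors.

    metric='cosine' gives the symmetric unit-diagonal cosine matrix;
    metric='euclidean' stores negated distances so that higher always
    means more similar (diagonal 0, unit-diagonal invariant waived).
    """
    x = _stack(vectors)
    if metric == "cosine":
        norms = np.linalg.norm(x, axis=1)
        if np.any(norms == 0):
            raise ValueError("cosine similarity undefined for a zero vector")
        sims = (x / norms[:, None]) @ (x / norms[:, None]).T
        sims = np.clip((sims + sims.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(sims, 1.0)
        unit_diag = True
    elif metric == "euclidean":
        sims = -cdist(x, x, metric="euclidean")
        sims = (sims + sims.T) / 2.0
        np.fill_diagonal(sims, 0.0)
        unit_diag = False
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return SimilarityMatrix(
        scan_index=[v.unit for v in vectors],
        values=sims,
        metric=metric,
        unit_diagonal=unit_diag,
    )


def identification_accuracy(
    vectors: Sequence[ConnectivityVector], metric: str = "cosine"
) -> Tuple[float, int]:
    """Fraction of query vectors whose nearest neighbor is same-subject.

    Every vector whose subject has at least one other vector in the
    cohort is a query.  A query succeeds iff its best same-subject
    similarity strictly exceeds its best different-subject similarity
    (so exact ties fail).  Window-level vectors of one subject count as
    same-subject matches — exactly the mechanism the dFC exploit uses.

    Returns (accuracy, n_queries).
    """
    sim = similarity_matrix(vectors, metric=metric)
    subjects = np.array([v.subject_id for v in vectors])
    s = sim.values
    n = len(vectors)
    successes = 0
    n_queries = 0
    for q in range(n):
        same = (subjects == subjects[q])
        same[q] = False
        if not same.any():
            continue
        n_queries += 1
        other = ~same
        other[q] = False
        if not other.any():
            # no competing subject: trivially successful match
            successes += 1
            continue
        if s[q, same].max() > s[q, other].max():
            successes += 1
    if n_queries == 0:
        raise ValueError("no subject has two or more vectors")
    return successes / n_queries, n_queries


def chance_level(n_subjects: int, scans_per_subject: int) -> float:
    """Analytic accuracy of uniform random matching.

    A query has S - 1 candidate vectors, scans_per_subject - 1 of which
    are same-subject, with S = n_subjects * scans_per_subject.
    """
    if scans_per_subject < 2:
        raise ValueError("scans_per_subject must be >= 2")
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    total = n_subjects * scans_per_subject
    return (scans_per_subject - 1) / (total - 1)
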