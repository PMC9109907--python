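"""Pairwise compound-diversity analytics over binary fingerprints.

Two dissimilarity metrics between fingerprints ``A`` and ``B``::

    Cosine(A, B)  = 1 - A.B / (|A|_2 |B|_2)
    Jaccard(A, B) = 1 - |A n B| / |A u B|      (bits read as sets)

Pairwise values are collected into the upper triangle of an n x n matrix and
summarized by distributional statistics plus an aggregate score.  Two
normalizations of the aggregate are reported side by side: ``mean`` divides
the summed dissimilarities by the true pair count n(n-1)/2, while
``halfsq_score`` divides by m = n^2/2, a convention that undercounts by the
factor (n-1)/n; callers get both rather than a silent choice between them.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .molgraph import Fingerprint, MolecularGraph, extract_scaffold

__all__ = [
    "DissimilarityMatrix",
    "DiversitySummary",
    "cosine_distance",
    "jaccard_dissimilarity",
    "pairwise_dissimilarity",
    "summarize_diversity",
    "scaffold_share_distribution",
    "pca_projection",
]

METRICS = ("cosine", "jaccard")


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Upper-triangular pairwise dissimilarities, stored condensed.

    ``values`` holds the n(n-1)/2 entries d_ij for i < j in row-major pair
    order (the same convention as ``scipy.spatial.distance.pdist``).
    """

    values: np.ndarray
    metric: str
    n: int

    def __post_init__(self):
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.n < 2:
            raise ValueError("need at least two fingerprints")
        values = np.asarray(self.values, dtype=float)
        if values.shape != (self.n * (self.n - 1) // 2,):
            raise ValueError("condensed value vector has wrong length")
        if (values < -1e-12).any() or (values > 1 + 1e-12).any():
            raise ValueError("dissimilarities must lie in [0, 1]")
        object.__setattr__(self, "values", np.clip(values, 0.0, 1.0))

    def entry(self, i: int, j: int) -> float:
        """d_ij for i < j."""
        if not 0 <= i < j < self.n:
            raise IndexError("need 0 <= i < j < n")
        return float(self.values[self.n * i - i * (i + 1) // 2 + (j - i - 1)])

    def square(self) -> np.ndarray:
        """Full symmetric matrix with zero diagonal."""
        out = np.zeros((self.n, self.n))
        iu = np.triu_indices(self.n, 1)
        out[iu] = self.values
        return out + out.T


@dataclass(frozen=True)
class DiversitySummary:
    """Distributional statistics of the pairwise dissimilarities.

    ``mean`` is the average over the n(n-1)/2 actual pairs (the quantity the
    percentile columns describe); ``halfsq_score`` is the same sum divided by
    m = n^2/2, hence always mean * (n-1)/n.
    """

    mean: float
    std: float
    p25: float
    p50: float
    p75: float
    max: float
    min: float
    halfsq_score: float
    n: int

    def as_dict(self) -> dict:
        return {
            "mean": self.mean, "std": self.std, "p25": self.p25, "p50": self.p50,
            "p75": self.p75, "max": self.max, "min": self.min,
            "halfsq_score": self.halfsq_score, "n": self.n,
        }


def _check_pair(A: Fingerprint, B: Fingerprint) -> tuple[np.ndarray, np.ndarray]:
    if A.length != B.length:
        raise ValueError("fingerprints have different lengths")
    return A.bits.astype(float), B.bits.astype(float)


def cosine_distance(A: Fingerprint, B: Fingerprint) -> float:
    """1 - A.B / (|A||B|); errors on an all-zero vector (undefined norm)."""
    a, b = _check_pair(A, B)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine distance undefined for an all-zero fingerprint")
    d = 1.0 - float(a @ b) / (na * nb)
    if abs(d) < 1e-12:  # identical supports: snap float error to an exact 0
        d = 0.0
    return float(np.clip(d, 0.0, 1.0))


def jaccard_dissimilarity(A: Fingerprint, B: Fingerprint) -> float:
    """1 - |intersection| / |union| of the bit supports."""
    a, b = _check_pair(A, B)
    union = float(np.maximum(a, b).sum())
    if union == 0:
        raise ValueError("Jaccard dissimilarity undefined for two all-zero fingerprints")
    inter = float((a * b).sum())
    return 1.0 - inter / union


def pairwise_dissimilarity(
    fps: list[Fingerprint], metric: str = "jaccard", ids: list[str] | None = None
) -> DissimilarityMatrix:
    """All-pairs dissimilarity of a fingerprint list (vectorized).

    Metric errors (all-zero fingerprints) are re-raised with the identity of
    the offending compound.
    """
    n = len(fps)
    if n < 2:
        raise ValueError("need at least two fingerprints")
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    F = np.stack([fp.bits for fp in fps]).astype(float)
    pop = F.sum(axis=1)
    if (pop == 0).any():
        bad = int(np.argmax(pop == 0))
        name = ids[bad] if ids else f"index {bad}"
        raise ValueError(f"all-zero fingerprint for compound {name}; filter featureless compounds")
    inter = F @ F.T
    iu = np.triu_indices(n, 1)
    if metric == "cosine":
        d = 1.0 - inter / np.sqrt(np.outer(pop, pop))
        d[np.abs(d) < 1e-12] = 0.0
    else:
        union = pop[:, None] + pop[None, :] - inter
        d = 1.0 - inter / union
    return DissimilarityMatrix(values=np.clip(d[iu], 0.0, 1.0), metric=metric, n=n)


def summarize_diversity(matrix: DissimilarityMatrix) -> DiversitySummary:
    """Summary statistics plus both aggregate-score normalizations."""
    v = matrix.values
    n = matrix.n
    total = float(v.sum())
    return DiversitySummary(
        mean=float(v.mean()),
        std=float(v.std()),
        p25=float(np.percentile(v, 25)),
        p50=float(np.percentile(v, 50)),
        p75=float(np.percentile(v, 75)),
        max=float(v.max()),
        min=float(v.min()),
        halfsq_score=total / (n * n / 2.0),
        n=n,
    )


def scaffold_share_distribution(
    graphs: list[MolecularGraph],
) -> tuple[dict[int, int], int]:
    """Histogram of scaffold sharing: molecules-per-scaffold -> scaffold count.

    Returns ``(histogram, n_acyclic)`` where ``histogram[k]`` counts the
    scaffolds shared by exactly ``k`` molecules; molecules with an empty
    (acyclic) scaffold are tallied separately in ``n_acyclic``.
    """
    if not graphs:
        raise ValueError("need at least one molecule")
    scaffold_of: Counter[str] = Counter()
    n_acyclic = 0
    for g in graphs:
        s = extract_scaffold(g)
        if s.is_empty:
            n_acyclic += 1
        else:
            scaffold_of[s.canonical_smiles] += 1
    hist: dict[int, int] = {}
    for count in scaffold_of.values():
        hist[count] = hist.get(count, 0) + 1
    return hist, n_acyclic


def pca_projection(fps: list[Fingerprint], k: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Top-k principal-component scores of the centered bit matrix.

    Returns ``(coords, explained_variance)`` with ``coords`` of shape (n, k)
    and variances in non-increasing order.  Degenerate all-identical input
    yields all-zero coordinates with a warning.
    """
    import warnings

    n = len(fps)
    if not (n > k >= 1):
        raise ValueError("need n > k >= 1")
    F = np.stack([fp.bits for fp in fps]).astype(float)
    Fc = F - F.mean(axis=0)
    if not Fc.any():
        warnings.warn("all fingerprints identical: zero-variance PCA", stacklevel=2)
        return np.zeros((n, k)), np.zeros(k)
    from sklearn.decomposition import PCA

    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(F)
    return coords, pca.explained_variance_
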