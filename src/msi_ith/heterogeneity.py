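"""Intratumor-heterogeneity metrics over pixel spectra and cluster maps.

Two complementary views of heterogeneity:

* the pairwise spectral similarity index — Pearson correlation of the
  component-abundance vectors of two pixels — summarized per ROI by its
  median and cumulative distribution; a homogeneous region has similarity
  near 1, a heterogeneous one a broad, lower distribution;
* the Gini-Simpson diversity index ``D = 1 - sum p_i^2`` over the cluster
  composition of a ROI — the probability that two randomly drawn pixels
  belong to different clusters.

Group contrasts (e.g. favorable vs progressive outcome) use the Wilcoxon
rank-sum test for two groups and Kruskal-Wallis for more.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SimilarityDistribution",
    "DiversityRecord",
    "similarity",
    "similarity_distribution",
    "simpson_index",
    "compare_groups",
]

CDF_GRID = np.linspace(-1.0, 1.0, 201)


# ---------------------------------------------------------------------------
# Pairwise similarity
# ---------------------------------------------------------------------------


def similarity(spec_a: np.ndarray, spec_b: np.ndarray, method: str = "pearson") -> float:
    """Similarity index of two component-abundance vectors.

    Default is the Pearson correlation (1 for identical shapes, -1 for
    perfectly anticorrelated ones); ``method="cosine"`` switches to cosine
    similarity.
    """
    a = np.asarray(spec_a, dtype=float)
    b = np.asarray(spec_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if method == "pearson":
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            raise ValueError("similarity undefined for a constant vector")
        return float(np.corrcoef(a, b)[0, 1])
    if method == "cosine":
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na == 0 or nb == 0:
            raise ValueError("similarity undefined for a zero vector")
        return float(a @ b / (na * nb))
    raise ValueError(f"unknown method {method!r}")


@dataclass
class SimilarityDistribution:
    """A sample of pairwise similarity values for one context."""

    context: str  # "intra-T" | "intra-N" | "inter-T/N" | free-form
    patient_id: str | None
    values: np.ndarray
    grid: np.ndarray = field(default_factory=lambda: CDF_GRID.copy())

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def median(self) -> float:
        return float(np.median(self.values))

    def cdf(self) -> np.ndarray:
        """Empirical CDF evaluated on the fixed grid."""
        s = np.sort(self.values)
        return np.searchsorted(s, self.grid, side="right") / len(s)


def _pair_sample(
    n_a: int,
    n_b: int | None,
    max_pairs: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Pair indices: exhaustive when the pair count fits in ``max_pairs``,
    otherwise a seeded uniform subsample.  ``n_b=None`` means intra mode
    (unordered pairs, no self-pairs)."""
    if n_b is None:
        total = n_a * (n_a - 1) // 2
        if total <= max_pairs:
            return np.triu_indices(n_a, k=1)
        i = rng.integers(0, n_a, size=2 * max_pairs)
        j = rng.integers(0, n_a, size=2 * max_pairs)
        ok = i != j
        i, j = i[ok][:max_pairs], j[ok][:max_pairs]
        while len(i) < max_pairs:
            ii = rng.integers(0, n_a, size=max_pairs)
            jj = rng.integers(0, n_a, size=max_pairs)
            ok = ii != jj
            i = np.concatenate([i, ii[ok]])[:max_pairs]
            j = np.concatenate([j, jj[ok]])[:max_pairs]
        return np.minimum(i, j), np.maximum(i, j)
    total = n_a * n_b
    if total <= max_pairs:
        i, j = np.meshgrid(np.arange(n_a), np.arange(n_b), indexing="ij")
        return i.ravel(), j.ravel()
    return (
        rng.integers(0, n_a, size=max_pairs),
        rng.integers(0, n_b, size=max_pairs),
    )


def similarity_distribution(
    abundances: np.ndarray,
    pixels_a: np.ndarray,
    pixels_b: np.ndarray | None = None,
    *,
    max_pairs: int = 100_000,
    seed: int = 0,
    context: str = "intra-T",
    patient_id: str | None = None,
    method: str = "pearson",
) -> SimilarityDistribution:
    """Distribution of pairwise similarities within one pixel set (intra)
    or across two sets (inter).

    All pairs are used when their number does not exceed ``max_pairs``;
    otherwise a seeded uniform subsample of ``max_pairs`` pairs is drawn.
    """
    values = np.asarray(abundances, dtype=float)
    idx_a = np.asarray(pixels_a, dtype=int)
    if len(idx_a) == 0:
        raise ValueError("empty pixel set")
    rng = np.random.default_rng(seed)
    if pixels_b is None:
        if len(idx_a) < 2:
            raise ValueError("intra mode needs at least 2 pixels")
        i, j = _pair_sample(len(idx_a), None, max_pairs, rng)
        rows_i, rows_j = idx_a[i], idx_a[j]
    else:
        idx_b = np.asarray(pixels_b, dtype=int)
        if len(idx_b) == 0:
            raise ValueError("empty pixel set")
        i, j = _pair_sample(len(idx_a), len(idx_b), max_pairs, rng)
        rows_i, rows_j = idx_a[i], idx_b[j]
    sub = values[np.concatenate([rows_i, rows_j])]
    if method == "pearson":
        z = sub - sub.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(z, axis=1)
        if np.any(norms == 0):
            raise ValueError("similarity undefined for a constant pixel vector")
        z /= norms[:, None]
    elif method == "cosine":
        norms = np.linalg.norm(sub, axis=1)
        if np.any(norms == 0):
            raise ValueError("similarity undefined for a zero pixel vector")
        z = sub / norms[:, None]
    else:
        raise ValueError(f"unknown method {method!r}")
    half = len(rows_i)
    sims = np.einsum("ij,ij->i", z[:half], z[half:])
    return SimilarityDistribution(
        context=context, patient_id=patient_id, values=sims
    )


# ---------------------------------------------------------------------------
# Simpson diversity
# ---------------------------------------------------------------------------


@dataclass
class DiversityRecord:
    patient_id: str
    roi: str
    level: int
    n_clusters: int
    simpson_d: float

    def __post_init__(self) -> None:
        upper = 1.0 - 1.0 / self.n_clusters if self.n_clusters else 0.0
        if not (0.0 <= self.simpson_d <= upper + 1e-12):
            raise ValueError("Simpson D outside [0, 1 - 1/n_clusters]")


def simpson_index(
    cluster_counts: Mapping[int, int] | Sequence[int], *, finite_sample: bool = False
) -> float:
    """Gini-Simpson diversity of a cluster composition.

    ``D = 1 - sum p_i^2`` with ``p_i = n_i / N`` (the probability that two
    pixels drawn with replacement fall in different clusters).  With
    ``finite_sample=True`` the without-replacement form
    ``1 - sum n_i (n_i - 1) / (N (N - 1))`` is used instead; the two
    differ by less than ``1/N``.
    """
    if isinstance(cluster_counts, Mapping):
        counts = np.asarray(list(cluster_counts.values()), dtype=float)
    else:
        counts = np.asarray(cluster_counts, dtype=float)
    counts = counts[counts > 0]
    total = counts.sum()
    if total < 1:
        raise ValueError("total count must be >= 1")
    if finite_sample:
        if total < 2:
            return 0.0
        return float(1.0 - np.sum(counts * (counts - 1)) / (total * (total - 1)))
    p = counts / total
    return float(1.0 - np.sum(p**2))


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------


def compare_groups(values_by_group: Mapping[str, Sequence[float]]) -> dict:
    """Nonparametric comparison of a per-patient heterogeneity metric
    between outcome groups.

    Two groups: Wilcoxon rank-sum (two-sided; exact when both samples have
    at most 20 untied observations, otherwise the normal approximation
    with tie correction).  More than two: Kruskal-Wallis.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(v) < 2 for v in groups.values()):
        raise ValueError("each group needs at least 2 observations")
    medians = {k: float(np.median(v)) for k, v in groups.items()}
    if len(groups) == 2:
        (ga, xa), (gb, xb) = groups.items()
        pooled = np.concatenate([xa, xb])
        has_ties = len(np.unique(pooled)) < len(pooled)
        exact = (not has_ties) and max(len(xa), len(xb)) <= 20
        res = stats.mannwhitneyu(
            xa,
            xb,
            alternative="two-sided",
            method="exact" if exact else "asymptotic",
            use_continuity=False,
        )
        return {
            "test": "wilcoxon-rank-sum",
            "statistic": float(res.statistic),
            "p_value": float(res.pvalue),
            "medians": medians,
            "exact": exact,
        }
    res = stats.kruskal(*groups.values())
    return {
        "test": "kruskal-wallis",
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "medians": medians,
        "exact": False,
    }
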