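"""Co-evolution scores for a gene set within one clade.

Two complementary statistics summarize how strongly a gene set co-evolves:

* the **threshold score** — the percentage of the N(N-1)/2 pairwise Pearson
  correlations between gene profiles that reach a chosen threshold
  (recommended around 0.7; paralogs typically exceed 0.9, unrelated genes
  sit near 0);
* the **cluster score** — complete-linkage hierarchical clustering on the
  correlation distance d = 1 - r, cut at height 0.2 (so every within-cluster
  pair has r >= 0.8), scored as sum_i (size_i / #clusters)^2, which rewards
  one or a few large coherent modules and penalizes fragmentation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .profiles import ProfileMatrix, ProfileError

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationMatrix",
    "ScoreConfig",
    "ClusterPartition",
    "pairwise_correlations",
    "count_pairs",
    "threshold_score",
    "cluster_partition",
    "cluster_score",
]

#: selectable algebraic readings of the cluster score
CLUSTER_SCORE_FORMS = ("fraction_squared", "sum_sq_over_c", "sum_over_c_sq")


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix over a gene set."""

    genes: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = len(self.genes)
        if n < 3:
            raise ProfileError("correlation matrix needs at least 3 genes")
        if self.r.shape != (n, n):
            raise ProfileError(f"correlation matrix shape {self.r.shape} != ({n},{n})")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ProfileError("correlation matrix is not symmetric")
        if not np.allclose(np.diag(self.r), 1.0):
            raise ProfileError("correlation matrix diagonal must be 1")
        if self.r.min() < -1 - 1e-9 or self.r.max() > 1 + 1e-9:
            raise ProfileError("correlations outside [-1, 1]")

    @property
    def n(self) -> int:
        return len(self.genes)

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.r, index=self.genes, columns=self.genes)
        df.index.name = "gene"
        return df


@dataclass(frozen=True)
class ScoreConfig:
    """Tunables of the scoring step.

    threshold : pairwise-correlation threshold for the threshold score and
        the network (recommended ~0.7, sensible range 0.65-0.9).
    cut_height : dendrogram cut height on d = 1 - r (0.2 <=> minimal
        within-cluster correlation 0.8).
    cluster_score_form : algebraic reading of the cluster score; the default
        ``fraction_squared`` is sum_i (size_i / c)^2.
    """

    threshold: float = 0.7
    cut_height: float = 0.2
    linkage: str = "complete"
    cluster_score_form: str = "fraction_squared"

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ProfileError("threshold must lie in (0, 1)")
        if not 0.0 < self.cut_height < 2.0:
            raise ProfileError("cut_height must lie in (0, 2)")
        if self.linkage != "complete":
            raise ProfileError("only complete linkage is supported")
        if self.cluster_score_form not in CLUSTER_SCORE_FORMS:
            raise ProfileError(
                f"cluster_score_form must be one of {CLUSTER_SCORE_FORMS}"
            )


@dataclass
class ClusterPartition:
    """Flat clustering of a gene set after cutting the dendrogram."""

    assignment: dict[str, int]  # gene -> cluster index 1..c
    sizes: list[int] = field(default_factory=list)
    merge_heights: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = sorted(set(self.assignment.values()))
        if not self.assignment:
            raise ProfileError("empty partition")
        if labels != list(range(1, len(labels) + 1)):
            raise ProfileError("cluster indices must be contiguous from 1")
        if not self.sizes:
            self.sizes = [
                sum(1 for v in self.assignment.values() if v == k) for k in labels
            ]
        if sum(self.sizes) != len(self.assignment):
            raise ProfileError("cluster sizes do not sum to the gene count")

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)


def pairwise_correlations(
    m: ProfileMatrix, gene_set: Sequence[str]
) -> CorrelationMatrix:
    """Pearson correlations between gene profiles across the matrix species.

    Profiles with zero variance cannot evidence co-evolution; their
    correlations are set to 0 (with a logged warning) instead of NaN.
    """
    genes = list(gene_set)
    if len(genes) < 3:
        raise ProfileError("need at least 3 genes for a correlation matrix")
    if m.n_species < 3:
        raise ProfileError("need at least 3 species columns for correlations")
    x = np.vstack([m.gene_row(g) for g in genes])
    sd = x.std(axis=1)
    flat = sd == 0
    if flat.any():
        logger.warning(
            "zero-variance profile(s), correlations set to 0: %s",
            ", ".join(g for g, f in zip(genes, flat) if f),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r[flat, :] = 0.0
    r[:, flat] = 0.0
    np.clip(r, -1.0, 1.0, out=r)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(genes, r)


def count_pairs(n: int) -> int:
    """Number of unordered gene pairs in a set of size n: n(n-1)/2."""
    if n < 2:
        raise ProfileError("pair count needs n >= 2")
    return n * (n - 1) // 2


def threshold_score(corr: CorrelationMatrix, t: float = 0.7) -> float:
    """Percentage of pairwise correlations with r >= t (diagonal excluded)."""
    if not 0.0 < t < 1.0:
        raise ProfileError("threshold must lie in (0, 1)")
    iu = np.triu_indices(corr.n, k=1)
    exceed = int((corr.r[iu] >= t).sum())
    return 100.0 * exceed / count_pairs(corr.n)


def cluster_partition(
    corr: CorrelationMatrix, cfg: ScoreConfig = ScoreConfig()
) -> ClusterPartition:
    """Complete-linkage clustering on d = 1 - r, cut at ``cfg.cut_height``.

    With complete linkage, cutting at height h guarantees that every pair
    within a cluster satisfies r >= 1 - h.  Cluster indices are relabelled
    by first occurrence in gene order so identical inputs always yield the
    identical partition.
    """
    d = 1.0 - corr.r
    np.fill_diagonal(d, 0.0)
    np.clip(d, 0.0, None, out=d)
    z = linkage(squareform(d, checks=False), method=cfg.linkage)
    raw = fcluster(z, t=cfg.cut_height, criterion="distance")
    relabel: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for gene, lab in zip(corr.genes, raw):
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
        assignment[gene] = relabel[lab]
    return ClusterPartition(assignment, merge_heights=[float(h) for h in z[:, 2]])


def cluster_score(p: ClusterPartition, form: str = "fraction_squared") -> float:
    """Cohesiveness score from cluster sizes s_i and cluster count c.

    The default reading is sum_i (s_i / c)^2: one cluster of N genes scores
    N^2, N singletons score 1/N.  Alternative readings (``sum_sq_over_c`` =
    sum s_i^2 / c, ``sum_over_c_sq`` = sum s_i / c^2) are selectable.
    """
    s = np.asarray(p.sizes, dtype=float)
    c = float(p.n_clusters)
    if form == "fraction_squared":
        return float(np.sum((s / c) ** 2))
    if form == "sum_sq_over_c":
        return float(np.sum(s**2) / c)
    if form == "sum_over_c_sq":
        return float(np.sum(s) / c**2)
    raise ProfileError(f"unknown cluster score form {form!r}")
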