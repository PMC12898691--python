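"""Empirical significance of gene-set co-evolution scores.

The observed score of a query gene set is compared, clade by clade, with
the scores of R size-matched random gene sets drawn uniformly from the
background of genes conserved in that clade (1000 sets by default).  The
add-one permutation estimator gives a strictly positive empirical p-value,
and Benjamini-Hochberg adjustment across the tested clades yields FDR
values.  A positive-control set (the Krebs-cycle genes, whose concerted
loss outside aerobic lineages makes them a benchmark of pathway-level
co-evolution) is scored alongside the query, padded with random genes when
the query is larger.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .profiles import (
    CladeMap,
    ConservationCriterion,
    ProfileError,
    ProfileMatrix,
    conserved_genes,
    filter_all_zero_genes,
    normalize_npp,
    restrict_to_clade,
)
from .scores import (
    ClusterPartition,
    CorrelationMatrix,
    ScoreConfig,
    cluster_partition,
    cluster_score,
    count_pairs,
    pairwise_correlations,
    threshold_score,
)

logger = logging.getLogger(__name__)

__all__ = [
    "NullDistribution",
    "ControlAugmentation",
    "CladeResult",
    "GeneSetResult",
    "sample_random_sets",
    "null_distribution",
    "empirical_pvalue",
    "bh_fdr",
    "augment_control_set",
    "run_gsa",
    "krebs_cycle_genes",
    "clade_seed",
]


@dataclass
class NullDistribution:
    """Scores of R size-matched random gene sets in one clade."""

    clade: str
    set_size: int
    scores: np.ndarray
    score_kind: str  # "threshold" | "cluster"
    seed: int

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.size < 1:
            raise ProfileError("null distribution needs at least one score")
        if self.score_kind not in ("threshold", "cluster"):
            raise ProfileError(f"unknown score kind {self.score_kind!r}")

    @property
    def R(self) -> int:
        return int(self.scores.size)


@dataclass
class ControlAugmentation:
    """Recipe for padding the positive-control set up to the query size."""

    control_genes: list[str]
    n_added: int
    background: list[str]
    seed: int


def clade_seed(master_seed: int, clade: str) -> int:
    """Deterministic per-clade child seed (stable across runs/platforms)."""
    return (int(master_seed) * 0x9E3779B1 + zlib.crc32(clade.encode())) & 0x7FFFFFFF


def sample_random_sets(
    background: Sequence[str], size: int, R: int, seed: int
) -> list[list[str]]:
    """Draw R gene sets of exactly ``size`` distinct genes, uniformly
    without replacement from ``background``; deterministic under seed."""
    background = list(background)
    if size > len(background):
        raise ProfileError(
            f"cannot draw {size} genes from a background of {len(background)}"
        )
    if R < 1:
        raise ProfileError("R must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(background)
    return [
        [background[i] for i in rng.choice(n, size=size, replace=False)]
        for _ in range(R)
    ]


# ---------------------------------------------------------------------------
# Fast subset scoring: pre-standardize profile rows once, then the Pearson
# correlation of any gene subset is a small inner product.


def _standardized_rows(values: np.ndarray) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    ss = np.sqrt((xc**2).sum(axis=1, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(ss > 0, xc / ss, 0.0)
    return z


def _subset_corr(z: np.ndarray, idx: np.ndarray) -> np.ndarray:
    r = z[idx] @ z[idx].T
    np.clip(r, -1.0, 1.0, out=r)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return r


def _scores_from_r(r: np.ndarray, genes: list[str], cfg: ScoreConfig):
    corr = CorrelationMatrix(genes, r)
    thr = threshold_score(corr, cfg.threshold)
    part = cluster_partition(corr, cfg)
    clu = cluster_score(part, cfg.cluster_score_form)
    return thr, clu, part


def _null_scores(
    m: ProfileMatrix,
    background: Sequence[str],
    size: int,
    R: int,
    seed: int,
    cfg: ScoreConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Threshold and cluster scores of R random sets from ``background``,
    scored identically to a query (same matrix, config, estimator)."""
    background = list(background)
    bg_idx = {g: i for i, g in enumerate(background)}
    z = _standardized_rows(np.vstack([m.gene_row(g) for g in background]))
    rng = np.random.default_rng(seed)
    thr = np.empty(R)
    clu = np.empty(R)
    n = len(background)
    for i in range(R):
        idx = rng.choice(n, size=size, replace=False)
        r = _subset_corr(z, idx)
        genes = [background[j] for j in idx]
        thr[i], clu[i], _ = _scores_from_r(r, genes, cfg)
    del bg_idx
    return thr, clu


def null_distribution(
    m: ProfileMatrix,
    background: Sequence[str],
    size: int,
    R: int,
    seed: int,
    cfg: ScoreConfig = ScoreConfig(),
    score_kind: str = "threshold",
    clade: str = "",
) -> NullDistribution:
    """Null distribution of one score kind for size-matched random sets."""
    if size < 3:
        raise ProfileError("random sets need at least 3 genes")
    thr, clu = _null_scores(m, background, size, R, seed, cfg)
    scores = thr if score_kind == "threshold" else clu
    return NullDistribution(clade, size, scores, score_kind, seed)


def empirical_pvalue(observed: float, null: NullDistribution | np.ndarray) -> float:
    """Add-one permutation p-value: (1 + #{null_i >= observed}) / (R + 1).

    Strictly positive; equals 1/(R+1) when the observation beats every
    null score and 1.0 when it beats none.
    """
    scores = null.scores if isinstance(null, NullDistribution) else np.asarray(null)
    if scores.size == 0:
        raise ProfileError("empty null distribution")
    return float((1 + int((scores >= observed).sum())) / (scores.size + 1))


def bh_fdr(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if (p <= 0).any() or (p > 1).any():
        raise ProfileError("p-values must lie in (0, 1]")
    return [float(q) for q in multipletests(p, method="fdr_bh")[1]]


def augment_control_set(ctrl: ControlAugmentation) -> list[str]:
    """Pad the control set with ``n_added`` uniform draws from the
    background (excluding control members) to match the query size."""
    if ctrl.n_added <= 0:
        return list(ctrl.control_genes)
    pool = [g for g in ctrl.background if g not in set(ctrl.control_genes)]
    if ctrl.n_added > len(pool):
        raise ProfileError(
            f"background too small: need {ctrl.n_added} extra genes, have {len(pool)}"
        )
    rng = np.random.default_rng(ctrl.seed)
    extra = [pool[i] for i in rng.choice(len(pool), size=ctrl.n_added, replace=False)]
    return list(ctrl.control_genes) + extra


def krebs_cycle_genes() -> list[str]:
    """Positive-control gene list: human Krebs (TCA) cycle enzymes per KEGG
    pathway membership, shipped with the package."""
    text = resources.files("cladecoev").joinpath("data/krebs_cycle_control.txt").read_text()
    return [ln.strip().upper() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]


# ---------------------------------------------------------------------------
# Orchestration


@dataclass
class CladeResult:
    """Scores and significance of the query within one clade."""

    clade: str
    n_species: int = 0
    n_input: int = 0
    n_conserved: int = 0
    genes_used: list[str] = field(default_factory=list)
    threshold_score: float | None = None
    cluster_score: float | None = None
    n_clusters: int | None = None
    partition: ClusterPartition | None = None
    correlations: CorrelationMatrix | None = None
    p_threshold: float | None = None
    p_cluster: float | None = None
    q_threshold: float | None = None
    q_cluster: float | None = None
    control_score: float | None = None
    null_threshold: np.ndarray | None = None
    null_cluster: np.ndarray | None = None
    seed: int = 0
    skipped: str | None = None


@dataclass
class GeneSetResult:
    """Full gene-set analysis outcome across clades."""

    input_genes: list[str]
    matched: list[str]
    unmatched: list[str]
    clade_results: list[CladeResult]
    config: ScoreConfig
    criterion: ConservationCriterion
    R: int
    seed: int

    def result(self, clade: str) -> CladeResult:
        for cr in self.clade_results:
            if cr.clade == clade:
                return cr
        raise ProfileError(f"no result for clade {clade!r}")

    def to_frame(self):
        import pandas as pd

        rows = []
        for cr in self.clade_results:
            rows.append(
                dict(
                    clade=cr.clade,
                    n_input=cr.n_input,
                    n_conserved=cr.n_conserved,
                    threshold_score=cr.threshold_score,
                    cluster_score=cr.cluster_score,
                    n_clusters=cr.n_clusters,
                    p_threshold=cr.p_threshold,
                    q_threshold=cr.q_threshold,
                    p_cluster=cr.p_cluster,
                    q_cluster=cr.q_cluster,
                    control_score=cr.control_score,
                    R=self.R,
                    seed=cr.seed,
                    skipped=cr.skipped or "",
                )
            )
        return pd.DataFrame(rows)


def _normalize_symbols(genes: Sequence[str]) -> list[str]:
    out: list[str] = []
    seen: set[str] = set()
    for g in genes:
        s = str(g).strip().upper()
        if s and s not in seen:
            seen.add(s)
            out.append(s)
    return out


def run_gsa(
    m: ProfileMatrix,
    clades: CladeMap,
    gene_set: Sequence[str],
    cfg: ScoreConfig = ScoreConfig(),
    criterion: ConservationCriterion = ConservationCriterion(),
    R: int = 1000,
    seed: int = 0,
    selected_clades: Sequence[str] | None = None,
    max_genes: int = 100,
    control_genes: Sequence[str] | None = None,
    null_background: str = "conserved",
    npp_epsilon: float = 0.01,
    npp_method: str = "zscore",
) -> GeneSetResult:
    """Run the full clade-wise co-evolution analysis of a gene set.

    For every selected clade the LNPP matrix is restricted to the clade's
    species, non-conserved genes are dropped, pairwise Pearson correlations
    of the query are computed on the per-species-normalized (NPP) profiles,
    the threshold and cluster scores are compared with R size-matched
    random gene sets, and BH-FDR is applied across clades.  Clades with
    fewer than 3 conserved query genes are skipped with a logged reason.

    Parameters
    ----------
    m : ProfileMatrix (LNPP variant)
        Full gene universe; conservation filtering uses these raw values.
    null_background : {"conserved", "all"}
        Pool for random sets — genes conserved in the clade (default,
        mirroring the exclusion of non-conserved genes from the random
        significance analysis) or the full gene universe.
    """
    if m.variant != "LNPP":
        raise ProfileError("run_gsa expects the LNPP matrix")
    input_genes = _normalize_symbols(gene_set)
    matched = [g for g in input_genes if m.has_gene(g)]
    unmatched = [g for g in input_genes if not m.has_gene(g)]
    if unmatched:
        logger.warning("unmatched gene symbol(s): %s", ", ".join(unmatched))
    if not matched:
        raise ProfileError("no input gene matches the profile matrix")
    if len(matched) < 3:
        raise ProfileError(f"need at least 3 matched genes, got {len(matched)}")
    if len(matched) > max_genes:
        raise ProfileError(
            f"{len(matched)} matched genes exceeds the limit of {max_genes} per query"
        )

    lnpp, _removed = filter_all_zero_genes(m)
    npp = normalize_npp(lnpp, floor_epsilon=npp_epsilon, method=npp_method)
    control = _normalize_symbols(control_genes) if control_genes else []

    todo = list(selected_clades) if selected_clades else list(clades.clade_names)
    results: list[CladeResult] = []
    for clade in todo:
        cseed = clade_seed(seed, clade)
        cr = CladeResult(clade=clade, n_input=len(matched), seed=cseed)
        results.append(cr)
        try:
            lnpp_c = restrict_to_clade(lnpp, clades, clade)
        except ProfileError as exc:
            cr.skipped = str(exc)
            logger.warning("clade %s skipped: %s", clade, exc)
            continue
        cr.n_species = lnpp_c.n_species
        cons = conserved_genes(lnpp_c, criterion)
        cons_set = set(cons)
        query_c = [g for g in matched if g in cons_set]
        cr.n_conserved = len(query_c)
        cr.genes_used = query_c
        if len(query_c) < 3:
            cr.skipped = f"only {len(query_c)} conserved query genes (<3)"
            logger.warning("clade %s skipped: %s", clade, cr.skipped)
            continue
        npp_c = restrict_to_clade(npp, clades, clade)
        corr = pairwise_correlations(npp_c, query_c)
        cr.correlations = corr
        cr.threshold_score = threshold_score(corr, cfg.threshold)
        part = cluster_partition(corr, cfg)
        cr.partition = part
        cr.n_clusters = part.n_clusters
        cr.cluster_score = cluster_score(part, cfg.cluster_score_form)

        background = cons if null_background == "conserved" else list(lnpp.genes)
        if len(background) < len(query_c):
            cr.skipped = "background smaller than the query"
            continue
        logger.info(
            "clade %s: %d conserved query genes, background %d, seed %d",
            clade, len(query_c), len(background), cseed,
        )
        thr_null, clu_null = _null_scores(
            npp_c, background, len(query_c), R, cseed, cfg
        )
        cr.null_threshold = thr_null
        cr.null_cluster = clu_null
        cr.p_threshold = empirical_pvalue(cr.threshold_score, thr_null)
        cr.p_cluster = empirical_pvalue(cr.cluster_score, clu_null)

        if control:
            ctrl_c = [g for g in control if g in cons_set]
            if len(ctrl_c) >= 3:
                target = len(query_c)
                if target > len(ctrl_c):
                    ctrl_c = augment_control_set(
                        ControlAugmentation(
                            ctrl_c, target - len(ctrl_c),
                            [g for g in background], cseed ^ 0x5BF0,
                        )
                    )
                ctrl_corr = pairwise_correlations(npp_c, ctrl_c)
                cr.control_score = threshold_score(ctrl_corr, cfg.threshold)

    # FDR across the clades actually tested, separately per score kind
    tested = [cr for cr in results if cr.p_threshold is not None]
    if tested:
        q_thr = bh_fdr([cr.p_threshold for cr in tested])
        q_clu = bh_fdr([cr.p_cluster for cr in tested])
        for cr, qt, qc in zip(tested, q_thr, q_clu):
            cr.q_threshold = qt
            cr.q_cluster = qc

    return GeneSetResult(
        input_genes=input_genes,
        matched=matched,
        unmatched=unmatched,
        clade_results=results,
        config=cfg,
        criterion=criterion,
        R=R,
        seed=seed,
    )
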