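"""scRNA-seq preprocessing and the significant-gene channel.

Pipeline: (optional) drop genes on excluded chromosomes, filter cells by the
number of expressed genes, then normalise counts in three steps — per-cell
scaling to the median library size, log1p, per-gene z-score — and finally clip
to global quantiles of the standardised value distribution.  The fitted
:class:`NormalizationStats` reapplies the identical transform to new data.

The significant-gene channel is a ranked gene subset used as an auxiliary
input.  An externally supplied ranking (e.g. from an RNA-velocity analysis)
is used verbatim when given; otherwise genes are ranked by the variance of
their normalised expression as a proxy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

from .io_formats import (
    CellByFeatureMatrix,
    FeatureAxis,
    GeneModelTable,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RnaFilterConfig",
    "NormalizationStats",
    "SignificantGeneRanking",
    "filter_cells",
    "normalize",
    "apply_normalization",
    "rank_significant_genes",
    "build_sg_matrix",
]


@dataclass
class RnaFilterConfig:
    min_genes_per_cell: int = 200
    max_genes_per_cell: int = 7000
    clip_quantile: float = 0.005
    excluded_chromosomes: tuple[str, ...] = ("chrX", "chrY", "X", "Y")
    clip_stage: str = "post_zscore"  # or "post_log"

    def __post_init__(self) -> None:
        if not 0 < self.min_genes_per_cell < self.max_genes_per_cell:
            raise ValidationError("need 0 < min_genes_per_cell < max_genes_per_cell")
        if not 0.0 <= self.clip_quantile < 0.5:
            raise ValidationError("clip_quantile must be in [0, 0.5)")
        if self.clip_stage not in ("post_zscore", "post_log"):
            raise ValidationError("clip_stage must be 'post_zscore' or 'post_log'")


@dataclass
class NormalizationStats:
    """Everything needed to replay the fitted transform on new cells."""

    median_total: float
    gene_mean: np.ndarray  # post-log per-gene mean
    gene_sd: np.ndarray  # post-log per-gene sd (0 where degenerate)
    clip_lo: float
    clip_hi: float
    clip_stage: str
    gene_ids: list[str] = field(default_factory=list)
    scale_factors: Optional[np.ndarray] = None  # per training cell, median/total

    @property
    def zero_variance_genes(self) -> np.ndarray:
        return np.flatnonzero(self.gene_sd == 0)


def _expressed_per_cell(values) -> np.ndarray:
    if sp.issparse(values):
        return np.asarray((values > 0).sum(axis=1)).ravel()
    return (np.asarray(values) > 0).sum(axis=1)


def drop_excluded_gene_chromosomes(
    rna: CellByFeatureMatrix, genes: GeneModelTable, cfg: RnaFilterConfig
) -> CellByFeatureMatrix:
    """Drop genes located on excluded chromosomes (needs a gene-model table)."""
    chrom = genes.chrom_of()
    excluded = set(cfg.excluded_chromosomes)
    keep = [
        i
        for i, gid in enumerate(rna.features.ids)
        if chrom.get(gid) not in excluded
    ]
    return rna.subset_features(keep)


def filter_cells(
    rna: CellByFeatureMatrix, cfg: RnaFilterConfig | None = None
) -> CellByFeatureMatrix:
    """Keep cells expressing between min and max genes (inclusive bounds)."""
    cfg = cfg or RnaFilterConfig()
    g = _expressed_per_cell(rna.values)
    keep = np.flatnonzero(
        (g >= cfg.min_genes_per_cell) & (g <= cfg.max_genes_per_cell)
    )
    if len(keep) < rna.n_cells:
        logger.info(
            "cell filter removed %d of %d cells", rna.n_cells - len(keep), rna.n_cells
        )
    return rna.subset_cells(keep)


def normalize(
    rna: CellByFeatureMatrix, cfg: RnaFilterConfig | None = None
) -> tuple[CellByFeatureMatrix, NormalizationStats]:
    """Median-count scaling, log1p, per-gene z-score, global quantile clipping.

    Steps: (1) scale each cell's counts by ``median_total / total(c)`` so all
    cells total the median library size; (2) ``log(1 + scaled)``; (3) z-score
    each gene (zero-variance genes map to 0); (4) clip all entries to the
    global [q, 1-q] quantiles of the standardised values (default q = 0.5%).
    """
    cfg = cfg or RnaFilterConfig()
    if rna.n_cells < 2:
        raise ValidationError("normalization needs at least 2 cells")
    x = rna.dense().astype(np.float64)
    totals = x.sum(axis=1)
    if np.any(totals == 0):
        raise ValidationError(
            "cells with zero total counts present; run filter_cells first"
        )
    median_total = float(np.median(totals))
    scale_factors = median_total / totals
    logx = np.log1p(x * scale_factors[:, None])

    gene_mean = logx.mean(axis=0)
    gene_sd = logx.std(axis=0)
    degenerate = gene_sd == 0
    if degenerate.any():
        logger.info("%d genes have zero variance after log; z-score set to 0",
                    int(degenerate.sum()))
    safe_sd = np.where(degenerate, 1.0, gene_sd)
    z = (logx - gene_mean) / safe_sd
    z[:, degenerate] = 0.0

    stage = z if cfg.clip_stage == "post_zscore" else logx
    if cfg.clip_quantile > 0:
        clip_lo = float(np.quantile(stage, cfg.clip_quantile))
        clip_hi = float(np.quantile(stage, 1.0 - cfg.clip_quantile))
    else:
        clip_lo, clip_hi = -np.inf, np.inf
    if cfg.clip_stage == "post_zscore":
        out = np.clip(z, clip_lo, clip_hi)
    else:
        logx = np.clip(logx, clip_lo, clip_hi)
        z = (logx - gene_mean) / safe_sd
        z[:, degenerate] = 0.0
        out = z
    stats = NormalizationStats(
        median_total=median_total,
        gene_mean=gene_mean,
        gene_sd=np.where(degenerate, 0.0, gene_sd),
        clip_lo=clip_lo,
        clip_hi=clip_hi,
        clip_stage=cfg.clip_stage,
        gene_ids=list(rna.features.ids),
        scale_factors=scale_factors,
    )
    normalized = CellByFeatureMatrix(
        barcodes=list(rna.barcodes), features=rna.features, values=out
    )
    return normalized, stats


def apply_normalization(
    rna: CellByFeatureMatrix, stats: NormalizationStats
) -> CellByFeatureMatrix:
    """Replay a fitted transform on new raw counts (identical gene order required)."""
    if stats.gene_ids and list(rna.features.ids) != list(stats.gene_ids):
        raise ValidationError("gene order differs from the fitted normalization")
    x = rna.dense().astype(np.float64)
    totals = x.sum(axis=1)
    if np.any(totals == 0):
        raise ValidationError("cells with zero total counts cannot be normalized")
    logx = np.log1p(x * (stats.median_total / totals)[:, None])
    degenerate = stats.gene_sd == 0
    safe_sd = np.where(degenerate, 1.0, stats.gene_sd)
    if stats.clip_stage == "post_log":
        logx = np.clip(logx, stats.clip_lo, stats.clip_hi)
    z = (logx - stats.gene_mean) / safe_sd
    z[:, degenerate] = 0.0
    if stats.clip_stage == "post_zscore":
        z = np.clip(z, stats.clip_lo, stats.clip_hi)
    return CellByFeatureMatrix(
        barcodes=list(rna.barcodes), features=rna.features, values=z
    )


@dataclass
class SignificantGeneRanking:
    """Genes ordered by decreasing score, with the provenance of the scores."""

    gene_ids: list[str]
    scores: list[float]
    provenance: str  # "external_list" or "variance_proxy"

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(self.scores):
            raise ValidationError("ranking ids and scores differ in length")
        if not all(np.isfinite(self.scores)):
            raise ValidationError("ranking scores must be finite")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def top(self, k: int) -> list[str]:
        return self.gene_ids[:k]


def rank_significant_genes(
    rna: CellByFeatureMatrix,
    external: Optional[Sequence[tuple[str, float]]] = None,
) -> SignificantGeneRanking:
    """Rank genes for the significant-gene channel.

    With ``external`` (e.g. velocity scores), the given order is kept,
    restricted to genes present in the matrix.  Otherwise genes are ranked by
    the variance of ``rna`` (expected to be the normalised matrix), descending,
    ties broken by gene id.
    """
    present = set(rna.features.ids)
    if external is not None:
        pairs = [(g, float(s)) for g, s in external if g in present]
        if not pairs:
            raise ValidationError(
                "external significant-gene list shares no genes with the matrix"
            )
        return SignificantGeneRanking(
            gene_ids=[g for g, _ in pairs],
            scores=[s for _, s in pairs],
            provenance="external_list",
        )
    x = rna.dense()
    var = np.asarray(x).var(axis=0)
    order = sorted(range(len(var)), key=lambda i: (-var[i], rna.features.ids[i]))
    return SignificantGeneRanking(
        gene_ids=[rna.features.ids[i] for i in order],
        scores=[float(var[i]) for i in order],
        provenance="variance_proxy",
    )


def build_sg_matrix(
    rna_normalized: CellByFeatureMatrix,
    ranking: SignificantGeneRanking,
    top_k: Optional[int] = None,
) -> CellByFeatureMatrix:
    """Column subset of the normalised RNA matrix: the top_k ranked genes, in rank order.

    Default ``top_k`` is min(2000, number of ranked genes).
    """
    if top_k is None:
        top_k = min(2000, len(ranking))
    if top_k <= 0:
        raise ValidationError("top_k must be positive")
    if top_k > len(ranking):
        raise ValidationError(
            f"top_k ({top_k}) exceeds ranking length ({len(ranking)})"
        )
    col_of = {g: i for i, g in enumerate(rna_normalized.features.ids)}
    try:
        idx = [col_of[g] for g in ranking.top(top_k)]
    except KeyError as exc:
        raise ValidationError(f"ranked gene missing from matrix: {exc}") from exc
    return rna_normalized.subset_features(idx)
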