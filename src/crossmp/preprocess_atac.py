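"""scATAC-seq preprocessing: sex-chromosome removal, overlapping-peak merging,
binarisation, and frequency-based peak filtering.

The canonical pipeline order is: drop excluded chromosomes -> merge
overlapping peaks -> binarize -> frequency filter.  Merging aggregates member
peaks by elementwise maximum, so merging and binarisation commute.

Boundary semantics follow the literal filter wording: peaks in *fewer than*
``min_cells_per_peak`` cells are removed (support equal to the threshold is
kept), and peaks in *more than* ``max_cell_fraction_per_peak`` of cells are
removed (support exactly at the fraction is kept).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_formats import (
    CellByFeatureMatrix,
    FeatureAxis,
    GenomicInterval,
    ValidationError,
    format_interval,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AtacFilterConfig",
    "drop_excluded_chromosomes",
    "merge_overlapping_peaks",
    "binarize",
    "filter_peaks_by_frequency",
    "preprocess_atac_pipeline",
]

DEFAULT_EXCLUDED_CHROMOSOMES = ("chrX", "chrY", "X", "Y")


@dataclass
class AtacFilterConfig:
    min_cells_per_peak: int = 5
    max_cell_fraction_per_peak: float = 0.10
    excluded_chromosomes: tuple[str, ...] = field(
        default=DEFAULT_EXCLUDED_CHROMOSOMES
    )

    def __post_init__(self) -> None:
        if self.min_cells_per_peak < 0:
            raise ValidationError("min_cells_per_peak must be >= 0")
        if not 0.0 < self.max_cell_fraction_per_peak <= 1.0:
            raise ValidationError("max_cell_fraction_per_peak must be in (0, 1]")
        self.excluded_chromosomes = tuple(self.excluded_chromosomes)


def drop_excluded_chromosomes(
    atac: CellByFeatureMatrix, cfg: AtacFilterConfig
) -> CellByFeatureMatrix:
    """Remove peaks on excluded chromosomes, preserving the order of survivors."""
    ivs = atac.features.require_intervals()
    excluded = set(cfg.excluded_chromosomes)
    keep = [i for i, iv in enumerate(ivs) if iv.chrom not in excluded]
    if not keep:
        logger.warning("all %d peaks fall on excluded chromosomes", len(ivs))
    return atac.subset_features(keep)


def merge_overlapping_peaks(atac: CellByFeatureMatrix) -> CellByFeatureMatrix:
    """Merge overlapping peaks into their interval unions.

    Merged groups are the connected components of the overlap graph per
    chromosome (half-open semantics: abutting intervals do not overlap).  A
    merged peak's per-cell value is the elementwise maximum over members, so
    presence in any member means presence in the merged peak.  Output is
    sorted by (chrom, start).
    """
    ivs = atac.features.require_intervals()
    order = sorted(range(len(ivs)), key=lambda i: (ivs[i].chrom, ivs[i].start, ivs[i].end))
    groups: list[list[int]] = []
    merged: list[GenomicInterval] = []
    for i in order:
        iv = ivs[i]
        if merged and merged[-1].chrom == iv.chrom and iv.start < merged[-1].end:
            groups[-1].append(i)
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(iv.chrom, merged[-1].start, iv.end)
        else:
            groups.append([i])
            merged.append(iv)

    dense_needed = sp.issparse(atac.values)
    cols = []
    for members in groups:
        block = atac.values[:, members]
        if dense_needed:
            col = sp.csr_matrix(block.max(axis=1))
        else:
            col = np.asarray(block).max(axis=1, keepdims=True)
        cols.append(col)
    values = sp.hstack(cols, format="csr") if dense_needed else np.hstack(cols)
    features = FeatureAxis(
        ids=[format_interval(iv) for iv in merged], intervals=list(merged)
    )
    return CellByFeatureMatrix(
        barcodes=list(atac.barcodes), features=features, values=values
    )


def binarize(atac: CellByFeatureMatrix) -> CellByFeatureMatrix:
    """Convert all nonzero accessibility values to 1."""
    if sp.issparse(atac.values):
        v = atac.values.copy()
        if np.any(v.data < 0):
            raise ValidationError("accessibility values must be non-negative")
        v.data = (v.data != 0).astype(np.int8)
        v.eliminate_zeros()
    else:
        if np.any(atac.values < 0):
            raise ValidationError("accessibility values must be non-negative")
        v = (np.asarray(atac.values) != 0).astype(np.int8)
    return CellByFeatureMatrix(
        barcodes=list(atac.barcodes), features=atac.features, values=v
    )


def filter_peaks_by_frequency(
    atac: CellByFeatureMatrix, cfg: AtacFilterConfig
) -> tuple[CellByFeatureMatrix, pd.DataFrame]:
    """Drop too-rare and too-common peaks from a binarized matrix.

    Keeps peak p iff ``min_cells_per_peak <= support(p) <= max_cell_fraction *
    n_cells`` where support is the number of cells with a 1.  Returns the
    surviving matrix and a per-peak audit table (peak, support, kept, reason).
    """
    if not atac.is_binary():
        raise ValidationError("frequency filter requires a binarized matrix")
    n_cells = atac.n_cells
    if sp.issparse(atac.values):
        support = np.asarray(atac.values.sum(axis=0)).ravel()
    else:
        support = atac.values.sum(axis=0)
    support = support.astype(np.int64)
    max_support = cfg.max_cell_fraction_per_peak * n_cells
    if cfg.min_cells_per_peak > max_support:
        logger.warning(
            "frequency thresholds jointly unsatisfiable at %d cells: "
            "need support >= %d and <= %.2f; all peaks will be removed",
            n_cells,
            cfg.min_cells_per_peak,
            max_support,
        )
    too_rare = support < cfg.min_cells_per_peak
    too_common = support > max_support
    kept = ~(too_rare | too_common)
    reason = np.where(too_rare, "too_rare", np.where(too_common, "too_common", ""))
    audit = pd.DataFrame(
        {
            "peak": list(atac.features.ids),
            "support": support,
            "kept": kept,
            "reason": reason,
        }
    )
    filtered = atac.subset_features(np.flatnonzero(kept))
    return filtered, audit


def preprocess_atac_pipeline(
    atac: CellByFeatureMatrix, cfg: AtacFilterConfig | None = None
) -> tuple[CellByFeatureMatrix, pd.DataFrame]:
    """Full ATAC preprocessing: drop chroms -> merge -> binarize -> frequency filter."""
    cfg = cfg or AtacFilterConfig()
    logger.info("ATAC preprocessing on %d cells x %d peaks", *atac.shape)
    out = drop_excluded_chromosomes(atac, cfg)
    out = merge_overlapping_peaks(out)
    out = binarize(out)
    out, audit = filter_peaks_by_frequency(out, cfg)
    logger.info("ATAC preprocessing kept %d peaks", out.n_features)
    return out, audit
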