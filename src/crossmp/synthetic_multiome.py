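"""Synthetic paired scRNA-seq / scATAC-seq data with known coupled structure.

Cells belong to discrete cell types.  Each type carries a gene-expression
program (per-gene negative-binomial mean) and a peak-accessibility program
(per-peak Bernoulli probability); on top of the discrete types, every cell
has a continuous program-intensity state (as real tissues have within-type
gradients), which scales its type's expression program and shifts the
accessibility of coupled peaks — the same latent state drives both
modalities.  A configurable fraction of peaks is *coupled*: each coupled
peak is linked to one gene, placed within 100 kb of that gene's TSS on the
same simulated chromosome, and its accessibility tracks the linked gene's
expression program across types and cell states — so chromatin carries real
information about expression (and the regulatory-potential score is
informative).  Uncoupled peaks are type- and state-independent noise.

The generated accessibility is already binary (Bernoulli draws), matching the
post-binarisation representation the model consumes.  Peak frequencies are
kept sparse (a few percent of cells), as in real scATAC-seq, so the default
frequency filters leave the signal intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp

from .io_formats import (
    CellByFeatureMatrix,
    FeatureAxis,
    GeneModel,
    GeneModelTable,
    GenomicInterval,
    ValidationError,
    format_interval,
)

__all__ = ["SimConfig", "SimTruth", "simulate_paired", "worked_fixture"]

CHROM_LENGTH = 10_000_000  # every simulated chromosome is 10 Mb


@dataclass
class SimConfig:
    """Conditions for :func:`simulate_paired`.

    Defaults are the standard study conditions used throughout the test
    suite: 1500 cells, 300 genes, 800 peaks on 4 chromosomes, 3 cell types,
    60% of peaks coupled to a gene program.
    """

    n_cells: int = 1500
    n_genes: int = 300
    n_peaks: int = 800
    n_chromosomes: int = 4
    n_cell_types: int = 3
    peak_gene_coupling: float = 0.6
    rna_depth_mean: float = 4000.0
    nb_dispersion: float = 2.0
    accessibility_logit_scale: float = 3.0
    program_effect_sd: float = 1.0
    base_abundance_sd: float = 0.7
    cell_state_sd: float = 0.5
    state_coupling: float = 0.8
    seed: int = 7

    def __post_init__(self) -> None:
        for name in ("n_cells", "n_genes", "n_peaks", "n_chromosomes", "n_cell_types"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"SimConfig.{name} must be positive")
        if not 0.0 <= self.peak_gene_coupling <= 1.0:
            raise ValidationError("peak_gene_coupling must be in [0, 1]")
        if self.rna_depth_mean <= 0 or self.nb_dispersion <= 0:
            raise ValidationError("rna_depth_mean and nb_dispersion must be positive")
        if self.n_peaks < self.n_chromosomes:
            raise ValidationError(
                f"n_peaks ({self.n_peaks}) must be >= n_chromosomes "
                f"({self.n_chromosomes})"
            )


@dataclass
class SimTruth:
    """Ground truth underlying a simulated pair of matrices."""

    cell_types: np.ndarray  # (n_cells,) int labels
    cell_state: np.ndarray  # (n_cells,) continuous program intensity (nominal 1)
    rna_mean: np.ndarray  # (n_types, n_genes) per-type NB mean at nominal depth/state
    atac_prob: np.ndarray  # (n_types, n_peaks) Bernoulli probability at nominal state
    cell_rna_mean: np.ndarray  # (n_cells, n_genes) exact per-cell NB mean
    cell_atac_prob: np.ndarray  # (n_cells, n_peaks) exact per-cell Bernoulli prob
    coupled: np.ndarray  # (n_peaks,) bool
    linked_gene: np.ndarray  # (n_peaks,) int index of linked gene, -1 if uncoupled
    library_size: np.ndarray = field(default=None)  # (n_cells,) expected RNA depth


def _place_positions(
    rng: np.random.Generator, n: int, lo: int, hi: int, min_gap: int, existing=None
) -> list[int]:
    """Sample ``n`` positions in [lo, hi) keeping pairwise gaps >= min_gap."""
    taken = sorted(existing) if existing else []
    out = []
    for _ in range(n):
        for _try in range(200):
            pos = int(rng.integers(lo, hi))
            i = np.searchsorted(taken, pos)
            ok = True
            if i > 0 and pos - taken[i - 1] < min_gap:
                ok = False
            if i < len(taken) and taken[i] - pos < min_gap:
                ok = False
            if ok:
                taken.insert(i, pos)
                out.append(pos)
                break
        else:
            raise RuntimeError("could not place positions without collisions")
    return out


def simulate_paired(
    cfg: SimConfig,
) -> tuple[CellByFeatureMatrix, CellByFeatureMatrix, GeneModelTable, SimTruth]:
    """Generate a barcode-aligned (RNA counts, binary ATAC) pair plus gene models."""
    rng = np.random.default_rng(cfg.seed)
    n_types = cfg.n_cell_types

    # --- genome layout -----------------------------------------------------
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    gene_chrom_idx = rng.integers(0, cfg.n_chromosomes, size=cfg.n_genes)
    genes: list[GeneModel] = []
    tss_positions = np.zeros(cfg.n_genes, dtype=int)
    placed_per_chrom: dict[int, list[int]] = {c: [] for c in range(cfg.n_chromosomes)}
    for g in range(cfg.n_genes):
        c = int(gene_chrom_idx[g])
        tss = _place_positions(
            rng, 1, 200_000, CHROM_LENGTH - 200_000, 5_000, placed_per_chrom[c]
        )[0]
        placed_per_chrom[c].append(tss)
        tss_positions[g] = tss
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(2, 6))
        exons = []
        cursor = tss
        direction = 1 if strand == "+" else -1
        for _ in range(n_exons):
            length = int(rng.integers(100, 401))
            gap = int(rng.integers(200, 2001))
            if direction == 1:
                exons.append(GenomicInterval(chroms[c], cursor, cursor + length))
                cursor += length + gap
            else:
                exons.append(GenomicInterval(chroms[c], cursor - length, cursor))
                cursor -= length + gap
        exons = sorted(exons, key=lambda e: e.start)
        genes.append(
            GeneModel(
                gene_id=f"gene{g + 1:04d}",
                chrom=chroms[c],
                strand=strand,
                tss=tss,
                exons=tuple(exons),
            )
        )
    gene_models = GeneModelTable(genes)

    # --- expression programs ----------------------------------------------
    base = rng.lognormal(mean=0.0, sigma=cfg.base_abundance_sd, size=cfg.n_genes)
    effect = rng.normal(0.0, cfg.program_effect_sd, size=(n_types, cfg.n_genes))
    rel = base[None, :] * np.exp(effect)  # (types, genes), unnormalised
    frac = rel / rel.sum(axis=1, keepdims=True)  # expression fraction per type
    rna_mean = frac * cfg.rna_depth_mean  # per-type mean at nominal depth/state

    # standardised program across types, used to couple peaks to genes
    z = (effect - effect.mean(axis=0, keepdims=True)) / (
        effect.std(axis=0, keepdims=True) + 1e-12
    )

    # --- peaks --------------------------------------------------------------
    n_coupled = int(round(cfg.peak_gene_coupling * cfg.n_peaks))
    coupled = np.zeros(cfg.n_peaks, dtype=bool)
    coupled[:n_coupled] = True
    linked_gene = np.full(cfg.n_peaks, -1, dtype=int)
    peak_width = 500
    peak_chrom = np.zeros(cfg.n_peaks, dtype=int)
    peak_start = np.zeros(cfg.n_peaks, dtype=int)
    peak_positions: dict[int, list[int]] = {c: [] for c in range(cfg.n_chromosomes)}

    for j in range(n_coupled):
        g = int(rng.integers(0, cfg.n_genes))
        linked_gene[j] = g
        c = int(gene_chrom_idx[g])
        tss = int(tss_positions[g])
        for _try in range(200):
            offset = int(rng.integers(1_000, 50_001)) * (1 if rng.random() < 0.5 else -1)
            start = tss + offset - peak_width // 2
            if 0 <= start and start + peak_width < CHROM_LENGTH:
                near = peak_positions[c]
                if all(abs(start - s) >= peak_width + 100 for s in near):
                    break
        peak_positions[c].append(start)
        peak_chrom[j] = c
        peak_start[j] = start
    for j in range(n_coupled, cfg.n_peaks):
        c = int(rng.integers(0, cfg.n_chromosomes))
        start = _place_positions(
            rng, 1, 0, CHROM_LENGTH - peak_width, peak_width + 100, peak_positions[c]
        )[0]
        peak_positions[c].append(start)
        peak_chrom[j] = c
        peak_start[j] = start

    # accessibility programs: coupled peaks track the linked gene's program;
    # the most-active type sits at a realistic scATAC frequency and other
    # types drop by accessibility_logit_scale per unit of program difference.
    logit_top = np.zeros(cfg.n_peaks)
    z_max = np.zeros(cfg.n_peaks)
    atac_prob = np.zeros((n_types, cfg.n_peaks))
    for j in range(cfg.n_peaks):
        if coupled[j]:
            zg = z[:, linked_gene[j]]
            top = float(rng.uniform(0.08, 0.18))
            logit_top[j] = np.log(top / (1.0 - top))
            z_max[j] = zg.max()
            logits = logit_top[j] + cfg.accessibility_logit_scale * (zg - z_max[j])
            atac_prob[:, j] = 1.0 / (1.0 + np.exp(-logits))
        else:
            atac_prob[:, j] = float(rng.uniform(0.01, 0.08))

    # --- draw cells ----------------------------------------------------------
    labels = rng.integers(0, n_types, size=cfg.n_cells)
    state = 1.0 + cfg.cell_state_sd * rng.standard_normal(cfg.n_cells)
    library = cfg.rna_depth_mean * rng.lognormal(-0.045, 0.3, size=cfg.n_cells)
    # each cell expresses its type's program scaled by its intensity state
    rel_c = base[None, :] * np.exp(effect[labels, :] * state[:, None])
    frac_c = rel_c / rel_c.sum(axis=1, keepdims=True)
    mean_cg = library[:, None] * frac_c
    theta = cfg.nb_dispersion
    # NB as Gamma-Poisson mixture
    lam = rng.gamma(shape=theta, scale=mean_cg / theta)
    rna_counts = rng.poisson(lam)

    # per-cell accessibility: the cell state shifts coupled-peak logits the
    # same way it scales the expression program
    cpk = np.flatnonzero(coupled)
    prob_c = np.tile(atac_prob[labels, :], 1)
    if cpk.size:
        zg_c = z[np.ix_(labels, linked_gene[cpk])]  # (cells, coupled peaks)
        shift = cfg.state_coupling * (state - 1.0)[:, None]
        logits = (
            logit_top[cpk][None, :]
            + cfg.accessibility_logit_scale * (zg_c + shift - z_max[cpk][None, :])
        )
        prob_c[:, cpk] = 1.0 / (1.0 + np.exp(-logits))
    atac_binary = (rng.random((cfg.n_cells, cfg.n_peaks)) < prob_c).astype(np.int8)

    barcodes = [f"cell{c + 1:05d}" for c in range(cfg.n_cells)]
    rna = CellByFeatureMatrix(
        barcodes=barcodes,
        features=FeatureAxis(ids=[g.gene_id for g in genes]),
        values=sp.csr_matrix(rna_counts),
    )
    peak_ivs = [
        GenomicInterval(chroms[peak_chrom[j]], int(peak_start[j]), int(peak_start[j]) + peak_width)
        for j in range(cfg.n_peaks)
    ]
    atac = CellByFeatureMatrix(
        barcodes=list(barcodes),
        features=FeatureAxis(
            ids=[format_interval(iv) for iv in peak_ivs], intervals=peak_ivs
        ),
        values=sp.csr_matrix(atac_binary),
    )
    truth = SimTruth(
        cell_types=labels,
        cell_state=state,
        rna_mean=rna_mean,
        atac_prob=atac_prob,
        cell_rna_mean=mean_cg,
        cell_atac_prob=prob_c,
        coupled=coupled,
        linked_gene=linked_gene,
        library_size=library,
    )
    return rna, atac, gene_models, truth


# ---------------------------------------------------------------------------
# worked fixture: every value literal, small enough to check by hand


_FIXTURE_BARCODES = ["c1", "c2", "c3", "c4", "c5", "c6", "c7", "c8"]

_FIXTURE_GENES = ["g1", "g2", "g3", "g4", "g5", "g6"]

# 8 cells x 6 genes raw counts
_FIXTURE_RNA = np.array(
    [
        [5, 0, 2, 1, 0, 3],
        [4, 1, 0, 0, 1, 2],
        [6, 0, 1, 2, 0, 4],
        [0, 7, 0, 1, 2, 0],
        [1, 8, 1, 0, 3, 0],
        [0, 6, 0, 0, 2, 1],
        [2, 1, 9, 4, 0, 0],
        [1, 0, 8, 5, 1, 0],
    ],
    dtype=np.int64,
)

# 10 peaks: 6 on chr1, 4 on chr2 (0-based half-open)
_FIXTURE_PEAKS = [
    ("chr1", 800, 1300),
    ("chr1", 1050, 1600),
    ("chr1", 5000, 5500),
    ("chr1", 9500, 10000),
    ("chr1", 40000, 40500),
    ("chr1", 120000, 120500),
    ("chr2", 700, 1200),
    ("chr2", 3000, 3500),
    ("chr2", 15000, 15500),
    ("chr2", 98000, 98500),
]

# 8 cells x 10 peaks, already binary
_FIXTURE_ATAC = np.array(
    [
        [1, 0, 1, 0, 0, 0, 1, 0, 0, 0],
        [1, 1, 0, 0, 1, 0, 0, 0, 1, 0],
        [0, 1, 1, 1, 0, 0, 1, 0, 0, 0],
        [0, 0, 0, 1, 0, 1, 0, 1, 0, 0],
        [0, 0, 1, 0, 0, 1, 0, 1, 0, 1],
        [1, 0, 0, 0, 1, 1, 0, 0, 0, 0],
        [0, 1, 0, 1, 0, 0, 1, 0, 1, 1],
        [0, 0, 0, 0, 1, 0, 0, 1, 0, 0],
    ],
    dtype=np.int8,
)

# gene models: g1 has exons 1000-1200 and 1500-1800 (total exon length 500)
_FIXTURE_GENE_ROWS = [
    ("g1", "chr1", "+", 1000, ((1000, 1200), (1500, 1800))),
    ("g2", "chr1", "-", 6000, ((5600, 5900), (5950, 6000))),
    ("g3", "chr1", "+", 41000, ((41000, 41400),)),
    ("g4", "chr2", "+", 1000, ((1000, 1250), (1600, 1850))),
    ("g5", "chr2", "-", 16000, ((15400, 15700), (15800, 16000))),
    ("g6", "chr2", "+", 99000, ((99000, 99600),)),
]


def worked_fixture() -> tuple[CellByFeatureMatrix, CellByFeatureMatrix, GeneModelTable]:
    """Tiny deterministic paired multiome: 8 cells, 6 genes, 10 peaks on 2 chromosomes.

    All values are literals in the source so oracle tests can be checked by hand.
    """
    rna = CellByFeatureMatrix(
        barcodes=list(_FIXTURE_BARCODES),
        features=FeatureAxis(ids=list(_FIXTURE_GENES)),
        values=_FIXTURE_RNA.copy(),
    )
    ivs = [GenomicInterval(c, s, e) for c, s, e in _FIXTURE_PEAKS]
    atac = CellByFeatureMatrix(
        barcodes=list(_FIXTURE_BARCODES),
        features=FeatureAxis(ids=[format_interval(iv) for iv in ivs], intervals=ivs),
        values=_FIXTURE_ATAC.copy(),
    )
    genes = [
        GeneModel(
            gene_id=gid,
            chrom=chrom,
            strand=strand,
            tss=tss,
            exons=tuple(GenomicInterval(chrom, s, e) for s, e in exons),
        )
        for gid, chrom, strand, tss, exons in _FIXTURE_GENE_ROWS
    ]
    return rna, atac, GeneModelTable(genes)
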