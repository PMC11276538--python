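"""End-to-end orchestration: preprocessing both modalities, deriving the
auxiliary channels, assembling training tensors, and the full synthetic
train/evaluate experiment used by the command line and the reproduction
script."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .gene_activity import RPConfig, gene_activity_scores
from .io_formats import CellByFeatureMatrix, GeneModelTable, ValidationError
from .model_core import LossWeights, ModelConfig, TranslationModel
from .preprocess_atac import AtacFilterConfig, preprocess_atac_pipeline
from .preprocess_rna import (
    NormalizationStats,
    RnaFilterConfig,
    SignificantGeneRanking,
    build_sg_matrix,
    drop_excluded_gene_chromosomes,
    filter_cells,
    normalize,
    rank_significant_genes,
)
from .synthetic_multiome import SimConfig, simulate_paired
from .train_eval import (
    EvalReport,
    TrainConfig,
    TrainingData,
    evaluate,
    predict,
    shuffled_baseline_metric,
    split_cells,
    train,
)

logger = logging.getLogger(__name__)

__all__ = ["PreparedChannels", "prepare_channels", "run_synthetic_experiment"]


def align_cells(
    rna: CellByFeatureMatrix, atac: CellByFeatureMatrix
) -> tuple[CellByFeatureMatrix, CellByFeatureMatrix]:
    """Restrict both modalities to shared barcodes, in the RNA matrix's order."""
    atac_pos = {b: i for i, b in enumerate(atac.barcodes)}
    rna_idx, atac_idx = [], []
    for i, b in enumerate(rna.barcodes):
        j = atac_pos.get(b)
        if j is not None:
            rna_idx.append(i)
            atac_idx.append(j)
    if not rna_idx:
        raise ValidationError("the two modalities share no barcodes")
    return rna.subset_cells(rna_idx), atac.subset_cells(atac_idx)


def chromosome_blocks_of(atac: CellByFeatureMatrix) -> list[tuple[str, int]]:
    """Ordered (chrom, n_peaks) runs of a chromosome-sorted peak matrix."""
    ivs = atac.features.require_intervals()
    blocks: list[tuple[str, int]] = []
    for iv in ivs:
        if blocks and blocks[-1][0] == iv.chrom:
            blocks[-1] = (iv.chrom, blocks[-1][1] + 1)
        else:
            blocks.append((iv.chrom, 1))
    if len({c for c, _ in blocks}) != len(blocks):
        raise ValidationError("peaks are not grouped by chromosome; sort them first")
    return blocks


@dataclass
class PreparedChannels:
    """Everything the network consumes, barcode-aligned, plus fitted transforms."""

    data: TrainingData
    model_config: ModelConfig
    barcodes: list[str]
    stats: NormalizationStats
    ranking: SignificantGeneRanking
    peak_ids: list[str]
    gene_ids: list[str]
    sg_gene_ids: list[str]
    gas_gene_order: list[str]


def prepare_channels(
    rna: CellByFeatureMatrix,
    atac: CellByFeatureMatrix,
    gene_models: GeneModelTable,
    atac_cfg: Optional[AtacFilterConfig] = None,
    rna_cfg: Optional[RnaFilterConfig] = None,
    rp_cfg: Optional[RPConfig] = None,
    sg_top_k: Optional[int] = None,
    external_sg: Optional[Sequence[tuple[str, float]]] = None,
    model_overrides: Optional[dict] = None,
) -> PreparedChannels:
    """Run both preprocessing pipelines and assemble the four input channels."""
    atac_cfg = atac_cfg or AtacFilterConfig()
    rna_cfg = rna_cfg or RnaFilterConfig()
    rp_cfg = rp_cfg or RPConfig()

    atac_pp, _audit = preprocess_atac_pipeline(atac, atac_cfg)
    if atac_pp.n_features == 0:
        raise ValidationError("no peaks survive ATAC preprocessing")

    rna_pp = drop_excluded_gene_chromosomes(rna, gene_models, rna_cfg)
    rna_pp = filter_cells(rna_pp, rna_cfg)
    if rna_pp.n_cells < 3:
        raise ValidationError("fewer than 3 cells survive the RNA cell filter")
    rna_pp, atac_pp = align_cells(rna_pp, atac_pp)

    rna_norm, stats = normalize(rna_pp, rna_cfg)
    ranking = rank_significant_genes(rna_norm, external=external_sg)
    x_sg = build_sg_matrix(rna_norm, ranking, top_k=sg_top_k)

    gas = gene_activity_scores(atac_pp, gene_models, rp_cfg)
    # group GAS columns by chromosome so the partitioned encoder can split them
    chrom = gene_models.chrom_of()
    tss = {g.gene_id: g.tss for g in gene_models}
    gas_order = sorted(
        range(gas.n_features),
        key=lambda i: (chrom[gas.features.ids[i]], tss[gas.features.ids[i]]),
    )
    gas = gas.subset_features(gas_order)
    gas_blocks: list[tuple[str, int]] = []
    for gid in gas.features.ids:
        c = chrom[gid]
        if gas_blocks and gas_blocks[-1][0] == c:
            gas_blocks[-1] = (c, gas_blocks[-1][1] + 1)
        else:
            gas_blocks.append((c, 1))

    overrides = model_overrides or {}
    model_config = ModelConfig(
        chromosome_blocks=chromosome_blocks_of(atac_pp),
        n_genes=rna_norm.n_features,
        n_sg_genes=x_sg.n_features,
        gas_blocks=gas_blocks,
        **overrides,
    )
    data = TrainingData(
        x_rna_counts=rna_pp.dense().astype(np.float64),
        x_rna_norm=rna_norm.dense(),
        x_sg=x_sg.dense(),
        x_atac=atac_pp.dense().astype(np.float64),
        x_gas=gas.dense(),
    )
    return PreparedChannels(
        data=data,
        model_config=model_config,
        barcodes=list(rna_pp.barcodes),
        stats=stats,
        ranking=ranking,
        peak_ids=list(atac_pp.features.ids),
        gene_ids=list(rna_norm.features.ids),
        sg_gene_ids=list(x_sg.features.ids),
        gas_gene_order=list(gas.features.ids),
    )


def run_synthetic_experiment(
    sim_cfg: Optional[SimConfig] = None,
    train_cfg: Optional[TrainConfig] = None,
    weights: Optional[LossWeights] = None,
    atac_cfg: Optional[AtacFilterConfig] = None,
    rna_cfg: Optional[RnaFilterConfig] = None,
    rp_cfg: Optional[RPConfig] = None,
    baseline_seed: int = 123,
) -> dict:
    """Simulate, preprocess, train, and score held-out translation.

    Returns a dictionary with the trained model, history, per-direction
    held-out reports, and shuffled-pairing baselines.
    """
    sim_cfg = sim_cfg or SimConfig()
    train_cfg = train_cfg or TrainConfig(seed=sim_cfg.seed)
    weights = weights or LossWeights()

    rna, atac, gene_models, truth = simulate_paired(sim_cfg)
    prepared = prepare_channels(
        rna, atac, gene_models, atac_cfg=atac_cfg, rna_cfg=rna_cfg, rp_cfg=rp_cfg
    )
    data = prepared.data
    model = TranslationModel(
        prepared.model_config, rng=np.random.default_rng(train_cfg.seed)
    )
    split = split_cells(data.n_cells, train_cfg)
    model, history = train(model, data, train_cfg, weights, split=split)
    test_idx = split[2]

    counts, norm, sg, atac_x, gas = data.rows(test_idx)
    rna_pred = predict(model, atac_x, gas, "atac_to_rna")
    atac_pred = predict(model, norm, sg, "rna_to_atac")
    rna_recon = predict(model, norm, sg, "rna_to_rna")

    # RNA predictions are NB means; compare on log1p scale against normalised truth
    report = evaluate(
        rna_pred=np.log1p(rna_pred),
        rna_truth=norm,
        atac_pred=atac_pred,
        atac_truth=atac_x,
    )
    recon_report = evaluate(rna_pred=np.log1p(rna_recon), rna_truth=norm)

    rng = np.random.default_rng(baseline_seed)
    base_p, base_s = shuffled_baseline_metric(np.log1p(rna_pred), norm, "rna", rng)
    base_auroc = shuffled_baseline_metric(atac_pred, atac_x, "atac", rng)

    return {
        "model": model,
        "history": history,
        "prepared": prepared,
        "split": split,
        "truth": truth,
        "report": report,
        "reconstruction_report": recon_report,
        "baseline_pearson": base_p,
        "baseline_spearman": base_s,
        "baseline_auroc": base_auroc,
    }
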