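"""Data splitting, mini-batch training with early stopping, and evaluation metrics.

Cells are split 70/15/15 into train/validation/test.  Training uses Adam
(lr 0.01) on shuffled mini-batches of 512 with the composite loss; after each
epoch the total validation loss is computed with the network in inference
mode, and training stops once validation has failed to improve for
``early_stopping_patience`` epochs beyond the best epoch, whose weights are
restored.

RNA predictions are scored with Pearson/Spearman correlations (overall on the
flattened matrices, and gene-wise across cells); ATAC predictions with AUROC
(overall and peak-wise).  Features whose truth is constant across cells are
excluded from feature-wise metrics rather than propagating NaNs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
from scipy.stats import pearsonr, spearmanr
from sklearn.metrics import roc_auc_score

from .autodiff import Adam, Tensor, clip_grad_norm
from .io_formats import ValidationError
from .model_core import LossWeights, ModelConfig, TranslationModel, total_loss

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "TrainingData",
    "EvalReport",
    "EarlyStopper",
    "split_cells",
    "train",
    "predict",
    "overall_metrics",
    "featurewise_metrics",
    "evaluate",
    "shuffled_baseline_metric",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class TrainConfig:
    learning_rate: float = 0.01
    batch_size: int = 512
    early_stopping_patience: int = 25
    max_epochs: int = 500
    train_frac: float = 0.70
    val_frac: float = 0.15
    test_frac: float = 0.15
    grad_clip_norm: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.train_frac + self.val_frac + self.test_frac - 1.0) > 1e-9:
            raise ValidationError("split fractions must sum to 1")
        if self.early_stopping_patience < 1:
            raise ValidationError("early_stopping_patience must be >= 1")
        if self.batch_size < 1:
            raise ValidationError("batch_size must be >= 1")


@dataclass
class TrainingData:
    """Barcode-aligned channels the model trains on (all dense float64 arrays)."""

    x_rna_counts: np.ndarray  # raw counts, NB target
    x_rna_norm: np.ndarray  # normalised expression, E_RNA input
    x_sg: np.ndarray  # significant-gene subset of the normalised matrix
    x_atac: np.ndarray  # binary accessibility, E_ATAC input and BCE target
    x_gas: np.ndarray  # gene activity scores, E_GAS input

    def __post_init__(self) -> None:
        n = self.x_rna_counts.shape[0]
        for name in ("x_rna_norm", "x_sg", "x_atac", "x_gas"):
            if getattr(self, name).shape[0] != n:
                raise ValidationError(f"{name} has a different number of cells")

    @property
    def n_cells(self) -> int:
        return self.x_rna_counts.shape[0]

    def rows(self, idx: np.ndarray) -> tuple[np.ndarray, ...]:
        return (
            self.x_rna_counts[idx],
            self.x_rna_norm[idx],
            self.x_sg[idx],
            self.x_atac[idx],
            self.x_gas[idx],
        )


def split_cells(
    n_cells: int, cfg: TrainConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random disjoint exhaustive train/val/test index split (floor/floor/remainder)."""
    if n_cells < 3:
        raise ValidationError("need at least 3 cells to split")
    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(n_cells)
    n_train = int(np.floor(cfg.train_frac * n_cells))
    n_val = int(np.floor(cfg.val_frac * n_cells))
    return perm[:n_train], perm[n_train : n_train + n_val], perm[n_train + n_val :]


class EarlyStopper:
    """Stops once the monitored loss has failed to improve for more than ``patience`` epochs."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best: float = np.inf
        self.best_epoch: int = 0
        self.epochs_since_best: int = 0

    def update(self, loss: float, epoch: int) -> bool:
        """Record an epoch's loss; returns True if it is a new best."""
        if loss < self.best:
            self.best = loss
            self.best_epoch = epoch
            self.epochs_since_best = 0
            return True
        self.epochs_since_best += 1
        return False

    @property
    def should_stop(self) -> bool:
        return self.epochs_since_best > self.patience


def _batched_loss(
    model: TranslationModel,
    data: TrainingData,
    idx: np.ndarray,
    weights: LossWeights,
    batch_size: int,
) -> dict[str, float]:
    """Entry-weighted mean loss breakdown over ``idx`` in inference mode."""
    model.set_training(False)
    sums: dict[str, float] = {}
    n_total = 0
    for lo in range(0, len(idx), batch_size):
        batch = idx[lo : lo + batch_size]
        counts, norm, sg, atac, gas = data.rows(batch)
        bundle, z_a, z_r = model.forward(norm, sg, atac, gas)
        _, breakdown = total_loss(
            bundle, counts, atac, z_a, z_r, weights, model.cfg.kl_symmetric
        )
        for k, v in breakdown.items():
            sums[k] = sums.get(k, 0.0) + v * len(batch)
        n_total += len(batch)
    return {k: v / n_total for k, v in sums.items()}


def train(
    model: TranslationModel,
    data: TrainingData,
    cfg: TrainConfig | None = None,
    weights: LossWeights | None = None,
    split: Optional[tuple[np.ndarray, np.ndarray, np.ndarray]] = None,
) -> tuple[TranslationModel, list[dict[str, float]]]:
    """Train in place; returns the model (best-validation weights) and per-epoch history."""
    cfg = cfg or TrainConfig()
    weights = weights or LossWeights()
    if split is None:
        split = split_cells(data.n_cells, cfg)
    train_idx, val_idx, _ = split
    rng = np.random.default_rng(cfg.seed)
    optimizer = Adam(model.parameters(), lr=cfg.learning_rate)
    stopper = EarlyStopper(cfg.early_stopping_patience)
    best_state: dict[str, np.ndarray] = {
        k: v.copy() for k, v in model.state_arrays().items()
    }
    history: list[dict[str, float]] = []

    for epoch in range(1, cfg.max_epochs + 1):
        model.set_training(True)
        perm = rng.permutation(train_idx)
        train_total = 0.0
        for lo in range(0, len(perm), cfg.batch_size):
            batch = perm[lo : lo + cfg.batch_size]
            counts, norm, sg, atac, gas = data.rows(batch)
            bundle, z_a, z_r = model.forward(norm, sg, atac, gas)
            loss, breakdown = total_loss(
                bundle, counts, atac, z_a, z_r, weights, model.cfg.kl_symmetric
            )
            optimizer.zero_grad()
            loss.backward()
            clip_grad_norm(optimizer.params, cfg.grad_clip_norm)
            optimizer.step()
            train_total += breakdown["total"] * len(batch)
        train_total /= len(train_idx)

        val = _batched_loss(model, data, val_idx, weights, cfg.batch_size)
        record = {"epoch": float(epoch), "train_total": train_total}
        record.update({f"val_{k}": v for k, v in val.items()})
        history.append(record)
        if stopper.update(val["total"], epoch):
            best_state = {k: v.copy() for k, v in model.state_arrays().items()}
        if stopper.should_stop:
            logger.info(
                "early stop at epoch %d (best epoch %d, val %.5f)",
                epoch,
                stopper.best_epoch,
                stopper.best,
            )
            break
    else:
        logger.info("hit max_epochs=%d (best epoch %d)", cfg.max_epochs, stopper.best_epoch)

    model.load_state_arrays(best_state)
    model.set_training(False)
    return model, history


DIRECTIONS = ("atac_to_rna", "rna_to_atac", "atac_to_atac", "rna_to_rna")


def predict(
    model: TranslationModel,
    primary: np.ndarray,
    auxiliary: np.ndarray,
    direction: str,
    batch_size: int = 1024,
) -> np.ndarray:
    """Deterministic inference along one translation path.

    ``primary``/``auxiliary`` are (binary ATAC, gene activity scores) for the
    ``atac_*`` directions and (normalised RNA, significant-gene subset) for the
    ``rna_*`` directions.  RNA outputs are the NB mean; ATAC outputs are
    probabilities.
    """
    if direction not in DIRECTIONS:
        raise ValidationError(f"direction must be one of {DIRECTIONS}")
    model.set_training(False)
    outs = []
    for lo in range(0, primary.shape[0], batch_size):
        p = primary[lo : lo + batch_size]
        a = auxiliary[lo : lo + batch_size]
        if direction.startswith("atac"):
            z = model.merge_latents(
                model.encode_atac(p, "ATAC"), model.encode_atac(a, "GAS")
            )
        else:
            z = model.merge_latents(
                model.encode_rna(p, "RNA"), model.encode_rna(a, "SG")
            )
        if direction.endswith("rna"):
            mean, _ = model.decode_rna(z)
            outs.append(mean.data)
        else:
            outs.append(model.decode_atac(z).data)
    return np.vstack(outs)


# ---------------------------------------------------------------------------
# metrics


@dataclass
class EvalReport:
    overall_pearson: Optional[float] = None
    overall_spearman: Optional[float] = None
    overall_auroc: Optional[float] = None
    gene_wise_correlations: Optional[np.ndarray] = None
    peak_wise_aurocs: Optional[np.ndarray] = None
    n_genes_evaluated: int = 0
    n_peaks_evaluated: int = 0
    n_genes_excluded: int = 0
    n_peaks_excluded: int = 0

    def to_dict(self) -> dict:
        def _mean(a):
            return None if a is None or len(a) == 0 else float(np.mean(a))

        return {
            "overall_pearson": self.overall_pearson,
            "overall_spearman": self.overall_spearman,
            "overall_auroc": self.overall_auroc,
            "mean_gene_wise_correlation": _mean(self.gene_wise_correlations),
            "mean_peak_wise_auroc": _mean(self.peak_wise_aurocs),
            "n_genes_evaluated": self.n_genes_evaluated,
            "n_peaks_evaluated": self.n_peaks_evaluated,
            "n_genes_excluded": self.n_genes_excluded,
            "n_peaks_excluded": self.n_peaks_excluded,
        }


def overall_metrics(pred: np.ndarray, truth: np.ndarray, modality: str):
    """RNA: (Pearson, Spearman) over flattened matrices. ATAC: AUROC."""
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValidationError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if modality == "rna":
        p = pearsonr(pred.ravel(), truth.ravel()).statistic
        s = spearmanr(pred.ravel(), truth.ravel()).statistic
        return float(p), float(s)
    if modality == "atac":
        y = truth.ravel()
        if y.min() == y.max():
            return None
        return float(roc_auc_score(y, pred.ravel()))
    raise ValidationError(f"modality must be 'rna' or 'atac', got {modality!r}")


def featurewise_metrics(
    pred: np.ndarray, truth: np.ndarray, modality: str
) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-feature metric across cells: Pearson (rna) or AUROC (atac).

    Returns (values, feature_indices, n_excluded).  Features with constant
    truth across cells are excluded; RNA features with constant predictions
    (correlation undefined) are excluded as well.
    """
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValidationError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    values, indices = [], []
    n_excluded = 0
    for j in range(truth.shape[1]):
        t, p = truth[:, j], pred[:, j]
        if t.min() == t.max():
            n_excluded += 1
            continue
        if modality == "rna":
            if p.min() == p.max():
                n_excluded += 1
                continue
            values.append(float(pearsonr(p, t).statistic))
        elif modality == "atac":
            values.append(float(roc_auc_score(t, p)))
        else:
            raise ValidationError(f"modality must be 'rna' or 'atac', got {modality!r}")
        indices.append(j)
    return np.asarray(values), np.asarray(indices, dtype=int), n_excluded


def evaluate(
    rna_pred: Optional[np.ndarray] = None,
    rna_truth: Optional[np.ndarray] = None,
    atac_pred: Optional[np.ndarray] = None,
    atac_truth: Optional[np.ndarray] = None,
) -> EvalReport:
    """Build a full report from whichever modality predictions are supplied."""
    report = EvalReport()
    if rna_pred is not None:
        report.overall_pearson, report.overall_spearman = overall_metrics(
            rna_pred, rna_truth, "rna"
        )
        vals, _, excl = featurewise_metrics(rna_pred, rna_truth, "rna")
        report.gene_wise_correlations = vals
        report.n_genes_evaluated = len(vals)
        report.n_genes_excluded = excl
    if atac_pred is not None:
        report.overall_auroc = overall_metrics(atac_pred, atac_truth, "atac")
        vals, _, excl = featurewise_metrics(atac_pred, atac_truth, "atac")
        report.peak_wise_aurocs = vals
        report.n_peaks_evaluated = len(vals)
        report.n_peaks_excluded = excl
    return report


def shuffled_baseline_metric(
    pred: np.ndarray, truth: np.ndarray, modality: str, rng: np.random.Generator
):
    """Same overall metric after destroying the cell pairing by permuting truth rows."""
    perm = rng.permutation(truth.shape[0])
    return overall_metrics(pred, truth[perm], modality)


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(
    path: Union[str, Path],
    model: TranslationModel,
    extras: Optional[dict] = None,
) -> None:
    """Single-file .npz checkpoint: versioned config JSON + weights (+ extras)."""
    meta = {
        "format_version": 1,
        "model_config": model.cfg.to_dict(),
        "extras": extras or {},
    }
    arrays = {f"state/{k}": v for k, v in model.state_arrays().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path: Union[str, Path]) -> tuple[TranslationModel, dict]:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"].tobytes()).decode())
        if meta.get("format_version") != 1:
            raise ValidationError(
                f"unsupported checkpoint version {meta.get('format_version')}"
            )
        cfg = ModelConfig.from_dict(meta["model_config"])
        model = TranslationModel(cfg)
        state = {
            k[len("state/") :]: npz[k] for k in npz.files if k.startswith("state/")
        }
    model.load_state_arrays(state)
    model.set_training(False)
    return model, meta.get("extras", {})
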