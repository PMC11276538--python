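"""The translation network: four encoders, two decoders, and the composite loss.

Two dense encoders embed normalised expression (all genes, and the
significant-gene subset) into a shared low-dimensional latent space; two
chromosome-partitioned encoders do the same for binary accessibility and for
the gene activity scores, processing each chromosome with its own small
fully connected sub-network before concatenating and projecting the per-
chromosome latents.  Same-side latents are merged by element-wise addition.
The RNA decoder emits negative-binomial mean (exponential head) and
dispersion (softplus head); the ATAC decoder expands the latent, splits it
back into per-chromosome blocks and restores each chromosome's peaks through
a sigmoid.

Training minimises NB negative log-likelihood on both RNA outputs, binary
cross-entropy on both ATAC outputs (weight ``w_bce``), and a KL divergence
between the two merged latents mapped through a row-wise softmax
(weight ``w_kl``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.special import gammaln

from .autodiff import (
    Adam,
    BatchNorm1d,
    Linear,
    Module,
    Parameter,
    PReLU,
    Tensor,
    concat,
)

__all__ = [
    "ModelConfig",
    "LossWeights",
    "LatentEmbedding",
    "PredictionBundle",
    "TranslationModel",
    "nb_nll",
    "bce_loss",
    "kl_latent",
    "total_loss",
]

_EPS = 1e-8
_EXP_CAP = 30.0  # exp head pre-activation cap; e^30 ~ 1e13 counts


@dataclass
class ModelConfig:
    chromosome_blocks: list[tuple[str, int]]  # ordered (chrom, n_peaks)
    n_genes: int
    n_sg_genes: int
    gas_blocks: Optional[list[tuple[str, int]]] = None  # (chrom, n_genes) for E_GAS
    latent_dim: int = 16
    rna_hidden: int = 64
    rna_decoder_hidden: int = 64
    per_chrom_hidden: int = 64  # capped at the block width
    merge_mode: str = "add"  # or "concat_project"
    gas_encoder_mode: str = "per_chromosome"  # or "dense"
    kl_symmetric: bool = False

    def __post_init__(self) -> None:
        if self.latent_dim <= 0:
            raise ValueError("latent_dim must be positive")
        if not self.chromosome_blocks:
            raise ValueError("chromosome_blocks must be non-empty")
        if any(n <= 0 for _, n in self.chromosome_blocks):
            raise ValueError("every chromosome block needs at least one peak")
        if self.merge_mode not in ("add", "concat_project"):
            raise ValueError("merge_mode must be 'add' or 'concat_project'")
        if self.gas_encoder_mode not in ("per_chromosome", "dense"):
            raise ValueError("gas_encoder_mode must be 'per_chromosome' or 'dense'")
        if self.gas_encoder_mode == "per_chromosome" and self.gas_blocks is None:
            # genes may all live on one block if no table is given
            self.gas_blocks = [("all", self.n_genes)]

    @property
    def n_peaks(self) -> int:
        return sum(n for _, n in self.chromosome_blocks)

    @property
    def concat_dim(self) -> int:
        return len(self.chromosome_blocks) * self.latent_dim

    def to_dict(self) -> dict:
        return {
            "chromosome_blocks": [[c, int(n)] for c, n in self.chromosome_blocks],
            "n_genes": self.n_genes,
            "n_sg_genes": self.n_sg_genes,
            "gas_blocks": None
            if self.gas_blocks is None
            else [[c, int(n)] for c, n in self.gas_blocks],
            "latent_dim": self.latent_dim,
            "rna_hidden": self.rna_hidden,
            "rna_decoder_hidden": self.rna_decoder_hidden,
            "per_chrom_hidden": self.per_chrom_hidden,
            "merge_mode": self.merge_mode,
            "gas_encoder_mode": self.gas_encoder_mode,
            "kl_symmetric": self.kl_symmetric,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["chromosome_blocks"] = [tuple(b) for b in d["chromosome_blocks"]]
        if d.get("gas_blocks") is not None:
            d["gas_blocks"] = [tuple(b) for b in d["gas_blocks"]]
        return cls(**d)


@dataclass
class LossWeights:
    w_bce: float = 1.33
    w_kl: float = 1.0

    def __post_init__(self) -> None:
        if self.w_bce < 0 or self.w_kl < 0:
            raise ValueError("loss weights must be non-negative")


@dataclass
class LatentEmbedding:
    """Cells x latent_dim embedding with the input channel that produced it."""

    values: Tensor
    source: str

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


@dataclass
class PredictionBundle:
    """The four translation outputs of one forward pass."""

    atac_from_atac: Tensor  # probabilities
    rna_from_atac: tuple[Tensor, Tensor]  # (mean, dispersion)
    atac_from_rna: Tensor
    rna_from_rna: tuple[Tensor, Tensor]


class DenseEncoder(Module):
    """Two FC layers, each followed by batch-norm and ReLU (expression channels)."""

    def __init__(self, n_in: int, hidden: int, latent: int, rng: np.random.Generator):
        self.fc1 = Linear(n_in, hidden, rng)
        self.bn1 = BatchNorm1d(hidden)
        self.fc2 = Linear(hidden, latent, rng)
        self.bn2 = BatchNorm1d(latent)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.bn1(self.fc1(x)).relu()
        return self.bn2(self.fc2(h)).relu()


class ChromBlockEncoder(Module):
    """Two FC layers with PReLU, mapping one chromosome's features to the latent width."""

    def __init__(self, n_in: int, hidden: int, latent: int, rng: np.random.Generator):
        hidden = max(min(hidden, n_in), latent)
        self.fc1 = Linear(n_in, hidden, rng)
        self.act1 = PReLU()
        self.fc2 = Linear(hidden, latent, rng)
        self.act2 = PReLU()

    def __call__(self, x: Tensor) -> Tensor:
        return self.act2(self.fc2(self.act1(self.fc1(x))))


class ChromPartitionedEncoder(Module):
    """Per-chromosome sub-networks -> concatenation -> FC + PReLU to the latent."""

    def __init__(
        self,
        blocks: Sequence[tuple[str, int]],
        hidden: int,
        latent: int,
        rng: np.random.Generator,
    ):
        self.block_sizes = [int(n) for _, n in blocks]
        self.block_encoders = [
            ChromBlockEncoder(n, hidden, latent, rng) for n in self.block_sizes
        ]
        self.concat_dim = len(self.block_sizes) * latent
        self.project = Linear(self.concat_dim, latent, rng)
        self.act = PReLU()
        self._last_concat_width: Optional[int] = None

    def __call__(self, x: Tensor) -> Tensor:
        n_in = sum(self.block_sizes)
        if x.shape[1] != n_in:
            raise ValueError(
                f"input width {x.shape[1]} != sum of block widths {n_in}"
            )
        outs = []
        lo = 0
        for enc, n in zip(self.block_encoders, self.block_sizes):
            outs.append(enc(x[:, lo : lo + n]))
            lo += n
        z = concat(outs, axis=1)
        self._last_concat_width = z.shape[1]
        return self.act(self.project(z))


class RnaDecoder(Module):
    """Latent -> hidden -> (exp mean head, softplus dispersion head)."""

    def __init__(self, latent: int, hidden: int, n_genes: int, rng: np.random.Generator):
        self.hidden_dim = hidden
        self.fc = Linear(latent, hidden, rng)
        self.mean_head = Linear(hidden, n_genes, rng)
        self.disp_head = Linear(hidden, n_genes, rng)

    def __call__(self, z: Tensor) -> tuple[Tensor, Tensor]:
        h = self.fc(z).relu()
        mean = self.mean_head(h).clip(-_EXP_CAP, _EXP_CAP).exp()
        dispersion = self.disp_head(h).softplus() + _EPS
        if not np.all(np.isfinite(mean.data)):
            bad = int(np.argwhere(~np.isfinite(mean.data))[0][0])
            raise FloatingPointError(f"non-finite NB mean at batch index {bad}")
        return mean, dispersion


class AtacDecoder(Module):
    """Latent -> expanded per-chromosome blocks -> per-block FC -> sigmoid."""

    def __init__(
        self,
        blocks: Sequence[tuple[str, int]],
        latent: int,
        rng: np.random.Generator,
    ):
        self.block_sizes = [int(n) for _, n in blocks]
        self.latent = latent
        self.expanded_dim = len(self.block_sizes) * latent
        self.expand = Linear(latent, self.expanded_dim, rng)
        self.act = PReLU()
        self.block_decoders = [Linear(latent, n, rng) for n in self.block_sizes]

    @property
    def n_blocks(self) -> int:
        return len(self.block_sizes)

    def __call__(self, z: Tensor) -> Tensor:
        h = self.act(self.expand(z))
        outs = []
        for i, dec in enumerate(self.block_decoders):
            lo = i * self.latent
            outs.append(dec(h[:, lo : lo + self.latent]).sigmoid())
        return concat(outs, axis=1)


class TranslationModel(Module):
    """Four encoders, merge, two decoders; one forward yields all four translation paths."""

    def __init__(self, cfg: ModelConfig, rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        L = cfg.latent_dim
        self.enc_rna = DenseEncoder(cfg.n_genes, cfg.rna_hidden, L, rng)
        self.enc_sg = DenseEncoder(cfg.n_sg_genes, cfg.rna_hidden, L, rng)
        self.enc_atac = ChromPartitionedEncoder(
            cfg.chromosome_blocks, cfg.per_chrom_hidden, L, rng
        )
        if cfg.gas_encoder_mode == "per_chromosome":
            self.enc_gas: Module = ChromPartitionedEncoder(
                cfg.gas_blocks, cfg.per_chrom_hidden, L, rng
            )
        else:
            self.enc_gas = DenseEncoder(cfg.n_genes, cfg.rna_hidden, L, rng)
        self.dec_rna = RnaDecoder(L, cfg.rna_decoder_hidden, cfg.n_genes, rng)
        self.dec_atac = AtacDecoder(cfg.chromosome_blocks, L, rng)
        if cfg.merge_mode == "concat_project":
            self.merge_proj_atac = Linear(2 * L, L, rng)
            self.merge_proj_rna = Linear(2 * L, L, rng)

    # -- encoder surface ------------------------------------------------------

    def encode_rna(self, x, which: str = "RNA") -> LatentEmbedding:
        x = Tensor.as_tensor(x)
        if which == "RNA":
            expected, enc = self.cfg.n_genes, self.enc_rna
        elif which == "SG":
            expected, enc = self.cfg.n_sg_genes, self.enc_sg
        else:
            raise ValueError(f"which must be 'RNA' or 'SG', got {which!r}")
        if x.shape[1] != expected:
            raise ValueError(
                f"{which} input width {x.shape[1]} != configured {expected}"
            )
        return LatentEmbedding(values=enc(x), source=which)

    def encode_atac(self, x, which: str = "ATAC") -> LatentEmbedding:
        x = Tensor.as_tensor(x)
        if which == "ATAC":
            return LatentEmbedding(values=self.enc_atac(x), source="ATAC")
        if which == "GAS":
            return LatentEmbedding(values=self.enc_gas(x), source="GAS")
        raise ValueError(f"which must be 'ATAC' or 'GAS', got {which!r}")

    def merge_latents(self, a: LatentEmbedding, b: LatentEmbedding) -> LatentEmbedding:
        if a.shape != b.shape:
            raise ValueError(f"latent shapes differ: {a.shape} vs {b.shape}")
        tag = f"{a.source}+{b.source}"
        if self.cfg.merge_mode == "add":
            return LatentEmbedding(values=a.values + b.values, source=tag)
        proj = self.merge_proj_atac if "ATAC" in tag else self.merge_proj_rna
        return LatentEmbedding(values=proj(concat([a.values, b.values])), source=tag)

    def decode_rna(self, z: LatentEmbedding) -> tuple[Tensor, Tensor]:
        return self.dec_rna(z.values)

    def decode_atac(self, z: LatentEmbedding) -> Tensor:
        return self.dec_atac(z.values)

    # -- full forward -----------------------------------------------------------

    def forward(
        self, x_rna, x_sg, x_atac, x_gas
    ) -> tuple[PredictionBundle, LatentEmbedding, LatentEmbedding]:
        z_atac = self.encode_atac(x_atac, "ATAC")
        z_gas = self.encode_atac(x_gas, "GAS")
        z_rna = self.encode_rna(x_rna, "RNA")
        z_sg = self.encode_rna(x_sg, "SG")
        z_a = self.merge_latents(z_atac, z_gas)
        z_r = self.merge_latents(z_rna, z_sg)
        bundle = PredictionBundle(
            atac_from_atac=self.decode_atac(z_a),
            rna_from_atac=self.decode_rna(z_a),
            atac_from_rna=self.decode_atac(z_r),
            rna_from_rna=self.decode_rna(z_r),
        )
        return bundle, z_a, z_r


# ---------------------------------------------------------------------------
# losses


ArrayLike = Union[np.ndarray, Tensor]


def nb_nll(x: ArrayLike, mean: ArrayLike, dispersion: ArrayLike) -> Tensor:
    """Mean negative binomial negative log-likelihood over all entries.

    Parameterised by mean mu and dispersion theta:
    NLL = lgamma(theta) + lgamma(x+1) - lgamma(x+theta)
          - theta*log(theta/(theta+mu)) - x*log(mu/(theta+mu)).
    """
    x_data = x.data if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)
    if np.any(x_data < 0):
        raise ValueError("counts must be non-negative")
    mu = Tensor.as_tensor(mean)
    theta = Tensor.as_tensor(dispersion)
    if np.any(mu.data <= 0) or np.any(theta.data <= 0):
        raise ValueError("NB mean and dispersion must be strictly positive")
    const = gammaln(x_data + 1.0)  # no gradient flows into the observed counts
    log_ratio = theta.log() - (theta + mu).log()
    nll = (
        theta.lgamma()
        + Tensor(const)
        - (theta + x_data).lgamma()
        - theta * log_ratio
        - Tensor(x_data) * (mu.log() - (theta + mu).log())
    )
    return nll.mean()


def bce_loss(y: ArrayLike, p: ArrayLike) -> Tensor:
    """Mean binary cross-entropy; probabilities clamped to [1e-8, 1-1e-8]."""
    y_data = y.data if isinstance(y, Tensor) else np.asarray(y, dtype=np.float64)
    if not np.all((y_data == 0) | (y_data == 1)):
        raise ValueError("BCE targets must be binary")
    p = Tensor.as_tensor(p).clip(_EPS, 1.0 - _EPS)
    y = Tensor(y_data)
    loss = -(y * p.log() + (1.0 - y) * (1.0 - p).log())
    return loss.mean()


def _log_softmax(z: Tensor) -> Tensor:
    shift = z - z.data.max(axis=1, keepdims=True)  # constant shift, softmax-invariant
    return shift - shift.exp().sum(axis=1, keepdims=True).log()


def kl_latent(
    z_a: Union[LatentEmbedding, ArrayLike],
    z_b: Union[LatentEmbedding, ArrayLike],
    symmetric: bool = False,
) -> Tensor:
    """KL divergence between rows of two latents mapped through softmax, mean over cells.

    The embeddings are deterministic, so each row is read as a point on the
    simplex via softmax; KL(a-side || b-side) is returned (symmetrised mean of
    both directions with ``symmetric=True``).
    """
    ta = z_a.values if isinstance(z_a, LatentEmbedding) else Tensor.as_tensor(z_a)
    tb = z_b.values if isinstance(z_b, LatentEmbedding) else Tensor.as_tensor(z_b)
    if ta.shape != tb.shape:
        raise ValueError(f"latent shapes differ: {ta.shape} vs {tb.shape}")
    ls_a, ls_b = _log_softmax(ta), _log_softmax(tb)
    q = ls_a.exp()
    kl_ab = (q * (ls_a - ls_b)).sum(axis=1).mean()
    if not symmetric:
        return kl_ab
    r = ls_b.exp()
    kl_ba = (r * (ls_b - ls_a)).sum(axis=1).mean()
    return (kl_ab + kl_ba) * 0.5


def total_loss(
    bundle: PredictionBundle,
    x_rna: ArrayLike,
    x_atac: ArrayLike,
    z_merged_atac: Union[LatentEmbedding, ArrayLike],
    z_merged_rna: Union[LatentEmbedding, ArrayLike],
    w: LossWeights | None = None,
    kl_symmetric: bool = False,
) -> tuple[Tensor, dict[str, float]]:
    """Composite training loss and its per-term breakdown.

    total = NB(rna_from_atac) + NB(rna_from_rna)
          + w_bce * (BCE(atac_from_atac) + BCE(atac_from_rna))
          + w_kl * KL(merged ATAC-side latent, merged RNA-side latent)
    """
    w = w or LossWeights()
    terms = {
        "nb_rna_from_atac": nb_nll(x_rna, *bundle.rna_from_atac),
        "nb_rna_from_rna": nb_nll(x_rna, *bundle.rna_from_rna),
        "bce_atac_from_atac": bce_loss(x_atac, bundle.atac_from_atac),
        "bce_atac_from_rna": bce_loss(x_atac, bundle.atac_from_rna),
        "kl_latent": kl_latent(z_merged_atac, z_merged_rna, symmetric=kl_symmetric),
    }
    for name, t in terms.items():
        if not np.isfinite(t.data):
            raise FloatingPointError(f"loss term {name} is non-finite")
    total = (
        terms["nb_rna_from_atac"]
        + terms["nb_rna_from_rna"]
        + w.w_bce * (terms["bce_atac_from_atac"] + terms["bce_atac_from_rna"])
        + w.w_kl * terms["kl_latent"]
    )
    breakdown = {k: float(t.data) for k, t in terms.items()}
    breakdown["total"] = float(total.data)
    return total, breakdown
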