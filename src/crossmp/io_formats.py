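"""Standard single-cell formats and the genomic coordinate conventions used package-wide.

All coordinates are 0-based half-open (BED convention), including intervals
parsed from peak names of the form ``chrom:start-end``.  Matrices are always
cells x features (barcodes as rows), whatever the on-disk orientation.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "FeatureAxis",
    "CellByFeatureMatrix",
    "GeneModel",
    "GeneModelTable",
    "FormatError",
    "ValidationError",
    "parse_interval",
    "format_interval",
    "read_matrix",
    "write_matrix",
    "read_gene_models",
    "write_gene_models",
    "write_peaks_bed",
]


class FormatError(ValueError):
    """A file does not conform to its declared on-disk layout."""


class ValidationError(ValueError):
    """An in-memory object violates a domain invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chromosome name must be non-empty")
        if self.start < 0:
            raise ValidationError(f"interval start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"interval end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


_INTERVAL_RE = re.compile(r"^([^:]+):(\d+)-(\d+)$")


def parse_interval(name: str) -> Optional[GenomicInterval]:
    """Parse ``chrom:start-end`` into an interval; ``None`` if not in that form."""
    m = _INTERVAL_RE.match(name)
    if m is None:
        return None
    return GenomicInterval(m.group(1), int(m.group(2)), int(m.group(3)))


def format_interval(iv: GenomicInterval) -> str:
    return f"{iv.chrom}:{iv.start}-{iv.end}"


@dataclass
class FeatureAxis:
    """Ordered feature identifiers with optional parallel genomic intervals."""

    ids: list[str]
    intervals: Optional[list[Optional[GenomicInterval]]] = None

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            dup = pd.Series(self.ids)
            dup = dup[dup.duplicated()].iloc[0]
            raise ValidationError(f"duplicate feature id: {dup!r}")
        if self.intervals is not None and len(self.intervals) != len(self.ids):
            raise ValidationError(
                f"intervals length {len(self.intervals)} != ids length {len(self.ids)}"
            )

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def from_names(cls, ids: Sequence[str]) -> "FeatureAxis":
        """Build an axis, parsing intervals from ``chrom:start-end`` names when present."""
        ids = list(ids)
        intervals: list[Optional[GenomicInterval]] = [parse_interval(i) for i in ids]
        if all(iv is None for iv in intervals):
            return cls(ids=ids, intervals=None)
        return cls(ids=ids, intervals=intervals)

    def subset(self, indices: Sequence[int]) -> "FeatureAxis":
        ids = [self.ids[i] for i in indices]
        ivs = None if self.intervals is None else [self.intervals[i] for i in indices]
        return FeatureAxis(ids=ids, intervals=ivs)

    def require_intervals(self) -> list[GenomicInterval]:
        if self.intervals is None or any(iv is None for iv in self.intervals):
            missing = (
                "no intervals attached"
                if self.intervals is None
                else next(i for i, iv in enumerate(self.intervals) if iv is None)
            )
            raise ValidationError(
                f"operation requires genomic intervals on all features ({missing})"
            )
        return list(self.intervals)  # type: ignore[arg-type]


Matrix = Union[np.ndarray, sp.spmatrix]


@dataclass
class CellByFeatureMatrix:
    """Cells x features numeric matrix with barcode and feature axes.

    ``values`` may be dense or any scipy sparse type; it is normalised to CSR
    so nonzero iteration never densifies.
    """

    barcodes: list[str]
    features: FeatureAxis
    values: Matrix = field(repr=False)

    def __post_init__(self) -> None:
        if len(set(self.barcodes)) != len(self.barcodes):
            s = pd.Series(self.barcodes)
            raise ValidationError(
                f"duplicate barcode: {s[s.duplicated()].iloc[0]!r}"
            )
        if sp.issparse(self.values):
            self.values = self.values.tocsr()
        else:
            self.values = np.asarray(self.values)
            if not np.all(np.isfinite(self.values)):
                raise ValidationError("matrix contains non-finite values")
        if self.values.shape != (len(self.barcodes), len(self.features)):
            raise ValidationError(
                f"matrix shape {self.values.shape} != "
                f"({len(self.barcodes)} barcodes, {len(self.features)} features)"
            )
        if sp.issparse(self.values) and not np.all(np.isfinite(self.values.data)):
            raise ValidationError("matrix contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def n_cells(self) -> int:
        return self.shape[0]

    @property
    def n_features(self) -> int:
        return self.shape[1]

    def dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense())
        return np.asarray(self.values)

    def is_binary(self) -> bool:
        data = self.values.data if sp.issparse(self.values) else self.values
        return bool(np.all((data == 0) | (data == 1)))

    def subset_features(self, indices: Sequence[int]) -> "CellByFeatureMatrix":
        idx = list(indices)
        return CellByFeatureMatrix(
            barcodes=list(self.barcodes),
            features=self.features.subset(idx),
            values=self.values[:, idx],
        )

    def subset_cells(self, indices: Sequence[int]) -> "CellByFeatureMatrix":
        idx = list(indices)
        return CellByFeatureMatrix(
            barcodes=[self.barcodes[i] for i in idx],
            features=self.features,
            values=self.values[idx, :],
        )


# ---------------------------------------------------------------------------
# matrix I/O


def _feature_names(m: CellByFeatureMatrix) -> list[str]:
    """Feature ids, with intervals re-encoded into names where the id is not already one."""
    if m.features.intervals is None:
        return list(m.features.ids)
    out = []
    for fid, iv in zip(m.features.ids, m.features.intervals):
        if iv is not None and parse_interval(fid) is None:
            out.append(format_interval(iv))
        else:
            out.append(fid)
    return out


def read_matrix(path: Union[str, Path], layout: str) -> CellByFeatureMatrix:
    """Read a cell-by-feature matrix from ``h5ad`` or an MTX triplet directory.

    Feature intervals are parsed from names of the form ``chrom:start-end``.
    For ``mtx_dir`` the on-disk orientation is resolved against the barcode
    and feature file lengths (10x writes features x barcodes).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if layout == "h5ad":
        import anndata

        adata = anndata.read_h5ad(path)
        barcodes = list(map(str, adata.obs_names))
        features = FeatureAxis.from_names(list(map(str, adata.var_names)))
        return CellByFeatureMatrix(barcodes=barcodes, features=features, values=adata.X)
    if layout == "mtx_dir":
        mtx = _find_one(path, ("matrix.mtx", "matrix.mtx.gz"))
        bc = _find_one(path, ("barcodes.tsv", "barcodes.tsv.gz"))
        ft = _find_one(path, ("features.tsv", "features.tsv.gz", "genes.tsv"))
        try:
            values = sp.csr_matrix(scipy.io.mmread(mtx))
        except Exception as exc:  # noqa: BLE001 - report the offending file
            raise FormatError(f"malformed Matrix Market file {mtx}: {exc}") from exc
        barcodes = _read_single_column(bc)
        names = _read_single_column(ft)
        if values.shape == (len(names), len(barcodes)):
            # 10x convention (features x barcodes on disk); for a square,
            # ambiguous matrix this convention is assumed
            values = values.T.tocsr()
        elif values.shape == (len(barcodes), len(names)):
            pass
        else:
            raise FormatError(
                f"matrix shape {values.shape} matches neither "
                f"({len(barcodes)}, {len(names)}) nor its transpose"
            )
        return CellByFeatureMatrix(
            barcodes=barcodes, features=FeatureAxis.from_names(names), values=values
        )
    raise ValueError(f"unknown layout {layout!r}; expected 'h5ad' or 'mtx_dir'")


def _find_one(directory: Path, candidates: Sequence[str]) -> Path:
    for name in candidates:
        p = directory / name
        if p.exists():
            return p
    raise FileNotFoundError(
        f"none of {list(candidates)} found in directory {directory}"
    )


def _read_single_column(path: Path) -> list[str]:
    if path.stat().st_size == 0:
        return []
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return list(df.iloc[:, 0])


def write_matrix(m: CellByFeatureMatrix, path: Union[str, Path], layout: str) -> None:
    """Write ``m`` so that :func:`read_matrix` recovers (barcodes, ids, values)."""
    path = Path(path)
    names = _feature_names(m)
    if layout == "h5ad":
        import anndata

        X = m.values if sp.issparse(m.values) else np.asarray(m.values)
        adata = anndata.AnnData(
            X=sp.csr_matrix(X) if sp.issparse(m.values) else X,
            obs=pd.DataFrame(index=pd.Index(m.barcodes, name="barcode")),
            var=pd.DataFrame(index=pd.Index(names, name="feature")),
        )
        adata.write_h5ad(path)
        return
    if layout == "mtx_dir":
        path.mkdir(parents=True, exist_ok=True)
        values = sp.coo_matrix(m.values)
        # 10x convention: features as rows on disk
        scipy.io.mmwrite(str(path / "matrix.mtx"), values.T)
        (path / "barcodes.tsv").write_text(
            "".join(b + "\n" for b in m.barcodes)
        )
        (path / "features.tsv").write_text("".join(n + "\n" for n in names))
        return
    raise ValueError(f"unknown layout {layout!r}; expected 'h5ad' or 'mtx_dir'")


def write_peaks_bed(m: CellByFeatureMatrix, path: Union[str, Path]) -> None:
    """Export the feature intervals as BED3."""
    ivs = m.features.require_intervals()
    with open(path, "w") as fh:
        for iv in ivs:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# gene models


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    tss: int
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.tss < 0:
            raise ValidationError(f"gene {self.gene_id}: negative TSS")
        if not self.exons:
            raise ValidationError(f"gene {self.gene_id}: no exons")
        for ex in self.exons:
            if ex.chrom != self.chrom:
                raise ValidationError(
                    f"gene {self.gene_id}: exon on {ex.chrom}, gene on {self.chrom}"
                )
        if self.total_exon_length <= 0:
            raise ValidationError(f"gene {self.gene_id}: total exon length must be > 0")

    @property
    def total_exon_length(self) -> int:
        return sum(ex.length for ex in self.exons)


class GeneModelTable:
    """Validated collection of gene models, ordered as loaded."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.genes: list[GeneModel] = list(genes)
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            s = pd.Series(ids)
            raise ValidationError(f"duplicate gene_id: {s[s.duplicated()].iloc[0]!r}")
        self._by_id = {g.gene_id: g for g in self.genes}

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def chrom_of(self) -> dict[str, str]:
        return {g.gene_id: g.chrom for g in self.genes}


def _parse_exons(chrom: str, text: str) -> tuple[GenomicInterval, ...]:
    exons = []
    for part in str(text).split(";"):
        part = part.strip()
        if not part:
            continue
        try:
            start_s, end_s = part.split("-")
            exons.append(GenomicInterval(chrom, int(start_s), int(end_s)))
        except ValidationError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise FormatError(f"malformed exon field {part!r}") from exc
    return tuple(exons)


GENE_MODEL_COLUMNS = ["gene_id", "chrom", "strand", "tss", "exons"]


def read_gene_models(path: Union[str, Path]) -> GeneModelTable:
    """Read a gene-model TSV: gene_id, chrom, strand, tss, exons (``start-end;...``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in GENE_MODEL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"gene model table missing columns: {missing}")
    genes = []
    for _, row in df.iterrows():
        genes.append(
            GeneModel(
                gene_id=row["gene_id"],
                chrom=row["chrom"],
                strand=row["strand"],
                tss=int(row["tss"]),
                exons=_parse_exons(row["chrom"], row["exons"]),
            )
        )
    return GeneModelTable(genes)


def write_gene_models(table: GeneModelTable, path: Union[str, Path]) -> None:
    rows = []
    for g in table:
        rows.append(
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "strand": g.strand,
                "tss": g.tss,
                "exons": ";".join(f"{e.start}-{e.end}" for e in g.exons),
            }
        )
    pd.DataFrame(rows, columns=GENE_MODEL_COLUMNS).to_csv(path, sep="\t", index=False)
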