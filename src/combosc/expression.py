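"""Expression-matrix container, standard-format I/O, QC and normalisation.

The unit of data is a cells x genes UMI count matrix plus a per-cell metadata
table (sample of origin, cell-type label, malignant flag).  Counts are kept
as-is; the normalised layer is log2(CPM/10 + 1), a counts-per-million
surrogate for TPM that is standard for UMI data where gene lengths do not
enter.  QC and cohort-inclusion rules use strict inequalities: a cell is
removed when it has *fewer than* ``qc_min_genes`` detected genes or *more
than* ``qc_max_mito_frac`` mitochondrial counts; a sample is excluded when it
has fewer than ``min_malignant_cells`` malignant cells or fewer than
``min_t_cells`` T cells.  Equality at a boundary always retains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .config import Config

META_COLUMNS = ("cell_id", "sample_id", "cell_type", "is_malignant")


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


class FormatError(ValueError):
    """Raised when an on-disk file does not match its declared shape."""


def _check_unique(ids: np.ndarray, axis: str) -> None:
    if len(ids) != len(set(ids)):
        dup = pd.Index(ids)
        dup = sorted(dup[dup.duplicated()].unique())
        raise ValidationError(f"duplicate {axis} identifiers: {dup[:5]}")


@dataclass
class ExpressionMatrix:
    """Cells x genes counts with an optional parallel normalised layer."""

    cell_ids: np.ndarray
    gene_ids: np.ndarray
    counts: sp.csr_matrix
    norm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        _check_unique(self.cell_ids, "cell")
        _check_unique(self.gene_ids, "gene")
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("counts must be non-negative")
        if self.norm is not None:
            self.norm = np.asarray(self.norm, dtype=float)
            if self.norm.shape != self.counts.shape:
                raise ValidationError("norm layer shape differs from counts")
            if not np.all(np.isfinite(self.norm)) or self.norm.min() < 0:
                raise ValidationError("norm values must be finite and >= 0")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def norm_frame(self) -> pd.DataFrame:
        if self.norm is None:
            raise ValidationError("normalised layer not populated; "
                                  "call normalize_log2_tpm first")
        return pd.DataFrame(self.norm, index=self.cell_ids,
                            columns=self.gene_ids)

    def subset_cells(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            mask = np.isin(self.cell_ids, mask)
        return ExpressionMatrix(
            cell_ids=self.cell_ids[mask],
            gene_ids=self.gene_ids.copy(),
            counts=self.counts[mask],
            norm=None if self.norm is None else self.norm[mask],
        )

    def to_anndata(self):
        """Bridge to the AnnData ecosystem (scanpy etc.)."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.counts.copy(),
            obs=pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id")),
            var=pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id")),
        )
        if self.norm is not None:
            adata.layers["lognorm"] = self.norm.copy()
        return adata


def _read_names(path: str | Path, axis: str) -> np.ndarray:
    names = [ln.strip().split("\t")[0]
             for ln in Path(path).read_text().splitlines() if ln.strip()]
    arr = np.asarray(names, dtype=object)
    _check_unique(arr, axis)
    return arr


def read_expression(matrix_path: str | Path,
                    cells_path: str | Path,
                    genes_path: str | Path,
                    format: str = "mtx",
                    genes_in_rows: bool = False) -> ExpressionMatrix:
    """Read a count matrix with its cell/gene name files.

    ``genes_in_rows`` declares the on-disk orientation (10x-style MTX files
    store genes as rows); the returned matrix is always cells x genes.
    """
    cells = _read_names(cells_path, "cell")
    genes = _read_names(genes_path, "gene")
    if format == "mtx":
        mat = sp.csr_matrix(mmread(str(matrix_path)))
    elif format == "dense":
        mat = sp.csr_matrix(
            pd.read_csv(matrix_path, sep=None, engine="python",
                        header=None).to_numpy(dtype=float)
        )
    else:
        raise FormatError(f"unknown format {format!r}; use 'mtx' or 'dense'")
    if genes_in_rows:
        mat = sp.csr_matrix(mat.T)
    if mat.shape[0] != len(cells):
        raise FormatError(
            f"cell axis mismatch: matrix has {mat.shape[0]} rows but "
            f"{len(cells)} cell names were provided"
        )
    if mat.shape[1] != len(genes):
        raise FormatError(
            f"gene axis mismatch: matrix has {mat.shape[1]} columns but "
            f"{len(genes)} gene names were provided"
        )
    return ExpressionMatrix(cell_ids=cells, gene_ids=genes, counts=mat)


def write_expression(m: ExpressionMatrix,
                     matrix_path: str | Path,
                     cells_path: str | Path,
                     genes_path: str | Path) -> None:
    """Write counts as MatrixMarket integer triplets plus name files."""
    mmwrite(str(matrix_path), sp.coo_matrix(m.counts.astype(np.int64)),
            field="integer")
    Path(cells_path).write_text("\n".join(map(str, m.cell_ids)) + "\n")
    Path(genes_path).write_text("\n".join(map(str, m.gene_ids)) + "\n")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"metadata is missing required columns {missing}")
    meta["is_malignant"] = meta["is_malignant"].astype(bool)
    return meta


def validate_metadata(meta: pd.DataFrame, m: ExpressionMatrix) -> None:
    """Every cell_id must appear in the companion matrix exactly once."""
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValidationError(f"metadata is missing columns {missing}")
    _check_unique(meta["cell_id"].to_numpy(dtype=object), "metadata cell")
    extra = set(meta["cell_id"]) - set(m.cell_ids)
    if extra:
        raise ValidationError(
            f"metadata refers to unknown cells: {sorted(extra)[:5]}"
        )


def qc_filter(m: ExpressionMatrix,
              cfg: Config | None = None) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Remove low-quality cells; return the filtered matrix and a report.

    A cell is removed when its detected-gene count is strictly below
    ``qc_min_genes`` or its mitochondrial count fraction is strictly above
    ``qc_max_mito_frac`` (mitochondrial genes recognised by symbol prefix).
    """
    cfg = cfg or Config()
    report_cols = ["cell_id", "n_genes", "mito_frac", "reason"]
    if m.n_cells == 0:
        return m, pd.DataFrame(columns=report_cols)
    detected = np.asarray((m.counts > 0).sum(axis=1)).ravel()
    totals = np.asarray(m.counts.sum(axis=1)).ravel().astype(float)
    mito_mask = np.array(
        [str(g).upper().startswith(cfg.mito_prefix.upper())
         for g in m.gene_ids]
    )
    mito = np.asarray(m.counts[:, mito_mask].sum(axis=1)).ravel().astype(float) \
        if mito_mask.any() else np.zeros(m.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, mito / np.maximum(totals, 1.0), 0.0)
    few = detected < cfg.qc_min_genes
    high_mito = frac > cfg.qc_max_mito_frac
    removed = few | high_mito
    reasons = []
    for i in np.flatnonzero(removed):
        r = []
        if few[i]:
            r.append(f"fewer than {cfg.qc_min_genes} genes")
        if high_mito[i]:
            r.append(f"mito fraction above {cfg.qc_max_mito_frac:g}")
        reasons.append("; ".join(r))
    report = pd.DataFrame({
        "cell_id": m.cell_ids[removed],
        "n_genes": detected[removed],
        "mito_frac": frac[removed],
        "reason": reasons,
    }, columns=report_cols)
    if removed.all():
        warnings.warn("QC removed every cell; returning an empty matrix")
    return m.subset_cells(~removed), report


def normalize_log2_tpm(m: ExpressionMatrix,
                       scale: float = 1e6) -> ExpressionMatrix:
    """Populate the log2(TPM/10 + 1) layer from counts.

    TPM is approximated by counts-per-million over the provided genes (UMI
    data carries no length bias).  Cells with zero total counts get an
    all-zero row and a warning.
    """
    totals = np.asarray(m.counts.sum(axis=1)).ravel().astype(float)
    zero = totals == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} cell(s) have zero total counts; "
                      "their normalised rows are set to zero")
    dense = np.asarray(m.counts.todense(), dtype=float)
    tpm = dense / np.where(zero, 1.0, totals)[:, None] * scale
    norm = np.log2(tpm / 10.0 + 1.0)
    norm[zero] = 0.0
    return ExpressionMatrix(cell_ids=m.cell_ids, gene_ids=m.gene_ids,
                            counts=m.counts, norm=norm)


@dataclass
class InclusionVerdict:
    sample_id: str
    n_malignant: int
    n_t_cells: int
    included: bool
    reasons: list[str] = field(default_factory=list)


def check_sample_inclusion(meta: pd.DataFrame,
                           cfg: Config | None = None,
                           t_cell_labels: set[str] | None = None
                           ) -> list[InclusionVerdict]:
    """Flag samples with too few malignant cells or too few T cells.

    Strict '<' boundaries: a sample with exactly ``min_malignant_cells``
    malignant cells and exactly ``min_t_cells`` T cells is included.
    """
    cfg = cfg or Config()
    t_cell_labels = t_cell_labels or DEFAULT_T_CELL_LABELS
    verdicts = []
    for sample_id, grp in meta.groupby("sample_id", sort=True):
        n_mal = int(grp["is_malignant"].sum())
        n_t = int(grp["cell_type"].isin(t_cell_labels).sum())
        reasons = []
        if n_mal < cfg.min_malignant_cells:
            reasons.append(
                f"fewer than {cfg.min_malignant_cells} malignant cells"
            )
        if n_t < cfg.min_t_cells:
            reasons.append(f"fewer than {cfg.min_t_cells} T cells")
        verdicts.append(InclusionVerdict(
            sample_id=str(sample_id), n_malignant=n_mal, n_t_cells=n_t,
            included=not reasons, reasons=reasons,
        ))
    return verdicts


DEFAULT_T_CELL_LABELS = frozenset({
    "T cell", "T_cell", "CD4 T cell", "CD8 T cell",
    "T_active", "T_memory", "T_exhausted",
})
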