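"""Cell- and gene-level quality control.

Cells are retained when they exceed 350 expressed genes (strict), exceed
1000 UMIs (strict), and have a mitochondrial UMI fraction strictly below
``median + 5 * MAD``, with the median and MAD computed over all input cells
before any removal.  Genes expressed in fewer than 20 cells are then
excluded.  The MAD here is unscaled (median of absolute deviations from the
median, no 1.4826 normal-consistency factor); the multiplier and all cutoffs
are configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import CountMatrix

logger = logging.getLogger(__name__)

__all__ = ["QCThresholds", "QCReport", "cell_filter", "gene_filter", "run_qc"]


@dataclass
class QCThresholds:
    """QC cutoffs; defaults follow the atlas protocol for mouse uterus data."""

    min_genes_per_cell: int = 350  # strict >
    min_umis_per_cell: int = 1000  # strict >
    mito_mad_multiplier: float = 5.0
    min_cells_per_gene: int = 20  # genes in fewer cells are excluded
    mad_scale: float = 1.0  # 1.4826 for normal-consistent MAD

    def __post_init__(self) -> None:
        if self.min_genes_per_cell <= 0 or self.min_umis_per_cell <= 0:
            raise ValueError("count thresholds must be positive")
        if not np.isfinite(self.mito_mad_multiplier) or self.mito_mad_multiplier < 0:
            raise ValueError("mito_mad_multiplier must be finite and non-negative")
        if self.min_cells_per_gene < 1:
            raise ValueError("min_cells_per_gene must be >= 1")


@dataclass
class QCReport:
    """Per-filter removal accounting for one QC pass."""

    n_cells_in: int = 0
    n_cells_out: int = 0
    n_genes_in: int = 0
    n_genes_out: int = 0
    removed_by: dict = field(default_factory=dict)
    mito_threshold: float | None = None

    def as_dict(self) -> dict:
        return {
            "n_cells_in": self.n_cells_in,
            "n_cells_out": self.n_cells_out,
            "n_genes_in": self.n_genes_in,
            "n_genes_out": self.n_genes_out,
            "mito_threshold": self.mito_threshold,
            **{f"removed_{k}": v for k, v in self.removed_by.items()},
        }


def mito_cutoff(mito_fractions: np.ndarray, multiplier: float, mad_scale: float = 1.0) -> float:
    """median + multiplier * MAD of the per-cell mito fractions."""
    med = float(np.median(mito_fractions))
    mad = float(np.median(np.abs(mito_fractions - med))) * mad_scale
    return med + multiplier * mad


def cell_filter(
    matrix: CountMatrix, thresholds: QCThresholds | None = None
) -> tuple[CountMatrix, QCReport]:
    """Apply the three cell-level filters in one pass.

    The mito threshold is computed on the full input population, so the
    operation is deliberately not idempotent: the pipeline applies it once.
    """
    thr = thresholds or QCThresholds()
    if matrix.n_cells == 0:
        raise ValueError("empty matrix")

    genes_det = matrix.genes_detected()
    libs = matrix.library_sizes()
    mito = matrix.mito_fractions()
    cut = mito_cutoff(mito, thr.mito_mad_multiplier, thr.mad_scale)

    pass_genes = genes_det > thr.min_genes_per_cell
    pass_umis = libs > thr.min_umis_per_cell
    pass_mito = mito < cut
    keep = pass_genes & pass_umis & pass_mito

    removed = {
        "low_genes": int((~pass_genes).sum()),
        "low_umis": int((~pass_umis).sum()),
        "high_mito": int((~pass_mito).sum()),
    }
    report = QCReport(
        n_cells_in=matrix.n_cells,
        n_cells_out=int(keep.sum()),
        n_genes_in=matrix.n_genes,
        n_genes_out=matrix.n_genes,
        removed_by=removed,
        mito_threshold=cut,
    )
    if not keep.any():
        dominant = max(removed, key=removed.get)
        raise ValueError(
            f"cell_filter removed all {matrix.n_cells} cells "
            f"(dominant filter: {dominant}, counts {removed})"
        )
    logger.info(
        "cell_filter: %d -> %d cells (mito threshold %.4g)",
        matrix.n_cells, int(keep.sum()), cut,
    )
    return matrix.subset_cells(np.flatnonzero(keep)), report


def gene_filter(
    matrix: CountMatrix, thresholds: QCThresholds | None = None
) -> tuple[CountMatrix, QCReport]:
    """Drop genes expressed (count > 0) in fewer than ``min_cells_per_gene`` cells."""
    thr = thresholds or QCThresholds()
    if matrix.n_genes == 0:
        raise ValueError("empty matrix")
    n_cells_expr = matrix.cells_expressing()
    keep = n_cells_expr >= thr.min_cells_per_gene
    report = QCReport(
        n_cells_in=matrix.n_cells,
        n_cells_out=matrix.n_cells,
        n_genes_in=matrix.n_genes,
        n_genes_out=int(keep.sum()),
        removed_by={"low_cell_count": int((~keep).sum())},
    )
    if not keep.any():
        raise ValueError("gene_filter removed all genes")
    logger.info("gene_filter: %d -> %d genes", matrix.n_genes, int(keep.sum()))
    return matrix.subset_genes(np.flatnonzero(keep)), report


def run_qc(
    matrix: CountMatrix, thresholds: QCThresholds | None = None
) -> tuple[CountMatrix, QCReport, QCReport]:
    """Cell filter followed by gene filter (the pipeline order)."""
    filtered, cell_report = cell_filter(matrix, thresholds)
    filtered, gene_report = gene_filter(filtered, thresholds)
    return filtered, cell_report, gene_report
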