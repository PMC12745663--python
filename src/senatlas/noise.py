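"""Transcriptional noise: cell-to-cell expression variability with age.

Per cell type, cells from the two compared age groups are capped at 300 per
group, library sizes are equalised by downsampling every cell (without
replacement) to the smallest library in the stratum, low-variability
"invariant" genes are selected by blocked coefficient of variation (10
expression blocks, lowest 10% CV per block, on cells pooled across the two
age groups so both are measured on one panel), and each cell's Euclidean
distance in log1p space — to the group centroid by default, or the mean
pairwise distance — summarises heterogeneity.  The statistic per cell type
is the log2 ratio of mean distance, aged over young.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "NoiseParams",
    "NoiseResult",
    "downsample_libraries",
    "select_invariant_genes",
    "transcriptional_noise",
]


@dataclass
class NoiseParams:
    """Noise-procedure parameters.

    min_cells
        Minimum cells a cell type must have in each compared age group.
    cap_cells
        Per-(cell type, age group) cap; larger groups are subsampled.
    n_blocks, cv_quantile
        Expression blocks and the per-block lowest-CV fraction selected.
    distance_mode
        ``centroid`` (distance to the group centroid) or ``pairwise``
        (mean distance to the other cells of the group).
    """

    min_cells: int = 10
    cap_cells: int = 300
    n_blocks: int = 10
    cv_quantile: float = 0.10
    distance_mode: str = "centroid"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_cells < 2:
            raise ValueError("min_cells must be >= 2")
        if self.cap_cells < self.min_cells:
            raise ValueError("cap_cells must be >= min_cells")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if not 0 < self.cv_quantile <= 1:
            raise ValueError("cv_quantile must be in (0, 1]")
        if self.distance_mode not in ("centroid", "pairwise"):
            raise ValueError("distance_mode must be 'centroid' or 'pairwise'")


@dataclass
class NoiseResult:
    """Per-cell distances and per-cell-type group noise / log2 ratios."""

    per_cell: pd.DataFrame
    summary: pd.DataFrame


def downsample_libraries(
    matrix: CountMatrix,
    target: int | None = None,
    seed: int | np.random.Generator = 0,
) -> CountMatrix:
    """Downsample every cell to an equal library size without replacement.

    Each cell's counts are replaced by a multivariate-hypergeometric draw of
    exactly ``target`` UMIs from its own counts (default target: the minimum
    library size among the cells), so the minimum-size cell is returned
    unchanged.
    """
    libs = matrix.library_sizes().astype(np.int64)
    if matrix.n_cells == 0:
        raise ValueError("no cells to downsample")
    if target is None:
        target = int(libs.min())
    if target <= 0:
        raise ValueError("downsampling target is 0 (a cell has an empty library)")
    if (libs < target).any():
        raise ValueError("target exceeds a cell's library size")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dense = matrix.dense().astype(np.int64)  # genes x cells
    out = np.empty_like(dense)
    for j in range(dense.shape[1]):
        if libs[j] == target:
            out[:, j] = dense[:, j]
        else:
            out[:, j] = rng.multivariate_hypergeometric(dense[:, j], target)
    return CountMatrix(out, matrix.gene_ids, matrix.cell_ids, matrix.mito_flags)


def select_invariant_genes(
    matrix: CountMatrix | np.ndarray, params: NoiseParams | None = None
) -> np.ndarray:
    """Low-CV gene indices, chosen per expression block.

    Genes with zero mean are excluded; the rest are ordered by mean
    expression, cut into ``n_blocks`` near-equal blocks, and within each
    block the ``ceil(block_size * cv_quantile)`` genes with the lowest
    CV (sd / mean, sample sd) are kept.  Returns sorted gene indices into
    the input matrix.
    """
    params = params or NoiseParams()
    X = matrix.dense() if isinstance(matrix, CountMatrix) else np.asarray(matrix)
    means = X.mean(axis=1)
    nonzero = np.flatnonzero(means > 0)
    if len(nonzero) < params.n_blocks:
        raise ValueError(
            f"only {len(nonzero)} genes with nonzero mean; need >= {params.n_blocks}"
        )
    sds = X[nonzero].std(axis=1, ddof=1)
    cv = sds / means[nonzero]
    order = nonzero[np.argsort(means[nonzero], kind="stable")]
    cv_by_gene = dict(zip(nonzero, cv))
    selected = []
    for block in np.array_split(order, params.n_blocks):
        k = math.ceil(len(block) * params.cv_quantile)
        block_cv = np.array([cv_by_gene[g] for g in block])
        picked = block[np.argsort(block_cv, kind="stable")[:k]]
        selected.extend(picked.tolist())
    return np.array(sorted(selected), dtype=int)


def _distances(L: np.ndarray, mode: str) -> np.ndarray:
    """Per-cell distance within one group; L is cells x genes log1p values."""
    if mode == "centroid":
        centroid = L.mean(axis=0, keepdims=True)
        return np.linalg.norm(L - centroid, axis=1)
    # pairwise: mean Euclidean distance to every other cell of the group
    from scipy.spatial.distance import squareform, pdist

    n = L.shape[0]
    D = squareform(pdist(L, metric="euclidean"))
    return D.sum(axis=1) / (n - 1)


def transcriptional_noise(
    matrix: CountMatrix,
    annotation: pd.DataFrame,
    params: NoiseParams | None = None,
    young: str = "young",
    aged: str = "aged",
) -> NoiseResult:
    """Aged-over-young transcriptional-noise log2 ratio per cell type.

    Parameters
    ----------
    matrix
        UMI counts (genes x cells), typically post-QC.
    annotation
        Per-cell metadata with ``cell_id``, ``cell_type``, ``age_group``.
    young, aged
        The two compared age-group levels.
    """
    params = params or NoiseParams()
    rng = np.random.default_rng(params.seed)
    ann = annotation.set_index("cell_id")
    cell_types = ann.loc[list(matrix.cell_ids), "cell_type"].to_numpy()
    ages = ann.loc[list(matrix.cell_ids), "age_group"].astype(str).to_numpy()

    per_cell_rows = []
    summary_rows = []
    for ct in pd.unique(cell_types):
        idx_y = np.flatnonzero((cell_types == ct) & (ages == young))
        idx_a = np.flatnonzero((cell_types == ct) & (ages == aged))
        if len(idx_y) < params.min_cells or len(idx_a) < params.min_cells:
            logger.warning(
                "cell type %r below min_cells (%d young, %d aged); dropped",
                ct, len(idx_y), len(idx_a),
            )
            continue
        if len(idx_y) > params.cap_cells:
            idx_y = np.sort(rng.choice(idx_y, size=params.cap_cells, replace=False))
        if len(idx_a) > params.cap_cells:
            idx_a = np.sort(rng.choice(idx_a, size=params.cap_cells, replace=False))

        pooled = np.concatenate([idx_y, idx_a])
        sub = matrix.subset_cells(pooled)
        sub = downsample_libraries(sub, seed=rng)
        genes = select_invariant_genes(sub, params)
        L = np.log1p(sub.dense()[genes, :].T.astype(float))  # cells x genes

        n_y = len(idx_y)
        groups = {young: L[:n_y], aged: L[n_y:]}
        noise = {}
        for age, block in groups.items():
            d = _distances(block, params.distance_mode)
            noise[age] = float(d.mean())
            per_cell_rows.append(pd.DataFrame({
                "cell_id": sub.cell_ids[:n_y] if age == young else sub.cell_ids[n_y:],
                "cell_type": ct,
                "age_group": age,
                "distance": d,
            }))
        if noise[young] > 0:
            ratio = float(np.log2(noise[aged] / noise[young]))
        else:
            logger.warning("cell type %r has zero young-group noise; ratio undefined", ct)
            ratio = np.nan
        summary_rows.append({
            "cell_type": ct,
            "n_young": n_y,
            "n_aged": len(idx_a),
            "n_invariant_genes": len(genes),
            "noise_young": noise[young],
            "noise_aged": noise[aged],
            "log2_ratio": ratio,
        })

    if not summary_rows:
        raise ValueError("no cell type met the min_cells requirement in both age groups")
    return NoiseResult(
        per_cell=pd.concat(per_cell_rows, ignore_index=True),
        summary=pd.DataFrame(summary_rows),
    )
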