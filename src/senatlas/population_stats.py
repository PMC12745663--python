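"""Cell-type composition testing with LTSR and one-vs-rest marker detection.

Composition: per cell type, per-sample cell counts are modelled with a
Poisson GLM (log link, offset log of the sample's total cells, binary age
covariate).  The local true sign rate, LTSR = Phi(|estimate| / SE), is the
probability that the estimated direction of the log2 fold change is correct
given its mean and variance; LTSR > 0.9 declares a composition change.

Markers: per gene, a two-sided Wilcoxon rank-sum test (normal approximation
with tie and continuity correction) on log-normalised expression, reported
with the Seurat-classic natural-log fold change and expression fractions,
screened at min.pct and BH-adjusted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix
from .scoring import log_normalize

logger = logging.getLogger(__name__)

__all__ = ["composition_ltsr", "find_markers", "MarkerParams", "ltsr"]

_LN2 = np.log(2.0)


def ltsr(estimate: np.ndarray, se: np.ndarray) -> np.ndarray:
    """Local true sign rate: Phi(|estimate| / SE), in [0.5, 1]."""
    estimate = np.asarray(estimate, dtype=float)
    se = np.asarray(se, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, np.abs(estimate) / se, np.inf)
    return scipy.stats.norm.cdf(z)


def _sample_counts(annotation: pd.DataFrame) -> pd.DataFrame:
    """Samples x cell-types count table with the sample's age group attached."""
    tab = (
        annotation.groupby(["sample_id", "cell_type"], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    ages = annotation.drop_duplicates("sample_id").set_index("sample_id")["age_group"]
    tab.insert(0, "_age_group", ages.loc[tab.index].astype(str).to_numpy())
    return tab


def composition_ltsr(
    annotation: pd.DataFrame,
    group_a: str = "young",
    group_b: str = "aged",
    ltsr_threshold: float = 0.9,
) -> pd.DataFrame:
    """Per-cell-type abundance change (group_b vs group_a) with LTSR.

    Returns a table with the log2 fold change of relative abundance, its
    standard error, LTSR and the significance flag, sorted by LTSR
    descending.  A cell type entirely absent from one group is fitted with a
    0.5 pseudo-count continuity correction and flagged.
    """
    tab = _sample_counts(annotation)
    tab = tab[tab["_age_group"].isin([group_a, group_b])]
    if tab.empty:
        raise ValueError(f"no samples in groups {group_a!r}/{group_b!r}")
    for g in (group_a, group_b):
        if (tab["_age_group"] == g).sum() < 2:
            raise ValueError(f"need >= 2 samples in group {g!r}")
    totals = tab.drop(columns="_age_group").sum(axis=1).to_numpy(dtype=float)
    if (totals == 0).any():
        raise ValueError("a sample has no cells")
    x = (tab["_age_group"] == group_b).to_numpy(dtype=float)
    X = sm.add_constant(x)

    rows = []
    for ct in tab.columns.drop("_age_group"):
        y = tab[ct].to_numpy(dtype=float)
        corrected = False
        for g_mask in (x == 0, x == 1):
            if y[g_mask].sum() == 0:
                corrected = True
        if corrected:
            y = y + 0.5
        fit = sm.GLM(
            y, X, family=sm.families.Poisson(), offset=np.log(totals)
        ).fit()
        beta, se = fit.params[1], fit.bse[1]
        rows.append({
            "cell_type": ct,
            "log2_fc": beta / _LN2,
            "se": se / _LN2,
            "ltsr": float(ltsr(beta, se)),
            "continuity_corrected": corrected,
        })
    out = pd.DataFrame(rows)
    out["significant"] = out["ltsr"] > ltsr_threshold
    return out.sort_values("ltsr", ascending=False, ignore_index=True)


@dataclass
class MarkerParams:
    """Marker-detection thresholds (Seurat-classic conventions)."""

    min_pct: float = 0.20  # screen: max(pct_in, pct_out) must exceed this
    logfc_threshold: float = 0.25
    alpha: float = 0.05
    log_base: float = np.e  # natural log ("avg_logFC" classic convention)


def find_markers(
    matrix: CountMatrix,
    annotation: pd.DataFrame,
    target_type: str,
    params: MarkerParams | None = None,
) -> pd.DataFrame:
    """One-vs-rest marker genes for ``target_type``.

    Per gene: two-sided Wilcoxon rank-sum on log-normalised expression
    between target cells and all others; ``avg_logFC`` is
    ``log(mean(expm1(x_in)) + 1) - log(mean(expm1(x_out)) + 1)``;
    ``pct_in``/``pct_out`` are the fractions of cells with nonzero counts.
    Genes are screened at ``max(pct_in, pct_out) > min_pct`` before testing;
    BH adjustment runs across tested genes.  ``passes`` requires
    ``avg_logFC > 0.25``, adjusted p < 0.05 and the min.pct screen.
    """
    params = params or MarkerParams()
    ann = annotation.set_index("cell_id")
    ct = ann.loc[list(matrix.cell_ids), "cell_type"].to_numpy()
    in_mask = ct == target_type
    n_in, n_out = int(in_mask.sum()), int((~in_mask).sum())
    if n_in < 3 or n_out < 3:
        raise ValueError(
            f"need >= 3 cells per side; got {n_in} {target_type!r} vs {n_out} others"
        )

    L = log_normalize(matrix)  # cells x genes
    Lin, Lout = L[in_mask], L[~in_mask]
    raw = matrix.dense().T  # cells x genes
    pct_in = (raw[in_mask] > 0).mean(axis=0)
    pct_out = (raw[~in_mask] > 0).mean(axis=0)
    mean_in = np.expm1(Lin).mean(axis=0)
    mean_out = np.expm1(Lout).mean(axis=0)
    logfc = (np.log(mean_in + 1) - np.log(mean_out + 1)) / np.log(params.log_base)

    tested = np.maximum(pct_in, pct_out) > params.min_pct
    pvals = np.full(matrix.n_genes, np.nan)
    if tested.any():
        with np.errstate(invalid="ignore", divide="ignore"):
            res = scipy.stats.mannwhitneyu(
                Lin[:, tested], Lout[:, tested],
                alternative="two-sided", method="asymptotic", axis=0,
            )
        p = np.asarray(res.pvalue, dtype=float)
        # a gene identical across every cell has zero rank variance -> p = 1
        p[~np.isfinite(p)] = 1.0
        pvals[tested] = p

    padj = np.full(matrix.n_genes, np.nan)
    if tested.any():
        padj[tested] = multipletests(pvals[tested], method="fdr_bh")[1]

    out = pd.DataFrame({
        "gene": matrix.gene_ids,
        "cell_type": target_type,
        "avg_logFC": logfc,
        "p_value": pvals,
        "p_adj": padj,
        "pct_in": pct_in,
        "pct_out": pct_out,
        "tested": tested,
    })
    out["passes"] = (
        tested
        & (out["avg_logFC"] > params.logfc_threshold)
        & (out["p_adj"] < params.alpha)
    )
    return out.sort_values(["passes", "p_adj"], ascending=[False, True], ignore_index=True)
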