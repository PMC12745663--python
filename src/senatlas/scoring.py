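"""Per-cell gene-set scoring and the unified senescence score (USS).

Two single-cell scoring kernels are provided:

``ssgsea``
    A rank-based running-sum enrichment score computed per cell.  Genes are
    ranked by descending expression (ties broken by stable gene order); the
    gene at position ``i`` (1-based) carries weight ``(N - i + 1) ** alpha``.
    The score is ``sum_i [P_in(i) - P_out(i)]`` where ``P_in`` is the
    weight-normalised cumulative fraction of set genes encountered up to
    position ``i`` and ``P_out`` the unweighted cumulative fraction of
    non-set genes.  The score depends on within-cell ranks only, so any
    strictly increasing per-cell transform of expression leaves it unchanged.

``module``
    A binned-control signature score on log-normalised expression (counts
    scaled to 10,000 per cell, log1p).  Genes are cut into ``n_bins``
    equal-frequency bins by mean expression; for each set gene ``n_ctrl``
    control genes are sampled from its bin, and the score is the mean over
    set genes minus the mean over the sampled control pool, per cell.

The USS integrates six senescence gene sets (SenMayo, CellAge, GenAge,
Senescence Eigengene, SASP, inflammatory response): within each cell type,
each set's per-cell scores are split at the median, and a cell is called
senescent when at least ``k`` of the six scores fall strictly above their
medians (default ``k = 6``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .io import USS_SET_NAMES, CountMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "ScoringParams",
    "ss_score",
    "module_score",
    "score_table",
    "uss_call",
    "uss_fractions",
    "log_normalize",
    "SSGSEAScorer",
    "ModuleScorer",
    "SenescenceCaller",
]


@dataclass
class ScoringParams:
    """Scoring hyper-parameters.

    alpha
        Rank-weight exponent of the running-sum kernel (0 = unweighted
        Kolmogorov-Smirnov-like statistic).
    n_bins, n_ctrl
        Expression bins and control genes per set gene for the module score.
    """

    alpha: float = 0.25
    n_bins: int = 24
    n_ctrl: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.n_bins < 1 or self.n_ctrl < 1:
            raise ValueError("n_bins and n_ctrl must be >= 1")


def log_normalize(matrix: CountMatrix, scale: float = 1e4) -> np.ndarray:
    """Cells x genes log1p(CP-scale) expression (dense)."""
    X = matrix.dense().T.astype(float)
    lib = X.sum(axis=1, keepdims=True)
    lib[lib == 0] = 1.0
    return np.log1p(X / lib * scale)


# ---------------------------------------------------------------------------
# running-sum kernel


def _running_sum_scores(
    X: np.ndarray, in_set: np.ndarray, alpha: float
) -> np.ndarray:
    """Running-sum enrichment for one set over cells x genes expression.

    Vectorised over cells; ties in expression are broken by stable gene
    order (lower gene index ranks first).
    """
    n_cells, n_genes = X.shape
    m = int(in_set.sum())
    if m == 0:
        raise ValueError("gene set has empty intersection with the matrix genes")
    if m == n_genes:
        raise ValueError("gene set covers the entire gene universe (empty complement)")
    order = np.argsort(-X, axis=1, kind="stable")
    hits = in_set[order]  # cells x genes, set membership in rank order
    w = (n_genes - np.arange(n_genes)).astype(float) ** alpha
    wh = w[None, :] * hits
    p_in = np.cumsum(wh, axis=1) / wh.sum(axis=1, keepdims=True)
    p_out = np.cumsum(~hits, axis=1) / float(n_genes - m)
    return (p_in - p_out).sum(axis=1)


def ss_score(
    matrix: CountMatrix,
    gene_set: Sequence[str],
    params: ScoringParams | None = None,
) -> np.ndarray:
    """Per-cell running-sum enrichment score for one gene set.

    Set genes absent from the matrix are ignored; the intersection must be
    non-empty and must not cover the whole gene universe.
    """
    params = params or ScoringParams()
    gene_index = {g: i for i, g in enumerate(matrix.gene_ids)}
    in_set = np.zeros(matrix.n_genes, dtype=bool)
    for g in set(gene_set):
        if g in gene_index:
            in_set[gene_index[g]] = True
    X = matrix.dense().T.astype(float)
    return _running_sum_scores(X, in_set, params.alpha)


# ---------------------------------------------------------------------------
# binned-control module score


def _bin_genes(gene_means: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency bin id per gene by mean expression (stable ties)."""
    order = np.argsort(gene_means, kind="stable")
    bin_id = np.empty(len(gene_means), dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bin_id[chunk] = b
    return bin_id


def _sample_controls(
    bin_id: np.ndarray, set_idx: np.ndarray, n_ctrl: int, rng: np.random.Generator
) -> np.ndarray:
    """Control-gene indices: n_ctrl per set gene from that gene's bin.

    Sampling is without replacement when the bin holds at least ``n_ctrl``
    genes, with replacement otherwise; the pooled sample keeps duplicates.
    """
    members = {b: np.flatnonzero(bin_id == b) for b in np.unique(bin_id[set_idx])}
    ctrl = []
    for gi in set_idx:
        pool = members[bin_id[gi]]
        replace = len(pool) < n_ctrl
        ctrl.append(rng.choice(pool, size=n_ctrl, replace=replace))
    return np.concatenate(ctrl)


def module_score(
    matrix: CountMatrix,
    gene_set: Sequence[str],
    params: ScoringParams | None = None,
) -> np.ndarray:
    """Per-cell binned-control module score for one gene set.

    All set genes must be present in the matrix; controls are drawn with a
    seeded generator so scores are reproducible.
    """
    params = params or ScoringParams()
    if not gene_set:
        raise ValueError("empty gene set")
    if params.n_bins > matrix.n_genes:
        raise ValueError("n_bins exceeds the number of genes")
    gene_index = {g: i for i, g in enumerate(matrix.gene_ids)}
    missing = [g for g in gene_set if g not in gene_index]
    if missing:
        raise KeyError(f"set genes absent from matrix: {missing[:5]}")
    set_idx = np.array([gene_index[g] for g in dict.fromkeys(gene_set)])

    X = log_normalize(matrix)
    bin_id = _bin_genes(X.mean(axis=0), params.n_bins)
    rng = np.random.default_rng(params.seed)
    ctrl_idx = _sample_controls(bin_id, set_idx, params.n_ctrl, rng)
    return X[:, set_idx].mean(axis=1) - X[:, ctrl_idx].mean(axis=1)


# ---------------------------------------------------------------------------
# tidy score tables and the USS caller


def score_table(
    matrix: CountMatrix,
    sets: GeneSetCollection | Mapping[str, Sequence[str]],
    method: str = "ssgsea",
    params: ScoringParams | None = None,
) -> pd.DataFrame:
    """Score every set in a collection; tidy table (cell_id, set, score, method).

    With ``method='ssgsea'`` the expensive per-cell ranking is computed once
    and shared across sets.
    """
    params = params or ScoringParams()
    mapping = sets.sets if isinstance(sets, GeneSetCollection) else dict(sets)
    frames = []
    if method == "ssgsea":
        gene_index = {g: i for i, g in enumerate(matrix.gene_ids)}
        X = matrix.dense().T.astype(float)
        n_genes = X.shape[1]
        order = np.argsort(-X, axis=1, kind="stable")
        w = (n_genes - np.arange(n_genes)).astype(float) ** params.alpha
        for name, genes in mapping.items():
            in_set = np.zeros(n_genes, dtype=bool)
            for g in set(genes):
                if g in gene_index:
                    in_set[gene_index[g]] = True
            m = int(in_set.sum())
            if m == 0:
                raise ValueError(f"set {name!r} has empty intersection with matrix genes")
            if m == n_genes:
                raise ValueError(f"set {name!r} covers the entire gene universe")
            hits = in_set[order]
            wh = w[None, :] * hits
            p_in = np.cumsum(wh, axis=1) / wh.sum(axis=1, keepdims=True)
            p_out = np.cumsum(~hits, axis=1) / float(n_genes - m)
            scores = (p_in - p_out).sum(axis=1)
            frames.append(pd.DataFrame(
                {"cell_id": matrix.cell_ids, "set": name, "score": scores,
                 "method": "ssgsea"}))
    elif method == "module":
        for name, genes in mapping.items():
            scores = module_score(matrix, list(genes), params)
            frames.append(pd.DataFrame(
                {"cell_id": matrix.cell_ids, "set": name, "score": scores,
                 "method": "module"}))
    else:
        raise ValueError(f"unknown scoring method {method!r}")
    return pd.concat(frames, ignore_index=True)


def _scores_wide(scores: pd.DataFrame, set_names: Sequence[str]) -> pd.DataFrame:
    if {"cell_id", "set", "score"}.issubset(scores.columns):
        wide = scores.pivot(index="cell_id", columns="set", values="score")
    else:
        wide = scores
    missing = [s for s in set_names if s not in wide.columns]
    if missing:
        raise KeyError(f"missing scored sets: {missing}")
    return wide[list(set_names)]


def uss_call(
    scores: pd.DataFrame,
    annotation: pd.DataFrame,
    k: int = 6,
    set_names: Sequence[str] = USS_SET_NAMES,
) -> pd.DataFrame:
    """Call senescent cells from the six per-set scores via median splits.

    Within each cell type, a set score counts as "upper half" when strictly
    greater than that set's median in that cell type (ties at the median fall
    in the lower half).  A cell is senescent when at least ``k`` of the sets
    are in the upper half.  Cell types with fewer than two cells are skipped
    with a warning.

    Parameters
    ----------
    scores
        Tidy table from :func:`score_table` (or wide cells x sets frame
        indexed by cell_id).
    annotation
        Per-cell metadata with ``cell_id`` and ``cell_type`` columns.
    """
    if not 1 <= k <= len(set_names):
        raise ValueError(f"k must be in 1..{len(set_names)}")
    wide = _scores_wide(scores, set_names)
    ann = annotation.set_index("cell_id")
    cell_types = ann.loc[wide.index, "cell_type"]

    out = []
    for ct, idx in wide.groupby(cell_types).groups.items():
        block = wide.loc[idx]
        if len(block) < 2:
            logger.warning("cell type %r has < 2 cells; skipped by uss_call", ct)
            continue
        above = block.gt(block.median(axis=0), axis=1)
        n_above = above.sum(axis=1)
        calls = pd.DataFrame({
            "cell_id": block.index,
            "cell_type": ct,
            **{f"above_{s}": above[s].to_numpy() for s in set_names},
            "n_sets_above": n_above.to_numpy(),
            "senescent": (n_above >= k).to_numpy(),
            "k": k,
        })
        out.append(calls)
    if not out:
        raise ValueError("no cell type had enough cells to call")
    return pd.concat(out, ignore_index=True)


def uss_fractions(calls: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Senescent fraction per (cell_type, age_group)."""
    ann = annotation.set_index("cell_id")
    merged = calls.assign(age_group=ann.loc[calls["cell_id"], "age_group"].to_numpy())
    grouped = merged.groupby(["cell_type", "age_group"], observed=True)
    out = grouped["senescent"].agg(["mean", "sum", "size"]).reset_index()
    return out.rename(columns={"mean": "fraction", "sum": "n_senescent", "size": "n_cells"})


def z_normalize_scores(scores: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Z-score each set within cell type (reporting aid; monotone per stratum,
    so median-split calls are unchanged)."""
    ann = annotation.set_index("cell_id")
    out = scores.copy()
    ct = ann.loc[out["cell_id"], "cell_type"].to_numpy()
    out["cell_type"] = ct
    grp = out.groupby(["cell_type", "set"], observed=True)["score"]
    out["score_z"] = (out["score"] - grp.transform("mean")) / grp.transform("std").replace(0, 1)
    return out


# ---------------------------------------------------------------------------
# sklearn-style estimators (cells are samples, genes are features)


class SSGSEAScorer(TransformerMixin, BaseEstimator):
    """Transform a cells x genes expression matrix into cells x sets
    running-sum enrichment scores.

    Parameters
    ----------
    gene_sets
        Mapping from set name to gene identifiers.
    gene_ids
        Feature names of the columns of ``X``, in order.
    alpha
        Rank-weight exponent.
    """

    def __init__(self, gene_sets: Mapping[str, Sequence[str]], gene_ids: Sequence[str],
                 alpha: float = 0.25):
        self.gene_sets = gene_sets
        self.gene_ids = gene_ids
        self.alpha = alpha

    def fit(self, X, y=None):
        X = check_array(X, accept_sparse=False)
        if X.shape[1] != len(self.gene_ids):
            raise ValueError("X has a different number of genes than gene_ids")
        index = {g: i for i, g in enumerate(self.gene_ids)}
        self.set_names_ = list(self.gene_sets)
        self.set_masks_ = []
        for name in self.set_names_:
            mask = np.zeros(X.shape[1], dtype=bool)
            for g in set(self.gene_sets[name]):
                if g in index:
                    mask[index[g]] = True
            if not mask.any() or mask.all():
                raise ValueError(f"set {name!r} is empty or covers all genes")
            self.set_masks_.append(mask)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "set_masks_")
        X = check_array(X, accept_sparse=False)
        return np.column_stack(
            [_running_sum_scores(X, mask, self.alpha) for mask in self.set_masks_]
        )

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "set_names_")
        return np.asarray(self.set_names_, dtype=object)


class ModuleScorer(TransformerMixin, BaseEstimator):
    """Binned-control module scores as a transformer over cells x genes counts.

    ``fit`` learns the expression bins and freezes the seeded control draw;
    ``transform`` evaluates the score on (possibly new) cells.
    """

    def __init__(self, gene_sets: Mapping[str, Sequence[str]], gene_ids: Sequence[str],
                 n_bins: int = 24, n_ctrl: int = 100, seed: int = 0, scale: float = 1e4):
        self.gene_sets = gene_sets
        self.gene_ids = gene_ids
        self.n_bins = n_bins
        self.n_ctrl = n_ctrl
        self.seed = seed
        self.scale = scale

    def _lognorm(self, X: np.ndarray) -> np.ndarray:
        lib = X.sum(axis=1, keepdims=True)
        lib[lib == 0] = 1.0
        return np.log1p(X / lib * self.scale)

    def fit(self, X, y=None):
        X = check_array(X, accept_sparse=False)
        if self.n_bins > X.shape[1]:
            raise ValueError("n_bins exceeds the number of genes")
        index = {g: i for i, g in enumerate(self.gene_ids)}
        L = self._lognorm(X.astype(float))
        bin_id = _bin_genes(L.mean(axis=0), self.n_bins)
        rng = np.random.default_rng(self.seed)
        self.set_names_ = list(self.gene_sets)
        self.set_idx_, self.ctrl_idx_ = [], []
        for name in self.set_names_:
            genes = list(dict.fromkeys(self.gene_sets[name]))
            if not genes:
                raise ValueError(f"set {name!r} is empty")
            missing = [g for g in genes if g not in index]
            if missing:
                raise KeyError(f"set {name!r} genes absent from matrix: {missing[:5]}")
            idx = np.array([index[g] for g in genes])
            self.set_idx_.append(idx)
            self.ctrl_idx_.append(_sample_controls(bin_id, idx, self.n_ctrl, rng))
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "set_idx_")
        X = check_array(X, accept_sparse=False)
        L = self._lognorm(X.astype(float))
        return np.column_stack([
            L[:, si].mean(axis=1) - L[:, ci].mean(axis=1)
            for si, ci in zip(self.set_idx_, self.ctrl_idx_)
        ])

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "set_names_")
        return np.asarray(self.set_names_, dtype=object)


class SenescenceCaller(BaseEstimator):
    """Median-split senescence caller over per-set score columns.

    ``fit`` learns per-cell-type, per-set medians from a cells x sets score
    matrix; ``predict`` flags cells with at least ``k`` scores strictly above
    their medians.
    """

    def __init__(self, k: int = 6):
        self.k = k

    def fit(self, X, cell_types):
        X = check_array(X, accept_sparse=False)
        cell_types = np.asarray(cell_types)
        if len(cell_types) != X.shape[0]:
            raise ValueError("cell_types length does not match X")
        if not 1 <= self.k <= X.shape[1]:
            raise ValueError(f"k must be in 1..{X.shape[1]}")
        self.medians_ = {
            ct: np.median(X[cell_types == ct], axis=0) for ct in np.unique(cell_types)
        }
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X, cell_types) -> np.ndarray:
        """Number of sets strictly above their (cell-type) median, per cell."""
        check_is_fitted(self, "medians_")
        X = check_array(X, accept_sparse=False)
        cell_types = np.asarray(cell_types)
        n_above = np.zeros(X.shape[0], dtype=int)
        for ct, med in self.medians_.items():
            mask = cell_types == ct
            n_above[mask] = (X[mask] > med).sum(axis=1)
        return n_above

    def predict(self, X, cell_types) -> np.ndarray:
        return self.decision_function(X, cell_types) >= self.k
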