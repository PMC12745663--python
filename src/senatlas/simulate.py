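"""Synthetic multi-sample, multi-cell-type UMI count generator.

Emulates the statistical structure the downstream senescence pipeline
assumes: negative-binomial UMI counts over a log-normal baseline expression
profile, cell-type marker programs, planted senescent subpopulations that
over-express six senescence gene sets, age-shifted cell-type composition,
age-increased NB dispersion, and a mitochondrial fraction with a
heavy-tailed contaminant component for the MAD filter to catch.  Ground
truth (per-cell senescent flags, planted fold changes and dispersion
multipliers) is returned for parameter-recovery tests.

Counts are drawn gene-wise NB(mean = library-size-scaled profile x cell-type
factor x senescence fold on set genes, dispersion per age group) via the
gamma-Poisson mixture.  The cell-type marker fold is renormalised inside the
type profile so library sizes stay on target across types; the senescence
fold is deliberately not renormalised, so flagged cells carry the extra
set-gene mass and the planted fold is recovered exactly in expectation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import AGE_GROUPS, USS_SET_NAMES, CountMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = ["SimDesign", "SimTruth", "generate", "plant_expression_check"]

#: Mouse mitochondrial protein-coding gene symbols (the ``mt-`` prefix drives
#: the QC mito flag).
MOUSE_MT_GENES = (
    "mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Atp8", "mt-Atp6", "mt-Co3",
    "mt-Nd3", "mt-Nd4l", "mt-Nd4", "mt-Nd5", "mt-Nd6", "mt-Cytb",
)


def _default_proportions() -> dict:
    return {
        "young": {"Stromal": 0.50, "Epithelial": 0.20, "NKT": 0.20, "Macrophage": 0.10},
        "aged": {"Stromal": 0.40, "Epithelial": 0.25, "NKT": 0.20, "Macrophage": 0.15},
    }


def _default_senescent() -> dict:
    return {"Stromal": {"young": 0.03, "aged": 0.10}}


@dataclass
class SimDesign:
    """Full specification of one simulated dataset.

    Defaults describe a desk-scale study: 2,000 genes, four endometrial cell
    types, three samples per age group of 500 cells, a 3-fold senescence
    program on all six sets, senescent stroma rising from 3% (young, 3 mo)
    to 10% (aged, 12 mo), and a 1.5x aged NB dispersion.
    """

    n_genes: int = 2000
    set_sizes: dict = field(default_factory=lambda: {s: 50 for s in USS_SET_NAMES})
    set_overlap: float = 0.10
    cell_types: tuple = ("Stromal", "Epithelial", "NKT", "Macrophage")
    proportions: dict = field(default_factory=_default_proportions)
    n_samples: dict = field(default_factory=lambda: {"young": 3, "aged": 3})
    cells_per_sample: int = 500
    profile_sigma: float = 1.5
    base_dispersion: float = 0.25
    dispersion_mult: dict = field(default_factory=lambda: {"young": 1.0, "aged": 1.5})
    senescent_fraction: dict = field(default_factory=_default_senescent)
    effect_size: float = 3.0
    n_mito: int = 13
    mito_beta: tuple = (10.0, 190.0)  # mean 5% baseline mito fraction
    mito_contaminant_frac: float = 0.03
    mito_contaminant_beta: tuple = (8.0, 12.0)  # mean 40%, caught by the MAD rule
    libsize_mean: float = 5000.0
    libsize_sigma: float = 0.35
    n_markers_per_type: int = 40
    marker_fold: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.cells_per_sample <= 0:
            raise ValueError("degenerate design: need > 0 genes and cells")
        if not 1 <= self.n_mito <= len(MOUSE_MT_GENES):
            raise ValueError(f"n_mito must be in 1..{len(MOUSE_MT_GENES)}")
        if self.effect_size < 1:
            raise ValueError("effect_size must be >= 1")
        if self.base_dispersion <= 0 or any(m <= 0 for m in self.dispersion_mult.values()):
            raise ValueError("dispersions must be > 0")
        for age in self.n_samples:
            if age not in AGE_GROUPS:
                raise ValueError(f"unknown age group {age!r}")
            props = self.proportions.get(age)
            if props is None or set(props) != set(self.cell_types):
                raise ValueError(f"proportions for {age!r} must cover all cell types")
            total = sum(props.values())
            if not np.isclose(total, 1.0):
                raise ValueError(f"proportions for {age!r} sum to {total}, not 1")
        for ct, by_age in self.senescent_fraction.items():
            if ct not in self.cell_types:
                raise ValueError(f"senescent_fraction for unknown cell type {ct!r}")
            for f in by_age.values():
                if not 0 <= f <= 1:
                    raise ValueError("senescent fractions must be in [0, 1]")
        reserved = (
            sum(self.set_sizes.values())
            + self.n_markers_per_type * len(self.cell_types)
            + self.n_mito
        )
        if reserved >= self.n_genes:
            raise ValueError(
                f"n_genes={self.n_genes} too small for {reserved} set/marker/mito genes"
            )


@dataclass
class SimTruth:
    """Generator ground truth for parameter-recovery tests."""

    cells: pd.DataFrame  # cell_id, sample_id, age_group, cell_type, senescent
    planted_fractions: pd.DataFrame  # cell_type, age_group, fraction
    composition_log2fc: pd.DataFrame  # cell_type, log2_fc (aged vs young)
    dispersion_mult: dict
    effect_size: float
    marker_genes: dict


def generate(
    design: SimDesign | None = None,
) -> tuple[CountMatrix, pd.DataFrame, GeneSetCollection, SimTruth]:
    """Simulate one dataset; identical seeds give bit-identical outputs.

    Returns the genes x cells count matrix, the per-cell annotation table,
    the six-senescence-set collection, and the ground truth.
    """
    design = design or SimDesign()
    design.validate()
    rng = np.random.default_rng(design.seed)

    # -- genes ------------------------------------------------------------
    n_mito = design.n_mito
    mito_names = np.array(MOUSE_MT_GENES[:n_mito], dtype=object)
    n_nuclear = design.n_genes - n_mito
    nuclear_names = np.array([f"Gene{i:05d}" for i in range(n_nuclear)], dtype=object)
    gene_names = np.concatenate([nuclear_names, mito_names])
    mito_idx = np.arange(n_nuclear, design.n_genes)
    nuclear_idx = np.arange(n_nuclear)

    # senescence sets and cell-type marker programs live on nuclear genes
    candidates = rng.permutation(nuclear_idx)
    total_set = sum(design.set_sizes.values())
    n_shared = int(round(design.set_overlap * min(design.set_sizes.values())))
    shared = candidates[:n_shared]
    cursor = n_shared
    sets = {}
    for name, size in design.set_sizes.items():
        own = candidates[cursor: cursor + size - n_shared]
        cursor += size - n_shared
        sets[name] = gene_names[np.concatenate([shared, own])].tolist()
    set_union = np.unique(np.concatenate(
        [shared] + [candidates[n_shared:cursor]]
    ))
    marker_genes: dict[str, np.ndarray] = {}
    for ct in design.cell_types:
        marker_genes[ct] = candidates[cursor: cursor + design.n_markers_per_type]
        cursor += design.n_markers_per_type
    collection = GeneSetCollection(sets)

    # -- baseline expression ----------------------------------------------
    rel = rng.lognormal(0.0, design.profile_sigma, design.n_genes)
    mito_profile = rel[mito_idx] / rel[mito_idx].sum()
    type_profiles = np.empty((len(design.cell_types), n_nuclear))
    for t, ct in enumerate(design.cell_types):
        r = rel[nuclear_idx].copy()
        r[marker_genes[ct]] *= design.marker_fold
        type_profiles[t] = r / r.sum()

    # -- cells -------------------------------------------------------------
    ages, samples, types, flags, cell_ids = [], [], [], [], []
    for age, n_samp in design.n_samples.items():
        props = np.array([design.proportions[age][ct] for ct in design.cell_types])
        for s in range(n_samp):
            sample_id = f"{age}{s + 1}"
            ct_idx = rng.choice(len(design.cell_types), size=design.cells_per_sample, p=props)
            for i, t in enumerate(ct_idx):
                ct = design.cell_types[t]
                frac = design.senescent_fraction.get(ct, {}).get(age, 0.0)
                flag = bool(rng.random() < frac) if frac > 0 else False
                ages.append(age)
                samples.append(sample_id)
                types.append(t)
                flags.append(flag)
                cell_ids.append(f"{sample_id}_c{i:04d}")
    n_cells = len(cell_ids)
    type_arr = np.array(types)
    flag_arr = np.array(flags, dtype=bool)
    age_arr = np.array(ages, dtype=object)

    # -- expression probabilities per cell ---------------------------------
    # mito fraction: Beta baseline with a heavy-tailed contaminant component
    a0, b0 = design.mito_beta
    a1, b1 = design.mito_contaminant_beta
    contam = rng.random(n_cells) < design.mito_contaminant_frac
    mito_frac = np.where(
        contam, rng.beta(a1, b1, n_cells), rng.beta(a0, b0, n_cells)
    )
    P = np.empty((n_cells, design.n_genes))
    P[:, nuclear_idx] = type_profiles[type_arr] * (1.0 - mito_frac)[:, None]
    P[:, mito_idx] = mito_profile[None, :] * mito_frac[:, None]
    if flag_arr.any():
        P[np.ix_(flag_arr, set_union)] *= design.effect_size

    # -- NB sampling (gamma-Poisson) ---------------------------------------
    lib = rng.lognormal(np.log(design.libsize_mean), design.libsize_sigma, n_cells)
    mu = P * lib[:, None]
    mult = np.array([design.dispersion_mult[a] for a in age_arr])
    phi = (design.base_dispersion * mult)[:, None]
    lam = rng.gamma(np.broadcast_to(1.0 / phi, mu.shape), mu * phi)
    counts = rng.poisson(lam).astype(np.int64)

    matrix = CountMatrix(
        counts=sp.csr_matrix(counts.T),  # genes x cells
        gene_ids=gene_names,
        cell_ids=np.array(cell_ids, dtype=object),
    )
    annotation = pd.DataFrame({
        "cell_id": cell_ids,
        "sample_id": samples,
        "age_group": pd.Categorical(ages, categories=list(AGE_GROUPS)),
        "cell_type": [design.cell_types[t] for t in types],
    })

    planted = [
        {"cell_type": ct, "age_group": age,
         "fraction": design.senescent_fraction.get(ct, {}).get(age, 0.0)}
        for ct in design.cell_types for age in design.n_samples
    ]
    comp_rows = []
    if {"young", "aged"} <= set(design.n_samples):
        for ct in design.cell_types:
            comp_rows.append({
                "cell_type": ct,
                "log2_fc": float(np.log2(
                    design.proportions["aged"][ct] / design.proportions["young"][ct]
                )),
            })
    truth = SimTruth(
        cells=annotation.assign(senescent=flag_arr),
        planted_fractions=pd.DataFrame(planted),
        composition_log2fc=pd.DataFrame(comp_rows),
        dispersion_mult=dict(design.dispersion_mult),
        effect_size=design.effect_size,
        marker_genes={ct: gene_names[idx].tolist() for ct, idx in marker_genes.items()},
    )
    return matrix, annotation, collection, truth


def plant_expression_check(
    matrix: CountMatrix,
    truth: SimTruth,
    sets: GeneSetCollection,
) -> pd.DataFrame:
    """Self-validation: per (cell type, set), the ratio of mean set-gene
    counts in flagged vs unflagged cells, which should sit near the planted
    effect size.  Strata without flagged cells are skipped with a warning."""
    gene_index = {g: i for i, g in enumerate(matrix.gene_ids)}
    cells = truth.cells.set_index("cell_id").loc[list(matrix.cell_ids)]
    dense = matrix.dense()
    rows = []
    for ct in cells["cell_type"].unique():
        mask_ct = (cells["cell_type"] == ct).to_numpy()
        flagged = mask_ct & cells["senescent"].to_numpy()
        unflagged = mask_ct & ~cells["senescent"].to_numpy()
        if not flagged.any() or not unflagged.any():
            logger.warning("cell type %r has an empty flagged/unflagged stratum; skipped", ct)
            continue
        for name, genes in sets.sets.items():
            idx = [gene_index[g] for g in genes if g in gene_index]
            set_sum = dense[idx, :].sum(axis=0)
            rows.append({
                "cell_type": ct,
                "set": name,
                "ratio": float(set_sum[flagged].mean() / set_sum[unflagged].mean()),
                "n_flagged": int(flagged.sum()),
                "n_unflagged": int(unflagged.sum()),
            })
    return pd.DataFrame(rows)
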