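"""Core data containers and readers/writers for the standard on-disk formats.

The pipeline's universal input is a sparse genes x cells UMI count matrix
(10x-style MatrixMarket trio), a per-cell metadata table (sample, age group,
cell type) and gene sets in GMT format.  Internally genes are always rows;
readers transpose as needed based on the sidecar line counts.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

__all__ = [
    "CountMatrix",
    "GeneSetCollection",
    "PipelineConfig",
    "USS_SET_NAMES",
    "AGE_GROUPS",
    "mito_flags_from_prefix",
    "read_mtx_triplet",
    "write_mtx_triplet",
    "read_gmt",
    "write_gmt",
    "read_cell_metadata",
    "write_cell_metadata",
]

#: The six gene sets integrated by the unified senescence score: SenMayo,
#: CellAge, GenAge, the Senescence Eigengene, SASP and inflammatory response.
USS_SET_NAMES = ("SM", "CA", "GA", "SE", "SASP", "IR")

#: Valid age-group levels (mouse ages 3 / 8 / 12 months).
AGE_GROUPS = ("young", "middle", "aged")

#: Month aliases accepted in metadata files.
_AGE_ALIASES = {
    "3": "young", "3m": "young", "3month": "young", "3months": "young",
    "8": "middle", "8m": "middle", "8month": "middle", "8months": "middle",
    "12": "aged", "12m": "aged", "12month": "aged", "12months": "aged",
}


def mito_flags_from_prefix(gene_symbols: Sequence[str], prefix: str = "mt-") -> np.ndarray:
    """Flag mitochondrial genes by a case-insensitive symbol prefix."""
    p = prefix.lower()
    return np.array([str(g).lower().startswith(p) for g in gene_symbols], dtype=bool)


@dataclass
class CountMatrix:
    """Sparse genes x cells UMI count matrix with identifiers and mito flags.

    Parameters
    ----------
    counts
        Non-negative integer sparse matrix, genes as rows, cells as columns.
    gene_ids, cell_ids
        Unique string identifiers for rows and columns.
    mito_flags
        Boolean per gene; derived from ``gene_ids`` with the default ``mt-``
        prefix when not supplied.
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    mito_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.mito_flags is None:
            self.mito_flags = mito_flags_from_prefix(self.gene_ids)
        self.mito_flags = np.asarray(self.mito_flags, dtype=bool)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(self.mito_flags) != len(self.gene_ids):
            raise ValueError("mito_flags length does not match gene count")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell identifiers")
        data = self.counts.data
        if data.size:
            if data.min() < 0:
                raise ValueError("counts contain negative entries")
            if not np.allclose(data, np.round(data)):
                raise ValueError("counts contain non-integer entries")

    # -- basic summaries -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> np.ndarray:
        """Total UMIs per cell."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def genes_detected(self) -> np.ndarray:
        """Number of genes with count > 0 per cell."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def cells_expressing(self) -> np.ndarray:
        """Number of cells with count > 0 per gene."""
        return np.asarray((self.counts > 0).sum(axis=1)).ravel()

    def mito_fractions(self) -> np.ndarray:
        """Per-cell fraction of UMIs on mitochondrial genes (0 where library 0)."""
        lib = self.library_sizes().astype(float)
        mito = np.asarray(self.counts[self.mito_flags, :].sum(axis=0)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(lib > 0, mito / lib, 0.0)
        return frac

    # -- subsetting ------------------------------------------------------
    def subset_cells(self, index: np.ndarray) -> "CountMatrix":
        return CountMatrix(
            self.counts[:, index], self.gene_ids, self.cell_ids[index], self.mito_flags
        )

    def subset_genes(self, index: np.ndarray) -> "CountMatrix":
        return CountMatrix(
            self.counts[index, :], self.gene_ids[index], self.cell_ids, self.mito_flags[index]
        )

    def dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())

    def to_anndata(self):
        """Cells x genes AnnData view (requires anndata)."""
        import anndata

        return anndata.AnnData(
            X=self.counts.T.tocsr(),
            obs=pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id")),
            var=pd.DataFrame(
                {"mito": self.mito_flags}, index=pd.Index(self.gene_ids, name="gene_id")
            ),
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-backed); duplicate genes within a set are collapsed."""

    sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        clean: dict[str, list[str]] = {}
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            seen: dict[str, None] = {}
            for g in genes:
                seen.setdefault(str(g))
            clean[str(name)] = list(seen)
        self.sets = clean

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)

    def require(self, names: Iterable[str] = USS_SET_NAMES) -> None:
        missing = [n for n in names if n not in self.sets]
        if missing:
            raise KeyError(f"missing required gene sets: {missing}")


@dataclass
class PipelineConfig:
    """Bundle of pipeline parameters with a single global seed.

    Sections mirror the pipeline stages; each maps onto that stage's
    parameter dataclass.  All stochastic operations draw their seed from
    here unless given one explicitly.
    """

    qc: dict = field(default_factory=dict)
    scoring: dict = field(default_factory=dict)
    noise: dict = field(default_factory=dict)
    composition: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (isinstance(self.seed, (int, np.integer)) and self.seed >= 0):
            raise ValueError("seed must be a non-negative integer")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"qc": self.qc, "scoring": self.scoring, "noise": self.noise,
                 "composition": self.composition, "seed": int(self.seed)},
                fh,
            )


# ---------------------------------------------------------------------------
# readers / writers


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _read_lines(path: str | Path) -> list[str]:
    with _open_text(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def read_mtx_triplet(
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
    mito_prefix: str = "mt-",
) -> CountMatrix:
    """Read a 10x-style MatrixMarket trio into a genes x cells CountMatrix.

    Orientation is inferred from the sidecar line counts: whichever matrix
    axis matches the features file becomes the gene axis.  Features files may
    carry one column (symbol) or the 10x ``id<TAB>symbol[<TAB>type]`` layout;
    mito flags are derived from the symbol column.
    """
    mat = scipy.io.mmread(str(matrix_path))
    feat_lines = _read_lines(features_path)
    barcodes = _read_lines(barcodes_path)
    n_feat, n_bar = len(feat_lines), len(barcodes)

    if mat.shape == (n_feat, n_bar):
        pass
    elif mat.shape == (n_bar, n_feat):
        mat = mat.T
    else:
        raise ValueError(
            f"matrix shape {mat.shape} matches neither features x barcodes "
            f"({n_feat} x {n_bar}) nor its transpose"
        )

    mat = sp.csr_matrix(mat)
    if mat.data.size and not np.allclose(mat.data, np.round(mat.data)):
        raise ValueError("matrix contains non-integer values")
    mat.data = np.round(mat.data).astype(np.int64)

    fields = [line.split("\t") for line in feat_lines]
    gene_ids = np.array([f[0] for f in fields], dtype=object)
    symbols = [f[1] if len(f) > 1 else f[0] for f in fields]
    return CountMatrix(
        counts=mat,
        gene_ids=gene_ids,
        cell_ids=np.array(barcodes, dtype=object),
        mito_flags=mito_flags_from_prefix(symbols, mito_prefix),
    )


def write_mtx_triplet(matrix: CountMatrix, out_dir: str | Path) -> None:
    """Write the MTX trio (matrix.mtx, features.tsv, barcodes.tsv)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(out / "matrix.mtx"), sp.coo_matrix(matrix.counts))
    with open(out / "features.tsv", "w") as fh:
        for g in matrix.gene_ids:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    with open(out / "barcodes.tsv", "w") as fh:
        for c in matrix.cell_ids:
            fh.write(f"{c}\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>genes...``."""
    sets: dict[str, list[str]] = {}
    for i, line in enumerate(_read_lines(path), start=1):
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"GMT line {i} has fewer than 3 tab-separated fields")
        name = parts[0]
        if name in sets:
            raise ValueError(f"duplicate gene set name {name!r} (line {i})")
        sets[name] = parts[2:]
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


_META_COLUMNS = ("cell_id", "sample_id", "age_group", "cell_type")


def read_cell_metadata(path: str | Path) -> pd.DataFrame:
    """Read the per-cell metadata TSV (cell_id, sample_id, age_group, cell_type).

    Age groups are validated against ``young/middle/aged``; mouse ages in
    months (3/8/12) are accepted as aliases and mapped to the levels.
    """
    meta = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata is missing required columns: {missing}")
    if meta["cell_id"].duplicated().any():
        dups = meta.loc[meta["cell_id"].duplicated(), "cell_id"].tolist()[:5]
        raise ValueError(f"duplicated cell_id values, e.g. {dups}")
    age = meta["age_group"].str.strip().str.lower().replace(_AGE_ALIASES)
    bad = sorted(set(age) - set(AGE_GROUPS))
    if bad:
        raise ValueError(f"unknown age_group level(s) {bad}; expected {AGE_GROUPS}")
    meta = meta.copy()
    meta["age_group"] = pd.Categorical(age, categories=list(AGE_GROUPS))
    return meta


def write_cell_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def validate_annotation(matrix: CountMatrix, meta: pd.DataFrame) -> pd.DataFrame:
    """Check every matrix cell is annotated and return metadata in matrix order."""
    meta = meta.set_index("cell_id", drop=False)
    missing = [c for c in matrix.cell_ids if c not in meta.index]
    if missing:
        raise ValueError(f"{len(missing)} cells lack metadata, e.g. {missing[:5]}")
    return meta.loc[list(matrix.cell_ids)].reset_index(drop=True)
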