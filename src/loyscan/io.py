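"""Sparse count-bundle and annotation table I/O.

The on-disk layout follows the dominant droplet single-cell convention:
MatrixMarket coordinate files with genes as rows and cells as columns
(1-based indices), a ``features.tsv`` giving the gene axis and a
``barcodes.tsv`` giving the cell axis.  Multi-layer bundles (spliced /
unspliced / ambiguous transcript counts, as produced by intron-aware
quantification) store one ``<layer>.mtx`` per layer sharing both axes;
a single-layer bundle uses the classic name ``matrix.mtx``.  Gzipped
matrices (``.mtx.gz``) are read transparently.
"""

from __future__ import annotations

import gzip
import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountBundle",
    "GeneAnnotation",
    "CellMetadata",
    "FormatError",
    "read_mtx_bundle",
    "write_mtx_bundle",
    "load_gene_annotation",
    "default_gene_annotation",
    "load_cell_metadata",
]

LAYER_NAMES = ("spliced", "unspliced", "ambiguous", "total")

FEATURE_COLUMNS = ["id", "symbol", "chromosome", "is_msy", "is_par", "is_mito"]


class FormatError(ValueError):
    """A file parsed, but its content violates the bundle contract."""


@dataclass
class CountBundle:
    """Sparse nonnegative-integer gene × cell count matrices with named layers.

    Parameters
    ----------
    genes
        Ordered gene identifiers (rows of every layer).
    cells
        Ordered cell barcodes (columns of every layer).
    layers
        Mapping layer name -> CSR matrix of shape ``(n_genes, n_cells)``.
        If no ``"total"`` layer is stored, :attr:`total` is the elementwise
        sum of the present layers.
    gene_symbols
        Optional gene symbols aligned with ``genes`` (defaults to the ids).
    """

    genes: np.ndarray
    cells: np.ndarray
    layers: dict[str, sp.csr_matrix]
    gene_symbols: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.cells = np.asarray(self.cells, dtype=object)
        if not self.layers:
            raise FormatError("a CountBundle needs at least one layer")
        clean: dict[str, sp.csr_matrix] = {}
        for name, mat in self.layers.items():
            mat = sp.csr_matrix(mat)
            if mat.shape != (self.n_genes, self.n_cells):
                raise FormatError(
                    f"layer {name!r} has shape {mat.shape}, expected "
                    f"({self.n_genes}, {self.n_cells})"
                )
            if mat.nnz and mat.data.min() < 0:
                raise FormatError(f"layer {name!r} contains negative counts")
            if not np.issubdtype(mat.dtype, np.integer):
                if mat.nnz and np.any(mat.data != np.round(mat.data)):
                    raise FormatError(f"layer {name!r} contains non-integer counts")
                mat = mat.astype(np.int64)
            clean[name] = mat
        self.layers = clean
        if len(set(self.genes)) != self.n_genes:
            raise FormatError("duplicate gene ids")
        if len(set(self.cells)) != self.n_cells:
            raise FormatError("duplicate cell barcodes")
        if self.gene_symbols is None:
            self.gene_symbols = self.genes.copy()
        else:
            self.gene_symbols = np.asarray(self.gene_symbols, dtype=object)
            if self.gene_symbols.shape != self.genes.shape:
                raise FormatError("gene_symbols length differs from genes")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def total(self) -> sp.csr_matrix:
        """Total counts: the stored ``total`` layer or the sum of all layers."""
        if "total" in self.layers:
            return self.layers["total"]
        mats = list(self.layers.values())
        out = mats[0]
        for m in mats[1:]:
            out = out + m
        return sp.csr_matrix(out)

    def layer_sum(self, names: list[str] | None = None) -> sp.csr_matrix:
        """Elementwise sum over the named layers (all layers if ``None``)."""
        if names is None:
            return self.total
        missing = [n for n in names if n not in self.layers]
        if missing:
            if names == ["total"] or names == ("total",):
                return self.total
            raise KeyError(f"unknown layers: {missing}")
        out = self.layers[names[0]]
        for n in names[1:]:
            out = out + self.layers[n]
        return sp.csr_matrix(out)

    def library_sizes(self) -> np.ndarray:
        """Per-cell total UMI counts over all layers."""
        return np.asarray(self.total.sum(axis=0)).ravel()

    def subset_cells(self, mask: np.ndarray) -> "CountBundle":
        """Return a bundle restricted to the cells selected by a boolean mask."""
        mask = np.asarray(mask, dtype=bool)
        return CountBundle(
            genes=self.genes,
            cells=self.cells[mask],
            layers={k: sp.csr_matrix(v[:, mask]) for k, v in self.layers.items()},
            gene_symbols=self.gene_symbols,
        )

    def equals(self, other: "CountBundle") -> bool:
        if (
            not np.array_equal(self.genes, other.genes)
            or not np.array_equal(self.cells, other.cells)
            or set(self.layers) != set(other.layers)
        ):
            return False
        return all((self.layers[k] != other.layers[k]).nnz == 0 for k in self.layers)


@dataclass
class GeneAnnotation:
    """Per-gene chromosome and region flags.

    ``is_msy`` marks genes in the male-specific region of the Y chromosome;
    ``is_par`` marks pseudoautosomal genes shared between X and Y.  A gene
    cannot carry both flags: PAR genes retain one expressed copy after loss
    of the Y and must never count towards MSY expression.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in FEATURE_COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(f"gene annotation missing columns: {missing}")
        tab = self.table.copy()
        for col in ("is_msy", "is_par", "is_mito"):
            tab[col] = tab[col].astype(int).astype(bool)
        if tab["id"].duplicated().any():
            dupes = tab.loc[tab["id"].duplicated(), "id"].tolist()
            raise FormatError(f"duplicate gene ids in annotation: {dupes[:5]}")
        both = tab["is_msy"] & tab["is_par"]
        if both.any():
            bad = tab.loc[both, "id"].tolist()
            raise FormatError(
                f"genes flagged both MSY and PAR (mutually exclusive): {bad[:5]}"
            )
        self.table = tab.set_index("id", drop=False)

    @property
    def msy_genes(self) -> list[str]:
        return self.table.loc[self.table["is_msy"], "id"].tolist()

    @property
    def par_genes(self) -> list[str]:
        return self.table.loc[self.table["is_par"], "id"].tolist()

    @property
    def mito_genes(self) -> list[str]:
        return self.table.loc[self.table["is_mito"], "id"].tolist()

    def flags_for(self, gene_ids: np.ndarray, column: str) -> np.ndarray:
        """Boolean flag vector aligned to ``gene_ids`` (absent genes -> False)."""
        flagged = set(self.table.loc[self.table[column], "id"])
        return np.array([g in flagged for g in gene_ids], dtype=bool)


@dataclass
class CellMetadata:
    """Per-cell sample of origin, donor sex, cluster and optional labels."""

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("barcode", "sample_id", "sex", "cluster")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise FormatError(f"cell metadata missing columns: {missing}")
        tab = self.table.copy()
        if tab["barcode"].duplicated().any():
            raise FormatError("duplicate barcodes in cell metadata")
        bad_sex = set(tab["sex"].dropna()) - {"male", "female"}
        if bad_sex:
            raise FormatError(f"sex must be 'male' or 'female', got {sorted(bad_sex)}")
        self.table = tab.set_index("barcode", drop=False)

    def aligned_to(self, cells: np.ndarray) -> pd.DataFrame:
        """Metadata rows in bundle cell order; every barcode must be present."""
        missing = [c for c in cells if c not in self.table.index]
        if missing:
            raise FormatError(
                f"{len(missing)} bundle barcodes absent from metadata "
                f"(first: {missing[:3]})"
            )
        return self.table.loc[list(cells)]


# ---------------------------------------------------------------------------
# readers / writers


def _open_maybe_gz(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _find_layer_file(directory: Path, layer: str) -> Path:
    candidates = [directory / f"{layer}.mtx", directory / f"{layer}.mtx.gz"]
    if layer == "total":
        candidates += [directory / "matrix.mtx", directory / "matrix.mtx.gz"]
    for cand in candidates:
        if cand.exists():
            return cand
    raise FileNotFoundError(
        f"no matrix file for layer {layer!r} in {directory} "
        f"(looked for {[c.name for c in candidates]})"
    )


def read_mtx_bundle(directory: str | Path, layer_names: list[str] | None = None) -> CountBundle:
    """Read a MatrixMarket bundle (one ``.mtx`` per layer plus shared axes).

    Parameters
    ----------
    directory
        Directory holding ``<layer>.mtx[.gz]`` (or ``matrix.mtx`` for a
        single ``total`` layer), ``features.tsv`` and ``barcodes.tsv``.
    layer_names
        Layers to read; default ``["total"]``.
    """
    directory = Path(directory)
    if layer_names is None:
        layer_names = ["total"]
    feat_path = directory / "features.tsv"
    bc_path = directory / "barcodes.tsv"
    for p in (feat_path, bc_path):
        if not p.exists():
            raise FileNotFoundError(f"missing axis file: {p}")
    features = pd.read_csv(feat_path, sep="\t", dtype=str)
    if "id" not in features.columns:
        raise FormatError(f"{feat_path} lacks an 'id' column")
    with open(bc_path) as fh:
        barcodes = [ln.strip() for ln in fh if ln.strip()]
    # barcodes.tsv has no header: a single column of barcodes
    layers = {}
    for layer in layer_names:
        path = _find_layer_file(directory, layer)
        with _open_maybe_gz(path) as fh:
            mat = scipy.io.mmread(fh)
        mat = sp.csr_matrix(mat)
        if mat.shape[0] != len(features):
            raise FormatError(
                f"{path.name}: {mat.shape[0]} rows but {len(features)} features"
            )
        if mat.shape[1] != len(barcodes):
            raise FormatError(
                f"{path.name}: {mat.shape[1]} columns but {len(barcodes)} barcodes"
            )
        layers[layer] = mat
    symbols = features["symbol"].to_numpy() if "symbol" in features else None
    return CountBundle(
        genes=features["id"].to_numpy(),
        cells=np.array(barcodes, dtype=object),
        layers=layers,
        gene_symbols=symbols,
    )


def write_mtx_bundle(
    bundle: CountBundle,
    directory: str | Path,
    annotation: GeneAnnotation | None = None,
) -> Path:
    """Write a bundle as 1-based MatrixMarket coordinate files plus TSV axes.

    Entry order within each matrix is column-major (all entries of cell 1,
    then cell 2, ...), so repeated writes of equal bundles are byte-identical.
    When an annotation is supplied the features file carries the full flag
    columns; otherwise only ``id`` and ``symbol``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for layer, mat in bundle.layers.items():
        name = "matrix.mtx" if layer == "total" and len(bundle.layers) == 1 else f"{layer}.mtx"
        coo = sp.coo_matrix(mat.tocsc())  # csc -> column-major entry order
        with open(directory / name, "wb") as fh:
            scipy.io.mmwrite(fh, coo, field="integer")
    feats = pd.DataFrame({"id": bundle.genes, "symbol": bundle.gene_symbols})
    if annotation is not None:
        ann = annotation.table.reindex(bundle.genes)
        feats["chromosome"] = ann["chromosome"].fillna("unknown").to_numpy()
        for col in ("is_msy", "is_par", "is_mito"):
            feats[col] = ann[col].fillna(False).astype(int).to_numpy()
    feats.to_csv(directory / "features.tsv", sep="\t", index=False)
    with open(directory / "barcodes.tsv", "w") as fh:
        fh.write("\n".join(map(str, bundle.cells)) + "\n")
    return directory


def load_gene_annotation(path: str | Path) -> GeneAnnotation:
    """Load and validate a gene-annotation TSV (columns: id, symbol,
    chromosome, is_msy, is_par, is_mito)."""
    table = pd.read_csv(path, sep="\t", dtype={"id": str, "symbol": str, "chromosome": str})
    return GeneAnnotation(table)


def default_gene_annotation() -> GeneAnnotation:
    """The packaged annotation of canonical MSY / PAR / mitochondrial genes.

    Ships a frozen list of the expressed male-specific-region genes
    (RPS4Y1, DDX3Y, EIF1AY, UTY, KDM5D, USP9Y, ZFY, NLGN4Y, TMSB4Y),
    the pseudoautosomal gene CD99 and the common mitochondrial transcripts;
    users working from a richer gene model should supply their own table.
    """
    with importlib.resources.as_file(
        importlib.resources.files("loyscan.data") / "gene_annotation.tsv"
    ) as path:
        return load_gene_annotation(path)


def load_cell_metadata(path: str | Path) -> CellMetadata:
    """Load a per-cell metadata TSV (barcode, sample_id, sex, cluster, ...)."""
    table = pd.read_csv(path, sep="\t", dtype={"barcode": str, "sample_id": str, "cluster": str})
    return CellMetadata(table)
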