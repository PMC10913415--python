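"""Per-cell LOY calling and cluster-level MSY adequacy scoring.

Two complementary calling rules are provided.

**Zero rule** — for deep, clean UMI data: a male cell is called LOY iff it
has zero reads from male-specific-region (MSY) genes across all requested
layers (spliced, unspliced and ambiguous transcript counts all participate).
The rule is exact for true-LOY cells (a cell without a Y cannot produce MSY
transcripts) and its specificity is governed by dropout: it requires MSY
coverage deep enough that a normal cell is very unlikely to show zero MSY
reads by chance.

**Female-background threshold rule** — for noisier data where female cells
show technical MSY background: the 95th quantile of total MSY expression
among female cells *with any MSY expression* defines a noise ceiling, and a
male cell is called LOY iff its total MSY expression is strictly below that
ceiling *and* comes from at most one MSY gene (real Y-bearing cells express
several MSY genes, background rarely does).

Cells from female donors are never assessed: they carry no Y to lose, and
keeping them out of the calls keeps downstream denominators honest.

The cluster MSY score quantifies whether a cluster expresses enough MSY to
make LOY calls trustworthy: the per-cell total MSY count is normalized to
library size (counts per 10,000 by default), averaged within the cluster
and scaled by 100; clusters below a configurable cutoff (default 250) are
flagged as inadequate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CellMetadata, CountBundle, GeneAnnotation

__all__ = [
    "LOYCallTable",
    "FemaleNoiseModel",
    "total_msy_per_cell",
    "call_loy_zero_rule",
    "estimate_female_threshold",
    "call_loy_threshold_rule",
    "cluster_msy_score",
]


class ConfigurationError(ValueError):
    pass


@dataclass
class FemaleNoiseModel:
    """Female MSY background: the noise ceiling for threshold-rule calling.

    ``threshold`` is the 95th linear-interpolation quantile of total MSY
    expression among the ``n_female_msy_pos`` female cells that had any MSY
    expression; male cells below it (from at most ``max_msy_genes`` genes)
    are called LOY.
    """

    threshold: float
    n_female_msy_pos: int
    quantile: float = 0.95
    max_msy_genes: int = 1
    units: str = "counts"  # or "normalized" (counts per `scale` library reads)
    scale: float = 10_000.0

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.n_female_msy_pos < 1:
            raise ValueError("need at least one MSY-positive female cell")


@dataclass
class LOYCallTable:
    """Per-cell tri-state LOY status with rule provenance.

    ``status`` is ``LOY`` / ``normal`` for male cells and ``not_assessed``
    for female cells; ``total_msy`` and ``n_msy_genes_expressed`` record the
    evidence each call was made on.
    """

    table: pd.DataFrame  # barcode, status, rule, total_msy, n_msy_genes_expressed
    rule: str

    def __post_init__(self) -> None:
        bad = set(self.table["status"]) - {"LOY", "normal", "not_assessed"}
        if bad:
            raise ValueError(f"invalid status values: {bad}")

    @property
    def n_loy(self) -> int:
        return int((self.table["status"] == "LOY").sum())

    @property
    def n_assessed(self) -> int:
        return int((self.table["status"] != "not_assessed").sum())

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def total_msy_per_cell(
    bundle: CountBundle,
    annotation: GeneAnnotation,
    layers: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Total MSY counts and number of expressed MSY genes per cell.

    Counts are summed over MSY-flagged genes across the named layers (all
    layers by default); pseudoautosomal genes are excluded by construction
    of the annotation.  Raises if no MSY gene is present in the bundle.
    """
    msy = annotation.flags_for(bundle.genes, "is_msy")
    if not msy.any():
        raise ConfigurationError(
            "no MSY-flagged annotation gene is present in the bundle"
        )
    summed = bundle.layer_sum(layers)[msy, :]
    total = np.asarray(summed.sum(axis=0)).ravel()
    n_genes = np.asarray((summed > 0).sum(axis=0)).ravel()
    return total, n_genes


def _msy_expression(
    bundle: CountBundle,
    annotation: GeneAnnotation,
    layers: list[str] | None,
    units: str,
    scale: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell total MSY expression in the requested units.

    ``counts`` sums raw UMIs; ``normalized`` rescales to counts per
    ``scale`` library reads, giving an effectively continuous quantity
    (ties at a quantile threshold are what break the at-most-5% guarantee
    on integer counts).
    """
    total, n_genes = total_msy_per_cell(bundle, annotation, layers)
    if units == "counts":
        return total.astype(float), n_genes
    if units == "normalized":
        lib = np.asarray(bundle.layer_sum(layers).sum(axis=0)).ravel().astype(float)
        lib[lib == 0] = 1.0
        return total / lib * scale, n_genes
    raise ValueError(f"unknown units {units!r} (use 'counts' or 'normalized')")


def _sex_per_cell(metadata: CellMetadata, cells: np.ndarray) -> np.ndarray:
    meta = metadata.aligned_to(cells)
    sex = meta["sex"].to_numpy()
    if pd.isna(sex).any():
        raise ValueError("missing sex label for some cells; infer or supply sex first")
    return sex


def call_loy_zero_rule(
    bundle: CountBundle,
    annotation: GeneAnnotation,
    metadata: CellMetadata,
    layers: list[str] | None = None,
) -> LOYCallTable:
    """Call LOY in male cells with zero MSY reads across the given layers."""
    total, n_genes = total_msy_per_cell(bundle, annotation, layers)
    sex = _sex_per_cell(metadata, bundle.cells)
    male = sex == "male"
    status = np.where(male, np.where(total == 0, "LOY", "normal"), "not_assessed")
    table = pd.DataFrame(
        {
            "barcode": bundle.cells,
            "status": status,
            "rule": "zero_rule",
            "total_msy": total,
            "n_msy_genes_expressed": n_genes,
        }
    )
    return LOYCallTable(table=table, rule="zero_rule")


def estimate_female_threshold(
    bundle: CountBundle,
    annotation: GeneAnnotation,
    metadata: CellMetadata,
    layers: list[str] | None = None,
    quantile: float = 0.95,
    units: str = "counts",
    scale: float = 10_000.0,
) -> FemaleNoiseModel:
    """Estimate the female MSY noise ceiling.

    The threshold is the ``quantile`` (default 0.95) linear-interpolation
    quantile of total MSY expression among female cells with any MSY
    expression, in raw ``counts`` (default) or library-size ``normalized``
    units.  Raises when there are no female cells, or none with MSY
    expression.
    """
    values, _ = _msy_expression(bundle, annotation, layers, units, scale)
    sex = _sex_per_cell(metadata, bundle.cells)
    female = sex == "female"
    if not female.any():
        raise ValueError("no female cells: cannot estimate the noise threshold")
    positives = values[female & (values > 0)]
    if positives.size == 0:
        raise ValueError("no MSY-positive female cells: cannot estimate threshold")
    threshold = float(np.quantile(positives, quantile, method="linear"))
    return FemaleNoiseModel(
        threshold=threshold, n_female_msy_pos=int(positives.size),
        quantile=quantile, units=units, scale=scale,
    )


def call_loy_threshold_rule(
    bundle: CountBundle,
    annotation: GeneAnnotation,
    metadata: CellMetadata,
    model: FemaleNoiseModel,
    layers: list[str] | None = None,
) -> LOYCallTable:
    """Call LOY in male cells below the female noise ceiling.

    A male cell is LOY iff its MSY expression (in the model's units) is
    strictly below ``model.threshold`` and it expresses at most
    ``model.max_msy_genes`` MSY genes.
    """
    values, n_genes = _msy_expression(
        bundle, annotation, layers, model.units, model.scale
    )
    total, _ = total_msy_per_cell(bundle, annotation, layers)
    sex = _sex_per_cell(metadata, bundle.cells)
    male = sex == "male"
    is_loy = (values < model.threshold) & (n_genes <= model.max_msy_genes)
    status = np.where(male, np.where(is_loy, "LOY", "normal"), "not_assessed")
    table = pd.DataFrame(
        {
            "barcode": bundle.cells,
            "status": status,
            "rule": "threshold_rule",
            "total_msy": total,
            "n_msy_genes_expressed": n_genes,
        }
    )
    return LOYCallTable(table=table, rule="threshold_rule")


def cluster_msy_score(
    bundle: CountBundle,
    annotation: GeneAnnotation,
    metadata: CellMetadata,
    layers: list[str] | None = None,
    normalization_scale: float = 10_000.0,
    threshold: float = 250.0,
) -> pd.DataFrame:
    """Score each cluster's MSY expression adequacy for LOY calling.

    ``score = 100 × mean over cells of (total_msy / library_size ×
    normalization_scale)``.  Clusters at or above ``threshold`` pass; empty
    clusters (or clusters whose cells all have zero library size) are
    reported as failing with ``score`` NaN and ``undefined = True``.
    Returns a DataFrame: cluster, n_cells, msy_score, passes, undefined.
    """
    total, _ = total_msy_per_cell(bundle, annotation, layers)
    libsize = np.asarray(bundle.layer_sum(layers).sum(axis=0)).ravel()
    meta = metadata.aligned_to(bundle.cells)
    clusters = meta["cluster"].to_numpy()
    rows = []
    for cl in pd.unique(clusters):
        idx = clusters == cl
        lib = libsize[idx]
        ok = lib > 0
        if not ok.any():
            rows.append((cl, int(idx.sum()), np.nan, False, True))
            continue
        per_cell = total[idx][ok] / lib[ok] * normalization_scale
        score = float(per_cell.mean() * 100.0)
        rows.append((cl, int(idx.sum()), score, score >= threshold, False))
    return pd.DataFrame(
        rows, columns=["cluster", "n_cells", "msy_score", "passes", "undefined"]
    )
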