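"""Cell-level quality control and donor-sex inference.

Two filtering regimes are supported through one criteria object: a
feature-count plus mitochondrial-percentage filter (the usual choice when
mitochondrial transcripts are quantified) and a feature-count plus total-UMI
filter (used for datasets where mitochondrial reads are unavailable).  All
bounds are strict: a cell passes ``min_features`` only with *more* features
than the bound and ``max_mito_pct`` only with *less* than the bound.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .io import CellMetadata, CountBundle, GeneAnnotation

__all__ = ["QCCriteria", "QCReport", "filter_cells", "infer_sample_sex"]


class ConfigurationError(ValueError):
    pass


@dataclass
class QCCriteria:
    """Strict (exclusive) per-cell QC bounds; unset bounds are not applied.

    ``min_features``/``max_features`` bound the number of genes with any
    count, ``max_mito_pct`` the percentage of reads from mitochondrial
    genes, and ``min_umi``/``max_umi`` the total raw UMI count.
    """

    min_features: int | None = None
    max_features: int | None = None
    max_mito_pct: float | None = None
    min_umi: int | None = None
    max_umi: int | None = None

    def validate(self) -> None:
        if all(
            v is None
            for v in (self.min_features, self.max_features, self.max_mito_pct,
                      self.min_umi, self.max_umi)
        ):
            raise ConfigurationError("QCCriteria: at least one criterion must be set")
        if (
            self.min_features is not None
            and self.max_features is not None
            and self.min_features >= self.max_features
        ):
            raise ConfigurationError("min_features must be below max_features")
        if (
            self.min_umi is not None
            and self.max_umi is not None
            and self.min_umi >= self.max_umi
        ):
            raise ConfigurationError("min_umi must be below max_umi")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "QCCriteria":
        return cls(**{k: d.get(k) for k in cls.__dataclass_fields__})


@dataclass
class QCReport:
    """Outcome of a filtering pass: per-cell flags and per-criterion tallies."""

    n_input: int
    n_passed: int
    n_failed_by_criterion: dict[str, int]
    per_cell: pd.DataFrame  # barcode, features, total_umi, mito_pct, passed

    def summary(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_passed": self.n_passed,
            "n_removed": self.n_input - self.n_passed,
            "n_failed_by_criterion": dict(self.n_failed_by_criterion),
        }


def cell_qc_metrics(
    bundle: CountBundle,
    annotation: GeneAnnotation | None = None,
    layers: list[str] | None = None,
) -> pd.DataFrame:
    """Per-cell expressed-feature count, total UMIs and mitochondrial %.

    Features are counted on the summed layers (all reads), matching an
    all-read LOY caller; mito % requires mito-flagged genes in ``annotation``.
    """
    total = bundle.layer_sum(layers)
    features = np.asarray((total > 0).sum(axis=0)).ravel()
    umi = np.asarray(total.sum(axis=0)).ravel()
    out = pd.DataFrame({"barcode": bundle.cells, "features": features, "total_umi": umi})
    if annotation is not None:
        mito = annotation.flags_for(bundle.genes, "is_mito")
        if mito.any():
            mito_counts = np.asarray(total[mito, :].sum(axis=0)).ravel()
            with np.errstate(invalid="ignore", divide="ignore"):
                out["mito_pct"] = np.where(umi > 0, 100.0 * mito_counts / umi, np.nan)
    return out


def filter_cells(
    bundle: CountBundle,
    annotation: GeneAnnotation,
    criteria: QCCriteria,
    layers: list[str] | None = None,
) -> tuple[CountBundle, QCReport]:
    """Remove cells violating any set criterion (all bounds exclusive)."""
    criteria.validate()
    metrics = cell_qc_metrics(bundle, annotation, layers)
    if criteria.max_mito_pct is not None and "mito_pct" not in metrics:
        raise ConfigurationError(
            "max_mito_pct set but the annotation flags no mitochondrial genes"
        )
    n = bundle.n_cells
    passed = np.ones(n, dtype=bool)
    failed_by: dict[str, int] = {}

    def apply(name: str, ok: np.ndarray) -> None:
        nonlocal passed
        failed_by[name] = int((~ok).sum())
        passed &= ok

    feats = metrics["features"].to_numpy()
    umi = metrics["total_umi"].to_numpy()
    if criteria.min_features is not None:
        apply("min_features", feats > criteria.min_features)
    if criteria.max_features is not None:
        apply("max_features", feats < criteria.max_features)
    if criteria.max_mito_pct is not None:
        mito = metrics["mito_pct"].to_numpy()
        apply("max_mito_pct", mito < criteria.max_mito_pct)
    if criteria.min_umi is not None:
        apply("min_umi", umi > criteria.min_umi)
    if criteria.max_umi is not None:
        apply("max_umi", umi < criteria.max_umi)

    per_cell = metrics.assign(passed=passed)
    report = QCReport(
        n_input=n,
        n_passed=int(passed.sum()),
        n_failed_by_criterion=failed_by,
        per_cell=per_cell,
    )
    return bundle.subset_cells(passed), report


def infer_sample_sex(
    bundle: CountBundle,
    annotation: GeneAnnotation,
    metadata: CellMetadata,
    cutoff: float = 0.5,
) -> pd.DataFrame:
    """Call donor sex per sample from the prevalence of MSY expression.

    A sample is labelled male iff the fraction of its cells with any MSY
    count strictly exceeds ``cutoff``; a fraction exactly at the cutoff is
    called female with a warning (ambient contamination can only inflate,
    never deflate, the fraction, so the conservative tie-break is female).
    Returns a DataFrame with sample_id, msy_cell_fraction and inferred sex.
    """
    msy = annotation.flags_for(bundle.genes, "is_msy")
    if not msy.any():
        raise ConfigurationError("annotation flags no MSY genes present in bundle")
    has_msy = np.asarray((bundle.total[msy, :] > 0).sum(axis=0)).ravel() > 0
    meta = metadata.aligned_to(bundle.cells)
    rows = []
    for sample_id, idx in pd.Series(
        np.arange(bundle.n_cells), index=meta["sample_id"].to_numpy()
    ).groupby(level=0):
        frac = float(has_msy[idx.to_numpy()].mean())
        if frac == cutoff:
            warnings.warn(
                f"sample {sample_id}: MSY cell fraction exactly at cutoff "
                f"{cutoff}; calling female", stacklevel=2,
            )
        rows.append((sample_id, frac, "male" if frac > cutoff else "female"))
    return pd.DataFrame(rows, columns=["sample_id", "msy_cell_fraction", "sex"])
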