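"""Marker-based cluster annotation with an "unidentified" fallback.

Clusters (taken as input, e.g. from a graph-based clustering) are labelled
by an ordered rule panel over canonical leukocyte markers: the first rule
whose required-high markers are all high and required-low markers all low
in a cluster assigns its label.  "High" is reproducible rather than
curated by eye: a marker is high in a cluster when the cluster's mean
normalized expression exceeds the mean of that marker's cluster means.
Treg clusters can be further separated into CTLA4+/CTLA4- maturation
states by the same flag on CTLA4.

Marker expression is scored on library-size-normalized (counts per 10,000),
log1p-transformed totals — the log normalization conventionally preferred
for expression comparisons.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import CellMetadata, CountBundle

__all__ = ["MarkerRule", "MarkerPanel", "score_markers", "assign_cell_types"]


class ConfigurationError(ValueError):
    pass


@dataclass
class MarkerRule:
    label: str
    high: list[str]
    low: list[str] = field(default_factory=list)


@dataclass
class MarkerPanel:
    """Ordered marker rules; first match wins, no match -> "unidentified"."""

    rules: list[MarkerRule]
    ctla4_split: bool = True
    ctla4_gene: str = "CTLA4"
    treg_label: str = "Treg"

    def __post_init__(self) -> None:
        labels = [r.label for r in self.rules]
        if len(set(labels)) != len(labels):
            raise ConfigurationError("duplicate labels in marker panel")

    @property
    def markers(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.rules:
            for m in r.high + r.low:
                seen.setdefault(m, None)
        if self.ctla4_split:
            seen.setdefault(self.ctla4_gene, None)
        return list(seen)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MarkerPanel":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        rules = [
            MarkerRule(label=r["label"], high=list(r.get("high", [])),
                       low=list(r.get("low", [])))
            for r in d["rules"]
        ]
        return cls(rules=rules, ctla4_split=bool(d.get("ctla4_split", True)))

    @classmethod
    def default(cls) -> "MarkerPanel":
        """The packaged PBMC/T-lymphocyte panel (CD4/FHIT/CCR7 naive split,
        FOXP3/IL2RA/TIGIT Tregs with CTLA4 separation, CD8A, NKG7/GNLY,
        FCN1/CD14[/FCGR3A] monocytes, CD19/VPREB3 B cells)."""
        with importlib.resources.as_file(
            importlib.resources.files("loyscan.data") / "marker_panel.yaml"
        ) as path:
            return cls.from_yaml(path)


def score_markers(
    bundle: CountBundle,
    metadata: CellMetadata,
    panel: MarkerPanel,
    layers: list[str] | None = None,
    scale: float = 10_000.0,
) -> pd.DataFrame:
    """Per-cluster mean normalized log expression of each panel marker.

    Returns a cluster × marker DataFrame of means of
    ``log1p(count / library_size × scale)``; markers absent from the bundle
    give NaN columns (with a warning).  An extra boolean frame is attached
    as ``.attrs["high"]``: marker high iff cluster mean > across-cluster
    mean of cluster means.
    """
    markers = panel.markers
    gene_index = {g: i for i, g in enumerate(bundle.genes)}
    symbol_index = {s: i for i, s in enumerate(bundle.gene_symbols)}
    present = {m: gene_index.get(m, symbol_index.get(m)) for m in markers}
    missing = [m for m, i in present.items() if i is None]
    if len(missing) == len(markers):
        raise ConfigurationError("no panel marker is present in the bundle")
    if missing:
        warnings.warn(f"panel markers absent from bundle: {missing}", stacklevel=2)

    total = bundle.layer_sum(layers).tocsr()
    lib = np.asarray(total.sum(axis=0)).ravel().astype(float)
    lib[lib == 0] = 1.0
    meta = metadata.aligned_to(bundle.cells)
    clusters = meta["cluster"].to_numpy()
    cluster_ids = list(pd.unique(clusters))

    scores = pd.DataFrame(index=cluster_ids, columns=markers, dtype=float)
    for m, row_i in present.items():
        if row_i is None:
            continue
        expr = np.log1p(np.asarray(total[row_i, :].todense()).ravel() / lib * scale)
        for cl in cluster_ids:
            scores.loc[cl, m] = expr[clusters == cl].mean()
    global_mean = scores.mean(axis=0)  # mean of cluster means per marker
    high = scores.gt(global_mean, axis=1)
    high[scores.isna()] = False
    scores.attrs["high"] = high
    scores.index.name = "cluster"
    return scores


def assign_cell_types(scores: pd.DataFrame, panel: MarkerPanel) -> pd.DataFrame:
    """Label each cluster by the first matching panel rule.

    A rule matches when every required-high marker is flagged high and every
    required-low marker is flagged low (i.e. not high) in the cluster;
    missing markers never satisfy a high requirement.  Clusters matching no
    rule are "unidentified".  With ``panel.ctla4_split``, Treg clusters
    become "Treg CTLA4+" or "Treg CTLA4-" by the CTLA4 high flag.

    Returns a DataFrame: cluster, cell_type, matched_rule, decision trace.
    """
    high: pd.DataFrame = scores.attrs["high"]
    rows = []
    for cl in scores.index:
        flags = high.loc[cl]
        label, matched, trace = "unidentified", None, []
        for rule in panel.rules:
            hi_ok = all(bool(flags.get(m, False)) for m in rule.high)
            lo_ok = all(not bool(flags.get(m, False)) for m in rule.low)
            trace.append(f"{rule.label}:{'match' if hi_ok and lo_ok else 'no'}")
            if hi_ok and lo_ok:
                label, matched = rule.label, rule.label
                break
        if panel.ctla4_split and label == panel.treg_label:
            pos = bool(flags.get(panel.ctla4_gene, False))
            label = f"{panel.treg_label} {panel.ctla4_gene}{'+' if pos else '-'}"
        rows.append((cl, label, matched, ";".join(trace)))
    out = pd.DataFrame(rows, columns=["cluster", "cell_type", "matched_rule", "trace"])
    return out
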