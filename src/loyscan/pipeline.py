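"""End-to-end orchestration: simulate/load → QC → call → score → type → stats.

A :class:`PipelineConfig` (round-tripping through YAML) fully describes a
run; :func:`run_pipeline` executes the stages in order, writes every table
as TSV into the output directory plus a ``report.json`` summary, and is
deterministic given the seed.  Clusters failing the MSY adequacy score are
flagged in the report and, when ``drop_failing_clusters`` is set, excluded
from the fraction table (exclusion can only remove LOY calls, never add).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .calling import (
    call_loy_threshold_rule,
    call_loy_zero_rule,
    cluster_msy_score,
    estimate_female_threshold,
)
from .celltypes import MarkerPanel, assign_cell_types, score_markers
from .io import (
    CellMetadata,
    load_cell_metadata,
    load_gene_annotation,
    read_mtx_bundle,
)
from .qc import QCCriteria, filter_cells, infer_sample_sex
from .simulate import SimParams, simulate_dataset, write_simulation
from .stats import loy_fraction_table, treg_abundance_analysis

log = logging.getLogger("loyscan")

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, YAML-serializable.

    ``input_mode`` is ``simulate`` (uses ``sim_params``) or ``mtx_bundle``
    (uses ``input_dir`` with optional ``metadata_path``/``annotation_path``;
    the packaged MSY/PAR/mito annotation is the fallback).
    """

    input_mode: str = "simulate"
    sim_params: SimParams = field(default_factory=SimParams)
    input_dir: str | None = None
    metadata_path: str | None = None
    annotation_path: str | None = None
    layers: list[str] | None = None  # None = all layers
    qc: QCCriteria = field(default_factory=lambda: QCCriteria(min_features=10, max_mito_pct=13.0))
    rule: str = "zero"  # or "threshold"
    cluster_score_threshold: float = 250.0
    drop_failing_clusters: bool = False
    marker_panel_path: str | None = None
    outdir: str = "loyscan_out"
    seed: int = 0
    write_simulated_bundle: bool = False

    def validate(self) -> None:
        if self.input_mode not in ("simulate", "mtx_bundle"):
            raise ValueError(f"unknown input_mode {self.input_mode!r}")
        if self.rule not in ("zero", "threshold"):
            raise ValueError(f"unknown LOY rule {self.rule!r} (use 'zero' or 'threshold')")
        if self.input_mode == "mtx_bundle" and not self.input_dir:
            raise ValueError("input_mode 'mtx_bundle' requires input_dir")
        self.qc.validate()

    def to_yaml(self, path: str | Path) -> None:
        d = {
            k: getattr(self, k)
            for k in self.__dataclass_fields__
            if k not in ("sim_params", "qc")
        }
        d["sim_params"] = self.sim_params.to_dict()
        d["qc"] = self.qc.to_dict()
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "sim_params" in d:
            d["sim_params"] = SimParams.from_dict(d["sim_params"])
        if "qc" in d:
            d["qc"] = QCCriteria.from_dict(d["qc"])
        return cls(**d)


@dataclass
class RunReport:
    """All tables and summaries produced by one pipeline run."""

    config_echo: dict
    seed: int
    version: str
    qc_summary: dict
    cluster_scores: pd.DataFrame
    cluster_types: pd.DataFrame
    fractions: pd.DataFrame
    tests: dict
    n_loy: int
    n_assessed: int
    timings: dict[str, float]

    def to_json_dict(self) -> dict:
        tests = {}
        for name, res in self.tests.items():
            if hasattr(res, "to_dict"):
                tests[name] = res.to_dict()
            elif isinstance(res, pd.DataFrame):
                tests[name] = res.to_dict(orient="records")
            else:
                tests[name] = res
        return {
            "version": self.version,
            "seed": self.seed,
            "config": self.config_echo,
            "qc": self.qc_summary,
            "n_loy": self.n_loy,
            "n_assessed": self.n_assessed,
            "n_clusters_scored": int(len(self.cluster_scores)),
            "n_clusters_failing_score": int((~self.cluster_scores["passes"]).sum()),
            "tests": tests,
            "timings_s": self.timings,
        }


def _stage(timings: dict, name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            timings[name] = round(time.perf_counter() - self.t0, 3)
            if exc is not None:
                log.error("stage %s: failed (%s)", name, exc)
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.2fs", name, timings[name])

    return _Timer()


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full LOY pipeline and write all outputs to ``outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    with _stage(timings, "input"):
        if config.input_mode == "simulate":
            params = config.sim_params
            params.seed = config.seed
            bundle, metadata, annotation, truth = simulate_dataset(params)
            truth.cells.to_csv(outdir / "truth.tsv", sep="\t", index=False)
            if config.write_simulated_bundle:
                write_simulation(outdir / "bundle", bundle, metadata, annotation, truth)
        else:
            layer_names = config.layers or ["total"]
            bundle = read_mtx_bundle(config.input_dir, layer_names)
            annotation = (
                load_gene_annotation(config.annotation_path)
                if config.annotation_path
                else load_gene_annotation(Path(config.input_dir) / "features.tsv")
            )
            meta_path = config.metadata_path or str(
                Path(config.input_dir) / "cell_metadata.tsv"
            )
            metadata = load_cell_metadata(meta_path)

    with _stage(timings, "qc"):
        bundle, qc_report = filter_cells(bundle, annotation, config.qc, config.layers)
        qc_report.per_cell.to_csv(outdir / "qc_cells.tsv", sep="\t", index=False)
        with open(outdir / "qc_summary.json", "w") as fh:
            json.dump(qc_report.summary(), fh, indent=2)

    with _stage(timings, "sex"):
        meta_aligned = metadata.aligned_to(bundle.cells)
        if meta_aligned["sex"].isna().any():
            sex_calls = infer_sample_sex(bundle, annotation, metadata)
            sex_map = dict(zip(sex_calls["sample_id"], sex_calls["sex"]))
            tab = metadata.table.copy()
            tab["sex"] = tab["sex"].fillna(tab["sample_id"].map(sex_map))
            metadata = CellMetadata(tab.reset_index(drop=True))
            sex_calls.to_csv(outdir / "sample_sex.tsv", sep="\t", index=False)

    with _stage(timings, "cluster_score"):
        scores = cluster_msy_score(
            bundle, annotation, metadata, config.layers,
            threshold=config.cluster_score_threshold,
        )
        scores.to_csv(outdir / "cluster_scores.tsv", sep="\t", index=False)

    with _stage(timings, "cell_typing"):
        panel = (
            MarkerPanel.from_yaml(config.marker_panel_path)
            if config.marker_panel_path
            else MarkerPanel.default()
        )
        marker_scores = score_markers(bundle, metadata, panel, config.layers)
        typing = assign_cell_types(marker_scores, panel)
        typing.to_csv(outdir / "cluster_types.tsv", sep="\t", index=False)

    with _stage(timings, "loy_calling"):
        if config.rule == "zero":
            calls = call_loy_zero_rule(bundle, annotation, metadata, config.layers)
        else:
            model = estimate_female_threshold(bundle, annotation, metadata, config.layers)
            calls = call_loy_threshold_rule(
                bundle, annotation, metadata, model, config.layers
            )
        calls.to_tsv(outdir / "loy_calls.tsv")

    with _stage(timings, "fractions"):
        use_metadata = metadata
        use_calls = calls
        if config.drop_failing_clusters:
            bad = set(scores.loc[~scores["passes"], "cluster"])
            meta_al = metadata.aligned_to(bundle.cells)
            keep_barcodes = set(meta_al.loc[~meta_al["cluster"].isin(bad), "barcode"])
            use_calls = type(calls)(
                table=calls.table[calls.table["barcode"].isin(keep_barcodes)].copy(),
                rule=calls.rule,
            )
        fractions = loy_fraction_table(use_calls, use_metadata, typing)
        fractions.to_csv(outdir / "loy_fractions.tsv", sep="\t", index=False)

    tests: dict = {}
    with _stage(timings, "statistics"):
        try:
            analysis = treg_abundance_analysis(fractions)
            tests["treg_vs_other_t_wilcoxon"] = analysis["wilcoxon"]
            reg = analysis["regression"]
            tests["treg_fraction_on_loy_regression"] = {
                "slope": reg.slope,
                "intercept": reg.intercept,
                "p_value": reg.test.p_value,
                "n": reg.n,
                "method": reg.method,
            }
            tests["treg_abundance_glm_type3"] = analysis["glm_type3"]
            analysis["per_sample"].to_csv(
                outdir / "treg_per_sample.tsv", sep="\t", index=False
            )
        except ValueError as exc:
            log.warning("Treg abundance analysis skipped: %s", exc)
            tests["treg_abundance_skipped"] = str(exc)

    report = RunReport(
        config_echo={"input_mode": config.input_mode, "rule": config.rule,
                     "layers": config.layers,
                     "cluster_score_threshold": config.cluster_score_threshold,
                     "drop_failing_clusters": config.drop_failing_clusters},
        seed=config.seed,
        version=__version__,
        qc_summary=qc_report.summary(),
        cluster_scores=scores,
        cluster_types=typing,
        fractions=fractions,
        tests=tests,
        n_loy=use_calls.n_loy,
        n_assessed=use_calls.n_assessed,
        timings=timings,
    )
    with open(outdir / "report.json", "w") as fh:
        json.dump(report.to_json_dict(), fh, indent=2, default=float)
    return report
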