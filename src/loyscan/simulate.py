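"""Synthetic multi-sample single-cell UMI count bundles with known LOY truth.

The generator emulates a droplet scRNA-seq cohort of PBMC-like samples from
male and female donors: gene counts are negative-binomial with a per-cell
log-normal library-depth multiplier (the standard overdispersed droplet
model, which produces realistic dropout), cell types are drawn per sample
with configurable proportions, and mosaic loss of chromosome Y (LOY) is
implemented as genotype — cells that truly lost the Y have all rates for
male-specific-region (MSY) genes set to zero, while pseudoautosomal genes
keep one of two copies (rate halved).  Female cells carry no Y, so their
genotype-derived MSY rate is always zero; any MSY signal in female cells
comes from the optional ambient-contamination stage, which models the
technical background observed in real droplet data.

Two cohort regimes are covered by one parameter: ``ambient_msy_rate = 0``
gives clean UMI data where true-LOY cells have exactly zero MSY transcripts,
and a positive rate gives noisy data where female cells show nonzero
background MSY expression (the regime that motivates quantile-threshold
calling).

Regulatory-T-cell coupling: per-sample LOY propensity varies on the logit
scale, and the share of Treg cells in a sample can be coupled to that
sample's realized Treg LOY level (``treg_coupling``), so the downstream
association analyses have a known generative sign to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .io import CellMetadata, CountBundle, GeneAnnotation, write_mtx_bundle

__all__ = ["SimParams", "SimTruth", "ParameterError", "simulate_dataset", "inject_ambient_msy"]


class ParameterError(ValueError):
    """Invalid simulation parameters."""


def _default_proportions() -> dict[str, float]:
    return {
        "Naive CD4 T": 0.22,
        "Helper T": 0.22,
        "Treg CTLA4+": 0.05,
        "Treg CTLA4-": 0.03,
        "Cytotoxic T": 0.20,
        "NK cell": 0.08,
        "B cell": 0.10,
        "Classical monocyte": 0.06,
        "Non-classical monocyte": 0.04,
    }


def _default_loy_fractions() -> dict[str, float]:
    # Tregs carry elevated LOY relative to other T cells; NK cells and
    # monocytes are the overall high-LOY leukocytes.
    return {
        "Naive CD4 T": 0.03,
        "Helper T": 0.03,
        "Treg CTLA4+": 0.18,
        "Treg CTLA4-": 0.18,
        "Cytotoxic T": 0.03,
        "NK cell": 0.15,
        "B cell": 0.03,
        "Classical monocyte": 0.12,
        "Non-classical monocyte": 0.12,
    }


def _default_msy_means() -> dict[str, float]:
    # RPS4Y1 dominates expressed MSY output in leukocytes.
    return {
        "RPS4Y1": 4.0,
        "DDX3Y": 1.0,
        "EIF1AY": 0.8,
        "UTY": 0.4,
        "KDM5D": 0.4,
        "USP9Y": 0.25,
        "ZFY": 0.2,
        "TMSB4Y": 0.15,
        "NLGN4Y": 0.05,
    }


def _default_marker_means() -> dict[str, dict[str, float]]:
    hi = 2.0  # 8x the 0.25 baseline of panel markers
    return {
        "Naive CD4 T": {"CD4": hi, "FHIT": hi, "CCR7": hi},
        "Helper T": {"CD4": hi},
        "Treg CTLA4+": {"CD4": hi, "FOXP3": hi, "IL2RA": hi, "TIGIT": hi, "CTLA4": hi},
        "Treg CTLA4-": {"CD4": hi, "FOXP3": hi, "IL2RA": hi, "TIGIT": hi},
        "Cytotoxic T": {"CD8A": hi},
        "NK cell": {"NKG7": hi, "GNLY": hi},
        "B cell": {"CD19": hi, "VPREB3": hi},
        "Classical monocyte": {"FCN1": hi, "CD14": hi},
        "Non-classical monocyte": {"FCN1": hi, "CD14": hi, "FCGR3A": hi},
    }


PANEL_MARKERS = (
    "CD4", "FHIT", "CCR7", "FOXP3", "IL2RA", "TIGIT", "CTLA4", "CD8A",
    "NKG7", "GNLY", "FCN1", "CD14", "FCGR3A", "CD19", "VPREB3",
)

MITO_GENES = ("MT-CO1", "MT-ND1", "MT-CYB", "MT-ATP6", "MT-ND4")


@dataclass
class SimParams:
    """Generative parameters for a synthetic LOY cohort.

    Defaults describe a clean validation-style cohort: 20 male and 4 female
    PBMC samples, Treg LOY at 18% versus 3% in other T cells, deep MSY
    coverage (expected ~7 MSY UMIs per normal male cell at unit depth) and
    no ambient MSY contamination.
    """

    n_samples_male: int = 20
    n_samples_female: int = 4
    cells_per_sample: int = 600
    cell_type_proportions: dict[str, float] = field(default_factory=_default_proportions)
    loy_fraction_by_type: dict[str, float] = field(default_factory=_default_loy_fractions)
    n_genes: int = 120
    msy_gene_means: dict[str, float] = field(default_factory=_default_msy_means)
    marker_gene_means: dict[str, dict[str, float]] = field(default_factory=_default_marker_means)
    marker_baseline_mean: float = 0.25
    par_gene_mean: float = 0.5
    background_gene_mean: float = 0.5
    depth_lognormal_mu_sigma: tuple[float, float] = (0.0, 0.35)
    nb_dispersion: float = 10.0
    unspliced_fraction: float = 0.25
    ambient_msy_rate: float = 0.0
    mito_fraction_beta: tuple[float, float] = (2.0, 30.0)
    loy_between_sample_sd: float = 0.5
    treg_coupling: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples_male + self.n_samples_female < 1:
            raise ParameterError("need at least one sample")
        if self.cells_per_sample < 1:
            raise ParameterError("cells_per_sample must be positive")
        if self.n_genes < 1:
            raise ParameterError("n_genes must be positive")
        total = sum(self.cell_type_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ParameterError(f"cell_type_proportions sum to {total}, expected 1")
        if any(p < 0 for p in self.cell_type_proportions.values()):
            raise ParameterError("cell type proportions must be nonnegative")
        for t, f in self.loy_fraction_by_type.items():
            if not 0.0 <= f <= 1.0:
                raise ParameterError(f"loy_fraction_by_type[{t!r}] = {f} not in [0, 1]")
        missing = set(self.cell_type_proportions) - set(self.loy_fraction_by_type)
        if missing:
            raise ParameterError(f"no LOY fraction for cell types: {sorted(missing)}")
        if self.nb_dispersion <= 0:
            raise ParameterError("nb_dispersion must be > 0")
        if self.ambient_msy_rate < 0:
            raise ParameterError("ambient_msy_rate must be >= 0")
        if not 0.0 <= self.unspliced_fraction <= 1.0:
            raise ParameterError("unspliced_fraction must be in [0, 1]")
        a, b = self.mito_fraction_beta
        if a <= 0 or b <= 0:
            raise ParameterError("mito_fraction_beta parameters must be positive")

    # -- YAML round-trip ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["depth_lognormal_mu_sigma"] = list(self.depth_lognormal_mu_sigma)
        d["mito_fraction_beta"] = list(self.mito_fraction_beta)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        d = dict(d)
        for key in ("depth_lognormal_mu_sigma", "mito_fraction_beta"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class SimTruth:
    """Ground-truth labels behind a simulated bundle.

    ``cells`` holds per-cell barcode, sample, sex, generating cell type and
    ``true_loy``; ``realized_fractions`` the per-(sample, cell type) mean of
    ``true_loy`` among that group's cells.
    """

    cells: pd.DataFrame
    realized_fractions: pd.DataFrame

    def to_tsv(self, path: str | Path) -> None:
        self.cells.to_csv(path, sep="\t", index=False)


def _gene_panel(params: SimParams) -> pd.DataFrame:
    """Assemble the simulated gene table with base rates and flags."""
    rows = []
    for g, mu in params.msy_gene_means.items():
        rows.append((g, "chrY", True, False, False, mu))
    rows.append(("CD99", "chrX;chrY", False, True, False, params.par_gene_mean))
    for g in MITO_GENES:
        rows.append((g, "chrM", False, False, True, 0.0))  # rate set per cell
    for g in PANEL_MARKERS:
        rows.append((g, "chr1", False, False, False, params.marker_baseline_mean))
    n_special = len(rows)
    if params.n_genes < n_special:
        raise ParameterError(
            f"n_genes = {params.n_genes} below the {n_special} named genes"
        )
    for i in range(params.n_genes - n_special):
        rows.append((f"FILLER{i + 1:04d}", "chr2", False, False, False,
                     params.background_gene_mean))
    return pd.DataFrame(
        rows, columns=["id", "chromosome", "is_msy", "is_par", "is_mito", "base_rate"]
    )


def simulate_dataset(
    params: SimParams,
) -> tuple[CountBundle, CellMetadata, GeneAnnotation, SimTruth]:
    """Simulate a cohort of male/female samples with known LOY labels.

    Returns a spliced/unspliced :class:`CountBundle`, per-cell metadata
    (sample, sex, cluster — one cluster per generating cell type), the gene
    annotation for the simulated genes, and the :class:`SimTruth` labels.
    Deterministic given ``params.seed``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    genes = _gene_panel(params)
    gene_ids = genes["id"].to_numpy()
    n_genes = len(genes)
    types = list(params.cell_type_proportions)
    base_props = np.array([params.cell_type_proportions[t] for t in types])
    treg_mask = np.array([t.startswith("Treg") for t in types])
    base_treg_loy = float(
        np.mean([params.loy_fraction_by_type[t] for t, m in zip(types, treg_mask) if m])
    ) if treg_mask.any() else 0.0

    samples = [(f"M{i + 1:03d}", "male") for i in range(params.n_samples_male)]
    samples += [(f"F{i + 1:03d}", "female") for i in range(params.n_samples_female)]

    rows_meta, rows_truth = [], []
    cell_type_idx, loy_flags, sample_of_cell = [], [], []
    for sample_id, sex in samples:
        # per-sample LOY propensity shift on the logit scale (males only)
        shift = rng.normal(0.0, params.loy_between_sample_sd)
        frac = {}
        for t in types:
            f = params.loy_fraction_by_type[t]
            if sex == "female" or f in (0.0, 1.0):
                frac[t] = 0.0 if sex == "female" else f
            else:
                frac[t] = float(1.0 / (1.0 + np.exp(-(np.log(f / (1 - f)) + shift))))
        props = base_props.copy()
        if sex == "male" and treg_mask.any() and base_treg_loy > 0 and params.treg_coupling != 0:
            sample_treg_loy = float(np.mean([frac[t] for t, m in zip(types, treg_mask) if m]))
            mult = 1.0 + params.treg_coupling * (sample_treg_loy - base_treg_loy) / base_treg_loy
            props[treg_mask] *= max(mult, 0.2)
        props = props / props.sum()
        kinds = rng.choice(len(types), size=params.cells_per_sample, p=props)
        for j, k in enumerate(kinds):
            t = types[k]
            loy = sex == "male" and bool(rng.random() < frac[t])
            barcode = f"{sample_id}_{j + 1:05d}"
            cell_type_idx.append(k)
            loy_flags.append(loy)
            sample_of_cell.append(sample_id)
            rows_meta.append((barcode, sample_id, sex, f"C{k}"))
            rows_truth.append((barcode, sample_id, sex, t, loy))

    n_cells = len(rows_meta)
    if n_cells == 0:
        raise ParameterError("simulation produced zero cells")
    cell_type_idx = np.array(cell_type_idx)
    loy_flags = np.array(loy_flags)
    sex_of_cell = np.array([r[2] for r in rows_meta])

    # per-gene per-cell mean rates
    mu_log, sigma_log = params.depth_lognormal_mu_sigma
    depth = rng.lognormal(mean=mu_log, sigma=sigma_log, size=n_cells)
    rate = np.tile(genes["base_rate"].to_numpy()[:, None], (1, n_cells))

    gene_row = {g: i for i, g in enumerate(gene_ids)}
    for k, t in enumerate(types):
        cols = np.flatnonzero(cell_type_idx == k)
        for marker, mu in params.marker_gene_means.get(t, {}).items():
            if marker in gene_row:
                rate[gene_row[marker], cols] = mu

    msy_rows = genes.index[genes["is_msy"]].to_numpy()
    par_rows = genes.index[genes["is_par"]].to_numpy()
    no_y = (sex_of_cell == "female") | loy_flags
    rate[np.ix_(msy_rows, np.flatnonzero(no_y))] = 0.0
    # one of two pseudoautosomal copies lost with the Y
    rate[np.ix_(par_rows, np.flatnonzero(loy_flags))] *= 0.5

    # mitochondrial rates chosen so the expected mito read share matches a
    # per-cell Beta draw
    mito_rows = genes.index[genes["is_mito"]].to_numpy()
    a, b = params.mito_fraction_beta
    mito_frac = rng.beta(a, b, size=n_cells)
    non_mito_rate = rate.sum(axis=0)
    mito_total = non_mito_rate * mito_frac / (1.0 - mito_frac)
    rate[mito_rows, :] = mito_total / len(mito_rows)

    mean = rate * depth[None, :]

    # negative binomial via gamma-Poisson mixture; zero mean stays exactly zero
    theta = params.nb_dispersion
    lam = np.zeros_like(mean)
    pos = mean > 0
    lam[pos] = rng.gamma(shape=theta, scale=mean[pos] / theta)
    total = rng.poisson(lam)

    unspliced = rng.binomial(total, params.unspliced_fraction)
    spliced = total - unspliced

    barcodes = np.array([r[0] for r in rows_meta], dtype=object)
    bundle = CountBundle(
        genes=gene_ids,
        cells=barcodes,
        layers={
            "spliced": sp.csr_matrix(spliced),
            "unspliced": sp.csr_matrix(unspliced),
        },
    )
    annotation = GeneAnnotation(
        genes.assign(symbol=genes["id"])[
            ["id", "symbol", "chromosome", "is_msy", "is_par", "is_mito"]
        ]
    )
    metadata = CellMetadata(
        pd.DataFrame(rows_meta, columns=["barcode", "sample_id", "sex", "cluster"])
    )
    truth_cells = pd.DataFrame(
        rows_truth, columns=["barcode", "sample_id", "sex", "cell_type", "true_loy"]
    )
    realized = (
        truth_cells.groupby(["sample_id", "cell_type"], sort=True)["true_loy"]
        .agg(n_cells="size", n_loy="sum", true_fraction="mean")
        .reset_index()
    )
    truth = SimTruth(cells=truth_cells, realized_fractions=realized)

    if params.ambient_msy_rate > 0:
        ambient_seed = int(rng.integers(0, 2**31 - 1))
        bundle = inject_ambient_msy(
            bundle, annotation, params.ambient_msy_rate, seed=ambient_seed,
            gene_weights=params.msy_gene_means,
        )
    return bundle, metadata, annotation, truth


def inject_ambient_msy(
    bundle: CountBundle,
    annotation: GeneAnnotation,
    rate: float,
    seed: int,
    gene_weights: dict[str, float] | None = None,
) -> CountBundle:
    """Add Poisson ambient MSY contamination to every cell.

    Each cell receives ``Poisson(rate)`` extra MSY UMIs, allocated across
    the MSY genes present in the bundle proportionally to ``gene_weights``
    (uniform if not given).  Counts are added to the spliced layer (ambient
    molecules are mature transcripts); non-MSY counts are unchanged.  With
    ``rate = 0`` the input is returned unchanged.

    The Poisson draws are realized as a fixed per-cell arrival stream, so
    for the same seed a larger rate only ever *adds* contamination on top
    of what a smaller rate produced: sweeps over rates are monotone cell by
    cell, which makes downstream anti-monotonicity of zero-MSY calls exact
    rather than statistical.  Rates above 20 are rejected (the stream holds
    64 arrivals per cell; overflow probability is negligible below that).
    """
    if rate < 0:
        raise ParameterError("ambient rate must be >= 0")
    if rate > 20:
        raise ParameterError("ambient rate above 20 UMIs/cell is unsupported")
    if rate == 0:
        return bundle
    rng = np.random.default_rng(seed)
    msy_flags = annotation.flags_for(bundle.genes, "is_msy")
    msy_rows = np.flatnonzero(msy_flags)
    if msy_rows.size == 0:
        raise ParameterError("bundle contains no MSY genes to contaminate")
    if gene_weights:
        w = np.array([gene_weights.get(bundle.genes[i], 0.0) for i in msy_rows])
        if w.sum() <= 0:
            w = np.ones(msy_rows.size)
    else:
        w = np.ones(msy_rows.size)
    w = w / w.sum()

    n_cells = bundle.n_cells
    K = 64  # fixed stream length: rate-independent so sweeps share draws
    arrivals = np.cumsum(rng.exponential(1.0, size=(n_cells, K)), axis=1)
    gene_of_arrival = msy_rows[
        np.searchsorted(np.cumsum(w), rng.random(size=(n_cells, K)))
    ]
    accepted = arrivals <= rate  # unit-rate process observed for `rate` time
    target = "spliced" if "spliced" in bundle.layers else next(iter(bundle.layers))
    cell_idx, arrival_idx = np.nonzero(accepted)
    extra = sp.coo_matrix(
        (
            np.ones(cell_idx.size, dtype=np.int64),
            (gene_of_arrival[cell_idx, arrival_idx], cell_idx),
        ),
        shape=(bundle.n_genes, n_cells),
    ).tocsr()
    layers = dict(bundle.layers)
    layers[target] = sp.csr_matrix(layers[target] + extra)
    return CountBundle(
        genes=bundle.genes, cells=bundle.cells, layers=layers,
        gene_symbols=bundle.gene_symbols,
    )


def write_simulation(
    outdir: str | Path,
    bundle: CountBundle,
    metadata: CellMetadata,
    annotation: GeneAnnotation,
    truth: SimTruth,
) -> Path:
    """Write a simulated dataset as an MTX bundle plus metadata/truth TSVs."""
    outdir = Path(outdir)
    write_mtx_bundle(bundle, outdir, annotation=annotation)
    metadata.table.to_csv(outdir / "cell_metadata.tsv", sep="\t", index=False)
    annotation.table.to_csv(outdir / "gene_annotation.tsv", sep="\t", index=False)
    truth.cells.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    truth.realized_fractions.to_csv(outdir / "truth_fractions.tsv", sep="\t", index=False)
    return outdir
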