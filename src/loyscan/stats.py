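"""The statistical battery for LOY enrichment analysis.

Implements, from first principles, the tests used to quantify LOY
enrichment across leukocyte subtypes:

* per-sample × cell-type LOY fraction tables;
* the Wilcoxon signed-rank test with exact enumeration-equivalent p-values
  at small n (via the generating-function distribution of the rank sum) and
  a tie- and continuity-corrected normal approximation otherwise;
* Theil–Sen median-of-pairwise-slopes regression (with the Siegel
  repeated-median variant), the robust line fit of choice when LOY
  percentages are far from normal, with a signed-rank p-value on the
  pairwise slopes;
* binomial / quasibinomial and negative-binomial GLMs fitted by
  iteratively reweighted least squares, with sum-to-zero factor coding;
* type-3 tests: each term is tested by refitting the model without that
  term's columns while every other term (including interactions) stays,
  referring the (dispersion-scaled) deviance difference to a chi-square.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import polygamma, psi
from scipy.stats import chi2, norm

__all__ = [
    "TestResult",
    "GLMFit",
    "loy_fraction_table",
    "wilcoxon_signed_rank",
    "theil_sen_regression",
    "build_design",
    "fit_glm",
    "type3_tests",
    "treg_abundance_analysis",
]


@dataclass
class TestResult:
    """A named test statistic with its p-value and method provenance."""

    name: str
    statistic: float
    p_value: float
    n: int
    method: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n": self.n,
            **{f"method_{k}": v for k, v in self.method.items()},
        }


# ---------------------------------------------------------------------------
# fraction tables


def loy_fraction_table(
    calls,
    metadata,
    typing: pd.DataFrame | None = None,
    emit_empty: bool = False,
) -> pd.DataFrame:
    """Per-(sample, cell type[, tissue]) LOY counts and percentages.

    Only assessed male cells enter denominators (``not_assessed`` cells are
    excluded).  ``typing`` maps cluster -> cell_type; without it the
    metadata's own ``cell_type`` column (or raw cluster) is used.  By
    default combinations absent from the data emit no row; ``emit_empty``
    adds n = 0 rows for every (sample, cell type) pair.
    """
    tab = calls.table.merge(
        metadata.table.reset_index(drop=True), on="barcode", how="left"
    )
    if typing is not None:
        tab = tab.merge(typing[["cluster", "cell_type"]], on="cluster", how="left")
    elif "cell_type" not in tab.columns:
        tab["cell_type"] = tab["cluster"]
    assessed = tab[tab["status"] != "not_assessed"].copy()
    if assessed.empty:
        warnings.warn("no assessed cells; fraction table is empty", stacklevel=2)
    keys = ["sample_id", "cell_type"]
    if "tissue" in assessed.columns and assessed["tissue"].notna().any():
        keys.append("tissue")
    grouped = (
        assessed.assign(is_loy=assessed["status"] == "LOY")
        .groupby(keys, sort=True, observed=True)["is_loy"]
        .agg(n_cells="size", n_loy="sum")
        .reset_index()
    )
    if emit_empty and not grouped.empty:
        full = pd.MultiIndex.from_product(
            [grouped["sample_id"].unique(), grouped["cell_type"].unique()],
            names=["sample_id", "cell_type"],
        )
        grouped = (
            grouped.set_index(["sample_id", "cell_type"])
            .reindex(full, fill_value=0)
            .reset_index()
        )
    grouped["pct_loy"] = np.where(
        grouped["n_cells"] > 0, 100.0 * grouped["n_loy"] / grouped["n_cells"], np.nan
    )
    return grouped


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


def _signed_rank_distribution(n: int) -> np.ndarray:
    """Counts of sign assignments by rank-sum: coefficients of ∏(1 + x^r)."""
    max_sum = n * (n + 1) // 2
    counts = np.zeros(max_sum + 1)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] += counts[: max_sum - r + 1].copy()
    return counts


def wilcoxon_signed_rank(
    x,
    y=None,
    alternative: str = "two-sided",
    exact_max_n: int = 25,
) -> TestResult:
    """Paired Wilcoxon signed-rank test.

    Zero differences are dropped (Wilcoxon's original procedure).  With at
    most ``exact_max_n`` nonzero differences and no tied absolute values,
    the p-value is exact (equivalent to enumerating all 2^n sign vectors);
    otherwise a normal approximation with mid-ranks, tie-corrected variance
    and continuity correction is used.  ``alternative`` is ``two-sided``,
    ``greater`` (x tends above y) or ``less``.
    """
    x = np.asarray(x, dtype=float)
    if y is None:
        d = x
    else:
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValueError("x and y must have equal length")
        d = x - y
    d = d[~np.isnan(d)]
    if d.size and np.all(d == 0):
        return TestResult(
            "wilcoxon_signed_rank", 0.0, 1.0, 0,
            {"exact": False, "alternative": alternative, "degenerate": True},
        )
    d = d[d != 0]
    n = d.size
    if n < 2:
        raise ValueError("fewer than 2 nonzero paired differences")
    absd = np.abs(d)
    ranks = pd.Series(absd).rank(method="average").to_numpy()
    w_plus = float(ranks[d > 0].sum())
    ties = pd.Series(absd).value_counts().to_numpy()
    has_ties = bool((ties > 1).any())

    if n <= exact_max_n and not has_ties:
        counts = _signed_rank_distribution(n)
        total = counts.sum()  # 2^n
        w = int(round(w_plus))
        p_ge = counts[w:].sum() / total
        p_le = counts[: w + 1].sum() / total
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_ge, p_le))
        return TestResult(
            "wilcoxon_signed_rank", w_plus, float(p), n,
            {"exact": True, "alternative": alternative},
        )

    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - ((ties**3 - ties).sum()) / 48.0
    sd = np.sqrt(var)
    if alternative == "greater":
        z = (w_plus - mean - 0.5) / sd
        p = norm.sf(z)
    elif alternative == "less":
        z = (w_plus - mean + 0.5) / sd
        p = norm.cdf(z)
    else:
        cc = 0.5 * np.sign(w_plus - mean)
        z = (w_plus - mean - cc) / sd if w_plus != mean else 0.0
        p = 2.0 * norm.sf(abs(z))
    return TestResult(
        "wilcoxon_signed_rank", w_plus, float(min(p, 1.0)), n,
        {"exact": False, "alternative": alternative, "tie_corrected": has_ties},
    )


# ---------------------------------------------------------------------------
# Theil–Sen / Siegel regression


@dataclass
class RobustLineFit:
    slope: float
    intercept: float
    test: TestResult
    n: int
    method: str


def theil_sen_regression(x, y, method: str = "theilsen") -> RobustLineFit:
    """Median-based robust regression of y on x.

    ``theilsen``: slope = median of all pairwise slopes (pairs with equal x
    excluded); intercept = median of ``y - slope * x``.  ``siegel``: slope =
    median over points of the median of that point's pairwise slopes.  The
    p-value is a one-sample Wilcoxon signed-rank of the pairwise slopes
    against zero, mirroring the summary of median-based linear model
    packages.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points")
    dx = x[:, None] - x[None, :]
    dy = y[:, None] - y[None, :]
    iu = np.triu_indices(n, k=1)
    dxu, dyu = dx[iu], dy[iu]
    valid = dxu != 0
    if not valid.any():
        raise ValueError("all x values identical: slope undefined")
    pair_slopes = dyu[valid] / dxu[valid]
    if method == "theilsen":
        slope = float(np.median(pair_slopes))
    elif method == "siegel":
        per_point = []
        for i in range(n):
            di = np.delete(dx[i], i)
            ei = np.delete(dy[i], i)
            ok = di != 0
            if ok.any():
                per_point.append(np.median(ei[ok] / di[ok]))
        slope = float(np.median(per_point))
    else:
        raise ValueError(f"unknown method {method!r}")
    intercept = float(np.median(y - slope * x))
    test = wilcoxon_signed_rank(pair_slopes, alternative="two-sided")
    test.name = f"{method}_slope"
    test.method["slope"] = slope
    return RobustLineFit(slope=slope, intercept=intercept, test=test, n=n, method=method)


# ---------------------------------------------------------------------------
# design matrices with sum-to-zero contrasts


class AliasingError(ValueError):
    pass


def _factor_columns(series: pd.Series, name: str) -> tuple[np.ndarray, list[str]]:
    """Sum-to-zero (deviation) coding: k levels -> k-1 columns; the last
    level (sorted order) is coded -1 in every column."""
    levels = sorted(pd.unique(series.astype(str)))
    k = len(levels)
    if k < 2:
        raise AliasingError(f"factor {name!r} has a single level")
    idx = pd.Categorical(series.astype(str), categories=levels).codes
    cols = np.zeros((len(series), k - 1))
    for j in range(k - 1):
        cols[idx == j, j] = 1.0
    cols[idx == k - 1, :] = -1.0
    names = [f"{name}[S.{levels[j]}]" for j in range(k - 1)]
    return cols, names


def build_design(
    data: pd.DataFrame, terms: list[str]
) -> tuple[np.ndarray, list[str], dict[str, slice]]:
    """Build an intercepted design matrix from main-effect and ``a:b``
    interaction terms; factors (non-numeric columns) get sum-to-zero
    contrasts.  Returns (X, column names, term -> column slice)."""
    pieces: dict[str, tuple[np.ndarray, list[str]]] = {}
    for col in {c for t in terms for c in t.split(":")}:
        if col not in data.columns:
            raise KeyError(f"term column {col!r} absent from data")
        s = data[col]
        if pd.api.types.is_numeric_dtype(s) and not isinstance(
            s.dtype, pd.CategoricalDtype
        ):
            pieces[col] = (s.to_numpy(dtype=float)[:, None], [col])
        else:
            pieces[col] = _factor_columns(s, col)

    blocks = [np.ones((len(data), 1))]
    names = ["(Intercept)"]
    slices: dict[str, slice] = {}
    start = 1
    for term in terms:
        comps = term.split(":")
        mats = [pieces[c][0] for c in comps]
        labs = [pieces[c][1] for c in comps]
        cols, cnames = mats[0], labs[0]
        for m, l in zip(mats[1:], labs[1:]):
            cols = np.concatenate(
                [cols[:, [i]] * m for i in range(cols.shape[1])], axis=1
            )
            cnames = [f"{a}:{b}" for a in cnames for b in l]
        blocks.append(cols)
        names.extend(cnames)
        slices[term] = slice(start, start + cols.shape[1])
        start += cols.shape[1]
    X = np.concatenate(blocks, axis=1)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise AliasingError(
            f"design is rank deficient ({np.linalg.matrix_rank(X)} < {X.shape[1]}): "
            "aliased terms"
        )
    return X, names, slices


# ---------------------------------------------------------------------------
# GLMs by IRLS


@dataclass
class GLMFit:
    """A fitted GLM with sum-contrast design bookkeeping."""

    family: str
    coef: pd.Series
    se: pd.Series
    deviance: float
    dispersion: float  # φ̂ for quasi families, 1 otherwise
    theta: float | None  # NB size parameter
    df_residual: int
    n: int
    converged: bool
    n_iter: int
    term_slices: dict[str, slice]
    mu: np.ndarray = field(repr=False, default=None)
    warnings_: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.deviance < -1e-8:
            raise ValueError("negative deviance")


def _binomial_deviance(y: np.ndarray, mu: np.ndarray, w: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        t2 = np.where(y < 1, (1 - y) * np.log((1 - y) / (1 - mu)), 0.0)
    return float(2.0 * np.sum(w * (t1 + t2)))


def _nb_deviance(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
    t2 = (y + theta) * np.log((y + theta) / (mu + theta))
    return float(2.0 * np.sum(t1 - t2))


def _irls(
    X: np.ndarray,
    y: np.ndarray,
    prior_w: np.ndarray,
    family: str,
    theta: float | None,
    offset: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, float, bool, int]:
    """Iteratively reweighted least squares for logit-binomial or log-NB."""
    n = y.size
    if family in ("binomial", "quasibinomial"):
        mu = (prior_w * y + 0.5) / (prior_w + 1.0)
        mu = np.clip(mu, 1e-10, 1 - 1e-10)
        eta = np.log(mu / (1 - mu))
    else:
        mu = np.maximum(y, 0.0) + 0.5
        eta = np.log(mu)
    beta = np.zeros(X.shape[1])
    dev = np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if family in ("binomial", "quasibinomial"):
            v = mu * (1 - mu)
            z = (eta - offset) + (y - mu) / v
            w = prior_w * v
        else:
            z = (eta - offset) + (y - mu) / mu
            w = prior_w * mu / (1.0 + mu / theta)
        WX = X * w[:, None]
        beta = np.linalg.solve(X.T @ WX, WX.T @ z)
        eta = X @ beta + offset
        if family in ("binomial", "quasibinomial"):
            eta = np.clip(eta, -30, 30)
            mu = 1.0 / (1.0 + np.exp(-eta))
            mu = np.clip(mu, 1e-10, 1 - 1e-10)
            new_dev = _binomial_deviance(y, mu, prior_w)
        else:
            eta = np.clip(eta, -30, 30)
            mu = np.exp(eta)
            new_dev = _nb_deviance(y, mu, theta)
        if np.isfinite(dev) and abs(new_dev - dev) < tol * (abs(new_dev) + 0.1):
            dev = new_dev
            converged = True
            break
        dev = new_dev
    return beta, mu, float(dev), converged, it


def _estimate_theta(
    y: np.ndarray, mu: np.ndarray, max_iter: int = 50, tol: float = 1e-8
) -> float:
    """Newton iterations on the NB profile likelihood for the size θ."""
    var = max(np.var(y), 1e-8)
    m = np.mean(y)
    theta = m**2 / max(var - m, 1e-8)
    theta = float(np.clip(theta, 1e-3, 1e6))
    for _ in range(max_iter):
        score = np.sum(
            psi(y + theta) - psi(theta) + np.log(theta) + 1.0
            - np.log(theta + mu) - (y + theta) / (theta + mu)
        )
        info = np.sum(
            polygamma(1, y + theta) - polygamma(1, theta) + 1.0 / theta
            - 2.0 / (mu + theta) + (y + theta) / (mu + theta) ** 2
        )
        if info == 0:
            break
        # damped Newton step on the profile score
        step = score / abs(info)
        new_theta = theta + step
        if new_theta <= 0:
            new_theta = theta / 2.0
        if abs(new_theta - theta) < tol * (theta + 0.1):
            theta = float(new_theta)
            break
        theta = float(min(new_theta, 1e8))
    return theta


def fit_glm(
    family: str,
    response,
    data: pd.DataFrame,
    terms: list[str],
    trials=None,
    offset=None,
    theta: float | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> GLMFit:
    """Fit a GLM by IRLS with sum-to-zero factor contrasts.

    ``family`` is ``binomial``, ``quasibinomial`` (logit link, ``response``
    = successes with ``trials``, or 0/1 outcomes) or ``negative_binomial``
    (log link, ``response`` = counts; θ estimated by alternating Newton
    updates with the IRLS unless supplied).  Quasibinomial dispersion is
    the Pearson χ²/df.  Convergence: relative deviance change below ``tol``
    within ``max_iter`` iterations, flagged otherwise.
    """
    if family not in ("binomial", "quasibinomial", "negative_binomial"):
        raise ValueError(f"unknown family {family!r}")
    y_raw = np.asarray(response, dtype=float)
    n = y_raw.size
    X, names, slices = build_design(data, terms)
    offset = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)

    warns: list[str] = []
    if family in ("binomial", "quasibinomial"):
        if trials is None:
            prior_w = np.ones(n)
            y = y_raw
        else:
            prior_w = np.asarray(trials, dtype=float)
            y = y_raw / prior_w
        if np.any((y < 0) | (y > 1)):
            raise ValueError("binomial response outside [0, trials]")
        beta, mu, dev, conv, it = _irls(X, y, prior_w, family, None, offset, tol, max_iter)
        pearson = float(np.sum(prior_w * (y - mu) ** 2 / (mu * (1 - mu))))
        df_resid = n - X.shape[1]
        phi = pearson / df_resid if (family == "quasibinomial" and df_resid > 0) else 1.0
        w = prior_w * mu * (1 - mu)
        theta_hat = None
    else:
        if np.any(y_raw < 0):
            raise ValueError("negative counts for a negative-binomial model")
        prior_w = np.ones(n)
        y = y_raw
        if theta is None:
            theta_hat = 1.0
            beta = mu = None
            dev, conv, it_total = np.inf, False, 0
            for _ in range(25):
                beta, mu, dev, conv, it = _irls(
                    X, y, prior_w, family, theta_hat, offset, tol, max_iter
                )
                it_total += it
                new_theta = _estimate_theta(y, mu)
                if abs(new_theta - theta_hat) < 1e-6 * (theta_hat + 0.1):
                    theta_hat = new_theta
                    break
                theta_hat = new_theta
            it = it_total
        else:
            theta_hat = float(theta)
            beta, mu, dev, conv, it = _irls(
                X, y, prior_w, family, theta_hat, offset, tol, max_iter
            )
        df_resid = n - X.shape[1]
        phi = 1.0
        w = mu / (1.0 + mu / theta_hat)

    if np.max(np.abs(beta)) > 15:
        warns.append("possible separation: very large coefficient on the link scale")

    XtWX = X.T @ (X * w[:, None])
    cov = np.linalg.inv(XtWX) * phi
    se = np.sqrt(np.diag(cov))
    fit = GLMFit(
        family=family,
        coef=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        deviance=max(dev, 0.0),
        dispersion=float(phi),
        theta=theta_hat,
        df_residual=df_resid,
        n=n,
        converged=conv,
        n_iter=it,
        term_slices=slices,
        mu=mu,
        warnings_=warns,
    )
    return fit


def type3_tests(
    family: str,
    response,
    data: pd.DataFrame,
    terms: list[str],
    trials=None,
    offset=None,
    theta: float | None = None,
) -> pd.DataFrame:
    """Type-3 per-term tests under sum-to-zero contrasts.

    Each term is tested by refitting the model with that term's columns
    removed while all other terms (including any interactions) remain; the
    statistic is the deviance difference, divided by the full model's
    Pearson dispersion for quasi families, referred to a chi-square with
    the term's column count as Df.  For negative-binomial models θ is held
    at the full-model estimate in the reduced fits.  Returns a DataFrame
    with columns term, LR, Df, p_value.
    """
    full = fit_glm(family, response, data, terms, trials=trials, offset=offset, theta=theta)
    theta_full = full.theta
    rows = []
    for term in terms:
        reduced_terms = [t for t in terms if t != term]
        X_full, _, slices = build_design(data, terms)
        df_term = slices[term].stop - slices[term].start
        if reduced_terms:
            red = fit_glm(
                family, response, data, reduced_terms, trials=trials,
                offset=offset, theta=theta_full,
            )
            dev_red = red.deviance
        else:
            dev_red = _intercept_only_deviance(
                family, response, trials, offset, theta_full
            )
        lr = (dev_red - full.deviance) / full.dispersion
        lr = max(lr, 0.0)
        rows.append((term, lr, df_term, float(chi2.sf(lr, df_term))))
    return pd.DataFrame(rows, columns=["term", "LR", "Df", "p_value"])


def _intercept_only_deviance(family, response, trials, offset, theta) -> float:
    y = np.asarray(response, dtype=float)
    n = y.size
    X = np.ones((n, 1))
    off = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)
    if family in ("binomial", "quasibinomial"):
        w = np.ones(n) if trials is None else np.asarray(trials, dtype=float)
        _, _, dev, _, _ = _irls(X, y / w, w, family, None, off)
    else:
        _, _, dev, _, _ = _irls(X, y, np.ones(n), family, theta, off)
    return dev


# ---------------------------------------------------------------------------
# the Treg abundance analysis


DEFAULT_OTHER_T = ("Naive CD4 T", "Helper T", "Cytotoxic T")
DEFAULT_CD4 = ("Naive CD4 T", "Helper T")


def treg_abundance_analysis(
    fractions: pd.DataFrame,
    treg_prefix: str = "Treg",
    other_t_types: tuple[str, ...] = DEFAULT_OTHER_T,
    cd4_types: tuple[str, ...] = DEFAULT_CD4,
    glm_family: str = "quasibinomial",
    pooling: str = "cell",
    regression: str = "theilsen",
) -> dict:
    """Quantify the association between Treg LOY and Treg abundance.

    From a fraction table, computes per sample: the Treg LOY percentage,
    the LOY percentage pooled over the other T-cell types (cell-weighted by
    default, ``pooling="type"`` averages the per-type percentages), and the
    Treg share of CD4+ cells (Tregs plus ``cd4_types``).  Returns

    * ``regression`` — Theil–Sen (or Siegel) fit of Treg share on Treg LOY%;
    * ``wilcoxon`` — paired signed-rank of Treg LOY% vs pooled other-T LOY%;
    * ``glm_type3`` — type-3 table of a GLM of Treg share (successes =
      Treg cells, trials = CD4+ cells) on Treg LOY%;
    * ``per_sample`` — the assembled per-sample frame.
    """
    f = fractions.copy()
    is_treg = f["cell_type"].astype(str).str.startswith(treg_prefix)
    rows = []
    for sample, sub in f.groupby("sample_id"):
        treg = sub[is_treg.loc[sub.index]]
        other = sub[sub["cell_type"].isin(other_t_types)]
        cd4 = sub[sub["cell_type"].isin(cd4_types) | is_treg.loc[sub.index]]
        if treg["n_cells"].sum() == 0 or other["n_cells"].sum() == 0:
            continue
        treg_loy_pct = 100.0 * treg["n_loy"].sum() / treg["n_cells"].sum()
        if pooling == "cell":
            other_loy_pct = 100.0 * other["n_loy"].sum() / other["n_cells"].sum()
        elif pooling == "type":
            other_loy_pct = float(other["pct_loy"].mean())
        else:
            raise ValueError(f"unknown pooling {pooling!r}")
        rows.append(
            (
                sample,
                float(treg_loy_pct),
                float(other_loy_pct),
                int(treg["n_cells"].sum()),
                int(cd4["n_cells"].sum()),
                float(treg["n_cells"].sum() / cd4["n_cells"].sum()),
            )
        )
    per_sample = pd.DataFrame(
        rows,
        columns=[
            "sample_id", "treg_loy_pct", "other_t_loy_pct",
            "n_treg", "n_cd4", "treg_fraction",
        ],
    )
    if len(per_sample) < 3:
        raise ValueError(
            f"only {len(per_sample)} samples with Tregs and other T cells; need >= 3"
        )
    reg = theil_sen_regression(
        per_sample["treg_loy_pct"], per_sample["treg_fraction"], method=regression
    )
    wilcox = wilcoxon_signed_rank(
        per_sample["treg_loy_pct"], per_sample["other_t_loy_pct"],
        alternative="two-sided",
    )
    glm_tab = type3_tests(
        glm_family,
        per_sample["n_treg"].to_numpy(),
        per_sample[["treg_loy_pct"]],
        terms=["treg_loy_pct"],
        trials=per_sample["n_cd4"].to_numpy(),
    )
    return {
        "regression": reg,
        "wilcoxon": wilcox,
        "glm_type3": glm_tab,
        "per_sample": per_sample,
    }
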