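"""The brain-body mass (BBM) model family and its diagnostics.

Variants of the scaling model in log10-gram space:

  * ``single``: one intercept and slope (the classical power law);
  * ``multiple-slopes``: a separate intercept and slope per taxonomic group,
    restricted to groups with at least ``min_group_size`` species (default
    20 — two parameters per group and ten data points per parameter);
  * ``quadratic``: a single curvilinear relationship with a squared
    log-body term; negative curvature means the marginal slope declines
    with body size;
  * ``quadratic+covariates``: the quadratic plus extra columns (BMR, brain
    network mean-short-path, ...);
  * ``asymptotic``: an experimental saturating alternative
    y = c − d·exp(−k·x) in log-log space.

The quadratic term is computed on mean-centered log body mass internally
(for conditioning) and coefficients are reported back-transformed to the
uncentered scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import phylo_gls
from .phylo_gls import BayesGLSFit, GLSFit
from .treeio import Phylogeny, prune_to_tips
from .varrates import MCMCSettings, RatePosterior, VarRatesPriors, fit_variable_rates

__all__ = [
    "AllometryModelSpec",
    "DesignInfo",
    "BBMFit",
    "build_design",
    "fit_bbm",
    "marginal_slope",
    "slope_mass_correlation",
    "group_slopes",
    "fit_asymptotic",
]

VARIANTS = ("single", "multiple-slopes", "quadratic", "quadratic+covariates",
            "asymptotic")


@dataclass
class AllometryModelSpec:
    variant: str = "quadratic"
    group_col: str = "group"
    min_group_size: int = 20          # inclusive: N >= 20 keeps a group
    covariates: tuple = ()
    center_quadratic: bool = True

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; "
                             f"choose from {VARIANTS}")
        if self.min_group_size < 4:
            raise ValueError("min_group_size must be >= 4 "
                             "(two parameters per group)")


@dataclass
class DesignInfo:
    X: np.ndarray
    names: list
    retained: np.ndarray              # boolean mask into the input table
    x_mean: float                     # centering constant for the quadratic
    report: dict = field(default_factory=dict)


def build_design(table: pd.DataFrame, spec: AllometryModelSpec) -> DesignInfo:
    """Build the regression design for a model variant.

    Groups below the size threshold are dropped from multi-group designs
    (and named in the report); rows with missing covariates are dropped for
    covariate variants.
    """
    x = table["log_body"].to_numpy(float)
    n = len(table)
    retained = np.ones(n, dtype=bool)
    report: dict = {"dropped_groups": {}, "dropped_rows_missing_covariate": 0}

    if spec.variant in ("quadratic+covariates",) and spec.covariates:
        for c in spec.covariates:
            retained &= np.isfinite(table[c].to_numpy(float))
        report["dropped_rows_missing_covariate"] = int(n - retained.sum())

    if spec.variant == "multiple-slopes":
        if spec.group_col not in table.columns:
            raise ValueError(f"grouping column {spec.group_col!r} missing")
        groups = table[spec.group_col].astype(str).to_numpy()
        counts = pd.Series(groups).value_counts()
        keep_groups = counts[counts >= spec.min_group_size].index.tolist()
        for g, c in counts.items():
            if g not in keep_groups:
                report["dropped_groups"][g] = int(c)
        if len(keep_groups) < 2:
            raise ValueError(
                "fewer than two groups meet the size threshold "
                f"({spec.min_group_size}); kept: {keep_groups}")
        retained &= np.isin(groups, keep_groups)
        xk = x[retained]
        gk = groups[retained]
        cols, names = [], []
        for g in sorted(keep_groups):
            ind = (gk == g).astype(float)
            cols.extend([ind, ind * xk])
            names.extend([f"intercept[{g}]", f"slope[{g}]"])
        X = np.column_stack(cols)
        return DesignInfo(X, names, retained, 0.0, report)

    xk = x[retained]
    x_mean = float(xk.mean()) if spec.center_quadratic else 0.0
    xc = xk - x_mean
    if spec.variant == "single":
        X = np.column_stack([np.ones(xk.size), xk])
        names = ["intercept", "log_body"]
        x_mean = 0.0
    elif spec.variant in ("quadratic", "quadratic+covariates"):
        X = np.column_stack([np.ones(xk.size), xc, xc ** 2])
        names = ["intercept", "log_body", "log_body_sq"]
        if spec.variant == "quadratic+covariates":
            for c in spec.covariates:
                X = np.column_stack([X, table.loc[retained, c].to_numpy(float)])
                names.append(c)
    elif spec.variant == "asymptotic":
        # nonlinear: handled by fit_asymptotic; expose raw x for callers
        X = np.column_stack([np.ones(xk.size), xk])
        names = ["intercept", "log_body"]
        x_mean = 0.0
    else:  # pragma: no cover
        raise AssertionError(spec.variant)
    report["n_retained"] = int(retained.sum())
    return DesignInfo(X, names, retained, x_mean, report)


def _uncenter(beta: np.ndarray, names: list, x_mean: float) -> np.ndarray:
    """Back-transform coefficients fitted on centered x to the raw scale.

    Works on a (S, p) sample matrix or a length-p vector; only the
    intercept / log_body / log_body_sq triple is affected.
    """
    if x_mean == 0.0 or "log_body_sq" not in names:
        return beta
    b = np.array(beta, float, copy=True)
    one = b.ndim == 1
    if one:
        b = b[None, :]
    i0, i1, i2 = (names.index(n) for n in
                  ("intercept", "log_body", "log_body_sq"))
    b0, b1, b2 = b[:, i0].copy(), b[:, i1].copy(), b[:, i2].copy()
    b[:, i1] = b1 - 2.0 * b2 * x_mean
    b[:, i0] = b0 - b1 * x_mean + b2 * x_mean ** 2
    return b[0] if one else b


@dataclass
class BBMFit:
    """A fitted brain-body model, coefficients on the uncentered scale."""

    spec: AllometryModelSpec
    names: list
    beta: np.ndarray                 # point estimate (ML or posterior median)
    engine: str
    design: DesignInfo
    result: object                   # GLSFit | BayesGLSFit | RatePosterior
    samples_beta: np.ndarray | None  # uncentered posterior draws, if Bayesian
    r2: float
    table: pd.DataFrame              # retained rows, tree tip order

    def predict(self, log_body) -> np.ndarray:
        x = np.asarray(log_body, float)
        if self.spec.variant in ("quadratic", "quadratic+covariates"):
            b = {n: v for n, v in zip(self.names, self.beta)}
            return (b["intercept"] + b["log_body"] * x
                    + b["log_body_sq"] * x ** 2)
        if self.spec.variant == "single":
            return self.beta[0] + self.beta[1] * x
        raise ValueError(f"predict unsupported for {self.spec.variant!r}")

    def px(self) -> dict:
        from .evidence import px
        if self.samples_beta is None:
            raise ValueError("Px needs a Bayesian engine")
        return {n: px(self.samples_beta[:, j])
                for j, n in enumerate(self.names)}

    def curvature(self) -> float:
        return float(self.beta[self.names.index("log_body_sq")])

    def log_evidence(self) -> float | None:
        if isinstance(self.result, BayesGLSFit):
            return self.result.log_evidence
        return None


def fit_bbm(tree: Phylogeny, table: pd.DataFrame, spec: AllometryModelSpec,
            engine: str = "ml", priors: VarRatesPriors | None = None,
            settings: MCMCSettings | None = None, n_samples: int = 2000,
            seed: int = 0) -> BBMFit:
    """Fit a BBM variant with the requested inference engine.

    Engines: ``ml`` (homogeneous-rate maximum likelihood), ``bayes``
    (homogeneous-rate conjugate posterior, exact draws), ``variable-rates``
    (reversible-jump MCMC with branch rate scalars). ``table`` must be in
    the tree's tip order (use :func:`allometree.treeio.match_and_prune`).
    """
    if list(table["species"]) != tree.tip_labels:
        raise ValueError("table must be aligned to tree tip order")
    if spec.variant == "asymptotic":
        return fit_asymptotic(tree, table, spec)
    info = build_design(table, spec)
    sub_table = table.loc[info.retained].reset_index(drop=True)
    if info.retained.all():
        sub_tree = tree
    else:
        sub_tree = prune_to_tips(tree, sub_table["species"].tolist())
        order = [sub_table["species"].tolist().index(s)
                 for s in sub_tree.tip_labels]
        sub_table = sub_table.iloc[order].reset_index(drop=True)
        info = build_design(sub_table, spec)
    y = sub_table["log_brain"].to_numpy(float)

    if engine == "ml":
        res = phylo_gls.gls_ml_fit(sub_tree, info.X, y, sub_tree.length,
                                   info.names)
        beta = _uncenter(res.beta, info.names, info.x_mean)
        return BBMFit(spec, info.names, beta, engine, info, res, None,
                      res.r2, sub_table)
    if engine == "bayes":
        res = phylo_gls.gls_bayes_fit(sub_tree, info.X, y, sub_tree.length,
                                      info.names, n_samples=n_samples,
                                      seed=seed)
        samples = _uncenter(res.samples_beta, info.names, info.x_mean)
        beta = np.median(samples, axis=0)
        return BBMFit(spec, info.names, beta, engine, info, res, samples,
                      res.r2, sub_table)
    if engine == "variable-rates":
        settings = settings or MCMCSettings(seed=seed)
        res = fit_variable_rates(sub_tree, info.X, y, priors, settings,
                                 info.names)
        samples = _uncenter(res.samples_beta, info.names, info.x_mean)
        beta = np.median(samples, axis=0)
        # R² of the median coefficients on the median rate-scaled tree
        from .varrates import median_scaled_tree
        sc = median_scaled_tree(res, sub_tree)
        ml = phylo_gls.gls_ml_fit(sc, info.X, y, sc.length, info.names)
        return BBMFit(spec, info.names, beta, engine, info, res, samples,
                      ml.r2, sub_table)
    raise ValueError(f"unknown engine {engine!r}")


def marginal_slope(fit: BBMFit, x=None) -> dict:
    """Marginal slope dy/dx = β₁ + 2β₂x of a quadratic fit (uncentered
    scale), plus the percentage reduction across the observed body-mass
    range."""
    if "log_body_sq" not in fit.names:
        raise ValueError("marginal_slope requires a quadratic fit")
    b1 = fit.beta[fit.names.index("log_body")]
    b2 = fit.beta[fit.names.index("log_body_sq")]
    obs = fit.table["log_body"].to_numpy(float)
    lo, hi = float(obs.min()), float(obs.max())
    s_lo, s_hi = b1 + 2 * b2 * lo, b1 + 2 * b2 * hi
    reduction = 0.0 if s_lo == 0 else 100.0 * (s_lo - s_hi) / s_lo
    out = {"slope_at_min": s_lo, "slope_at_max": s_hi,
           "percent_reduction": reduction, "x_range": (lo, hi)}
    if x is not None:
        out["slope"] = b1 + 2 * b2 * np.asarray(x, float)
    return out


def group_slopes(fit: BBMFit) -> pd.DataFrame:
    """Per-group slope point estimates and median log body mass from a
    multiple-slopes fit."""
    if fit.spec.variant != "multiple-slopes":
        raise ValueError("group_slopes requires a multiple-slopes fit")
    rows = []
    for j, nm in enumerate(fit.names):
        if not nm.startswith("slope["):
            continue
        g = nm[6:-1]
        mask = fit.table[fit.spec.group_col].astype(str) == g
        rows.append({"group": g, "slope": float(fit.beta[j]),
                     "median_log_body":
                         float(fit.table.loc[mask, "log_body"].median()),
                     "n": int(mask.sum())})
    return pd.DataFrame(rows)


def slope_mass_correlation(slopes: pd.DataFrame, exclude=()):
    """Spearman rank correlation between group slope and median log body
    mass.

    Ties get average ranks. The p-value is by exact permutation when fewer
    than 10 groups remain (every permutation enumerated), otherwise by the
    t-approximation. Returns (rho, p, n_groups).
    """
    df = slopes[~slopes["group"].isin(set(exclude))]
    s = df["slope"].to_numpy(float)
    m = df["median_log_body"].to_numpy(float)
    n = s.size
    if n < 4:
        raise ValueError("need at least 4 groups")
    if np.ptp(s) == 0 or np.ptp(m) == 0:
        return np.nan, np.nan, n
    rho = float(stats.spearmanr(s, m).statistic)
    if n < 10:
        rs = stats.rankdata(s)
        rm = stats.rankdata(m)
        from itertools import permutations
        obs = np.corrcoef(rs, rm)[0, 1]
        count = total = 0
        for perm in permutations(range(n)):
            r = np.corrcoef(rs[list(perm)], rm)[0, 1]
            total += 1
            if abs(r) >= abs(obs) - 1e-12:
                count += 1
        p = count / total
    else:
        p = float(stats.spearmanr(s, m).pvalue)
    return rho, float(p), n


def fit_asymptotic(tree: Phylogeny, table: pd.DataFrame,
                   spec: AllometryModelSpec) -> BBMFit:
    """Experimental saturating model y = c − d·exp(−k·x) in log-log space.

    The rate k is profiled by 1-D optimization; (c, d) are GLS-linear given
    k. A stand-in for power-curve alternatives whose exact form varies in
    the literature.
    """
    x = table["log_body"].to_numpy(float)
    y = table["log_brain"].to_numpy(float)
    xs = (x - x.min()) / max(np.ptp(x), 1e-9)

    def profile_rss(log_k):
        k = np.exp(log_k)
        X = np.column_stack([np.ones(x.size), -np.exp(-k * xs)])
        try:
            f = phylo_gls.gls_ml_fit(tree, X, y, tree.length)
        except np.linalg.LinAlgError:
            return np.inf
        return f.rss

    opt = optimize.minimize_scalar(profile_rss, bounds=(-4.0, 4.0),
                                   method="bounded")
    k = float(np.exp(opt.x))
    X = np.column_stack([np.ones(x.size), -np.exp(-k * xs)])
    res = phylo_gls.gls_ml_fit(tree, X, y, tree.length, ["c", "d"])
    info = DesignInfo(X, ["c", "d"], np.ones(len(table), bool), 0.0,
                      {"k": k, "experimental": True})
    beta = np.array([res.beta[0], res.beta[1], k])
    return BBMFit(spec, ["c", "d", "k"], beta, "ml", info, res, None,
                  res.r2, table)
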