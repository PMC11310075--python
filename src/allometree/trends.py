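"""Pathwise rates and directional trends in relative brain mass.

A branch whose rate scalar exceeds 1 has experienced more residual (relative
brain mass) change than its duration alone predicts. The sum of rate-scaled
branch lengths from the root to a tip — the pathwise rate — therefore
measures how much adaptive change that species has accumulated. A
systematic association between relative brain mass and pathwise rate can
only arise from repeated directional change, i.e. an evolutionary trend.

Trend regressions are phylogenetic (BM covariance) on the median rate-scaled
tree, so that the extra variance accrued on fast branches is in the error
model and does not masquerade as a trend.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import phylo_gls
from .allometry import BBMFit
from .treeio import Phylogeny

__all__ = [
    "pathwise_rates",
    "relative_brain",
    "trend_regression",
    "TrendResult",
]


def pathwise_rates(scaled_tree: Phylogeny) -> pd.DataFrame:
    """Per-species sum of rate-scaled branch lengths root → tip on a given
    (e.g. median-rate-scaled) tree."""
    depths = scaled_tree.node_depths()
    tips = scaled_tree.tip_indices
    return pd.DataFrame({
        "species": [scaled_tree.labels[i] for i in tips],
        "pathwise_rate": depths[tips],
    })


def _path_matrix(tree: Phylogeny, branches: np.ndarray) -> np.ndarray:
    """Node × branch indicator: branch b lies on the root path of node i."""
    col = {int(b): j for j, b in enumerate(branches)}
    P = np.zeros((tree.n_nodes, branches.size))
    for node in tree.postorder()[::-1]:   # preorder
        p = tree.parent[node]
        if p < 0:
            continue
        P[node] = P[p]
        P[node, col[node]] = 1.0
    return P


def posterior_node_pathwise(posterior, tree: Phylogeny,
                            summary: str = "median") -> np.ndarray:
    """Pathwise rate per node, summarized across the rate posterior.

    For each retained sample the path sum uses that sample's scalars; the
    per-node median (or mean) is then taken across samples. This is not the
    same as summing on the median-scaled tree: the per-branch median is a
    much harsher summary (a branch with an uncertain shift contributes its
    full scaled length to many samples but nothing to the branchwise
    median), and the two only agree when medians commute with the sum.
    """
    P = _path_matrix(tree, posterior.branches)
    scaled = posterior.samples_r * tree.length[posterior.branches]  # (S, B)
    paths = scaled @ P.T                                            # (S, N)
    if summary == "median":
        return np.median(paths, axis=0)
    if summary == "mean":
        return paths.mean(axis=0)
    if summary == "mode":
        # half-sample mode per node, adequate for unimodal path sums
        out = np.empty(paths.shape[1])
        for j in range(paths.shape[1]):
            s = np.sort(paths[:, j])
            while s.size > 2:
                h = s.size // 2
                widths = s[h:] - s[:s.size - h]
                i = int(np.argmin(widths))
                s = s[i:i + h + 1]
            out[j] = s.mean()
        return out
    raise ValueError(f"unknown summary {summary!r}")


def posterior_pathwise_rates(posterior, tree: Phylogeny,
                             summary: str = "median") -> pd.DataFrame:
    """Per-species pathwise rate summarized across the posterior (the
    default trend predictor)."""
    vals = posterior_node_pathwise(posterior, tree, summary)
    tips = tree.tip_indices
    return pd.DataFrame({
        "species": [tree.labels[i] for i in tips],
        "pathwise_rate": vals[tips],
    })


def relative_brain(table: pd.DataFrame, fit: BBMFit) -> pd.DataFrame:
    """Relative brain mass: observed log brain minus the fitted
    posterior-median BBM prediction at the species' body mass."""
    missing = set(table["species"]) - set(fit.table["species"])
    if missing:
        raise ValueError(f"species absent from the BBM fit: {sorted(missing)[:5]}")
    pred = fit.predict(table["log_body"].to_numpy(float))
    return pd.DataFrame({
        "species": table["species"].to_numpy(),
        "relative_brain": table["log_brain"].to_numpy(float) - pred,
    })


@dataclass
class TrendResult:
    table: pd.DataFrame          # group, slope, px, n
    fit: object                  # underlying BayesGLSFit
    names: list
    per_group: bool

    def slope(self, group: str = "all") -> float:
        row = self.table[self.table["group"] == group]
        if row.empty:
            raise KeyError(group)
        return float(row["slope"].iloc[0])


def trend_regression(rel_brain: pd.DataFrame, pathwise: pd.DataFrame,
                     groups: pd.Series | None, scaled_tree: Phylogeny,
                     per_group: bool = False, min_group_size: int = 20,
                     group_intercepts: bool = False,
                     n_samples: int = 2000, seed: int = 0) -> TrendResult:
    """Bayesian phylogenetic regression of relative brain mass on pathwise
    rate, on the rate-scaled tree.

    With ``per_group`` the slope varies by group (groups meeting the size
    threshold; smaller groups pool into ``rest``) around a common intercept
    — a trend then shows up as that group's excess relative brain mass per
    unit of accumulated rate. ``group_intercepts`` additionally frees the
    intercepts, in which case only within-group covariation identifies the
    slopes. Px per slope.
    """
    df = rel_brain.merge(pathwise, on="species")
    order = {s: i for i, s in enumerate(scaled_tree.tip_labels)}
    missing = set(scaled_tree.tip_labels) - set(df["species"])
    if missing:
        raise ValueError(f"tips without trend data: {sorted(missing)[:5]}")
    df = df.sort_values("species", key=lambda s: s.map(order)).reset_index(drop=True)
    y = df["relative_brain"].to_numpy(float)
    path = df["pathwise_rate"].to_numpy(float)
    if np.ptp(path) < 1e-12:
        raise ValueError("pathwise rates have zero variance: no rate "
                         "heterogeneity detected, trend is unidentifiable")

    if not per_group or groups is None:
        X = np.column_stack([np.ones(y.size), path])
        names = ["intercept", "pathwise[all]"]
        glabels = ["all"]
    else:
        g = pd.Series(groups).astype(str).to_numpy()
        gdf = pd.DataFrame({"species": rel_brain["species"], "group": g})
        df = df.merge(gdf, on="species")
        gg = df["group"].to_numpy()
        counts = pd.Series(gg).value_counts()
        eligible = sorted(counts[counts >= min_group_size].index)
        lab = np.where(np.isin(gg, eligible), gg, "rest")
        glabels = sorted(set(lab), key=lambda s: (s == "rest", s))
        cols, names = [], []
        if not group_intercepts:
            cols.append(np.ones(y.size))
            names.append("intercept")
        for gname in glabels:
            ind = (lab == gname).astype(float)
            if group_intercepts:
                cols.append(ind)
                names.append(f"intercept[{gname}]")
            cols.append(ind * path)
            names.append(f"pathwise[{gname}]")
        X = np.column_stack(cols)

    fit = phylo_gls.gls_bayes_fit(scaled_tree, X, y, scaled_tree.length,
                                  names, n_samples=n_samples, seed=seed)
    from .evidence import px
    rows = []
    for j, nm in enumerate(names):
        if not nm.startswith("pathwise["):
            continue
        gname = nm[9:-1]
        n_g = y.size if gname == "all" else int((X[:, j] != 0).sum())
        rows.append({"group": gname,
                     "slope": float(np.median(fit.samples_beta[:, j])),
                     "px": px(fit.samples_beta[:, j]),
                     "n": n_g})
    return TrendResult(pd.DataFrame(rows), fit, names,
                       per_group=bool(per_group and groups is not None))
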