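"""Branchwise reconstruction of brain and body mass change.

Internal-node trait values are best linear unbiased predictions (BLUPs):
conditional expectations of the joint Gaussian (Brownian) model given the
tip data, computed by a linear-time upward-downward message-passing sweep
on the rate-scaled tree. Directional structure enters through node-specific
prior means (a trend term proportional to the node's pathwise rate, and for
body mass the fitted pathwise-rate relationship), so reconstructions are
trend-adjusted rather than naive midpoint averages.

From the node values, every branch gets a change Δ = descendant − ancestor
for each trait, a direction, a per-Myr proportional change, and a
standardized magnitude (z-score of |Δ| over all branches); Z_brain − Z_body
is the statistic behind the clade-level comparison of where brain change
outran body change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import phylo_gls
from .treeio import Phylogeny
from .varrates import RatePosterior, mean_scaled_tree

__all__ = [
    "bm_conditional_node_means",
    "node_groups",
    "impute_ancestral_body",
    "impute_ancestral_brain",
    "branch_changes",
    "group_change_summary",
    "ancova_tukey",
    "compact_letter_display",
    "AncovaResult",
]


def bm_conditional_node_means(tree: Phylogeny, tip_values: np.ndarray,
                              lengths: np.ndarray | None = None,
                              node_means: np.ndarray | None = None
                              ) -> np.ndarray:
    """E[node value | tip data] under BM with known node-specific means.

    Gaussian belief propagation (upward-downward) in branch-length variance
    units; the BM rate σ² cancels from conditional means. ``node_means``
    defaults to zero everywhere; tips reproduce their data exactly.
    """
    lengths = tree.length if lengths is None else np.asarray(lengths, float)
    n = tree.n_nodes
    mu_prior = np.zeros(n) if node_means is None else np.asarray(node_means, float)
    tips = tree.tip_indices
    resid = np.asarray(tip_values, float) - mu_prior[tips]

    indptr, cidx = tree.children_csr()
    post = tree.postorder()
    # upward messages: subtree-conditional distribution at each node
    up_mean = np.zeros(n)
    up_var = np.zeros(n)            # variance of node value given its subtree
    tip_pos = {int(t): i for i, t in enumerate(tips)}
    for node in post:
        kids = cidx[indptr[node]:indptr[node + 1]]
        if kids.size == 0:
            up_mean[node] = resid[tip_pos[int(node)]]
            up_var[node] = 0.0
            continue
        prec = 0.0
        wmean = 0.0
        for c in kids:
            v = up_var[c] + lengths[c]
            if v <= 0:
                # zero-length branch to a known child pins the node
                prec, wmean = np.inf, up_mean[c]
                break
            prec += 1.0 / v
            wmean += up_mean[c] / v
        if np.isinf(prec):
            up_mean[node], up_var[node] = wmean, 0.0
        else:
            up_mean[node] = wmean / prec
            up_var[node] = 1.0 / prec

    # downward pass: message to each node from the rest of the tree
    down_mean = np.zeros(n)
    down_prec = np.zeros(n)         # 0 = uninformative (flat root prior)
    out = np.zeros(n)
    for node in post[::-1]:         # preorder
        kids = cidx[indptr[node]:indptr[node + 1]]
        # posterior at this node
        if kids.size == 0:
            out[node] = resid[tip_pos[int(node)]]
        else:
            pu = np.inf if up_var[node] == 0 else 1.0 / up_var[node]
            pd_ = down_prec[node]
            if np.isinf(pu):
                out[node] = up_mean[node]
            elif pu + pd_ == 0:
                out[node] = 0.0     # no information anywhere (degenerate)
            else:
                out[node] = ((pu * up_mean[node] + pd_ * down_mean[node])
                             / (pu + pd_))
        # cavity message to each child
        for c in kids:
            prec = down_prec[node]
            wmean = down_prec[node] * down_mean[node]
            pinned = False
            for s in kids:
                if s == c:
                    continue
                v = up_var[s] + lengths[s]
                if v <= 0:
                    prec, wmean, pinned = np.inf, up_mean[s], True
                    break
                prec += 1.0 / v
                wmean += up_mean[s] / v
            if pinned:
                cav_mean, cav_var = wmean, 0.0
            elif prec == 0:
                down_prec[c] = 0.0
                down_mean[c] = 0.0
                continue
            else:
                cav_mean, cav_var = wmean / prec, 1.0 / prec
            v_msg = cav_var + lengths[c]
            if v_msg <= 0:
                down_prec[c] = np.inf
                down_mean[c] = cav_mean
            else:
                down_prec[c] = 1.0 / v_msg
                down_mean[c] = cav_mean
    return mu_prior + out


def node_groups(tree: Phylogeny, tip_groups: dict) -> list:
    """Group label per node: a node belongs to a group iff all its tip
    descendants do; mixed nodes get None."""
    lab: list = [None] * tree.n_nodes
    indptr, cidx = tree.children_csr()
    for node in tree.postorder():
        kids = cidx[indptr[node]:indptr[node + 1]]
        if kids.size == 0:
            lab[node] = tip_groups.get(tree.labels[node])
            continue
        kinds = {lab[c] for c in kids}
        lab[node] = kinds.pop() if len(kinds) == 1 else None
    return lab


def impute_ancestral_body(tree: Phylogeny, body_posterior: RatePosterior,
                          table: pd.DataFrame) -> dict:
    """Impute body mass at every node from a body-only variable-rates run.

    The body rate-scaled tree supplies node pathwise rates; the ML
    relationship body ~ α + β·pathwise on that tree gives trend-adjusted
    node means (a phylogenetic Cope's-rule correction); BLUP conditioning
    adds the Brownian residual component.
    """
    if list(table["species"]) != tree.tip_labels:
        raise ValueError("table must be aligned to tree tip order")
    from .trends import posterior_node_pathwise
    scaled = mean_scaled_tree(body_posterior, tree)
    node_path = posterior_node_pathwise(body_posterior, tree, summary="mean")
    y = table["log_body"].to_numpy(float)
    tip_path = node_path[tree.tip_indices]
    # with no detected body rate heterogeneity the pathwise predictor is
    # constant and the trend term drops out (plain BLUP)
    alpha = beta = 0.0
    fit = None
    if np.ptp(tip_path) > 1e-8 * max(abs(tip_path).max(), 1.0):
        X = np.column_stack([np.ones(y.size), tip_path])
        try:
            fit = phylo_gls.gls_ml_fit(scaled, X, y, scaled.length,
                                       ["alpha", "beta_pathwise"])
            alpha, beta = float(fit.beta[0]), float(fit.beta[1])
        except np.linalg.LinAlgError:
            fit = None
    if fit is None:
        f0 = phylo_gls.gls_ml_fit(scaled, np.ones((y.size, 1)), y,
                                  scaled.length, ["alpha"])
        alpha, beta = float(f0.beta[0]), 0.0
        fit = f0
    mu = alpha + beta * node_path
    node_body = bm_conditional_node_means(tree, y, scaled.length, mu)
    return {"node_body": node_body, "alpha": alpha,
            "beta_pathwise": beta, "fit": fit,
            "scaled_tree": scaled, "node_pathwise": node_path}


def impute_ancestral_brain(tree: Phylogeny, node_body: np.ndarray,
                           bbm_fit, brain_posterior: RatePosterior,
                           table: pd.DataFrame,
                           trend_slopes: dict | None = None,
                           common_trend: float = 0.0) -> dict:
    """Impute brain mass at every node from imputed body masses plus the
    fitted BBM and trend parameters.

    Node prior mean = quadratic BBM prediction at the node's body mass
    + trend slope × node pathwise rate (group-specific where the node lies
    wholly inside a group with an estimated trend, otherwise the common
    slope). The BM-conditional residual component is added by BLUP on the
    brain rate-scaled tree.
    """
    if list(table["species"]) != tree.tip_labels:
        raise ValueError("table must be aligned to tree tip order")
    from .trends import posterior_node_pathwise
    scaled = mean_scaled_tree(brain_posterior, tree)
    node_path = posterior_node_pathwise(brain_posterior, tree, summary="mean")
    tip_groups = dict(zip(table["species"], table.get("group", "all")))
    ng = node_groups(tree, tip_groups)
    slopes = trend_slopes or {}
    trend = np.array([slopes.get(g, common_trend) for g in ng])
    mu = bbm_fit.predict(node_body) + trend * node_path
    y = table["log_brain"].to_numpy(float)
    node_brain = bm_conditional_node_means(tree, y, scaled.length, mu)
    return {"node_brain": node_brain, "scaled_tree": scaled,
            "node_pathwise": node_path, "node_group": ng}


def branch_changes(tree: Phylogeny, node_brain: np.ndarray,
                   node_body: np.ndarray, groups: list | None = None,
                   rate_scalars: np.ndarray | None = None) -> pd.DataFrame:
    """Per-branch change decomposition (one row per non-root node).

    Δ values are descendant − ancestor on the log10 scale; the per-Myr
    proportional change is the geometric rate 10^(Δ/t) − 1 (flagged NaN on
    zero-length branches); Z columns are z-scores of |Δ| over all branches.
    """
    rows = []
    for node in range(tree.n_nodes):
        p = tree.parent[node]
        if p < 0:
            continue
        t = float(tree.length[node])
        db = float(node_brain[node] - node_brain[p])
        dx = float(node_body[node] - node_body[p])
        with np.errstate(over="ignore"):
            pr_b = float(np.power(10.0, db / t) - 1.0) if t > 0 else np.nan
            pr_x = float(np.power(10.0, dx / t) - 1.0) if t > 0 else np.nan
        rows.append({
            "child": node, "parent": int(p), "t": t,
            "r": float(rate_scalars[node]) if rate_scalars is not None else np.nan,
            "delta_brain": db, "delta_body": dx,
            "brain_increase": db > 0, "body_increase": dx > 0,
            "prop_brain_per_myr": pr_b,
            "prop_body_per_myr": pr_x,
            "zero_length": t == 0.0,
            "ancestor_brain": float(node_brain[p]),
            "group": groups[node] if groups is not None else None,
            "is_tip_branch": bool(tree.n_children[node] == 0),
        })
    df = pd.DataFrame(rows)
    for trait in ("brain", "body"):
        a = np.abs(df[f"delta_{trait}"])
        sd = a.std(ddof=0)
        df[f"z_{trait}"] = (a - a.mean()) / sd if sd > 0 else 0.0
    df["z_diff"] = df["z_brain"] - df["z_body"]
    return df


def group_change_summary(changes: pd.DataFrame) -> pd.DataFrame:
    """Per-group proportions of branches with brain/body increase and the
    median standardized brain-vs-body difference."""
    sub = changes[changes["group"].notna()]
    out = (sub.groupby("group")
           .agg(n_branches=("child", "size"),
                prop_brain_increase=("brain_increase", "mean"),
                prop_body_increase=("body_increase", "mean"),
                median_z_diff=("z_diff", "median"))
           .reset_index())
    return out


# ---------------------------------------------------------------------------
# ANCOVA + Tukey HSD with compact letter display
# ---------------------------------------------------------------------------

@dataclass
class AncovaResult:
    model: object                   # statsmodels OLS results
    group_p: float                  # ANCOVA p-value for the group factor
    adjusted_means: pd.Series
    pairwise: pd.DataFrame          # group_a, group_b, diff, q, p
    letters: dict
    alpha: float


def compact_letter_display(names: list, nonsig: set,
                           order_stat: dict | None = None) -> dict:
    """Minimal compact letter display for an all-pairs comparison.

    ``nonsig`` holds frozensets {a, b} of pairs NOT significantly different.
    Letters are cliques of the non-significance graph: every non-significant
    pair shares a letter, no significant pair does. The cover is exact
    (minimal number of letters) — group counts here are small. Letters are
    assigned in descending order of ``order_stat`` (e.g. adjusted means).
    """
    import itertools

    import networkx as nx

    if len(names) == 1:
        return {names[0]: "A"}
    G = nx.Graph()
    G.add_nodes_from(names)
    G.add_edges_from((a, b) for a, b in itertools.combinations(names, 2)
                     if frozenset((a, b)) in nonsig)
    cliques = [frozenset(c) for c in nx.find_cliques(G)]
    need_edges = {frozenset(e) for e in G.edges}
    need_nodes = set(names)
    best = None
    for k in range(1, len(cliques) + 1):
        for combo in itertools.combinations(cliques, k):
            nodes = set().union(*combo)
            if nodes != need_nodes:
                continue
            edges = {frozenset(p) for c in combo
                     for p in itertools.combinations(c, 2)}
            if need_edges <= edges:
                best = combo
                break
        if best is not None:
            break
    assert best is not None  # all maximal cliques always form a valid cover
    stat = order_stat or {n: 0.0 for n in names}
    ordered = sorted(best, key=lambda c: -max(stat[n] for n in c))
    letters = {n: "" for n in names}
    for i, clique in enumerate(ordered):
        ch = chr(ord("A") + i)
        for n in sorted(clique, key=lambda n: -stat[n]):
            letters[n] += ch
    return {n: "".join(sorted(v)) for n, v in letters.items()}


def ancova_tukey(changes: pd.DataFrame, group_col: str = "group",
                 response: str = "delta_brain", covariate: str = "delta_body",
                 include_ancestor: bool = True, alpha: float = 0.05
                 ) -> AncovaResult:
    """Branchwise ANCOVA of brain change on body change with a group factor,
    followed by all-pairs Tukey HSD on the covariate-adjusted group means.

    ``include_ancestor`` adds the ancestral (start-of-branch) brain value as
    a covariate — the "accounting for ancestry" adjustment; switchable so
    both variants can be reported. Groups sharing no significant difference
    share a letter; letters are ordered by descending adjusted mean.
    """
    import statsmodels.api as sm
    from scipy.stats import studentized_range

    df = changes[changes[group_col].notna()].copy()
    counts = df[group_col].value_counts()
    keep = counts[counts >= 3].index
    df = df[df[group_col].isin(keep)]
    names = sorted(df[group_col].unique())
    k = len(names)
    if k == 0:
        raise ValueError("no groups with at least 3 branches")

    covs = [covariate] + ([("ancestor_brain")] if include_ancestor else [])
    for c in covs:
        if df[c].std(ddof=0) == 0:
            raise ValueError(f"singular covariate {c!r}")
    G = pd.get_dummies(df[group_col], dtype=float)[names].to_numpy()
    C = df[covs].to_numpy(float)
    X = np.column_stack([G, C])
    colnames = [f"g[{n}]" for n in names] + covs
    res = sm.OLS(df[response].to_numpy(float),
                 pd.DataFrame(X, columns=colnames)).fit()

    if k == 1:
        return AncovaResult(res, np.nan, pd.Series({names[0]: res.params[0]}),
                            pd.DataFrame(columns=["group_a", "group_b",
                                                  "diff", "q", "p"]),
                            {names[0]: "A"}, alpha)

    # group-factor test against the pooled-intercept model
    X0 = np.column_stack([np.ones(len(df)), C])
    res0 = sm.OLS(df[response].to_numpy(float), X0).fit()
    f_test = res.compare_f_test(res0)
    group_p = float(f_test[1])

    cbar = C.mean(axis=0)
    cov_params = res.cov_params().to_numpy()
    adj, var = {}, {}
    for i, n in enumerate(names):
        v = np.zeros(X.shape[1])
        v[i] = 1.0
        v[k:] = cbar
        adj[n] = float(v @ res.params.to_numpy())
        var[n] = float(v @ cov_params @ v)
    dfres = res.df_resid
    rows = []
    nonsig = set()
    for i in range(k):
        for j in range(i + 1, k):
            a, b = names[i], names[j]
            vi = np.zeros(X.shape[1])
            vi[i], vi[j] = 1.0, -1.0
            vd = float(vi @ cov_params @ vi)
            diff = adj[a] - adj[b]
            q = abs(diff) / np.sqrt(vd / 2.0)
            p = float(studentized_range.sf(q, k, dfres))
            rows.append({"group_a": a, "group_b": b, "diff": diff,
                         "q": q, "p": p})
            if p > alpha:
                nonsig.add(frozenset((a, b)))
    letters = compact_letter_display(names, nonsig, adj)
    return AncovaResult(res, group_p, pd.Series(adj), pd.DataFrame(rows),
                        letters, alpha)
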