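import numpy as np
import pytest

from allometree.treeio import read_newick


@pytest.fixture
def cherry():
    return read_newick("(A:1,B:1);")


@pytest.fixture
def balanced4():
    return read_newick("((A:1,B:1):2,(C:1.5,D:1.5):1.5);")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def dense_bm_loglik(tree, X, y, beta, sigma2):
    """Dense multivariate-normal oracle for the pruning likelihood."""
    from scipy.stats import multivariate_normal
    V = tree.mrca_depths()
    return multivariate_normal.logpdf(y, mean=X @ beta, cov=sigma2 * V)


def random_tree(rng, n_tips, min_len=0.05, max_len=2.0):
    """Random binary tree with random branch lengths (not ultrametric)."""
    from allometree.synthgen import simulate_tree
    t = simulate_tree(n_tips, seed=int(rng.integers(2 ** 31)), age=1.0)
    lengths = rng.uniform(min_len, max_len, size=t.n_nodes)
    lengths[t.root] = 0.0
    return t.with_lengths(lengths)


def kriging_node_means(tree, tip_vals, node_means=None):
    """Dense joint-Gaussian conditional node means with a flat root prior
    (independent oracle for the message-passing BLUP)."""
    n = tree.n_nodes
    mu = np.zeros(n) if node_means is None else np.asarray(node_means, float)
    paths = []
    for i in range(n):
        s = set()
        j = i
        while j >= 0:
            s.add(j)
            j = tree.parent[j]
        paths.append(s)
    C = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            C[i, j] = sum(tree.length[k] for k in (paths[i] & paths[j]))
    tips = tree.tip_indices
    resid = np.asarray(tip_vals, float) - mu[tips]
    Cti = np.linalg.inv(C[np.ix_(tips, tips)])
    one = np.ones(len(tips))
    root_hat = (one @ Cti @ resid) / (one @ Cti @ one)
    out = mu.copy()
    for i in range(n):
        out[i] = mu[i] + root_hat + C[i, tips] @ Cti @ (resid - root_hat * one)
    out[tips] = tip_vals
    return out
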