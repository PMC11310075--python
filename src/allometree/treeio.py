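"""Trees and trait tables: parsing, validation, taxon reconciliation, pruning.

The in-memory tree is a flat, array-backed structure (parent pointers +
branch lengths in Myr) because every downstream computation — pruning
likelihoods, rate-scaled trees, pathwise rates, ancestral reconstruction —
wants deterministic integer-indexed traversals rather than an object graph.
Dendropy handles Newick/Nexus serialization at the boundary.

Mass convention: all masses are stored and modelled as log10 grams.
Raw-gram inputs are aggregated (sample-size-weighted arithmetic mean) on the
raw scale and logged once, at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Phylogeny",
    "TreeParseError",
    "TraitTableError",
    "read_newick",
    "read_nexus",
    "write_newick",
    "read_trait_table",
    "match_and_prune",
]


class TreeParseError(ValueError):
    """Malformed tree input."""


class TraitTableError(ValueError):
    """Trait table fails validation; carries per-row details."""

    def __init__(self, message: str, rows: list[str] | None = None):
        super().__init__(message)
        self.rows = rows or []


@dataclass
class Phylogeny:
    """Rooted phylogeny with branch lengths in Myr.

    Nodes are integers ``0..n_nodes-1``. ``parent[i] == -1`` exactly for the
    root; ``length[i]`` is the branch above node ``i`` (0 for the root).
    Tips carry labels; internal labels are optional. Polytomies are allowed.
    """

    parent: np.ndarray
    length: np.ndarray
    labels: list
    _postorder: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.length = np.asarray(self.length, dtype=np.float64)
        if self.parent.shape != self.length.shape:
            raise ValueError("parent and length must have equal shape")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise ValueError(f"tree must have exactly one root, found {roots.size}")
        if np.any(self.length < 0):
            raise ValueError("negative branch length")
        tips = self.tip_indices
        tip_labels = [self.labels[i] for i in tips]
        if len(set(tip_labels)) != len(tip_labels):
            raise ValueError("duplicate tip labels")

    # -- structure ---------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    @property
    def n_children(self) -> np.ndarray:
        return np.bincount(self.parent[self.parent >= 0], minlength=self.n_nodes)

    @property
    def tip_indices(self) -> np.ndarray:
        """Tips in label-stable order (increasing node id == input order)."""
        return np.flatnonzero(self.n_children == 0)

    @property
    def n_tips(self) -> int:
        return int(self.tip_indices.size)

    @property
    def tip_labels(self) -> list:
        return [self.labels[i] for i in self.tip_indices]

    def children_csr(self) -> tuple[np.ndarray, np.ndarray]:
        """Children of each node as (indptr, indices), deterministic order."""
        order = np.argsort(self.parent, kind="stable")
        order = order[self.parent[order] >= 0]
        counts = self.n_children
        indptr = np.zeros(self.n_nodes + 1, dtype=np.int64)
        np.cumsum(counts, out=indptr[1:])
        return indptr, order.astype(np.int64)

    def postorder(self) -> np.ndarray:
        """Deterministic postorder (children before parents)."""
        if self._postorder is None:
            indptr, cidx = self.children_csr()
            out = np.empty(self.n_nodes, dtype=np.int64)
            stack = [(self.root, False)]
            k = 0
            while stack:
                node, done = stack.pop()
                if done:
                    out[k] = node
                    k += 1
                else:
                    stack.append((node, True))
                    for c in cidx[indptr[node]:indptr[node + 1]][::-1]:
                        stack.append((int(c), False))
            self._postorder = out
        return self._postorder

    def node_depths(self, length: np.ndarray | None = None) -> np.ndarray:
        """Root-to-node path lengths."""
        length = self.length if length is None else np.asarray(length, float)
        depth = np.zeros(self.n_nodes)
        for node in self.postorder()[::-1]:
            p = self.parent[node]
            if p >= 0:
                depth[node] = depth[p] + length[node]
        return depth

    def mrca_depths(self, length: np.ndarray | None = None) -> np.ndarray:
        """Tips × tips matrix of shared root-to-MRCA path lengths (BM covariance
        per unit rate)."""
        depth = self.node_depths(length)
        tips = self.tip_indices
        pos = {int(t): k for k, t in enumerate(tips)}
        nt = tips.size
        V = np.zeros((nt, nt))
        under: dict[int, list[int]] = {}
        indptr, cidx = self.children_csr()
        for node in self.postorder():
            kids = cidx[indptr[node]:indptr[node + 1]]
            if kids.size == 0:
                under[node] = [pos[int(node)]]
                continue
            groups = [under.pop(int(c)) for c in kids]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    V[np.ix_(groups[a], groups[b])] = depth[node]
                    V[np.ix_(groups[b], groups[a])] = depth[node]
            under[node] = [i for g in groups for i in g]
        V[np.diag_indices(nt)] = depth[tips]
        return V

    def clade_nodes(self, node: int) -> np.ndarray:
        """All nodes in the clade rooted at ``node`` (inclusive), postorder."""
        post = self.postorder()
        keep = np.zeros(self.n_nodes, dtype=bool)
        keep[node] = True
        for nd in post[::-1]:
            p = self.parent[nd]
            if p >= 0 and keep[p]:
                keep[nd] = True
        return post[keep[post]]

    def mrca(self, labels) -> int:
        want = set(labels)
        tips = [i for i in self.tip_indices if self.labels[i] in want]
        if not tips:
            raise ValueError("no matching tips")
        paths = []
        for t in tips:
            path = []
            while t >= 0:
                path.append(t)
                t = self.parent[t]
            paths.append(path[::-1])
        k = 0
        while all(len(p) > k and p[k] == paths[0][k] for p in paths):
            k += 1
        return paths[0][k - 1]

    def with_lengths(self, length: np.ndarray) -> "Phylogeny":
        return Phylogeny(self.parent.copy(), np.asarray(length, float).copy(),
                         list(self.labels))

    # -- serialization -----------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=np.int64)
        length = np.zeros(len(nodes))
        labels: list = [None] * len(nodes)
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                if nd.edge.length is None:
                    raise TreeParseError(
                        f"missing branch length on edge above node {i}")
                length[i] = float(nd.edge.length)
            if nd.taxon is not None:
                labels[i] = nd.taxon.label
            elif nd.label is not None:
                labels[i] = nd.label
            if nd.is_leaf() and labels[i] is None:
                raise TreeParseError(f"unlabelled tip (node {i})")
        return cls(parent, length, labels)

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=taxa)
        dnodes = [dendropy.Node() for _ in range(self.n_nodes)]
        nch = self.n_children
        for i in range(self.n_nodes):
            p = self.parent[i]
            if p >= 0:
                dnodes[p].add_child(dnodes[i])
                dnodes[i].edge.length = float(self.length[i])
            if nch[i] == 0:
                dnodes[i].taxon = taxa.new_taxon(str(self.labels[i]))
            elif self.labels[i] is not None:
                dnodes[i].label = str(self.labels[i])
        tree.seed_node = dnodes[self.root]
        return tree

    def to_newick(self) -> str:
        s = self.to_dendropy().as_string(schema="newick",
                                         suppress_rooting=True,
                                         unquoted_underscores=True)
        return s.strip()


def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string (branch lengths required on non-root edges)."""
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeParseError(f"malformed Newick: {exc}") from exc
    return Phylogeny.from_dendropy(tree)


def read_nexus(text: str) -> Phylogeny:
    try:
        tree = dendropy.Tree.get(data=text, schema="nexus",
                                 preserve_underscores=True)
    except Exception as exc:
        raise TreeParseError(f"malformed Nexus: {exc}") from exc
    return Phylogeny.from_dendropy(tree)


def write_newick(tree: Phylogeny, path=None) -> str:
    s = tree.to_newick()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s + "\n")
    return s


# ---------------------------------------------------------------------------
# Trait tables
# ---------------------------------------------------------------------------

DEFAULT_SCHEMA = {
    "species": "species",
    "brain": "brain_g",
    "body": "body_g",
    "group": "group",
    "sample_size": None,
    "covariates": (),
}


def read_trait_table(source, schema: dict | None = None, sep: str = ",",
                     log10_input: bool = False) -> pd.DataFrame:
    """Read a delimited species trait table into canonical form.

    Returns a DataFrame with columns ``species``, ``log_brain``, ``log_body``
    (log10 g), ``group``, ``n_samples`` and any requested covariates, one row
    per species. Duplicate species rows are combined by sample-size-weighted
    arithmetic mean on the raw (unlogged) gram scale, then logged; rows
    without a sample size get weight 1.

    Parameters
    ----------
    source : path, file-like or DataFrame
    schema : mapping with keys ``species``, ``brain``, ``body`` (required
        column names), and optionally ``group``, ``sample_size``,
        ``covariates`` (sequence of column names, carried through by
        weighted mean on their given scale).
    log10_input : if True, ``brain``/``body`` columns are already log10 g and
        are back-transformed before aggregation.
    """
    cfg = dict(DEFAULT_SCHEMA)
    cfg.update(schema or {})
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep=sep)
    for key in ("species", "brain", "body"):
        col = cfg[key]
        if col not in df.columns:
            raise TraitTableError(f"required column {col!r} missing")

    bad_rows = []
    for key in ("brain", "body"):
        vals = pd.to_numeric(df[cfg[key]], errors="coerce")
        bad = ~np.isfinite(vals.to_numpy(float))
        for sp in df.loc[bad, cfg["species"]]:
            bad_rows.append(f"{sp}: non-numeric or missing {key} mass")
        df[cfg[key]] = vals
    if bad_rows:
        raise TraitTableError(
            f"{len(bad_rows)} row(s) with invalid masses", rows=bad_rows)

    brain = df[cfg["brain"]].to_numpy(float)
    body = df[cfg["body"]].to_numpy(float)
    if log10_input:
        brain, body = 10.0 ** brain, 10.0 ** body
    if np.any(brain <= 0) or np.any(body <= 0):
        raise TraitTableError("masses must be positive (grams)")

    if cfg["sample_size"] and cfg["sample_size"] in df.columns:
        w = pd.to_numeric(df[cfg["sample_size"]], errors="coerce")
        w = w.fillna(1.0).clip(lower=1.0).to_numpy(float)
    else:
        w = np.ones(len(df))

    work = pd.DataFrame({
        "species": df[cfg["species"]].astype(str),
        "_brain": brain, "_body": body, "_w": w,
    })
    if cfg["group"] and cfg["group"] in df.columns:
        work["group"] = df[cfg["group"]].astype(str).to_numpy()
    else:
        work["group"] = "all"
    covs = list(cfg["covariates"] or ())
    for c in covs:
        if c not in df.columns:
            raise TraitTableError(f"covariate column {c!r} missing")
        work[c] = pd.to_numeric(df[c], errors="coerce").to_numpy(float)

    def _agg(g: pd.DataFrame) -> pd.Series:
        wt = g["_w"].to_numpy()
        out = {
            "log_brain": np.log10(np.average(g["_brain"], weights=wt)),
            "log_body": np.log10(np.average(g["_body"], weights=wt)),
            "group": g["group"].iloc[0],
            "n_samples": float(wt.sum()),
        }
        for c in covs:
            vals = g[c].to_numpy()
            ok = np.isfinite(vals)
            out[c] = np.average(vals[ok], weights=wt[ok]) if ok.any() else np.nan
        return pd.Series(out)

    table = (work.groupby("species", sort=True)
             .apply(_agg, include_groups=False).reset_index())
    return table


def match_and_prune(tree: Phylogeny, table: pd.DataFrame, seed: int = 0
                    ) -> tuple[Phylogeny, pd.DataFrame, dict]:
    """Reconcile tree tips and table species; prune both to the shared set.

    When several table rows map to one tip (only possible if the caller
    merged tables with colliding names), one is chosen from the seeded
    random stream. Returns (pruned tree, matched table in tree tip order,
    report with dropped names on both sides).
    """
    rng = np.random.default_rng(seed)
    tip_set = set(tree.tip_labels)
    species = table["species"].tolist()
    shared = tip_set & set(species)
    if not shared:
        raise ValueError("no species shared between tree and trait table")
    dropped_tips = sorted(tip_set - shared)
    dropped_rows = sorted(set(species) - shared)

    pruned = prune_to_tips(tree, shared)
    rows = []
    by_species = {sp: grp.index.to_list()
                  for sp, grp in table.groupby("species", sort=False)}
    for lab in pruned.tip_labels:
        idx = by_species[lab]
        rows.append(idx[0] if len(idx) == 1 else idx[int(rng.integers(len(idx)))])
    matched = table.loc[rows].reset_index(drop=True)
    report = {"dropped_tips": dropped_tips, "dropped_rows": dropped_rows,
              "n_matched": len(rows)}
    return pruned, matched, report


def prune_to_tips(tree: Phylogeny, keep_labels) -> Phylogeny:
    """Prune to the given tip labels, collapsing degree-2 internals by
    summing branch lengths. Path lengths among survivors are preserved."""
    keep_labels = set(keep_labels)
    keep = np.zeros(tree.n_nodes, dtype=bool)
    for i in tree.tip_indices:
        if tree.labels[i] in keep_labels:
            keep[i] = True
    if not keep.any():
        raise ValueError("no tips to keep")
    # a node survives if it has a kept descendant
    post = tree.postorder()
    alive = keep.copy()
    for node in post:
        p = tree.parent[node]
        if p >= 0 and alive[node]:
            alive[p] = True
    # count surviving children
    nkids = np.zeros(tree.n_nodes, dtype=np.int64)
    for node in range(tree.n_nodes):
        p = tree.parent[node]
        if p >= 0 and alive[node]:
            nkids[p] += 1
    # new parent/length skipping unary chains; find new root first
    root = tree.root
    while nkids[root] == 1 and not keep[root]:
        root = next(c for c in range(tree.n_nodes)
                    if alive[c] and tree.parent[c] == root)
    # left-first preorder over surviving nodes (preserves tip order)
    indptr, cidx = tree.children_csr()
    preorder = []
    stack = [tree.root]
    while stack:
        node = stack.pop()
        preorder.append(node)
        stack.extend(int(c) for c in cidx[indptr[node]:indptr[node + 1]][::-1])
    retained = []
    for node in preorder:
        if not alive[node]:
            continue
        if node != root:
            # skip if unary pass-through (and not itself a kept tip)
            if nkids[node] == 1 and not keep[node]:
                continue
            # ancestor walk: accumulate lengths through unary nodes
            p = tree.parent[node]
            ln = tree.length[node]
            while p != root and (nkids[p] == 1 and not keep[p]):
                ln += tree.length[p]
                p = tree.parent[p]
            if node == root:
                continue
            retained.append((node, p, ln))
        else:
            retained.append((node, -1, 0.0))
    old_ids = [r[0] for r in retained]
    remap = {old: new for new, old in enumerate(old_ids)}
    parent = np.array([remap.get(r[1], -1) for r in retained], dtype=np.int64)
    length = np.array([r[2] for r in retained])
    labels = [tree.labels[i] for i in old_ids]
    return Phylogeny(parent, length, labels)
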