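"""Trees, the pruning likelihood, ML fitting, and the infinite-branch limit.

The phylogenetic likelihood P(D | tree, model) is computed with
Felsenstein's pruning algorithm over the 20-state amino-acid alphabet,
averaging over discrete-gamma rate categories, with per-site scaling to
avoid underflow.  Gap (and unknown) characters are treated as missing
data: their partial likelihood vector is all ones, so an all-gap column
contributes exactly zero to the log-likelihood.

Branch lengths and the gamma shape are fit by coordinate ascent: Brent
line searches on one branch at a time, using cached "below"/"above"
conditional likelihood vectors so each branch evaluation costs a single
20x20 contraction per site and category, with the gamma shape profiled
on an outer one-dimensional search.

The independent-origins hypothesis corresponds, for a reversible
stationary model, to a joint tree whose connecting branch has infinite
length: as the branch grows, the transition matrix converges to rank one
(every row tends to the stationary frequencies) and the joint likelihood
factorizes into the product of the two subtree likelihoods.
:func:`io_limit_gap` measures that convergence directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

from .models import ReversibleEigensystem, SubstitutionModel
from .seqs import GAP_CODE, Alignment

__all__ = [
    "PhyloTree",
    "LikelihoodResult",
    "parse_newick",
    "write_newick",
    "log_likelihood",
    "fit_ml",
    "io_limit_gap",
    "join_trees",
    "nj_topology",
]

_ALPHA_BOUNDS = (0.05, 100.0)
_BRANCH_MAX = 50.0


class NewickError(ValueError):
    pass


@dataclass
class PhyloTree:
    """Rooted tree stored as flat arrays (root may be multifurcating).

    ``parent[i]`` is the parent index (-1 for the root), ``lengths[i]``
    the length of the branch above node ``i`` (nan for the root), and
    ``names[i]`` the leaf label (None for internal nodes).  Likelihoods
    under a reversible model are invariant to root placement, so an
    unrooted binary tree is represented with a trifurcating root.
    """

    parent: np.ndarray
    children: list[list[int]]
    lengths: np.ndarray
    names: list[str | None]

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.lengths = np.asarray(self.lengths, dtype=float)
        branch = self.lengths[self.parent >= 0]
        if np.any(branch < 0) or np.any(~np.isfinite(branch)):
            raise ValueError("branch lengths must be finite and >= 0")
        leaves = [n for n in self.names if n is not None]
        if len(set(leaves)) != len(leaves):
            dup = sorted({n for n in leaves if leaves.count(n) > 1})
            raise NewickError(f"duplicate leaf label(s): {dup}")

    # -- structure ---------------------------------------------------------
    @property
    def root(self) -> int:
        return int(np.nonzero(self.parent < 0)[0][0])

    @property
    def n_nodes(self) -> int:
        return len(self.names)

    @property
    def n_branches(self) -> int:
        return self.n_nodes - 1

    def leaves(self) -> list[int]:
        return [i for i, n in enumerate(self.names) if n is not None]

    def leaf_labels(self) -> list[str]:
        return [self.names[i] for i in self.leaves()]

    def postorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children[node])
        return order[::-1]

    def preorder(self) -> list[int]:
        return self.postorder()[::-1]

    def copy(self) -> "PhyloTree":
        return PhyloTree(
            self.parent.copy(),
            [list(c) for c in self.children],
            self.lengths.copy(),
            list(self.names),
        )

    def total_length(self) -> float:
        return float(np.nansum(self.lengths[self.parent >= 0]))

    def with_lengths(self, lengths: np.ndarray) -> "PhyloTree":
        t = self.copy()
        t.lengths = np.asarray(lengths, dtype=float).copy()
        t.lengths[t.root] = np.nan
        return t

    def branch_lengths(self) -> dict[str, float]:
        """Branch lengths keyed by a stable split label (leaf-set string)."""
        below = self._leafsets()
        return {
            "|".join(sorted(below[i])): float(self.lengths[i])
            for i in range(self.n_nodes)
            if self.parent[i] >= 0
        }

    def _leafsets(self) -> list[set[str]]:
        below: list[set[str]] = [set() for _ in range(self.n_nodes)]
        for node in self.postorder():
            if self.names[node] is not None:
                below[node].add(self.names[node])
            for c in self.children[node]:
                below[node] |= below[c]
        return below

    # -- newick ------------------------------------------------------------
    def to_newick(self) -> str:
        def rec(node: int) -> str:
            if not self.children[node]:
                label = self.names[node] or ""
            else:
                label = "(" + ",".join(rec(c) for c in self.children[node]) + ")"
            if self.parent[node] < 0:
                return label
            return f"{label}:{self.lengths[node]:.10g}"

        return rec(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise NewickError(f"malformed Newick: {exc}") from None
        return cls.from_dendropy(dtree)

    @classmethod
    def from_dendropy(cls, dtree: "dendropy.Tree") -> "PhyloTree":
        nodes = list(dtree.preorder_node_iter())
        index = {id(n): i for i, n in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=np.int64)
        lengths = np.full(len(nodes), np.nan)
        children: list[list[int]] = [[] for _ in nodes]
        names: list[str | None] = [None] * len(nodes)
        for i, n in enumerate(nodes):
            if n.parent_node is not None:
                p = index[id(n.parent_node)]
                parent[i] = p
                children[p].append(i)
                lengths[i] = n.edge.length if n.edge.length is not None else 0.0
            if n.is_leaf():
                names[i] = n.taxon.label if n.taxon is not None else None
                if names[i] is None:
                    raise NewickError("leaf without a label")
        return cls(parent, children, lengths, names)


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string (duplicate leaf labels are rejected)."""
    return PhyloTree.from_newick(text)


def write_newick(tree: PhyloTree) -> str:
    return tree.to_newick()


@dataclass
class LikelihoodResult:
    """Fitted (or evaluated) likelihood for one tree/alignment pair."""

    log_likelihood: float
    per_site_log_likelihoods: np.ndarray
    n_sites: int
    fitted_alpha: float | None
    fitted_branch_lengths: dict[str, float]
    tree: PhyloTree
    converged: bool = True

    def tsv_row(self, label: str = "") -> str:
        return "\t".join(
            [
                label,
                f"{self.log_likelihood:.6f}",
                str(self.n_sites),
                "NA" if self.fitted_alpha is None else f"{self.fitted_alpha:.6f}",
                f"{sum(self.fitted_branch_lengths.values()):.6f}",
                str(int(self.converged)),
            ]
        )


class TreeLikelihood:
    """Pruning-likelihood engine bound to one alignment/tree/model triple.

    Partial likelihoods are stored per node as (n_categories, n_sites, 20)
    arrays; per-site log scale factors are accumulated separately.
    """

    def __init__(self, alignment: Alignment, tree: PhyloTree, model: SubstitutionModel):
        if alignment.n_columns == 0:
            raise ValueError("zero-length alignment")
        labels = tree.leaf_labels()
        if set(labels) != set(alignment.ids):
            raise ValueError(
                "tree leaves and alignment rows disagree: "
                f"tree-only={sorted(set(labels) - set(alignment.ids))}, "
                f"alignment-only={sorted(set(alignment.ids) - set(labels))}"
            )
        self.tree = tree.copy()
        self.model = model
        self.eig = ReversibleEigensystem.from_model(model)
        self.pi = model.frequencies
        mat = alignment.select(labels).matrix()
        self.codes = {node: mat[i] for i, node in enumerate(tree.leaves())}
        self.n_sites = alignment.n_columns
        self.n_states = model.n_states
        self.rates = model.category_rates()
        self._leaf_partial_cache: dict[int, np.ndarray] = {}

    # -- building blocks ---------------------------------------------------
    def set_alpha(self, alpha: float | None) -> None:
        self.model = self.model.with_gamma(alpha, self.model.n_categories)
        self.rates = self.model.category_rates()

    def _leaf_partial(self, node: int) -> np.ndarray:
        out = self._leaf_partial_cache.get(node)
        if out is None:
            codes = self.codes[node]
            out = np.zeros((self.n_sites, self.n_states + 1))
            out[np.arange(self.n_sites), codes] = 1.0
            out[codes == GAP_CODE, :] = 1.0
            out = out[:, : self.n_states]
            self._leaf_partial_cache[node] = out
        return out

    def _pmats(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("branch length must be non-negative")
        expw = np.exp(self.eig.eigenvalues[None, :] * (t * self.rates[:, None]))
        p = (self.eig.left[None, :, :] * expw[:, None, :]) @ self.eig.right
        np.clip(p, 0.0, 1.0, out=p)
        return p

    def down_pass(self):
        """Postorder conditional likelihoods below each node.

        Returns (partials, scales): partials[node] has shape
        (n_cat, n_sites, n_states); scales[node] is the per-site log of the
        factors divided out below (shared across categories).
        """
        K = len(self.rates)
        partials: dict[int, np.ndarray] = {}
        scales: dict[int, np.ndarray] = {}
        for node in self.tree.postorder():
            if not self.tree.children[node]:
                partials[node] = np.broadcast_to(
                    self._leaf_partial(node), (K, self.n_sites, self.n_states)
                )
                scales[node] = np.zeros(self.n_sites)
                continue
            acc = np.ones((K, self.n_sites, self.n_states))
            sc = np.zeros(self.n_sites)
            for c in self.tree.children[node]:
                p = self._pmats(self.tree.lengths[c])
                acc = acc * (partials[c] @ p.transpose(0, 2, 1))
                sc += scales[c]
            m = acc.max(axis=(0, 2))
            m = np.where(m > 0, m, 1.0)
            acc /= m[None, :, None]
            partials[node] = acc
            scales[node] = sc + np.log(m)
        return partials, scales

    def up_pass(self, partials, scales):
        """Preorder "above" arrays: pi-weighted likelihood of everything
        outside the subtree of each node, as a function of that node's state."""
        K = len(self.rates)
        root = self.tree.root
        above: dict[int, np.ndarray] = {
            root: np.broadcast_to(self.pi, (K, self.n_sites, self.n_states)).copy()
        }
        ascale: dict[int, np.ndarray] = {root: np.zeros(self.n_sites)}
        for node in self.tree.preorder():
            kids = self.tree.children[node]
            for c in kids:
                out = above[node].copy()
                osc = ascale[node].copy()
                for s in kids:
                    if s is c:
                        continue
                    p = self._pmats(self.tree.lengths[s])
                    out = out * (partials[s] @ p.transpose(0, 2, 1))
                    osc += scales[s]
                m = out.max(axis=(0, 2))
                m = np.where(m > 0, m, 1.0)
                out /= m[None, :, None]
                osc += np.log(m)
                # transfer across the branch to c (function of c's state)
                p = self._pmats(self.tree.lengths[c])
                above[c] = out @ p
                ascale[c] = osc
        return above, ascale

    def site_log_likelihoods(self) -> np.ndarray:
        partials, scales = self.down_pass()
        root = self.tree.root
        site = (partials[root] @ self.pi).mean(axis=0)
        return np.log(np.maximum(site, 1e-300)) + scales[root]

    def log_likelihood(self) -> float:
        return float(self.site_log_likelihoods().sum())

    # -- branch-conditional likelihood ------------------------------------
    def _branch_env(self, node: int, partials, scales, above, ascale):
        """Quantities for logL as a function of one branch length."""
        parent = self.tree.parent[node]
        out = above[parent].copy()
        osc = ascale[parent].copy()
        for s in self.tree.children[parent]:
            if s == node:
                continue
            p = self._pmats(self.tree.lengths[s])
            out = out * (partials[s] @ p.transpose(0, 2, 1))
            osc += scales[s]
        below = partials[node]
        const = osc + scales[node]

        def loglik(t: float) -> float:
            p = self._pmats(t)
            site = (out * (below @ p.transpose(0, 2, 1))).sum(axis=2).mean(axis=0)
            return float((np.log(np.maximum(site, 1e-300)) + const).sum())

        return loglik

    # -- optimization ------------------------------------------------------
    def optimize_branch_lengths(self, sweeps: int = 3, xtol: float = 1e-4) -> float:
        """Coordinate-ascent Brent sweeps over all branches; returns logL.

        The conditional environment of each branch is refreshed before its
        line search, so every accepted move is a true improvement and the
        overall log-likelihood is monotone non-decreasing.
        """
        best = self.log_likelihood()
        order = [n for n in self.tree.preorder() if self.tree.parent[n] >= 0]

        def one_sweep(refresh_each_branch: bool) -> None:
            if not refresh_each_branch:
                partials, scales = self.down_pass()
                above, ascale = self.up_pass(partials, scales)
            for node in order:
                if refresh_each_branch:
                    partials, scales = self.down_pass()
                    above, ascale = self.up_pass(partials, scales)
                f = self._branch_env(node, partials, scales, above, ascale)
                current = f(self.tree.lengths[node])
                res = minimize_scalar(
                    lambda t: -f(t),
                    bounds=(0.0, _BRANCH_MAX),
                    method="bounded",
                    options={"xatol": xtol},
                )
                if -res.fun > current:
                    self.tree.lengths[node] = float(res.x)

        for _ in range(sweeps):
            start_lengths = self.tree.lengths.copy()
            # fast sweep: conditional environments computed once; they go
            # slightly stale as branches update, so verify and fall back to
            # per-branch refreshed (exact coordinate-ascent) sweeps if the
            # overall log-likelihood ever fails to improve
            one_sweep(refresh_each_branch=False)
            new = self.log_likelihood()
            if new < best:
                self.tree.lengths = start_lengths
                one_sweep(refresh_each_branch=True)
                new = self.log_likelihood()
            if new - best < 1e-4:
                return max(best, new)
            best = new
        return best

    def optimize_alpha(self) -> float:
        def neg(log_a: float) -> float:
            self.set_alpha(float(np.exp(log_a)))
            return -self.log_likelihood()

        res = minimize_scalar(
            neg,
            bounds=(np.log(_ALPHA_BOUNDS[0]), np.log(_ALPHA_BOUNDS[1])),
            method="bounded",
            options={"xatol": 1e-3},
        )
        self.set_alpha(float(np.exp(res.x)))
        return -float(res.fun)


def log_likelihood(
    alignment: Alignment, tree: PhyloTree, model: SubstitutionModel
) -> LikelihoodResult:
    """Pruning log-likelihood of *alignment* on *tree* (no fitting)."""
    engine = TreeLikelihood(alignment, tree, model)
    site = engine.site_log_likelihoods()
    return LikelihoodResult(
        log_likelihood=float(site.sum()),
        per_site_log_likelihoods=site,
        n_sites=engine.n_sites,
        fitted_alpha=model.gamma_shape,
        fitted_branch_lengths=tree.branch_lengths(),
        tree=tree.copy(),
    )


def _distance_start_lengths(alignment: Alignment, tree: PhyloTree) -> np.ndarray:
    """Heuristic starting branch lengths from corrected pairwise distances."""
    d = _ml_pairwise_distances(alignment)
    mean_d = float(np.mean(d[np.triu_indices_from(d, k=1)])) if d.shape[0] > 1 else 0.1
    start = max(mean_d, 1e-3) / 2.0
    lengths = tree.lengths.copy()
    lengths[np.asarray(tree.parent) >= 0] = start
    return lengths


def _ml_pairwise_distances(alignment: Alignment) -> np.ndarray:
    """Gamma-free 20-state Poisson-corrected distances between rows."""
    m = alignment.matrix()
    n = m.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (m[i] != GAP_CODE) & (m[j] != GAP_CODE)
            if ok.sum() == 0:
                p = 0.0
            else:
                p = float(np.mean(m[i][ok] != m[j][ok]))
            p = min(p, 0.94)  # keep the log-correction finite
            d[i, j] = d[j, i] = -(19.0 / 20.0) * np.log(1.0 - 20.0 * p / 19.0)
    return d


def fit_ml(
    alignment: Alignment,
    tree_topology: PhyloTree,
    model: SubstitutionModel,
    optimize: tuple[str, ...] = ("branch_lengths", "alpha"),
    starting_lengths: str = "distance",
    max_rounds: int = 8,
    tol: float = 1e-4,
    xtol: float = 1e-4,
) -> LikelihoodResult:
    """ML fit of branch lengths and/or gamma shape on a fixed topology.

    ``starting_lengths``: ``"distance"`` initializes every branch from the
    mean corrected pairwise distance; ``"keep"`` starts from the lengths
    already on the topology.
    """
    if model.plus_f:
        model = model.with_frequencies(alignment.observed_frequencies())
    engine = TreeLikelihood(alignment, tree_topology, model)
    if starting_lengths == "distance":
        engine.tree.lengths = _distance_start_lengths(alignment, tree_topology)
        engine.tree.lengths[engine.tree.root] = np.nan
    elif starting_lengths != "keep":
        raise ValueError("starting_lengths must be 'distance' or 'keep'")

    do_bl = "branch_lengths" in optimize
    do_alpha = "alpha" in optimize and model.gamma_shape is not None
    best = engine.log_likelihood()
    start_ll = best
    converged = not (do_bl or do_alpha)
    for _ in range(max_rounds):
        current = best
        if do_bl:
            current = engine.optimize_branch_lengths(sweeps=3, xtol=xtol)
        if do_alpha:
            current = engine.optimize_alpha()
        if abs(current - best) < tol:
            best = max(best, current)
            converged = True
            break
        best = max(best, current)
    site = engine.site_log_likelihoods()
    ll = float(site.sum())
    if ll < start_ll - 1e-6:  # never report worse than the starting point
        ll, converged = start_ll, False
    return LikelihoodResult(
        log_likelihood=ll,
        per_site_log_likelihoods=site,
        n_sites=engine.n_sites,
        fitted_alpha=engine.model.gamma_shape,
        fitted_branch_lengths=engine.tree.branch_lengths(),
        tree=engine.tree.copy(),
        converged=converged,
    )


def join_trees(tree_a: PhyloTree, tree_b: PhyloTree, joining_branch_length: float) -> PhyloTree:
    """Connect two subtrees' roots with a branch, giving one joint tree.

    The root of *tree_b* is attached below the root of *tree_a* with the
    given branch length; under a reversible model the placement of the
    root along that branch is immaterial.
    """
    if set(tree_a.leaf_labels()) & set(tree_b.leaf_labels()):
        raise ValueError("leaf sets overlap; cannot join")
    if joining_branch_length < 0:
        raise ValueError("joining branch length must be >= 0")
    na = tree_a.n_nodes
    parent = np.concatenate([tree_a.parent, tree_b.parent + na])
    lengths = np.concatenate([tree_a.lengths, tree_b.lengths])
    children = [list(c) for c in tree_a.children] + [
        [c + na for c in cs] for cs in tree_b.children
    ]
    names = list(tree_a.names) + list(tree_b.names)
    b_root = tree_b.root + na
    parent[b_root] = tree_a.root
    children[tree_a.root].append(b_root)
    lengths[b_root] = joining_branch_length
    return PhyloTree(parent, children, lengths, names)


def io_limit_gap(
    alignment: Alignment,
    tree_a: PhyloTree,
    tree_b: PhyloTree,
    joining_branch_length: float,
    model: SubstitutionModel,
) -> float:
    """|logL_joint(t) - (logL_A + logL_B)| for the connecting branch *t*.

    As t grows the joint likelihood converges to the product of the two
    independent-tree likelihoods computed with stationary root
    frequencies — the sense in which independent origins equals an
    infinitely long connecting branch.
    """
    joint = join_trees(tree_a, tree_b, joining_branch_length)
    ll_joint = log_likelihood(alignment, joint, model).log_likelihood
    ll_a = log_likelihood(alignment.select(tree_a.leaf_labels()), tree_a, model).log_likelihood
    ll_b = log_likelihood(alignment.select(tree_b.leaf_labels()), tree_b, model).log_likelihood
    return abs(ll_joint - (ll_a + ll_b))


def nj_topology(alignment: Alignment) -> PhyloTree:
    """Neighbor-joining topology from corrected pairwise distances."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    d = _ml_pairwise_distances(alignment)
    dm = DistanceMatrix(d, ids=list(alignment.ids))
    newick = nj(dm, result_constructor=str)
    tree = parse_newick(newick)
    tree.lengths[np.asarray(tree.parent) >= 0] = np.maximum(
        tree.lengths[np.asarray(tree.parent) >= 0], 0.0
    )
    return tree
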