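"""Sum-of-trees regression machinery (BART).

Implements the regression-tree state, the regularizing tree-structure prior
alpha * (1 + depth)^(-beta), Metropolis-Hastings tree moves (grow / prune /
change), conjugate leaf-value sampling and one Bayesian backfitting sweep over
the ensemble.  All randomness flows through a single ``numpy.random.Generator``
owned by the caller, so equal seeds give bit-identical chains.

Conventions
-----------
* Split rules are ``x[var] <= cut`` (left branch); cutpoints are drawn uniformly
  from the unique observed values of the variable within the node, excluding the
  maximum, so both children are guaranteed at least one observation.
* The marginal likelihood of a leaf integrates its value over the
  Normal(0, sigma_mu^2) prior; only the terms that differ between competing
  structures are evaluated.
* Move probabilities are grow/prune/change = 0.4/0.4/0.2, except that a
  single-leaf tree proposes grow with probability 1.
"""

from __future__ import annotations

import math

import numpy as np

P_GROW, P_PRUNE, P_CHANGE = 0.4, 0.4, 0.2


def split_probability(depth: int, alpha: float, beta: float) -> float:
    """Prior probability that a node at ``depth`` (root = 0) is internal."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0,1)")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if depth < 0:
        raise ValueError("depth must be nonnegative")
    return alpha * (1.0 + depth) ** (-beta)


class Node:
    """A tree node; a leaf iff ``var`` is None.  Every node caches the training
    row indices routed to it, which makes prune proposals and sufficient
    statistics O(node size)."""

    __slots__ = ("var", "cut", "left", "right", "parent", "value", "idx", "depth")

    def __init__(self, idx: np.ndarray, depth: int, parent: "Node | None" = None):
        self.var: int | None = None
        self.cut: float = 0.0
        self.left: Node | None = None
        self.right: Node | None = None
        self.parent = parent
        self.value: float = 0.0
        self.idx = idx
        self.depth = depth

    @property
    def is_leaf(self) -> bool:
        return self.var is None


class Tree:
    """A single regression tree over a fixed training matrix."""

    def __init__(self, n_rows: int):
        self.root = Node(np.arange(n_rows), 0)

    def leaves(self) -> list[Node]:
        out, stack = [], [self.root]
        while stack:
            nd = stack.pop()
            if nd.is_leaf:
                out.append(nd)
            else:
                stack.append(nd.left)
                stack.append(nd.right)
        return out

    def singly_internal(self) -> list[Node]:
        """Internal nodes whose two children are both leaves (prunable/changeable)."""
        out, stack = [], [self.root]
        while stack:
            nd = stack.pop()
            if not nd.is_leaf:
                if nd.left.is_leaf and nd.right.is_leaf:
                    out.append(nd)
                else:
                    stack.append(nd.left)
                    stack.append(nd.right)
        return out

    def depth(self) -> int:
        return max(leaf.depth for leaf in self.leaves())

    def predict_training(self, n_rows: int) -> np.ndarray:
        fit = np.empty(n_rows)
        for leaf in self.leaves():
            fit[leaf.idx] = leaf.value
        return fit


# ---------------------------------------------------------------------------
# marginal likelihood
# ---------------------------------------------------------------------------

def _leaf_marginal_loglik(n: int, s: float, sigma2: float, sigma_mu2: float) -> float:
    """Log marginal likelihood terms of a leaf that vary with the partition.

    For residuals r in a leaf with value ~ Normal(0, sigma_mu2) integrated out,
    the partition-dependent part is
        0.5*log(sigma2/(sigma2 + n*sigma_mu2)) + sigma_mu2*s^2 / (2*sigma2*(sigma2+n*sigma_mu2))
    with s = sum(r); the Gaussian normalizing terms cancel between structures.
    """
    denom = sigma2 + n * sigma_mu2
    return 0.5 * math.log(sigma2 / denom) + sigma_mu2 * s * s / (2.0 * sigma2 * denom)


def _log_struct_ratio(depth: int, alpha: float, beta: float) -> float:
    """Log prior ratio of 'node at depth split into two leaves' vs 'node is a leaf'."""
    p_d = split_probability(depth, alpha, beta)
    p_child = split_probability(depth + 1, alpha, beta)
    return math.log(p_d) + 2.0 * math.log1p(-p_child) - math.log1p(-p_d)


def _draw_rule(X: np.ndarray, idx: np.ndarray, rng: np.random.Generator):
    """Propose (var, cut) uniformly: variable over all columns, cut over the
    node's valid grid for that variable.  Returns None when the drawn variable
    has a single distinct value in the node (the move is then rejected)."""
    var = int(rng.integers(X.shape[1]))
    vals = np.unique(X[idx, var])
    if vals.size < 2:
        return None
    cut = float(vals[int(rng.integers(vals.size - 1))])
    return var, cut


# ---------------------------------------------------------------------------
# MH tree moves
# ---------------------------------------------------------------------------

def propose_tree_move(
    tree: Tree,
    X: np.ndarray,
    residuals: np.ndarray,
    sigma: float,
    sigma_mu: float,
    alpha: float,
    beta: float,
    rng: np.random.Generator,
    use_likelihood: bool = True,
) -> bool:
    """One Metropolis-Hastings structure move on ``tree`` given partial residuals.

    Returns True when the proposal was accepted.  ``use_likelihood=False`` turns
    the marginal-likelihood ratio off, so the kernel targets the tree prior
    alone (used to verify the prior is sampled correctly).
    """
    sigma2, sigma_mu2 = sigma * sigma, sigma_mu * sigma_mu

    def ll(node_idx: np.ndarray) -> float:
        if not use_likelihood:
            return 0.0
        return _leaf_marginal_loglik(
            node_idx.size, float(residuals[node_idx].sum()), sigma2, sigma_mu2
        )

    root_is_leaf = tree.root.is_leaf
    if root_is_leaf:
        kind = "grow"
    else:
        u = rng.random()
        kind = "grow" if u < P_GROW else ("prune" if u < P_GROW + P_PRUNE else "change")

    if kind == "grow":
        leaves = tree.leaves()
        leaf = leaves[int(rng.integers(len(leaves)))]
        rule = _draw_rule(X, leaf.idx, rng)
        if rule is None:
            return False
        var, cut = rule
        go_left = X[leaf.idx, var] <= cut
        idx_l, idx_r = leaf.idx[go_left], leaf.idx[~go_left]

        si = tree.singly_internal()
        # after growing: leaf becomes singly internal; its parent (if it was
        # singly internal) no longer is
        w_after = len(si) + 1 - (1 if leaf.parent is not None and leaf.parent in si else 0)
        p_grow_here = 1.0 if root_is_leaf else P_GROW

        log_acc = (
            ll(idx_l) + ll(idx_r) - ll(leaf.idx)
            + _log_struct_ratio(leaf.depth, alpha, beta)
            + math.log(P_PRUNE) - math.log(w_after)
            - math.log(p_grow_here) + math.log(len(leaves))
        )
        if math.log(rng.random()) < log_acc:
            leaf.var, leaf.cut = var, cut
            leaf.left = Node(idx_l, leaf.depth + 1, leaf)
            leaf.right = Node(idx_r, leaf.depth + 1, leaf)
            return True
        return False

    if kind == "prune":
        si = tree.singly_internal()
        node = si[int(rng.integers(len(si)))]
        n_leaves_after = len(tree.leaves()) - 1
        p_grow_after = 1.0 if node is tree.root else P_GROW
        log_acc = (
            ll(node.idx) - ll(node.left.idx) - ll(node.right.idx)
            - _log_struct_ratio(node.depth, alpha, beta)
            + math.log(p_grow_after) - math.log(n_leaves_after)
            - math.log(P_PRUNE) + math.log(len(si))
        )
        if math.log(rng.random()) < log_acc:
            node.var = None
            node.left = node.right = None
            return True
        return False

    # change: re-draw the split rule of a singly-internal node
    si = tree.singly_internal()
    node = si[int(rng.integers(len(si)))]
    rule = _draw_rule(X, node.idx, rng)
    if rule is None:
        return False
    var, cut = rule
    go_left = X[node.idx, var] <= cut
    idx_l, idx_r = node.idx[go_left], node.idx[~go_left]
    if idx_l.size == 0 or idx_r.size == 0:
        return False
    log_acc = (
        ll(idx_l) + ll(idx_r) - ll(node.left.idx) - ll(node.right.idx)
    )
    if math.log(rng.random()) < log_acc:
        node.var, node.cut = var, cut
        node.left.idx, node.right.idx = idx_l, idx_r
        return True
    return False


def sample_leaf_values(
    tree: Tree,
    residuals: np.ndarray,
    sigma: float,
    sigma_mu: float,
    rng: np.random.Generator,
    out_fit: np.ndarray | None = None,
) -> np.ndarray:
    """Draw every leaf value from its conjugate normal posterior.

    Posterior for a leaf with n residuals summing to s:
        variance V = 1 / (n/sigma^2 + 1/sigma_mu^2),  mean = V * s / sigma^2.
    Returns (and optionally fills in place) the per-row fit vector of the tree.
    """
    if out_fit is None:
        out_fit = np.empty_like(residuals)
    inv_s2 = 1.0 / (sigma * sigma)
    inv_mu2 = 1.0 / (sigma_mu * sigma_mu)
    for leaf in tree.leaves():
        n = leaf.idx.size
        if n == 0:
            raise RuntimeError("empty leaf encountered; move rules must prevent this")
        v = 1.0 / (n * inv_s2 + inv_mu2)
        mean = v * float(residuals[leaf.idx].sum()) * inv_s2
        leaf.value = mean + math.sqrt(v) * rng.standard_normal()
        out_fit[leaf.idx] = leaf.value
    return out_fit


# ---------------------------------------------------------------------------
# forest
# ---------------------------------------------------------------------------

class Forest:
    """m regression trees with cached per-record fitted values.

    ``tree_fits[t]`` holds tree t's contribution for every training row and
    ``total_fit`` their sum; both are maintained incrementally and can be
    checked against full recomputation with :meth:`recompute_fits`.
    """

    def __init__(self, n_trees: int, n_rows: int, sigma_mu: float):
        self.trees = [Tree(n_rows) for _ in range(n_trees)]
        self.sigma_mu = float(sigma_mu)
        self.tree_fits = np.zeros((n_trees, n_rows))
        self.total_fit = np.zeros(n_rows)

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def recompute_fits(self) -> np.ndarray:
        """Recompute the ensemble fit from scratch (cache consistency oracle)."""
        n = self.total_fit.shape[0]
        return np.sum([t.predict_training(n) for t in self.trees], axis=0)


def backfit_sweep(
    forest: Forest,
    X: np.ndarray,
    target: np.ndarray,
    sigma: float,
    alpha: float,
    beta: float,
    rng: np.random.Generator,
    n_moves_per_tree: int = 1,
) -> int:
    """One Bayesian backfitting pass: update every tree against the partial
    residual of ``target`` net of all other trees, then redraw its leaf values.

    Returns the number of accepted structure moves.
    """
    accepted = 0
    for t, tree in enumerate(forest.trees):
        partial = target - forest.total_fit + forest.tree_fits[t]
        for _ in range(n_moves_per_tree):
            accepted += propose_tree_move(
                tree, X, partial, sigma, forest.sigma_mu, alpha, beta, rng
            )
        old = forest.tree_fits[t].copy()
        sample_leaf_values(
            tree, partial, sigma, forest.sigma_mu, rng, out_fit=forest.tree_fits[t]
        )
        forest.total_fit += forest.tree_fits[t] - old
    return accepted


# ---------------------------------------------------------------------------
# compact (flat-array) forests for storage and out-of-sample prediction
# ---------------------------------------------------------------------------

def forest_to_arrays(forest: Forest) -> dict:
    """Flatten a forest into parallel node arrays (var = -1 marks a leaf)."""
    var, cut, left, right, value, offsets = [], [], [], [], [], [0]
    for tree in forest.trees:
        base = len(var)
        order: list[Node] = []
        stack = [tree.root]
        pos: dict[int, int] = {}
        while stack:
            nd = stack.pop()
            pos[id(nd)] = base + len(order)
            order.append(nd)
            if not nd.is_leaf:
                stack.append(nd.right)
                stack.append(nd.left)
        # children are pushed after the parent, so ids resolve in a second pass
        for nd in order:
            if nd.is_leaf:
                var.append(-1)
                cut.append(0.0)
                left.append(-1)
                right.append(-1)
                value.append(nd.value)
            else:
                var.append(nd.var)
                cut.append(nd.cut)
                left.append(pos[id(nd.left)])
                right.append(pos[id(nd.right)])
                value.append(0.0)
        offsets.append(len(var))
    return {
        "var": np.asarray(var, dtype=np.int32),
        "cut": np.asarray(cut, dtype=np.float64),
        "left": np.asarray(left, dtype=np.int32),
        "right": np.asarray(right, dtype=np.int32),
        "value": np.asarray(value, dtype=np.float64),
        "tree_offsets": np.asarray(offsets, dtype=np.int64),
    }


def evaluate_forest_arrays(arrays: dict, X: np.ndarray) -> np.ndarray:
    """Evaluate a flattened forest at the rows of ``X`` (sum over trees)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    out = np.zeros(n)
    var, cut = arrays["var"], arrays["cut"]
    left, right, value = arrays["left"], arrays["right"], arrays["value"]
    offsets = arrays["tree_offsets"]
    rows = np.arange(n)
    for t in range(len(offsets) - 1):
        node = np.full(n, offsets[t], dtype=np.int64)
        while True:
            internal = var[node] >= 0
            if not internal.any():
                break
            act = rows[internal]
            nd = node[act]
            go_left = X[act, var[nd]] <= cut[nd]
            node[act] = np.where(go_left, left[nd], right[nd])
        out += value[node]
    return out
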