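"""Distance trees, bootstrap support, Fitch parsimony and bipartitions.

Neighbor joining stands in for heavyweight tree searches: the
delimitation logic downstream consumes only split supports and
congruence, which NJ + bootstrap provide deterministically at desk
scale.  Externally supplied posterior probabilities are honoured
alongside computed bootstrap values.
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _iupac
from .errors import EsudelimError, UndefinedDistanceError, SaturationError
from .matrices import DIAG_ZERO, LabelledMatrix
from .seqmodels import Alignment, SubstitutionModel, corrected_distance
from .trees import Split, Support, SupportTree, canonical_split

WILDCARD = np.uint8(15)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: LabelledMatrix) -> SupportTree:
    """Canonical neighbor joining (Saitou & Nei / Studier & Keppler).

    Negative branch-length estimates are clamped to zero with the
    deficit moved onto the sister edge, preserving the joined pair's
    path length.  Requires a complete matrix with n >= 3.
    """
    if np.isnan(dm.values).any():
        raise EsudelimError(
            "distance matrix has missing entries; impute or remove those "
            "units before neighbor joining")
    n = dm.n
    if n < 3:
        raise EsudelimError("neighbor joining needs at least 3 units")

    d = dm.values.astype(float).copy()
    np.fill_diagonal(d, 0.0)
    nodes = [_esc(l) for l in dm.labels]  # newick fragments
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_, j_ = np.unravel_index(np.argmin(q), q.shape)
        if i_ > j_:
            i_, j_ = j_, i_
        a, b = active[i_], active[j_]
        dab = d[a, b]
        va = 0.5 * dab + (r[i_] - r[j_]) / (2.0 * (m - 2))
        vb = dab - va
        va, vb = _clamp_pair(va, vb)
        # distances from the new node to the others
        new_row = np.zeros(d.shape[0] + 1)
        for k_pos, k in enumerate(active):
            if k in (a, b):
                continue
            new_row[k] = 0.5 * (d[a, k] + d[b, k] - dab)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(f"({nodes[a]}:{va:.10g},{nodes[b]}:{vb:.10g})")
        active = [k for k in active if k not in (a, b)] + [d.shape[0] - 1]

    a, b, c = active
    va = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    vb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    vc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    va, vb, vc = (max(v, 0.0) for v in (va, vb, vc))
    newick = (f"({nodes[a]}:{va:.10g},{nodes[b]}:{vb:.10g},"
              f"{nodes[c]}:{vc:.10g});")
    return SupportTree.from_newick(newick, parse_supports=False)


def _clamp_pair(va: float, vb: float) -> tuple[float, float]:
    if va < 0.0:
        vb += va
        va = 0.0
    if vb < 0.0:
        va += vb
        vb = 0.0
    return max(va, 0.0), max(vb, 0.0)


def _esc(label: str) -> str:
    if any(ch in label for ch in "(),:;[] '\t"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# bipartition sets and support filtering
# ---------------------------------------------------------------------------

@dataclass
class BipartitionSet:
    """Non-trivial leaf-label splits with their supports."""

    leaves: frozenset[str]
    splits: dict[Split, Support] = field(default_factory=dict)

    def __contains__(self, split: Split) -> bool:
        return split in self.splits

    def __len__(self) -> int:
        return len(self.splits)

    def restrict(self, leaf_subset: set[str]) -> "BipartitionSet":
        common = frozenset(self.leaves & set(leaf_subset))
        out: dict[Split, Support] = {}
        for split, sup in self.splits.items():
            r = canonical_split(set(split), set(common))
            if r is not None and r not in out:
                out[r] = sup
        return BipartitionSet(common, out)


def supported_bipartitions(tree: SupportTree, bs_min: float = 70.0,
                           pp_min: float = 0.95) -> BipartitionSet:
    """Splits whose support passes either threshold (strictly greater).

    A split qualifies if ANY available support type exceeds its
    threshold: bootstrap > ``bs_min`` (percent) or posterior
    probability > ``pp_min``.
    """
    if not tree.supports:
        raise EsudelimError("tree carries no support values")
    leaves = frozenset(tree.leaf_labels)
    out = {}
    for split, sup in tree.supports.items():
        ok = (sup.bs is not None and sup.bs > bs_min) or \
             (sup.pp is not None and sup.pp > pp_min)
        if ok:
            out[split] = sup
    return BipartitionSet(leaves, out)


def splits_conflict(a: Split, b: Split, leaves: frozenset[str]) -> bool:
    """Two splits (canonical, same leaf universe) are incompatible iff
    all four intersections of their sides are non-empty."""
    a1, a2 = set(a), leaves - a
    b1, b2 = set(b), leaves - b
    return all((a1 & b1, a1 & b2, a2 & b1, a2 & b2))


# ---------------------------------------------------------------------------
# Fitch parsimony
# ---------------------------------------------------------------------------

def _parsimony_masks(aln: Alignment) -> np.ndarray:
    """(n, L) masks with every gap/ambiguity turned into a wildcard."""
    masks = aln.masks.copy()
    masks[~_iupac.is_unambiguous(masks)] = WILDCARD
    return masks


def _compress(masks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    patterns, counts = np.unique(masks.T, axis=0, return_counts=True)
    return patterns.T.copy(), counts.astype(np.int64)


def fitch_length(aln: Alignment, tree: SupportTree) -> int:
    """Fitch small-parsimony length of ``aln`` on ``tree``.

    Gaps and ambiguity codes are zero-cost wildcards.  Multifurcating
    nodes are resolved by sequential pairwise union (standard Fitch
    generalisation).
    """
    tree.require_leaves(aln.labels)
    masks, counts = _compress(_parsimony_masks(aln))
    row = {lab: k for k, lab in enumerate(aln.labels)}
    cost = np.zeros(masks.shape[1], dtype=np.int64)

    def walk(node) -> np.ndarray:
        if node.is_leaf():
            return masks[row[node.taxon.label]]
        state = None
        for child in node.child_nodes():
            cs = walk(child)
            if state is None:
                state = cs
            else:
                inter = state & cs
                miss = inter == 0
                cost[miss] += 1
                state = np.where(miss, state | cs, inter)
        return state

    walk(tree.tree.seed_node)
    return int((cost * counts).sum())


# ---------------------------------------------------------------------------
# exhaustive / heuristic parsimony search
# ---------------------------------------------------------------------------

def _insertions(t, leaf: int):
    yield (t, leaf)
    if isinstance(t, tuple):
        for sub in _insertions(t[0], leaf):
            yield (sub, t[1])
        for sub in _insertions(t[1], leaf):
            yield (t[0], sub)


def _rooted_topologies(leaves: list[int]):
    """All rooted binary shapes over ``leaves`` (used with an extra leaf
    0 attached at the root to enumerate unrooted trees)."""
    trees = [leaves[0]]
    for leaf in leaves[1:]:
        trees = [t2 for t in trees for t2 in _insertions(t, leaf)]
    return trees


def _compile_program(t, n: int) -> list[tuple[int, int]]:
    """Postorder merge steps; slots 0..n-1 are leaves, leaf 0 joins last."""
    prog: list[tuple[int, int]] = []
    counter = [n]

    def walk(node) -> int:
        if isinstance(node, int):
            return node
        a, b = walk(node[0]), walk(node[1])
        prog.append((a, b))
        slot = counter[0]
        counter[0] += 1
        return slot

    root = walk(t)
    prog.append((root, 0))
    return prog


@functools.lru_cache(maxsize=8)
def _topology_table(n: int):
    shapes = _rooted_topologies(list(range(1, n)))
    progs = np.array([_compile_program(t, n) for t in shapes],
                     dtype=np.int64)  # (T, n-1, 2)
    return shapes, progs


def _tuple_to_newick(t, labels: list[str]) -> str:
    def fmt(node) -> str:
        if isinstance(node, int):
            return _esc(labels[node])
        return f"({fmt(node[0])},{fmt(node[1])})"
    return f"({fmt(t)},{_esc(labels[0])});"


def _lengths_exhaustive(masks: np.ndarray, counts: np.ndarray,
                        n: int, chunk: int = 20000) -> tuple[int, int]:
    """(best index, best length) over all unrooted topologies."""
    _, progs = _topology_table(n)
    T = progs.shape[0]
    npat = masks.shape[1]
    best_len = np.iinfo(np.int64).max
    best_idx = -1
    for lo in range(0, T, chunk):
        pr = progs[lo:lo + chunk]
        t = pr.shape[0]
        states = np.empty((t, 2 * n - 1, npat), dtype=np.uint8)
        states[:, :n] = masks[None, :, :]
        cost = np.zeros((t, npat), dtype=np.int64)
        rows = np.arange(t)
        for s in range(n - 1):
            a = states[rows, pr[:, s, 0]]
            b = states[rows, pr[:, s, 1]]
            inter = a & b
            miss = inter == 0
            cost += miss
            states[rows, n + s] = np.where(miss, a | b, inter)
        totals = cost @ counts
        k = int(np.argmin(totals))
        if totals[k] < best_len:
            best_len = int(totals[k])
            best_idx = lo + k
    return best_idx, best_len


def _program_length(prog, masks: np.ndarray, counts: np.ndarray,
                    n: int) -> int:
    states: list[np.ndarray] = [masks[i] for i in range(n)]
    cost = np.zeros(masks.shape[1], dtype=np.int64)
    for a, b in prog:
        inter = states[a] & states[b]
        miss = inter == 0
        cost += miss
        states.append(np.where(miss, states[a] | states[b], inter))
    return int((cost * counts).sum())


def _nni_neighbours(t):
    """Deterministically ordered NNI rearrangements of a rooted shape."""
    out = []

    def rebuild(node, path, repl):
        if not path:
            return repl
        l, r = node
        if path[0] == 0:
            return (rebuild(l, path[1:], repl), r)
        return (l, rebuild(r, path[1:], repl))

    def walk(node, path):
        if not isinstance(node, tuple):
            return
        l, r = node
        for side, child, sib in ((0, l, r), (1, r, l)):
            if isinstance(child, tuple):
                c0, c1 = child
                if side == 0:
                    out.append(rebuild(t, path, ((c0, sib), c1)))
                    out.append(rebuild(t, path, ((c1, sib), c0)))
                else:
                    out.append(rebuild(t, path, (c1, (c0, sib))))
                    out.append(rebuild(t, path, (c0, (c1, sib))))
            walk(child, path + [side])

    walk(t, [])
    return out


def parsimony_best(aln: Alignment, exhaustive_max: int = 9
                   ) -> tuple[SupportTree, int]:
    """Most-parsimonious tree: exhaustive for small n, otherwise NJ
    start plus first-improvement NNI hill-climbing."""
    tree_shape, length = _best_shape(aln, exhaustive_max)
    newick = _tuple_to_newick(tree_shape, aln.labels)
    return SupportTree.from_newick(newick, parse_supports=False), length


def best_parsimony_length(masks: np.ndarray, counts: np.ndarray,
                          exhaustive_max: int = 9) -> int:
    """Length-only parsimony search on pre-encoded site patterns."""
    n = masks.shape[0]
    if n <= exhaustive_max:
        return _lengths_exhaustive(masks, counts, n)[1]
    return _nni_search(masks, counts, n)[1]


def _best_shape(aln: Alignment, exhaustive_max: int):
    masks, counts = _compress(_parsimony_masks(aln))
    n = aln.n
    if n < 4:
        raise EsudelimError("parsimony search needs at least 4 taxa")
    if n <= exhaustive_max:
        shapes, _ = _topology_table(n)
        idx, length = _lengths_exhaustive(masks, counts, n)
        return shapes[idx], length
    return _nni_search(masks, counts, n)


def _nni_search(masks: np.ndarray, counts: np.ndarray, n: int):
    shape = _nj_shape(masks, n)
    best = _program_length(_compile_program(shape, n), masks, counts, n)
    improved = True
    while improved:
        improved = False
        for cand in _nni_neighbours(shape):
            length = _program_length(_compile_program(cand, n),
                                     masks, counts, n)
            if length < best:
                shape, best = cand, length
                improved = True
                break
    return shape, best


def _nj_shape(masks: np.ndarray, n: int):
    """NJ starting shape from p-distances on the wildcarded masks."""
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = (masks[i] != WILDCARD) & (masks[j] != WILDCARD)
            tot = int(both.sum())
            p = float((masks[i][both] != masks[j][both]).sum()) / tot \
                if tot else 0.0
            vals[i, j] = vals[j, i] = p
    labels = [str(i) for i in range(n)]
    tree = nj_tree(LabelledMatrix(labels, vals, DIAG_ZERO))
    return _shape_from_tree(tree, labels)


def _shape_from_tree(tree: SupportTree, labels: list[str]):
    """Re-root an unrooted tree at leaf '0' and return the nested-tuple
    shape over the remaining leaf indices."""
    tree.tree.is_rooted = False
    node0 = next(lf for lf in tree.tree.leaf_node_iter()
                 if lf.taxon.label == labels[0])
    tree.tree.reroot_at_edge(node0.edge, update_bipartitions=False)

    def build(node):
        kids = [c for c in node.child_nodes()]
        if not kids:
            return int(node.taxon.label)
        subs = [build(c) for c in kids if c is not node0]
        shape = subs[0]
        for s in subs[1:]:
            shape = (shape, s)
        return shape

    root = tree.tree.seed_node
    subs = [build(c) for c in root.child_nodes() if c is not node0]
    shape = subs[0]
    for s in subs[1:]:
        shape = (shape, s)
    return shape


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def _corrected_matrix(aln: Alignment, model: SubstitutionModel
                      ) -> LabelledMatrix:
    n = aln.n
    vals = np.zeros((n, n))
    masks = aln.masks
    for i in range(n):
        for j in range(i + 1, n):
            rec = corrected_distance(masks[i], masks[j], model)
            vals[i, j] = vals[j, i] = rec.d
    return LabelledMatrix(list(aln.labels), vals, DIAG_ZERO)


def _resolved_splits(tree: SupportTree, tol: float = 1e-12):
    """Non-trivial splits on internal edges of positive length;
    zero-length edges (e.g. clamped NJ estimates) carry no resolution."""
    from .trees import canonical_split
    leafset = set(tree.leaf_labels)
    out = set()
    for node in tree.tree.preorder_internal_node_iter():
        if node is tree.tree.seed_node:
            continue
        if (node.edge.length or 0.0) <= tol:
            continue
        side = {lf.taxon.label for lf in node.leaf_iter()}
        sp = canonical_split(side, leafset)
        if sp is not None:
            out.add(sp)
    return out


def bootstrap_support(aln: Alignment, model: SubstitutionModel,
                      n_reps: int = 100, seed: int = 0) -> SupportTree:
    """NJ tree from corrected distances with site-resampling bootstrap.

    BS per original-tree split = percentage of usable replicates whose
    NJ tree contains that split.  Replicates where a distance is
    undefined or saturated are dropped (warning if more than 10% drop).
    Deterministic given ``seed``.
    """
    if n_reps < 1:
        raise EsudelimError("n_reps must be >= 1")
    tree = nj_tree(_corrected_matrix(aln, model))
    orig_splits = _resolved_splits(tree)
    hits = {sp: 0 for sp in orig_splits}
    rng = np.random.default_rng(seed)
    used = 0
    dropped = 0
    L = aln.length
    for _ in range(n_reps):
        idx = rng.integers(0, L, size=L)
        rep = aln.take_sites(idx)
        try:
            rep_tree = nj_tree(_corrected_matrix(rep, model))
        except (UndefinedDistanceError, SaturationError):
            dropped += 1
            continue
        used += 1
        for sp in _resolved_splits(rep_tree):
            if sp in hits:
                hits[sp] += 1
    if dropped > 0.1 * n_reps:
        warnings.warn(f"{dropped}/{n_reps} bootstrap replicates dropped "
                      "(undefined or saturated distances)")
    for sp in orig_splits:
        bs = 100.0 * hits[sp] / used if used else 0.0
        tree.supports[sp] = Support(bs=bs)
    return tree
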