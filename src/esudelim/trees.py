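"""Tree container with per-edge support values.

Wraps a dendropy tree and keeps bootstrap (BS, percent) and posterior
probability (PP, 0-1) support per non-trivial bipartition.  Newick I/O
encodes supports as internal node labels, either "BS" or "BS/PP".

Bipartitions are represented canonically as the frozenset of leaf labels
on the side NOT containing the lexicographically smallest leaf, so splits
from different trees over the same leaf set compare directly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import dendropy

from .errors import EsudelimError, LabelMismatchError

Split = frozenset


@dataclass
class Support:
    bs: float | None = None  # bootstrap percentage in [0, 100]
    pp: float | None = None  # posterior probability in [0, 1]

    def label(self) -> str:
        if self.bs is not None and self.pp is not None:
            return f"{self.bs:g}/{self.pp:g}"
        if self.bs is not None:
            return f"{self.bs:g}"
        if self.pp is not None:
            return f"/{self.pp:g}"
        return ""


def canonical_split(side: set[str], all_leaves: set[str]) -> Split | None:
    """Canonical form of a bipartition side; None if trivial."""
    ref = min(all_leaves)
    side = set(side) & all_leaves
    if ref in side:
        side = all_leaves - side
    if len(side) < 2 or len(side) > len(all_leaves) - 2:
        return None
    return frozenset(side)


class SupportTree:
    """Unrooted tree over uniquely-labelled leaves with edge supports."""

    def __init__(self, tree: dendropy.Tree,
                 supports: dict[Split, Support] | None = None):
        self.tree = tree
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise EsudelimError("duplicate leaf labels")
        self._leaves = labels
        self.supports: dict[Split, Support] = supports or {}

    # -- construction ---------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str, parse_supports: bool = True
                    ) -> "SupportTree":
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True,
                                 suppress_internal_node_taxa=True)
        st = cls(tree)
        if parse_supports:
            leafset = set(st._leaves)
            for node in tree.preorder_internal_node_iter():
                if not node.label:
                    continue
                sup = _parse_support_label(node.label)
                if sup is None:
                    continue
                side = {lf.taxon.label for lf in node.leaf_iter()}
                split = canonical_split(side, leafset)
                if split is not None:
                    st.supports[split] = sup
        return st

    # -- queries --------------------------------------------------------
    @property
    def leaf_labels(self) -> list[str]:
        return list(self._leaves)

    def splits(self) -> set[Split]:
        """All non-trivial bipartitions of the topology."""
        leafset = set(self._leaves)
        out = set()
        for node in self.tree.preorder_internal_node_iter():
            side = {lf.taxon.label for lf in node.leaf_iter()}
            sp = canonical_split(side, leafset)
            if sp is not None:
                out.add(sp)
        return out

    def support_for(self, split: Split) -> Support | None:
        return self.supports.get(split)

    def require_leaves(self, labels: list[str]) -> None:
        """Check leaf set equals ``labels``; report orphans on mismatch."""
        have, want = set(self._leaves), set(labels)
        if have != want:
            raise LabelMismatchError(
                f"tree-only leaves: {sorted(have - want)}; "
                f"data-only labels: {sorted(want - have)}")

    # -- I/O ------------------------------------------------------------
    def newick(self, with_supports: bool = True) -> str:
        tree = self.tree.clone(depth=1)
        if with_supports:
            leafset = set(self._leaves)
            for node in tree.preorder_internal_node_iter():
                side = {lf.taxon.label for lf in node.leaf_iter()}
                sp = canonical_split(side, leafset)
                sup = self.supports.get(sp) if sp is not None else None
                node.label = sup.label() if sup is not None else None
        out = io.StringIO()
        tree.write(file=out, schema="newick", unquoted_underscores=True,
                   suppress_rooting=True)
        return out.getvalue().strip()

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        return self.newick()


def _parse_support_label(label: str) -> Support | None:
    label = label.strip()
    if not label:
        return None
    try:
        if "/" in label:
            bs_s, pp_s = label.split("/", 1)
            bs = float(bs_s) if bs_s else None
            pp = float(pp_s) if pp_s else None
            return Support(bs=bs, pp=pp)
        return Support(bs=float(label))
    except ValueError:
        return None
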