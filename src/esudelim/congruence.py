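"""Between-locus congruence: the incongruence length difference (ILD)
permutation test and supported-clade agreement."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EsudelimError
from .seqmodels import Alignment
from .treetools import (BipartitionSet, _parsimony_masks,
                        best_parsimony_length)


@dataclass
class IldResult:
    """Outcome of the partition-homogeneity (ILD) permutation test.

    ``d_obs`` is the observed length excess: the most-parsimonious
    length of the combined data minus the sum of the per-partition best
    lengths; it is non-negative by construction.  ``p_value`` uses the
    add-one convention (1 + #{null >= d_obs}) / (1 + n_reps), so it is
    never zero and attains 1.0 when the observed excess is minimal.
    """

    d_obs: int
    null_d: list[int]
    p_value: float
    n_reps: int
    seed: int

    def __post_init__(self) -> None:
        if self.d_obs < 0:
            raise EsudelimError("negative observed length excess")


def ild_test(aln_a: Alignment, aln_b: Alignment, n_reps: int = 100,
             seed: int = 0, exhaustive_max: int = 9) -> IldResult:
    """Farris incongruence length difference test between two loci.

    Both alignments must cover the same specimens.  Each replicate
    re-partitions the pooled site columns (without replacement) into
    pseudo-partitions of the original sizes and recomputes the excess;
    constant sites are retained so partition sizes are preserved.
    Deterministic given ``seed``.
    """
    if set(aln_a.labels) != set(aln_b.labels):
        only_a = sorted(set(aln_a.labels) - set(aln_b.labels))
        only_b = sorted(set(aln_b.labels) - set(aln_a.labels))
        raise EsudelimError(
            f"specimen sets differ; only in first: {only_a}, "
            f"only in second: {only_b}")
    if n_reps < 19:
        raise EsudelimError("ILD needs at least 19 replicates")

    aln_b = aln_b.subset(aln_a.labels)
    combined = aln_a.concatenate(aln_b)
    masks = _parsimony_masks(combined)
    len_a = aln_a.length

    def best(cols: np.ndarray) -> int:
        sub, counts = _unique_cols(masks[:, cols])
        return best_parsimony_length(sub, counts, exhaustive_max)

    l_comb = best(np.arange(masks.shape[1]))
    l_a = best(np.arange(len_a))
    l_b = best(np.arange(len_a, masks.shape[1]))
    d_obs = l_comb - l_a - l_b

    # canonical pooled column order, so the null draw depends only on
    # the pooled multiset of sites, not on their input order
    pooled = masks[:, np.lexsort(masks)]

    def best_pooled(cols: np.ndarray) -> int:
        sub, counts = _unique_cols(pooled[:, cols])
        return best_parsimony_length(sub, counts, exhaustive_max)

    rng = np.random.default_rng(seed)
    null: list[int] = []
    for _ in range(n_reps):
        perm = rng.permutation(masks.shape[1])
        la = best_pooled(perm[:len_a])
        lb = best_pooled(perm[len_a:])
        null.append(l_comb - la - lb)
    p = (1 + sum(1 for d in null if d >= d_obs)) / (1 + n_reps)
    return IldResult(d_obs, null, p, n_reps, seed)


def _unique_cols(masks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    patterns, counts = np.unique(masks.T, axis=0, return_counts=True)
    return patterns.T.copy(), counts.astype(np.int64)


def shared_supported_clades(bp_a: BipartitionSet, bp_b: BipartitionSet,
                            restrict_to: set[str] | None = None):
    """Intersection/differences of supported splits on the common leaves.

    Returns ``(shared, only_a, only_b, ratio)`` where ``ratio`` is
    |shared| / |union| (1.0 when neither tree has supported splits on
    the common leaf set: no disagreement is possible).
    """
    common = set(bp_a.leaves) & set(bp_b.leaves)
    if restrict_to is not None:
        common &= set(restrict_to)
    if not common:
        raise EsudelimError("empty common leaf set")
    ra = bp_a.restrict(common)
    rb = bp_b.restrict(common)
    shared_keys = set(ra.splits) & set(rb.splits)
    shared = BipartitionSet(frozenset(common),
                            {s: ra.splits[s] for s in shared_keys})
    only_a = BipartitionSet(frozenset(common),
                            {s: v for s, v in ra.splits.items()
                             if s not in shared_keys})
    only_b = BipartitionSet(frozenset(common),
                            {s: v for s, v in rb.splits.items()
                             if s not in shared_keys})
    union = len(set(ra.splits) | set(rb.splits))
    ratio = len(shared_keys) / union if union else 1.0
    return shared, only_a, only_b, ratio
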