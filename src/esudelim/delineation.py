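"""ESU delineation: the between-versus-within divergence gap rule plus a
multi-locus support-congruence veto.

A candidate unit is accepted when, in every locus, its minimum distance
to every other unit strictly exceeds the larger of the two units'
within-unit maxima (the conservative per-pair reading of the barcoding
gap), and no well-supported split in any locus conflicts with its
monophyly.  Singleton units have within-unit divergence 0 by
convention, mirroring the '-' diagonal of printed divergence tables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .errors import EsudelimError, UndefinedDistanceError
from .matrices import DIAG_WITHIN, LabelledMatrix
from .partition import UnitPartition
from .treetools import BipartitionSet

PairKey = tuple[str, str]


def _pair(u: str, v: str) -> PairKey:
    return (u, v) if u <= v else (v, u)


def _is_unit_level(dm: LabelledMatrix, part: UnitPartition) -> bool:
    return dm.diagonal_semantics == DIAG_WITHIN


def _members_in(dm: LabelledMatrix, part: UnitPartition, u: str) -> list[str]:
    return [s for s in part.members(u) if s in dm.labels]


def inter_unit_min(dm: LabelledMatrix, part: UnitPartition,
                   u: str, v: str) -> float:
    """Minimum corrected distance over cross-unit pairs (or the printed
    between-unit cells of a unit-level matrix)."""
    if u == v:
        raise EsudelimError("inter_unit_min needs two distinct units")
    mu, mv = _members_in(dm, part, u), _members_in(dm, part, v)
    if not mu or not mv:
        raise UndefinedDistanceError(
            f"no cross pair between {u!r} and {v!r} in matrix")
    vals = [dm.value(a, b) for a in mu for b in mv]
    if all(np.isnan(v) for v in vals):
        raise UndefinedDistanceError(f"no value for pair ({u}, {v})")
    return float(np.nanmin(vals))


def intra_unit_max(dm: LabelledMatrix, part: UnitPartition, u: str,
                   agg: str = "max") -> float:
    """Within-unit divergence (maximum by default, mean by flag);
    singletons return 0.

    On a unit-level matrix a candidate unit may group several printed
    units; its within divergence then covers the member diagonals and
    the between-member cells (all of which lie inside the candidate).
    """
    members = _members_in(dm, part, u)
    vals: list[float] = []
    if _is_unit_level(dm, part):
        vals += [dm.diagonal(m) for m in members]
    elif len(members) < 2:
        return 0.0
    vals += [dm.value(a, b)
             for a, b in itertools.combinations(members, 2)]
    vals = [v for v in vals if not np.isnan(v)]
    if not vals:
        return 0.0
    return float(max(vals) if agg == "max" else np.mean(vals))


def unit_summary(dm: LabelledMatrix, part: UnitPartition,
                 intra: str = "max") -> LabelledMatrix:
    """Unit-level matrix: between-unit minima off-diagonal, within-unit
    aggregate on the diagonal (missing for singletons)."""
    units = part.units
    n = len(units)
    vals = np.full((n, n), np.nan)
    for i, u in enumerate(units):
        members = [s for s in part.members(u) if s in dm.labels]
        vals[i, i] = intra_unit_max(dm, part, u, agg=intra) \
            if len(members) > 1 else np.nan
        for j in range(i + 1, n):
            d = inter_unit_min(dm, part, u, units[j])
            vals[i, j] = vals[j, i] = d
    return LabelledMatrix(list(units), vals, DIAG_WITHIN)


@dataclass
class EsuReport:
    """Structured outcome of the delineation rule."""

    units: UnitPartition
    inter_min: dict[str, dict[PairKey, float]]        # locus -> pair -> d
    intra_max: dict[str, dict[str, float]]            # locus -> unit -> d
    gap_ok: dict[PairKey, dict[str, bool]]            # pair -> locus -> flag
    congruent: dict[str, bool]                        # unit -> flag
    accepted: list[str]
    merge_suggestions: list[tuple[str, str, str]] = field(default_factory=list)
    missing_units: dict[str, list[str]] = field(default_factory=dict)
    strict: bool = True

    # -- (de)serialisation ---------------------------------------------
    def to_dict(self) -> dict:
        return {
            "strict": self.strict,
            "units": {u: self.units.members(u) for u in self.units.units},
            "parts": self.units.parts,
            "inter_min": {loc: {f"{u}|{v}": d for (u, v), d in pairs.items()}
                          for loc, pairs in self.inter_min.items()},
            "intra_max": self.intra_max,
            "gap_ok": {f"{u}|{v}": flags
                       for (u, v), flags in self.gap_ok.items()},
            "congruent": self.congruent,
            "accepted": self.accepted,
            "merge_suggestions": [list(m) for m in self.merge_suggestions],
            "missing_units": self.missing_units,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EsuReport":
        assignment = {s: u for u, mem in d["units"].items() for s in mem}
        units = UnitPartition(assignment, list(d["units"]),
                              d.get("parts"))
        return cls(
            units=units,
            inter_min={loc: {tuple(k.split("|")): v for k, v in pairs.items()}
                       for loc, pairs in d["inter_min"].items()},
            intra_max=d["intra_max"],
            gap_ok={tuple(k.split("|")): v for k, v in d["gap_ok"].items()},
            congruent=d["congruent"],
            accepted=list(d["accepted"]),
            merge_suggestions=[tuple(m) for m in d["merge_suggestions"]],
            missing_units=d.get("missing_units", {}),
            strict=d.get("strict", True),
        )

    def summary(self) -> str:
        lines = [f"{len(self.accepted)} unit(s) accepted: "
                 f"{', '.join(self.accepted)}"]
        rejected = [u for u in self.units.units if u not in self.accepted]
        if rejected:
            lines.append(f"rejected: {', '.join(rejected)}")
        for u, v, loc in self.merge_suggestions:
            lines.append(f"consider merging {u} + {v} (no gap in {loc})")
        return "\n".join(lines)


def delineate(dms: dict[str, LabelledMatrix], candidates: UnitPartition,
              supports: dict[str, BipartitionSet] | None = None,
              strict: bool = True, intra: str = "max") -> EsuReport:
    """Apply the gap rule per unit pair per locus, with supported-split
    conflicts acting as a veto on a unit's acceptance.

    A unit absent from some locus's matrix is flagged in
    ``missing_units`` and cannot be accepted; it is never silently
    dropped.
    """
    if not dms:
        raise EsudelimError("no distance matrices supplied")
    units = candidates.units
    missing: dict[str, list[str]] = {}
    for locus, dm in dms.items():
        absent = [u for u in units if not _members_in(dm, candidates, u)]
        if absent:
            missing[locus] = absent

    inter: dict[str, dict[PairKey, float]] = {}
    intra_d: dict[str, dict[str, float]] = {}
    gap_ok: dict[PairKey, dict[str, bool]] = {}
    merge: list[tuple[str, str, str]] = []
    for locus, dm in dms.items():
        absent = set(missing.get(locus, []))
        inter[locus] = {}
        intra_d[locus] = {
            u: intra_unit_max(dm, candidates, u, agg=intra)
            for u in units if u not in absent}
        for u, v in itertools.combinations(units, 2):
            if u in absent or v in absent:
                continue
            key = _pair(u, v)
            d = inter_unit_min(dm, candidates, u, v)
            inter[locus][key] = d
            floor = max(intra_d[locus][u], intra_d[locus][v])
            ok = d > floor if strict else d >= floor
            gap_ok.setdefault(key, {})[locus] = ok
            if not ok:
                merge.append((key[0], key[1], locus))

    congruent = {u: True for u in units}
    if supports:
        for locus, bp in supports.items():
            if bp is None or not len(bp):
                continue
            universe = bp.leaves
            for u in units:
                members = frozenset(candidates.members(u)) & universe
                if len(members) < 2:
                    continue
                for split in bp.splits:
                    if _conflicts(members, split, universe - split):
                        congruent[u] = False
                        break

    accepted = []
    for u in units:
        if any(u in absent for absent in missing.values()):
            continue
        pair_flags = [flags[locus]
                      for key, flags in gap_ok.items() if u in key
                      for locus in flags]
        if pair_flags and all(pair_flags) and congruent[u]:
            accepted.append(u)
        elif not pair_flags and len(units) == 1 and congruent[u]:
            accepted.append(u)

    return EsuReport(units=candidates, inter_min=inter, intra_max=intra_d,
                     gap_ok=gap_ok, congruent=congruent, accepted=accepted,
                     merge_suggestions=merge, missing_units=missing,
                     strict=strict)


def _conflicts(members: frozenset[str], split: frozenset[str],
               complement: frozenset[str]) -> bool:
    """A split conflicts with the monophyly of ``members`` unless one
    contains the other (on either side)."""
    inside = members & split
    if not inside or members <= split:
        return False
    if split <= members or members <= complement or complement <= members:
        return False
    return True


def cluster_parts(dm: LabelledMatrix, cut: float,
                  linkage: str = "single") -> dict[str, str]:
    """Single-linkage parts: connected components of the graph joining
    units with distance < ``cut``; parts named 'A', 'B', ... in order of
    first appearance."""
    if linkage != "single":
        raise EsudelimError("only single linkage is implemented")
    labels = dm.labels
    parent = {l: l for l in labels}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in itertools.combinations(labels, 2):
        d = dm.value(u, v)
        if not np.isnan(d) and d < cut:
            parent[find(u)] = find(v)

    part_of: dict[str, str] = {}
    names: dict[str, str] = {}
    for l in labels:
        root = find(l)
        if root not in names:
            names[root] = _part_name(len(names))
        part_of[l] = names[root]
    return part_of


def _part_name(i: int) -> str:
    """0 -> 'A', 25 -> 'Z', 26 -> 'AA', ..."""
    name = ""
    i += 1
    while i:
        i, rem = divmod(i - 1, 26)
        name = chr(ord("A") + rem) + name
    return name


def candidates_from_gap(dm: LabelledMatrix, cut: float) -> UnitPartition:
    """Candidate units from single-linkage clustering of a
    specimen-level distance matrix at the barcoding-gap cut."""
    return UnitPartition(cluster_parts(dm, cut))


def part_divergence_ranges(dm: LabelledMatrix, parts: dict[str, str]
                           ) -> dict[str, tuple[float, float]]:
    """Divergence ranges of a unit-level matrix under a part assignment.

    Returns ``{"between": (min, max), "within <part>": (min, max), ...}``
    where between covers cells linking different parts and each within
    range covers all cells of one part's block, including the printed
    within-unit diagonal (missing singleton diagonals are skipped).
    """
    between: list[float] = []
    within: dict[str, list[float]] = {}
    for i, u in enumerate(dm.labels):
        for j in range(i, dm.n):
            v = dm.values[i, j]
            if np.isnan(v):
                continue
            pu, pv = parts[u], parts[dm.labels[j]]
            if pu == pv:
                within.setdefault(pu, []).append(float(v))
            else:
                between.append(float(v))
    out: dict[str, tuple[float, float]] = {
        "between": (min(between), max(between))}
    for p in sorted(within):
        out[f"within {p}"] = (min(within[p]), max(within[p]))
    return out
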