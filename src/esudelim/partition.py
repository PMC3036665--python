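"""Assignment of specimens to candidate units and units to parts."""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import EsudelimError


@dataclass
class UnitPartition:
    """Maps specimens to candidate units (haplotypes, ESUs) and,
    optionally, units to coarser parts (e.g. the deep clades A/B).

    ``units`` fixes a reporting order; every unit must be non-empty and
    every specimen is assigned exactly once (enforced by the dict).
    """

    assignment: dict[str, str]
    units: list[str] = field(default_factory=list)
    parts: dict[str, str] | None = None

    def __post_init__(self) -> None:
        seen = set(self.assignment.values())
        if not self.units:
            # first-seen order
            self.units = list(dict.fromkeys(self.assignment.values()))
        empty = [u for u in self.units if u not in seen]
        if empty:
            raise EsudelimError(f"empty units: {empty}")
        extra = seen - set(self.units)
        if extra:
            raise EsudelimError(f"assignment uses unlisted units: {sorted(extra)}")

    def members(self, unit: str) -> list[str]:
        return [s for s, u in self.assignment.items() if u == unit]

    @property
    def specimens(self) -> list[str]:
        return list(self.assignment)

    @classmethod
    def identity(cls, labels: list[str]) -> "UnitPartition":
        """Each label is its own unit (unit-level matrices)."""
        return cls({lab: lab for lab in labels}, list(labels))

    def relabel_units(self, mapping: dict[str, str]) -> "UnitPartition":
        return UnitPartition(
            {s: mapping.get(u, u) for s, u in self.assignment.items()},
            [mapping.get(u, u) for u in self.units],
            None if self.parts is None
            else {mapping.get(u, u): p for u, p in self.parts.items()},
        )
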