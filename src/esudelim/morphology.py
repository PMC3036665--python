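"""Four-character spicule morphology: modal unit profiles, deviant
specimens, ESU diagnosability, and the key to species.

Characters (controlled vocabularies):

* ``large_style`` — spination of the blunt ends of the choanosomal
  large styles: smooth | spined
* ``tornotes`` — shape of the tornote endings: fusiform | tylote |
  mucronate
* ``acanthostrongyle`` — shape of the spines: truncate | simple_shape
* ``chela`` — chela size class, pre-binarised at 30 um: lt30 | gt30
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .errors import FormatError
from .partition import UnitPartition

CHARACTERS = ("large_style", "tornotes", "acanthostrongyle", "chela")

VOCABULARY: dict[str, tuple[str, ...]] = {
    "large_style": ("smooth", "spined"),
    "tornotes": ("fusiform", "tylote", "mucronate"),
    "acanthostrongyle": ("truncate", "simple_shape"),
    "chela": ("lt30", "gt30"),
}

#: synonyms accepted on input, normalised to the vocabulary
STATE_ALIASES = {
    "simple shape": "simple_shape",
    "simple": "simple_shape",
    "<30": "lt30",
    ">30": "gt30",
}

AMBIGUOUS = "ambiguous"

StateTuple = tuple[str, str, str, str]


def normalise_state(character: str, state: str) -> str:
    s = STATE_ALIASES.get(state.strip().lower(), state.strip().lower())
    if s not in VOCABULARY[character]:
        raise FormatError(
            f"unknown {character} state {state!r}; allowed: "
            f"{', '.join(VOCABULARY[character])}")
    return s


@dataclass
class MorphMatrix:
    """Specimen x character state table (one row per specimen)."""

    df: pd.DataFrame  # index: specimen; columns: locality + CHARACTERS

    def __post_init__(self) -> None:
        missing = [c for c in CHARACTERS if c not in self.df.columns]
        if missing:
            raise FormatError(f"missing character columns: {missing}")
        if self.df.index.duplicated().any():
            dups = self.df.index[self.df.index.duplicated()].tolist()
            raise FormatError(f"duplicate specimens: {dups}")
        for c in CHARACTERS:
            self.df[c] = [normalise_state(c, s) for s in self.df[c]]

    @property
    def specimens(self) -> list[str]:
        return list(self.df.index)

    def states(self, specimen: str) -> StateTuple:
        row = self.df.loc[specimen]
        return tuple(row[c] for c in CHARACTERS)  # type: ignore[return-value]

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class MorphProfile:
    """Per-unit modal character states plus the specimens deviating from
    their unit's mode.  A tied character is recorded as 'ambiguous',
    never silently broken."""

    profiles: dict[str, dict[str, str]]  # unit -> character -> state
    deviants: list[tuple[str, str, str, str]] = field(default_factory=list)
    # (specimen, character, observed, modal)

    def profile_tuple(self, unit: str) -> StateTuple:
        p = self.profiles[unit]
        return tuple(p[c] for c in CHARACTERS)  # type: ignore[return-value]


def modal_profiles(mm: MorphMatrix, units: UnitPartition) -> MorphProfile:
    """Majority state per character per unit; specimens differing from
    their unit's modal state are listed as deviants."""
    unassigned = [s for s in mm.specimens if s not in units.assignment]
    if unassigned:
        raise FormatError(f"specimens without a unit: {unassigned}")
    profiles: dict[str, dict[str, str]] = {}
    deviants: list[tuple[str, str, str, str]] = []
    for unit in units.units:
        members = [s for s in units.members(unit) if s in mm.df.index]
        if not members:
            continue
        prof: dict[str, str] = {}
        for c in CHARACTERS:
            counts = Counter(mm.df.loc[s, c] for s in members)
            top = counts.most_common()
            if len(top) > 1 and top[0][1] == top[1][1]:
                prof[c] = AMBIGUOUS
                continue
            prof[c] = top[0][0]
            for s in members:
                obs = mm.df.loc[s, c]
                if obs != prof[c]:
                    deviants.append((s, c, obs, prof[c]))
        profiles[unit] = prof
    return MorphProfile(profiles, deviants)


def diagnosability(profile: MorphProfile) -> list[list[str]]:
    """Partition units into groups with identical modal profiles
    (mutually indistinguishable on all four characters)."""
    groups: dict[StateTuple, list[str]] = {}
    for unit in profile.profiles:
        groups.setdefault(profile.profile_tuple(unit), []).append(unit)
    return list(groups.values())


#: the key to species; chela matters everywhere it is listed
_KEY: dict[StateTuple, str] = {
    ("smooth", "fusiform", "truncate", "lt30"): "P. microcionides group",
    ("spined", "mucronate", "simple_shape", "lt30"): "P. ambigua",
    ("spined", "mucronate", "simple_shape", "gt30"): "P. grandichelata",
    ("spined", "tylote", "simple_shape", "lt30"): "P. tylotata",
    ("spined", "tylote", "simple_shape", "gt30"): "putative new (Cadiz type)",
}

UNASSIGNED = "unassigned"


def apply_key(states: StateTuple) -> str:
    """Assign a taxon label from one character tuple; combinations
    outside the key return 'unassigned'."""
    states = tuple(normalise_state(c, s)
                   for c, s in zip(CHARACTERS, states))
    return _KEY.get(states, UNASSIGNED)


def concordance_table(mm: MorphMatrix, units: UnitPartition) -> pd.DataFrame:
    """ESU x morphotype contingency table over individual specimens."""
    rows = []
    for s in mm.specimens:
        rows.append({"unit": units.assignment.get(s, UNASSIGNED),
                     "morphotype": apply_key(mm.states(s))})
    df = pd.DataFrame(rows)
    return pd.crosstab(df["unit"], df["morphotype"])
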