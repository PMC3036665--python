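"""Bundled fixtures: the published unit-level divergence tables and the
morphology table they accompany, shipped exactly as printed (tab
separated, decimal commas, '-' for singleton diagonals).

The COI table labels its large Part-B clade "H8a-e" (five mitochondrial
haplotypes sharing a single nuclear genotype, "H8", in the 28S table);
``COI_TO_ESU`` maps between the two labellings.
"""

from __future__ import annotations

from importlib import resources

from ..matrices import LabelledMatrix
from ..morphology import MorphMatrix
from ..partition import UnitPartition

#: unit-name harmonisation between the per-locus tables
COI_TO_ESU = {"H8a-e": "H8"}

#: the two deep clades of the published trees
PART_OF = {"H7": "B", "H8": "B", "H1": "A", "H2": "A", "H3": "A",
           "H4": "A", "H5": "A", "H6": "A"}


def fixture_path(name: str) -> str:
    return str(resources.files(__package__).joinpath(name))


def table1_coi(esu_labels: bool = False) -> LabelledMatrix:
    """COI unit-level corrected divergence (between-unit below diagonal,
    within-unit on it)."""
    from ..formats_io import read_distance_table
    m = read_distance_table(fixture_path("table1_coi.tsv"))
    return m.rename(COI_TO_ESU) if esu_labels else m


def table2_28s() -> LabelledMatrix:
    """28S unit-level corrected divergence."""
    from ..formats_io import read_distance_table
    return read_distance_table(fixture_path("table2_28s.tsv"))


def table3_morphology() -> tuple[MorphMatrix, UnitPartition]:
    """The 46-specimen morphology table with its unit identities."""
    from ..formats_io import read_morph_matrix
    mm, esu = read_morph_matrix(fixture_path("table3_morphology.csv"))
    order = list(dict.fromkeys(esu.values()))
    return mm, UnitPartition(esu, order)
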