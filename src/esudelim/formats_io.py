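"""Readers and writers for every external representation the pipeline
touches: FASTA alignments, labelled distance tables (lower-triangle or
square, PHYLIP-style or TSV, with ',' or '.' decimals per cell),
specimen metadata CSV, morphology CSV, and the structured JSON report.

Decimal commas are supported because published divergence tables often
print "0,019"-style values; detection is per cell, never per file.  A
'-' diagonal cell marks a singleton unit whose within-unit divergence
is treated as 0 downstream.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._iupac import encode
from .delineation import EsuReport
from .errors import AlignmentError, FormatError
from .matrices import DIAG_WITHIN, LabelledMatrix
from .morphology import CHARACTERS, MorphMatrix
from .seqmodels import Alignment


# ---------------------------------------------------------------------------
# specimen metadata
# ---------------------------------------------------------------------------

@dataclass
class SpecimenRecord:
    """One specimen: id, locality code and the loci sequenced for it.

    By convention an uppercase locality code marks a deep-water site
    (>50 m) and a lowercase code a shallow one.
    """

    specimen_id: str
    locality_code: str
    loci_present: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.locality_code:
            raise FormatError(
                f"specimen {self.specimen_id!r} has empty locality code")

    @property
    def is_deep(self) -> bool:
        return self.locality_code == self.locality_code.upper()


def read_specimens(path) -> list[SpecimenRecord]:
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"specimen_id", "locality_code"}
    if not required <= set(df.columns):
        raise FormatError(f"specimen CSV needs columns {sorted(required)}")
    ids = df["specimen_id"].tolist()
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate specimen ids")
    out = []
    for _, row in df.iterrows():
        loci = frozenset(x for x in row.get("loci", "").split(";") if x)
        out.append(SpecimenRecord(row["specimen_id"], row["locality_code"],
                                  loci))
    return out


def write_specimens(records: list[SpecimenRecord], path) -> None:
    pd.DataFrame(
        {"specimen_id": [r.specimen_id for r in records],
         "locality_code": [r.locality_code for r in records],
         "loci": [";".join(sorted(r.loci_present)) for r in records]}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

def read_alignment(path, locus: str = "") -> Alignment:
    """Read an aligned multi-FASTA file; sequences are uppercased and
    validated against the IUPAC alphabet (gap '-' preserved)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no records in {path}")
    labels = [r.id for r in records]
    seqs = [str(r.seq).upper() for r in records]
    for label, seq in zip(labels, seqs):
        try:
            encode(seq)
        except ValueError as exc:
            raise FormatError(f"record {label!r}: {exc}") from None
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise AlignmentError(
            f"records of unequal length in {path}: {sorted(lengths)}")
    return Alignment(labels, seqs, locus or Path(str(path)).stem)


def write_alignment(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for label, seq in zip(aln.labels, aln.sequences):
            fh.write(f">{label}\n{seq}\n")


# ---------------------------------------------------------------------------
# distance tables
# ---------------------------------------------------------------------------

_MISSING = {"-", "", "na", "nan"}


def _parse_cell(cell: str) -> float:
    """One numeric cell; decimal comma or dot decided per cell."""
    s = cell.strip()
    if s.lower() in _MISSING:
        return np.nan
    try:
        v = float(s.replace(",", "."))
    except ValueError:
        raise FormatError(f"unparseable distance value {cell!r}") from None
    if v < 0:
        raise FormatError(f"negative distance value {cell!r}")
    return v


def read_distance_table(path, diagonal_semantics: str = DIAG_WITHIN
                        ) -> LabelledMatrix:
    """Read a labelled lower-triangle (canonical) or full-square
    distance table, or a PHYLIP-style square matrix.

    Lower-triangle rows carry the diagonal as their last cell; '-'
    means a missing (singleton) diagonal.  A full square matrix must be
    symmetric within 1e-9.
    """
    lines = [ln.rstrip("\n") for ln in open(path)
             if ln.strip()]
    if not lines:
        raise FormatError(f"no rows in {path}")

    def split(ln: str) -> list[str]:
        return ln.split("\t") if "\t" in ln else ln.split()

    first = split(lines[0])
    if len(first) == 1 and first[0].strip().isdigit():
        # PHYLIP square: count line, then label + n values
        n = int(first[0])
        rows = [split(ln) for ln in lines[1:]]
        if len(rows) != n:
            raise FormatError(f"PHYLIP matrix expects {n} rows")
        labels = [r[0] for r in rows]
        vals = np.array([[_parse_cell(c) for c in r[1:]] for r in rows])
        if vals.shape != (n, n):
            raise FormatError("PHYLIP matrix rows have wrong cell counts")
        return LabelledMatrix(labels, vals, diagonal_semantics)

    header = [h for h in first[1:] if h.strip()]
    rows = [split(ln) for ln in lines[1:]]
    labels = [r[0] for r in rows]
    n = len(labels)
    if header and len(header) != n:
        raise FormatError("header and row labels disagree in count")
    cells = [[_parse_cell(c) for c in r[1:]] for r in rows]
    widths = [len(c) for c in cells]
    vals = np.full((n, n), np.nan)
    if widths == list(range(1, n + 1)):          # lower triangle + diagonal
        for i, row in enumerate(cells):
            for j, v in enumerate(row):
                vals[i, j] = v
                vals[j, i] = v
    elif widths == list(range(0, n)):            # strict lower triangle
        for i, row in enumerate(cells):
            for j, v in enumerate(row):
                vals[i, j] = v
                vals[j, i] = v
        np.fill_diagonal(vals, 0.0)
    elif all(w == n for w in widths):            # full square
        vals = np.array(cells)
    else:
        raise FormatError(
            "rows are neither a lower triangle nor a full square")
    return LabelledMatrix(labels, vals, diagonal_semantics)


def write_distance_table(m: LabelledMatrix, path, decimal: str = ".") -> None:
    """Write the canonical labelled lower-triangle (with diagonal)."""
    def fmt(v: float) -> str:
        if np.isnan(v):
            return "-"
        s = f"{v:.10g}"
        return s.replace(".", ",") if decimal == "," else s

    with open(path, "w") as fh:
        fh.write("unit\t" + "\t".join(m.labels) + "\n")
        for i, lab in enumerate(m.labels):
            cells = [fmt(m.values[i, j]) for j in range(i + 1)]
            fh.write(lab + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# morphology
# ---------------------------------------------------------------------------

def read_morph_matrix(path) -> tuple[MorphMatrix, dict[str, str]]:
    """Read the morphology CSV.

    Expected columns: specimen, locality, large_style, tornotes,
    acanthostrongyle, chela (chela as '<30'/'>30' or 'lt30'/'gt30');
    an optional 'esu' column with prior unit identities is returned as
    the second element (empty dict when absent).
    """
    df = pd.read_csv(path, dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"specimen", "locality", *CHARACTERS}
    if not required <= set(df.columns):
        raise FormatError(
            f"morphology CSV needs columns {sorted(required)}; "
            f"got {list(df.columns)}")
    esu = dict(zip(df["specimen"], df["esu"])) if "esu" in df.columns else {}
    df = df.set_index("specimen")
    mm = MorphMatrix(df[["locality", *CHARACTERS]].copy())
    return mm, esu


def write_morph_matrix(mm: MorphMatrix, path,
                       esu: dict[str, str] | None = None) -> None:
    df = mm.df.copy()
    df.insert(0, "specimen", df.index)
    if esu:
        df["esu"] = [esu.get(s, "") for s in df.index]
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def write_report(report: EsuReport, path) -> None:
    """Machine-readable JSON report with an embedded human summary;
    round-trips losslessly through :func:`read_report`."""
    if not report.units.units:
        raise FormatError("no units in report")
    payload = {"format": "esudelim-report", "version": 1,
               "summary": report.summary(), "report": report.to_dict()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_report(path) -> EsuReport:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "esudelim-report":
        raise FormatError(f"{path} is not an esudelim report")
    return EsuReport.from_dict(payload["report"])


def file_digest(path) -> str:
    """sha256 of a file, for run provenance logging."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
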