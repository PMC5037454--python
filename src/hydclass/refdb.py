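"""Reference-database data model and I/O.

Sequences are hydrogenase catalytic subunits (or decoy homologs); labels live
in a three-level taxonomy (type -> group -> subclass) with 38 terminal
hydrogenase classes plus four decoy families of non-H2-metabolizing homologs
(Nuo, Ehr, NARF, HmdII).  The class catalog bundled with the package records,
for every class, its name, predicted physiological function, and whether it
was newly delineated or carried over from earlier schemes.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SequenceRecord",
    "ClassLabel",
    "CatalogEntry",
    "ReferenceDatabase",
    "FastaError",
    "LabelError",
    "NIFE_CODES",
    "FEFE_CODES",
    "FE_CODES",
    "DECOY_CODES",
    "read_fasta",
    "write_fasta",
    "load_labels",
    "load_reference",
    "load_catalog",
    "filter_and_export",
]

#: Closed subclass catalog, keyed by hydrogenase type.
NIFE_CODES = frozenset(
    [f"1{c}" for c in "abcdefghijk"]
    + [f"2{c}" for c in "abcde"]
    + [f"3{c}" for c in "abcd"]
    + [f"4{c}" for c in "abcdefghi"]
)
#: "A" is the unrefined [FeFe] Group A; A1-A4 are its genetic-organization subtypes.
FEFE_CODES = frozenset(["A", "A1", "A2", "A3", "A4", "B", "C1", "C2", "C3"])
FE_CODES = frozenset(["Fe"])
#: Families homologous to hydrogenases that do not metabolize H2.
DECOY_CODES = frozenset(["Nuo", "Ehr", "NARF", "HmdII"])

_ALL_CODES = NIFE_CODES | FEFE_CODES | FE_CODES | DECOY_CODES

_VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYXBZU*")


class FastaError(ValueError):
    """Malformed FASTA input."""


class LabelError(ValueError):
    """Label table inconsistent with the sequence set or the class catalog."""


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence with a unique identifier.

    Residues are uppercase over the 20 standard amino acids plus the
    ambiguity/rarity codes X, B, Z and U; a terminal stop ``*`` is stripped
    during normalization.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise FastaError(f"record {self.id!r} has an empty sequence")
        bad = set(self.residues) - _VALID_RESIDUES
        if bad:
            pos = min(i for i, r in enumerate(self.residues) if r in bad)
            raise FastaError(
                f"record {self.id!r}: invalid residue {self.residues[pos]!r} "
                f"at position {pos}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    @staticmethod
    def normalize(raw: str) -> str:
        s = raw.strip().upper()
        if s.endswith("*"):
            s = s[:-1]
        return s


@dataclass(frozen=True, order=True)
class ClassLabel:
    """A node in the class taxonomy, or a decoy family."""

    hydrogenase_type: str  # NiFe | FeFe | Fe | DECOY
    subclass_code: str

    def __post_init__(self) -> None:
        expected = _type_of(self.subclass_code)
        if expected is None:
            raise LabelError(f"unknown subclass code {self.subclass_code!r}")
        if expected != self.hydrogenase_type:
            raise LabelError(
                f"code {self.subclass_code!r} belongs to type {expected}, "
                f"not {self.hydrogenase_type}"
            )

    @classmethod
    def parse(cls, code: str) -> "ClassLabel":
        code = code.strip()
        t = _type_of(code)
        if t is None:
            raise LabelError(f"unknown subclass code {code!r}")
        return cls(t, code)

    @property
    def is_decoy(self) -> bool:
        return self.hydrogenase_type == "DECOY"

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.subclass_code


def _type_of(code: str) -> str | None:
    if code in NIFE_CODES:
        return "NiFe"
    if code in FEFE_CODES:
        return "FeFe"
    if code in FE_CODES:
        return "Fe"
    if code in DECOY_CODES:
        return "DECOY"
    return None


@dataclass(frozen=True)
class CatalogEntry:
    """One row of the 38-class catalog."""

    label: ClassLabel
    name: str
    predicted_function: str
    provenance: str  # "prior work" or "This work"

    @property
    def putative(self) -> bool:
        return "(putative)" in self.name


@dataclass
class ReferenceDatabase:
    """Labeled reference sequences for classification and network analysis."""

    records: list[SequenceRecord]
    labels: dict[str, ClassLabel]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise LabelError(f"duplicate sequence ids: {', '.join(dupes)}")
        missing = [i for i in ids if i not in self.labels]
        extra = sorted(set(self.labels) - set(ids))
        if missing:
            raise LabelError(f"ids without labels: {', '.join(missing)}")
        if extra:
            raise LabelError(f"labels without sequences: {', '.join(extra)}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def record(self, rec_id: str) -> SequenceRecord:
        try:
            return next(r for r in self.records if r.id == rec_id)
        except StopIteration:
            raise KeyError(rec_id) from None

    @property
    def classes(self) -> set[ClassLabel]:
        return set(self.labels.values())

    @property
    def n_hydrogenase_classes(self) -> int:
        return sum(1 for c in self.classes if not c.is_decoy)

    @property
    def total_residues(self) -> int:
        return sum(r.length for r in self.records)

    def subset(self, ids: Iterable[str]) -> "ReferenceDatabase":
        keep = set(ids)
        return ReferenceDatabase(
            records=[r for r in self.records if r.id in keep],
            labels={i: l for i, l in self.labels.items() if i in keep},
        )


def read_fasta(source: str) -> list[SequenceRecord]:
    """Parse FASTA from a path or from raw text.

    Wrapped sequence lines are joined; residues uppercased; a terminal stop
    codon character is stripped.  Text before the first header, or a record
    with no residues, raises :class:`FastaError`.
    """
    text = _slurp(source)
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if not stripped.startswith(">"):
            raise FastaError(f"line {lineno}: sequence data before first '>' header")
        break
    out: list[SequenceRecord] = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        residues = SequenceRecord.normalize(str(rec.seq))
        if not residues:
            raise FastaError(f"record {rec.id!r} has an empty sequence")
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        out.append(SequenceRecord(id=rec.id, residues=residues, description=desc))
    ids = [r.id for r in out]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise FastaError(f"duplicate ids in FASTA: {', '.join(dupes)}")
    return out


def write_fasta(records: Iterable[SequenceRecord], width: int = 60) -> str:
    """Render records as multi-FASTA with lines wrapped at ``width`` columns."""
    chunks: list[str] = []
    for r in records:
        header = f">{r.id}" + (f" {r.description}" if r.description else "")
        body = "\n".join(
            r.residues[i : i + width] for i in range(0, len(r.residues), width)
        )
        chunks.append(f"{header}\n{body}\n")
    return "".join(chunks)


def load_labels(source: str) -> dict[str, ClassLabel]:
    """Read the 2-column TSV label table (header ``id<TAB>subclass``)."""
    text = _slurp(source)
    labels: dict[str, ClassLabel] = {}
    lines = [l for l in text.splitlines() if l.strip()]
    if not lines:
        return labels
    start = 1 if lines[0].lower().startswith("id") else 0
    for line in lines[start:]:
        parts = line.split("\t")
        if len(parts) < 2:
            raise LabelError(f"label line lacks two tab-separated columns: {line!r}")
        rec_id, code = parts[0].strip(), parts[1].strip()
        if rec_id in labels:
            raise LabelError(f"duplicate label for id {rec_id!r}")
        labels[rec_id] = ClassLabel.parse(code)
    return labels


def load_reference(fasta: str, labels: str) -> ReferenceDatabase:
    """Assemble a :class:`ReferenceDatabase` from a FASTA file and a label TSV.

    The labeling must be a total function from record ids onto the closed
    catalog (hydrogenase subclasses plus decoy families); any mismatch is an
    error listing the offending ids.
    """
    return ReferenceDatabase(records=read_fasta(fasta), labels=load_labels(labels))


def load_catalog() -> list[CatalogEntry]:
    """Load the bundled 38-class catalog (29 [NiFe] + 8 [FeFe] + 1 [Fe]).

    [NiFeSe] selenocysteine variants are noted within 1a/3a/3c rather than
    listed as separate classes, and the unrefined [FeFe] Group "A" is not a
    catalog row: its members resolve to A1-A4.
    """
    data = resources.files("hydclass.data").joinpath("class_catalog.tsv").read_text()
    entries: list[CatalogEntry] = []
    reader = csv.DictReader(io.StringIO(data), delimiter="\t")
    for row in reader:
        entries.append(
            CatalogEntry(
                label=ClassLabel.parse(row["code"]),
                name=row["name"],
                predicted_function=row["predicted_function"],
                provenance=row["provenance"],
            )
        )
    return entries


def filter_and_export(
    db: ReferenceDatabase,
    predicate: Callable[[SequenceRecord, ClassLabel], bool] | None = None,
    format: str = "CSV",
) -> str:
    """Filter the database and render the selection as CSV or FASTA.

    Output is ordered by record id so exports are deterministic.  The CSV has
    columns ``id,type,subclass,description`` with RFC-4180 quoting.
    """
    selected = sorted(
        (r for r in db.records if predicate is None or predicate(r, db.labels[r.id])),
        key=lambda r: r.id,
    )
    fmt = format.upper()
    if fmt == "FASTA":
        return write_fasta(selected)
    if fmt == "CSV":
        buf = io.StringIO()
        w = csv.writer(buf, lineterminator="\n")
        w.writerow(["id", "type", "subclass", "description"])
        for r in selected:
            lab = db.labels[r.id]
            w.writerow([r.id, lab.hydrogenase_type, lab.subclass_code, r.description])
        return buf.getvalue()
    raise ValueError(f"unknown export format {format!r} (expected CSV or FASTA)")


def _slurp(source: str) -> str:
    """Accept a filesystem path or raw text (text must contain a newline or '>')."""
    import os

    if os.path.exists(source) and not source.lstrip().startswith(">"):
        with open(source) as fh:
            return fh.read()
    if source.lstrip().startswith(">") or "\n" in source or "\t" in source:
        return source
    if os.path.exists(source):
        with open(source) as fh:
            return fh.read()
    raise FileNotFoundError(source)
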