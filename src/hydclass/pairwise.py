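"""BLAST-style distance oracle over protein sequences.

The classifier's distance measure is that of a protein homology search:
optimal Smith-Waterman local alignment score under BLOSUM62 with affine gaps,
converted to bit scores and E-values with the Karlin-Altschul statistics for
that scoring system.  The default backend runs the exact dynamic program
in-process (no external binary needed); an external tabular-output search
tool can be dropped in behind the same :class:`AlignmentHit` contract, in
which case only the neighbor ORDER — not absolute E-values — is expected to
be reproducible across backends.

Conventions
-----------
* Gap cost: ``gap_open + gap_extend * L`` for a gap of length ``L`` (the
  BLAST cost convention for "open 11, extend 1").
* Effective search space: the plain product ``m * n`` of query length and
  database residue count.  Neighbor ranking, not absolute E-value fidelity,
  drives the classifier, and the homology threshold is configurable.
* Ambiguity codes X/B/Z are scored by their BLOSUM62 columns; selenocysteine
  (U) is scored as cysteine.
"""

from __future__ import annotations

import math
import shlex
import subprocess
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .refdb import ReferenceDatabase, SequenceRecord

__all__ = [
    "ScoringScheme",
    "AlignmentHit",
    "local_align",
    "to_bits_and_evalue",
    "search",
    "all_vs_all",
    "hits_to_frame",
    "ExternalSearchBackend",
]

# Published gapped Karlin-Altschul parameters for BLOSUM62 / open 11 / extend 1.
_DEFAULT_LAMBDA = 0.267
_DEFAULT_KAPPA = 0.041


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix, affine gap penalties, and E-value statistics."""

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = _DEFAULT_LAMBDA
    kappa: float = _DEFAULT_KAPPA

    def __post_init__(self) -> None:
        if self.gap_open < self.gap_extend:
            raise ValueError("gap_open must be >= gap_extend")
        if self.lam <= 0 or self.kappa <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")

    @property
    def matrix(self):
        return _load_matrix(self.matrix_name)

    def aligner(self) -> Align.PairwiseAligner:
        return _make_aligner(
            self.matrix_name, self.gap_open, self.gap_extend
        )


@lru_cache(maxsize=4)
def _load_matrix(name: str):
    return substitution_matrices.load(name)


@lru_cache(maxsize=4)
def _make_aligner(matrix_name: str, gap_open: int, gap_extend: int):
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _load_matrix(matrix_name)
    # Biopython charges open_gap_score for the FIRST gapped position; the
    # BLAST convention charges open + extend for it.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


@dataclass(frozen=True)
class AlignmentHit:
    """A query-subject local-alignment result."""

    query_id: str
    subject_id: str
    raw_score: int
    bit_score: float
    e_value: float
    query_len: int
    subject_len: int

    @property
    def log_e(self) -> float:
        return math.log10(self.e_value) if self.e_value > 0 else -math.inf


def _encode(record: SequenceRecord, alphabet: str) -> str:
    """Map residues onto the substitution-matrix alphabet (U scored as C)."""
    s = record.residues.replace("U", "C")
    bad = set(s) - set(alphabet)
    if bad:
        pos = min(i for i, r in enumerate(s) if r in bad)
        raise ValueError(
            f"record {record.id!r}: residue {s[pos]!r} at position {pos} "
            f"is outside the scoring alphabet"
        )
    return s


def local_align(
    a: SequenceRecord, b: SequenceRecord, scheme: ScoringScheme | None = None
) -> int:
    """Optimal Smith-Waterman local-alignment raw score (symmetric, >= 0)."""
    scheme = scheme or ScoringScheme()
    alphabet = str(scheme.matrix.alphabet)
    aligner = scheme.aligner()
    score = aligner.score(_encode(a, alphabet), _encode(b, alphabet))
    return int(round(max(score, 0.0)))


def to_bits_and_evalue(
    raw_score: int, scheme: ScoringScheme, m: int, n: int
) -> tuple[float, float]:
    """Karlin-Altschul transform: raw score -> (bit score, E-value).

    ``bits = (lambda * S - ln kappa) / ln 2`` and ``E = m * n * 2**-bits``
    with the plain-product search space (no length correction).
    """
    if raw_score < 0:
        raise ValueError("raw_score must be >= 0")
    if m <= 0 or n <= 0:
        raise ValueError("sequence/search-space lengths must be positive")
    bits = (scheme.lam * raw_score - math.log(scheme.kappa)) / math.log(2)
    e_value = float(m) * float(n) * math.pow(2.0, -bits)
    return bits, e_value


def _hit(
    query: SequenceRecord,
    subject: SequenceRecord,
    scheme: ScoringScheme,
    n_space: int,
    aligner=None,
    alphabet: str | None = None,
) -> AlignmentHit:
    if aligner is None:
        aligner = scheme.aligner()
        alphabet = str(scheme.matrix.alphabet)
    raw = int(round(max(aligner.score(_encode(query, alphabet), _encode(subject, alphabet)), 0.0)))
    bits, e = to_bits_and_evalue(raw, scheme, query.length, n_space)
    return AlignmentHit(
        query_id=query.id,
        subject_id=subject.id,
        raw_score=raw,
        bit_score=bits,
        e_value=e,
        query_len=query.length,
        subject_len=subject.length,
    )


def _sort_key(h: AlignmentHit):
    return (h.e_value, -h.bit_score, h.subject_id)


def search(
    query: SequenceRecord,
    db: ReferenceDatabase,
    scheme: ScoringScheme | None = None,
    max_e: float = math.inf,
) -> list[AlignmentHit]:
    """Score a query against every database member; keep hits with E <= max_e.

    Hits are sorted ascending by E-value, ties broken by descending bit score,
    then by subject id.
    """
    if len(db) == 0:
        raise ValueError("reference database is empty")
    scheme = scheme or ScoringScheme()
    aligner = scheme.aligner()
    alphabet = str(scheme.matrix.alphabet)
    n_space = db.total_residues
    hits = [
        _hit(query, subj, scheme, n_space, aligner, alphabet) for subj in db.records
    ]
    hits = [h for h in hits if h.e_value <= max_e]
    hits.sort(key=_sort_key)
    return hits


def all_vs_all(
    db: ReferenceDatabase,
    scheme: ScoringScheme | None = None,
    max_e: float = math.inf,
) -> list[AlignmentHit]:
    """Every ordered pair (i, j) with E <= max_e, self pairs included.

    Self and duplicate pairs are the network layer's job to remove.  Scores
    are computed once per unordered pair (the local-alignment score is
    symmetric); the two directed hits differ only through the query-length
    factor in the E-value.
    """
    if len(db) == 0:
        raise ValueError("reference database is empty")
    scheme = scheme or ScoringScheme()
    aligner = scheme.aligner()
    alphabet = str(scheme.matrix.alphabet)
    n_space = db.total_residues
    records = db.records
    encoded = [_encode(r, alphabet) for r in records]
    hits: list[AlignmentHit] = []
    for i, qi in enumerate(records):
        for j, sj in enumerate(records):
            if j < i:
                continue
            raw = int(round(max(aligner.score(encoded[i], encoded[j]), 0.0)))
            for q, s in ((qi, sj),) if i == j else ((qi, sj), (sj, qi)):
                bits, e = to_bits_and_evalue(raw, scheme, q.length, n_space)
                if e <= max_e:
                    hits.append(
                        AlignmentHit(q.id, s.id, raw, bits, e, q.length, s.length)
                    )
    hits.sort(key=lambda h: (h.query_id, h.e_value, -h.bit_score, h.subject_id))
    return hits


def hits_to_frame(hits: Iterable[AlignmentHit]) -> pd.DataFrame:
    """Tabular view mirroring BLAST outfmt 6 field names."""
    return pd.DataFrame(
        [
            {
                "qseqid": h.query_id,
                "sseqid": h.subject_id,
                "bitscore": h.bit_score,
                "evalue": h.e_value,
            }
            for h in hits
        ],
        columns=["qseqid", "sseqid", "bitscore", "evalue"],
    )


class ExternalSearchBackend:
    """Run an external tabular-output search tool via a command template.

    The template receives ``{query}`` and ``{db}`` (FASTA paths) and must
    print tab-separated ``qseqid sseqid bitscore evalue`` rows (BLAST
    ``-outfmt "6 qseqid sseqid bitscore evalue"``).  Only neighbor ranking is
    guaranteed to agree with the internal backend.
    """

    def __init__(self, command_template: str):
        self.command_template = command_template

    def search(self, query_path: str, db_path: str) -> list[AlignmentHit]:
        cmd = self.command_template.format(query=query_path, db=db_path)
        proc = subprocess.run(
            shlex.split(cmd), capture_output=True, text=True, check=True
        )
        return self.parse_tabular(proc.stdout)

    @staticmethod
    def parse_tabular(text: str) -> list[AlignmentHit]:
        hits = []
        for line in text.splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            q, s, bits, e = line.split("\t")[:4]
            hits.append(
                AlignmentHit(
                    query_id=q,
                    subject_id=s,
                    raw_score=0,
                    bit_score=float(bits),
                    e_value=float(e),
                    query_len=0,
                    subject_len=0,
                )
            )
        hits.sort(key=_sort_key)
        return hits
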