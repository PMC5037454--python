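"""Pre-classification screening gates.

Before a query reaches the k-NN stage, two checks establish that it plausibly
encodes a hydrogenase catalytic subunit:

1. **Conserved-domain gate** — the query must carry one of the three catalytic
   domains: ``cl21493`` (Complex1_49kDa superfamily; [NiFe]), ``cl14953``
   (Fe_hyd_lg_C superfamily; [FeFe]) or ``pfam03201`` (HMD; [Fe]).  The
   matched domain also fixes the hydrogenase type the query is expected to
   receive, which downstream code uses for a consistency warning.
2. **Homology gate** — the best E-value against the reference database must
   be at or below the threshold (default 1e-5).

A query failing either gate is labeled a non-hydrogenase.  Domain search
requires a profile database that cannot be bundled, so three backends are
provided: an external command (e.g. RPS-BLAST against CDD), a mock lookup
table for tests, and a bypass that defers entirely to the homology gate.
"""

from __future__ import annotations

import logging
import shlex
import subprocess
from dataclasses import dataclass
from typing import Iterable, Mapping, Protocol, Sequence

from .pairwise import AlignmentHit, ScoringScheme, search
from .refdb import ReferenceDatabase, SequenceRecord

__all__ = [
    "DomainAnnotation",
    "ScreenResult",
    "DomainBackend",
    "MockDomainBackend",
    "BypassDomainBackend",
    "ExternalDomainBackend",
    "DomainBackendError",
    "CATALYTIC_DOMAINS",
    "HOMOLOGY_THRESHOLD",
    "domain_check",
    "homology_check",
    "screen",
]

logger = logging.getLogger(__name__)

#: Accession -> hydrogenase type for the three catalytic domains.
CATALYTIC_DOMAINS: dict[str, str] = {
    "cl21493": "NiFe",  # Complex1_49kDa superfamily
    "cl14953": "FeFe",  # Fe_hyd_lg_C superfamily
    "pfam03201": "Fe",  # HMD
}

#: Queries whose best reference E-value exceeds this are non-hydrogenases.
HOMOLOGY_THRESHOLD = 1e-5

#: Default acceptance E-value for a domain hit reported by a backend.
DOMAIN_HIT_EVALUE = 0.01


class DomainBackendError(RuntimeError):
    """The domain backend itself failed (distinct from 'no domain found')."""


@dataclass(frozen=True)
class DomainAnnotation:
    """One conserved-domain hit on a sequence."""

    domain_name: str
    accession: str
    e_value: float = 0.0

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError("domain e_value must be >= 0")


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of both gates for one query."""

    domain_ok: bool
    homology_ok: bool
    best_hit: AlignmentHit | None = None
    matched_domain: DomainAnnotation | None = None

    @property
    def passed(self) -> bool:
        return self.domain_ok and self.homology_ok

    @property
    def failure_reason(self) -> str | None:
        """Failing gate, the domain gate reported first when both fail."""
        if not self.domain_ok:
            return "failed_domain"
        if not self.homology_ok:
            return "failed_homology"
        return None

    @property
    def matched_type(self) -> str | None:
        """Hydrogenase type implied by the matched catalytic domain.

        ``None`` under the bypass backend, whose synthetic annotations carry
        no information about the actual domain content.
        """
        if self.matched_domain is None or self.matched_domain.domain_name == "bypass":
            return None
        return CATALYTIC_DOMAINS.get(self.matched_domain.accession)


class DomainBackend(Protocol):
    def annotate(self, seq: SequenceRecord) -> list[DomainAnnotation]: ...


class MockDomainBackend:
    """Lookup-table backend for tests: id -> annotations.

    Built directly from a mapping or from a TSV table with columns
    ``id, accession, name, evalue``.
    """

    def __init__(self, table: Mapping[str, Sequence[DomainAnnotation]]):
        self._table = {k: list(v) for k, v in table.items()}

    @classmethod
    def from_tsv(cls, text: str) -> "MockDomainBackend":
        table: dict[str, list[DomainAnnotation]] = {}
        lines = [l for l in text.splitlines() if l.strip()]
        start = 1 if lines and lines[0].lower().startswith("id") else 0
        for line in lines[start:]:
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"mock table line lacks 3 columns: {line!r}")
            rec_id, acc, name = parts[0], parts[1], parts[2]
            e = float(parts[3]) if len(parts) > 3 else 0.0
            table.setdefault(rec_id, []).append(DomainAnnotation(name, acc, e))
        return cls(table)

    def annotate(self, seq: SequenceRecord) -> list[DomainAnnotation]:
        return list(self._table.get(seq.id, []))


class BypassDomainBackend:
    """Treat every sequence as domain-positive; homology gate decides alone.

    For fully offline runs without a conserved-domain profile database.  The
    first use logs a warning because the domain gate is effectively disabled.
    """

    _warned = False

    def annotate(self, seq: SequenceRecord) -> list[DomainAnnotation]:
        if not BypassDomainBackend._warned:
            logger.warning(
                "domain gate bypassed: every query is treated as carrying a "
                "catalytic domain; classification rests on the homology gate"
            )
            BypassDomainBackend._warned = True
        return [DomainAnnotation("bypass", acc, 0.0) for acc in CATALYTIC_DOMAINS]


class ExternalDomainBackend:
    """Run an external profile-search command (e.g. RPS-BLAST against CDD).

    The command template receives ``{query}`` (a FASTA path) and must emit
    tab-separated rows ``qseqid, accession, name, evalue``.
    """

    def __init__(self, command_template: str, max_e: float = DOMAIN_HIT_EVALUE):
        self.command_template = command_template
        self.max_e = max_e

    def annotate(self, seq: SequenceRecord) -> list[DomainAnnotation]:
        import tempfile

        from .refdb import write_fasta

        with tempfile.NamedTemporaryFile("w", suffix=".faa", delete=False) as fh:
            fh.write(write_fasta([seq]))
            path = fh.name
        cmd = self.command_template.format(query=path)
        try:
            proc = subprocess.run(
                shlex.split(cmd), capture_output=True, text=True, check=True
            )
        except (subprocess.CalledProcessError, FileNotFoundError) as exc:
            raise DomainBackendError(f"domain backend failed: {exc}") from exc
        out = []
        for line in proc.stdout.splitlines():
            if not line.strip():
                continue
            parts = line.split("\t")
            _, acc, name = parts[0], parts[1], parts[2]
            e = float(parts[3]) if len(parts) > 3 else 0.0
            if e <= self.max_e:
                out.append(DomainAnnotation(name, acc, e))
        return out


def domain_check(
    seq: SequenceRecord, backend: DomainBackend, max_e: float = DOMAIN_HIT_EVALUE
) -> tuple[bool, DomainAnnotation | None]:
    """True iff the backend reports one of the three catalytic domains."""
    annotations = backend.annotate(seq)
    matches = [
        a
        for a in annotations
        if a.accession in CATALYTIC_DOMAINS and a.e_value <= max_e
    ]
    if not matches:
        return False, None
    best = min(matches, key=lambda a: a.e_value)
    return True, best


def homology_check(
    hits: Sequence[AlignmentHit], threshold: float = HOMOLOGY_THRESHOLD
) -> bool:
    """True iff the best (first) hit exists and its E-value <= threshold."""
    return bool(hits) and hits[0].e_value <= threshold


def screen(
    seq: SequenceRecord,
    db: ReferenceDatabase,
    domain_backend: DomainBackend | None = None,
    threshold: float = HOMOLOGY_THRESHOLD,
    scheme: ScoringScheme | None = None,
    hits: Sequence[AlignmentHit] | None = None,
) -> ScreenResult:
    """Run both gates; the query proceeds to k-NN iff both pass.

    ``hits`` may carry a precomputed ranked hit list (as from
    :func:`hydclass.pairwise.search`) to avoid re-aligning.
    """
    backend = domain_backend or BypassDomainBackend()
    domain_ok, matched = domain_check(seq, backend)
    if hits is None:
        hits = search(seq, db, scheme=scheme)
    best = hits[0] if hits else None
    homology_ok = homology_check(hits, threshold)
    return ScreenResult(
        domain_ok=domain_ok,
        homology_ok=homology_ok,
        best_hit=best,
        matched_domain=matched,
    )
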