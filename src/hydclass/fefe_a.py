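"""[FeFe] Group A subtyping from the downstream gene's conserved domains.

Group A [FeFe]-hydrogenases cannot be split into their functional subtypes
(A1 fermentative, A2 glutamate-synthase-linked, A3 electron-bifurcating,
A4 formate-dehydrogenase-linked) by catalytic-subunit sequence alone: they
diversified through changes in domain architecture and quaternary structure.
The subtype is instead read off the conserved domains of the protein encoded
immediately downstream of the catalytic subunit:

* ``NuoF`` present                       -> **A3**
* any of ``GltA``, ``GltD``, ``glutamate synthase small subunit``,
  ``putative oxidoreductase`` — without ``NuoF`` -> **A2**
* ``HycB`` present (no NuoF, no glutamate-synthase domain) -> **A4**
* none of the vocabulary present          -> **A1**

Precedence for co-occurring domains is A3 > A2 > A4 > A1: NuoF explicitly
overrides the glutamate-synthase set, and the glutamate-synthase set is
checked before HycB.  Conflict resolutions are logged.  Supplying the
downstream sequence (or its annotations) is the caller's job; gene calling
is out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

from .refdb import ClassLabel, SequenceRecord
from .screening import DomainBackend

__all__ = [
    "DownstreamDomains",
    "GROUP_A_VOCABULARY",
    "A2_DOMAINS",
    "classify_group_a",
    "extract_downstream_domains",
]

logger = logging.getLogger(__name__)

#: Domains of the downstream protein that discriminate the A subtypes.
A2_DOMAINS = frozenset(
    ["glta", "gltd", "glutamate synthase small subunit", "putative oxidoreductase"]
)
A3_DOMAIN = "nuof"
A4_DOMAIN = "hycb"
GROUP_A_VOCABULARY = frozenset(A2_DOMAINS | {A3_DOMAIN, A4_DOMAIN})


@dataclass(frozen=True)
class DownstreamDomains:
    """Case-normalized set of rule-vocabulary domains on a downstream protein."""

    query_id: str
    domains: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        normalized = frozenset(d.strip().lower() for d in self.domains)
        object.__setattr__(self, "domains", normalized & GROUP_A_VOCABULARY)


def classify_group_a(domains: DownstreamDomains) -> ClassLabel:
    """Map a downstream-domain set to subtype A1, A2, A3 or A4.

    Total on all domain sets; out-of-vocabulary domains never change the
    result (they are dropped at construction).
    """
    d = domains.domains
    hits = d & GROUP_A_VOCABULARY
    if len({A3_DOMAIN, A4_DOMAIN} & hits) + (1 if hits & A2_DOMAINS else 0) > 1:
        logger.info(
            "downstream domains %s of %s match several subtype rules; "
            "applying precedence A3 > A2 > A4",
            sorted(hits),
            domains.query_id,
        )
    if A3_DOMAIN in d:
        code = "A3"
    elif d & A2_DOMAINS:
        code = "A2"
    elif A4_DOMAIN in d:
        code = "A4"
    else:
        code = "A1"
    return ClassLabel.parse(code)


def extract_downstream_domains(
    seq: SequenceRecord, backend: DomainBackend
) -> DownstreamDomains:
    """Annotate a downstream protein and keep only rule-vocabulary domains."""
    annotations = backend.annotate(seq)
    names = frozenset(a.domain_name.strip().lower() for a in annotations)
    return DownstreamDomains(query_id=seq.id, domains=names & GROUP_A_VOCABULARY)
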