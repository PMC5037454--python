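"""Synthetic labeled protein families for exercising every pipeline stage.

Real hydrogenase reference data is a curated external dataset; these
generators stand in for it with families whose within-family alignment
E-values are far smaller than between-family E-values — the separability
regime the classifier relies on.  Each family grows from an independent
random seed sequence (between-family similarity is therefore at chance
level); members are derived by per-site substitution at a fixed rate plus
geometric-length indels.  Decoy families and mock conserved-domain
annotation tables (catalytic domains keyed to family type; downstream-domain
token sets for the Group A rules) are generated alongside so the screening
gates and rule engine run without any external profile database.

All generation is deterministic under the supplied seeds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .fefe_a import GROUP_A_VOCABULARY, DownstreamDomains
from .refdb import ClassLabel, ReferenceDatabase, SequenceRecord
from .screening import CATALYTIC_DOMAINS, DomainAnnotation, MockDomainBackend

__all__ = [
    "FamilySpec",
    "generate_family",
    "generate_reference",
    "generate_downstream_sets",
    "default_reference_specs",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Catalytic-domain accession implanted for each hydrogenase type.
_TYPE_TO_DOMAIN = {
    "NiFe": ("cl21493", "Complex1_49kDa superfamily"),
    "FeFe": ("cl14953", "Fe_hyd_lg_C superfamily"),
    "Fe": ("pfam03201", "HMD"),
}

DEFAULT_SEED_LENGTH = 120
DEFAULT_SUBSTITUTION_RATE = 0.25
DEFAULT_INDEL_RATE = 0.01


@dataclass(frozen=True)
class FamilySpec:
    """Recipe for one synthetic protein family."""

    label: ClassLabel
    n_members: int = 20
    seed_length: int = DEFAULT_SEED_LENGTH
    substitution_rate: float = DEFAULT_SUBSTITUTION_RATE
    indel_rate: float = DEFAULT_INDEL_RATE
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        if self.seed_length < 1:
            raise ValueError("seed_length must be >= 1")
        if not (0 <= self.substitution_rate < 1):
            raise ValueError("substitution_rate must be in [0, 1)")
        if not (0 <= self.indel_rate < 1):
            raise ValueError("indel_rate must be in [0, 1)")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _mutate(rng: np.random.Generator, seed_seq: str, spec: FamilySpec) -> str:
    residues = []
    for r in seed_seq:
        # geometric-length insertion before this site
        if spec.indel_rate and rng.random() < spec.indel_rate / 2:
            ins_len = rng.geometric(0.5)
            residues.extend(_random_seq(rng, ins_len))
        # deletion of this site
        if spec.indel_rate and rng.random() < spec.indel_rate / 2:
            continue
        if rng.random() < spec.substitution_rate:
            residues.append(rng.choice([a for a in AMINO_ACIDS if a != r]))
        else:
            residues.append(r)
    if not residues:
        residues.append(rng.choice(list(AMINO_ACIDS)))
    return "".join(residues)


def generate_family(spec: FamilySpec, id_prefix: str | None = None) -> list[SequenceRecord]:
    """One random seed sequence; members are seeded-deterministic mutants of it."""
    rng = np.random.default_rng(spec.rng_seed)
    prefix = id_prefix or f"{spec.label.subclass_code}"
    seed_seq = _random_seq(rng, spec.seed_length)
    records = []
    for i in range(spec.n_members):
        residues = _mutate(rng, seed_seq, spec)
        records.append(
            SequenceRecord(
                id=f"{prefix}_{i:03d}",
                residues=residues,
                description=f"synthetic {spec.label.subclass_code} member",
            )
        )
    return records


def generate_reference(
    family_specs: Sequence[FamilySpec],
    decoy_specs: Sequence[FamilySpec] = (),
    implant_domains: bool = True,
) -> tuple[ReferenceDatabase, MockDomainBackend]:
    """Labeled reference database plus a mock conserved-domain backend.

    Every member of a hydrogenase family is annotated with the catalytic
    domain of its type (decoys get an unrelated annotation), so the mock
    domain gate behaves like a real profile search on this data.
    """
    if len(family_specs) < 2:
        raise ValueError("need at least 2 families")
    records: list[SequenceRecord] = []
    labels: dict[str, ClassLabel] = {}
    table: dict[str, list[DomainAnnotation]] = {}
    seen_prefix: dict[str, int] = {}
    for spec in itertools.chain(family_specs, decoy_specs):
        code = spec.label.subclass_code
        n = seen_prefix.get(code, 0)
        seen_prefix[code] = n + 1
        prefix = code if n == 0 else f"{code}v{n}"
        fam = generate_family(spec, id_prefix=prefix)
        for rec in fam:
            records.append(rec)
            labels[rec.id] = spec.label
            if implant_domains:
                if spec.label.is_decoy:
                    table[rec.id] = [
                        DomainAnnotation("unrelated domain", "pfam00000", 1e-10)
                    ]
                else:
                    acc, name = _TYPE_TO_DOMAIN[spec.label.hydrogenase_type]
                    table[rec.id] = [DomainAnnotation(name, acc, 1e-30)]
    db = ReferenceDatabase(records=records, labels=labels)
    return db, MockDomainBackend(table)


def default_reference_specs(
    n_families: int = 5,
    n_members: int = 20,
    substitution_rate: float = DEFAULT_SUBSTITUTION_RATE,
    seed_length: int = DEFAULT_SEED_LENGTH,
    indel_rate: float = DEFAULT_INDEL_RATE,
    seed: int = 0,
    codes: Sequence[str] = ("1a", "1h", "3b", "A", "Fe"),
) -> list[FamilySpec]:
    """Family specs for the standard separable test reference."""
    if n_families > len(codes):
        raise ValueError(f"at most {len(codes)} family codes available")
    return [
        FamilySpec(
            label=ClassLabel.parse(codes[i]),
            n_members=n_members,
            seed_length=seed_length,
            substitution_rate=substitution_rate,
            indel_rate=indel_rate,
            rng_seed=seed * 1000 + i,
        )
        for i in range(n_families)
    ]


def generate_downstream_sets(
    cases: Iterable[frozenset[str] | set[str]] | None = None,
    seed: int = 0,
    seq_length: int = 80,
) -> tuple[list[SequenceRecord], MockDomainBackend, list[DownstreamDomains]]:
    """Downstream-protein records plus mock annotations for Group A rule cases.

    Each requested case (a subset of the rule vocabulary) yields one
    downstream sequence whose mock annotations are exactly that subset.  By
    default all 64 subsets of the six-token vocabulary are emitted.
    """
    if cases is None:
        vocab = sorted(GROUP_A_VOCABULARY)
        cases = [
            frozenset(c)
            for r in range(len(vocab) + 1)
            for c in itertools.combinations(vocab, r)
        ]
    rng = np.random.default_rng(seed)
    records, truth = [], []
    table: dict[str, list[DomainAnnotation]] = {}
    for i, case in enumerate(cases):
        rec_id = f"ds_{i:03d}"
        records.append(
            SequenceRecord(
                id=rec_id,
                residues=_random_seq(rng, seq_length),
                description="synthetic downstream protein",
            )
        )
        table[rec_id] = [
            DomainAnnotation(name, f"mock{j:04d}", 1e-12)
            for j, name in enumerate(sorted(case))
        ]
        truth.append(DownstreamDomains(query_id=rec_id, domains=frozenset(case)))
    return records, MockDomainBackend(table), truth
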