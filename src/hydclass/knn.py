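"""k-nearest-neighbor hydrogenase classification over alignment distances.

The classifier is a homology search reread as a k-NN problem: the distance
from a query to each labeled reference sequence is the pairwise alignment
E-value, the k closest references are the neighbors, and the predicted class
is the majority vote of their labels (default k = 4, chosen by
cross-validation as nearly as precise as k = 1 but more robust to labeling
errors in the reference set).  Decoy families — proteins homologous to
hydrogenase catalytic subunits that do not metabolize H2 (Nuo, Ehr, NARF,
HmdII) — sit in the reference set as first-class labels; a decoy majority
means the query is reported as a non-hydrogenase rather than forced into a
hydrogenase class.

:class:`HydrogenaseKNN` exposes the classifier in scikit-learn estimator
form (``fit`` / ``predict`` / ``get_params``), so it composes with sklearn
model selection; :func:`classify`, :func:`nearest_neighbors` and
:func:`majority_vote` are the corresponding functional entry points.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .fefe_a import DownstreamDomains, classify_group_a, extract_downstream_domains
from .pairwise import AlignmentHit, ScoringScheme, search
from .refdb import ClassLabel, ReferenceDatabase, SequenceRecord
from .screening import (
    HOMOLOGY_THRESHOLD,
    BypassDomainBackend,
    DomainBackend,
    ScreenResult,
    screen,
)

__all__ = [
    "NONHYDROGENASE",
    "Neighbor",
    "Prediction",
    "HydrogenaseKNN",
    "nearest_neighbors",
    "majority_vote",
    "classify",
    "classify_batch",
]

logger = logging.getLogger(__name__)

#: Final label for queries rejected by a gate or voted into a decoy family.
NONHYDROGENASE = "NONHYDROGENASE"

DEFAULT_K = 4

_GROUP_A_CODES = frozenset(["A", "A1", "A2", "A3", "A4"])


@dataclass(frozen=True)
class Neighbor:
    """One of the k references closest to the query."""

    subject_id: str
    label: ClassLabel
    e_value: float
    bit_score: float
    rank: int  # 1 = nearest


@dataclass(frozen=True)
class Prediction:
    """Classifier output for a single query."""

    query_id: str
    final_label: ClassLabel | None
    reason: str  # classified | failed_domain | failed_homology | decoy_majority
    neighbors: tuple[Neighbor, ...] = ()
    votes: Mapping[ClassLabel, int] = field(default_factory=dict)
    closest_homolog: str | None = None
    closest_evalue: float | None = None
    decoy_family: str | None = None
    matched_type: str | None = None
    warning: str | None = None

    @property
    def final_code(self) -> str:
        """Subclass code, or ``NONHYDROGENASE`` for rejected queries."""
        return self.final_label.subclass_code if self.final_label else NONHYDROGENASE

    @property
    def is_hydrogenase(self) -> bool:
        return self.final_label is not None


def nearest_neighbors(
    query: SequenceRecord,
    db: ReferenceDatabase,
    k: int = DEFAULT_K,
    scheme: ScoringScheme | None = None,
    threshold: float = HOMOLOGY_THRESHOLD,
    exclude_self: bool = True,
    hits: Sequence[AlignmentHit] | None = None,
) -> list[Neighbor]:
    """Top-k reference hits with E <= threshold, nearest first.

    A record with the query's own id is excluded when ``exclude_self`` so
    that held-out evaluation never votes with the query itself.  Fewer than
    k neighbors are returned when fewer pass the threshold.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if hits is None:
        hits = search(query, db, scheme=scheme)
    out: list[Neighbor] = []
    for h in hits:
        if h.e_value > threshold:
            break  # hits are sorted ascending by E-value
        if exclude_self and h.subject_id == query.id:
            continue
        out.append(
            Neighbor(
                subject_id=h.subject_id,
                label=db.labels[h.subject_id],
                e_value=h.e_value,
                bit_score=h.bit_score,
                rank=len(out) + 1,
            )
        )
        if len(out) == k:
            break
    return out


def majority_vote(
    neighbors: Sequence[Neighbor],
) -> tuple[ClassLabel, dict[ClassLabel, int]]:
    """Label with the most votes; ties go to the label of the nearest neighbor.

    The tie rule keeps the classifier consistent with its homology-search
    framing: among equally-supported classes, trust the closest homolog.
    """
    if not neighbors:
        raise ValueError("majority_vote requires at least one neighbor")
    votes = Counter(n.label for n in neighbors)
    top = max(votes.values())
    tied = [lab for lab, c in votes.items() if c == top]
    if len(tied) == 1:
        winner = tied[0]
    else:
        winner = min(
            tied, key=lambda lab: min(n.rank for n in neighbors if n.label == lab)
        )
    return winner, dict(votes)


class HydrogenaseKNN(BaseEstimator, ClassifierMixin):
    """Hydrogenase class k-NN over pairwise-alignment E-value distances.

    Parameters
    ----------
    k : int, default 4
        Number of neighbors in the vote.
    threshold : float, default 1e-5
        Homology gate: queries whose best reference E-value exceeds this are
        labeled non-hydrogenases, and neighbors above it never vote.
    scheme : ScoringScheme, optional
        Alignment scoring system (BLOSUM62, gap 11/1 by default).
    domain_backend : DomainBackend, optional
        Conserved-domain gate backend; the bypass backend (gate always
        passes) when omitted.
    apply_screen : bool, default True
        Run the two screening gates before voting.
    exclude_self : bool, default True
        Drop a reference record sharing the query's id from the neighbor
        list (leave-self-out).

    Attributes
    ----------
    reference_ : ReferenceDatabase
        The fitted labeled reference set.
    classes_ : ndarray of str
        Sorted subclass codes seen during fit.
    """

    def __init__(
        self,
        k: int = DEFAULT_K,
        threshold: float = HOMOLOGY_THRESHOLD,
        scheme: ScoringScheme | None = None,
        domain_backend: DomainBackend | None = None,
        apply_screen: bool = True,
        exclude_self: bool = True,
    ):
        self.k = k
        self.threshold = threshold
        self.scheme = scheme
        self.domain_backend = domain_backend
        self.apply_screen = apply_screen
        self.exclude_self = exclude_self

    # -- sklearn surface ---------------------------------------------------

    def fit(self, X, y=None) -> "HydrogenaseKNN":
        """Store the labeled reference set.

        ``X`` may be a :class:`ReferenceDatabase` (then ``y`` is ignored) or
        a sequence of :class:`SequenceRecord`/strings with ``y`` the matching
        labels (subclass codes or :class:`ClassLabel`).
        """
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if isinstance(X, ReferenceDatabase):
            db = X
        else:
            records = [_as_record(x, i) for i, x in enumerate(X)]
            if y is None:
                raise ValueError("labels are required when X is not a database")
            labels = {
                r.id: (l if isinstance(l, ClassLabel) else ClassLabel.parse(str(l)))
                for r, l in zip(records, y, strict=True)
            }
            db = ReferenceDatabase(records=records, labels=labels)
        if db.n_hydrogenase_classes < 1 or len(db.classes) < 2:
            raise ValueError(
                "reference database needs at least 2 classes for classification"
            )
        self.reference_ = db
        self.classes_ = np.array(
            sorted({l.subclass_code for l in db.labels.values()})
        )
        return self

    def predict(self, X) -> np.ndarray:
        """Subclass codes (``NONHYDROGENASE`` for rejected queries)."""
        return np.array([p.final_code for p in self.predict_detail(X)])

    def predict_detail(
        self,
        X,
        downstream: Mapping[str, DownstreamDomains | SequenceRecord] | None = None,
    ) -> list[Prediction]:
        """Full per-query :class:`Prediction` objects.

        ``downstream`` optionally maps query ids to the protein encoded
        immediately downstream (or its pre-extracted domain set); it refines
        [FeFe] Group A winners into subtypes A1-A4.
        """
        self._check_fitted()
        if isinstance(X, (SequenceRecord, str)):
            X = [X]
        out = []
        for i, x in enumerate(X):  # per-record isolation for batch runs
            query_id = getattr(x, "id", f"query_{i}")
            try:
                rec = _as_record(x, i)
                out.append(self._classify_one(rec, downstream))
            except Exception as exc:
                logger.error("query %s failed: %s", query_id, exc)
                out.append(
                    Prediction(
                        query_id=query_id,
                        final_label=None,
                        reason=f"error: {exc}",
                    )
                )
        return out

    # -- mechanics ---------------------------------------------------------

    def _classify_one(
        self,
        query: SequenceRecord,
        downstream: Mapping[str, DownstreamDomains | SequenceRecord] | None,
    ) -> Prediction:
        db = self.reference_
        hits = search(query, db, scheme=self.scheme)
        hits_voting = [
            h for h in hits if not (self.exclude_self and h.subject_id == query.id)
        ]
        best = hits_voting[0] if hits_voting else None
        closest_id = best.subject_id if best else None
        closest_e = best.e_value if best else None

        matched_type = None
        if self.apply_screen:
            result: ScreenResult = screen(
                query,
                db,
                domain_backend=self.domain_backend,
                threshold=self.threshold,
                scheme=self.scheme,
                hits=hits_voting,
            )
            matched_type = result.matched_type
            if not result.passed:
                return Prediction(
                    query_id=query.id,
                    final_label=None,
                    reason=result.failure_reason,
                    closest_homolog=closest_id,
                    closest_evalue=closest_e,
                    matched_type=matched_type,
                )

        neighbors = nearest_neighbors(
            query,
            db,
            k=self.k,
            threshold=self.threshold,
            exclude_self=self.exclude_self,
            hits=hits,
        )
        if not neighbors:
            return Prediction(
                query_id=query.id,
                final_label=None,
                reason="failed_homology",
                closest_homolog=closest_id,
                closest_evalue=closest_e,
                matched_type=matched_type,
            )
        winner, votes = majority_vote(neighbors)

        if winner.is_decoy:
            return Prediction(
                query_id=query.id,
                final_label=None,
                reason="decoy_majority",
                neighbors=tuple(neighbors),
                votes=votes,
                closest_homolog=closest_id,
                closest_evalue=closest_e,
                decoy_family=winner.subclass_code,
                matched_type=matched_type,
            )

        warning = None
        if matched_type and winner.hydrogenase_type != matched_type:
            warning = (
                f"voted type {winner.hydrogenase_type} conflicts with matched "
                f"catalytic domain type {matched_type}"
            )
            logger.warning("query %s: %s", query.id, warning)

        if (
            downstream is not None
            and winner.hydrogenase_type == "FeFe"
            and winner.subclass_code in _GROUP_A_CODES
            and query.id in downstream
        ):
            winner = self._refine_group_a(query.id, downstream[query.id])

        return Prediction(
            query_id=query.id,
            final_label=winner,
            reason="classified",
            neighbors=tuple(neighbors),
            votes=votes,
            closest_homolog=closest_id,
            closest_evalue=closest_e,
            matched_type=matched_type,
            warning=warning,
        )

    def _refine_group_a(
        self, query_id: str, downstream: DownstreamDomains | SequenceRecord
    ) -> ClassLabel:
        if isinstance(downstream, SequenceRecord):
            backend = self.domain_backend or BypassDomainBackend()
            domains = extract_downstream_domains(downstream, backend)
            domains = DownstreamDomains(query_id=query_id, domains=domains.domains)
        else:
            domains = downstream
        return classify_group_a(domains)

    def _check_fitted(self) -> None:
        if not hasattr(self, "reference_"):
            raise RuntimeError("classifier is not fitted; call fit() first")


def _as_record(x, index: int) -> SequenceRecord:
    if isinstance(x, SequenceRecord):
        return x
    return SequenceRecord(id=f"query_{index}", residues=SequenceRecord.normalize(str(x)))


def classify(
    query: SequenceRecord,
    db: ReferenceDatabase,
    k: int = DEFAULT_K,
    downstream: Mapping[str, DownstreamDomains | SequenceRecord] | None = None,
    **options,
) -> Prediction:
    """Screen, find neighbors, and vote for a single query."""
    clf = HydrogenaseKNN(k=k, **options).fit(db)
    return clf.predict_detail([query], downstream=downstream)[0]


def classify_batch(
    queries: Iterable[SequenceRecord],
    db: ReferenceDatabase,
    k: int = DEFAULT_K,
    downstream: Mapping[str, DownstreamDomains | SequenceRecord] | None = None,
    **options,
) -> list[Prediction]:
    """Classify many queries; per-record failures never abort the batch."""
    clf = HydrogenaseKNN(k=k, **options).fit(db)
    return clf.predict_detail(list(queries), downstream=downstream)
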