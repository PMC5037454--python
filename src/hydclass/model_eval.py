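"""Model selection: K-fold cross-validation and the k = 1..10 precision sweep.

The reference set is split into K parts of (near-)equal size, stratified by
class where a class has at least K members; each part is held out in turn,
classified against a reference composed only of the remaining parts (the
screening gates run against the training part too, so there is no leakage),
and the fraction of correct labels is the fold's precision.  The sweep
reuses one fold assignment — and one set of per-fold alignments — across all
values of k, so the per-k precisions are directly comparable.

"Precision" here is the overall fraction of held-out sequences whose
predicted label equals the known label (micro-averaged accuracy); per-class
macro precision is additionally reported for transparency.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from statistics import mean as _mean
from statistics import pstdev
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .knn import NONHYDROGENASE, HydrogenaseKNN, Neighbor, majority_vote
from .pairwise import ScoringScheme
from .refdb import ClassLabel, ReferenceDatabase
from .screening import HOMOLOGY_THRESHOLD, DomainBackend

__all__ = [
    "FoldAssignment",
    "CVResult",
    "precision",
    "macro_precision",
    "assign_folds",
    "cross_validate",
    "k_sweep",
    "sweep_to_frame",
]

DEFAULT_FOLDS = 5
DEFAULT_K_RANGE = range(1, 11)


@dataclass(frozen=True)
class FoldAssignment:
    """Deterministic id -> fold mapping (reproducible from ids, n_folds, seed)."""

    n_folds: int
    fold_of: Mapping[str, int]
    seed: int

    def fold_ids(self, fold: int) -> list[str]:
        return sorted(i for i, f in self.fold_of.items() if f == fold)

    @property
    def sizes(self) -> list[int]:
        return [len(self.fold_ids(f)) for f in range(self.n_folds)]

    @property
    def digest(self) -> str:
        """Stable hash of the assignment, recorded in CV reports."""
        payload = ";".join(f"{i}:{f}" for i, f in sorted(self.fold_of.items()))
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class CVResult:
    """Cross-validated precision for one neighbor count k."""

    k: int
    per_fold_precision: tuple[float, ...]
    macro_per_fold: tuple[float, ...] = ()
    seed: int = 0
    fold_digest: str = ""

    @property
    def mean(self) -> float:
        return _mean(self.per_fold_precision)

    @property
    def sd(self) -> float:
        return pstdev(self.per_fold_precision)


def precision(
    predicted: Mapping[str, str], truth: Mapping[str, str]
) -> float:
    """Fraction of ids whose predicted label equals the known label."""
    if set(predicted) != set(truth):
        missing = set(truth) ^ set(predicted)
        raise ValueError(f"prediction/truth key mismatch: {sorted(missing)[:5]}")
    if not truth:
        raise ValueError("empty prediction set")
    return sum(predicted[i] == truth[i] for i in truth) / len(truth)


def macro_precision(
    predicted: Mapping[str, str], truth: Mapping[str, str]
) -> float:
    """Unweighted mean of per-class precision over predicted classes."""
    y_true = pd.Series(truth)
    y_pred = pd.Series(predicted).reindex(y_true.index)
    per_class = []
    for cls in sorted(y_pred.unique()):
        sel = y_pred == cls
        per_class.append(float((y_true[sel] == cls).mean()))
    return float(np.mean(per_class))


def assign_folds(
    db: ReferenceDatabase, n_folds: int = DEFAULT_FOLDS, seed: int = 0
) -> FoldAssignment:
    """Stratified-where-possible fold assignment with near-equal fold sizes.

    Ids within each class are shuffled (seeded) and dealt round-robin across
    folds, starting each class at a rotating offset so small classes do not
    pile onto fold 0.  Fold sizes differ by at most one when the dealing
    order allows; classes smaller than n_folds simply occupy fewer folds.
    """
    if len(db) < n_folds:
        raise ValueError(f"database of {len(db)} records cannot fill {n_folds} folds")
    rng = np.random.default_rng(seed)
    by_class: dict[ClassLabel, list[str]] = {}
    for rec in db.records:
        by_class.setdefault(db.labels[rec.id], []).append(rec.id)

    fold_of: dict[str, int] = {}
    counts = [0] * n_folds
    for label in sorted(by_class, key=lambda l: (-len(by_class[l]), l.subclass_code)):
        ids = sorted(by_class[label])
        rng.shuffle(ids)
        for rec_id in ids:
            fold = int(np.argmin(counts))
            fold_of[rec_id] = fold
            counts[fold] += 1
    return FoldAssignment(n_folds=n_folds, fold_of=fold_of, seed=seed)


def _predict_fold(
    db: ReferenceDatabase,
    folds: FoldAssignment,
    fold: int,
    ks: Sequence[int],
    threshold: float,
    scheme: ScoringScheme | None,
    domain_backend: DomainBackend | None,
    apply_screen: bool,
) -> dict[int, dict[str, str]]:
    """Classify one held-out fold for every k at once (alignments shared)."""
    held = set(folds.fold_ids(fold))
    train = db.subset(i for i in db.labels if i not in held)
    k_max = max(ks)
    clf = HydrogenaseKNN(
        k=k_max,
        threshold=threshold,
        scheme=scheme,
        domain_backend=domain_backend,
        apply_screen=apply_screen,
    ).fit(train)
    out: dict[int, dict[str, str]] = {k: {} for k in ks}
    for rec_id in sorted(held):
        pred_full = clf.predict_detail([db.record(rec_id)])[0]
        for k in ks:
            if pred_full.reason != "classified" and not pred_full.neighbors:
                out[k][rec_id] = pred_full.final_code
                continue
            top = list(pred_full.neighbors[:k])
            if not top:
                out[k][rec_id] = NONHYDROGENASE
                continue
            winner, _ = majority_vote(top)
            out[k][rec_id] = NONHYDROGENASE if winner.is_decoy else winner.subclass_code
    return out


def cross_validate(
    db: ReferenceDatabase,
    k_neighbors: int = 4,
    n_folds: int = DEFAULT_FOLDS,
    seed: int = 0,
    threshold: float = HOMOLOGY_THRESHOLD,
    scheme: ScoringScheme | None = None,
    domain_backend: DomainBackend | None = None,
    apply_screen: bool = True,
) -> CVResult:
    """K-fold cross-validated precision at one neighbor count."""
    return k_sweep(
        db,
        k_range=[k_neighbors],
        n_folds=n_folds,
        seed=seed,
        threshold=threshold,
        scheme=scheme,
        domain_backend=domain_backend,
        apply_screen=apply_screen,
    )[0]


def k_sweep(
    db: ReferenceDatabase,
    k_range: Sequence[int] = DEFAULT_K_RANGE,
    n_folds: int = DEFAULT_FOLDS,
    seed: int = 0,
    threshold: float = HOMOLOGY_THRESHOLD,
    scheme: ScoringScheme | None = None,
    domain_backend: DomainBackend | None = None,
    apply_screen: bool = True,
) -> list[CVResult]:
    """One CVResult per k, all ks sharing the same fold assignment."""
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 1:
        raise ValueError("k_range must contain integers >= 1")
    folds = assign_folds(db, n_folds=n_folds, seed=seed)
    truth = {i: l.subclass_code for i, l in db.labels.items()}

    per_k_fold: dict[int, list[float]] = {k: [] for k in ks}
    per_k_fold_macro: dict[int, list[float]] = {k: [] for k in ks}
    for fold in range(n_folds):
        preds = _predict_fold(
            db, folds, fold, ks, threshold, scheme, domain_backend, apply_screen
        )
        held_truth = {i: truth[i] for i in folds.fold_ids(fold)}
        for k in ks:
            per_k_fold[k].append(precision(preds[k], held_truth))
            per_k_fold_macro[k].append(macro_precision(preds[k], held_truth))

    return [
        CVResult(
            k=k,
            per_fold_precision=tuple(per_k_fold[k]),
            macro_per_fold=tuple(per_k_fold_macro[k]),
            seed=seed,
            fold_digest=folds.digest,
        )
        for k in ks
    ]


def sweep_to_frame(results: Sequence[CVResult]) -> pd.DataFrame:
    """Long-form CV report: one row per (k, fold) plus a summary row per k."""
    rows = []
    for r in results:
        for fold, p in enumerate(r.per_fold_precision):
            rows.append(
                {"k": r.k, "fold": fold, "precision": p, "mean": "", "sd": "",
                 "seed": r.seed, "fold_digest": r.fold_digest}
            )
        rows.append(
            {"k": r.k, "fold": "summary", "precision": "", "mean": r.mean,
             "sd": r.sd, "seed": r.seed, "fold_digest": r.fold_digest}
        )
    return pd.DataFrame(rows)
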