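"""k-NN voting, decoy exclusion, and the end-to-end classify pipeline."""

import random

import numpy as np
import pytest

from hydclass.knn import (
    NONHYDROGENASE,
    HydrogenaseKNN,
    Neighbor,
    classify,
    majority_vote,
    nearest_neighbors,
)
from hydclass.fefe_a import DownstreamDomains
from hydclass.pairwise import ScoringScheme
from hydclass.refdb import ClassLabel, ReferenceDatabase, SequenceRecord
from hydclass.screening import DomainAnnotation, MockDomainBackend
from hydclass.synthetic import FamilySpec, generate_reference

from _oracles import ka_bits_evalue, sw_affine_bruteforce


def _nb(label, rank, e=1e-30):
    return Neighbor(subject_id=f"s{rank}", label=ClassLabel.parse(label),
                    e_value=e, bit_score=100.0, rank=rank)


class TestMajorityVote:
    def test_strict_majority(self):
        winner, votes = majority_vote(
            [_nb("1a", 1), _nb("1a", 2), _nb("1a", 3), _nb("3b", 4)]
        )
        assert winner.subclass_code == "1a"
        assert {l.subclass_code: c for l, c in votes.items()} == {"1a": 3, "3b": 1}

    def test_tie_broken_by_nearest_neighbor(self):
        winner, _ = majority_vote(
            [_nb("3b", 1), _nb("1a", 2), _nb("1a", 3), _nb("3b", 4)]
        )
        assert winner.subclass_code == "3b"

    def test_single_neighbor(self):
        winner, votes = majority_vote([_nb("2e", 1)])
        assert winner.subclass_code == "2e" and sum(votes.values()) == 1

    def test_empty_list_is_error(self):
        with pytest.raises(ValueError):
            majority_vote([])


class TestNearestNeighbors:
    def test_self_excluded_from_neighbors(self, small_db):
        q = small_db.records[0]
        nbs = nearest_neighbors(q, small_db, k=1)
        assert nbs[0].subject_id != q.id
        assert nbs[0].label == small_db.labels[q.id]  # within-family

    def test_db_smaller_than_k_returns_all_qualifying(self, small_db):
        q = small_db.records[0]
        nbs = nearest_neighbors(q, small_db, k=500)
        assert 1 <= len(nbs) < 500
        assert all(n.e_value <= 1e-5 for n in nbs)

    def test_ranks_contiguous_evalues_nondecreasing(self, small_db):
        nbs = nearest_neighbors(small_db.records[2], small_db, k=4)
        assert [n.rank for n in nbs] == list(range(1, len(nbs) + 1))
        evs = [n.e_value for n in nbs]
        assert evs == sorted(evs)

    def test_k_below_one_rejected(self, small_db):
        with pytest.raises(ValueError):
            nearest_neighbors(small_db.records[0], small_db, k=0)

    def test_neighbor_sets_and_votes_match_bruteforce(self):
        """Neighbor ranking and votes equal exhaustive scoring, many seeds."""
        scheme = ScoringScheme()
        for seed in range(25):
            rng = random.Random(seed)
            specs = [
                FamilySpec(ClassLabel.parse(code), n_members=rng.randint(3, 6),
                           seed_length=60, substitution_rate=0.15,
                           indel_rate=0.0, rng_seed=seed * 10 + j)
                for j, code in enumerate(["1a", "3b", "A"])
            ]
            db, _ = generate_reference(specs, implant_domains=False)
            q = db.records[rng.randrange(len(db))]
            nbs = nearest_neighbors(q, db, k=4)

            n_space = db.total_residues
            evs = {}
            for r in db.records:
                if r.id == q.id:
                    continue
                raw = sw_affine_bruteforce(q.residues, r.residues)
                evs[r.id] = ka_bits_evalue(raw, scheme.lam, scheme.kappa,
                                           q.length, n_space)[1]
            expected = sorted(
                (i for i in evs if evs[i] <= 1e-5), key=lambda i: (evs[i], i)
            )[:4]
            assert [n.subject_id for n in nbs] == expected


class TestClassify:
    def test_query_identical_to_reference_gets_its_label(self, small_db):
        q = small_db.records[0]
        dup = SequenceRecord(id="dup_query", residues=q.residues)
        backend = MockDomainBackend(
            {"dup_query": [DomainAnnotation("Complex1_49kDa superfamily",
                                            "cl21493", 1e-20)]}
        )
        pred = classify(dup, small_db, domain_backend=backend)
        assert pred.reason == "classified"
        assert pred.final_label == small_db.labels[q.id]
        assert pred.closest_homolog == q.id

    def test_self_consistency_with_k1_no_exclusion(self, small_db, mock_backend):
        q = small_db.records[4]
        pred = classify(q, small_db, k=1, exclude_self=False,
                        domain_backend=mock_backend)
        assert pred.final_label == small_db.labels[q.id]
        assert pred.closest_homolog == q.id

    def test_decoy_majority_reported_as_nonhydrogenase(self, small_db, mock_backend):
        decoy_member = next(r for r in small_db.records
                            if small_db.labels[r.id].is_decoy)
        dup = SequenceRecord(id="decoyish", residues=decoy_member.residues)
        # decoys carry no catalytic domain: bypass the domain gate to reach the vote
        pred = classify(dup, small_db, apply_screen=False)
        assert pred.final_code == NONHYDROGENASE
        assert pred.reason == "decoy_majority"
        assert pred.decoy_family == "Nuo"

    def test_unrelated_query_fails_homology(self, small_db, mock_backend):
        rng = np.random.default_rng(99)
        residues = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=80))
        q = SequenceRecord(id="rand", residues=residues)
        pred = classify(q, small_db, apply_screen=True)
        assert pred.final_code == NONHYDROGENASE
        assert pred.reason == "failed_homology"

    def test_group_a_refined_by_downstream_domains(self, small_db):
        fam_a = next(r for r in small_db.records
                     if small_db.labels[r.id].subclass_code == "A")
        dup = SequenceRecord(id="qa", residues=fam_a.residues)
        backend = MockDomainBackend(
            {"qa": [DomainAnnotation("Fe_hyd_lg_C superfamily", "cl14953", 1e-25)]}
        )
        downstream = {"qa": DownstreamDomains("qa", frozenset({"nuof"}))}
        pred = classify(dup, small_db, domain_backend=backend,
                        downstream=downstream)
        assert pred.final_code == "A3"

    def test_group_a_unrefined_without_downstream(self, small_db):
        fam_a = next(r for r in small_db.records
                     if small_db.labels[r.id].subclass_code == "A")
        dup = SequenceRecord(id="qa", residues=fam_a.residues)
        backend = MockDomainBackend(
            {"qa": [DomainAnnotation("Fe_hyd_lg_C superfamily", "cl14953", 1e-25)]}
        )
        pred = classify(dup, small_db, domain_backend=backend)
        assert pred.final_code == "A"

    def test_prediction_invariant_under_db_permutation(self, small_db, mock_backend):
        q = SequenceRecord(id="qq", residues=small_db.records[1].residues)
        rng = random.Random(7)
        records = list(small_db.records)
        rng.shuffle(records)
        shuffled = ReferenceDatabase(records=records, labels=dict(small_db.labels))
        p1 = classify(q, small_db, domain_backend=mock_backend)
        p2 = classify(q, shuffled, domain_backend=mock_backend)
        assert p1.final_code == p2.final_code
        assert [n.subject_id for n in p1.neighbors] == [n.subject_id for n in p2.neighbors]


class TestEstimatorSurface:
    def test_fit_predict_on_sequences_and_labels(self, small_db):
        X = [r for r in small_db.records]
        y = [small_db.labels[r.id].subclass_code for r in small_db.records]
        clf = HydrogenaseKNN(k=3, apply_screen=False).fit(X, y)
        assert set(clf.classes_) == set(y)
        preds = clf.predict(X)
        # hydrogenase families recover their label; decoy members are
        # reported as non-hydrogenases rather than as their decoy family
        expected = np.array(
            [c if not ClassLabel.parse(c).is_decoy else NONHYDROGENASE for c in y]
        )
        assert (preds == expected).all()

    def test_get_set_params_roundtrip(self):
        clf = HydrogenaseKNN()
        params = clf.get_params()
        assert params["k"] == 4 and params["threshold"] == 1e-5
        clf.set_params(k=7)
        assert clf.k == 7

    def test_unfitted_predict_raises(self, small_db):
        with pytest.raises(RuntimeError):
            HydrogenaseKNN().predict([small_db.records[0]])

    def test_single_class_reference_rejected(self):
        recs = [SequenceRecord(id=f"s{i}", residues="MKLVWQERTY") for i in range(3)]
        with pytest.raises(ValueError):
            HydrogenaseKNN().fit(recs, ["1a", "1a", "1a"])

    def test_per_record_failures_do_not_abort_batch(self, small_db):
        backend = MockDomainBackend(
            {"ok": [DomainAnnotation("Complex1_49kDa superfamily",
                                     "cl21493", 1e-20)]}
        )
        clf = HydrogenaseKNN(domain_backend=backend).fit(small_db)

        class Boom:
            id = "boom"
            residues = property(lambda self: (_ for _ in ()).throw(RuntimeError("x")))

        good = SequenceRecord(id="ok", residues=small_db.records[0].residues)
        preds = clf.predict_detail([good, Boom(), good])
        assert len(preds) == 3
        assert preds[0].reason == "classified"
        assert preds[1].reason.startswith("error")
        assert preds[2].reason == "classified"
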