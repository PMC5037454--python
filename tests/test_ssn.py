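"""Sequence-similarity-network construction, sweep, and clustering."""

import math
import random

import pytest

from hydclass.pairwise import AlignmentHit, all_vs_all
from hydclass.refdb import ClassLabel
from hydclass.ssn import (
    build_network,
    components,
    ssn_classify,
    sweep_cutoffs,
    to_edge_tsv,
    to_graphml,
)
from hydclass.synthetic import FamilySpec, generate_reference

from _oracles import UnionFind


def _hit(q, s, e):
    return AlignmentHit(q, s, 100, 50.0, e, 100, 100)


@pytest.fixture(scope="module")
def planted_families():
    """3 separated families; returns (db, hits, within/between logE bands)."""
    specs = [
        FamilySpec(ClassLabel.parse(code), n_members=8, seed_length=100,
                   substitution_rate=0.08, indel_rate=0.0, rng_seed=70 + i)
        for i, code in enumerate(["1a", "3b", "A"])
    ]
    db, _ = generate_reference(specs, implant_domains=False)
    hits = all_vs_all(db, max_e=1e6)
    fam = lambda rid: rid.split("_")[0]
    within = [h.log_e for h in hits
              if h.query_id != h.subject_id and fam(h.query_id) == fam(h.subject_id)]
    between = [h.log_e for h in hits if fam(h.query_id) != fam(h.subject_id)]
    return db, hits, max(within), min(between, default=0.0)


class TestBuildNetwork:
    def test_duplicate_directed_hits_collapse_to_min(self):
        net = build_network([_hit("a", "b", 1e-20), _hit("b", "a", 1e-18)], -5)
        assert net.edges == {frozenset(("a", "b")): pytest.approx(-20.0)}

    def test_self_hits_removed(self):
        net = build_network([_hit("a", "a", 0.0)], -5)
        assert net.n_edges == 0 and net.nodes == {"a"}

    def test_cutoff_excludes_weak_edges(self):
        hits = [_hit("a", "b", 1e-20), _hit("a", "c", 1e-6)]
        net = build_network(hits, -10)
        assert net.edges.keys() == {frozenset(("a", "b"))}

    def test_edge_count_monotone_in_cutoff(self):
        rng = random.Random(0)
        hits = [_hit(f"n{rng.randrange(20)}", f"n{rng.randrange(20)}",
                     10 ** -rng.uniform(0, 100)) for _ in range(200)]
        n_loose = build_network(hits, -5).n_edges
        n_strict = build_network(hits, -50).n_edges
        assert n_loose >= n_strict

    def test_order_independent(self):
        rng = random.Random(1)
        hits = [_hit(f"n{rng.randrange(10)}", f"n{rng.randrange(10)}",
                     10 ** -rng.uniform(0, 60)) for _ in range(100)]
        shuffled = list(hits)
        rng.shuffle(shuffled)
        assert build_network(hits, -10).edges == build_network(shuffled, -10).edges


class TestComponents:
    def test_separated_families_pure_components(self, planted_families):
        db, hits, within_max, _ = planted_families
        net = build_network(hits, within_max, nodes=[r.id for r in db.records])
        cs = components(net, labels=db.labels)
        assert len(cs) == 3
        assert all(c.purity == 1.0 for c in cs.clusters)
        assert {c.majority_label.subclass_code for c in cs.clusters} == {"1a", "3b", "A"}

    def test_strict_cutoff_gives_singletons(self, planted_families):
        db, hits, *_ = planted_families
        net = build_network(hits, -10000, nodes=[r.id for r in db.records])
        assert len(components(net)) == len(db)

    def test_matches_union_find_oracle_on_random_graphs(self):
        rng = random.Random(5)
        for _ in range(20):
            n = rng.randint(3, 25)
            ids = [f"n{i}" for i in range(n)]
            hits = [
                _hit(rng.choice(ids), rng.choice(ids), 10 ** -rng.uniform(0, 40))
                for _ in range(rng.randint(0, 60))
            ]
            cutoff = -rng.uniform(0, 40)
            net = build_network(hits, cutoff, nodes=ids)
            got = {c.members for c in components(net).clusters}
            uf = UnionFind(ids)
            for h in hits:
                if h.query_id != h.subject_id and math.log10(h.e_value) <= cutoff:
                    uf.union(h.query_id, h.subject_id)
            assert got == uf.groups()


class TestSweep:
    def test_component_count_monotone_nonincreasing_cutoff(self, planted_families):
        db, hits, *_ = planted_families
        sweep = sweep_cutoffs(hits, start=-5, stop=-200, step=-5,
                              nodes=[r.id for r in db.records])
        counts = [n for _, n, _ in sweep]
        assert counts == sorted(counts)  # finer cutoffs only split components
        assert len(sweep) == 40

    def test_planted_plateau_flagged_stable(self, planted_families):
        db, hits, within_max, between_min = planted_families
        assert within_max < -5 < between_min  # constructed separation
        sweep = sweep_cutoffs(hits, start=-5, stop=within_max, step=-5,
                              nodes=[r.id for r in db.records])
        for i, (cutoff, n, stable) in enumerate(sweep):
            assert n == 3
            if i > 0:
                assert stable

    def test_single_family_splits_beyond_its_edges(self):
        specs = [
            FamilySpec(ClassLabel.parse("1a"), n_members=6, seed_length=100,
                       substitution_rate=0.05, indel_rate=0.0, rng_seed=80),
            FamilySpec(ClassLabel.parse("3b"), n_members=1, seed_length=100,
                       substitution_rate=0.0, indel_rate=0.0, rng_seed=81),
        ]
        db, _ = generate_reference(specs, implant_domains=False)
        fam_ids = [r.id for r in db.records if r.id.startswith("1a")]
        hits = [h for h in all_vs_all(db, max_e=1e6)
                if h.query_id in fam_ids and h.subject_id in fam_ids]
        weakest = max(h.log_e for h in hits if h.query_id != h.subject_id)
        above = sweep_cutoffs(hits, start=-5, stop=weakest, step=-5, nodes=fam_ids)
        assert all(n == 1 for _, n, _ in above)
        far_below = sweep_cutoffs(hits, start=weakest - 400, stop=weakest - 405,
                                  step=-5, nodes=fam_ids)
        assert far_below[0][1] > 1


class TestSSNClassify:
    def test_query_joins_pure_component(self, planted_families):
        db, hits, within_max, _ = planted_families
        member = db.records[0]
        query_hits = list(hits) + [_hit("query", member.id, 1e-80)]
        label = ssn_classify("query", query_hits, within_max, db.labels,
                             nodes=[r.id for r in db.records])
        assert label == db.labels[member.id]

    def test_isolated_query_unassigned(self, planted_families):
        db, hits, within_max, _ = planted_families
        label = ssn_classify("loner", hits, within_max, db.labels,
                             nodes=[r.id for r in db.records])
        assert label is None

    def test_agreement_with_knn_on_separable_data(self, planted_families):
        """The network classifier and the k-NN vote agree on separable data."""
        from hydclass.knn import HydrogenaseKNN
        from hydclass.pairwise import search

        db, hits, within_max, _ = planted_families
        clf = HydrogenaseKNN(apply_screen=False, exclude_self=True).fit(db)
        agree = 0
        probes = db.records[::6]
        for rec in probes:
            knn_label = clf.predict_detail([rec])[0].final_label
            probe_hits = [h for h in hits
                          if rec.id not in (h.query_id, h.subject_id)]
            probe_hits += [h for h in search(rec, db) if h.subject_id != rec.id]
            ssn_label = ssn_classify(rec.id, probe_hits, within_max,
                                     {k: v for k, v in db.labels.items() if k != rec.id},
                                     nodes=[r.id for r in db.records if r.id != rec.id])
            agree += knn_label == ssn_label
        assert agree == len(probes)


class TestExport:
    def test_edge_tsv_deterministic_and_parseable(self):
        hits = [_hit("b", "a", 1e-20), _hit("a", "b", 1e-22), _hit("c", "a", 1e-9)]
        text = to_edge_tsv(build_network(hits, -5))
        lines = text.strip().splitlines()
        assert lines[0] == "id1\tid2\tlogE"
        assert lines[1].startswith("a\tb\t-22")
        assert len(lines) == 3

    def test_graphml_contains_nodes(self):
        xml = to_graphml(build_network([_hit("a", "b", 1e-20)], -5))
        assert "graphml" in xml and 'id="a"' in xml
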