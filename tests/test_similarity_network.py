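"""Bipartite graph filters, relationship scores, and MinHash LSH behaviour."""

import itertools

import numpy as np
import pytest

from targetrank import (
    AssociationRecord,
    LshConfig,
    build_graph,
    lsh_candidates,
    relationship_score,
    similar_entities,
)
from targetrank.errors import GraphLookupError, ScoringDomainError
from targetrank.similarity_network import minhash_signatures


def assoc(target, disease, overall, count):
    return AssociationRecord(
        target_id=target, disease_id=disease,
        source_scores={"chembl": overall}, type_scores={"known_drug": overall},
        overall=overall, evidence_count={"chembl": count}, total_evidence=count,
    )


def graph_from_sets(neighbor_sets, overall=0.5, count=5):
    records = [
        assoc(t, d, overall, count) for t, ds in neighbor_sets.items() for d in ds
    ]
    return build_graph(records)


class TestBuildGraph:
    @pytest.mark.parametrize(
        "count,overall,kept",
        [
            (3, 0.2, True),      # both thresholds met (count inclusive)
            (2, 0.9, False),     # too few evidence
            (5, 0.1, False),     # score must be strictly greater than 0.1
            (5, 0.10001, True),
        ],
    )
    def test_edge_filters(self, count, overall, kept):
        g = build_graph([assoc("T1", "D1", overall, count)])
        assert (("T1", "D1") in g.edge_scores) is kept

    def test_degrees_match_edges(self):
        g = graph_from_sets({"T1": {"D1", "D2"}, "T2": {"D2"}})
        assert g.degree("T1", "targets") == 2
        assert g.degree("D2", "diseases") == 2
        recomputed = {d for (_, d) in g.edge_scores}
        assert set(g.diseases) == recomputed


class TestRelationshipScore:
    def test_identical_sets_score_one_both_modes(self):
        g = graph_from_sets({"A": {"D1", "D2"}, "B": {"D1", "D2"}})
        for mode in ("unweighted", "weighted"):
            assert relationship_score("A", "B", g, weighting=mode).score == 1.0

    def test_disjoint_sets_score_zero(self):
        g = graph_from_sets({"A": {"D1"}, "B": {"D2"}})
        assert relationship_score("A", "B", g, weighting="unweighted").score == 0.0

    def test_unweighted_jaccard(self):
        g = graph_from_sets({"A": {"D1", "D2", "D3"}, "B": {"D2", "D3", "D4"}})
        rel = relationship_score("A", "B", g, weighting="unweighted")
        assert rel.score == pytest.approx(0.5)  # 2 shared / 4 union

    def test_weighted_by_inverse_degree(self):
        # eight fillers lift degree(D3) to 10, diluting its weight to 1/10
        sets = {"A": {"D1", "D2", "D3"}, "B": {"D2", "D3", "D4"}}
        for i in range(8):
            sets[f"X{i}"] = {"D3", f"DX{i}"}
        g = graph_from_sets(sets)
        assert g.degree("D3", "diseases") == 10
        w = {"D1": 1 / 1, "D2": 1 / 2, "D3": 1 / 10, "D4": 1 / 1}
        expected = (w["D2"] + w["D3"]) / sum(w.values())
        rel = relationship_score("A", "B", g, weighting="weighted")
        assert rel.score == pytest.approx(expected)
        # shared diseases ranked rarest-first
        assert rel.shared == ("D2", "D3")

    def test_symmetry(self):
        g = graph_from_sets({"A": {"D1", "D2", "D3"}, "B": {"D2", "D3", "D4"}})
        for mode in ("unweighted", "weighted"):
            ab = relationship_score("A", "B", g, weighting=mode).score
            ba = relationship_score("B", "A", g, weighting=mode).score
            assert ab == pytest.approx(ba)

    def test_shared_rare_disease_scores_higher_than_shared_common(self):
        # same set sizes and overlap cardinality; only the shared disease's
        # degree differs: rare shared neighbour must not score lower
        sets = {"A": {"R", "C", "D1"}, "B": {"R", "C", "D2"}}
        for i in range(8):
            sets[f"X{i}"] = {"C", f"DX{i}"}  # inflate degree of C only
        g = graph_from_sets(sets)
        rare_only = {"A2": {"R2", "D3"}, "B2": {"R2", "D4"}}
        common_only = {"A3": {"C3", "D5"}, "B3": {"C3", "D6"}}
        filler = {f"Y{i}": {"C3", f"DY{i}"} for i in range(8)}
        g2 = graph_from_sets({**rare_only, **common_only, **filler})
        rare_score = relationship_score("A2", "B2", g2, weighting="weighted").score
        common_score = relationship_score("A3", "B3", g2, weighting="weighted").score
        assert rare_score >= common_score

    def test_sum_denominator_mode(self):
        g = graph_from_sets({"A": {"D1", "D2"}, "B": {"D1", "D2"}})
        rel = relationship_score("A", "B", g, weighting="unweighted",
                                 denominator="sum")
        assert rel.score == pytest.approx(0.5)  # 2 shared / (2 + 2)

    def test_unknown_entity(self):
        g = graph_from_sets({"A": {"D1"}})
        with pytest.raises(GraphLookupError):
            relationship_score("A", "NOPE", g)


class TestMinHashLsh:
    def test_bands_times_rows_must_equal_hashes(self):
        with pytest.raises(ScoringDomainError):
            LshConfig(num_hashes=128, bands=10, rows_per_band=10)

    def test_identical_sets_always_candidates(self):
        g = graph_from_sets({"A": {"D1", "D2"}, "B": {"D1", "D2"}, "C": {"D9"}})
        for seed in range(10):
            cands = lsh_candidates(g, "targets", LshConfig(seed=seed))
            assert ("A", "B") in cands

    def test_disjoint_sets_rarely_candidates(self):
        sets = {"A": {f"D{i}" for i in range(10)},
                "B": {f"E{i}" for i in range(10)}}
        g = graph_from_sets(sets)
        hits = sum(
            ("A", "B") in lsh_candidates(g, "targets", LshConfig(seed=seed))
            for seed in range(100)
        )
        assert hits <= 5  # banding probability at J=0 is ~0

    def test_empty_side_yields_empty_set(self):
        g = build_graph([])
        assert lsh_candidates(g, "targets", LshConfig()) == set()

    def test_collision_rate_estimates_jaccard(self):
        """Per-hash collision frequency ~ Jaccard within 3 standard errors."""
        a = {f"D{i}" for i in range(0, 40)}
        b = {f"D{i}" for i in range(20, 60)}
        true_j = len(a & b) / len(a | b)  # 20/60
        config = LshConfig(num_hashes=128, bands=32, rows_per_band=4, seed=42)
        sigs = minhash_signatures({"a": a, "b": b}, config)
        rate = float(np.mean(sigs["a"] == sigs["b"]))
        se = np.sqrt(true_j * (1 - true_j) / config.num_hashes)
        assert abs(rate - true_j) <= 3 * se

    def test_candidates_cover_high_jaccard_pairs_on_synthetic_graph(self):
        """On 200-entity graphs every pair with J >= 0.5 is shortlisted."""
        misses = 0
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            sets = {
                f"T{i:03d}": {f"D{j}" for j in rng.choice(400, size=8, replace=False)}
                for i in range(180)
            }
            # planted near-duplicate pairs with high overlap
            for i in range(10):
                base = {f"D{j}" for j in rng.choice(400, size=10, replace=False)}
                sets[f"P{i}a"] = base
                sets[f"P{i}b"] = set(itertools.islice(base, 9)) | {f"D{400 + i}"}
            g = graph_from_sets(sets)
            exact_high = {
                tuple(sorted((x, y)))
                for x, y in itertools.combinations(sets, 2)
                if len(sets[x] & sets[y]) / len(sets[x] | sets[y]) >= 0.5
            }
            assert exact_high  # the construction must plant some
            cands = lsh_candidates(g, "targets", LshConfig(seed=seed))
            misses += bool(exact_high - cands)
        assert misses == 0


class TestSimilarEntities:
    def test_unique_sharer_forced(self):
        g = graph_from_sets({"A": {"D1"}, "B": {"D1"}, "C": {"D2"}})
        sim = similar_entities("A", g, k=5)
        assert [s.entity_b for s in sim] == ["B"]

    def test_k_larger_than_candidates_no_padding(self):
        g = graph_from_sets({"A": {"D1"}, "B": {"D1"}})
        assert len(similar_entities("A", g, k=100)) == 1

    def test_ties_broken_lexicographically(self):
        g = graph_from_sets({"A": {"D1", "D2"}, "C": {"D1", "D2"}, "B": {"D1", "D2"}})
        sim = similar_entities("A", g, k=5, weighting="unweighted")
        assert [s.entity_b for s in sim] == ["B", "C"]

    def test_exact_ranking_on_small_graphs(self):
        rng = np.random.default_rng(7)
        sets = {
            f"T{i:02d}": {f"D{j}" for j in rng.choice(30, size=5, replace=False)}
            for i in range(40)
        }
        g = graph_from_sets(sets)
        query = "T00"
        exact = sorted(
            (
                relationship_score(query, other, g, weighting="weighted")
                for other in sets
                if other != query
            ),
            key=lambda r: (-r.score, r.entity_b),
        )
        exact = [r for r in exact if r.score > 0][:10]
        got = similar_entities(query, g, k=10, weighting="weighted")
        assert [(r.entity_b, r.score) for r in got] == [
            (r.entity_b, r.score) for r in exact
        ]

    def test_disease_side(self):
        g = graph_from_sets({"T1": {"D1", "D2"}, "T2": {"D1", "D2"}})
        sim = similar_entities("D1", g, k=5, side="diseases")
        assert [s.entity_b for s in sim] == ["D2"]
        assert sim[0].score == 1.0
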