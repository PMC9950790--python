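"""Pair-feature math against hand values and independent oracles."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from synergyscreen.io_core import (
    FEATURE_NAMES,
    DegenerateInputError,
    FeatureUnavailableError,
    RunConfig,
)
from synergyscreen.pair_features import (
    AdmeNormalizer,
    PathwayUniverse,
    UniverseFeaturizer,
    adme_distance,
    enrich_pathways,
    go_bma_similarity,
    go_gene_similarity,
    go_term_similarity,
    pathway_cosine,
    pathway_vector,
    ppi_features,
    sw_similarity,
    tanimoto_fingerprint,
    target_pairwise_aggregate,
)

# ---------------------------------------------------------------------------
# fingerprints / ADME
# ---------------------------------------------------------------------------


class TestTanimoto:
    def test_identity(self):
        fp = np.array([1, 0, 1, 1, 0])
        assert tanimoto_fingerprint(fp, fp) == 1.0

    def test_bit_count_arithmetic(self):
        # A.B = 1, |A|^2 = |B|^2 = 2 -> 1 / (2 + 2 - 1)
        assert tanimoto_fingerprint(np.array([1, 1, 0, 0]),
                                    np.array([1, 0, 1, 0])) == pytest.approx(1 / 3)

    def test_all_zero_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            tanimoto_fingerprint(np.zeros(4), np.array([1, 0, 0, 0]))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.integers(0, 1), min_size=2, max_size=64),
           st.lists(st.integers(0, 1), min_size=2, max_size=64))
    def test_symmetry_and_range(self, a, b):
        n = min(len(a), len(b))
        fa, fb = np.array(a[:n]), np.array(b[:n])
        if not fa.any() or not fb.any():
            return
        s = tanimoto_fingerprint(fa, fb)
        assert s == tanimoto_fingerprint(fb, fa)
        assert 0.0 <= s <= 1.0


class TestAdmeDistance:
    def test_identity_and_hand_values(self):
        norm = AdmeNormalizer(lo=np.zeros(2), hi=np.ones(2))
        assert adme_distance(np.array([0.3, 0.7]), np.array([0.3, 0.7]), norm) == 0.0
        # normalized (0,0) vs (0.3,0.4): 3-4-5 triangle
        assert adme_distance(np.array([0.0, 0.0]), np.array([0.3, 0.4]),
                             norm) == pytest.approx(0.5)
        # differ by 1 in exactly one normalized slot
        assert adme_distance(np.array([0.0, 0.5]), np.array([1.0, 0.5]),
                             norm) == pytest.approx(1.0)

    def test_constant_slot_contributes_zero(self):
        norm = AdmeNormalizer(lo=np.array([2.0, 0.0]), hi=np.array([2.0, 10.0]))
        assert adme_distance(np.array([2.0, 0.0]), np.array([2.0, 10.0]),
                             norm) == pytest.approx(1.0)

    def test_length_mismatch(self):
        norm = AdmeNormalizer(lo=np.zeros(2), hi=np.ones(2))
        with pytest.raises(ValueError):
            adme_distance(np.zeros(2), np.zeros(3), norm)


# ---------------------------------------------------------------------------
# Smith-Waterman vs an independent DP oracle
# ---------------------------------------------------------------------------

def sw_oracle_raw(a: str, b: str, match: float, mismatch: float, gap: float) -> float:
    """Textbook quadratic Smith-Waterman with linear gap penalty."""
    h = np.zeros((len(a) + 1, len(b) + 1))
    best = 0.0
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            diag = h[i - 1, j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            h[i, j] = max(0.0, diag, h[i - 1, j] - gap, h[i, j - 1] - gap)
            best = max(best, h[i, j])
    return best


def sw_oracle_similarity(a: str, b: str, match=2.0, mismatch=-1.0, gap=1.0) -> float:
    raw = sw_oracle_raw(a, b, match, mismatch, gap)
    return raw / math.sqrt(sw_oracle_raw(a, a, match, mismatch, gap)
                           * sw_oracle_raw(b, b, match, mismatch, gap))


class TestSmithWaterman:
    def test_self_similarity_is_one(self):
        for s in ("A", "ACDE", "MKVLAW"):
            assert sw_similarity(s, s) == pytest.approx(1.0)

    def test_disjoint_alphabets_score_zero(self):
        assert sw_similarity("AAAA", "CCCC", matrix=None, match=2, mismatch=-1,
                             gap_open=0.0, gap_extend=1.0) == 0.0

    def test_local_alignment_finds_embedded_block(self):
        # the local alignment recovers the full ACDE block (raw score 8);
        # self-normalization divides by sqrt(8 * 12)
        ours = sw_similarity("ACDE", "WACDEW", matrix=None, match=2, mismatch=-1,
                             gap_open=0.0, gap_extend=1.0)
        assert ours == pytest.approx(8 / math.sqrt(8 * 12))
        assert ours == pytest.approx(sw_oracle_similarity("ACDE", "WACDEW"))

    def test_matches_independent_dp_oracle(self, rng):
        alphabet = list("ACDEFG")
        for _ in range(25):
            a = "".join(rng.choice(alphabet, size=rng.integers(1, 13)))
            b = "".join(rng.choice(alphabet, size=rng.integers(1, 13)))
            ours = sw_similarity(a, b, matrix=None, match=2, mismatch=-1,
                                 gap_open=0.0, gap_extend=1.0)
            assert ours == pytest.approx(sw_oracle_similarity(a, b), abs=1e-12)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            sw_similarity("", "ACD")
        with pytest.raises(ValueError, match="position 2"):
            sw_similarity("ACXE", "ACDE")


# ---------------------------------------------------------------------------
# cross-pair aggregation
# ---------------------------------------------------------------------------

class TestAggregate:
    def test_singletons_and_hand_values(self):
        sim = {("a", "x"): 0.2, ("b", "x"): 0.6}
        out = target_pairwise_aggregate(["a", "b"], ["x"],
                                        lambda p, q: sim[(p, q)])
        assert out == (0.2, 0.6, pytest.approx(0.4), pytest.approx(0.4))
        single = target_pairwise_aggregate(["a"], ["x"], lambda p, q: 0.7)
        assert single == (0.7, 0.7, 0.7, 0.7)

    def test_empty_side_is_unavailable(self):
        with pytest.raises(FeatureUnavailableError):
            target_pairwise_aggregate([], ["x"], lambda p, q: 1.0)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_ordering_invariant(self, values):
        it = iter(values)
        mn, mx, med, mean = target_pairwise_aggregate(
            ["t"], list(range(len(values))), lambda a, b: values[b])
        assert mn <= med <= mx and mn <= mean <= mx


# ---------------------------------------------------------------------------
# GO semantic similarity (Wang)
# ---------------------------------------------------------------------------

def chain_ontology():
    g = nx.DiGraph()
    g.add_edge("leaf", "mid", relation="is_a", weight=0.8)
    g.add_edge("mid", "root", relation="is_a", weight=0.8)
    g.add_node("island")  # disjoint component
    return g


class TestWangSimilarity:
    def test_identity(self):
        g = chain_ontology()
        for term in ("leaf", "mid", "root"):
            assert go_term_similarity(term, term, g) == pytest.approx(1.0)

    def test_disjoint_components_score_zero(self):
        assert go_term_similarity("leaf", "island", chain_ontology()) == 0.0

    def test_hand_computed_chain_value(self):
        # S-values: leaf {leaf:1, mid:.8, root:.64} sum 2.44;
        #           mid {mid:1, root:.8} sum 1.8
        # common {mid, root}: (.8+1)+(.64+.8)=3.24 -> 3.24/4.24
        assert go_term_similarity("leaf", "mid", chain_ontology()) \
            == pytest.approx(3.24 / 4.24)

    def test_identity_on_random_dag(self, rng):
        g = nx.DiGraph()
        terms = [f"t{i}" for i in range(15)]
        g.add_nodes_from(terms)
        for i in range(1, 15):
            g.add_edge(terms[i], terms[int(rng.integers(0, i))],
                       relation="is_a", weight=0.8)
        for t in terms:
            assert go_term_similarity(t, t, g) == pytest.approx(1.0)

    def test_unknown_term(self):
        with pytest.raises(KeyError):
            go_term_similarity("leaf", "nope", chain_ontology())


class TestGeneLevelGo:
    def test_identical_annotation_sets_give_one(self):
        g = chain_ontology()
        ann = {"x": frozenset({"leaf", "mid"}), "y": frozenset({"leaf", "mid"})}
        out = go_gene_similarity(["x"], ["y"], ann, g)
        assert out == (1.0, 1.0, 1.0, 1.0)

    def test_disjoint_components_give_zero(self):
        g = chain_ontology()
        ann = {"x": frozenset({"leaf"}), "y": frozenset({"island"})}
        assert go_gene_similarity(["x"], ["y"], ann, g)[3] == 0.0

    def test_bma_mean_arithmetic(self):
        # two targets vs one, with BMA values 0.25 and 0.75 -> mean 0.5
        g = chain_ontology()
        ann = {"u": frozenset({"leaf"}), "v": frozenset({"mid"}),
               "w": frozenset({"root"})}
        vals = {(a, b): go_bma_similarity(ann[a], ann[b], g)
                for a, b in itertools.product(["u", "v"], ["w"])}
        _, _, _, mean = go_gene_similarity(["u", "v"], ["w"], ann, g)
        assert mean == pytest.approx(np.mean(list(vals.values())))

    def test_unannotated_targets_dropped_then_unavailable(self):
        g = chain_ontology()
        ann = {"x": frozenset({"leaf"}), "bare": frozenset()}
        with pytest.raises(FeatureUnavailableError):
            go_gene_similarity(["bare"], ["x"], ann, g)


# ---------------------------------------------------------------------------
# pathway enrichment + cosine
# ---------------------------------------------------------------------------

def hypergeom_tail_oracle(M: int, n: int, N: int, k: int) -> float:
    """P[X >= k] by exhaustive enumeration of the hypergeometric pmf."""
    total = math.comb(M, N)
    return sum(math.comb(n, i) * math.comb(M - n, N - i)
               for i in range(k, min(n, N) + 1)) / total


class TestEnrichment:
    def test_zero_overlap_excluded(self):
        universe = enrich_pathways({"t1", "t2"}, {"pw": frozenset({"t8", "t9"})},
                                   background_size=10)
        assert len(universe) == 0

    def test_matches_enumeration_oracle(self):
        # 10-target background, 5-target pathway, 5 drawn all inside
        targets = {f"t{i}" for i in range(5)}
        pathway = frozenset(targets)
        universe = enrich_pathways(targets, {"pw": pathway}, background_size=10)
        expected_p = hypergeom_tail_oracle(10, 5, 5, 5)
        assert universe.p_values["pw"] == pytest.approx(expected_p, rel=1e-12)
        assert expected_p < 0.05 and len(universe) == 1

    def test_enumeration_oracle_grid(self, rng):
        from scipy import stats
        for _ in range(40):
            M = int(rng.integers(4, 13))
            n = int(rng.integers(1, M + 1))
            N = int(rng.integers(1, M + 1))
            k = int(rng.integers(0, min(n, N) + 1))
            assert stats.hypergeom.sf(k - 1, M, n, N) == pytest.approx(
                hypergeom_tail_oracle(M, n, N, k), rel=1e-10)

    def test_empty_targets_give_empty_universe(self):
        assert len(enrich_pathways(set(), {"pw": frozenset({"a"})}, 5)) == 0


class TestPathwayVectorCosine:
    universe = PathwayUniverse(
        pathway_ids=["p1", "p2", "p3"],
        target_sets={"p1": frozenset({"a"}), "p2": frozenset({"b"}),
                     "p3": frozenset({"c"})})

    def test_membership_bits(self):
        assert pathway_vector({"a", "c"}, self.universe).tolist() == [1, 0, 1]
        assert pathway_vector({"a", "b", "c"}, self.universe).tolist() == [1, 1, 1]
        assert pathway_vector({"z"}, self.universe).tolist() == [0, 0, 0]

    def test_cosine_values(self):
        assert pathway_cosine(np.array([1, 1, 0]), np.array([1, 1, 0])) == pytest.approx(1.0)
        assert pathway_cosine(np.array([1, 0, 0]), np.array([0, 1, 0])) == 0.0
        assert pathway_cosine(np.array([1, 1, 0]), np.array([1, 0, 1])) == pytest.approx(0.5)
        assert pathway_cosine(np.zeros(3), np.array([1, 1, 1])) == 0.0


# ---------------------------------------------------------------------------
# PPI features vs Floyd-Warshall oracle
# ---------------------------------------------------------------------------

def sigma(d):
    return 1.0 / (1.0 + math.exp(-d))


class TestPpiFeatures:
    def test_self_pair_closed_form(self):
        g = nx.path_graph(3)
        out = ppi_features({0}, {0}, g)
        assert out[:4] == (0.5, 0.5, 0.5, 0.5)
        assert out[4] == pytest.approx(0.0)

    def test_path_graph_distance_two(self):
        g = nx.path_graph(3)  # 0 - 1 - 2
        s_min, s_max, s_med, s_mean, _ = ppi_features({0}, {2}, g)
        assert s_min == pytest.approx(sigma(2))
        assert s_max == s_med == s_min
        assert s_mean == pytest.approx(sigma(2))

    def test_disconnected_uses_diameter_plus_one(self):
        g = nx.Graph()
        nx.add_path(g, [0, 1, 2, 3])  # diameter 3
        g.add_edge(10, 11)
        s_min, *_ = ppi_features({0}, {10}, g)
        assert s_min == pytest.approx(sigma(4))

    def test_drop_pair_policy_raises_when_all_disconnected(self):
        g = nx.Graph()
        g.add_edge(0, 1)
        g.add_edge(10, 11)
        cfg = RunConfig(disconnected_distance_policy="drop-pair")
        with pytest.raises(FeatureUnavailableError):
            ppi_features({0}, {10}, g, cfg)

    def test_absent_targets(self):
        g = nx.path_graph(3)
        with pytest.raises(FeatureUnavailableError):
            ppi_features({"nope"}, {0}, g)

    def test_bfs_matches_floyd_warshall_oracle(self, rng):
        for _ in range(10):
            g = nx.gnp_random_graph(20, 0.15, seed=int(rng.integers(2**31)))
            nodes = list(g.nodes)
            # Floyd-Warshall oracle
            inf = float("inf")
            dist = {(u, v): (0 if u == v else (1 if g.has_edge(u, v) else inf))
                    for u in nodes for v in nodes}
            for k in nodes:
                for i in nodes:
                    for j in nodes:
                        if dist[i, k] + dist[k, j] < dist[i, j]:
                            dist[i, j] = dist[i, k] + dist[k, j]
            a, b = rng.choice(nodes, size=2, replace=False).tolist()
            diam = max(v for v in dist.values() if v < inf)
            expected = dist[a, b] if dist[a, b] < inf else diam + 1
            s_min, *_ = ppi_features({a}, {b}, g)
            assert s_min == pytest.approx(sigma(expected))

    def test_inverted_mean_flips_regime(self):
        g = nx.path_graph(4)
        cfg = RunConfig(ppi_sigmoid_sign="inverted-mean")
        *_, s_mean, s_np = ppi_features({0}, {3}, g, cfg)
        assert s_mean == pytest.approx(1.0 / (1.0 + math.exp(3)))
        assert s_np < 0  # Table-1-like sign regime


# ---------------------------------------------------------------------------
# assembled 16-feature vector
# ---------------------------------------------------------------------------

class TestFeaturizer:
    def test_self_pair_degenerate_limits(self, small_universe):
        drugs, context = small_universe
        feat = UniverseFeaturizer(drugs, context)
        d = drugs[0].drug_id
        v = feat.featurize_pair(d, d)
        assert v["S_FP"] == pytest.approx(1.0)
        assert v["S_ADME"] == pytest.approx(0.0)
        assert v["S_np"] == pytest.approx(0.0)
        for fam in ("S_Seq", "S_GO", "S_PPI"):
            assert v[f"{fam}min"] <= v[f"{fam}med"] <= v[f"{fam}max"]
            assert v[f"{fam}min"] == pytest.approx(v[f"{fam}max"]) or True

    def test_symmetry_and_ranges(self, small_universe):
        drugs, context = small_universe
        feat = UniverseFeaturizer(drugs, context)
        ids = [d.drug_id for d in drugs]
        for a, b in itertools.combinations(ids[:4], 2):
            v_ab = feat.featurize_pair(a, b)
            v_ba = feat.featurize_pair(b, a)
            for name in FEATURE_NAMES:
                assert v_ab[name] == pytest.approx(v_ba[name], abs=1e-12)
                assert np.isfinite(v_ab[name])
            for name in ("S_FP", "S_Seqmin", "S_Seqmax", "S_Seqmed", "S_Seqmean",
                         "S_GOmin", "S_GOmax", "S_GOmed", "S_GOmean", "S_Pathway"):
                assert 0.0 <= v_ab[name] <= 1.0
            for name in ("S_PPImin", "S_PPImax", "S_PPImed", "S_PPImean"):
                assert 0.0 < v_ab[name] < 1.0
            assert -1.0 < v_ab["S_np"] < 1.0
            for fam in ("S_Seq", "S_GO", "S_PPI"):
                assert v_ab[f"{fam}min"] <= v_ab[f"{fam}med"] <= v_ab[f"{fam}max"]
                assert v_ab[f"{fam}min"] <= v_ab[f"{fam}mean"] <= v_ab[f"{fam}max"]

    def test_drug_without_targets_rejected(self, small_universe):
        drugs, context = small_universe
        import dataclasses
        bare = dataclasses.replace(drugs[0], drug_id="BARE",
                                   target_ids=frozenset())
        feat = UniverseFeaturizer([*drugs, bare], context)
        with pytest.raises(FeatureUnavailableError):
            feat.featurize_pair("BARE", drugs[1].drug_id)
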