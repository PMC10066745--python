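"""Similarity graph construction, Markov clustering and pangenome partition."""

import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from mycopan.orthology import (
    Orthogroup,
    build_similarity_graph,
    mcl_cluster,
    pairwise_similarity,
    partition_pangenome,
    single_copy_orthogroups,
)
from mycopan.synthetic import SimulationConfig, simulate_pangenome


class TestPairwiseSimilarity:
    def test_identical_sequences(self):
        e = pairwise_similarity("M" + "KVLHAGDE" * 12, "M" + "KVLHAGDE" * 12)
        assert e.identity == 1.0 and e.coverage == 1.0

    def test_single_mismatch_hand_alignment(self):
        # one mismatch over five aligned columns
        e = pairwise_similarity("MKVLH", "MKILH")
        assert e.identity == pytest.approx(0.8)
        assert e.coverage == pytest.approx(1.0)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_similarity("", "MKV")

    def test_unrelated_sequences_fall_below_thresholds(self):
        # no positive-scoring local alignment at all between disjoint alphabets
        e = pairwise_similarity("MMMMWWWWMMMMWWWW" * 4, "HHHHCCCCHHHHCCCC" * 4)
        assert e.identity == 0.0 and e.coverage == 0.0


class TestBuildSimilarityGraph:
    def test_identical_proteins_yield_one_edge(self):
        seq = "MKVLHAGDERTYWFPQ" * 6
        g = build_similarity_graph({"a": {"g1": seq}, "b": {"g2": seq}})
        assert g.number_of_edges() == 1
        assert g.has_edge(("a", "g1"), ("b", "g2"))

    def test_low_divergence_family_forms_clique(self):
        cfg = SimulationConfig(
            seed=20, d=0.1, n_core=8, n_accessory=0, n_specific=0, n_species=4
        )
        proteins, truth = simulate_pangenome(cfg)
        g = build_similarity_graph(proteins)
        for _, fam in truth.groupby("og_id"):
            members = [(r.species_id, r.gene_id) for r in fam.itertuples()]
            for i, a in enumerate(members):
                for b in members[i + 1 :]:
                    assert g.has_edge(a, b)

    def test_high_divergence_families_fall_apart(self):
        # expected pairwise identity ~0.4: families must not form cliques;
        # local alignment may rescue an occasional borderline pair, so assert
        # edges are rare rather than strictly absent
        cfg = SimulationConfig(
            seed=21, d=0.6, n_core=10, n_accessory=0, n_specific=0, n_species=3
        )
        proteins, truth = simulate_pangenome(cfg)
        g = build_similarity_graph(proteins)
        n_pairs = sum(
            len(fam) * (len(fam) - 1) // 2 for _, fam in truth.groupby("og_id")
        )
        assert g.number_of_edges() <= 0.1 * n_pairs
        for _, fam in truth.groupby("og_id"):
            members = [(r.species_id, r.gene_id) for r in fam.itertuples()]
            present = sum(
                g.has_edge(a, b)
                for i, a in enumerate(members)
                for b in members[i + 1 :]
            )
            assert present < len(members) * (len(members) - 1) // 2

    def test_prefilter_matches_exhaustive_alignment(self):
        cfg = SimulationConfig(
            seed=22, d=0.15, n_core=5, n_accessory=0, n_specific=5, n_species=3
        )
        proteins, _ = simulate_pangenome(cfg)
        fast = build_similarity_graph(proteins, kmer_prefilter=True)
        slow = build_similarity_graph(proteins, kmer_prefilter=False)
        assert set(fast.edges) == set(slow.edges)


def reference_mcl(graph: nx.Graph, inflation: float = 3.0) -> list[frozenset]:
    """Independent dense-matrix MCL used as the clustering oracle."""
    nodes = sorted(graph.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    m = np.zeros((n, n))
    for a, b, d in graph.edges(data=True):
        m[idx[a], idx[b]] = m[idx[b], idx[a]] = d.get("weight", 1.0)
    m += np.eye(n)
    m /= m.sum(axis=0)
    for _ in range(200):
        prev = m.copy()
        m = np.linalg.matrix_power(m, 2) ** inflation
        m /= m.sum(axis=0)
        if np.abs(m - prev).max() < 1e-8:
            break
    clusters = set()
    for r in range(n):
        if m[r, r] > 1e-8:
            clusters.add(frozenset(nodes[j] for j in np.flatnonzero(m[r] > 1e-8)))
    return sorted(clusters, key=min)


class TestMclCluster:
    @staticmethod
    def _sets(orthogroups: list[Orthogroup]) -> set[frozenset]:
        return {frozenset(og.members) for og in orthogroups}

    def test_two_disconnected_triangles(self):
        g = nx.Graph()
        for tri in (("a1", "a2", "a3"), ("b1", "b2", "b3")):
            for i in range(3):
                g.add_edge(("s", tri[i]), ("s", tri[(i + 1) % 3]), weight=1.0)
        ogs, converged = mcl_cluster(g)
        assert converged
        assert self._sets(ogs) == {
            frozenset({("s", "a1"), ("s", "a2"), ("s", "a3")}),
            frozenset({("s", "b1"), ("s", "b2"), ("s", "b3")}),
        }

    def test_singleton_node_is_singleton_orthogroup(self):
        g = nx.Graph()
        g.add_node(("s", "lonely"))
        ogs, _ = mcl_cluster(g)
        assert len(ogs) == 1 and ogs[0].members == ((("s", "lonely")),)

    def test_barbell_graph_matches_reference_mcl(self):
        raw = nx.barbell_graph(6, 0)
        g = nx.Graph()
        for a, b in raw.edges:
            g.add_edge(("s", f"n{a:02d}"), ("s", f"n{b:02d}"), weight=1.0)
        ogs, _ = mcl_cluster(g)
        expected = {frozenset(c) for c in reference_mcl(g)}
        assert self._sets(ogs) == expected

    def test_clustering_invariant_to_input_order(self):
        cfg = SimulationConfig(seed=23, d=0.1, n_core=6, n_accessory=4, n_specific=4)
        proteins, _ = simulate_pangenome(cfg)
        g = build_similarity_graph(proteins)
        h = nx.Graph()
        h.add_nodes_from(reversed(list(g.nodes)))
        h.add_edges_from(
            (b, a, d) for a, b, d in reversed(list(g.edges(data=True)))
        )
        assert self._sets(mcl_cluster(g)[0]) == self._sets(mcl_cluster(h)[0])


class TestPartition:
    species9 = [f"sp{i}" for i in range(9)]

    @staticmethod
    def og(og_id, species):
        return Orthogroup(og_id, tuple((s, f"{s}_{og_id}") for s in species))

    def test_all_species_is_core_one_is_specific(self):
        ogs = [
            self.og("all", self.species9),
            self.og("one", self.species9[:1]),
            self.og("some", self.species9[:4]),
        ]
        part = partition_pangenome(ogs, self.species9)
        assert part.labels == {"all": "core", "one": "specific", "some": "accessory"}
        assert sum(part.counts.values()) == 3

    def test_reported_core_percentage_from_published_scale_counts(self):
        # 5,531 core + 9,677 accessory + 26,560 specific orthogroups
        ogs = (
            [self.og(f"c{i}", self.species9) for i in range(5_531)]
            + [self.og(f"a{i}", self.species9[:2]) for i in range(9_677)]
            + [self.og(f"s{i}", self.species9[:1]) for i in range(26_560)]
        )
        part = partition_pangenome(ogs, self.species9)
        assert round(part.percentages["core"]) == 13
        assert round(part.percentages["accessory"]) == 23

    def test_recovery_on_simulated_pangenome(self):
        cfg = SimulationConfig(seed=24, d=0.15, n_core=15, n_accessory=15, n_specific=15)
        proteins, truth = simulate_pangenome(cfg)
        ogs, _ = mcl_cluster(build_similarity_graph(proteins))
        inferred = {m: og.og_id for og in ogs for m in og.members}
        nodes = sorted(inferred)
        truth_map = dict(zip(zip(truth.species_id, truth.gene_id), truth.og_id))
        ari = adjusted_rand_score(
            [truth_map[v] for v in nodes], [inferred[v] for v in nodes]
        )
        assert ari >= 0.95
        part = partition_pangenome(ogs, sorted(proteins))
        assert part.counts == {"core": 15, "accessory": 15, "specific": 15}

    def test_single_copy_excludes_paralogous_core_groups(self):
        species = ["s1", "s2", "s3"]
        clean = self.og("clean", species)
        with_paralog = Orthogroup(
            "dup", tuple([("s1", "x1"), ("s1", "x2"), ("s2", "y"), ("s3", "z")])
        )
        assert single_copy_orthogroups([clean, with_paralog], species) == ["clean"]

    def test_planted_single_copy_count_recovered(self):
        cfg = SimulationConfig(
            seed=25, d=0.1, n_core=12, n_accessory=6, n_specific=6,
            core_paralog_fraction=0.0,
        )
        proteins, _ = simulate_pangenome(cfg)
        ogs, _ = mcl_cluster(build_similarity_graph(proteins))
        assert len(single_copy_orthogroups(ogs, sorted(proteins))) == 12
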