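"""Protein orthology: similarity graph, Markov clustering, pangenome partition.

Orthogroups are inferred FastOrtho-style: all-vs-all local protein alignment,
an undirected similarity graph keeping edges with >= 50% identity and >= 50%
coverage, and Markov clustering (MCL) of that graph at inflation 3.0.  The
pangenome is then partitioned into the core genome (orthogroups with at least
one member in every species), the accessory genome (members in >= 2 but not
all species) and the species-specific genome (exactly one species).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

Node = tuple[str, str]  # (species_id, gene_id)


@dataclass(frozen=True)
class SimilarityEdge:
    """An above-threshold pairwise protein similarity (canonical a < b order)."""

    gene_a: str
    gene_b: str
    identity: float
    coverage: float
    score: float

    def __post_init__(self) -> None:
        if self.gene_b < self.gene_a:
            object.__setattr__(self, "gene_a", self.gene_b)
            object.__setattr__(self, "gene_b", self.gene_a)


@dataclass(frozen=True)
class Orthogroup:
    og_id: str
    members: tuple[Node, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"orthogroup {self.og_id} has no members")

    @property
    def n_species(self) -> int:
        return len({sp for sp, _ in self.members})

    @property
    def species(self) -> set[str]:
        return {sp for sp, _ in self.members}


@dataclass
class PangenomePartition:
    """Core/accessory/specific labels with counts and reporting percentages."""

    labels: dict[str, str]
    counts: dict[str, int]
    percentages: dict[str, float]

    @property
    def n_orthogroups(self) -> int:
        return sum(self.counts.values())


def make_aligner() -> Align.PairwiseAligner:
    """Local affine-gap protein aligner (BLOSUM62, open -11, extend -1)."""
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "local"
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def pairwise_similarity(
    seq_a: str,
    seq_b: str,
    aligner: Align.PairwiseAligner | None = None,
    gene_a: str = "a",
    gene_b: str = "b",
) -> SimilarityEdge:
    """Align two protein sequences and report identity, coverage and score.

    identity = matches / alignment columns (gap columns included);
    coverage = aligned span in the shorter sequence / shorter-sequence length.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    if aligner is None:
        aligner = make_aligner()
    try:
        alignment = aligner.align(seq_a, seq_b)[0]
    except IndexError:
        # no positive-scoring local alignment exists: maximally dissimilar
        return SimilarityEdge(
            gene_a=gene_a, gene_b=gene_b, identity=0.0, coverage=0.0, score=0.0
        )
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / columns if columns else 0.0
    coords = alignment.coordinates
    span_a = int(coords[0, -1] - coords[0, 0])
    span_b = int(coords[1, -1] - coords[1, 0])
    shorter_span = span_a if len(seq_a) <= len(seq_b) else span_b
    coverage = shorter_span / min(len(seq_a), len(seq_b))
    return SimilarityEdge(
        gene_a=gene_a,
        gene_b=gene_b,
        identity=identity,
        coverage=coverage,
        score=float(alignment.score),
    )


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def build_similarity_graph(
    proteins: Mapping[str, Mapping[str, str]],
    min_identity: float = 0.50,
    min_coverage: float = 0.50,
    kmer_prefilter: bool = True,
    kmer_k: int = 4,
    kmer_min_containment: float = 0.02,
) -> nx.Graph:
    """All-vs-all similarity graph over ``{species: {gene_id: sequence}}``.

    Edges (weighted by identity) are kept iff identity >= ``min_identity``
    AND coverage >= ``min_coverage``; within-species (paralog) pairs are
    aligned like cross-species pairs, self-pairs never.  The optional k-mer
    prescreen skips alignments between pairs sharing almost no k-mers, which
    cannot reach 50% identity; it is a speed device only and can be disabled.
    """
    nodes: list[Node] = sorted(
        (sp, gid) for sp, genes in proteins.items() for gid in genes
    )
    seqs = {(sp, gid): proteins[sp][gid] for sp, gid in nodes}
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    aligner = make_aligner()
    kmers = (
        {n: _kmer_set(seqs[n], kmer_k) for n in nodes} if kmer_prefilter else None
    )
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            if kmers is not None:
                shared = len(kmers[a] & kmers[b])
                denom = min(len(kmers[a]), len(kmers[b]))
                if denom == 0 or shared / denom < kmer_min_containment:
                    continue
            edge = pairwise_similarity(seqs[a], seqs[b], aligner)
            if edge.identity >= min_identity and edge.coverage >= min_coverage:
                graph.add_edge(
                    a, b, weight=edge.identity, coverage=edge.coverage, score=edge.score
                )
    return graph


def load_similarity_edges(
    path: str | Path, min_identity: float = 0.50, min_coverage: float = 0.50
) -> nx.Graph:
    """Similarity graph from a precomputed edges TSV.

    Expected columns: species_a, gene_a, species_b, gene_b, identity,
    coverage.  This is the entry point for real data where similarities come
    from an external all-vs-all search.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"species_a", "gene_a", "species_b", "gene_b", "identity", "coverage"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"edges TSV missing columns: {sorted(missing)}")
    graph = nx.Graph()
    for row in df.itertuples(index=False):
        a: Node = (row.species_a, row.gene_a)
        b: Node = (row.species_b, row.gene_b)
        graph.add_node(a)
        graph.add_node(b)
        if a != b and row.identity >= min_identity and row.coverage >= min_coverage:
            graph.add_edge(a, b, weight=float(row.identity))
    return graph


def _mcl_component(
    nodes: list[Node],
    graph: nx.Graph,
    inflation: float,
    max_iter: int,
    tol: float,
    prune: float = 1e-9,
) -> tuple[list[set[Node]], bool]:
    """Dense MCL on one connected component; returns (clusters, converged)."""
    n = len(nodes)
    index = {node: i for i, node in enumerate(nodes)}
    M = np.zeros((n, n))
    for a, b, data in graph.edges(nodes, data=True):
        i, j = index[a], index[b]
        M[i, j] = M[j, i] = data.get("weight", 1.0)
    np.fill_diagonal(M, 1.0)  # self loops regularize the flow
    M /= M.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        prev = M
        M = M @ M  # expansion
        np.power(M, inflation, out=M)  # inflation
        M[M < prune] = 0.0
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0.0] = 1.0
        M /= colsum
        if np.abs(M - prev).max() < tol:
            converged = True
            break
    # attractor rows (positive diagonal) seed the clusters; attractors that
    # flow into each other belong to one attractor system
    attractors = list(np.flatnonzero(np.diag(M) > tol))
    if not attractors:  # pathological non-convergence: keep component whole
        return [set(nodes)], converged
    systems = nx.Graph()
    systems.add_nodes_from(attractors)
    for r in attractors:
        for s in attractors:
            if r < s and (M[r, s] > tol or M[s, r] > tol):
                systems.add_edge(r, s)
    clusters_idx: list[set[int]] = [set(c) for c in nx.connected_components(systems)]
    clusters_idx.sort(key=min)
    attractor_of = {i: k for k, cluster in enumerate(clusters_idx) for i in cluster}
    # non-attractor nodes join the system(s) they flow to; ambiguous nodes go
    # to the cluster with the larger total original edge weight, then to the
    # cluster with the smallest member (hence smallest og id)
    for j in range(n):
        if j in attractor_of:
            continue
        candidates = sorted({attractor_of[int(r)] for r in attractors if M[r, j] > tol})
        if not candidates:
            clusters_idx.append({j})
            continue
        if len(candidates) == 1:
            clusters_idx[candidates[0]].add(j)
            continue

        def pull(k: int) -> float:
            return sum(
                graph[nodes[j]][nodes[i]]["weight"]
                for i in clusters_idx[k]
                if graph.has_edge(nodes[j], nodes[i])
            )

        best = sorted(candidates, key=lambda k: (-pull(k), min(clusters_idx[k])))[0]
        clusters_idx[best].add(j)
    clusters = [{nodes[i] for i in cluster} for cluster in clusters_idx]
    return clusters, converged


def mcl_cluster(
    graph: nx.Graph,
    inflation: float = 3.0,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> tuple[list[Orthogroup], bool]:
    """Markov clustering of the similarity graph into orthogroups.

    Column-normalized random-walk matrix with unit self loops; alternate
    expansion (matrix squaring) and inflation (entrywise power, renormalize)
    until the matrix is stable to ``tol`` or ``max_iter`` is reached.  Run
    independently per connected component (flow never crosses components).
    Returns the orthogroups (deterministically named og00000, og00001, ... in
    order of their smallest member) and a global convergence flag.
    """
    all_clusters: list[set[Node]] = []
    all_converged = True
    for component in nx.connected_components(graph):
        nodes = sorted(component)
        if len(nodes) == 1:
            all_clusters.append(set(nodes))
            continue
        clusters, converged = _mcl_component(nodes, graph, inflation, max_iter, tol)
        all_converged &= converged
        all_clusters.extend(clusters)
    all_clusters.sort(key=lambda c: min(c))
    orthogroups = [
        Orthogroup(og_id=f"og{i:05d}", members=tuple(sorted(cluster)))
        for i, cluster in enumerate(all_clusters)
    ]
    return orthogroups, all_converged


def partition_pangenome(
    orthogroups: Iterable[Orthogroup], species_list: Iterable[str]
) -> PangenomePartition:
    """Label orthogroups core / accessory / specific over ``species_list``.

    core: members in every listed species; specific: exactly one species;
    accessory: anything in between.  Percentages are reported rounded to the
    nearest integer (as conventional in pangenome summaries) but stored
    unrounded.
    """
    n_total = len(set(species_list))
    if n_total == 0:
        raise ValueError("species_list is empty")
    labels: dict[str, str] = {}
    counts = {"core": 0, "accessory": 0, "specific": 0}
    for og in orthogroups:
        if og.n_species == n_total:
            label = "core"
        elif og.n_species == 1:
            label = "specific"
        else:
            label = "accessory"
        labels[og.og_id] = label
        counts[label] += 1
    total = sum(counts.values())
    percentages = {
        k: (100.0 * v / total if total else 0.0) for k, v in counts.items()
    }
    return PangenomePartition(labels=labels, counts=counts, percentages=percentages)


def single_copy_orthogroups(
    orthogroups: Iterable[Orthogroup], species_list: Iterable[str]
) -> list[str]:
    """Core orthogroups with exactly one member per species (phylogeny markers)."""
    species = set(species_list)
    out = []
    for og in orthogroups:
        per_species: dict[str, int] = {}
        for sp, _ in og.members:
            per_species[sp] = per_species.get(sp, 0) + 1
        if set(per_species) == species and all(v == 1 for v in per_species.values()):
            out.append(og.og_id)
    return out


def orthogroups_to_frame(orthogroups: Iterable[Orthogroup]) -> pd.DataFrame:
    rows = [
        (og.og_id, sp, gid) for og in orthogroups for sp, gid in og.members
    ]
    return pd.DataFrame(rows, columns=["og_id", "species_id", "gene_id"])
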