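"""Ortholog family inference: reciprocal best hits + two-stage clustering.

For every ordered pair of genomes the proteomes are searched against
each other; a reciprocal best hit (RBB) is a gene pair where each gene
is the other's unique best subject.  RBB pairs, weighted by bit score,
form a graph that is clustered in two stages: single-linkage (connected
components) followed by Markov clustering (expansion 2, inflation 3)
within each component.  Clusters below the minimum size become
singletons.  The strain x family presence/absence matrix appends every
singleton gene as a prevalence-1 column so unique genes still count in
pan-genome curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .model import GenomePanel, PanelTruth
from .search import SimilarityHit, best_hits, pairwise_search


def reciprocal_best_hits(
    hits_ab: Sequence[SimilarityHit], hits_ba: Sequence[SimilarityHit]
) -> list[tuple[str, str, float]]:
    """RBB pairs from the two directed searches of one genome pair.

    Returns ``(gene_a, gene_b, weight)`` triples where *weight* is the
    mean of the two directed best-hit bit scores.  A pair qualifies iff
    each gene is the other's unique best subject (ties resolved by bit
    score, then identity, then lexicographic subject id).
    """
    best_ab = best_hits(list(hits_ab))
    best_ba = best_hits(list(hits_ba))
    pairs = []
    for a, hit in sorted(best_ab.items()):
        b = hit.subject_id
        back = best_ba.get(b)
        if back is not None and back.subject_id == a:
            pairs.append((a, b, (hit.bit_score + back.bit_score) / 2.0))
    return pairs


@dataclass
class OrthologFamilySet:
    """Disjoint gene families plus leftover singleton genes."""

    families: dict[str, set[str]] = field(default_factory=dict)
    singletons: set[str] = field(default_factory=set)
    gene_strain: dict[str, str] = field(default_factory=dict)
    inflation: float = 3.0
    min_cluster_size: int = 2

    def family_of(self) -> dict[str, str]:
        """gene_id -> family_id (singletons map to their own gene id)."""
        out = {}
        for fid, members in self.families.items():
            for g in members:
                out[g] = fid
        for g in self.singletons:
            out[g] = g
        return out

    def strains_of(self, family_id: str) -> set[str]:
        return {self.gene_strain[g] for g in self.families[family_id]}


def markov_cluster(
    subgraph: nx.Graph,
    inflation: float = 3.0,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> list[set[str]]:
    """MCL on one weighted component (expansion power 2).

    Self-loops with weight equal to each node's maximum incident edge
    weight are added before normalisation; without them two-node
    components oscillate with period two and never converge.  Attractor
    rows of the converged matrix define clusters; a node attracted by
    several systems joins the one holding the largest mass (ties:
    lexicographically smallest attractor).
    """
    nodes = sorted(subgraph.nodes)
    n = len(nodes)
    if n == 1:
        return [set(nodes)]
    pos = {v: i for i, v in enumerate(nodes)}
    m = np.zeros((n, n))
    for u, v, w in subgraph.edges(data="weight", default=1.0):
        if w <= 0:
            raise ValueError(f"non-positive edge weight on ({u}, {v})")
        m[pos[u], pos[v]] = w
        m[pos[v], pos[u]] = w
    np.fill_diagonal(m, m.max(axis=0))

    def normalise(x: np.ndarray) -> np.ndarray:
        return x / x.sum(axis=0, keepdims=True)

    m = normalise(m)
    for _ in range(max_iter):
        expanded = normalise(m @ m)
        inflated = normalise(expanded**inflation)
        if np.abs(inflated - m).max() < tol:
            m = inflated
            break
        m = inflated

    attract_tol = 1e-6
    attractors = [i for i in range(n) if m[i, i] > attract_tol]
    # group attractors that attract one another into systems
    sys_graph = nx.Graph()
    sys_graph.add_nodes_from(attractors)
    for i in attractors:
        for j in attractors:
            if i < j and (m[i, j] > attract_tol or m[j, i] > attract_tol):
                sys_graph.add_edge(i, j)
    systems = [sorted(c) for c in nx.connected_components(sys_graph)]
    systems.sort()

    assignment: dict[int, tuple[float, int, int]] = {}
    for sys_idx, system in enumerate(systems):
        for j in range(n):
            mass = float(sum(m[i, j] for i in system))
            if mass <= attract_tol:
                continue
            # prefer larger mass, then the smaller lead attractor
            cand = (-mass, system[0], sys_idx)
            if j not in assignment or cand < assignment[j]:
                assignment[j] = cand
    clusters: dict[int, set[str]] = {}
    for j, (_, _, sys_idx) in assignment.items():
        clusters.setdefault(sys_idx, set()).add(nodes[j])
    # nodes attracted by nothing (numerically washed out) become their own cluster
    for j in range(n):
        if j not in assignment:
            clusters[len(systems) + j] = {nodes[j]}
    return [clusters[k] for k in sorted(clusters)]


def cluster_orthologs(
    rbb_graph: nx.Graph,
    all_genes: Mapping[str, str] | None = None,
    inflation: float = 3.0,
    min_cluster_size: int = 2,
) -> OrthologFamilySet:
    """Two-stage clustering of the RBB graph into ortholog families.

    Stage 1 is single-linkage (connected components); stage 2 applies
    Markov clustering within each component.  Clusters smaller than
    *min_cluster_size* are dissolved into singletons.  *all_genes*
    (gene_id -> strain_id) supplies strain attribution and any genes
    with no RBB edge, which become singletons.
    """
    for u, v, w in rbb_graph.edges(data="weight", default=1.0):
        if w <= 0:
            raise ValueError(f"non-positive edge weight on ({u}, {v})")
    result = OrthologFamilySet(inflation=inflation, min_cluster_size=min_cluster_size)
    if all_genes:
        result.gene_strain = dict(all_genes)
    clusters: list[set[str]] = []
    for component in nx.connected_components(rbb_graph):
        sub = rbb_graph.subgraph(component)
        clusters.extend(markov_cluster(sub, inflation=inflation))
    kept = [c for c in clusters if len(c) >= min_cluster_size]
    dropped = [c for c in clusters if len(c) < min_cluster_size]
    kept.sort(key=lambda c: tuple(sorted(c)))
    width = max(5, len(str(len(kept))))
    for i, members in enumerate(kept, start=1):
        result.families[f"F{i:0{width}d}"] = set(members)
    for c in dropped:
        result.singletons.update(c)
    if all_genes:
        clustered = set().union(*kept) if kept else set()
        clustered |= result.singletons
        result.singletons.update(g for g in all_genes if g not in clustered)
    return result


@dataclass
class PresenceAbsenceMatrix:
    """Binary strain x gene-family matrix with singleton columns appended."""

    df: pd.DataFrame
    family_columns: list[str]
    singleton_columns: list[str]
    modal_replicon_class: dict[str, str] = field(default_factory=dict)

    @property
    def strains(self) -> list[str]:
        return list(self.df.index)

    def values(self) -> np.ndarray:
        return self.df.to_numpy(dtype=bool)


def build_presence_absence(
    families: OrthologFamilySet,
    strains: Sequence[str],
    gene_replicon_class: Mapping[str, str] | None = None,
) -> PresenceAbsenceMatrix:
    """Binarised presence/absence matrix over *strains*.

    entry(s, f) = 1 iff strain *s* carries at least one member of
    family *f* (paralogs collapse to a single 1).  Every singleton gene
    is appended as its own prevalence-1 column.  If a gene's strain is
    unknown a ``KeyError``-style ValueError is raised.
    """
    strains = list(strains)
    strain_set = set(strains)
    for gene, strain in families.gene_strain.items():
        if strain not in strain_set:
            raise ValueError(f"gene {gene!r} attributed to unknown strain {strain!r}")

    def strain_of(gene: str) -> str:
        try:
            return families.gene_strain[gene]
        except KeyError:
            raise ValueError(f"gene {gene!r} has no strain attribution") from None

    fam_cols = sorted(families.families)
    single_cols = sorted(families.singletons)
    data = np.zeros((len(strains), len(fam_cols) + len(single_cols)), dtype=np.int8)
    row = {s: i for i, s in enumerate(strains)}
    for j, fid in enumerate(fam_cols):
        for gene in families.families[fid]:
            data[row[strain_of(gene)], j] = 1
    for j, gene in enumerate(single_cols):
        data[row[strain_of(gene)], len(fam_cols) + j] = 1
    df = pd.DataFrame(data, index=strains, columns=fam_cols + single_cols)

    modal: dict[str, str] = {}
    if gene_replicon_class:
        for fid in fam_cols:
            classes = sorted(
                gene_replicon_class.get(g) for g in families.families[fid]
                if gene_replicon_class.get(g) is not None
            )
            if classes:
                vals, counts = np.unique(classes, return_counts=True)
                modal[fid] = str(vals[np.argmax(counts)])
        for gene in single_cols:
            if gene_replicon_class.get(gene) is not None:
                modal[gene] = gene_replicon_class[gene]
    return PresenceAbsenceMatrix(df, fam_cols, single_cols, modal)


def panel_ortholog_families(
    panel: GenomePanel,
    min_identity: float = 40.0,
    min_query_cov: float = 0.5,
    min_bitscore: float = 50.0,
    inflation: float = 3.0,
    min_cluster_size: int = 2,
    prefilter: bool = True,
) -> tuple[OrthologFamilySet, PresenceAbsenceMatrix]:
    """All-vs-all RBB computation and clustering for a whole panel."""
    proteomes = panel.proteomes()
    ids = sorted(proteomes)
    graph = nx.Graph()
    for a_i in range(len(ids)):
        for b_i in range(a_i + 1, len(ids)):
            a, b = ids[a_i], ids[b_i]
            hits_ab = pairwise_search(
                proteomes[a], proteomes[b],
                min_identity=min_identity, min_query_cov=min_query_cov,
                min_bitscore=min_bitscore, prefilter=prefilter,
            )
            hits_ba = pairwise_search(
                proteomes[b], proteomes[a],
                min_identity=min_identity, min_query_cov=min_query_cov,
                min_bitscore=min_bitscore, prefilter=prefilter,
            )
            for ga, gb, w in reciprocal_best_hits(hits_ab, hits_ba):
                graph.add_edge(ga, gb, weight=w)
    gene_strain = panel.gene_strain_map()
    families = cluster_orthologs(
        graph, all_genes=gene_strain,
        inflation=inflation, min_cluster_size=min_cluster_size,
    )
    gene_class = {
        g.gene_id: g.replicon_class
        for s in panel for g in s.genes.values()
        if g.replicon_class is not None
    }
    matrix = build_presence_absence(families, panel.strain_ids, gene_class or None)
    return families, matrix


def family_recovery_ari(families: OrthologFamilySet, truth: PanelTruth) -> float:
    """Adjusted Rand index between inferred and true gene families."""
    from sklearn.metrics import adjusted_rand_score

    inferred = families.family_of()
    genes = sorted(truth.family_membership)
    true_labels = [truth.family_membership[g] for g in genes]
    pred_labels = [inferred.get(g, g) for g in genes]
    return float(adjusted_rand_score(true_labels, pred_labels))
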