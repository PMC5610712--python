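"""Replicon assignment, reference-cluster presence and functional profiles.

Contigs are assigned to replicon classes in two steps: replication /
partition marker genes (repA, repE, parA) called at high nucleotide
identity over their full length place a contig on the repA-type
megaplasmid; otherwise the contig goes to the replicon class whose
reference sequences cover the largest fraction of its fragments, or to
"unassigned" below a configurable homology floor.  This reconstructs
the marker-plus-homology behaviour used for multi-replicon draft
assemblies; all thresholds are configurable.

Reference-cluster (e.g. exopolysaccharide operon) presence is called
per gene from transferred labels, with a cluster-level call requiring a
minimum number of matched genes.  Functional count matrices tabulate
labelled genes per strain, replicon class and category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import edlib
import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .genome_metrics import AniParams, _best_fragment_identity, _fragments, _nt_aligner
from .model import REPA_MEGAPLASMID, UNASSIGNED, GeneModel


@dataclass
class MarkerSet:
    """Nucleotide marker genes diagnostic of a replicon class."""

    markers: dict[str, str]                    # marker id -> sequence
    expected_class: str = REPA_MEGAPLASMID

    def __post_init__(self) -> None:
        if len(self.markers) != len(set(self.markers)):
            raise ValueError("marker ids must be unique")


def _marker_identity(marker: str, contig: str) -> float:
    """Percent identity of the marker aligned over its full length."""
    best = -1
    for target in (contig, str(Seq(contig).reverse_complement())):
        if len(target) < 1:
            continue
        res = edlib.align(marker, target, mode="HW", task="distance")
        dist = res["editDistance"]
        if dist >= 0 and (best < 0 or dist < best):
            best = dist
    if best < 0:
        return 0.0
    return 100.0 * max(0, len(marker) - best) / len(marker)


def assign_replicons(
    contigs: Mapping[str, str],
    markers: MarkerSet,
    references: Mapping[str, Sequence[str]],
    min_marker_identity: float = 93.0,
    min_fragment_identity: float = 70.0,
    homology_floor: float = 0.1,
    fragment_length: int = 1020,
) -> dict[str, tuple[str, dict]]:
    """Assign each contig to a replicon class.

    *references* maps a replicon class to reference sequences of that
    class.  Returns ``{contig_id: (class, evidence)}`` where evidence
    records marker identities and per-class fragment coverage.  A contig
    whose best reference coverage falls below *homology_floor* is
    returned as "unassigned".
    """
    if not references:
        raise ValueError("at least one reference class is required")
    params = AniParams(
        fragment_length=fragment_length,
        min_fragment_identity=min_fragment_identity,
        min_fragment_coverage=0.7,
    )
    aligner = _nt_aligner()
    ref_targets = {
        cls: list(seqs) + [str(Seq(s).reverse_complement()) for s in seqs]
        for cls, seqs in references.items()
    }
    out: dict[str, tuple[str, dict]] = {}
    for cid in sorted(contigs):
        seq = contigs[cid]
        if not seq:
            raise ValueError(f"contig {cid!r} is empty")
        marker_ids = {
            mid: _marker_identity(mseq, seq) for mid, mseq in sorted(markers.markers.items())
        }
        marker_hits = {m: v for m, v in marker_ids.items() if v >= min_marker_identity}
        if marker_hits:
            out[cid] = (
                markers.expected_class,
                {"markers": marker_ids, "coverage": {}},
            )
            continue
        frags = _fragments([seq], params)
        coverage = {}
        for cls in sorted(ref_targets):
            retained = 0
            for frag in frags:
                ident, cov = _best_fragment_identity(frag, ref_targets[cls], aligner)
                if ident >= params.min_fragment_identity and cov >= params.min_fragment_coverage:
                    retained += 1
            coverage[cls] = retained / len(frags) if frags else 0.0
        best_cls = max(sorted(coverage), key=lambda c: coverage[c])
        assigned = best_cls if coverage[best_cls] >= homology_floor else UNASSIGNED
        out[cid] = (assigned, {"markers": marker_ids, "coverage": coverage})
    return out


@dataclass
class ReferenceCluster:
    """An ordered reference gene cluster (synteny-preserving)."""

    name: str
    genes: list[tuple[str, str, str]]   # (gene_id, protein, functional tag)
    source_strain: str = ""

    def __post_init__(self) -> None:
        if len(self.genes) < 2:
            raise ValueError("a reference cluster needs at least 2 genes")
        ids = [g[0] for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("reference cluster gene ids must be unique")

    @property
    def gene_ids(self) -> list[str]:
        return [g[0] for g in self.genes]

    def reference_proteins(self) -> dict[str, tuple[str, str]]:
        """As a transfer_annotation reference: {id: (label=own id, protein)}."""
        return {gid: (gid, protein) for gid, protein, _tag in self.genes}


@dataclass
class ClusterPresenceCall:
    cluster: str
    presence: dict[str, bool]          # reference gene id -> present
    total_present: int
    present: bool                      # cluster-level call
    observed_order: list[str]          # reference ids in strain gene order


def call_cluster_presence(
    strain_genes: Sequence[GeneModel],
    cluster: ReferenceCluster,
    scheme: str | None = None,
    min_genes: int = 18,
) -> ClusterPresenceCall:
    """Per-gene and cluster-level presence of a reference cluster.

    *strain_genes* must already carry labels mapping them to reference
    cluster gene ids (scheme defaults to the cluster name).  The cluster
    is called present when at least *min_genes* reference genes are
    matched; the observed order of matched genes (by replicon and
    coordinate) is reported for synteny inspection.
    """
    scheme = scheme or cluster.name
    if min_genes > len(cluster.genes):
        raise ValueError(
            f"min_genes={min_genes} exceeds cluster size {len(cluster.genes)}"
        )
    matched: dict[str, list[GeneModel]] = {}
    for g in strain_genes:
        if scheme in g.labels:
            label = g.labels[scheme][0]
            if label in cluster.gene_ids:
                matched.setdefault(label, []).append(g)
    presence = {gid: gid in matched for gid in cluster.gene_ids}
    total = sum(presence.values())
    ordered_genes = sorted(
        ((g, label) for label, genes in matched.items() for g in genes),
        key=lambda t: (t[0].replicon_id, t[0].start),
    )
    return ClusterPresenceCall(
        cluster=cluster.name,
        presence=presence,
        total_present=total,
        present=total >= min_genes,
        observed_order=[label for _g, label in ordered_genes],
    )


@dataclass
class FeatureCounts:
    counts: pd.DataFrame        # rows: (strain, replicon class); columns: categories
    proportions: pd.DataFrame   # rows normalised to sum 1


def feature_count_matrix(
    genes: Sequence[GeneModel],
    scheme: str,
    categories: Sequence[str] | None = None,
) -> FeatureCounts:
    """Strain x replicon-class x category gene counts and proportions.

    Only genes labelled under *scheme* contribute; each gene counts once
    under its (single, best-scoring) label.  Strains carrying no genes
    of a replicon class yield no row for that class.  Proportions are
    normalised within each (strain, replicon class) row.
    """
    rows = []
    for g in genes:
        if scheme not in g.labels:
            continue
        if g.replicon_class is None:
            raise ValueError(f"gene {g.gene_id!r} lacks a replicon class")
        rows.append((g.strain_id, g.replicon_class, g.labels[scheme][0]))
    if not rows:
        empty = pd.DataFrame()
        return FeatureCounts(empty, empty)
    df = pd.DataFrame(rows, columns=["strain", "replicon_class", "category"])
    counts = (
        df.groupby(["strain", "replicon_class", "category"])
        .size()
        .unstack(fill_value=0)
        .sort_index()
    )
    if categories is not None:
        counts = counts.reindex(columns=list(categories), fill_value=0)
    proportions = counts.div(counts.sum(axis=1), axis=0)
    return FeatureCounts(counts, proportions)
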