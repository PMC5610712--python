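"""Whole-genome pairwise metrics: fragment-based ANI and POCP.

ANI follows the classic fragment algorithm: genome A is cut into
consecutive 1020 nt fragments, each fragment is locally aligned to
genome B (both strands), and fragments are retained when the alignment
reaches >= 30% identity over >= 70% of the fragment length.  The
directed ANI is the mean identity of retained fragments and the
reported value averages the two directions.  Fragment placement uses a
fast infix edit-distance scan (edlib) to locate the best target region,
followed by a blastn-scored local alignment (match 2, mismatch -3, gap
open 5, extend 2) that supplies the identity and coverage entering the
retention rule.

POCP counts, for each genome of a pair, the proteins with at least one
hit in the other genome at e-value <= 1e-5, identity >= 40% and
alignable region > 50% of the query length:
POCP = (C1 + C2) / (T1 + T2) * 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import edlib
import numpy as np
import pandas as pd
from Bio import Align
from Bio.Seq import Seq
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .model import Strain
from .search import pairwise_search


@dataclass
class AniParams:
    fragment_length: int = 1020
    min_fragment_identity: float = 30.0   # percent
    min_fragment_coverage: float = 0.7    # fraction of fragment length
    min_retained_fragments: int = 20
    min_final_fragment: int = 100         # shorter trailing fragments are dropped
    both_directions: bool = True

    def validate(self) -> None:
        if self.fragment_length < 100:
            raise ValueError("fragment_length must be >= 100")
        if not 0 <= self.min_fragment_identity <= 100:
            raise ValueError("min_fragment_identity outside [0, 100]")
        if not 0 < self.min_fragment_coverage <= 1:
            raise ValueError("min_fragment_coverage outside (0, 1]")


@dataclass
class AniResult:
    ani: float                 # percent; nan when nothing is retained
    ani_ab: float
    ani_ba: float
    retained_ab: int
    retained_ba: int
    fragments_ab: int
    fragments_ba: int
    reliable: bool


def _genome_seqs(genome) -> list[str]:
    if isinstance(genome, Strain):
        return [r.sequence for r in genome.replicons.values()]
    if isinstance(genome, str):
        return [genome]
    return list(genome.values())


def _fragments(seqs: Sequence[str], params: AniParams) -> list[str]:
    frags = []
    for seq in seqs:
        for i in range(0, len(seq), params.fragment_length):
            frag = seq[i : i + params.fragment_length]
            if len(frag) == params.fragment_length or len(frag) >= params.min_final_fragment:
                frags.append(frag)
    return frags


def _nt_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(mode="local")
    aligner.match_score = 2.0
    aligner.mismatch_score = -3.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -2.0
    return aligner


def _best_fragment_identity(
    frag: str,
    targets: Sequence[str],
    aligner: Align.PairwiseAligner,
    margin: int = 50,
    fast_path_min: float = 80.0,
) -> tuple[float, float]:
    """(percent identity, query coverage) of the best local match of *frag*.

    When the infix edit distance already implies an identity of at
    least *fast_path_min* percent the whole fragment clearly aligns,
    so the edit-distance identity is returned directly (coverage 1);
    weaker candidates get the full local-alignment treatment, which is
    what rejects spurious matches between unrelated sequences.
    """
    best = None  # (edit_distance, target_idx, start, end)
    for idx, target in enumerate(targets):
        res = edlib.align(frag, target, mode="HW", task="locations")
        dist = res["editDistance"]
        if dist >= 0 and (best is None or dist < best[0]):
            start, end = res["locations"][0]
            best = (dist, idx, start, end)
    if best is None:
        return 0.0, 0.0
    dist, idx, start, end = best
    est_identity = 100.0 * max(0, len(frag) - dist) / len(frag)
    if est_identity >= fast_path_min:
        return est_identity, 1.0
    target = targets[idx]
    region = target[max(0, start - margin) : min(len(target), end + 1 + margin)]
    alignments = aligner.align(frag, region)
    try:
        aln = alignments[0]
    except IndexError:
        return 0.0, 0.0
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.internal_gaps
    if columns == 0:
        return 0.0, 0.0
    q_ranges = aln.aligned[0]
    span = int(q_ranges[-1][1]) - int(q_ranges[0][0])
    return 100.0 * counts.identities / columns, span / len(frag)


def _directed_ani(
    seqs_a: Sequence[str], targets_b: Sequence[str], params: AniParams
) -> tuple[float, int, int]:
    aligner = _nt_aligner()
    frags = _fragments(seqs_a, params)
    identities = []
    for frag in frags:
        ident, cov = _best_fragment_identity(frag, targets_b, aligner)
        if ident >= params.min_fragment_identity and cov >= params.min_fragment_coverage:
            identities.append(ident)
    ani = float(np.mean(identities)) if identities else float("nan")
    return ani, len(identities), len(frags)


def ani_pair(genome_a, genome_b, params: AniParams | None = None) -> AniResult:
    """Fragment-based average nucleotide identity between two genomes.

    Genomes may be Strain objects, ``{replicon_id: seq}`` mappings or
    plain sequences.  When fewer than ``min_retained_fragments`` survive
    the retention rule in either direction the result is flagged
    unreliable but still reported.
    """
    params = params or AniParams()
    params.validate()
    seqs_a = _genome_seqs(genome_a)
    seqs_b = _genome_seqs(genome_b)
    if not any(seqs_a) or not any(seqs_b):
        raise ValueError("both genomes must be non-empty")
    targets_b = seqs_b + [str(Seq(s).reverse_complement()) for s in seqs_b]
    ani_ab, kept_ab, total_ab = _directed_ani(seqs_a, targets_b, params)
    if params.both_directions:
        targets_a = seqs_a + [str(Seq(s).reverse_complement()) for s in seqs_a]
        ani_ba, kept_ba, total_ba = _directed_ani(seqs_b, targets_a, params)
        vals = [v for v in (ani_ab, ani_ba) if not np.isnan(v)]
        ani = float(np.mean(vals)) if vals else float("nan")
    else:
        ani_ba, kept_ba, total_ba = float("nan"), 0, 0
        ani = ani_ab
    reliable = kept_ab >= params.min_retained_fragments and (
        not params.both_directions or kept_ba >= params.min_retained_fragments
    )
    return AniResult(ani, ani_ab, ani_ba, kept_ab, kept_ba, total_ab, total_ba, reliable)


@dataclass
class PocpResult:
    pocp: float
    c1: int
    c2: int
    t1: int
    t2: int


def pocp_formula(c1: int, c2: int, t1: int, t2: int) -> float:
    return 100.0 * (c1 + c2) / (t1 + t2)


def pocp_pair(
    proteome_a: Mapping[str, str],
    proteome_b: Mapping[str, str],
    max_evalue: float = 1e-5,
    min_identity: float = 40.0,
    min_query_cov: float = 0.5,
    prefilter: bool = True,
) -> PocpResult:
    """Percentage of conserved proteins between two proteomes."""
    if not proteome_a or not proteome_b:
        raise ValueError("both proteomes must be non-empty")
    kwargs = dict(
        min_identity=min_identity,
        min_query_cov=min_query_cov,
        min_bitscore=0.0,
        max_evalue=max_evalue,
        prefilter=prefilter,
    )
    hits_ab = pairwise_search(proteome_a, proteome_b, **kwargs)
    hits_ba = pairwise_search(proteome_b, proteome_a, **kwargs)
    c1 = len({h.query_id for h in hits_ab})
    c2 = len({h.query_id for h in hits_ba})
    t1, t2 = len(proteome_a), len(proteome_b)
    return PocpResult(pocp_formula(c1, c2, t1, t2), c1, c2, t1, t2)


def classify_species(ani_value: float, cutoff: float = 95.0) -> bool:
    """Conspecificity call from an ANI value (boundary inclusive)."""
    if not 0.0 <= ani_value <= 100.0:
        raise ValueError("ANI value outside [0, 100]")
    return ani_value >= cutoff


@dataclass
class PairwiseMetricMatrix:
    """Symmetric strain x strain percentage matrix with diagnostics."""

    df: pd.DataFrame
    metric: str
    diagnostics: dict[tuple[str, str], object] = field(default_factory=dict)


def panel_ani_matrix(panel, params: AniParams | None = None) -> PairwiseMetricMatrix:
    strains = sorted(panel.strains)
    n = len(strains)
    df = pd.DataFrame(np.full((n, n), 100.0), index=strains, columns=strains)
    diag: dict[tuple[str, str], AniResult] = {}
    for i in range(n):
        for j in range(i + 1, n):
            res = ani_pair(panel.strains[strains[i]], panel.strains[strains[j]], params)
            df.iloc[i, j] = df.iloc[j, i] = res.ani
            diag[(strains[i], strains[j])] = res
    return PairwiseMetricMatrix(df, "ANI", diag)


def panel_pocp_matrix(panel, **kwargs) -> PairwiseMetricMatrix:
    strains = sorted(panel.strains)
    proteomes = panel.proteomes()
    n = len(strains)
    df = pd.DataFrame(np.full((n, n), 100.0), index=strains, columns=strains)
    diag: dict[tuple[str, str], PocpResult] = {}
    for i in range(n):
        for j in range(i + 1, n):
            res = pocp_pair(proteomes[strains[i]], proteomes[strains[j]], **kwargs)
            df.iloc[i, j] = df.iloc[j, i] = res.pocp
            diag[(strains[i], strains[j])] = res
    return PairwiseMetricMatrix(df, "POCP", diag)


@dataclass
class MatrixClustering:
    linkage: np.ndarray
    leaf_order: list[str]
    newick: str


def cluster_metric_matrix(matrix) -> MatrixClustering:
    """Complete-linkage clustering of metric-matrix rows.

    Rows are treated as feature vectors under Euclidean distance, as in
    similarity-heatmap figures.  Labels are sorted lexicographically
    before clustering so that tied merges resolve deterministically.
    """
    df = matrix.df if isinstance(matrix, PairwiseMetricMatrix) else matrix
    if df.shape[0] != df.shape[1]:
        raise ValueError("metric matrix must be square")
    if df.shape[0] < 2:
        raise ValueError("need at least two strains to cluster")
    labels = sorted(str(x) for x in df.index)
    ordered = df.loc[labels, labels]
    dist = pdist(ordered.to_numpy(dtype=float), metric="euclidean")
    link = hierarchy.linkage(dist, method="complete")
    leaves = hierarchy.leaves_list(link)
    tree = hierarchy.to_tree(link)

    def to_newick(node, parent_height: float) -> str:
        length = max(0.0, parent_height - (node.dist if not node.is_leaf() else 0.0))
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = to_newick(node.left, node.dist)
        right = to_newick(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    newick = f"({to_newick(tree.left, tree.dist)},{to_newick(tree.right, tree.dist)});"
    return MatrixClustering(link, [labels[i] for i in leaves], newick)
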