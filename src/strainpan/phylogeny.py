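"""Core-gene concatenation, SNP distances and distance-based trees.

Single-copy core families (exactly one member in every strain) are
concatenated in sorted family order, aligned, stripped of every column
containing a gap, and compared by pairwise SNP counts (differing
columns).  Trees are built by neighbor joining on the SNP matrix with
bootstrap supports from column resampling; maximum-likelihood engines
can be substituted by exporting the alignment FASTA and importing any
Newick tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .orthology import OrthologFamilySet

logger = logging.getLogger(__name__)

GAP = "-"


@dataclass
class CoreAlignment:
    """Equal-length per-strain sequences, optionally gap-free.

    ``blocks`` records (family_id, start, end) half-open column spans of
    each concatenated gene; stripping gap columns invalidates them.
    """

    sequences: dict[str, str]
    blocks: list[tuple[str, int, int]] | None = None
    gap_free: bool = False
    alphabet: str = "aa"

    @property
    def is_aligned(self) -> bool:
        return len({len(s) for s in self.sequences.values()}) <= 1

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    def to_array(self) -> np.ndarray:
        if not self.is_aligned:
            raise ValueError("sequences must all have equal length")
        names = sorted(self.sequences)
        return np.array(
            [np.frombuffer(self.sequences[s].upper().encode(), dtype=np.uint8) for s in names]
        )


def concatenate_core(
    families: OrthologFamilySet,
    strains: Sequence[str],
    gene_sequences: Mapping[str, str],
    alphabet: str = "aa",
) -> CoreAlignment:
    """Concatenate single-copy core genes per strain in sorted family order.

    Families missing from any strain, or with more than one copy in any
    strain, are excluded (counted and logged, not an error).  The result
    is unaligned in general; on panels where all copies of a family have
    equal length it is already a valid alignment.
    """
    strains = list(strains)
    usable: dict[str, dict[str, str]] = {}
    excluded = 0
    for fid in sorted(families.families):
        members = families.families[fid]
        per_strain: dict[str, list[str]] = {}
        for g in members:
            per_strain.setdefault(families.gene_strain[g], []).append(g)
        if set(per_strain) != set(strains) or any(len(v) != 1 for v in per_strain.values()):
            excluded += 1
            continue
        usable[fid] = {s: gene_sequences[v[0]] for s, v in per_strain.items()}
    if excluded:
        logger.info("concatenate_core: excluded %d non-single-copy families", excluded)
    parts: dict[str, list[str]] = {s: [] for s in strains}
    blocks = []
    pos = 0
    for fid, seqs in usable.items():
        width = max(len(x) for x in seqs.values())
        blocks.append((fid, pos, pos + width))
        pos += width
        for s in strains:
            parts[s].append(seqs[s])
    concatenated = {s: "".join(parts[s]) for s in strains}
    aligned = len({len(x) for x in concatenated.values()}) <= 1
    return CoreAlignment(
        concatenated, blocks=blocks,
        gap_free=aligned and all(GAP not in s for s in concatenated.values()),
        alphabet=alphabet,
    )


AlignEngine = Callable[[dict[str, str]], dict[str, str]]


def passthrough_align(sequences: dict[str, str]) -> dict[str, str]:
    """Internal fallback aligner: valid only for equal-length inputs."""
    if len({len(s) for s in sequences.values()}) > 1:
        raise ValueError(
            "sequences have unequal lengths; use an external aligner "
            "(e.g. mafft_align) for gapped alignment"
        )
    return dict(sequences)


def mafft_align(sequences: dict[str, str]) -> dict[str, str]:
    """Align with the mafft command-line tool (must be on PATH)."""
    import subprocess
    import tempfile

    from .io import read_fasta, write_fasta

    with tempfile.TemporaryDirectory() as tmp:
        inp = f"{tmp}/in.fasta"
        write_fasta(inp, sequences)
        out = subprocess.run(
            ["mafft", "--quiet", "--auto", inp],
            check=True, capture_output=True, text=True,
        )
        outp = f"{tmp}/out.fasta"
        with open(outp, "w") as fh:
            fh.write(out.stdout)
        aligned = read_fasta(outp)
    return {name: aligned[name].upper() for name in sequences}


def align_core(alignment: CoreAlignment, engine: AlignEngine = passthrough_align) -> CoreAlignment:
    aligned = engine(alignment.sequences)
    return CoreAlignment(
        aligned,
        blocks=alignment.blocks,
        gap_free=all(GAP not in s for s in aligned.values()),
        alphabet=alignment.alphabet,
    )


def strip_gap_columns(alignment: CoreAlignment) -> CoreAlignment:
    """Keep exactly the columns where no sequence has a gap."""
    names = sorted(alignment.sequences)
    arr = alignment.to_array()
    keep = ~(arr == ord(GAP)).any(axis=0)
    stripped = arr[:, keep]
    sequences = {
        name: stripped[i].tobytes().decode() for i, name in enumerate(names)
    }
    return CoreAlignment(sequences, blocks=None, gap_free=True, alphabet=alphabet_of(alignment))


def alphabet_of(alignment: CoreAlignment) -> str:
    return alignment.alphabet


@dataclass
class SnpDistanceMatrix:
    df: pd.DataFrame  # integer counts of differing columns
    alignment_length: int


def snp_distance(alignment: CoreAlignment) -> SnpDistanceMatrix:
    """Pairwise count of differing columns (case-insensitive Hamming)."""
    if not alignment.gap_free:
        raise ValueError("SNP distances require a gap-free alignment")
    names = sorted(alignment.sequences)
    arr = alignment.to_array()
    n = len(names)
    out = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        diff = (arr[i + 1 :] != arr[i]).sum(axis=1)
        out[i, i + 1 :] = diff
        out[i + 1 :, i] = diff
    return SnpDistanceMatrix(pd.DataFrame(out, index=names, columns=names), arr.shape[1])


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def distance_tree(matrix, collapse_tol: float = 1e-12) -> TreeNode:
    """Neighbor-joining tree from a symmetric zero-diagonal matrix.

    Negative branch lengths are clamped to zero with the deficit moved
    to the sibling branch.  Internal edges of length <= *collapse_tol*
    are collapsed, so uninformative data yields a star-like tree.
    Returns an unrooted skbio TreeNode (trifurcating root).
    """
    df = matrix.df if isinstance(matrix, SnpDistanceMatrix) else matrix
    labels = [str(x) for x in df.index]
    d = df.to_numpy(dtype=float).copy()
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN entries")
    if d.shape[0] != d.shape[1] or d.shape[0] < 2:
        raise ValueError("need a square matrix over >= 2 taxa")

    nodes: list[TreeNode] = [TreeNode(name=name) for name in labels]
    if len(nodes) == 2:
        half = d[0, 1] / 2.0
        for nd in nodes:
            nd.length = half
        return TreeNode(children=nodes)

    active = list(range(len(nodes)))
    dist = d

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return li, max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = dist[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # deterministic minimum: smallest Q, ties by lexicographic label pair
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                pair_names = tuple(sorted((nodes[active[i]].name or "", nodes[active[j]].name or "")))
                key = (q[i, j], pair_names)
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = clamp(li, lj)
        ni, nj = nodes[active[i]], nodes[active[j]]
        ni.length, nj.length = li, lj
        parent = TreeNode(children=[ni, nj])
        parent.name = None
        new_dist = 0.5 * (sub[i, :] + sub[j, :] - dij)
        gi, gj = active[i], active[j]
        nodes.append(parent)
        dist = np.pad(dist, ((0, 1), (0, 1)))
        for k_local, k_global in enumerate(active):
            dist[-1, k_global] = dist[k_global, -1] = new_dist[k_local]
        dist[-1, -1] = 0.0
        active = [g for g in active if g not in (gi, gj)] + [len(nodes) - 1]

    a, b, c = active
    dab, dac, dbc = dist[a, b], dist[a, c], dist[b, c]
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    for idx, length in zip((a, b, c), (la, lb, lc)):
        nodes[idx].length = max(0.0, length)
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])

    # collapse uninformative internal edges
    for node in list(root.non_tips(include_self=False)):
        if node.length is not None and node.length <= collapse_tol:
            parent = node.parent
            for child in list(node.children):
                node.remove(child)
                parent.append(child)
            parent.remove(node)
    return root


def bipartitions(tree: TreeNode) -> set[frozenset[frozenset[str]]]:
    """Unrooted bipartition set induced by the internal edges."""
    taxa = frozenset(t.name for t in tree.tips())
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = taxa - side
        if len(side) >= 2 and len(other) >= 2:
            parts.add(frozenset({side, other}))
    return parts


@dataclass
class SupportTree:
    """A tree with bootstrap supports on its internal bipartitions."""

    tree: TreeNode
    supports: dict[frozenset[frozenset[str]], float] = field(default_factory=dict)
    n_replicates: int = 0
    root_taxon: str | None = None

    def newick(self) -> str:
        return str(self.tree)

    def annotate_supports(self) -> None:
        """Write integer supports into internal node names for Newick export."""
        for node in self.tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            taxa = frozenset(t.name for t in self.tree.tips())
            key = frozenset({side, taxa - side})
            if key in self.supports:
                node.name = str(int(round(self.supports[key])))


def bootstrap_tree(
    alignment: CoreAlignment, n_replicates: int = 100, seed: int | None = None
) -> SupportTree:
    """Column-resampling bootstrap of the NJ tree.

    The full-data tree is built from SNP distances; each replicate
    resamples alignment columns with replacement and rebuilds the tree;
    supports are the percentage of replicates whose bipartition set
    contains each internal bipartition of the full-data tree.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if not alignment.gap_free:
        raise ValueError("bootstrap requires a gap-free alignment")
    if len(alignment.sequences) < 4:
        raise ValueError("bootstrap supports need >= 4 taxa")
    names = sorted(alignment.sequences)
    arr = alignment.to_array()
    full = distance_tree(snp_distance(alignment))
    target = bipartitions(full)
    counts = {key: 0 for key in target}
    rng = np.random.default_rng(seed)
    ncols = arr.shape[1]
    for _ in range(n_replicates):
        cols = rng.integers(0, ncols, size=ncols)
        sample = arr[:, cols]
        reps = {
            name: sample[i].tobytes().decode() for i, name in enumerate(names)
        }
        rep_tree = distance_tree(snp_distance(CoreAlignment(reps, gap_free=True)))
        rep_parts = bipartitions(rep_tree)
        for key in target:
            if key in rep_parts:
                counts[key] += 1
    supports = {key: 100.0 * c / n_replicates for key, c in counts.items()}
    result = SupportTree(full, supports, n_replicates)
    result.annotate_supports()
    return result


def root_tree(
    support_tree: SupportTree, outgroup: str, display_shorten: bool = False
) -> SupportTree:
    """Root on the outgroup's pendant edge (split at its midpoint).

    ``display_shorten`` flags that plots may draw the root branch
    shorter; Newick branch lengths are never altered.
    """
    tree = support_tree.tree.copy()
    try:
        tip = tree.find(outgroup)
    except Exception as exc:
        raise ValueError(f"unknown outgroup {outgroup!r}") from exc
    if not tip.is_tip():
        raise ValueError(f"outgroup {outgroup!r} is not a leaf")
    rooted = tree.root_at(tip, above=True, branch_attrs=[])
    out = SupportTree(
        rooted, dict(support_tree.supports), support_tree.n_replicates, outgroup
    )
    out.annotate_supports()
    if display_shorten:
        rooted.display_shortened_root = True
    return out
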