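"""Gene-call reconciliation and thresholded best-hit annotation transfer.

Prokaryotic gene predictors usually agree on the stop codon of a gene
but disagree on the start.  Reconciliation therefore treats calls that
share a strand and a stop-side coordinate as the same gene and keeps
the longest extent; calls reported by a single predictor are retained
to minimise false-negative predictions.

Annotation transfer assigns each gene the label of its best-scoring
reference hit passing identity >= 40%, query coverage >= 50% and bit
score >= 60 (all configurable).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .model import GeneModel
from .search import best_hits, pairwise_search


@dataclass(frozen=True)
class GeneCall:
    replicon_id: str
    start: int       # 1-based inclusive
    end: int
    strand: str


@dataclass
class GeneCallSet:
    """Output of one gene predictor on one genome."""

    predictor_id: str
    calls: list[GeneCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.calls)) != len(self.calls):
            raise ValueError(
                f"predictor {self.predictor_id!r} contains duplicate calls"
            )


def _stop_coord(call: GeneCall) -> int:
    """3' (stop-side) coordinate: end on '+', start on '-'."""
    return call.end if call.strand == "+" else call.start


def reconcile_gene_calls(
    callsets: Sequence[GeneCallSet],
    replicon_lengths: Mapping[str, int] | None = None,
) -> list[GeneCall]:
    """Merge predictor outputs into one non-redundant call set.

    Calls sharing strand and stop coordinate are merged into a single
    call spanning the longest extent; single-predictor calls are kept.
    Output is sorted by replicon then start.
    """
    if not callsets:
        raise ValueError("at least one callset is required")
    merged: dict[tuple[str, str, int], GeneCall] = {}
    for cs in callsets:
        for call in cs.calls:
            if call.start < 1 or call.start > call.end:
                raise ValueError(f"invalid call coordinates {call}")
            if replicon_lengths is not None:
                limit = replicon_lengths.get(call.replicon_id)
                if limit is not None and call.end > limit:
                    raise ValueError(
                        f"call {call} exceeds replicon "
                        f"{call.replicon_id!r} length {limit}"
                    )
            key = (call.replicon_id, call.strand, _stop_coord(call))
            cur = merged.get(key)
            if cur is None:
                merged[key] = call
            elif call.strand == "+" and call.start < cur.start:
                merged[key] = call
            elif call.strand == "-" and call.end > cur.end:
                merged[key] = call
    return sorted(merged.values(), key=lambda c: (c.replicon_id, c.start, c.end))


def transfer_annotation(
    genes: Sequence[GeneModel],
    reference: Mapping[str, tuple[str, str]],
    scheme: str = "annotation",
    min_identity: float = 40.0,
    min_query_cov: float = 0.5,
    min_bitscore: float = 60.0,
    prefilter: bool = True,
) -> list[GeneModel]:
    """Label genes from a reference set of ``{ref_id: (label, protein)}``.

    Each gene receives the label of its best-scoring reference hit
    passing all thresholds (best = highest bit score, ties broken by
    identity then reference id), or no label.  Labels are written into
    ``gene.labels[scheme]`` in place; the gene list is returned for
    chaining.
    """
    if not reference:
        raise ValueError("reference protein set is empty")
    queries = {g.gene_id: g.protein for g in genes}
    if not queries:
        return list(genes)
    subjects = {rid: seq for rid, (label, seq) in reference.items()}
    hits = pairwise_search(
        queries,
        subjects,
        min_identity=min_identity,
        min_query_cov=min_query_cov,
        min_bitscore=min_bitscore,
        prefilter=prefilter,
    )
    best = best_hits(hits)
    by_id = {g.gene_id: g for g in genes}
    for qid, hit in best.items():
        label = reference[hit.subject_id][0]
        by_id[qid].labels[scheme] = (label, hit.bit_score)
    return list(genes)


_LPXTG = re.compile(r"LP.TG")


def scan_lpxtg(protein: str, window: int = 50) -> tuple[bool, int | None]:
    """Scan for a C-terminal LPXTG cell-wall sorting motif.

    Returns ``(hit, position)`` where position is the 0-based start of
    the motif.  A hit requires the whole motif to lie within the final
    *window* residues; sortase substrates carry the signal close to the
    C-terminus, so matches elsewhere are ignored.
    """
    if not protein:
        raise ValueError("empty protein sequence")
    tail_start = max(0, len(protein) - window)
    m = _LPXTG.search(protein, tail_start)
    if m is None:
        return False, None
    return True, m.start()
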