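"""Protein similarity search: seeded Smith-Waterman with bit scores.

The engine performs local alignment with BLOSUM62, gap open 11 /
extend 1, and converts raw scores to bit scores with the standard
gapped Karlin-Altschul constants for that scoring system
(lambda = 0.267, K = 0.041).  E-values use database size = total
subject residues; only bit score, percent identity and query coverage
gate hits.

A BLAST-style k-mer seed prefilter (k = 5, two shared seeds by default)
restricts which query/subject pairs are aligned; ``prefilter=False``
aligns every pair exhaustively and is used as the oracle in tests.
Exact-match seeding loses sensitivity below roughly 50% identity;
searches hunting weaker homology should disable the prefilter.
An external search engine can be substituted by producing
:class:`SimilarityHit` records from its tabular output.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping

from Bio import Align
from Bio.Align import substitution_matrices

from .model import check_proteome

# gapped Karlin-Altschul parameters for BLOSUM62, open 11 / extend 1
_LAMBDA = 0.267
_K = 0.041
_LN2 = math.log(2.0)

_PROTEIN_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX"


@dataclass(frozen=True)
class SimilarityHit:
    """One qualifying local alignment between a query and a subject."""

    query_id: str
    subject_id: str
    percent_identity: float      # [0, 100]
    alignment_length: int        # columns, gaps included
    query_coverage: float        # aligned span / query length, [0, 1]
    bit_score: float
    e_value: float
    mismatches: int = 0
    gap_opens: int = 0
    query_start: int = 0         # 1-based
    query_end: int = 0
    subject_start: int = 0
    subject_end: int = 0

    def __post_init__(self) -> None:
        if self.alignment_length < 1:
            raise ValueError("alignment_length must be >= 1")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("percent_identity outside [0, 100]")
        if not 0.0 <= self.query_coverage <= 1.0 + 1e-9:
            raise ValueError("query_coverage outside [0, 1]")


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(mode="local")
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def bit_score(raw_score: float) -> float:
    """Karlin-Altschul bit scaling of a raw alignment score."""
    return (_LAMBDA * raw_score - math.log(_K)) / _LN2


def e_value(bits: float, query_len: int, db_residues: int) -> float:
    return query_len * db_residues * 2.0 ** (-bits)


def _seed_index(subjects: Mapping[str, str], k: int) -> dict[str, list[str]]:
    index: dict[str, list[str]] = {}
    for sid, seq in subjects.items():
        for kmer in {seq[i : i + k] for i in range(len(seq) - k + 1)}:
            index.setdefault(kmer, []).append(sid)
    return index


def _candidates(query: str, index: dict[str, list[str]], k: int, min_hits: int) -> list[str]:
    counts: Counter[str] = Counter()
    for kmer in {query[i : i + k] for i in range(len(query) - k + 1)}:
        for sid in index.get(kmer, ()):
            counts[sid] += 1
    return [sid for sid, c in counts.items() if c >= min_hits]


def align_pair(
    aligner: Align.PairwiseAligner,
    query_id: str,
    query: str,
    subject_id: str,
    subject: str,
    db_residues: int,
) -> SimilarityHit | None:
    """Best local alignment of one pair as a SimilarityHit (no thresholds)."""
    alignments = aligner.align(query, subject)
    try:
        aln = alignments[0]
    except IndexError:
        return None
    counts = aln.counts()
    identities = counts.identities
    mismatches = counts.mismatches
    gaps = counts.internal_gaps
    length = identities + mismatches + gaps
    if length == 0:
        return None
    q_ranges, s_ranges = aln.aligned
    qstart, qend = int(q_ranges[0][0]), int(q_ranges[-1][1])
    sstart, send = int(s_ranges[0][0]), int(s_ranges[-1][1])
    bits = bit_score(aln.score)
    gap_opens = (
        counts.open_internal_insertions + counts.open_internal_deletions
    )
    return SimilarityHit(
        query_id=query_id,
        subject_id=subject_id,
        percent_identity=100.0 * identities / length,
        alignment_length=length,
        query_coverage=(qend - qstart) / len(query),
        bit_score=bits,
        e_value=e_value(bits, len(query), db_residues),
        mismatches=mismatches,
        gap_opens=gap_opens,
        query_start=qstart + 1,
        query_end=qend,
        subject_start=sstart + 1,
        subject_end=send,
    )


def pairwise_search(
    queries: Mapping[str, str],
    subjects: Mapping[str, str],
    min_identity: float = 40.0,
    min_query_cov: float = 0.5,
    min_bitscore: float = 50.0,
    max_evalue: float | None = None,
    prefilter: bool = True,
    seed_k: int = 5,
    min_seed_hits: int = 2,
) -> list[SimilarityHit]:
    """Search every query against a subject proteome.

    Returns at most one hit per (query, subject) pair: the best local
    alignment, kept only if it passes all of the identity / coverage /
    bit-score (and optional e-value) thresholds.  Deterministic for
    fixed inputs; hits are ordered by query id then descending bit
    score.
    """
    if not queries or not subjects:
        raise ValueError("both proteomes must be non-empty")
    check_proteome(queries, _PROTEIN_ALPHABET)
    check_proteome(subjects, _PROTEIN_ALPHABET)
    aligner = _make_aligner()
    db_residues = sum(len(s) for s in subjects.values())
    index = _seed_index(subjects, seed_k) if prefilter else None
    # raw score needed for the bit threshold, inverted once
    min_raw = (min_bitscore * _LN2 + math.log(_K)) / _LAMBDA

    hits: list[SimilarityHit] = []
    for qid in sorted(queries):
        qseq = queries[qid]
        if index is not None:
            subject_ids = sorted(_candidates(qseq, index, seed_k, min_seed_hits))
        else:
            subject_ids = sorted(subjects)
        per_query: list[SimilarityHit] = []
        for sid in subject_ids:
            sseq = subjects[sid]
            if aligner.score(qseq, sseq) < min_raw:
                continue
            hit = align_pair(aligner, qid, qseq, sid, sseq, db_residues)
            if hit is None:
                continue
            if hit.percent_identity < min_identity:
                continue
            if hit.query_coverage < min_query_cov:
                continue
            if hit.bit_score < min_bitscore:
                continue
            if max_evalue is not None and hit.e_value > max_evalue:
                continue
            per_query.append(hit)
        per_query.sort(key=lambda h: (-h.bit_score, -h.percent_identity, h.subject_id))
        hits.extend(per_query)
    return hits


def best_hits(hits: list[SimilarityHit]) -> dict[str, SimilarityHit]:
    """Unique best subject per query.

    Best = highest bit score; ties broken by higher identity, then
    lexicographically smallest subject id, so the winner is always
    unique.
    """
    best: dict[str, SimilarityHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None:
            best[h.query_id] = h
            continue
        key = (-h.bit_score, -h.percent_identity, h.subject_id)
        cur_key = (-cur.bit_score, -cur.percent_identity, cur.subject_id)
        if key < cur_key:
            best[h.query_id] = h
    return best
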