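"""File-format helpers: FASTA, GFF3, tabular hit files and matrices."""

from __future__ import annotations

from typing import Iterable

import pandas as pd
from Bio import SeqIO

#: column layout of the de facto 12-column tabular similarity-search format
HIT_COLUMNS = [
    "query", "subject", "identity", "length", "mismatches", "gapopens",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_fasta(path: str, with_description: bool = False):
    """Read FASTA into ``{id: seq}`` (or ``{id: (description, seq)}``)."""
    out = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA record id {rec.id!r} in {path}")
        if with_description:
            desc = rec.description[len(rec.id):].strip()
            out[rec.id] = (desc, str(rec.seq))
        else:
            out[rec.id] = str(rec.seq)
    return out


def write_fasta(path: str, records: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for rid, seq in records.items():
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_gff3_genes(path: str) -> list[tuple[str, str, int, int, str]]:
    """Yield (gene_id, replicon_id, start, end, strand) from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    out = []
    for feat in db.all_features(order_by=("seqid", "start")):
        gid = feat.attributes.get("ID", [feat.id])[0]
        out.append((gid, feat.seqid, feat.start, feat.end, feat.strand))
    return out


def read_labelled_fasta(path: str) -> dict[str, tuple[str, str]]:
    """FASTA with ``label=...`` in the description -> ``{id: (label, seq)}``."""
    out = {}
    for rid, (desc, seq) in read_fasta(path, with_description=True).items():
        label = rid
        for token in desc.split():
            if token.startswith("label="):
                label = token[len("label="):]
        out[rid] = (label, seq)
    return out


def write_hit_table(path: str, hits: Iterable) -> None:
    """Write SimilarityHit records in the 12-column tabular format."""
    rows = [
        [
            h.query_id, h.subject_id, f"{h.percent_identity:.2f}", h.alignment_length,
            h.mismatches, h.gap_opens, h.query_start, h.query_end,
            h.subject_start, h.subject_end, f"{h.e_value:.2e}", f"{h.bit_score:.1f}",
        ]
        for h in hits
    ]
    pd.DataFrame(rows, columns=HIT_COLUMNS).to_csv(path, sep="\t", index=False, header=False)


def read_hit_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", names=HIT_COLUMNS)


def write_matrix_tsv(path: str, matrix: pd.DataFrame, float_format: str = "%.2f") -> None:
    matrix.to_csv(path, sep="\t", float_format=float_format)


def read_matrix_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
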