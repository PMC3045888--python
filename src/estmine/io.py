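"""Standard-format I/O: FASTA/FASTQ reads, TSV tables, truth/manifest JSON.

Sequence formats go through Biopython; tabular formats through pandas.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .preprocess import EstRead, SimilarityHit

_HIT_COLUMNS = [
    "query_id", "subject_id", "pct_identity", "align_length", "mismatches",
    "gapopens", "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def _to_record(read: EstRead) -> SeqRecord:
    rec = SeqRecord(Seq(read.sequence), id=read.read_id, description="")
    if read.qualities is not None:
        rec.letter_annotations["phred_quality"] = list(read.qualities)
    return rec


def write_reads(reads, path, fmt: str | None = None) -> None:
    """Write reads as FASTA, or FASTQ when qualities are present (or forced)."""
    path = Path(path)
    if fmt is None:
        fmt = "fastq" if any(r.qualities is not None for r in reads) else "fasta"
    SeqIO.write((_to_record(r) for r in reads), path, fmt)


def read_reads(path, library_table: dict | None = None, fmt: str | None = None):
    """Read FASTA/FASTQ into EstRead objects; library ids come from
    ``library_table`` (read_id -> library_id), defaulting to 'unknown'."""
    path = Path(path)
    if fmt is None:
        fmt = "fastq" if path.suffix in (".fq", ".fastq") else "fasta"
    library_table = library_table or {}
    reads = []
    for rec in SeqIO.parse(path, fmt):
        reads.append(
            EstRead(
                read_id=rec.id,
                library_id=library_table.get(rec.id, "unknown"),
                sequence=str(rec.seq).upper(),
                qualities=rec.letter_annotations.get("phred_quality"),
            )
        )
    return reads


def write_library_table(reads, designs, path) -> None:
    """TSV of read_id, library_id, condition."""
    cond = {d.library_id: d.condition for d in designs}
    df = pd.DataFrame(
        {
            "read_id": [r.read_id for r in reads],
            "library_id": [r.library_id for r in reads],
            "condition": [cond.get(r.library_id, "unknown") for r in reads],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_library_table(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["read_id"], df["library_id"]))


def read_hit_table(path):
    """12-column tabular similarity hits -> list of SimilarityHit."""
    df = pd.read_csv(path, sep="\t", header=None, names=_HIT_COLUMNS)
    return [
        SimilarityHit(
            query_id=str(r.query_id),
            subject_id=str(r.subject_id),
            pct_identity=float(r.pct_identity),
            align_length=int(r.align_length),
            evalue=float(r.evalue),
            bitscore=float(r.bitscore),
        )
        for r in df.itertuples()
    ]


def write_hit_table(hits, path) -> None:
    rows = [
        [h.query_id, h.subject_id, h.pct_identity, h.align_length,
         0, 0, 1, h.align_length, 1, h.align_length, h.evalue, h.bitscore]
        for h in hits
    ]
    pd.DataFrame(rows, columns=_HIT_COLUMNS).to_csv(
        path, sep="\t", index=False, header=False
    )


def write_contig_fasta(contigs, path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(c.consensus), id=c.contig_id, description="") for c in contigs),
        Path(path), "fasta",
    )


def write_membership(contigs, path) -> None:
    rows = [
        (m.read_id, c.contig_id, m.offset, m.strand)
        for c in contigs for m in c.members
    ]
    pd.DataFrame(rows, columns=["read_id", "contig_id", "offset", "strand"]).to_csv(
        path, sep="\t", index=False
    )


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    import numpy as np

    if isinstance(o, (set, frozenset)):
        return sorted(o)
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def write_snp_table(results, contigs, path) -> None:
    """VCF-like TSV of SNP calls (1-based positions, consensus base as ref)."""
    by_id = {c.contig_id: c for c in contigs}
    rows = []
    for res in results:
        for call in res.calls:
            ordered = sorted(call.alleles.items(), key=lambda kv: (-kv[1], kv[0]))
            ref = call.ref_allele
            alts = ",".join(b for b, _ in ordered if b != ref)
            support = ";".join(f"{b}:{s}" for b, s in ordered)
            rows.append(
                (call.contig_id, call.position + 1, ref, alts, support,
                 call.allelic_class, call.mutation_class, call.synonymy,
                 round(call.confidence, 4))
            )
    pd.DataFrame(
        rows,
        columns=["contig", "pos", "ref", "alt", "support",
                 "allelic_class", "mutation_class", "synonymy", "confidence"],
    ).to_csv(path, sep="\t", index=False)
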