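"""Intron catalog construction from genome + annotation.

Enumerates the inter-exon gaps of every transcript, stores each intron in
transcript orientation (so the donor site is always the 5' end of the stored
sequence), and assigns ranks 1..n along the transcript.  Coordinates are
0-based half-open internally; GTF input (1-based inclusive) is converted on
read and BED output keeps the half-open convention.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "IntronRecord",
    "extract_introns",
    "terminal_dinucleotides",
    "intron_rank_distance",
    "deduplicate_catalog",
    "write_catalog_tsv",
    "read_catalog_tsv",
    "write_catalog_bed",
]

CATALOG_COLUMNS = [
    "intron_id",
    "gene_id",
    "transcript_id",
    "chrom",
    "start",
    "end",
    "strand",
    "rank",
    "sequence",
    "donor_dinuc",
    "acceptor_dinuc",
]


@dataclass(frozen=True)
class IntronRecord:
    """One intron of one transcript, sequence stored 5'->3' of the transcript."""

    intron_id: str
    gene_id: str
    transcript_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str
    rank: int
    sequence: str
    donor_dinuc: str
    acceptor_dinuc: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.intron_id}: end must exceed start")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.intron_id}: strand must be + or -")
        if self.rank < 1:
            raise ValueError(f"{self.intron_id}: rank must be >= 1")
        if len(self.sequence) != self.end - self.start:
            raise ValueError(f"{self.intron_id}: sequence length != end - start")

    @property
    def length(self) -> int:
        return self.end - self.start


def terminal_dinucleotides(intron: "IntronRecord | str") -> tuple[str, str]:
    """Donor and acceptor terminal 2-mers of an intron sequence, uppercased.

    The donor dinucleotide distinguishes the canonical pairs of the two intron
    classes (GT...AG for U2 and U12-GTAG, AT...AC for U12-ATAC).
    """
    seq = intron.sequence if isinstance(intron, IntronRecord) else intron
    seq = seq.upper()
    if len(seq) < 4:
        raise ValueError("intron sequence shorter than 4 nt has no distinct termini")
    return seq[:2], seq[-2:]


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    if isinstance(genome, Mapping):
        if chrom not in genome:
            raise KeyError(f"chromosome {chrom!r} missing from genome")
        return str(genome[chrom][start:end]).upper()
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} missing from genome")
    return str(genome[chrom][start:end]).upper()


def _open_genome(genome):
    if isinstance(genome, (str, os.PathLike)):
        import pyfaidx

        return pyfaidx.Fasta(str(genome))
    return genome


def _exons_by_transcript(annotation) -> dict[tuple[str, str], list]:
    """Group exon features by (gene_id, transcript_id) via gffutils."""
    import gffutils

    from_string = isinstance(annotation, str) and "\t" in annotation
    if from_string or isinstance(annotation, (str, os.PathLike)):
        db = gffutils.create_db(
            str(annotation),
            from_string=from_string,
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    else:
        db = annotation
    groups: dict[tuple[str, str], list] = {}
    for feat in db.features_of_type("exon"):
        gene_id = feat.attributes.get("gene_id", [None])[0]
        tx_id = feat.attributes.get("transcript_id", [None])[0]
        if gene_id is None or tx_id is None:
            raise ValueError(f"exon at {feat.seqid}:{feat.start} lacks gene_id/transcript_id")
        groups.setdefault((gene_id, tx_id), []).append(feat)
    return groups


def extract_introns(genome, annotation) -> list[IntronRecord]:
    """Enumerate introns for every multi-exon transcript in the annotation.

    Parameters
    ----------
    genome
        FASTA path, pyfaidx.Fasta, or mapping chrom -> sequence string.
    annotation
        GTF path (attributes must carry ``gene_id`` and ``transcript_id``)
        or an open gffutils database.

    Single-exon transcripts contribute no introns.  Overlapping exons within
    one transcript raise; a missing chromosome raises naming it.
    """
    fasta = _open_genome(genome)
    records: list[IntronRecord] = []
    for (gene_id, tx_id), exons in sorted(_exons_by_transcript(annotation).items()):
        exons = sorted(exons, key=lambda f: f.start)
        chrom = exons[0].seqid
        strand = exons[0].strand
        # gffutils keeps GTF 1-based inclusive coordinates: convert.
        spans = [(f.start - 1, f.end) for f in exons]
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping exons in transcript {tx_id}")
        gaps = [(e1, s2) for (s1, e1), (s2, e2) in zip(spans, spans[1:])]
        if strand == "-":
            gaps = gaps[::-1]  # rank 1 is the transcript-5'-most intron
        for rank, (gstart, gend) in enumerate(gaps, start=1):
            raw = _fetch(fasta, chrom, gstart, gend)
            seq = str(Seq(raw).reverse_complement()) if strand == "-" else raw
            donor, acceptor = seq[:2], seq[-2:]
            records.append(
                IntronRecord(
                    intron_id=f"{tx_id}.i{rank}",
                    gene_id=gene_id,
                    transcript_id=tx_id,
                    chrom=chrom,
                    start=gstart,
                    end=gend,
                    strand=strand,
                    rank=rank,
                    sequence=seq,
                    donor_dinuc=donor,
                    acceptor_dinuc=acceptor,
                )
            )
    return records


def deduplicate_catalog(catalog: Sequence[IntronRecord]) -> list[IntronRecord]:
    """One record per distinct genomic intron per gene (first transcript wins).

    Classification operates on deduplicated introns; per-transcript ranks are
    retained on the original catalog for gene-level adjacency distances.
    """
    seen: set[tuple] = set()
    out = []
    for rec in catalog:
        key = (rec.gene_id, rec.chrom, rec.start, rec.end, rec.strand)
        if key not in seen:
            seen.add(key)
            out.append(rec)
    return out


def intron_rank_distance(
    catalog: Sequence[IntronRecord], query: str, targets: Iterable[str]
) -> int | None:
    """Minimum rank separation between ``query`` and any target in the same gene.

    Distance 1 means the query intron sits immediately upstream or downstream
    of a target intron along the transcript.  Returns None when no target
    shares the query's gene.  Ranks of all transcript copies of an intron are
    considered, and the minimum over all rank pairs is taken (gene-level
    distance).
    """
    by_id: dict[str, list[IntronRecord]] = {}
    for rec in catalog:
        by_id.setdefault(rec.intron_id, []).append(rec)
    if query not in by_id:
        raise KeyError(f"unknown intron_id {query!r}")
    targets = set(targets)
    for t in targets:
        if t not in by_id:
            raise KeyError(f"unknown intron_id {t!r}")
    best: int | None = None
    for q in by_id[query]:
        for t in targets:
            for trec in by_id[t]:
                if trec.gene_id != q.gene_id:
                    continue
                d = abs(q.rank - trec.rank)
                if best is None or d < best:
                    best = d
    return best


def catalog_to_frame(catalog: Sequence[IntronRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{c: getattr(rec, c) for c in CATALOG_COLUMNS} for rec in catalog],
        columns=CATALOG_COLUMNS,
    )


def write_catalog_tsv(catalog: Sequence[IntronRecord], path) -> None:
    catalog_to_frame(catalog).to_csv(path, sep="\t", index=False)


def read_catalog_tsv(path) -> list[IntronRecord]:
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in ("intron_id", "gene_id", "transcript_id", "chrom")})
    return [
        IntronRecord(
            intron_id=row.intron_id,
            gene_id=row.gene_id,
            transcript_id=row.transcript_id,
            chrom=row.chrom,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            rank=int(row.rank),
            sequence=row.sequence,
            donor_dinuc=row.donor_dinuc,
            acceptor_dinuc=row.acceptor_dinuc,
        )
        for row in df.itertuples()
    ]


def write_catalog_bed(catalog: Sequence[IntronRecord], path) -> None:
    """BED6, name = intron_id, score = 0."""
    with open(path, "w") as fh:
        for rec in catalog:
            fh.write(
                f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.intron_id}\t0\t{rec.strand}\n"
            )
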