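"""Sequence, annotation and table ingestion.

Transcripts are represented in transcript (spliced, sense-strand) coordinates
as a contiguous partition 5'UTR | CDS | 3'UTR, using 0-based half-open
intervals.  GTF/GFF3 input uses 1-based inclusive genomic coordinates and is
converted on the way in/out.  The stop codon is considered part of the CDS
span (Ensembl convention), so GTF ``stop_codon`` features are merged into the
CDS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript with region-resolved, sense-oriented sequence."""

    transcript_id: str
    gene_id: str
    sequence: str
    utr5_span: tuple[int, int]
    cds_span: tuple[int, int]
    utr3_span: tuple[int, int]

    def __post_init__(self) -> None:
        u5, cds, u3 = self.utr5_span, self.cds_span, self.utr3_span
        if not (u5[0] == 0 and u5[1] == cds[0] and cds[1] == u3[0]
                and u3[1] == len(self.sequence)):
            raise ValueError(
                f"{self.transcript_id}: spans {u5}/{cds}/{u3} do not form a "
                f"contiguous partition of a length-{len(self.sequence)} sequence")

    @property
    def utr5(self) -> str:
        return self.sequence[self.utr5_span[0]:self.utr5_span[1]]

    @property
    def cds(self) -> str:
        return self.sequence[self.cds_span[0]:self.cds_span[1]]

    @property
    def utr3(self) -> str:
        return self.sequence[self.utr3_span[0]:self.utr3_span[1]]

    @property
    def cds_frame_ok(self) -> bool:
        """Whether the CDS is non-empty and in frame (admissible to codon analyses)."""
        n = self.cds_span[1] - self.cds_span[0]
        return n > 0 and n % 3 == 0


@dataclass
class TranscriptModel:
    """Genomic structure of one transcript plus its transcript-space spans."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]          # genomic, 0-based half-open, sorted
    cds_segments: list[tuple[int, int]]   # genomic, 0-based half-open, sorted
    utr5_span: tuple[int, int] = (0, 0)   # transcript coordinates
    cds_span: tuple[int, int] = (0, 0)
    utr3_span: tuple[int, int] = (0, 0)
    cds_frame_ok: bool = True

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def to_transcript_coord(self, gpos: int) -> int:
        """Map a genomic base to its sense-strand transcript offset."""
        if self.strand == "+":
            off = 0
            for s, e in self.exons:
                if s <= gpos < e:
                    return off + (gpos - s)
                off += e - s
        else:
            off = 0
            for s, e in reversed(self.exons):
                if s <= gpos < e:
                    return off + (e - 1 - gpos)
                off += e - s
        raise ValueError(f"genomic position {gpos} not exonic in {self.transcript_id}")

    def genomic_segments(self, t_start: int, t_end: int
                         ) -> list[tuple[int, int]]:
        """Map a transcript-coordinate interval back to genomic segments."""
        segs: list[tuple[int, int]] = []
        off = 0
        exons = self.exons if self.strand == "+" else list(reversed(self.exons))
        for s, e in exons:
            n = e - s
            lo, hi = max(t_start - off, 0), min(t_end - off, n)
            if lo < hi:
                if self.strand == "+":
                    segs.append((s + lo, s + hi))
                else:
                    segs.append((e - hi, e - lo))
            off += n
        return sorted(segs)

    def resolve_spans(self) -> None:
        """Lift CDS genomic segments to transcript coordinates and derive UTRs."""
        total = self.length
        if not self.cds_segments:
            self.utr5_span, self.cds_span, self.utr3_span = (0, 0), (0, 0), (0, total)
            return
        if self.strand == "+":
            first = min(s for s, _ in self.cds_segments)
            last = max(e for _, e in self.cds_segments) - 1
        else:
            first = max(e for _, e in self.cds_segments) - 1
            last = min(s for s, _ in self.cds_segments)
        t_start = self.to_transcript_coord(first)
        t_end = self.to_transcript_coord(last) + 1
        cds_len = sum(e - s for s, e in self.cds_segments)
        if t_end - t_start != cds_len:
            raise AnnotationError(
                f"{self.transcript_id}: CDS not contiguous in transcript space")
        self.cds_frame_ok = cds_len % 3 == 0
        self.utr5_span = (0, t_start)
        self.cds_span = (t_start, t_end)
        self.utr3_span = (t_end, total)


@dataclass
class AnnotationSet:
    """gene_id -> transcript structures; one entry per transcript."""

    genes: dict[str, list[TranscriptModel]] = field(default_factory=dict)

    def add(self, tx: TranscriptModel) -> None:
        if any(t.transcript_id == tx.transcript_id
               for txs in self.genes.values() for t in txs):
            raise AnnotationError(f"duplicate transcript id {tx.transcript_id}")
        self.genes.setdefault(tx.gene_id, []).append(tx)

    def transcripts(self) -> Iterable[TranscriptModel]:
        for txs in self.genes.values():
            yield from txs

    def __len__(self) -> int:
        return sum(len(v) for v in self.genes.values())


def read_transcript_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a transcript FASTA into an ordered list of (id, uppercase sequence).

    Duplicate ids, empty files and non-ACGTN characters are hard errors; the
    latter is reported with the offending file line.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate transcript id {rec.id}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_BASES
        if bad:
            raise ValueError(
                f"non-IUPAC character {sorted(bad)[0]!r} in record {rec.id} "
                f"(line {_locate_bad_line(path, bad)})")
        records.append((rec.id, seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def _locate_bad_line(path: Path, bad: set[str]) -> int:
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if line.startswith(">"):
                continue
            if set(line.strip().upper()) & bad:
                return i
    return -1


def read_annotation(path: str | Path, dialect: str = "gtf") -> AnnotationSet:
    """Parse a GTF or GFF3 file into sense-oriented transcript structures.

    Exon and CDS features are assembled per transcript; ``stop_codon``
    features (GTF) are merged into the CDS.  Transcripts whose CDS length is
    not divisible by 3 are flagged (``cds_frame_ok``), not rejected.
    """
    if dialect not in ("gtf", "gff3"):
        raise ValueError(f"dialect must be 'gtf' or 'gff3', got {dialect!r}")
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", disable_infer_genes=True,
        disable_infer_transcripts=True)

    exons: dict[str, dict] = {}
    cdss: dict[str, list[tuple[int, int]]] = {}
    tx_gene: dict[str, str] = {}

    if dialect == "gff3":
        # resolve gene linkage through mRNA/transcript parents
        for f in db.all_features():
            if f.featuretype in ("mRNA", "transcript"):
                tid = f.attributes.get("ID", [None])[0]
                gid = f.attributes.get("Parent", [None])[0]
                if tid is not None and gid is not None:
                    tx_gene[tid] = gid

    for f in db.all_features():
        if f.featuretype not in ("exon", "CDS", "stop_codon"):
            continue
        if dialect == "gtf":
            tids = f.attributes.get("transcript_id", [])
            gids = f.attributes.get("gene_id", [])
            if not gids:
                raise AnnotationError(f"feature at {f.seqid}:{f.start} missing gene_id")
            if not tids:
                raise AnnotationError(
                    f"feature at {f.seqid}:{f.start} missing transcript_id")
            tid, gid = tids[0], gids[0]
        else:
            tids = f.attributes.get("Parent", [])
            if not tids:
                raise AnnotationError(f"feature at {f.seqid}:{f.start} missing Parent")
            tid = tids[0]
            gid = tx_gene.get(tid)
            if gid is None:
                raise AnnotationError(f"transcript {tid} missing gene_id linkage")
        tx_gene[tid] = gid
        iv = (f.start - 1, f.end)  # 1-based inclusive -> 0-based half-open
        if f.featuretype == "exon":
            ex = exons.setdefault(tid, {"chrom": f.seqid, "strand": f.strand,
                                        "ivs": []})
            ex["ivs"].append(iv)
        else:
            cdss.setdefault(tid, []).append(iv)

    ann = AnnotationSet()
    for tid, ex in sorted(exons.items()):
        segs = _merge_intervals(cdss.get(tid, []))
        tx = TranscriptModel(
            transcript_id=tid, gene_id=tx_gene[tid], chrom=ex["chrom"],
            strand=ex["strand"], exons=sorted(ex["ivs"]), cds_segments=segs)
        tx.resolve_spans()
        if not tx.cds_frame_ok:
            warnings.warn(f"transcript {tid}: CDS length not divisible by 3; "
                          "flagged for exclusion from codon analyses")
        ann.add(tx)
    return ann


def _merge_intervals(ivs: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge abutting/overlapping intervals (joins CDS and stop_codon)."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def write_gtf(ann: AnnotationSet, path: str | Path) -> None:
    """Write an AnnotationSet back to GTF (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        for gid in sorted(ann.genes):
            for tx in sorted(ann.genes[gid], key=lambda t: t.transcript_id):
                attrs = f'gene_id "{gid}"; transcript_id "{tx.transcript_id}";'
                for s, e in tx.exons:
                    fh.write(f"{tx.chrom}\tgcfate\texon\t{s + 1}\t{e}\t.\t"
                             f"{tx.strand}\t.\t{attrs}\n")
                for s, e in tx.cds_segments:
                    fh.write(f"{tx.chrom}\tgcfate\tCDS\t{s + 1}\t{e}\t.\t"
                             f"{tx.strand}\t0\t{attrs}\n")


def select_representative(ann: AnnotationSet, min_length: int = 500) -> AnnotationSet:
    """Keep one transcript per gene: the longest isoform, at least ``min_length`` nt.

    Ties on length are broken by lexicographically smallest transcript_id.
    Genes whose longest isoform is shorter than ``min_length`` are dropped.
    """
    out = AnnotationSet()
    for gid, txs in ann.genes.items():
        best = min(txs, key=lambda t: (-t.length, t.transcript_id))
        if best.length >= min_length:
            out.add(best)
    return out


def build_records(ann: AnnotationSet,
                  sequences: Mapping[str, str]) -> list[TranscriptRecord]:
    """Combine annotation spans with transcript sequences into records."""
    records = []
    for tx in ann.transcripts():
        seq = sequences.get(tx.transcript_id)
        if seq is None:
            warnings.warn(f"no sequence for {tx.transcript_id}; skipped")
            continue
        if len(seq) != tx.length:
            raise AnnotationError(
                f"{tx.transcript_id}: sequence length {len(seq)} != "
                f"annotated exonic length {tx.length}")
        records.append(TranscriptRecord(
            transcript_id=tx.transcript_id, gene_id=tx.gene_id, sequence=seq,
            utr5_span=tx.utr5_span, cds_span=tx.cds_span, utr3_span=tx.utr3_span))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path,
                width: int = 60) -> None:
    """Write (id, sequence) pairs as wrapped FASTA."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_table(path: str | Path, required: Sequence[str],
               key: str = "gene_id", sep: str = "\t") -> pd.DataFrame:
    """Read a keyed TSV/CSV with header; missing values kept as NaN.

    Raises on absent mandatory columns (listing the schema) and on duplicated
    keys.  Returns a DataFrame indexed by ``key``.
    """
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in [key, *required] if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing mandatory column(s) {missing}; "
            f"expected schema: [{key!r} (key), {list(required)}]")
    if df[key].duplicated().any():
        dups = df.loc[df[key].duplicated(), key].unique()
        raise ValueError(f"{path}: duplicated key(s) {list(dups)[:5]}")
    return df.set_index(key)
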