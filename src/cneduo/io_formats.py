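"""Domain types and file-format readers/writers.

Every genomic position inside the package lives in a single coordinate
convention: 0-based, half-open, BED-style.  Formats that use 1-based
inclusive coordinates (GFF3) are converted at the boundary, in both
directions, so that reading a file we wrote reproduces the original
printed coordinates.

Supported formats: FASTA, GFF3 (gene/transcript/exon), BED6 CTSS files
(score column = CAGE tag count), BED12 spliced reads (blocks = aligned
segments), bedGraph signal tracks, and TSV expression matrices
(rows = feature IDs, columns = sample IDs, values = TPM).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

VALID_STRANDS = ("+", "-", ".")
FASTA_ALPHABET = frozenset("ACGTN")


class ParseError(ValueError):
    """Malformed input file; carries the offending path and line number."""

    def __init__(self, message: str, path: str | Path | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = str(path) if path is not None else None
        self.line = line


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A located, stranded span on a named sequence (0-based, half-open)."""

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.seq_id:
            raise ValueError("seq_id must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript with its exon chain; introns are the gaps between exons."""

    transcript_id: str
    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    biotype: str = "coding"

    def __post_init__(self) -> None:
        if self.biotype not in ("coding", "noncoding"):
            raise ValueError(f"biotype must be coding|noncoding, got {self.biotype!r}")
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        object.__setattr__(self, "exons", tuple(self.exons))
        prev_end = None
        for ex in self.exons:
            if ex.seq_id != self.interval.seq_id or ex.strand != self.interval.strand:
                raise ValueError(
                    f"exon {ex} disagrees with transcript {self.transcript_id} "
                    f"on seq_id/strand"
                )
            if not self.interval.contains(ex):
                raise ValueError(f"exon {ex} outside transcript span {self.interval}")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(
                    f"exons of {self.transcript_id} overlap or are unsorted"
                )
            prev_end = ex.end

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(
                    GenomicInterval(self.interval.seq_id, a.end, b.start, self.interval.strand)
                )
        return tuple(out)

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def seq_id(self) -> str:
        return self.interval.seq_id


@dataclass(frozen=True)
class SplicedRead:
    """A (possibly spliced) read alignment: ordered aligned blocks on one strand."""

    name: str
    blocks: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("read must have at least one block")
        object.__setattr__(self, "blocks", tuple(self.blocks))
        prev_end = None
        for b in self.blocks:
            if b.width <= 0:
                raise ValueError("zero-length block")
            if prev_end is not None and b.start < prev_end:
                raise ValueError("blocks overlap or are unsorted")
            prev_end = b.end

    @property
    def seq_id(self) -> str:
        return self.blocks[0].seq_id

    @property
    def strand(self) -> str:
        return self.blocks[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.seq_id, self.blocks[0].start, self.blocks[-1].end, self.strand
        )


@dataclass(frozen=True)
class CtssRecord:
    """A single-base CAGE transcription start site with its tag count."""

    position: GenomicInterval
    tag_count: int

    def __post_init__(self) -> None:
        if self.position.width != 1:
            raise ValueError("CTSS position must have width 1")
        if self.position.strand not in ("+", "-"):
            raise ValueError("CTSS must be stranded (+ or -)")
        if self.tag_count < 0:
            raise ValueError("tag_count must be >= 0")


@dataclass
class SignalTrack:
    """Per-base non-negative signal (reads per million) on one sequence."""

    seq_id: str
    values: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pos, v in self.values.items():
            if pos < 0:
                raise ValueError(f"negative position {pos}")
            if v < 0:
                raise ValueError(f"negative signal {v} at {pos}")

    def mean(self, start: int, end: int) -> tuple[float, int]:
        """Mean over [start, end); uncovered positions count as 0.

        Returns (mean, number_of_uncovered_positions).
        """
        if end <= start:
            raise ValueError("empty window")
        total = 0.0
        uncovered = 0
        for pos in range(start, end):
            v = self.values.get(pos)
            if v is None:
                uncovered += 1
            else:
                total += v
        return total / (end - start), uncovered


class ExpressionMatrix:
    """Feature x sample table of non-negative TPM values (pandas-backed)."""

    def __init__(self, values: pd.DataFrame):
        if values.index.has_duplicates or values.columns.has_duplicates:
            raise ValueError("feature and sample ids must be unique")
        if (values.values < 0).any():
            raise ValueError("TPM values must be non-negative")
        self.values = values.astype(float)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def feature(self, feature_id: str) -> pd.Series:
        if feature_id not in self.values.index:
            raise KeyError(f"unknown feature {feature_id!r}")
        return self.values.loc[feature_id]

    def __eq__(self, other) -> bool:  # round-trip friendly equality
        return isinstance(other, ExpressionMatrix) and self.values.equals(other.values)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into {seq_id: upper-cased sequence}.

    IDs are the first whitespace-delimited token of the header.  Sequences
    must be over {A,C,G,T,N} (case-insensitive).
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ParseError("empty FASTA file", path)
    for i, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise ParseError("expected FASTA header line starting with '>'", path, i)
        break
    out: dict[str, str] = {}
    for record in SeqIO.parse(io.StringIO(text), "fasta"):
        seq = str(record.seq).upper()
        bad = set(seq) - FASTA_ALPHABET
        if bad:
            raise ParseError(
                f"record {record.id!r} contains invalid characters {sorted(bad)}", path
            )
        if record.id in out:
            raise ParseError(f"duplicate sequence id {record.id!r}", path)
        out[record.id] = seq
    if not out:
        raise ParseError("no FASTA records found", path)
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for seq_id, seq in sequences.items():
            fh.write(f">{seq_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_TRANSCRIPT_TYPES = {"mRNA", "transcript", "ncRNA", "lnc_RNA", "lncRNA"}
_NONCODING_TYPES = {"ncRNA", "lnc_RNA", "lncRNA"}


def read_gff3(path: str | Path) -> list[TranscriptModel]:
    """Read gene/transcript/exon features from GFF3 into transcript models.

    GFF3's 1-based inclusive coordinates become 0-based half-open.  Exons
    are grouped under their Parent transcript and sorted by start.
    """
    import gffutils

    path = Path(path)
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    transcripts: dict[str, dict] = {}
    gene_of: dict[str, str] = {}
    for feat in db.all_features():
        if feat.featuretype in _TRANSCRIPT_TYPES:
            parents = feat.attributes.get("Parent", [])
            gene_id = parents[0] if parents else feat.attributes.get("gene_id", [feat.id])[0]
            if feat.featuretype in _NONCODING_TYPES:
                biotype = "noncoding"
            else:
                bt = (feat.attributes.get("biotype") or feat.attributes.get("transcript_biotype") or [""])[0]
                biotype = "noncoding" if ("nc" in bt or "noncoding" in bt) else "coding"
            transcripts[feat.id] = {
                "interval": GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand),
                "biotype": biotype,
                "exons": [],
            }
            gene_of[feat.id] = gene_id
    for feat in db.features_of_type("exon"):
        parents = feat.attributes.get("Parent", [])
        if not parents:
            raise ParseError(f"exon {feat.id} has no Parent attribute", path)
        for parent in parents:
            if parent not in transcripts:
                raise ParseError(f"exon {feat.id} has unknown Parent {parent!r}", path)
            tx = transcripts[parent]
            if feat.strand != tx["interval"].strand:
                raise ParseError(
                    f"exon {feat.id} strand {feat.strand} differs from "
                    f"transcript {parent} strand {tx['interval'].strand}",
                    path,
                )
            tx["exons"].append(
                GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
            )
    models = []
    for tx_id, tx in transcripts.items():
        exons = sorted(tx["exons"], key=lambda e: e.start)
        if not exons:  # transcript without exon children: treat span as one exon
            exons = [tx["interval"]]
        models.append(
            TranscriptModel(
                transcript_id=tx_id,
                gene_id=gene_of[tx_id],
                interval=tx["interval"],
                exons=tuple(exons),
                biotype=tx["biotype"],
            )
        )
    models.sort(key=lambda m: (m.interval.seq_id, m.interval.start, m.transcript_id))
    return models


def write_gff3(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write transcript models as GFF3 (gene -> transcript -> exon)."""
    transcripts = list(transcripts)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        genes: dict[str, list[TranscriptModel]] = {}
        for tx in transcripts:
            genes.setdefault(tx.gene_id, []).append(tx)
        for gene_id, txs in genes.items():
            seq_id = txs[0].interval.seq_id
            strand = txs[0].interval.strand
            g_start = min(t.interval.start for t in txs)
            g_end = max(t.interval.end for t in txs)
            fh.write(
                f"{seq_id}\tcneduo\tgene\t{g_start + 1}\t{g_end}\t.\t{strand}\t.\t"
                f"ID={gene_id}\n"
            )
            for tx in txs:
                ftype = "ncRNA" if tx.biotype == "noncoding" else "mRNA"
                iv = tx.interval
                fh.write(
                    f"{iv.seq_id}\tcneduo\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{iv.strand}\t.\tID={tx.transcript_id};Parent={gene_id}\n"
                )
                for i, ex in enumerate(tx.exons, start=1):
                    fh.write(
                        f"{ex.seq_id}\tcneduo\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                        f"{ex.strand}\t.\tID={tx.transcript_id}.exon{i};"
                        f"Parent={tx.transcript_id}\n"
                    )


# ---------------------------------------------------------------------------
# BED6 CTSS
# ---------------------------------------------------------------------------


def read_ctss_bed(path: str | Path) -> list[CtssRecord]:
    """BED6 where each record is a single-base CTSS; score = tag count."""
    path = Path(path)
    records = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"expected >= 6 BED fields, got {len(fields)}", path, i)
            try:
                start, end = int(fields[1]), int(fields[2])
                count = int(fields[4])
            except ValueError as exc:
                raise ParseError(f"non-numeric coordinate or score: {exc}", path, i) from exc
            if start < 0:
                raise ParseError("negative coordinate", path, i)
            try:
                records.append(
                    CtssRecord(GenomicInterval(fields[0], start, end, fields[5]), count)
                )
            except ValueError as exc:
                raise ParseError(str(exc), path, i) from exc
    return records


def write_ctss_bed(records: Iterable[CtssRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            p = r.position
            fh.write(f"{p.seq_id}\t{p.start}\t{p.end}\t.\t{r.tag_count}\t{p.strand}\n")


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------


def read_bedgraph(path: str | Path) -> SignalTrack:
    path = Path(path)
    seq_id = None
    values: dict[int, float] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(f"expected 4 bedGraph fields, got {len(fields)}", path, i)
            try:
                start, end = int(fields[1]), int(fields[2])
                value = float(fields[3])
            except ValueError as exc:
                raise ParseError(f"non-numeric field: {exc}", path, i) from exc
            if start < 0 or end <= start:
                raise ParseError(f"bad interval [{start}, {end})", path, i)
            if value < 0:
                raise ParseError(f"negative signal value {value}", path, i)
            if seq_id is None:
                seq_id = fields[0]
            elif fields[0] != seq_id:
                raise ParseError(
                    f"multiple sequence ids in one track ({seq_id!r}, {fields[0]!r})", path, i
                )
            for pos in range(start, end):
                values[pos] = value
    if seq_id is None:
        raise ParseError("empty bedGraph file", path)
    return SignalTrack(seq_id, values)


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    """Write as maximal runs of contiguous positions with equal value."""
    with open(path, "w") as fh:
        positions = sorted(track.values)
        i = 0
        while i < len(positions):
            j = i
            while (
                j + 1 < len(positions)
                and positions[j + 1] == positions[j] + 1
                and track.values[positions[j + 1]] == track.values[positions[i]]
            ):
                j += 1
            value = track.values[positions[i]]
            fh.write(f"{track.seq_id}\t{positions[i]}\t{positions[j] + 1}\t{value:g}\n")
            i = j + 1


# ---------------------------------------------------------------------------
# BED12 spliced reads
# ---------------------------------------------------------------------------


def read_bed12(path: str | Path) -> list[SplicedRead]:
    path = Path(path)
    reads = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(f"expected 12 BED12 fields, got {len(fields)}", path, i)
            try:
                start, end = int(fields[1]), int(fields[2])
                n_blocks = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise ParseError(f"non-numeric field: {exc}", path, i) from exc
            if start < 0:
                raise ParseError("negative coordinate", path, i)
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise ParseError("blockCount disagrees with block lists", path, i)
            strand = fields[5]
            blocks = []
            for size, off in zip(sizes, offsets):
                if size <= 0:
                    raise ParseError("zero-length block", path, i)
                blocks.append(GenomicInterval(fields[0], start + off, start + off + size, strand))
            if blocks[-1].end != end:
                raise ParseError("last block does not reach chromEnd", path, i)
            try:
                reads.append(SplicedRead(fields[3], tuple(blocks)))
            except ValueError as exc:
                raise ParseError(str(exc), path, i) from exc
    return reads


def write_bed12(reads: Iterable[SplicedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            span = r.span
            sizes = ",".join(str(b.width) for b in r.blocks)
            offsets = ",".join(str(b.start - span.start) for b in r.blocks)
            fh.write(
                f"{span.seq_id}\t{span.start}\t{span.end}\t{r.name}\t0\t{span.strand}\t"
                f"{span.start}\t{span.end}\t0\t{len(r.blocks)}\t{sizes}\t{offsets}\n"
            )


# ---------------------------------------------------------------------------
# Expression TSV
# ---------------------------------------------------------------------------


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index.name = None
    if df.empty and df.columns.empty:
        raise ParseError("empty expression matrix", path)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"non-numeric expression value: {exc}", path) from exc
    if np.isnan(df.values).any():
        raise ParseError("missing values in expression matrix", path)
    try:
        return ExpressionMatrix(df)
    except ValueError as exc:
        raise ParseError(str(exc), path) from exc


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature_id")
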