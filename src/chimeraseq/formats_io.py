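"""Readers and writers for the external formats the pipeline touches.

Supported formats: PSL (Blat's 21-column alignment table), FASTA, FASTQ
(Sanger Phred+33, fixed — no encoding autodetection), BED12, JASPAR PFM
text, and tab-separated report tables.  All genomic intervals are 0-based
half-open throughout the package; that is PSL/BED native semantics, and
1-based coordinates appear only in human-readable report columns that say
so.

Parsers validate strictly and raise rather than silently repairing input:
:class:`FormatError` for syntactic problems (with the offending line
number) and :class:`ValidationError` for records that parse but violate an
invariant.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs

__all__ = [
    "FormatError",
    "ValidationError",
    "GenomeStore",
    "AlignmentRecord",
    "ReadRecord",
    "Pfm",
    "Bed12Record",
    "read_psl",
    "write_psl",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_jaspar",
    "write_jaspar",
    "read_bed12",
    "write_bed12",
    "bed12_to_alignment",
    "write_report",
    "read_report",
]


class FormatError(ValueError):
    """A file could not be parsed."""


class ValidationError(ValueError):
    """A parsed record violates a format invariant."""


_ALPHABET = set("ACGTN")


@dataclass
class GenomeStore:
    """In-memory nucleotide sequences keyed by (unique) name.

    Holds a genome, a transcript set or an EST set alike; sequences are
    upper-case over {A,C,G,T,N}.
    """

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            bad = set(seq) - _ALPHABET
            if bad:
                raise ValidationError(
                    f"sequence {name!r} contains non-ACGTN characters: {sorted(bad)}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def __iter__(self):
        return iter(self.sequences)


@dataclass
class AlignmentRecord:
    """One transcript-to-genome alignment with PSL semantics.

    Query coordinates (``qStart``/``qEnd``) are always in plus-strand query
    coordinates; for minus-strand alignments the per-block ``qStarts`` are
    in reverse-complemented query coordinates, as in PSL.  Records imported
    from BED12 carry ``qStart is None`` because BED lacks query
    coordinates; such records cannot enter junction gap/overlap math.
    """

    qName: str
    qSize: int
    qStart: int | None
    qEnd: int | None
    tName: str
    tSize: int
    tStart: int
    tEnd: int
    strand: str
    blockSizes: list[int]
    qStarts: list[int]
    tStarts: list[int]
    matches: int
    mismatches: int

    @property
    def identity(self) -> float:
        return self.matches / (self.matches + self.mismatches)

    @property
    def aligned_query_length(self) -> int | None:
        if self.qStart is None:
            return None
        return self.qEnd - self.qStart

    @property
    def target_blocks(self) -> list[tuple[int, int]]:
        """Genomic exon blocks as half-open intervals, ascending."""
        return [(t, t + s) for t, s in zip(self.tStarts, self.blockSizes)]

    def validate(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"{self.qName}: strand must be + or -")
        if not self.blockSizes or not (
            len(self.blockSizes) == len(self.qStarts) == len(self.tStarts)
        ):
            raise ValidationError(f"{self.qName}: block lists inconsistent")
        if any(s <= 0 for s in self.blockSizes):
            raise ValidationError(f"{self.qName}: non-positive block size")
        for prev, cur, size in zip(self.tStarts, self.tStarts[1:], self.blockSizes):
            if cur < prev + size:
                raise ValidationError(f"{self.qName}: target blocks overlap/unsorted")
        if self.tStarts[0] != self.tStart or self.tStarts[-1] + self.blockSizes[-1] != self.tEnd:
            raise ValidationError(f"{self.qName}: blocks disagree with target span")
        if not (0 <= self.tStart < self.tEnd <= self.tSize):
            raise ValidationError(f"{self.qName}: target span out of bounds")
        if self.qStart is not None:
            if not (0 <= self.qStart < self.qEnd <= self.qSize):
                raise ValidationError(f"{self.qName}: query span out of bounds")
            for prev, cur, size in zip(self.qStarts, self.qStarts[1:], self.blockSizes):
                if cur < prev + size:
                    raise ValidationError(f"{self.qName}: query blocks overlap/unsorted")
            lo = self.qStart if self.strand == "+" else self.qSize - self.qEnd
            hi = self.qEnd if self.strand == "+" else self.qSize - self.qStart
            if self.qStarts[0] != lo or self.qStarts[-1] + self.blockSizes[-1] != hi:
                raise ValidationError(
                    f"{self.qName}: blockSizes/qStarts disagree with qStart..qEnd"
                )
        if self.matches < 0 or self.mismatches < 0 or self.matches + self.mismatches == 0:
            raise ValidationError(f"{self.qName}: bad match/mismatch counts")


@dataclass
class ReadRecord:
    """A single-end sequencing read with per-base Phred qualities."""

    read_id: str
    sample_id: str
    seq: str
    qual: list[int]

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValidationError(f"{self.read_id}: seq/qual length mismatch")
        if self.qual and (min(self.qual) < 0 or max(self.qual) > 60):
            raise ValidationError(f"{self.read_id}: Phred scores outside [0, 60]")


@dataclass
class Pfm:
    """Position frequency matrix: 4 x W counts with rows ordered A,C,G,T."""

    motif_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4 or self.counts.shape[1] < 1:
            raise ValidationError(f"{self.motif_id}: counts must be 4 x W with W >= 1")
        if (self.counts < 0).any():
            raise ValidationError(f"{self.motif_id}: negative count")
        if (self.counts.sum(axis=0) <= 0).any():
            raise ValidationError(f"{self.motif_id}: zero column sum")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.counts.sum(axis=0, keepdims=True)


@dataclass
class Bed12Record:
    chrom: str
    start: int
    end: int
    name: str
    strand: str
    block_sizes: list[int]
    block_starts: list[int]  # relative to `start`

    @property
    def blocks(self) -> list[tuple[int, int]]:
        return [(self.start + b, self.start + b + s)
                for b, s in zip(self.block_starts, self.block_sizes)]


# ---------------------------------------------------------------------------
# PSL


_PSL_HEADER_PREFIXES = ("psLayout", "match", "-----", "\t")


def _int_list(text: str) -> list[int]:
    return [int(x) for x in text.rstrip(",").split(",") if x != ""]


def read_psl(path: str | Path) -> list[AlignmentRecord]:
    """Parse a Blat PSL file (optional header tolerated)."""
    records: list[AlignmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped.strip():
                continue
            if stripped.startswith(_PSL_HEADER_PREFIXES):
                continue
            fields = stripped.split("\t")
            if len(fields) != 21:
                raise FormatError(
                    f"{path}:{lineno}: expected 21 PSL columns, got {len(fields)}"
                )
            try:
                rec = AlignmentRecord(
                    matches=int(fields[0]),
                    mismatches=int(fields[1]),
                    strand=fields[8],
                    qName=fields[9],
                    qSize=int(fields[10]),
                    qStart=int(fields[11]),
                    qEnd=int(fields[12]),
                    tName=fields[13],
                    tSize=int(fields[14]),
                    tStart=int(fields[15]),
                    tEnd=int(fields[16]),
                    blockSizes=_int_list(fields[18]),
                    qStarts=_int_list(fields[19]),
                    tStarts=_int_list(fields[20]),
                )
                if int(fields[17]) != len(rec.blockSizes):
                    raise ValidationError(f"{rec.qName}: blockCount disagrees with blockSizes")
            except ValidationError:
                raise
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            try:
                rec.validate()
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return records


def write_psl(records: list[AlignmentRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            if r.qStart is None:
                raise ValidationError(f"{r.qName}: cannot write PSL without query coordinates")
            row = [
                r.matches, r.mismatches, 0, 0, 0, 0, 0, 0, r.strand,
                r.qName, r.qSize, r.qStart, r.qEnd,
                r.tName, r.tSize, r.tStart, r.tEnd,
                len(r.blockSizes),
                ",".join(map(str, r.blockSizes)) + ",",
                ",".join(map(str, r.qStarts)) + ",",
                ",".join(map(str, r.tStarts)) + ",",
            ]
            fh.write("\t".join(map(str, row)) + "\n")


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | Path) -> GenomeStore:
    """Read FASTA into a :class:`GenomeStore`.

    Sequence names are the first whitespace-delimited token of the header;
    duplicates are rejected; sequences are upper-cased and must be ACGTN.
    """
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise FormatError(f"{path}: duplicate FASTA header {rec.id!r}")
        sequences[rec.id] = str(rec.seq).upper()
    return GenomeStore(sequences)


def write_fasta(sequences: dict[str, str] | GenomeStore, path: str | Path, width: int = 60) -> None:
    if isinstance(sequences, GenomeStore):
        sequences = sequences.sequences
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str | Path, sample_id: str) -> list[ReadRecord]:
    """Read Sanger (Phred+33) FASTQ; each read is tagged with ``sample_id``."""
    reads: list[ReadRecord] = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            reads.append(
                ReadRecord(
                    read_id=rec.id,
                    sample_id=sample_id,
                    seq=str(rec.seq).upper(),
                    qual=list(rec.letter_annotations["phred_quality"]),
                )
            )
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    return reads


def write_fastq(reads: list[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qual)
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# JASPAR PFM text


def read_jaspar(path: str | Path) -> list[Pfm]:
    """Read a JASPAR-format PFM library (rows reordered to A,C,G,T)."""
    try:
        with open(path) as fh:
            parsed = bio_motifs.parse(fh, "jaspar")
    except Exception as exc:  # Bio raises bare ValueError/KeyError on bad input
        raise FormatError(f"{path}: {exc}") from exc
    pfms: list[Pfm] = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
        pfms.append(Pfm(motif_id=m.matrix_id or m.name, counts=counts))
    return pfms


def write_jaspar(pfms: list[Pfm], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pfms:
            fh.write(f">{p.motif_id}\n")
            for base, row in zip("ACGT", p.counts):
                fh.write(f"{base} [ " + " ".join(f"{v:g}" for v in row) + " ]\n")


# ---------------------------------------------------------------------------
# BED12


def read_bed12(path: str | Path) -> list[Bed12Record]:
    records: list[Bed12Record] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise FormatError(f"{path}:{lineno}: expected 12 BED columns")
            try:
                rec = Bed12Record(
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    name=fields[3],
                    strand=fields[5],
                    block_sizes=_int_list(fields[10]),
                    block_starts=_int_list(fields[11]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if len(rec.block_sizes) != int(fields[9]):
                raise ValidationError(f"{path}:{lineno}: blockCount mismatch")
            records.append(rec)
    return records


def write_bed12(records: list[Bed12Record], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            row = [
                r.chrom, r.start, r.end, r.name, 0, r.strand, r.start, r.end,
                "0,0,0", len(r.block_sizes),
                ",".join(map(str, r.block_sizes)) + ",",
                ",".join(map(str, r.block_starts)) + ",",
            ]
            fh.write("\t".join(map(str, row)) + "\n")


def bed12_to_alignment(rec: Bed12Record, tSize: int) -> AlignmentRecord:
    """Convert a BED12 entry to an alignment record without query coordinates.

    BED lacks the query span, so the junction gap/overlap of a candidate
    built from such records is unknowable; discovery excludes them.
    """
    total = sum(rec.block_sizes)
    return AlignmentRecord(
        qName=rec.name,
        qSize=total,
        qStart=None,
        qEnd=None,
        tName=rec.chrom,
        tSize=tSize,
        tStart=rec.start,
        tEnd=rec.end,
        strand=rec.strand,
        blockSizes=list(rec.block_sizes),
        qStarts=[],
        tStarts=[rec.start + b for b in rec.block_starts],
        matches=total,
        mismatches=0,
    )


# ---------------------------------------------------------------------------
# TSV reports

#: schema name -> (column tuple, primary sort key columns)
REPORT_SCHEMAS: dict[str, tuple[tuple[str, ...], list[str]]] = {
    "candidates": (
        ("mrna_id", "fusion_class", "order_type", "gap_overlap", "junction_q",
         "chrom5", "strand5", "start5", "end5", "chrom3", "strand3", "start3", "end3"),
        ["mrna_id"],
    ),
    "rejects": (("mrna_id", "stage", "reason"), ["mrna_id", "stage"]),
    "verified": (
        ("mrna_id", "status", "aligned_precisely", "donor", "acceptor",
         "canonical", "frame_ok", "passed", "reason"),
        ["mrna_id"],
    ),
    "est_support": (("chimera_id", "n_spanning", "supported", "est_ids"), ["chimera_id"]),
    "junction_counts": (("event_id", "sample_id", "n_reads"), ["event_id", "sample_id"]),
    "validation": (
        ("event_id", "n_reads", "n_start_positions", "n_samples", "validated"),
        ["event_id"],
    ),
    "stats": (("event_id", "mean", "sd", "cv_percent", "ranksum_p"), ["event_id"]),
    "motifs": (
        ("chimera_id", "category5", "category3", "width", "site5", "site3",
         "score", "empirical_p", "best_pfm", "best_pfm_p", "best_pfm_q"),
        ["chimera_id"],
    ),
    "venn": (("group", "count"), ["group"]),
}


def write_report(records: list[dict], path: str | Path, schema: str) -> None:
    """Write a deterministic TSV report for a named schema."""
    if schema not in REPORT_SCHEMAS:
        raise ValidationError(f"unknown report schema {schema!r}")
    columns, keys = REPORT_SCHEMAS[schema]
    df = pd.DataFrame(records, columns=list(columns))
    if len(df):
        missing = [c for c in columns if df[c].isna().all() and not any(c in r for r in records)]
        if missing:
            raise ValidationError(f"records missing schema columns: {missing}")
        df = df.sort_values(keys, kind="mergesort").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False)


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
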