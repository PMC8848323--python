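"""Readers and writers for the external formats the pipeline touches.

All internal coordinates are 0-based half-open. Conversions happen only at
the I/O boundary: GFF3 and RepeatMasker ``.out`` are 1-based inclusive on
disk, BED is 0-based half-open, and the BLAST tabular ``sstart`` column is
1-based. Every writer emits a ``#`` header line stating its convention.

Plain and gzip-compressed text are both accepted for every reader.
"""

from __future__ import annotations

import csv
import gzip
import io as _stdio
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
#: IUPAC ambiguity codes collapsed to N under the permissive flag.
IUPAC_AMBIGUOUS = frozenset("RYSWKMBDHVU")

BLAST12_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)
HIT5_COLUMNS = ("qseqid", "sseqid", "sstart", "length", "pident")


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence over {A,C,G,T,N}, stored uppercase."""

    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class Assembly:
    """An ordered collection of uniquely named sequence records."""

    records: list[SequenceRecord]
    name: str = "assembly"

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate sequence ids: {dupes}")

    @property
    def total_length(self) -> int:
        return sum(r.length for r in self.records)

    def __getitem__(self, seq_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == seq_id:
                return r
        raise KeyError(seq_id)

    def __contains__(self, seq_id: str) -> bool:
        return any(r.id == seq_id for r in self.records)

    def lengths(self) -> dict[str, int]:
        return {r.id: r.length for r in self.records}


@dataclass(frozen=True)
class FeatureInterval:
    """A 0-based half-open interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "."
    kind: str = "other"
    attrs: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.seq_id}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class HitRecord:
    """One row of a tabular homology hit table (sstart kept 1-based as on disk)."""

    qseqid: str
    sseqid: str
    sstart: int
    length: int
    pident: float

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"hit {self.qseqid}: alignment length {self.length} < 1")
        if not (0.0 <= self.pident <= 100.0):
            raise ValueError(f"hit {self.qseqid}: pident {self.pident} outside [0, 100]")


# ---------------------------------------------------------------------------
# helpers


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _clean_sequence(raw: str, permissive: bool, rec_id: str) -> tuple[str, int]:
    seq = raw.upper()
    bad = set(seq) - VALID_BASES
    if not bad:
        return seq, 0
    if not permissive:
        raise FormatError(
            f"record {rec_id!r} contains illegal characters {sorted(bad)}; "
            "pass permissive=True to map IUPAC ambiguity codes to N"
        )
    unknown = bad - IUPAC_AMBIGUOUS
    if unknown:
        raise FormatError(
            f"record {rec_id!r} contains non-nucleotide characters {sorted(unknown)}"
        )
    table = str.maketrans({c: "N" for c in bad})
    mapped = sum(seq.count(c) for c in bad)
    return seq.translate(table), mapped


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, permissive: bool = False, name: str | None = None) -> Assembly:
    """Read a (possibly gzipped) FASTA file into an :class:`Assembly`.

    Record ids are the first whitespace-delimited token of each header,
    sequences are uppercased. Letters outside {A,C,G,T,N} raise unless
    ``permissive`` is set, in which case IUPAC ambiguity codes map to N
    (with a logged count).
    """
    records: list[SequenceRecord] = []
    total_mapped = 0
    with _open_text(path) as fh:
        for bio_rec in SeqIO.parse(fh, "fasta"):
            seq, mapped = _clean_sequence(str(bio_rec.seq), permissive, bio_rec.id)
            total_mapped += mapped
            records.append(SequenceRecord(id=bio_rec.id, seq=seq))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    if total_mapped:
        logger.info("mapped %d ambiguous bases to N while reading %s", total_mapped, path)
    return Assembly(records=records, name=name or Path(path).stem)


def write_fasta(assembly: Assembly, path: str | Path, width: int = 60) -> None:
    with _open_text(path, "wt") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(
            _BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in assembly.records
        )


# ---------------------------------------------------------------------------
# GFF3


def read_gff3_genes(path: str | Path, feature_type: str = "gene") -> list[FeatureInterval]:
    """Read GFF3 rows of ``feature_type`` as 0-based half-open gene intervals.

    GFF3 is 1-based inclusive on disk; ``start-1`` converts. Comment and
    directive lines are skipped. A row with start > end raises naming the
    offending line.
    """
    out: list[FeatureInterval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise FormatError(f"{path}:{lineno}: expected ≥8 GFF3 columns, got {len(fields)}")
            seq_id, _source, ftype, start_s, end_s = fields[:5]
            if ftype != feature_type:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric coordinates") from None
            if start > end:
                raise FormatError(f"{path}:{lineno}: start {start} > end {end}")
            strand = fields[6] if fields[6] in "+-" else "."
            attrs = {}
            if len(fields) >= 9:
                for item in fields[8].split(";"):
                    if "=" in item:
                        k, v = item.split("=", 1)
                        attrs[k.strip()] = v.strip()
            out.append(
                FeatureInterval(seq_id, start - 1, end, strand=strand, kind="gene", attrs=attrs)
            )
    return out


def write_gff3_genes(intervals: Iterable[FeatureInterval], path: str | Path) -> None:
    """Write gene intervals as minimal GFF3 (internal 0-based → 1-based inclusive)."""
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for iv in intervals:
            attrs = ";".join(f"{k}={v}" for k, v in iv.attrs.items()) or "."
            fh.write(
                f"{iv.seq_id}\tsynpaint\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand if iv.strand in '+-' else '.'}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# repeat intervals (BED / RepeatMasker .out)


def read_repeat_intervals(path: str | Path, format: str = "bed") -> list[FeatureInterval]:
    """Read repeat annotations into 0-based half-open intervals (kind=repeat).

    ``format="bed"`` expects ≥3 tab-separated columns, already 0-based
    half-open. ``format="repeatmasker_out"`` expects the standard ``.out``
    layout: 3 header lines then whitespace-separated columns with the query
    name, 1-based begin and end in columns 5–7 and the repeat name/family in
    columns 10–11. The repeat family is stored under ``attrs["family"]``.
    """
    out: list[FeatureInterval] = []
    if format == "bed":
        with _open_text(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise FormatError(f"{path}:{lineno}: expected ≥3 BED columns")
                try:
                    start, end = int(fields[1]), int(fields[2])
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: non-numeric BED coordinates") from None
                attrs = {"family": fields[3]} if len(fields) > 3 else {}
                out.append(FeatureInterval(fields[0], start, end, kind="repeat", attrs=attrs))
    elif format == "repeatmasker_out":
        with _open_text(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if lineno <= 3:  # two header lines + blank
                    continue
                fields = line.split()
                if not fields:
                    continue
                if len(fields) < 11:
                    raise FormatError(f"{path}:{lineno}: expected ≥11 RepeatMasker columns")
                try:
                    begin, end = int(fields[5]), int(fields[6])
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: non-numeric RepeatMasker coordinates"
                    ) from None
                out.append(
                    FeatureInterval(
                        fields[4], begin - 1, end, kind="repeat",
                        attrs={"family": fields[10], "name": fields[9]},
                    )
                )
    else:
        raise ValueError(f"unknown repeat format {format!r}")
    return out


def write_repeat_bed(intervals: Iterable[FeatureInterval], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for iv in intervals:
            fam = iv.attrs.get("family", ".")
            fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{fam}\n")


# ---------------------------------------------------------------------------
# hit tables


def read_hit_table(
    path: str | Path,
    columns: Sequence[str] = HIT5_COLUMNS,
) -> list[HitRecord]:
    """Read a tab-separated, headerless homology hit table.

    The default layout is the 5-column dialect ``qseqid sseqid sstart length
    pident``; passing ``columns=BLAST12_COLUMNS`` (or any ordering naming the
    five required fields) accepts other tabular dialects. Row order is
    preserved; ``sstart`` stays 1-based as on disk.
    """
    required = set(HIT5_COLUMNS)
    missing = required - set(columns)
    if missing:
        raise ValueError(f"column spec lacks required fields: {sorted(missing)}")
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=list(columns), comment="#",
            dtype=str, keep_default_na=False,
        )
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] != len(columns):
        raise FormatError(
            f"{path}: expected {len(columns)} columns, found {df.shape[1]}"
        )
    out: list[HitRecord] = []
    for row in df.itertuples(index=True):
        try:
            out.append(
                HitRecord(
                    qseqid=getattr(row, "qseqid"),
                    sseqid=getattr(row, "sseqid"),
                    sstart=int(getattr(row, "sstart")),
                    length=int(getattr(row, "length")),
                    pident=float(getattr(row, "pident")),
                )
            )
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: row {row.Index + 1}: {exc}") from None
    return out


def write_hit_table(hits: Iterable[HitRecord], path: str | Path) -> None:
    """Write hits in the 5-column dialect (sstart 1-based)."""
    with _open_text(path, "wt") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for h in hits:
            w.writerow([h.qseqid, h.sseqid, h.sstart, h.length, f"{h.pident:g}"])


# ---------------------------------------------------------------------------
# painting tables


def write_painting_bed(painting, path: str | Path) -> None:
    """Write syntenic blocks as BED6 on query coordinates.

    Name field is ``<species>:<target_scaffold>``, score is the block marker
    count capped at 1000 (BED validity); the companion TSV from
    :func:`write_painting_tsv` carries the true count.
    """
    with _open_text(path, "wt") as fh:
        fh.write("# synpaint painting blocks; coordinates 0-based half-open\n")
        for b in painting.blocks:
            fh.write(
                f"{b.query_chrom}\t{b.query_span[0]}\t{b.query_span[1]}\t"
                f"{b.species}:{b.target_scaffold}\t{min(b.marker_count, 1000)}\t+\n"
            )


_PAINTING_TSV_COLS = (
    "species", "query_chrom", "first_index", "last_index",
    "marker_count", "target_scaffold", "target_min", "target_max",
)


def write_painting_tsv(painting, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("# synpaint painting blocks; marker indices inclusive; "
                 "target span 0-based half-open\n")
        fh.write("\t".join(_PAINTING_TSV_COLS) + "\n")
        for b in painting.blocks:
            fh.write(
                f"{b.species}\t{b.query_chrom}\t{b.first_index}\t{b.last_index}\t"
                f"{b.marker_count}\t{b.target_scaffold}\t{b.target_span[0]}\t"
                f"{b.target_span[1]}\n"
            )


def read_painting_tsv(path: str | Path):
    """Re-read a painting TSV into a PaintingTable (params not recoverable)."""
    from .painting import PaintingParams, PaintingTable, SyntenyBlock

    df = pd.read_csv(path, sep="\t", comment="#")
    blocks = []
    for row in df.itertuples(index=False):
        blocks.append(
            SyntenyBlock(
                query_chrom=row.query_chrom,
                species=row.species,
                target_scaffold=row.target_scaffold,
                first_index=int(row.first_index),
                last_index=int(row.last_index),
                marker_count=int(row.marker_count),
                query_span=(int(row.first_index) * 100, (int(row.last_index) + 1) * 100),
                target_span=(int(row.target_min), int(row.target_max)),
            )
        )
    species = sorted({b.species for b in blocks})
    return PaintingTable(
        assembly_name=Path(path).stem, species=species, blocks=blocks,
        params=PaintingParams(),
    )
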