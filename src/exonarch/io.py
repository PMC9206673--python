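"""On-disk formats and read demultiplexing.

Everything in the pipeline uses 0-based, half-open coordinates, which is
also BED's native convention; any 1-based display is formatting only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import pandas as pd

__all__ = [
    "GeneLocus",
    "ReadRecord",
    "SampleEntry",
    "SampleSheet",
    "DemuxResult",
    "FormatError",
    "revcomp",
    "read_fasta_or_fastq",
    "write_fastq",
    "write_fasta",
    "demultiplex",
    "read_sample_sheet",
    "write_sample_sheet",
    "write_exons_bed",
    "read_exons_bed",
    "write_transcripts_bed12",
    "read_bed12",
    "write_counts_tsv",
    "read_counts_tsv",
]

_DNA_OK = re.compile(r"^[ACGTN]+$")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

Orientation = Literal["forward", "reverse", "unknown"]


class FormatError(ValueError):
    """A malformed on-disk record; the message names the offending record."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _normalize_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class GeneLocus:
    """A single genomic locus stored on its transcribed strand.

    ``strand`` records the transcribed strand of the amplicon relative to
    the stored sequence; all coordinates are 0-based half-open offsets
    into ``sequence``.
    """

    name: str
    sequence: str
    strand: Literal["+", "-"] = "+"
    coordinate_system: str = "0-based, half-open"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("locus sequence must be non-empty")
        if not _DNA_OK.match(self.sequence):
            raise ValueError("locus sequence restricted to A/C/G/T/N")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadRecord:
    """One sequencing read (CCS-like or ONT-like)."""

    read_id: str
    sequence: str
    qualities: list[int] | None = None
    sample_id: str | None = None
    orientation: Orientation = "unknown"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id}: empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(f"read {self.read_id}: quality/sequence length mismatch")

    def reverse_complement(self) -> "ReadRecord":
        quals = None if self.qualities is None else self.qualities[::-1]
        return ReadRecord(self.read_id, revcomp(self.sequence), quals,
                          self.sample_id, self.orientation)


@dataclass(frozen=True)
class SampleEntry:
    sample_id: str
    barcode_fwd: str
    barcode_rev: str
    metadata: Mapping[str, str] = field(default_factory=dict)


@dataclass
class SampleSheet:
    """The multiplexing design: one barcode pair per sample."""

    entries: list[SampleEntry]

    def __post_init__(self) -> None:
        ids = [e.sample_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_ids must be unique")
        for side in ("barcode_fwd", "barcode_rev"):
            codes = [getattr(e, side) for e in self.entries]
            if len(set(codes)) != len(codes):
                raise ValueError(f"{side} barcodes must be unique")
            for c in codes:
                if len(c) < 6:
                    raise ValueError("barcodes must be at least 6 nt")
                if not _DNA_OK.match(c) or "N" in c:
                    raise ValueError("barcodes must be A/C/G/T only")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def sample_ids(self) -> list[str]:
        return [e.sample_id for e in self.entries]


# ---------------------------------------------------------------------------
# FASTA / FASTQ

def read_fasta_or_fastq(path: str | Path) -> list[ReadRecord]:
    """Read records from FASTA or FASTQ, auto-detected from the first byte.

    Sequences are upcased and U is converted to T.  Qualities are
    populated iff the file is FASTQ.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    if first == ">":
        fmt = "fasta"
    elif first == "@":
        fmt = "fastq"
    else:
        raise FormatError(f"{path}: not FASTA or FASTQ (starts with {first!r})")

    from Bio import SeqIO

    records: list[ReadRecord] = []
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), fmt)):
            seq = _normalize_dna(str(rec.seq))
            if not seq:
                raise FormatError(f"{path}: record {i} ({rec.id}) has no sequence")
            quals = None
            if fmt == "fastq":
                quals = list(rec.letter_annotations["phred_quality"])
            records.append(ReadRecord(rec.id, seq, quals))
    except FormatError:
        raise
    except ValueError as exc:  # Biopython length-mismatch etc.
        raise FormatError(f"{path}: malformed record {len(records)}: {exc}") from exc
    return records


def write_fastq(reads: Iterable[ReadRecord], path: str | Path,
                default_quality: int = 30) -> None:
    with open(path, "w") as fh:
        for r in reads:
            quals = r.qualities or [default_quality] * len(r.sequence)
            qstr = "".join(chr(q + 33) for q in quals)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qstr}\n")


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path,
                width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Demultiplexing

def _min_hamming(barcode: str, window: str) -> int:
    """Minimum Hamming distance of ``barcode`` over all offsets in ``window``.

    N in the read never counts as a match.
    """
    b = len(barcode)
    if len(window) < b:
        return b  # worst case: nothing alignable
    best = b
    for off in range(len(window) - b + 1):
        d = 0
        for x, y in zip(barcode, window[off:off + b]):
            if x != y or y == "N":
                d += 1
                if d >= best:
                    break
        if d < best:
            best = d
            if best == 0:
                return 0
    return best


@dataclass
class DemuxResult:
    """Outcome of demultiplexing; assigned reads are normalized to forward
    orientation (sequence reverse-complemented when the forward barcode was
    found on the reverse strand), with ``orientation`` recording the strand
    the barcode was detected on."""

    assigned: list[ReadRecord]
    ambiguous: list[ReadRecord]
    unassigned: list[ReadRecord]
    per_sample: dict[str, int]

    @property
    def report(self) -> pd.DataFrame:
        rows = [{"category": f"sample:{s}", "count": n}
                for s, n in sorted(self.per_sample.items())]
        rows.append({"category": "ambiguous", "count": len(self.ambiguous)})
        rows.append({"category": "unassigned", "count": len(self.unassigned)})
        return pd.DataFrame(rows)

    @property
    def n_total(self) -> int:
        return len(self.assigned) + len(self.ambiguous) + len(self.unassigned)


def demultiplex(reads: Iterable[ReadRecord], sheet: SampleSheet,
                max_mismatch: int = 2, window: int = 100,
                require_both: bool = False) -> DemuxResult:
    """Assign each read to the unique sample whose forward barcode matches
    within ``max_mismatch`` in the first ``window`` bases of the read or of
    its reverse complement.

    Reads matching two different samples within tolerance are flagged
    ambiguous; reads matching none are unassigned; neither is dropped.
    With ``require_both`` the reverse barcode (reverse-complemented, at the
    3' end) must also match within tolerance.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    assigned: list[ReadRecord] = []
    ambiguous: list[ReadRecord] = []
    unassigned: list[ReadRecord] = []
    per_sample: dict[str, int] = {e.sample_id: 0 for e in sheet}

    for read in reads:
        fwd5 = read.sequence[:window]
        rev5 = revcomp(read.sequence[-window:]) if len(read.sequence) > window \
            else revcomp(read.sequence)
        hits: list[tuple[int, int, str]] = []  # (distance, orient_rank, sample)
        for entry in sheet:
            d_f = _min_hamming(entry.barcode_fwd, fwd5)
            d_r = _min_hamming(entry.barcode_fwd, rev5)
            d = min(d_f, d_r)
            if d <= max_mismatch:
                orient = 0 if d_f <= d_r else 1
                hits.append((d, orient, entry.sample_id))
        if not hits:
            read.orientation = "unknown"
            unassigned.append(read)
            continue
        if len({h[2] for h in hits}) > 1:
            read.orientation = "unknown"
            ambiguous.append(read)
            continue
        d, orient, sample = min(hits)
        oriented = read if orient == 0 else read.reverse_complement()
        if require_both:
            entry = next(e for e in sheet if e.sample_id == sample)
            tail = revcomp(oriented.sequence[-window:])
            if _min_hamming(entry.barcode_rev, tail) > max_mismatch:
                read.orientation = "unknown"
                unassigned.append(read)
                continue
        oriented.sample_id = sample
        oriented.orientation = "forward" if orient == 0 else "reverse"
        assigned.append(oriented)
        per_sample[sample] += 1

    return DemuxResult(assigned, ambiguous, unassigned, per_sample)


# ---------------------------------------------------------------------------
# Sample sheet TSV

def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "barcode_fwd", "barcode_rev"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
    meta_cols = [c for c in df.columns if c not in required]
    entries = []
    for _, row in df.iterrows():
        meta = {c: row[c] for c in meta_cols if pd.notna(row[c])}
        entries.append(SampleEntry(row["sample_id"], row["barcode_fwd"],
                                   row["barcode_rev"], meta))
    return SampleSheet(entries)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    meta_keys: list[str] = []
    for e in sheet:
        for k in e.metadata:
            if k not in meta_keys:
                meta_keys.append(k)
    rows = []
    for e in sheet:
        row = {"sample_id": e.sample_id, "barcode_fwd": e.barcode_fwd,
               "barcode_rev": e.barcode_rev}
        row.update({k: e.metadata.get(k, "") for k in meta_keys})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED / BED12 / counts

def write_exons_bed(catalog, locus: GeneLocus, path: str | Path) -> None:
    """Write the exon catalog as 4-column BED (0-based half-open)."""
    exons = sorted(catalog.exons, key=lambda e: (e.start, e.end))
    for a, b in zip(exons, exons[1:]):
        if b.start < a.start:
            raise ValueError("exon catalog is not sortable by (start, end)")
    with open(path, "w") as fh:
        for e in exons:
            fh.write(f"{locus.name}\t{e.start}\t{e.end}\t{e.name}\n")


def read_exons_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Return (name, start, end) tuples from a 4+-column BED."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}: line {i + 1}: expected >=4 BED columns")
            out.append((parts[3], int(parts[1]), int(parts[2])))
    return out


def _bed12_line(chrom: str, name: str, blocks: list[tuple[int, int]],
                score: int, strand: str) -> str:
    start = blocks[0][0]
    end = blocks[-1][1]
    sizes = ",".join(str(b - a) for a, b in blocks) + ","
    starts = ",".join(str(a - start) for a, b in blocks) + ","
    return (f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\t"
            f"{start}\t{end}\t0\t{len(blocks)}\t{sizes}\t{starts}")


def write_transcripts_bed12(clusters, locus: GeneLocus, catalog,
                            path: str | Path) -> None:
    """Write one BED12 line per transcript cluster; blockStarts/blockSizes
    reconstruct the exact exon chain."""
    coords = {e.name: (e.start, e.end) for e in catalog.exons}
    with open(path, "w") as fh:
        for cl in clusters:
            blocks = [coords[n] for n in cl.barcode.exon_names]
            fh.write(_bed12_line(locus.name, cl.name, blocks,
                                 min(cl.total_count, 1000), locus.strand) + "\n")


def read_bed12(path: str | Path) -> list[tuple[str, list[tuple[int, int]]]]:
    """Return (name, [(start, end), ...]) per BED12 line."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 12:
                raise FormatError(f"{path}: line {i + 1}: expected 12 BED columns")
            chrom_start = int(parts[1])
            n = int(parts[9])
            sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
            starts = [int(x) for x in parts[11].rstrip(",").split(",")]
            if len(sizes) != n or len(starts) != n:
                raise FormatError(f"{path}: line {i + 1}: blockCount mismatch")
            if any(b <= a for a, b in zip(starts, starts[1:])):
                raise FormatError(f"{path}: line {i + 1}: blockStarts not increasing")
            blocks = [(chrom_start + s, chrom_start + s + sz)
                      for s, sz in zip(starts, sizes)]
            out.append((parts[3], blocks))
    return out


def write_counts_tsv(matrix, path: str | Path) -> None:
    """Counts TSV: transcripts as rows, samples as columns, integer cells."""
    matrix.counts.to_csv(path, sep="\t", index_label="transcript")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="transcript")
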