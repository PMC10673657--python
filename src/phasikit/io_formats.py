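"""Readers/writers for the external formats the pipeline touches, read
collapsing, length selection, repeat filtering, and exact-match mapping.

Coordinate convention: 1-based inclusive everywhere internally.  BED export
converts to 0-based half-open; GFF3 export stays 1-based.  The collapsed
FASTA header dialect is the de-facto sRNA convention ``><id>_x<count>``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")
_VALID_RE = re.compile(r"^[ACGTUN]+$")
_COLLAPSED_RE = re.compile(r"^(?P<id>.+)_x(?P<count>\d+)$")


def normalize_sequence(seq: str) -> str:
    """Uppercase and convert U to T."""
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class UniqueRead:
    """A distinct sRNA sequence with per-library counts.

    The unit of all abundance accounting: reads that share a sequence are
    collapsed into one record whose ``counts`` map library id to read count.
    """

    sequence: str
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequence = normalize_sequence(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())


@dataclass
class ReadPlacement:
    """One ungapped, full-length genomic placement of a UniqueRead.

    ``start`` is the 1-based leftmost (plus-strand) genomic coordinate
    regardless of strand.
    """

    read: UniqueRead
    contig: str
    start: int
    strand: str  # '+' or '-'

    @property
    def length(self) -> int:
        return self.read.length

    @property
    def end(self) -> int:
        return self.start + self.read.length - 1


# ---------------------------------------------------------------------------
# read collapsing and selection
# ---------------------------------------------------------------------------

def collapse_reads(libraries: Mapping[str, Iterable[str]]) -> list[UniqueRead]:
    """Collapse raw sequences into UniqueReads with per-library counts.

    ``libraries`` maps library id to an iterable of raw read sequences.
    Sequences containing characters outside ACGTUN are rejected with a
    logged warning.  The result is order-independent: reads are returned
    sorted by sequence.
    """
    table: dict[str, dict[str, int]] = {}
    n_rejected = 0
    for lib_id in sorted(libraries):
        for raw in libraries[lib_id]:
            seq = normalize_sequence(raw)
            if not seq or not _VALID_RE.match(seq):
                n_rejected += 1
                logger.warning("rejecting read with invalid characters: %r", raw)
                continue
            table.setdefault(seq, {})
            table[seq][lib_id] = table[seq].get(lib_id, 0) + 1
    if n_rejected:
        logger.warning("collapse_reads rejected %d reads", n_rejected)
    return [UniqueRead(seq, counts) for seq, counts in sorted(table.items())]


def select_lengths(reads: Iterable[UniqueRead], lengths: Iterable[int]) -> list[UniqueRead]:
    """Keep exactly the reads whose length is in ``lengths`` (subset of 15..35)."""
    wanted = set(lengths)
    if not wanted <= set(range(15, 36)):
        raise ValueError(f"lengths must be within 15..35, got {sorted(wanted)}")
    return [r for r in reads if r.length in wanted]


def filter_repeat_reads(
    reads: Iterable[UniqueRead], repeats: Iterable[str] | str | Path
) -> list[UniqueRead]:
    """Drop reads occurring as exact full-length substrings of repeat sequences.

    Both orientations are checked: a read is removed when its sequence or its
    reverse complement occurs in any repeat.  An empty repeat set is an
    identity transform with a logged warning.
    """
    if isinstance(repeats, (str, Path)):
        repeat_seqs = [str(rec.seq) for rec in SeqIO.parse(str(repeats), "fasta")]
    else:
        repeat_seqs = list(repeats)
    repeat_seqs = [normalize_sequence(s) for s in repeat_seqs]
    if not repeat_seqs:
        logger.warning("empty repeat set: repeat filtering is a no-op")
        return list(reads)
    # '#' never occurs in nucleotide text, so joining cannot create spurious hits
    haystack = "#".join(repeat_seqs)
    kept = []
    n_removed = 0
    for read in reads:
        if read.sequence in haystack or revcomp(read.sequence) in haystack:
            n_removed += 1
        else:
            kept.append(read)
    logger.info("repeat filter removed %d of %d reads", n_removed, n_removed + len(kept))
    return kept


# ---------------------------------------------------------------------------
# mapping
# ---------------------------------------------------------------------------

def map_reads(
    reads: Sequence[UniqueRead], genome: Mapping[str, str]
) -> list[ReadPlacement]:
    """Report all exact full-length matches of each read on both strands.

    Uses a per-length substring index of the genome; minus-strand placements
    are recorded by their leftmost plus-strand coordinate.
    """
    if not genome:
        raise ValueError("genome is empty")
    lengths = sorted({r.length for r in reads})
    # index[L][substring] -> list of (contig, 1-based start)
    index: dict[int, dict[str, list[tuple[str, int]]]] = {L: {} for L in lengths}
    for contig in sorted(genome):
        seq = normalize_sequence(genome[contig])
        for L in lengths:
            idx = index[L]
            for i in range(len(seq) - L + 1):
                idx.setdefault(seq[i : i + L], []).append((contig, i + 1))
    placements: list[ReadPlacement] = []
    for read in reads:
        idx = index[read.length]
        for contig, start in idx.get(read.sequence, ()):
            placements.append(ReadPlacement(read, contig, start, "+"))
        for contig, start in idx.get(revcomp(read.sequence), ()):
            placements.append(ReadPlacement(read, contig, start, "-"))
    placements.sort(key=lambda p: (p.contig, p.start, p.strand, p.read.sequence))
    return placements


def read_alignments(
    sam_path: str | Path,
    library_id: str = "lib1",
    counts_by_sequence: Mapping[str, Mapping[str, int]] | None = None,
) -> list[ReadPlacement]:
    """Import placements from a SAM/BAM file.

    Only ungapped, full-length, 0-mismatch alignments are kept; others are
    dropped with a counter in the log.  Per-library counts are recovered from
    collapsed-style query names (``<id>_x<count>``), from
    ``counts_by_sequence`` when given, else default to 1 in ``library_id``.
    Malformed records raise with the offending query name.
    """
    import pysam

    placements: list[ReadPlacement] = []
    n_dropped = 0
    cache: dict[str, UniqueRead] = {}
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        for i, rec in enumerate(fh):
            if rec.is_unmapped:
                continue
            try:
                query = rec.query_sequence
                if query is None:
                    raise ValueError("missing sequence")
                cigar = rec.cigartuples or []
            except Exception as exc:  # pragma: no cover - defensive
                raise ValueError(f"malformed SAM record at line {i + 1}") from exc
            full_match = len(cigar) == 1 and cigar[0][0] in (0, 7) and cigar[0][1] == len(query)
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            if not full_match or nm != 0:
                n_dropped += 1
                continue
            seq = normalize_sequence(query)
            strand = "-" if rec.is_reverse else "+"
            if strand == "-":
                seq = revcomp(seq)  # original read orientation
            if seq not in cache:
                counts: dict[str, int]
                if counts_by_sequence and seq in counts_by_sequence:
                    counts = dict(counts_by_sequence[seq])
                else:
                    m = _COLLAPSED_RE.match(rec.query_name or "")
                    counts = {library_id: int(m.group("count")) if m else 1}
                cache[seq] = UniqueRead(seq, counts)
            placements.append(
                ReadPlacement(cache[seq], rec.reference_name, rec.reference_start + 1, strand)
            )
    if n_dropped:
        logger.info("read_alignments dropped %d gapped/clipped/mismatched records", n_dropped)
    placements.sort(key=lambda p: (p.contig, p.start, p.strand, p.read.sequence))
    return placements


# ---------------------------------------------------------------------------
# FASTA / table IO
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> uppercase sequence dict."""
    return {
        rec.id: normalize_sequence(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(path: str | Path, records: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n{seq}\n")


def read_fastq_sequences(path: str | Path) -> list[str]:
    """Sequences only; qualities are ignored."""
    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fastq")]


def read_collapsed_fasta(path: str | Path) -> dict[str, int]:
    """Read a collapsed FASTA (``><id>_x<count>``) into sequence -> count."""
    counts: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _COLLAPSED_RE.match(rec.id)
        if not m:
            raise ValueError(f"not a collapsed-FASTA header: {rec.id!r}")
        seq = normalize_sequence(str(rec.seq))
        counts[seq] = counts.get(seq, 0) + int(m.group("count"))
    return counts


def write_collapsed_fasta(path: str | Path, counts: Mapping[str, int], prefix: str = "read") -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(sorted(counts), start=1):
            fh.write(f">{prefix}{i}_x{counts[seq]}\n{seq}\n")


def read_degradome_tsv(path: str | Path) -> dict[str, dict[int, int]]:
    """Read a degradome table (transcript_id, 1-based 5' position, count).

    A header line is tolerated.  Counts at a repeated (transcript, position)
    accumulate.
    """
    table: dict[str, dict[int, int]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed degradome row at line {line_no}")
            tid, pos_s, count_s = parts[0], parts[1], parts[2]
            if line_no == 1 and not pos_s.lstrip("-").isdigit():
                continue  # header
            pos, count = int(pos_s), int(count_s)
            if pos < 1 or count < 0:
                raise ValueError(f"{path}: invalid degradome row at line {line_no}")
            table.setdefault(tid, {})
            table[tid][pos] = table[tid].get(pos, 0) + count
    return table


def write_degradome_tsv(path: str | Path, table: Mapping[str, Mapping[int, int]]) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tposition\tcount\n")
        for tid in sorted(table):
            for pos in sorted(table[tid]):
                fh.write(f"{tid}\t{pos}\t{table[tid][pos]}\n")


def write_placements_tsv(path: str | Path, placements: Sequence[ReadPlacement]) -> None:
    """Placement table with per-library counts (column per library)."""
    libs = sorted({lib for pl in placements for lib in pl.read.counts})
    with open(path, "w") as fh:
        fh.write("contig\tstart\tstrand\tsequence\t" + "\t".join(libs) + "\n")
        for pl in placements:
            row = [pl.contig, str(pl.start), pl.strand, pl.read.sequence]
            row += [str(pl.read.counts.get(lib, 0)) for lib in libs]
            fh.write("\t".join(row) + "\n")


def read_placements_tsv(path: str | Path) -> list[ReadPlacement]:
    placements: list[ReadPlacement] = []
    cache: dict[str, UniqueRead] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        libs = header[4:]
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            contig, start, strand, seq = parts[0], int(parts[1]), parts[2], parts[3]
            if seq not in cache:
                counts = {lib: int(v) for lib, v in zip(libs, parts[4:]) if int(v)}
                cache[seq] = UniqueRead(seq, counts)
            placements.append(ReadPlacement(cache[seq], contig, start, strand))
    return placements


def write_gff3(path: str | Path, rows: Iterable[Mapping[str, object]]) -> None:
    """Write generic GFF3 rows.

    Each row needs keys contig, source, type, start, end, score, strand,
    attributes (already formatted ``key=value;...``).
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in rows:
            fh.write(
                "\t".join(
                    [
                        str(r["contig"]),
                        str(r.get("source", "phasikit")),
                        str(r["type"]),
                        str(r["start"]),
                        str(r["end"]),
                        str(r.get("score", ".")),
                        str(r.get("strand", ".")),
                        ".",
                        str(r.get("attributes", ".")),
                    ]
                )
                + "\n"
            )


def write_bed6(path: str | Path, rows: Iterable[Mapping[str, object]]) -> None:
    """BED6 export; internal 1-based inclusive -> 0-based half-open."""
    with open(path, "w") as fh:
        for r in rows:
            fh.write(
                "\t".join(
                    [
                        str(r["contig"]),
                        str(int(r["start"]) - 1),
                        str(r["end"]),
                        str(r.get("name", ".")),
                        str(r.get("score", 0)),
                        str(r.get("strand", ".")),
                    ]
                )
                + "\n"
            )
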