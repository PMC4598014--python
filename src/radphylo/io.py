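"""File formats and demultiplexing.

Readers/writers for FASTQ, FASTA, relaxed PHYLIP, NEXUS and Newick, plus the
two-column barcode map and barcode-based demultiplexing of single-end reads.
FASTQ/FASTA parsing is delegated to Biopython; PHYLIP-relaxed to Biopython's
AlignIO dialect; Newick to dendropy.  Qualities are Phred+33 by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

import dendropy
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BarcodedRead:
    """A single-end short read: identifier, bases, integer Phred scores."""

    read_id: str
    seq: str
    qual: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"{self.read_id}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}"
            )
        if self.qual and (min(self.qual) < 0 or max(self.qual) > 60):
            raise ValueError(f"{self.read_id}: Phred scores outside [0, 60]")


def hamming(a: str, b: str) -> int:
    """Positional mismatch count between equal-length strings.

    An N in either string counts as a mismatch against any base.
    """
    if len(a) != len(b):
        raise ValueError("length mismatch")
    return sum(1 for x, y in zip(a, b) if x != y or x == "N" or y == "N")


@dataclass(frozen=True)
class BarcodeMap:
    """Sample ↔ barcode table with pairwise Hamming distance >= 3."""

    entries: tuple[tuple[str, str], ...]
    min_distance: int = 3

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        lengths = {len(bc) for _, bc in self.entries}
        if len(lengths) > 1:
            raise ValueError(f"barcodes of mixed lengths: {sorted(lengths)}")
        for sample, bc in self.entries:
            if sample in seen:
                raise ValueError(f"duplicate sample id {sample!r}")
            if set(bc) - set("ACGT"):
                raise ValueError(f"barcode {bc!r} for {sample!r} is not over ACGT")
            seen[sample] = bc
        items = list(self.entries)
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                d = hamming(items[i][1], items[j][1])
                if d < self.min_distance:
                    raise ValueError(
                        f"barcodes {items[i][0]}:{items[i][1]} and "
                        f"{items[j][0]}:{items[j][1]} differ at only {d} "
                        f"position(s); minimum is {self.min_distance}"
                    )

    @property
    def barcode_length(self) -> int:
        return len(self.entries[0][1]) if self.entries else 0

    @property
    def samples(self) -> list[str]:
        return [s for s, _ in self.entries]


def read_barcode_map(path: str | Path, min_distance: int = 3) -> BarcodeMap:
    """Parse a two-column (sample, barcode) whitespace-separated text file."""
    entries: list[tuple[str, str]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected two columns, got {len(parts)}")
        entries.append((parts[0], parts[1].upper()))
    return BarcodeMap(tuple(entries), min_distance=min_distance)


def demultiplex(
    reads: Iterable[BarcodedRead],
    barcode_map: BarcodeMap,
    max_mismatch: int = 1,
) -> tuple[dict[str, list[BarcodedRead]], int]:
    """Assign reads to samples by their leading barcode.

    Each read is assigned to the nearest barcode within ``max_mismatch``
    Hamming mismatches (N counts as a mismatch); the barcode bases (and their
    qualities) are stripped from assigned reads.  With all pairwise barcode
    distances >= 2*max_mismatch + 1 the nearest barcode is unique; an exact
    tie is logged and the read left unassigned.

    Returns (per-sample read lists, unassigned count).
    """
    blen = barcode_map.barcode_length
    out: dict[str, list[BarcodedRead]] = {s: [] for s in barcode_map.samples}
    unassigned = 0
    for read in reads:
        if len(read.seq) < blen:
            unassigned += 1
            continue
        prefix = read.seq[:blen]
        best: list[str] = []
        best_d = max_mismatch + 1
        for sample, bc in barcode_map.entries:
            d = hamming(prefix, bc)
            if d < best_d:
                best, best_d = [sample], d
            elif d == best_d:
                best.append(sample)
        if best_d > max_mismatch or len(best) != 1:
            if len(best) > 1 and best_d <= max_mismatch:
                logger.warning(
                    "read %s: barcode tie between %s at %d mismatch(es); unassigned",
                    read.read_id, best, best_d,
                )
            unassigned += 1
            continue
        out[best[0]].append(
            BarcodedRead(read.read_id, read.seq[blen:], read.qual[blen:])
        )
    return out, unassigned


# ---------------------------------------------------------------------------
# FASTQ / FASTA


def read_fastq(path: str | Path | IO[str], offset: int = 33) -> Iterator[BarcodedRead]:
    """Stream FASTQ records as :class:`BarcodedRead` (Phred+33 by default)."""
    fmt = "fastq" if offset == 33 else "fastq-illumina"
    for rec in SeqIO.parse(path, fmt):
        yield BarcodedRead(
            rec.id, str(rec.seq).upper(),
            tuple(rec.letter_annotations["phred_quality"]),
        )


def write_fastq(
    reads: Iterable[BarcodedRead], path: str | Path | IO[str], offset: int = 33
) -> int:
    fmt = "fastq" if offset == 33 else "fastq-illumina"
    records = (
        SeqRecord(
            Seq(r.seq), id=r.read_id, description="",
            letter_annotations={"phred_quality": list(r.qual)},
        )
        for r in reads
    )
    return SeqIO.write(records, path, fmt)


def read_fasta(path: str | Path | IO[str]) -> list[tuple[str, str]]:
    """Read FASTA as a list of (name, sequence) pairs."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path | IO[str]) -> int:
    recs = (SeqRecord(Seq(seq), id=name, description="") for name, seq in records)
    return SeqIO.write(recs, path, "fasta")


# ---------------------------------------------------------------------------
# Alignment formats


def write_phylip(rows: dict[str, str], path: str | Path | IO[str]) -> None:
    """Write a relaxed-PHYLIP alignment (name, whitespace, full sequence)."""
    aln = MultipleSeqAlignment(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in rows.items()]
    )
    AlignIO.write(aln, path, "phylip-relaxed")


def read_phylip(path: str | Path | IO[str]) -> dict[str, str]:
    aln = AlignIO.read(path, "phylip-relaxed")
    return {rec.id: str(rec.seq) for rec in aln}


def write_nexus(
    rows: dict[str, str],
    path: str | Path,
    charsets: list[tuple[str, int, int]] | None = None,
) -> None:
    """Write a NEXUS data block (IUPAC symbols, missing '?', gap '-').

    ``charsets`` are (name, start, end) in 0-based half-open coordinates and
    are exported 1-based inclusive, per NEXUS convention.
    """
    if not rows:
        raise ValueError("empty alignment")
    nchar = len(next(iter(rows.values())))
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"    DIMENSIONS NTAX={len(rows)} NCHAR={nchar};",
        "    FORMAT DATATYPE=DNA MISSING=? GAP=-;",
        "    MATRIX",
    ]
    width = max(len(n) for n in rows) + 2
    for name, seq in rows.items():
        if len(seq) != nchar:
            raise ValueError(f"row {name!r} length {len(seq)} != {nchar}")
        lines.append(f"    {name:<{width}}{seq}")
    lines += ["    ;", "END;"]
    if charsets:
        lines.append("BEGIN SETS;")
        for name, start, end in charsets:
            lines.append(f"    CHARSET {name} = {start + 1}-{end};")
        lines.append("END;")
    Path(path).write_text("\n".join(lines) + "\n")


def read_nexus(path: str | Path) -> dict[str, str]:
    """Read the MATRIX of a NEXUS data block written by :func:`write_nexus`."""
    rows: dict[str, str] = {}
    in_matrix = False
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.strip()
        upper = stripped.upper()
        if upper == "MATRIX":
            in_matrix = True
            continue
        if in_matrix:
            if stripped == ";":
                in_matrix = False
                continue
            parts = stripped.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: malformed matrix row")
            rows[parts[0]] = parts[1].upper()
    if not rows:
        raise ValueError(f"{path}: no MATRIX block found")
    return rows


# ---------------------------------------------------------------------------
# Trees


def read_newick(source: str | Path) -> dendropy.Tree:
    """Parse one Newick tree from a string or file path."""
    text = Path(source).read_text() if isinstance(source, Path) else str(source)
    if "(" not in text and Path(text).exists():
        text = Path(text).read_text()
    return dendropy.Tree.get(data=text, schema="newick")


def read_newick_list(path: str | Path) -> list[dendropy.Tree]:
    """Parse a file holding one Newick tree per line, on a shared taxon set."""
    trees = dendropy.TreeList.get(path=str(path), schema="newick")
    return list(trees)


def write_newick(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    text = tree.as_string(schema="newick", suppress_rooting=True)
    if path is not None:
        Path(path).write_text(text)
    return text
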