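"""Minimal, dialect-explicit readers and writers for the formats the pipeline touches.

Conventions enforced at the boundary:

* genomic intervals are 0-based, half-open everywhere in memory; BED is native,
  SAM positions are converted on read;
* the only table dialect is TSV with a mandatory header row;
* writers emit UTF-8 with LF line endings.

Only the narrow subset of each format needed by the pipeline is supported
(text SAM, BED6, plain FASTA, GMT, TSV).  Binary formats are out of scope.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .enrichment import GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentRecord",
    "MiRNALocus",
    "ParseError",
    "read_bed",
    "write_bed",
    "read_sam_minimal",
    "read_fasta",
    "write_fasta",
    "detect_alphabet",
    "read_gmt",
    "write_gmt",
    "read_table",
    "write_table",
    "read_groups",
    "write_groups",
    "cigar_reference_span",
]


class ParseError(ValueError):
    """A malformed line or record in an input file."""


@dataclass(frozen=True)
class AlignmentRecord:
    """One aligned (or unaligned) read; coordinates 0-based half-open."""

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str | None
    edit_distance: int
    mapped: bool

    def __post_init__(self) -> None:
        if self.mapped:
            if self.start >= self.end:
                raise ValueError(
                    f"mapped record {self.read_id!r} requires start < end "
                    f"(got {self.start} >= {self.end})"
                )
            if self.strand not in ("+", "-"):
                raise ValueError(f"mapped record {self.read_id!r} requires strand +/-")
        if self.edit_distance < 0:
            raise ValueError("edit_distance must be non-negative")


@dataclass(frozen=True)
class MiRNALocus:
    """An annotated miRNA locus (0-based half-open interval)."""

    mirna_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"locus {self.mirna_id!r}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"locus {self.mirna_id!r}: strand must be + or -")


# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[MiRNALocus]:
    """Read a BED6 file of miRNA loci.

    Column 4 becomes ``mirna_id`` (must be unique), column 6 the strand.
    BED start/end map verbatim onto the internal 0-based half-open interval.
    """
    loci: list[MiRNALocus] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: BED6 requires >= 6 columns")
            chrom, start_s, end_s, name, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if strand not in ("+", "-"):
                raise ParseError(
                    f"{path}:{lineno}: strand must be + or - (got {strand!r})"
                )
            if name in seen:
                raise ParseError(f"{path}:{lineno}: duplicate mirna_id {name!r}")
            seen.add(name)
            try:
                loci.append(MiRNALocus(name, chrom, start, end, strand))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return loci


def write_bed(loci: Iterable[MiRNALocus], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for loc in loci:
            fh.write(
                f"{loc.chrom}\t{loc.start}\t{loc.end}\t{loc.mirna_id}\t0\t{loc.strand}\n"
            )


# ---------------------------------------------------------------------------
# SAM (minimal text subset)
# ---------------------------------------------------------------------------

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
# reference-consuming operations
_REF_OPS = frozenset("MDN=X")


def cigar_reference_span(cigar: str) -> int:
    """Number of reference bases consumed by a CIGAR string (M/D/N/=/X)."""
    if cigar == "*" or not cigar:
        raise ParseError(f"unparseable CIGAR {cigar!r}")
    pos = 0
    span = 0
    for match in _CIGAR_RE.finditer(cigar):
        if match.start() != pos:
            raise ParseError(f"unparseable CIGAR {cigar!r}")
        pos = match.end()
        length, op = int(match.group(1)), match.group(2)
        if op in _REF_OPS:
            span += length
    if pos != len(cigar):
        raise ParseError(f"unparseable CIGAR {cigar!r}")
    return span


def read_sam_minimal(path: str | Path) -> list[AlignmentRecord]:
    """Read a text SAM file, consulting only FLAG, RNAME, POS, CIGAR and NM:i.

    POS (1-based) is converted to a 0-based start; end = start + reference
    span of the CIGAR.  FLAG bit 0x10 sets strand '-', bit 0x4 marks the
    record unmapped.  A missing NM tag is treated as edit distance 0 with a
    warning; a record with an unparseable CIGAR is skipped with a warning.
    """
    records: list[AlignmentRecord] = []
    n_skipped = 0
    n_missing_nm = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("@"):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise ParseError(f"{path}:{lineno}: SAM record has < 11 fields")
            qname, flag_s, rname, pos_s, _mapq, cigar = fields[:6]
            try:
                flag = int(flag_s)
                pos = int(pos_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer FLAG/POS") from exc
            mapped = not flag & 0x4
            if not mapped:
                records.append(
                    AlignmentRecord(qname, rname, 0, 0, None, 0, mapped=False)
                )
                continue
            try:
                span = cigar_reference_span(cigar)
            except ParseError:
                logger.warning("%s:%d: skipping record with CIGAR %r", path, lineno, cigar)
                n_skipped += 1
                continue
            nm = None
            for tag in fields[11:]:
                if tag.startswith("NM:i:"):
                    nm = int(tag[5:])
                    break
            if nm is None:
                n_missing_nm += 1
                nm = 0
            start = pos - 1
            strand = "-" if flag & 0x10 else "+"
            records.append(
                AlignmentRecord(qname, rname, start, start + span, strand, nm, mapped=True)
            )
    if n_missing_nm:
        logger.warning(
            "%s: %d record(s) without NM tag treated as edit distance 0",
            path,
            n_missing_nm,
        )
    if n_skipped:
        logger.warning("%s: skipped %d record(s) with unparseable CIGAR", path, n_skipped)
    return records


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read plain FASTA into an ordered ``{id: SEQUENCE}`` mapping.

    The id is the header token before the first whitespace; sequences are
    uppercased but never transliterated between T and U.  Duplicate ids and
    empty sequences are errors.
    """
    seqs: dict[str, str] = {}
    current: str | None = None
    chunks: list[str] = []

    def _flush() -> None:
        if current is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ParseError(f"{path}: empty sequence for id {current!r}")
        seqs[current] = seq

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                current = line[1:].split()[0] if line[1:].split() else ""
                if not current:
                    raise ParseError(f"{path}:{lineno}: empty FASTA header")
                if current in seqs:
                    raise ParseError(f"{path}:{lineno}: duplicate id {current!r}")
                chunks = []
            else:
                if current is None:
                    raise ParseError(f"{path}:{lineno}: sequence before any header")
                chunks.append(line.upper())
    _flush()
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def detect_alphabet(sequence: str) -> str:
    """Classify a sequence as ``"RNA"``, ``"DNA"`` or ``"ambiguous"``.

    A sequence without T or U (e.g. ``"ACG"``) is ambiguous; a sequence with
    both is invalid.
    """
    letters = set(sequence.upper())
    if not letters <= set("ACGTU"):
        raise ValueError(f"non-nucleotide characters: {sorted(letters - set('ACGTU'))}")
    if "T" in letters and "U" in letters:
        raise ValueError("sequence mixes T and U")
    if "U" in letters:
        return "RNA"
    if "T" in letters:
        return "DNA"
    return "ambiguous"


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from GMT (name, description, members...)."""
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT requires >= 3 columns")
            term_id, name = fields[0], fields[1]
            members = list(dict.fromkeys(m for m in fields[2:] if m))
            if not members:
                raise ParseError(f"{path}:{lineno}: gene set {term_id!r} is empty")
            sets.append(GeneSet(term_id=term_id, name=name, members=tuple(members)))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for gs in sets:
            fh.write("\t".join([gs.term_id, gs.name, *gs.members]) + "\n")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV table whose first column is the row index (header mandatory)."""
    return pd.read_csv(path, sep="\t", header=0, index_col=0)


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", lineterminator="\n")


def read_groups(path: str | Path) -> dict[str, str]:
    """Read a sample→group TSV with columns ``sample_id`` and ``group``."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    if df["sample_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate sample ids")
    return dict(zip(df["sample_id"], df["group"]))


def write_groups(groups: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample_id\tgroup\n")
        for sample, group in groups.items():
            fh.write(f"{sample}\t{group}\n")
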