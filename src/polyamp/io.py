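"""Sequence and table I/O for the amplicon pipeline.

Reads arrive either as paired FASTA + QUAL files (the 454 convention) or as
Sanger/phred+33 FASTQ.  All coordinates are 0-based half-open internally;
human-readable reports use 1-based closed intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("polyamp")

READ_ALPHABET = frozenset("ACGTN")
MAX_QUALITY = 93

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class QualifiedRead:
    """One sequencing read: identifier, bases and per-base phred scores."""

    read_id: str
    bases: str
    quals: list[int]
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise FormatError(
                f"read {self.read_id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality scores"
            )
        for i, b in enumerate(self.bases):
            if b not in READ_ALPHABET:
                raise FormatError(
                    f"read {self.read_id!r}: non-ACGTN symbol {b!r} at position {i}"
                )
        for q in self.quals:
            if not (0 <= q <= MAX_QUALITY):
                raise FormatError(
                    f"read {self.read_id!r}: quality {q} outside [0, {MAX_QUALITY}]"
                )

    def __len__(self) -> int:
        return len(self.bases)

    def slice(self, start: int, stop: int) -> "QualifiedRead":
        """Return the [start, stop) sub-read (0-based, half-open)."""
        return QualifiedRead(
            self.read_id, self.bases[start:stop], self.quals[start:stop], self.source
        )

    def reverse_complement(self) -> "QualifiedRead":
        return QualifiedRead(
            self.read_id,
            self.bases.translate(_COMPLEMENT)[::-1],
            self.quals[::-1],
            self.source,
        )

    @property
    def mean_quality(self) -> float:
        return sum(self.quals) / len(self.quals) if self.quals else 0.0


@dataclass
class GeneRegion:
    """An amplified gene region: primer pair and expected copy number.

    ``expected_copies`` is 1 for plastid regions and 2 for nuclear regions
    carrying a homeologous copy pair.
    """

    name: str
    fwd_primer: str
    rev_primer: str
    expected_copies: int = 1
    expected_len: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        for label, p in (("fwd_primer", self.fwd_primer), ("rev_primer", self.rev_primer)):
            if not p or any(b not in "ACGT" for b in p):
                raise ValueError(
                    f"region {self.name!r}: {label} must be nonempty uppercase ACGT, got {p!r}"
                )
        if self.expected_copies not in (1, 2):
            raise ValueError(
                f"region {self.name!r}: expected_copies must be 1 or 2, got {self.expected_copies}"
            )


def _sniff_fastq(path: Path) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return line.startswith("@")
    return False


def read_sequences(
    path_fasta: str | Path,
    path_qual: str | Path | None = None,
    default_quality: int = 30,
) -> list[QualifiedRead]:
    """Load reads from FASTA(+QUAL) or FASTQ.

    When ``path_qual`` is absent and the file looks like FASTQ it is parsed as
    Sanger FASTQ.  A plain FASTA without QUAL gets a constant quality
    (``default_quality``) for every base, with a logged warning.
    """
    path_fasta = Path(path_fasta)
    if not path_fasta.exists():
        raise FileNotFoundError(path_fasta)
    reads: list[QualifiedRead] = []
    if path_qual is None and _sniff_fastq(path_fasta):
        for i, rec in enumerate(SeqIO.parse(str(path_fasta), "fastq")):
            reads.append(
                QualifiedRead(
                    rec.id,
                    str(rec.seq).upper(),
                    list(rec.letter_annotations["phred_quality"]),
                    f"{path_fasta.name}#{i}",
                )
            )
        return reads
    if path_qual is None:
        logger.warning(
            "no QUAL file for %s; assigning constant quality %d", path_fasta, default_quality
        )
        for i, rec in enumerate(SeqIO.parse(str(path_fasta), "fasta")):
            seq = str(rec.seq).upper()
            reads.append(
                QualifiedRead(rec.id, seq, [default_quality] * len(seq), f"{path_fasta.name}#{i}")
            )
        return reads

    path_qual = Path(path_qual)
    fasta_recs = list(SeqIO.parse(str(path_fasta), "fasta"))
    qual_recs = list(SeqIO.parse(str(path_qual), "qual"))
    if len(fasta_recs) != len(qual_recs):
        raise FormatError(
            f"{path_fasta.name} has {len(fasta_recs)} records but "
            f"{path_qual.name} has {len(qual_recs)}"
        )
    for i, (frec, qrec) in enumerate(zip(fasta_recs, qual_recs)):
        if frec.id != qrec.id:
            raise FormatError(
                f"FASTA/QUAL id mismatch at record {i}: {frec.id!r} vs {qrec.id!r}"
            )
        reads.append(
            QualifiedRead(
                frec.id,
                str(frec.seq).upper(),
                list(qrec.letter_annotations["phred_quality"]),
                f"{path_fasta.name}#{i}",
            )
        )
    return reads


def write_sequences(
    reads: Sequence[QualifiedRead],
    path: str | Path,
    format: str = "fastq",
    qual_path: str | Path | None = None,
) -> list[Path]:
    """Write reads as FASTQ or paired FASTA+QUAL; returns the paths written.

    Round-trips with :func:`read_sequences` (ids, bases, quals).
    """
    path = Path(path)
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.bases), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = list(r.quals)
        records.append(rec)
    if format == "fastq":
        for r in reads:
            if max(r.quals, default=0) > MAX_QUALITY:
                raise ValueError(f"read {r.read_id!r}: quality above {MAX_QUALITY} in FASTQ mode")
        SeqIO.write(records, str(path), "fastq")
        return [path]
    if format == "fasta+qual":
        if qual_path is None:
            qual_path = path.with_suffix(".qual")
        qual_path = Path(qual_path)
        SeqIO.write(records, str(path), "fasta")
        SeqIO.write(records, str(qual_path), "qual")
        return [path, qual_path]
    raise ValueError(f"unknown format {format!r} (expected 'fastq' or 'fasta+qual')")


def read_region_table(path: str | Path) -> list[GeneRegion]:
    """Parse a headered TSV of gene regions.

    Columns: name, fwd_primer, rev_primer, expected_copies[, min_len, max_len].
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"name", "fwd_primer", "rev_primer", "expected_copies"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"region table {path} missing columns: {sorted(missing)}")
    regions = []
    for _, row in df.iterrows():
        expected_len = None
        if "min_len" in df.columns and "max_len" in df.columns:
            if not (pd.isna(row["min_len"]) or pd.isna(row["max_len"])):
                expected_len = (int(row["min_len"]), int(row["max_len"]))
        regions.append(
            GeneRegion(
                name=row["name"],
                fwd_primer=row["fwd_primer"].upper(),
                rev_primer=row["rev_primer"].upper(),
                expected_copies=int(row["expected_copies"]),
                expected_len=expected_len,
            )
        )
    return regions


def write_region_table(regions: Sequence[GeneRegion], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "name": [r.name for r in regions],
            "fwd_primer": [r.fwd_primer for r in regions],
            "rev_primer": [r.rev_primer for r in regions],
            "expected_copies": [r.expected_copies for r in regions],
        }
    ).to_csv(path, sep="\t", index=False)
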