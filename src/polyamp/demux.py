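"""Region assignment, orientation and trimming of barcoded amplicon reads.

The canonical read layout (sequencing from the A-adapter end) is

    barcode word (4 bp) - ligation T - primer - insert - rc(other primer)
    - ligation A - adapter B

where the primer after the barcode is the region's forward primer (forward
orientation) or its reverse primer (the other strand was ligated to the
barcode; reverse orientation).  Reads are assigned to a region by fuzzy
primer matching near the 5' end, the barcode word is resolved through the
checksum sample sheet, and the insert is excised; reverse-orientation
inserts are reverse-complemented so everything downstream sees the forward
strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

from . import barcodes
from .barcodes import Rejection, SampleSheet
from .io import GeneRegion, QualifiedRead

# GS FLX Titanium adapters (Lib-L chemistry)
ADAPTER_A = "CGTATCGCCTCCCTCGCGCCATCAG"
ADAPTER_B = "CTGAGCGGGCTGGCAAGGCGCATAG"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def fuzzy_find(
    pattern: str, text: str, max_mismatch: int, window: Optional[int] = None
) -> Optional[tuple[int, int]]:
    """Best occurrence of ``pattern`` in ``text`` with <= max_mismatch
    substitutions, scanning start positions up to ``window`` (or the whole
    text).  Returns (position, mismatches) or None.  N counts as a mismatch.
    """
    m = len(pattern)
    limit = len(text) - m
    if window is not None:
        limit = min(limit, window)
    best: Optional[tuple[int, int]] = None
    for start in range(0, limit + 1):
        mm = 0
        for a, b in zip(pattern, text[start : start + m]):
            if a != b:
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            if best is None or mm < best[1]:
                best = (start, mm)
                if mm == 0:
                    break
    return best


@dataclass
class RegionHit:
    status: str  # assigned | unassigned | ambiguous
    region: Optional[str] = None
    orientation: Optional[str] = None  # forward | reverse
    primer_start: int = -1
    mismatches: int = -1


@dataclass
class DemuxedRead:
    """A read assigned to a region, oriented to the forward strand."""

    read: QualifiedRead
    region: str
    orientation: str
    insert_interval: tuple[int, int]
    barcode_word: Optional[str] = None


@dataclass
class TrimResult:
    sample_id: str
    insert: QualifiedRead
    barcode_word: str
    region: str
    orientation: str


def assign_region(
    read: QualifiedRead,
    regions: Sequence[GeneRegion],
    max_mismatch: int = 1,
    window: int = 40,
) -> RegionHit:
    """Assign a read to a gene region by primer matching near the 5' end.

    Searches each region's forward and reverse primer within the first
    ``window`` start positions; the primer found tells both the region and
    the orientation.  Equally good hits in two regions -> ambiguous.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    hits: list[tuple[int, str, str, int]] = []  # (mismatches, region, orientation, pos)
    for region in regions:
        for primer, orientation in (
            (region.fwd_primer, "forward"),
            (region.rev_primer, "reverse"),
        ):
            found = fuzzy_find(primer, read.bases, max_mismatch, window)
            if found is not None:
                hits.append((found[1], region.name, orientation, found[0]))
                continue
            # fragmented read starting inside the primer: a primer suffix of
            # >= 10 bases at position 0 still identifies the region (the
            # barcode is gone, so downstream trimming rejects word_missing)
            for k in range(1, len(primer) - 9):
                tail = primer[k:]
                if len(read.bases) < len(tail):
                    continue
                mm = sum(1 for a, b in zip(tail, read.bases) if a != b)
                if mm <= max_mismatch:
                    hits.append((mm, region.name, orientation, 0))
                    break
    if not hits:
        return RegionHit("unassigned")
    hits.sort()
    best = hits[0]
    rivals = [h for h in hits[1:] if h[0] == best[0] and h[1] != best[1]]
    if rivals:
        return RegionHit("ambiguous")
    return RegionHit("assigned", best[1], best[2], best[3], best[0])


def trim_to_insert(
    read: QualifiedRead,
    hit: RegionHit,
    sheet: SampleSheet,
    region: GeneRegion,
    max_mismatch: int = 1,
) -> Union[TrimResult, Rejection]:
    """Excise the amplicon insert and resolve the sample barcode.

    The 4-base word sits immediately 5' of the ligation T + matched primer;
    reads starting inside the primer (fragmented, no barcode reachable) are
    rejected as WORD_MISSING.  The 3' side is trimmed at the reverse
    complement of the opposite primer when present.  Reverse-orientation
    inserts are reverse-complemented (qualities reversed).
    """
    if hit.status != "assigned":
        raise ValueError("trim_to_insert requires an assigned RegionHit")
    p = hit.primer_start
    if p < 5:
        return Rejection.WORD_MISSING
    word = read.bases[p - 5 : p - 1]
    resolved = barcodes.deconvolve(word, sheet)
    if isinstance(resolved, Rejection):
        return resolved

    if hit.orientation == "forward":
        primer_5p, primer_3p = region.fwd_primer, region.rev_primer
    else:
        primer_5p, primer_3p = region.rev_primer, region.fwd_primer
    insert_start = p + len(primer_5p)
    insert_end = _find_insert_end(read.bases, insert_start, primer_3p, max_mismatch)
    if insert_end - insert_start < 1:
        return EMPTY_INSERT
    insert = read.slice(insert_start, insert_end)
    if hit.orientation == "reverse":
        insert = insert.reverse_complement()
    return TrimResult(resolved, insert, word, hit.region or "", hit.orientation or "")


def _find_insert_end(
    bases: str, insert_start: int, primer_3p: str, max_mismatch: int
) -> int:
    """Locate the 3' end of the insert.

    The tail of a full-length read is rc(primer_3p) + ligation A + adapter B.
    The primer search tolerates more mismatches than the 5' match (errors
    here merely shift a trim), with the adapter and a partial primer prefix
    as fallbacks for error-riddled or truncated tails.
    """
    tail = reverse_complement(primer_3p)
    rest = bases[insert_start:]
    found = fuzzy_find(tail, rest, max(3, max_mismatch))
    if found is not None:
        return insert_start + found[0]
    fa = fuzzy_find(ADAPTER_B, rest, 3)
    if fa is not None:
        return insert_start + max(fa[0] - 1 - len(tail), 0)
    # truncated read ending inside the primer tail
    for ln in range(len(tail) - 1, 7, -1):
        pos = len(rest) - ln
        if pos < 0:
            continue
        mm = sum(1 for a, b in zip(tail[:ln], rest[pos:]) if a != b)
        if mm <= 1:
            return insert_start + pos
    return len(bases)


class EmptyInsert:
    """Sentinel rejection: nothing left between the primers after trimming."""

    value = "empty_insert"

    def __repr__(self) -> str:  # pragma: no cover
        return "EMPTY_INSERT"


EMPTY_INSERT = EmptyInsert()
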