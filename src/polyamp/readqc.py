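"""Read quality control: end trimming, low-quality masking, length filtering.

Bases below the masking threshold (phred < 15 by default) are replaced by N
so they never vote in consensus or error-rate calculations; read ends are
trimmed back to the first sliding window whose mean quality clears the
threshold; short leftovers are removed.  QC is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .io import QualifiedRead


@dataclass
class QcParams:
    mask_quality: int = 15
    end_window: int = 10
    end_mean_quality: float = 15.0
    min_length: int = 100

    def __post_init__(self) -> None:
        if self.end_window < 1:
            raise ValueError("end_window must be >= 1")
        if min(self.mask_quality, self.end_mean_quality, self.min_length) < 0:
            raise ValueError("QC thresholds must be non-negative")


def trim_ends(read: QualifiedRead, p: QcParams) -> QualifiedRead:
    """Trim low-quality ends.

    From each end a window of ``end_window`` bases advances inward until its
    mean quality reaches ``end_mean_quality``; the enclosed slice is returned.
    The whole read may be consumed (empty reads are removed later by the
    length filter).
    """
    n = len(read)
    if n == 0:
        return read
    w = min(p.end_window, n)
    q = read.quals
    # cumulative sums for O(1) window means
    cum = [0] * (n + 1)
    for i, v in enumerate(q):
        cum[i + 1] = cum[i] + v
    thr = p.end_mean_quality * w
    left = None
    for i in range(0, n - w + 1):
        if cum[i + w] - cum[i] >= thr:
            left = i
            break
    if left is None:
        return read.slice(0, 0)
    # step past any leading bases of the window still under the threshold
    while left < n and q[left] < p.end_mean_quality:
        left += 1
    right = None
    for j in range(n, w - 1, -1):
        if cum[j] - cum[j - w] >= thr:
            right = j
            break
    if right is None:
        return read.slice(0, 0)
    while right > 0 and q[right - 1] < p.end_mean_quality:
        right -= 1
    if right <= left:
        return read.slice(0, 0)
    return read.slice(left, right)


def mask_low_quality(read: QualifiedRead, p: QcParams) -> QualifiedRead:
    """Replace every base with quality below ``mask_quality`` by N.

    Qualities and read length are unchanged.
    """
    bases = "".join(
        "N" if q < p.mask_quality else b for b, q in zip(read.bases, read.quals)
    )
    return QualifiedRead(read.read_id, bases, list(read.quals), read.source)


def length_filter(
    reads: Sequence[QualifiedRead], p: QcParams
) -> tuple[list[QualifiedRead], int]:
    """Retain reads of length >= min_length; returns (retained, discard count)."""
    kept = [r for r in reads if len(r) >= p.min_length]
    return kept, len(reads) - len(kept)


def apply_qc(read: QualifiedRead, p: QcParams) -> Optional[QualifiedRead]:
    """Trim ends, mask low-quality calls, drop the read if it ends up short.

    Returns None when the read fails the length filter.
    """
    out = mask_low_quality(trim_ends(read, p), p)
    if len(out) < p.min_length:
        return None
    return out
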