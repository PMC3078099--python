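"""Checksum-protected 4-base barcode words and sample deconvolution.

Each barcode word is a 3-bp code plus one checksum base chosen so that the
sum of base indices (A=0, C=1, G=2, T=3) over all four bases is 0 mod 4.
Exactly 64 of the 256 possible 4-mers are therefore valid, and any single
substitution changes the sum mod 4, so every single-base miscall in the word
is detected.  Matching is exact: mismatched words are discarded, never
error-corrected.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Union

BASES = "ACGT"
_INDEX = {b: i for i, b in enumerate(BASES)}

WORD_LENGTH = 4


def checksum_base(code: str) -> str:
    """Checksum base for a 3-bp code: the base making the index sum 0 mod 4."""
    if len(code) != 3:
        raise ValueError(f"code must be 3 bases, got {code!r}")
    try:
        s = sum(_INDEX[b] for b in code)
    except KeyError as exc:
        raise ValueError(f"non-ACGT symbol in code {code!r}") from exc
    return BASES[(-s) % 4]


@dataclass(frozen=True)
class BarcodeWord:
    code: str
    check: str

    def __post_init__(self) -> None:
        if checksum_base(self.code) != self.check:
            raise ValueError(f"invalid checksum {self.check!r} for code {self.code!r}")

    @property
    def word(self) -> str:
        return self.code + self.check


def generate_barcode_words() -> list[BarcodeWord]:
    """All 64 valid barcode words, sorted lexicographically."""
    words = [
        BarcodeWord(code := a + b + c, checksum_base(code))
        for a in BASES
        for b in BASES
        for c in BASES
    ]
    return sorted(words, key=lambda w: w.word)


def validate_word(word: str) -> bool:
    """Accept iff the 4th base is the checksum of the first three (N rejects)."""
    if len(word) != WORD_LENGTH:
        raise ValueError(f"word must be {WORD_LENGTH} bases, got {word!r}")
    if any(b not in "ACGTN" for b in word):
        raise ValueError(f"word {word!r} contains symbols outside ACGTN")
    if "N" in word:
        return False
    return word[3] == checksum_base(word[:3])


class Rejection(enum.Enum):
    """Why a read failed barcode deconvolution."""

    CHECKSUM_FAIL = "checksum_fail"
    UNKNOWN_WORD = "unknown_word"
    WORD_MISSING = "word_missing"


@dataclass
class SampleSheet:
    """Mapping of valid barcode words to sample identifiers."""

    entries: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.entries) > 64:
            raise ValueError(f"sample sheet has {len(self.entries)} entries; at most 64 allowed")
        for word in self.entries:
            if not validate_word(word):
                raise ValueError(f"sample sheet word {word!r} fails the checksum")
        samples = list(self.entries.values())
        if len(set(samples)) != len(samples):
            raise ValueError("sample identifiers are not unique")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleSheet":
        """Load a headered TSV with columns word, sample_id."""
        import pandas as pd

        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"word", "sample_id"} <= set(df.columns):
            raise ValueError(f"sample sheet {path} needs columns word, sample_id")
        return cls(dict(zip(df["word"], df["sample_id"])))

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"word": list(self.entries), "sample_id": list(self.entries.values())}
        ).to_csv(path, sep="\t", index=False)

    def __len__(self) -> int:
        return len(self.entries)


def deconvolve(prefix: str, sheet: SampleSheet) -> Union[str, Rejection]:
    """Resolve the 4-base word at the start of ``prefix`` to a sample id.

    ``prefix`` is the oriented read sequence whose first four bases should be
    the barcode word (immediately preceding the ligation T + primer).  Returns
    the sample id, or a :class:`Rejection` reason.
    """
    if len(prefix) < WORD_LENGTH:
        return Rejection.WORD_MISSING
    word = prefix[:WORD_LENGTH]
    if any(b not in "ACGTN" for b in word):
        return Rejection.WORD_MISSING
    if not validate_word(word):
        return Rejection.CHECKSUM_FAIL
    sample = sheet.entries.get(word)
    if sample is None:
        return Rejection.UNKNOWN_WORD
    return sample
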