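"""PCR-recombinant (chimera) detection among apparent alleles.

A PCR chimera is an artifactual sequence whose two ends derive from
different template alleles.  Candidates — apparent alleles in a minority of
a group's reads — are declared recombinant when some breakpoint splits them
into a prefix matching one common allele and a suffix matching a different
common allele, while no single common allele explains the whole sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .allele_calling import GAP, AlleleCall, align_group
from .io import QualifiedRead


@dataclass
class ChimeraParams:
    minority_threshold: float = 0.05  # exclusive fraction of group reads
    parent_tolerance: int = 1  # max mismatches per matched segment
    min_segment: int = 30  # min bases matched to each parent

    def __post_init__(self) -> None:
        if not (0 < self.minority_threshold < 1):
            raise ValueError("minority_threshold must be in (0, 1)")


@dataclass
class ChimeraReport:
    candidate: str  # allele label of the inspected call
    verdict: str  # recombinant | clean
    parent_1: Optional[str] = None
    parent_2: Optional[str] = None
    breakpoint_interval: Optional[tuple[int, int]] = None  # aligned columns, half-open

    def __post_init__(self) -> None:
        if self.verdict == "recombinant":
            if self.parent_1 is None or self.parent_1 == self.parent_2:
                raise ValueError("recombinant verdict requires two distinct parents")
            if not self.breakpoint_interval or (
                self.breakpoint_interval[1] <= self.breakpoint_interval[0]
            ):
                raise ValueError("recombinant verdict requires a nonempty breakpoint interval")


def _profiles(
    cand_row: str,
    cand_cov: tuple[int, int],
    parent_row: str,
    parent_cov: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative mismatch / matched-base counts of candidate vs one parent.

    Columns where either side is N or outside coverage are neutral; gap
    columns within coverage count as mismatches (an indel disagreement),
    equal non-gap symbols count as matched bases.
    """
    n = len(cand_row)
    mism = np.zeros(n + 1, dtype=int)
    match = np.zeros(n + 1, dtype=int)
    lo = max(cand_cov[0], parent_cov[0])
    hi = min(cand_cov[1], parent_cov[1])
    for c in range(n):
        m = x = 0
        if lo <= c < hi:
            a, b = cand_row[c], parent_row[c]
            if "N" not in (a, b):
                if a == b:
                    if a != GAP:
                        x = 1
                else:
                    m = 1
        mism[c + 1] = mism[c] + m
        match[c + 1] = match[c] + x
    return mism, match


def detect_recombinants(
    calls: Sequence[AlleleCall],
    total_reads: int,
    p: ChimeraParams = ChimeraParams(),
    reads: Optional[dict[str, QualifiedRead]] = None,
) -> list[ChimeraReport]:
    """Scan one group's minority alleles for PCR recombinants.

    ``calls`` are all allele calls of one (sample, region) group, flagged or
    not; ``total_reads`` is the group read count used for the minority
    criterion.  Common alleles are the unflagged calls at or above the
    minority threshold; with fewer than two of them there is nothing to
    recombine and the scan returns no reports.

    When ``reads`` (read_id -> masked read) is supplied, a multi-read
    candidate whose consensus scans clean is also examined read by read:
    chimeras from the same parent pair but different breakpoints co-cluster
    into a consensus with no single junction, yet every member read has one.
    The cluster is called recombinant only if all its members are.
    """
    calls = list(calls)
    common = [
        c
        for c in calls
        if not c.flags
        and total_reads > 0
        and c.support_count / total_reads >= p.minority_threshold
    ]
    if len(common) < 2:
        return []
    candidates = [c for c in calls if c not in common]
    reports = []
    for cand in candidates:
        report = _scan_candidate(cand, common, p)
        if (
            report.verdict == "clean"
            and reads is not None
            and cand.support_count >= 2
            and all(rid in reads for rid in cand.supporting_read_ids)
        ):
            member_reports = []
            for rid in cand.supporting_read_ids:
                member = AlleleCall(
                    sample=cand.sample,
                    region=cand.region,
                    allele_label=cand.allele_label,
                    consensus=reads[rid].bases.strip("N"),
                    supporting_read_ids=[rid],
                )
                member_reports.append(_scan_candidate(member, common, p))
            if member_reports and all(r.verdict == "recombinant" for r in member_reports):
                first = member_reports[0]
                lo = min(r.breakpoint_interval[0] for r in member_reports)
                hi = max(r.breakpoint_interval[1] for r in member_reports)
                report = ChimeraReport(
                    cand.allele_label,
                    "recombinant",
                    parent_1=first.parent_1,
                    parent_2=first.parent_2,
                    breakpoint_interval=(lo, hi),
                )
        reports.append(report)
    return reports


def _scan_candidate(
    cand: AlleleCall, common: list[AlleleCall], p: ChimeraParams
) -> ChimeraReport:
    seqs = [cand.consensus] + [c.consensus for c in common]
    pseudo = [QualifiedRead(f"s{i}", s, [40] * len(s)) for i, s in enumerate(seqs)]
    aln = align_group(pseudo)
    # align_group preserves input order in rows
    cand_row, cand_cov = aln.rows[0], aln.coverage[0]
    n_cols = aln.n_columns

    profiles = []
    for i, parent in enumerate(common, start=1):
        mism, match = _profiles(cand_row, cand_cov, aln.rows[i], aln.coverage[i])
        profiles.append((parent, mism, match))

    # single-parent match => clean
    for parent, mism, match in profiles:
        if mism[-1] <= 2 * p.parent_tolerance:
            return ChimeraReport(cand.allele_label, "clean")

    best: Optional[tuple[str, str, int, int]] = None  # p1, p2, first_k, last_k
    per_pair: dict[tuple[str, str], list[int]] = {}
    for k in range(1, n_cols):
        prefix_ok = [
            parent.allele_label
            for parent, mism, match in profiles
            if mism[k] <= p.parent_tolerance and match[k] >= p.min_segment
        ]
        suffix_ok = [
            parent.allele_label
            for parent, mism, match in profiles
            if (mism[-1] - mism[k]) <= p.parent_tolerance
            and (match[-1] - match[k]) >= p.min_segment
        ]
        for p1 in prefix_ok:
            for p2 in suffix_ok:
                if p1 != p2:
                    per_pair.setdefault((p1, p2), []).append(k)
    if not per_pair:
        return ChimeraReport(cand.allele_label, "clean")
    (p1, p2), ks = max(per_pair.items(), key=lambda kv: len(kv[1]))
    return ChimeraReport(
        cand.allele_label,
        "recombinant",
        parent_1=p1,
        parent_2=p2,
        breakpoint_interval=(min(ks), max(ks) + 1),
    )
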