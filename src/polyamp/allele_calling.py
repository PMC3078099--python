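"""Per-sample allele calling for homeologous loci.

Each (sample, region) read group is star-aligned against its longest read,
reads are clustered by haplotype over the variable columns, and clusters are
accepted as distinct alleles only when they differ consistently by at least
``min_diff`` base positions in more than ``consistency`` of their reads —
the stringency that makes the workflow robust to residual sequencing error.
Alleles of a two-copy nuclear region are then partitioned into homeologous
copies A and B across samples, diagnosed by fixed differences, absence of
shared polymorphisms, and diagnostic indels.  Sequencing error is estimated
from single-copy (plastid) alignments where every non-consensus call is an
error.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .io import QualifiedRead

logger = logging.getLogger("polyamp")

GAP = "-"
_ALPHABET = "ACGTN"


def _make_aligner() -> Align.PairwiseAligner:
    """Affine-gap global aligner with free end gaps; N is neutral."""
    matrix = substitution_matrices.Array(_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            if "N" in (a, b):
                matrix[a, b] = 0.0
            elif a == b:
                matrix[a, b] = 2.0
            else:
                matrix[a, b] = -2.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -8.0
    aligner.extend_gap_score = -1.0
    aligner.open_end_insertion_score = 0.0
    aligner.extend_end_insertion_score = 0.0
    aligner.open_end_deletion_score = 0.0
    aligner.extend_end_deletion_score = 0.0
    return aligner


_ALIGNER = _make_aligner()


@dataclass
class GroupAlignment:
    """Multiple alignment of all reads for one (sample, region)."""

    sample: str
    region: str
    read_ids: list[str]
    rows: list[str]
    row_mean_quality: list[float]
    coverage: list[tuple[int, int]]  # per row, [first, last) aligned column
    qual_rows: Optional[list[list[int]]] = None  # per-column quality, -1 at gaps

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"alignment rows have unequal lengths {lengths}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def ungapped_row(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")

    def symbol(self, i: int, col: int) -> str:
        """Aligned symbol for row i at col; uncovered positions report N."""
        lo, hi = self.coverage[i]
        if not (lo <= col < hi):
            return "N"
        return self.rows[i][col]

    def base_quality(self, i: int, col: int) -> float:
        if self.qual_rows is not None:
            q = self.qual_rows[i][col]
            if q >= 0:
                return float(q)
        return self.row_mean_quality[i]

    def consensus(self, row_indices: Optional[Sequence[int]] = None) -> str:
        """Majority symbol per column over {A,C,G,T,-}; N and uncovered
        positions do not vote.  Ties go to the symbol backed by the highest
        summed base quality (erroneous calls carry lower scores), then
        alphabetically.  Columns with no votes render as N."""
        idx = list(range(self.n_rows)) if row_indices is None else list(row_indices)
        out = []
        for col in range(self.n_columns):
            votes: Counter = Counter()
            qual: dict[str, float] = defaultdict(float)
            for i in idx:
                s = self.symbol(i, col)
                if s == "N":
                    continue
                votes[s] += 1
                qual[s] += self.base_quality(i, col) if s != GAP else self.row_mean_quality[i]
            if not votes:
                out.append("N")
                continue
            best = min(votes)
            best_key = (votes[best], qual[best])
            for s in sorted(votes):
                key = (votes[s], qual[s])
                if key > best_key:
                    best, best_key = s, key
            out.append(best)
        return "".join(out)

    def variable_columns(self, min_minor: int = 1) -> list[int]:
        """Columns with >= 2 distinct non-N symbols among covering rows.

        With ``min_minor`` > 1 every symbol must be carried by at least that
        many rows, which screens out columns whose variation is a singleton
        (indistinguishable from a sequencing error)."""
        cols = []
        for col in range(self.n_columns):
            counts = Counter()
            for i in range(self.n_rows):
                s = self.symbol(i, col)
                if s != "N":
                    counts[s] += 1
            if sum(1 for c in counts.values() if c >= min_minor) >= 2:
                cols.append(col)
        return cols

    def repeat_columns(self, min_run: int = 6) -> set[int]:
        """Columns inside mononucleotide runs of > 5 bp on the consensus.

        Run length is measured on the ungapped consensus; gap columns flanked
        by the run are included (length variation in such runs is unreliable
        in pyrosequencing-style data)."""
        cons = self.consensus()
        # map ungapped consensus positions to columns
        base_cols = [c for c, s in enumerate(cons) if s not in (GAP, "N")]
        ungapped = "".join(cons[c] for c in base_cols)
        flagged: set[int] = set()
        i = 0
        while i < len(ungapped):
            j = i
            while j < len(ungapped) and ungapped[j] == ungapped[i]:
                j += 1
            if j - i >= min_run:
                lo, hi = base_cols[i], base_cols[j - 1]
                # include adjacent gap columns: length variation at a run's
                # edge is part of the same unreliable stretch
                while lo > 0 and cons[lo - 1] == GAP:
                    lo -= 1
                while hi + 1 < len(cons) and cons[hi + 1] == GAP:
                    hi += 1
                flagged.update(range(lo, hi + 1))
            i = j
        return flagged


def align_group(
    reads: Sequence[QualifiedRead], sample: str = "", region: str = ""
) -> GroupAlignment:
    """Star-align a read group against a pivot.

    The pivot is the longest read (ties broken by lexicographically smallest
    id); every other read is pairwise-aligned to it with affine gap costs and
    the pairwise alignments are merged column-wise (once a gap, always a
    gap).  Leading/trailing gaps record truncation, not deletion, and are
    reported as uncovered via ``coverage``.
    """
    if not reads:
        raise ValueError("align_group requires at least one read")
    order = sorted(range(len(reads)), key=lambda i: (-len(reads[i]), reads[i].read_id))
    pivot_i = order[0]
    pivot = reads[pivot_i]
    lp = len(pivot)

    # per read: insertions before pivot position t, aligned char per pivot pos,
    # covered pivot interval
    per_read = []
    for i, read in enumerate(reads):
        if i == pivot_i:
            continue
        if len(read) == 0:
            per_read.append((i, {}, [GAP] * lp, (0, 0)))
            continue
        aln = _ALIGNER.align(pivot.bases, read.bases)[0]
        t_blocks, q_blocks = aln.aligned
        ins: dict[int, str] = {}
        chars = [GAP] * lp
        if len(t_blocks) == 0:
            per_read.append((i, {0: read.bases}, chars, (0, 0)))
            continue
        # unaligned query head/tail become insertions at the flanking pivot pos
        if q_blocks[0][0] > 0:
            ins[int(t_blocks[0][0])] = read.bases[: q_blocks[0][0]]
        if q_blocks[-1][1] < len(read):
            t_end = int(t_blocks[-1][1])
            ins[t_end] = ins.get(t_end, "") + read.bases[q_blocks[-1][1] :]
        for bi in range(len(t_blocks)):
            t0, t1 = map(int, t_blocks[bi])
            q0, q1 = map(int, q_blocks[bi])
            for k in range(t1 - t0):
                chars[t0 + k] = read.bases[q0 + k]
            if bi + 1 < len(t_blocks):
                nq0 = int(q_blocks[bi + 1][0])
                if nq0 > q1:  # query insertion between blocks
                    at = int(t_blocks[bi + 1][0])
                    ins[at] = ins.get(at, "") + read.bases[q1:nq0]
        cov = (int(t_blocks[0][0]), int(t_blocks[-1][1]))
        per_read.append((i, ins, chars, cov))

    ins_len = [0] * (lp + 1)
    for _, ins, _, _ in per_read:
        for t, seg in ins.items():
            ins_len[t] = max(ins_len[t], len(seg))

    # column layout: for t in 0..lp: ins_len[t] insertion columns, then pivot col t
    col_of_pivot = [0] * lp
    col = 0
    ins_col_start = [0] * (lp + 1)
    for t in range(lp + 1):
        ins_col_start[t] = col
        col += ins_len[t]
        if t < lp:
            col_of_pivot[t] = col
            col += 1
    n_cols = col

    rows: list[Optional[str]] = [None] * len(reads)
    qual_rows: list[Optional[list[int]]] = [None] * len(reads)
    coverage: list[tuple[int, int]] = [(0, 0)] * len(reads)
    pivot_row = [GAP] * n_cols
    pivot_quals = [-1] * n_cols
    for t in range(lp):
        pivot_row[col_of_pivot[t]] = pivot.bases[t]
        pivot_quals[col_of_pivot[t]] = pivot.quals[t]
    rows[pivot_i] = "".join(pivot_row)
    qual_rows[pivot_i] = pivot_quals
    coverage[pivot_i] = (0, n_cols)

    for i, ins, chars, cov in per_read:
        read = reads[i]
        row = [GAP] * n_cols
        qrow = [-1] * n_cols
        first, last = n_cols, 0
        for t, seg in sorted(ins.items()):
            start = ins_col_start[t]
            for k, ch in enumerate(seg):
                row[start + k] = ch
            first = min(first, start)
            last = max(last, start + len(seg))
        for t in range(cov[0], cov[1]):
            c = col_of_pivot[t]
            row[c] = chars[t]
        if cov[1] > cov[0]:
            first = min(first, col_of_pivot[cov[0]])
            last = max(last, col_of_pivot[cov[1] - 1] + 1)
        if first > last:
            first = last = 0
        # qualities: walk the row left to right consuming read bases in order
        qi = 0
        for c in range(n_cols):
            if row[c] != GAP:
                qrow[c] = read.quals[qi]
                qi += 1
        rows[i] = "".join(row)
        qual_rows[i] = qrow
        coverage[i] = (first, last)

    return GroupAlignment(
        sample=sample,
        region=region,
        read_ids=[r.read_id for r in reads],
        rows=[r for r in rows if r is not None],
        row_mean_quality=[r.mean_quality for r in reads],
        coverage=coverage,
        qual_rows=[q for q in qual_rows if q is not None],
    )


@dataclass
class AlleleCallingParams:
    min_diff: int = 2  # bases required to declare distinct alleles
    consistency: float = 0.80  # fraction of a cluster's reads backing each difference
    min_support: int = 2
    minor_fraction_floor: float = 0.05

    def __post_init__(self) -> None:
        if self.min_diff < 1:
            raise ValueError("min_diff must be >= 1")
        if not (0 < self.consistency <= 1):
            raise ValueError("consistency must be in (0, 1]")


@dataclass
class AlleleCall:
    sample: str
    region: str
    allele_label: str
    consensus: str
    supporting_read_ids: list[str]
    copy_label: str = "unassigned"  # A | B | unassigned
    flags: set[str] = field(default_factory=set)
    aligned_consensus: str = ""

    @property
    def support_count(self) -> int:
        return len(self.supporting_read_ids)


def _restricted_diff(cons_a: str, cons_b: str, cols: Sequence[int]) -> int:
    """Disagreements between two cluster consensi over the given columns
    (N never counts)."""
    n = 0
    for col in cols:
        x, y = cons_a[col], cons_b[col]
        if x != y and "N" not in (x, y):
            n += 1
    return n


def _cluster_patterns(patterns: list[tuple]) -> list[list[int]]:
    """Greedy leader clustering of haplotype patterns.

    Reads are visited most-informative first (fewest wildcards) and join the
    largest cluster whose majority pattern they do not contradict at any
    mutually determined column; a read conflicting with every cluster founds
    a new one.  Wildcards ('?': masked or uncovered) never conflict, so
    partially observed reads fall into the haplotype they are consistent
    with.
    """
    order = sorted(
        range(len(patterns)), key=lambda i: (sum(1 for s in patterns[i] if s == "?"), i)
    )
    members: list[list[int]] = []
    counts: list[list[Counter]] = []  # per cluster, per column symbol counts

    def majority(ci: int, col: int) -> Optional[str]:
        c = counts[ci][col]
        if not c:
            return None
        return max(sorted(c), key=lambda s: c[s])

    for i in order:
        pat = patterns[i]
        best, best_key = None, None
        for ci in range(len(members)):
            conflicts = 0
            for col, s in enumerate(pat):
                if s == "?":
                    continue
                m = majority(ci, col)
                if m is not None and m != s:
                    conflicts += 1
            key = (conflicts, -len(members[ci]), ci)
            if best_key is None or key < best_key:
                best, best_key = ci, key
        if best is not None and best_key is not None and best_key[0] == 0:
            members[best].append(i)
            for col, s in enumerate(pat):
                if s != "?":
                    counts[best][col][s] += 1
        else:
            members.append([i])
            counts.append([Counter({s: 1}) if s != "?" else Counter() for s in pat])
    return members


def call_alleles(
    aln: GroupAlignment,
    p: AlleleCallingParams = AlleleCallingParams(),
    expected_copies: Optional[int] = None,
) -> list[AlleleCall]:
    """Cluster a group alignment into allele calls.

    Reads are grouped by haplotype over the variable columns (N and
    uncovered positions are wildcards); clusters whose consensi differ at
    fewer than ``min_diff`` non-repeat columns are merged into the larger
    cluster, as are clusters failing the per-column consistency test.
    Clusters below ``min_support`` reads or below ``minor_fraction_floor``
    of the group are flagged ``low_support`` (the chimera scan inspects
    them).
    """
    if aln.n_rows == 0:
        return []
    varcols = aln.variable_columns(min_minor=2)
    repeat_cols = aln.repeat_columns()
    # alleles can only be told apart at supported variable columns; columns
    # whose variation is a singleton are error-indistinguishable and never
    # count toward allele differences
    diff_cols = [c for c in varcols if c not in repeat_cols]

    patterns = []
    for i in range(aln.n_rows):
        patterns.append(tuple(aln.symbol(i, c) if aln.symbol(i, c) != "N" else "?"
                              for c in varcols))
    clusters = _cluster_patterns(patterns)

    def cons(members: list[int]) -> str:
        return aln.consensus(members)

    consensi = [cons(m) for m in clusters]

    def column_fraction(ci: int, col: int, symbol: str) -> float:
        """Fraction of cluster ci's informative (non-N, covered) reads
        carrying ``symbol`` at ``col``."""
        total = hits = 0
        for i in clusters[ci]:
            s = aln.symbol(i, col)
            if s == "N":
                continue
            total += 1
            if s == symbol:
                hits += 1
        return hits / total if total else 1.0

    def consistent_diff(ci: int, cj: int) -> int:
        """Columns at which the two clusters differ consistently: consensi
        disagree and each side's base is carried by > ``consistency`` of its
        own informative reads.  Columns noisy within either cluster carry no
        weight toward declaring distinct alleles."""
        n = 0
        for col in diff_cols:
            x, y = consensi[ci][col], consensi[cj][col]
            if x == y or "N" in (x, y):
                continue
            if (
                column_fraction(ci, col, x) > p.consistency
                and column_fraction(cj, col, y) > p.consistency
            ):
                n += 1
        return n

    # two clusters are distinct alleles only when they differ consistently
    # at >= min_diff columns; otherwise the smaller merges into the larger
    merged = True
    while merged and len(clusters) > 1:
        merged = False
        for ci in sorted(range(len(clusters)), key=lambda c: len(clusters[c])):
            best, best_d = None, None
            for cj in range(len(clusters)):
                if cj == ci or len(clusters[cj]) < len(clusters[ci]):
                    continue
                if len(clusters[cj]) == len(clusters[ci]) and cj > ci:
                    continue
                d = consistent_diff(ci, cj)
                if best_d is None or d < best_d:
                    best, best_d = cj, d
            if best is not None and best_d is not None and best_d < p.min_diff:
                clusters[best].extend(clusters[ci])
                del clusters[ci]
                consensi[:] = [cons(m) for m in clusters]
                merged = True
                break

    total_reads = aln.n_rows
    order = sorted(range(len(clusters)), key=lambda c: (-len(clusters[c]), consensi[c]))
    calls = []
    for rank, ci in enumerate(order, start=1):
        members = clusters[ci]
        flags: set[str] = set()
        if len(members) < p.min_support or len(members) / total_reads < p.minor_fraction_floor:
            flags.add("low_support")
        aligned = consensi[ci]
        calls.append(
            AlleleCall(
                sample=aln.sample,
                region=aln.region,
                allele_label=f"allele{rank}",
                # terminal Ns are no-coverage edge columns, not sequence
                consensus=aligned.replace(GAP, "").strip("N"),
                supporting_read_ids=[aln.read_ids[i] for i in members],
                flags=flags,
                aligned_consensus=aligned,
            )
        )
    # surplus apparent alleles beyond the locus ploidy are suspect artifacts:
    # keep the best-supported expected_copies*2, flag the rest for inspection
    # by the chimera scan (extra apparent gene copies are excluded from
    # downstream copy analysis, not silently trusted)
    unflagged = [c for c in calls if not c.flags]
    if expected_copies is not None and len(unflagged) > expected_copies * 2:
        logger.warning(
            "%s/%s: %d unflagged alleles exceed the expected maximum %d",
            aln.sample,
            aln.region,
            len(unflagged),
            expected_copies * 2,
        )
        n_extra = len(unflagged) - expected_copies * 2
        for c in sorted(unflagged, key=lambda c: c.support_count)[:n_extra]:
            c.flags.add("surplus")
    return calls


@dataclass
class CopyPartition:
    """Assignment of one region's alleles to homeologous copies A and B."""

    region: str
    copy_a: list[AlleleCall]
    copy_b: list[AlleleCall]
    fixed_difference_count: int
    shared_polymorphism_count: int
    diagnostic_indels: list[tuple[tuple[int, int], int]]
    separable: bool = True


def _pairwise_distance(rows: list[str], cov: list[tuple[int, int]]) -> np.ndarray:
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            lo = max(cov[i][0], cov[j][0])
            hi = min(cov[i][1], cov[j][1])
            dist = sum(
                1
                for c in range(lo, hi)
                if rows[i][c] != rows[j][c] and "N" not in (rows[i][c], rows[j][c])
            )
            d[i, j] = d[j, i] = dist
    return d


def partition_copies(
    alleles: Sequence[AlleleCall],
    separation_factor: float = 2.0,
) -> CopyPartition:
    """Split one region's alleles (across samples) into copies A and B.

    Allele consensi are star-aligned and single-linkage clustered into two
    groups at the largest distance gap; the group with more supporting reads
    is labelled B (copy B over-amplifies in this system).  The split is
    accepted only when the mean between-group distance exceeds
    ``separation_factor`` times the largest within-group distance.  Fixed
    differences, shared polymorphisms, and diagnostic indels are reported
    over the aligned columns.
    """
    alleles = list(alleles)
    if len(alleles) < 2:
        raise ValueError("partition_copies needs at least 2 alleles")
    region = alleles[0].region
    pseudo = [
        QualifiedRead(f"a{i}", a.consensus, [40] * len(a.consensus))
        for i, a in enumerate(alleles)
    ]
    aln = align_group(pseudo, sample="*", region=region)
    # align_group may reorder nothing: rows follow input order
    dist = _pairwise_distance(aln.rows, aln.coverage)

    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    z = linkage(squareform(dist, checks=False), method="single")
    labels = fcluster(z, t=2, criterion="maxclust")
    ga = [i for i, l in enumerate(labels) if l == labels[0]]
    gb = [i for i, l in enumerate(labels) if l != labels[0]]

    def _unassigned() -> CopyPartition:
        logger.warning("region %s: copies not separable", region)
        for a in alleles:
            a.copy_label = "unassigned"
        return CopyPartition(region, [], [], 0, 0, [], separable=False)

    if not gb:
        return _unassigned()
    within = [dist[i, j] for g in (ga, gb) for i in g for j in g if i < j]
    between = [dist[i, j] for i in ga for j in gb]
    between_mean = float(np.mean(between))
    within_max = max(within) if within else 0.0
    if between_mean == 0 or between_mean < separation_factor * within_max:
        return _unassigned()

    support = lambda g: sum(alleles[i].support_count for i in g)
    if support(gb) < support(ga):
        ga, gb = gb, ga
    rows_a = [aln.rows[i] for i in ga]
    rows_b = [aln.rows[i] for i in gb]
    fixed, shared, indels = _column_diagnostics(rows_a, rows_b)

    group_a = [alleles[i] for i in ga]
    group_b = [alleles[i] for i in gb]
    for label, group in (("A", group_a), ("B", group_b)):
        group.sort(key=lambda a: (a.sample, -a.support_count))
        per_sample: dict[str, int] = defaultdict(int)
        for a in group:
            a.copy_label = label
            per_sample[a.sample] += 1
            a.allele_label = f"{label}{per_sample[a.sample]}"
    return CopyPartition(region, group_a, group_b, fixed, shared, indels)


def _column_diagnostics(
    rows_a: list[str], rows_b: list[str]
) -> tuple[int, int, list[tuple[tuple[int, int], int]]]:
    n_cols = len(rows_a[0])
    fixed = shared = 0
    indel_diag_cols = []
    for col in range(n_cols):
        sa = {r[col] for r in rows_a if r[col] != "N"}
        sb = {r[col] for r in rows_b if r[col] != "N"}
        if not sa or not sb:
            continue
        if GAP in sa or GAP in sb:
            if sa == {GAP} and GAP not in sb:
                indel_diag_cols.append(col)
            elif sb == {GAP} and GAP not in sa:
                indel_diag_cols.append(col)
            continue
        if len(sa) == 1 and len(sb) == 1 and sa != sb:
            fixed += 1
        elif len(sa) > 1 and len(sb) > 1 and sa == sb:
            shared += 1
    # group consecutive diagnostic indel columns into blocks
    indels: list[tuple[tuple[int, int], int]] = []
    for col in indel_diag_cols:
        if indels and indels[-1][0][1] == col:
            (lo, _), _ = indels[-1]
            indels[-1] = ((lo, col + 1), col + 1 - lo)
        else:
            indels.append(((col, col + 1), 1))
    return fixed, shared, indels


def fixed_differences(
    group_a: Sequence[str], group_b: Sequence[str]
) -> tuple[int, int]:
    """Count fixed base differences and shared polymorphisms between two
    groups of aligned consensi.

    A fixed difference is a column where every A member carries one base and
    every B member a different base; a shared polymorphism is a column
    polymorphic within both groups with the same segregating bases.  Columns
    containing gaps are excluded from the base counts (they are indel
    evidence, tallied separately by :func:`partition_copies`).
    """
    lengths = {len(s) for s in list(group_a) + list(group_b)}
    if len(lengths) != 1:
        raise ValueError(f"sequences have unequal column counts {lengths}")
    fixed, shared, _ = _column_diagnostics(list(group_a), list(group_b))
    return fixed, shared


def code_indels(
    rows: Sequence[str], min_carriers: int = 2, max_repeat: int = 5
) -> tuple[list[str], list[tuple[int, int]]]:
    """Append one a/c column per scored indel to an alignment of consensi.

    A scored indel is a gap block with identical start and end shared by at
    least ``min_carriers`` sequences but not all; blocks inside
    mononucleotide runs longer than ``max_repeat`` on the consensus, and
    singleton blocks, are skipped.  Carriers receive 'c' (indel present),
    others 'a', weighting each indel as a single transversion.  Returns the
    extended rows and the scored (start, end) blocks.
    """
    rows = list(rows)
    if len(rows) < 2:
        raise ValueError("code_indels needs at least 2 sequences")
    n_cols = len(rows[0])
    if any(len(r) != n_cols for r in rows):
        raise ValueError("rows must have equal length")

    ga = GroupAlignment(
        sample="*",
        region="*",
        read_ids=[f"s{i}" for i in range(len(rows))],
        rows=rows,
        row_mean_quality=[40.0] * len(rows),
        coverage=[(0, n_cols)] * len(rows),
    )
    repeat_cols = ga.repeat_columns(min_run=max_repeat + 1)

    blocks: dict[tuple[int, int], list[int]] = defaultdict(list)
    for i, row in enumerate(rows):
        first = len(row) - len(row.lstrip(GAP))
        last = len(row.rstrip(GAP))
        c = first
        while c < last:
            if row[c] == GAP:
                start = c
                while c < last and row[c] == GAP:
                    c += 1
                blocks[(start, c)].append(i)
            else:
                c += 1

    scored = []
    for (start, end), carriers in sorted(blocks.items()):
        if len(carriers) < min_carriers or len(carriers) == len(rows):
            continue
        if all(col in repeat_cols for col in range(start, end)):
            continue
        scored.append(((start, end), set(carriers)))
    out = list(rows)
    for (start, end), carriers in scored:
        out = [
            r + ("c" if i in carriers else "a") for i, r in enumerate(out)
        ]
    return out, [b for b, _ in scored]


@dataclass
class ErrorRateEstimate:
    numerator: int
    denominator: int

    @property
    def rate(self) -> float:
        return self.numerator / self.denominator


def estimate_error_rate(alignments: Sequence[GroupAlignment]) -> ErrorRateEstimate:
    """Estimate sequencing error from single-copy region alignments.

    Within each alignment every read should match the sample consensus, so
    non-consensus, non-N calls at substitution columns are errors.  Columns
    containing any gap (length variation) are excluded entirely, as are
    masked N calls — matching how the residual post-QC error rate is defined.
    """
    num = den = 0
    for aln in alignments:
        cons = aln.consensus()
        for col in range(aln.n_columns):
            symbols = [
                aln.symbol(i, col)
                for i in range(aln.n_rows)
                if aln.symbol(i, col) != "N"
            ]
            if not symbols or GAP in symbols:
                continue
            c = cons[col]
            if c in (GAP, "N"):
                continue
            den += len(symbols)
            num += sum(1 for s in symbols if s != c)
    if den == 0:
        raise ValueError("no bases surveyed; error rate undefined")
    return ErrorRateEstimate(num, den)
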