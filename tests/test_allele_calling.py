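"""Star alignment, allele clustering, copy partition, indel coding and the
error-rate estimator."""

import numpy as np
import pytest

from polyamp.allele_calling import (
    AlleleCallingParams,
    align_group,
    call_alleles,
    code_indels,
    estimate_error_rate,
    fixed_differences,
    partition_copies,
)
from polyamp.io import QualifiedRead


def reads_from(seqs, prefix="r", q=35):
    return [
        QualifiedRead(f"{prefix}{i}", s, [q] * len(s)) for i, s in enumerate(seqs)
    ]


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(202)


# --- alignment -------------------------------------------------------------


def test_identical_reads_align_without_gaps():
    aln = align_group(reads_from(["ACGTACGTACGT"] * 5), "S", "R")
    assert set(aln.rows) == {"ACGTACGTACGT"}
    assert aln.n_columns == 12


def test_seven_base_deletion_yields_gap_block(rng):
    """Two haplotypes separated by a 7-bp indel produce a 7-column gap."""
    a = random_seq(rng, 200)
    b = a[:90] + a[97:]
    aln = align_group(reads_from([a, a, b, b]), "S", "R")
    gapped = [r for r in aln.rows if "-" in r]
    assert len(gapped) == 2
    runs = max(len(run) for run in gapped[0].split("-") if True)
    assert gapped[0].count("-") == 7
    # contiguous block
    first = gapped[0].index("-")
    assert gapped[0][first : first + 7] == "-" * 7


def test_ungapping_rows_reproduces_reads(rng):
    seqs = [random_seq(rng, 150) for _ in range(6)]
    aln = align_group(reads_from(seqs), "S", "R")
    for i, s in enumerate(seqs):
        assert aln.ungapped_row(i) == s


# --- allele calling --------------------------------------------------------


def test_single_haplotype_gives_one_allele(rng):
    aln = align_group(reads_from([random_seq(rng, 120)] * 20), "S", "R")
    calls = call_alleles(aln)
    assert len(calls) == 1
    assert calls[0].support_count == 20
    assert not calls[0].flags


def mutate(seq, positions, rng):
    out = list(seq)
    for p in positions:
        out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)


def test_two_base_difference_separates_alleles(rng):
    base = random_seq(rng, 150)
    other = mutate(base, [30, 100], rng)
    aln = align_group(reads_from([base] * 10 + [other] * 10), "S", "R")
    calls = call_alleles(aln)
    assert len(calls) == 2
    assert sorted(c.support_count for c in calls) == [10, 10]
    assert {c.consensus for c in calls} == {base, other}


def test_single_base_difference_is_merged(rng):
    """The 2-bp stringency: one consistent difference is not an allele."""
    base = random_seq(rng, 150)
    near = mutate(base, [70], rng)
    aln = align_group(reads_from([base] * 10 + [near] * 10), "S", "R")
    calls = call_alleles(aln)
    assert len(calls) == 1
    assert calls[0].support_count == 20


def test_raising_min_diff_never_increases_allele_count(rng):
    base = random_seq(rng, 150)
    seqs = (
        [base] * 8
        + [mutate(base, [10, 60], rng)] * 6
        + [mutate(base, [20, 80, 120], rng)] * 6
    )
    aln = align_group(reads_from(seqs), "S", "R")
    counts = []
    for md in (1, 2, 3, 4, 6):
        calls = call_alleles(aln, AlleleCallingParams(min_diff=md))
        counts.append(sum(1 for c in calls if not c.flags))
    assert counts == sorted(counts, reverse=True)


def test_minority_cluster_is_flagged(rng):
    """A haplotype below 5% of the group is flagged, not called."""
    base = random_seq(rng, 150)
    rare = mutate(base, [40, 90, 130], rng)
    reads = reads_from([base] * 50) + reads_from([rare] * 2, prefix="q")
    calls = call_alleles(align_group(reads, "S", "R"))
    flagged = [c for c in calls if c.flags]
    assert len(flagged) == 1
    assert flagged[0].support_count == 2
    assert "low_support" in flagged[0].flags
    assert flagged[0].consensus == rare


def test_singleton_with_private_variants_merges_into_allele(rng):
    """One read can never found an allele: its private variants are
    indistinguishable from PCR error and it joins the main cluster."""
    base = random_seq(rng, 150)
    rare = mutate(base, [40, 90, 130], rng)
    calls = call_alleles(align_group(reads_from([base] * 30 + [rare]), "S", "R"))
    assert len(calls) == 1
    assert calls[0].support_count == 31
    assert calls[0].consensus == base


def test_support_conservation(rng):
    base = random_seq(rng, 150)
    seqs = [base] * 12 + [mutate(base, [5, 75], rng)] * 7 + [mutate(base, [9, 33, 66], rng)]
    aln = align_group(reads_from(seqs), "S", "R")
    calls = call_alleles(aln)
    assert sum(c.support_count for c in calls) == len(seqs)
    all_ids = sorted(rid for c in calls for rid in c.supporting_read_ids)
    assert all_ids == sorted(r.read_id for r in reads_from(seqs))


def test_masked_bases_do_not_split_alleles(rng):
    """N-masked positions are wildcards, not differences."""
    base = random_seq(rng, 150)
    reads = reads_from([base] * 10)
    noisy = "N" + base[1:75] + "N" + base[76:]
    reads.append(QualifiedRead("rN", noisy, [2] + [35] * 74 + [2] + [35] * 74))
    calls = call_alleles(align_group(reads, "S", "R"))
    assert len(calls) == 1
    assert calls[0].support_count == 11
    assert calls[0].consensus == base


# --- copy partition --------------------------------------------------------


def build_region_calls(rng, n_fixed=19, indel=7, allele_diff=3, per=8):
    """Two diverged copies, two alleles each, across several samples."""
    L = 420
    copy_a = random_seq(rng, L)
    sites = rng.choice(L - 60, size=n_fixed + 2 * allele_diff, replace=False) + 30
    fixed_sites = sites[:n_fixed]
    copy_b_full = mutate(copy_a, fixed_sites, rng)
    cut = L // 2
    alleles = {
        "A1": copy_a,
        "A2": mutate(copy_a, sites[n_fixed : n_fixed + allele_diff], rng),
        "B1": copy_b_full[: cut] + copy_b_full[cut + indel :],
        "B2": mutate(copy_b_full, sites[n_fixed + allele_diff :], rng)[: cut]
        + mutate(copy_b_full, sites[n_fixed + allele_diff :], rng)[cut + indel :],
    }
    from polyamp.allele_calling import AlleleCall

    calls = []
    for s in range(3):
        for label, seq in alleles.items():
            calls.append(
                AlleleCall(
                    sample=f"S{s}",
                    region="R",
                    allele_label=label,
                    consensus=seq,
                    supporting_read_ids=[f"{s}{label}{i}" for i in range(
                        per * (2 if label.startswith("B") else 1)
                    )],
                )
            )
    return calls, alleles, n_fixed, indel


def test_partition_recovers_copies_and_diagnostics(rng):
    calls, alleles, n_fixed, indel = build_region_calls(rng)
    part = partition_copies(calls)
    assert part.separable
    assert part.fixed_difference_count == n_fixed
    assert part.shared_polymorphism_count == 0
    assert sum(length for _, length in part.diagnostic_indels) == indel
    # copy B was given twice the support, so the bigger group is B
    a_cons = {c.consensus for c in part.copy_a}
    b_cons = {c.consensus for c in part.copy_b}
    assert a_cons == {alleles["A1"], alleles["A2"]}
    assert b_cons == {alleles["B1"], alleles["B2"]}
    # every sample carries both alleles of both copies, numbered per sample
    labels = sorted(c.allele_label for c in part.copy_a + part.copy_b)
    assert labels == sorted(["A1", "A2", "B1", "B2"] * 3)
    for c in part.copy_a + part.copy_b:
        assert c.copy_label == c.allele_label[0]


def test_partition_identical_sets_not_separable(rng):
    from polyamp.allele_calling import AlleleCall

    seq = random_seq(rng, 200)
    calls = [
        AlleleCall("S0", "R", f"a{i}", seq, [f"r{i}{j}" for j in range(5)])
        for i in range(4)
    ]
    part = partition_copies(calls)
    assert not part.separable
    assert all(c.copy_label == "unassigned" for c in calls)


# --- fixed differences -----------------------------------------------------


def test_fixed_differences_hand_examples():
    assert fixed_differences(["ACGT"], ["ACGA"]) == (1, 0)
    # column 2 fixed C/T, column 4 a shared polymorphism (T/C in both)
    assert fixed_differences(["ACGT", "ACGC"], ["ATGT", "ATGC"]) == (1, 1)
    assert fixed_differences(["ACGT"], ["ACGT"]) == (0, 0)
    with pytest.raises(ValueError):
        fixed_differences(["ACGT"], ["ACG"])


def test_fixed_differences_excludes_gap_columns():
    assert fixed_differences(["AC-T"], ["ACGA"]) == (1, 0)


# --- indel coding ----------------------------------------------------------


def test_indel_coding_shared_block():
    """A 7-bp deletion in 3 of 6 sequences appends one a/c column."""
    full = "ACGTGTTACAGGCATCGATTGCAACGGCAT"
    gapped = full[:10] + "-" * 7 + full[17:]
    rows = [full] * 3 + [gapped] * 3
    out, scored = code_indels(rows)
    assert scored == [(10, 17)]
    assert [r[-1] for r in out] == ["a"] * 3 + ["c"] * 3
    assert all(r[:-1] == orig for r, orig in zip(out, rows))


def test_singleton_indel_not_scored():
    full = "ACGTGTTACAGGCATCGATTGCAACGGCAT"
    gapped = full[:10] + "---" + full[13:]
    out, scored = code_indels([full] * 5 + [gapped])
    assert scored == []
    assert out == [full] * 5 + [gapped]


def test_indel_inside_long_homopolymer_not_scored():
    """Length variation in a >5 bp mononucleotide run is unreliable."""
    core = "ACGTC" + "A" * 8 + "GCATG"
    gapped = "ACGTC" + "A" * 6 + "--" + "GCATG"
    out, scored = code_indels([core] * 3 + [gapped] * 3)
    assert scored == []


# --- error rate ------------------------------------------------------------


def test_error_rate_arithmetic(rng):
    """26 scattered single-base variants over 20,000 surveyed bases."""
    base = random_seq(rng, 400)
    seqs = [base] * 50  # 50 x 400 = 20,000 calls
    mut_reads = reads_from(seqs)
    positions = rng.choice(400, size=26, replace=False)
    for k, pos in enumerate(positions):
        i = k % 49 + 1
        s = mut_reads[i].bases
        mut_reads[i] = QualifiedRead(
            mut_reads[i].read_id,
            s[:pos] + ("A" if s[pos] != "A" else "G") + s[pos + 1 :],
            mut_reads[i].quals,
        )
    est = estimate_error_rate([align_group(mut_reads, "S", "R")])
    assert est.denominator == 20_000
    assert est.numerator == 26
    assert est.rate == pytest.approx(0.0013)


def test_error_rate_zero_for_identical_reads(rng):
    aln = align_group(reads_from([random_seq(rng, 300)] * 10), "S", "R")
    est = estimate_error_rate([aln])
    assert est.numerator == 0 and est.rate == 0.0


def test_error_rate_excludes_masked_and_empty():
    r1 = QualifiedRead("a", "ACGT", [30] * 4)
    r2 = QualifiedRead("b", "ANGT", [30, 2, 30, 30])
    est = estimate_error_rate([align_group([r1, r2], "S", "R")])
    assert est.denominator == 7  # the N call is not surveyed
    assert est.numerator == 0
    with pytest.raises(ValueError):
        estimate_error_rate([])
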