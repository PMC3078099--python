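"""Synthetic dataset generator: determinism, truth accounting, injections."""

import numpy as np
import pytest

from polyamp.demux import reverse_complement
from polyamp.io import QualifiedRead, read_sequences
from polyamp.simdata import (
    ErrorQualityModel,
    RegionSim,
    SimConfig,
    inject_chimera,
    inject_errors,
    simulate_dataset,
)


def small_config(seed=0, **kw):
    defaults = dict(
        n_samples=4,
        regions=[
            RegionSim("cp", length=300, expected_copies=1),
            RegionSim("nuc", length=360, expected_copies=2, divergence_subs=16,
                      diagnostic_indels=(7,), copy_ratio=1.5),
        ],
        read_count_params=(12, 20),
        seed=seed,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


def test_same_seed_gives_byte_identical_output(tmp_path):
    d1 = simulate_dataset(small_config(seed=9))
    d2 = simulate_dataset(small_config(seed=9))
    assert [(r.read_id, r.bases, r.quals) for r in d1.reads] == [
        (r.read_id, r.bases, r.quals) for r in d2.reads
    ]
    p1 = d1.write(tmp_path / "a")
    p2 = d2.write(tmp_path / "b")
    assert p1["reads"].read_bytes() == p2["reads"].read_bytes()
    assert p1["quals"].read_bytes() == p2["quals"].read_bytes()


def test_different_seeds_differ():
    d1 = simulate_dataset(small_config(seed=1))
    d2 = simulate_dataset(small_config(seed=2))
    assert d1.reads[0].bases != d2.reads[0].bases


def test_read_accounting_matches_truth():
    ds = simulate_dataset(small_config(seed=3))
    assert len(ds.reads) == len(ds.truth.reads)
    assert {r.read_id for r in ds.reads} == {t.read_id for t in ds.truth.reads}


def test_written_files_parse_back(tmp_path):
    ds = simulate_dataset(small_config(seed=4))
    paths = ds.write(tmp_path, format="fasta+qual")
    back = read_sequences(paths["reads"], paths["quals"])
    assert len(back) == len(ds.reads)
    assert back[0].bases == ds.reads[0].bases


def test_error_free_reads_have_expected_layout():
    ds = simulate_dataset(small_config(seed=5, error_rate=0.0, chimera_rate=0.0))
    byid = ds.truth.reads_by_id()
    regions = {r.name: r for r in ds.regions}
    word_of = {s: w for w, s in ds.sheet.entries.items()}
    for read in ds.reads[:40]:
        tr = byid[read.read_id]
        gr = regions[tr.region]
        insert = ds.truth.allele_sequence(tr.region, tr.allele_label)
        word = word_of[tr.sample]
        if tr.orientation == "forward":
            expected = word + "T" + gr.fwd_primer + insert
        else:
            expected = word + "T" + gr.rev_primer + reverse_complement(insert)
        assert read.bases.startswith(expected)


def test_fixed_and_indel_divergence_in_truth():
    ds = simulate_dataset(small_config(seed=6))
    rt = ds.truth.region_truth["nuc"]
    assert rt.fixed_substitutions == 16
    assert rt.indels == (7,)
    assert len(rt.alleles["A1"]) - len(rt.alleles["B1"]) == 7


def test_chimera_fraction_matches_rate():
    cfg = small_config(seed=7, chimera_rate=0.05, read_count_params=(60, 90))
    ds = simulate_dataset(cfg)
    nuc = [t for t in ds.truth.reads if t.region == "nuc"]
    frac = sum(1 for t in nuc if t.chimera_parents) / len(nuc)
    se = (0.05 * 0.95 / len(nuc)) ** 0.5
    assert abs(frac - 0.05) <= 3 * se
    # plastid cells cannot recombine
    assert all(t.chimera_parents is None for t in ds.truth.reads if t.region == "cp")


def test_inject_errors_counting():
    rng = np.random.default_rng(0)
    model = ErrorQualityModel()
    n = err = 0
    read = QualifiedRead("r", "ACGT" * 2500, [35] * 10_000)
    for _ in range(100):
        out, pos = inject_errors(read, 0.005, model, rng)
        n += len(read)
        err += len(pos)
        for p in pos:
            assert out.bases[p] != read.bases[p]
    expect = n * 0.005
    assert abs(err - expect) <= 3 * (n * 0.005 * 0.995) ** 0.5


def test_inject_errors_rate_zero_is_identity():
    rng = np.random.default_rng(0)
    read = QualifiedRead("r", "ACGT" * 10, [35] * 40)
    out, pos = inject_errors(read, 0.0, ErrorQualityModel(), rng)
    assert out.bases == read.bases and pos == ()
    with pytest.raises(ValueError):
        inject_errors(read, 1.0, ErrorQualityModel(), rng)


def test_error_quality_split_controls_masking():
    rng = np.random.default_rng(1)
    model = ErrorQualityModel(masked_fraction=0.8)
    read = QualifiedRead("r", "ACGT" * 25_000, [35] * 100_000)
    out, pos = inject_errors(read, 0.01, model, rng)
    quals = np.array([out.quals[p] for p in pos])
    frac_masked = (quals < 15).mean()
    assert abs(frac_masked - 0.8) < 0.05


def test_inject_chimera_homologous_junction():
    rng = np.random.default_rng(2)
    base = "".join(rng.choice(list("ACGT"), size=300))
    other = list(base)
    for p in (60, 120, 200, 250):
        other[p] = "A" if other[p] != "A" else "C"
    other = "".join(other)
    seq, k = inject_chimera(base, other, rng, margin=30)
    assert 30 <= k <= 270
    assert seq[:k] == base[:k]
    assert seq[k:] == other[k:]  # equal lengths: homologous resume point
    with pytest.raises(ValueError):
        inject_chimera(base, base, rng)


def test_inject_chimera_across_indel_keeps_frames():
    """Breakpoint past a deletion resumes at the homologous position, so the
    junction carries no spurious indel."""
    rng = np.random.default_rng(3)
    base = "".join(rng.choice(list("ACGT"), size=300))
    deleted = base[:100] + base[107:]
    for _ in range(20):
        seq, k = inject_chimera(base, deleted, rng, margin=30)
        if k >= 107:
            assert seq == base[:k] + deleted[k - 7 :]
        elif k < 100:
            assert seq == base[:k] + deleted[k:]


def test_sample_cap():
    with pytest.raises(ValueError):
        SimConfig(n_samples=65)
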