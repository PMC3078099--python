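"""Synthetic barcoded polyploid amplicon datasets with full truth tables.

The generator emulates a pooled 454-style run over allotetraploid samples:
each nuclear region carries two homeologous copies separated by fixed
substitutions and diagnostic indels (e.g. a 7-bp indel), with up to two
alleles per copy; plastid regions are single-copy.  Reads follow the
adapter/barcode layout (4-base checksum word + ligation T + primer +
insert), carry per-base errors whose quality scores determine whether
masking removes them, and include PCR chimeras at a few percent.  Every
read and allele is recorded in a truth table so the whole pipeline is
testable without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import barcodes
from .demux import ADAPTER_B, reverse_complement
from .io import GeneRegion, QualifiedRead, write_region_table, write_sequences

BASES = "ACGT"


@dataclass
class RegionSim:
    """Simulation parameters for one gene region.

    ``divergence_subs`` fixed substitutions and ``diagnostic_indels``
    (deletion lengths in copy B) separate the homeologous copies of a
    nuclear region; ``copy_ratio`` is the B:A read ratio.  Plastid regions
    (expected_copies=1) instead carry ``n_haplotypes`` region haplotypes,
    one per sample.
    """

    name: str
    length: int = 420
    expected_copies: int = 2
    divergence_subs: int = 19
    diagnostic_indels: tuple[int, ...] = ()
    copy_ratio: float = 1.5
    allele_diff: int = 4
    n_haplotypes: int = 2


def default_study_regions() -> list[RegionSim]:
    """Three plastid + two nuclear regions mirroring the study design:
    one nuclear pair separated by 19 substitutions and a 7-bp indel
    (B:A ratio 1.29), the other by 35 substitutions and four 1-4 bp indels
    (ratio 1.87)."""
    return [
        RegionSim("cp_trnHpsbA", length=400, expected_copies=1),
        RegionSim("cp_rpl32trnL", length=420, expected_copies=1),
        RegionSim("cp_rpl16", length=440, expected_copies=1),
        RegionSim(
            "nuc_DMC1",
            length=475,
            expected_copies=2,
            divergence_subs=19,
            diagnostic_indels=(7,),
            copy_ratio=1.29,
        ),
        RegionSim(
            "nuc_CDO504",
            length=412,
            expected_copies=2,
            divergence_subs=35,
            diagnostic_indels=(1, 2, 3, 4),
            copy_ratio=1.87,
        ),
    ]


@dataclass
class ErrorQualityModel:
    """Quality scores for erroneous base calls.

    A fraction ``masked_fraction`` of errors receive sub-threshold quality
    (masked to N by QC); the rest pass the mask and remain as residual
    errors — the quantity the error-rate estimator sees.
    """

    masked_fraction: float = 0.8
    masked_range: tuple[int, int] = (2, 14)
    unmasked_range: tuple[int, int] = (15, 25)

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        masked = rng.random(size) < self.masked_fraction
        lo = rng.integers(self.masked_range[0], self.masked_range[1] + 1, size)
        hi = rng.integers(self.unmasked_range[0], self.unmasked_range[1] + 1, size)
        return np.where(masked, lo, hi)


@dataclass
class SimConfig:
    n_samples: int = 16
    regions: list[RegionSim] = field(default_factory=default_study_regions)
    het_prob: float = 0.6  # P(a copy carries two alleles in a sample)
    read_count_model: str = "uniform"  # uniform | negbin
    read_count_params: tuple[float, float] = (30, 80)  # (low, high) or (mean, k)
    reverse_prob: float = 0.5
    error_rate: float = 0.005
    error_quality: ErrorQualityModel = field(default_factory=ErrorQualityModel)
    correct_q_mean: float = 34.0
    correct_q_sd: float = 5.0
    chimera_rate: float = 0.03
    chimera_margin: int = 30
    dropout: float = 0.0
    read_length_model: str = "full"  # full | truncated
    read_length_params: tuple[float, float] = (278, 153)
    primer_length: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.het_prob, self.error_rate, self.chimera_rate, self.dropout,
                     self.reverse_prob):
            if not (0 <= rate <= 1):
                raise ValueError(f"rate {rate} outside [0, 1]")
        if self.error_rate >= 1:
            raise ValueError("error_rate must be < 1")
        if self.n_samples > 64:
            raise ValueError("n_samples exceeds the 64-word barcode vocabulary")


@dataclass
class TruthRead:
    read_id: str
    sample: str
    region: str
    allele_label: Optional[str]  # None for chimeras
    chimera_parents: Optional[tuple[str, str]] = None
    chimera_breakpoint: Optional[int] = None  # insert coordinate
    error_positions: tuple[int, ...] = ()  # emitted-read coordinates
    orientation: str = "forward"


@dataclass
class RegionTruth:
    alleles: dict[str, str]  # label -> insert sequence (forward strand)
    copy_of: dict[str, str]  # label -> A | B | P
    fixed_substitutions: int = 0
    indels: tuple[int, ...] = ()


@dataclass
class SimTruth:
    region_truth: dict[str, RegionTruth]
    cell_alleles: dict[tuple[str, str], list[str]]
    reads: list[TruthRead]
    dropout_cells: set[tuple[str, str]] = field(default_factory=set)

    def reads_by_id(self) -> dict[str, TruthRead]:
        return {r.read_id: r for r in self.reads}

    def allele_sequence(self, region: str, label: str) -> str:
        return self.region_truth[region].alleles[label]

    def expected_alleles(self, sample: str, region: str) -> list[tuple[str, str]]:
        labels = self.cell_alleles.get((sample, region), [])
        return [(l, self.allele_sequence(region, l)) for l in labels]


@dataclass
class SimulatedDataset:
    reads: list[QualifiedRead]
    sheet: barcodes.SampleSheet
    regions: list[GeneRegion]
    truth: SimTruth
    config: SimConfig

    def write(self, outdir: str | Path, format: str = "fasta+qual") -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        if format == "fastq":
            write_sequences(self.reads, outdir / "reads.fastq", "fastq")
            paths["reads"] = outdir / "reads.fastq"
        else:
            write_sequences(self.reads, outdir / "reads.fasta", "fasta+qual")
            paths["reads"] = outdir / "reads.fasta"
            paths["quals"] = outdir / "reads.qual"
        self.sheet.to_tsv(outdir / "sheet.tsv")
        write_region_table(self.regions, outdir / "regions.tsv")
        paths["sheet"] = outdir / "sheet.tsv"
        paths["regions"] = outdir / "regions.tsv"
        _write_truth(self.truth, outdir)
        paths["truth_alleles"] = outdir / "truth_alleles.tsv"
        paths["truth_reads"] = outdir / "truth_reads.tsv"
        return paths


def _write_truth(truth: SimTruth, outdir: Path) -> None:
    import pandas as pd

    rows = []
    for (sample, region), labels in sorted(truth.cell_alleles.items()):
        for label in labels:
            rows.append(
                {
                    "sample": sample,
                    "region": region,
                    "allele": label,
                    "copy": truth.region_truth[region].copy_of[label],
                    "sequence": truth.region_truth[region].alleles[label],
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "truth_alleles.tsv", sep="\t", index=False)
    rows = [
        {
            "read_id": r.read_id,
            "sample": r.sample,
            "region": r.region,
            "allele": r.allele_label or "",
            "chimera_parents": "|".join(r.chimera_parents) if r.chimera_parents else "",
            "chimera_breakpoint": r.chimera_breakpoint if r.chimera_breakpoint is not None else "",
            "n_errors": len(r.error_positions),
            "orientation": r.orientation,
        }
        for r in truth.reads
    ]
    pd.DataFrame(rows).to_csv(outdir / "truth_reads.tsv", sep="\t", index=False)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def _substitute(seq: str, positions: Sequence[int], rng: np.random.Generator) -> str:
    out = list(seq)
    for pos in positions:
        out[pos] = rng.choice([b for b in BASES if b != out[pos]])
    return "".join(out)


def inject_errors(
    read: QualifiedRead,
    rate: float,
    quality_model: ErrorQualityModel,
    rng: np.random.Generator,
) -> tuple[QualifiedRead, tuple[int, ...]]:
    """Substitute each base independently with probability ``rate``.

    Erroneous bases get qualities from ``quality_model`` (so that masking
    removes a configurable fraction of them); returns the mutated read and
    the error positions.
    """
    if not (0 <= rate < 1):
        raise ValueError("rate must be in [0, 1)")
    if rate == 0 or len(read) == 0:
        return read, ()
    hits = np.flatnonzero(rng.random(len(read)) < rate)
    if hits.size == 0:
        return read, ()
    bases = list(read.bases)
    quals = list(read.quals)
    err_quals = quality_model.draw(rng, hits.size)
    for pos, q in zip(hits, err_quals):
        bases[pos] = rng.choice([b for b in BASES if b != bases[pos]])
        quals[pos] = int(q)
    return (
        QualifiedRead(read.read_id, "".join(bases), quals, read.source),
        tuple(int(h) for h in hits),
    )


def inject_chimera(
    parent1: str, parent2: str, rng: np.random.Generator, margin: int = 30
) -> tuple[str, int]:
    """Join parent1's prefix to parent2's suffix at a uniform breakpoint
    at least ``margin`` bases from both ends.

    The breakpoint is mapped through a pairwise alignment of the parents so
    the suffix resumes at the homologous position — PCR template switching
    re-anneals the partially extended strand at the homologous site, so no
    spurious insertion or deletion appears at the junction.
    """
    if parent1 == parent2:
        raise ValueError("chimera parents must be distinct")
    hi = min(len(parent1), len(parent2)) - margin
    if hi <= margin:
        raise ValueError("parents too short for the requested margin")
    from .allele_calling import _ALIGNER

    aln = _ALIGNER.align(parent1, parent2)[0]
    t_blocks, q_blocks = aln.aligned

    def homolog(k1: int) -> Optional[int]:
        for (t0, t1), (q0, q1) in zip(t_blocks, q_blocks):
            if t0 <= k1 < t1:
                return int(q0 + (k1 - t0))
            if k1 < t0:
                return int(q0)
        return None

    for _ in range(100):
        k1 = int(rng.integers(margin, hi))
        k2 = homolog(k1)
        if k2 is not None and margin <= k2 <= len(parent2) - margin:
            return parent1[:k1] + parent2[k2:], k1
    raise ValueError("could not place a homologous breakpoint")


def _build_region_truth(
    spec: RegionSim, rng: np.random.Generator
) -> tuple[RegionTruth, GeneRegion]:
    fwd = _random_seq(rng, 20)
    rev = _random_seq(rng, 20)
    L = spec.length
    ancestral = _random_seq(rng, L)
    if spec.expected_copies == 1:
        alleles: dict[str, str] = {}
        copy_of: dict[str, str] = {}
        prev = ancestral
        pos_pool = list(rng.choice(L, size=3 * max(1, spec.n_haplotypes - 1), replace=False))
        for h in range(spec.n_haplotypes):
            label = f"P{h + 1}"
            if h == 0:
                alleles[label] = ancestral
            else:
                alleles[label] = _substitute(ancestral, pos_pool[3 * (h - 1) : 3 * h], rng)
            copy_of[label] = "P"
        truth = RegionTruth(alleles, copy_of)
    else:
        # reserve indel intervals, then disjoint substitution sites outside them
        indel_intervals: list[tuple[int, int]] = []
        margin = 40
        for ln in spec.diagnostic_indels:
            for _ in range(100):
                s = int(rng.integers(margin, L - margin - ln))
                if all(s + ln + 5 < a or s > b + 5 for a, b in indel_intervals):
                    indel_intervals.append((s, s + ln))
                    break
            else:  # pragma: no cover - pathological spec
                raise ValueError("could not place diagnostic indels")
        deleted = {i for a, b in indel_intervals for i in range(a, b)}
        # keep substitution sites clear of indel flanks so gap placement in
        # downstream alignments cannot absorb a diagnostic substitution
        blocked = {i for a, b in indel_intervals for i in range(a - 3, b + 3)}
        free = [i for i in range(L) if i not in blocked]
        need = spec.divergence_subs + 2 * spec.allele_diff
        sites = list(rng.choice(free, size=need, replace=False))
        div_sites = sites[: spec.divergence_subs]
        a2_sites = sites[spec.divergence_subs : spec.divergence_subs + spec.allele_diff]
        b2_sites = sites[spec.divergence_subs + spec.allele_diff :]

        def delete(seq: str) -> str:
            return "".join(c for i, c in enumerate(seq) if i not in deleted)

        copy_a = ancestral
        copy_b_full = _substitute(ancestral, div_sites, rng)
        alleles = {
            "A1": copy_a,
            "A2": _substitute(copy_a, a2_sites, rng),
            "B1": delete(copy_b_full),
            "B2": delete(_substitute(copy_b_full, b2_sites, rng)),
        }
        copy_of = {"A1": "A", "A2": "A", "B1": "B", "B2": "B"}
        truth = RegionTruth(
            alleles,
            copy_of,
            fixed_substitutions=spec.divergence_subs,
            indels=tuple(spec.diagnostic_indels),
        )
    region = GeneRegion(
        name=spec.name,
        fwd_primer=fwd,
        rev_primer=rev,
        expected_copies=spec.expected_copies,
    )
    return truth, region


def _cell_read_count(cfg: SimConfig, rng: np.random.Generator) -> int:
    if cfg.read_count_model == "uniform":
        low, high = cfg.read_count_params
        return int(rng.integers(int(low), int(high) + 1))
    if cfg.read_count_model == "negbin":
        mean, k = cfg.read_count_params
        p = k / (k + mean)
        return int(rng.negative_binomial(k, p))
    raise ValueError(f"unknown read_count_model {cfg.read_count_model!r}")


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Generate a full dataset (reads, sample sheet, region table, truth).

    Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    words = barcodes.generate_barcode_words()[: cfg.n_samples]
    samples = [f"S{i + 1:02d}" for i in range(cfg.n_samples)]
    sheet = barcodes.SampleSheet(dict(zip((w.word for w in words), samples)))
    word_of = {s: w.word for w, s in zip(words, samples)}

    region_truth: dict[str, RegionTruth] = {}
    regions: list[GeneRegion] = []
    for spec in cfg.regions:
        truth, region = _build_region_truth(spec, rng)
        region_truth[spec.name] = truth
        regions.append(region)
    region_by_name = {r.name: r for r in regions}

    cell_alleles: dict[tuple[str, str], list[str]] = {}
    for sample in samples:
        for spec in cfg.regions:
            if spec.expected_copies == 1:
                hap = f"P{int(rng.integers(1, spec.n_haplotypes + 1))}"
                cell_alleles[(sample, spec.name)] = [hap]
            else:
                labels = []
                for copy in ("A", "B"):
                    pool = [f"{copy}1", f"{copy}2"]
                    if rng.random() < cfg.het_prob:
                        labels.extend(pool)
                    else:
                        labels.append(pool[int(rng.integers(0, 2))])
                cell_alleles[(sample, spec.name)] = labels

    reads: list[QualifiedRead] = []
    truth_reads: list[TruthRead] = []
    dropout_cells: set[tuple[str, str]] = set()
    counter = 0
    for sample in samples:
        for spec in cfg.regions:
            cell = (sample, spec.name)
            if cfg.dropout > 0 and rng.random() < cfg.dropout:
                dropout_cells.add(cell)
                continue
            n_reads = _cell_read_count(cfg, rng)
            labels = cell_alleles[cell]
            rtruth = region_truth[spec.name]
            if spec.expected_copies == 2:
                r = spec.copy_ratio
                mass = {"A": 1.0 / (1.0 + r), "B": r / (1.0 + r)}
                n_per_copy = {c: sum(1 for l in labels if rtruth.copy_of[l] == c) for c in "AB"}
                weights = np.array(
                    [mass[rtruth.copy_of[l]] / n_per_copy[rtruth.copy_of[l]] for l in labels]
                )
            else:
                weights = np.ones(len(labels))
            weights = weights / weights.sum()
            a_labels = [l for l in labels if rtruth.copy_of.get(l) == "A"]
            b_labels = [l for l in labels if rtruth.copy_of.get(l) == "B"]
            for _ in range(n_reads):
                counter += 1
                read_id = f"r{counter:06d}"
                is_chimera = (
                    spec.expected_copies == 2
                    and cfg.chimera_rate > 0
                    and rng.random() < cfg.chimera_rate
                )
                if is_chimera:
                    pa = a_labels[int(rng.integers(0, len(a_labels)))]
                    pb = b_labels[int(rng.integers(0, len(b_labels)))]
                    parents = (pa, pb) if rng.random() < 0.5 else (pb, pa)
                    insert, bp = inject_chimera(
                        rtruth.alleles[parents[0]],
                        rtruth.alleles[parents[1]],
                        rng,
                        cfg.chimera_margin,
                    )
                    allele_label = None
                else:
                    allele_label = labels[int(rng.choice(len(labels), p=weights))]
                    insert, bp, parents = rtruth.alleles[allele_label], None, None
                orientation = "reverse" if rng.random() < cfg.reverse_prob else "forward"
                gr = region_by_name[spec.name]
                if orientation == "forward":
                    full = (
                        word_of[sample]
                        + "T"
                        + gr.fwd_primer
                        + insert
                        + reverse_complement(gr.rev_primer)
                        + "A"
                        + ADAPTER_B
                    )
                else:
                    full = (
                        word_of[sample]
                        + "T"
                        + gr.rev_primer
                        + reverse_complement(insert)
                        + reverse_complement(gr.fwd_primer)
                        + "A"
                        + ADAPTER_B
                    )
                if cfg.read_length_model == "truncated":
                    mean, sd = cfg.read_length_params
                    ln = int(np.clip(rng.normal(mean, sd), 40, len(full)))
                    full = full[:ln]
                quals = np.clip(
                    np.rint(rng.normal(cfg.correct_q_mean, cfg.correct_q_sd, len(full))),
                    2,
                    40,
                ).astype(int)
                read = QualifiedRead(read_id, full, [int(q) for q in quals], "sim")
                read, err_pos = inject_errors(read, cfg.error_rate, cfg.error_quality, rng)
                reads.append(read)
                truth_reads.append(
                    TruthRead(
                        read_id,
                        sample,
                        spec.name,
                        allele_label,
                        chimera_parents=parents,
                        chimera_breakpoint=bp,
                        error_positions=err_pos,
                        orientation=orientation,
                    )
                )

    truth = SimTruth(region_truth, cell_alleles, truth_reads, dropout_cells)
    return SimulatedDataset(reads, sheet, regions, truth, cfg)


# ---------------------------------------------------------------------------
# truth-based evaluation helpers


def realized_error_rate(
    qc_reads: Sequence[QualifiedRead],
    truth: SimTruth,
    region_names: set[str],
) -> tuple[int, int]:
    """Realized post-mask substitution rate among surviving QC'd reads.

    Each non-chimeric read of the given regions is aligned to its source
    allele; N bases are excluded.  Returns (mismatches, bases surveyed) —
    the quantity the pipeline's error-rate estimator targets.
    """
    import edlib

    by_id = truth.reads_by_id()
    equalities = [("N", b) for b in BASES]
    mism = total = 0
    for read in qc_reads:
        tr = by_id.get(read.read_id)
        if tr is None or tr.region not in region_names or tr.allele_label is None:
            continue
        target = truth.allele_sequence(tr.region, tr.allele_label)
        res = edlib.align(read.bases, target, mode="HW", task="distance",
                          additionalEqualities=equalities)
        mism += res["editDistance"]
        total += sum(1 for b in read.bases if b != "N")
    return mism, total


def allele_recovery(
    truth: SimTruth,
    calls: Sequence,
    regions: Optional[set[str]] = None,
    min_truth_reads: int = 2,
) -> tuple[int, int, list[tuple[str, str, str]]]:
    """Fraction of truth alleles recovered by called alleles.

    A truth allele of a non-dropout cell counts as recovered when some
    non-recombinant call for that (sample, region) reproduces its sequence
    exactly.  Alleles that drew fewer than ``min_truth_reads`` reads are
    excluded from the denominator: a single read can never found an allele
    (that sampling risk is what the read-depth model quantifies), so such
    alleles are unobservable by design, not pipeline failures.
    Returns (recovered, total, missing).
    """
    by_cell: dict[tuple[str, str], list] = {}
    for c in calls:
        if "recombinant" in c.flags:
            continue
        by_cell.setdefault((c.sample, c.region), []).append(c)
    emitted: dict[tuple[str, str, str], int] = {}
    for tr in truth.reads:
        if tr.allele_label is not None:
            key = (tr.sample, tr.region, tr.allele_label)
            emitted[key] = emitted.get(key, 0) + 1
    recovered = total = 0
    missing = []
    for (sample, region), labels in sorted(truth.cell_alleles.items()):
        if (sample, region) in truth.dropout_cells:
            continue
        if regions is not None and region not in regions:
            continue
        for label in labels:
            if emitted.get((sample, region, label), 0) < min_truth_reads:
                continue
            seq = truth.allele_sequence(region, label)
            total += 1
            if any(c.consensus == seq for c in by_cell.get((sample, region), [])):
                recovered += 1
            else:
                missing.append((sample, region, label))
    return recovered, total, missing
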