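"""End-to-end workflow: region assignment, barcode deconvolution, QC,
grouping, alignment, allele calling, chimera flagging and reporting.

Every read either survives to a (sample, region) group or is discarded with
a logged (stage, reason) record, so read counts are conserved at every
stage.  Reports use 1-based closed coordinates; internal intervals are
0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .allele_calling import (
    AlleleCall,
    AlleleCallingParams,
    CopyPartition,
    ErrorRateEstimate,
    GroupAlignment,
    align_group,
    call_alleles,
    estimate_error_rate,
    partition_copies,
)
from .barcodes import Rejection, SampleSheet
from .chimera_scan import ChimeraParams, ChimeraReport, detect_recombinants
from .demux import EMPTY_INSERT, assign_region, trim_to_insert
from .io import GeneRegion, QualifiedRead, read_sequences
from .readqc import QcParams, apply_qc

logger = logging.getLogger("polyamp")


@dataclass
class RunConfig:
    qc: QcParams = field(default_factory=QcParams)
    allele: AlleleCallingParams = field(default_factory=AlleleCallingParams)
    chimera: ChimeraParams = field(default_factory=ChimeraParams)
    primer_window: int = 40
    max_primer_mismatch: int = 1
    default_quality: int = 30
    seed: Optional[int] = None
    outdir: Optional[str] = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "qc" in raw:
            kwargs["qc"] = QcParams(**raw["qc"])
        if "allele" in raw:
            kwargs["allele"] = AlleleCallingParams(**raw["allele"])
        if "chimera" in raw:
            kwargs["chimera"] = ChimeraParams(**raw["chimera"])
        for key in ("primer_window", "max_primer_mismatch", "default_quality", "seed", "outdir"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


@dataclass
class PipelineResult:
    counts: pd.DataFrame  # useful reads per (sample, region), recombinants removed
    raw_counts: pd.DataFrame  # reads per cell after QC, before chimera removal
    alleles: list[AlleleCall]
    partitions: dict[str, CopyPartition]
    chimera_reports: list[tuple[str, str, ChimeraReport]]  # (sample, region, report)
    error_rates: dict[str, ErrorRateEstimate]
    attrition: pd.DataFrame  # stage, reason, count
    read_log: list[tuple[str, str, str]]  # read_id, stage, reason
    groups: dict[tuple[str, str], GroupAlignment]
    qc_reads: dict[tuple[str, str], list[QualifiedRead]]

    def summary(self) -> str:
        lines = ["pipeline summary", "----------------"]
        for _, row in self.attrition.iterrows():
            lines.append(f"{row['stage']:>14s}  {row['reason']:<16s} {row['count']}")
        lines.append(f"groups: {len(self.groups)}")
        lines.append(f"alleles called: {sum(1 for a in self.alleles if not a.flags)}"
                     f" (+{sum(1 for a in self.alleles if a.flags)} flagged)")
        for name, est in self.error_rates.items():
            lines.append(
                f"error rate [{name}]: {est.numerator}/{est.denominator}"
                f" = {est.rate * 100:.3f}%"
            )
        return "\n".join(lines)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.counts.to_csv(outdir / "read_counts.tsv", sep="\t")
        self.attrition.to_csv(outdir / "attrition.tsv", sep="\t", index=False)
        rows = []
        with open(outdir / "alleles.fasta", "w") as fh:
            for a in self.alleles:
                header = f"{a.sample}|{a.region}|{a.copy_label}|{a.allele_label}|{a.support_count}"
                fh.write(f">{header}\n{a.consensus}\n")
                rows.append(
                    {
                        "sample": a.sample,
                        "region": a.region,
                        "copy": a.copy_label,
                        "allele": a.allele_label,
                        "support": a.support_count,
                        "flags": ",".join(sorted(a.flags)),
                        "length": len(a.consensus),
                    }
                )
        pd.DataFrame(rows).to_csv(outdir / "alleles.tsv", sep="\t", index=False)
        rows = [
            {
                "sample": s,
                "region": r,
                "candidate": rep.candidate,
                "verdict": rep.verdict,
                "parent_1": rep.parent_1 or "",
                "parent_2": rep.parent_2 or "",
                # 1-based closed interval for the report
                "breakpoint_from": str(rep.breakpoint_interval[0] + 1) if rep.breakpoint_interval else "",
                "breakpoint_to": str(rep.breakpoint_interval[1]) if rep.breakpoint_interval else "",
            }
            for s, r, rep in self.chimera_reports
        ]
        pd.DataFrame(rows).to_csv(outdir / "chimeras.tsv", sep="\t", index=False)


def run_pipeline(
    reads: Union[Sequence[QualifiedRead], str, Path],
    sheet: Union[SampleSheet, str, Path],
    regions: Union[Sequence[GeneRegion], str, Path],
    config: Optional[RunConfig] = None,
    qual_path: Optional[Union[str, Path]] = None,
) -> PipelineResult:
    """Run the full deconvolution/QC/allele-calling workflow."""
    config = config or RunConfig()
    if not isinstance(reads, (list, tuple)):
        reads = read_sequences(reads, qual_path, config.default_quality)
    if not isinstance(sheet, SampleSheet):
        sheet = SampleSheet.from_tsv(sheet)
    if not isinstance(regions, (list, tuple)):
        from .io import read_region_table

        regions = read_region_table(regions)
    region_by_name = {r.name: r for r in regions}

    read_log: list[tuple[str, str, str]] = []
    groups_reads: dict[tuple[str, str], list[QualifiedRead]] = {}

    n_in = len(reads)
    for read in reads:
        hit = assign_region(read, regions, config.max_primer_mismatch, config.primer_window)
        if hit.status != "assigned":
            read_log.append((read.read_id, "region_assignment", hit.status))
            continue
        trimmed = trim_to_insert(
            read, hit, sheet, region_by_name[hit.region], config.max_primer_mismatch
        )
        if isinstance(trimmed, Rejection):
            read_log.append((read.read_id, "deconvolution", trimmed.value))
            continue
        if trimmed is EMPTY_INSERT:
            read_log.append((read.read_id, "trimming", "empty_insert"))
            continue
        qc_read = apply_qc(trimmed.insert, config.qc)
        if qc_read is None:
            read_log.append((read.read_id, "quality_control", "too_short"))
            continue
        read_log.append((read.read_id, "grouped", f"{trimmed.sample_id}/{hit.region}"))
        groups_reads.setdefault((trimmed.sample_id, hit.region), []).append(qc_read)

    kept = sum(len(v) for v in groups_reads.values())
    assert kept + sum(1 for _, stage, _ in read_log if stage != "grouped") == n_in

    sample_ids = sorted(set(sheet.entries.values()))
    region_names = [r.name for r in regions]
    raw_counts = pd.DataFrame(0, index=sample_ids, columns=region_names)
    counts = raw_counts.copy()

    alleles: list[AlleleCall] = []
    raw_reports: list[tuple] = []  # (sample, region, report, label->call map)
    groups: dict[tuple[str, str], GroupAlignment] = {}
    for (sample, region), cell_reads in sorted(groups_reads.items()):
        aln = align_group(cell_reads, sample, region)
        groups[(sample, region)] = aln
        raw_counts.loc[sample, region] = len(cell_reads)
        calls = call_alleles(aln, config.allele, region_by_name[region].expected_copies)
        reports = detect_recombinants(
            calls,
            len(cell_reads),
            config.chimera,
            reads={r.read_id: r for r in cell_reads},
        )
        recombinant_labels = {r.candidate for r in reports if r.verdict == "recombinant"}
        n_recombinant_reads = 0
        for c in calls:
            if c.allele_label in recombinant_labels:
                c.flags.add("recombinant")
                n_recombinant_reads += c.support_count
        counts.loc[sample, region] = len(cell_reads) - n_recombinant_reads
        alleles.extend(calls)
        label_map = {c.allele_label: c for c in calls}
        raw_reports.extend((sample, region, r, label_map) for r in reports)

    partitions: dict[str, CopyPartition] = {}
    for region in regions:
        if region.expected_copies != 2:
            continue
        region_alleles = [
            a for a in alleles if a.region == region.name and not a.flags
        ]
        if len(region_alleles) >= 2:
            partitions[region.name] = partition_copies(region_alleles)

    # partitioning renames alleles (A1, B2, ...); re-point chimera reports
    chimera_reports: list[tuple[str, str, ChimeraReport]] = []
    for sample, region, rep, label_map in raw_reports:
        for attr in ("candidate", "parent_1", "parent_2"):
            old = getattr(rep, attr)
            if old in label_map:
                setattr(rep, attr, label_map[old].allele_label)
        chimera_reports.append((sample, region, rep))

    error_rates: dict[str, ErrorRateEstimate] = {}
    for region in regions:
        if region.expected_copies != 1:
            continue
        alns = [g for (s, rn), g in groups.items() if rn == region.name]
        if alns:
            try:
                error_rates[region.name] = estimate_error_rate(alns)
            except ValueError:
                logger.warning("error rate undefined for region %s", region.name)

    stage_counts = (
        pd.Series([(s, r) for _, s, r in read_log])
        .value_counts()
        .rename_axis("key")
        .reset_index(name="count")
    )
    attrition = pd.DataFrame(
        {
            "stage": [k[0] for k in stage_counts["key"]],
            "reason": [k[1] for k in stage_counts["key"]],
            "count": stage_counts["count"],
        }
    )

    return PipelineResult(
        counts=counts,
        raw_counts=raw_counts,
        alleles=alleles,
        partitions=partitions,
        chimera_reports=chimera_reports,
        error_rates=error_rates,
        attrition=attrition,
        read_log=read_log,
        groups=groups,
        qc_reads=groups_reads,
    )
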