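"""End-to-end orchestration and truth-based evaluation.

Three run modes mirror the three library designs: ``snp_discovery``
(standard RAD-PE, bins of 30-1000 pairs, SNP calling between samples),
``partial_digest`` (whole-genome tiling with a frequent cutter, bins of
25-500 pairs) and ``long_insert`` (two-pass assembly, bins of at least
1000 pairs). Evaluation places contigs on the simulated truth genome and
reports genome coverage at placement depths, per-contig error counts and
the N50 statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import radbin, simulate
from .assembler import (
    AssemblyParams,
    AssemblyResult,
    assemble_bin_best_of_three,
    assemble_long_insert_two_pass,
)
from ._dna import revcomp
from .radbin import BinFilterConfig, BinReport, RadBin
from .seqio import ReadPair, write_contigs_fasta
from .stats import n50
from .variants import SnpRecord, call_bin_snps, write_snp_report, write_vcf

logger = logging.getLogger(__name__)

__all__ = [
    "n50",
    "PipelineConfig",
    "RunReport",
    "ContigEvaluation",
    "evaluate_contigs",
    "run_pipeline",
    "MODE_DEFAULTS",
]

#: Per-mode bin count thresholds (min instances, max instances).
MODE_DEFAULTS: Dict[str, Tuple[int, int]] = {
    "snp_discovery": (30, 1000),
    "partial_digest": (25, 500),
    "long_insert": (1000, 1_000_000),
}


@dataclass
class PipelineConfig:
    mode: str = "snp_discovery"
    bin_filter: Optional[BinFilterConfig] = None
    assembly: AssemblyParams = field(default_factory=AssemblyParams)
    min_allele_count: int = 4
    min_base_quality: int = 20
    coverage_cap: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODE_DEFAULTS:
            raise ValueError(
                f"unknown mode {self.mode!r}; expected one of {sorted(MODE_DEFAULTS)}"
            )
        if self.bin_filter is None:
            lo, hi = MODE_DEFAULTS[self.mode]
            self.bin_filter = BinFilterConfig(
                min_count=lo, max_count=hi, coverage_cap=self.coverage_cap
            )


@dataclass
class ContigEvaluation:
    contig_id: str
    placed: bool
    start: int = -1  # 0-based on the truth sequence (may wrap if circular)
    end: int = -1
    strand: str = "."
    error_count: int = 0
    errors_near_end: int = 0  # errors within 30 bp of a contig end


@dataclass
class RunReport:
    mode: str
    n_pairs: int = 0
    n_bins_total: int = 0
    n_bins_kept: int = 0
    n_bins_low: int = 0
    n_bins_repetitive: int = 0
    n_bins_derivative: int = 0
    n_pairs_discarded_short: int = 0
    n_contigs: int = 0
    total_assembled_length: int = 0
    n50_all: int = 0
    n50_longest_per_tag: int = 0
    n_snp_records: int = 0
    coverage_ge1: float = float("nan")
    coverage_ge5: float = float("nan")


def _place_exact(contig: str, genome: str, circular: bool) -> Optional[Tuple[int, str]]:
    search = genome + (genome[: len(contig) - 1] if circular else "")
    pos = search.find(contig)
    if pos != -1:
        return pos, "+"
    pos = search.find(revcomp(contig))
    if pos != -1:
        return pos, "-"
    return None


class _TruthPlacer:
    """Place contigs on a truth genome: exact search first, then a
    seed-anchored gapless comparison for contigs containing errors."""

    def __init__(self, genome: str, circular: bool, seed_len: int = 21):
        self.genome = genome
        self.circular = circular
        self.seed_len = seed_len
        ext = genome + (genome[: seed_len - 1] if circular else "")
        self._index: Dict[str, List[int]] = {}
        for i in range(len(ext) - seed_len + 1):
            self._index.setdefault(ext[i : i + seed_len], []).append(i)

    def place(self, contig_id: str, contig: str) -> ContigEvaluation:
        hit = _place_exact(contig, self.genome, self.circular)
        if hit is not None:
            pos, strand = hit
            return ContigEvaluation(
                contig_id=contig_id,
                placed=True,
                start=pos,
                end=pos + len(contig),
                strand=strand,
            )
        best: Optional[ContigEvaluation] = None
        s = self.seed_len
        for strand in "+-":
            query = contig if strand == "+" else revcomp(contig)
            for off in list(range(0, len(query) - s + 1, s))[:8]:
                for anchor in self._index.get(query[off : off + s], [])[:4]:
                    start = anchor - off
                    window = self._slice(start, start + len(query))
                    if len(window) < len(query):
                        continue
                    mism = [
                        i for i in range(len(query)) if window[i] != query[i]
                    ]
                    cand = ContigEvaluation(
                        contig_id=contig_id,
                        placed=True,
                        start=start,
                        end=start + len(query),
                        strand=strand,
                        error_count=len(mism),
                        errors_near_end=sum(
                            1
                            for i in mism
                            if i < 30 or i >= len(query) - 30
                        ),
                    )
                    if best is None or cand.error_count < best.error_count:
                        best = cand
                if best is not None and best.error_count <= 2:
                    break
            if best is not None and best.error_count == 0:
                break
        if best is not None and best.error_count <= 0.1 * len(contig):
            return best
        return ContigEvaluation(contig_id=contig_id, placed=False)

    def _slice(self, start: int, end: int) -> str:
        n = len(self.genome)
        if not self.circular:
            if start < 0 or end > n:
                return ""
            return self.genome[start:end]
        start %= n
        length = end - start if end >= start else 0
        out = self.genome[start : start + length]
        while len(out) < length:
            out += self.genome[: length - len(out)]
        return out


def evaluate_contigs(
    contigs: Sequence[Tuple[str, str]],
    truth: Union[simulate.SyntheticGenome, simulate.DiploidTruth],
) -> Tuple[List[ContigEvaluation], np.ndarray]:
    """Place each (id, sequence) contig on the truth genome and return the
    placements plus the per-base count of distinct contig placements.

    For diploid truth, placement is attempted on both haplotypes and the
    coverage profile is over the reference haplotype.
    """
    if isinstance(truth, simulate.DiploidTruth):
        genomes = list(truth.haplotypes)
    else:
        genomes = [truth]
    placers = [_TruthPlacer(g.sequence, g.circular) for g in genomes]
    ref_len = len(genomes[0].sequence)
    coverage = np.zeros(ref_len, dtype=np.int32)
    evals: List[ContigEvaluation] = []
    for contig_id, seq in contigs:
        ev = ContigEvaluation(contig_id=contig_id, placed=False)
        for placer in placers:
            ev = placer.place(contig_id, seq)
            if ev.placed:
                break
        evals.append(ev)
        if ev.placed:
            for pos in range(ev.start, ev.end):
                coverage[pos % ref_len] += 1
    return evals, coverage


@dataclass
class PipelineOutput:
    report: RunReport
    results: Dict[str, AssemblyResult]
    bins: Dict[str, RadBin]
    bin_report: BinReport
    snp_records: List[SnpRecord]
    evaluations: List[ContigEvaluation] = field(default_factory=list)
    coverage: Optional[np.ndarray] = None


def run_pipeline(
    pairs: Sequence[ReadPair],
    config: PipelineConfig,
    truth: Union[simulate.SyntheticGenome, simulate.DiploidTruth, None] = None,
    region_length_estimate: Optional[int] = None,
    contig_fasta: Optional[str] = None,
    snp_report: Optional[str] = None,
    vcf: Optional[str] = None,
) -> PipelineOutput:
    """Filter -> bin -> threshold -> cap -> assemble -> call -> evaluate.

    ``pairs`` are demultiplexed, quality-filtered read pairs. When a
    simulated ``truth`` is supplied, contigs are placed against it and
    the coverage profile is added to the report.
    """
    cfg = config
    bf = cfg.bin_filter
    assert bf is not None
    region = region_length_estimate or cfg.assembly.min_contig_length * 8
    bins, discarded = radbin.bin_by_tag(
        pairs, tag_length=bf.tag_length, region_length_estimate=region
    )
    n_total = len(bins)
    kept, report = radbin.apply_count_filters(bins, bf)
    kept = radbin.remove_mismatch_derivatives(kept, report.repetitive, report)
    kept = {
        tag: radbin.cap_bin_coverage(b, bf.coverage_cap) for tag, b in kept.items()
    }
    logger.info(
        "bins: %d total, %d kept, %d low, %d repetitive, %d derivative",
        n_total,
        len(kept),
        len(report.low),
        len(report.repetitive),
        len(report.derivative),
    )
    assemble = (
        assemble_long_insert_two_pass
        if cfg.mode == "long_insert"
        else assemble_bin_best_of_three
    )
    results: Dict[str, AssemblyResult] = {}
    for tag in sorted(kept):
        results[tag] = assemble(kept[tag], cfg.assembly)

    tag_order = sorted(results)
    tag_index = {tag: i + 1 for i, tag in enumerate(tag_order)}
    all_lengths: List[int] = []
    longest_per_tag: List[int] = []
    named_contigs: List[Tuple[str, str]] = []
    from .seqio import contig_header

    for tag in tag_order:
        res = results[tag]
        lengths = [c.length for c in res.contigs]
        all_lengths.extend(lengths)
        if lengths:
            longest_per_tag.append(max(lengths))
        for node, contig in enumerate(res.contigs, start=1):
            named_contigs.append(
                (
                    contig_header(
                        tag_index[tag], tag, node, contig.length,
                        contig.mean_kmer_coverage,
                    ),
                    contig.sequence,
                )
            )
    if contig_fasta:
        write_contigs_fasta(
            (
                (tag_index[tag], tag, results[tag].contigs)
                for tag in tag_order
            ),
            contig_fasta,
        )

    snp_records: List[SnpRecord] = []
    if cfg.mode == "snp_discovery":
        for tag in tag_order:
            res = results[tag]
            if not res.contigs:
                continue
            contigs = [
                (
                    contig_header(
                        tag_index[tag], tag, node, c.length, c.mean_kmer_coverage
                    ),
                    c.sequence,
                )
                for node, c in enumerate(res.contigs, start=1)
            ]
            snp_records.extend(
                call_bin_snps(
                    contigs,
                    kept[tag].pairs_by_sample(),
                    min_allele_count=cfg.min_allele_count,
                    min_base_quality=cfg.min_base_quality,
                )
            )
        if snp_report:
            write_snp_report(snp_records, snp_report)
        if vcf:
            write_vcf(snp_records, dict(named_contigs), vcf)

    out = PipelineOutput(
        report=RunReport(
            mode=cfg.mode,
            n_pairs=len(pairs),
            n_bins_total=n_total,
            n_bins_kept=len(kept),
            n_bins_low=len(report.low),
            n_bins_repetitive=len(report.repetitive),
            n_bins_derivative=len(report.derivative),
            n_pairs_discarded_short=discarded,
            n_contigs=len(all_lengths),
            total_assembled_length=sum(all_lengths),
            n50_all=n50(all_lengths),
            n50_longest_per_tag=n50(longest_per_tag),
            n_snp_records=len(snp_records),
        ),
        results=results,
        bins=kept,
        bin_report=report,
        snp_records=snp_records,
    )
    if truth is not None:
        evals, coverage = evaluate_contigs(named_contigs, truth)
        out.evaluations = evals
        out.coverage = coverage
        if len(coverage):
            out.report.coverage_ge1 = float((coverage >= 1).mean())
            out.report.coverage_ge5 = float((coverage >= 5).mean())
    return out
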