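"""Partition read pairs into RAD-tag bins and apply the count filters.

A RAD tag is the fixed-length prefix of (barcode-trimmed) read 1: the
restriction-site residual plus adjacent genomic sequence. All read pairs
sharing a tag form one bin, the unit of local assembly. Bins are then
filtered on pooled counts: too few reads means the locus lacks depth for
variant calling, too many means a repetitive tag, and single-mismatch
derivatives of repetitive tags are sequencing-error shadows of those
repeats and are removed with them. Over-sequenced bins are capped at a
fold-coverage threshold by deterministic prefix truncation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Set, Tuple

from ._dna import ALPHABET
from .seqio import ReadPair, UNASSIGNED

DEFAULT_TAG_LENGTH = 39


@dataclass
class RadTag:
    sequence: str
    count: int = 0


@dataclass
class RadBin:
    """All read pairs whose read 1 begins with one tag sequence."""

    tag: RadTag
    pairs: List[ReadPair] = field(default_factory=list)
    #: Expected span of the sheared-end region; defaults to the upper
    #: bound of the shear size-selection window. Used for depth estimates.
    region_length_estimate: int = 800

    @property
    def count(self) -> int:
        return len(self.pairs)

    def pairs_by_sample(self) -> Dict[str, List[ReadPair]]:
        out: Dict[str, List[ReadPair]] = {}
        for pair in self.pairs:
            out.setdefault(pair.sample, []).append(pair)
        return out

    def depth_estimate(self) -> float:
        """Fold coverage of the sheared-end region implied by read-2 bases."""
        return sum(len(p.read2) for p in self.pairs) / self.region_length_estimate


@dataclass
class BinFilterConfig:
    min_count: int
    max_count: int
    coverage_cap: float = 30.0
    tag_length: int = DEFAULT_TAG_LENGTH

    def __post_init__(self) -> None:
        if not (0 < self.min_count < self.max_count):
            raise ValueError(
                f"need 0 < min_count < max_count, got {self.min_count}/{self.max_count}"
            )


@dataclass
class BinReport:
    """Fate of every tag seen: kept / low / repetitive / derivative, plus
    the number of pairs discarded because read 1 was shorter than the tag."""

    kept: List[str] = field(default_factory=list)
    low: List[str] = field(default_factory=list)
    repetitive: List[str] = field(default_factory=list)
    derivative: List[str] = field(default_factory=list)
    discarded_short: int = 0
    counts: Dict[str, int] = field(default_factory=dict)

    def write_tsv(self, path) -> None:
        with open(path, "w") as out:
            out.write("tag\tcount\tfate\n")
            for fate in ("kept", "low", "repetitive", "derivative"):
                for tag in getattr(self, fate):
                    out.write(f"{tag}\t{self.counts.get(tag, 0)}\t{fate}\n")


def bin_by_tag(
    pairs: Iterable[ReadPair],
    tag_length: int = DEFAULT_TAG_LENGTH,
    region_length_estimate: int = 800,
    include_unassigned: bool = False,
) -> Tuple[Dict[str, RadBin], int]:
    """Group read pairs by the first ``tag_length`` bases of read 1.

    Pairs whose read 1 is shorter than the tag are discarded and counted.
    Returns (bins keyed by tag sequence, number discarded). Bin content
    order follows input order; the bin map itself is insertion-ordered
    but identical as a mapping under any permutation of the input.
    """
    bins: Dict[str, RadBin] = {}
    discarded = 0
    for pair in pairs:
        if pair.sample == UNASSIGNED and not include_unassigned:
            continue
        if len(pair.read1) < tag_length:
            discarded += 1
            continue
        tag = pair.read1.bases[:tag_length]
        bin_ = bins.get(tag)
        if bin_ is None:
            bin_ = bins[tag] = RadBin(
                tag=RadTag(sequence=tag),
                region_length_estimate=region_length_estimate,
            )
        bin_.pairs.append(pair)
        bin_.tag.count += 1
    return bins, discarded


def apply_count_filters(
    bins: Dict[str, RadBin], cfg: BinFilterConfig
) -> Tuple[Dict[str, RadBin], BinReport]:
    """Keep bins with ``min_count <= count < max_count`` (pooled over samples).

    Bins at or above ``max_count`` are recorded as repetitive so their
    single-mismatch derivatives can be removed next.
    """
    report = BinReport()
    kept: Dict[str, RadBin] = {}
    for tag, bin_ in bins.items():
        report.counts[tag] = bin_.count
        if bin_.count >= cfg.max_count:
            report.repetitive.append(tag)
        elif bin_.count < cfg.min_count:
            report.low.append(tag)
        else:
            kept[tag] = bin_
            report.kept.append(tag)
    return kept, report


def _mismatch_neighbourhood(tags: Iterable[str]) -> Set[str]:
    out: Set[str] = set()
    for tag in tags:
        for i, base in enumerate(tag):
            for alt in ALPHABET:
                if alt != base:
                    out.add(tag[:i] + alt + tag[i + 1 :])
    return out


def remove_mismatch_derivatives(
    bins: Dict[str, RadBin],
    repetitive_tags: Iterable[str],
    report: BinReport | None = None,
) -> Dict[str, RadBin]:
    """Drop bins whose tag is at Hamming distance 1 from any repetitive tag."""
    neighbourhood = _mismatch_neighbourhood(repetitive_tags)
    kept: Dict[str, RadBin] = {}
    for tag, bin_ in bins.items():
        if tag in neighbourhood:
            if report is not None:
                report.derivative.append(tag)
                if tag in report.kept:
                    report.kept.remove(tag)
        else:
            kept[tag] = bin_
    return kept


def cap_bin_coverage(bin_: RadBin, cap: float = 30.0) -> RadBin:
    """Truncate a bin so estimated read-2 coverage does not exceed ``cap`` fold.

    Pairs are kept in input order until the next pair would push
    ``sum(len(read2)) / region_length_estimate`` above the cap. Prefix
    truncation (rather than random subsampling) keeps runs reproducible.
    """
    if cap <= 0:
        raise ValueError(f"coverage cap must be positive, got {cap}")
    budget = cap * bin_.region_length_estimate
    total = 0
    kept: List[ReadPair] = []
    for pair in bin_.pairs:
        if total + len(pair.read2) > budget:
            break
        total += len(pair.read2)
        kept.append(pair)
    if len(kept) == len(bin_.pairs):
        return bin_
    return replace(
        bin_, pairs=kept, tag=RadTag(sequence=bin_.tag.sequence, count=len(kept))
    )
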