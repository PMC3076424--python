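"""Read-back alignment, pileups, threshold SNP calling and haplotypes.

Reads are mapped to their bin's contigs by seed-and-extend (exact 17-mer
seeds, then gapless or banded gapped extension); pileups keep only bases
at or above a quality floor; genotypes come from a simple counting rule:
an allele is real in a sample only if seen at least four times, a sample
with one passing allele is homozygous, two passing alleles heterozygous,
none (usually low coverage) a no-call. The same threshold covers small
indels. Bins whose tag itself is polymorphic appear as two tags one
mismatch apart; pairing them phases every variant on their contigs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import edlib

from ._dna import hamming, revcomp
from .radbin import RadBin
from .seqio import SequenceRead

GAP_OPEN = 4
GAP_EXTEND = 1
MATCH = 1
MISMATCH = 2


@dataclass
class Alignment:
    read_id: str
    sample: str
    contig_id: str
    start: int  # 0-based position on the contig
    strand: str
    score: float
    #: (contig_pos, base, qual) for every aligned (match or mismatch) base
    base_calls: List[Tuple[int, str, int]]
    #: (anchor contig_pos, inserted sequence, qual) — anchored at the
    #: contig base preceding the insertion
    insertions: List[Tuple[int, str, int]] = field(default_factory=list)
    #: (first deleted contig_pos, length, qual of the flanking read base)
    deletions: List[Tuple[int, int, int]] = field(default_factory=list)


class ContigAligner:
    """Seed-and-extend aligner for one contig.

    Exact seeds of ``seed_len`` anchor a diagonal; if the gapless
    interpretation of that diagonal has at most two mismatches it is
    accepted directly, otherwise a banded gapped alignment (match +1,
    mismatch -2, gap open -4, gap extend -1) is run around the diagonal.
    Alignments scoring below ``min_score_frac`` times the read length are
    rejected.
    """

    def __init__(
        self,
        contig_id: str,
        sequence: str,
        seed_len: int = 17,
        band: int = 10,
        min_score_frac: float = 0.6,
    ):
        self.contig_id = contig_id
        self.sequence = sequence
        self.seed_len = seed_len
        self.band = band
        self.min_score_frac = min_score_frac
        self._index: Dict[str, List[int]] = {}
        for i in range(len(sequence) - seed_len + 1):
            self._index.setdefault(sequence[i : i + seed_len], []).append(i)

    def _diagonals(self, query: str) -> List[int]:
        s = self.seed_len
        if len(query) < s:
            return []
        offsets = list(range(0, len(query) - s + 1, s))
        if offsets[-1] != len(query) - s:
            offsets.append(len(query) - s)
        diags: List[int] = []
        for off in offsets:
            hits = self._index.get(query[off : off + s])
            if hits:
                for h in hits:
                    d = h - off
                    if d not in diags:
                        diags.append(d)
                break  # first seeding offset is enough to anchor
        return diags

    def align(self, read: SequenceRead, sample: str = "") -> Optional[Alignment]:
        best: Optional[Alignment] = None
        for strand in "+-":
            if strand == "+":
                query, quals = read.bases, read.quals
            else:
                query, quals = revcomp(read.bases), tuple(reversed(read.quals))
            for diag in self._diagonals(query):
                aln = self._align_at(read.id, sample, query, quals, diag, strand)
                if aln is not None and (best is None or aln.score > best.score):
                    best = aln
        if best is not None and best.score >= self.min_score_frac * len(read):
            return best
        return None

    def _align_at(
        self,
        read_id: str,
        sample: str,
        query: str,
        quals: Sequence[int],
        diag: int,
        strand: str,
    ) -> Optional[Alignment]:
        ref = self.sequence
        m = len(query)
        if 0 <= diag and diag + m <= len(ref):
            window = ref[diag : diag + m]
            mismatches = [i for i in range(m) if window[i] != query[i]]
            if len(mismatches) <= 2:
                score = (m - len(mismatches)) * MATCH - len(mismatches) * MISMATCH
                return Alignment(
                    read_id=read_id,
                    sample=sample,
                    contig_id=self.contig_id,
                    start=diag,
                    strand=strand,
                    score=score,
                    base_calls=[(diag + i, query[i], quals[i]) for i in range(m)],
                )
        return self._banded(read_id, sample, query, quals, diag, strand)

    def _banded(
        self,
        read_id: str,
        sample: str,
        query: str,
        quals: Sequence[int],
        diag: int,
        strand: str,
    ) -> Optional[Alignment]:
        ref = self.sequence
        m = len(query)
        w_start = max(0, diag - self.band)
        w_end = min(len(ref), diag + m + self.band)
        window = ref[w_start:w_end]
        n = len(window)
        if n == 0:
            return None
        NEG = float("-inf")
        # semi-global: the read aligns end-to-end, free start/end in window
        M = [[NEG] * (n + 1) for _ in range(m + 1)]
        X = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in ref (insertion)
        Y = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in read (deletion)
        for j in range(n + 1):
            M[0][j] = 0.0
        for i in range(1, m + 1):
            qc = query[i - 1]
            Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
            Mi, Xi, Yi = M[i], X[i], Y[i]
            Xi[0] = max(Mp[0] - GAP_OPEN, Xp[0] - GAP_EXTEND)
            for j in range(1, n + 1):
                s = MATCH if qc == window[j - 1] else -MISMATCH
                prev = max(Mp[j - 1], Xp[j - 1], Yp[j - 1])
                if prev > NEG:
                    Mi[j] = prev + s
                Xi[j] = max(Mp[j] - GAP_OPEN, Xp[j] - GAP_EXTEND)
                Yi[j] = max(Mi[j - 1] - GAP_OPEN, Yi[j - 1] - GAP_EXTEND)
        end_j = max(range(n + 1), key=lambda j: M[m][j])
        score = M[m][end_j]
        if score == NEG:
            return None
        # traceback from (m, end_j): collect raw ops, newest first
        ops: List[Tuple[str, int, int]] = []  # (op, read_idx, window_idx)
        i, j, state = m, end_j, "M"
        while i > 0:
            if state == "M":
                ops.append(("M", i - 1, j - 1))
                prev = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
                if prev == M[i - 1][j - 1]:
                    state = "M"
                elif prev == X[i - 1][j - 1]:
                    state = "X"
                else:
                    state = "Y"
                i, j = i - 1, j - 1
            elif state == "X":
                ops.append(("I", i - 1, j))
                if X[i][j] == M[i - 1][j] - GAP_OPEN:
                    state = "M"
                i -= 1
            else:  # Y consumes a window base as a deletion
                ops.append(("D", i, j - 1))
                if Y[i][j] == M[i][j - 1] - GAP_OPEN:
                    state = "M"
                j -= 1
        ops.reverse()
        start = w_start + j
        base_calls: List[Tuple[int, str, int]] = []
        insertions: List[Tuple[int, str, int]] = []
        deletions: List[Tuple[int, int, int]] = []
        idx = 0
        while idx < len(ops):
            op, ri, wj = ops[idx]
            if op == "M":
                base_calls.append((w_start + wj, query[ri], quals[ri]))
                idx += 1
            elif op == "I":
                run = [ri]
                idx += 1
                while idx < len(ops) and ops[idx][0] == "I":
                    run.append(ops[idx][1])
                    idx += 1
                seq = "".join(query[r] for r in run)
                insertions.append(
                    (w_start + wj - 1, seq, min(quals[r] for r in run))
                )
            else:
                first = wj
                length = 1
                idx += 1
                while idx < len(ops) and ops[idx][0] == "D":
                    length += 1
                    idx += 1
                deletions.append(
                    (w_start + first, length, quals[min(ri, m - 1)])
                )
        return Alignment(
            read_id=read_id,
            sample=sample,
            contig_id=self.contig_id,
            start=start,
            strand=strand,
            score=score,
            base_calls=base_calls,
            insertions=insertions,
            deletions=deletions,
        )


def align_read_to_contig(
    contig_sequence: str,
    read: SequenceRead,
    sample: str = "",
    contig_id: str = "contig",
    **kwargs,
) -> Optional[Alignment]:
    """One-shot convenience wrapper around :class:`ContigAligner`."""
    return ContigAligner(contig_id, contig_sequence, **kwargs).align(read, sample)


def align_to_best_contig(
    aligners: Sequence[ContigAligner], read: SequenceRead, sample: str = ""
) -> Optional[Alignment]:
    """Align against every contig of a bin; equally good hits on two
    different contigs are ambiguous and yield None."""
    hits = [a for a in (al.align(read, sample) for al in aligners) if a is not None]
    if not hits:
        return None
    hits.sort(key=lambda a: -a.score)
    if len(hits) > 1 and hits[0].score == hits[1].score:
        return None
    return hits[0]


PileupColumn = Dict[str, Counter]  # sample -> allele -> count


def build_pileup(
    contig_sequence: str,
    alignments: Iterable[Alignment],
    min_base_quality: int = 20,
) -> Dict[int, PileupColumn]:
    """Per-position per-sample allele counts, high-quality bases only.

    Alleles are single bases, ``+SEQ`` for an insertion anchored at the
    preceding contig base, or ``-N`` for a deletion counted at its first
    deleted position. Positions are 0-based here; reports are 1-based.
    """
    pileup: Dict[int, PileupColumn] = {}

    def bump(pos: int, sample: str, allele: str) -> None:
        pileup.setdefault(pos, {}).setdefault(sample, Counter())[allele] += 1

    for aln in alignments:
        for pos, base, qual in aln.base_calls:
            if qual >= min_base_quality and base != "N":
                bump(pos, aln.sample, base)
        for pos, seq, qual in aln.insertions:
            if qual >= min_base_quality:
                bump(pos, aln.sample, f"+{seq}")
        for pos, length, qual in aln.deletions:
            if qual >= min_base_quality:
                bump(pos, aln.sample, f"-{length}")
    return pileup


@dataclass
class GenotypeCall:
    sample: str
    alleles: Tuple[str, ...]  # () = no call; 1 = hom; 2 = het
    multi_allelic: bool = False

    def render(self) -> str:
        if not self.alleles or self.multi_allelic:
            return "-"
        if len(self.alleles) == 1:
            return self.alleles[0]
        return f"[{self.alleles[0]}/{self.alleles[1]}]"

    @property
    def is_call(self) -> bool:
        return bool(self.alleles) and not self.multi_allelic


def call_site(
    column: PileupColumn,
    ref_base: str,
    samples: Sequence[str],
    min_allele_count: int = 4,
) -> List[GenotypeCall]:
    """Genotype each sample by the counting rule: alleles with at least
    ``min_allele_count`` observations pass; 0 passing gives a no-call,
    1 a homozygote, 2 a heterozygote (reference allele first), 3+ a
    flagged multi-allelic no-call."""
    calls: List[GenotypeCall] = []
    for sample in samples:
        counts = column.get(sample, Counter())
        passing = [a for a, c in counts.items() if c >= min_allele_count]
        if not passing:
            calls.append(GenotypeCall(sample, ()))
        elif len(passing) == 1:
            calls.append(GenotypeCall(sample, (passing[0],)))
        elif len(passing) == 2:
            passing.sort(key=lambda a: (a != ref_base, -counts[a], a))
            calls.append(GenotypeCall(sample, tuple(passing)))
        else:
            calls.append(GenotypeCall(sample, (), multi_allelic=True))
    return calls


@dataclass
class SnpRecord:
    contig: str  # contig FASTA header
    pos: int  # 1-based position on the contig
    ref: str
    calls: List[GenotypeCall]


def call_contig_snps(
    contig_header: str,
    contig_sequence: str,
    pileup: Dict[int, PileupColumn],
    samples: Sequence[str],
    min_allele_count: int = 4,
) -> List[SnpRecord]:
    """Emit a record wherever a sample's called genotype includes an
    allele that differs from the contig consensus."""
    records: List[SnpRecord] = []
    for pos in sorted(pileup):
        ref_base = contig_sequence[pos]
        calls = call_site(pileup[pos], ref_base, samples, min_allele_count)
        variant = any(
            c.is_call and any(a != ref_base for a in c.alleles) for c in calls
        )
        if variant:
            records.append(
                SnpRecord(contig=contig_header, pos=pos + 1, ref=ref_base, calls=calls)
            )
    return records


def call_bin_snps(
    contigs: Sequence[Tuple[str, str]],
    pairs_by_sample: Dict[str, Sequence],
    min_allele_count: int = 4,
    min_base_quality: int = 20,
    aligner_kwargs: Optional[dict] = None,
) -> List[SnpRecord]:
    """Align each sample's read-2 sequences back to the bin's contigs
    (assembled from the pooled samples) and call per-sample genotypes.

    ``contigs`` is a list of (header, sequence); reads mapping equally
    well to two contigs are dropped as ambiguous.
    """
    aligners = [
        ContigAligner(header, seq, **(aligner_kwargs or {}))
        for header, seq in contigs
    ]
    samples = sorted(pairs_by_sample)
    by_contig: Dict[str, List[Alignment]] = {h: [] for h, _ in contigs}
    for sample in samples:
        for pair in pairs_by_sample[sample]:
            aln = align_to_best_contig(aligners, pair.read2, sample)
            if aln is not None:
                by_contig[aln.contig_id].append(aln)
    records: List[SnpRecord] = []
    for header, seq in contigs:
        pileup = build_pileup(seq, by_contig[header], min_base_quality)
        records.extend(
            call_contig_snps(header, seq, pileup, samples, min_allele_count)
        )
    return records


def write_snp_report(records: Iterable[SnpRecord], path) -> None:
    """Two-line report dialect: contig header, then
    ``<pos> <ref> <sample> <genotype> <sample> <genotype> …``."""
    with open(path, "w") as out:
        for rec in records:
            out.write(rec.contig + "\n")
            fields = [str(rec.pos), rec.ref]
            for call in rec.calls:
                fields.append(call.sample)
                fields.append(call.render())
            out.write(" ".join(fields) + "\n")


def parse_snp_report(path) -> List[SnpRecord]:
    records: List[SnpRecord] = []
    with open(path) as handle:
        lines = [l.rstrip("\n") for l in handle if l.strip()]
    for contig_line, snp_line in zip(lines[::2], lines[1::2]):
        fields = snp_line.split(" ")
        pos, ref = int(fields[0]), fields[1]
        calls = []
        for sample, gt in zip(fields[2::2], fields[3::2]):
            if gt == "-":
                calls.append(GenotypeCall(sample, ()))
            elif gt.startswith("["):
                a, b = gt[1:-1].split("/")
                calls.append(GenotypeCall(sample, (a, b)))
            else:
                calls.append(GenotypeCall(sample, (gt,)))
        records.append(SnpRecord(contig=contig_line, pos=pos, ref=ref, calls=calls))
    return records


def _vcf_ref_alt(
    rec: SnpRecord, contig_seq: str, allele: str
) -> Optional[Tuple[int, str, str]]:
    """Map an internal allele string to (1-based POS, REF, ALT),
    left-anchoring indels on the previous base."""
    pos0 = rec.pos - 1
    if allele.startswith("+"):
        return rec.pos, rec.ref, rec.ref + allele[1:]
    if allele.startswith("-"):
        length = int(allele[1:])
        if pos0 == 0:
            return None
        anchor = contig_seq[pos0 - 1]
        return rec.pos - 1, anchor + contig_seq[pos0 : pos0 + length], anchor
    return rec.pos, rec.ref, allele


def write_vcf(
    records: Iterable[SnpRecord],
    contig_sequences: Dict[str, str],
    path,
    source: str = "radpe",
) -> None:
    """Minimal VCF 4.2 with one line per variant allele set and GT calls."""
    records = list(records)
    samples: List[str] = []
    for rec in records:
        for call in rec.calls:
            if call.sample not in samples:
                samples.append(call.sample)
    with open(path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write(f"##source={source}\n")
        out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for contig, seq in contig_sequences.items():
            out.write(f"##contig=<ID={contig},length={len(seq)}>\n")
        out.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for rec in records:
            seq = contig_sequences[rec.contig]
            alt_alleles: List[str] = []
            for call in rec.calls:
                for a in call.alleles:
                    if a != rec.ref and a not in alt_alleles:
                        alt_alleles.append(a)
            mapped = [_vcf_ref_alt(rec, seq, a) for a in alt_alleles]
            if not mapped or any(m is None for m in mapped):
                continue
            pos_set = {m[0] for m in mapped} | {len(m[1]) for m in mapped}
            if len({m[0] for m in mapped}) > 1:
                continue  # mixed indel/SNP anchors: emit separately
            pos = mapped[0][0]
            ref = max((m[1] for m in mapped), key=len)
            alts = []
            for m in mapped:
                alt = m[2] + ref[len(m[1]) :]
                alts.append(alt)
            allele_index = {rec.ref: 0}
            for a, alt in zip(alt_alleles, alts):
                allele_index[a] = alts.index(alt) + 1
            gts = []
            for sample in samples:
                call = next((c for c in rec.calls if c.sample == sample), None)
                if call is None or not call.is_call:
                    gts.append("./.")
                elif len(call.alleles) == 1:
                    idx = allele_index.get(call.alleles[0], ".")
                    gts.append(f"{idx}/{idx}")
                else:
                    i0 = allele_index.get(call.alleles[0], ".")
                    i1 = allele_index.get(call.alleles[1], ".")
                    gts.append(f"{i0}/{i1}")
            out.write(
                f"{rec.contig}\t{pos}\t.\t{ref}\t{','.join(alts)}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


@dataclass
class HaplotypePair:
    """Two RAD tags one mismatch apart: the two alleles of one locus."""

    tag_a: str
    tag_b: str
    count_a: int
    count_b: int
    contig_a: str
    contig_b: str
    #: (1-based position on contig_a, base on a, base on b); '-' for gaps
    differences: List[Tuple[int, str, str]]


def _contig_differences(a: str, b: str) -> List[Tuple[int, str, str]]:
    """Position-wise differences between two contig alleles (best of b and
    its reverse complement against a)."""
    best = None
    for candidate in (b, revcomp(b)):
        res = edlib.align(candidate, a, task="path", mode="NW")
        if best is None or res["editDistance"] < best[0]["editDistance"]:
            best = (res, candidate)
    res, b_or = best
    nice = edlib.getNiceAlignment(res, b_or, a)
    qa, ta = nice["query_aligned"], nice["target_aligned"]
    # overhanging contig ends are span differences, not variants; gap
    # placement near an end is also ambiguous (a terminal gap can slide
    # inward past a coincidentally matching base), so trim each end up to
    # the first window of 15 gap-free columns
    gap_free = [qa[i] != "-" and ta[i] != "-" for i in range(len(qa))]
    window = 15
    lo, hi = 0, len(qa)
    while lo + window <= hi and not all(gap_free[lo : lo + window]):
        lo += 1
    while hi - window >= lo and not all(gap_free[hi - window : hi]):
        hi -= 1
    diffs: List[Tuple[int, str, str]] = []
    a_pos = lo - ta[:lo].count("-")
    for qc, tc in zip(qa[lo:hi], ta[lo:hi]):
        if tc != "-":
            a_pos += 1
        if qc != tc:
            diffs.append((a_pos, tc, qc))
    return diffs


def pair_biallelic_tags(
    bins: Dict[str, RadBin],
    results: Dict[str, "object"],
    ratio_bounds: Tuple[float, float] = (1 / 3, 3.0),
) -> List[HaplotypePair]:
    """Pair tags at Hamming distance exactly 1 whose read counts are
    balanced (two alleles of one locus are expected near 1:1). Tags with
    two possible partners are ambiguous and left unpaired.
    """
    tags = sorted(t for t in bins if t in results and results[t].contigs)
    partners: Dict[str, List[str]] = {t: [] for t in tags}
    for i, ta in enumerate(tags):
        for tb in tags[i + 1 :]:
            if hamming(ta, tb) == 1:
                partners[ta].append(tb)
                partners[tb].append(ta)
    out: List[HaplotypePair] = []
    for ta in tags:
        if len(partners[ta]) != 1:
            continue
        tb = partners[ta][0]
        if len(partners[tb]) != 1 or ta > tb:
            continue
        ca, cb = bins[ta].count, bins[tb].count
        ratio = ca / cb
        if not (ratio_bounds[0] <= ratio <= ratio_bounds[1]):
            continue
        contig_a = results[ta].contigs[0].sequence
        contig_b = results[tb].contigs[0].sequence
        out.append(
            HaplotypePair(
                tag_a=ta,
                tag_b=tb,
                count_a=ca,
                count_b=cb,
                contig_a=contig_a,
                contig_b=contig_b,
                differences=_contig_differences(contig_a, contig_b),
            )
        )
    return out
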