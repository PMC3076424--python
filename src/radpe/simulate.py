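"""Synthetic genomes, restriction digests and RAD paired-end libraries.

The simulator is the oracle for the whole pipeline: it produces genomes
(optionally diploid, with a planted variant table), digests them with
palindromic restriction enzymes at a configurable per-site cut
probability (1.0 = complete digest, lower values model the partial
digests used for whole-genome tiling), shears and size-selects RAD
fragments, and emits paired-end reads with a known error model. Every
read, fragment and variant is recorded in truth tables so tests can
compare pipeline output against the simulated ground truth.

Library geometry follows the bench protocol: read 1 starts at a cut
site with the enzyme's residual sequence (``TGCAGG…`` for SbfI after
CCTGCA^GG cutting) and read 2 is the reverse complement of the randomly
sheared far end. A long-insert mode models the double-circularization
construction that places sequence 1-6 kb from the cut site at the far
end of a short sequencable fragment, together with the ligation
junction every final fragment carries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from ._dna import revcomp
from .seqio import ReadPair, SequenceRead


def _rng(seed: Union[int, np.random.Generator, None]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A palindromic restriction enzyme.

    ``cut_offset`` is the top-strand cut position within the site, chosen
    so that the retained residual ``site[cut_offset:]`` is what read 1
    begins with after adapter ligation.
    """

    name: str
    site: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not (0 <= self.cut_offset <= len(self.site)):
            raise ValueError("cut offset outside recognition site")
        if revcomp(self.site) != self.site:
            raise ValueError(f"{self.name}: site must be palindromic")

    @property
    def residual(self) -> str:
        return self.site[self.cut_offset :]


ENZYMES: Dict[str, RestrictionEnzyme] = {
    "SbfI": RestrictionEnzyme("SbfI", "CCTGCAGG", 2),  # read 1 begins TGCAGG
    "NlaIII": RestrictionEnzyme("NlaIII", "CATG", 0),
    "Sau3AI": RestrictionEnzyme("Sau3AI", "GATC", 0),
}


@dataclass
class SyntheticGenome:
    sequence: str
    topology: str = "linear"  # or "circular"

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def circular(self) -> bool:
        return self.topology == "circular"

    def slice(self, start: int, end: int) -> str:
        """Extract [start, end) with circular wrap-around."""
        n = len(self.sequence)
        start %= n
        end = start + (end - start if end >= start else end + n - start)
        if end <= n:
            return self.sequence[start:end]
        return self.sequence[start:] + self.sequence[: end - n]


@dataclass
class Variant:
    """Planted variant, 0-based position on the reference haplotype."""

    position: int
    ref: str
    alt: str
    type: str  # snp | ins | del


@dataclass
class DiploidTruth:
    reference: SyntheticGenome
    alternate: SyntheticGenome
    variants: List[Variant]

    @property
    def haplotypes(self) -> Tuple[SyntheticGenome, SyntheticGenome]:
        return (self.reference, self.alternate)


def generate_genome(
    length: int,
    gc_fraction: float = 0.5,
    topology: str = "linear",
    seed: Union[int, np.random.Generator, None] = None,
) -> SyntheticGenome:
    """I.i.d. random genome with the requested GC content."""
    if length <= 0:
        raise ValueError(f"genome length must be positive, got {length}")
    rng = _rng(seed)
    p = np.array(
        [
            (1 - gc_fraction) / 2,
            gc_fraction / 2,
            gc_fraction / 2,
            (1 - gc_fraction) / 2,
        ]
    )
    bases = rng.choice(np.array(list("ACGT")), size=length, p=p)
    return SyntheticGenome(sequence="".join(bases), topology=topology)


def plant_variants(
    genome: SyntheticGenome,
    n_snp: int = 0,
    n_ins: int = 0,
    n_del: int = 0,
    seed: Union[int, np.random.Generator, None] = None,
    min_spacing: int = 10,
    indel_length: int = 1,
    edge_margin: int = 50,
) -> DiploidTruth:
    """Plant variants on a copy of the genome, returning both haplotypes.

    Variant positions are distinct and at least ``min_spacing`` apart so
    each variant can be recovered independently.
    """
    n_total = n_snp + n_ins + n_del
    rng = _rng(seed)
    seq = genome.sequence
    usable = len(seq) - 2 * edge_margin
    if n_total * (min_spacing + indel_length) > usable:
        raise ValueError("too many variants for this genome length")
    positions: List[int] = []
    attempts = 0
    while len(positions) < n_total:
        attempts += 1
        if attempts > 1000 * max(1, n_total):
            raise ValueError("could not satisfy variant spacing")
        pos = int(rng.integers(edge_margin, len(seq) - edge_margin))
        if all(abs(pos - p) >= min_spacing for p in positions):
            positions.append(pos)
    positions.sort()
    kinds = ["snp"] * n_snp + ["ins"] * n_ins + ["del"] * n_del
    rng.shuffle(kinds)
    variants: List[Variant] = []
    for pos, kind in zip(positions, kinds):
        ref_base = seq[pos]
        if kind == "snp":
            alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
            variants.append(Variant(pos, ref_base, alt, "snp"))
        elif kind == "ins":
            ins = "".join(rng.choice(list("ACGT"), size=indel_length))
            variants.append(Variant(pos, ref_base, ref_base + ins, "ins"))
        else:
            variants.append(
                Variant(pos, seq[pos : pos + 1 + indel_length], ref_base, "del")
            )
    # apply right-to-left so earlier positions stay valid
    alt_seq = seq
    for var in reversed(variants):
        alt_seq = (
            alt_seq[: var.position]
            + var.alt
            + alt_seq[var.position + len(var.ref) :]
        )
    return DiploidTruth(
        reference=genome,
        alternate=SyntheticGenome(sequence=alt_seq, topology=genome.topology),
        variants=variants,
    )


@dataclass(frozen=True)
class Cut:
    """One realized restriction cut. ``breakpoint`` is the top-strand cut
    coordinate (site start + offset); ``rev_anchor`` is where the
    reverse-orientation tag read is anchored (site end - offset)."""

    site_start: int
    enzyme: RestrictionEnzyme

    @property
    def breakpoint(self) -> int:
        return self.site_start + self.enzyme.cut_offset

    @property
    def rev_anchor(self) -> int:
        return self.site_start + len(self.enzyme.site) - self.enzyme.cut_offset


@dataclass
class Fragment:
    """A digest fragment: [start, end) on its source haplotype; ``end`` may
    exceed the genome length for fragments wrapping a circular origin."""

    haplotype: int
    start: int
    end: int
    left_cut: Optional[Cut] = None
    right_cut: Optional[Cut] = None
    copy: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def rad_end(self) -> str:
        if self.left_cut and self.right_cut:
            return "both"
        if self.left_cut:
            return "left"
        if self.right_cut:
            return "right"
        return "none"


def find_sites(genome: SyntheticGenome, enzymes: Sequence[RestrictionEnzyme]) -> List[Cut]:
    """All recognition-site cuts, sorted by breakpoint; circular genomes
    include sites spanning the origin."""
    seq = genome.sequence
    cuts: List[Cut] = []
    for enzyme in enzymes:
        search = seq
        if genome.circular:
            search = seq + seq[: len(enzyme.site) - 1]
        pos = search.find(enzyme.site)
        while pos != -1:
            cuts.append(Cut(site_start=pos, enzyme=enzyme))
            pos = search.find(enzyme.site, pos + 1)
    cuts.sort(key=lambda c: (c.breakpoint, c.enzyme.name))
    return cuts


def digest(
    genome: SyntheticGenome,
    enzymes: Sequence[RestrictionEnzyme],
    partial_cut_prob: float = 1.0,
    molecule_copies: int = 1,
    seed: Union[int, np.random.Generator, None] = None,
    haplotype: int = 0,
) -> List[Fragment]:
    """Digest each molecule copy, cutting each site independently with
    probability ``partial_cut_prob``."""
    if not enzymes:
        raise ValueError("need at least one enzyme")
    rng = _rng(seed)
    cuts = find_sites(genome, enzymes)
    n = len(genome.sequence)
    fragments: List[Fragment] = []
    for copy in range(molecule_copies):
        if cuts:
            mask = rng.random(len(cuts)) < partial_cut_prob
            chosen = [c for c, m in zip(cuts, mask) if m]
        else:
            chosen = []
        if genome.circular:
            if not chosen:
                continue  # an uncut circle yields no sequencable ends
            for cut, nxt in zip(chosen, chosen[1:] + [chosen[0]]):
                start = cut.breakpoint
                end = nxt.breakpoint if nxt.breakpoint > start else nxt.breakpoint + n
                fragments.append(
                    Fragment(
                        haplotype=haplotype,
                        start=start,
                        end=end,
                        left_cut=cut,
                        right_cut=nxt,
                        copy=copy,
                    )
                )
        else:
            bounds = [0] + [c.breakpoint for c in chosen] + [n]
            cut_at = [None] + list(chosen) + [None]
            for i in range(len(bounds) - 1):
                if bounds[i] == bounds[i + 1]:
                    continue
                fragments.append(
                    Fragment(
                        haplotype=haplotype,
                        start=bounds[i],
                        end=bounds[i + 1],
                        left_cut=cut_at[i],
                        right_cut=cut_at[i + 1],
                        copy=copy,
                    )
                )
    return fragments


@dataclass
class SimConfig:
    """Library geometry and error model.

    Defaults describe a standard single-digest RAD-PE SNP-discovery
    library: 2x60 bp reads with a 300-800 bp sheared-fragment gel window.
    Named constructors give the partial-digest whole-genome and
    long-insert geometries (40+80 bp asymmetric reads).
    """

    read1_len: int = 60
    read2_len: int = 60
    shear_window: Tuple[int, int] = (300, 800)
    size_select: Tuple[int, int] = (300, 800)
    #: Digest-level gel window (partial-digest protocol); None = keep all.
    fragment_select: Optional[Tuple[int, int]] = None
    error_rate: float = 0.0
    depth: int = 40  # read pairs per RAD tag
    partial_cut_prob: float = 1.0
    molecule_copies: int = 1
    qual_correct: int = 40
    qual_error: int = 15

    def __post_init__(self) -> None:
        for lo, hi in filter(None, (self.shear_window, self.size_select, self.fragment_select)):
            if not (0 < lo <= hi):
                raise ValueError("size windows must satisfy 0 < min <= max")
        if not (0.0 <= self.error_rate <= 1.0 and 0.0 <= self.partial_cut_prob <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")

    @classmethod
    def partial_digest(cls, **overrides) -> "SimConfig":
        """Whole-genome tiling geometry: 40+80 bp reads, 1-5 kb digest
        window, 200-1200 bp shear window, partial cut probability 0.1
        (a digestion level whose fragment pool populates the 1-5 kb gel
        window), 50 molecule copies."""
        defaults = dict(
            read1_len=40,
            read2_len=80,
            shear_window=(200, 1200),
            size_select=(200, 1200),
            fragment_select=(1000, 5000),
            partial_cut_prob=0.1,
            molecule_copies=50,
            depth=40,
        )
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def long_insert(cls, **overrides) -> "SimConfig":
        """Double-circularization geometry: inserts 1-6 kb from the cut
        site, 40+80 bp reads, ~600 bp final fragments."""
        defaults = dict(
            read1_len=40,
            read2_len=80,
            shear_window=(400, 800),
            size_select=(1000, 6000),
            depth=1000,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class ShearedPiece:
    """A sheared, size-selected piece retaining one restriction-cut end.

    ``anchor`` is the genome coordinate of the tag end; ``direction`` is
    '+' when the piece extends rightward from the anchor on the forward
    strand and '-' when it extends leftward (tag read on the reverse
    strand). Coordinates may wrap on circular genomes.
    """

    haplotype: int
    anchor: int
    direction: str
    length: int

    @property
    def span(self) -> Tuple[int, int]:
        if self.direction == "+":
            return (self.anchor, self.anchor + self.length)
        return (self.anchor - self.length, self.anchor)


def shear_and_select(
    fragments: Iterable[Fragment],
    cfg: SimConfig,
    seed: Union[int, np.random.Generator, None] = None,
    rounds: int = 1,
) -> List[ShearedPiece]:
    """Shear each fragment and keep cut-end pieces inside the gel window.

    Each fragment is sheared ``rounds`` times independently, emulating
    the many identical molecule copies a real library contains. The
    retained piece at a cut end has its sheared endpoint uniform within
    the size-selection window (pieces extending past the fragment's
    other end are discarded, as they would carry a second cut end).
    """
    rng = _rng(seed)
    lo, hi = cfg.size_select
    pieces: List[ShearedPiece] = []
    fragments = list(fragments)
    for _ in range(rounds):
        for frag in fragments:
            for which, cut in (("left", frag.left_cut), ("right", frag.right_cut)):
                if cut is None:
                    continue
                length = int(rng.integers(lo, hi + 1))
                if length > frag.length:
                    continue
                if which == "left":
                    pieces.append(
                        ShearedPiece(
                            haplotype=frag.haplotype,
                            anchor=frag.start,
                            direction="+",
                            length=length,
                        )
                    )
                else:
                    pieces.append(
                        ShearedPiece(
                            haplotype=frag.haplotype,
                            anchor=frag.start + frag.length
                            + (cut.rev_anchor - cut.breakpoint),
                            direction="-",
                            length=length,
                        )
                    )
    return pieces


@dataclass
class ReadTruth:
    read_id: str
    sample: str
    haplotype: int
    start: int
    end: int
    direction: str
    anchor: int


def _apply_errors(
    seq: str, rng: np.random.Generator, cfg: SimConfig
) -> Tuple[str, Tuple[int, ...]]:
    if cfg.error_rate <= 0:
        return seq, tuple([cfg.qual_correct] * len(seq))
    bases = list(seq)
    quals = [cfg.qual_correct] * len(seq)
    hits = np.nonzero(rng.random(len(seq)) < cfg.error_rate)[0]
    for i in hits:
        bases[i] = str(rng.choice([b for b in "ACGT" if b != bases[i]]))
        quals[i] = cfg.qual_error
    return "".join(bases), tuple(quals)


def make_read_pairs(
    pieces: Iterable[ShearedPiece],
    truth: Union[DiploidTruth, SyntheticGenome],
    cfg: SimConfig,
    seed: Union[int, np.random.Generator, None] = None,
    sample: str = "S1",
    id_prefix: str = "sim",
) -> Tuple[List[ReadPair], List[ReadTruth]]:
    """Emit one read pair per sheared piece, capped at ``cfg.depth`` pairs
    per RAD tag (anchor/direction), with the per-base error model applied.

    Read 1 reads inward from the cut end (it begins with the enzyme
    residual); read 2 is the reverse complement of the piece's sheared
    end. Pieces shorter than read1_len + read2_len are skipped.
    """
    rng = _rng(seed)
    if isinstance(truth, DiploidTruth):
        haplotypes = truth.haplotypes
    else:
        haplotypes = (truth,)
    pairs: List[ReadPair] = []
    rows: List[ReadTruth] = []
    per_tag: Dict[Tuple[int, str], int] = {}
    counter = 0
    for piece in pieces:
        if piece.length < cfg.read1_len + cfg.read2_len:
            continue
        key = (piece.anchor, piece.direction)
        if per_tag.get(key, 0) >= cfg.depth:
            continue
        per_tag[key] = per_tag.get(key, 0) + 1
        hap = haplotypes[piece.haplotype]
        start, end = piece.span
        if piece.direction == "+":
            molecule = hap.slice(start, end)
        else:
            molecule = revcomp(hap.slice(start, end))
        r1_seq, r1_quals = _apply_errors(molecule[: cfg.read1_len], rng, cfg)
        r2_seq, r2_quals = _apply_errors(
            revcomp(molecule[-cfg.read2_len :]), rng, cfg
        )
        read_id = f"{id_prefix}:{counter}"
        counter += 1
        pairs.append(
            ReadPair(
                read1=SequenceRead(id=f"{read_id}/1", bases=r1_seq, quals=r1_quals),
                read2=SequenceRead(id=f"{read_id}/2", bases=r2_seq, quals=r2_quals),
                sample=sample,
            )
        )
        rows.append(
            ReadTruth(
                read_id=read_id,
                sample=sample,
                haplotype=piece.haplotype,
                start=start,
                end=end,
                direction=piece.direction,
                anchor=piece.anchor,
            )
        )
    return pairs, rows


def simulate_library(
    truth: Union[DiploidTruth, SyntheticGenome],
    enzymes: Sequence[RestrictionEnzyme],
    cfg: SimConfig,
    seed: Union[int, np.random.Generator, None] = None,
    sample: str = "S1",
    shear_rounds: Optional[int] = None,
) -> Tuple[List[ReadPair], List[ReadTruth], List[Fragment]]:
    """Digest -> size-select -> shear -> read pairs, for one sample.

    ``shear_rounds`` defaults to twice the target depth so that every tag
    with at least one selected fragment accumulates enough distinct
    sheared molecules to reach ``cfg.depth`` pairs.
    """
    rng = _rng(seed)
    haplotypes = (
        truth.haplotypes if isinstance(truth, DiploidTruth) else (truth,)
    )
    fragments: List[Fragment] = []
    for hap_idx, hap in enumerate(haplotypes):
        fragments.extend(
            digest(
                hap,
                enzymes,
                partial_cut_prob=cfg.partial_cut_prob,
                molecule_copies=cfg.molecule_copies,
                seed=rng,
                haplotype=hap_idx,
            )
        )
    if cfg.fragment_select is not None:
        lo, hi = cfg.fragment_select
        fragments = [f for f in fragments if lo <= f.length <= hi]
    rounds = shear_rounds if shear_rounds is not None else 2 * cfg.depth
    pieces = shear_and_select(fragments, cfg, seed=rng, rounds=rounds)
    pairs, rows = make_read_pairs(pieces, truth, cfg, seed=rng, sample=sample)
    return pairs, rows, fragments


@dataclass
class JunctionTruth:
    read_id: str
    anchor: int
    direction: str
    #: distance of the far (read 2) end from the cut site
    far_distance: int


def simulate_long_insert(
    genome: SyntheticGenome,
    enzyme: RestrictionEnzyme,
    cfg: SimConfig,
    seed: Union[int, np.random.Generator, None] = None,
    sample: str = "S1",
) -> Tuple[List[ReadPair], List[JunctionTruth]]:
    """Long-insert library: read 2 samples sequence far from the cut site.

    Per emitted molecule: insert length L ~ uniform(size_select) measured
    from a cut site, second-shear offset y ~ uniform(0, shear_mean -
    read2_len); read 2 is the reverse complement of the read2_len bases
    ending at distance L - y from the site, read 1 is the tag at the
    site. Molecules too short to hold both reads are skipped.
    """
    rng = _rng(seed)
    cuts = find_sites(genome, [enzyme])
    if not cuts:
        return [], []
    lo, hi = cfg.size_select
    shear_mean = sum(cfg.shear_window) // 2
    y_max = max(0, shear_mean - cfg.read2_len)
    pairs: List[ReadPair] = []
    junctions: List[JunctionTruth] = []
    counter = 0
    for cut in cuts:
        for direction in "+-":
            anchor = cut.breakpoint if direction == "+" else cut.rev_anchor
            for _ in range(cfg.depth):
                insert_len = int(rng.integers(lo, hi + 1))
                y = int(rng.integers(0, y_max + 1))
                far = insert_len - y
                if far - cfg.read2_len <= cfg.read1_len:
                    continue
                if direction == "+":
                    r1 = genome.slice(anchor, anchor + cfg.read1_len)
                    r2_src = genome.slice(anchor + far - cfg.read2_len, anchor + far)
                    r2 = revcomp(r2_src)
                else:
                    r1 = revcomp(genome.slice(anchor - cfg.read1_len, anchor))
                    r2_src = revcomp(
                        genome.slice(anchor - far, anchor - far + cfg.read2_len)
                    )
                    r2 = revcomp(r2_src)
                r1_seq, r1_quals = _apply_errors(r1, rng, cfg)
                r2_seq, r2_quals = _apply_errors(r2, rng, cfg)
                read_id = f"li:{counter}"
                counter += 1
                pairs.append(
                    ReadPair(
                        read1=SequenceRead(
                            id=f"{read_id}/1", bases=r1_seq, quals=r1_quals
                        ),
                        read2=SequenceRead(
                            id=f"{read_id}/2", bases=r2_seq, quals=r2_quals
                        ),
                        sample=sample,
                    )
                )
                junctions.append(
                    JunctionTruth(
                        read_id=read_id,
                        anchor=anchor,
                        direction=direction,
                        far_distance=far,
                    )
                )
    return pairs, junctions


def junction_read_fraction(
    n_fragments: int,
    fragment_len_mean: float,
    read1_len: int,
    read2_len: int,
    seed: Union[int, np.random.Generator, None] = None,
    fragment_len_sd: float = 0.0,
    min_len: float = 200.0,
) -> float:
    """Monte-Carlo fraction of final long-insert fragments whose
    circularization junction falls inside a read.

    Each final fragment carries exactly one junction at a uniformly
    random internal position; a fragment is counted when the junction
    lies within the first ``read1_len`` or last ``read2_len`` bases. For
    a fixed length F the closed form is (read1_len + read2_len) / F.
    """
    if fragment_len_mean < read1_len + read2_len:
        raise ValueError("mean fragment length is below the combined read length")
    rng = _rng(seed)
    if fragment_len_sd > 0:
        lengths = rng.normal(fragment_len_mean, fragment_len_sd, size=n_fragments)
        while True:
            bad = lengths <= min_len
            if not bad.any():
                break
            lengths[bad] = rng.normal(fragment_len_mean, fragment_len_sd, size=bad.sum())
    else:
        lengths = np.full(n_fragments, float(fragment_len_mean))
    junctions = rng.random(n_fragments) * lengths
    in_read = (junctions < read1_len) | (junctions > lengths - read2_len)
    return float(in_read.mean())


# ---------------------------------------------------------------------------
# Per-locus diploid simulation for variant-calling tests


@dataclass
class LocusSnpTruth:
    position: int  # 0-based on the locus reference
    ref: str
    alt: str
    het_samples: Tuple[str, ...]


@dataclass
class LocusSim:
    reference: str  # locus reference sequence (tag at the start)
    pairs: List[ReadPair]
    snps: List[LocusSnpTruth]


def simulate_snp_loci(
    n_loci: int,
    samples: Sequence[str] = ("low-110", "high-141"),
    region_range: Tuple[int, int] = (300, 800),
    depth: int = 30,
    error_rate: float = 0.0,
    n_snps_per_locus: int = 1,
    read1_len: int = 60,
    read2_len: int = 60,
    seed: Union[int, np.random.Generator, None] = None,
    enzyme: RestrictionEnzyme = ENZYMES["SbfI"],
) -> List[LocusSim]:
    """Independent diploid RAD loci with planted heterozygous SNPs.

    Each locus is a random region whose left end carries the enzyme
    residual (the RAD tag). Every planted SNP is heterozygous in one
    randomly chosen sample and homozygous reference in the others, and
    lies inside the read-2-covered span. Per sample, enough pairs are
    emitted for ~``depth``-fold read-2 coverage; each pair samples one of
    the sample's two haplotypes.
    """
    rng = _rng(seed)
    cfg = SimConfig(
        read1_len=read1_len, read2_len=read2_len, error_rate=error_rate
    )
    loci: List[LocusSim] = []
    min_shear = read1_len + read2_len + 20
    for locus_idx in range(n_loci):
        region_len = int(rng.integers(region_range[0], region_range[1] + 1))
        body = generate_genome(region_len - len(enzyme.residual), seed=rng).sequence
        ref = enzyme.residual + body
        snps: List[LocusSnpTruth] = []
        lo_pos, hi_pos = min_shear + 30, region_len - 50
        positions: List[int] = []
        for _ in range(n_snps_per_locus):
            for _attempt in range(200):
                pos = int(rng.integers(lo_pos, hi_pos))
                if all(abs(pos - p) >= 10 for p in positions):
                    positions.append(pos)
                    break
        for pos in sorted(positions):
            alt = str(rng.choice([b for b in "ACGT" if b != ref[pos]]))
            het_sample = str(rng.choice(list(samples)))
            snps.append(
                LocusSnpTruth(
                    position=pos, ref=ref[pos], alt=alt, het_samples=(het_sample,)
                )
            )
        pairs: List[ReadPair] = []
        n_pairs = max(1, round(depth * (region_len - min_shear) / read2_len))
        for sample in samples:
            alt_seq = ref
            for snp in snps:
                if sample in snp.het_samples:
                    alt_seq = (
                        alt_seq[: snp.position] + snp.alt + alt_seq[snp.position + 1 :]
                    )
            haplotypes = (ref, alt_seq)
            for i in range(n_pairs):
                hap = haplotypes[int(rng.integers(0, 2))]
                shear = int(rng.integers(min_shear, region_len + 1))
                molecule = hap[:shear]
                r1_seq, r1_quals = _apply_errors(molecule[:read1_len], rng, cfg)
                r2_seq, r2_quals = _apply_errors(
                    revcomp(molecule[-read2_len:]), rng, cfg
                )
                rid = f"locus{locus_idx}:{sample}:{i}"
                pairs.append(
                    ReadPair(
                        read1=SequenceRead(id=f"{rid}/1", bases=r1_seq, quals=r1_quals),
                        read2=SequenceRead(id=f"{rid}/2", bases=r2_seq, quals=r2_quals),
                        sample=sample,
                    )
                )
        loci.append(LocusSim(reference=ref, pairs=pairs, snps=snps))
    return loci


def write_truth_tsv(rows: Iterable[ReadTruth], path) -> None:
    """Read-level truth table (1-based inclusive coordinates in output)."""
    with open(path, "w") as out:
        out.write("read_id\tsample\thaplotype\tstart\tend\tdirection\tanchor\n")
        for r in rows:
            out.write(
                f"{r.read_id}\t{r.sample}\t{r.haplotype}\t{r.start + 1}\t{r.end}"
                f"\t{r.direction}\t{r.anchor + 1}\n"
            )


def write_fragments_bed(fragments: Iterable[Fragment], path, genome_length: int) -> None:
    """Digest fragment coordinates as BED (0-based half-open; wrapping
    fragments are split at the origin)."""
    with open(path, "w") as out:
        for i, frag in enumerate(fragments):
            name = f"frag{i}_{frag.rad_end}"
            if frag.end <= genome_length:
                out.write(f"hap{frag.haplotype}\t{frag.start}\t{frag.end}\t{name}\n")
            else:
                out.write(f"hap{frag.haplotype}\t{frag.start}\t{genome_length}\t{name}\n")
                out.write(f"hap{frag.haplotype}\t0\t{frag.end - genome_length}\t{name}\n")
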