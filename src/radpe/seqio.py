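"""Sequence I/O and read-level filters.

FASTQ parsing supports the two phred encodings seen on early Illumina
instruments (offset 33, and the offset-64 "Illumina 1.5+" dialect in
which quality 'K' decodes to 11). Contig FASTA output uses the
``<tagIndex>_<tagSequence>_NODE_<n>_length_<L>_cov_<c>`` header dialect
so that downstream SNP reports can reference contigs unambiguously.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field, replace
from typing import IO, Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger(__name__)

#: Sample label for read pairs whose barcode matched no configured sample.
UNASSIGNED = "UNASSIGNED"

#: Supported quality encodings, name -> ASCII offset.
ENCODINGS = {"phred33": 33, "phred64": 64}


class FastqFormatError(ValueError):
    """A FASTQ record is malformed or truncated."""


class PairingError(ValueError):
    """The two FASTQ files of a pair disagree in record count."""


@dataclass
class SequenceRead:
    """One sequencing read: id, bases over {A,C,G,T,N}, integer phred scores."""

    id: str
    bases: str
    quals: Tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.id}: {len(self.bases)} bases but {len(self.quals)} quality scores"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class ReadPair:
    """A paired-end record; ``sample`` is a label or :data:`UNASSIGNED`."""

    read1: SequenceRead
    read2: SequenceRead
    sample: str = UNASSIGNED


def _open(path, mode: str = "rt") -> IO:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _decode_quals(qual_str: str, offset: int, record: str) -> Tuple[int, ...]:
    quals = tuple(ord(c) - offset for c in qual_str)
    for q in quals:
        if q < 0 or q > 62:
            raise FastqFormatError(
                f"record {record}: quality character {qual_str!r} out of range "
                f"for offset {offset}"
            )
    return quals


def parse_fastq(path, encoding: str = "phred33") -> Iterator[SequenceRead]:
    """Stream reads from a 4-line FASTQ file (gzip transparent)."""
    offset = ENCODINGS[encoding]
    index = 0
    with _open(path) as handle:
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                yield SequenceRead(
                    id=title.split()[0],
                    bases=seq.upper(),
                    quals=_decode_quals(qual, offset, f"{index} in {path}"),
                )
                index += 1
        except ValueError as exc:
            if isinstance(exc, FastqFormatError):
                raise
            raise FastqFormatError(
                f"malformed FASTQ record {index} in {path}: {exc}"
            ) from exc


def parse_fastq_pairs(path1, path2, encoding: str = "phred33") -> Iterator[ReadPair]:
    """Stream read pairs from two parallel FASTQ files, in file order."""
    it1 = parse_fastq(path1, encoding)
    it2 = parse_fastq(path2, encoding)
    sentinel = object()
    index = 0
    while True:
        r1 = next(it1, sentinel)
        r2 = next(it2, sentinel)
        if r1 is sentinel and r2 is sentinel:
            return
        if r1 is sentinel or r2 is sentinel:
            short = path1 if r1 is sentinel else path2
            raise PairingError(
                f"files ran out of sync at record {index}: {short} is shorter"
            )
        yield ReadPair(read1=r1, read2=r2)
        index += 1


def write_fastq(reads: Iterable[SequenceRead], path, encoding: str = "phred33") -> None:
    offset = ENCODINGS[encoding]
    with _open(path, "wt") as out:
        for read in reads:
            qual = "".join(chr(q + offset) for q in read.quals)
            out.write(f"@{read.id}\n{read.bases}\n+\n{qual}\n")


def quality_filter(pair: ReadPair, max_poor: int = 25, poor_max_score: int = 11) -> bool:
    """Keep a pair unless either read has more than ``max_poor`` bases at
    phred <= ``poor_max_score``.

    The default 11 is 'K' under the offset-64 encoding; the whole pair is
    dropped together because an orphaned mate cannot be binned.
    Returns True to keep, False to drop.
    """
    for read in (pair.read1, pair.read2):
        n_poor = sum(1 for q in read.quals if q <= poor_max_score)
        if n_poor > max_poor:
            return False
    return True


def demultiplex(pair: ReadPair, barcodes: Dict[str, str]) -> ReadPair:
    """Assign a sample by exact in-line barcode match on read 1 and trim it.

    Non-matching pairs come back labelled :data:`UNASSIGNED` with read 1
    untouched; they are excluded downstream.
    """
    lengths = {len(b) for b in barcodes.values()}
    if len(lengths) != 1:
        raise ValueError(f"barcodes must share one length, got lengths {sorted(lengths)}")
    (blen,) = lengths
    prefix = pair.read1.bases[:blen]
    for sample, barcode in barcodes.items():
        if prefix == barcode:
            trimmed = SequenceRead(
                id=pair.read1.id,
                bases=pair.read1.bases[blen:],
                quals=pair.read1.quals[blen:],
            )
            return replace(pair, read1=trimmed, sample=sample)
    return replace(pair, sample=UNASSIGNED)


def contig_header(tag_index: int, tag_sequence: str, node: int, length: int, cov: float) -> str:
    """File-S4-style contig name, e.g. ``32831_TGCAGG…_NODE_1_length_338_cov_9.647929``."""
    return f"{tag_index}_{tag_sequence}_NODE_{node}_length_{length}_cov_{cov:.6f}"


def write_contigs_fasta(results, path, line_width: int = 60) -> int:
    """Write per-tag contigs as FASTA.

    ``results`` is an iterable of ``(tag_index, tag_sequence, contigs)``
    where each contig exposes ``sequence``, ``length`` and
    ``mean_kmer_coverage``. Empty contigs are skipped with a warning.
    Returns the number of records written.
    """
    written = 0
    with _open(path, "wt") as out:
        for tag_index, tag_sequence, contigs in results:
            for node, contig in enumerate(contigs, start=1):
                if not contig.sequence:
                    logger.warning(
                        "skipping empty contig %d of tag %s", node, tag_sequence
                    )
                    continue
                header = contig_header(
                    tag_index, tag_sequence, node, contig.length, contig.mean_kmer_coverage
                )
                out.write(f">{header}\n")
                for i in range(0, len(contig.sequence), line_width):
                    out.write(contig.sequence[i : i + line_width] + "\n")
                written += 1
    return written


def parse_fasta(path) -> List[Tuple[str, str]]:
    """Read a FASTA file as (header, sequence) tuples."""
    records: List[Tuple[str, str]] = []
    header: Optional[str] = None
    chunks: List[str] = []
    with _open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if header is not None:
                    records.append((header, "".join(chunks)))
                header = line[1:]
                chunks = []
            elif line:
                chunks.append(line)
    if header is not None:
        records.append((header, "".join(chunks)))
    return records
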