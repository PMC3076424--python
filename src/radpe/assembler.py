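"""Local de Bruijn assembly of one RAD bin's sheared-end reads.

Each bin's read-2 sequences are decomposed into canonical k-mers, the
graph is cleaned (coverage cutoff, tip clipping, bubble popping) and
maximal unbranched paths are emitted as contigs. The word length is
chosen per bin: three trials (a fixed low k, a coverage-predicted k and
a fixed high k) are run and the one with the greatest total assembled
length wins, mirroring how per-locus assembly lets parameters track the
wide depth variation between loci. Long-insert libraries get a second
pass: a first assembly at k=41 produces contigs that are fed back as
long sequences into a lower-k assembly, where they thread through the
unitig graph and resolve repeats longer than the second word length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import edlib

from ._dna import canonical, revcomp
from .radbin import RadBin, RadTag
from .stats import n50

_BASES = "ACGT"


@dataclass
class AssemblyParams:
    k_low: int = 21
    k_high: int = 31
    min_contig_length: int = 100
    #: Tips shorter than this are clipped; None means 2k.
    tip_max_length: Optional[int] = None
    bubble_identity: float = 0.9
    #: k-mers with multiplicity below this are dropped. This is an
    #: error-removal device; use 1 for error-free input.
    cov_cutoff: int = 2
    #: First-pass word length for the long-insert two-pass mode.
    k_long_pass1: int = 41

    def tip_max(self, k: int) -> int:
        return self.tip_max_length if self.tip_max_length is not None else 2 * k


@dataclass
class Contig:
    sequence: str
    length: int
    mean_kmer_coverage: float


@dataclass
class AssemblyResult:
    tag: RadTag
    contigs: List[Contig]
    chosen_k: int
    total_assembled_length: int
    #: (k, total assembled length) for every trial that was run.
    trials: List[Tuple[int, int]] = field(default_factory=list)

    @property
    def failed(self) -> bool:
        return not self.contigs


class KmerGraph:
    """Canonical k-mer multiset with implicit (k-1)-overlap adjacency."""

    def __init__(self, k: int):
        if k % 2 == 0:
            raise ValueError(f"word length must be odd, got {k}")
        self.k = k
        self.counts: Dict[str, int] = {}

    def __len__(self) -> int:
        return len(self.counts)

    def add_sequence(self, seq: str, weight: int = 1) -> None:
        k = self.k
        counts = self.counts
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            ckm = canonical(kmer)
            counts[ckm] = counts.get(ckm, 0) + weight

    def successors(self, kmer: str) -> List[str]:
        suffix = kmer[1:]
        return [
            suffix + b for b in _BASES if canonical(suffix + b) in self.counts
        ]

    def predecessors(self, kmer: str) -> List[str]:
        prefix = kmer[:-1]
        return [
            b + prefix for b in _BASES if canonical(b + prefix) in self.counts
        ]

    def remove(self, kmers: Iterable[str]) -> None:
        for kmer in kmers:
            self.counts.pop(canonical(kmer), None)


def build_kmer_graph(seqs: Iterable[str], k: int) -> KmerGraph:
    graph = KmerGraph(k)
    for seq in seqs:
        graph.add_sequence(seq)
    return graph


@dataclass
class _Unitig:
    """A maximal unbranched path, as oriented k-mers."""

    path: List[str]
    covs: List[int]

    @property
    def sequence(self) -> str:
        return self.path[0] + "".join(km[-1] for km in self.path[1:])

    def oriented_canonically(self) -> "_Unitig":
        seq = self.sequence
        if revcomp(seq) < seq:
            return _Unitig(
                path=[revcomp(km) for km in reversed(self.path)],
                covs=list(reversed(self.covs)),
            )
        return self


def _unitigs(graph: KmerGraph) -> List[_Unitig]:
    """Partition the graph's k-mers into maximal unbranched paths."""
    visited: Set[str] = set()
    out: List[_Unitig] = []
    for start in sorted(graph.counts):
        if start in visited:
            continue
        path = [start]
        in_path = {start}
        # extend right
        cur = start
        while True:
            succs = graph.successors(cur)
            if len(succs) != 1:
                break
            nxt = succs[0]
            if canonical(nxt) in in_path or canonical(nxt) in visited:
                break
            if len(graph.predecessors(nxt)) != 1:
                break
            path.append(nxt)
            in_path.add(canonical(nxt))
            cur = nxt
        # extend left
        cur = start
        while True:
            preds = graph.predecessors(cur)
            if len(preds) != 1:
                break
            prv = preds[0]
            if canonical(prv) in in_path or canonical(prv) in visited:
                break
            if len(graph.successors(prv)) != 1:
                break
            path.insert(0, prv)
            in_path.add(canonical(prv))
            cur = prv
        visited |= in_path
        out.append(
            _Unitig(path=path, covs=[graph.counts[canonical(km)] for km in path])
        )
    return out


def _drop_low_coverage(graph: KmerGraph, cov_cutoff: int) -> bool:
    if cov_cutoff <= 1:
        return False
    low = [km for km, c in graph.counts.items() if c < cov_cutoff]
    for km in low:
        del graph.counts[km]
    return bool(low)


def _clip_tips(graph: KmerGraph, params: AssemblyParams) -> bool:
    changed = False
    for unitig in _unitigs(graph):
        left_dead = not graph.predecessors(unitig.path[0])
        right_dead = not graph.successors(unitig.path[-1])
        if left_dead != right_dead and len(unitig.sequence) < params.tip_max(graph.k):
            graph.remove(unitig.path)
            changed = True
    return changed


def _identity(a: str, b: str) -> float:
    dist = min(
        edlib.align(a, b, task="distance")["editDistance"],
        edlib.align(a, revcomp(b), task="distance")["editDistance"],
    )
    return 1.0 - dist / max(len(a), len(b))


def _pop_bubbles(graph: KmerGraph, params: AssemblyParams) -> bool:
    """Merge parallel unbranched paths sharing both junctions, keeping the
    higher-coverage branch."""
    groups: Dict[FrozenSet[FrozenSet[str]], List[_Unitig]] = {}
    for unitig in _unitigs(graph):
        u = unitig.oriented_canonically()
        left = frozenset(canonical(p) for p in graph.predecessors(u.path[0]))
        right = frozenset(canonical(s) for s in graph.successors(u.path[-1]))
        if not left or not right:
            continue
        groups.setdefault(frozenset((left, right)), []).append(u)
    for members in groups.values():
        if len(members) < 2:
            continue
        members.sort(
            key=lambda u: (sum(u.covs) / len(u.covs), u.sequence), reverse=True
        )
        keeper = members[0]
        for branch in members[1:]:
            if _identity(keeper.sequence, branch.sequence) >= params.bubble_identity:
                graph.remove(branch.path)
                return True
    return False


def simplify(graph: KmerGraph, params: AssemblyParams) -> KmerGraph:
    """Clean the graph in place: coverage cutoff, then tip clipping and
    bubble popping to a fixpoint."""
    _drop_low_coverage(graph, params.cov_cutoff)
    changed = True
    while changed:
        changed = _clip_tips(graph, params)
        changed = _pop_bubbles(graph, params) or changed
    return graph


def extract_contigs(graph: KmerGraph, min_contig_length: int = 100) -> List[Contig]:
    """Emit maximal unbranched paths as contigs, canonically oriented and
    sorted longest first (ties broken by sequence) for determinism."""
    contigs = []
    for unitig in _unitigs(graph):
        u = unitig.oriented_canonically()
        seq = u.sequence
        if len(seq) < min_contig_length:
            continue
        contigs.append(
            Contig(
                sequence=seq,
                length=len(seq),
                mean_kmer_coverage=sum(u.covs) / len(u.covs),
            )
        )
    contigs.sort(key=lambda c: (-c.length, c.sequence))
    return contigs


def predict_k(depth: float) -> int:
    """Step map from bin depth to word length: deeper bins support longer
    words because each position is sampled by more reads."""
    if depth < 10:
        return 21
    if depth < 30:
        return 25
    if depth <= 100:
        return 29
    return 31


def assemble_sequences(
    seqs: Sequence[str],
    k: int,
    params: AssemblyParams,
    long_seqs: Sequence[str] = (),
) -> List[Contig]:
    """One assembly trial: build, simplify, extract (and, when long
    sequences are supplied, thread them to resolve repeat junctions)."""
    graph = build_kmer_graph(list(seqs) + list(long_seqs), k)
    simplify(graph, params)
    if not long_seqs:
        return extract_contigs(graph, params.min_contig_length)
    unitig_seqs = [u.oriented_canonically().sequence for u in _unitigs(graph)]
    merged = _merge_with_long_sequences(unitig_seqs, long_seqs, k)
    contigs = []
    for seq in merged:
        if len(seq) < params.min_contig_length:
            continue
        seq = min(seq, revcomp(seq))
        covs = [
            graph.counts[canonical(seq[i : i + k])]
            for i in range(len(seq) - k + 1)
            if canonical(seq[i : i + k]) in graph.counts
        ]
        contigs.append(
            Contig(
                sequence=seq,
                length=len(seq),
                mean_kmer_coverage=sum(covs) / len(covs) if covs else 0.0,
            )
        )
    contigs.sort(key=lambda c: (-c.length, c.sequence))
    return contigs


def _thread(seq: str, kmap: Dict[str, Optional[int]], k: int) -> List[Tuple[int, str]]:
    """Map a long sequence to the ordered list of unitigs it traverses."""
    path: List[Tuple[int, str]] = []
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        hit: Optional[Tuple[int, str]] = None
        if kmer in kmap:
            idx = kmap[kmer]
            hit = (idx, "+") if idx is not None else None
        else:
            rc = revcomp(kmer)
            if rc in kmap:
                idx = kmap[rc]
                hit = (idx, "-") if idx is not None else None
        if hit is not None and (not path or path[-1] != hit):
            path.append(hit)
    return path


def _merge_with_long_sequences(
    seqs: List[str], long_seqs: Sequence[str], k: int, max_rounds: int = 200
) -> List[str]:
    """Resolve unitig-graph junctions using long sequences as guides.

    A long sequence passing through unitigs A -> R -> B is evidence that
    A and B are joined through R in the underlying molecule. Whenever the
    observed (in, out) transitions through a junction unitig form a
    one-to-one matching, the first matched pair is spliced into a single
    sequence (overlaps of k-1 are verified literally); the junction
    unitig is duplicated if other matched pairs still need it. Repeats
    until no junction can be resolved.
    """
    seqs = list(seqs)
    for _ in range(max_rounds):
        kmap: Dict[str, Optional[int]] = {}
        for idx, s in enumerate(seqs):
            for i in range(len(s) - k + 1):
                kmer = s[i : i + k]
                if kmer in kmap or revcomp(kmer) in kmap:
                    key = kmer if kmer in kmap else revcomp(kmer)
                    kmap[key] = None  # ambiguous: present in >1 sequence
                else:
                    kmap[kmer] = idx
        transitions: Dict[int, Set[Tuple[Tuple[int, str], Tuple[int, str]]]] = {}
        for long_seq in long_seqs:
            path = _thread(long_seq, kmap, k)
            for (a, b, c) in zip(path, path[1:], path[2:]):
                if b[1] == "-":
                    flip = lambda n: (n[0], "+" if n[1] == "-" else "-")
                    a, b, c = flip(c), flip(b), flip(a)
                if len({a[0], b[0], c[0]}) != 3:
                    continue
                transitions.setdefault(b[0], set()).add((a, c))
        merged_any = False
        for mid in sorted(transitions):
            pairs = sorted(transitions[mid])
            ins = [p[0] for p in pairs]
            outs = [p[1] for p in pairs]
            if len(set(ins)) != len(pairs) or len(set(outs)) != len(pairs):
                continue  # ambiguous junction: leave unresolved
            # compose maximal chains: the out of one traversal may be the
            # in of the next (A-R-B then B-R-C gives A+R+B+R+C)
            next_of = dict(pairs)
            entries = [n for n in ins if n not in set(outs)]
            if not entries:
                continue  # cyclic through this junction: leave it
            m_seq = seqs[mid]

            def oriented(node: Tuple[int, str]) -> str:
                idx, strand = node
                return seqs[idx] if strand == "+" else revcomp(seqs[idx])

            chains: List[List[Tuple[int, str]]] = []
            ok = True
            for entry in entries:
                chain = [entry]
                while chain[-1] in next_of:
                    chain.append(next_of[chain[-1]])
                for left, right in zip(chain, chain[1:]):
                    if (
                        oriented(left)[-(k - 1) :] != m_seq[: k - 1]
                        or m_seq[-(k - 1) :] != oriented(right)[: k - 1]
                    ):
                        ok = False
                chains.append(chain)
            used = [n for chain in chains for n in chain]
            if not ok or len(set(i for i, _ in used)) != len(used):
                continue
            new_seqs = []
            for chain in chains:
                merged = oriented(chain[0])
                for node in chain[1:]:
                    merged += m_seq[k - 1 :] + oriented(node)[k - 1 :]
                new_seqs.append(merged)
            drop = {i for i, _ in used} | {mid}
            seqs = [s for i, s in enumerate(seqs) if i not in drop] + new_seqs
            merged_any = True
            break
        if not merged_any:
            break
    return seqs


def _result_from_contigs(
    tag: RadTag, contigs: List[Contig], k: int, trials: List[Tuple[int, int]]
) -> AssemblyResult:
    return AssemblyResult(
        tag=tag,
        contigs=contigs,
        chosen_k=k,
        total_assembled_length=sum(c.length for c in contigs),
        trials=trials,
    )


def assemble_bin_best_of_three(
    bin_: RadBin, params: AssemblyParams = AssemblyParams()
) -> AssemblyResult:
    """Assemble one bin at three word lengths and keep the trial with the
    greatest total contig length (ties: larger N50, then smaller k)."""
    seqs = [p.read2.bases for p in bin_.pairs]
    depth = bin_.depth_estimate() if bin_.pairs else 0.0
    ks = sorted({params.k_low, predict_k(depth), params.k_high})
    trials: List[Tuple[int, List[Contig]]] = [
        (k, assemble_sequences(seqs, k, params)) for k in ks
    ]
    trial_totals = [(k, sum(c.length for c in contigs)) for k, contigs in trials]
    best_k, best = max(
        trials,
        key=lambda t: (
            sum(c.length for c in t[1]),
            n50([c.length for c in t[1]]),
            -t[0],
        ),
    )
    return _result_from_contigs(bin_.tag, best, best_k, trial_totals)


def assemble_long_insert_two_pass(
    bin_: RadBin, params: AssemblyParams = AssemblyParams()
) -> AssemblyResult:
    """Two-pass long-insert assembly: pass 1 at k=41, then a
    coverage-predicted k with pass-1 contigs threaded as long sequences."""
    seqs = [p.read2.bases for p in bin_.pairs]
    if not seqs:
        return _result_from_contigs(bin_.tag, [], params.k_long_pass1, [])
    pass1 = assemble_sequences(seqs, params.k_long_pass1, params)
    depth = bin_.depth_estimate()
    k2 = predict_k(depth)
    contigs = assemble_sequences(
        seqs, k2, params, long_seqs=[c.sequence for c in pass1]
    )
    trials = [
        (params.k_long_pass1, sum(c.length for c in pass1)),
        (k2, sum(c.length for c in contigs)),
    ]
    return _result_from_contigs(bin_.tag, contigs, k2, trials)
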