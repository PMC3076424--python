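"""Assembly summary statistics."""

from __future__ import annotations

from typing import Iterable


def n50(lengths: Iterable[int]) -> int:
    """N50 of a set of contig lengths.

    The smallest length L such that contigs of length >= L together
    contain at least half of the total assembled bases. Empty input
    gives 0.
    """
    ls = sorted(lengths, reverse=True)
    if not ls:
        return 0
    total = sum(ls)
    acc = 0
    for length in ls:
        acc += length
        if 2 * acc >= total:
            return length
    return ls[-1]  # pragma: no cover - unreachable
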