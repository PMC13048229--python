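"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: the alignment oracle
enumerates every monotone global alignment explicitly, and the consensus
oracle walks prefix tie-groups of the descending count ordering.
"""

from itertools import groupby


def enumerate_alignments(a: str, b: str):
    """Yield every global alignment of a and b as (gapped_a, gapped_b).

    No gap-gap columns.  Exponential; only usable for short sequences.
    """
    if not a and not b:
        yield "", ""
        return
    if a and b:
        for ga, gb in enumerate_alignments(a[1:], b[1:]):
            yield a[0] + ga, b[0] + gb
    if a:
        for ga, gb in enumerate_alignments(a[1:], b):
            yield a[0] + ga, "-" + gb
    if b:
        for ga, gb in enumerate_alignments(a, b[1:]):
            yield "-" + ga, b[0] + gb


def score_alignment(ga: str, gb: str, scoring) -> float:
    return sum(scoring.pair_score(x, y) for x, y in zip(ga, gb))


def best_alignment_score(a: str, b: str, scoring) -> float:
    """Maximum score over the exhaustive enumeration of global alignments."""
    return max(score_alignment(ga, gb, scoring) for ga, gb in enumerate_alignments(a, b))


def column_consensus_oracle(counts: dict, threshold: float) -> str:
    """Prefix-tie-group consensus oracle.

    Gap wins only with a strict majority over every nucleotide; otherwise
    the first prefix group (nucleotides grouped by equal count, counts
    descending) whose cumulative rate reaches the threshold is returned as
    an IUPAC code; if none reaches it, all observed nucleotides are taken.
    """
    from msabench.iupac import symbol_for_set

    counts = {c: n for c, n in counts.items() if n > 0}
    total = sum(counts.values())
    nucs = sorted(
        ((n, c) for c, n in counts.items() if c != "-"), reverse=True
    )
    if not nucs or counts.get("-", 0) > nucs[0][0]:
        return "-"
    groups = [
        [c for _, c in grp]
        for _, grp in groupby(nucs, key=lambda item: item[0])
    ]
    chosen: set = set()
    cum = 0
    for grp in groups:
        chosen.update(grp)
        cum += sum(counts[c] for c in grp)
        if cum / total >= threshold:
            return symbol_for_set(chosen)
    return symbol_for_set(chosen)


def compositions(total: int, n_parts: int):
    """All tuples of n_parts non-negative ints summing to total."""
    if n_parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in compositions(total - first, n_parts - 1):
            yield (first,) + rest
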