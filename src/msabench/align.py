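"""Exact global pairwise alignment and a center-star multiple aligner.

The pairwise aligner is a Needleman-Wunsch dynamic program with linear gap
penalties over the full IUPAC alphabet.  Scoring distinguishes three
character relations: identical, *compatible* (distinct codes whose
nucleotide sets intersect, e.g. ``Y`` vs ``C``) and incompatible.  Traceback
ties are broken deterministically: diagonal, then up (gap in ``b``), then
left (gap in ``a``).

The center-star aligner picks the sequence with the best summed pairwise
score to all others, aligns everything to it, and merges the pairwise
alignments with the "once a gap in the center, always a gap" rule.  It is a
heuristic stand-in for external MSA tools, good enough to exercise the
consensus/evaluation pipeline end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from msabench.consensus import Msa
from msabench.iupac import GAP, IUPAC_CODES, canonicalize_seq, codes_match

_CODE_INDEX = {c: i for i, c in enumerate(IUPAC_CODES)}


@dataclass(frozen=True)
class Scoring:
    """Linear-gap scoring scheme over IUPAC codes.

    ``match >= compatible > mismatch`` and ``gap < 0`` are required; a
    positive ``compatible`` score rewards IUPAC-consistent pairings so that
    ambiguity codes from diploid sites align onto their underlying alleles.
    """

    match: float = 2.0
    compatible: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0

    def __post_init__(self) -> None:
        if not (self.match >= self.compatible > self.mismatch):
            raise ValueError("scoring requires match >= compatible > mismatch")
        if self.gap >= 0:
            raise ValueError("gap penalty must be negative")

    def matrix(self) -> np.ndarray:
        """15x15 substitution matrix indexed by IUPAC code order."""
        n = len(IUPAC_CODES)
        mat = np.full((n, n), self.mismatch, dtype=np.float64)
        for i, a in enumerate(IUPAC_CODES):
            for j, b in enumerate(IUPAC_CODES):
                if a == b:
                    mat[i, j] = self.match
                elif codes_match(a, b):
                    mat[i, j] = self.compatible
        return mat

    def pair_score(self, a: str, b: str) -> float:
        if a == GAP or b == GAP:
            return self.gap
        if a == b:
            return self.match
        return self.compatible if codes_match(a, b) else self.mismatch


DEFAULT_SCORING = Scoring()


@dataclass(frozen=True)
class PairwiseAlignment:
    """An end-to-end alignment of two sequences.

    ``gapped_a`` and ``gapped_b`` have equal length (``columns``); stripping
    gaps recovers the input sequences; no column is gap-gap.
    """

    gapped_a: str
    gapped_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.gapped_a) != len(self.gapped_b):
            raise ValueError("aligned rows must have equal length")

    @property
    def columns(self) -> int:
        return len(self.gapped_a)

    def __iter__(self):
        """Iterate over aligned character pairs."""
        return zip(self.gapped_a, self.gapped_b)


def _encode(seq: str, name: str) -> np.ndarray:
    try:
        return np.fromiter((_CODE_INDEX[c] for c in seq), dtype=np.intp, count=len(seq))
    except KeyError:
        for pos, c in enumerate(seq):
            if c not in _CODE_INDEX:
                raise ValueError(
                    f"non-IUPAC character {c!r} at position {pos} of {name}"
                ) from None
        raise


def _dp_matrix(ai: np.ndarray, bi: np.ndarray, scoring: Scoring) -> np.ndarray:
    """Full (m+1)x(n+1) table of optimal prefix scores."""
    m, n = len(ai), len(bi)
    g = float(scoring.gap)
    sub = scoring.matrix()
    score = np.empty((m + 1, n + 1), dtype=np.float64)
    idx = np.arange(n + 1, dtype=np.float64)
    score[0] = idx * g
    gsteps = idx * g  # cost of j trailing left-moves
    for i in range(1, m + 1):
        prev = score[i - 1]
        best = np.empty(n + 1, dtype=np.float64)
        best[0] = prev[0] + g
        # best score into (i, j) via diagonal or up move
        np.maximum(prev[:-1] + sub[ai[i - 1], bi], prev[1:] + g, out=best[1:])
        # close the left-move chain: S[i,j] = max_k (best[k] + (j-k) * g)
        best -= gsteps
        np.maximum.accumulate(best, out=best)
        best += gsteps
        score[i] = best
    return score


def global_align(a: str, b: str, scoring: Scoring = DEFAULT_SCORING) -> PairwiseAlignment:
    """Optimal end-to-end alignment of ``a`` and ``b`` (Needleman-Wunsch).

    Linear gap penalties; the returned score is the global optimum.
    Traceback prefers diagonal over up over left, so the output is
    deterministic.  Either sequence may be empty.
    """
    sa = canonicalize_seq(a)
    sb = canonicalize_seq(b)
    ai = _encode(sa, "first sequence")
    bi = _encode(sb, "second sequence")
    m, n = len(ai), len(bi)
    if m == 0 or n == 0:
        cols = max(m, n)
        return PairwiseAlignment(
            gapped_a=sa + GAP * (cols - m),
            gapped_b=sb + GAP * (cols - n),
            score=cols * scoring.gap,
        )
    sub = scoring.matrix()
    score = _dp_matrix(ai, bi, scoring)
    g = float(scoring.gap)
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = m, n
    while i > 0 or j > 0:
        s = score[i, j]
        if i > 0 and j > 0 and s == score[i - 1, j - 1] + sub[ai[i - 1], bi[j - 1]]:
            out_a.append(sa[i - 1])
            out_b.append(sb[j - 1])
            i -= 1
            j -= 1
        elif i > 0 and s == score[i - 1, j] + g:
            out_a.append(sa[i - 1])
            out_b.append(GAP)
            i -= 1
        else:
            out_a.append(GAP)
            out_b.append(sb[j - 1])
            j -= 1
    return PairwiseAlignment(
        gapped_a="".join(reversed(out_a)),
        gapped_b="".join(reversed(out_b)),
        score=float(score[m, n]),
    )


def alignment_score(a: str, b: str, scoring: Scoring = DEFAULT_SCORING) -> float:
    """Optimal global alignment score without traceback (less memory churn)."""
    sa = canonicalize_seq(a)
    sb = canonicalize_seq(b)
    if not sa or not sb:
        return max(len(sa), len(sb)) * scoring.gap
    ai = _encode(sa, "first sequence")
    bi = _encode(sb, "second sequence")
    return float(_dp_matrix(ai, bi, scoring)[len(ai), len(bi)])


def _center_gap_profile(gapped_center: str) -> list[int]:
    """Run lengths of gaps before each center position (and after the last)."""
    profile = [0]
    for c in gapped_center:
        if c == GAP:
            profile[-1] += 1
        else:
            profile.append(0)
    return profile


def _project_row(gapped_center: str, gapped_seq: str, max_gaps: list[int]) -> str:
    """Re-pad one pairwise alignment onto the merged center gap profile."""
    out: list[str] = []
    block: list[str] = []
    k = 0
    for cc, sc in zip(gapped_center, gapped_seq):
        if cc == GAP:
            block.append(sc)
        else:
            out.append("".join(block) + GAP * (max_gaps[k] - len(block)))
            block = []
            out.append(sc)
            k += 1
    out.append("".join(block) + GAP * (max_gaps[k] - len(block)))
    return "".join(out)


def center_star_msa(
    seqs,
    scoring: Scoring = DEFAULT_SCORING,
    row_ids=None,
    max_exact_center: int = 50,
) -> Msa:
    """Center-star multiple alignment of ``seqs``.

    The center is the sequence with the maximal summed pairwise alignment
    score against all others (exact all-pairs selection up to
    ``max_exact_center`` sequences, first sequence beyond that to cap the
    quadratic cost).  Every other sequence is aligned to the center and the
    pairwise alignments are merged column-wise: a gap opened in the center
    by any pairwise alignment is propagated to all rows.
    """
    seqs = [canonicalize_seq(s) for s in seqs]
    if len(seqs) < 2:
        raise ValueError("center-star MSA needs at least 2 sequences")
    if row_ids is None:
        row_ids = [f"seq{i}" for i in range(len(seqs))]
    if len(row_ids) != len(seqs):
        raise ValueError("row_ids length must equal number of sequences")

    if len(seqs) <= max_exact_center:
        n = len(seqs)
        totals = np.zeros(n)
        for i in range(n):
            for j in range(i + 1, n):
                s = alignment_score(seqs[i], seqs[j], scoring)
                totals[i] += s
                totals[j] += s
        center_idx = int(np.argmax(totals))
    else:
        center_idx = 0
    center = seqs[center_idx]

    pairs = []
    for i, s in enumerate(seqs):
        if i == center_idx:
            continue
        aln = global_align(center, s, scoring)
        pairs.append((i, aln))

    max_gaps = [0] * (len(center) + 1)
    for _, aln in pairs:
        profile = _center_gap_profile(aln.gapped_a)
        for k, v in enumerate(profile):
            if v > max_gaps[k]:
                max_gaps[k] = v

    rows: dict[int, str] = {
        center_idx: _project_row(center, center, max_gaps)
    }
    for i, aln in pairs:
        rows[i] = _project_row(aln.gapped_a, aln.gapped_b, max_gaps)

    ordered = [rows[i] for i in range(len(seqs))]
    return Msa(rows=ordered, row_ids=list(row_ids))
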