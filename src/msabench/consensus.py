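"""Per-column IUPAC threshold consensus of a multiple sequence alignment.

Each MSA column is summarised independently.  If the gap character is
strictly the most frequent character in the column, the column's consensus
is a gap.  Otherwise nucleotides are taken in descending order of count,
whole tie-groups at a time (so order between equally frequent nucleotides
never matters), until their cumulative appearance rate reaches the
threshold; the accumulated nucleotide set is emitted as its IUPAC code.

Appearance rates are counted against the total number of rows in the
column, gaps included.  The default threshold is 0.7, which lets a balanced
heterozygous site (50/50 split of two alleles) surface as its two-nucleotide
ambiguity code.

The *metaconsensus* applies the same machinery to an MSA built from the
consensus sequences of several tools.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from msabench.iupac import GAP, canonicalize_seq, symbol_for_set

DEFAULT_THRESHOLD = 0.7


@dataclass
class Msa:
    """A rectangular block of equal-length gapped rows.

    Rows are normally plain DNA over {A,C,G,T,-}; ambiguity codes are legal
    as well so that a meta-MSA of IUPAC consensus sequences can be
    represented by the same type.
    """

    rows: list[str]
    row_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("an MSA needs at least one row")
        self.rows = [canonicalize_seq(r, allow_gap=True) for r in self.rows]
        width = len(self.rows[0])
        if any(len(r) != width for r in self.rows):
            raise ValueError("all MSA rows must have equal length")
        if any(set(r) == {GAP} for r in self.rows):
            raise ValueError("an MSA row may not be all gaps")
        if not self.row_ids:
            self.row_ids = [f"seq{i}" for i in range(len(self.rows))]
        if len(self.row_ids) != len(self.rows):
            raise ValueError("row_ids length must equal row count")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)

    def ungapped_rows(self) -> list[str]:
        return [row.replace(GAP, "") for row in self.rows]


@dataclass(frozen=True)
class ConsensusSequence:
    """Gapped and ungapped consensus plus the threshold that produced it."""

    gapped: str
    threshold: float

    @property
    def ungapped(self) -> str:
        return self.gapped.replace(GAP, "")

    @property
    def size(self) -> int:
        """Length of the ungapped consensus (the consensus-size metric)."""
        return len(self.ungapped)


def column_consensus(counts, threshold: float = DEFAULT_THRESHOLD) -> str:
    """Consensus character for one column given its character counts.

    ``counts`` maps characters in {A,C,G,T,-} to occurrence counts; the
    column total is their sum.  Returns an IUPAC code or ``-``.

    The gap is returned only when it is strictly more frequent than every
    nucleotide; a gap/nucleotide tie resolves to the nucleotide path.
    The threshold comparison is inclusive (cumulative rate >= threshold).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    counts = {c: int(n) for c, n in dict(counts).items() if n}
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("empty column")
    bad = set(counts) - set("ACGT" + GAP)
    if bad:
        raise ValueError(f"unexpected column characters: {sorted(bad)}")

    gap_count = counts.get(GAP, 0)
    nuc_counts = {c: n for c, n in counts.items() if c != GAP}
    if not nuc_counts or gap_count > max(nuc_counts.values()):
        return GAP

    # group nucleotides by count, descending; take whole tie-groups so that
    # equally frequent nucleotides enter together
    by_count: dict[int, set[str]] = {}
    for c, n in nuc_counts.items():
        by_count.setdefault(n, set()).add(c)
    chosen: set[str] = set()
    cumulative = 0
    for n in sorted(by_count, reverse=True):
        chosen |= by_count[n]
        cumulative += n * len(by_count[n])
        if cumulative / total >= threshold:
            break
    return symbol_for_set(chosen)


def msa_consensus(msa: Msa, threshold: float = DEFAULT_THRESHOLD) -> ConsensusSequence:
    """Apply :func:`column_consensus` to every column, left to right."""
    gapped = "".join(
        column_consensus(Counter(msa.column(j)), threshold) for j in range(msa.n_cols)
    )
    return ConsensusSequence(gapped=gapped, threshold=threshold)


def metaconsensus(
    consensi,
    threshold: float = DEFAULT_THRESHOLD,
    aligner=None,
) -> ConsensusSequence:
    """Consensus of several (ungapped) consensus sequences.

    The inputs are stacked into a meta-MSA by ``aligner`` -- a callable
    taking a list of sequences and returning an :class:`Msa`; by default the
    built-in center-star aligner -- and the threshold consensus is taken of
    that MSA.
    """
    consensi = list(consensi)
    if len(consensi) < 2:
        raise ValueError("metaconsensus needs at least 2 consensus sequences")
    if aligner is None:
        from msabench.align import center_star_msa

        aligner = center_star_msa
    meta = aligner(consensi)
    return msa_consensus(meta, threshold)


def read_msa_fasta(path) -> Msa:
    """Load an aligned FASTA file (equal-length gapped records) as an Msa."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no records in {path}")
    return Msa(rows=[str(r.seq) for r in records], row_ids=[r.id for r in records])


def write_consensus_fasta(
    consensus: ConsensusSequence,
    path,
    seq_id: str = "consensus",
    gapped: bool = False,
    sidecar: bool = True,
    n_rows: int | None = None,
    n_cols: int | None = None,
) -> None:
    """Write a consensus as single-record FASTA plus a JSON metadata sidecar."""
    seq = consensus.gapped if gapped else consensus.ungapped
    record = SeqRecord(Seq(seq), id=seq_id, description=f"threshold={consensus.threshold}")
    SeqIO.write([record], str(path), "fasta")
    if sidecar:
        meta = {
            "threshold": consensus.threshold,
            "consensus_size": consensus.size,
            "n_rows": n_rows,
            "n_cols": n_cols if n_cols is not None else len(consensus.gapped),
        }
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=2) + "\n")
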