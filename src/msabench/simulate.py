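"""Synthetic read generation and region/reference plumbing.

Reads are exact windows of a reference region corrupted by a controlled
error process: each template base independently suffers an error with
probability ``rate``; the error type (substitution / insertion / deletion)
is drawn from the profile's type composition.  Canned profiles cover the
four classic regimes -- SUB, INS and DEL are single-type, and MIX combines
23% substitutions, 31% insertions and 46% deletions in the style of an ONT
error model.

Every introduced edit is recorded in a truth log whose edit script, applied
back to the template, reproduces the read exactly; parameter-recovery tests
and acceptance checks lean on that invariant.

The module also builds IUPAC-encoded diploid references from two haplotypes
(substitution columns become two-nucleotide ambiguity codes and are recorded
as heterozygous sites; indel columns keep the first haplotype's character and
are flagged as excluded), and extracts region-spanning reads from
coordinate-sorted SAM/BAM alignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from msabench.align import DEFAULT_SCORING, Scoring, global_align
from msabench.iupac import GAP, canonicalize_seq, symbol_for_set

NUCLEOTIDES = "ACGT"

#: Region sizes exercised by default in benchmark grids.
DEFAULT_REGION_SIZES = (100, 200, 500, 1000, 2000, 5000, 10000)

#: Default number of random starting positions per region size.
DEFAULT_N_POSITIONS = 10

#: Error-type composition of the MIX profile: (sub, ins, del).
MIX_COMPOSITION = (0.23, 0.31, 0.46)

PROFILE_KINDS = ("SUB", "INS", "DEL", "MIX")


@dataclass(frozen=True)
class ErrorProfile:
    """Overall error rate plus the fractions of errors by type."""

    rate: float
    p_sub: float
    p_ins: float
    p_del: float

    def __post_init__(self) -> None:
        if not 0 <= self.rate <= 1:
            raise ValueError("error rate must be in [0, 1]")
        for name in ("p_sub", "p_ins", "p_del"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if abs(self.p_sub + self.p_ins + self.p_del - 1.0) > 1e-9:
            raise ValueError("type fractions must sum to 1")


@dataclass(frozen=True)
class Region:
    """A window on a reference sequence, 0-based half-open."""

    seq_id: str
    start: int
    length: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("region start must be >= 0")
        if self.length < 1:
            raise ValueError("region length must be >= 1")

    @property
    def end(self) -> int:
        return self.start + self.length

    def slice(self, reference: str) -> str:
        if self.end > len(reference):
            raise ValueError(
                f"region {self.start}:{self.end} exceeds reference "
                f"length {len(reference)}"
            )
        return reference[self.start : self.end]


@dataclass(frozen=True)
class DiploidReference:
    """IUPAC-encoded consensus of two haplotypes.

    ``het_sites`` lists ``(position, code)`` pairs where ``code`` is the
    two-nucleotide IUPAC symbol of a substitution between the haplotypes;
    ``excluded_sites`` are positions arising from indel columns, left out of
    heterozygosity accounting.
    """

    iupac_seq: str
    het_sites: tuple = ()
    excluded_sites: tuple = ()
    hap_ids: tuple = ("hapA", "hapB")


@dataclass
class ReadTruth:
    """Truth-log entry for one simulated read.

    ``edits`` is the edit script, a list of ``(template_pos, op, base)``
    tuples ordered by template position with ``op`` in {'S','I','D'};
    insertions occur before the template position they carry.
    """

    edits: list = field(default_factory=list)
    haplotype: int | None = None

    @property
    def n_sub(self) -> int:
        return sum(1 for _, op, _ in self.edits if op == "S")

    @property
    def n_ins(self) -> int:
        return sum(1 for _, op, _ in self.edits if op == "I")

    @property
    def n_del(self) -> int:
        return sum(1 for _, op, _ in self.edits if op == "D")

    @property
    def n_errors(self) -> int:
        return len(self.edits)

    def apply(self, template: str) -> str:
        """Replay the edit script on ``template`` (round-trip oracle)."""
        by_pos: dict[int, list] = {}
        for pos, op, base in self.edits:
            by_pos.setdefault(pos, []).append((op, base))
        out: list[str] = []
        for i, c in enumerate(template):
            ops = by_pos.get(i, [])
            emit = c
            for op, base in ops:
                if op == "I":
                    out.append(base)
                elif op == "S":
                    emit = base
                elif op == "D":
                    emit = ""
            out.append(emit)
        for op, base in by_pos.get(len(template), []):
            if op == "I":
                out.append(base)
        return "".join(out)


def make_profile(kind: str, rate: float) -> ErrorProfile:
    """Canned error profile: SUB, INS, DEL (single-type) or MIX (23/31/46)."""
    kind = kind.upper()
    if kind == "SUB":
        mix = (1.0, 0.0, 0.0)
    elif kind == "INS":
        mix = (0.0, 1.0, 0.0)
    elif kind == "DEL":
        mix = (0.0, 0.0, 1.0)
    elif kind == "MIX":
        mix = MIX_COMPOSITION
    else:
        raise ValueError(f"unknown profile kind {kind!r}; expected one of {PROFILE_KINDS}")
    return ErrorProfile(rate=rate, p_sub=mix[0], p_ins=mix[1], p_del=mix[2])


def random_sequence(length: int, rng: np.random.Generator) -> str:
    """Uniform random DNA sequence."""
    if length < 1:
        raise ValueError("length must be >= 1")
    return "".join(rng.choice(list(NUCLEOTIDES), size=length))


def simulate_read(
    template: str,
    profile: ErrorProfile,
    rng: np.random.Generator,
) -> tuple[str, ReadTruth]:
    """Corrupt ``template`` according to ``profile``.

    At most one error event per template base; insertions are placed before
    the base they hit; substitutions always change the base.  Returns the
    read and its truth-log entry.
    """
    template = canonicalize_seq(template)
    if not template:
        raise ValueError("template must be non-empty")
    n = len(template)
    hit = rng.random(n) < profile.rate
    n_hits = int(hit.sum())
    truth = ReadTruth()
    if n_hits == 0:
        return template, truth
    kinds = rng.choice(3, size=n_hits, p=(profile.p_sub, profile.p_ins, profile.p_del))
    out: list[str] = []
    k = 0
    for i, c in enumerate(template):
        if not hit[i]:
            out.append(c)
            continue
        op = kinds[k]
        k += 1
        if op == 0:  # substitution: uniformly among the three other bases
            alt = NUCLEOTIDES.replace(c, "")
            base = alt[rng.integers(3)]
            truth.edits.append((i, "S", base))
            out.append(base)
        elif op == 1:  # insertion before the current base
            base = NUCLEOTIDES[rng.integers(4)]
            truth.edits.append((i, "I", base))
            out.append(base)
            out.append(c)
        else:  # deletion
            truth.edits.append((i, "D", ""))
    return "".join(out), truth


def sample_regions(
    ref_length: int,
    sizes=DEFAULT_REGION_SIZES,
    n_per_size: int = DEFAULT_N_POSITIONS,
    rng: np.random.Generator | None = None,
    seq_id: str = "ref",
) -> list[Region]:
    """Draw random starting positions and cross them with the region sizes.

    ``n_per_size`` start positions are drawn uniformly such that the largest
    requested size fits from every start, then each start is combined with
    every size, yielding ``len(sizes) * n_per_size`` regions.
    """
    sizes = list(sizes)
    if not sizes:
        raise ValueError("need at least one region size")
    if n_per_size < 1:
        raise ValueError("n_per_size must be >= 1")
    max_size = max(sizes)
    if max_size > ref_length:
        raise ValueError(
            f"region size {max_size} exceeds reference length {ref_length}"
        )
    if rng is None:
        rng = np.random.default_rng()
    starts = rng.integers(0, ref_length - max_size + 1, size=n_per_size)
    return [
        Region(seq_id=seq_id, start=int(s), length=int(size))
        for size in sizes
        for s in starts
    ]


def reads_for_region(
    reference: str,
    region: Region,
    depth: int,
    profile: ErrorProfile,
    rng: np.random.Generator,
    haplotypes=None,
) -> tuple[list[str], list[ReadTruth]]:
    """Simulate exactly ``depth`` reads spanning ``region``.

    In haploid mode every read is drawn from the region's substring of
    ``reference``.  In diploid mode ``haplotypes`` is a pair of sequences and
    the reads split 50/50 between the two haplotype windows (odd depth
    assigns the extra read by a seeded coin flip); the truth log records
    each read's source haplotype.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    reads: list[str] = []
    truths: list[ReadTruth] = []
    if haplotypes is None:
        template = region.slice(canonicalize_seq(reference))
        for _ in range(depth):
            read, truth = simulate_read(template, profile, rng)
            reads.append(read)
            truths.append(truth)
    else:
        hap_a, hap_b = (canonicalize_seq(h) for h in haplotypes)
        templates = (region.slice(hap_a), region.slice(hap_b))
        n_a = depth // 2
        if depth % 2:
            n_a += int(rng.integers(2))
        assignment = [0] * n_a + [1] * (depth - n_a)
        for hap in assignment:
            read, truth = simulate_read(templates[hap], profile, rng)
            truth.haplotype = hap
            reads.append(read)
            truths.append(truth)
    return reads, truths


def build_diploid_reference(
    hap_a: str,
    hap_b: str,
    scoring: Scoring = DEFAULT_SCORING,
    hap_ids=("hapA", "hapB"),
) -> DiploidReference:
    """Collapse two haplotypes into one IUPAC reference.

    The haplotypes are aligned globally; substitution columns become their
    two-nucleotide IUPAC code and are recorded as heterozygous sites; indel
    columns keep the first haplotype's character (positions flagged as
    excluded, and insertion columns of the second haplotype are dropped);
    identical columns copy the shared base.
    """
    hap_a = canonicalize_seq(hap_a)
    hap_b = canonicalize_seq(hap_b)
    if not hap_a or not hap_b:
        raise ValueError("both haplotypes must be non-empty")
    aln = global_align(hap_a, hap_b, scoring)
    seq: list[str] = []
    het_sites: list[tuple[int, str]] = []
    excluded: list[int] = []
    for a, b in aln:
        if a == GAP:
            continue  # insertion private to hap_b: dropped
        pos = len(seq)
        if b == GAP:
            excluded.append(pos)
            seq.append(a)
        elif a == b:
            seq.append(a)
        else:
            code = symbol_for_set({a, b})
            het_sites.append((pos, code))
            seq.append(code)
    return DiploidReference(
        iupac_seq="".join(seq),
        het_sites=tuple(het_sites),
        excluded_sites=tuple(excluded),
        hap_ids=tuple(hap_ids),
    )


def extract_reads_from_sam(
    alignments,
    region: Region,
    depth: int,
    rng: np.random.Generator,
    allow_fewer: bool = False,
) -> list[str]:
    """Select and clip region-spanning reads from SAM/BAM alignments.

    ``alignments`` is a path or an open :class:`pysam.AlignmentFile`.  Only
    primary alignments that fully span the region are eligible; each is
    clipped to the region boundaries via its aligned pairs (insertions that
    fall inside the window are kept).  ``depth`` reads are sampled uniformly
    without replacement; if fewer spanning reads exist, an error is raised
    unless ``allow_fewer``, in which case all of them are returned.
    """
    import pysam

    if depth < 1:
        raise ValueError("depth must be >= 1")
    opened = False
    if not hasattr(alignments, "fetch"):
        alignments = pysam.AlignmentFile(str(alignments))
        opened = True
    try:
        try:
            candidates = alignments.fetch(region.seq_id, region.start, region.end)
        except ValueError:
            # plain text SAM without an index: scan the whole file
            candidates = (
                a
                for a in alignments.fetch(until_eof=True)
                if a.reference_name == region.seq_id
            )
        spanning = []
        for aln in candidates:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.reference_start > region.start or aln.reference_end < region.end:
                continue
            spanning.append(aln)
        spanning.sort(key=lambda a: (a.reference_start, a.query_name))
        if len(spanning) < depth:
            if not allow_fewer:
                raise ValueError(
                    f"only {len(spanning)} reads span region "
                    f"{region.seq_id}:{region.start}-{region.end}, "
                    f"need {depth}"
                )
            chosen = spanning
        else:
            idx = rng.choice(len(spanning), size=depth, replace=False)
            chosen = [spanning[i] for i in sorted(idx)]
        return [_clip_to_region(aln, region) for aln in chosen]
    finally:
        if opened:
            alignments.close()


def _clip_to_region(aln, region: Region) -> str:
    """Query substring aligned inside the region, via aligned pairs."""
    query = aln.query_sequence
    parts: list[str] = []
    inside = False
    for qpos, rpos in aln.get_aligned_pairs():
        if rpos is not None:
            inside = region.start <= rpos < region.end
        if inside and qpos is not None:
            parts.append(query[qpos])
    return canonicalize_seq("".join(parts))
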