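"""Evaluation of consensus sequences against a reference.

A consensus is compared to its reference through an exact global alignment,
from which five metrics are derived:

* **identity rate** -- alignment columns with strictly identical characters,
  divided by the consensus size;
* **ambiguous character rate** -- consensus characters outside {A,C,G,T},
  divided by the consensus size;
* **match rate** -- alignment columns whose IUPAC codes share a potential
  nucleotide, divided by the consensus size;
* **error rate** -- non-matching alignment columns (indel columns included),
  divided by the consensus size;
* **consensus size** -- the length of the ungapped consensus.

Because all rates are normalised by the consensus size, the error rate may
exceed 1 when the reference is much longer than the consensus; an
alignment-column-normalised error rate is carried alongside for reporting.

For diploid references the module scores heterozygous-site recovery: a true
positive is a consensus IUPAC symbol equal to the site's exact two-nucleotide
code at that site, recall divides true positives by the number of
heterozygous sites, and precision divides them by the total number of
ambiguity symbols in the consensus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

from msabench.align import DEFAULT_SCORING, Scoring, global_align
from msabench.iupac import GAP, codes_match


@dataclass(frozen=True)
class EvalMetrics:
    """The five consensus-vs-reference evaluation metrics.

    ``error_rate_aligned`` is a companion to ``error_rate`` normalised by
    the number of alignment columns instead of the consensus size.
    """

    identity_rate: float
    ambiguous_rate: float
    match_rate: float
    error_rate: float
    consensus_size: int
    error_rate_aligned: float = 0.0

    RATE_FIELDS = (
        "identity_rate",
        "ambiguous_rate",
        "match_rate",
        "error_rate",
        "consensus_size",
        "error_rate_aligned",
    )

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class HetEvalResult:
    """Heterozygous-site recovery counts and the derived recall/precision."""

    tp: int
    fn: int
    fp: int

    @property
    def recall(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else math.nan

    @property
    def precision(self) -> float:
        denom = self.tp + self.fp
        return self.tp / denom if denom else math.nan


@dataclass(frozen=True)
class MetricSummary:
    """Per-metric mean and standard deviation across replicates."""

    means: dict[str, float]
    stds: dict[str, float]
    n: int


def evaluate_consensus(
    consensus: str,
    reference: str,
    scoring: Scoring = DEFAULT_SCORING,
) -> EvalMetrics:
    """Align ``consensus`` to ``reference`` globally and compute the metrics."""
    if not consensus or not reference:
        raise ValueError("consensus and reference must be non-empty")
    aln = global_align(consensus, reference, scoring)
    size = len(aln.gapped_a.replace(GAP, ""))
    identical = 0
    matched = 0
    for a, b in aln:
        if a == b and a != GAP:
            identical += 1
        if a != GAP and b != GAP and codes_match(a, b):
            matched += 1
    errors = aln.columns - matched
    ambiguous = sum(1 for c in aln.gapped_a if c not in "ACGT" + GAP)
    return EvalMetrics(
        identity_rate=identical / size,
        ambiguous_rate=ambiguous / size,
        match_rate=matched / size,
        error_rate=errors / size,
        consensus_size=size,
        error_rate_aligned=errors / aln.columns if aln.columns else 0.0,
    )


def read_error_rate(
    reads,
    reference: str,
    scoring: Scoring = DEFAULT_SCORING,
) -> float:
    """Mean per-read error rate estimated by global alignment to ``reference``.

    Each read's rate is the fraction of its alignment columns (indels
    included) that do not match the reference.
    """
    reads = list(reads)
    if not reads:
        raise ValueError("need at least one read")
    rates = []
    for read in reads:
        aln = global_align(read, reference, scoring)
        matched = sum(
            1 for a, b in aln if a != GAP and b != GAP and codes_match(a, b)
        )
        rates.append((aln.columns - matched) / aln.columns)
    return float(np.mean(rates))


def het_eval(
    consensus: str,
    diploid_ref,
    scoring: Scoring = DEFAULT_SCORING,
) -> HetEvalResult:
    """Score recovery of heterozygous sites from an IUPAC consensus.

    The consensus is aligned to the diploid reference's IUPAC sequence and
    alignment columns are mapped back to reference coordinates.  A true
    positive requires the consensus to carry the site's exact ambiguity
    code; any other ambiguity symbol in the consensus counts as a false
    positive (and, at a het site, additionally leaves the site unrecovered).
    """
    het_sites = dict(diploid_ref.het_sites)
    aln = global_align(consensus, diploid_ref.iupac_seq, scoring)
    tp = 0
    fp = 0
    ref_pos = -1
    for a, b in aln:
        if b != GAP:
            ref_pos += 1
        if a in "ACGT" or a == GAP:
            continue
        if b != GAP and het_sites.get(ref_pos) == a:
            tp += 1
        else:
            fp += 1
    fn = len(het_sites) - tp
    return HetEvalResult(tp=tp, fn=fn, fp=fp)


def aggregate(records) -> MetricSummary:
    """Arithmetic mean and population standard deviation per metric."""
    records = list(records)
    if not records:
        raise ValueError("need at least one metrics record")
    means: dict[str, float] = {}
    stds: dict[str, float] = {}
    for name in EvalMetrics.RATE_FIELDS:
        values = np.array([getattr(r, name) for r in records], dtype=float)
        means[name] = float(values.mean())
        stds[name] = float(values.std(ddof=0))
    return MetricSummary(means=means, stds=stds, n=len(records))
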