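"""Benchmark-grid orchestration.

An experiment grid is the cross product of datasets, region sizes,
sequencing depths, replicate regions and MSA methods; every experiment runs
the same pipeline: select reads for a region at the requested depth, build
an MSA (through an external-tool adapter or the built-in center-star
aligner), take the IUPAC threshold consensus, and evaluate it against the
region's reference.  Failures of individual experiments are recorded and do
not abort the grid.

Summaries mirror the headline tables: per tool and dataset, the minimum and
maximum over (size, depth) combinations of the mean identity rate across
replicate regions; and the metaconsensus comparison tallying how often a
metaconsensus beats / ties / loses to the best and worst per-tool consensus
on each region.
"""

from __future__ import annotations

import shlex
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from msabench.align import DEFAULT_SCORING, Scoring, center_star_msa
from msabench.consensus import DEFAULT_THRESHOLD, Msa, msa_consensus, read_msa_fasta
from msabench.metrics import EvalMetrics, aggregate, evaluate_consensus
from msabench.simulate import (
    DEFAULT_N_POSITIONS,
    DEFAULT_REGION_SIZES,
    ErrorProfile,
    Region,
    make_profile,
    reads_for_region,
    sample_regions,
)

DEFAULT_DEPTHS = (10, 20, 30, 45, 50, 60, 100, 150, 200)
DEFAULT_ERROR_RATES = (0.01, 0.02, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30)

OK = "OK"
SKIPPED = "SKIPPED"
FAILED = "FAILED"


@dataclass(frozen=True)
class GridConfig:
    """Dimensions and parameters of a benchmark grid."""

    datasets: tuple = ("dataset",)
    region_sizes: tuple = DEFAULT_REGION_SIZES
    depths: tuple = DEFAULT_DEPTHS
    n_regions: int = DEFAULT_N_POSITIONS
    tools: tuple = ("builtin",)
    threshold: float = DEFAULT_THRESHOLD
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("datasets", "region_sizes", "depths", "tools"):
            if not getattr(self, name):
                raise ValueError(f"grid dimension {name!r} must be non-empty")
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "GridConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in raw.items() if k in known}
        for key in ("datasets", "region_sizes", "depths", "tools"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


@dataclass(frozen=True)
class ExperimentSpec:
    """One cell of the grid, uniquely identified by its coordinates."""

    dataset: str
    region_size: int
    region_index: int
    depth: int
    tool: str
    seed: int = 0

    @property
    def key(self) -> tuple:
        return (self.dataset, self.region_size, self.region_index, self.depth, self.tool)


@dataclass
class ExperimentResult:
    spec: ExperimentSpec
    status: str
    metrics: EvalMetrics | None = None
    reason: str = ""


def enumerate_plan(config: GridConfig) -> list[ExperimentSpec]:
    """Deterministic dataset-major cross product of the grid dimensions.

    The plan size is ``|datasets| * |sizes| * |depths| * n_regions *
    |tools|``.
    """
    return [
        ExperimentSpec(
            dataset=ds,
            region_size=size,
            region_index=ri,
            depth=depth,
            tool=tool,
            seed=config.seed,
        )
        for ds in config.datasets
        for size in config.region_sizes
        for depth in config.depths
        for ri in range(config.n_regions)
        for tool in config.tools
    ]


def simulated_dataset_plan(
    kinds=("DEL", "INS", "SUB", "MIX"),
    rates=DEFAULT_ERROR_RATES,
) -> list[tuple[str, ErrorProfile]]:
    """Enumerate the simulated dataset configurations: kinds x error rates.

    Each configuration is ``(name, profile)`` with names like ``MIX-10``
    (error type and percent rate).
    """
    plan = []
    for kind in kinds:
        for rate in rates:
            name = f"{kind}-{round(rate * 100):g}"
            plan.append((name, make_profile(kind, rate)))
    return plan


# --------------------------------------------------------------------------
# MSA method adapters


class BuiltinAligner:
    """The in-package center-star MSA, always available."""

    name = "builtin"

    def __init__(self, scoring: Scoring = DEFAULT_SCORING):
        self.scoring = scoring

    def available(self) -> bool:
        return True

    def build_msa(self, reads, row_ids=None) -> Msa:
        return center_star_msa(reads, self.scoring, row_ids=row_ids)


@dataclass
class ToolAdapter:
    """External MSA tool driven by a shell command template.

    The template must contain ``{input}`` and ``{output}`` placeholders; the
    input is a FASTA of reads, the output an aligned FASTA.  The adapter
    enforces row conservation: gap-stripped output rows must equal the input
    reads (matched by record id).
    """

    name: str
    template: str

    def available(self) -> bool:
        try:
            executable = shlex.split(self.template)[0]
        except (ValueError, IndexError):
            return False
        return shutil.which(executable) is not None

    def build_msa(self, reads, row_ids=None) -> Msa:
        reads = list(reads)
        if row_ids is None:
            row_ids = [f"read{i}" for i in range(len(reads))]
        with tempfile.TemporaryDirectory(prefix="msabench-") as tmp:
            in_path = Path(tmp) / "reads.fasta"
            out_path = Path(tmp) / "msa.fasta"
            SeqIO.write(
                [
                    SeqRecord(Seq(s), id=rid, description="")
                    for rid, s in zip(row_ids, reads)
                ],
                str(in_path),
                "fasta",
            )
            cmd = self.template.format(input=in_path, output=out_path)
            proc = subprocess.run(
                cmd, shell=True, capture_output=True, text=True
            )
            if proc.returncode != 0:
                raise RuntimeError(
                    f"tool {self.name!r} failed (exit {proc.returncode}): "
                    f"{proc.stderr.strip()[:500]}"
                )
            msa = read_msa_fasta(out_path)
        check_row_conservation(msa, reads, row_ids)
        return msa


def check_row_conservation(msa: Msa, reads, row_ids) -> None:
    """Verify that an MSA's gap-stripped rows equal the input reads."""
    expected = dict(zip(row_ids, reads))
    if sorted(msa.row_ids) != sorted(expected):
        raise ValueError(
            "MSA row ids do not match input reads: "
            f"got {sorted(msa.row_ids)[:5]}..., expected {sorted(expected)[:5]}..."
        )
    for rid, row in zip(msa.row_ids, msa.rows):
        if row.replace("-", "") != expected[rid]:
            raise ValueError(
                f"row conservation violated for read {rid!r}: "
                "gap-stripped MSA row differs from the input read"
            )


# --------------------------------------------------------------------------
# Grid execution


@dataclass
class ExperimentContext:
    """Shared inputs of a grid run: reference(s), profiles, parameters.

    ``references`` maps dataset name to reference sequence; ``profiles``
    maps dataset name to its error profile.  Regions are sampled once per
    dataset (same starting positions across sizes) from a seeded stream.
    """

    references: dict
    profiles: dict
    config: GridConfig
    scoring: Scoring = DEFAULT_SCORING
    aligners: dict = field(default_factory=dict)
    _regions: dict = field(default_factory=dict, repr=False)

    def aligner_for(self, tool: str):
        if tool in self.aligners:
            return self.aligners[tool]
        if tool == "builtin":
            return BuiltinAligner(self.scoring)
        return None

    def region_for(self, spec: ExperimentSpec) -> Region:
        key = (spec.dataset, spec.region_size, spec.region_index)
        if key not in self._regions:
            ref = self.references[spec.dataset]
            rng = np.random.default_rng(
                [self.config.seed, _stable_hash(spec.dataset), spec.region_size]
            )
            regions = sample_regions(
                len(ref),
                sizes=[spec.region_size],
                n_per_size=self.config.n_regions,
                rng=rng,
                seq_id=spec.dataset,
            )
            for i, region in enumerate(regions):
                self._regions[(spec.dataset, spec.region_size, i)] = region
        return self._regions[key]

    def reads_for(self, spec: ExperimentSpec):
        """Simulated reads for a spec; identical for every tool of a cell."""
        ref = self.references[spec.dataset]
        region = self.region_for(spec)
        rng = np.random.default_rng(
            [
                self.config.seed,
                _stable_hash(spec.dataset),
                spec.region_size,
                spec.region_index,
                spec.depth,
            ]
        )
        reads, _ = reads_for_region(
            ref, region, spec.depth, self.profiles[spec.dataset], rng
        )
        return reads, region


def _stable_hash(text: str) -> int:
    """Deterministic 32-bit hash of a string (process-independent)."""
    h = 2166136261
    for ch in text.encode():
        h = ((h ^ ch) * 16777619) & 0xFFFFFFFF
    return h


def run_experiment(
    spec: ExperimentSpec,
    context: ExperimentContext,
    aligner=None,
) -> ExperimentResult:
    """Execute one grid cell: reads -> MSA -> consensus -> evaluation."""
    if aligner is None:
        aligner = context.aligner_for(spec.tool)
    if aligner is None:
        return ExperimentResult(spec, SKIPPED, reason=f"no adapter for tool {spec.tool!r}")
    if not aligner.available():
        return ExperimentResult(
            spec, SKIPPED, reason=f"tool {spec.tool!r} is not available"
        )
    try:
        reads, region = context.reads_for(spec)
        row_ids = [f"read{i}" for i in range(len(reads))]
        msa = aligner.build_msa(reads, row_ids=row_ids)
        check_row_conservation(msa, reads, row_ids)
        consensus = msa_consensus(msa, context.config.threshold)
        reference = context.references[spec.dataset]
        metrics = evaluate_consensus(
            consensus.ungapped, region.slice(reference), context.scoring
        )
    except Exception as exc:  # noqa: BLE001 -- grid must survive bad cells
        return ExperimentResult(spec, FAILED, reason=str(exc))
    return ExperimentResult(spec, OK, metrics=metrics)


def run_grid(context: ExperimentContext, log=None) -> pd.DataFrame:
    """Run every experiment of the context's grid; one row per experiment."""
    rows = []
    for spec in enumerate_plan(context.config):
        result = run_experiment(spec, context)
        if log is not None:
            log.write(
                f"{result.status}\t{spec.dataset}\tsize={spec.region_size}\t"
                f"region={spec.region_index}\tdepth={spec.depth}\t"
                f"tool={spec.tool}\t{result.reason}\n"
            )
        row = {
            "dataset": spec.dataset,
            "region_size": spec.region_size,
            "region_index": spec.region_index,
            "depth": spec.depth,
            "tool": spec.tool,
            "status": result.status,
            "reason": result.reason,
        }
        if result.metrics is not None:
            row.update(result.metrics.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_grid(results: pd.DataFrame) -> pd.DataFrame:
    """Per tool x dataset min-max of the mean identity rate.

    For every (tool, dataset), the identity rate is averaged over replicate
    regions within each (region_size, depth) combination; the summary
    reports the minimum (worst combination) and maximum (best combination)
    of those means, plus mean/std of all metrics across every successful
    experiment.
    """
    ok = results[results["status"] == OK]
    if ok.empty:
        raise ValueError("all experiments failed; nothing to summarize")
    rows = []
    for (tool, dataset), group in ok.groupby(["tool", "dataset"]):
        combo_means = group.groupby(["region_size", "depth"])["identity_rate"].mean()
        metrics = [
            EvalMetrics(
                identity_rate=r.identity_rate,
                ambiguous_rate=r.ambiguous_rate,
                match_rate=r.match_rate,
                error_rate=r.error_rate,
                consensus_size=r.consensus_size,
                error_rate_aligned=r.error_rate_aligned,
            )
            for r in group.itertuples()
        ]
        summary = aggregate(metrics)
        row = {
            "tool": tool,
            "dataset": dataset,
            "n_experiments": len(group),
            "min_mean_identity": float(combo_means.min()),
            "max_mean_identity": float(combo_means.max()),
        }
        for name, value in summary.means.items():
            row[f"mean_{name}"] = value
        for name, value in summary.stds.items():
            row[f"std_{name}"] = value
        rows.append(row)
    return pd.DataFrame(rows)


def compare_metaconsensus(
    per_tool: pd.DataFrame,
    meta: pd.DataFrame,
    ndigits: int = 4,
) -> dict:
    """Tally metaconsensus identity against the best and worst tool.

    ``per_tool`` has columns (region, tool, identity_rate); ``meta`` has
    (region, identity_rate).  Per region, the best and worst per-tool
    identities are found and the metaconsensus is compared to each after
    rounding to ``ndigits`` decimals; the tallies count superior (>), equal
    (=) and inferior (<) regions, and the deltas are mean differences on the
    unrounded values.
    """
    meta_by_region = dict(zip(meta["region"], meta["identity_rate"]))
    tool_regions = set(per_tool["region"])
    if tool_regions != set(meta_by_region):
        raise ValueError("per-tool and metaconsensus region sets differ")
    tallies = {
        "vs_best": {">": 0, "=": 0, "<": 0},
        "vs_worst": {">": 0, "=": 0, "<": 0},
    }
    deltas_best = []
    deltas_worst = []
    for region, group in per_tool.groupby("region"):
        best = group["identity_rate"].max()
        worst = group["identity_rate"].min()
        m = meta_by_region[region]
        for label, ref_val, deltas in (
            ("vs_best", best, deltas_best),
            ("vs_worst", worst, deltas_worst),
        ):
            a, b = round(m, ndigits), round(ref_val, ndigits)
            tallies[label][">" if a > b else "<" if a < b else "="] += 1
            deltas.append(m - ref_val)
    tallies["delta_avg_best"] = float(np.mean(deltas_best))
    tallies["delta_avg_worst"] = float(np.mean(deltas_worst))
    tallies["n_regions"] = len(deltas_best)
    return tallies
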