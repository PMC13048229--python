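# msabench

Benchmark multiple-sequence-alignment (MSA) methods on noisy long-read
segments by building per-column **IUPAC threshold consensus** sequences and
scoring them against a reference.

A benchmark experiment is one cell of a grid (dataset × region size ×
sequencing depth × replicate region × MSA method) and runs the same
pipeline end to end:

1. sample a genomic region and select reads spanning it at the requested
   depth (simulated with a controlled error rate/profile, or extracted from
   a SAM/BAM alignment of real reads);
2. build an MSA of the reads — via an external-tool adapter, or the
   built-in center-star aligner so everything runs without external
   binaries;
3. take the threshold consensus of the MSA: per column, the most frequent
   nucleotides are accumulated (whole tie-groups at a time) until their
   cumulative rate reaches the threshold, and the accumulated set is
   emitted as an IUPAC code; a column whose strictly most frequent
   character is a gap stays a gap;
4. align the consensus globally to the reference and compute identity,
   ambiguity, match and error rates plus consensus size. For diploid
   (IUPAC-encoded) references, recall and precision of heterozygous-site
   recovery are computed as well.

A *metaconsensus* — the threshold consensus of several per-tool consensus
sequences stacked into a meta-MSA — and min–max/mean–std summary tables are
also provided.

## Layout

| module | contents |
| --- | --- |
| `msabench.iupac` | IUPAC symbol/nucleotide-set bijection and the code compatibility relation |
| `msabench.align` | Needleman–Wunsch global alignment (linear gaps, IUPAC-aware scoring) and center-star MSA |
| `msabench.consensus` | `Msa`, per-column threshold consensus, metaconsensus, aligned-FASTA I/O |
| `msabench.metrics` | evaluation metrics, read error-rate estimation, het-site recall/precision, aggregation |
| `msabench.simulate` | error-profile read simulator with truth logs, region sampling, diploid reference construction, SAM read extraction |
| `msabench.bench` | grid enumeration/execution, tool adapters, summaries, metaconsensus comparison |
| `msabench.cli` | `msabench` command-line interface |

## CLI

```sh
msabench --help
```

Subcommands: `simulate-reads`, `make-diploid`, `sample-regions`,
`extract-reads`, `msa`, `consensus`, `evaluate`, `het-eval`, `plan`,
`bench`, `metaconsensus`, `summarize`. A typical simulated run:

```sh
msabench simulate-reads --reference ref.fasta --start 100 --length 500 \
    --depth 45 --error-type MIX --error-rate 0.10 --seed 1 \
    --out reads.fasta --truth-out truth.tsv
msabench msa --reads reads.fasta --out msa.fasta
msabench consensus --msa msa.fasta --threshold 0.7 --out cons.fasta
msabench evaluate --consensus cons.fasta --reference window.fasta
```

Grids are driven by a YAML config (`datasets`, `region_sizes`, `depths`,
`n_regions`, `tools`, `threshold`, `seed`):

```sh
msabench plan --config grid.yaml
msabench bench --config grid.yaml --reference ref.fasta \
    --error-type MIX --error-rate 0.10 --out results.tsv --summary-out summary.tsv
```

External MSA tools plug in through `ToolAdapter` command templates
(`mytool {input} > {output}`); missing binaries degrade to SKIPPED
experiments, and every adapter result is checked for row conservation
(gap-stripped MSA rows must equal the input reads).

## Defaults

Region sizes 100–10,000 bases, depths 10×–200×, 10 regions per
combination, consensus threshold 0.7, MIX error composition 23%
substitutions / 31% insertions / 46% deletions, error rates 1–30%.
Alignment scoring defaults to match=2, compatible=1, mismatch=−1, gap=−2.
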