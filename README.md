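# timegrn

Time-resolved gene regulatory network (GRN) construction from
paired-condition time-course multi-omics. The pipeline integrates:

- **expression** — per-gene direction calls (`up`/`down`/`none`) at
  0/1/3/5/7/9/12 h from RNA-seq FPKM fold-change rules (abundance gate 10,
  FC cutoffs 1.5/0.5, a dedicated time-zero rule) and from nCounter assays
  (positive-control and housekeeping lane normalization, background
  subtraction, FC 1.2/0.8 with a pooled-variance t-test), consolidated
  across platforms by non-contradiction at shared time points;
- **chromatin** — enrichment filtering of H3K27ac/H3K27me3 peaks
  (p < 1e-5, FC > 1.2, q-score > 3), bedtools-style merging into unique
  sites (100 bp gap) and classification of each site's joint mark pattern
  into 16 indices: activation (1–3), repression (4–6), poised (7–12),
  no change (13–16);
- **loci** — CTCF-bounded regulatory windows (strongest peak within
  500 kb per side) owning each candidate gene's sites and sequences;
- **motifs** — PWM log2-odds scanning of site sequences on both strands
  (FIMO-style pseudocount, score > 10);
- **grn_builder** — signed edges per time point (co-regulation →
  positive, opposition → negative; reversed at repression sites), with
  the regulator gated to be expressed at the same or the immediately
  preceding time point, ChIP epochs mapped 0–5 h → 5 h, 7–9 h → 9 h,
  12 h → 12 h, duplicate-edge removal, isolated-gene pruning and
  site-resolved subnetworks (500 bp cross-time merge);
- **network_analysis** — per-time outdegree and unnormalized directed
  betweenness centrality with core-gene ranking;
- **synthetic_data** — a deterministic scenario generator that plants a
  ground-truth network (genome, GTF, CTCF BED, peak tables, FPKM table,
  triplicate nCounter lanes with lane effects, MEME motif library) so the
  whole pipeline is testable offline; at zero noise the pipeline recovers
  the planted edge set exactly.

Exports: canonical edge TSV, BioTapestry-style Model Hierarchy CSV and
Time Expression XML (minimal documented dialect with bundled round-trip
parsers), and UCSC-style BED tracks.

## CLI

```bash
timegrn simulate --seed 1 --out scenario/           # synthetic inputs
timegrn build    --scenario scenario/ --out-dir out # full pipeline
timegrn metrics  --edges out/edges.tsv --out out/metrics.tsv
timegrn export   --edges out/edges.tsv --profile out/profile.csv \
                 --sites out/sites.tsv --out-dir out/exports
```

Stage-by-stage commands (`expression`, `chromatin`, `loci`, `scan`,
`subnetwork`) operate on the same scenario directory and chain through
plain-text TSV/CSV artifacts. Thresholds are configurable via
`--config thresholds.yaml` (keys mirror `timegrn.config.PipelineConfig`:
`min_fpkm`, `up_fc`, `down_fc`, `nano_up`, `nano_down`, `score_threshold`,
`merge_gap`, `subnetwork_gap`, `max_search`, ...). Add `-v` before the
subcommand for per-filter in/out counts.

## Layout

```
src/timegrn/
  config.py       thresholds + YAML I/O
  expression.py   FPKM rules, nCounter normalization/DE, integration
  chromatin.py    peak filter, interval merge, 16-index classification
  loci.py         GTF/CTCF parsing, locus construction, FASTA extraction
  motifs.py       PWM library I/O, log-odds scanning
  grn.py          edge inference, dedup, pruning, subnetworks
  network.py      outdegree, betweenness (Brandes), core ranking
  biotapestry.py  model CSV / time-expression XML / BED round trips
  synthetic.py    scenario generator with planted ground truth
  pipeline.py     stage orchestration over a scenario directory
  cli.py          click entry points
```
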