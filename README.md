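# lbdkit

Graph-based open and closed literature-based discovery (LBD) over temporal
biomedical co-occurrence graphs.

Given a year-stamped, weighted co-occurrence graph, `lbdkit` ranks discovery
candidates under the ABC paradigm — closed discovery ranks linking terms B
for a given (A, C) pair, open discovery ranks two-hop targets C for a given
A — and evaluates the rankings with tie-aware rank metrics under
case-replication and time-sliced protocols.

Two families of scorers are provided:

- **Co-occurrence baselines** — eight association metrics (`count`,
  `doc-count`, `jaccard`, `scp`, `npmi`, `chi2`, `ttest`, `llr`) combined
  with path aggregators (`min`/`avg`/`max`) and per-candidate accumulators
  (`sum`/`max`).
- **Neural approaches** — node embeddings trained by weighted edge sampling
  (first- plus second-order proximity, concatenated), five node-combination
  methods (`avg`, `concat`, `hadamard`, `w1`, `w2`), and four rankers:
  CD-1/OD-1 (an MLP link scorer feeding the aggregator/accumulator
  machinery), CD-2 (an MLP scoring the combined A-B-C vector directly) and
  OD-2 (a CNN scoring a packed window of all A-B-C path vectors per
  candidate). All models are implemented on NumPy with analytic gradients.

A synthetic-data module generates temporal graphs with planted triadic
closure (future links preferentially complete high-Jaccard wedges) plus
derived gold cases, so the whole pipeline is testable without external data.

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria, including a
planted-signal recovery run on 300-node graphs (~2 min); the rest of the
suite finishes in seconds.

## CLI

The `lbdkit` entry point exposes `synth`, `build`, `embed`, `train`,
`discover`, `evaluate` and `pipeline`:

```sh
# generate a toy dataset (edge/node/totals TSVs plus case files)
lbdkit synth --preset tiny --seed 3 --out-dir data/

# validate and summarise the pre-cutoff slice
lbdkit build --edges data/edges.tsv --nodes data/nodes.tsv \
             --totals data/totals.tsv --cutoff 2010

# train embeddings, then a link-scorer MLP
lbdkit embed --edges data/edges.tsv --nodes data/nodes.tsv \
             --totals data/totals.tsv --cutoff 2010 \
             --dim 16 --seed 1 --out data/emb.txt
lbdkit train --edges data/edges.tsv --nodes data/nodes.tsv \
             --totals data/totals.tsv --cutoff 2010 \
             --embeddings data/emb.txt --model mlp --examples link \
             --combiner hadamard --seed 1 --out data/mlp.json

# rank candidates for one query
lbdkit discover --edges data/edges.tsv --nodes data/nodes.tsv \
                --totals data/totals.tsv --cutoff 2010 \
                --mode open --approach od1 --a E007 \
                --embeddings data/emb.txt --model data/mlp.json \
                --out ranking.tsv

# run the case-replication protocol for a baseline
lbdkit evaluate --edges data/edges.tsv --nodes data/nodes.tsv \
                --totals data/totals.tsv --cases data/cases_open.txt \
                --mode open --approach baseline --metric jaccard \
                --agg min --acc sum --out report.txt

# or everything end to end from a YAML config
lbdkit pipeline --config pipeline.yaml --out-dir run/
```

Rankings are TSVs (`rank`, `entity`, `score`, `tie_adjusted_rank`);
identical configurations and seeds reproduce outputs byte for byte.

## Data formats

- **Edge TSV**: `entity1 entity2 year sent_count doc_count` (undirected;
  duplicate rows are canonicalised and summed).
- **Node TSV**: `entity entity_type year sent_occurrence_count`.
- **Totals TSV**: `year total_sentences total_documents`.
- **Case file**: blank-line-separated `key: value` blocks with `a`, optional
  `c` (closed discovery only), `gold`, `cutoff_year`.
- **Embeddings**: word2vec-style text (`count dim` header, one
  `id v1 ... vd` row per node); any externally produced file in this format
  can be plugged in.

## Package layout

| module | contents |
| --- | --- |
| `lbdkit.graph` | temporal graph, slicing, B/C candidate generation, time split |
| `lbdkit.metrics` | the eight contingency-count association metrics |
| `lbdkit.embeddings` | first/second-order proximity embeddings, text I/O |
| `lbdkit.paths` | node-vector combiners, aggregators, accumulators |
| `lbdkit.scorers` | MLP/CNN scorers, Adam, training-set builders, window packing |
| `lbdkit.discovery` | baseline and neural rankers plus approach orchestration |
| `lbdkit.evaluation` | tie-median ranks, MRR/MAP/R-precision, both protocols |
| `lbdkit.synthetic` | planted-closure graph generator and case derivation |
| `lbdkit.cli` | command-line surface and pipeline |
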