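# semindex

Hierarchical coarse-to-fine multi-label semantic indexing of short documents
(title + abstract), combining:

- a **fixed-length document encoder** ("document word sequence embedding"):
  every document is mapped to exactly `L` token positions (pad with a
  reserved `UNKNOWN` token, or keep only the occurrences of the most
  frequent words), and every position is widened to four words — the token
  plus up to three extension words drawn from its entity class and its
  category-map entries — each replaced by its `d`-dimensional embedding,
  giving an `L x 4d` matrix per document;
- **category/entity meta-features**: row-stochastic word-class (P1),
  word-category (P2) and category-class (P3) distributions, with P2
  estimated per word by simplex-constrained least squares from
  `P1 ~= P2 @ P3`; greedy longest-match lexicon entity tagging; and a
  seeded random projection of entity-class counts into a global entity
  vector;
- a **convolutional feature extractor** whose first-layer windows are
  aligned with whole word sub-vectors (kernel width = embedding dimension,
  feature-axis stride = embedding dimension), with k-max pooling, ReLU,
  inverted dropout, and a full hand-written backward pass;
- a **two-hidden-layer deep Boltzmann machine with label units** that fuses
  the convolutional features with the global entity vector in its visible
  layer (`V = sigmoid(C y_c + E y_e)`), is pretrained layer-wise with CD-1
  and trained contrastively with label units, and provides a deterministic
  mean-field test path (doubled bottom-up weights, h1 re-sampling);
- a **coarse-to-fine classifier**: labels are clustered by k-means on label
  embeddings; sigmoid-linear heads with mean-squared-error losses decide
  cluster membership and then labels within selected clusters; a flat
  per-label member/non-member baseline (`dbc`) is included for comparison;
- a **multi-label evaluation suite**: macro/micro precision, recall, F1 and
  Jaccard-style similarity, plus threshold-sweep ROC curves with
  trapezoid AUC;
- seeded **synthetic-data generators** producing corpora, embedding tables,
  category maps and entity lexicons with the statistical structure the
  method assumes (clustered label embeddings, label-dependent Zipf word
  distributions, unbalanced label frequencies, planted entities), in
  exactly the file formats the I/O layer reads.

## CLI

```bash
# generate a synthetic dataset (YAML spec keys = SyntheticSpec fields)
semindex synth --spec spec.yaml --out data/

# train (run.yaml keys = RunConfig fields; includes data paths)
semindex train --config run.yaml --out model.npz

# predict and evaluate
semindex predict  --model model.npz --corpus data/corpus.jsonl --out preds.jsonl
semindex evaluate --model model.npz --corpus data/corpus.jsonl --out report/
```

`RunConfig.mode` selects the pipeline variant:

- `bcnn` — full stack (CNN -> fusion -> Boltzmann machine -> hierarchy).
  Training runs in three phases: CNN warm-up through temporary heads,
  generative DBM pretraining + contrastive label training, then joint SGD
  fine-tuning of heads, DBM, fusion matrices and CNN together.
- `hc`   — hierarchy heads read the CNN output directly (DBM bypassed).
- `dbc`  — flat per-label two-node baseline on the CNN output.

`RunConfig.x_source` chooses what the decision heads read in `bcnn` mode:
the DBM's label-score layer (`scores`, default) or the re-sampled top
hidden layer (`h2`).

## File formats

- **Corpus**: JSON-lines; one object per line with `id`, `title`,
  `abstract`, `labels`.
- **Embeddings** (word and label): word2vec text format (`"N d"` header,
  space-separated rows). An optional `UNKNOWN` row supplies the
  out-of-vocabulary vector (zero vector otherwise).
- **Category map**: TSV, column 1 = word, columns 2..k = category terms.
- **Entity lexicon**: TSV, column 1 = space-joined token phrase,
  column 2 = entity class.
- **Model archive**: a single `.npz` with all weight arrays plus a JSON
  manifest (config, label vocabulary, embedding table, category map,
  entity lexicon, training history).

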