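# profun

Multimodal protein function prediction at desk scale: residue contact
graphs from predicted structures, biased-random-walk node embeddings,
a hierarchical graph-pooling network fused with global sequence
embeddings, and protein-centric GO multilabel evaluation (Fmax, AUC,
AUPR). A synthetic-data generator produces complete toy datasets
(PDB structures, FASTA sequences, a miniature OBO ontology, annotation
TSVs) with planted, learnable signal so the entire pipeline runs offline.

## How it works

1. **structure_graph** — parses single-chain PDB files into Cα traces and
   builds the residue contact graph: an edge joins residues whose Cα atoms
   are strictly closer than 10 Å (configurable), with self-loops for the
   spectral convolutions.
2. **node2vec** — second-order biased random walks (return parameter
   `p = 0.8`, in-out parameter `q = 1.2` by default) embedded by
   skip-gram with negative sampling, implemented in numpy and fully
   deterministic under a seed.
3. **sequence** — per-residue one-hot matrices and a global per-protein
   embedding: an adapter for precomputed protein-language-model vectors, a
   deterministic k-mer-hash mock, or the mean-pooled one-hot composition.
4. **golabels** — OBO parsing (`is_a` only), true-path propagation, rare-term
   filtering, binary label matrices per namespace.
5. **model** — six stacked ConvPoolBlocks (3-layer GraphConv with symmetric
   degree normalisation → self-attention top-k pooling at ratio 0.75 →
   mean∥max readout), readouts summed, fused with the sequence embedding,
   encoded by a 3-layer / 8-head transformer over three tokens, classified
   by a 3-layer head with logistic outputs. Built on a small reverse-mode
   autodiff engine over numpy (`autodiff.py`) — no GPU framework required.
6. **train_eval** — 7:2:1 splits, Adam with gradient clipping, binary
   cross-entropy, early stopping on validation Fmax; metrics: protein-centric
   Fmax over a 101-point threshold grid, micro-averaged AUC and AUPR.

## CLI

Every stage is a subcommand of `profun`; `run-all` chains them with
digest-based skipping (unchanged stages are not recomputed):

```sh
profun simulate --out-dir data --n-proteins 200 --seed 0
profun build-graphs --pdb-dir data/pdb --out-dir out/graphs --threshold 10.0
profun embed-nodes --graphs out/graphs --out out/node_embeddings --p 0.8 --q 1.2 --dim 30 --seed 0
profun embed-seqs --fasta data/sequences.fasta --out out/seq_embeddings.tsv --mode mock --dim 64 --seed 0
profun prepare-labels --obo data/go.obo --annotations data/annotations.tsv \
    --namespace MFO --min-proteins 25 --out out/labels.tsv
profun run-all --out-dir out --seed 0          # simulate → ... → evaluate
profun evaluate --labels out/labels.tsv --preds out/predictions.tsv --metrics-out metrics.txt
```

Configuration is a flat `section.key = value` text file
(sections: `synth`, `graph`, `walk`, `seq`, `labels`, `model`, `train`,
`split`), passed as `--config`; `--seed` overrides every section's seed.
With identical seeds and single-threaded execution, two `run-all`
invocations produce byte-identical metrics reports.

## Scale notes

Module-level Node2Vec defaults (10 walks × length 80, dim 30) match common
practice; the pipeline defaults to a lighter walk configuration
(5 × 20, dim 16) so a 200-protein run finishes in minutes on one CPU.
Both are fully configurable.
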