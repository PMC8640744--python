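# dms2func

Supervised sequence–function models for deep mutational scanning (DMS) data.

The package encodes protein variants as per-residue feature matrices (21-letter
one-hot plus a PCA projection of amino-acid physicochemical properties), trains
four regression architectures — linear, fully connected, sequence convolutional
(valid, unpadded) and graph convolutional over a residue contact graph — and
provides the surrounding experimental machinery:

- **sequence_data** — variant notation (`E19Q,A24Y`), wild-type FASTA and
  dataset TSV I/O, Hamming distances.
- **encoding** — property-matrix PCA (19 components capture 100% of the
  variance of a 20-row table) and one-hot ⊕ property variant encoding.
- **structure_graph** — Cβ (Cα for glycine) contact graphs from PDB files at a
  distance threshold, plus shuffled / disconnected / sequential / complete
  baseline graphs.
- **models** — the four architectures in pure numpy with hand-written
  backpropagation, including the order-independent graph convolution
  `z_i = σ(W_C·x_i + mean_{j∈N_i}(W_N·x_j) + b)`.
- **experiments** — random 81/9/10 splits, reduced-size training subsets,
  mutational/positional extrapolation splits with discarded overlap pools,
  Adam + MSE training with early stopping (patience 15, min delta 1e-5, max
  300 epochs), and evaluation (Pearson/Spearman/MSE, recall-at-budget, top-N
  statistics, random-ranking baselines).
- **resampling** — wild-type-normalized log-ratio enrichment scores with +0.5
  pseudocounts, multinomial resampling of read-count tables, and the
  library-size × read-count grid experiment.
- **interpretation** — integrated-gradients attributions (wild-type baseline,
  midpoint Riemann sum), per-position aggregation, latent-layer extraction,
  and full single-mutant prediction matrices.
- **design** — random-restart hill climbing at fixed Hamming distance n,
  maximizing the minimum prediction of a model ensemble.
- **synthetic_data** — seeded synthetic fitness landscapes (additive +
  pairwise-epistatic + noise), DMS-style datasets, and simulated read counts,
  so everything is testable without downloads.

## CLI

```bash
dms2func synth --seed 7 --out fixtures/          # synthetic FASTA/TSV fixture
dms2func data validate --dataset fixtures/dataset.tsv --wt fixtures/wt.fasta
dms2func graph --pdb protein.pdb --chain A --threshold 7.0 --out edges.txt
dms2func train --dataset fixtures/dataset.tsv --wt fixtures/wt.fasta \
    --arch seq_conv --seed 7 --out run/
dms2func model describe --arch graph_conv --graph edges.txt --length 56
dms2func mutscan --model run/model.npz --wt fixtures/wt.fasta \
    --projection run/projection.csv --out scan.csv
dms2func attribute --model run/model.npz --dataset fixtures/dataset.tsv \
    --wt fixtures/wt.fasta --projection run/projection.csv --out attr.csv
dms2func design --wt fixtures/wt.fasta --models run/model.npz \
    --projection run/projection.csv --n 10 --restarts 10 --seed 7 \
    --out designs.tsv
dms2func resample --counts fixtures/counts.tsv --wt fixtures/wt.fasta \
    --grid grid.yaml --seed 7 --out grid.csv
```

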