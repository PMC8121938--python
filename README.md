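# m6aconvkit

Identification of DNA N6-methyladenine (6mA) sites in fixed-length plant
genome windows (41 bp, centered on a candidate adenine) with a
multi-branch 1D convolutional classifier, plus an attention-based model
variant for extracting the sequence motifs the classifier relies on.

The package implements:

- **Four sequence encodings** — monomer one-hot (41×4), overlapping-dimer
  one-hot (40×16), a dinucleotide-physicochemical-property (DPP) matrix
  (40×k, Z-score normalised per property), and a four-column matrix of
  ring-structure / functional-group / hydrogen-bonding codes plus the
  per-position lingering density.
- **Correlation-aware DPP selection** — per-property logistic-regression
  scoring by five-fold cross-validated MCC, top-20 ranking, and pruning of
  properties with |Pearson r| > 0.9 against the topmost property.
- **The classifier** — four convolutional branches (three 1D conv layers
  each), each compressed to a single sigmoid confidence ("Feature
  Learner"), coordinated by a final sigmoid dense layer ("Coordinator").
  A sample is called positive iff the output probability is strictly
  greater than 0.5.
- **The attention variant** — a bidirectional LSTM over the monomer
  one-hot time steps produces an output matrix O (L×H); the dot product
  with the convolutional feature vector C is softmax-normalised into an
  attention distribution S used for potential-motif extraction
  (positions with S > 1/L are *active*; maximal runs of active positions
  are *active regions*; k-mers inside active regions are aggregated over
  positive samples).
- **Evaluation** — Acc/Sn/Sp/MCC, rank-based auROC with ROC points,
  stratified k-fold and jackknife cross-validation, random undersampling
  for imbalanced-training experiments, and a one-tailed Wilcoxon
  signed-rank comparison of paired fold scores.
- **Synthetic data** — a seeded generator for labeled 41-bp windows with
  a planted class-discriminating motif and a decoy motif whose
  containment frequency is matched between classes (default "GAGG" at
  17%, so the decoy cannot leak a trivial signal), plus synthetic DPP
  tables with optionally planted informative/duplicate/negated
  properties.

The networks are implemented on a small NumPy reverse-mode autodiff
engine (see `m6aconvkit.network.autodiff`), so the package has no
deep-learning-framework dependency, runs on one CPU, and is
bit-deterministic given a seed.

## CLI

```sh
# generate a synthetic labeled dataset and a synthetic DPP table
m6aconvkit --seed 0 simulate --n-pos 1000 --n-neg 1000 \
    -o data.fasta --dpp-out props.tsv

# four-step property selection
m6aconvkit --seed 0 select-dpp --fasta data.fasta --dpp-table props.tsv \
    -o selection.json

# train / predict / evaluate
m6aconvkit --seed 0 train --fasta data.fasta --dpp-table props.tsv \
    --selected selection.json -o model.npz
m6aconvkit predict --model model.npz --fasta data.fasta \
    --dpp-table props.tsv -o predictions.csv
m6aconvkit --seed 0 evaluate --fasta data.fasta --dpp-table props.tsv \
    --selected selection.json --k 5 -o report.json --roc-csv roc.csv

# attention model, motif extraction, feature significance
m6aconvkit --seed 0 train --attention --fasta data.fasta \
    --dpp-table props.tsv --selected selection.json -o attention.npz
m6aconvkit motifs --model attention.npz --fasta data.fasta \
    --dpp-table props.tsv -o motifs.csv
m6aconvkit significance --model model.npz --fasta data.fasta \
    --dpp-table props.tsv -o significance.csv
```

Labels travel in FASTA description lines as `label=0` / `label=1`.
A YAML config file (`--config`) can override any architecture
hyperparameter (`conv_filters`, `conv_kernels`, `attention_hidden`,
`learning_rate`, `batch_size`, `epochs`, ...).

## Reference values (not reproduced here)

The published full-scale results — five-fold cross-validation auROC 0.98,
accuracy 93.97% and MCC 0.88 on a benchmark of 154,000 sequences per
class — require the external benchmark dataset and full-scale training.
They are documented here as reference values only; the test suite
replaces them with property-based checks on synthetic data (planted-
signal recovery, fold consistency, imbalance behaviour).

## Conventions

- Monomer one-hot column order is (A, T, C, G); the 16 dimer columns are
  lexicographic over that order (AA, AT, AC, AG, TA, ...), shared between
  the dimer one-hot encoding and DPP tables.
- Positions are 1-based in user-facing reports, 0-based internally.
- Probability exactly 0.5 is a negative call (strict threshold).
- Z-scores use the population standard deviation over the 16 dimer
  values; constant properties map to all-zero vectors with a warning.
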