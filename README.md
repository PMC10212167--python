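# tcncall

Per-nucleotide DNA mutation calling with a temporal convolutional network.

`tcncall` labels **every nucleotide** of a DNA sequence as *normal*, *SNV*,
*insertion* or *deletion* — so a mutation's type **and** its index in the
sequence come straight out of the model, without aligning against a
reference at call time. It is aimed at people studying machine-learning
approaches to somatic mutation detection (e.g. in breast-cancer gene
panels), who need a controlled, fully reproducible test bed: the package
ships a seeded mutation simulator with exact ground truth in place of
restricted patient data.

## The model

DNA is first mapped to integer codes with a k-mer table (k ∈ {1, 2, 3}):
the integer mapping T,C,A,G → 1,2,3,4, or the positional base-4 k-mer code
(digit order A=0, T=1, G=2, C=3, so `AA`=1, `AT`=2, …, `CC`=16 for 2-mers)
emitted at stride 1, one code per nucleotide. Code 0 is reserved for
padding ('N') and end overhangs. Long sequences are reshaped into 150 bp
windows with 50 bp overlap.

The one-hot encoded code sequence ((m+1) × n, m = 4^k) enters a stack of
residual blocks, one per dilation factor d ∈ {1, 2, 4, 8, 16, 32}. Each
block applies twice

    weight-normalized dilated causal Conv1D (128 kernels, size K = 16)
    → ReLU → spatial dropout (0.1)

and adds a skip connection (1×1 Conv1D when channel counts differ):
`o = ReLU(x + F(x))`. The dilated causal convolution

    F(x)(t) = Σ_{i=0}^{K−1} f(i) · x_{t−d·i}

sees only positions ≤ t; dilations doubling per block grow the receptive
field to 1 + Σ 2(K−1)d = 1891 positions for the default configuration. A
1×1 Conv1D and a time-distributed softmax produce four class
probabilities per position. Training uses masked per-position
cross-entropy with Adam (lr 0.0005, batch 256), a stratified 90:10
train/test split, and Random Under Sampling of mutation-free windows.
Performance is reported as per-class precision, recall and F1
(P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R)), one-vs-rest ROC AUC per
mutation class, and a macro-F1 over the mutation classes present in the
truth.

The network and its training loop are implemented in NumPy (im2col +
BLAS), with explicit per-layer gradients; runs are bit-reproducible from
one master seed on a single thread. See `docs/methods.md` for every
convention and default.

## Worked example

Simulate an SNV-only dataset from 4 random 300 bp references, train a
small network, and evaluate on the held-out 10% of windows (about
7 minutes on one CPU core):

```sh
tcncall simulate --config demo.yaml --out data
tcncall train    --config demo.yaml --dataset data --out run
tcncall evaluate --config demo.yaml --model run --dataset data --out eval
```

with `demo.yaml`:

```yaml
seed: 7
k: 2
simulator: {n_refs: 4, ref_len: 300, n_samples: 1000, type_props: [1.0, 0.0, 0.0]}
train:     {learning_rate: 0.005, epochs: 60, batch_size: 64, val_fraction: 0.0}
tcn:       {n_channels: 32, kernel_size: 8, dilations: [1, 2, 4, 8]}
```

The final command prints the headline metric

```
macro_f1_mutations	0.726768
```

and writes `eval/report.tsv` / `eval/confusion.txt`:

```
metric	class	value
precision	normal	0.995895
recall	normal	0.999141
f1	normal	0.997515
precision	SNV	0.885135
recall	SNV	0.616471
f1	SNV	0.726768
auc	SNV	0.968421
...

true\pred	normal	SNV	INS	DEL
normal	39543	34	0	0
SNV	163	262	0	0
INS	0	0	0	0
DEL	0	0	0	0
```

Reading: of the 40,002 held-out (non-padding) positions, 425 are true
SNVs; the model recovers 262 of them at their exact index with only 34
false alarms (precision 0.89, recall 0.62). Precision/recall/F1 for the
`normal` class are near 1 because unmutated positions dominate; the `SNV`
row is the informative one — the model flags point substitutions by
comparing each position against the reference panel it memorized during
training, with no reference supplied at prediction time. The AUC of 0.97
means the SNV probability track separates mutated from unmutated
positions well even where the hard argmax label does not flip. The INS
and DEL rows are empty by construction (`type_props` makes this dataset
SNV-only), so those classes are reported NA for AUC and excluded from the
supported-class macro-F1.

`tcncall predict --model run --fasta data/samples.fasta --out calls.tsv --k 2`
then emits discrete calls (`sequence_id  start_1based  end_1based  type
mean_prob`), merging runs of identical labels and stitching overlapping
windows (earlier window wins; `--vote` averages instead).

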