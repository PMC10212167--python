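# Methods

`tcncall` labels every nucleotide of a DNA sequence as normal, SNV,
insertion or deletion, using a temporal convolutional network (TCN) over
k-mer integer encodings. This note records the model, the conventions the
implementation fixes where more than one reasonable choice existed, the
synthetic data generator's assumptions, and the numerical details needed
to reproduce results exactly.

## Sequence encoding

DNA over {A,C,G,T,N} is mapped position by position to integer codes:

- **Integer (1-mer) mapping**: T→1, C→2, A→3, G→4. This conventional
  single-nucleotide mapping predates the k-mer tables and deliberately does
  not follow their digit order; it is special-cased rather than derived.
- **k-mer mapping (k ≥ 2)**: positional base-4 code with digit order
  A=0, T=1, G=2, C=3: `code(s) = 1 + Σ_j digit(s[j])·4^(k−1−j)`, so
  AA…A = 1 and CC…C = 4^k. The number of non-padding codes is m = 4^k
  (16 for 2-mers, 64 for 3-mers).
- **Padding code 0** is reserved for every window that contains a non-ACGT
  character or overhangs the 3′ end.

Codes are emitted at stride 1 — one code per nucleotide, the k-mer
anchored at its first base — so the label vector and the code vector have
identical length n and the per-position classifier stays aligned. The
anchoring convention is a documented choice: anchoring at the last base
would be equally consistent; what matters is that one convention is fixed
and the final k−1 positions degrade to the padding code.

Long sequences are cut into windows of W = 150 positions with an overlap
of O = 50 (stride S = 100). Windows start at offsets 0, S, 2S, …, adding a
window while the previous one has not reached the sequence end; the final
window is right-padded with code 0 / label 0. A length-n sequence
therefore yields max(1, ceil((n−W)/S)+1) windows, and concatenating
windows with later overlap regions dropped reconstructs the input.

Labels: 0 = normal, 1 = SNV, 2 = insertion, 3 = deletion. Indel label
conventions (underdetermined by the label semantics alone, fixed here):
every inserted base carries label 2; a deletion — whose bases are absent
from the sample — labels the single position immediately 3′ of the
breakpoint with 3; at a collision, deletion > insertion > SNV. Coordinates
are 0-based half-open internally and 1-based inclusive in every TSV.

## The network

Input is the one-hot expansion of the code vector: m+1 channels (channel 0
is padding) × n positions. The network is a stack of residual blocks, one
per dilation factor d ∈ {1, 2, 4, 8, 16, 32} (defaults), each block being
two repetitions of

    weight-normalized dilated causal convolution (128 filters, K = 16 taps)
    → ReLU → spatial dropout (rate 0.1)

with a skip connection — identity when channel counts match, a 1×1
convolution otherwise — and a final ReLU: `o = ReLU(skip(x) + F(x))`.
The dilated causal convolution is

    y[t] = Σ_{i=0}^{K−1} f(i) · x[t − d·i],

with left zero-padding of (K−1)·d, so output length equals input length
and no output position depends on any later input. With d = 1 this is the
standard causal convolution. Weight normalization re-parameterizes each
filter as w = g·v/‖v‖, so ‖w‖ = |g| always. Spatial dropout zeroes whole
channels across all positions (independently per sample) and rescales
survivors by 1/(1−rate); it is the identity at inference.

After the blocks, a 1×1 convolution (n_channels → n_channels) with ReLU
and a position-shared affine map produce 4 logits per position; a softmax
per position gives the class distribution. The receptive field is

    1 + Σ_blocks convs_per_block · (K−1) · d  = 1891

for the default configuration — far beyond the 150-position window, so
every output position can condition on the entire window prefix.

Choices the architecture description leaves open, fixed here: two
convolutions per residual block (the canonical TCN block), one-hot rather
than learned embedding as the default input (a learned embedding is
available behind `TCNConfig`), 1×1 convolution width equal to n_channels,
and ReLU between the 1×1 convolution and the class projection.

The network, its backward pass and the Adam optimizer are implemented
directly in NumPy: convolutions as im2col + BLAS matrix products, with
explicit per-layer gradients (verified against float64 finite differences
to 9 significant digits during development). Everything runs in float32;
a single master seed drives initialization, shuffling and dropout, making
single-threaded runs bit-reproducible.

## Training

Windows are split 90:10 into train and test, stratified by the binary flag
"window contains any nonzero label", seeded. Random Under Sampling (RUS)
then balances the train set only: all mutation-containing windows are
kept and all-normal windows are subsampled to at most `rus_ratio` (default
1.0) times their count. The loss is per-position categorical
cross-entropy averaged over non-padding positions (positions whose input
code is 0 are masked; configurable off). Optimization is Adam
(β₁ = 0.9, β₂ = 0.999, ε = 1e−8) at learning rate 0.0005, batch 256,
100 epochs by default. An optional validation slice (default 10% of train)
is used for per-epoch macro-F1 reporting only — never for model selection
or early stopping.

## Evaluation

A 4×4 confusion matrix (rows = truth, columns = prediction) over all
non-masked positions feeds per-class precision = TP/(TP+FP),
recall = TP/(TP+FN) and F1 = 2PR/(P+R), with zero-denominator conventions
precision = 0 when TP+FP = 0, recall = 0 when TP+FN = 0, F1 = 0 when
P+R = 0. One-vs-rest ROC AUC per mutation class uses the class's softmax
probability as score and equals the Mann–Whitney concordance statistic; an
absent class raises an explicit undefined-metric error rather than
reporting 0.

The headline number, `macro_f1_mutations`, is the unweighted mean of F1
over the mutation classes (1–3) **with support in the truth labels**.
Averaging in unsupported classes (F1 = 0 by convention) would report an
artifact of dataset composition — an SNV-only dataset would cap the macro
at 1/3 regardless of model quality. The strict all-three average is kept
alongside as `macro_f1_mutations_all`, and a micro-F1 pooled over classes
1–3 is also reported; class 0's dominance makes any pooled-with-normal
figure uninformative.

Predicted label tracks are reduced to discrete calls by merging maximal
runs of identical nonzero labels; each call carries 1-based inclusive
coordinates, its type and the called class's mean probability over the
run. At prediction time, sequences longer than one window are stitched by
keeping the earlier window's positions in each overlap (an averaging
"vote" mode is available behind a flag).

## The simulator

The generator stands in for curated somatic-mutation data (long mutated
gene samples) and hospital short-read data with per-read SNV annotations.
It draws uniform i.i.d. reference sequences, implants mutations, and
optionally slices uniform random reads (≤ 144 bp) with exactly sliced
label tracks and an optional SNV-only read filter.

Defaults and their grounds:

- `type_props = (0.7633, 0.1079, 0.1288)` — the SNV/insertion/deletion
  proportions observed in breast-cancer somatic mutation data
  (duplications folded into insertions).
- `muts_per_sample = 3.0`, Poisson-truncated at ≥ 1 — every sample carries
  at least one mutation, as in mutation-call archives where a sample is
  present *because* it was mutated; 1–10 events per few-hundred-bp sample
  is the realistic upper range for heavily mutated panels.
- `indel_len_range = (1, 3)` — short indels dominate real somatic calls.
- `read_len ≤ 144` — the short-read platform cap.

Mutations occupy non-overlapping reference spans (a deletion additionally
reserves the following base so its label position always exists) and are
applied as a single left-to-right piecewise assembly, so sample
coordinates and truth labels are exact by construction. Sample length
always equals reference length + inserted − deleted bases.

What the generator does **not** emulate: sequencing error and quality
scores, coverage structure, strand, recurrent mutation hotspots,
GC/composition bias, and homology between references. Passing tests on
this generator therefore demonstrate that the pipeline's bookkeeping,
learning machinery and metrics are correct — not that the model's
headline performance transfers to real patient data, where sequence
redundancy and mutation recurrence (which the network exploits) are both
far stronger and differently structured.

## Numerical details

- Float comparisons use absolute tolerance 1e−6 (float32 throughout).
- Softmax subtracts the row max before exponentiation.
- Argmax ties break toward the lower class index (normal wins a tie).
- Cross-entropy clips probabilities at 1e−12 before the log.
- Degenerate inputs: empty sequences cannot be encoded; an empty dataset
  exports valid empty files; a training set with no mutated windows is
  left unchanged by RUS.
- Problem sizes in the test suite are deliberately small (tens to a few
  thousand windows, 2–32 channels); the package's own demonstration
  experiment uses 4 references × 300 bp and 3000 single-mutation-type
  samples, a scale chosen so a full simulate–train–evaluate cycle runs in
  minutes on one CPU core.

## Known limitations

- Detection without a reference works by memorizing the training
  references; the model cannot flag mutations in sequence contexts it has
  never seen, and the simulator's uniform random references make the
  memorization task *harder* than real gene panels (no motif structure to
  compress).
- At desk scale the SNV-recovery task has a long optimization plateau:
  at the default learning rate (5e−4) and a few thousand Adam steps the
  model stays in the all-normal regime (mutation-class F1 = 0 despite a
  falling loss), while the README's worked-example configuration (10×
  learning rate, 60 epochs) lifts the same architecture to SNV F1 ≈ 0.73
  with AUC ≈ 0.97. The per-epoch history written by `tcncall train`
  makes the plateau directly visible.
- The causal (left-only) convolution is kept for architectural fidelity
  even though per-base labeling is an offline task where a bidirectional
  context would be strictly more informative.
- No quality scores, no k > 6, no reverse-complement handling, no GPU.
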