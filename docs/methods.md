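# Methods

## Problem and model

`casminer` addresses discovery and rational engineering of Cas9 nucleases
from protein sequence alone. Cas9 orthologs perform nearly identical
RNA-guided DNA cleavage while sharing little pairwise sequence identity, so
homology search misses distant family members. The package instead trains a
binary sequence classifier whose negative class is manufactured from the
positive class itself: each positive sequence is partially shuffled, which
exactly preserves amino-acid composition while destroying positional
features. A model that separates the two classes has therefore learned
order-dependent sequence characteristics rather than composition.

### Shuffled negatives

For a shuffle threshold p ∈ [0, 1] and a sequence of length L,
`round(p·L)` positions are drawn uniformly without replacement and the
residues at those positions are rearranged by a uniform random permutation
(a selected position may keep its residue; a derangement is not forced).
This is the simplest contract that exactly preserves the residue multiset,
and it makes the expected fixed-point count of a full shuffle (p = 1) equal
to 1, which the tests verify by simulation. Scattered-position selection is
used; contiguous-block shuffling is not implemented. Per-sequence seeds are
derived from SHA-256 of `(base_seed, sequence id)` so a dataset's content
does not depend on record order. One negative is generated per positive
(balanced classes). The default sweep runs p = 0.1 … 1.0 in steps of 0.1,
yielding ten negative datasets; the operating threshold used by the mining
model is p = 0.8.

### Classifier

The classifier is a CNN-LSTM: token embedding (width 32, 26-token alphabet
of the 20 standard residues, X/B/Z/U/O and PAD) → two same-padded 1-D
convolution blocks (64 filters, kernel 7, ReLU, max-pool 4) → a
length-masked LSTM (64 units) whose hidden state at each sequence's last
valid frame feeds a dense ReLU layer (32) and a sigmoid scalar. An
alternative readout (`lstm_pooling="mean"`) averages the hidden states over
valid frames instead: it attributes credit position-symmetrically (useful
when studying fingerprints) but converges noticeably later on the synthetic
task because each frame's gradient is diluted by the average, so the
final-state readout remains the default. Training
minimises binary cross-entropy with Adam (learning rate 1e-3, batch 32,
20 epochs by default), with an 80/20 stratified train/test split. The
network is implemented directly in NumPy with hand-written forward and
backward passes; gradient correctness is verified against central finite
differences in the test suite (exactly, in float64, away from pooling
ties — at tied max-pool inputs, which arise systematically in padded
regions, backpropagation returns one valid subgradient of the several).

Padding is inert by construction: the PAD embedding row is frozen at zero
and the LSTM is masked by true sequence length, so a prediction depends
only on the real residues. This also allows batches to be cropped to the
longest member (plus a receptive-field margin) without changing any score,
which is how training at capacity 1820 stays tractable on one CPU.

Sequences longer than the 1820-residue capacity are truncated with a
warning rather than rejected; mining inputs are pre-filtered to ≤1600
residues, so truncation only affects out-of-window queries.

### Evaluation battery

`evaluate()` thresholds scores at a cutoff (default 0.5, strict `>`,
matching the ">50%" reporting convention) and derives accuracy, precision
(reported as 0 with a warning when nothing is predicted positive), recall,
F1 and AUC. AUC is the Mann-Whitney rank statistic with ties counted 0.5
(computed via scikit-learn); the tests cross-check it against brute-force
pairwise concordance.

### Grad-CAM fingerprints

Saliency targets the last convolutional layer's post-ReLU activations
(before its pool). Channel weights are the position-averaged gradients of
the positive logit; the weighted channel sum is clipped at zero,
interpolated linearly from conv-frame centres back to residue coordinates,
and min-max normalised to [0, 1] (an all-zero map stays zero). Peaks are
local maxima exceeding mean + z·std (default z = 2) with closer maxima than
`min_separation` (default 20 residues) suppressed in favour of the higher;
a flat track yields no peaks. The peak criterion is this package's
algorithmic substitute for what is otherwise a visual judgement.

### Mining cascade

External tools provide the inputs: Pfam domain hits (HMMER) and CRISPR
repeat counts enter as a TSV. Stages: (1) keep lengths in [800, 1600]
(inclusive); (2) partition into 100-residue bins, half-open `[lo, lo+w)`
with a closed final bin, labelled inclusively (`1301-1400` for the bin
starting at 1300) to match conventional reporting; (3) choose the bin with
the most records carrying ≥3 distinct Cas9-related domains (RuvC_III,
Cas9_BH, Cas9_REC, HNH_4, Cas9_PI; repeated hits of one domain count once;
ties go to the longer bin with a warning); (4) score the chosen bin,
reporting the count at strictly >0.5 and keeping scores ≥0.9; (5) among
survivors with strictly more than 50 repeats near the locus (records with
no repeat annotation are excluded with a log message), rank by score
descending. Scores may come from a fitted model or from a precomputed
column in the table, which is also what makes the cascade enumerable by
hand in tests.

### Mutation design

Given an aligned homolog family (aligned FASTA; alignment construction is
standard external tooling), two matrices are built over reference
coordinates:

* **Conservation (PSAP)**: P[s, a] = (count of residue a in the column
  aligned to s + α) / (countable residues in the column + 20α), default
  α = 1. Gaps and non-standard letters are excluded from the counts; an
  uncountable column becomes uniform with a warning.
* **Characteristic matrix**: each homolog is fingerprinted on its ungapped
  sequence; saliency is projected through the alignment, and C[s, a] is the
  mean saliency of homologs carrying a at s, defined only where at least
  `min_support` (default 3) homologs support the pair. Core sites are
  positions whose across-homolog mean saliency reaches the 75th percentile.

For every candidate (core site s, mutant a ≠ wild type) with both C values
defined, Diff scores are matrix-level differences (mutant − wild type).
Candidates are ranked by each Diff separately (descending; ties share the
minimum rank) and the total ranking score is the sum of the two ranks;
designs with a total strictly below the cutoff (default 30) are reported in
`wtPOSmut` notation. Two genuinely open choices are resolved here and
flagged: the total is the *sum of ranks* (not a rank of a combined score),
and Diffs are matrix-level differences rather than in-silico mutagenesis
rescoring; the module surface leaves the latter open as an extension point.

## Synthetic data

The generator stands in for external resources (UniRef positive sets,
genome annotation tables, homolog families) and defines the conditions the
tests run at:

* **Positives**: background residues drawn i.i.d. (uniform by default; a
  Swiss-Prot-like composition preset is available) with three fixed
  10-residue motifs planted at relative positions 0.10/0.50/0.85 with ±25
  residue jitter — the learnable analogue of catalytic and binding
  segments. Motif spans are recorded as ground truth. The full-scale
  fixture is 400 positives of 800-1200 residues.
* **Homolog families**: indel-free point-substituted copies of a reference
  (per-position rate `sub_rate`, one-tenth of it at designated conserved
  positions, uniform over the 19 alternatives), so the column map is the
  identity and matrix logic is isolated from alignment artifacts.
* **Mining tables**: a "campaign-shape" table whose dominant bin, score
  boundaries (0.5/0.9) and repeat boundaries (49/50/51/56, with one
  unannotated top scorer) make every cascade stage enumerable by hand.

What passing on these fixtures does *not* show: real Cas9 discrimination
involves correlated motifs, domain architecture and length structure far
richer than i.i.d. background plus planted words; the fixtures validate the
machinery (learning, attribution, filtering, ranking), not biological
performance. One behaviour specific to the synthetic task deserves note:
because any single planted motif suffices for perfect classification,
gradient descent has no pressure to learn all three, and with the
final-state readout the saliency concentrates on the motif nearest the
sequence end. Saliency inside motif spans still dominates saliency outside
them (the unit suite asserts this), but a sharp, exclusive concentration of
the very top saliency positions onto the 3% of residues the motifs occupy
is not achievable here: with three 10-residue motifs in an 800-1200-residue
sequence the top-5% position set is larger than the motif mass itself, so
even a perfectly concentrated map tops out near 60% in-span — and honest
conv-resolution attribution necessarily spreads beyond the spans. Training on 20%-shuffled negatives, where planted motifs
survive largely intact in both classes, sits near chance on the synthetic
task — consistent with the monotone accuracy-versus-threshold trend the
acceptance suite asserts, which compares means over three seeds at
p ∈ {0.2, 0.5, 1.0}.

## Numerical choices and problem sizes

* float32 parameters and activations; losses and metrics in float64.
* Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8); Glorot-uniform initialisation;
  LSTM forget-gate bias initialised to 1.
* Default 20 epochs: on the synthetic task the loss typically breaks
  through between epochs 6 and 12 depending on the shuffle threshold, and
  the remaining epochs consolidate; the count is overridable wherever a
  config is accepted.
* All randomness flows from explicit integer seeds; sub-seeds are SHA-256
  derivations, keeping runs reproducible and order-independent.
* Test suite problem sizes: the heavy checks train nine models (three
  thresholds × three seeds) at the full 400+400 / 800-1200-residue fixture;
  unit tests use a miniature 120+120 / 150-220-residue fixture that trains
  in seconds.
* `scripts/acceptance.py` trains once at p = 0.8 (the mining model's
  operating threshold) on the full-scale fixture and recomputes every
  reported quantity from scratch under the given seed.

## Known limitations

* The architecture and training protocol are this package's own defaults;
  they are deliberately small, CPU-friendly stand-ins, not a claim about
  any particular published model's hyper-parameters.
* No GPU path, no pretrained embeddings, no multi-class (Cas12/Cas13) head.
* Profile-HMM search, CRISPR-array detection, MSA construction and
  structure-based analyses are out of scope; their outputs are inputs here.
* Characteristic-matrix support depends on family size and divergence:
  small or highly conserved families legitimately produce few or no
  design candidates.
* The sum-of-ranks design filter only admits candidates when the saliency
  and conservation rankings agree near their tops. On the synthetic
  homolog family the two Diff rankings are essentially independent, so
  with thousands of candidates the default cutoff of 30 typically admits
  none — the script reports the candidate count and the best total rank
  alongside, and a curated real family with correlated structure is where
  the filter becomes selective.
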