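# Methods

## Corpus preparation

Input is plain text (one utterance per line, one file per document) with
a TSV sidecar giving the age in months of the child each document was
addressed to. Utterances are lower-cased and split on whitespace;
sentence-boundary punctuation (`. ! , ?`) stays in the corpus as
standalone tokens, a crude stand-in for the pauses and prosody that mark
utterance boundaries. A user-supplied alias table regularizes spelling
variants, and proper names are replaced by the gender tokens FNAME /
MNAME. Morphological splitting is a deliberately simple rule: plural
(-s/-es), possessive (-'s/-s'), diminutive (-ie/-y), past (-ed) and
progressive (-ing) endings are split off as tokens of their own, but
only when the candidate stem is attested in a supplied stem lexicon —
this blocks nonsense splits like *is → i -s* without a real parser. The
splitter is pluggable; anything producing token sequences can replace it.

The vocabulary keeps the most frequent word types up to a size limit
(reference setting 4096), with frequency ties broken lexicographically
so builds are deterministic. Reserved symbols occupy inventory slots:
UNKNOWN (all out-of-vocabulary tokens map to it, and it carries their
total frequency mass so vocabulary frequencies sum to the corpus token
count) and BOUNDARY (left-context padding for stream-initial windows).
Keeping reserved symbols inside the limit means a model built on the
vocabulary has exactly `size_limit` input/output units. The train/test
split is at document level (no document straddles the split), seeded,
and both halves keep age ordering. The encoded, age-ordered training
stream is cut into `n` equal partitions of `floor(N/n)` tokens;
remainder tokens are dropped and the count reported (at the reference
scale, 5,244,672 tokens / 256 partitions = 20,487 exactly, no drop).

## The learners

All weights initialize from a truncated normal with parameter sd `1/m`,
`m` the number of units in the layer above (hidden matrices `1/H`,
output matrices `1/V`), redrawn beyond ±2 sd; note the resulting sample
sd is 0.8796/m, the standard truncated-normal shrinkage. Output biases
(and LSTM gate biases) start at zero.

**Windows.** For every corpus word the recurrent models see a sequence
of at most 7 tokens — the word and its six predecessors — from a reset
hidden state, and predict the next word; the cross-entropy −ln p(target)
is taken at the final step only, so there is exactly one prediction
error per corpus word. (A variant computing the loss at every window
step is a plausible alternative reading; the final-step form is the
default because one error per word matches the mini-batch accounting of
"64 words per update".) Stream-initial windows are left-padded with
BOUNDARY.

**SRN.** `h_t = tanh(W_in·onehot(x_t) + W_rec·h_{t-1})`, output softmax
with max-subtraction stabilization. **LSTM.** Classic gate set — input,
forget, output sigmoid gates and a tanh candidate, all affine in
[current input, previous output]; cell `c_t = f⊙c_{t-1} + i⊙tanh(g)`,
output `h_t = o⊙tanh(c_t)`. No peephole connections; the forget-bias
offset is configurable and defaults to 0. Backpropagation is truncated
at the window (≤ 7 steps). Both backward passes are verified against
central finite differences to a relative error of 1e-4, which is the
central correctness oracle of the package.

**Skip-gram.** Input/output embedding tables; (center, context) pairs
within a symmetric ±3 window; negative-sampling objective
`−log σ(u·v) − Σ log σ(−u_neg·v)` with k = 5 negatives drawn from the
unigram distribution raised to 0.75, redrawn when a draw collides with
the true context word. No frequent-word subsampling by default (its
required foreknowledge of corpus statistics is cognitively implausible);
learning rate decays linearly from 0.025 to 1e-4 over 20 epochs
(reference setting). Negative sampling is used rather than hierarchical
softmax; the two are reported to perform equivalently for this task and
negative sampling is simpler to state and test.

## Training regime

Partitions are presented in the block-repetition order 1,1,1,1,2,2,2,2,…
(`local_iterations` repetitions each, in age order), modelling day-level
consolidation rather than whole-corpus epochs. `local_iterations` has no
canonical value and must be set explicitly; tests and examples use the
worked-example value 4 or a scaled-down 2. Updates use Adagrad
(ε = 1e-8, accumulators never reset) on the *mean* gradient over
mini-batches of 64 windows; batch means are exact, so mini-batch size
trades speed for nothing qualitative (verified down to size 1).
Replicates differ only in the initialization/training seed; runs are
bit-reproducible single-threaded under a fixed seed.

## Representations and evaluation

Contextual representations: the trained model re-reads the corpus with
frozen weights; the hidden state at the end of every window anchored at
(i.e. ending with) a word is cached, and the word's vector is the mean
over its occurrences. Words that never occur are flagged undefined and
excluded downstream. Skip-gram representations are input-embedding rows.

Similarity is the Pearson correlation of representation vectors
(Spearman-like alternatives can be computed from the representation
matrix directly, but Pearson is the package's definition). Inter-model
reliability correlates two models' flattened probe-by-vocabulary
similarity matrices, excluding self-pairs (row word = column word),
which are identically 1 and uninformative.

The balanced-accuracy sweep enumerates thresholds 0.0…1.0 in steps of
0.001. Per probe, against every other probe: same-category pairs with
S > r are hits, otherwise misses; different-category pairs with S > r
are false alarms, otherwise correct rejections. Ties S = r classify as
"different", consistent with the strict inequality for hits. Negative
correlations fall below every grid threshold and are therefore always
"different". Sensitivity and specificity are per-probe (each unordered
pair contributes to both its endpoints' counts), and the reported score
is the across-probe mean balanced accuracy at the single global
threshold maximizing it — per-probe optimal thresholds are not used.
Chance is 0.5 by construction; with a finite grid and finite probe set
the best-threshold selection adds a small optimism (≈ +1 point at 100
probes, < +0.5 at 720).

Category-level structure averages probe-pair similarities within and
between categories after removing the self-similarity diagonal;
singleton categories get an undefined within-cell. Hierarchical
clustering is agglomerative with average linkage on distance 1 − S
(no linkage is canonical for this analysis; average linkage is the
common default for similarity heatmaps), with SciPy's deterministic
leaf ordering. PCA centers but does not scale the word-by-hidden-unit
matrix, since hidden units share one activation range. t-SNE plots
delegate to scikit-learn and are explicitly non-deterministic, so they
are a visualization convenience, not a tested computation.

Perplexity is exp(mean −ln p(word | its 7-token window)) with windows
built exactly as in training. A perfect predictor scores 1; an
untrained model over a 4096-symbol inventory is near-uniform and scores
≈ 4096 (the initialization makes logits O(1e-3)).

## The synthetic generator

The generator emulates the features of child-directed speech that the
pipeline depends on: Zipfian unigram frequencies over target words
(sampling probability ∝ rank^(−a)), short punctuation-terminated
utterances, age-ordered documents (ages are document indices), and —
the planted ground truth — semantic categories realized as pools of
lexical frames (utterance templates with one slot) shared by all
members of a category. Substitutability within a frame pool is exactly
the signal a sequence predictor can learn. `frame_overlap` shares
frames across categories, `polysemy_rate` assigns words to two
categories' frames, and `age_drift` linearly interpolates each
category's frame mixture between an early- and a late-biased mixture
across document age. Frames are finite templates rather than a grammar:
sufficient to create substitutability structure and cheap to verify by
brute force — a bag-of-contexts nearest-centroid classifier recovers
the planted categories perfectly at zero noise and serves as the oracle
trained models are compared against.

What the generator does **not** emulate: syntax (agreement, recursion,
embedding), referential grounding, discourse structure, or the lexical
statistics of real child-directed speech beyond the Zipf law. Passing
tests on synthetic corpora therefore show that the implementation
learns and measures what it claims under known conditions — not that
real speech to children contains the same signal at the same strength.

## Scaled-down test conditions

The full-scale conditions (4096-word vocabulary, 512 hidden units,
5.2M training tokens, 256 partitions, 10 replicates) need hours of
training. The test suite's end-to-end analogue uses the generator's
default easy setting — 10 categories × 8 words, zero overlap, ~200k
tokens — with a 1024-slot vocabulary, hidden size 64, 8 partitions,
2 local iterations, 2 SRN + 2 LSTM replicates and one 5-epoch
Skip-gram. These sizes were chosen once as the smallest configuration
at which the qualitative results are comfortably stable: all models
reach balanced accuracy well above 0.8, within-architecture replicate
reliability exceeds cross-architecture reliability, and the
category-averaged similarity matrix is diagonally dominant.

## Numerical notes and limitations

* Softmax uses max subtraction; sigmoids are computed via tanh for
  symmetric saturation behaviour.
* Vocabulary frequency ties break lexicographically; nearest-neighbor
  similarity ties break lexicographically; the best sweep threshold
  ties break toward the lowest threshold.
* Degenerate inputs fail loudly: empty test sets, singleton clustering,
  zero-variance representation vectors (NaN similarity plus a warning),
  out-of-range token ids.
* Pure-NumPy training is single-threaded-deterministic but slow at full
  scale; the package is built for exactness and inspectability, not
  throughput.
* Document-level splitting with few documents can make the realized
  test fraction coarse; the splitter clamps to at least one document on
  each side.
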