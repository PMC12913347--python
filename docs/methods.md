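# Methods

## Phonological similarity

Both transcriptions pass through the same normalization before edit
counting. Unicode canonical decomposition (NFD) is applied first so
precomposed accented vowels and base + combining sequences behave
identically; all combining marks and the suprasegmental/delimiter set
(ˈ ˌ ː ˑ . | ‖ ties, slashes, brackets, spaces) are dropped, so a
stressed vowel counts as exactly one phoneme. The eight English
diphthongs are then replaced — longest match first, left to right,
non-overlapping — by the reserved digits 1–8 in the order
/aɪ aʊ eɪ oʊ ɔɪ ɪə eə ʊə/. Affricates written as two characters (/tʃ/,
/dʒ/) are counted as written; they are not collapsed.

The edit distance is the standard two-row dynamic program over phoneme
symbols (unit costs for insertion, deletion, substitution). Similarity is
`1 − d / max(len_T, len_R)`, kept at full float precision internally and
rounded to 4 decimal places only in file output. Both transcriptions
empty is an error (the ratio is undefined); one empty transcription
yields similarity 0.

The division by the longer transcription is what makes the measure
length-fair: ten mismatching phonemes in an eleven-phoneme pair
(telescope/hippopotamus, similarity 0.09) no longer look "similar" the
way shared-phoneme counting rules would have it, while a transposition in
a three-phoneme pair (top/pot, 0.33) still clears a sensibly trained
cutoff.

## Semantic similarity

Cosine similarity over an embedding lexicon exposed as an interface
(`dimension`, membership, vector lookup). Two backends ship: an
in-memory lexicon serialized as TSV (used by tests and the simulator) and
a reader for the word2vec text format for pretrained vectors. Candidate
response forms are the response itself, its underscore-joined compound
decomposition when that key exists (all contiguous 2–3 part splits with
parts ≥ 2 characters are tried), and its first-letter capitalization when
that key exists; the reported score is the maximum over candidates. A
configuration flag additionally capitalizes the *target* (off by
default — the worked capitonym usage varies the response). Negative
cosines are legitimate scores and are not clamped; thresholding handles
them. A target missing from the vocabulary is a configuration error
(targets are test items); a response with no scoreable variant is a
nonword and skips semantic evaluation entirely.

## Lexical knowledge

Synonymy, sense inventories, and the hypernym DAG sit behind one
`LexicalKB` structure loadable from JSON. "Predominantly a noun" is
operationalized as *the first-listed (most frequent) sense is a noun*.
The lowest common hypernym of two noun senses is the deepest common
ancestor (depth = longest path to a root); the hierarchy tag fires if any
LCH lemma equals the target (HYPONYM) or, checked second, the response
(HYPERNYM), across all noun-sense pairs. Identity and co-lemmas of a
shared synset return no hierarchy link: those pairs are synonyms and the
cascade catches them one step earlier. The packaged fixture KB
(~60 words) intentionally reproduces a known resource quirk: *plant* and
*flower* join only at the overly broad node *whole*, so no
hypernym/hyponym link is detected for that pair.

## Thresholds and training

Human tags collapse to binary standards as described in the README; R
and NR trials carry no label on either dimension (correct responses are
short-circuited before scoring; non-responses are excluded first), and
nonword tags are excluded from the semantic standard only. Grid search
is vectorized over the full 1001-point grid; the accuracy curve is
retained and exportable. Ties break toward the smallest threshold, which
makes results reproducible and, on separable data, lands at the bottom of
the separability gap. Binarization is inclusive (≥) on both dimensions;
the phonological side mirrors the semantic rule for consistency.

## Cross-validation

Tenfold partitioning uses a seeded shuffled K-fold (sizes differ by at
most one); subject- and item-level leave-one-out group all trials of a
participant or a target word into one fold each, ordered by sorted unit
label (deterministic, no seed). Per fold, thresholds are retrained on the
held-in trials and agreement is computed on both partitions; a fold whose
training partition yields an empty binary standard is an error rather
than a silent skip. The cross-dataset mode applies each training fold's
thresholds to the entirety of a second dataset. Machine-only hierarchy
tags are mapped to S for agreement with human codes (human coders have no
such category); a strict mode disables the mapping. The default
tenfold seed is 20260217.

## The simulator

`SimSpec` defaults describe a single pass of a 38-participant, 175-item
battery; tests use smaller slices (typically 4–6 subjects × 25–40 items
× 1–2 repetitions, and 10 seeds for the noisy-recovery check) to keep
runtimes in seconds. Response categories are drawn from a fixed mixture —
R .55, S .13, F .08, M .06, U .08, N .06, NU .04, a realistic aphasic
naming profile adopted once as the package's own choice.

Each item owns a planted cluster {target, mixed neighbour, semantic
neighbour}; all formal and unrelated distractors share one extra cluster.
Embedding vectors are `sqrt(w)·cluster_axis + sqrt(1−w)·private_axis`
with `w ~ within_cos ± jitter` (defaults 0.75 ± 0.04), so within-cluster
cosines concentrate near 0.75 and between-cluster cosines are exactly 0;
an infeasible margin (`within − jitter < margin`) raises at construction.
Words are vowel-final CV pseudo-words with a one-to-one letter↔IPA map
drawn from two disjoint phoneme inventories: phonological neighbours are
single-phoneme edits of the target (similarity ≥ 0.6 at the lengths
used), phonologically unrelated material comes from the other inventory
(similarity exactly 0). Generated orthographies are constrained to be
lemmatization fixed points so a CSV round trip cannot change a word's
vocabulary status. The planted generative thresholds default to
s\* = 0.40 and p\* = 0.25, inside both separability gaps, and every
constructed response is checked against them at generation time. Label
noise, when requested, replaces the human tag with a different uniformly
drawn category using a dedicated RNG stream, so the same seed yields the
same underlying trials with and without corruption.

What the simulator does *not* emulate: graded, overlapping similarity
distributions (real semantic and phonological scores are continuous and
non-separable, which is why real-data agreement plateaus near 90% rather
than 100%), homophone diversity, visual errors and descriptions,
participant severity profiles, or session effects. Passing tests on
simulated data therefore demonstrate correctness of the machinery —
scoring, thresholding, cascade, cross-validation — not field accuracy on
clinical data.

## Numerical and test-scale choices

- Edit-distance verification runs the memoized recursive oracle
  exhaustively over all string pairs up to length 3 on a 4-symbol
  alphabet, plus a 5,000-pair seeded sample at lengths 4–6; the full
  length-≤6 cross product (≈30M pairs) adds no distinct structure.
- The noisy-recovery check uses 10 seeds × 480 trials; the test asserts
  the grand mean lies within 3 standard errors of the expected 1 − q.
- Fold-size assertions at study scale (22,649 trials) run on lightweight
  synthetic records, since only the partitioner is exercised.
- Scores are compared at full precision internally; printed values are
  rounded to 2 (worked examples) or 4 (file output) decimals.

## Limitations

- The lemmatizer is rule-based (regular plurals plus a small irregular
  table), adequate for single-word naming responses, not a general
  lemmatizer.
- The compound splitter enumerates contiguous splits and relies entirely
  on the vocabulary to validate them; it has no frequency prior.
- Suprasegmental stripping covers the common marks; transcription systems
  using additional diacritics may need the set extended.
- Semantic scores inherit their backend's biases: homophones with diverse
  contexts (e.g. *cross*) dilute similarity, and taxonomy gaps in the
  knowledge base propagate to hierarchy tags.
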