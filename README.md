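# paracoder

Automated coding of single-word speech errors (paraphasias) in English
picture-naming data.

## The problem

In picture-naming tests — widely used with individuals with aphasia —
each response is classified into one of seven standard categories:
correct (R), semantic error (S, *dog* for *cat*), phonological/formal
error (F, *mat* for *cat*), mixed error (M, *rat* for *cat*), unrelated
word (U, *bread* for *cat*), phonologically related nonword (N, *cak*),
and phonologically unrelated nonword (NU, *choko*), plus a non-response
code (NR). Manual coding is slow, rule-bound, and subjective. `paracoder`
automates it with a data-driven approach: two continuous similarity
scores, two trained thresholds, and a deterministic decision cascade.

## The model

**Semantic similarity** is the cosine between word-embedding vectors of
target and response over a pluggable lexicon (a 300-dimensional
corpus-trained model in production; a deterministic planted-cluster
lexicon for tests and simulation). A response missing from the vocabulary
is a nonword and is routed to phonology only.

**Phonological similarity** is the complement of the length-normalized
Levenshtein distance between IPA transcriptions:

    PhonSim(T, R) = 1 − L_d(IPA_T, IPA_R) / max(len(IPA_T), len(IPA_R))

where `L_d` counts minimum single-phoneme insertions, deletions and
substitutions. Before comparison each transcription is normalized so one
symbol = one phoneme: stress/length diacritics are stripped and the eight
English diphthongs (/aɪ/, /aʊ/, /eɪ/, /oʊ/, /ɔɪ/, /ɪə/, /eə/, /ʊə/) are
each collapsed to a single placeholder, so /laɪt/ → `l1t` (3 phonemes).

**Thresholds.** A semantic cutoff *s* and a phonological cutoff *p*
binarize the scores (related iff score ≥ cutoff). Both are trained by
exhaustive grid search over 1001 values (0 to 1, step 0.001) against
human-coded binary standards: S/M count as semantically related vs F/U
unrelated; F/M/N as phonologically related vs S/U/NU unrelated.

**The cascade** assigns one tag per trial, first match wins:
onomatopoeia → NR; synonym/identity → R; hypernym/hyponym via the lowest
common hypernym of noun senses → HYPERNYM/HYPONYM; out-of-vocabulary
response → N or NU by the phonological decision; otherwise the
(semantic, phonological) decisions map (Y,N)→S, (N,Y)→F, (Y,Y)→M,
(N,N)→U. Compound responses ("cheesecake"/"cheese_cake") and capitonyms
("father"/"Father") are scored in all surface variants, keeping the max.

**Validation.** Tenfold, subject-level leave-one-out, and item-level
leave-one-out cross-validation (plus a cross-dataset mode) retrain
thresholds per fold and report train/test agreement with the human tags.

## Worked example

```python
>>> from paracoder import phon_similarity
>>> r = phon_similarity("kæt", "kɪ́tən")   # cat -> kitten
>>> r.distance, r.max_len, round(r.similarity, 4)
(3, 5, 0.4)
```

Three edits turn /kæt/ into /kɪtən/ (the stressed vowel counts once);
normalizing by the longer transcription (5 phonemes) gives
1 − 3/5 = **0.40**.

End to end, on a simulated dataset (the generator plants separable
semantic clusters and phoneme-edit neighbours, so a correct coder can
reach perfect agreement):

```bash
$ paracoder simulate --seed 11 --subjects 4 --items 30 --out-dir demo
simulated 120 trials -> demo
$ paracoder train --trials demo/trials.csv --embeddings demo/lexicon.tsv \
      --kb demo/kb.json --out demo/thresholds.json
semantic: threshold=0.001 agreement=1.0000
phonological: threshold=0.001 agreement=1.0000
thresholds -> demo/thresholds.json
$ paracoder crossval --trials demo/trials.csv --scheme subject \
      --embeddings demo/lexicon.tsv --kb demo/kb.json --out demo/cv.json
subject: mean test accuracy 1.0000 (range 1.0000-1.0000) -> demo/cv.json
```

The trained thresholds land at the bottom of the planted separability gap
(ties break toward the smallest grid point), classify both binary
standards perfectly, and every held-out subject's tags agree with the
simulated human codes. `paracoder code` then applies trained thresholds
to any trial CSV, writing per-trial scores, Y/N decisions, the final tag,
and the cascade rule that fired.

To run against pretrained vectors, pass `--embeddings model.txt
--word2vec` (word2vec text format) and supply your own knowledge base
JSON; the packaged fixtures keep everything runnable offline.

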