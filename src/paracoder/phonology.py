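"""IPA normalization and length-normalized Levenshtein phonological similarity.

A response is phonologically compared to its target on the phoneme level:
both IPA transcriptions are normalized so that each phoneme occupies exactly
one symbol (diphthongs collapsed, stress/length diacritics stripped), then
the minimum single-symbol edit count (insertions, deletions, substitutions)
is divided by the length of the longer transcription and subtracted from 1:

    PhonSim(T, R) = 1 - L_d(IPA_T, IPA_R) / max(len(IPA_T), len(IPA_R))

giving a similarity in [0, 1], where 1 means identical pronunciations.
Normalizing by length removes the bias that lets long words accumulate
coincidental phoneme overlap, and the edit model is position-sensitive: a
phoneme that migrates between syllable positions costs two edits while an
in-place mismatch costs one.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass
from typing import Sequence, Union

__all__ = [
    "DIPHTHONGS",
    "PhonComparison",
    "PhonemeSequence",
    "levenshtein",
    "normalize_ipa",
    "phon_similarity",
]

# The eight primary English diphthongs. Each functions as a single phoneme
# and is collapsed to one reserved placeholder digit before edit counting,
# so /laɪt/ becomes the 3-symbol string "l1t".
DIPHTHONGS: tuple[tuple[str, str], ...] = (
    ("aɪ", "1"),
    ("aʊ", "2"),
    ("eɪ", "3"),
    ("oʊ", "4"),
    ("ɔɪ", "5"),
    ("ɪə", "6"),
    ("eə", "7"),
    ("ʊə", "8"),
)

# Suprasegmental / delimiter characters that do not count as phonemes:
# primary and secondary stress, length marks, syllable breaks, ties, and
# the slashes and brackets that sometimes delimit transcriptions.
_STRIP_CHARS = set("ˈˌːˑ.|‖‿͜͡/[] ()")


@dataclass(frozen=True)
class PhonemeSequence:
    """An IPA transcription normalized to one symbol per phoneme.

    ``raw`` is the string as supplied; ``symbols`` is the normalized
    sequence after diacritic stripping and diphthong collapsing.
    """

    raw: str
    symbols: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(self.symbols)


@dataclass(frozen=True)
class PhonComparison:
    """Edit distance and normalized similarity for one IPA pair."""

    distance: int
    max_len: int
    similarity: float


def normalize_ipa(raw: str) -> PhonemeSequence:
    """Normalize an IPA string to a sequence of atomic phoneme symbols.

    Canonical (NFD) decomposition is applied first so precomposed and
    combining accented vowels behave identically; combining diacritics and
    suprasegmental marks are then stripped (a stressed vowel counts as one
    phoneme), and finally each of the eight diphthongs is replaced by its
    single-digit placeholder, longest match first, left to right.

    An empty input yields an empty sequence.
    """
    decomposed = unicodedata.normalize("NFD", raw)
    kept = [c for c in decomposed if not unicodedata.combining(c) and c not in _STRIP_CHARS]
    text = "".join(kept)
    for digraph, placeholder in DIPHTHONGS:
        text = text.replace(digraph, placeholder)
    return PhonemeSequence(raw=raw, symbols=tuple(text))


def _symbols(x: Union[PhonemeSequence, Sequence[str], str]) -> Sequence[str]:
    if isinstance(x, PhonemeSequence):
        return x.symbols
    return x


def levenshtein(a: Union[PhonemeSequence, Sequence[str], str],
                b: Union[PhonemeSequence, Sequence[str], str]) -> int:
    """Minimum number of single-symbol insertions, deletions and
    substitutions transforming ``a`` into ``b`` (dynamic programming,
    two-row formulation)."""
    sa, sb = _symbols(a), _symbols(b)
    if len(sa) < len(sb):  # iterate over the longer, keep the shorter as row
        sa, sb = sb, sa
    if not sb:
        return len(sa)
    prev = list(range(len(sb) + 1))
    for i, ca in enumerate(sa, start=1):
        curr = [i] + [0] * len(sb)
        for j, cb in enumerate(sb, start=1):
            curr[j] = min(
                prev[j] + 1,        # deletion
                curr[j - 1] + 1,    # insertion
                prev[j - 1] + (ca != cb),  # substitution / match
            )
        prev = curr
    return prev[-1]


def phon_similarity(target_ipa: str, response_ipa: str) -> PhonComparison:
    """Length-normalized phonological similarity of two IPA transcriptions.

    Both inputs are normalized with :func:`normalize_ipa` before the edit
    distance is computed. Raises ``ValueError`` when both transcriptions
    normalize to the empty sequence (the ratio is undefined).

    >>> round(phon_similarity("kæt", "kɪ́tən").similarity, 2)
    0.4
    """
    t = normalize_ipa(target_ipa)
    r = normalize_ipa(response_ipa)
    max_len = max(len(t), len(r))
    if max_len == 0:
        raise ValueError("phonological similarity undefined: both transcriptions are empty")
    d = levenshtein(t, r)
    return PhonComparison(distance=d, max_len=max_len, similarity=1.0 - d / max_len)
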