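"""Configurable word lists and the syllable heuristic (German defaults).

Every list here is a default, not an assertion about the one true inventory:
deployments analysing other corpora swap them via the feature-extraction
config.
"""

from __future__ import annotations

import re

#: Filled-pause forms typical of spoken German transcription.
FILLED_PAUSES = frozenset({"äh", "ähm", "hm", "mhm", "öh", "öhm"})

#: Discourse markers counted as connectives in addition to SCONJ/CCONJ tokens.
DISCOURSE_CONNECTIVES = frozenset({
    "und", "aber", "oder", "denn", "sondern", "doch", "also", "deshalb",
    "deswegen", "trotzdem", "dann", "danach", "außerdem", "jedoch", "weil",
    "obwohl", "während", "dass", "wenn", "als", "damit", "sodass", "bevor",
    "nachdem", "seitdem", "falls",
})

#: Dependency relations marking a subordinate-clause head (with subtypes).
SUBORDINATE_DEPRELS = frozenset({"ccomp", "xcomp", "advcl", "acl", "csubj"})


def is_subordinate_deprel(deprel: str,
                          base_set: frozenset[str] = SUBORDINATE_DEPRELS) -> bool:
    """True for the base relations and their subtyped variants (``acl:relcl``)."""
    return deprel.split(":")[0] in base_set


#: Small negative-affect lexicon for the sentiment fixture.
NEGATIVE_WORDS = frozenset({
    "traurig", "angst", "schlecht", "dunkel", "allein", "einsam", "tot",
    "krank", "schmerz", "weinen", "verloren", "schlimm", "leid", "trauer",
    "wut", "böse", "kalt", "leer", "müde", "hoffnungslos",
})

_VOWEL_GROUP = re.compile(r"[aeiouyäöü]+", re.IGNORECASE)


def count_syllables(word: str) -> int:
    """Vowel-group syllable heuristic.

    German diphthongs and double vowels (``ei``, ``au``, ``eu``, ``ie``, ...)
    are contiguous vowel letters, so counting maximal vowel groups treats them
    as one syllable.  Words without vowels (digits, fragments) count as one.
    """
    return max(1, len(_VOWEL_GROUP.findall(word)))
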