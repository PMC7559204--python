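"""Lancaster (Paice/Husk) stemmer: an iterative suffix-stripping rule engine.

The Lancaster stemmer reduces English words to short, aggressive stems
("ulcerative" -> "ulc", "colitis" -> "colit", "diabetes" -> "diabet") by
repeatedly applying suffix-rewrite rules until a terminating rule fires or no
rule applies.  Each rule is keyed by the final letter of the current word and
says: if the word ends with this suffix (and, for *intact* rules, has not been
rewritten yet), remove N characters, append a replacement, and either continue
stemming or stop.  A rewrite is only performed if the resulting stem is
*acceptable*: a stem starting with a vowel must keep at least 2 letters; one
starting with a consonant must keep at least 3 and contain a vowel early on
('y' counts as a vowel here).

The default rule set pinned below is the standard published Paice/Husk table
(115 rules).  It is version-pinned data: changing it silently changes every
stem key in a stem->category map built against it, so treat it as frozen.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

__all__ = ["StemRule", "StemRuleSet", "default_rules", "stem_word", "stem_text"]

_VOWELS = "aeiouy"


@dataclass(frozen=True)
class StemRule:
    """One suffix-rewrite rule.

    ``suffix`` is the ending matched (in normal reading order), ``intact``
    restricts the rule to words not yet rewritten, ``remove`` is the number of
    trailing characters dropped, ``append`` the replacement appended, and
    ``cont`` whether stemming continues after this rule fires.
    """

    suffix: str
    remove: int
    append: str = ""
    intact: bool = False
    cont: bool = False

    def __post_init__(self) -> None:
        if not self.suffix:
            raise ValueError("rule suffix must be non-empty")
        if not 0 <= self.remove <= len(self.suffix):
            raise ValueError(f"remove count out of range for suffix {self.suffix!r}")


# The standard Paice/Husk rule table.  Tuples: (suffix, remove, append,
# intact, cont).  Rules are scanned in order within the section keyed by the
# word's final letter; "remove 0" rules act as protectors (they match, change
# nothing, and stop).
_DEFAULT_RULE_TABLE: Tuple[Tuple[str, int, str, bool, bool], ...] = (
    # -a-
    ("ia", 2, "", True, False),
    ("a", 1, "", True, False),
    # -b-
    ("bb", 1, "", False, False),
    # -c-
    ("ytic", 3, "s", False, False),
    ("ic", 2, "", False, True),
    ("nc", 1, "t", False, True),
    # -d-
    ("dd", 1, "", False, False),
    ("ied", 3, "y", False, True),
    ("ceed", 2, "ss", False, False),
    ("eed", 1, "", False, False),
    ("ed", 2, "", False, True),
    ("hood", 4, "", False, True),
    # -e-
    ("e", 1, "", False, True),
    # -f-
    ("lief", 1, "v", False, False),
    ("if", 2, "", False, True),
    # -g-
    ("ing", 3, "", False, True),
    ("iag", 3, "y", False, False),
    ("ag", 2, "", False, True),
    ("gg", 1, "", False, False),
    # -h-
    ("th", 2, "", True, False),
    ("guish", 5, "ct", False, False),
    ("ish", 3, "", False, True),
    # -i-
    ("i", 1, "", True, False),
    ("i", 1, "y", False, True),
    # -j-
    ("ij", 1, "d", False, False),
    ("fuj", 1, "s", False, False),
    ("uj", 1, "d", False, False),
    ("oj", 1, "d", False, False),
    ("hej", 1, "r", False, False),
    ("verj", 1, "t", False, False),
    ("misj", 2, "t", False, False),
    ("nj", 1, "d", False, False),
    ("j", 1, "s", False, False),
    # -l-
    ("ifiabl", 6, "", False, False),
    ("iabl", 4, "y", False, False),
    ("abl", 3, "", False, True),
    ("ibl", 3, "", False, False),
    ("bil", 2, "l", False, True),
    ("cl", 1, "", False, False),
    ("iful", 4, "y", False, False),
    ("ful", 3, "", False, True),
    ("ul", 2, "", False, False),
    ("ial", 3, "", False, True),
    ("ual", 3, "", False, True),
    ("al", 2, "", False, True),
    ("ll", 1, "", False, False),
    # -m-
    ("ium", 3, "", False, False),
    ("um", 2, "", True, False),
    ("ism", 3, "", False, True),
    ("mm", 1, "", False, False),
    # -n-
    ("sion", 4, "j", False, True),
    ("xion", 4, "ct", False, False),
    ("ion", 3, "", False, True),
    ("ian", 3, "", False, True),
    ("an", 2, "", False, True),
    ("een", 0, "", False, False),
    ("en", 2, "", False, True),
    ("nn", 1, "", False, False),
    # -p-
    ("ship", 4, "", False, True),
    ("pp", 1, "", False, False),
    # -r-
    ("er", 2, "", False, True),
    ("ear", 0, "", False, False),
    ("ar", 2, "", False, False),
    ("or", 2, "", False, True),
    ("ur", 2, "", False, True),
    ("rr", 1, "", False, False),
    ("tr", 1, "", False, True),
    ("ier", 3, "y", False, True),
    # -s-
    ("ies", 3, "y", False, True),
    ("sis", 2, "", False, False),
    ("is", 2, "", False, True),
    ("ness", 4, "", False, True),
    ("ss", 0, "", False, False),
    ("ous", 3, "", False, True),
    ("us", 2, "", True, False),
    ("s", 1, "", True, True),
    ("s", 0, "", False, False),
    # -t-
    ("plicat", 4, "y", False, False),
    ("at", 2, "", False, True),
    ("ment", 4, "", False, True),
    ("ent", 3, "", False, True),
    ("ant", 3, "", False, True),
    ("ript", 2, "b", False, False),
    ("orpt", 2, "b", False, False),
    ("duct", 1, "", False, False),
    ("sumpt", 2, "", False, False),
    ("cept", 2, "iv", False, False),
    ("olut", 2, "v", False, False),
    ("sist", 0, "", False, False),
    ("ist", 3, "", False, True),
    ("tt", 1, "", False, False),
    # -u-
    ("iqu", 3, "", False, False),
    ("ogu", 1, "", False, False),
    # -v-
    ("siv", 3, "j", False, True),
    ("eiv", 0, "", False, False),
    ("iv", 2, "", False, True),
    # -y-
    ("bly", 1, "", False, True),
    ("ily", 3, "y", False, True),
    ("ply", 0, "", False, False),
    ("ly", 2, "", False, True),
    ("ogy", 1, "", False, False),
    ("phy", 1, "", False, False),
    ("omy", 1, "", False, False),
    ("opy", 1, "", False, False),
    ("ity", 3, "", False, True),
    ("ety", 3, "", False, True),
    ("lty", 2, "", False, False),
    ("istry", 5, "", False, False),
    ("ary", 3, "", False, True),
    ("ory", 3, "", False, True),
    ("ify", 3, "", False, False),
    ("ncy", 2, "t", False, True),
    ("acy", 3, "", False, True),
    # -z-
    ("iz", 2, "", False, True),
    ("yz", 1, "s", False, False),
)


class StemRuleSet:
    """An ordered Paice/Husk rule table indexed by final letter."""

    def __init__(self, rules: Sequence[StemRule]):
        if not rules:
            raise ValueError("rule set must contain at least one rule")
        self.rules: Tuple[StemRule, ...] = tuple(rules)
        self._by_last_letter: Dict[str, List[StemRule]] = {}
        for rule in self.rules:
            self._by_last_letter.setdefault(rule.suffix[-1], []).append(rule)

    def section(self, letter: str) -> Sequence[StemRule]:
        return self._by_last_letter.get(letter, ())

    def __len__(self) -> int:
        return len(self.rules)


_DEFAULT_RULESET = StemRuleSet(
    [
        StemRule(suffix, remove, append, intact, cont)
        for suffix, remove, append, intact, cont in _DEFAULT_RULE_TABLE
    ]
)


def default_rules() -> StemRuleSet:
    """The pinned standard Paice/Husk rule table."""
    return _DEFAULT_RULESET


def _acceptable(word: str, remove: int) -> bool:
    # Acceptability is judged on the length after removal, with the vowel
    # requirement checked on the leading letters of the pre-removal word.
    if word[0] in _VOWELS:
        return len(word) - remove >= 2
    if len(word) - remove < 3:
        return False
    return word[1] in _VOWELS or (len(word) > 2 and word[2] in _VOWELS)


def stem_word(word: str, rules: StemRuleSet | None = None) -> str:
    """Stem a single token.

    The token is case-folded.  Tokens that are not purely alphabetic (e.g.
    "b12", "b/p") are returned unchanged apart from case folding: the rule
    table is defined over letters only.
    """
    rules = rules or _DEFAULT_RULESET
    word = word.casefold()
    if not word.isalpha():
        return word
    original = word
    while word:
        applied = False
        for rule in rules.section(word[-1]):
            if not word.endswith(rule.suffix):
                continue
            if rule.intact and word != original:
                continue
            if not _acceptable(word, rule.remove):
                continue
            word = word[: len(word) - rule.remove] + rule.append
            applied = True
            if not rule.cont:
                return word
            break
        if not applied:
            break
    return word


def stem_text(text: str, rules: StemRuleSet | None = None) -> str:
    """Stem every whitespace-separated token of *text*, rejoined by spaces.

    Raises
    ------
    ValueError
        If the input is empty or whitespace-only (a rejected record).
    """
    tokens = text.split()
    if not tokens:
        raise ValueError("cannot stem empty text")
    return " ".join(stem_word(token, rules) for token in tokens)
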