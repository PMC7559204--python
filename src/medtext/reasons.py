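"""Reason branch: per-word spell correction, stemming, stem-map lookup, overrides.

Free-text reasons for medication use ("high blood pressure", "ulcerative
colitis") are grouped into organ-system disease categories:

1. each word is spell-corrected against a general-language word list (the
   dictionary word with highest Levenshtein ratio, if that ratio exceeds the
   threshold; otherwise the word is kept);
2. each word is reduced to its Lancaster stem and the stems are rejoined
   ("ulcerative colitis" -> "ulc colit");
3. the whole stem string is looked up in a manually curated stem->category
   map — exact hit first, then fuzzy (requiring BOTH the distance and the
   ratio clause by default, the stricter of the two printed rules);
4. records that map nowhere go to the manual queue; curator-supplied
   raw-text->category overrides are applied last and always win.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .lexicon import LexiconBundle, StemCategoryMap, WordList
from .match import Combinator, MatchPolicy, best_match
from .records import RawRecord
from .stemmer import StemRuleSet, stem_text

__all__ = [
    "ReasonStatus",
    "ReasonMatch",
    "DEFAULT_REASON_POLICY",
    "normalize_reason_text",
    "spell_correct_word",
    "map_reason",
    "apply_overrides",
    "process_reasons",
]

DEFAULT_REASON_POLICY = MatchPolicy(combinator=Combinator.ALL)

# Keep letters, digits and "/" (clinical shorthand like "b/p"); everything
# else becomes a token boundary.
_REASON_CLEAN_RE = re.compile(r"[^a-z0-9/]+")
_ALPHA_RE = re.compile(r"^[a-z]+$")


class ReasonStatus(str, enum.Enum):
    AUTO = "auto"
    MANUAL_QUEUE = "manual_queue"
    OVERRIDDEN = "overridden"


@dataclass(frozen=True)
class ReasonMatch:
    """Outcome of processing one raw reason entry."""

    raw: str
    corrected: str
    stem_string: str
    status: ReasonStatus
    category: Optional[str] = None
    match_distance: Optional[int] = None
    match_ratio: Optional[float] = None
    subject_id: str = ""
    error: Optional[str] = None

    def __post_init__(self) -> None:
        if self.status is ReasonStatus.MANUAL_QUEUE:
            if self.category is not None:
                raise ValueError("manual-queue reason cannot carry a category")
        elif self.category is None:
            raise ValueError(f"{self.status.value} reason must carry a category")


def normalize_reason_text(raw: str) -> str:
    """Case-fold, strip punctuation (keeping '/'), collapse whitespace."""
    return " ".join(_REASON_CLEAN_RE.sub(" ", raw.casefold()).split())


def spell_correct_word(
    word: str,
    wordlist: WordList,
    policy: MatchPolicy = DEFAULT_REASON_POLICY,
) -> str:
    """Spell-correct one token against the general dictionary.

    Dictionary members and non-alphabetic tokens ("b12", "b/p") pass through
    unchanged; otherwise the dictionary word with the highest ratio replaces
    the token if that ratio exceeds the policy's ratio threshold.
    """
    if word in wordlist or not _ALPHA_RE.match(word):
        return word
    result = best_match(word, sorted(wordlist.words), policy.ratio_only())
    return result.candidate if result is not None else word


def map_reason(
    stem_string: str,
    stem_map: StemCategoryMap,
    policy: MatchPolicy = DEFAULT_REASON_POLICY,
) -> Optional[Tuple[str, int, float]]:
    """Look up a stem string in the stem->category map.

    An exact key hit returns its category at distance 0 / ratio 1; otherwise
    the best fuzzy key under the policy (both clauses by default).  Returns
    (category, distance, ratio) or None.
    """
    exact = stem_map.get(stem_string)
    if exact is not None:
        return exact, 0, 1.0
    if not stem_map.entries:
        return None
    result = best_match(stem_string, stem_map.stems, policy)
    if result is None:
        return None
    return stem_map.entries[result.candidate], result.distance, result.ratio


def apply_overrides(
    results: Sequence[ReasonMatch],
    overrides: Mapping[str, str],
) -> List[ReasonMatch]:
    """Apply curator raw-text -> category overrides (curation always wins).

    Override keys are matched against the case-folded, whitespace-collapsed
    raw text.  Idempotent: applying the same overrides twice is a no-op.
    """
    folded: Dict[str, str] = {}
    for key, category in overrides.items():
        if not category:
            raise ValueError(f"override for {key!r} has an empty category")
        folded[" ".join(key.casefold().split())] = category
    if not folded:
        return list(results)
    updated = []
    for result in results:
        key = " ".join(result.raw.casefold().split())
        if key in folded:
            updated.append(
                ReasonMatch(
                    raw=result.raw,
                    corrected=result.corrected,
                    stem_string=result.stem_string,
                    status=ReasonStatus.OVERRIDDEN,
                    category=folded[key],
                    match_distance=result.match_distance,
                    match_ratio=result.match_ratio,
                    subject_id=result.subject_id,
                )
            )
        else:
            updated.append(result)
    return updated


def process_reasons(
    records: Sequence[RawRecord],
    bundle: LexiconBundle,
    policy: MatchPolicy = DEFAULT_REASON_POLICY,
    rules: Optional[StemRuleSet] = None,
    overrides: Optional[Mapping[str, str]] = None,
) -> List[ReasonMatch]:
    """Run the full reason branch over *records*, preserving order.

    Per-record failures (empty reason text) land in the manual queue with the
    error recorded; the batch always completes.
    """
    results: List[ReasonMatch] = []
    for record in records:
        raw = record.reason_raw
        normalized = normalize_reason_text(raw)
        if not normalized:
            results.append(
                ReasonMatch(
                    raw=raw,
                    corrected="",
                    stem_string="",
                    status=ReasonStatus.MANUAL_QUEUE,
                    subject_id=record.subject_id,
                    error="empty reason entry",
                )
            )
            continue
        corrected = " ".join(
            spell_correct_word(tok, bundle.wordlist, policy) for tok in normalized.split()
        )
        stems = stem_text(corrected, rules)
        mapped = map_reason(stems, bundle.stem_map, policy)
        if mapped is None:
            results.append(
                ReasonMatch(
                    raw=raw,
                    corrected=corrected,
                    stem_string=stems,
                    status=ReasonStatus.MANUAL_QUEUE,
                    subject_id=record.subject_id,
                )
            )
        else:
            category, distance, ratio = mapped
            results.append(
                ReasonMatch(
                    raw=raw,
                    corrected=corrected,
                    stem_string=stems,
                    status=ReasonStatus.AUTO,
                    category=category,
                    match_distance=distance,
                    match_ratio=ratio,
                    subject_id=record.subject_id,
                )
            )
    if overrides:
        results = apply_overrides(results, overrides)
    return results
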