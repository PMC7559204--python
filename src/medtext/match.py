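"""Edit-distance core: Levenshtein distance, normalized ratio, and match policies.

The similarity measure used throughout the package is the unit-cost Levenshtein
distance ``lev(a, b)`` (minimum number of single-character insertions, deletions
and substitutions turning *a* into *b*) together with the normalized ratio

    ratio(a, b) = (|a| + |b| - lev(a, b)) / (|a| + |b|)

Note the ratio uses the plain unit-cost distance.  Some fuzzy-matching
libraries (e.g. python-Levenshtein's ``ratio``) charge substitutions a cost of
2 in their normalized similarity; that variant is deliberately NOT used here,
so values computed by this module can differ from those libraries on strings
where substitutions occur.

Acceptance of a fuzzy match is governed by a :class:`MatchPolicy`: a ratio
threshold (strict ``>``), a distance threshold (strict ``<``) and a combinator
saying whether one clause suffices (``ANY``, the drug-matching rule) or both
must hold (``ALL``, the reason-matching rule).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

__all__ = [
    "Combinator",
    "MatchPolicy",
    "MatchResult",
    "levenshtein_distance",
    "levenshtein_ratio",
    "passes_policy",
    "best_match",
]


class Combinator(str, enum.Enum):
    """How the ratio and distance clauses of a policy combine."""

    ANY = "any"
    ALL = "all"


@dataclass(frozen=True)
class MatchPolicy:
    """Thresholds governing acceptance of a fuzzy match.

    Parameters
    ----------
    ratio_threshold:
        Minimum ratio, exclusive: a candidate passes the ratio clause when
        ``ratio > ratio_threshold``.  Default 0.85.
    distance_threshold:
        Distance bound, exclusive: a candidate passes the distance clause when
        ``distance < distance_threshold``.  Default 2 (i.e. distance <= 1).
    combinator:
        ``Combinator.ANY`` accepts when either clause holds (drug rule);
        ``Combinator.ALL`` requires both (reason rule).
    """

    ratio_threshold: float = 0.85
    distance_threshold: int = 2
    combinator: Combinator = Combinator.ANY

    def __post_init__(self) -> None:
        if not 0.0 <= self.ratio_threshold <= 1.0:
            raise ValueError(
                f"ratio_threshold must be in [0, 1], got {self.ratio_threshold}"
            )
        if self.distance_threshold < 0:
            raise ValueError(
                f"distance_threshold must be >= 0, got {self.distance_threshold}"
            )
        if not isinstance(self.combinator, Combinator):
            object.__setattr__(self, "combinator", Combinator(self.combinator))

    def ratio_only(self) -> "MatchPolicy":
        """Variant of this policy whose distance clause can never fire.

        Used for the supplement and word-level spell-check rules, which are
        stated in terms of the ratio alone.
        """
        return MatchPolicy(self.ratio_threshold, 0, Combinator.ANY)


@dataclass(frozen=True)
class MatchResult:
    """Outcome of comparing a query against one candidate string."""

    candidate: str
    distance: int
    ratio: float
    accepted: bool


def levenshtein_distance(a: str, b: str) -> int:
    """Unit-cost Levenshtein distance between two strings.

    Iterative two-row dynamic programming over the standard recursion with
    base case ``max(i, j)`` when ``min(i, j) == 0`` and substitution cost 1
    when the compared characters differ, 0 when they are equal.
    """
    if a == b:
        return 0
    if len(a) < len(b):  # iterate over the longer string's rows
        a, b = b, a
    if not b:
        return len(a)
    previous = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        current = [i]
        for j, cb in enumerate(b, start=1):
            current.append(
                min(
                    previous[j] + 1,  # deletion from a
                    current[j - 1] + 1,  # insertion into a
                    previous[j - 1] + (ca != cb),  # substitution
                )
            )
        previous = current
    return previous[-1]


def levenshtein_ratio(a: str, b: str) -> float:
    """Normalized similarity ``(|a| + |b| - lev(a, b)) / (|a| + |b|)``.

    Ranges over [0, 1]; equals 1 iff the strings are equal.  Two empty strings
    are defined to have ratio 1.0 (they are identical; avoids 0/0).
    """
    total = len(a) + len(b)
    if total == 0:
        return 1.0
    return (total - levenshtein_distance(a, b)) / total


def passes_policy(distance: int, ratio: float, policy: MatchPolicy) -> bool:
    """Whether a (distance, ratio) pair is accepted under *policy*.

    Both comparisons are strict: ratio strictly over the ratio threshold,
    distance strictly under the distance threshold.
    """
    ratio_ok = ratio > policy.ratio_threshold
    distance_ok = distance < policy.distance_threshold
    if policy.combinator is Combinator.ANY:
        return ratio_ok or distance_ok
    return ratio_ok and distance_ok


def best_match(
    query: str,
    candidates: Sequence[str],
    policy: MatchPolicy,
) -> Optional[MatchResult]:
    """Best accepted candidate for *query*, or ``None`` if nothing passes.

    Every candidate is scored; among accepted candidates the winner has
    maximal ratio, ties broken by minimal distance, then by lexicographically
    smallest candidate.  Deterministic and order-independent in the candidate
    list.  Candidates are compared verbatim: case folding and whitespace
    normalization are the caller's responsibility.

    Raises
    ------
    ValueError
        If the candidate list is empty (a configuration error, distinct from
        "nothing matched").
    """
    if not candidates:
        raise ValueError("best_match requires a non-empty candidate list")
    best: Optional[MatchResult] = None
    for candidate in candidates:
        distance = levenshtein_distance(query, candidate)
        ratio = levenshtein_ratio(query, candidate)
        if not passes_policy(distance, ratio, policy):
            continue
        if (
            best is None
            or ratio > best.ratio
            or (ratio == best.ratio and distance < best.distance)
            or (
                ratio == best.ratio
                and distance == best.distance
                and candidate < best.candidate
            )
        ):
            best = MatchResult(candidate, distance, ratio, True)
    return best
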