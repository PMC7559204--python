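"""Fuzzy string matching: Levenshtein distance, ratio, and match policies.

Shows the acceptance rules used throughout the pipeline: a candidate passes
when its ratio strictly exceeds 0.85 OR its distance is strictly under 2
(drug rule), or when BOTH hold (reason rule).
"""

from medtext import (
    Combinator,
    MatchPolicy,
    best_match,
    levenshtein_distance,
    levenshtein_ratio,
)

pairs = [
    ("metoprolol", "metoprold"),
    ("fexofenadine", "fexafenedine"),
    ("vitamin b12", "vitemin b12"),
    ("vitamin b12", "vit b12"),
]
print("pair  ->  distance, ratio")
for a, b in pairs:
    d = levenshtein_distance(a, b)
    r = levenshtein_ratio(a, b)
    print(f"  {a!r} vs {b!r}: distance {d}, ratio {r:.4f}")
# Note the last pair: the abbreviation sits at ratio ~0.78, below the 0.85
# threshold, which is why abbreviations must be lexicon entries of their own.

drug_rule = MatchPolicy()  # ratio > 0.85 OR distance < 2
reason_rule = MatchPolicy(combinator=Combinator.ALL)  # both clauses

candidates = ["fexofenadine", "quinapril", "metoprolol"]
result = best_match("fexafenedine", candidates, drug_rule)
print(
    f"\nbest_match('fexafenedine') -> {result.candidate} "
    f"(distance {result.distance}, ratio {result.ratio:.4f})"
)
# distance 2 fails the distance clause, but ratio 0.9167 > 0.85 accepts it.
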