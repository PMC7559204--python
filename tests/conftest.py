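"""Shared fixtures: packaged lexicons, worked-example rows, and the
independent edit-distance oracle (direct memoized recursion of the defining
equation, kept separate from the dynamic-programming implementation)."""

from functools import lru_cache

import pytest

import medtext as mt


def levenshtein_oracle(a: str, b: str) -> int:
    """Direct memoized recursion: base case max(i, j) when min(i, j) = 0,
    unit substitution cost when characters differ."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if min(i, j) == 0:
            return max(i, j)
        return min(
            rec(i - 1, j) + 1,
            rec(i, j - 1) + 1,
            rec(i - 1, j - 1) + (a[i - 1] != b[j - 1]),
        )

    return rec(len(a), len(b))


@pytest.fixture(scope="session")
def bundle() -> mt.LexiconBundle:
    return mt.load_bundle(mt.fixture_dir())


@pytest.fixture(scope="session")
def fixture_records():
    return mt.read_records_tsv(mt.fixture_dir() / "records.tsv")


# Worked examples: raw medication -> (status, canonical, class labels).
MEDICATION_GOLDENS = [
    ("Fexafenedine", "mapped", "fexofenadine", {"antihistamines"}),
    ("fexfenadine", "mapped", "fexofenadine", {"antihistamines"}),
    ("Hydrochlorothazide", "mapped", "hydrochlorothiazide", {"diuretics"}),
    ("Hydrochlorthiazide", "mapped", "hydrochlorothiazide", {"diuretics"}),
    ("Metoprolol Succ ER", "mapped", "metoprolol", {"beta-adrenergic blocking agents"}),
    ("Metoprolol Tart", "mapped", "metoprolol", {"beta-adrenergic blocking agents"}),
    ("Quinipril", "mapped", "quinapril", {"angiotensin converting enzyme inhibitors"}),
    ("Vit B12", "supplement_excluded", None, set()),
    ("vitemin B12", "supplement_excluded", None, set()),
]

# Worked examples: raw reason -> (expected stem string, expected category).
REASON_GOLDENS = [
    ("arthritis", "arthrit", "arthritis"),
    ("musculoskeletal", "musculoskelet", "joint/musculoskeletal problem"),
    ("gastritis", "gastrit", "gastrointestinal disease"),
    ("ulcerative colitis", "ulc colit", "gastrointestinal disease"),
    ("asthmatic", "asthm", "asthma"),
    ("diarrhea", "diarrhe", "autonomic symptoms"),
    ("depression", "depress", "depression and related disorders"),
    ("diabetes", "diabet", "diabetes"),
]
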