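"""Synthetic corpora standing in for restricted study data.

The study datasets behind this kind of pipeline (self-reported medication
entries from epidemiological surveys) are typically not shareable, so this
module generates what they look like structurally: a drug/supplement lexicon
with controlled pairwise separation, raw entries that are canonical names
corrupted by a seeded edit-operation model, a stated fraction of supplement
entries, and unmappable garbage strings — each paired with a reason drawn
from the stem map and with full ground truth recorded per record.

Controlled separation is the lever that makes recovery provable: if every
pair of distinct lexicon names is at Levenshtein distance >= 2*d + 1 and
entries are corrupted by fewer than d edits, the true name is the unique
lexicon name within the acceptance ball, so the pipeline must recover it.
"""

from __future__ import annotations

import enum
import random
import zlib
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

from .lexicon import AtcCode, DrugEntry, LexiconBundle, StemCategoryMap, SupplementLexicon, WordList
from .match import levenshtein_distance
from .meds import MedMatch, MedStatus
from .reasons import ReasonMatch
from .records import RawRecord
from .stemmer import stem_text

__all__ = [
    "EditOp",
    "CorruptionSpec",
    "TrueKind",
    "GroundTruthRecord",
    "EvalMetrics",
    "generate_lexicon",
    "corrupt",
    "generate_corpus",
    "evaluate",
    "write_truth_tsv",
]

_CONSONANTS = "bcdfgklmnprstvz"
_VOWELS = "aeiou"
_ALPHABET = "abcdefghijklmnopqrstuvwxyz"


class EditOp(str, enum.Enum):
    INSERT = "insert"
    DELETE = "delete"
    SUBSTITUTE = "substitute"


@dataclass(frozen=True)
class CorruptionSpec:
    """How raw entries are misspelled: exactly *n_edits* random operations."""

    n_edits: int = 1
    operations: FrozenSet[EditOp] = frozenset(EditOp)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_edits < 0:
            raise ValueError("n_edits must be >= 0")
        if self.n_edits > 0 and not self.operations:
            raise ValueError("operations must be non-empty when n_edits > 0")


class TrueKind(str, enum.Enum):
    DRUG = "drug"
    SUPPLEMENT = "supplement"
    GARBAGE = "garbage"


@dataclass(frozen=True)
class GroundTruthRecord:
    raw: str
    true_kind: TrueKind
    true_canonical: Optional[str] = None
    true_category: Optional[str] = None

    def __post_init__(self) -> None:
        if self.true_kind is TrueKind.DRUG and not self.true_canonical:
            raise ValueError("drug ground truth must carry the true canonical name")


@dataclass(frozen=True)
class EvalMetrics:
    """Canonical-name recovery scores of a pipeline run against ground truth."""

    precision: float
    recall: float
    auto_mapped_fraction: float
    supplement_confusions: int

    def __post_init__(self) -> None:
        for name in ("precision", "recall", "auto_mapped_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")


def _syllable_name(rng: random.Random, n_syllables: int) -> str:
    return "".join(
        rng.choice(_CONSONANTS) + rng.choice(_VOWELS) for _ in range(n_syllables)
    )


def _separated_names(
    rng: random.Random,
    count: int,
    min_separation: int,
    existing: List[str],
    max_tries: int = 20_000,
) -> List[str]:
    names: List[str] = []
    tries = 0
    while len(names) < count:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not generate {count} names with pairwise distance >= "
                f"{min_separation} after {max_tries} tries"
            )
        candidate = _syllable_name(rng, rng.randint(3, 5))
        pool = existing + names
        if all(levenshtein_distance(candidate, other) >= min_separation for other in pool):
            names.append(candidate)
    return names


def generate_lexicon(
    n_drugs: int,
    n_supplements: int,
    min_separation: int = 5,
    seed: int = 0,
    n_categories: int = 6,
    max_tries: int = 20_000,
) -> LexiconBundle:
    """Synthesize a lexicon bundle with controlled name separation.

    Every pair of distinct names across the drug and supplement lexicons has
    Levenshtein distance >= *min_separation*.  Drugs receive synthetic concept
    ids and 1-2 synthetic level-3 ATC codes; the stem map holds
    *n_categories* synthetic disease words mapped to numbered categories, and
    the word list contains those disease words.  Deterministic per seed.
    """
    if n_drugs < 1 or n_supplements < 1:
        raise ValueError("n_drugs and n_supplements must be >= 1")
    if min_separation < 1:
        raise ValueError("min_separation must be >= 1")
    rng = random.Random(seed)
    drug_names = _separated_names(rng, n_drugs, min_separation, [], max_tries)
    supplement_names = _separated_names(rng, n_supplements, min_separation, drug_names, max_tries)

    atc_pool = [
        AtcCode(f"{letter}{number:02d}{sub}", f"synthetic class {letter}{number:02d}{sub}")
        for letter in "ABCN"
        for number in (1, 2)
        for sub in "AB"
    ]
    drugs = [
        DrugEntry(
            canonical_name=name,
            concept_id=f"SYN{i:05d}",
            atc_codes=frozenset(rng.sample(atc_pool, rng.randint(1, 2))),
        )
        for i, name in enumerate(drug_names, start=1)
    ]

    # Disease words separated from each other so reason stems never collide.
    disease_words = _separated_names(
        rng, n_categories, min_separation, drug_names + supplement_names, max_tries
    )
    stem_map = StemCategoryMap(
        {stem_text(word): f"category {i:02d}" for i, word in enumerate(disease_words, start=1)}
    )
    wordlist = WordList(frozenset(disease_words))
    return LexiconBundle(
        drugs=drugs,
        supplements=SupplementLexicon(frozenset(supplement_names)),
        stem_map=stem_map,
        wordlist=wordlist,
    )


def _reason_words(bundle: LexiconBundle) -> List[str]:
    # The generator's word list carries the un-stemmed disease words whose
    # stems key the stem map; recover the pairing deterministically.
    pairs = []
    for word in sorted(bundle.wordlist.words):
        category = bundle.stem_map.get(stem_text(word))
        if category is not None:
            pairs.append((word, category))
    if not pairs:
        raise ValueError("bundle word list contains no stem-map source words")
    return pairs


def corrupt(name: str, spec: CorruptionSpec) -> str:
    """Apply exactly ``spec.n_edits`` random edit operations to *name*.

    Deterministic per (name, spec).  The result is guaranteed to be within
    Levenshtein distance ``n_edits`` of the input (edits can cancel, so the
    distance may be smaller).  The result is never emptied: a deletion on a
    single-character string is replaced by a substitution/insertion.
    """
    if not name:
        raise ValueError("cannot corrupt an empty name")
    rng = random.Random(spec.seed * 2_654_435_761 + zlib.crc32(name.encode("utf-8")))
    ops = sorted(spec.operations, key=lambda op: op.value)
    text = list(name)
    for _ in range(spec.n_edits):
        op = rng.choice(ops)
        if op is EditOp.DELETE and len(text) <= 1:
            op = EditOp.SUBSTITUTE if EditOp.SUBSTITUTE in ops else EditOp.INSERT
        if op is EditOp.INSERT:
            pos = rng.randrange(len(text) + 1)
            text.insert(pos, rng.choice(_ALPHABET))
        elif op is EditOp.DELETE:
            del text[rng.randrange(len(text))]
        else:  # substitute with a differing character
            pos = rng.randrange(len(text))
            text[pos] = rng.choice(_ALPHABET.replace(text[pos], ""))
    return "".join(text)


def _allocate(n: int, fractions: Sequence[float]) -> List[int]:
    # Largest-remainder allocation: deterministic, sums exactly to n.
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    floors = [int(n * f) for f in fractions]
    remainders = [(n * f - int(n * f), -i) for i, f in enumerate(fractions)]
    shortfall = n - sum(floors)
    for _, neg_i in sorted(remainders, reverse=True)[:shortfall]:
        floors[-neg_i] += 1
    return floors


def generate_corpus(
    bundle: LexiconBundle,
    n_records: int,
    drug_frac: float = 0.6,
    supplement_frac: float = 0.3,
    garbage_frac: float = 0.1,
    corruption: CorruptionSpec = CorruptionSpec(),
) -> Tuple[List[RawRecord], List[GroundTruthRecord]]:
    """Assemble a corpus of raw records with per-record ground truth.

    Composition counts are allocated deterministically from the fractions
    (largest-remainder rounding), drug and supplement names are corrupted per
    *corruption*, and garbage strings are resampled until they sit at
    Levenshtein distance > 3 from every lexicon name.  Each record gets a
    reason drawn from the stem map's source words.  Default mix (60% drugs,
    30% supplements, 10% garbage) reflects that roughly half of raw study
    records are supplements or unmappable residue.
    """
    rng = random.Random(corruption.seed * 1_000_003 + n_records)
    n_drug, n_supp, n_garbage = _allocate(
        n_records, [drug_frac, supplement_frac, garbage_frac]
    )
    drug_names = sorted(e.canonical_name for e in bundle.drugs)
    supplement_names = sorted(bundle.supplements.names)
    all_names = drug_names + supplement_names
    reasons = _reason_words(bundle)

    records: List[RawRecord] = []
    truth: List[GroundTruthRecord] = []

    def add(raw_med: str, kind: TrueKind, canonical: Optional[str]) -> None:
        reason_word, category = reasons[rng.randrange(len(reasons))]
        index = len(records) + 1
        records.append(RawRecord(f"S{index:05d}", raw_med, reason_word))
        truth.append(GroundTruthRecord(raw_med, kind, canonical, category))

    for _ in range(n_drug):
        name = drug_names[rng.randrange(len(drug_names))]
        spec = CorruptionSpec(corruption.n_edits, corruption.operations, rng.randrange(2**31))
        add(corrupt(name, spec), TrueKind.DRUG, name)
    for _ in range(n_supp):
        name = supplement_names[rng.randrange(len(supplement_names))]
        spec = CorruptionSpec(corruption.n_edits, corruption.operations, rng.randrange(2**31))
        add(corrupt(name, spec), TrueKind.SUPPLEMENT, name)
    for _ in range(n_garbage):
        while True:
            raw = "".join(rng.choice(_ALPHABET) for _ in range(rng.randint(8, 12)))
            if all(levenshtein_distance(raw, name) > 3 for name in all_names):
                break
        add(raw, TrueKind.GARBAGE, None)
    return records, truth


def evaluate(
    med_results: Sequence[MedMatch],
    reason_results: Sequence[ReasonMatch],
    truth: Sequence[GroundTruthRecord],
) -> EvalMetrics:
    """Score a pipeline run against corpus ground truth.

    - *precision*: of records mapped to a drug, the fraction whose true kind
      is drug and whose canonical name was recovered exactly.
    - *recall*: of true drug records, the fraction mapped to the correct
      canonical name.
    - *auto_mapped_fraction*: over distinct non-supplement raw medication
      terms (case-folded), the fraction resolved automatically — the paper's
      convention of counting distinct terms, not records.
    - *supplement_confusions*: true supplements mapped as drugs plus true
      drugs excluded as supplements.
    """
    if len(med_results) != len(truth):
        raise ValueError(
            f"med_results ({len(med_results)}) and truth ({len(truth)}) differ in length"
        )
    mapped_total = correct = true_drugs = confusions = 0
    distinct_terms: Dict[str, bool] = {}
    for result, gt in zip(med_results, truth):
        if gt.true_kind is TrueKind.DRUG:
            true_drugs += 1
        if result.status is MedStatus.MAPPED:
            mapped_total += 1
            if gt.true_kind is TrueKind.DRUG and result.canonical_name == gt.true_canonical:
                correct += 1
            if gt.true_kind is TrueKind.SUPPLEMENT:
                confusions += 1
        elif result.status is MedStatus.SUPPLEMENT_EXCLUDED:
            if gt.true_kind is TrueKind.DRUG:
                confusions += 1
        if result.status is not MedStatus.SUPPLEMENT_EXCLUDED:
            term = " ".join(result.raw.casefold().split())
            auto = result.status is MedStatus.MAPPED
            distinct_terms[term] = distinct_terms.get(term, False) or auto
    precision = correct / mapped_total if mapped_total else (1.0 if true_drugs == 0 else 0.0)
    recall = correct / true_drugs if true_drugs else 1.0
    auto_fraction = (
        sum(distinct_terms.values()) / len(distinct_terms) if distinct_terms else 1.0
    )
    return EvalMetrics(
        precision=precision,
        recall=recall,
        auto_mapped_fraction=auto_fraction,
        supplement_confusions=confusions,
    )


def write_truth_tsv(truth: Sequence[GroundTruthRecord], path) -> None:
    """Write ground truth alongside a generated corpus."""
    import csv
    from pathlib import Path

    with Path(path).open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["raw", "true_kind", "true_canonical", "true_category"])
        for gt in truth:
            writer.writerow(
                [gt.raw, gt.true_kind.value, gt.true_canonical or "", gt.true_category or ""]
            )
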