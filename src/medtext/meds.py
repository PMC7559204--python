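"""Medication branch: preprocess, exclude supplements, normalize, map to ATC classes.

Each raw medication entry flows through, in order:

1. *Preprocessing* — case folding, punctuation and dosage-token stripping
   ("Metoprolol Succ ER" -> "metoprolol", "ibuprofen 200 mg" -> "ibuprofen").
2. *Supplement check* — fuzzy comparison against the supplement lexicon using
   the ratio clause only; a hit excludes the record from drug processing.
3. *Normalization* — fuzzy best match against all canonical drug names and
   synonyms (ratio-over-threshold OR distance-under-threshold by default); a
   synonym hit resolves to its entry's canonical generic name.
4. *Class mapping* — the canonical name's concept id is looked up through the
   ontology adapter and its ATC codes truncated to the requested level
   (default 3, the therapeutic/pharmacologic subgroup).

Records that survive the supplement check but match no drug go to the manual
review queue; every record receives exactly one status.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from typing import FrozenSet, List, Optional, Sequence, Tuple

from .lexicon import AtcCode, DrugEntry, LexiconBundle, OntologyAdapter, SupplementLexicon, atc_classes
from .match import MatchPolicy, best_match
from .records import RawRecord

__all__ = [
    "MedStatus",
    "MedMatch",
    "DEFAULT_FORM_STOPLIST",
    "preprocess_name",
    "classify_supplement",
    "normalize_medication",
    "process_medications",
]

# Dose-form and packaging tokens that carry no information about the compound.
DEFAULT_FORM_STOPLIST: FrozenSet[str] = frozenset(
    {
        "er", "xr", "sr", "cr", "la", "succ", "tart", "tab", "tabs", "cap",
        "caps", "generic", "extra", "strength", "inhaler", "nebulizer",
    }
)

_UNITS = ("mg", "mcg", "ml", "g")
_NUMBER_RE = re.compile(r"^\d+(\.\d+)?$")
_NUMBER_UNIT_RE = re.compile(r"^\d+(\.\d+)?(%s)$" % "|".join(_UNITS))
_NON_ALNUM_RE = re.compile(r"[^a-z0-9]+")


class MedStatus(str, enum.Enum):
    SUPPLEMENT_EXCLUDED = "supplement_excluded"
    MAPPED = "mapped"
    MANUAL_QUEUE = "manual_queue"


@dataclass(frozen=True)
class MedMatch:
    """Outcome of processing one raw medication entry."""

    raw: str
    preprocessed: str
    status: MedStatus
    canonical_name: Optional[str] = None
    concept_id: Optional[str] = None
    atc_classes: FrozenSet[AtcCode] = frozenset()
    match_distance: Optional[int] = None
    match_ratio: Optional[float] = None
    subject_id: str = ""
    error: Optional[str] = None

    def __post_init__(self) -> None:
        if self.status is MedStatus.MAPPED:
            if not self.canonical_name or self.concept_id is None:
                raise ValueError("mapped record must carry canonical name and concept id")
        elif self.status is MedStatus.SUPPLEMENT_EXCLUDED:
            if self.atc_classes:
                raise ValueError("supplement-excluded record cannot carry ATC classes")
        elif self.canonical_name is not None:
            raise ValueError("manual-queue record cannot carry a canonical name")


def preprocess_name(raw: str, form_stoplist: FrozenSet[str] = DEFAULT_FORM_STOPLIST) -> str:
    """Normalize a raw medication string for matching.

    Case-folds, replaces punctuation with spaces, collapses whitespace, and
    drops tokens that are pure numbers, number+unit (mg/mcg/ml/g), bare units,
    or members of the dose-form stoplist.  If every token would be dropped the
    case-folded original is returned instead, so the result is never empty.

    Raises
    ------
    ValueError
        If the input is empty or whitespace-only.
    """
    folded = " ".join(raw.casefold().split())
    if not folded:
        raise ValueError("empty medication entry")
    tokens = [t for t in _NON_ALNUM_RE.sub(" ", folded).split() if t]
    kept = [
        t
        for t in tokens
        if t not in form_stoplist
        and t not in _UNITS
        and not _NUMBER_RE.match(t)
        and not _NUMBER_UNIT_RE.match(t)
    ]
    return " ".join(kept) if kept else folded


def classify_supplement(
    preprocessed: str,
    supplements: SupplementLexicon,
    policy: MatchPolicy = MatchPolicy(),
) -> bool:
    """Whether a preprocessed entry is a supplement.

    The supplement rule is stated in terms of the ratio alone: the entry is a
    supplement iff some supplement name exceeds the policy's ratio threshold.
    The policy's distance clause is ignored here.
    """
    if not supplements.names:
        return False
    result = best_match(preprocessed, sorted(supplements.names), policy.ratio_only())
    return result is not None


def normalize_medication(
    preprocessed: str,
    drugs: Sequence[DrugEntry],
    policy: MatchPolicy = MatchPolicy(),
) -> Optional[Tuple[str, str, int, float]]:
    """Spell-correct and normalize to a canonical drug name.

    Matches against every canonical name and synonym; a synonym hit resolves
    to its entry's canonical name.  Returns (canonical_name, concept_id,
    distance, ratio) or None when nothing passes the policy.
    """
    table = {}
    for entry in drugs:
        for name in (entry.canonical_name, *entry.synonyms):
            table.setdefault(name, entry)
    result = best_match(preprocessed, sorted(table), policy)
    if result is None:
        return None
    entry = table[result.candidate]
    return entry.canonical_name, entry.concept_id, result.distance, result.ratio


def process_medications(
    records: Sequence[RawRecord],
    bundle: LexiconBundle,
    policy: MatchPolicy = MatchPolicy(),
    adapter: Optional[OntologyAdapter] = None,
    atc_level: int = 3,
    form_stoplist: FrozenSet[str] = DEFAULT_FORM_STOPLIST,
) -> List[MedMatch]:
    """Run the full medication branch over *records*, preserving order.

    Per-record failures (e.g. an empty medication field) are collected on the
    record itself (status ``manual_queue`` with ``error`` set) rather than
    aborting the batch.
    """
    from .lexicon import BundleAdapter  # default offline adapter

    if adapter is None:
        adapter = BundleAdapter(bundle)
    results: List[MedMatch] = []
    for record in records:
        raw = record.medication_raw
        try:
            preprocessed = preprocess_name(raw, form_stoplist)
        except ValueError as exc:
            results.append(
                MedMatch(
                    raw=raw,
                    preprocessed="",
                    status=MedStatus.MANUAL_QUEUE,
                    subject_id=record.subject_id,
                    error=str(exc),
                )
            )
            continue
        if classify_supplement(preprocessed, bundle.supplements, policy):
            results.append(
                MedMatch(
                    raw=raw,
                    preprocessed=preprocessed,
                    status=MedStatus.SUPPLEMENT_EXCLUDED,
                    subject_id=record.subject_id,
                )
            )
            continue
        normalized = normalize_medication(preprocessed, bundle.drugs, policy)
        if normalized is None:
            results.append(
                MedMatch(
                    raw=raw,
                    preprocessed=preprocessed,
                    status=MedStatus.MANUAL_QUEUE,
                    subject_id=record.subject_id,
                )
            )
            continue
        canonical, concept_id, distance, ratio = normalized
        classes: FrozenSet[AtcCode] = frozenset()
        if concept_id:
            try:
                classes = atc_classes(concept_id, atc_level, adapter)
            except KeyError:
                classes = frozenset()
        results.append(
            MedMatch(
                raw=raw,
                preprocessed=preprocessed,
                status=MedStatus.MAPPED,
                canonical_name=canonical,
                concept_id=concept_id,
                atc_classes=classes,
                match_distance=distance,
                match_ratio=ratio,
                subject_id=record.subject_id,
            )
        )
    return results
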