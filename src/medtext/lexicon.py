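"""Knowledge sources: drug lexicon with ATC codes, supplement list, stem map, word list.

The study-time knowledge sources (drug and supplement names crawled from drug
databases, RxNorm concept ids, ATC class assignments) are modeled here as
file-backed lexicons so the pipeline is reproducible offline.  Concept and
class lookups go through a small adapter contract (:class:`OntologyAdapter`),
whose required implementation (:class:`BundleAdapter`) answers from the loaded
lexicon; a remote adapter talking to a live terminology service can implement
the same contract but is never exercised by the test suite.

File formats (all UTF-8; TSV tables carry a header row):

- ``drugs.tsv``: columns ``canonical_name``, ``synonyms`` (pipe-separated),
  ``concept_id``, ``atc_codes`` (pipe-separated ``code:label`` pairs).
- ``supplements.tsv``: one supplement name per line.
- ``stem_map.tsv``: columns ``stem``, ``category``.
- ``wordlist.txt``: one general-language word per line.

A JSON mirror (``lexicon.json``) with the same field names is also supported.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Protocol, Set

__all__ = [
    "AtcCode",
    "DrugEntry",
    "SupplementLexicon",
    "StemCategoryMap",
    "WordList",
    "LexiconBundle",
    "LexiconValidationError",
    "LookupFailure",
    "OntologyAdapter",
    "BundleAdapter",
    "load_bundle",
    "save_bundle",
    "resolve_concept",
    "atc_classes",
    "fixture_dir",
]

# Level 1: anatomical main group (one letter); level 2: + two digits;
# level 3: therapeutic/pharmacologic subgroup (+ one letter).
_ATC_RE = re.compile(r"^[A-Z](\d{2}([A-Z])?)?$")
_ATC_LEVEL_LENGTH = {1: 1, 2: 3, 3: 4}


class LexiconValidationError(ValueError):
    """A lexicon file or bundle failed validation.

    Carries the offending path and line number when known.
    """

    def __init__(self, message: str, path: Optional[Path] = None, line: Optional[int] = None):
        self.path = path
        self.line = line
        where = ""
        if path is not None:
            where = f"{path}"
            if line is not None:
                where += f":{line}"
            where = f" [{where}]"
        super().__init__(message + where)


class LookupFailure(KeyError):
    """An adapter lookup failed (unknown id or unreachable backend)."""


@dataclass(frozen=True)
class AtcCode:
    """An ATC code at level 1-3 with its therapeutic class label."""

    code: str
    label: str = ""

    def __post_init__(self) -> None:
        if not _ATC_RE.match(self.code):
            raise LexiconValidationError(
                f"invalid ATC level 1-3 code: {self.code!r}"
            )

    @property
    def level(self) -> int:
        return {1: 1, 3: 2, 4: 3}[len(self.code)]

    def truncate(self, level: int) -> "AtcCode":
        """This code truncated to *level* (1-3).  The label is retained as a
        best available description of the truncated class."""
        if level not in _ATC_LEVEL_LENGTH:
            raise ValueError(f"ATC level must be 1, 2 or 3, got {level}")
        if level >= self.level:
            return self
        return AtcCode(self.code[: _ATC_LEVEL_LENGTH[level]], self.label)


@dataclass(frozen=True)
class DrugEntry:
    """One drug: canonical (generic) name, synonyms, concept id, ATC codes."""

    canonical_name: str
    synonyms: FrozenSet[str] = frozenset()
    concept_id: str = ""
    atc_codes: FrozenSet[AtcCode] = frozenset()

    def __post_init__(self) -> None:
        if not self.canonical_name:
            raise LexiconValidationError("drug canonical_name must be non-empty")
        if self.canonical_name in self.synonyms:
            raise LexiconValidationError(
                f"{self.canonical_name!r} listed among its own synonyms"
            )


@dataclass(frozen=True)
class SupplementLexicon:
    names: FrozenSet[str] = frozenset()

    def __post_init__(self) -> None:
        if any(not n for n in self.names):
            raise LexiconValidationError("supplement names must be non-empty")

    def __contains__(self, name: str) -> bool:
        return name in self.names


@dataclass(frozen=True)
class StemCategoryMap:
    """Mapping from space-joined per-token stem strings to disease categories."""

    entries: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for stem, category in self.entries.items():
            if not stem or not category:
                raise LexiconValidationError(
                    f"stem map entry {stem!r} -> {category!r} must be non-empty"
                )

    @property
    def stems(self) -> List[str]:
        return sorted(self.entries)

    def get(self, stem: str) -> Optional[str]:
        return self.entries.get(stem)


@dataclass(frozen=True)
class WordList:
    words: FrozenSet[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.words:
            raise LexiconValidationError("word list must be non-empty")

    def __contains__(self, word: str) -> bool:
        return word in self.words


@dataclass(frozen=True)
class LexiconBundle:
    """All knowledge sources the pipelines consume, validated together."""

    drugs: List[DrugEntry]
    supplements: SupplementLexicon
    stem_map: StemCategoryMap
    wordlist: WordList

    def __post_init__(self) -> None:
        if not self.drugs:
            raise LexiconValidationError("drug lexicon is empty")
        seen: Set[str] = set()
        for entry in self.drugs:
            if entry.canonical_name in seen:
                raise LexiconValidationError(
                    f"duplicate canonical drug name {entry.canonical_name!r}"
                )
            seen.add(entry.canonical_name)
        collisions = seen & set(self.supplements.names)
        if collisions:
            raise LexiconValidationError(
                f"names present in both drug and supplement lexicons: {sorted(collisions)}"
            )

    def drug_by_name(self) -> Dict[str, DrugEntry]:
        """Lookup from every canonical name AND synonym to its entry."""
        table: Dict[str, DrugEntry] = {}
        for entry in self.drugs:
            for name in (entry.canonical_name, *entry.synonyms):
                if name in table and table[name] is not entry:
                    raise LexiconValidationError(
                        f"name {name!r} appears in multiple drug entries"
                    )
                table[name] = entry
        return table

    def unlabeled_drugs(self) -> List[str]:
        """Canonical names with no ATC codes (flagged, not fatal)."""
        return [e.canonical_name for e in self.drugs if not e.atc_codes]


class OntologyAdapter(Protocol):
    """Contract for concept-id and drug-class lookups.

    The offline :class:`BundleAdapter` answers from the loaded lexicon and is
    the implementation used everywhere in this package.  A remote adapter
    backed by a terminology REST service may implement the same two methods;
    it must raise :class:`LookupFailure` when the service is unreachable
    rather than silently returning nothing.
    """

    def resolve_concept(self, name: str) -> Optional[str]:
        """Concept id for a canonical drug name, or None if unknown."""
        ...

    def atc_codes(self, concept_id: str) -> FrozenSet[AtcCode]:
        """Full (level-3) ATC codes for a concept; raises LookupFailure."""
        ...


class BundleAdapter:
    """Offline ontology adapter answering from a :class:`LexiconBundle`."""

    def __init__(self, bundle: LexiconBundle):
        self._by_canonical = {e.canonical_name: e for e in bundle.drugs}
        self._by_concept = {e.concept_id: e for e in bundle.drugs if e.concept_id}

    def resolve_concept(self, name: str) -> Optional[str]:
        entry = self._by_canonical.get(name)
        return entry.concept_id if entry and entry.concept_id else None

    def atc_codes(self, concept_id: str) -> FrozenSet[AtcCode]:
        entry = self._by_concept.get(concept_id)
        if entry is None:
            raise LookupFailure(f"unknown concept id: {concept_id!r}")
        return entry.atc_codes


def resolve_concept(name: str, adapter: OntologyAdapter) -> Optional[str]:
    """Concept id for a canonical drug name via *adapter* (None if unknown)."""
    return adapter.resolve_concept(name)


def atc_classes(concept_id: str, level: int, adapter: OntologyAdapter) -> FrozenSet[AtcCode]:
    """ATC codes of a concept truncated to *level* and deduplicated.

    When two full codes truncate to the same code with different labels, the
    lexicographically smallest label is kept so results are deterministic.
    """
    if level not in (1, 2, 3):
        raise ValueError(f"ATC level must be in 1..3, got {level}")
    truncated: Dict[str, str] = {}
    for code in adapter.atc_codes(concept_id):
        cut = code.truncate(level)
        if cut.code not in truncated or cut.label < truncated[cut.code]:
            truncated[cut.code] = cut.label
    return frozenset(AtcCode(c, lbl) for c, lbl in truncated.items())


# ---------------------------------------------------------------------------
# File I/O


def _fold(text: str) -> str:
    return " ".join(text.casefold().split())


def _read_tsv(path: Path, expected_columns: List[str]) -> List[tuple]:
    rows = []
    try:
        handle = path.open(newline="", encoding="utf-8")
    except OSError as exc:
        raise FileNotFoundError(f"cannot read lexicon file {path}: {exc}") from exc
    with handle:
        reader = csv.reader(handle, delimiter="\t")
        header = next(reader, None)
        if header != expected_columns:
            raise LexiconValidationError(
                f"expected header {expected_columns}, got {header}", path, 1
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(expected_columns):
                raise LexiconValidationError(
                    f"expected {len(expected_columns)} columns, got {len(row)}",
                    path,
                    lineno,
                )
            rows.append((lineno, row))
    return rows


def _parse_atc_field(raw: str, path: Path, lineno: int) -> FrozenSet[AtcCode]:
    codes = set()
    for pair in filter(None, (p.strip() for p in raw.split("|"))):
        code, _, label = pair.partition(":")
        try:
            codes.add(AtcCode(code.strip().upper(), label.strip()))
        except LexiconValidationError as exc:
            raise LexiconValidationError(str(exc), path, lineno) from exc
    return frozenset(codes)


def _read_drugs_tsv(path: Path) -> List[DrugEntry]:
    entries = []
    for lineno, row in _read_tsv(
        path, ["canonical_name", "synonyms", "concept_id", "atc_codes"]
    ):
        canonical = _fold(row[0])
        synonyms = frozenset(
            s for s in (_fold(p) for p in row[1].split("|")) if s and s != canonical
        )
        try:
            entries.append(
                DrugEntry(
                    canonical_name=canonical,
                    synonyms=synonyms,
                    concept_id=row[2].strip(),
                    atc_codes=_parse_atc_field(row[3], path, lineno),
                )
            )
        except LexiconValidationError as exc:
            if exc.path is None:
                raise LexiconValidationError(str(exc), path, lineno) from exc
            raise
    return entries


def _read_lines(path: Path) -> List[str]:
    with path.open(encoding="utf-8") as handle:
        return [_fold(line) for line in handle if line.strip()]


def _read_stem_map_tsv(path: Path) -> StemCategoryMap:
    entries: Dict[str, str] = {}
    for lineno, row in _read_tsv(path, ["stem", "category"]):
        stem = _fold(row[0])
        if stem in entries:
            raise LexiconValidationError(f"duplicate stem key {stem!r}", path, lineno)
        entries[stem] = row[1].strip()
    return StemCategoryMap(entries)


def load_bundle(directory: str | Path, format: str = "tsv") -> LexiconBundle:
    """Load and validate a lexicon bundle from *directory*.

    ``format="tsv"`` reads ``drugs.tsv``, ``supplements.tsv``, ``stem_map.tsv``
    and ``wordlist.txt``; ``format="json"`` reads ``lexicon.json``.  All names
    are case-folded and whitespace-collapsed on load.  Raises
    :class:`FileNotFoundError` for missing files and
    :class:`LexiconValidationError` (with file and line) for malformed content.
    """
    directory = Path(directory)
    if format == "tsv":
        drugs = _read_drugs_tsv(directory / "drugs.tsv")
        supplements = SupplementLexicon(frozenset(_read_lines(directory / "supplements.tsv")))
        stem_map = _read_stem_map_tsv(directory / "stem_map.tsv")
        wordlist = WordList(frozenset(_read_lines(directory / "wordlist.txt")))
    elif format == "json":
        path = directory / "lexicon.json"
        try:
            payload = json.loads(path.read_text(encoding="utf-8"))
        except OSError as exc:
            raise FileNotFoundError(f"cannot read {path}: {exc}") from exc
        except json.JSONDecodeError as exc:
            raise LexiconValidationError(f"malformed JSON: {exc}", path) from exc
        drugs = [
            DrugEntry(
                canonical_name=_fold(d["canonical_name"]),
                synonyms=frozenset(
                    s
                    for s in (_fold(x) for x in d.get("synonyms", []))
                    if s and s != _fold(d["canonical_name"])
                ),
                concept_id=d.get("concept_id", ""),
                atc_codes=frozenset(
                    AtcCode(c["code"].upper(), c.get("label", ""))
                    for c in d.get("atc_codes", [])
                ),
            )
            for d in payload["drugs"]
        ]
        supplements = SupplementLexicon(
            frozenset(_fold(s) for s in payload["supplements"])
        )
        stem_map = StemCategoryMap(
            {_fold(k): v for k, v in payload["stem_map"].items()}
        )
        wordlist = WordList(frozenset(_fold(w) for w in payload["wordlist"]))
    else:
        raise ValueError(f"unknown lexicon format: {format!r}")
    return LexiconBundle(drugs, supplements, stem_map, wordlist)


def save_bundle(bundle: LexiconBundle, directory: str | Path, format: str = "tsv") -> None:
    """Write *bundle* to *directory* in the given format (inverse of load)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if format == "tsv":
        with (directory / "drugs.tsv").open("w", encoding="utf-8", newline="") as handle:
            writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
            writer.writerow(["canonical_name", "synonyms", "concept_id", "atc_codes"])
            for entry in bundle.drugs:
                writer.writerow(
                    [
                        entry.canonical_name,
                        "|".join(sorted(entry.synonyms)),
                        entry.concept_id,
                        "|".join(
                            f"{c.code}:{c.label}" for c in sorted(entry.atc_codes, key=lambda c: c.code)
                        ),
                    ]
                )
        (directory / "supplements.tsv").write_text(
            "".join(f"{n}\n" for n in sorted(bundle.supplements.names)), encoding="utf-8"
        )
        with (directory / "stem_map.tsv").open("w", encoding="utf-8", newline="") as handle:
            writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
            writer.writerow(["stem", "category"])
            for stem in bundle.stem_map.stems:
                writer.writerow([stem, bundle.stem_map.entries[stem]])
        (directory / "wordlist.txt").write_text(
            "".join(f"{w}\n" for w in sorted(bundle.wordlist.words)), encoding="utf-8"
        )
    elif format == "json":
        payload = {
            "drugs": [
                {
                    "canonical_name": e.canonical_name,
                    "synonyms": sorted(e.synonyms),
                    "concept_id": e.concept_id,
                    "atc_codes": [
                        {"code": c.code, "label": c.label}
                        for c in sorted(e.atc_codes, key=lambda c: c.code)
                    ],
                }
                for e in bundle.drugs
            ],
            "supplements": sorted(bundle.supplements.names),
            "stem_map": dict(sorted(bundle.stem_map.entries.items())),
            "wordlist": sorted(bundle.wordlist.words),
        }
        (directory / "lexicon.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
    else:
        raise ValueError(f"unknown lexicon format: {format!r}")


def fixture_dir() -> Path:
    """Directory of the small lexicon fixtures packaged with medtext."""
    return Path(__file__).parent / "data" / "fixtures"
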