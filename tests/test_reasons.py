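"""Reason branch: spell correction, stem mapping, overrides, batch behavior."""

import pytest

from medtext.match import Combinator, MatchPolicy
from medtext.reasons import (
    ReasonStatus,
    apply_overrides,
    map_reason,
    process_reasons,
    spell_correct_word,
)
from medtext.records import RawRecord

from conftest import REASON_GOLDENS


class TestSpellCorrect:
    @pytest.mark.parametrize(
        "word, expected",
        [
            ("arthritis", "arthritis"),  # dictionary member unchanged
            ("vitemin", "vitamin"),
            ("diabtes", "diabetes"),
            ("qqqq", "qqqq"),  # nothing passes, unchanged
            ("b12", "b12"),  # non-alphabetic token untouched
        ],
    )
    def test_examples(self, bundle, word, expected):
        assert spell_correct_word(word, bundle.wordlist) == expected


class TestMapReason:
    @pytest.mark.parametrize(
        "stems, category",
        [
            ("ulc colit", "gastrointestinal disease"),
            ("arthr", "arthritis"),
            ("arthrit", "arthritis"),
            ("htn", "hypertension"),
        ],
    )
    def test_examples(self, bundle, stems, category):
        result = map_reason(stems, bundle.stem_map)
        assert result is not None and result[0] == category

    def test_exact_hit_has_distance_zero(self, bundle):
        assert map_reason("diabet", bundle.stem_map) == ("diabetes", 0, 1.0)

    def test_unmappable_is_absent(self, bundle):
        assert map_reason("zzz qqq", bundle.stem_map) is None

    def test_all_combinator_requires_both_clauses(self, bundle):
        # 'diabe' is distance 1 from key 'diabet' (passes distance) with
        # ratio 10/11 ≈ 0.91 (passes ratio) -> accepted; 'dia' is distance 3
        # -> rejected even though some ratio-only policy might allow it.
        assert map_reason("diabe", bundle.stem_map) is not None
        assert map_reason("dia", bundle.stem_map) is None


class TestOverrides:
    def test_override_rescues_manual_queue(self, bundle):
        results = process_reasons([RawRecord("S1", "", "sore everywhere")], bundle)
        assert results[0].status is ReasonStatus.MANUAL_QUEUE
        fixed = apply_overrides(results, {"Sore Everywhere": "pain"})
        assert fixed[0].status is ReasonStatus.OVERRIDDEN
        assert fixed[0].category == "pain"

    def test_override_beats_auto_mapping(self, bundle):
        results = process_reasons([RawRecord("S1", "", "diabetes")], bundle)
        assert results[0].status is ReasonStatus.AUTO
        fixed = apply_overrides(results, {"diabetes": "endocrine disease"})
        assert fixed[0].status is ReasonStatus.OVERRIDDEN
        assert fixed[0].category == "endocrine disease"

    def test_idempotent_and_identity_on_empty(self, bundle):
        results = process_reasons([RawRecord("S1", "", "diabetes")], bundle)
        assert apply_overrides(results, {}) == results
        once = apply_overrides(results, {"diabetes": "endocrine disease"})
        assert apply_overrides(once, {"diabetes": "endocrine disease"}) == once

    def test_empty_category_rejected(self, bundle):
        results = process_reasons([RawRecord("S1", "", "diabetes")], bundle)
        with pytest.raises(ValueError):
            apply_overrides(results, {"diabetes": ""})


class TestBatch:
    def test_table_goldens_end_to_end(self, bundle):
        records = [RawRecord("S1", "", raw) for raw, _, _ in REASON_GOLDENS]
        results = process_reasons(records, bundle)
        for result, (raw, stems, category) in zip(results, REASON_GOLDENS):
            assert result.status is ReasonStatus.AUTO
            assert result.stem_string == stems
            assert result.category == category

    def test_abbreviated_representations(self, bundle):
        records = [
            RawRecord("S1", "", "high blood pressure"),
            RawRecord("S1", "", "HTN"),
            RawRecord("S1", "", "b/p"),
        ]
        results = process_reasons(records, bundle)
        assert all(r.category == "hypertension" for r in results)

    def test_spelling_error_corrected_before_mapping(self, bundle):
        results = process_reasons([RawRecord("S1", "", "ulcerative collitis")], bundle)
        assert results[0].corrected == "ulcerative colitis"
        assert results[0].category == "gastrointestinal disease"

    def test_empty_input_and_empty_reason(self, bundle):
        assert process_reasons([], bundle) == []
        results = process_reasons([RawRecord("S1", "aspirin", "")], bundle)
        assert results[0].status is ReasonStatus.MANUAL_QUEUE
        assert results[0].error

    def test_partition_invariant(self, bundle, fixture_records):
        results = process_reasons(
            fixture_records, bundle, overrides={"headache": "pain"}
        )
        counts = {s: sum(r.status is s for r in results) for s in ReasonStatus}
        assert sum(counts.values()) == len(fixture_records)
        assert counts[ReasonStatus.OVERRIDDEN] == 1

    def test_map_monotonicity_in_ratio_threshold(self, bundle, fixture_records):
        """Lowering the ratio threshold never decreases the mapped count.

        Asserted at the stem-mapping stage: the stems are computed once at
        default settings, then looked up under progressively looser policies.
        (End-to-end counts need not be monotone, because a looser threshold
        also makes word-level spell correction more aggressive.)
        """
        stems = [
            r.stem_string
            for r in process_reasons(fixture_records, bundle)
            if r.stem_string
        ]
        mapped_counts = []
        for threshold in (1.0, 0.95, 0.85, 0.7, 0.5):
            policy = MatchPolicy(ratio_threshold=threshold, combinator=Combinator.ALL)
            mapped_counts.append(
                sum(map_reason(s, bundle.stem_map, policy) is not None for s in stems)
            )
        assert mapped_counts == sorted(mapped_counts)
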