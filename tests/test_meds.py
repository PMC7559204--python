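"""Medication branch: preprocessing, supplement exclusion, normalization, batch."""

import pytest

from medtext.match import MatchPolicy
from medtext.meds import (
    MedStatus,
    classify_supplement,
    normalize_medication,
    preprocess_name,
    process_medications,
)
from medtext.records import RawRecord

from conftest import MEDICATION_GOLDENS


class TestPreprocess:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("Metoprolol Succ ER", "metoprolol"),
            ("ibuprofen 200 mg", "ibuprofen"),
            ("ibuprofen 200mg", "ibuprofen"),
            ("aspirin", "aspirin"),
            ("Extra Strength Advil", "advil"),
            ("Albuteral  Inhaler", "albuteral"),
            ("Aspirin (Bayer)", "aspirin bayer"),
        ],
    )
    def test_examples(self, raw, expected):
        assert preprocess_name(raw) == expected

    def test_never_returns_empty(self):
        # every token drops -> fall back to the case-folded original
        assert preprocess_name("ER 200 mg") == "er 200 mg"

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            preprocess_name("   ")


class TestSupplementCheck:
    @pytest.mark.parametrize(
        "name, expected",
        [
            ("vitamin c", True),
            ("metoprolol", False),
            ("vit b12", True),  # stored abbreviation synonym
            ("vitemin b12", True),  # one edit from 'vitamin b12'
            ("melatonin", True),
        ],
    )
    def test_examples(self, bundle, name, expected):
        assert classify_supplement(name, bundle.supplements) is expected

    def test_uses_ratio_clause_only(self, bundle):
        # 'vitamin x' is distance 1 from 'vitamin c' but ratio 17/18 > 0.85;
        # 'zinc oxide' is within no ratio bound; a tiny distance alone must
        # not make something a supplement under a distance-friendly policy.
        policy = MatchPolicy(ratio_threshold=0.99, distance_threshold=100)
        assert classify_supplement("metoprolol", bundle.supplements, policy) is False


class TestNormalize:
    @pytest.mark.parametrize(
        "name, canonical",
        [
            ("fexafenedine", "fexofenadine"),
            ("quinipril", "quinapril"),
            ("advil", "ibuprofen"),  # synonym resolves to its canonical name
            ("metoprold", "metoprolol"),
        ],
    )
    def test_examples(self, bundle, name, canonical):
        result = normalize_medication(name, bundle.drugs)
        assert result is not None and result[0] == canonical

    def test_garbage_is_absent(self, bundle):
        assert normalize_medication("xqzzt", bundle.drugs) is None


class TestBatch:
    def table4_records(self):
        meds = ["Fexafenedine", "Hydrochlorothazide", "Metoprolol Succ ER",
                "Quinipril", "Vit B12"]
        return [RawRecord(f"S{i}", m, "") for i, m in enumerate(meds)]

    def test_table_goldens_end_to_end(self, bundle):
        records = [RawRecord("S1", raw, "") for raw, *_ in MEDICATION_GOLDENS]
        results = process_medications(records, bundle)
        for result, (raw, status, canonical, labels) in zip(results, MEDICATION_GOLDENS):
            assert result.raw == raw
            assert result.status.value == status
            assert result.canonical_name == canonical
            assert {c.label for c in result.atc_classes} == labels

    def test_empty_input(self, bundle):
        assert process_medications([], bundle) == []

    def test_partition_invariant(self, bundle, fixture_records):
        results = process_medications(fixture_records, bundle)
        counts = {s: sum(r.status is s for r in results) for s in MedStatus}
        assert sum(counts.values()) == len(fixture_records)
        assert [r.raw for r in results] == [r.medication_raw for r in fixture_records]

    def test_supplements_never_map_as_drugs(self, bundle, fixture_records):
        results = process_medications(fixture_records, bundle)
        mapped = {r.canonical_name for r in results if r.status is MedStatus.MAPPED}
        assert not (mapped & set(bundle.supplements.names))

    def test_empty_medication_goes_to_manual_queue_with_error(self, bundle):
        results = process_medications([RawRecord("S1", "  ", "pain")], bundle)
        assert results[0].status is MedStatus.MANUAL_QUEUE
        assert results[0].error

    def test_threshold_monotonicity(self, bundle, fixture_records):
        """Raising the ratio threshold never increases the matched count.

        Asserted at the drug-matching stage over fixed preprocessed names.
        (End-to-end mapped counts need not be monotone: a looser ratio also
        loosens the upstream supplement check, which can swallow records.)
        """
        names = [preprocess_name(r.medication_raw) for r in fixture_records]
        matched_counts = []
        for threshold in (0.5, 0.7, 0.85, 0.95, 1.0):
            policy = MatchPolicy(ratio_threshold=threshold)
            matched_counts.append(
                sum(normalize_medication(n, bundle.drugs, policy) is not None for n in names)
            )
        assert matched_counts == sorted(matched_counts, reverse=True)

    def test_idempotence_on_canonical_names(self, bundle, fixture_records):
        """Re-running on mapped canonical names maps each to itself exactly."""
        first = process_medications(fixture_records, bundle)
        canonical = [
            RawRecord(r.subject_id, r.canonical_name, "")
            for r in first
            if r.status is MedStatus.MAPPED
        ]
        second = process_medications(canonical, bundle)
        for record, result in zip(canonical, second):
            assert result.status is MedStatus.MAPPED
            assert result.canonical_name == record.medication_raw
            assert result.match_distance == 0
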