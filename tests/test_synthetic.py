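"""Synthetic corpus generator: separation, corruption, composition, scoring."""

import itertools

import pytest

from medtext.match import levenshtein_distance
from medtext.meds import MedStatus, process_medications
from medtext.reasons import process_reasons
from medtext.synthetic import (
    CorruptionSpec,
    EditOp,
    TrueKind,
    corrupt,
    evaluate,
    generate_corpus,
    generate_lexicon,
)


@pytest.fixture(scope="module")
def small_bundle():
    return generate_lexicon(n_drugs=10, n_supplements=5, min_separation=5, seed=7)


class TestGenerateLexicon:
    def test_minimum_pairwise_separation(self, small_bundle):
        names = sorted(
            {e.canonical_name for e in small_bundle.drugs}
            | set(small_bundle.supplements.names)
        )
        for a, b in itertools.combinations(names, 2):
            assert levenshtein_distance(a, b) >= 5

    def test_two_name_bundle(self):
        bundle = generate_lexicon(1, 1, min_separation=1, seed=1)
        assert len(bundle.drugs) == 1 and len(bundle.supplements.names) == 1

    def test_seeded_determinism(self):
        assert generate_lexicon(6, 3, 4, seed=11) == generate_lexicon(6, 3, 4, seed=11)
        assert generate_lexicon(6, 3, 4, seed=11) != generate_lexicon(6, 3, 4, seed=12)

    def test_drugs_carry_concepts_and_codes(self, small_bundle):
        for entry in small_bundle.drugs:
            assert entry.concept_id
            assert 1 <= len(entry.atc_codes) <= 2

    def test_infeasible_separation_errors(self):
        with pytest.raises(RuntimeError):
            generate_lexicon(50, 50, min_separation=10, seed=0, max_tries=300)


class TestCorrupt:
    def test_zero_edits_is_identity(self):
        assert corrupt("metoprolol", CorruptionSpec(n_edits=0, seed=3)) == "metoprolol"

    @pytest.mark.parametrize("n_edits", [1, 2, 3])
    def test_distance_bounded_by_edit_count(self, small_bundle, n_edits):
        names = [e.canonical_name for e in small_bundle.drugs]
        for seed, name in enumerate(names):
            out = corrupt(name, CorruptionSpec(n_edits=n_edits, seed=seed))
            assert levenshtein_distance(name, out) <= n_edits
            assert out  # never emptied

    def test_seeded_repeat_identical(self):
        spec = CorruptionSpec(n_edits=2, seed=42)
        assert corrupt("fexofenadine", spec) == corrupt("fexofenadine", spec)

    def test_restricted_operations(self):
        spec = CorruptionSpec(
            n_edits=2, operations=frozenset({EditOp.DELETE}), seed=9
        )
        out = corrupt("metoprolol", spec)
        assert len(out) == 8  # two deletions, nothing else

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            CorruptionSpec(n_edits=-1)
        with pytest.raises(ValueError):
            CorruptionSpec(n_edits=1, operations=frozenset())


class TestGenerateCorpus:
    def test_exact_composition(self, small_bundle):
        _, truth = generate_corpus(
            small_bundle, 200, 0.6, 0.3, 0.1, CorruptionSpec(n_edits=1, seed=5)
        )
        kinds = [t.true_kind for t in truth]
        assert kinds.count(TrueKind.DRUG) == 120
        assert kinds.count(TrueKind.SUPPLEMENT) == 60
        assert kinds.count(TrueKind.GARBAGE) == 20

    def test_garbage_is_far_from_lexicon(self, small_bundle):
        _, truth = generate_corpus(
            small_bundle, 50, 0.0, 0.0, 1.0, CorruptionSpec(n_edits=0, seed=2)
        )
        names = [e.canonical_name for e in small_bundle.drugs] + sorted(
            small_bundle.supplements.names
        )
        for gt in truth:
            assert all(levenshtein_distance(gt.raw, n) > 3 for n in names)

    def test_clean_drug_corpus_fully_mapped(self, small_bundle):
        records, truth = generate_corpus(
            small_bundle, 40, 1.0, 0.0, 0.0, CorruptionSpec(n_edits=0, seed=8)
        )
        results = process_medications(records, small_bundle)
        assert all(r.status is MedStatus.MAPPED for r in results)
        assert [r.canonical_name for r in results] == [t.true_canonical for t in truth]

    def test_reproducible(self, small_bundle):
        spec = CorruptionSpec(n_edits=1, seed=13)
        assert generate_corpus(small_bundle, 30, corruption=spec) == generate_corpus(
            small_bundle, 30, corruption=spec
        )

    def test_bad_fractions_rejected(self, small_bundle):
        with pytest.raises(ValueError):
            generate_corpus(small_bundle, 10, 0.5, 0.2, 0.1)


class TestEvaluate:
    def run(self, bundle, records, truth):
        meds = process_medications(records, bundle)
        reasons = process_reasons(records, bundle)
        return evaluate(meds, reasons, truth)

    def test_perfect_on_clean_corpus(self, small_bundle):
        records, truth = generate_corpus(
            small_bundle, 60, corruption=CorruptionSpec(n_edits=0, seed=4)
        )
        metrics = self.run(small_bundle, records, truth)
        assert metrics.precision == 1.0
        assert metrics.recall == 1.0
        assert metrics.supplement_confusions == 0

    def test_single_edit_corruption_still_perfect(self, small_bundle):
        """min separation 5 with 1-edit corruption leaves the true name the
        unique candidate inside the acceptance ball."""
        records, truth = generate_corpus(
            small_bundle, 60, corruption=CorruptionSpec(n_edits=1, seed=4)
        )
        metrics = self.run(small_bundle, records, truth)
        assert metrics.precision == 1.0 and metrics.recall == 1.0

    def test_all_manual_gives_zero_recall(self, small_bundle):
        from medtext.match import MatchPolicy

        records, truth = generate_corpus(
            small_bundle, 30, corruption=CorruptionSpec(n_edits=0, seed=6)
        )
        # an unsatisfiable policy: ratio must exceed 1.0 and distance be < 0
        impossible = MatchPolicy(ratio_threshold=1.0, distance_threshold=0)
        meds = process_medications(records, small_bundle, policy=impossible)
        assert all(r.status is MedStatus.MANUAL_QUEUE for r in meds)
        reasons = process_reasons(records, small_bundle)
        metrics = evaluate(meds, reasons, truth)
        assert metrics.recall == 0.0
        assert metrics.auto_mapped_fraction == 0.0

    def test_length_mismatch_rejected(self, small_bundle):
        records, truth = generate_corpus(
            small_bundle, 10, corruption=CorruptionSpec(n_edits=0, seed=1)
        )
        meds = process_medications(records, small_bundle)
        reasons = process_reasons(records, small_bundle)
        with pytest.raises(ValueError):
            evaluate(meds[:-1], reasons, truth)
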