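import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spsp.classify as classify_mod
from spsp import (
    accuracy_from_confusion,
    build_class_indices,
    classify_sequence,
    cosine_similarity,
    loso_evaluate,
)
from spsp.errors import DomainError, ProtocolError
from tests.conftest import make_sequences


def manual_cosine(a, b):
    """Independent scalar-loop evaluation of the similarity formula."""
    dot = sum(x * y for x, y in zip(a, b))
    na = math.sqrt(sum(x * x for x in a))
    nb = math.sqrt(sum(y * y for y in b))
    return dot / (na * nb)


class TestCosineSimilarity:
    def test_identical(self, rng):
        v = rng.standard_normal(20)
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_orthogonal(self):
        assert cosine_similarity([1.0, 0.0], [0.0, 1.0]) == 0.0

    def test_45_degrees(self):
        assert cosine_similarity([1.0, 1.0], [1.0, 0.0]) == pytest.approx(
            0.7071067811865476
        )

    def test_length_mismatch(self):
        with pytest.raises(DomainError):
            cosine_similarity([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_zero_norm(self):
        with pytest.raises(DomainError):
            cosine_similarity([0.0, 0.0], [1.0, 2.0])

    def test_matches_manual_loop(self, rng):
        for _ in range(20):
            a = rng.standard_normal(7)
            b = rng.standard_normal(7)
            assert cosine_similarity(a, b) == pytest.approx(
                manual_cosine(a, b), rel=1e-12
            )

    @given(
        data=st.lists(
            st.tuples(
                st.floats(-100, 100).filter(lambda x: x == 0 or abs(x) > 1e-6),
                st.floats(-100, 100).filter(lambda x: x == 0 or abs(x) > 1e-6),
            ),
            min_size=2,
            max_size=20,
        ),
        c=st.floats(1e-3, 1e3),
    )
    @settings(max_examples=100, deadline=None)
    def test_bounded_symmetric_scale_invariant(self, data, c):
        a = np.array([x for x, _ in data])
        b = np.array([y for _, y in data])
        if np.linalg.norm(a) == 0 or np.linalg.norm(b) == 0:
            return
        s = cosine_similarity(a, b)
        assert -1.0 - 1e-12 <= s <= 1.0 + 1e-12
        assert s == pytest.approx(cosine_similarity(b, a), rel=1e-12, abs=1e-12)
        assert s == pytest.approx(cosine_similarity(a, c * b), rel=1e-9, abs=1e-9)


class TestBuildClassIndices:
    def test_idempotent_mean(self):
        seqs = make_sequences([[1, 2, 2, 1]] * 2, ["a", "a"], ["s1", "s2"], S=2)
        indices = build_class_indices(seqs, ["a"])
        np.testing.assert_allclose(indices["a"].template, [1, 2, 2, 1])
        assert indices["a"].n_contributors == 2

    def test_pairwise_mean(self):
        seqs = make_sequences([[1, 1], [3, 3]], ["a", "a"], ["s1", "s2"], S=3)
        np.testing.assert_allclose(
            build_class_indices(seqs, ["a"])["a"].template, [2.0, 2.0]
        )

    def test_matches_accumulation_oracle(self, rng):
        rows = [rng.integers(1, 5, size=10) for _ in range(6)]
        seqs = make_sequences(
            rows, ["a"] * 6, [f"s{i}" for i in range(6)], S=4
        )
        template = build_class_indices(seqs, ["a"])["a"].template
        for col in range(10):
            total = 0
            for row in rows:
                total += row[col]
            assert template[col] == pytest.approx(total / 6)

    def test_mixed_lengths(self):
        seqs = make_sequences([[1, 2], [1, 2, 3]], ["a", "a"], ["s1", "s2"], S=3)
        with pytest.raises(DomainError, match="length"):
            build_class_indices(seqs, ["a"])

    def test_empty_class_named(self):
        seqs = make_sequences([[1, 2]], ["a"], ["s1"], S=2)
        with pytest.raises(DomainError, match="'b'"):
            build_class_indices(seqs, ["a", "b"])

    def test_per_subject_weighting(self):
        # subject s1 has two trials, s2 one; per-subject weighting averages
        # s1's trials before pooling, per-trial weighting does not
        seqs = make_sequences(
            [[1, 1], [3, 3], [5, 5]], ["a", "a", "a"], ["s1", "s1", "s2"], S=5
        )
        per_trial = build_class_indices(seqs, ["a"], weighting="per_trial")
        per_subject = build_class_indices(seqs, ["a"], weighting="per_subject")
        np.testing.assert_allclose(per_trial["a"].template, [3.0, 3.0])
        np.testing.assert_allclose(per_subject["a"].template, [3.5, 3.5])


class TestClassifySequence:
    def test_self_similarity_wins(self, rng):
        target = rng.integers(1, 5, size=30)
        other = rng.integers(1, 5, size=30)
        seqs = make_sequences([target, other], ["a", "b"], ["s1", "s1"], S=4)
        indices = build_class_indices(seqs, ["a", "b"])
        test_seq = make_sequences([target], ["a"], ["s2"], S=4)[0]
        scores = classify_sequence(test_seq, indices, ["a", "b"])
        assert scores.predicted == "a"
        assert scores.per_label["a"] == pytest.approx(1.0)

    def test_identical_templates_tie(self):
        seqs = make_sequences([[1, 2, 3], [1, 2, 3]], ["a", "b"], ["s1", "s1"], S=3)
        indices = build_class_indices(seqs, ["a", "b"])
        test_seq = make_sequences([[3, 2, 1]], [None], ["s2"], S=3)[0]
        scores = classify_sequence(test_seq, indices, ["b", "a"])
        assert scores.tie_flag
        assert scores.predicted == "b"  # earliest in the supplied order

    def test_three_class_hand_computed(self):
        # length-4 vectors; expected cosines computed with the manual loop
        templates = {"a": [1, 1, 2, 2], "b": [2, 2, 1, 1], "c": [1, 2, 1, 2]}
        seqs = make_sequences(
            list(templates.values()), list(templates), ["s1"] * 3, S=2
        )
        indices = build_class_indices(seqs, list(templates))
        probe = [1, 1, 2, 1]
        test_seq = make_sequences([probe], [None], ["s2"], S=2)[0]
        scores = classify_sequence(test_seq, indices, list(templates))
        for label, template in templates.items():
            assert scores.per_label[label] == pytest.approx(
                manual_cosine(probe, template), rel=1e-12
            )
        expected = max(templates, key=lambda k: manual_cosine(probe, templates[k]))
        assert scores.predicted == expected

    def test_length_mismatch(self):
        seqs = make_sequences([[1, 2], [2, 1]], ["a", "b"], ["s1", "s1"], S=2)
        indices = build_class_indices(seqs, ["a", "b"])
        test_seq = make_sequences([[1, 2, 1]], [None], ["s2"], S=2)[0]
        with pytest.raises(DomainError):
            classify_sequence(test_seq, indices, ["a", "b"])


def _separable_dataset(n_subjects=4):
    """Each class's sequence is identical across subjects and distinct."""
    class_patterns = {"a": [1, 1, 1, 4], "b": [4, 4, 4, 1], "c": [1, 4, 1, 4]}
    rows, labels, subjects = [], [], []
    for i in range(n_subjects):
        for label, pattern in class_patterns.items():
            rows.append(pattern)
            labels.append(label)
            subjects.append(f"s{i}")
    return make_sequences(rows, labels, subjects, S=4)


class TestLosoEvaluate:
    def test_perfect_separability(self):
        report = loso_evaluate(_separable_dataset(), ["a", "b", "c"])
        assert report.total_accuracy_micro == 1.0
        assert report.total_accuracy_mean_subject == 1.0
        assert np.trace(report.confusion) == report.confusion.sum()
        assert report.n_folds == 4

    def test_confusion_conservation(self, rng):
        rows = [rng.integers(1, 5, size=12) for _ in range(12)]
        labels = ["a", "b"] * 6
        subjects = [f"s{i // 2}" for i in range(12)]
        report = loso_evaluate(
            make_sequences(rows, labels, subjects, S=4), ["a", "b"]
        )
        assert report.confusion.sum() == 12

    def test_random_labels_near_chance(self, rng):
        # 50 Monte-Carlo replicates of random sequences with balanced labels
        hits = 0
        total = 0
        for _ in range(50):
            rows = [rng.integers(1, 5, size=16) for _ in range(16)]
            labels = ["a", "b"] * 8
            subjects = [f"s{i // 2}" for i in range(16)]
            report = loso_evaluate(
                make_sequences(rows, labels, subjects, S=4), ["a", "b"]
            )
            hits += int(np.trace(report.confusion))
            total += int(report.confusion.sum())
        p_hat = hits / total
        half_width = 2.576 * math.sqrt(0.25 / total)
        assert abs(p_hat - 0.5) <= half_width

    def test_subject_missing_class(self):
        seqs = make_sequences(
            [[1, 2], [2, 1], [1, 2]], ["a", "b", "a"], ["s1", "s1", "s2"], S=2
        )
        with pytest.raises(ProtocolError, match="'s2'.*'b'"):
            loso_evaluate(seqs, ["a", "b"])

    def test_single_subject(self):
        seqs = make_sequences([[1, 2], [2, 1]], ["a", "b"], ["s1", "s1"], S=2)
        with pytest.raises(ProtocolError, match="2 subjects"):
            loso_evaluate(seqs, ["a", "b"])

    def test_no_leakage(self, monkeypatch):
        """Every fold's training set provably excludes the held-out subject."""
        seen: list[tuple[set, set]] = []
        real_build = classify_mod.build_class_indices

        def spy(training, class_labels=None, weighting="per_trial"):
            seen.append(set(s.subject_id for s in training))
            return real_build(training, class_labels, weighting=weighting)

        monkeypatch.setattr(classify_mod, "build_class_indices", spy)
        dataset = _separable_dataset(5)
        loso_evaluate(dataset, ["a", "b", "c"])
        all_subjects = {s.subject_id for s in dataset}
        assert len(seen) == 5
        held_out = [all_subjects - train for train in seen]
        assert sorted(next(iter(h)) for h in held_out) == sorted(all_subjects)

    def test_indices_unaffected_by_held_out_corruption(self, rng):
        """Corrupting one subject's symbols leaves that fold's templates
        unchanged, because its data never enters training."""
        dataset = _separable_dataset(4)
        train = [s for s in dataset if s.subject_id != "s0"]
        clean = build_class_indices(train, ["a", "b", "c"])
        corrupted_dataset = []
        for s in dataset:
            if s.subject_id == "s0":
                s = make_sequences(
                    [rng.integers(1, 5, size=4)], [s.label], ["s0"], S=4
                )[0]
            corrupted_dataset.append(s)
        train2 = [s for s in corrupted_dataset if s.subject_id != "s0"]
        dirty = build_class_indices(train2, ["a", "b", "c"])
        for label in clean:
            np.testing.assert_array_equal(
                clean[label].template, dirty[label].template
            )

    def test_table_micro_accuracy(self):
        # two-class confusion with counts (32, 0; 1, 31)
        seqs = _separable_dataset(2)
        report = loso_evaluate(seqs, ["a", "b", "c"])
        _, micro = accuracy_from_confusion(np.array([[32, 0], [1, 31]]))
        assert micro == pytest.approx(0.984375)
        assert report is not None


class TestAccuracyFromConfusion:
    def test_identity_like(self):
        per_class, micro = accuracy_from_confusion(np.diag([5, 5]))
        assert per_class == [1.0, 1.0]
        assert micro == 1.0

    def test_four_class_table(self):
        confusion = np.array(
            [
                [29, 0, 3, 0],
                [0, 29, 2, 1],
                [1, 2, 29, 0],
                [3, 0, 2, 27],
            ]
        )
        per_class, micro = accuracy_from_confusion(confusion)
        assert per_class == pytest.approx([0.90625, 0.90625, 0.90625, 0.84375])
        assert micro == pytest.approx(114 / 128)

    def test_five_class_table_micro(self):
        confusion = np.array(
            [
                [26, 0, 3, 0, 3],
                [0, 29, 2, 0, 1],
                [1, 2, 28, 0, 1],
                [2, 0, 2, 27, 1],
                [3, 0, 2, 1, 26],
            ]
        )
        _, micro = accuracy_from_confusion(confusion)
        assert micro == pytest.approx(0.85)

    def test_zero_row_reported_absent(self):
        per_class, micro = accuracy_from_confusion(
            np.array([[3, 0], [0, 0]])
        )
        assert per_class == [1.0, None]
        assert micro == 1.0

    def test_non_square(self):
        with pytest.raises(DomainError):
            accuracy_from_confusion(np.zeros((2, 3), dtype=int))
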