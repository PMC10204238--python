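"""Case-based reasoning: featurization, similarity kernel, k-NN
classification, leave-one-out fitness, and the GA optimizer."""

import numpy as np
import pytest

from headdx.cbr import (CaseBase, Feature, FeatureSchema, FeatureWeights,
                        GAParams, classify_cbr, featurize, hybrid_diagnose,
                        loo_accuracy, optimize_weights_ga, similarity)
from headdx.cohort import generate_patient, planted_casebase
from headdx.records import DiagnosisLabel as L
from headdx.vignettes import borderline_pm_ptth, make_record

MIXED = FeatureSchema((
    Feature(name="x", kind="numeric", range=(0, 1)),
    Feature(name="cat", kind="categorical", categories=("a", "b")),
))
BIN3 = FeatureSchema(tuple(
    Feature(name=f"b{i}", kind="binary") for i in range(3)))


class TestFeaturize:
    def test_vas_min_max_scaled(self, schema, mo_record):
        vec = dict(zip(schema.names, featurize(mo_record, schema)))
        assert vec["vas"] == pytest.approx(6 / 9)

    def test_categorical_kept_symbolic(self, schema, mo_record):
        vec = dict(zip(schema.names, featurize(mo_record, schema)))
        assert vec["laterality"] == "unilateral"

    def test_duration_scaling_hand_arithmetic(self, schema):
        record = make_record(duration=4320)
        vec = dict(zip(schema.names, featurize(record, schema)))
        assert vec["duration_minutes"] == pytest.approx((4320 - 5) / 10075)

    def test_unresolvable_feature_named_in_error(self, mo_record):
        bad = FeatureSchema((Feature(name="shoe_size", kind="numeric",
                                     range=(0, 60)),))
        with pytest.raises(ValueError, match="shoe_size"):
            featurize(mo_record, bad)


class TestSimilarity:
    def test_identity_is_one(self):
        w = FeatureWeights.uniform(2)
        assert similarity([0.3, "a"], [0.3, "a"], w, MIXED) == pytest.approx(1.0)

    def test_fully_discordant_binary_vectors_score_zero(self):
        w = FeatureWeights.uniform(3)
        assert similarity([0, 1, 0], [1, 0, 1], w, BIN3) == pytest.approx(0.0)

    def test_hand_example_mixed_types(self):
        w = FeatureWeights((0.5, 0.5))
        # 0.5 * (1 - |0.2 - 0.6|) + 0.5 * [a == a] = 0.5*0.6 + 0.5 = 0.8
        assert similarity([0.2, "a"], [0.6, "a"], w, MIXED) == pytest.approx(0.8)

    def test_symmetry_and_bounds_on_random_vectors(self, rng):
        schema = FeatureSchema((
            Feature(name="n1", kind="numeric", range=(0, 1)),
            Feature(name="b1", kind="binary"),
            Feature(name="c1", kind="categorical", categories=("a", "b", "c")),
        ))
        for _ in range(200):
            x = [float(rng.random()), float(rng.integers(2)),
                 str(rng.choice(["a", "b", "c"]))]
            y = [float(rng.random()), float(rng.integers(2)),
                 str(rng.choice(["a", "b", "c"]))]
            w = FeatureWeights.normalized(rng.random(3))
            sxy = similarity(x, y, w, schema)
            assert 0.0 <= sxy <= 1.0 + 1e-12
            assert sxy == pytest.approx(similarity(y, x, w, schema))
            assert similarity(x, x, w, schema) == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            similarity([0.1], [0.1, "a"], FeatureWeights.uniform(2), MIXED)

    def test_weights_must_be_normalized_nonnegative(self):
        with pytest.raises(ValueError):
            FeatureWeights((0.5, 0.6))
        with pytest.raises(ValueError):
            FeatureWeights((-0.5, 1.5))


class TestClassify:
    def test_exact_match_wins_with_k1(self):
        base = CaseBase(BIN3, [[0, 0, 1], [1, 1, 0]], [L.PM, L.PTTH])
        assert classify_cbr([1, 1, 0], base, k=1) == L.PTTH

    def test_single_label_base_always_returns_it(self, rng):
        base = CaseBase(BIN3, [[0, 0, 0], [1, 1, 1]], [L.PM, L.PM])
        for _ in range(10):
            vec = [float(b) for b in rng.integers(0, 2, 3)]
            assert classify_cbr(vec, base) == L.PM

    def test_three_case_toy_base_with_concentrated_weight(self):
        # all weight on the first feature: only it decides the neighbour
        base = CaseBase(BIN3, [[1, 0, 0], [0, 1, 1], [0, 0, 0]],
                        [L.PM, L.PTTH, L.PTTH])
        w = FeatureWeights((1.0, 0.0, 0.0))
        assert classify_cbr([1, 1, 1], base, w, k=1) == L.PM

    def test_k_must_be_odd(self):
        base = CaseBase(BIN3, [[0, 0, 0], [1, 1, 1]], [L.PM, L.PTTH])
        with pytest.raises(ValueError):
            classify_cbr([0, 0, 0], base, k=2)

    def test_k1_equals_brute_force_argmax_on_random_bases(self, rng):
        schema = FeatureSchema((
            Feature(name="n1", kind="numeric", range=(0, 1)),
            Feature(name="n2", kind="numeric", range=(0, 1)),
            Feature(name="b1", kind="binary"),
        ))
        for _ in range(10):
            n = int(rng.integers(5, 50))
            vectors = [[float(rng.random()), float(rng.random()),
                        float(rng.integers(2))] for _ in range(n)]
            labels = [L.PM if rng.random() < 0.5 else L.PTTH for _ in range(n)]
            base = CaseBase(schema, vectors, labels)
            w = FeatureWeights.normalized(rng.random(3))
            probe = [float(rng.random()), float(rng.random()),
                     float(rng.integers(2))]
            sims = [similarity(probe, v, w, schema) for v in vectors]
            assert classify_cbr(probe, base, w, k=1) == \
                labels[int(np.argmax(sims))]


class TestLooAccuracy:
    def test_identical_vectors_same_label(self):
        base = CaseBase(BIN3, [[1, 0, 1], [1, 0, 1]], [L.PM, L.PM])
        assert loo_accuracy(base) == 1.0

    def test_identical_vectors_different_labels(self):
        base = CaseBase(BIN3, [[1, 0, 1], [1, 0, 1]], [L.PM, L.PTTH])
        assert loo_accuracy(base) == 0.0

    def test_xor_structured_base_hand_enumeration(self):
        # every case's nearest neighbours carry the opposite XOR label
        schema = FeatureSchema((Feature(name="a", kind="binary"),
                                Feature(name="b", kind="binary")))
        base = CaseBase(schema,
                        [[0, 0], [0, 1], [1, 0], [1, 1]],
                        [L.PM, L.PTTH, L.PTTH, L.PM])
        assert loo_accuracy(base) == 0.0

    def test_generic_k_agrees_with_fast_path(self, rng):
        cb, _ = planted_casebase(n_cases=12, n_noise=3, seed=3)
        w = FeatureWeights.normalized(rng.random(4))
        fast = loo_accuracy(cb, w, k=1)
        slow = sum(
            classify_cbr(cb.vectors[i],
                         CaseBase(cb.schema,
                                  cb.vectors[:i] + cb.vectors[i + 1:],
                                  cb.labels[:i] + cb.labels[i + 1:]),
                         w, k=1) == cb.labels[i]
            for i in range(len(cb))) / len(cb)
        assert fast == pytest.approx(slow)


class TestGA:
    def test_same_seed_reproduces_weights_exactly(self):
        cb, _ = planted_casebase(seed=4)
        params = GAParams(seed=11, generations=15)
        w1, h1 = optimize_weights_ga(cb, params)
        w2, h2 = optimize_weights_ga(cb, params)
        assert w1.w == w2.w and h1 == h2

    def test_single_label_base_is_solved_at_generation_zero(self):
        base = CaseBase(BIN3, [[0, 0, 0], [1, 1, 1], [0, 1, 0]],
                        [L.PM, L.PM, L.PM])
        _, history = optimize_weights_ga(base, GAParams(seed=0))
        assert history[0]["best"] == 1.0

    def test_running_best_is_nondecreasing(self):
        cb, _ = planted_casebase(seed=9)
        _, history = optimize_weights_ga(cb, GAParams(seed=9, generations=30))
        best = [h["best"] for h in history]
        assert best == sorted(best)

    def test_planted_informative_feature_recovered(self):
        cb, planted = planted_casebase(seed=1)
        weights, _ = optimize_weights_ga(cb, GAParams(seed=1))
        assert int(np.argmax(weights.w)) == planted
        assert loo_accuracy(cb, weights) >= loo_accuracy(cb)

    def test_degenerate_case_base_rejected(self):
        with pytest.raises(ValueError):
            CaseBase(BIN3, [[0, 0, 0]], [L.PM])


class TestHybrid:
    def test_rule_path_skips_cbr(self, mo_record, pm_ptth_casebase):
        result = hybrid_diagnose(mo_record, casebase=pm_ptth_casebase)
        assert (result.label, result.method) == (L.MO, "rule")

    def test_borderline_goes_to_cbr_and_matches_nearest_case(
            self, pm_ptth_casebase):
        result = hybrid_diagnose(borderline_pm_ptth(),
                                 casebase=pm_ptth_casebase)
        assert (result.label, result.method) == (L.PM, "cbr")

    def test_borderline_without_relevant_cases_lands_in_others(self):
        base = CaseBase(BIN3, [[0, 0, 0], [1, 1, 1]], [L.MO, L.CH])
        result = hybrid_diagnose(borderline_pm_ptth(), casebase=base)
        assert result.label == L.OTHERS
        assert result.notes

    def test_red_flags_annotate_but_never_suppress(self, rng):
        record = generate_patient(L.MO, 1.0, rng, red_flag=True)
        result = hybrid_diagnose(record)
        assert result.label == L.MO
        assert result.pending_secondary_exclusion
        assert result.warnings


def test_casebase_csv_round_trip(tmp_path, schema, rng):
    from headdx.cohort import generate_casebase
    base = generate_casebase(n_per_label=5, seed=2)
    path = tmp_path / "cases.csv"
    base.to_csv(path)
    again = CaseBase.from_csv(path, schema)
    assert again.labels == base.labels
    for a, b in zip(again.vectors, base.vectors):
        for va, vb in zip(a, b):
            if isinstance(va, float):
                assert va == pytest.approx(vb)
            else:
                assert va == vb
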