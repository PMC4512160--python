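"""Training-label stratification, grid search, calibrated SVM train/predict."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bdc import (
    GridConfig,
    SampleAnnotation,
    SimConfig,
    SVMHyperparams,
    TrainedModel,
    TrainingThresholdConfig,
    grid_search,
    predict,
    simulate_cohort,
    stratify_training_labels,
    train,
    train_classifier,
)
from bdc.normalization import zscore_normalize

from conftest import FIXED_HP


def _annotations(probs):
    return [
        SampleAnnotation(sample_id=f"s{i}", class_probability=p)
        for i, p in enumerate(probs)
    ]


class TestStratifyTrainingLabels:
    def test_strict_threshold(self):
        labels = stratify_training_labels(
            _annotations([0.96, 0.6]), TrainingThresholdConfig(0.95)
        )
        assert labels["s0"] == "BL"
        assert labels["s1"] == "DLBCL"

    def test_wide_threshold_flips_intermediate(self):
        labels = stratify_training_labels(
            _annotations([0.6]), TrainingThresholdConfig(0.5)
        )
        assert labels["s0"] == "BL"

    def test_missing_probability_errors(self):
        anns = _annotations([0.9]) + [SampleAnnotation(sample_id="nop")]
        with pytest.raises(ValueError, match="nop"):
            stratify_training_labels(anns, TrainingThresholdConfig(0.95))

    def test_exclusion_variant_drops_mid_probability_samples(self):
        labels = stratify_training_labels(
            _annotations([0.97, 0.5, 0.02]),
            TrainingThresholdConfig(0.95),
            exclude_below_threshold=True,
        )
        assert set(labels.index) == {"s0", "s2"}
        assert labels["s0"] == "BL" and labels["s2"] == "DLBCL"

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0, 1), min_size=1, max_size=30),
        st.tuples(
            st.floats(0.05, 0.95), st.floats(0.05, 0.95)
        ).map(lambda t: (max(t), min(t))).filter(lambda t: t[0] > t[1]),
    )
    def test_label_nesting(self, probs, thresholds):
        """BL set at a stricter threshold is nested in the wider one."""
        t1, t2 = thresholds
        anns = _annotations(probs)
        bl1 = {
            s for s, l in stratify_training_labels(
                anns, TrainingThresholdConfig(t1)
            ).items() if l == "BL"
        }
        bl2 = {
            s for s, l in stratify_training_labels(
                anns, TrainingThresholdConfig(t2)
            ).items() if l == "BL"
        }
        assert bl1 <= bl2


class TestGridConfig:
    def test_default_grid_is_11_by_10(self):
        grid = GridConfig()
        assert len(grid.c_exponents) == 11
        assert len(grid.gamma_exponents) == 10
        assert len(grid.candidates()) == 110
        assert grid.c_exponents == tuple(range(-5, 16, 2))
        assert grid.gamma_exponents == tuple(range(3, -16, -2))

    def test_empty_exponents_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            GridConfig(c_exponents=())

    def test_candidate_order_supports_tie_break(self):
        # smallest c first, then largest gamma within each c
        cands = GridConfig().candidates()
        assert cands[0] == SVMHyperparams(c=2.0**-5, gamma=2.0**3)
        assert cands[1].gamma < cands[0].gamma
        assert cands[9].c == 2.0**-5 and cands[10].c == 2.0**-3


class TestGridSearch:
    def test_separable_cohort_reaches_high_cv_accuracy(self):
        """Strong-signal synthetic cohorts should grid-search to >=95% CV accuracy."""
        from bdc.classifier import _cv_accuracy
        from sklearn.model_selection import StratifiedKFold

        for seed in range(5):
            cohort = simulate_cohort(
                SimConfig(
                    n_genes=28, n_signature=28, n_bl=60, n_dlbcl=60,
                    n_intermediate=0, effect_size=3.0, seed=seed,
                )
            )
            sub, _ = zscore_normalize(cohort.platform_a)
            y = np.array([cohort.truth_labels[s] for s in sub.sample_ids])
            grid = GridConfig(seed=seed)
            hp = grid_search(sub, y, grid)
            folds = list(
                StratifiedKFold(5, shuffle=True, random_state=seed).split(
                    sub.values.T, y
                )
            )
            acc, _ = _cv_accuracy(sub.values.T, y, hp, folds, seed)
            assert acc >= 0.95

    def test_single_class_rejected(self, small_cohort):
        sub, _ = zscore_normalize(
            small_cohort.platform_a.subset_genes(
                list(small_cohort.signature_genes.symbols)
            )
        )
        with pytest.raises(ValueError, match="both classes"):
            grid_search(sub, ["BL"] * sub.n_samples)


@pytest.fixture(scope="module")
def normalized_training(small_cohort):
    sub = small_cohort.platform_a.subset_genes(
        list(small_cohort.signature_genes.symbols)
    )
    keep = [
        s for s in sub.sample_ids
        if small_cohort.truth_labels[s] != "intermediate"
    ]
    from dataclasses import replace

    sub = replace(sub, data=sub.data[keep])
    normalized, stats = zscore_normalize(sub)
    y = np.array([small_cohort.truth_labels[s] for s in keep])
    return normalized, y, stats


class TestTrainPredict:

    def test_training_set_accuracy(self, normalized_training):
        x, y, stats = normalized_training
        model = train(x, y, FIXED_HP, seed=0, frozen_stats=stats)
        results = predict(model, x)
        pred = np.array([r.predicted_class for r in results])
        assert (pred == y).mean() >= 0.95

    def test_probabilities_complementary_and_rule_consistent(
        self, trained_model, small_cohort
    ):
        results = predict(trained_model, small_cohort.platform_b)
        for r in results:
            assert 0.0 <= r.bl_probability <= 1.0
            expected = "BL" if r.bl_probability > 0.5 else "DLBCL"
            assert r.predicted_class == expected

    def test_heldout_bl_probability_high_at_strong_effect(self):
        cohort = simulate_cohort(
            SimConfig(
                n_genes=300, n_signature=28, n_bl=50, n_dlbcl=50,
                n_intermediate=0, effect_size=3.0, seed=5,
            )
        )
        model = train_classifier(
            cohort.platform_a, cohort.annotations, cohort.signature_genes,
            seed=5,
        )
        from bdc.evaluation import _normalize_for_mode

        sub = cohort.platform_b.subset_genes(list(model.gene_order.symbols))
        results = predict(model, _normalize_for_mode(sub, "zscore"))
        bl_probs = [
            r.bl_probability for r in results
            if cohort.truth_labels[r.sample_id] == "BL"
        ]
        assert np.mean(bl_probs) > 0.9

    def test_balanced_cohort_mean_probability_near_half(
        self, trained_model, small_cohort
    ):
        from dataclasses import replace

        from bdc.evaluation import _normalize_for_mode

        keep = [
            s for s in small_cohort.platform_b.sample_ids
            if small_cohort.truth_labels[s] != "intermediate"
        ]
        sub = replace(
            small_cohort.platform_b, data=small_cohort.platform_b.data[keep]
        )
        sub = sub.subset_genes(list(trained_model.gene_order.symbols))
        results = predict(trained_model, _normalize_for_mode(sub, "zscore"))
        mean_p = np.mean([r.bl_probability for r in results])
        assert 0.4 <= mean_p <= 0.6

    def test_single_class_training_rejected(self, normalized_training):
        x, y, _ = normalized_training
        with pytest.raises(ValueError, match="both classes"):
            train(x, np.array(["BL"] * len(y)), FIXED_HP)

    def test_missing_gene_strict_mode_errors(self, trained_model, small_cohort):
        from dataclasses import replace

        dropped_gene = trained_model.gene_order.symbols[0]
        crippled = replace(
            small_cohort.platform_b,
            data=small_cohort.platform_b.data.drop(index=dropped_gene),
        )
        with pytest.raises(ValueError, match=dropped_gene):
            predict(trained_model, crippled)

    def test_missing_gene_imputed_with_allow_missing(
        self, trained_model, small_cohort
    ):
        from dataclasses import replace

        dropped_gene = trained_model.gene_order.symbols[0]
        crippled = replace(
            small_cohort.platform_b,
            data=small_cohort.platform_b.data.drop(index=dropped_gene),
        )
        with pytest.warns(UserWarning, match=dropped_gene):
            results = predict(trained_model, crippled, allow_missing=True)
        assert len(results) == small_cohort.platform_b.n_samples


class TestModelSerialization:
    def test_round_trip_preserves_probabilities_bitwise(
        self, trained_model, small_cohort, tmp_path
    ):
        path = tmp_path / "model.json"
        trained_model.save(path)
        loaded = TrainedModel.load(path)
        before = predict(trained_model, small_cohort.platform_b)
        after = predict(loaded, small_cohort.platform_b)
        assert [r.bl_probability for r in before] == [
            r.bl_probability for r in after
        ]
        assert loaded.hyperparams == trained_model.hyperparams
        assert loaded.gene_order.symbols == trained_model.gene_order.symbols

    def test_unknown_format_version_rejected(self, trained_model, tmp_path):
        import json

        path = tmp_path / "model.json"
        trained_model.save(path)
        doc = json.loads(path.read_text())
        doc["format_version"] = 99
        path.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="format_version"):
            TrainedModel.load(path)
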