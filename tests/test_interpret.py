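"""Occlusion importance, concept classification and concept scores."""

import numpy as np
import pytest

from moma import synthesis
from moma.features import FeatureBag
from moma.interpret import (ConceptModel, ImportanceMap, concept_scores,
                            occlusion_importance, render_heatmap,
                            train_concept_classifier)
from moma.synthesis import CONCEPTS, make_concept_texture


def _bag(X, slide_id="s"):
    X = np.asarray(X, float)
    return FeatureBag(slide_id, X,
                      [f"{slide_id}_r0_c{i}" for i in range(len(X))])


class _ConstantModel:
    """Ignores its inputs: every forward returns the same probabilities."""

    def forward(self, bag, cluster_ids):
        class Out:
            class_probabilities = np.array([0.3, 0.7])
        return Out()


class _LinearLogitModel:
    """Surrogate whose logit is beta . mean(tile features): the occlusion
    delta has a closed form."""

    def __init__(self, beta):
        self.beta = np.asarray(beta, float)

    def prob(self, features):
        logit = self.beta @ features.mean(axis=0)
        p1 = 1.0 / (1.0 + np.exp(-logit))
        return np.array([1.0 - p1, p1])

    def forward(self, bag, cluster_ids):
        probs = self.prob(bag.features)

        class Out:
            class_probabilities = probs
        return Out()


class TestOcclusionImportance:
    def test_constant_model_gives_zero_importance(self):
        bag = _bag(np.random.default_rng(0).standard_normal((6, 4)))
        imp = occlusion_importance(bag, np.zeros(6, int), _ConstantModel())
        assert np.allclose(imp.importance, 0.0)

    def test_matches_analytic_delta_for_linear_logit(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((8, 5))
        beta = rng.standard_normal(5)
        model = _LinearLogitModel(beta)
        imp = occlusion_importance(_bag(X), np.zeros(8, int), model,
                                   target_class=1)
        for i in range(8):
            rest = np.delete(X, i, axis=0)
            expected = model.prob(X)[1] - model.prob(rest)[1]
            assert imp.importance[i] == pytest.approx(expected, abs=1e-6)

    def test_additive_logit_preserves_contribution_order(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((7, 3))
        beta = np.array([1.0, -0.5, 0.25])
        model = _LinearLogitModel(beta)
        imp = occlusion_importance(_bag(X), np.zeros(7, int), model).importance
        contrib = X @ beta
        assert np.array_equal(np.argsort(imp), np.argsort(contrib))

    def test_single_tile_falls_back_to_uniform_prior(self):
        model = _ConstantModel()
        imp = occlusion_importance(_bag(np.zeros((1, 4))), np.zeros(1, int), model)
        assert imp.importance[0] == pytest.approx(0.7 - 0.5)

    def test_planted_region_attains_maximal_importance(self, planted_pipeline):
        """On the trained planted cohort the tumor tiles of a positive test
        slide carry the highest occlusion importance."""
        pipe = planted_pipeline
        best = 0
        for sid in pipe.test_ids:
            if pipe.labels[sid] != 1:
                continue
            bag = pipe.bags[sid]
            imp = occlusion_importance(bag, pipe.assignments[sid].cluster_ids,
                                       pipe.model, target_class=1)
            coords = list(zip(imp.grid_rows, imp.grid_cols))
            is_tumor = np.array([tuple(rc) in pipe.tumor_tiles[sid]
                                 for rc in coords])
            if is_tumor[np.argmax(imp.importance)]:
                best += 1
        n_pos = sum(pipe.labels[s] == 1 for s in pipe.test_ids)
        assert best >= 0.8 * n_pos  # argmax tile is a planted tumor tile


class TestConceptClassifier:
    def test_high_holdout_accuracy(self, concept_model):
        assert concept_model.holdout_accuracy >= 0.99

    def test_training_deterministic(self):
        rng1 = np.random.default_rng(0)
        pairs = [(make_concept_texture(c, 64, int(rng1.integers(2**31))), c)
                 for c in CONCEPTS for _ in range(30)]
        m1 = train_concept_classifier(pairs, seed=0)
        m2 = train_concept_classifier(pairs, seed=0)
        test = np.stack([make_concept_texture(c, 64, 999) for c in CONCEPTS])
        assert m1.predict(test) == m2.predict(test)

    def test_missing_concept_rejected(self):
        pairs = [(make_concept_texture("TUM", 64, i), "TUM") for i in range(10)]
        with pytest.raises(ValueError, match="missing concept"):
            train_concept_classifier(pairs, seed=0)

    def test_per_class_accuracy_reported(self, concept_model):
        assert set(concept_model.per_class_accuracy) == set(CONCEPTS)

    def test_predict_proba_rows_simplex(self, concept_model):
        test = np.stack([make_concept_texture(c, 64, 5) for c in CONCEPTS])
        p = concept_model.predict_proba(test)
        assert p.shape == (7, 7)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-9)

    def test_model_roundtrip(self, concept_model, tmp_path):
        concept_model.save(tmp_path / "cm.npz")
        back = ConceptModel.load(tmp_path / "cm.npz")
        test = np.stack([make_concept_texture(c, 64, 3) for c in CONCEPTS])
        assert np.allclose(back.predict_proba(test),
                           concept_model.predict_proba(test))


def _one_hot_model(concepts_per_region):
    """A stub concept model that returns fixed one-hot rows."""

    class Stub:
        def predict_proba(self, patches):
            rows = np.zeros((len(patches), 7))
            for i, c in enumerate(concepts_per_region[:len(patches)]):
                rows[i, CONCEPTS.index(c)] = 1.0
            return rows
    return Stub()


def _map(importances):
    n = len(importances)
    return ImportanceMap("s", [f"s_r0_c{i}" for i in range(n)],
                         np.zeros(n, int), np.arange(n), np.array(importances))


class TestConceptScores:
    def test_single_selected_one_hot_region(self):
        imp = _map([0.9, 0.1])
        patches = np.zeros((2, 8, 8, 3), np.uint8)
        scores = concept_scores(imp, patches, _one_hot_model(["TUM", "STR"]),
                                threshold=0.7, scale="raw")
        assert scores["TUM"] == 100.0
        assert all(scores[c] == 0.0 for c in CONCEPTS if c != "TUM")

    def test_equal_raw_scores_both_scale_to_100(self):
        imp = _map([0.8, 0.8, 0.1])
        patches = np.zeros((3, 8, 8, 3), np.uint8)
        scores = concept_scores(imp, patches,
                                _one_hot_model(["TUM", "STR", "LYM"]),
                                threshold=0.7, scale="raw")
        assert scores["TUM"] == 100.0 and scores["STR"] == 100.0
        assert scores["LYM"] == 0.0

    def test_unreachable_threshold_gives_all_zero(self, caplog):
        import logging
        imp = _map([0.9, 0.5])
        patches = np.zeros((2, 8, 8, 3), np.uint8)
        with caplog.at_level(logging.WARNING, logger="moma.interpret"):
            scores = concept_scores(imp, patches, _one_hot_model(["TUM", "STR"]),
                                    threshold=1.01, scale="raw")
        assert all(v == 0.0 for v in scores.values())
        assert any("no region exceeds" in r.message for r in caplog.records)

    def test_max_is_100_when_selection_nonempty(self):
        rng = np.random.default_rng(3)
        imp = _map(rng.uniform(0.75, 1.0, 5))
        patches = np.zeros((5, 8, 8, 3), np.uint8)
        scores = concept_scores(
            imp, patches, _one_hot_model(["TUM", "STR", "LYM", "MUS", "MUC"]),
            threshold=0.7, scale="raw")
        assert max(scores.values()) == 100.0

    def test_invariant_to_region_order(self):
        # patch content encodes its concept so reversing region order must
        # not change the score dict
        class ContentStub:
            def predict_proba(self, patches):
                rows = np.zeros((len(patches), 7))
                for i, patch in enumerate(patches):
                    rows[i, int(patch[0, 0, 0])] = 1.0
                return rows

        imp_values = [0.9, 0.8, 0.2]
        patches = np.stack([np.full((8, 8, 3), i, np.uint8) for i in range(3)])
        fwd = concept_scores(_map(imp_values), patches, ContentStub(),
                             threshold=0.7, scale="raw")
        rev = concept_scores(_map(imp_values[::-1]), patches[::-1],
                             ContentStub(), threshold=0.7, scale="raw")
        assert fwd == rev

    def test_normalized_scale_rescales_importance(self):
        # raw importances below 0.7 still select after min-max normalization
        imp = _map([0.30, 0.05, 0.01])
        patches = np.zeros((3, 8, 8, 3), np.uint8)
        scores = concept_scores(imp, patches,
                                _one_hot_model(["TUM", "STR", "LYM"]),
                                threshold=0.7, scale="normalized")
        assert scores["TUM"] == 100.0


class TestHeatmap:
    def _slide_and_map(self):
        img = np.full((64, 128, 3), 200, np.uint8)
        imp = ImportanceMap("s", ["s_r0_c0", "s_r0_c1"], np.array([0, 0]),
                            np.array([0, 1]), np.array([0.0, 0.8]))
        return img, imp

    def test_zero_importance_blends_neutral_color(self):
        img, _ = self._slide_and_map()
        imp = ImportanceMap("s", ["s_r0_c0"], np.array([0]), np.array([0]),
                            np.array([0.0]))
        out = render_heatmap(imp, img[:, :64], 64, alpha=0.4)
        from matplotlib import colormaps
        neutral = 255.0 * np.array(colormaps["coolwarm"](0.5)[:3])
        expected = np.round(0.6 * 200 + 0.4 * neutral)
        assert np.all(np.abs(out[:, :64].astype(float) - expected) <= 1)

    def test_monotone_importance_monotone_red_channel(self):
        img = np.full((32, 96, 3), 200, np.uint8)
        imp = ImportanceMap("s", [f"s_r0_c{i}" for i in range(3)],
                            np.zeros(3, int), np.arange(3),
                            np.array([-0.5, 0.0, 0.5]))
        out = render_heatmap(imp, img, 32)
        reds = [out[16, 16 + 32 * i, 0].astype(int) for i in range(3)]
        blues = [out[16, 16 + 32 * i, 2].astype(int) for i in range(3)]
        assert reds[0] < reds[1] < reds[2]
        assert blues[0] > blues[1] > blues[2]

    def test_rendering_deterministic(self, tmp_path):
        img, imp = self._slide_and_map()
        p1, p2 = tmp_path / "a.png", tmp_path / "b.png"
        render_heatmap(imp, img, 64, out_path=p1)
        render_heatmap(imp, img, 64, out_path=p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_size_mismatch_rejected(self):
        img, imp = self._slide_and_map()
        with pytest.raises(ValueError, match="fit"):
            render_heatmap(imp, img[:32], 64)
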