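"""Embedding and random-forest classification: separability, determinism, ROC."""

import numpy as np
import pytest

import hoofbeats as hb
from hoofbeats import pipeline
from hoofbeats.classify import ClassifierReport, roc_curves
from hoofbeats.errors import InvalidParameterError, ValidationError


@pytest.fixture(scope="module")
def separable_embedding():
    # near-zero jitter: clusters remain trivially separable, while the tiny
    # dither avoids massed duplicate rows that would push umap-learn onto
    # its non-reproducible random-init fallback
    from dataclasses import replace

    specs = [replace(s, jitter_cv=0.002) for s in hb.default_specs(duration_s=30.0)]
    pop = hb.PopulationSpec(n_individuals=3, individual_tempo_sd=0.15, seed=1)
    recs = hb.simulate_population(pop, specs)
    triplets = pipeline.build_triplet_table(recs)
    return hb.embed_triplets(triplets, n_neighbors=10, seed=1)


def test_zero_jitter_gaits_classified_perfectly(separable_embedding):
    rep = hb.train_classifier(separable_embedding, "gait", n_trees=100, seed=1)
    assert rep.overall_accuracy_pct == 100.0
    assert rep.oob_error_pct < 2.0
    assert all(a == 1.0 for a in rep.per_class_auc.values())
    # confusion matrix rows sum to training class totals
    assert (rep.confusion.sum(axis=1) > 0).all()
    assert rep.confusion.values.sum() == len(rep.train_idx)


def test_embedding_deterministic_under_seed():
    # jittered data: duplicate-free rows keep the spectral initialization
    # (and hence the full embedding) on its seeded path
    pop = hb.PopulationSpec(n_individuals=2, individual_tempo_sd=0.1, seed=3)
    recs = hb.simulate_population(pop, hb.default_specs(20.0))
    triplets = pipeline.build_triplet_table(recs)
    a = hb.embed_triplets(triplets, n_neighbors=10, seed=9)
    b = hb.embed_triplets(triplets, n_neighbors=10, seed=9)
    assert np.array_equal(a.coords, b.coords)


def test_classifier_report_deterministic(separable_embedding):
    a = hb.train_classifier(separable_embedding, "gait", n_trees=50, seed=4)
    b = hb.train_classifier(separable_embedding, "gait", n_trees=50, seed=4)
    assert a.oob_error_pct == b.oob_error_pct
    assert a.overall_accuracy_pct == b.overall_accuracy_pct
    assert a.confusion.equals(b.confusion)
    assert np.array_equal(a.train_idx, b.train_idx)


def test_gait_clusters_have_high_silhouette(tiny_embedding):
    from sklearn.metrics import silhouette_score

    score = silhouette_score(tiny_embedding.coords, tiny_embedding.gait)
    assert score > 0.5


def test_permuted_labels_fall_to_chance(tiny_embedding):
    """A label-permutation null: held-out accuracy near the majority rate."""
    # balance classes so the chance level equals the majority-class rate
    n_min = min(np.sum(tiny_embedding.gait == g) for g in set(tiny_embedding.gait))
    keep = np.concatenate(
        [np.flatnonzero(tiny_embedding.gait == g)[:n_min] for g in sorted(set(tiny_embedding.gait))]
    )
    accs = []
    for perm_seed in range(4):
        rng = np.random.default_rng(perm_seed)
        shuffled = hb.EmbeddingResult(
            coords=tiny_embedding.coords[keep],
            individual_id=tiny_embedding.individual_id[keep],
            gait=rng.permutation(tiny_embedding.gait[keep]),
            n_neighbors=tiny_embedding.n_neighbors,
            min_dist=tiny_embedding.min_dist,
            metric=tiny_embedding.metric,
            seed=tiny_embedding.seed,
        )
        rep = hb.train_classifier(shuffled, "gait", n_trees=200, seed=0)
        accs.append(rep.test_accuracy_pct)
    majority_pct = 100.0 / 3.0
    assert abs(np.mean(accs) - majority_pct) < 5.0


def test_error_trace_consistent_with_final_accuracy(separable_embedding):
    rep = hb.train_classifier(separable_embedding, "gait", n_trees=60, seed=2)
    assert rep.error_trace["n_trees"].iloc[-1] == 60
    final = rep.error_trace["test_error"].iloc[-1]
    assert np.isclose(100.0 * (1.0 - final), rep.test_accuracy_pct)


def test_importance_reported_for_both_dimensions(separable_embedding):
    rep = hb.train_classifier(separable_embedding, "gait", n_trees=50, seed=2)
    assert set(rep.importance) == {"V1", "V2"}
    assert np.isclose(rep.importance["V1"] + rep.importance["V2"], 1.0)


def _fake_report(y, scores, classes):
    return ClassifierReport(
        label_kind="gait", classes=classes, oob_error_pct=0.0,
        confusion=None, per_class_auc={}, overall_accuracy_pct=0.0,
        test_accuracy_pct=0.0, importance={}, error_trace=None,
        train_idx=np.arange(len(y)), test_idx=np.array([]), seed=0,
        train_scores=scores, test_scores=scores, y_train=y, y_test=y,
    )


def test_roc_perfect_and_reversed_scores(rng):
    y = np.array(["a"] * 500 + ["b"] * 500)
    perfect = np.column_stack([(y == "a").astype(float), (y == "b").astype(float)])
    curves = roc_curves(_fake_report(y, perfect, ["a", "b"]))
    assert curves["a"]["auc"] == 1.0 and curves["b"]["auc"] == 1.0
    random_scores = rng.uniform(size=(1000, 1))
    scores = np.column_stack([random_scores, 1 - random_scores])
    curves_rand = roc_curves(_fake_report(y, scores, ["a", "b"]))
    assert abs(curves_rand["a"]["auc"] - 0.5) < 0.05
    reversed_scores = scores[:, ::-1]
    curves_rev = roc_curves(_fake_report(y, reversed_scores, ["a", "b"]))
    assert np.isclose(curves_rev["a"]["auc"], 1.0 - curves_rand["a"]["auc"])


def test_roc_single_class_rejected():
    y = np.array(["a"] * 10)
    scores = np.ones((10, 1))
    with pytest.raises(ValidationError):
        roc_curves(_fake_report(y, scores, ["a"]))


def test_too_few_triplets_rejected(zero_jitter_specs):
    rec = hb.simulate_recording(
        next(s for s in zero_jitter_specs if s.gait == "walk"), seed=0
    )
    triplets = hb.make_triplets(hb.compute_intervals(rec))
    with pytest.raises(InvalidParameterError):
        hb.embed_triplets(triplets, n_neighbors=len(triplets) + 5)
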