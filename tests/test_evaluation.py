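import numpy as np
import pandas as pd
import pytest

from netfeat import (
    CVConfig,
    GeneNetwork,
    SimulationConfig,
    SubsampleConfig,
    ValidationError,
    auc,
    cnf_predict,
    compute_features,
    evaluate_feature_type,
    generate_study,
    run_cnf_cv,
    run_cv,
    subsample_experiment,
)
from netfeat.evaluation import fit_fold_model, fold_assignments, stratified_subsample

from conftest import random_dataset


def pairwise_auc_oracle(scores, labels):
    """O(n^2) Mann-Whitney count: wins + half-ties over all pos/neg pairs."""
    scores, labels = np.asarray(scores, dtype=float), np.asarray(labels)
    pos, neg = scores[labels == 1], scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


# -- AUC --------------------------------------------------------------------


def test_auc_perfect_separation():
    assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0


def test_auc_all_ties():
    assert auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5


@pytest.mark.parametrize("seed", range(8))
def test_auc_matches_pairwise_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, 200))
    scores = np.round(rng.standard_normal(n), 1)  # rounding forces ties
    labels = rng.integers(0, 2, size=n)
    if len(np.unique(labels)) < 2:
        labels[0], labels[1] = 0, 1
    assert auc(scores, labels) == pytest.approx(pairwise_auc_oracle(scores, labels))


def test_auc_single_class_rejected():
    with pytest.raises(ValidationError):
        auc([0.1, 0.2], [1, 1])


# -- cross-validation -------------------------------------------------------


def test_run_cv_shape_and_determinism():
    """10 repetitions x 5 folds gives exactly 50 AUCs; the same seed twice
    gives bitwise identical matrices."""
    dataset = random_dataset(20, 80, seed=1)
    fm = compute_features(dataset, "Gene")
    config = CVConfig(n_folds=5, n_repetitions=10, seed=42)
    res1 = run_cv(fm, dataset.outcome.to_numpy(), config)
    res2 = run_cv(fm, dataset.outcome.to_numpy(), config)
    assert res1.per_fold_auc.shape == (10, 5)
    np.testing.assert_array_equal(res1.per_fold_auc, res2.per_fold_auc)
    assert res1.mean_auc == pytest.approx(res1.per_fold_auc.mean())
    # a different seed reshuffles folds
    res3 = run_cv(fm, dataset.outcome.to_numpy(), CVConfig(n_repetitions=10, seed=43))
    assert not np.array_equal(res1.per_fold_auc, res3.per_fold_auc)


def test_null_features_score_near_half():
    """Label-independent features give mean AUC ~= 0.5 over several seeds."""
    means = []
    for seed in range(6):
        dataset = random_dataset(30, 300, seed=seed + 100)
        fm = compute_features(dataset, "Gene")
        res = run_cv(fm, dataset.outcome.to_numpy(), CVConfig(n_repetitions=2, seed=seed))
        means.append(res.mean_auc)
    assert abs(np.mean(means) - 0.5) < 0.05


def test_fold_assignments_are_stratified_partitions():
    y = np.array([1] * 20 + [0] * 60)
    config = CVConfig(n_folds=5, n_repetitions=3, seed=9)
    for folds in fold_assignments(y, config):
        all_idx = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(all_idx, np.arange(80))
        for test in folds:
            assert set(y[test]) == {0, 1}
            assert np.sum(y[test] == 1) == 4  # 20 positives over 5 folds


def test_standardization_uses_training_folds_only():
    """Perturbing a held-out patient never changes the fitted model."""
    rng = np.random.default_rng(3)
    X = rng.standard_normal((60, 8))
    y = np.arange(60) % 2
    train = np.arange(40)
    scaler1, model1 = fit_fold_model(X[train], y[train], CVConfig())
    X_perturbed = X.copy()
    X_perturbed[55] += 1e6  # a test-fold patient
    scaler2, model2 = fit_fold_model(X_perturbed[train], y[train], CVConfig())
    np.testing.assert_array_equal(scaler1.mean_, scaler2.mean_)
    np.testing.assert_array_equal(model1.coef_, model2.coef_)


# -- CNF --------------------------------------------------------------------


def test_cnf_predict_idempotent_and_mean():
    v = np.array([0.2, 0.7, 0.4])
    np.testing.assert_allclose(cnf_predict([v] * 8), v, rtol=1e-12)
    components = [[p] for p in (0.2, 0.4, 0.6, 0.8, 0.2, 0.4, 0.6, 0.8)]
    assert cnf_predict(components)[0] == pytest.approx(0.5)


def test_cnf_predict_validates_inputs():
    with pytest.raises(ValidationError, match="length"):
        cnf_predict([[0.1, 0.2], [0.3]])
    with pytest.raises(ValidationError, match="probabilities"):
        cnf_predict([[0.1], [1.3]])


def test_cnf_reduces_to_single_model_on_edgeless_networks():
    """With edgeless networks all eight component types equal the Gene
    features, so the ensemble equals any single component model exactly."""
    dataset = random_dataset(15, 60, seed=8)
    empty = GeneNetwork(nodes=dataset.gene_ids)
    networks = {"CE": empty, "PPI": empty}
    config = CVConfig(n_repetitions=2, seed=5)
    cnf = run_cnf_cv(dataset, networks, config)
    single = run_cv(
        compute_features(dataset, "CEMEAN", empty), dataset.outcome.to_numpy(), config
    )
    np.testing.assert_allclose(cnf.per_fold_auc, single.per_fold_auc, atol=1e-12)


def test_component_models_share_fold_splits():
    """Fold assignments depend only on (labels, config), so the eight CNF
    component models see bitwise identical splits within a repetition."""
    y = np.array([1] * 15 + [0] * 45)
    config = CVConfig(n_repetitions=2, seed=17)
    a = fold_assignments(y, config)
    b = fold_assignments(y, config)
    for folds_a, folds_b in zip(a, b):
        for fa, fb in zip(folds_a, folds_b):
            np.testing.assert_array_equal(fa, fb)


def _half_module_network(study, parity):
    """Cliques for every other module only; the rest stay isolated."""
    ms = study.config.module_size
    genes = sorted(study.true_network.nodes)
    index = {g: i for i, g in enumerate(genes)}
    edges = [
        (a, b)
        for a, b in study.true_network.edges
        if (index[a] // ms) % 2 == parity
    ]
    return GeneNetwork(edges=edges, nodes=genes)


def test_cnf_matches_best_component_on_complementary_views():
    """Two networks carrying disjoint halves of the module signal: no single
    component sees everything, and the probability-averaged ensemble keeps
    up with the (selection-biased) best of the eight components in the
    majority of seeds, up to one fold-level standard error."""
    wins = 0
    for seed in range(5):
        study = generate_study(
            SimulationConfig(n_genes=200, cohorts=(("c1", 100, 200),), seed=seed)
        )
        nets = {
            "CE": _half_module_network(study, 0),
            "PPI": _half_module_network(study, 1),
        }
        config = CVConfig(n_repetitions=2, seed=seed)
        cnf = run_cnf_cv(study.dataset, nets, config)
        components = [
            evaluate_feature_type(study.dataset, name, nets, config)
            for name in ("CEMEAN", "CEMED", "PPIMEAN", "PPIMED")
        ]
        best = max(res.mean_auc for res in components)
        se = cnf.per_fold_auc.std(ddof=1) / np.sqrt(cnf.per_fold_auc.size)
        if cnf.mean_auc >= best - se:
            wins += 1
    assert wins >= 3


# -- subsampling ------------------------------------------------------------


def test_stratified_subsample_preserves_class_ratio():
    dataset = random_dataset(10, 200, seed=2)
    rng = np.random.default_rng(0)
    sub = stratified_subsample(dataset, 0.5, rng)
    assert sub.n_patients == 100
    assert sub.outcome.sum() == 50  # half of the 100 positives


def test_subsample_grid_shape():
    """The default grid spans 90% down to 10% with 10 draws per level."""
    config = SubsampleConfig()
    assert len(config.percentages) == 9
    assert config.n_subsamples == 10
    assert config.percentages[0] == 0.9 and config.percentages[-1] == 0.1


def test_full_percentage_single_draw_equals_full_dataset(small_study, small_networks):
    dataset = small_study.dataset
    cv = CVConfig(n_repetitions=1, seed=4)
    curve = subsample_experiment(
        dataset,
        small_networks,
        cv,
        SubsampleConfig(percentages=(1.0,), n_subsamples=1, seed=0),
        feature_types=("Gene",),
    )
    fm = compute_features(dataset, "Gene")
    direct = run_cv(fm, dataset.outcome.to_numpy(), cv)
    assert curve["mean_auc"].iloc[0] == pytest.approx(direct.mean_auc)


def test_subsample_too_small_for_folds(small_study, small_networks):
    with pytest.raises(ValidationError):
        subsample_experiment(
            small_study.dataset,
            small_networks,
            CVConfig(n_folds=5, n_repetitions=1, seed=0),
            SubsampleConfig(percentages=(0.05,), n_subsamples=1, seed=0),
            feature_types=("Gene",),
        )
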