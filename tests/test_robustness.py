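import numpy as np
import pandas as pd
import pytest

from netfeat import (
    CoexpressionConfig,
    RobustnessConfig,
    ValidationError,
    build_mutual_knn,
    compute_features,
    compute_significance,
    overlap_fold_change,
    robustness_summary,
    select_top_genes,
)
from netfeat.network import degree_summary


def make_table(p_by_feature):
    return pd.DataFrame(
        {"feature_id": list(p_by_feature), "p_value": list(p_by_feature.values())}
    )


# -- top-gene selection -----------------------------------------------------


def test_node_based_selection_is_one_gene_per_feature():
    p = {f"g{i:03d}": (i + 1) / 201 for i in range(200)}
    config = RobustnessConfig(top_k_genes=160)
    genes = select_top_genes(make_table(p), "CEMEAN", {}, config)
    assert genes == [f"g{i:03d}" for i in range(160)]


def test_edge_pooling_stop_and_truncate():
    """Edges ranked [(a,b),(b,c),(d,e)] with target 4 genes -> a,b,c,d."""
    table = make_table({"a|b": 0.01, "b|c": 0.02, "d|e": 0.03})
    prov = {fid: frozenset(fid.split("|")) for fid in table["feature_id"]}
    config = RobustnessConfig(top_k_genes=4)
    assert select_top_genes(table, "CEEdge", prov, config) == ["a", "b", "c", "d"]


def test_edge_pooling_replay_property(small_study):
    """Every selected gene belongs to an edge ranked no worse than the last
    consumed edge, and the result has exactly the requested size."""
    dataset, net = small_study.dataset, small_study.true_network
    fm = compute_features(dataset, "PPIEdge", net)
    table = compute_significance(fm, dataset.outcome.to_numpy())
    config = RobustnessConfig(top_k_genes=60)
    genes = select_top_genes(table, "PPIEdge", fm.provenance, config)
    assert len(genes) == 60
    ranked = table.sort_values(["p_value", "feature_id"])["feature_id"].tolist()
    consumed, pooled = [], set()
    for fid in ranked:
        consumed.append(fid)
        pooled |= set(fid.split("|"))
        if len(pooled) >= 60:
            break
    allowed = set().union(*(set(f.split("|")) for f in consumed))
    assert set(genes) <= allowed


def test_selection_universe_too_small():
    with pytest.raises(ValidationError):
        select_top_genes(make_table({"a": 0.1}), "Gene", {}, RobustnessConfig(top_k_genes=2))


# -- overlap fold change ----------------------------------------------------


def test_identical_sets_fold_is_universe_over_k():
    sets = [f"g{i}" for i in range(160)]
    observed, expected, fold = overlap_fold_change(sets, sets, 12750)
    assert observed == 160
    assert expected == pytest.approx(160 * 160 / 12750)
    assert fold == pytest.approx(12750 / 160)  # 79.6875


def test_disjoint_sets_use_pseudocount():
    a = [f"a{i}" for i in range(160)]
    b = [f"b{i}" for i in range(160)]
    observed, expected, fold = overlap_fold_change(a, b, 12750)
    assert observed == 0
    assert fold == pytest.approx(0.5 / (160 * 160 / 12750))


def test_size_mismatch_rejected():
    with pytest.raises(ValidationError, match="sizes differ"):
        overlap_fold_change(["a"], ["a", "b"], 10)


def test_expected_overlap_matches_monte_carlo():
    """Two independent uniform 160-of-12750 draws have mean overlap k^2/N
    (hypergeometric mean); checked by simulation."""
    rng = np.random.default_rng(2024)
    k, n, reps = 160, 12750, 3000
    overlaps = np.empty(reps)
    for r in range(reps):
        a = rng.choice(n, size=k, replace=False)
        b = rng.choice(n, size=k, replace=False)
        overlaps[r] = len(np.intersect1d(a, b))
    expected = k * k / n
    se = overlaps.std(ddof=1) / np.sqrt(reps)
    assert abs(overlaps.mean() - expected) < 4 * se + 1e-9


# -- summaries --------------------------------------------------------------


def test_twelve_cohorts_give_66_pairs():
    sets = {f"c{i}": [f"g{i}_{j}" for j in range(5)] for i in range(12)}
    result = robustness_summary(sets, universe_size=1000)
    assert len(result.pairwise) == 66


def test_shared_set_geometric_mean_is_identity_fold():
    shared = [f"g{i}" for i in range(10)]
    sets = {f"c{i}": shared for i in range(5)}
    result = robustness_summary(sets, universe_size=400)
    assert result.geometric_mean_fold == pytest.approx(400 / 10)


def test_two_cohorts_degenerate_to_single_fold():
    sets = {"a": ["g1", "g2"], "b": ["g2", "g3"]}
    result = robustness_summary(sets, universe_size=100)
    assert len(result.pairwise) == 1
    assert result.geometric_mean_fold == pytest.approx(result.pairwise["fold"].iloc[0])


def test_geometric_mean_invariant_to_cohort_relabeling():
    rng = np.random.default_rng(5)
    sets = {
        f"c{i}": list(rng.choice([f"g{j}" for j in range(200)], size=20, replace=False))
        for i in range(6)
    }
    base = robustness_summary(sets, 200).geometric_mean_fold
    relabeled = {f"z{9 - int(k[1])}": v for k, v in sets.items()}
    assert robustness_summary(relabeled, 200).geometric_mean_fold == pytest.approx(base)


def test_single_cohort_rejected():
    with pytest.raises(ValidationError):
        robustness_summary({"only": ["g1"]}, 10)


# -- degree bias diagnostic -------------------------------------------------


def test_edge_feature_top_genes_are_degree_biased():
    """On a hub-containing (preferential-attachment) network, the genes
    pooled from top-ranked edge features have higher mean degree than the
    network average even when expression carries no class signal: hubs sit
    on more edges, so edge-based selection samples them size-biasedly."""
    import networkx as nx

    from netfeat import GeneNetwork, SimulationConfig, generate_study

    study = generate_study(
        SimulationConfig(
            n_genes=200, effect_size=0.0, cohorts=(("c1", 60, 120),), seed=77
        )
    )
    genes = sorted(study.dataset.gene_ids)
    ba = nx.barabasi_albert_graph(len(genes), m=3, seed=5)
    net = GeneNetwork(
        edges=[(genes[a], genes[b]) for a, b in ba.edges], nodes=genes
    )
    fm = compute_features(study.dataset, "PPIEdge", net)
    table = compute_significance(fm, study.dataset.outcome.to_numpy())
    genes_top = select_top_genes(
        table, "PPIEdge", fm.provenance, RobustnessConfig(top_k_genes=40)
    )
    top_mean = degree_summary(net, genes_top).mean_degree
    network_mean = degree_summary(net).mean_degree
    assert top_mean > network_mean


def test_degree_diagnostics_reported_per_cohort(small_study, small_networks):
    sets = {"a": list(sorted(small_study.true_network.nodes))[:30],
            "b": list(sorted(small_study.true_network.nodes))[30:60]}
    result = robustness_summary(
        sets, 200, network=small_networks["PPI"], config=RobustnessConfig(top_k_genes=30)
    )
    assert set(result.degree_diagnostics["cohort"]) == {"a", "b"}
    # module cliques: every node has degree module_size - 1
    assert (result.degree_diagnostics["mean_degree"] == 9).all()
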