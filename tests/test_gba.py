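"""Neighbor voting, multifunctionality, CV, AUC: oracles and invariants."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import netgba as ng
from netgba.annotations import AnnotationSet
from netgba.errors import ConfigurationError, EvaluationError
from netgba.network import CoexpressionNetwork


def _net_from_weights(weights):
    g = nx.Graph()
    for (u, v), w in weights.items():
        g.add_edge(u, v, weight=w, abs_weight=abs(w))
    return CoexpressionNetwork(g)


def _ann(memberships, universe):
    return AnnotationSet(
        memberships={t: frozenset(g) for t, g in memberships.items()},
        universe=frozenset(universe),
    )


# -- multifunctionality --------------------------------------------------


def test_mf_unannotated_gene_scores_zero():
    ann = _ann({"GO:0000001": {"gA"}}, {"gA", "gB"})
    mf = ng.multifunctionality_scores(ann)
    assert dict(zip(mf["gene_id"], mf["mf_score"]))["gB"] == 0.0


def test_mf_single_term_printed_value():
    """One term with 10 members in a 100-gene universe: MF = 1/(10*90)."""
    universe = {f"g{i:03d}" for i in range(100)}
    members = set(sorted(universe)[:10])
    mf = ng.multifunctionality_scores(_ann({"GO:0000001": members}, universe))
    scores = dict(zip(mf["gene_id"], mf["mf_score"]))
    for g in members:
        assert scores[g] == pytest.approx(1.0 / 900.0)


def _mf_bruteforce(ann):
    out = {}
    for gene in ann.universe:
        total = 0.0
        for term in ann.terms:
            if gene in ann.genes_of(term) and ann.out_count(term) > 0:
                total += 1.0 / (ann.in_count(term) * ann.out_count(term))
        out[gene] = total
    return out


def test_mf_matches_bruteforce_double_loop():
    rng = np.random.default_rng(12)
    for _ in range(100):
        universe = [f"g{i}" for i in range(int(rng.integers(4, 12)))]
        memberships = {}
        for k in range(int(rng.integers(1, 5))):
            size = int(rng.integers(1, len(universe) + 1))
            memberships[f"GO:{k + 1:07d}"] = set(
                rng.choice(universe, size=size, replace=False)
            )
        ann = _ann(memberships, universe)
        mf = ng.multifunctionality_scores(ann)
        expected = _mf_bruteforce(ann)
        for gene, score in zip(mf["gene_id"], mf["mf_score"]):
            assert score == pytest.approx(expected[gene], abs=1e-12)


def test_mf_rank_one_is_most_multifunctional():
    ann = _ann(
        {"GO:0000001": {"gA", "gB"}, "GO:0000002": {"gA"}}, {"gA", "gB", "gC"}
    )
    mf = ng.multifunctionality_scores(ann)
    by_gene = mf.set_index("gene_id")
    assert by_gene.loc["gA", "mf_rank"] == 1
    assert by_gene.loc["gC", "mf_score"] == 0.0


def test_mf_ignores_whole_universe_term(caplog):
    ann = _ann(
        {"GO:0000001": {"gA", "gB"}, "GO:0000002": {"gA"}}, {"gA", "gB"}
    )
    with caplog.at_level("WARNING"):
        mf = ng.multifunctionality_scores(ann)
    scores = dict(zip(mf["gene_id"], mf["mf_score"]))
    assert scores["gA"] == pytest.approx(1.0)  # only the 1-in/1-out term counts
    assert "whole universe" in caplog.text


# -- neighbor voting -----------------------------------------------------


def test_voting_toy_weights_give_two_thirds():
    """Weights 0.9/0.5/0.1 to a,b,c with a,c annotated: (0.9+0.1)/1.5."""
    net = _net_from_weights(
        {("i", "a"): 0.9, ("i", "b"): 0.5, ("i", "c"): 0.1}
    )
    ann = _ann({"GO:0000001": {"a", "c"}}, {"i", "a", "b", "c"})
    scores = ng.neighbor_voting_scores(net, ann, {"a", "b", "c"})
    assert scores.loc["i", "GO:0000001"] == pytest.approx(2.0 / 3.0)


def test_voting_extremes():
    net = _net_from_weights(
        {("i", "a"): 0.5, ("i", "b"): 0.5, ("a", "b"): 0.5}
    )
    all_in = _ann({"GO:0000001": {"a", "b"}}, {"i", "a", "b"})
    none_in = _ann({"GO:0000001": {"i"}}, {"i", "a", "b"})
    assert ng.neighbor_voting_scores(net, all_in, {"a", "b"}).loc[
        "i", "GO:0000001"
    ] == pytest.approx(1.0)
    assert ng.neighbor_voting_scores(net, none_in, {"a", "b"}).loc[
        "i", "GO:0000001"
    ] == pytest.approx(0.0)


def test_voting_negative_weights_count_by_magnitude():
    net = _net_from_weights({("i", "a"): -0.9, ("i", "b"): 0.3})
    ann = _ann({"GO:0000001": {"a"}}, {"i", "a", "b"})
    scores = ng.neighbor_voting_scores(net, ann, {"a", "b"})
    assert scores.loc["i", "GO:0000001"] == pytest.approx(0.9 / 1.2)


def test_voting_disconnected_gene_receives_the_prior():
    net = _net_from_weights({("a", "b"): 0.7, ("i", "a"): 0.0, ("i", "b"): 0.0})
    ann = _ann({"GO:0000001": {"a"}}, {"i", "a", "b"})
    scores = ng.neighbor_voting_scores(net, ann, {"a", "b"})
    assert scores.loc["i", "GO:0000001"] == pytest.approx(0.5)  # 1 of 2 visible


def test_voting_own_annotation_never_votes_for_itself():
    net = _net_from_weights({("i", "a"): 0.9, ("i", "b"): 0.1})
    with_self = _ann({"GO:0000001": {"i", "a"}}, {"i", "a", "b"})
    without = _ann({"GO:0000001": {"a"}}, {"i", "a", "b"})
    s1 = ng.neighbor_voting_scores(net, with_self, {"i", "a", "b"})
    s2 = ng.neighbor_voting_scores(net, without, {"i", "a", "b"})
    assert s1.loc["i", "GO:0000001"] == pytest.approx(s2.loc["i", "GO:0000001"])


def test_voting_requires_visible_labels():
    net = _net_from_weights({("a", "b"): 0.5})
    ann = _ann({"GO:0000001": {"a"}}, {"a", "b"})
    with pytest.raises(EvaluationError):
        ng.neighbor_voting_scores(net, ann, set())


# -- CV splitting --------------------------------------------------------


@pytest.mark.parametrize(
    "n_genes,n_folds,sizes", [(9, 3, [3, 3, 3]), (10, 3, [4, 3, 3]), (7, 2, [4, 3])]
)
def test_cv_fold_sizes(n_genes, n_folds, sizes):
    genes = [f"g{i}" for i in range(n_genes)]
    folds = ng.cv_split(genes, n_folds=n_folds, seed=1)
    assert [len(f) for f in folds] == sizes
    assert sorted(itertools.chain.from_iterable(folds)) == sorted(genes)


def test_cv_split_deterministic_and_seed_sensitive():
    genes = [f"g{i}" for i in range(12)]
    assert ng.cv_split(genes, seed=5) == ng.cv_split(genes, seed=5)
    assert ng.cv_split(genes, seed=5) != ng.cv_split(genes, seed=6)


def test_cv_split_rejects_too_many_folds():
    with pytest.raises(ConfigurationError):
        ng.cv_split(["a", "b"], n_folds=3)


# -- ROC AUC -------------------------------------------------------------


def _auc_pairs(scores, pos, neg):
    wins = 0.0
    for p in pos:
        for n in neg:
            if scores[p] > scores[n]:
                wins += 1.0
            elif scores[p] == scores[n]:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def test_auc_printed_examples():
    assert ng.roc_auc({"a": 0.9, "b": 0.8, "c": 0.1}, ["a", "b"], ["c"]) == 1.0
    assert ng.roc_auc({"a": 0.5, "b": 0.5, "c": 0.5}, ["a"], ["b", "c"]) == 0.5
    scores = {"p1": 0.9, "p2": 0.4, "n1": 0.6, "n2": 0.2}
    assert ng.roc_auc(scores, ["p1", "p2"], ["n1", "n2"]) == pytest.approx(0.75)


def test_auc_matches_exhaustive_pair_counting():
    rng = np.random.default_rng(23)
    for _ in range(100):
        n = int(rng.integers(4, 50))
        genes = [f"g{i}" for i in range(n)]
        scores = dict(zip(genes, np.round(rng.normal(size=n), 1)))  # force ties
        k = int(rng.integers(1, n))
        pos, neg = genes[:k], genes[k:]
        assert ng.roc_auc(scores, pos, neg) == pytest.approx(
            _auc_pairs(scores, pos, neg), abs=1e-12
        )


def test_auc_matches_sklearn():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(29)
    for _ in range(25):
        n = int(rng.integers(6, 40))
        y = np.r_[np.ones(n // 2), np.zeros(n - n // 2)]
        s = np.round(rng.normal(size=n), 1)
        genes = [f"g{i}" for i in range(n)]
        scores = dict(zip(genes, s))
        pos = [g for g, label in zip(genes, y) if label == 1]
        neg = [g for g, label in zip(genes, y) if label == 0]
        assert ng.roc_auc(scores, pos, neg) == pytest.approx(
            roc_auc_score(y, s), abs=1e-12
        )


def test_auc_rejects_degenerate_classes():
    with pytest.raises(EvaluationError):
        ng.roc_auc({"a": 1.0}, ["a"], [])
    with pytest.raises(EvaluationError):
        ng.roc_auc({"a": 1.0, "b": 0.0}, ["a", "b"], ["b"])


# -- optimal-function selection -----------------------------------------


def test_select_optimal_is_strict_at_the_threshold():
    perf = pd.DataFrame(
        {"term": ["t1", "t2", "t3"], "mean_auc": [0.9, 0.7, 0.75]}
    )
    out = ng.select_optimal(perf, 0.7)
    assert list(out["term"]) == ["t1", "t3"]  # 0.7 exactly is excluded
    assert list(out["mean_auc"]) == [0.9, 0.75]


def test_select_optimal_counts_enumerated_example():
    perf = pd.DataFrame({"term": list("abc"), "mean_auc": [0.9, 0.75, 0.65]})
    assert len(ng.select_optimal(perf, 0.7)) == 2


# -- cross-validated evaluation -----------------------------------------


def _evaluate_bruteforce(net, ann, folds):
    """Independent reimplementation: plain loops, no shared code paths."""
    nodes = sorted(net.graph.nodes)
    results = {}
    for term in sorted(ann.memberships):
        members = ann.memberships[term]
        fold_aucs = []
        for fold in folds:
            held = set(fold)
            visible = [g for g in nodes if g not in held]
            scores = {}
            for i in nodes:
                num = den = 0.0
                for j in visible:
                    if j == i:
                        continue
                    w = (
                        abs(net.graph[i][j]["weight"])
                        if net.graph.has_edge(i, j)
                        else 0.0
                    )
                    den += w
                    if j in members:
                        num += w
                if den > 0:
                    scores[i] = num / den
                else:
                    scores[i] = sum(1 for j in visible if j in members) / len(visible)
            pos = [g for g in held if g in members]
            neg = [g for g in held if g not in members]
            if not pos or not neg:
                fold_aucs.append(float("nan"))  # fold without both classes
                continue
            wins = 0.0
            for p in pos:
                for n in neg:
                    if scores[p] > scores[n]:
                        wins += 1.0
                    elif scores[p] == scores[n]:
                        wins += 0.5
            fold_aucs.append(wins / (len(pos) * len(neg)))
        results[term] = fold_aucs
    return results


def test_evaluate_terms_matches_independent_pipeline_oracle():
    """20-gene, 2-term toy: fold AUCs equal a from-scratch reimplementation."""
    rng = np.random.default_rng(31)
    genes = [f"g{i:02d}" for i in range(20)]
    a = rng.normal(size=(20, 20))
    corr = np.tanh((a + a.T) / 3)
    np.fill_diagonal(corr, 1.0)
    net = ng.build_network(pd.DataFrame(corr, index=genes, columns=genes))
    ann = _ann(
        {
            "GO:0000001": set(rng.choice(genes, size=9, replace=False)),
            "GO:0000002": set(rng.choice(genes, size=7, replace=False)),
        },
        genes,
    )
    seed = 13
    with np.errstate(invalid="ignore"):
        table = ng.evaluate_terms(net, ann, n_folds=3, seed=seed)
    folds = ng.cv_split(sorted(genes), n_folds=3, seed=seed)
    expected = _evaluate_bruteforce(net, ann, folds)
    for _, row in table.iterrows():
        for k in range(3):
            want = expected[row["term"]][k]
            got = row[f"auc_fold_{k + 1}"]
            if np.isnan(want):
                assert np.isnan(got)  # one-class fold: AUC undefined
            else:
                assert got == pytest.approx(want, abs=1e-12)
        assert row["mean_auc"] == pytest.approx(
            np.nanmean(expected[row["term"]]), abs=1e-12
        )


def test_held_out_annotations_cannot_leak_into_voting_scores():
    """Changing a held-out gene's annotations leaves its fold scores unchanged."""
    rng = np.random.default_rng(37)
    genes = [f"g{i:02d}" for i in range(15)]
    a = rng.normal(size=(15, 15))
    corr = np.tanh((a + a.T) / 3)
    np.fill_diagonal(corr, 1.0)
    net = ng.build_network(pd.DataFrame(corr, index=genes, columns=genes))
    members = set(genes[:6])
    held = set(genes[10:])
    visible = [g for g in genes if g not in held]
    target = genes[12]

    ann1 = _ann({"GO:0000001": members}, genes)
    ann2 = _ann({"GO:0000001": members | {target}}, genes)
    s1 = ng.neighbor_voting_scores(net, ann1, visible)
    s2 = ng.neighbor_voting_scores(net, ann2, visible)
    pd.testing.assert_frame_equal(s1, s2)


def test_terms_with_too_few_positives_are_skipped(caplog):
    rng = np.random.default_rng(41)
    genes = [f"g{i}" for i in range(12)]
    a = rng.normal(size=(12, 12))
    corr = np.tanh((a + a.T) / 3)
    np.fill_diagonal(corr, 1.0)
    net = ng.build_network(pd.DataFrame(corr, index=genes, columns=genes))
    ann = _ann({"GO:0000001": set(genes[:6]), "GO:0000002": {genes[0]}}, genes)
    with caplog.at_level("WARNING"):
        table = ng.evaluate_terms(net, ann, n_folds=3, seed=1)
    assert list(table["term"]) == ["GO:0000001"]
    assert "skipped" in caplog.text


def test_planted_coherent_terms_are_learnable(small_network):
    net, filtered, truth = small_network
    res = ng.NeighborVoting(net, filtered).fit(n_folds=3, seed=3)
    planted = res.term_table[res.term_table["term"].isin(truth.coherent_terms)]
    assert len(planted) > 0
    assert planted["mean_auc"].mean() > 0.6
    assert len(res.optimal) > 0


def test_permuted_annotations_sit_at_chance(small_network):
    net, filtered, _ = small_network
    means = []
    for s in range(5):
        table = ng.evaluate_terms(net, filtered.permuted(100 + s), seed=s)
        means.append(table["mean_auc"].mean())
    assert 0.4 <= float(np.mean(means)) <= 0.6


def test_auc_increases_with_coherence_and_module_strength():
    """Mean AUC of planted terms is non-decreasing along a 3-point grid."""

    def mean_planted_auc(coherence, rho):
        vals = []
        for seed in (1, 2, 3):
            cfg = ng.SimulationConfig(
                n_genes=150,
                n_de_genes=150,
                n_modules=4,
                module_size=25,
                module_rho=rho,
                n_terms=6,
                term_coherence=coherence,
                min_term_size=24,
                max_term_size=28,
                seed=seed,
            )
            matrix, truth = ng.generate_expression(cfg)
            ann, truth = ng.generate_annotations(truth, cfg)
            res = ng.DifferentialExpression(matrix).fit()
            net = ng.build_network(ng.spearman_matrix(matrix, res.deg_ids))
            filtered = ng.filter_terms(ann.restrict(res.deg_ids), 20)
            table = ng.evaluate_terms(net, filtered, seed=seed)
            planted = table[table["term"].isin(truth.coherent_terms)]
            vals.append(planted["mean_auc"].mean())
        return float(np.mean(vals))

    tol = 0.02  # Monte-Carlo slack on a non-strict trend
    by_coherence = [mean_planted_auc(c, 0.8) for c in (0.2, 0.6, 0.95)]
    assert by_coherence[1] >= by_coherence[0] - tol
    assert by_coherence[2] >= by_coherence[1] - tol
    by_rho = [mean_planted_auc(0.8, r) for r in (0.3, 0.6, 0.9)]
    assert by_rho[1] >= by_rho[0] - tol
    assert by_rho[2] >= by_rho[1] - tol


def test_results_object_reports_and_exports(tmp_path, small_network):
    net, filtered, _ = small_network
    res = ng.NeighborVoting(net, filtered).fit(n_folds=3, seed=3)
    text = res.summary()
    assert "terms evaluated" in text
    hist = res.auc_histogram(bins=10)
    assert hist["count"].sum() == len(res.term_table)
    path = tmp_path / "perf.tsv"
    res.to_tsv(path)
    back = pd.read_csv(path, sep="\t")
    assert len(back) == len(res.term_table)
    assert back["is_optimal"].sum() == len(res.optimal)
    # fold AUCs average to the recorded mean
    fold_cols = [c for c in back.columns if c.startswith("auc_fold_")]
    np.testing.assert_allclose(
        back[fold_cols].mean(axis=1), back["mean_auc"], atol=1e-5
    )


def test_combined_predictor_flag(small_network):
    net, filtered, _ = small_network
    table = ng.evaluate_terms(net, filtered, seed=2, combined=True)
    assert "combined_auc" in table
    assert table["combined_auc"].between(0, 1).all()
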