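"""Concordance index, correlation suite, per-drug reports, AUC, cross-platform."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from hubdrug import (
    concordance_index,
    correlation_metrics,
    cross_platform_concordance,
    evaluate_per_drug,
    extreme_response_auc,
    gene_sensitivity_correlations,
    hub_vs_nonhub_test,
)


def brute_force_ci(pred, obs, orientation="direct"):
    """Exhaustive pair counting on tie-free vectors: rescaled Kendall tau."""
    pred, obs = np.asarray(pred), np.asarray(obs)
    n = len(pred)
    conc = disc = 0
    for i in range(n):
        for j in range(i + 1, n):
            s = np.sign(pred[i] - pred[j]) * np.sign(obs[i] - obs[j])
            conc += s > 0
            disc += s < 0
    tau = (conc - disc) / (n * (n - 1) / 2)
    return (tau + 1) / 2 if orientation == "direct" else (1 - tau) / 2


class TestConcordanceIndex:
    def test_hand_counted_three_point_example(self):
        res = concordance_index([1, 3, 2], [1, 2, 3])
        assert res.tau == pytest.approx(1 / 3)
        assert res.ci == pytest.approx(2 / 3)

    def test_perfect_predictor_is_exactly_one(self):
        obs = np.arange(1, 101, dtype=float)
        res = concordance_index(obs, obs)
        assert res.ci == 1.0

    def test_sign_reversal(self):
        rng = np.random.default_rng(0)
        obs = rng.normal(0, 1, 50)
        assert concordance_index(-obs, obs, "inverse").ci == 1.0
        assert concordance_index(-obs, obs, "direct").ci == 0.0

    def test_random_predictor_sits_at_half(self):
        rng = np.random.default_rng(1)
        res = concordance_index(rng.normal(0, 1, 10_000), rng.normal(0, 1, 10_000))
        assert res.ci == pytest.approx(0.5, abs=0.02)

    def test_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(2)
        for n in (4, 7, 12):
            pred = rng.normal(0, 1, n)
            obs = rng.normal(0, 1, n)
            for orientation in ("direct", "inverse"):
                assert concordance_index(pred, obs, orientation).ci == pytest.approx(
                    brute_force_ci(pred, obs, orientation), abs=1e-12)

    def test_inverse_orientation_equals_direct_on_negated_observations(self):
        rng = np.random.default_rng(3)
        pred, obs = rng.normal(0, 1, 40), rng.normal(0, 1, 40)
        assert concordance_index(pred, obs, "inverse").ci == pytest.approx(
            concordance_index(pred, -obs, "direct").ci, abs=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.integers(-1000, 1000), min_size=4, max_size=15, unique=True),
           st.integers(0, 2**16))
    def test_invariant_under_strictly_increasing_transforms(self, obs, seed):
        obs = np.asarray(obs, dtype=float)
        pred = np.random.default_rng(seed).normal(0, 1, len(obs))
        base = concordance_index(pred, obs).ci
        assert concordance_index(np.exp(pred / 50), obs).ci == pytest.approx(base)
        assert concordance_index(pred, 3 * obs + 7).ci == pytest.approx(base)

    def test_interval_brackets_estimate_and_lies_in_unit_range(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 100)
        y = 0.5 * x + rng.normal(0, 1, 100)
        res = concordance_index(x, y)
        lo, hi = res.interval_95
        assert 0.0 <= lo <= res.ci <= hi <= 1.0

    def test_fisher_interval_coverage_under_gaussian_copula(self):
        # target tau = 0.4 via rho = sin(pi * tau / 2)
        tau_true = 0.4
        rho = np.sin(np.pi * tau_true / 2)
        target = (tau_true + 1) / 2
        rng = np.random.default_rng(5)
        cov = [[1, rho], [rho, 1]]
        hits = 0
        for _ in range(200):
            x, y = rng.multivariate_normal([0, 0], cov, size=200).T
            lo, hi = concordance_index(x, y).interval_95
            hits += lo <= target <= hi
        assert hits / 200 == pytest.approx(0.95, abs=0.05)

    def test_constant_inputs_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            concordance_index([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError, match="constant"):
            concordance_index([1, 2, 3], [2, 2, 2])


class TestCorrelationMetrics:
    def test_positive_affine_map_gives_all_ones(self):
        obs = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
        p, s, k = correlation_metrics(2 * obs + 5, obs)
        assert (p, s, k) == pytest.approx((1.0, 1.0, 1.0))

    def test_monotone_nonlinear_map_preserves_ranks_only(self):
        obs = np.linspace(-2, 2, 20)
        p, s, k = correlation_metrics(obs**3, obs)
        assert s == pytest.approx(1.0) and k == pytest.approx(1.0)
        assert p < 1.0

    def test_matches_textbook_formulas_on_fixed_vectors(self):
        pred = np.array([2.1, -0.3, 1.7, 0.4, -1.2, 3.3, 0.0, 0.9])
        obs = np.array([1.0, 0.2, 2.5, -0.4, -0.8, 2.9, 0.7, 0.1])
        p, s, k = correlation_metrics(pred, obs)
        pc, oc = pred - pred.mean(), obs - obs.mean()
        assert p == pytest.approx((pc @ oc) / np.sqrt((pc @ pc) * (oc @ oc)), abs=1e-12)
        rp = stats.rankdata(pred) - stats.rankdata(pred).mean()
        ro = stats.rankdata(obs) - stats.rankdata(obs).mean()
        assert s == pytest.approx((rp @ ro) / np.sqrt((rp @ rp) * (ro @ ro)), abs=1e-12)
        conc = sum(np.sign(pred[i] - pred[j]) * np.sign(obs[i] - obs[j])
                   for i in range(8) for j in range(i + 1, 8))
        assert k == pytest.approx(conc / (8 * 7 / 2), abs=1e-12)


def _pred_and_sens(rng, n_cells=40, drugs=("d1", "d2", "d3"), noise=0.0):
    cells = [f"C{i}" for i in range(n_cells)]
    pred = pd.DataFrame(rng.normal(0, 1, (n_cells, len(drugs))),
                        index=cells, columns=list(drugs))
    rows = []
    for d in drugs:
        obs = pred[d].to_numpy() + rng.normal(0, noise, n_cells) if noise else pred[d].to_numpy()
        rows.append(pd.DataFrame({"cell_line": cells, "drug": d,
                                  "value": obs, "measure": "AA"}))
    return pred, pd.concat(rows, ignore_index=True)


class TestEvaluatePerDrug:
    def test_noiseless_predictions_score_near_one_per_drug(self):
        pred, sens = _pred_and_sens(np.random.default_rng(0))
        report = evaluate_per_drug(pred, sens)
        assert set(report.index) == {"d1", "d2", "d3", "overall"}
        assert (report["ci"] >= 0.99).all()

    def test_within_drug_permutation_gives_chance_level(self):
        rng = np.random.default_rng(1)
        pred, sens = _pred_and_sens(rng, n_cells=400)
        sens["value"] = sens.groupby("drug")["value"].transform(
            lambda v: rng.permutation(v.to_numpy()))
        report = evaluate_per_drug(pred, sens)
        for d in ("d1", "d2", "d3"):
            assert report.loc[d, "ci"] == pytest.approx(0.5, abs=0.05)

    def test_inverse_orientation_matches_direct_on_negated_data(self):
        rng = np.random.default_rng(2)
        pred, sens = _pred_and_sens(rng, noise=0.7)
        inv = sens.assign(value=-sens["value"], measure="LNIC50")
        rep_inv = evaluate_per_drug(pred, inv, orientation="inverse")
        rep_dir = evaluate_per_drug(pred, sens, orientation="direct")
        np.testing.assert_allclose(rep_inv["ci"], rep_dir["ci"], atol=1e-12)

    def test_sparse_drugs_warned_and_omitted(self):
        rng = np.random.default_rng(3)
        pred, sens = _pred_and_sens(rng)
        sens = pd.concat([sens, pd.DataFrame({
            "cell_line": ["C0", "C1"], "drug": "rare",
            "value": [0.1, 0.2], "measure": "AA"})], ignore_index=True)
        pred["rare"] = 0.5
        with pytest.warns(UserWarning, match="fewer than"):
            report = evaluate_per_drug(pred, sens)
        assert "rare" not in report.index

    def test_no_overlap_is_an_error(self):
        pred, sens = _pred_and_sens(np.random.default_rng(4))
        sens["cell_line"] = "elsewhere"
        with pytest.raises(ValueError, match="overlap"):
            evaluate_per_drug(pred, sens)


class TestGeneSensitivityCorrelations:
    def test_toy_pooled_expansion_matches_manual_computation(self):
        expr = pd.DataFrame([[1.0, 2.0, 4.0], [0.3, -0.1, 0.2]],
                            index=["G0", "G1"], columns=["C0", "C1", "C2"])
        sens = pd.DataFrame({
            "cell_line": ["C0", "C1", "C2", "C0", "C1", "C2"],
            "drug": ["d1"] * 3 + ["d2"] * 3,
            "value": [0.5, 1.5, 3.0, 0.0, 1.0, 2.0], "measure": "AA"})
        r = gene_sensitivity_correlations(expr, sens)
        for g in ("G0", "G1"):
            replicated = expr.loc[g, sens["cell_line"]].to_numpy()
            assert r[g] == pytest.approx(
                np.corrcoef(replicated, sens["value"])[0, 1], abs=1e-12)

    def test_single_planted_effect_maximizes_that_genes_correlation(self, make_config):
        from hubdrug import generate_expression, generate_sensitivity
        cfg = make_config(n_genes=12, n_samples=300, modules=((3, 0.95, 0.7),),
                          shared_beta=(1.0,), sensitivity_noise_sd=0.0, seed=6)
        expr, truth = generate_expression(cfg)
        sens = generate_sensitivity(expr, truth, cfg)
        r = gene_sensitivity_correlations(expr, sens).abs()
        assert r.idxmax() == truth.planted_hub_ids[0]

    def test_null_effects_stay_small(self, make_config):
        from hubdrug import generate_expression, generate_sensitivity
        cfg = make_config(n_genes=10, n_samples=2000, modules=((3, 0.95, 0.7),),
                          shared_beta=(0.0,), sensitivity_noise_sd=1.0, seed=7)
        expr, truth = generate_expression(cfg)
        sens = generate_sensitivity(expr, truth, cfg)
        r = gene_sensitivity_correlations(expr, sens)
        assert (r.abs() < 3 / np.sqrt(len(sens))).all()


class TestHubVsNonhubTest:
    def test_identical_groups_give_t_zero_p_one(self):
        corrs = pd.Series([0.2, 0.2, 0.2, 0.2], index=list("abcd"))
        mh, mn, t, p = hub_vs_nonhub_test(corrs, {"a", "b"})
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_separated_groups_are_significant(self):
        rng = np.random.default_rng(8)
        hub = pd.Series(-0.3 + rng.normal(0, 0.01, 10),
                        index=[f"h{i}" for i in range(10)])
        non = pd.Series(rng.normal(0, 0.01, 10), index=[f"n{i}" for i in range(10)])
        _, _, _, p = hub_vs_nonhub_test(pd.concat([hub, non]), set(hub.index))
        assert p < 0.001

    def test_matches_pooled_variance_formula(self):
        a = np.array([0.1, -0.2, 0.05, 0.3, -0.1])
        b = np.array([0.4, 0.25, 0.5, 0.35, 0.6])
        corrs = pd.Series(np.concatenate([a, b]),
                          index=[f"g{i}" for i in range(10)])
        _, _, t, _ = hub_vs_nonhub_test(corrs, {f"g{i}" for i in range(5)})
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (len(a) + len(b) - 2)
        expected = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        assert t == pytest.approx(expected, abs=1e-10)

    def test_small_group_rejected(self):
        corrs = pd.Series([0.1, 0.2, 0.3], index=list("abc"))
        with pytest.raises(ValueError):
            hub_vs_nonhub_test(corrs, {"a"})


class TestExtremeResponseAUC:
    def test_perfect_ranking_gives_auc_one(self):
        rng = np.random.default_rng(9)
        cells = [f"C{i}" for i in range(200)]
        obs = rng.normal(0, 1, 200)
        pred = pd.DataFrame({"d1": obs}, index=cells)
        sens = pd.DataFrame({"cell_line": cells, "drug": "d1",
                             "value": obs, "measure": "AA"})
        assert extreme_response_auc(pred, sens)["d1"] == 1.0

    def test_random_scores_give_chance_auc(self):
        rng = np.random.default_rng(10)
        cells = [f"C{i}" for i in range(500)]
        pred = pd.DataFrame({"d1": rng.normal(0, 1, 500)}, index=cells)
        sens = pd.DataFrame({"cell_line": cells, "drug": "d1",
                             "value": rng.normal(0, 1, 500), "measure": "AA"})
        assert extreme_response_auc(pred, sens)["d1"] == pytest.approx(0.5, abs=0.05)

    def test_seven_sample_brute_force_pair_count(self):
        # 4 extreme-sensitive vs 3 extreme-resistant observed labels
        obs = np.array([1.0, 1.0, 1.0, 1.0, -1.0, -1.0, -1.0])
        scores = np.array([0.9, 0.8, 0.7, 0.2, 0.6, 0.1, 0.0])
        pairs = [(s, r) for s in scores[:4] for r in scores[4:]]
        expected = np.mean([1.0 if s > r else 0.5 if s == r else 0.0
                            for s, r in pairs])
        cells = [f"C{i}" for i in range(7)]
        pred = pd.DataFrame({"d1": scores}, index=cells)
        sens = pd.DataFrame({"cell_line": cells, "drug": "d1",
                             "value": obs, "measure": "AA"})
        assert extreme_response_auc(pred, sens)["d1"] == pytest.approx(expected)

    def test_equals_exhaustive_enumeration_on_small_inputs(self):
        rng = np.random.default_rng(11)
        for trial in range(5):
            n = 30
            cells = [f"C{i}" for i in range(n)]
            obs = rng.normal(0, 1, n)
            scores = np.round(rng.normal(0, 1, n), 1)  # rounding creates ties
            pred = pd.DataFrame({"d1": scores}, index=cells)
            sens = pd.DataFrame({"cell_line": cells, "drug": "d1",
                                 "value": obs, "measure": "AA"})
            out = extreme_response_auc(pred, sens)
            if "d1" not in out.index:
                continue
            z = (obs - obs.mean()) / obs.std(ddof=1)
            s_scores = scores[z > 0.8]
            r_scores = scores[z < -0.8]
            expected = np.mean([1.0 if a > b else 0.5 if a == b else 0.0
                                for a in s_scores for b in r_scores])
            assert out["d1"] == pytest.approx(expected, abs=1e-12)

    def test_single_class_drug_skipped_with_warning(self):
        cells = [f"C{i}" for i in range(10)]
        obs = np.concatenate([np.full(9, 0.0), [10.0]])  # only a sensitive tail
        pred = pd.DataFrame({"d1": np.arange(10.0)}, index=cells)
        sens = pd.DataFrame({"cell_line": cells, "drug": "d1",
                             "value": obs, "measure": "AA"})
        with pytest.warns(UserWarning, match="skipped"):
            out = extreme_response_auc(pred, sens)
        assert "d1" not in out.index


class TestCrossPlatform:
    def test_monotone_transform_preserves_all_ranks(self):
        rng = np.random.default_rng(12)
        a = pd.DataFrame(rng.normal(0, 1, (5, 20)),
                         index=[f"G{i}" for i in range(5)],
                         columns=[f"S{j}" for j in range(20)])
        b = 2.0**a
        per_gene, mean_rho, (lo, hi) = cross_platform_concordance(a, b)
        assert np.allclose(per_gene.values, 1.0)
        assert mean_rho == pytest.approx(1.0)

    def test_independent_platforms_average_near_zero(self):
        rng = np.random.default_rng(13)
        idx = [f"G{i}" for i in range(50)]
        cols = [f"S{j}" for j in range(100)]
        a = pd.DataFrame(rng.normal(0, 1, (50, 100)), index=idx, columns=cols)
        b = pd.DataFrame(rng.normal(0, 1, (50, 100)), index=idx, columns=cols)
        _, mean_rho, _ = cross_platform_concordance(a, b)
        assert mean_rho == pytest.approx(0.0, abs=0.05)

    def test_per_gene_values_match_scipy_spearman(self):
        rng = np.random.default_rng(14)
        idx = [f"G{i}" for i in range(5)]
        cols = [f"S{j}" for j in range(10)]
        a = pd.DataFrame(rng.normal(0, 1, (5, 10)), index=idx, columns=cols)
        b = pd.DataFrame(rng.normal(0, 1, (5, 10)), index=idx, columns=cols)
        per_gene, _, _ = cross_platform_concordance(a, b)
        for g in idx:
            assert per_gene[g] == pytest.approx(
                stats.spearmanr(a.loc[g], b.loc[g]).statistic, abs=1e-12)

    def test_empty_intersection_is_an_error(self):
        a = pd.DataFrame([[1.0, 2.0, 3.0]], index=["G1"], columns=list("xyz"))
        b = pd.DataFrame([[1.0, 2.0, 3.0]], index=["G2"], columns=list("xyz"))
        with pytest.raises(ValueError):
            cross_platform_concordance(a, b)
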