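"""Edge selection, network strength, cross-validation and external transfer."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cpmreserve import (ConnectivityMatrix, EdgeMaskPair, aggregate_model,
                        apply_external, combined_strength, evaluate,
                        fit_strength_model, network_strength,
                        optimize_threshold, run_loocv, run_repeated_kfold,
                        select_edges)
from cpmreserve.cpm import (CPMFoldModels, FoldModel, _edge_stats,
                            edge_matrix)


def _noise_edges(n_edges, n, seed=0):
    return np.random.default_rng(seed).standard_normal((n_edges, n))


class TestSelectEdges:
    def test_planted_strong_edge_selected(self):
        rng = np.random.default_rng(42)
        n = 200
        y = rng.standard_normal(n)
        X = rng.standard_normal((45, n))
        # population r = 0.6: x = 0.75*y + noise (0.6/sqrt(1-0.36)=0.75)
        X[7] = 0.75 * y + rng.standard_normal(n)
        X[13] = -(0.75 * y + rng.standard_normal(n))
        masks = select_edges(X, y, p_threshold=0.0009)
        assert masks.pos[7] and masks.neg[13]

    def test_per_edge_stats_match_scipy(self):
        """Vectorised r/p vs scipy.stats.pearsonr per edge (oracle)."""
        rng = np.random.default_rng(3)
        X = rng.standard_normal((20, 40))
        y = rng.standard_normal(40)
        r, p, df = _edge_stats(X, y, None)
        assert df == 38
        for e in range(20):
            r_ref, p_ref = stats.pearsonr(X[e], y)
            assert r[e] == pytest.approx(r_ref, abs=1e-12)
            assert p[e] == pytest.approx(p_ref, rel=1e-9)

    def test_partial_correlation_matches_manual_residualisation(self):
        rng = np.random.default_rng(4)
        n = 60
        C = rng.standard_normal((n, 2))
        y = C @ [0.5, -0.3] + rng.standard_normal(n)
        X = rng.standard_normal((10, n))
        X[2] += 0.8 * y
        r, p, df = _edge_stats(X, y, C)
        assert df == n - 4
        # oracle: explicit OLS residuals then plain correlation
        D = np.column_stack([np.ones(n), C])
        H = D @ np.linalg.pinv(D)
        yr = y - H @ y
        for e in (0, 2, 7):
            xr = X[e] - H @ X[e]
            assert r[e] == pytest.approx(stats.pearsonr(xr, yr)[0], abs=1e-10)

    def test_empty_covariate_set_equals_plain(self):
        X = _noise_edges(30, 50, seed=5)
        y = np.random.default_rng(6).standard_normal(50)
        a = select_edges(X, y, 0.05)
        b = select_edges(X, y, 0.05, covariates=np.empty((50, 0)))
        assert np.array_equal(a.pos, b.pos) and np.array_equal(a.neg, b.neg)
        assert np.allclose(a.r, b.r)

    def test_zero_threshold_selects_nothing(self):
        X = _noise_edges(10, 30)
        y = np.random.default_rng(1).standard_normal(30)
        masks = select_edges(X, y, 0.0)
        assert masks.n_pos == 0 and masks.n_neg == 0

    def test_constant_target_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            select_edges(_noise_edges(6, 20), np.ones(20), 0.05)

    def test_target_collinear_with_covariate_rejected(self):
        y = np.random.default_rng(2).standard_normal(30)
        with pytest.raises(ValueError, match="collinear"):
            select_edges(_noise_edges(6, 30), y, 0.05, covariates=y[:, None])

    def test_masks_disjoint_by_construction(self):
        with pytest.raises(ValueError, match="disjoint"):
            EdgeMaskPair(pos=np.array([True]), neg=np.array([True]),
                         r=np.array([0.5]), p=np.array([0.01]),
                         threshold=0.05, node_ids=np.array([1, 2]))


class TestNetworkStrength:
    def test_hand_sum_three_nodes(self):
        vals = np.zeros((3, 3))
        vals[0, 1] = vals[1, 0] = 0.2
        vals[0, 2] = vals[2, 0] = -0.1
        vals[1, 2] = vals[2, 1] = 0.4
        m = ConnectivityMatrix(values=vals)
        assert network_strength(m, np.ones((3, 3)) - np.eye(3)) == \
            pytest.approx(0.5)

    def test_zero_matrix_and_empty_mask(self):
        m = np.zeros((4, 4))
        assert network_strength(m, np.ones((4, 4))) == 0.0
        assert network_strength(np.arange(16.).reshape(4, 4),
                                np.zeros((4, 4))) == 0.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            network_strength(np.zeros((3, 3)), np.zeros((4, 4)))

    @given(st.integers(3, 20), st.integers(0, 10 ** 6))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_equals_brute_force_pair_loop(self, n, seed):
        rng = np.random.default_rng(seed)
        vals = rng.standard_normal((n, n))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0.0)
        mask = rng.integers(0, 2, (n, n))
        mask = np.triu(mask, 1)
        mask = mask + mask.T
        brute = sum(vals[i, j] for i in range(n) for j in range(i + 1, n)
                    if mask[i, j])
        assert network_strength(vals, mask) == pytest.approx(brute, abs=1e-9)

    def test_combined_equals_signed_mask_strength(self, rng):
        n = 6
        vals = rng.standard_normal((n, n))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0.0)
        pos = np.zeros((n, n)); neg = np.zeros((n, n))
        pos[0, 1] = pos[1, 0] = 1; pos[2, 3] = pos[3, 2] = 1
        neg[1, 2] = neg[2, 1] = 1
        combo = combined_strength(network_strength(vals, pos),
                                  network_strength(vals, neg))
        assert combo == pytest.approx(network_strength(vals, pos - neg))

    def test_combined_definition(self):
        assert combined_strength(0.0, 0.0) == 0.0
        assert combined_strength(1.5, 0.5) == 1.0


class TestStrengthModel:
    def test_exact_line(self):
        s = np.array([0.0, 1, 2, 3])
        intercept, slope = fit_strength_model(s, 2 * s + 1)
        assert (intercept, slope) == (pytest.approx(1.0), pytest.approx(2.0))

    def test_centered_data_zero_intercept(self):
        s = np.array([-1.0, 0, 1, 2]) - 0.5
        y = 3 * s
        intercept, _ = fit_strength_model(s, y)
        assert intercept == pytest.approx(0.0, abs=1e-12)

    def test_normal_equation_oracle(self):
        s = np.array([1.0, 2, 4, 7])
        y = np.array([0.3, -0.2, 1.1, 2.0])
        n = len(s)
        slope = (n * (s * y).sum() - s.sum() * y.sum()) / \
                (n * (s * s).sum() - s.sum() ** 2)
        intercept = y.mean() - slope * s.mean()
        assert fit_strength_model(s, y) == (pytest.approx(intercept),
                                            pytest.approx(slope))

    def test_constant_strengths_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_strength_model(np.ones(5), np.arange(5.0))


class TestEvaluate:
    def test_perfect_and_inverted(self):
        obs = np.array([-1.0, 0.0, 1.0, 2.0])
        m = evaluate(obs, obs)
        assert (m.r, m.r2, m.mae) == (pytest.approx(1.0), pytest.approx(1.0),
                                      0.0)
        centered = obs - obs.mean()
        m2 = evaluate(-centered, centered)
        assert m2.r == pytest.approx(-1.0)
        assert m2.mae == pytest.approx(2 * np.abs(centered).mean())

    def test_five_point_hand_oracle(self):
        pred = np.array([0.1, 0.5, -0.2, 0.8, 0.3])
        obs = np.array([0.0, 0.7, -0.1, 0.5, 0.6])
        m = evaluate(pred, obs)
        r_ref = np.corrcoef(pred, obs)[0, 1]
        assert m.r == pytest.approx(r_ref)
        assert m.r2 == pytest.approx(r_ref ** 2)
        assert m.mae == pytest.approx(np.abs(pred - obs).mean())

    def test_constant_input_keeps_mae(self):
        m = evaluate(np.ones(5), np.arange(5.0))
        assert m.r is None and m.note is not None
        assert m.mae == pytest.approx(np.abs(1 - np.arange(5.0)).mean())


class TestCrossValidation:
    def test_every_subject_predicted_once(self, small_cohort_fit):
        X, node_ids, res = small_cohort_fit
        preds, folds = run_loocv((X, node_ids), res.residuals, 0.001)
        n = res.residuals.shape[0]
        for tail in ("positive", "negative", "combined"):
            assert np.isfinite(preds.predicted[tail]).all()
        assert folds.n_folds == n
        assert np.array_equal(np.sort(folds.fold_assignment), np.arange(n))

    def test_no_leakage_fold_masks_from_exclusion_set(self):
        """Stored fold masks equal masks recomputed on the training subset
        only, and differ from full-sample selection."""
        rng = np.random.default_rng(8)
        n, n_edges = 24, 66
        X = rng.standard_normal((n_edges, n))
        y = rng.standard_normal(n)
        X[5] += 0.9 * y
        preds, folds = run_loocv((X, np.arange(1, 13)), y, 0.1)
        full = select_edges(X, y, 0.1)
        any_diff = False
        for i, fm in enumerate(folds.folds):
            train = np.delete(np.arange(n), i)
            ref = select_edges(X[:, train], y[train], 0.1)
            assert np.array_equal(fm.masks.pos, ref.pos)
            assert np.array_equal(fm.masks.neg, ref.neg)
            assert np.allclose(fm.masks.p, ref.p)
            if not np.allclose(fm.masks.p, full.p):
                any_diff = True
        assert any_diff  # held-out subject's inclusion changes the p-values

    def test_kfold_equals_loocv_when_k_is_n(self, small_cohort_fit):
        X, node_ids, res = small_cohort_fit
        y = res.residuals
        n = y.shape[0]
        loocv_preds, _ = run_loocv((X, node_ids), y, 0.001)
        rk = run_repeated_kfold((X, node_ids), y, k=n, repeats=1,
                                p_threshold=0.001, seed=3)
        for tail in ("positive", "negative", "combined"):
            assert np.array_equal(loocv_preds.predicted[tail],
                                  rk.predictions[0].predicted[tail])

    def test_kfold_seeded_reproducible(self, small_cohort_fit):
        X, node_ids, res = small_cohort_fit
        y = res.residuals
        a = run_repeated_kfold((X, node_ids), y, k=5, repeats=2,
                               p_threshold=0.01, seed=11)
        b = run_repeated_kfold((X, node_ids), y, k=5, repeats=2,
                               p_threshold=0.01, seed=11)
        assert a.metrics.equals(b.metrics)
        for pa, pb in zip(a.predictions, b.predictions):
            assert np.array_equal(pa.predicted["combined"],
                                  pb.predicted["combined"])

    def test_kfold_consistent_with_loocv(self, small_cohort_fit):
        """Mean combined r over repeated 10-fold ~ the LOOCV r."""
        X, node_ids, res = small_cohort_fit
        y = res.residuals
        loocv_preds, _ = run_loocv((X, node_ids), y, 0.001)
        r_loo = evaluate(loocv_preds.predicted["combined"], y).r
        rk = run_repeated_kfold((X, node_ids), y, k=10, repeats=20,
                                p_threshold=0.001, seed=21)
        r_kf = rk.metrics.query("tail == 'combined'")["r"].mean()
        assert abs(r_kf - r_loo) < 0.1

    def test_k_out_of_range(self, small_cohort_fit):
        X, node_ids, res = small_cohort_fit
        with pytest.raises(ValueError, match="k must"):
            run_repeated_kfold((X, node_ids), res.residuals, k=1, repeats=1,
                               p_threshold=0.01)

    def test_fold_sizes_differ_by_at_most_one(self, small_cohort_fit):
        X, node_ids, res = small_cohort_fit
        rk = run_repeated_kfold((X, node_ids), res.residuals, k=7, repeats=1,
                                p_threshold=0.001, seed=2)
        sizes = [len(f.test_indices) for f in rk.fold_models[0].folds]
        assert max(sizes) - min(sizes) <= 1
        assert sum(sizes) == res.residuals.shape[0]

    def test_combined_metrics_invariant_to_unselected_edge_shift(self,
                                                                 small_cohort_fit):
        X, node_ids, res = small_cohort_fit
        y = res.residuals
        preds, folds = run_loocv((X, node_ids), y, 0.0009)
        ever = np.zeros(X.shape[0], dtype=bool)
        for fm in folds.folds:
            ever |= fm.masks.pos | fm.masks.neg
        X2 = X.copy()
        X2[~ever] += 5.0  # constant shift on never-selected edges
        preds2, _ = run_loocv((X2, node_ids), y, 0.0009)
        m1 = evaluate(preds.predicted["combined"], y)
        m2 = evaluate(preds2.predicted["combined"], y)
        assert m1.r == pytest.approx(m2.r, abs=1e-6)
        assert m1.mae == pytest.approx(m2.mae, abs=1e-6)


class TestOptimizeThreshold:
    def test_single_element_grid(self, small_cohort_fit):
        X, node_ids, res = small_cohort_fit
        out = optimize_threshold((X, node_ids), res.residuals, [0.005])
        assert out.best_threshold == 0.005
        assert len(out.trace) == 1

    def test_grid_validation(self, small_cohort_fit):
        X, node_ids, res = small_cohort_fit
        with pytest.raises(ValueError, match="outside"):
            optimize_threshold((X, node_ids), res.residuals, [0.01, 1.5])
        with pytest.raises(ValueError, match="empty"):
            optimize_threshold((X, node_ids), res.residuals, [])

    def test_planted_signal_admits_planted_edges(self, small_cohort,
                                                 small_cohort_fit):
        X, node_ids, res = small_cohort_fit
        out = optimize_threshold((X, node_ids), res.residuals,
                                 [0.0009, 0.01, 0.05])
        sel = select_edges(X, res.residuals, out.best_threshold)
        planted = np.concatenate([small_cohort.pos_edges,
                                  small_cohort.neg_edges])
        hits = sel.pos[small_cohort.pos_edges].sum() + \
            sel.neg[small_cohort.neg_edges].sum()
        assert hits / planted.size >= 0.8
        assert out.significant

    def test_pure_noise_not_significant(self):
        rng = np.random.default_rng(17)
        X = rng.standard_normal((105, 60))  # 15-node roster
        y = rng.standard_normal(60)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = optimize_threshold((X, np.arange(1, 16)), y,
                                     [0.001, 0.01, 0.05])
        # lenient grid points select only chance edges -> r near 0; strict
        # points leave empty masks whose mean-fallback predictions carry the
        # well-known leave-one-out anticorrelation (r -> -1), never a
        # spuriously positive signal
        r_lenient = out.trace.loc[out.trace["threshold"] == 0.05,
                                  "r_combined"].item()
        assert abs(r_lenient) < 0.45
        assert not out.significant


def _toy_fold_models():
    """Three folds with hand-enumerable masks on a 4-node (6-edge) roster."""
    node_ids = np.arange(1, 5)
    pos_sets = [{0, 1, 2}, {0, 1}, {0, 1, 5}]
    neg_sets = [{3}, {3, 4}, {3}]
    folds = []
    for k, (ps, ns) in enumerate(zip(pos_sets, neg_sets)):
        pos = np.zeros(6, dtype=bool); pos[list(ps)] = True
        neg = np.zeros(6, dtype=bool); neg[list(ns)] = True
        masks = EdgeMaskPair(pos=pos, neg=neg, r=np.zeros(6),
                             p=np.ones(6), threshold=0.05, node_ids=node_ids)
        folds.append(FoldModel(masks=masks,
                               params={t: (0.1 * k, 1.0 + k)
                                       for t in ("positive", "negative",
                                                 "combined")},
                               fallback={t: 0.0 for t in ("positive",
                                                          "negative",
                                                          "combined")},
                               test_indices=np.array([k])))
    return CPMFoldModels(folds=folds, fold_assignment=np.arange(3),
                         threshold=0.05, covariate_names=[],
                         node_ids=node_ids)


class TestAggregate:
    def test_single_fold_aggregate_is_that_fold(self):
        fm = _toy_fold_models()
        fm.folds = fm.folds[:1]
        agg = aggregate_model(fm, rule="intersection")
        assert np.array_equal(agg.pos_mask, fm.folds[0].masks.pos)
        assert agg.params["combined"] == (0.0, 1.0)

    def test_rules_match_hand_enumeration(self):
        fm = _toy_fold_models()
        inter = aggregate_model(fm, rule="intersection")
        union = aggregate_model(fm, rule="union")
        freq = aggregate_model(fm, rule="frequency", min_frequency=2 / 3)
        assert set(np.flatnonzero(inter.pos_mask)) == {0, 1}
        assert set(np.flatnonzero(inter.neg_mask)) == {3}
        assert set(np.flatnonzero(union.pos_mask)) == {0, 1, 2, 5}
        assert set(np.flatnonzero(union.neg_mask)) == {3, 4}
        assert set(np.flatnonzero(freq.pos_mask)) == {0, 1}
        # averaged line parameters over the three folds
        assert inter.params["positive"] == (pytest.approx(0.1),
                                            pytest.approx(2.0))

    def test_edge_in_every_fold_survives_all_rules(self):
        fm = _toy_fold_models()
        for rule in ("intersection", "union", "frequency"):
            agg = aggregate_model(fm, rule=rule)
            assert agg.pos_mask[0] and agg.pos_mask[1]

    def test_empty_aggregate_warns_and_records(self):
        fm = _toy_fold_models()
        for f in fm.folds:
            f.masks.neg[:] = False
        with pytest.warns(UserWarning, match="negative mask is empty"):
            agg = aggregate_model(fm, rule="intersection")
        assert any("negative" in n for n in agg.notes)


class TestExternalApplication:
    def test_node_roster_mismatch(self, small_cohort_fit):
        X, node_ids, res = small_cohort_fit
        _, folds = run_loocv((X, node_ids), res.residuals, 0.001)
        model = aggregate_model(folds)
        with pytest.raises(ValueError, match="roster"):
            apply_external(model, (X, np.arange(2, node_ids.size + 2)))

    def test_self_application_consistent_with_loocv(self, small_cohort_fit):
        X, node_ids, res = small_cohort_fit
        y = res.residuals
        preds, folds = run_loocv((X, node_ids), y, 0.001)
        model = aggregate_model(folds)
        ext = apply_external(model, (X, node_ids), target=y)
        r = np.corrcoef(ext.predictions.predicted["combined"],
                        preds.predicted["combined"])[0, 1]
        assert r >= 0.9

    def test_transfer_to_shared_truth_cohort(self, small_cohort,
                                             small_cohort_fit):
        from cpmreserve import GeneratorConfig, fit_cr_residual, \
            generate_cohort
        X, node_ids, res = small_cohort_fit
        _, folds = run_loocv((X, node_ids), res.residuals, 0.001)
        model = aggregate_model(folds)
        cfg2 = GeneratorConfig(**{**small_cohort.config.to_dict(),
                                  "seed": 99, "n_subjects": 120})
        ext_cohort = generate_cohort(cfg2,
                                     planted_edges=(small_cohort.pos_edges,
                                                    small_cohort.neg_edges))
        Xe = edge_matrix(ext_cohort.matrices)
        ye = fit_cr_residual(ext_cohort.cohort).residuals
        out = apply_external(model, Xe, target=ye)
        assert out.metrics["combined"].r > 0
        assert out.meaningful["combined"]

    def test_sign_flipped_transfer_flagged_not_meaningful(self, small_cohort,
                                                          small_cohort_fit):
        from cpmreserve import GeneratorConfig, fit_cr_residual, \
            generate_cohort
        X, node_ids, res = small_cohort_fit
        _, folds = run_loocv((X, node_ids), res.residuals, 0.001)
        model = aggregate_model(folds)
        cfg2 = GeneratorConfig(**{**small_cohort.config.to_dict(),
                                  "seed": 100, "n_subjects": 120})
        ext_cohort = generate_cohort(cfg2,
                                     planted_edges=(small_cohort.pos_edges,
                                                    small_cohort.neg_edges),
                                     flip_coupling=True)
        Xe = edge_matrix(ext_cohort.matrices)
        ye = fit_cr_residual(ext_cohort.cohort).residuals
        out = apply_external(model, Xe, target=ye)
        assert out.metrics["combined"].r < 0
        assert not out.meaningful["combined"]
        assert "not meaningful" in out.metrics["combined"].note
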