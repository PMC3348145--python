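"""SNR ranking, selection rules, weighted voting, ROC — against oracles."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from ovmorph import signature as sig
from ovmorph import synthetic as syn

from _oracles import (
    auc_pair_count,
    bh_stepup,
    select_features_loop,
    select_genes_loop,
    snr_direct,
)


class TestSnr:
    def test_equal_means_give_zero(self):
        assert sig.snr([1.0, 2.0, 3.0], [1.5, 2.0, 2.5]) == 0.0

    def test_hand_value(self):
        # sample SDs are 1/sqrt(2) each, so SNR = -2 / sqrt(2) = -1.4142
        assert sig.snr([1.0, 2.0], [3.0, 4.0]) == pytest.approx(-1.4142, abs=1e-4)

    def test_antisymmetric_and_matches_direct_formula(self, rng):
        a, b = rng.normal(size=30), rng.normal(1.0, 2.0, size=25)
        assert sig.snr(a, b) == pytest.approx(snr_direct(a, b), abs=1e-12)
        assert sig.snr(b, a) == pytest.approx(-sig.snr(a, b), abs=1e-12)

    def test_degenerate_spread_raises(self):
        with pytest.raises(sig.DegenerateFeatureError):
            sig.snr([1.0, 1.0, 1.0], [2.0, 2.0])


class TestBhAdjust:
    def test_hand_stepup_example(self):
        p = [0.01, 0.02, 0.03, 0.04, 0.05]
        assert sig.bh_adjust(p) == pytest.approx([0.05] * 5)

    def test_single_p_unchanged(self):
        assert sig.bh_adjust([0.123])[0] == pytest.approx(0.123)

    def test_matches_stepup_oracle_and_properties(self, rng):
        p = rng.uniform(size=97)
        q = sig.bh_adjust(p)
        assert q == pytest.approx(bh_stepup(p), abs=1e-12)
        assert np.all(q >= p) and np.all(q <= 1.0)
        # significance order preserved (ties in q allowed)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestPrescreen:
    def test_zero_quantiles_identity(self, expression_cohort):
        m, _, _ = expression_cohort
        out = sig.prescreen_genes(m, 0.0, 0.0)
        pd.testing.assert_frame_equal(out, m)

    def test_constant_gene_removed(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(5, 1, size=(20, 30)),
                         index=[f"G{i}" for i in range(20)])
        m.iloc[0] = 5.0
        out = sig.prescreen_genes(m, 0.2, 0.0)
        assert "G0" not in out.index

    def test_matches_two_predicate_loop(self, rng):
        m = pd.DataFrame(rng.normal(6, 2, size=(1000, 40)),
                         index=[f"G{i}" for i in range(1000)])
        out = sig.prescreen_genes(m, 0.3, 0.4)
        sds = m.std(axis=1, ddof=1)
        meds = m.median(axis=1)
        sd_thr = np.quantile(sds, 0.3)
        med_thr = np.quantile(meds, 0.4)
        expected = [g for g in m.index
                    if sds[g] > sd_thr and meds[g] > med_thr]
        assert list(out.index) == expected


class TestSelectMorphFeatures:
    def test_constant_feature_never_selected(self, rng):
        labels = pd.Series(["sensitive"] * 20 + ["resistant"] * 10,
                           index=[f"S{i}" for i in range(30)])
        f = pd.DataFrame(rng.normal(size=(30, 5)), index=labels.index,
                         columns=list("abcde"))
        f["a"] = 1.0
        chosen = {e.feature_id for e in sig.select_morph_features(f, labels, 0.5)}
        assert "a" not in chosen

    def test_planted_up_down_recovery_and_ranking(self):
        m, labels, truth = syn.generate_feature_dataset(seed=0)
        entries = sig.select_morph_features(m, labels, fdr_max=0.02)
        chosen = [e.feature_id for e in entries]
        assert set(chosen) == set(truth.up_features) | set(truth.down_features)
        # positive-SNR (sensitive-favouring) features head the ranking
        assert set(chosen[:5]) == set(truth.up_features)
        assert set(chosen[-10:]) == set(truth.down_features)
        assert all(e.w > 0 for e in entries[:5])
        assert all(e.w < 0 for e in entries[-10:])

    def test_matches_brute_force_loop(self, rng):
        labels = pd.Series(["sensitive"] * 25 + ["resistant"] * 15,
                           index=[f"S{i}" for i in range(40)])
        f = pd.DataFrame(rng.normal(size=(40, 60)), index=labels.index,
                         columns=[f"F{j}" for j in range(60)])
        f.iloc[:25, :4] += 1.5
        entries = sig.select_morph_features(f, labels, fdr_max=0.1)
        expected = select_features_loop(f.to_numpy(), labels.values, 0.1)
        assert {e.feature_id for e in entries} == {f.columns[j] for j in expected}

    def test_entry_invariants(self):
        m, labels, _ = syn.generate_feature_dataset(seed=2)
        for e in sig.select_morph_features(m, labels, fdr_max=0.02):
            assert math.copysign(1, e.w) == math.copysign(1, e.mu_sensitive - e.mu_resistant)
            assert min(e.mu_sensitive, e.mu_resistant) <= e.b <= max(e.mu_sensitive, e.mu_resistant)


class TestSelectGenes:
    def test_cutoff_one_reduces_to_t_test(self, expression_cohort):
        m, labels, _ = expression_cohort
        by_fc = {e.feature_id for e in sig.select_genes(m, labels, 1.0, 0.01)}
        oracle = select_genes_loop(m.to_numpy(), labels.values, 1.0, 0.01)
        assert by_fc == {m.index[i] for i in oracle}

    def test_planted_signal_recovered_with_directions(self, expression_cohort):
        m, labels, truth = expression_cohort
        entries = sig.select_genes(m, labels, fold_change_cutoff=1.5, p_max=0.05)
        chosen = {e.feature_id for e in entries}
        assert chosen == truth.informative_gene_ids
        n_up_res = sum(1 for e in entries if e.fold_change > 1)
        assert n_up_res == sum(1 for v in truth.direction.values() if v > 0)

    def test_matches_two_predicate_loop(self, rng):
        labels = pd.Series(["sensitive"] * 30 + ["resistant"] * 20,
                           index=[f"S{i}" for i in range(50)])
        m = pd.DataFrame(rng.normal(7, 1, size=(100, 50)),
                         index=[f"G{i}" for i in range(100)], columns=labels.index)
        entries = sig.select_genes(m, labels, 1.3, 0.1)
        expected = select_genes_loop(m.to_numpy(), labels.values, 1.3, 0.1)
        assert {e.feature_id for e in entries} == {m.index[i] for i in expected}


class TestTuneFoldChange:
    def test_single_candidate_returned(self, expression_cohort):
        m, labels, _ = expression_cohort
        best, curve = sig.tune_fold_change_cutoff(m, labels, [1.5])
        assert best == 1.5
        assert len(curve) == 1
        assert 0.0 <= curve["accuracy"].iloc[0] <= 1.0

    def test_empty_selection_flagged_with_majority_accuracy(self, expression_cohort):
        m, labels, _ = expression_cohort
        best, curve = sig.tune_fold_change_cutoff(m, labels, [1.5, 1e6])
        row = curve[curve["cutoff"] == 1e6].iloc[0]
        assert row["empty_selection"]
        assert row["accuracy"] == pytest.approx(max(labels.value_counts(normalize=True)))
        assert best == 1.5

    def test_best_cutoff_at_or_above_noise_scale(self):
        # strong planted genes at 4-fold; weak decoys die at a 1.5 cutoff
        m, labels, _ = syn.generate_expression_dataset(
            n_samples=80, n_genes=200, n_informative=10, log2_fold_change=2.0,
            noise_sd=0.5, resistant_fraction=0.4, seed=8,
        )
        best, curve = sig.tune_fold_change_cutoff(m, labels, [1.1, 1.5, 2.0, 3.0])
        assert best >= 1.1
        assert curve["accuracy"].between(0, 1).all()
        assert curve["accuracy"].idxmax() is not None


class TestWeightedVoting:
    def test_fitted_means_match_direct_loop(self, expression_cohort):
        m, labels, truth = expression_cohort
        entries = sig.select_genes(m, labels, 1.5, 0.05)
        model = sig.fit_weighted_voting(m, labels, entries)
        for e in model.entries:
            sens = m.loc[e.feature_id, (labels == "sensitive").values]
            res = m.loc[e.feature_id, (labels == "resistant").values]
            assert e.mu_sensitive == pytest.approx(sens.mean(), abs=1e-12)
            assert e.mu_resistant == pytest.approx(res.mean(), abs=1e-12)
            assert e.b == pytest.approx((sens.mean() + res.mean()) / 2, abs=1e-12)
            assert e.w == pytest.approx(
                snr_direct(sens.to_numpy(), res.to_numpy()), abs=1e-12)

    def test_refit_is_idempotent(self, expression_cohort):
        m, labels, _ = expression_cohort
        entries = sig.select_genes(m, labels, 1.5, 0.05)
        m1 = sig.fit_weighted_voting(m, labels, entries)
        m2 = sig.fit_weighted_voting(m, labels, m1.entries)
        assert [vars(a) for a in m1.entries] == [vars(b) for b in m2.entries]

    def test_sample_at_midpoints_scores_zero(self, expression_cohort):
        m, labels, _ = expression_cohort
        entries = sig.select_genes(m, labels, 1.5, 0.05)
        model = sig.fit_weighted_voting(m, labels, entries)
        x = pd.Series({e.feature_id: e.b for e in model.entries})
        assert sig.predict_score(model, x) == pytest.approx(0.0, abs=1e-12)

    def test_two_gene_hand_example(self):
        entries = [
            sig.SignatureEntry("g1", w=1.0, mu_sensitive=2.0, mu_resistant=0.0,
                               b=1.0, fold_change=0.5, p_value=0.01, q_value=0.02),
            sig.SignatureEntry("g2", w=-1.0, mu_sensitive=0.0, mu_resistant=2.0,
                               b=1.0, fold_change=2.0, p_value=0.01, q_value=0.02),
        ]
        model = sig.PredictiveModel(entries, score_cutoff=0.0)
        x = pd.Series({"g1": 2.0, "g2": 0.0})
        assert sig.predict_score(model, x) == pytest.approx(1.0)
        assert sig.classify(model, pd.Series({"s": 1.0})).iloc[0] == "sensitive"

    def test_reflection_negates_score(self, expression_cohort):
        m, labels, _ = expression_cohort
        model = sig.fit_weighted_voting(
            m, labels, sig.select_genes(m, labels, 1.5, 0.05))
        x = m.iloc[:, 0]
        b = pd.Series({e.feature_id: e.b for e in model.entries})
        reflected = (2 * b).reindex(x.index).fillna(0) - x
        s1 = sig.predict_score(model, x)
        s2 = sig.predict_score(model, reflected)
        assert s2 == pytest.approx(-s1, abs=1e-10)

    def test_missing_genes_renormalized_with_warning(self, expression_cohort):
        m, labels, _ = expression_cohort
        model = sig.fit_weighted_voting(
            m, labels, sig.select_genes(m, labels, 1.5, 0.05))
        x = m.iloc[:, 0].drop(index=model.feature_ids[0])
        with pytest.warns(UserWarning, match="renormalized"):
            sig.predict_score(model, x)
        with pytest.raises(ValueError, match="no features"):
            sig.predict_score(model, pd.Series({"nope": 1.0}))

    def test_vectorized_scores_equal_scalar_path(self, expression_cohort):
        m, labels, _ = expression_cohort
        model = sig.fit_weighted_voting(
            m, labels, sig.select_genes(m, labels, 1.5, 0.05))
        scores = sig.predict_scores(model, m)
        for sid in m.columns[:5]:
            assert scores[sid] == pytest.approx(
                sig.predict_score(model, m[sid]), abs=1e-12)


class TestRoc:
    def test_perfect_separation(self):
        scores = pd.Series([1.0, 2.0, 3.0, -1.0, -2.0],
                           index=list("abcde"))
        labels = pd.Series(["sensitive"] * 3 + ["resistant"] * 2,
                           index=list("abcde"))
        r = sig.roc_and_cutoff(scores, labels)
        assert r.auc == 1.0
        assert r.sensitivity == 1.0 and r.specificity == 1.0

    def test_auc_matches_pair_counting_oracle(self, rng):
        scores = pd.Series(rng.normal(size=60), index=range(60))
        labels = pd.Series(np.where(rng.uniform(size=60) < 0.5,
                                    "sensitive", "resistant"), index=range(60))
        if labels.nunique() < 2:
            labels.iloc[0] = "sensitive"
            labels.iloc[1] = "resistant"
        r = sig.roc_and_cutoff(scores, labels)
        assert r.auc == pytest.approx(
            auc_pair_count(scores, labels == "sensitive"), abs=1e-12)

    def test_independent_labels_auc_near_half(self):
        aucs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            scores = pd.Series(rng.normal(size=400), index=range(400))
            labels = pd.Series(np.where(rng.uniform(size=400) < 0.6,
                                        "sensitive", "resistant"), index=range(400))
            aucs.append(sig.roc_and_cutoff(scores, labels).auc)
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_constant_scores_degenerate(self):
        scores = pd.Series([1.0] * 10, index=range(10))
        labels = pd.Series(["sensitive"] * 6 + ["resistant"] * 4, index=range(10))
        r = sig.roc_and_cutoff(scores, labels)
        assert r.auc == 0.5 and r.degenerate and math.isnan(r.cutoff)

    def test_user_cutoff_honoured(self):
        scores = pd.Series([0.3, 0.1, -0.2, -0.5], index=range(4))
        labels = pd.Series(["sensitive", "sensitive", "resistant", "resistant"],
                           index=range(4))
        r = sig.roc_and_cutoff(scores, labels, cutoff=-0.3)
        assert r.cutoff == -0.3
        assert r.sensitivity == 1.0
        assert r.specificity == 0.5  # -0.2 > -0.3 misclassified, -0.5 <= cutoff


class TestSplitByQuantile:
    def test_seven_three_split(self):
        scores = pd.Series(np.arange(10.0), index=range(10))
        g = sig.split_by_quantile(scores, 0.7)
        assert (g == "high-score").sum() == 7
        assert set(g[scores >= 3].unique()) == {"high-score"}

    def test_study_split_171_of_244(self):
        rng = np.random.default_rng(0)
        scores = pd.Series(rng.normal(size=244), index=range(244))
        g = sig.split_by_quantile(scores, 0.701)
        assert (g == "high-score").sum() == 171
        assert (g == "low-score").sum() == 73

    def test_sizes_always_sum_to_n(self, rng):
        for n in (3, 11, 57):
            scores = pd.Series(rng.normal(size=n), index=range(n))
            g = sig.split_by_quantile(scores, 0.4)
            assert len(g) == n and g.notna().all()


class TestJarqueBera:
    def test_normal_sample_calibration(self):
        ok = 0
        for seed in range(40):
            v = np.random.default_rng(seed).normal(size=5000)
            _, p = sig.jarque_bera(v)
            ok += p > 0.01
        assert ok >= 38  # >= 95% of seeds

    def test_skewed_sample_rejected(self):
        v = np.random.default_rng(3).exponential(size=500)
        stat, p = sig.jarque_bera(v)
        assert p < 0.01 and stat >= 0

    def test_guards(self):
        with pytest.raises(ValueError):
            sig.jarque_bera([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            sig.jarque_bera([2.0] * 20)


def test_operating_point_accuracy_identity():
    """Printed operating point: sens 95.2%, spec 70%, classes 165/67 => 87.9%."""
    acc = sig.operating_point_accuracy(0.952, 0.70, 165, 67)
    assert round(100 * acc, 1) == 87.9
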