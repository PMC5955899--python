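import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

from keydyn import (
    PipelineConfig,
    auc_vs_sessions,
    bootstrap_roc,
    group_feature_comparison,
    selection_frequency,
    sensitivity_specificity,
    updrs_correlations,
)
from keydyn.pipeline import LOSOResult, SubjectPrediction

from oracles import mannwhitney_exact_p


def fake_loso(pf_by_subject, labels):
    preds = {}
    for sid, pf in pf_by_subject.items():
        pf = np.asarray(pf, float)
        preds[sid] = SubjectPrediction(
            subject_id=sid,
            label=labels[sid],
            session_index=list(range(1, len(pf) + 1)),
            first_stage=pd.DataFrame({"P_HT": pf, "P_NFT": pf, "P_NP": pf}),
            p_f=pf,
            probability=float(pf.mean()),
            predicted_label="PD" if pf.mean() >= 0.5 else "control",
        )
    return LOSOResult(preds, [], PipelineConfig())


class TestBootstrapROC:
    def test_perfect_separation(self):
        roc = bootstrap_roc([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0], n_boot=200, seed=0)
        assert roc.auc == 1.0
        assert roc.auc_mean == 1.0
        assert roc.ci == (1.0, 1.0)
        assert sensitivity_specificity(roc) == (1.0, 1.0)

    def test_label_independent_scores_give_chance_auc(self):
        rng = np.random.default_rng(42)
        scores = rng.uniform(size=500)
        labels = rng.integers(0, 2, 500)
        roc = bootstrap_roc(scores, labels, n_boot=1000, seed=1)
        assert abs(roc.auc_mean - 0.5) < 0.05

    def test_bootstrap_mean_converges_to_point_auc(self):
        rng = np.random.default_rng(3)
        scores = np.concatenate([rng.normal(0.6, 0.15, 40), rng.normal(0.4, 0.15, 40)])
        labels = np.array([1] * 40 + [0] * 40)
        r100 = bootstrap_roc(scores, labels, n_boot=100, seed=2)
        r1000 = bootstrap_roc(scores, labels, n_boot=1000, seed=2)
        assert abs(r1000.auc_mean - r1000.auc) <= abs(r100.auc_mean - r100.auc) + 0.01
        assert abs(r1000.auc_mean - r1000.auc) < 0.02

    def test_roc_curve_monotone(self):
        rng = np.random.default_rng(4)
        scores = rng.uniform(size=60)
        labels = rng.integers(0, 2, 60)
        roc = bootstrap_roc(scores, labels, n_boot=50, seed=0)
        assert (np.diff(roc.fpr) >= 0).all()
        assert (np.diff(roc.tpr) >= 0).all()

    def test_string_labels_accepted(self):
        roc = bootstrap_roc([0.9, 0.2, 0.8, 0.1], ["PD", "control", "PD", "control"],
                            n_boot=50, seed=0)
        assert roc.auc == 1.0


class TestOperatingPoint:
    def test_symmetric_overlap_balances_sensitivity_specificity(self):
        rng = np.random.default_rng(5)
        n = 2000
        scores = np.concatenate([rng.normal(0.6, 0.1, n), rng.normal(0.4, 0.1, n)])
        labels = np.array([1] * n + [0] * n)
        roc = bootstrap_roc(scores, labels, n_boot=20, seed=0)
        sens, spec = sensitivity_specificity(roc)
        assert abs(sens - spec) < 0.05

    def test_degenerate_single_threshold_scores(self):
        roc = bootstrap_roc([0.7, 0.7, 0.7, 0.2], [1, 0, 1, 0], n_boot=20, seed=0)
        sens, spec = sensitivity_specificity(roc)
        assert 0.0 <= sens <= 1.0 and 0.0 <= spec <= 1.0


class TestAUCvsSessions:
    def test_full_session_count_matches_direct_auc(self):
        rng = np.random.default_rng(6)
        labels = {f"S{i}": ("PD" if i < 8 else "control") for i in range(16)}
        pf = {
            sid: np.clip(rng.normal(0.7 if lab == "PD" else 0.3, 0.2, 10), 0, 1)
            for sid, lab in labels.items()
        }
        loso = fake_loso(pf, labels)
        curve = auc_vs_sessions(loso, max_sessions=10, n_repeats=5, seed=0)
        y = np.array([1 if labels[s] == "PD" else 0 for s in pf])
        direct_mean = roc_auc_score(y, [pf[s].mean() for s in pf])
        direct_median = roc_auc_score(y, [np.median(pf[s]) for s in pf])
        at_max = curve[curve["n_sessions"] == 10].set_index("voting")["auc"]
        assert at_max["mean"] == pytest.approx(direct_mean)
        assert at_max["median"] == pytest.approx(direct_median)

    def test_more_sessions_do_not_hurt(self):
        rng = np.random.default_rng(7)
        labels = {f"S{i}": ("PD" if i < 10 else "control") for i in range(20)}
        pf = {
            sid: np.clip(rng.normal(0.65 if lab == "PD" else 0.35, 0.25, 10), 0, 1)
            for sid, lab in labels.items()
        }
        curve = auc_vs_sessions(fake_loso(pf, labels), max_sessions=10, n_repeats=30, seed=1)
        mean_curve = curve[curve["voting"] == "mean"].sort_values("n_sessions")["auc"].to_numpy()
        assert mean_curve[-1] >= mean_curve[0] - 0.02


class TestGroupComparison:
    def test_disjoint_supports_reach_minimal_p(self):
        table = pd.DataFrame(
            {
                "variable": ["HT"] * 16,
                "label": ["PD"] * 8 + ["control"] * 8,
                "mu_mean": list(np.linspace(0.2, 0.3, 8)) + list(np.linspace(0.05, 0.1, 8)),
            }
        )
        for f in ("mu_std", "sigma_mean", "sigma_std", "skew_mean", "skew_std",
                  "kurt_mean", "kurt_std", "cov_mean", "cov_std", "cov_abs_sum"):
            table[f] = np.linspace(0, 1, 16)
        out = group_feature_comparison(table)
        p = out[(out["variable"] == "HT") & (out["feature"] == "mu_mean")].iloc[0]["p_value"]
        # smallest attainable two-sided p for 8 vs 8
        assert p == pytest.approx(2.0 / 12870, rel=1e-6)

    @pytest.mark.parametrize("n1,n2,seed", [(4, 4, 0), (5, 3, 1), (8, 8, 2), (6, 7, 3)])
    def test_small_sample_p_matches_exhaustive_enumeration(self, n1, n2, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0.5, 1.0, n1)
        y = rng.normal(0.0, 1.0, n2)
        u_oracle, p_oracle = mannwhitney_exact_p(x, y)
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
        assert res.statistic == pytest.approx(u_oracle)
        assert res.pvalue == pytest.approx(p_oracle, rel=1e-9)

    def test_constant_feature_reported_as_degenerate(self):
        table = pd.DataFrame(
            {
                "variable": ["NP"] * 10,
                "label": ["PD"] * 5 + ["control"] * 5,
            }
        )
        for f in ("mu_mean", "mu_std", "sigma_mean", "sigma_std", "skew_mean",
                  "skew_std", "kurt_mean", "kurt_std", "cov_mean", "cov_std",
                  "cov_abs_sum"):
            table[f] = 1.0
        out = group_feature_comparison(table)
        row = out[(out["variable"] == "NP") & (out["feature"] == "mu_mean")].iloc[0]
        assert np.isnan(row["p_value"]) and "degenerate" in row["note"]


class TestSelectionFrequency:
    def test_always_and_never_selected(self):
        loso = fake_loso({"A": [0.9], "B": [0.1]}, {"A": "PD", "B": "control"})
        loso.selected_features = [
            {"HT": ["mu_mean"], "NFT": [], "NP": ["mu_mean", "cov_mean"]},
            {"HT": ["mu_mean"], "NFT": [], "NP": ["cov_mean"]},
        ]
        freq = selection_frequency(loso).set_index(["variable", "feature"])["selected_pct"]
        assert freq[("HT", "mu_mean")] == 100.0
        assert freq[("HT", "sigma_mean")] == 0.0
        assert freq[("NP", "mu_mean")] == 50.0


class TestUPDRSCorrelations:
    def _features(self, values):
        rows = []
        for i, v in enumerate(values):
            rows.append({"subject_id": f"S{i}", "session_index": 1, "variable": "HT",
                         "label": "PD", "mu_mean": v})
        return pd.DataFrame(rows)

    def test_feature_equal_to_score_gives_unit_correlation(self):
        feats = self._features([1.0, 2.0, 3.0, 4.0, 5.0])
        updrs = pd.DataFrame(
            {"subject_id": [f"S{i}" for i in range(5)], "total": [1, 2, 3, 4, 5]}
        )
        out = updrs_correlations(feats, updrs, which=[("HT", "mu_mean")])
        assert out.iloc[0]["r_s"] == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        feats = self._features([5.0, 4.0, 3.0, 2.0, 1.0])
        updrs = pd.DataFrame(
            {"subject_id": [f"S{i}" for i in range(5)], "total": [1, 2, 3, 4, 5]}
        )
        out = updrs_correlations(feats, updrs, which=[("HT", "mu_mean")])
        assert out.iloc[0]["r_s"] == pytest.approx(-1.0)

    def test_synthetic_cohort_recovers_the_planted_sign_pattern(self):
        """With severity-linked generation, HT features correlate positively
        with motor scores while NFT skewness and NP level correlate
        negatively, across all subjects (controls scored zero)."""
        from keydyn import extract_feature_table, generate_cohort

        cohort = generate_cohort(12, 10, 4, seed=77)
        feats = extract_feature_table(cohort.subjects)
        updrs = pd.DataFrame(
            [{"subject_id": s.subject_id, "total": s.updrs_total} for s in cohort.subjects]
        )
        out = updrs_correlations(feats, updrs).set_index(["variable", "feature"])
        assert out.loc[("HT", "mu_mean"), "r_s"].item() > 0.4
        assert out.loc[("HT", "sigma_mean"), "r_s"].item() > 0.4
        assert out.loc[("NFT", "skew_mean"), "r_s"].item() < -0.4
        assert out.loc[("NP", "mu_mean"), "r_s"].item() < -0.4

    def test_zero_variance_item_reported_undefined(self):
        feats = self._features([1.0, 2.0, 3.0])
        updrs = pd.DataFrame({"subject_id": ["S0", "S1", "S2"], "total": [0, 0, 0]})
        out = updrs_correlations(feats, updrs, which=[("HT", "mu_mean")])
        assert np.isnan(out.iloc[0]["r_s"]) and out.iloc[0]["note"]
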