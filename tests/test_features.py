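import numpy as np
import pytest

from keydyn import (
    ConstantWindowError,
    FeatureConfig,
    NoValidWindowsError,
    estimate_pdf,
    hold_times,
    moment_stats,
    pdf_covariance,
    session_feature_vector,
    window_subsequences,
)
from keydyn.features import FEATURE_NAMES, extract_feature_table
from keydyn.sequences import VariableSequence
from keydyn.simulate import generate_cohort, generate_session, make_profile

from conftest import make_session
from oracles import kde_bruteforce, moments_bruteforce, pdf_cov_bruteforce


def seq(values, starts, ends, variable="HT"):
    return VariableSequence(variable, np.asarray(values, float),
                            np.asarray(starts, float), np.asarray(ends, float))


class TestWindowing:
    def test_uniform_split_into_two_windows(self):
        presses = [int(k * 1500) for k in range(20)]
        s = make_session(presses, [p + 100 for p in presses])
        windows = window_subsequences(hold_times(s))
        assert [w.index for w in windows] == [1, 2]
        assert [len(w) for w in windows] == [10, 10]

    def test_minimum_count_rule_drops_sparse_window(self):
        presses = [0, 2000, 4000, 6000, 8000, 10000, 16000, 19000, 22000]
        s = make_session(presses, [p + 100 for p in presses])
        windows = window_subsequences(hold_times(s))
        assert [w.index for w in windows] == [1]
        assert len(windows[0]) == 6

    def test_boundary_straddling_element_excluded_from_both_windows(self):
        # element press 14.9 s / release 15.1 s straddles the window edge
        sq = seq([0.2], [14.9], [15.1])
        cfg = FeatureConfig(min_elements=1)
        windows = window_subsequences(
            seq([0.1, 0.2], [1.0, 14.9], [1.1, 15.1]), cfg
        )
        assert [len(w) for w in windows] == [1]  # only the interior element
        with pytest.raises(NoValidWindowsError):
            window_subsequences(sq, cfg)

    def test_first_keystroke_belongs_to_window_one(self):
        sq = seq([0.1] * 5, [0.0, 1, 2, 3, 4], [0.1, 1.1, 2.1, 3.1, 4.1])
        windows = window_subsequences(sq)
        assert len(windows[0]) == 5

    def test_no_valid_window_raises(self):
        with pytest.raises(NoValidWindowsError):
            window_subsequences(seq([0.1, 0.1], [0, 1], [0.1, 1.1]))


class TestMoments:
    def test_symmetric_sample(self):
        st = moment_stats(np.array([1.0, 2, 3, 4, 5]))
        assert st.mu == pytest.approx(3.0)
        assert st.sigma == pytest.approx(np.sqrt(2.5))
        assert st.skew == pytest.approx(0.0, abs=1e-14)

    @pytest.mark.parametrize(
        "sample",
        [
            [0.1, 0.1, 0.1, 0.1, 0.9],
            [0.12, 0.18, 0.09, 0.40, 0.11, 0.13],
            list(np.random.default_rng(3).lognormal(-2, 0.4, 10)),
        ],
    )
    def test_matches_bruteforce_formula_evaluation(self, sample):
        st = moment_stats(np.asarray(sample))
        mu, sigma, skew, kurt = moments_bruteforce(sample)
        assert st.mu == pytest.approx(mu, rel=1e-12)
        assert st.sigma == pytest.approx(sigma, rel=1e-12)
        assert st.skew == pytest.approx(skew, rel=1e-12)
        assert st.kurt == pytest.approx(kurt, rel=1e-12)

    def test_gaussian_kurtosis_is_raw(self):
        x = np.random.default_rng(0).normal(size=50_000)
        assert moment_stats(x).kurt == pytest.approx(3.0, abs=0.1)

    def test_constant_window_rejected(self):
        with pytest.raises(ConstantWindowError):
            moment_stats(np.full(6, 0.2))


class TestKDE:
    def test_matches_bruteforce_kernel_sum(self):
        cfg = FeatureConfig()
        vals = np.array([0.08, 0.11, 0.09, 0.14, 0.10])
        ours = estimate_pdf(vals, "HT", cfg)
        brute = kde_bruteforce(vals, cfg.grid("HT"), cfg.bandwidths["HT"])
        np.testing.assert_allclose(ours, brute, rtol=1e-12)

    def test_identical_windows_give_identical_pdfs(self):
        vals = np.array([0.1, 0.2, 0.15, 0.12, 0.18])
        np.testing.assert_array_equal(
            estimate_pdf(vals, "NP"), estimate_pdf(vals.copy(), "NP")
        )

    def test_density_peaks_at_the_data_location(self):
        cfg = FeatureConfig()
        grid = cfg.grid("NP")
        x0 = grid[4]
        pdf = estimate_pdf(np.full(5, x0), "NP", cfg)
        assert pdf.argmax() == 4

    def test_densities_nonnegative_per_variable(self):
        for var in ("HT", "NFT", "NP"):
            pdf = estimate_pdf(np.array([0.0, 0.1, 0.2, 0.05, 0.15]), var)
            assert (pdf >= 0).all()


class TestPDFCovariance:
    def test_identical_pdfs_covariance_equals_grid_variance(self):
        f = np.random.default_rng(1).random(10)
        c_mean, c_std, c_abs = pdf_covariance([f, f])
        assert c_mean == pytest.approx(f.var(ddof=1))
        assert c_std == 0.0
        assert c_abs == pytest.approx(abs(f.var(ddof=1)))

    def test_constant_pdf_has_zero_covariance(self):
        f = np.random.default_rng(2).random(10)
        c_mean, _, c_abs = pdf_covariance([np.full(10, 0.3), f])
        assert c_mean == pytest.approx(0.0, abs=1e-15)
        assert c_abs == pytest.approx(0.0, abs=1e-15)

    def test_matches_double_loop_oracle(self):
        F = np.random.default_rng(3).random((3, 10))
        C = pdf_cov_bruteforce(F)
        cu = C[np.triu_indices(3, k=1)]
        c_mean, c_std, c_abs = pdf_covariance(F)
        assert c_mean == pytest.approx(cu.mean(), rel=1e-12)
        assert c_std == pytest.approx(cu.std(ddof=1), rel=1e-12)
        assert c_abs == pytest.approx(np.abs(cu).sum(), rel=1e-12)

    def test_single_window_summaries_are_zero(self):
        assert pdf_covariance([np.random.default_rng(4).random(10)]) == (0.0, 0.0, 0.0)


class TestSessionFeatureVector:
    def test_vector_lengths_per_variable(self):
        s = generate_session(make_profile("PD"), 90, seed=5)
        assert len(session_feature_vector(s, "HT")) == 11
        assert len(session_feature_vector(s, "NFT")) == 9
        assert len(session_feature_vector(s, "NP")) == 11

    def test_extraction_is_deterministic(self):
        s = generate_session(make_profile("control"), 80, seed=6)
        v1 = session_feature_vector(s, "HT")
        v2 = session_feature_vector(s, "HT")
        assert (v1 == v2).all()

    def test_identical_windows_zero_dispersion(self):
        # two windows with identical values, offset by exactly one window
        base = [0, 1500, 3000, 4500, 6000, 7500]
        presses = base + [p + 15000 for p in base]
        ht = [100, 140, 90, 200, 160, 110] * 2
        s = make_session(presses, [p + h for p, h in zip(presses, ht)])
        v = session_feature_vector(s, "HT")
        for name in ("mu_std", "sigma_std", "skew_std", "kurt_std", "cov_std"):
            assert v[name] == pytest.approx(0.0, abs=1e-14)

    def test_two_window_vector_matches_hand_aggregation(self):
        base = [0, 1500, 3000, 4500, 6000, 7500]
        presses = base + [p + 15000 for p in base]
        ht = [100, 140, 90, 200, 160, 110, 95, 180, 130, 105, 150, 170]
        s = make_session(presses, [p + h for p, h in zip(presses, ht)])
        cfg = FeatureConfig()
        v = session_feature_vector(s, "HT", cfg)

        w1 = np.array(ht[:6]) / 1000.0
        w2 = np.array(ht[6:]) / 1000.0
        m1, m2 = moments_bruteforce(w1), moments_bruteforce(w2)
        assert v["mu_mean"] == pytest.approx((m1[0] + m2[0]) / 2, rel=1e-12)
        assert v["mu_std"] == pytest.approx(np.std([m1[0], m2[0]], ddof=1), rel=1e-12)
        assert v["skew_mean"] == pytest.approx((m1[2] + m2[2]) / 2, rel=1e-12)
        f1 = kde_bruteforce(w1, cfg.grid("HT"), cfg.bandwidths["HT"])
        f2 = kde_bruteforce(w2, cfg.grid("HT"), cfg.bandwidths["HT"])
        c12 = pdf_cov_bruteforce([f1, f2])[0, 1]
        assert v["cov_mean"] == pytest.approx(c12, rel=1e-10)
        assert v["cov_std"] == 0.0
        assert v["cov_abs_sum"] == pytest.approx(abs(c12), rel=1e-10)


class TestFeatureTable:
    def test_long_format_over_cohort(self):
        cohort = generate_cohort(2, 2, 3, seed=77)
        table = extract_feature_table(cohort.subjects)
        assert set(table["variable"]) == {"HT", "NFT", "NP"}
        assert set(table["label"]) == {"PD", "control"}
        nft = table[table["variable"] == "NFT"]
        assert nft["mu_mean"].isna().all()  # zero-mean channel omits the pair
        ht = table[table["variable"] == "HT"]
        assert ht[FEATURE_NAMES["HT"]].notna().all().all()
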