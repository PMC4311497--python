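import numpy as np
import pytest

from homeostat.spikedata import SpikeTrain, TimeSegment, population_mfr
from homeostat.stability import (RateBins, baseline_change_correlation,
                                 bin_rates, classify_population,
                                 compare_rate_distributions, cv_by_binsize,
                                 mfr_timecourse, permutation_change_test,
                                 segment_representativeness)
from homeostat.synthdata import Perturbation, SynthConfig, gen_session

from conftest import make_session


def poisson_train(rate, seg, seed, uid="u"):
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate * seg.duration)
    return SpikeTrain(uid, np.sort(rng.uniform(seg.start, seg.end, n)), seg)


def const_bins(uid, n, rate, bin_width=60.0, start=0.0):
    seg = TimeSegment(start, start + n * bin_width)
    return RateBins(uid, seg, bin_width, np.full(n, rate * bin_width))


class TestBinRates:
    def test_bin_count_and_uniform_rates(self):
        seg = TimeSegment(0, 1200)
        tr = SpikeTrain("u", np.arange(0, 1200.0), seg)  # exact 1 Hz
        rb = bin_rates(tr, seg)
        assert rb.n_bins == 20
        assert np.allclose(rb.rates, 1.0)

    def test_counts_conserved(self, poisson_train_fixture=None):
        seg = TimeSegment(0, 1250)  # trailing 50 s dropped
        tr = poisson_train(2.0, seg, 3)
        rb = bin_rates(tr, seg)
        covered = TimeSegment(0, 1200)
        n_cov = np.searchsorted(tr.times, 1200.0)
        assert rb.counts.sum() == n_cov

    def test_too_short_segment(self):
        seg = TimeSegment(0, 30)
        with pytest.raises(ValueError):
            bin_rates(SpikeTrain("u", [], seg), seg)


class TestPermutationTest:
    def test_identical_constant_bins_stable(self):
        a = const_bins("u", 20, 1.0)
        b = const_bins("u", 20, 1.0, start=1200.0)
        c = permutation_change_test(a, b, n_iter=1000, seed=1)
        assert c.label == "stable"
        assert c.observed_diff == 0.0

    def test_maximal_separation_increased(self):
        a = const_bins("u", 20, 0.0)
        b = const_bins("u", 20, 1.0, start=1200.0)
        c = permutation_change_test(a, b, n_iter=1000, seed=1)
        assert c.label == "increased"

    def test_symmetry_mirrors_label(self):
        seg_a, seg_b = TimeSegment(0, 1200), TimeSegment(1200, 2400)
        a = bin_rates(poisson_train(1.0, seg_a, 5), seg_a)
        b = bin_rates(poisson_train(3.0, seg_b, 6), seg_b)
        fwd = permutation_change_test(a, b, n_iter=2000, seed=2)
        rev = permutation_change_test(b, a, n_iter=2000, seed=2)
        assert fwd.observed_diff == pytest.approx(-rev.observed_diff)
        assert fwd.label == "increased" and rev.label == "decreased"

    def test_deterministic_under_seed(self):
        seg_a, seg_b = TimeSegment(0, 1200), TimeSegment(1200, 2400)
        a = bin_rates(poisson_train(1.0, seg_a, 7), seg_a)
        b = bin_rates(poisson_train(1.0, seg_b, 8), seg_b)
        c1 = permutation_change_test(a, b, seed=9)
        c2 = permutation_change_test(a, b, seed=9)
        assert (c1.null_lo, c1.null_hi, c1.label) == (c2.null_lo, c2.null_hi,
                                                      c2.label)

    def test_type_one_error_calibration(self):
        """~5% of stationary Poisson units flagged at alpha 0.05 (300 units)."""
        flagged = 0
        n_units = 300
        for k in range(n_units):
            seg_a, seg_b = TimeSegment(0, 1200), TimeSegment(1200, 2400)
            ta = poisson_train(1.0, seg_a, 1000 + k, uid=f"u{k}")
            tb = poisson_train(1.0, seg_b, 5000 + k, uid=f"u{k}")
            c = permutation_change_test(bin_rates(ta, seg_a),
                                        bin_rates(tb, seg_b),
                                        n_iter=2000, seed=k)
            flagged += c.label != "stable"
        assert 0.03 <= flagged / n_units <= 0.07

    def test_power_at_rate_ratio_three(self):
        """Power >= 0.9 for a 1 Hz vs 3 Hz change with 20+20 one-min bins."""
        detected = 0
        n_units = 100
        for k in range(n_units):
            seg_a, seg_b = TimeSegment(0, 1200), TimeSegment(1200, 2400)
            ta = poisson_train(1.0, seg_a, 100 + k, uid=f"u{k}")
            tb = poisson_train(3.0, seg_b, 700 + k, uid=f"u{k}")
            c = permutation_change_test(bin_rates(ta, seg_a),
                                        bin_rates(tb, seg_b),
                                        n_iter=2000, seed=k)
            detected += c.label == "increased"
        assert detected / n_units >= 0.9

    def test_bootstrap_variant_runs(self):
        seg_a, seg_b = TimeSegment(0, 1200), TimeSegment(1200, 2400)
        a = bin_rates(poisson_train(1.0, seg_a, 1), seg_a)
        b = bin_rates(poisson_train(1.0, seg_b, 2), seg_b)
        c = permutation_change_test(a, b, n_iter=1000, seed=3,
                                    method="bootstrap")
        assert c.label in {"stable", "increased", "decreased"}


class TestClassifyPopulation:
    def test_single_unit_percentages(self):
        s = make_session({"u": np.arange(0.5, 2400.0)}, 2400.0)
        summary, table = classify_population(
            s, TimeSegment(0, 1200), TimeSegment(1200, 2400), n_iter=500,
            seed=1)
        assert summary["n_units"] == 1
        vals = {summary["pct_stable"], summary["pct_increased"],
                summary["pct_decreased"]}
        assert vals <= {0.0, 100.0}

    def test_stationary_session_mostly_stable(self):
        cfg = SynthConfig(n_units=60, duration=2400.0, burst_event_rate=0.0,
                          rate_lognorm=(1.0, 0.5), seed=23)
        session, _ = gen_session(cfg)
        summary, _ = classify_population(
            session, TimeSegment(0, 1200), TimeSegment(1200, 2400),
            n_iter=2000, seed=5)
        assert summary["pct_stable"] >= 85.0

    def test_dispersed_recovery_dissociation(self, perturbed_session):
        """Population MFR recovers while most units change individually."""
        session, truth = perturbed_session
        seg_a = TimeSegment(1800.0, 3000.0)            # late baseline
        seg_b = TimeSegment(session.duration - 1200.0, session.duration)
        summary, _ = classify_population(session, seg_a, seg_b, n_iter=2000,
                                         seed=6)
        mfr_ratio = (population_mfr(session, seg_b)
                     / population_mfr(session, seg_a))
        assert 0.7 < mfr_ratio < 1.3          # population recovered
        assert summary["pct_stable"] < 50.0   # few units kept their set point


class TestTimecourse:
    def test_stationary_near_100pct(self):
        session, _ = gen_session(SynthConfig(n_units=30,
                                             duration=4 * 3600.0, seed=2))
        tc = mfr_timecourse(session, baseline=TimeSegment(0, 3600.0))
        assert np.all(np.abs(tc["pct_of_baseline"] - 100.0) < 15.0)

    def test_acute_suppression_first_hour(self):
        session, _ = gen_session(SynthConfig(
            n_units=30, duration=3 * 3600.0, seed=3,
            perturbation=Perturbation(onset=3600.0, suppression_factor=0.012,
                                      recovery_tau=1e6, unit_dispersion=0.0)))
        tc = mfr_timecourse(session, baseline="baseline")
        assert 0.5 < tc["pct_of_baseline"].iloc[1] < 3.0

    def test_fast_recovery_returns_to_baseline(self):
        session, _ = gen_session(SynthConfig(
            n_units=30, duration=6 * 3600.0, seed=4,
            perturbation=Perturbation(onset=3600.0, suppression_factor=0.012,
                                      recovery_tau=900.0,
                                      unit_dispersion=0.0)))
        tc = mfr_timecourse(session, baseline="baseline")
        assert abs(tc["pct_of_baseline"].iloc[-1] - 100.0) < 15.0


class TestCV:
    def test_deterministic_uniform_zero_cv(self):
        seg = TimeSegment(0, 8 * 3600.0)
        tr = SpikeTrain("u", np.arange(0.5, 8 * 3600.0, 1.0), seg)
        df = cv_by_binsize(tr, seg)
        assert np.allclose(df["cv_pct"], 0.0, atol=1e-9)

    def test_poisson_cv_closed_form(self):
        """CV of per-bin Poisson counts ~ 100/sqrt(rate*T), within 20%."""
        seg = TimeSegment(0, 8 * 3600.0)
        tr = poisson_train(2.0, seg, 31)
        # bin sizes with >= 240 bins each, so the CV estimate's own
        # sampling error (~CV/sqrt(2 n_bins)) stays well inside 20%
        df = cv_by_binsize(tr, seg, bin_sizes=(10.0, 30.0, 120.0))
        for _, row in df.iterrows():
            expected = 100.0 / np.sqrt(2.0 * row["bin_size_s"])
            assert abs(row["cv_pct"] - expected) / expected < 0.2

    def test_cv_decreases_with_bin_size(self):
        seg = TimeSegment(0, 8 * 3600.0)
        tr = poisson_train(1.0, seg, 32)
        df = cv_by_binsize(tr, seg)
        assert df["cv_pct"].iloc[-1] <= df["cv_pct"].iloc[0]


class TestRepresentativeness:
    def test_deterministic_train_ratio_one(self):
        s = make_session({"u": np.arange(0.5, 2 * 3600.0, 1.0)}, 2 * 3600.0)
        df = segment_representativeness(s)
        assert np.allclose(df["ratio"], 1.0)

    def test_full_window_identity(self):
        s = make_session({"u": np.arange(0.5, 2 * 3600.0, 1.0)}, 2 * 3600.0)
        df = segment_representativeness(s, window_min=60.0)
        assert np.allclose(df["ratio"], 1.0)

    def test_poisson_concentration(self):
        seg = TimeSegment(0, 4 * 3600.0)
        trains = {f"u{k}": poisson_train(1.0 + k * 0.5, seg, 200 + k).times
                  for k in range(10)}
        s = make_session(trains, 4 * 3600.0)
        df = segment_representativeness(s)
        within_10 = float((np.abs(df["ratio"] - 1.0) <= 0.10).mean())
        assert within_10 >= 0.9


class TestDistributionComparisons:
    def test_identical_samples(self):
        r = np.array([0.5, 1.0, 2.0, 4.0])
        out = compare_rate_distributions(r, r)
        assert out["ks_statistic"] == 0.0
        assert out["p_value"] == pytest.approx(1.0)

    def test_disjoint_supports(self):
        out = compare_rate_distributions(np.array([0.1, 0.2, 0.3]),
                                         np.array([10.0, 20.0, 30.0]))
        assert out["ks_statistic"] == 1.0

    def test_null_p_values_roughly_uniform(self):
        """Two draws from one log-normal give ~uniform KS p-values."""
        from scipy import stats
        rng = np.random.default_rng(77)
        ps = []
        for _ in range(120):
            a = np.exp(rng.standard_normal(300))
            b = np.exp(rng.standard_normal(300))
            ps.append(compare_rate_distributions(a, b)["p_value"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestBaselineChangeCorrelation:
    def test_no_change_undefined(self):
        r = np.array([0.5, 1.0, 2.0])
        out = baseline_change_correlation(r, r)
        assert np.isnan(out["spearman_r"])

    def test_perfect_inverse(self):
        r0 = np.array([0.5, 1.0, 2.0, 4.0])
        out = baseline_change_correlation(r0, 2.0 / r0)
        assert out["spearman_r"] == pytest.approx(-1.0)

    def test_regression_to_mean_negative_sign(self):
        """Independent re-draws of Poisson rates yield negative correlation
        between baseline and percent change."""
        rng = np.random.default_rng(55)
        base = np.exp(rng.standard_normal(150))
        r0 = rng.poisson(base * 1200) / 1200.0
        r2 = rng.poisson(base * 1200) / 1200.0
        ok = r0 > 0
        out = baseline_change_correlation(r0[ok], r2[ok])
        assert out["spearman_r"] < 0
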