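import numpy as np
import pytest
from scipy import stats

from pallidyn import simulate as sim
from pallidyn.types import SimConfig


def cv(x):
    return np.std(x, ddof=1) / np.mean(x)


class TestGammaRenewal:
    def test_poisson_cv_near_one(self):
        tr = sim.gen_gamma_renewal(20, 1, 200, seed=1)
        assert 0.93 <= cv(tr.isi()) <= 1.07

    def test_high_shape_is_regular(self):
        tr = sim.gen_gamma_renewal(20, 100, 200, seed=1)
        assert cv(tr.isi()) < 0.15

    def test_count_matches_renewal_law(self):
        mean = 20 * 200
        for seed in range(5):
            n = sim.gen_gamma_renewal(20, 1, 200, seed=seed).n_spikes
            assert abs(n - mean) < 4 * np.sqrt(mean)

    @pytest.mark.parametrize("shape", [0.5, 2, 10])
    def test_cv_converges_to_inverse_sqrt_shape(self, shape):
        tr = sim.gen_gamma_renewal(20, shape, 500, seed=3)
        assert cv(tr.isi()) == pytest.approx(1 / np.sqrt(shape), rel=0.05)

    def test_bitwise_reproducible(self):
        a = sim.gen_gamma_renewal(20, 2, 50, seed=9)
        b = sim.gen_gamma_renewal(20, 2, 50, seed=9)
        assert np.array_equal(a.times, b.times)

    def test_too_few_expected_spikes_rejected(self):
        with pytest.raises(ValueError, match="longer duration"):
            sim.gen_gamma_renewal(0.05, 1, 10, seed=0)


class TestBurstyTrain:
    def test_zero_burst_rate_degenerates_to_renewal(self):
        cfg = SimConfig(base_rate=10, shape=1, duration=30, burst_rate=0, seed=4)
        a = sim.gen_bursty_train(cfg)
        b = sim.gen_gamma_renewal(10, 1, 30, seed=4)
        assert np.array_equal(a.times, b.times)

    def test_intra_burst_isi_matches_rate(self):
        cfg = SimConfig(base_rate=2, shape=1, duration=60, burst_rate=0.5,
                        intra_burst_rate=200, burst_len=12, seed=5)
        tr = sim.gen_bursty_train(cfg)
        isis = []
        for a, b in tr.annotations["bursts"]:
            inside = tr.times[(tr.times >= a) & (tr.times <= b + 1e-9)]
            if inside.size > 3:
                isis.extend(np.diff(inside))
        assert np.mean(isis) == pytest.approx(1 / 200, rel=0.10)

    def test_bursts_not_denser_than_background_rejected(self):
        cfg = SimConfig(base_rate=50, intra_burst_rate=20, burst_rate=0.5, seed=0)
        with pytest.raises(ValueError, match="denser than background"):
            sim.gen_bursty_train(cfg)

    def test_planted_windows_disjoint_and_recorded(self):
        cfg = SimConfig(base_rate=5, duration=30, burst_rate=0.4, intra_burst_rate=150, seed=6)
        tr = sim.gen_bursty_train(cfg)
        w = tr.annotations["bursts"]
        assert all(w[i][1] <= w[i + 1][0] for i in range(len(w) - 1))


class TestOscillatoryTrain:
    def test_zero_depth_is_homogeneous_poisson(self):
        tr = sim.gen_oscillatory_train(30, 5, 0.0, 100, seed=7)
        assert cv(tr.isi()) == pytest.approx(1.0, abs=0.07)

    def test_thinning_preserves_mean_rate(self):
        rates = [sim.gen_oscillatory_train(30, 5, 0.8, 60, seed=s).rate for s in range(10)]
        assert np.mean(rates) == pytest.approx(30, rel=0.05)

    def test_time_rescaling_yields_unit_exponential_isis(self):
        """Under the true intensity, rescaled spike times of the thinned
        process must be a unit-rate Poisson process (KS not rejecting)."""
        rate, f, d = 30.0, 5.0, 0.8
        n_reject = 0
        for seed in range(30):
            tr = sim.gen_oscillatory_train(rate, f, d, 60, seed=seed)
            lam = rate * tr.times + rate * d / (2 * np.pi * f) * (1 - np.cos(2 * np.pi * f * tr.times))
            u = np.diff(lam)
            p = stats.kstest(u, "expon").pvalue
            n_reject += p < 0.01
        assert n_reject <= 3  # ~1% nominal; allow Monte-Carlo slack


class TestInjectPauses:
    def test_zero_rate_is_identity(self):
        tr = sim.gen_gamma_renewal(20, 1, 20, seed=8)
        assert sim.inject_pauses(tr, 0, 0.5, seed=1) is tr

    def test_duration_unchanged_and_windows_recorded(self):
        tr = sim.gen_gamma_renewal(20, 1, 20, seed=8)
        out = sim.inject_pauses(tr, 0.3, 1.0, seed=2)
        assert out.duration == tr.duration
        assert "pauses" in out.annotations
        for a, b in out.annotations["pauses"]:
            assert not np.any((out.times >= a) & (out.times < b))

    def test_planted_pauses_recovered_by_detector(self):
        from pallidyn.features import FeatureConfig, detect_pauses

        planted, detected = 0, 0
        for seed in range(50):
            tr = sim.gen_gamma_renewal(30, 1, 20, seed=100 + seed)
            out = sim.inject_pauses(tr, 0.2, 1.0, seed=seed)
            planted += sum(1 for a, b in out.annotations["pauses"] if b - a >= 0.25)
            detected += len(detect_pauses(out, FeatureConfig()).pauses)
        assert detected == pytest.approx(planted, rel=0.20)


class TestCohort:
    def test_n_per_gene_honored_and_deterministic(self, profiles):
        c1 = sim.gen_cohort(profiles, 5, 20.0, seed=3)
        c2 = sim.gen_cohort(profiles, 5, 20.0, seed=3)
        assert len(c1) == 45
        assert all(np.array_equal(a.times, b.times) for a, b in zip(c1, c2))

    def test_firing_rate_calibrated_to_profile(self, profiles):
        trains = [t for t in sim.gen_cohort(profiles, 200, 20.0, seed=1) if t.gene == "AOPEP"]
        mean_rate = np.mean([t.rate for t in trains])
        se2 = 2 * profiles["AOPEP"].sd("firing_rate") / np.sqrt(200)
        assert abs(mean_rate - profiles["AOPEP"].mean("firing_rate")) < se2


class TestSyntheticClinical:
    def test_scores_clipped_and_reproducible(self):
        df = sim.gen_synthetic_clinical(20, group_effect=30, seed=5)
        assert df["bfmdrs_fu1"].between(0, 128).all()
        assert df.equals(sim.gen_synthetic_clinical(20, group_effect=30, seed=5))

    def test_planted_effect_detected_by_mannwhitney(self):
        hits = 0
        for seed in range(100):
            df = sim.gen_synthetic_clinical(24, group_effect=35, seed=seed)
            pct = 100 * (df["bfmdrs_fu1"] - df["bfmdrs_pre"]) / df["bfmdrs_pre"]
            a, b = pct[df["group"] == "A"], pct[df["group"] == "B"]
            hits += stats.mannwhitneyu(a, b, alternative="greater").pvalue < 0.05
        assert hits >= 90

    def test_null_effect_is_symmetric(self):
        ps = []
        for seed in range(50):
            df = sim.gen_synthetic_clinical(30, group_effect=0, seed=seed)
            pct = 100 * (df["bfmdrs_fu1"] - df["bfmdrs_pre"]) / df["bfmdrs_pre"]
            a, b = pct[df["group"] == "A"], pct[df["group"] == "B"]
            ps.append(stats.mannwhitneyu(a, b, alternative="greater").pvalue)
        assert 0.3 < np.median(ps) < 0.7
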