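import math

import numpy as np
import pytest
from scipy.stats import norm

from invivosyn import (
    BootstrapConfig,
    GrowthCurve,
    StudyDataset,
    bca_interval,
    bootstrap_pvalue,
    bootstrap_synergy,
    estimate_synergy,
    group_egr,
    make_scenario,
    simulate_study,
    stratified_resample,
)
from invivosyn.bootstrap import RESAMPLE_ORDER, _boot_group_means


def bca_oracle(boot, observed, jack, level=0.95):
    """Straight transcription of Efron's BCa formulas."""
    boot = np.asarray(boot, float)
    jack = np.asarray(jack, float)
    prop = (np.sum(boot < observed) + 0.5 * np.sum(boot == observed)) / boot.size
    z0 = norm.ppf(prop)
    d = jack.mean() - jack
    a = np.sum(d**3) / (6.0 * np.sum(d**2) ** 1.5)
    z_alpha = norm.ppf((1 - level) / 2)
    a1 = norm.cdf(z0 + (z0 + z_alpha) / (1 - a * (z0 + z_alpha)))
    a2 = norm.cdf(z0 + (z0 - z_alpha) / (1 - a * (z0 - z_alpha)))
    return np.quantile(boot, a1), np.quantile(boot, a2)


class TestStratifiedResample:
    def _study(self, sizes=(3, 3, 3, 3)):
        curves = []
        for g, n in zip(RESAMPLE_ORDER, sizes):
            for i in range(n):
                days = np.array([0.0, 7.0, 14.0])
                curves.append(GrowthCurve(f"{g}{i}", g, days,
                                          100 * np.exp(0.05 * (i + 1) * days)))
        return StudyDataset(curves=curves)

    @pytest.mark.parametrize("sizes", [(3, 3, 3, 3), (10, 8, 9, 10)])
    def test_group_sizes_preserved(self, sizes):
        ds = self._study(sizes)
        rs = stratified_resample(ds, np.random.default_rng(0))
        assert tuple(rs.group_sizes[g] for g in RESAMPLE_ORDER) == sizes

    def test_deterministic_given_rng_state(self):
        ds = self._study()
        a = stratified_resample(ds, np.random.default_rng(42))
        b = stratified_resample(ds, np.random.default_rng(42))
        for ca, cb in zip(a.curves, b.curves):
            assert ca.mouse_id == cb.mouse_id
            np.testing.assert_array_equal(ca.volumes, cb.volumes)

    def test_resampled_mice_get_unique_ids(self):
        ds = self._study((2, 2, 2, 2))
        rs = stratified_resample(ds, np.random.default_rng(1))
        ids = [c.mouse_id for c in rs.curves]
        assert len(set(ids)) == len(ids)


class TestBcaInterval:
    def test_matches_independent_efron_oracle_on_random_sets(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = int(rng.integers(20, 40))
            # skewed bootstrap distribution
            boot = rng.gamma(shape=rng.uniform(0.5, 5), scale=1.0,
                             size=int(rng.integers(200, 800)))
            observed = float(np.median(boot) * rng.uniform(0.8, 1.2))
            jack = rng.gamma(shape=2.0, scale=1.0, size=n)
            level = float(rng.uniform(0.8, 0.99))
            got = bca_interval(boot, observed, jack, level)
            lo, hi = bca_oracle(boot, observed, jack, level)
            assert got.lower == pytest.approx(lo, rel=1e-10, abs=1e-12)
            assert got.upper == pytest.approx(hi, rel=1e-10, abs=1e-12)

    def test_symmetric_no_correction_equals_percentile(self):
        half = np.linspace(0.1, 3.0, 500)
        boot = np.concatenate([5.0 - half, 5.0 + half])  # symmetric, obs at median
        jack = np.array([4.0, 5.0, 6.0, 4.5, 5.5])  # zero skew -> a = 0
        got = bca_interval(boot, 5.0, jack, 0.95)
        assert got.z0 == pytest.approx(0.0, abs=1e-12)
        assert got.accel == pytest.approx(0.0, abs=1e-12)
        assert got.lower == pytest.approx(np.quantile(boot, 0.025), rel=1e-12)
        assert got.upper == pytest.approx(np.quantile(boot, 0.975), rel=1e-12)

    def test_degenerate_distribution(self):
        got = bca_interval(np.full(100, 3.7), 3.7, np.full(5, 3.7), 0.95)
        assert (got.lower, got.upper) == (3.7, 3.7)
        assert got.degenerate

    def test_complete_separation_clamps_with_flag(self):
        boot = np.linspace(1.0, 2.0, 200)
        got = bca_interval(boot, 5.0, np.array([1.0, 1.5, 2.0]), 0.95)
        assert got.clamped
        assert got.lower <= got.upper


class TestBootstrapPvalue:
    def test_null_beyond_all_boot_values_hits_floor(self):
        rng = np.random.default_rng(0)
        boot = rng.normal(5.0, 1.0, size=400)
        p = bootstrap_pvalue(boot, -100.0, (0.0, 0.0))
        assert p == pytest.approx(1.0 / 400)

    def test_central_null_has_p_near_one(self):
        rng = np.random.default_rng(1)
        boot = rng.normal(0.0, 1.0, size=1000)
        p = bootstrap_pvalue(boot, float(np.median(boot)), (0.0, 0.0))
        assert p > 0.9

    @pytest.mark.parametrize("seed", range(10))
    def test_consistency_with_interval_at_any_level(self, seed):
        rng = np.random.default_rng(seed)
        boot = rng.gamma(2.0, 1.0, size=500) - rng.uniform(0, 3)
        jack = rng.gamma(2.0, 0.3, size=12)
        observed = float(np.mean(boot))
        interval = bca_interval(boot, observed, jack, 0.95)
        p = bootstrap_pvalue(boot, 0.0, (interval.z0, interval.accel))
        outside = 0.0 < interval.lower or 0.0 > interval.upper
        if abs(p - 0.05) > 1e-4:  # away from the razor edge
            assert (p < 0.05) == outside

    def test_degenerate_distribution_gives_nan(self):
        assert np.isnan(bootstrap_pvalue(np.full(50, 2.0), 0.0, (0.0, 0.0)))


class TestBootstrapSynergy:
    def test_reproducible_with_seed(self, exp_study):
        ds = exp_study(n=4, jitter=0.1, seed=5)
        cfg = BootstrapConfig(n_boot=200, seed=77)
        a = bootstrap_synergy(ds, cfg)
        b = bootstrap_synergy(ds, cfg)
        assert a.ci.p_value == b.ci.p_value
        assert (a.ci.lower, a.ci.upper) == (b.ci.lower, b.ci.upper)
        np.testing.assert_array_equal(a.ss.boot, b.ss.boot)

    def test_cached_egr_path_equals_full_pipeline_resampling(self, exp_study):
        """Resampling per-mouse eGRs must equal re-running eGR -> CI on each
        resampled dataset, replicate for replicate."""
        ds = exp_study(n=3, jitter=0.15, seed=9)
        egrs = group_egr(ds)
        values = egrs.values_by_group()
        n_boot, seed = 10, 123
        means = _boot_group_means(values, n_boot, np.random.default_rng(seed))

        idx = {}
        rng = np.random.default_rng(seed)
        for g in RESAMPLE_ORDER:
            idx[g] = rng.integers(0, values[g].size, size=(n_boot, values[g].size))
        for b in range(n_boot):
            curves = []
            for g in RESAMPLE_ORDER:
                pool = ds.curves_by_group(g)
                for j, i in enumerate(idx[g][b]):
                    src = pool[i]
                    curves.append(GrowthCurve(f"{g}-{j}", g, src.days, src.volumes))
            naive = estimate_synergy(group_egr(StudyDataset(curves=curves)),
                                     "bliss", 21.0)
            fast = math.exp(
                21.0 * (means["C"][b] + means["AB"][b]
                        - means["A"][b] - means["B"][b])
            )
            assert naive.ci == pytest.approx(fast, rel=1e-12)

    def test_zero_variance_study_is_degenerate_additive(self):
        days = np.array([0.0, 7.0, 14.0, 21.0])
        rates = {"C": 0.10, "A": 0.07, "B": 0.06, "AB": 0.03}  # AB additive
        curves = [
            GrowthCurve(f"{g}{i}", g, days, 200 * np.exp(k * days))
            for g, k in rates.items() for i in range(3)
        ]
        inf = bootstrap_synergy(StudyDataset(curves=curves),
                                BootstrapConfig(n_boot=100, seed=0))
        assert inf.estimate.ci == pytest.approx(1.0, rel=1e-12)
        assert inf.estimate.ss == pytest.approx(0.0, abs=1e-10)
        assert inf.ci.degenerate and inf.ss.degenerate
        assert np.isnan(inf.ci.p_value) and np.isnan(inf.ss.p_value)

    def test_ci_ss_verdicts_agree_in_every_replicate(self, exp_study):
        ds = exp_study(n=3, jitter=0.2, seed=2)
        inf = bootstrap_synergy(ds, BootstrapConfig(n_boot=300, seed=4))
        np.testing.assert_array_equal(np.sign(np.log(inf.ci.boot)),
                                      -np.sign(inf.ss.boot))

    def test_p_value_invariant_to_evaluation_time(self):
        sc = make_scenario(tgi=(0.5, 0.4, 0.75), n_per_group=5)
        ds = simulate_study(sc, seed=11)
        ps, cis = [], []
        for t in (7.0, 14.0, 21.0, 42.0):
            inf = bootstrap_synergy(ds, BootstrapConfig(n_boot=300, seed=9,
                                                        t_eval=t))
            ps.append(inf.ci.p_value)
            cis.append(inf.ci.observed)
        assert len(set(ps)) == 1  # bitwise identical
        assert len(set(np.round(cis, 6))) == 4

    def test_unbalanced_strata_supported(self):
        rng = np.random.default_rng(3)
        curves = []
        days = np.array([0.0, 7.0, 14.0, 21.0])
        for g, n, k in zip(RESAMPLE_ORDER, (10, 8, 9, 10),
                           (0.10, 0.07, 0.08, 0.03)):
            for i in range(n):
                v = 200 * np.exp((k + rng.normal(0, 0.01)) * days)
                curves.append(GrowthCurve(f"{g}{i}", g, days, v))
        inf = bootstrap_synergy(StudyDataset(curves=curves),
                                BootstrapConfig(n_boot=300, seed=1))
        assert inf.group_sizes == {"C": 10, "A": 8, "B": 9, "AB": 10}
        assert 0.0 < inf.ci.p_value <= 1.0
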