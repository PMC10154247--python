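"""Growth-rate, exchange-rate and carbon-partition estimation."""

import numpy as np
import pytest

from comamflux.physiology import (
    GrowthSeries,
    PhysiologyError,
    carbon_partition,
    classify_secretion,
    exchange_rate,
    growth_rate,
)
from comamflux.synth import generate_growth_series


def exact_series(mu=0.25, od0=0.1, hours=3.0, n=7, conversion=0.26, q=None,
                 c0=10.0):
    t = np.linspace(0, hours, n)
    od = od0 * np.exp(mu * t)
    conc = {}
    if q is not None:
        X = od * conversion
        conc["S"] = c0 + (q / mu) * (X - X[0])
    return GrowthSeries(t, od, conc, conversion)


class TestGrowthRate:
    def test_exact_exponential_closed_form(self):
        # OD 0.1 -> 0.8 over 3 h: mu = ln(8)/3
        s = exact_series(mu=np.log(8) / 3, od0=0.1, hours=3.0)
        mu, sd = growth_rate(s)
        assert mu == pytest.approx(np.log(8) / 3, abs=1e-12)
        assert sd == pytest.approx(0.0, abs=1e-10)

    def test_constant_od_gives_zero(self):
        s = GrowthSeries([0, 1, 2, 3], [0.4] * 4, {}, 0.26)
        mu, _ = growth_rate(s)
        assert mu == pytest.approx(0.0, abs=1e-14)

    def test_noisy_exponential_recovery(self):
        s = generate_growth_series(mu=0.25, q_map={}, noise=0.02,
                                   n_points=8, t_end_h=6.0, seed=3)
        mu, _ = growth_rate(s)
        assert mu == pytest.approx(0.25, abs=0.02)

    def test_too_few_points_rejected(self):
        s = GrowthSeries([0, 1], [0.1, 0.2], {}, 0.26)
        with pytest.raises(PhysiologyError):
            growth_rate(s)


class TestExchangeRate:
    def test_uptake_from_constructed_slope(self):
        # dC/dX = -46 at mu = 0.26 -> q = -11.96 (consumption)
        mu = 0.26
        s = exact_series(mu=mu, q=-11.96, c0=20.0)
        q, _ = exchange_rate(s, "S", mu)
        assert q == pytest.approx(-11.96, rel=1e-9)

    def test_constant_concentration_gives_zero(self):
        s = exact_series(q=0.0)
        q, _ = exchange_rate(s, "S", 0.25)
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_secretion_recovery_at_noise(self):
        # PCA-scale secretion rate recovered within 5% at 2% noise
        s = generate_growth_series(mu=0.26, q_map={"PCA": 0.49},
                                   noise=0.02, t_end_h=8.0, n_points=12,
                                   seed=11)
        mu, _ = growth_rate(s)
        q, _ = exchange_rate(s, "PCA", mu)
        assert q == pytest.approx(0.49, rel=0.05)

    def test_missing_conversion_factor_raises(self):
        s = GrowthSeries([0, 1, 2], [0.1, 0.2, 0.4], {"S": [1, 2, 3]}, None)
        with pytest.raises(PhysiologyError, match="conversion"):
            exchange_rate(s, "S", 0.3)

    def test_generator_round_trip_zero_noise(self):
        for q in (-11.9, 0.49, 0.0):
            s = generate_growth_series(mu=0.26, q_map={"C": q}, noise=0.0,
                                       seed=0)
            got, _ = exchange_rate(s, "C", 0.26)
            assert got == pytest.approx(q, abs=1e-10)

    def test_rate_invariant_to_time_rescaling(self):
        s = exact_series(mu=0.25, q=-5.0)
        q_h, _ = exchange_rate(s, "S", 0.25)
        s_min = GrowthSeries(s.time_h * 60.0, s.od600, s.concentrations, 0.26)
        q_min, _ = exchange_rate(s_min, "S", 0.25 / 60.0)
        assert q_min * 60.0 == pytest.approx(q_h, rel=1e-9)


class TestCarbonPartition:
    def test_complement(self):
        # biomass fraction engineered to 0.55, no secretions -> other = 0.45
        uptake = {"4HB": 10.0}
        mu = 0.3
        bc = 0.55 * 10.0 * 7 / mu
        p = carbon_partition(mu, uptake, {}, {"4HB": 7}, bc)
        assert p["biomass"] == pytest.approx(0.55)
        assert p["other"] == pytest.approx(0.45)

    def test_secretion_fraction_from_printed_scale_rates(self):
        # PCA 0.49 + PDC 0.46 (7 carbons each) against uptake 11.9 x 7 C
        p = carbon_partition(0.26, {"4HB": 11.9},
                             {"PCA": 0.49, "PDC": 0.46},
                             {"4HB": 7, "PCA": 7, "PDC": 7},
                             biomass_c_content=40.0)
        assert p["secretion"] == pytest.approx((0.49 + 0.46) * 7 / 83.3,
                                               rel=1e-3)

    def test_scale_invariance(self):
        a = carbon_partition(0.3, {"S": 5.0}, {"P": 1.0},
                             {"S": 4, "P": 3}, 30.0)
        b = carbon_partition(0.6, {"S": 10.0}, {"P": 2.0},
                             {"S": 4, "P": 3}, 30.0)
        for k in a:
            assert a[k] == pytest.approx(b[k])

    def test_fractions_sum_to_one_after_clipping(self):
        with pytest.warns(UserWarning, match="carbon balance"):
            p = carbon_partition(1.0, {"S": 1.0}, {}, {"S": 1},
                                 biomass_c_content=2.0)
        assert sum(p.values()) == pytest.approx(1.0)


class TestClassifySecretion:
    def test_increasing_series_flagged(self):
        s = exact_series(q=0.5)
        assert classify_secretion(s, "S")

    def test_decreasing_series_not_flagged(self):
        s = exact_series(q=-0.5)
        assert not classify_secretion(s, "S")

    def test_flat_noisy_series_not_flagged(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 6, 10)
        s = GrowthSeries(t, 0.1 * np.exp(0.2 * t),
                         {"S": 5.0 + rng.normal(0, 0.05, size=t.shape)}, 0.26)
        assert not classify_secretion(s, "S")


class TestRecoveryCalibration:
    def test_exchange_rate_within_three_sd(self):
        # generator -> estimator round trip: q inside +-3 regression sds in
        # >= 95% of seeded trials
        hits = 0
        n = 60
        for seed in range(n):
            s = generate_growth_series(mu=0.26, q_map={"C": -11.9},
                                       noise=0.02, n_points=10, seed=seed)
            mu, _ = growth_rate(s)
            q, sd = exchange_rate(s, "C", mu)
            if abs(q - (-11.9)) <= 3 * sd:
                hits += 1
        assert hits / n >= 0.95
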