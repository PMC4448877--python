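"""Exponential-decay survival model, BWE algebra, and risk rankings."""

import math

import numpy as np
import pandas as pd
import pytest

from ballastrisk.risk import (
    DecayParams,
    bwe_density,
    composite_lambda,
    default_lambda_grid,
    density_at,
    propagule_pressure,
    sensitivity_rank,
    top_routes,
)


class TestDensity:
    def test_initial_density(self):
        assert density_at(0.0) == pytest.approx(2113.489)

    def test_no_decay_constant(self):
        p = DecayParams(lam=0.0)
        assert density_at(100.0, p) == pytest.approx(p.d0)

    def test_ten_days_default_decay(self):
        # 2113.489 * exp(-1.61), evaluated independently
        assert density_at(10.0) == pytest.approx(2113.489 * math.exp(-1.61), rel=1e-12)
        assert density_at(10.0) == pytest.approx(422.46, abs=0.01)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            density_at(-0.1)

    def test_strictly_decreasing(self):
        t = np.linspace(0, 30, 100)
        d = density_at(t)
        assert (np.diff(d) < 0).all()


class TestCompositeLambda:
    def test_identical_rates(self):
        assert composite_lambda(0.161, 0.161, 0.3) == pytest.approx(0.161)

    def test_endpoints(self):
        assert composite_lambda(0.1, 0.3, 1.0) == pytest.approx(0.1)
        assert composite_lambda(0.1, 0.3, 0.0) == pytest.approx(0.3)

    def test_midpoint(self):
        assert composite_lambda(0.1, 0.3, 0.5) == pytest.approx(0.2)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            composite_lambda(0.1, 0.3, 1.5)


class TestBweDensity:
    def test_reduces_to_plain_decay(self):
        p = DecayParams(r=1.0)
        for T in (0.0, 3.5, 20.0):
            assert bwe_density(T, p) == pytest.approx(density_at(T, p), rel=1e-12)

    def test_total_removal(self):
        p = DecayParams(r=0.0)
        assert bwe_density(10.0, p) == 0.0

    def test_factorised_equals_composite_form(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            mu1, mu2 = rng.uniform(0, 1, 2)
            pe, r = rng.uniform(0, 1, 2)
            T = rng.uniform(0, 40)
            params = DecayParams(mu1=mu1, mu2=mu2, p_exchange=pe, r=r)
            lam = composite_lambda(mu1, mu2, pe)
            composite = params.d0 * r * math.exp(-lam * T)
            assert bwe_density(T, params) == pytest.approx(composite, rel=1e-12)


def _records(rows):
    return pd.DataFrame(
        rows,
        columns=["voyage_id", "source_port", "dest_port", "source_ecoregion",
                 "dest_ecoregion", "expected_discharge_m3", "predictive_variance_m6"],
    )


def _dist(pairs):
    return pd.DataFrame(
        [{"source_port": s, "dest_port": d, "distance_nm": nm} for (s, d), nm in pairs.items()]
    )


class TestPropagulePressure:
    def test_zero_duration_no_decay(self):
        rec = _records([("j1", "A", "Z", 1, 9, 1000.0, 0.0)])
        res = propagule_pressure(rec, _dist({("A", "Z"): 0.0}))
        assert res.route_risk["propagules"].iloc[0] == pytest.approx(1000.0 * 2113.489)

    def test_linearity_in_volume(self):
        rec = _records([("j1", "A", "Z", 1, 9, 1000.0, 0.0),
                        ("j2", "B", "Z", 2, 9, 500.0, 0.0)])
        dist = _dist({("A", "Z"): 720.0, ("B", "Z"): 3600.0})
        base = propagule_pressure(rec, dist)
        doubled_rec = rec.assign(expected_discharge_m3=2 * rec["expected_discharge_m3"])
        doubled = propagule_pressure(doubled_rec, dist)
        assert doubled.route_risk["propagules"].sum() == pytest.approx(
            2 * base.route_risk["propagules"].sum()
        )

    def test_share_of_nearer_source_hand_computed(self):
        # equal volumes at 5 and 15 days; share = e^-0.805/(e^-0.805 + e^-2.415)
        rec = _records([("j1", "A", "Z", 1, 9, 1000.0, 0.0),
                        ("j2", "B", "Z", 2, 9, 1000.0, 0.0)])
        dist = _dist({("A", "Z"): 5 * 360.0, ("B", "Z"): 15 * 360.0})
        res = propagule_pressure(rec, dist)
        by_src = res.source_ecoregions.set_index("source_ecoregion")["propagules"]
        share = by_src[1] / by_src.sum()
        expect = math.exp(-0.805) / (math.exp(-0.805) + math.exp(-2.415))
        assert share == pytest.approx(expect, rel=1e-12)
        assert share == pytest.approx(0.833, abs=5e-4)

    def test_missing_distance_excluded_and_counted(self):
        rec = _records([("j1", "A", "Z", 1, 9, 1000.0, 0.0),
                        ("j2", "B", "Z", 2, 9, 500.0, 0.0)])
        res = propagule_pressure(rec, _dist({("A", "Z"): 720.0}))
        assert res.n_missing_distance == 1
        assert len(res.route_risk) == 1

    def test_d0_and_r_are_pure_scale_factors(self):
        rec = _records([("j1", "A", "Z", 1, 9, 1000.0, 0.0),
                        ("j2", "B", "Y", 2, 8, 800.0, 0.0)])
        dist = _dist({("A", "Z"): 720.0, ("B", "Y"): 4000.0})
        a = propagule_pressure(rec, dist, DecayParams())
        b = propagule_pressure(rec, dist, DecayParams(d0=1.0, r=0.5))
        ratio = a.route_risk["propagules"] / b.route_risk["propagules"]
        assert np.allclose(ratio, ratio.iloc[0])


class TestSensitivity:
    def _two_source_records(self):
        # near source with moderate volume, far source with high volume
        return _records([("j1", "A", "Z", 1, 9, 800.0, 0.0),
                         ("j2", "B", "Z", 2, 9, 2000.0, 0.0)])

    def test_lambda_zero_matches_volume_ranking(self):
        rec = self._two_source_records()
        dist = _dist({("A", "Z"): 720.0, ("B", "Z"): 7200.0})
        sens = sensitivity_rank(rec, dist, [0.0])
        src = sens[(sens["role"] == "source")].set_index("ecoregion")
        # at lambda=0 the high-volume far source ranks first
        assert src.loc[2, "rank"] == 1
        assert src.loc[1, "rank"] == 2

    def test_near_source_rank_non_increasing_in_lambda(self):
        rec = self._two_source_records()
        dist = _dist({("A", "Z"): 720.0, ("B", "Z"): 7200.0})
        grid = default_lambda_grid(25)
        sens = sensitivity_rank(rec, dist, grid)
        near = sens[(sens["role"] == "source") & (sens["ecoregion"] == 1)]
        ranks = near.sort_values("lam")["rank"].to_numpy()
        assert (np.diff(ranks) <= 0).all()

    def test_single_source_always_rank_one(self):
        rec = _records([("j1", "A", "Z", 1, 9, 800.0, 0.0)])
        dist = _dist({("A", "Z"): 720.0})
        sens = sensitivity_rank(rec, dist, default_lambda_grid(10))
        assert (sens[sens["role"] == "source"]["rank"] == 1).all()

    def test_empty_grid_rejected(self):
        rec = _records([("j1", "A", "Z", 1, 9, 800.0, 0.0)])
        with pytest.raises(ValueError):
            sensitivity_rank(rec, _dist({("A", "Z"): 720.0}), [])

    def test_rankings_are_permutations(self):
        rec = self._two_source_records()
        dist = _dist({("A", "Z"): 720.0, ("B", "Z"): 7200.0})
        sens = sensitivity_rank(rec, dist, [0.01, 0.25, 0.5])
        for (_, role), grp in sens.groupby(["lam", "role"]):
            assert sorted(grp["rank"]) == list(range(1, len(grp) + 1))


class TestTopRoutes:
    def _routes(self):
        return pd.DataFrame(
            {
                "source_port": ["A", "B", "C"],
                "dest_port": ["Z", "Z", "Y"],
                "voyage_count": [5, 3, 2],
                "total_discharge_m3": [50.0, 30.0, 20.0],
                "propagules": [100.0, 90.0, 80.0],
            }
        )

    def test_share_with_n_exceeding_routes(self):
        _, share = top_routes(self._routes(), "volume", n=10)
        assert share == pytest.approx(1.0)

    def test_hand_computed_share(self):
        top, share = top_routes(self._routes(), "volume", n=2)
        assert share == pytest.approx(0.80)
        assert list(top["source_port"]) == ["A", "B"]

    def test_lambda_zero_propagule_order_equals_volume_order(self):
        rec = pd.DataFrame(
            {
                "voyage_id": ["j1", "j2", "j3"],
                "source_port": ["A", "B", "C"],
                "dest_port": ["Z", "Z", "Y"],
                "source_ecoregion": [1, 2, 3],
                "dest_ecoregion": [9, 9, 8],
                "expected_discharge_m3": [50.0, 100.0, 20.0],
                "predictive_variance_m6": [0.0, 0.0, 0.0],
            }
        )
        dist = _dist({("A", "Z"): 720.0, ("B", "Z"): 7000.0, ("C", "Y"): 300.0})
        res = propagule_pressure(rec, dist, DecayParams(lam=0.0))
        by_vol, _ = top_routes(res.route_risk, "volume", 3)
        by_prop, _ = top_routes(res.route_risk, "propagules", 3)
        assert list(by_vol["source_port"]) == list(by_prop["source_port"])

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError):
            top_routes(self._routes(), "tonnage", 2)
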