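"""Great-circle distances, distance correlations, permutation ANOVA and the
perturbation-robustness test."""

import math

import numpy as np
import pandas as pd
import pytest

from paleoxeno.geo import (
    EARTH_RADIUS_KM,
    GeoPoint,
    distance_correlation,
    great_circle_km,
    load_gateways,
    permutation_anova,
    perturbation_robustness,
    pipes_association,
    spearman_with_p,
)


def law_of_cosines_km(a, b):
    """Independent spherical-law-of-cosines distance."""
    p1, p2 = math.radians(a.lat), math.radians(b.lat)
    dl = math.radians(b.lon - a.lon)
    return EARTH_RADIUS_KM * math.acos(
        min(1.0, math.sin(p1) * math.sin(p2) + math.cos(p1) * math.cos(p2) * math.cos(dl))
    )


def make_sites(lats, lons):
    n = len(lats)
    return pd.DataFrame(
        {
            "sample_id": range(1, n + 1),
            "site_label": [f"s{i}" for i in range(n)],
            "lat_deg": lats,
            "lon_deg": lons,
            "region": ["North"] * n,
        }
    )


class TestGreatCircle:
    def test_zero_distance_to_self(self):
        p = GeoPoint("x", 62.0, 130.0)
        assert great_circle_km(p, p) == 0.0

    def test_antipodal_points(self):
        a = GeoPoint("a", 0.0, 0.0)
        b = GeoPoint("b", 0.0, 180.0)
        assert great_circle_km(a, b) == pytest.approx(math.pi * EARTH_RADIUS_KM, rel=1e-12)

    def test_matches_law_of_cosines_oracle(self):
        yakutsk = GeoPoint("Yakutsk", 62.03, 129.73)
        okhotsk = GeoPoint("Okhotsk", 59.36, 143.24)
        d = great_circle_km(yakutsk, okhotsk)
        assert d == pytest.approx(law_of_cosines_km(yakutsk, okhotsk), rel=1e-3)
        assert 700 < d < 900  # sanity: regional scale

    def test_coordinate_validation(self):
        with pytest.raises(ValueError):
            GeoPoint("bad", 91.0, 0.0)

    def test_builtin_gateways(self):
        gws = {g.label: g for g in load_gateways()}
        assert set(gws) == {"NE", "E", "SE", "W", "NW"}
        assert gws["NE"].lat == pytest.approx(66.45)
        assert gws["NE"].lon == pytest.approx(143.22)


class TestSpearmanWithP:
    def test_exact_small_n_agrees_with_enumeration_logic(self):
        # a perfect monotone relation at n=5: the exact two-sided p is
        # 2/5! * (#ties at the extreme) = 2/120
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 4.0, 6.0, 8.0, 10.0]
        rs, p = spearman_with_p(x, y)
        assert rs == pytest.approx(1.0)
        assert p == pytest.approx(2 / 120)

    def test_large_n_t_approximation_matches_scipy(self):
        from scipy import stats as sps

        rng = np.random.default_rng(5)
        x, y = rng.normal(size=(2, 40))
        rs, p = spearman_with_p(x, y)
        ref = sps.spearmanr(x, y)
        assert rs == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_with_p([1.0] * 10, list(range(10)))


class TestDistanceCorrelation:
    def test_perfect_negative_gradient(self):
        sites = make_sites(lats=[62, 63, 64, 65, 66, 67], lons=[130] * 6)
        ref = GeoPoint("N", 70.0, 130.0)
        # concentration rises with latitude, i.e. falls with distance
        values = pd.Series([10.0, 20, 30, 40, 50, 60], index=range(1, 7))
        res = distance_correlation(values, sites, ref)
        assert res.rs == pytest.approx(-1.0)

    def test_null_p_values_are_uniform(self):
        # independent values vs distances: KS test on 200 replicate p-values
        from scipy import stats as sps

        rng = np.random.default_rng(21)
        sites = make_sites(
            lats=rng.uniform(60, 68, size=30), lons=rng.uniform(120, 140, size=30)
        )
        ref = GeoPoint("NE", 66.45, 143.22)
        ps = []
        for _ in range(200):
            vals = pd.Series(rng.normal(size=30), index=range(1, 31))
            ps.append(distance_correlation(vals, sites, ref).p_value)
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_too_few_sites_rejected(self):
        sites = make_sites([62, 63, 64], [130, 131, 132])
        with pytest.raises(ValueError, match=">= 5"):
            distance_correlation(
                pd.Series([1.0, 2, 3], index=[1, 2, 3]), sites, GeoPoint("r", 60, 120)
            )


class TestPermutationAnova:
    def test_identical_groups_give_f_zero_p_one(self):
        groups = [[5.0, 5, 5], [5.0, 5, 5], [5.0, 5, 5]]
        f, p = permutation_anova(groups, n_perm=200, seed=1)
        assert f == 0.0
        assert p == 1.0

    def test_separated_groups_detected(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 20)
        b = rng.normal(5, 1, 20)
        f, p = permutation_anova([a, b], n_perm=2000, seed=3)
        assert p <= 0.001

    def test_f_statistic_matches_scipy(self):
        from scipy import stats as sps

        rng = np.random.default_rng(4)
        groups = [rng.normal(size=8), rng.normal(1, 1, size=10), rng.normal(size=9)]
        f, _ = permutation_anova(groups, n_perm=10, seed=0)
        assert f == pytest.approx(sps.f_oneway(*groups).statistic, rel=1e-10)

    def test_rank_only_invariance_under_monotone_transform(self):
        # permutation p depends on the permutation distribution of F, which
        # is not rank-invariant in general; but identical seeds and data
        # give identical results (determinism contract)
        groups = [[1.0, 2, 3], [4.0, 5, 6]]
        assert permutation_anova(groups, 500, seed=7) == permutation_anova(
            groups, 500, seed=7
        )

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            permutation_anova([[1.0, 2, 3]], 100, seed=1)


class TestPerturbationRobustness:
    def test_noop_when_selection_too_small(self):
        from scipy import stats as sps

        rng = np.random.default_rng(8)
        v = rng.normal(size=10)
        d = rng.normal(size=10)
        # fraction 0.05 of n=10 selects one value: permuting a singleton is
        # a no-op, so every replicate equals the observed statistic
        obs = abs(np.corrcoef(sps.rankdata(v), sps.rankdata(d))[0, 1])
        rob = perturbation_robustness(v, d, fraction=0.05, n_rep=50, seed=1)
        assert rob == (1.0 if obs > 0.5 else 0.0)

    def test_monotone_relation_survives(self):
        d = np.linspace(0, 100, 40)
        v = 100 - d
        rob = perturbation_robustness(v, d, fraction=0.1, n_rep=2000, seed=2)
        assert rob > 0.95

    def test_independent_data_fails(self):
        rng = np.random.default_rng(9)
        rob = perturbation_robustness(
            rng.normal(size=40), rng.normal(size=40), fraction=0.1, n_rep=2000, seed=3
        )
        assert rob < 0.05

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            perturbation_robustness([1.0, 2], [1.0, 2], fraction=0.0, n_rep=10)


class TestPipesAssociation:
    def test_pipes_at_nearest_sites_give_negative_rs(self):
        lats = list(np.linspace(62, 67, 12))
        sites = make_sites(lats, [130.0] * 12)
        ref = GeoPoint("S", 60.0, 130.0)
        # pipes only at the 4 southernmost (nearest) sites
        pipe = pd.Series([1.0] * 4 + [0.0] * 8, index=range(1, 13))
        res = pipes_association(pipe, sites, ref, n_rep=200, seed=4)
        assert res.rs < 0

    def test_constant_indicator_rejected(self):
        sites = make_sites(list(np.linspace(62, 64, 6)), [130.0] * 6)
        with pytest.raises(ValueError, match="constant"):
            pipes_association(
                pd.Series([1.0] * 6, index=range(1, 7)), sites, GeoPoint("r", 60, 120)
            )
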