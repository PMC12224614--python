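"""Spatial matching and association statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petscan import plastic_assoc as pa


def exact_mw_p(x, y):
    """Two-sided Mann-Whitney p by full permutation enumeration (no ties)."""
    pooled = list(x) + list(y)
    n1 = len(x)
    u_obs = sum(1 for a in x for b in y if a > b)
    us = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        us.append(sum(1 for a in xs for b in ys if a > b))
    us = np.array(us)
    mean = len(x) * len(y) / 2
    return np.mean(np.abs(us - mean) >= abs(u_obs - mean))


class TestMatching:
    def test_record_beyond_radius_discarded(self):
        plastic = pd.DataFrame(
            {"record_id": ["p1"], "latitude": [0.0], "longitude": [0.0],
             "concentration": [10.0]}
        )
        # ~600 km away at the equator (5.4 degrees of longitude)
        samples = pd.DataFrame(
            {"sample_id": ["s1"], "latitude": [0.0], "longitude": [5.4],
             "depth": [5.0], "normalized_abundance": [0.1]}
        )
        assert len(pa.match_records(plastic, samples)) == 0
        wide = pa.MatchConfig(radius_deg=6.0)
        assert len(pa.match_records(plastic, samples, wide)) == 1

    def test_deep_samples_excluded(self):
        plastic = pd.DataFrame(
            {"record_id": ["p1"], "latitude": [0.0], "longitude": [0.0],
             "concentration": [1.0]}
        )
        samples = pd.DataFrame(
            {"sample_id": ["deep", "shallow"], "latitude": [0.0, 0.0],
             "longitude": [0.1, 3.0], "depth": [200.0, 5.0],
             "normalized_abundance": [0.5, 0.2]}
        )
        out = pa.match_records(plastic, samples)
        assert list(out["sample_id"]) == ["shallow"]

    def test_all_samples_at_nearest_location_join(self):
        plastic = pd.DataFrame(
            {"record_id": ["p1"], "latitude": [10.0], "longitude": [10.0],
             "concentration": [3.0]}
        )
        samples = pd.DataFrame(
            {"sample_id": ["a", "b", "c"],
             "latitude": [10.5, 10.5, 12.0], "longitude": [10.0, 10.0, 10.0],
             "depth": [5.0, 8.0, 5.0], "normalized_abundance": [0.1, 0.2, 0.3]}
        )
        out = pa.match_records(plastic, samples)
        assert sorted(out["sample_id"]) == ["a", "b"]

    def test_matches_equal_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        plastic = pd.DataFrame(
            {"record_id": [f"p{i}" for i in range(20)],
             "latitude": rng.uniform(-40, 40, 20),
             "longitude": rng.uniform(-170, 170, 20),
             "concentration": rng.uniform(0, 100, 20)}
        )
        samples = pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(10)],
             "latitude": rng.uniform(-40, 40, 10),
             "longitude": rng.uniform(-170, 170, 10),
             "depth": rng.uniform(0, 20, 10),
             "normalized_abundance": rng.lognormal(-6, 1, 10)}
        )
        cfg = pa.MatchConfig()
        got = pa.match_records(plastic, samples, cfg)
        # oracle: all-pairs distances, nearest eligible sample within radius
        expected = []
        elig = samples[samples["depth"] <= cfg.max_sample_depth]
        for p in plastic.itertuples(index=False):
            dists = [
                (pa.haversine_km(p.latitude, p.longitude, s.latitude, s.longitude), s.sample_id)
                for s in elig.itertuples(index=False)
            ]
            d, sid = min(dists)
            if d <= cfg.radius_km:
                expected.append((p.record_id, sid))
        assert set(zip(got["record_id"], got["sample_id"])) == set(expected)

    def test_stable_under_row_permutation(self):
        rng = np.random.default_rng(3)
        plastic = pd.DataFrame(
            {"record_id": [f"p{i}" for i in range(15)],
             "latitude": rng.uniform(-30, 30, 15),
             "longitude": rng.uniform(-100, 100, 15),
             "concentration": rng.uniform(0, 10, 15)}
        )
        samples = pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(8)],
             "latitude": rng.uniform(-30, 30, 8),
             "longitude": rng.uniform(-100, 100, 8),
             "depth": np.full(8, 5.0),
             "normalized_abundance": rng.lognormal(-6, 1, 8)}
        )
        a = pa.match_records(plastic, samples)
        b = pa.match_records(
            plastic.sample(frac=1, random_state=1),
            samples.sample(frac=1, random_state=2),
        )
        pd.testing.assert_frame_equal(a, b)

    def test_outputs_respect_radius_and_depth_invariants(self):
        rng = np.random.default_rng(11)
        plastic = pd.DataFrame(
            {"record_id": [f"p{i}" for i in range(30)],
             "latitude": rng.uniform(-50, 50, 30),
             "longitude": rng.uniform(-170, 170, 30),
             "concentration": rng.uniform(0, 50, 30)}
        )
        samples = pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(25)],
             "latitude": rng.uniform(-50, 50, 25),
             "longitude": rng.uniform(-170, 170, 25),
             "depth": rng.uniform(0, 30, 25),
             "normalized_abundance": rng.lognormal(-6, 1, 25)}
        )
        cfg = pa.MatchConfig()
        out = pa.match_records(plastic, samples, cfg)
        assert (out["distance_km"] <= cfg.radius_km).all()
        assert (out["depth"] <= cfg.max_sample_depth).all()

    def test_coordinates_out_of_range_rejected(self):
        plastic = pd.DataFrame(
            {"record_id": ["p"], "latitude": [95.0], "longitude": [0.0],
             "concentration": [1.0]}
        )
        samples = pd.DataFrame(
            {"sample_id": ["s"], "latitude": [0.0], "longitude": [0.0],
             "depth": [1.0], "normalized_abundance": [0.1]}
        )
        with pytest.raises(pa.AssociationError):
            pa.match_records(plastic, samples)


class TestMannWhitney:
    def test_fully_separated_small_groups(self):
        res = pa.mann_whitney([1, 2, 3], [4, 5, 6])
        assert res["U1"] == 0.0
        assert res["method"] == "exact"
        assert res["p_two_sided"] == pytest.approx(exact_mw_p([1, 2, 3], [4, 5, 6]))

    def test_identical_groups_give_half_u(self):
        res = pa.mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert res["U1"] == pytest.approx(4 * 4 / 2)

    def test_agrees_with_enumeration_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(5):
            x = rng.normal(0, 1, size=5)
            y = rng.normal(0.8, 1, size=6)
            res = pa.mann_whitney(x, y)
            assert res["p_two_sided"] == pytest.approx(exact_mw_p(x, y))
            assert res["U1"] == sum(1 for a in x for b in y if a > b)

    @given(
        x=st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=25),
        y=st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=25),
    )
    @settings(deadline=None, max_examples=60)
    def test_u_identity(self, x, y):
        res = pa.mann_whitney(x, y)
        assert res["U1"] + res["U2"] == pytest.approx(len(x) * len(y))

    def test_empty_group_rejected(self):
        with pytest.raises(pa.AssociationError):
            pa.mann_whitney([], [1.0])


class TestLinearFit:
    def test_collinear_data_r2_one(self):
        x = np.arange(10.0)
        assert pa.linear_fit(x, 3 * x + 1)["r_squared"] == pytest.approx(1.0)

    def test_zero_variance_x_rejected(self):
        with pytest.raises(pa.AssociationError):
            pa.linear_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_points_rejected(self):
        with pytest.raises(pa.AssociationError):
            pa.linear_fit([1.0, 2.0], [1.0, 2.0])

    def test_null_relation_rarely_significant(self):
        """Independent x,y: slope p uniform, so ~5% rejections at alpha=0.05."""
        rng = np.random.default_rng(19)
        rejections = 0
        n_seeds = 100
        for _ in range(n_seeds):
            x = rng.lognormal(0, 1, size=500)
            y = rng.lognormal(0, 1, size=500)
            if pa.linear_fit(x, y)["p_value"] < 0.05:
                rejections += 1
        assert rejections / n_seeds <= 0.10
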