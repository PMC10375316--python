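import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from steroidscreen.normalize import Endpoint
from steroidscreen.npstats import (Direction, StatsConfig, compute_stat_calls,
                                   kruskal_wallis, mann_whitney,
                                   normality_screen, pool_replicates, star_bin)


def brute_force_mw_p(x, y):
    """Independent oracle: enumerate every rank arrangement (no ties)."""
    pooled = list(x) + list(y)
    n1 = len(x)
    ranks = sps.rankdata(pooled)
    u_from = lambda idx: sum(ranks[i] for i in idx) - n1 * (n1 + 1) / 2
    n2 = len(y)
    observed = min(u_from(range(n1)), n1 * n2 - u_from(range(n1)))
    count = total = 0
    for idx in combinations(range(n1 + n2), n1):
        u = u_from(idx)
        if min(u, n1 * n2 - u) <= observed + 1e-9:
            count += 1
        total += 1
    return count / total


class TestPoolReplicates:
    def _df(self, drop_bio=None):
        rows = []
        for bio in (1, 2, 3):
            if bio == drop_bio:
                continue
            for tech in (1, 2, 3):
                rows.append({"chemical_id": "x", "endpoint": "estrogen_activity",
                             "conc_h295r": 1e-6, "plate_id": f"p{bio}",
                             "bio_rep": bio, "tech_rep": tech, "v": 1.0})
        return pd.DataFrame(rows)

    def test_nominal_nine(self):
        groups = pool_replicates(self._df(), "v")
        assert len(groups[("x", "estrogen_activity", 1e-6)]) == 9

    def test_missing_bio_rep_gives_six(self):
        groups = pool_replicates(self._df(drop_bio=2), "v")
        assert len(groups[("x", "estrogen_activity", 1e-6)]) == 6

    def test_duplicate_record_error(self):
        df = self._df()
        with pytest.raises(ValueError, match="duplicate"):
            pool_replicates(pd.concat([df, df.iloc[[0]]]), "v")


class TestKruskalWallis:
    def test_identical_groups(self):
        h, p = kruskal_wallis([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]])
        assert h == 0.0 and p == 1.0

    def test_separated_groups(self):
        groups = [[1, 2, 3], [10, 11, 12], [20, 21, 22]]
        h, p = kruskal_wallis(groups)
        # oracle: rank-formula hand computation, no ties
        # H = 12/(N(N+1)) * sum(R_i^2/n_i) - 3(N+1), N=9
        r = [6.0, 15.0, 24.0]
        h_hand = 12 / (9 * 10) * sum(ri ** 2 / 3 for ri in r) - 3 * 10
        assert h == pytest.approx(h_hand)
        assert p < 0.05

    def test_single_group(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 2.0]])

    def test_small_group(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], [2.0, 3.0]])


class TestMannWhitney:
    def test_complete_separation(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(2 / 20)  # enumeration over C(6,3) arrangements

    def test_identical_samples(self):
        _, p = mann_whitney([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        assert p == 1.0

    def test_ties_with_no_shift(self):
        _, p = mann_whitney([1, 2, 2, 3], [1, 2, 2, 3])
        assert p == 1.0

    def test_empty_side(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    @settings(max_examples=150, deadline=None)
    @given(st.integers(1, 5), st.integers(1, 5), st.randoms(use_true_random=False))
    def test_exact_matches_brute_force(self, n1, n2, rnd):
        if n1 + n2 > 10:
            return
        values = rnd.sample(range(1000), n1 + n2)
        x, y = [float(v) for v in values[:n1]], [float(v) for v in values[n1:]]
        _, p = mann_whitney(x, y)
        assert p == pytest.approx(brute_force_mw_p(x, y), abs=1e-9)

    @settings(max_examples=60, deadline=None)
    @given(st.randoms(use_true_random=False))
    def test_monotone_transform_invariance(self, rnd):
        values = rnd.sample(range(1000), 10)
        x, y = [float(v) for v in values[:5]], [float(v) for v in values[5:]]
        _, p1 = mann_whitney(x, y)
        f = lambda v: math.exp(v / 200.0)
        _, p2 = mann_whitney([f(v) for v in x], [f(v) for v in y])
        assert p1 == pytest.approx(p2)

    @settings(max_examples=60, deadline=None)
    @given(st.randoms(use_true_random=False))
    def test_swap_reflects_u(self, rnd):
        values = rnd.sample(range(1000), 9)
        x, y = [float(v) for v in values[:4]], [float(v) for v in values[4:]]
        u_xy, p_xy = mann_whitney(x, y)
        u_yx, p_yx = mann_whitney(y, x)
        assert u_yx == pytest.approx(len(x) * len(y) - u_xy)
        assert p_xy == pytest.approx(p_yx)


class TestStarBin:
    @pytest.mark.parametrize("p,expected", [
        (0.5, "ns"), (0.05, "*"), (0.03, "*"), (0.01, "**"), (0.005, "**"),
        (0.001, "***"), (0.0005, "***"), (0.0001, "****"), (5e-5, "****"),
    ])
    def test_bins(self, p, expected):
        assert star_bin(p) == expected

    def test_hash_family(self):
        assert star_bin(0.03, "direct") == "#"
        assert star_bin(5e-5, "direct") == "####"

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            star_bin(1.5)


class TestNormalityScreen:
    def test_normal_sample_usually_passes(self):
        rng = np.random.default_rng(0)
        ok = 0
        for _ in range(100):
            df = normality_screen({"g": rng.normal(size=9)})
            ok += df["shapiro_p"].iloc[0] > 0.05
        assert ok >= 90

    def test_skewed_sample_often_fails(self):
        rng = np.random.default_rng(0)
        low = 0
        for _ in range(100):
            df = normality_screen({"g": rng.exponential(size=9) ** 3})
            low += df["shapiro_p"].iloc[0] < 0.05
        assert low > 50

    def test_constant_flagged(self):
        df = normality_screen({"g": [1.0, 1.0, 1.0]})
        assert df["flag"].iloc[0] == "constant"
        assert df["shapiro_p"].iloc[0] is None


class TestComputeStatCalls:
    def _df(self, shift_by_conc):
        rng = np.random.default_rng(1)
        rows = []
        for bio in (1, 2, 3):
            for tech in (1, 2, 3):
                rows.append({"chemical_id": None, "endpoint": "estrogen_activity",
                             "conc_h295r": math.nan, "plate_id": f"p{bio}",
                             "bio_rep": bio, "tech_rep": tech,
                             "role": "vehicle_control",
                             "pct_of_basal": 100 + rng.normal(0, 3),
                             "pct_ri": 50.0})
        for conc, shift in shift_by_conc.items():
            for bio in (1, 2, 3):
                for tech in (1, 2, 3):
                    rows.append({"chemical_id": "x", "endpoint": "estrogen_activity",
                                 "conc_h295r": conc, "plate_id": f"p{bio}",
                                 "bio_rep": bio, "tech_rep": tech,
                                 "role": "h295r_treated",
                                 "pct_of_basal": 100 + shift + rng.normal(0, 3),
                                 "pct_ri": 50.0})
        return pd.DataFrame(rows)

    def test_obvious_decrease(self):
        calls = compute_stat_calls(self._df({1e-6: -50.0}),
                                   Endpoint.ESTROGEN_ACTIVITY)
        (call,) = calls
        assert call.significant
        assert call.direction is Direction.DOWN
        assert call.star_bin != "ns"
        assert call.n_treated == 9 and call.n_control == 9

    def test_null_not_significant(self):
        calls = compute_stat_calls(self._df({1e-6: 0.0}),
                                   Endpoint.ESTROGEN_ACTIVITY)
        assert not calls[0].significant
        assert calls[0].star_bin == "ns"

    def test_gate_suppresses_isolated_noise(self):
        # with the omnibus gate off, the pairwise p decides alone
        df = self._df({1e-6: -50.0})
        gated = compute_stat_calls(df, Endpoint.ESTROGEN_ACTIVITY,
                                   StatsConfig(omnibus_gate=True))
        ungated = compute_stat_calls(df, Endpoint.ESTROGEN_ACTIVITY,
                                     StatsConfig(omnibus_gate=False))
        assert gated[0].significant and ungated[0].significant

    def test_significant_iff_starred(self):
        for shift in (-50.0, -5.0, 0.0, 40.0):
            calls = compute_stat_calls(self._df({1e-6: shift, 3e-6: shift}),
                                       Endpoint.ESTROGEN_ACTIVITY)
            for c in calls:
                assert c.significant == (c.star_bin != "ns")
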