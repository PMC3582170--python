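"""Descriptive statistics, Duncan's multiple range test, Pearson matrix."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cordstereo.fixtures import round_half_up
from cordstereo.stats import (
    GroupSample,
    duncan_critical_range,
    duncan_mrt,
    mean_se,
    pearson_matrix,
    ratio_percent,
    relative_weight,
)


# ---------------------------------------------------------------- oracle
def duncan_oracle(groups: dict, alpha=0.05):
    """Independent enumeration of the protected range procedure.

    Every window of consecutive ordered means is tested against its own
    critical range; a window passes when its range does not exceed R_p.
    Two groups are non-significant iff some passing window contains both;
    letters are assembled from the maximal passing windows (plus singleton
    letters for uncovered groups) in descending-mean order.
    """
    labels = sorted(groups, key=lambda g: -np.mean(groups[g]))
    m = [float(np.mean(groups[g])) for g in labels]
    k = len(labels)
    n = len(next(iter(groups.values())))
    df = k * (n - 1)
    mse = np.mean([np.var(groups[g], ddof=1) for g in labels])
    passing = []
    for u in range(k):
        for v in range(u + 1, k):
            R = duncan_critical_range(v - u + 1, df, alpha, mse, n)
            if m[u] - m[v] <= R + 1e-12:
                passing.append((u, v))
    maximal = [
        w
        for w in passing
        if not any(o != w and o[0] <= w[0] and w[1] <= o[1] for o in passing)
    ]
    covered = {i for u, v in maximal for i in range(u, v + 1)}
    intervals = sorted(maximal + [(i, i) for i in range(k) if i not in covered])
    letters = {g: "" for g in labels}
    for idx, (u, v) in enumerate(intervals):
        for i in range(u, v + 1):
            letters[labels[i]] += "abcdefghijklmnopqrstuvwxyz"[idx]
    sig = {}
    for i, j in itertools.combinations(range(k), 2):
        sig[(labels[i], labels[j])] = not any(
            u <= i and j <= v for u, v in passing
        )
    return letters, sig


class TestMeanSE:
    def test_published_length_row(self):
        m, se = mean_se([51.4, 56.1, 65.2, 66.0, 67.5])
        assert round_half_up(m, 1) == 61.2
        assert round_half_up(se, 1) == 3.2

    def test_published_body_weight_row(self):
        m, se = mean_se([230, 300, 480, 420, 450])
        assert m == 376
        assert round_half_up(se, 1) == 47.6

    def test_constant_sample(self):
        m, se = mean_se([3.0, 3.0, 3.0])
        assert se == 0.0

    def test_requires_two(self):
        with pytest.raises(ValueError):
            mean_se([1.0])


class TestDuncan:
    def test_two_groups_reduce_to_single_range(self):
        g = {"hi": (10.0, 11.0, 9.0, 10.5, 9.5), "lo": (1.0, 2.0, 0.0, 1.5, 0.5)}
        res = duncan_mrt(g)
        assert res.letters["hi"] == "a"
        assert res.letters["lo"] == "b"
        assert res.significant("hi", "lo")
        # shrink the separation below the critical range: one letter
        g2 = {"hi": (1.2, 1.1, 0.9, 1.0, 0.8), "lo": (1.0, 0.9, 1.1, 0.8, 1.2)}
        res2 = duncan_mrt(g2)
        assert res2.letters["hi"] == res2.letters["lo"] == "a"

    def test_identical_groups_share_a(self):
        g = {f"G{i}": (5.0, 6.0, 4.0, 5.5, 4.5) for i in range(5)}
        res = duncan_mrt(g)
        assert set(res.letters.values()) == {"a"}

    def test_fully_separated_groups_all_distinct(self, rng):
        g = {
            f"G{i}": tuple(rng.normal(20.0 * i, 1.0, 5)) for i in range(8)
        }
        res = duncan_mrt(g)
        assert sorted(res.letters.values()) == list("abcdefgh")
        oracle_letters, _ = duncan_oracle(g)
        assert res.letters == oracle_letters

    @pytest.mark.parametrize("spread", [0.5, 1.0, 2.0, 4.0])
    def test_matches_enumeration_oracle(self, spread, rng):
        """Random mixed-separation fixtures: letters and the full pairwise
        significance relation agree with the independent enumeration."""
        for rep in range(12):
            g = {
                f"G{i}": tuple(rng.normal(rng.uniform(0, spread), 1.0, 5))
                for i in range(8)
            }
            res = duncan_mrt(g)
            oracle_letters, oracle_sig = duncan_oracle(g)
            assert res.letters == oracle_letters
            for (a, b), s in oracle_sig.items():
                assert res.significant(a, b) == s

    def test_letter_display_reconstructs_significance(self, rng):
        """Sharing a letter is exactly pairwise non-significance."""
        g = {f"G{i}": tuple(rng.normal(i * 0.8, 1.0, 5)) for i in range(8)}
        res = duncan_mrt(g)
        for a, b in itertools.combinations(g, 2):
            share = bool(set(res.letters[a]) & set(res.letters[b]))
            assert share == (not res.significant(a, b))

    def test_unequal_n_rejected(self):
        with pytest.raises(ValueError):
            duncan_mrt({"a": (1.0, 2.0), "b": (1.0, 2.0, 3.0)})

    def test_null_error_rate_near_protected_level(self):
        """Under the global null with 8 groups the chance of any separation
        equals the protected level of the full-range test,
        1 - (1-alpha)^(k-1) ~ 0.30."""
        rng = np.random.default_rng(2024)
        k, n, sims = 8, 5, 400
        hits = 0
        for _ in range(sims):
            g = {f"G{i}": tuple(rng.normal(0.0, 1.0, n)) for i in range(k)}
            res = duncan_mrt(g)
            hits += len(set(res.letters.values())) > 1
        rate = hits / sims
        nominal = 1 - 0.95 ** (k - 1)
        assert abs(rate - nominal) < 0.10


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(6, dtype=float)
        tab = pd.DataFrame({"x": x, "y": 2 * x + 1})
        ct = pearson_matrix(tab)
        assert ct.r.loc["x", "y"] == pytest.approx(1.0)
        assert ct.stars.loc["x", "y"] == "***"

    def test_orthogonal_pair(self):
        tab = pd.DataFrame({"x": [-1.0, 0.0, 1.0], "y": [1.0, -2.0, 1.0]})
        ct = pearson_matrix(tab)
        assert ct.r.loc["x", "y"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_flagged(self):
        tab = pd.DataFrame({"x": [1.0, 1.0, 1.0, 1.0], "y": [1.0, 2.0, 3.0, 4.0]})
        ct = pearson_matrix(tab)
        assert np.isnan(ct.r.loc["x", "y"])
        assert ct.stars.loc["x", "y"] == ""

    def test_too_few_observations(self):
        tab = pd.DataFrame({"x": [1.0, 2.0], "y": [2.0, 1.0]})
        with pytest.raises(ValueError):
            pearson_matrix(tab)

    def test_correlated_normals_recover_rho(self, rng):
        rs = []
        for _ in range(30):
            z = rng.multivariate_normal([0, 0], [[1, 0.8], [0.8, 1]], size=40)
            ct = pearson_matrix(pd.DataFrame(z, columns=["a", "b"]))
            rs.append(ct.r.loc["a", "b"])
        assert np.mean(rs) == pytest.approx(0.8, abs=0.05)

    def test_star_levels_agree_with_permutation_oracle(self, rng):
        """Parametric two-sided p lands in the same star band as a
        permutation p on clear-signal and clear-null fixtures."""
        x = rng.normal(size=24)
        cases = {
            "***": 1.2 * x + rng.normal(scale=0.3, size=24),
            "": rng.normal(size=24),
        }
        for expected, y in cases.items():
            tab = pd.DataFrame({"x": x, "y": y})
            ct = pearson_matrix(tab)
            r_obs = abs(ct.r.loc["x", "y"])
            perm = sum(
                abs(sps.pearsonr(x, rng.permutation(y)).statistic) >= r_obs
                for _ in range(2000)
            ) / 2000
            param_stars = ct.stars.loc["x", "y"]
            perm_stars = (
                "***" if perm < 0.001 else "**" if perm < 0.01
                else "*" if perm < 0.05 else ""
            )
            assert param_stars == perm_stars == expected


class TestPooling:
    def test_both_modes(self):
        from cordstereo.stats import pool_for_correlation

        tab = pd.DataFrame(
            {
                "animal": ["A1", "A1", "A2", "A2"],
                "segment": ["C1", "C2", "C1", "C2"],
                "x": [1.0, 2.0, 3.0, 4.0],
            }
        )
        per_obs = pool_for_correlation(tab, "animal_segment")
        assert len(per_obs) == 4
        per_seg = pool_for_correlation(tab, "segment_mean")
        assert sorted(per_seg["x"]) == [2.0, 3.0]
        with pytest.raises(ValueError):
            pool_for_correlation(tab, "bogus")


class TestRatios:
    def test_relative_weight_published_pony(self):
        assert round_half_up(relative_weight(207.2, 230), 3) == 0.090

    def test_part_equals_whole(self):
        assert ratio_percent(7.7, 7.7) == pytest.approx(100.0)

    def test_published_weight_ratio_mean(self):
        csc = [87.8, 77.3, 130.8, 116.6, 123.4]
        sc = [207.2, 186.3, 305.9, 267.0, 281.6]
        ratios = [ratio_percent(c, s) for c, s in zip(csc, sc)]
        m, se = mean_se(ratios)
        assert round_half_up(m, 1) == 42.8
        assert round_half_up(se, 1) == 0.4

    def test_invalid_denominators(self):
        with pytest.raises(ValueError):
            ratio_percent(1.0, 0.0)
        with pytest.raises(ValueError):
            relative_weight(1.0, 0.0)
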