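"""Genus pooling, nested ANOVA, IndVal, BH adjustment, DWV delta-Ct."""

import itertools
import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import beeqmp as bq
from beeqmp.datamodel import CountMatrix, CtTable, SampleTable


def _m(rows, cols=None):
    arr = np.asarray(rows, dtype=float)
    cols = cols or [f"a{j}" for j in range(arr.shape[1])]
    return CountMatrix(
        pd.DataFrame(arr, index=[f"s{i}" for i in range(arr.shape[0])], columns=cols)
    )


class TestPoolByGenus:
    def test_two_asvs_sum(self):
        m = _m([[1, 2]], cols=["a0", "a1"])
        tax = bq.TaxonomyTable(pd.DataFrame({"genus": ["g", "g"]}, index=["a0", "a1"]))
        out = bq.pool_by_genus(m, tax)
        assert out.data.loc["s0", "g"] == 3.0

    def test_totals_preserved_and_ten_genera(self, profile, study, genus_abund):
        assert genus_abund.shape[1] == 10
        assert np.allclose(genus_abund.totals(), profile.totals(), atol=1e-9)

    def test_missing_genus_is_an_error(self, profile, study):
        tax = bq.TaxonomyTable(pd.DataFrame({"genus": ["g"]}, index=["ASV1"]))
        with pytest.raises(ValueError, match="without genus"):
            bq.pool_by_genus(profile, tax)


def _hive_design(values, conditions, locations):
    """One bee per hive, so hive means equal the given values."""
    rows, ys = [], {}
    for i, (v, c, l) in enumerate(zip(values, conditions, locations)):
        sid, hive = f"s{i}", f"h{i}"
        rows.append({"sample_id": sid, "hive_id": hive, "location": l,
                     "condition": c, "role": "bee"})
        ys[sid] = float(v)
    return pd.Series(ys), SampleTable(pd.DataFrame(rows).set_index("sample_id"))


class TestNestedAnova:
    def test_constant_response_gives_f0_p1(self):
        y, samples = _hive_design([5, 5, 5, 5, 5, 5],
                                  ["survived"] * 3 + ["failed"] * 3,
                                  ["x", "y", "x", "y", "x", "y"])
        res = bq.nested_anova(y, samples)
        assert res.table.loc["condition", "F"] == 0.0
        assert res.table.loc["condition", "p_value"] == 1.0

    def test_balanced_two_by_two_hand_partition(self):
        y, samples = _hive_design(
            [10, 10, 20, 20],
            ["failed", "failed", "survived", "survived"],
            ["x", "y", "x", "y"],
        )
        res = bq.nested_anova(y, samples)
        assert res.table.loc["condition", "SS"] == pytest.approx(100.0, abs=1e-9)
        assert res.table.loc["location", "SS"] == pytest.approx(0.0, abs=1e-9)

    def test_matches_statsmodels_on_balanced_design(self):
        rng = np.random.default_rng(0)
        conds = ["survived", "failed"] * 6
        locs = ["x"] * 6 + ["y"] * 6
        y, samples = _hive_design(rng.normal(size=12), conds, locs)
        res = bq.nested_anova(y, samples)

        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        df = pd.DataFrame({"y": y.to_numpy(),
                           "c": conds, "l": locs})
        fit = ols("y ~ C(c) + C(l) + C(c):C(l)", data=df).fit()
        ref = sm.stats.anova_lm(fit, typ=1)
        assert res.table.loc["condition", "SS"] == pytest.approx(
            ref.loc["C(c)", "sum_sq"], abs=1e-8
        )
        assert res.table.loc["condition:location", "p_value"] == pytest.approx(
            ref.loc["C(c):C(l)", "PR(>F)"], abs=1e-8
        )

    def test_aggregates_bees_to_hive_means(self):
        # duplicate bees per hive must not inflate the degrees of freedom
        rows, ys = [], {}
        vals = {"h0": 1.0, "h1": 2.0, "h2": 5.0, "h3": 6.0}
        hives = {"h0": ("failed", "x"), "h1": ("failed", "y"),
                 "h2": ("survived", "x"), "h3": ("survived", "y")}
        i = 0
        for h, (c, l) in hives.items():
            for b in range(3):
                sid = f"s{i}"; i += 1
                rows.append({"sample_id": sid, "hive_id": h, "location": l,
                             "condition": c, "role": "bee"})
                ys[sid] = vals[h] + 0.1 * (b - 1)
        y = pd.Series(ys)
        samples = SampleTable(pd.DataFrame(rows).set_index("sample_id"))
        res = bq.nested_anova(y, samples)
        total_df = res.table["df"].sum()
        assert total_df == 3  # 4 hives - 1, not 12 bees - 1

    def test_bee_level_variant_uses_hive_stratum(self, profile, bees):
        res = bq.nested_anova(profile.totals(), bees, level="bee")
        assert "hive_id" in res.table.index
        assert res.table.loc["hive_id", "df"] > 0

    def test_interaction_dropped_when_not_estimable(self):
        y, samples = _hive_design(
            [1, 2, 3, 4],
            ["failed", "failed", "survived", "survived"],
            ["x", "x", "y", "y"],  # condition determines location
        )
        with pytest.warns(UserWarning, match="interaction dropped"):
            res = bq.nested_anova(y, samples)
        assert "condition:location" not in res.table.index


class TestIndval:
    def _labels(self, groups):
        return pd.Series(groups, index=[f"s{i}" for i in range(len(groups))])

    def test_perfect_indicator(self):
        m = _m([[5], [7], [6], [0], [0], [0]])
        labels = self._labels(["survived"] * 3 + ["failed"] * 3)
        res = bq.indval(m, labels, method="exact")
        assert res.loc["a0", "stat"] == pytest.approx(1.0, abs=1e-12)
        # minimum attainable exact p: the true split and its mirror out of C(6,3)
        assert res.loc["a0", "p_value"] == pytest.approx(2 / 20, abs=1e-12)

    def test_formula_by_hand(self):
        # group means 2 vs 1, full presence in the best group
        m = _m([[2], [2], [1], [1]])
        labels = self._labels(["g1", "g1", "g2", "g2"])
        res = bq.indval(m, labels, n_perm=99, seed=0)
        assert res.loc["a0", "stat"] == pytest.approx(math.sqrt(2 / 3), abs=1e-12)

    def test_statistic_squared_is_a_times_b(self, profile, bees):
        res = bq.indval(profile, bees, n_perm=99, seed=0)
        assert np.allclose(res["stat"] ** 2, res["A"] * res["B"], atol=1e-12)
        assert (res["adj_p"] >= res["p_value"] - 1e-12).all()

    def test_exact_p_matches_brute_force_oracle(self, micro):
        """Package exact mode vs an independently coded enumeration."""
        counts = micro.counts.select_samples(micro.samples.bee_ids)
        labels = micro.samples.factor("condition", counts.sample_ids)
        res = bq.indval(counts, labels, method="exact")

        X = counts.values
        y = np.asarray(labels)
        n1 = int((y == "failed").sum())
        n = len(y)
        stats_obs = []
        for a in range(X.shape[1]):
            stats_obs.append(self._oracle_stat(X[:, a], y == "failed"))
        count = np.zeros(X.shape[1])
        total = 0
        for combo in itertools.combinations(range(n), n1):
            mask = np.zeros(n, dtype=bool)
            mask[list(combo)] = True
            total += 1
            for a in range(X.shape[1]):
                if self._oracle_stat(X[:, a], mask) >= stats_obs[a] - 1e-12:
                    count[a] += 1
        assert np.allclose(res["p_value"].to_numpy(), count / total, atol=1e-12)
        assert np.allclose(res["stat"].to_numpy(), stats_obs, atol=1e-12)

    @staticmethod
    def _oracle_stat(x, in_g1):
        out = []
        for mask in (in_g1, ~in_g1):
            mean_in = x[mask].mean()
            mean_out = x[~mask].mean()
            if mean_in + mean_out == 0:
                out.append(0.0)
                continue
            A = mean_in / (mean_in + mean_out)
            B = (x[mask] > 0).mean()
            out.append(math.sqrt(A * B))
        return max(out)

    def test_invariant_to_relabeling_and_sample_order(self):
        rng = np.random.default_rng(4)
        m = _m(rng.integers(0, 10, size=(8, 3)))
        labels = self._labels(["u"] * 4 + ["v"] * 4)
        res1 = bq.indval(m, labels, method="exact")
        # swap group names and shuffle sample order
        perm = rng.permutation(8)
        m2 = CountMatrix(m.data.iloc[perm])
        relabeled = labels.map({"u": "v", "v": "u"}).iloc[perm]
        res2 = bq.indval(m2, relabeled, method="exact")
        assert np.allclose(res1["stat"], res2["stat"], atol=1e-12)
        assert np.allclose(res1["p_value"], res2["p_value"], atol=1e-12)

    def test_absent_asv_stat_zero_p_one(self):
        m = _m([[1, 0], [2, 0], [3, 0], [4, 0]])
        labels = self._labels(["g1", "g1", "g2", "g2"])
        res = bq.indval(m, labels, n_perm=99, seed=0)
        assert res.loc["a1", "stat"] == 0.0
        assert res.loc["a1", "p_value"] == 1.0


class TestBHAdjust:
    def test_step_up_by_hand(self):
        out = bq.bh_adjust([0.01, 0.04, 0.03])
        assert np.allclose(out, [0.03, 0.04, 0.04], atol=1e-12)

    def test_single_p_unchanged(self):
        assert bq.bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_equal_unchanged(self):
        assert np.allclose(bq.bh_adjust([0.3, 0.3, 0.3]), 0.3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bq.bh_adjust([0.5, 1.2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_never_decreases_and_preserves_ranks(self, ps):
        adj = bq.bh_adjust(ps)
        assert (adj >= np.asarray(ps) - 1e-15).all()
        assert (adj <= 1.0 + 1e-15).all()
        order = np.argsort(ps, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestDwv:
    def _ct(self, gapdh, dwv_c, sample="s1"):
        rows = []
        for assay, val in (("GAPDH", gapdh), ("DWV_C", dwv_c)):
            for rep in (1, 2, 3):
                rows.append({"sample_id": sample, "assay": assay,
                             "replicate": rep, "ct": val})
        return CtTable(pd.DataFrame(rows))

    def test_delta_ct_subtraction(self):
        out = bq.dwv_delta_ct(self._ct(20.0, 25.0))
        assert out.iloc[0]["dct"] == pytest.approx(-5.0)
        assert out.iloc[0]["strain"] == "C"

    def test_equal_ct_gives_zero(self):
        out = bq.dwv_delta_ct(self._ct(21.0, 21.0))
        assert out.iloc[0]["dct"] == pytest.approx(0.0)

    def test_missing_gapdh_is_an_error(self):
        rows = pd.DataFrame({"sample_id": ["s1"], "assay": ["DWV_A"],
                             "replicate": [1], "ct": [20.0]})
        with pytest.raises(ValueError, match="GAPDH"):
            bq.dwv_delta_ct(CtTable(rows))

    def test_planted_location_shift_detected_on_strain_c_only(self):
        """The generator plants a between-location delta-Ct shift on DWV-C;
        the nested ANOVA finds it there (and not systematically on A)."""
        hits_c, hits_a = 0, 0
        n_rep = 50
        for r in range(n_rep):
            s = bq.generate_study(seed=7000 + r)
            dwv = bq.dwv_delta_ct(s.ct)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = bq.dwv_anova(dwv, s.samples)
            if res["C"].p_value("location") < 0.05:
                hits_c += 1
            if res["A"].p_value("location") < 0.05:
                hits_a += 1
        assert hits_c / n_rep >= 0.80
        assert hits_a / n_rep <= 0.30
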