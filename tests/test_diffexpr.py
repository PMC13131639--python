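import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synoclust import diffexpr, io_core, simulate
from synoclust.diffexpr import (associate_metadata, bh_adjust,
                                de_cluster_vs_rest, de_degeneration,
                                fisher_exact_table, welch_anova,
                                wilcoxon_rank_sum)

from conftest import make_matrix


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def ranksum_exact_oracle(x, y):
    """Two-sided p by full enumeration of group assignments."""
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)
    obs = sum(sorted(pooled).index(v) + 1 for v in x)  # rank sum, no ties
    ranks = {v: r + 1 for r, v in enumerate(sorted(pooled))}
    obs = sum(ranks[v] for v in x)
    mean = n1 * (len(pooled) + 1) / 2
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        rs = sum(ranks[pooled[i]] for i in combo)
        if abs(rs - mean) >= abs(obs - mean) - 1e-12:
            count += 1
        total += 1
    return count / total


def bh_oracle(p):
    """Literal step-up rule: q_i = min_{p_j >= p_i} m * p_j / rank_j."""
    p = list(p)
    m = len(p)
    ranked = sorted(range(m), key=lambda i: p[i])
    out = [None] * m
    for i in range(m):
        candidates = [m * p[j] / (ranked.index(j) + 1)
                      for j in range(m) if p[j] >= p[i]]
        out[i] = min(1.0, min(candidates))
    return out


def fisher_2x2_oracle(a, b, c, d):
    """Two-sided Fisher p: sum of hypergeometric probs <= P(observed)."""
    n = a + b + c + d
    r1, c1 = a + b, a + c

    def prob(k):
        return (math.comb(r1, k) * math.comb(n - r1, c1 - k)
                / math.comb(n, c1))

    p_obs = prob(a)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    return sum(prob(k) for k in range(lo, hi + 1)
               if prob(k) <= p_obs * (1 + 1e-9))


# ---------------------------------------------------------------------------
# wilcoxon_rank_sum
# ---------------------------------------------------------------------------

class TestWilcoxonRankSum:
    def test_extreme_separation_exact(self):
        stat, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], mode="exact")
        assert p == pytest.approx(2 / 20)

    def test_identical_samples_p_near_one(self):
        _, p = wilcoxon_rank_sum([1, 2, 2, 3], [1, 2, 2, 3],
                                 mode="normal_tie_corrected")
        assert p > 0.9

    def test_empty_input_errors(self):
        with pytest.raises(ValueError, match="non-empty"):
            wilcoxon_rank_sum([], [1.0])

    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 4), (3, 5), (5, 5),
                                       (4, 8), (6, 6)])
    def test_exact_matches_enumeration(self, n1, n2, rng):
        x = rng.permutation(np.arange(1.0, n1 + n2 + 1))[:n1]
        y = np.setdiff1d(np.arange(1.0, n1 + n2 + 1), x)
        _, p = wilcoxon_rank_sum(x, y, mode="exact")
        assert p == pytest.approx(ranksum_exact_oracle(x, y), abs=1e-12)

    def test_auto_dispatch(self):
        # no ties, small n -> exact: p values are rational with known denom
        _, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], mode="auto")
        assert p == pytest.approx(0.1)

    def test_exact_refuses_ties(self):
        with pytest.raises(ValueError, match="ties"):
            wilcoxon_rank_sum([1, 1, 2], [2, 3, 4], mode="exact")


# ---------------------------------------------------------------------------
# bh_adjust
# ---------------------------------------------------------------------------

class TestBhAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_p(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_clipping(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0]), [1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=12))
    @settings(max_examples=100, deadline=None)
    def test_matches_stepup_oracle(self, p):
        np.testing.assert_allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2,
                    max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_inflating(self, p):
        # BH is monotone in its inputs, so double adjustment is pointwise
        # inflating and can only shrink the rejection set (exact
        # idempotence of rejections fails at boundary levels because the
        # attained q-scale is discrete)
        q = bh_adjust(p)
        qq = bh_adjust(q)
        assert np.all(qq >= q - 1e-12)
        for level in (0.01, 0.05, 0.2):
            assert set(np.flatnonzero(qq <= level)) <= \
                set(np.flatnonzero(q <= level))
        # order preserving
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(np.asarray(q)[order]) >= -1e-12)


# ---------------------------------------------------------------------------
# Welch ANOVA
# ---------------------------------------------------------------------------

class TestWelchAnova:
    def test_matches_reference_implementation(self, rng):
        # reference: statsmodels-style computation via scipy on shifted data
        groups = [rng.normal(loc=mu, scale=sc, size=n)
                  for mu, sc, n in [(0, 1, 12), (0.5, 2, 20), (1, 0.5, 8)]]
        f, p = welch_anova(groups)
        from scipy.stats import alexandergovern
        # Welch and Alexander-Govern agree closely under normality
        ag = alexandergovern(*groups)
        assert p == pytest.approx(ag.pvalue, abs=0.02)

    def test_equal_groups_p_one(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        f, p = welch_anova([g, g + 1e-12, g - 1e-12])
        assert p > 0.99

    def test_strong_shift_rejects(self, rng):
        g1 = rng.normal(0, 1, 20)
        g2 = rng.normal(5, 1, 20)
        _, p = welch_anova([g1, g2])
        assert p < 1e-6


# ---------------------------------------------------------------------------
# Fisher's exact
# ---------------------------------------------------------------------------

class TestFisherExact:
    def test_hand_table(self):
        p = fisher_exact_table(np.array([[3, 7], [8, 2]]))
        assert p == pytest.approx(fisher_2x2_oracle(3, 7, 8, 2), rel=1e-9)

    def test_exhaustive_small_margins(self):
        # all 2x2 tables with both row sums <= 6 (exhaustive oracle check;
        # margins <= 15 covered in the acceptance suite)
        for r1 in range(1, 7):
            for r2 in range(1, 7):
                for a in range(r1 + 1):
                    for c in range(r2 + 1):
                        tab = np.array([[a, r1 - a], [c, r2 - c]])
                        p = fisher_exact_table(tab)
                        expected = fisher_2x2_oracle(a, r1 - a, c, r2 - c)
                        assert p == pytest.approx(expected, rel=1e-9), tab

    def test_mc_large_table_close_to_exact_2x2_embedding(self):
        # 3x2 with an empty row reduces to 2x2 after trimming
        tab = np.array([[3, 7], [8, 2], [0, 0]])
        p = fisher_exact_table(tab)
        assert p == pytest.approx(fisher_2x2_oracle(3, 7, 8, 2), rel=1e-9)

    def test_mc_calibration_3x3(self):
        # Monte-Carlo p close to R's fisher.test exact value for this table
        # (oracle: exhaustive enumeration below)
        tab = np.array([[5, 1, 1], [1, 5, 1], [1, 1, 5]])
        exact = _fisher_exact_enumerate(tab)
        p = fisher_exact_table(tab, n_mc=40000, seed=0)
        assert p == pytest.approx(exact, abs=0.01)


def _fisher_exact_enumerate(table):
    """Exhaustive network-free enumeration of r x c tables with fixed
    margins, summing probabilities <= P(observed)."""
    from math import lgamma

    table = np.asarray(table)
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)

    def logp(t):
        n = t.sum()
        lp = sum(lgamma(r + 1) for r in rows) + \
            sum(lgamma(c + 1) for c in cols) - lgamma(n + 1) - \
            sum(lgamma(v + 1) for v in t.flat)
        return lp

    obs = logp(table)
    total = 0.0
    hit = 0.0

    def recurse(partial, ri):
        nonlocal total, hit
        if ri == len(rows) - 1:
            last = cols - np.sum(partial, axis=0) if partial else cols
            last = cols - (np.sum(partial, axis=0) if len(partial) else 0)
            if np.all(last >= 0) and last.sum() == rows[-1]:
                t = np.array(partial + [list(last)])
                lp = logp(t)
                pr = math.exp(lp)
                total += pr
                if lp <= obs + 1e-9:
                    hit += pr
            return
        # enumerate row ri compositions
        remaining = cols - (np.sum(partial, axis=0) if len(partial) else 0)

        def comps(total_row, caps):
            if len(caps) == 1:
                if total_row <= caps[0]:
                    yield [total_row]
                return
            for v in range(min(total_row, caps[0]) + 1):
                for rest in comps(total_row - v, caps[1:]):
                    yield [v] + rest

        for row in comps(rows[ri], list(remaining)):
            recurse(partial + [row], ri + 1)

    recurse([], 0)
    return hit / total


# ---------------------------------------------------------------------------
# DE engines
# ---------------------------------------------------------------------------

class TestDeClusterVsRest:
    def test_planted_recovery_power(self, small_logcpm):
        mat, meta = small_logcpm
        labels = meta.table["cluster"].to_numpy()
        res = de_cluster_vs_rest(mat, labels, "C1")
        planted = set(meta.true_markers[1])
        up = set(res.up_genes())
        power = len(up & planted) / len(planted)
        assert power >= 0.9

    def test_constant_gene(self):
        vals = np.vstack([np.ones(8), np.arange(8.0)])
        m = make_matrix(vals, layer="logcpm")
        labels = np.array(["A"] * 4 + ["B"] * 4)
        res = de_cluster_vs_rest(m, labels, "A", expressed_min_frac=0.0)
        assert res.table.loc["g0", "p_value"] == 1.0
        assert res.table.loc["g0", "log2_fold_change"] == 0.0

    def test_degenerate_group_errors(self):
        m = make_matrix(np.ones((3, 4)), layer="logcpm")
        with pytest.raises(ValueError):
            de_cluster_vs_rest(m, np.array(["A", "B", "B", "B"]), "A")

    def test_expressed_filter(self):
        vals = np.vstack([np.zeros(10), np.arange(10.0)])
        vals[0, 0] = 1.0  # expressed in 10% only
        m = make_matrix(vals, layer="logcpm")
        labels = np.array(["A"] * 5 + ["B"] * 5)
        res = de_cluster_vs_rest(m, labels, "A", expressed_min_frac=0.2)
        assert "g0" not in res.table.index
        assert "g1" in res.table.index

    def test_q_preserves_p_order(self, small_logcpm):
        mat, meta = small_logcpm
        labels = meta.table["cluster"].to_numpy()
        res = de_cluster_vs_rest(mat, labels, "C2")
        t = res.table.sort_values("p_value")
        assert np.all(np.diff(t["q_value"]) >= -1e-12)


class TestDeDegeneration:
    def test_planted_shift_recovered(self, rng):
        n = 60
        d_oarsi = np.array([15] * 30 + [22] * 30)
        vals = rng.normal(5, 1, size=(50, n))
        vals[:10, 30:] += 2  # shifted up in high-degeneration samples
        m = make_matrix(vals, layer="logcpm")
        table = pd.DataFrame({"d_oarsi": d_oarsi},
                             index=pd.Index(m.sample_ids, name="sample_id"))
        meta = io_core.SampleMetadata(table)
        res = de_degeneration(m, meta, threshold=20)
        up = set(res.up_genes())
        assert {f"g{i}" for i in range(10)} <= up

    def test_threshold_above_all_errors(self, small_logcpm):
        mat, meta = small_logcpm
        with pytest.raises(ValueError, match="stratum"):
            de_degeneration(mat, meta, threshold=100)

    def test_swapping_strata_flips_signs(self, rng):
        n = 20
        vals = rng.normal(5, 1, size=(30, n))
        d = np.array([10] * 10 + [25] * 10)
        table = pd.DataFrame({"d_oarsi": d},
                             index=pd.Index([f"s{j}" for j in range(n)],
                                            name="sample_id"))
        m = make_matrix(vals, layer="logcpm")
        meta = io_core.SampleMetadata(table)
        res = de_degeneration(m, meta, threshold=20)
        flipped_meta = io_core.SampleMetadata(
            table.assign(d_oarsi=np.where(d >= 20, 10, 25)))
        res_f = de_degeneration(m, flipped_meta, threshold=20)
        np.testing.assert_allclose(res.table["p_value"],
                                   res_f.table["p_value"], atol=1e-12)
        np.testing.assert_allclose(res.table["log2_fold_change"],
                                   -res_f.table["log2_fold_change"],
                                   atol=1e-12)


# ---------------------------------------------------------------------------
# Metadata association
# ---------------------------------------------------------------------------

class TestAssociateMetadata:
    def test_dispatch_and_fields(self, small_bulk):
        _, meta = small_bulk
        labels = meta.table["cluster"].to_numpy()
        out = associate_metadata(meta, labels, fisher_mc=2000)
        t = out.table.set_index("variable")
        assert t.loc["major_trauma", "test_used"] == "fisher_exact"
        assert t.loc["d_oarsi", "test_used"] in ("kruskal_wallis",
                                                 "welch_anova")
        assert ((t["p_value"] >= 0) & (t["p_value"] <= 1)).all()

    def test_categorical_2x2_matches_hypergeometric(self):
        labels = np.array(["A"] * 10 + ["B"] * 10)
        covariate = ["yes"] * 3 + ["no"] * 7 + ["yes"] * 8 + ["no"] * 2
        table = pd.DataFrame({"flag": covariate},
                             index=pd.Index([f"s{i}" for i in range(20)],
                                            name="sample_id"))
        meta = io_core.SampleMetadata(table, {"flag": "categorical"})
        out = associate_metadata(meta, labels)
        p = out.table.set_index("variable").loc["flag", "p_value"]
        assert p == pytest.approx(fisher_2x2_oracle(3, 7, 8, 2), rel=1e-9)

    def test_all_missing_variable_skipped_with_warning(self):
        table = pd.DataFrame(
            {"x": [np.nan] * 8, "y": list(range(8))},
            index=pd.Index([f"s{i}" for i in range(8)], name="sample_id"))
        meta = io_core.SampleMetadata(table, {"x": "continuous",
                                              "y": "continuous"})
        labels = np.array(["A"] * 4 + ["B"] * 4)
        out = associate_metadata(meta, labels)
        assert any("x" in w for w in out.warnings)
        assert "x" not in out.table["variable"].tolist()

    def test_normal_data_uses_welch_with_mean_sd(self, rng):
        table = pd.DataFrame(
            {"v": rng.normal(10, 2, size=40)},
            index=pd.Index([f"s{i}" for i in range(40)], name="sample_id"))
        meta = io_core.SampleMetadata(table, {"v": "continuous"})
        labels = np.repeat(["A", "B"], 20)
        out = associate_metadata(meta, labels)
        row = out.table.set_index("variable").loc["v"]
        assert row["test_used"] == "welch_anova"
        assert "mean" in out.summaries["v"].columns

    def test_skewed_data_uses_kruskal_with_median_iqr(self, rng):
        vals = rng.exponential(1, size=60) ** 3
        table = pd.DataFrame(
            {"v": vals},
            index=pd.Index([f"s{i}" for i in range(60)], name="sample_id"))
        meta = io_core.SampleMetadata(table, {"v": "continuous"})
        labels = np.repeat(["A", "B", "C"], 20)
        out = associate_metadata(meta, labels)
        row = out.table.set_index("variable").loc["v"]
        assert row["test_used"] == "kruskal_wallis"
        assert "median" in out.summaries["v"].columns

    def test_trauma_pattern_rejects(self):
        # paper-like group sizes with an elevated binary covariate in the
        # small cluster plus depressed rates elsewhere
        rng = np.random.default_rng(7)
        sizes = {"C1": 39, "C2": 51, "C3": 36, "C4": 9}
        labels = np.concatenate([[c] * n for c, n in sizes.items()])
        rates = {"C1": 0.10, "C2": 0.04, "C3": 0.14, "C4": 0.60}
        flags = np.concatenate([
            rng.random(n) < rates[c] for c, n in sizes.items()])
        table = pd.DataFrame(
            {"trauma": np.where(flags, "yes", "no")},
            index=pd.Index([f"s{i}" for i in range(135)], name="sample_id"))
        meta = io_core.SampleMetadata(table, {"trauma": "categorical"})
        out = associate_metadata(meta, labels, fisher_mc=20000)
        p = out.table.set_index("variable").loc["trauma", "p_value"]
        assert p < 0.05
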