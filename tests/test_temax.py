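"""TE_max quartiles, mRNA-level binning, trend fits, enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from teflux.synthetic import plant_te_trend
from teflux.temax import (
    QUARTILE_LABELS,
    bin_means,
    bin_rna,
    category_enrichment,
    compute_te_max,
    filter_and_quartile,
    fit_trend,
    slope_difference,
)


class TestTEMax:
    def test_row_max_examples(self):
        te = pd.DataFrame({"a": [0.5, 1.0], "b": [1.2, np.nan], "c": [0.9, np.nan]},
                          index=["g1", "g2"])
        tm = compute_te_max(te)
        assert tm["g1"] == 1.2
        assert tm["g2"] == 1.0  # single defined condition

    def test_matches_row_max_oracle(self, rng):
        te = pd.DataFrame(rng.random((20, 3)), columns=list("abc"))
        tm = compute_te_max(te)
        for i in te.index:
            assert tm[i] == te.loc[i].max()

    def test_all_nan_rows_dropped(self):
        te = pd.DataFrame({"a": [np.nan, 1.0]}, index=["g1", "g2"])
        assert list(compute_te_max(te).index) == ["g2"]


class TestFilterAndQuartile:
    def _inputs(self, te_vals, fpkm=100.0):
        idx = [f"g{i}" for i in range(len(te_vals))]
        return (pd.Series(te_vals, index=idx),
                pd.Series([fpkm] * len(te_vals), index=idx))

    def test_strict_te_boundaries(self):
        te, fpkm = self._inputs([5.0, 0.01, 4.99, 0.011] + list(np.linspace(0.5, 2, 8)))
        rec = filter_and_quartile(te, fpkm)
        assert "g0" not in rec.index and "g1" not in rec.index
        assert "g2" in rec.index and "g3" in rec.index

    def test_strict_fpkm_boundary(self):
        te = pd.Series(np.linspace(0.5, 2, 10), index=[f"g{i}" for i in range(10)])
        fpkm = pd.Series([10.0] * 2 + [11.0] * 8, index=te.index)
        rec = filter_and_quartile(te, fpkm)
        assert len(rec) == 8 and "g0" not in rec.index

    def test_100_distinct_survivors_split_25_per_quartile(self):
        te, fpkm = self._inputs(list(np.linspace(0.1, 4.5, 100)))
        rec = filter_and_quartile(te, fpkm)
        counts = rec["quartile"].value_counts()
        assert sorted(counts.tolist()) == [25, 25, 25, 25]

    def test_partition_covers_all_survivors_once(self, rng):
        te, fpkm = self._inputs(list(rng.uniform(0.02, 4.9, 57)))
        rec = filter_and_quartile(te, fpkm)
        assert rec["quartile"].notna().all()
        assert len(rec) == 57

    def test_too_few_survivors_rejected(self):
        te, fpkm = self._inputs([1.0] * 5)
        with pytest.raises(ValueError, match="survive"):
            filter_and_quartile(te, fpkm)


class TestBinRNA:
    def _records(self, rng, n=200):
        te = pd.Series(rng.uniform(0.02, 4.9, n), index=[f"g{i}" for i in range(n)])
        fpkm = pd.Series(rng.lognormal(5, 1, n) + 10.5, index=te.index)
        return filter_and_quartile(te, fpkm)

    def test_equal_count_bins(self, rng):
        binned = bin_rna(self._records(rng))
        counts = binned["rna_bin"].value_counts()
        assert counts.max() - counts.min() <= 1

    def test_row_order_invariance(self, rng):
        rec = self._records(rng)
        a = bin_rna(rec).sort_index()
        b = bin_rna(rec.iloc[::-1]).sort_index()
        pd.testing.assert_frame_equal(a, b)

    def test_ci_matches_closed_form(self):
        rec = pd.DataFrame({
            "te_max": [1.0, 2.0, 4.0], "fpkm": [100.0] * 3,
            "quartile": ["high"] * 3, "rna_bin": [1, 1, 1],
            "log2_te": np.log2([1.0, 2.0, 4.0]), "log2_fpkm": [np.log2(100)] * 3,
        })
        means = bin_means(rec)
        vals = np.log2([1.0, 2.0, 4.0])
        half = sps.t.ppf(0.975, 2) * vals.std(ddof=1) / np.sqrt(3)
        assert means["mean_log2_te"].iloc[0] == pytest.approx(vals.mean())
        assert means["ci_hi"].iloc[0] - means["mean_log2_te"].iloc[0] == pytest.approx(half)


class TestTrendFit:
    def test_noiseless_line_recovered(self):
        df = pd.DataFrame({
            "rna_bin": list(range(1, 11)) * 3,
            "log2_te": [2 * b + 1 for b in range(1, 11)] * 3,
            "quartile": ["high"] * 30,
        })
        fit = fit_trend(df, "high")
        assert fit.slope == pytest.approx(2.0)
        assert fit.pvalue < 1e-12
        assert fit.ci_lo <= 2.0 + 1e-12 and 2.0 - 1e-12 <= fit.ci_hi

    def test_null_pvalues_uniform(self, rng):
        """Slope-0 noise gives uniform Wald p over 500 replicates."""
        pvals = []
        for _ in range(500):
            df = pd.DataFrame({
                "rna_bin": np.repeat(np.arange(1, 11), 5),
                "log2_te": rng.normal(0, 1, 50),
                "quartile": ["high"] * 50,
            })
            pvals.append(fit_trend(df, "high").pvalue)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_planted_sign_pattern(self):
        """The generator's trend plant: positive high slope, negative low
        slope, both CIs excluding zero."""
        binned = bin_rna(filter_and_quartile(
            plant_te_trend(seed=5)["te_max"], plant_te_trend(seed=5)["fpkm"]))
        hi = fit_trend(binned, "high")
        lo = fit_trend(binned, "low")
        assert hi.slope > 0 and hi.ci_lo > 0
        assert lo.slope < 0 and lo.ci_hi < 0

    def test_too_few_bins_rejected(self):
        df = pd.DataFrame({"rna_bin": [1, 2], "log2_te": [0.0, 1.0],
                           "quartile": ["high"] * 2})
        with pytest.raises(ValueError, match="3 bins"):
            fit_trend(df, "high")


class TestSlopeDifference:
    def _frame(self, slope_hi, slope_lo, noise, rng, n=200):
        rows = []
        for q, s in (("high", slope_hi), ("low", slope_lo)):
            bins = rng.integers(1, 11, n)
            rows.append(pd.DataFrame({
                "rna_bin": bins,
                "log2_te": s * bins + rng.normal(0, noise, n),
                "quartile": [q] * n,
            }))
        return pd.concat(rows, ignore_index=True)

    def test_identical_groups_null(self, rng):
        df = self._frame(0.5, 0.5, 0.5, rng)
        res = slope_difference(df)
        assert res["interaction_p"] > 0.05

    def test_opposite_slopes_detected(self, rng):
        df = self._frame(1.0, -1.0, 0.3, rng)
        res = slope_difference(df)
        assert res["interaction_p"] < 0.01
        assert res["slope_a"] > 0 > res["slope_b"]

    def test_permutation_consistency(self, rng):
        """Permuting group labels gives an empirical null consistent with
        the analytic interaction p."""
        df = self._frame(0.35, 0.2, 0.6, rng, n=60)
        obs = slope_difference(df)["interaction_p"]
        stat_obs = abs(fit_trend(df, "high").slope - fit_trend(df, "low").slope)
        perm_stats = []
        labels = df["quartile"].to_numpy().copy()
        for _ in range(300):
            rng.shuffle(labels)
            d2 = df.assign(quartile=labels)
            perm_stats.append(
                abs(fit_trend(d2, "high").slope - fit_trend(d2, "low").slope)
            )
        emp_p = (np.sum(np.array(perm_stats) >= stat_obs) + 1) / 301
        # analytic and empirical p agree in order of magnitude
        assert (emp_p < 0.1) == (obs < 0.1)


class TestEnrichment:
    def _records(self, quartiles):
        return pd.DataFrame({
            "quartile": pd.Categorical(quartiles, categories=QUARTILE_LABELS),
        }, index=[f"g{i}" for i in range(len(quartiles))])

    def test_concentrated_category_flagged(self):
        """20 of 100 genes all in one quartile: hypergeometric tail oracle
        confirms the Fisher call."""
        quart = ["high"] * 25 + ["low"] * 25 + ["medium-low"] * 25 + ["medium-high"] * 25
        rec = self._records(quart)
        cats = pd.Series("other", index=rec.index)
        cats.iloc[:20] = "energy"  # all inside the high quartile
        out = category_enrichment(rec, cats)
        cell = out[(out["category"] == "energy") & (out["quartile"] == "high")].iloc[0]
        assert cell["n_genes"] == 20 and cell["enriched"]
        oracle = sps.hypergeom.sf(19, 100, 20, 25)  # P(X >= 20)
        assert cell["pvalue"] <= oracle * 2 + 1e-12

    def test_proportional_category_not_flagged(self):
        quart = (["high"] * 10 + ["low"] * 10 + ["medium-low"] * 10 + ["medium-high"] * 10)
        rec = self._records(quart)
        cats = pd.Series(["c1", "c2"] * 20, index=rec.index)
        out = category_enrichment(rec, cats)
        assert not out["enriched"].any()
        assert (out["pvalue"] > 0.5).all()

    def test_2x2_matches_hypergeometric_enumeration(self):
        """(a,b,c,d) = (8,2,2,8): two-sided Fisher p from first principles."""
        quart = ["high"] * 10 + ["low"] * 10
        rec = self._records(quart)
        cats = pd.Series(["in"] * 8 + ["out"] * 2 + ["in"] * 2 + ["out"] * 8,
                         index=rec.index)
        out = category_enrichment(rec, cats)
        cell = out[(out["category"] == "in") & (out["quartile"] == "high")].iloc[0]
        # enumerate the hypergeometric: 10 in-category, 10 high, N=20
        probs = [sps.hypergeom.pmf(k, 20, 10, 10) for k in range(11)]
        p_obs = probs[8]
        expected = sum(p for p in probs if p <= p_obs + 1e-12)
        assert cell["pvalue"] == pytest.approx(expected, rel=1e-6)

    def test_invariant_to_quartile_label_order(self, rng):
        quart = rng.choice(QUARTILE_LABELS, 80)
        rec = self._records(list(quart))
        cats = pd.Series(rng.choice(["x", "y", "z"], 80), index=rec.index)
        a = category_enrichment(rec, cats)
        rec2 = rec.iloc[::-1]
        b = category_enrichment(rec2, cats)
        merged = a.merge(b, on=["category", "quartile"], suffixes=("_a", "_b"))
        assert np.allclose(merged["pvalue_a"], merged["pvalue_b"])

    def test_unlabeled_record_rejected(self):
        rec = self._records(["high", "low"])
        cats = pd.Series({"g0": "x"})
        with pytest.raises(ValueError, match="category label"):
            category_enrichment(rec, cats)


class TestEndToEndPattern:
    def test_fig_style_plant_recovers_full_pattern(self):
        """Planted optimized/suboptimized mRNAs: positive high slope,
        negative low slope, CIs excluding 0, slope difference p < 0.01."""
        df = plant_te_trend(n_per_group=80, seed=17)
        rec = filter_and_quartile(df["te_max"], df["fpkm"])
        # planted group structure survives the data-driven quartiles
        merged = rec.join(df["group"])
        agreement = (merged["quartile"].astype(str) == merged["group"]).mean()
        assert agreement > 0.95
        binned = bin_rna(rec)
        hi, lo = fit_trend(binned, "high"), fit_trend(binned, "low")
        assert hi.slope > 0 and hi.ci_lo > 0
        assert lo.slope < 0 and lo.ci_hi < 0
        res = slope_difference(binned)
        assert res["interaction_p"] < 0.01
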