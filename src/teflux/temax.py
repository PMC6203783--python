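"""TE_max quartiles versus mRNA level: the competition-for-ribosomes trend.

TE_max — the maximum TE a gene attains across growth conditions — proxies
the mRNA's maximal affinity for the ribosome. After filtering to
non-extreme TE (0.01 < TE < 5) and expressed mRNA (FPKM > 10), genes are
split into TE_max quartiles, mRNA levels are grouped into ten bins, and
log2 TE is regressed on bin index within each quartile. Optimized mRNAs
(high quartile) show TE rising with mRNA level; suboptimized mRNAs show
the opposite. Functional-category enrichment per quartile uses 2x2 Fisher
exact tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

TE_MIN, TE_MAX_FILTER = 0.01, 5.0
FPKM_MIN = 10.0
N_RNA_BINS = 10
QUARTILE_LABELS = ["low", "medium-low", "medium-high", "high"]


def compute_te_max(te: pd.DataFrame) -> pd.Series:
    """Row-wise max TE over conditions (NaN-aware); genes with no defined
    TE in any condition are dropped."""
    te_max = te.max(axis=1, skipna=True)
    return te_max.dropna().rename("te_max")


def filter_and_quartile(te_max: pd.Series, fpkm: pd.Series) -> pd.DataFrame:
    """Strict filters 0.01 < TE_max < 5 and FPKM > 10, then quartiles.

    Quartile boundaries are the 25/50/75th percentiles of the surviving
    TE_max values (linear-interpolation quantiles); labels low ->
    medium-low -> medium-high -> high.
    """
    df = pd.DataFrame({"te_max": te_max, "fpkm": fpkm}).dropna()
    survivors = df[
        (df["te_max"] > TE_MIN) & (df["te_max"] < TE_MAX_FILTER) & (df["fpkm"] > FPKM_MIN)
    ].copy()
    if len(survivors) < 8:
        raise ValueError(f"only {len(survivors)} genes survive the filters; need >= 8")
    q = np.percentile(survivors["te_max"], [25, 50, 75])
    survivors["quartile"] = pd.cut(
        survivors["te_max"],
        bins=[-np.inf, *q, np.inf],
        labels=QUARTILE_LABELS,
    )
    return survivors


def bin_rna(records: pd.DataFrame, n_bins: int = N_RNA_BINS, equal_width: bool = False) -> pd.DataFrame:
    """Assign each surviving gene to one of ten log2-FPKM bins.

    Default is equal-count (decile) bins so per-bin confidence intervals
    are comparable; ``equal_width`` switches to equal-width bins in log2
    space. Adds ``log2_fpkm``, ``log2_te`` and ``rna_bin`` (1..n_bins).
    """
    out = records.copy()
    out["log2_fpkm"] = np.log2(out["fpkm"])
    out["log2_te"] = np.log2(out["te_max"])
    if equal_width:
        out["rna_bin"] = pd.cut(out["log2_fpkm"], bins=n_bins, labels=False) + 1
    else:
        out["rna_bin"] = (
            pd.qcut(out["log2_fpkm"], q=n_bins, labels=False, duplicates="drop") + 1
        )
    return out


def bin_means(binned: pd.DataFrame, by_quartile: bool = True) -> pd.DataFrame:
    """Per (quartile, bin) mean log2 TE with a 95% t confidence interval."""
    keys = ["quartile", "rna_bin"] if by_quartile else ["rna_bin"]
    rows = []
    for key, grp in binned.groupby(keys, observed=True):
        vals = grp["log2_te"].to_numpy()
        mean = vals.mean()
        if len(vals) > 1:
            half = stats.t.ppf(0.975, len(vals) - 1) * vals.std(ddof=1) / np.sqrt(len(vals))
        else:
            half = np.nan
        row = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        row.update({"n": len(vals), "mean_log2_te": mean, "ci_lo": mean - half, "ci_hi": mean + half})
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class TrendFit:
    slope: float
    intercept: float
    se: float
    ci_lo: float
    ci_hi: float
    pvalue: float  # Wald test of zero slope
    n: int


def fit_trend(binned: pd.DataFrame, quartile: str | None = None) -> TrendFit:
    """OLS of per-gene log2 TE on RNA-bin index, with the Wald test of a
    zero slope. Per-gene points are used for inference; bin means are only
    for display."""
    df = binned if quartile is None else binned[binned["quartile"] == quartile]
    if df["rna_bin"].nunique() < 3:
        raise ValueError("need data in at least 3 bins to fit a trend")
    X = sm.add_constant(df["rna_bin"].astype(float))
    fit = sm.OLS(df["log2_te"].to_numpy(), X.to_numpy()).fit()
    ci = fit.conf_int()[1]
    return TrendFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        se=float(fit.bse[1]),
        ci_lo=float(ci[0]),
        ci_hi=float(ci[1]),
        pvalue=float(fit.pvalues[1]),
        n=int(fit.nobs),
    )


def slope_difference(binned: pd.DataFrame, q_a: str = "high", q_b: str = "low") -> dict:
    """Test whether two quartile groups have different trend slopes.

    Primary: Wald p of the quartile x bin interaction in the pooled OLS.
    Also reports a Tukey-HSD-style pairwise comparison of the two slope
    estimates (difference over pooled SE against the studentized range is
    approximated here by the equivalent two-group t comparison).
    """
    sub = binned[binned["quartile"].isin([q_a, q_b])].copy()
    if sub.empty:
        raise ValueError("both quartile groups must contain data")
    x = sub["rna_bin"].astype(float).to_numpy()
    g = (sub["quartile"] == q_a).astype(float).to_numpy()
    X = np.column_stack([np.ones(len(sub)), x, g, x * g])
    fit = sm.OLS(sub["log2_te"].to_numpy(), X).fit()
    interaction_p = float(fit.pvalues[3])
    fa = fit_trend(binned, q_a)
    fb = fit_trend(binned, q_b)
    z = (fa.slope - fb.slope) / np.hypot(fa.se, fb.se)
    pairwise_p = float(2 * stats.norm.sf(abs(z)))
    return {
        "slope_a": fa.slope,
        "slope_b": fb.slope,
        "interaction_p": interaction_p,
        "pairwise_p": pairwise_p,
    }


def category_enrichment(
    records: pd.DataFrame, categories: pd.Series, alpha: float = 0.05, adjust: bool = False
) -> pd.DataFrame:
    """2x2 Fisher exact enrichment of each functional category within each
    TE_max quartile.

    For every (category, quartile) cell the table is (in-category &
    in-quartile) vs the three complements over the filtered gene universe.
    Raw p is flagged at ``alpha``; a BH-adjusted column is available with
    ``adjust``. Empty categories are skipped.
    """
    if not records.index.isin(categories.index).all():
        raise ValueError("every record needs a category label")
    cats = categories.reindex(records.index)
    total = len(records)
    rows = []
    for cat, cat_mask in ((c, cats == c) for c in sorted(cats.dropna().unique())):
        n_cat = int(cat_mask.sum())
        if n_cat == 0:
            continue
        for quart in QUARTILE_LABELS:
            q_mask = (records["quartile"] == quart).to_numpy()
            a = int((cat_mask.to_numpy() & q_mask).sum())
            b = n_cat - a
            c = int(q_mask.sum()) - a
            d = total - a - b - c
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            rows.append(
                {"category": cat, "quartile": quart, "n_genes": a, "pvalue": p,
                 "odds_in": (a / max(b, 1)) / max(c / max(d, 1), 1e-300)}
            )
    out = pd.DataFrame(rows)
    if adjust and len(out):
        from statsmodels.stats.multitest import multipletests

        out["padj"] = multipletests(out["pvalue"], method="fdr_bh")[1]
        out["enriched"] = (out["padj"] < alpha) & (out["odds_in"] > 1)
    else:
        out["enriched"] = (out["pvalue"] < alpha) & (out["odds_in"] > 1)
    return out
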