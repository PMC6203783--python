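"""Normalization, translational efficiency, and replicate QC.

Expression is normalized per library as reads (Ribo-seq, RPKM) or fragments
(RNA-seq, FPKM) per kilobase of gene per million mapped:

    value = count * 1e9 / (gene_length_nt * library_size)

TE per gene and condition is the ratio of the replicate-mean Ribo-seq RPKM
to the replicate-mean RNA-seq FPKM. Genes are eligible only if every
replicate of both assays is nonzero in that condition; the low/high TE sets
are the genes strictly below the 20th / strictly above the 80th percentile
of eligible TE values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ExpressionMatrix:
    """Length- and depth-normalized expression (genes x libraries)."""

    values: pd.DataFrame
    library_sizes: pd.Series
    gene_lengths: pd.Series


@dataclass
class TETable:
    """Per-gene, per-condition TE plus the supporting means and gene sets."""

    te: pd.DataFrame                 # genes x conditions, NaN where undefined
    mean_rna_fpkm: pd.DataFrame
    mean_ribo_rpkm: pd.DataFrame
    eligible: pd.DataFrame           # bool, nonzero in every replicate of both assays
    low_set: dict[str, set[str]] | None = None
    high_set: dict[str, set[str]] | None = None


def normalize_per_kb_per_million(
    counts: pd.DataFrame, gene_lengths: pd.Series
) -> ExpressionMatrix:
    """RPKM/FPKM normalization of a gene x library count matrix."""
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()[:5]
        raise ValueError(f"gene lengths missing for {missing}...")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    lib_sizes = counts.sum(axis=0).astype(float)
    if (lib_sizes <= 0).any():
        empty = lib_sizes.index[lib_sizes <= 0].tolist()
        raise ValueError(f"zero library size for {empty}")
    values = counts.div(lengths, axis=0).div(lib_sizes, axis=1) * 1e9
    return ExpressionMatrix(values=values, library_sizes=lib_sizes, gene_lengths=lengths)


def condition_of(library: str) -> str:
    """Library naming convention '<assay>_<condition>_<replicate>'."""
    parts = library.split("_")
    if len(parts) < 3:
        raise ValueError(f"library name {library!r} is not '<assay>_<condition>_<rep>'")
    return "_".join(parts[1:-1])


def _replicate_groups(columns: pd.Index) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {}
    for col in columns:
        groups.setdefault(condition_of(col), []).append(col)
    return groups


def compute_te(ribo: ExpressionMatrix, rna: ExpressionMatrix) -> TETable:
    """Replicate-mean Ribo RPKM over replicate-mean RNA FPKM, per condition.

    TE is NaN (undefined, never infinite) wherever a gene fails the
    nonzero-in-every-replicate criterion in either assay.
    """
    if not ribo.values.index.equals(rna.values.index):
        raise ValueError("ribo and rna matrices must share an identical gene universe")
    ribo_groups = _replicate_groups(ribo.values.columns)
    rna_groups = _replicate_groups(rna.values.columns)
    conditions = sorted(set(ribo_groups) & set(rna_groups))
    if not conditions:
        raise ValueError("no shared conditions between the two assays")

    mean_ribo = pd.DataFrame(
        {c: ribo.values[ribo_groups[c]].mean(axis=1) for c in conditions}
    )
    mean_rna = pd.DataFrame({c: rna.values[rna_groups[c]].mean(axis=1) for c in conditions})
    eligible = pd.DataFrame(
        {
            c: (ribo.values[ribo_groups[c]] > 0).all(axis=1)
            & (rna.values[rna_groups[c]] > 0).all(axis=1)
            for c in conditions
        }
    )
    te = (mean_ribo / mean_rna).where(eligible)
    return TETable(
        te=te, mean_rna_fpkm=mean_rna, mean_ribo_rpkm=mean_ribo, eligible=eligible
    )


def replicate_correlation(
    matrix: ExpressionMatrix,
    method: str = "pearson",
    level: str = "gene",
    subsystem_map: pd.DataFrame | None = None,
    log2: bool = False,
) -> pd.Series:
    """Correlation between the two replicates of each condition.

    ``level='subsystem'`` first sums values per subsystem (requires a
    gene_id/subsystem map). Constant vectors give NaN, reported as such.
    By default correlations are computed on the normalized values directly;
    ``log2`` applies log2(x + 1) first.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    values = matrix.values
    if level == "subsystem":
        if subsystem_map is None:
            raise ValueError("subsystem-level correlation needs a subsystem map")
        merged = values.join(subsystem_map.set_index("gene_id")["subsystem"], how="inner")
        values = merged.groupby("subsystem").sum()
    elif level != "gene":
        raise ValueError(f"unknown level {level!r}")
    if log2:
        values = np.log2(values + 1)

    out = {}
    for cond, cols in _replicate_groups(values.columns).items():
        if len(cols) < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 replicates")
        a, b = values[cols[0]], values[cols[1]]
        if a.nunique() <= 1 or b.nunique() <= 1:
            out[cond] = np.nan
            continue
        if method == "pearson":
            out[cond] = stats.pearsonr(a, b).statistic
        else:
            out[cond] = stats.spearmanr(a, b).statistic
    return pd.Series(out, name=f"{method}_{level}")


def te_percentile_sets(
    table: TETable, low_pct: float = 20.0, high_pct: float = 80.0
) -> TETable:
    """Attach the low-/high-TE gene sets (strict percentile exceedance).

    Percentiles are linear-interpolation (type-7) quantiles of the eligible
    TE values within each condition; membership is strict (< low threshold,
    > high threshold), so with all-equal TEs both sets are empty.
    """
    low, high = {}, {}
    for cond in table.te.columns:
        vals = table.te[cond].dropna()
        if len(vals) < 5:
            raise ValueError(
                f"condition {cond!r}: only {len(vals)} eligible genes; percentiles need >= 5"
            )
        lo_thr = np.percentile(vals, low_pct)
        hi_thr = np.percentile(vals, high_pct)
        low[cond] = set(vals.index[vals < lo_thr])
        high[cond] = set(vals.index[vals > hi_thr])
    table.low_set = low
    table.high_set = high
    return table
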