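"""Subsystem-level resource allocation and differential-TE calls.

Genes are aggregated into functional subsystems (RAST-style; only annotated
genes contribute). Within each experiment (assay x condition) the summed
expression is normalized to percent of the total annotated expression;
subsystem TE is the ratio of the percent-translation to percent-
transcription layers. A cross-condition percent layer (the per-experiment
percents summed over conditions and renormalized) supports direct
comparison across growth conditions.

A subsystem is called differentially translationally efficient under the
heterotrophic condition when (1) its translation differs from both
autotrophic conditions (adjusted p < 0.01 each) while the two autotrophic
conditions do not differ (adjusted p > 0.01), (2) its heterotrophic
translation percent exceeds the 50th percentile, and (3) its heterotrophic
TE exceeds its TE in each autotrophic condition. The autotrophic call is
the mirror image (anchored versus the heterotrophic condition).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexpr import nb_wald_test
from .quantify import condition_of


@dataclass
class SubsystemMatrix:
    """Aggregated expression plus its percent-normalized layers."""

    summed: pd.DataFrame                    # subsystem x library
    percent_within: pd.DataFrame | None = None   # subsystem x (assay, condition)
    percent_across: pd.DataFrame | None = None   # subsystem x assay
    subsystem_te: pd.DataFrame | None = None     # subsystem x condition
    n_unmapped_genes: int = 0
    degenerate: bool = False


def aggregate_to_subsystems(
    values: pd.DataFrame, subsystem_map: pd.DataFrame
) -> SubsystemMatrix:
    """Sum a gene x library matrix into subsystems.

    Multi-membership is allowed: a gene mapped to two subsystems contributes
    to both. Genes absent from the map are excluded and counted.
    """
    if subsystem_map.empty:
        raise ValueError("subsystem map is empty")
    missing = set(subsystem_map["gene_id"]) - set(values.index)
    if missing:
        raise ValueError(f"mapped genes absent from the matrix: {sorted(missing)[:5]}...")
    merged = subsystem_map[["gene_id", "subsystem"]].merge(
        values, left_on="gene_id", right_index=True
    )
    summed = merged.drop(columns="gene_id").groupby("subsystem").sum()
    n_unmapped = len(set(values.index) - set(subsystem_map["gene_id"]))
    return SubsystemMatrix(summed=summed, n_unmapped_genes=n_unmapped)


def _assay_of(library: str) -> str:
    return library.split("_")[0]


def percent_normalize(sub: SubsystemMatrix) -> SubsystemMatrix:
    """Fill the percent layers and subsystem TE.

    percent_within: replicate-mean expression per (assay, condition),
    normalized so each experiment's subsystems sum to 100. percent_across:
    the within-experiment percents summed over conditions per assay,
    renormalized to percent. subsystem_te: percent Ribo / percent RNA per
    condition.
    """
    if (sub.summed.to_numpy() == 0).all():
        sub.degenerate = True
        sub.percent_within = None
        sub.percent_across = None
        sub.subsystem_te = None
        return sub

    groups: dict[tuple[str, str], list[str]] = {}
    for col in sub.summed.columns:
        groups.setdefault((_assay_of(col), condition_of(col)), []).append(col)

    within = {}
    for (assay, cond), cols in groups.items():
        mean = sub.summed[cols].mean(axis=1)
        total = mean.sum()
        if total <= 0:
            raise ValueError(f"experiment {(assay, cond)} has zero total expression")
        within[(assay, cond)] = 100.0 * mean / total
    pw = pd.DataFrame(within)
    pw.columns = pd.MultiIndex.from_tuples(pw.columns, names=["assay", "condition"])
    sub.percent_within = pw

    across = {}
    for assay in pw.columns.get_level_values("assay").unique():
        block = pw[assay]
        across[assay] = 100.0 * block.sum(axis=1) / block.sum(axis=1).sum()
    sub.percent_across = pd.DataFrame(across)

    if {"ribo", "rna"} <= set(pw.columns.get_level_values("assay")):
        conds = sorted(
            set(pw["ribo"].columns) & set(pw["rna"].columns)
        )
        sub.subsystem_te = pd.DataFrame(
            {c: pw[("ribo", c)] / pw[("rna", c)] for c in conds}
        )
    return sub


def differential_test(
    counts: pd.DataFrame,
    condition: pd.Series,
    contrasts: list[tuple[str, str]],
    level: str = "gene",
    subsystem_map: pd.DataFrame | None = None,
) -> dict[tuple[str, str], pd.DataFrame]:
    """NB Wald test per contrast, at gene level or on per-subsystem summed
    raw counts (count models need counts, not normalized values)."""
    if level == "subsystem":
        if subsystem_map is None:
            raise ValueError("subsystem-level testing needs a subsystem map")
        counts = aggregate_to_subsystems(counts, subsystem_map).summed
    elif level != "gene":
        raise ValueError(f"unknown level {level!r}")
    return {c: nb_wald_test(counts, condition, c) for c in contrasts}


# ------------------------------------------------------------ differential-TE calls


def build_subsystem_stats(
    ribo_counts: pd.DataFrame,
    condition: pd.Series,
    sub: SubsystemMatrix,
    het: str,
    autos: tuple[str, str],
    subsystem_map: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble the per-subsystem statistics the call rules consume:
    adjusted p for the three translation contrasts, percent translation, and
    subsystem TE per condition."""
    a1, a2 = autos
    contrasts = [(het, a1), (het, a2), (a1, a2)]
    tests = differential_test(
        ribo_counts, condition, contrasts, level="subsystem", subsystem_map=subsystem_map
    )
    if sub.percent_within is None or sub.subsystem_te is None:
        raise ValueError("percent_normalize must run before building subsystem stats")
    stats = pd.DataFrame(index=sub.summed.index)
    for (x, y), res in tests.items():
        stats[f"padj_{x}_vs_{y}"] = res["padj"].reindex(stats.index)
    for cond in (het, a1, a2):
        stats[f"trans_pct_{cond}"] = sub.percent_within[("ribo", cond)].reindex(stats.index)
        stats[f"te_{cond}"] = sub.subsystem_te[cond].reindex(stats.index)
    return stats


def call_diff_te_heterotrophic(
    stats: pd.DataFrame, het: str, autos: tuple[str, str], alpha: float = 0.01
) -> set[str]:
    """Subsystems with differentially efficient translation under the
    heterotrophic condition (see module docstring for the three clauses)."""
    a1, a2 = autos
    _require(stats, [f"padj_{het}_vs_{a1}", f"padj_{het}_vs_{a2}", f"padj_{a1}_vs_{a2}",
                     f"trans_pct_{het}", f"te_{het}", f"te_{a1}", f"te_{a2}"])
    sig = (stats[f"padj_{het}_vs_{a1}"] < alpha) & (stats[f"padj_{het}_vs_{a2}"] < alpha)
    aux = stats[f"padj_{a1}_vs_{a2}"] > alpha
    pct = stats[f"trans_pct_{het}"] > np.percentile(stats[f"trans_pct_{het}"].dropna(), 50)
    te = (stats[f"te_{het}"] > stats[f"te_{a1}"]) & (stats[f"te_{het}"] > stats[f"te_{a2}"])
    mask = sig & aux & pct & te
    return set(stats.index[mask.fillna(False)])


def call_diff_te_autotrophic(
    stats: pd.DataFrame, het: str, autos: tuple[str, str], alpha: float = 0.01
) -> set[str]:
    """Mirror call: both autotrophic conditions differ from the heterotrophic
    one, both sit above their own 50th translation percentiles, and both
    translate above the heterotrophic level."""
    a1, a2 = autos
    _require(stats, [f"padj_{het}_vs_{a1}", f"padj_{het}_vs_{a2}",
                     f"trans_pct_{het}", f"trans_pct_{a1}", f"trans_pct_{a2}"])
    sig = (stats[f"padj_{het}_vs_{a1}"] < alpha) & (stats[f"padj_{het}_vs_{a2}"] < alpha)
    pct = (
        (stats[f"trans_pct_{a1}"] > np.percentile(stats[f"trans_pct_{a1}"].dropna(), 50))
        & (stats[f"trans_pct_{a2}"] > np.percentile(stats[f"trans_pct_{a2}"].dropna(), 50))
    )
    lvl = (stats[f"trans_pct_{a1}"] > stats[f"trans_pct_{het}"]) & (
        stats[f"trans_pct_{a2}"] > stats[f"trans_pct_{het}"]
    )
    mask = sig & pct & lvl
    return set(stats.index[mask.fillna(False)])


def _require(stats: pd.DataFrame, cols: list[str]) -> None:
    missing = [c for c in cols if c not in stats.columns]
    if missing:
        raise ValueError(f"stats table is missing columns {missing}")
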