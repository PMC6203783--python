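"""TSS calling from paired RPP-treated/untreated 5'-end coverage.

A candidate TSS is a position whose treated library reaches ``min_reads``
while the matched untreated library is zero there (the RPP treatment makes
only true triphosphorylated 5' ends ligatable, so treated-only signal marks
genuine starts and not processing products). Candidates from the configured
dataset-pairs (default eight: four conditions x two replicates) are merged
within a small window and scored 1-8 by how many pairs support them, then
categorized by genomic context:

    P (primary)   within -250..+50 of a start codon, same strand;
    I (internal)  in a CDS from +50 past the start codon to the stop, sense;
    A (antisense) overlapping any ORF on the opposite strand;
    O (orphan)    none of the above.

Precedence is P > I > A > O, so the partition is exclusive.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import GeneModel, TSSRecord

UPSTREAM_WINDOW = 250   # nt upstream of the start codon still "primary"
DOWNSTREAM_WINDOW = 50  # nt downstream of the start codon still "primary"


def detect_candidates(
    treated: np.ndarray, untreated: np.ndarray, min_reads: int = 5
) -> np.ndarray:
    """Positions (0-based) with treated >= min_reads and untreated == 0."""
    treated = np.asarray(treated)
    untreated = np.asarray(untreated)
    if treated.shape != untreated.shape:
        raise ValueError(
            f"coverage length mismatch: {treated.shape} vs {untreated.shape}"
        )
    return np.flatnonzero((treated >= min_reads) & (untreated == 0))


def score_tss(
    candidate_sets: Sequence[Mapping[str, Mapping[str, np.ndarray]]],
    merge_window: int = 3,
    n_datasets: int = 8,
) -> list[TSSRecord]:
    """Cluster per-dataset candidate positions and score by support.

    ``candidate_sets`` holds, per dataset-pair, {strand: {replicon:
    positions}}. Candidates on the same strand within ``merge_window`` nt
    are chained into one cluster; the reported position is the mode across
    supporting datasets (ties -> smallest position) and the score is the
    number of dataset-pairs contributing at least one candidate.
    """
    if len(candidate_sets) == 0:
        raise ValueError("no candidate datasets given")
    if len(candidate_sets) != n_datasets:
        raise ValueError(
            f"expected {n_datasets} dataset-pairs, got {len(candidate_sets)}"
        )

    by_key: dict[tuple[str, str], list[tuple[int, int]]] = defaultdict(list)
    for ds_idx, per_strand in enumerate(candidate_sets):
        for strand, per_rep in per_strand.items():
            for replicon, positions in per_rep.items():
                for pos in np.asarray(positions, dtype=int):
                    by_key[(replicon, strand)].append((int(pos), ds_idx))

    records: list[TSSRecord] = []
    for (replicon, strand), hits in sorted(by_key.items()):
        hits.sort()
        cluster: list[tuple[int, int]] = []
        prev = None
        for pos, ds in hits:
            if prev is not None and pos - prev > merge_window:
                records.append(_finalize_cluster(cluster, replicon, strand))
                cluster = []
            cluster.append((pos, ds))
            prev = pos
        if cluster:
            records.append(_finalize_cluster(cluster, replicon, strand))
    records.sort(key=lambda r: (r.replicon, r.position, r.strand))
    return records


def _finalize_cluster(cluster: list[tuple[int, int]], replicon: str, strand: str) -> TSSRecord:
    positions = [p for p, _ in cluster]
    datasets = sorted({d for _, d in cluster})
    counts = pd.Series(positions).value_counts()
    top = counts[counts == counts.max()].index.min()
    return TSSRecord(
        replicon=replicon,
        position=int(top),
        strand=strand,
        score=len(datasets),
        support=tuple(datasets),
    )


def categorize(records: list[TSSRecord], genes: Sequence[GeneModel]) -> list[TSSRecord]:
    """Assign P/I/A/O categories in place (precedence P > I > A > O).

    A primary TSS is associated with the gene whose start codon is nearest
    among those whose primary window contains the TSS; internal/antisense
    TSSs are associated with the overlapped gene.
    """
    for rec in records:
        rec.category, rec.gene_id = _categorize_one(rec, genes)
    return records


def _signed_offset(rec: TSSRecord, gene: GeneModel) -> int:
    """Offset of the TSS from the start codon in transcription orientation
    (negative = upstream of the start codon)."""
    if gene.strand == "+":
        return rec.position - gene.start
    return (gene.end - 1) - rec.position


def _categorize_one(rec: TSSRecord, genes: Sequence[GeneModel]) -> tuple[str, str]:
    primary: list[tuple[int, str]] = []
    internal: list[str] = []
    antisense: list[str] = []
    for gene in genes:
        if gene.replicon != rec.replicon:
            continue
        overlaps = gene.start <= rec.position < gene.end
        if gene.strand == rec.strand:
            off = _signed_offset(rec, gene)
            if -UPSTREAM_WINDOW <= off <= DOWNSTREAM_WINDOW:
                primary.append((abs(off), gene.gene_id))
            elif overlaps and off > DOWNSTREAM_WINDOW:
                internal.append(gene.gene_id)
        elif overlaps:
            antisense.append(gene.gene_id)
    if primary:
        return "P", min(primary)[1]
    if internal:
        return "I", internal[0]
    if antisense:
        return "A", antisense[0]
    return "O", ""


def assign_utr(
    records: list[TSSRecord], genes: Sequence[GeneModel], bin_width: int = 20
) -> tuple[pd.DataFrame, pd.Series, float]:
    """5'UTR lengths for primary TSSs.

    utr_length = distance from the TSS to the start codon in transcription
    orientation; TSSs at or downstream of the start codon (offset 0..+50)
    get length 0 and a leaderless-like flag. Returns (per-gene table,
    20-nt-binned histogram, median length).
    """
    by_id = {g.gene_id: g for g in genes}
    rows = []
    for rec in records:
        if rec.category != "P" or not rec.gene_id:
            continue
        gene = by_id[rec.gene_id]
        off = _signed_offset(rec, gene)
        utr = max(0, -off)
        rec.utr_length = utr
        rec.leaderless_like = off >= 0
        rows.append(
            {
                "gene_id": rec.gene_id,
                "tss_position": rec.position,
                "utr_length": utr,
                "leaderless_like": rec.leaderless_like,
            }
        )
    table = pd.DataFrame(rows, columns=["gene_id", "tss_position", "utr_length", "leaderless_like"])
    if table.empty:
        return table, pd.Series(dtype=int), float("nan")
    edges = np.arange(0, table["utr_length"].max() + bin_width + 1, bin_width)
    hist = pd.cut(table["utr_length"], bins=edges, right=False).value_counts().sort_index()
    return table, hist, float(table["utr_length"].median())


def operon_coverage(
    mean_operon_gene_content: float, n_primary_tss: int, n_genes: int
) -> float:
    """Percent of gene content covered by primary TSSs, counting operons:
    100 * mean operonic gene content * primary TSS count / gene count."""
    if n_genes <= 0:
        raise ValueError("n_genes must be > 0")
    if mean_operon_gene_content <= 0 or n_primary_tss <= 0:
        raise ValueError("inputs must be positive")
    return 100.0 * mean_operon_gene_content * n_primary_tss / n_genes


def call_tss(
    coverage_pairs: Sequence[Mapping[str, Mapping[str, Mapping[str, np.ndarray]]]],
    genes: Sequence[GeneModel],
    min_reads: int = 5,
    merge_window: int = 3,
) -> list[TSSRecord]:
    """End-to-end: detect per dataset-pair, merge/score, categorize.

    ``coverage_pairs`` holds per dataset-pair
    {'treated'|'untreated': {strand: {replicon: vector}}}.
    """
    candidate_sets = []
    for pair in coverage_pairs:
        per_strand: dict[str, dict[str, np.ndarray]] = {}
        for strand in pair["treated"]:
            per_strand[strand] = {}
            for replicon, treated in pair["treated"][strand].items():
                untreated = pair["untreated"][strand][replicon]
                per_strand[strand][replicon] = detect_candidates(
                    treated, untreated, min_reads=min_reads
                )
        candidate_sets.append(per_strand)
    records = score_tss(candidate_sets, merge_window=merge_window, n_datasets=len(candidate_sets))
    return categorize(records, genes)


def tss_catalog(records: list[TSSRecord]) -> pd.DataFrame:
    """TSV-ready catalog (1-based positions on export)."""
    return pd.DataFrame(
        [
            {
                "replicon": r.replicon,
                "position": r.position + 1,
                "strand": r.strand,
                "score": r.score,
                "category": r.category,
                "gene_id": r.gene_id,
                "utr_length": r.utr_length,
            }
            for r in records
        ],
        columns=["replicon", "position", "strand", "score", "category", "gene_id", "utr_length"],
    )
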