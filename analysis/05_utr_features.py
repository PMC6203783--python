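#!/usr/bin/env python
"""5'UTR and coding-region features versus TE.

Scans each gene's 25-nt upstream region for the strongest anti-SD duplex
(RBS), computes the RBS distance, URR AU%, CAI (reference: top decile of
Ribo-seq RPKM), coding AU%, and dG affinity bins, then compares the
features of low- vs high-TE genes with rank-sum tests.
"""

import argparse
from pathlib import Path

import pandas as pd

from teflux import io as tio
from teflux import quantify
from teflux.utr import cai_weights, compare_groups, utr_feature_table

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--quantify", type=Path, default=Path("results/quantify"))
parser.add_argument("--tss", type=Path, default=Path("results/tss"))
parser.add_argument("--out", type=Path, default=Path("results/utr"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

genome = tio.read_fasta(args.data / "genome.fasta")
genes = tio.read_gff3(args.data / "genes.gff3")
ribo = pd.read_csv(args.quantify / "rpkm_ribo.tsv", sep="\t", index_col=0)
te = pd.read_csv(args.quantify / "te.tsv", sep="\t", index_col=0)
utr_lengths = (
    pd.read_csv(args.tss / "utr_lengths.tsv", sep="\t")
    .drop_duplicates("gene_id").set_index("gene_id")["utr_length"]
)

mean_ribo = ribo.mean(axis=1)
ref_ids = mean_ribo[mean_ribo >= mean_ribo.quantile(0.9)].index
by_id = {g.gene_id: g for g in genes}
weights = cai_weights([by_id[g].cds_sequence(genome) for g in ref_ids])
features = utr_feature_table(genes, genome, utr_lengths, weights)
tio.write_tsv(features, args.out / "utr_features.tsv")

# low/high-TE comparison per condition, pooled over conditions for brevity
pooled_te = te.mean(axis=1).dropna()
lo = pooled_te[pooled_te < pooled_te.quantile(0.2)].index
hi = pooled_te[pooled_te > pooled_te.quantile(0.8)].index
report = {}
for feat in ("delta_g", "urr_au", "cai", "coding_au", "rbs_distance_5p"):
    a = features.loc[features.index.intersection(hi), feat].dropna()
    b = features.loc[features.index.intersection(lo), feat].dropna()
    stat, p = compare_groups(a, b, test="rank_sum")
    report[feat] = {"high_median": float(a.median()), "low_median": float(b.median()),
                    "ranksum_p": float(p)}
    print(f"{feat:16s} high {a.median():8.2f}  low {b.median():8.2f}  p={p:.2e}")
tio.write_json(report, args.out / "group_comparisons.json")
print(f"wrote {args.out}/")
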