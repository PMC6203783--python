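#!/usr/bin/env python
"""Call, score and categorize TSSs; assign 5'UTRs; operon coverage.

Candidates are positions with >= 5 reads in an RPP-treated library and
zero in the matched untreated library; candidates within 3 nt merge, the
score (1-8) counts supporting dataset-pairs, and categories follow the
P > I > A > O precedence. Operon coverage uses the dataset's own mean
operonic gene content.
"""

import argparse
from pathlib import Path

import pandas as pd

from teflux import io as tio
from teflux.tss import assign_utr, call_tss, operon_coverage, tss_catalog

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--out", type=Path, default=Path("results/tss"))
parser.add_argument("--n-datasets", type=int, default=8)
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

genome = tio.read_fasta(args.data / "genome.fasta")
genes = tio.read_gff3(args.data / "genes.gff3")
lengths = {k: len(v) for k, v in genome.items()}
pairs = []
for d in range(1, args.n_datasets + 1):
    pair = {"treated": {}, "untreated": {}}
    for treatment in ("treated", "untreated"):
        for strand, tag in (("+", "fwd"), ("-", "rev")):
            path = args.data / "tss_coverage" / f"ds{d}_{treatment}_{tag}.bedGraph"
            pair[treatment][strand] = tio.read_bedgraph(path, lengths)
    pairs.append(pair)

records = call_tss(pairs, genes, min_reads=5, merge_window=3)
utr_table, hist, median_utr = assign_utr(records, genes)
catalog = tss_catalog(records)
tio.write_tsv(catalog, args.out / "tss_catalog.tsv", index=False)
tio.write_tsv(utr_table, args.out / "utr_lengths.tsv", index=False)

operons = pd.read_csv(args.data / "operons.tsv", sep="\t")
mean_content = operons.groupby("operon_id").size().mean()
n_primary = int((catalog["category"] == "P").sum())
cov = operon_coverage(mean_content, n_primary, len(genes))

print(f"{len(records)} TSSs:", catalog["category"].value_counts().to_dict())
print(f"median 5'UTR {median_utr:.0f} nt; most frequent bin {hist.idxmax()}")
print(f"operon coverage: {cov:.1f}% "
      f"(mean operonic content {mean_content:.2f}, {n_primary} primary TSSs)")
print(f"wrote {args.out}/")
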