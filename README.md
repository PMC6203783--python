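# teflux

Condition-dependent translational-efficiency analysis for bacteria, built
around the multi-omics design used to study resource allocation in
acetogens grown autotrophically (CO or H₂:CO₂) versus heterotrophically
(fructose): paired RNA-seq and Ribo-seq count tables, plus RPP-differential
TSS-seq coverage, analyzed from normalization through 5′UTR feature
statistics. A synthetic-data generator plants recoverable ground truth for
every stage, so the whole pipeline runs and validates with no downloads.

## What it computes

* **Translational efficiency (TE)** per gene and condition:
  `TE = Ribo-seq RPKM / RNA-seq FPKM`, with
  `RPKM = count × 10⁹ / (gene length × library size)`, replicate-mean
  combination, eligibility criteria (nonzero in every replicate of both
  assays), replicate correlations, and the <20th / >80th percentile TE sets.
* **Subsystem resource allocation**: expression summed per functional
  subsystem, percent-normalized per experiment; subsystem TE = percent
  translation / percent transcription; differential translation via a
  self-implemented negative-binomial GLM Wald test (median-of-ratios size
  factors, trended dispersion, BH correction); three-clause heterotrophic
  and autotrophic differential-TE calls.
* **TSS calling**: candidates where an RPP-treated library has ≥ 5 reads
  and the matched untreated library has none; clustering within 3 nt;
  scores 1–8 over the eight dataset-pairs; P/I/A/O categorization
  (primary −250..+50 of a start codon; internal; antisense; orphan) with
  precedence P > I > A > O; 5′UTR lengths and operon coverage
  `100 × mean operonic gene content × primary TSSs / genes`.
* **5′UTR / coding features**: RBS located as the 10-nt window of the
  25-nt upstream region with the most negative hybridization ΔG against
  the anti-Shine–Dalgarno octamer `AAGGAGGU` (built-in Turner 2004
  nearest-neighbor RNA:RNA duplex model; ViennaRNA adapter for
  cross-checks); RBS distance (modal 13 nt); AU% of the 15-nt upstream RBS
  region (URR) gated on TSS position; CAI; coding AU%; 11 ΔG bins over
  [0, −12.7]; rank-sum / signed-rank group comparisons.
* **TE_max versus mRNA level**: max TE across conditions, filters
  0.01 < TE < 5 and FPKM > 10, quartiles, ten mRNA-level bins, per-quartile
  log2-TE trend regressions with Wald tests, high-vs-low slope-difference
  test, and Fisher-exact category enrichment per quartile.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (each step writes its tables under `results/`):

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_quantify.py
python analysis/03_subsystems.py
python analysis/04_tss.py
python analysis/05_utr_features.py
python analysis/06_temax_trend.py
```

With seed 1 this prints, among other things:

```
differential-TE (heterotrophic): ['SS001', 'SS002']
differential-TE (autotrophic):  ['SS005', 'SS006']
```

— the generator planted translational upregulation in SS001–SS003 under
fructose and SS004–SS006 under both autotrophic conditions, and the
three-clause calls recover most of the plant at this sequencing depth;

```
delta_g          high   -11.60  low    -6.80  p=1.91e-17
urr_au           high    93.33  low    46.67  p=2.67e-23
```

— genes planted with a perfect Shine–Dalgarno complement and an AU-rich
URR (true TE 3.0) separate decisively from suboptimal genes (TE 0.3) in
the estimated-TE comparison; and

```
planted-pattern check: high slope +0.194 [+0.183,+0.205],
low slope -0.234 [-0.245,-0.222], difference p=6.16e-102
```

— optimized mRNAs show TE rising with mRNA level while suboptimized
mRNAs fall, with the slope difference decisive.

The same stages are exposed as a CLI (`teflux simulate|quantify|tss|utr|
temax|all`) for running on real count tables and coverage files.

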