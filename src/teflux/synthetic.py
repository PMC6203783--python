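"""Synthetic dataset generator with planted ground truth.

Emulates the statistical structure of a bacterial multi-omics experiment in
an AT-rich acetogen grown under three conditions (two autotrophic, one
heterotrophic):

* a low-GC genome (default 31.1% GC) carrying non-overlapping genes, each
  with a 5'UTR whose ribosome-binding site (RBS), RBS distance and upstream
  AU content are planted per gene;
* negative-binomial RNA-seq counts (mean proportional to gene length x
  expression x depth) and Ribo-seq counts (RNA mean x planted true TE), two
  replicates per condition;
* strand-specific 5'-end coverage for paired RPP-treated/untreated TSS-seq
  libraries (default eight pairs: four conditions x two replicates), with
  signal pileups only at planted TSSs in the treated libraries.

Every planted quantity is recorded in ``SyntheticDataset.truth`` so each
downstream stage can be validated against construction.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as tio
from .models import GeneModel, revcomp

ASD_RNA = "AAGGAGGU"
#: DNA complement of the anti-SD octamer (a perfect Shine-Dalgarno site)
OPTIMAL_RBS = "ACCTCCTT"
#: 4-nt core (complement of the GGAG core) for weak sites
WEAK_RBS_CORE = "CTCC"

RBS_QUALITIES = ("optimal", "weak", "absent")

# default planted TE by RBS quality: optimized 5'UTRs translate efficiently
DEFAULT_TE_BY_QUALITY = {"optimal": 3.0, "weak": 1.0, "absent": 0.3}
# default planted URR AU fraction by RBS quality (genome background ~0.69 AU)
DEFAULT_URR_AU_BY_QUALITY = {"optimal": 0.95, "weak": 0.70, "absent": 0.45}

SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


@dataclass
class SyntheticSpec:
    """Parameters of the planted experiment.

    ``dispersion`` is the NB dispersion alpha with variance = mu + alpha mu^2
    (alpha = 0 is Poisson); ``depth`` is the expected library size per
    library. ``rbs_distance`` is the distance from the RBS 5' end to the
    start codon (the organism's validated modal distance, 13 nt).
    """

    n_genes: int = 300
    genome_gc: float = 0.311
    genome_length: int | None = None
    utr_length_range: tuple[int, int] = (45, 65)
    cds_length_range: tuple[int, int] = (300, 900)
    intergenic_range: tuple[int, int] = (60, 140)
    operon_sizes: Sequence[int] = (1,)
    strands: str | Sequence[str] = "random"
    conditions: Sequence[str] = ("CO", "H2CO2", "fructose")
    n_replicates: int = 2
    rbs_quality: Sequence[str] | None = None
    rbs_distance: int = 13
    urr_au: float | Sequence[float] | None = None
    true_te: Sequence[float] | None = None
    center_te: bool = True
    condition_effects: np.ndarray | None = None  # (n_genes, n_conditions) log2FC on mRNA
    translation_effects: np.ndarray | None = None  # log2FC on Ribo only (condition-specific TE)
    base_expression: Sequence[float] | None = None
    dispersion: float = 0.1
    depth: float = 1e6
    n_tss_datasets: int = 8
    tss_support: Sequence[int] | int = 8
    tss_signal: int = 50
    tss_noise_rate: float = 0.0
    replicon_name: str = "chr"
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if not (0.0 <= self.genome_gc <= 1.0):
            raise ValueError("genome_gc must lie in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        for name in ("utr_length_range", "cds_length_range", "intergenic_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"{name} must be a non-negative interval, got ({lo}, {hi})")
        if self.utr_length_range[0] < self.rbs_distance:
            raise ValueError(
                f"UTRs of length {self.utr_length_range[0]} cannot hold an RBS at "
                f"distance {self.rbs_distance}"
            )
        if self.n_tss_datasets < 1:
            raise ValueError("need at least one TSS dataset pair")


@dataclass
class SyntheticDataset:
    """A generated genome + annotation + (optionally) counts and coverage."""

    spec: SyntheticSpec
    genome: dict[str, str]
    genes: list[GeneModel]
    subsystem_map: pd.DataFrame
    operons: pd.DataFrame
    truth: pd.DataFrame  # indexed by gene_id
    tss_truth: list[dict]
    counts: pd.DataFrame | None = None
    library_sizes: pd.Series | None = None
    tss_coverage: list[dict] | None = None

    @property
    def gene_lengths(self) -> pd.Series:
        return pd.Series({g.gene_id: g.length for g in self.genes}, name="length")


# ------------------------------------------------------------------ genome


def build_genome(spec: SyntheticSpec) -> SyntheticDataset:
    """Lay out genes with planted 5'UTR features on a background genome.

    Genes are packed left to right with random intergenic spacers, so they
    never overlap. Each gene gets a planted TSS at the 5'UTR start, an RBS
    of the requested quality at the requested distance, and (when the UTR is
    long enough) a 15-nt URR of the requested AU fraction immediately 5' of
    the RBS window.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes

    qualities = _resolve_qualities(spec, rng)
    urr_au = _resolve_urr_au(spec, qualities)
    strands = _resolve_strands(spec, rng)
    operon_ids = _assign_operons(spec, n)

    parts: list[str] = []
    cursor = 0
    genes: list[GeneModel] = []
    rows: list[dict] = []
    tss_truth: list[dict] = []
    rep = spec.replicon_name

    for i in range(n):
        gid = f"g{i + 1:04d}"
        spacer = int(rng.integers(spec.intergenic_range[0], spec.intergenic_range[1] + 1))
        utr_len = int(rng.integers(spec.utr_length_range[0], spec.utr_length_range[1] + 1))
        cds_len = int(rng.integers(spec.cds_length_range[0] // 3, spec.cds_length_range[1] // 3 + 1)) * 3
        strand = strands[i]

        utr = _build_utr(utr_len, qualities[i], spec.rbs_distance, urr_au[i], spec.genome_gc, rng)
        cds = _build_cds(cds_len, spec.genome_gc, rng)
        pad = _background(spacer, spec.genome_gc, rng)

        if strand == "+":
            parts.extend([pad, utr, cds])
            utr_start = cursor + spacer
            cds_start = utr_start + utr_len
            cds_end = cds_start + cds_len
            tss_pos = utr_start
            cursor = cds_end
        else:
            parts.extend([pad, revcomp(cds), revcomp(utr)])
            cds_start = cursor + spacer
            cds_end = cds_start + cds_len
            tss_pos = cds_end + utr_len - 1
            cursor = cds_end + utr_len

        genes.append(GeneModel(gene_id=gid, replicon=rep, start=cds_start, end=cds_end, strand=strand))
        rows.append(
            {
                "gene_id": gid,
                "strand": strand,
                "utr_length": utr_len,
                "rbs_quality": qualities[i],
                "rbs_distance": spec.rbs_distance,
                "urr_au": urr_au[i],
                "tss_pos": tss_pos,
                "operon_id": operon_ids[i],
            }
        )
        tss_truth.append({"replicon": rep, "position": tss_pos, "strand": strand, "gene_id": gid})

    tail = int(rng.integers(spec.intergenic_range[0], spec.intergenic_range[1] + 1))
    parts.append(_background(tail, spec.genome_gc, rng))
    sequence = "".join(parts)

    if spec.genome_length is not None:
        if len(sequence) > spec.genome_length:
            raise ValueError(
                f"genes + UTRs + spacers need {len(sequence)} nt, more than the "
                f"requested genome length {spec.genome_length}"
            )
        sequence += _background(spec.genome_length - len(sequence), spec.genome_gc, rng)

    truth = pd.DataFrame(rows).set_index("gene_id") if rows else pd.DataFrame(
        columns=["strand", "utr_length", "rbs_quality", "rbs_distance", "urr_au", "tss_pos", "operon_id"]
    )
    subsystem_map = _build_subsystem_map(genes, qualities)
    operons = pd.DataFrame(
        {"gene_id": [g.gene_id for g in genes], "operon_id": operon_ids}
    )
    return SyntheticDataset(
        spec=spec,
        genome={rep: sequence},
        genes=genes,
        subsystem_map=subsystem_map,
        operons=operons,
        truth=truth,
        tss_truth=tss_truth,
    )


def _resolve_qualities(spec: SyntheticSpec, rng: np.random.Generator) -> list[str]:
    if spec.rbs_quality is not None:
        qualities = list(spec.rbs_quality)
        if len(qualities) != spec.n_genes:
            raise ValueError("rbs_quality must have one entry per gene")
        bad = set(qualities) - set(RBS_QUALITIES)
        if bad:
            raise ValueError(f"unknown rbs_quality values: {sorted(bad)}")
        return qualities
    return [RBS_QUALITIES[i % 3] for i in range(spec.n_genes)]


def _resolve_urr_au(spec: SyntheticSpec, qualities: list[str]) -> list[float]:
    if spec.urr_au is None:
        return [DEFAULT_URR_AU_BY_QUALITY[q] for q in qualities]
    if np.isscalar(spec.urr_au):
        return [float(spec.urr_au)] * spec.n_genes
    vals = [float(v) for v in spec.urr_au]
    if len(vals) != spec.n_genes:
        raise ValueError("urr_au must be scalar or one value per gene")
    return vals


def _resolve_strands(spec: SyntheticSpec, rng: np.random.Generator) -> list[str]:
    if spec.strands == "random":
        return [("+", "-")[i] for i in rng.integers(0, 2, size=spec.n_genes)]
    if spec.strands in ("+", "-"):
        return [spec.strands] * spec.n_genes
    strands = list(spec.strands)
    if len(strands) != spec.n_genes:
        raise ValueError("strands must be '+', '-', 'random', or one value per gene")
    return strands


def _assign_operons(spec: SyntheticSpec, n: int) -> list[int]:
    sizes = list(spec.operon_sizes) or [1]
    ids: list[int] = []
    op = 0
    while len(ids) < n:
        size = sizes[op % len(sizes)]
        ids.extend([op] * size)
        op += 1
    return ids[:n]


def _background(n: int, gc: float, rng: np.random.Generator) -> str:
    if n <= 0:
        return ""
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=probs)])


def _au_controlled(n: int, au: float, rng: np.random.Generator) -> str:
    """Sequence with an exact A+T count of round(au * n)."""
    n_au = int(round(au * n))
    chars = list(rng.choice(["A", "T"], size=n_au)) + list(rng.choice(["G", "C"], size=n - n_au))
    rng.shuffle(chars)
    return "".join(chars)


def _build_utr(utr_len: int, quality: str, distance: int, urr_au: float,
               gc: float, rng: np.random.Generator) -> str:
    """Coding-strand 5'UTR with the RBS and URR planted at fixed offsets.

    Upstream position p (1-based, counted from the start codon) maps to
    string index utr_len - p. The RBS octamer occupies positions
    distance..distance-7; the URR is the 15 nt immediately 5' of the 10-nt
    window whose 5' end sits at ``distance`` (positions distance+15+2 ..
    distance+3 relative to the window layout used by the scanner).
    """
    seq = list(_background(utr_len, gc, rng))

    def put(pos_from_start: int, s: str) -> None:
        # place s so that its 5' end is at upstream position pos_from_start
        idx = utr_len - pos_from_start
        if idx < 0 or idx + len(s) > utr_len:
            return
        seq[idx : idx + len(s)] = list(s)

    # the reported RBS is the best-scoring 10-nt window; planting the
    # octamer one base inside the window whose 5' end sits at ``distance``
    # gives that window both flanking (dangling-end) bases, making it the
    # unique energy optimum, so the scanner reports exactly ``distance``
    if quality == "optimal":
        put(distance - 1, OPTIMAL_RBS)
    elif quality == "weak":
        put(distance - 2, WEAK_RBS_CORE)
    else:
        # shuffled octamer: same composition, no SD complementarity planted
        shuffled = list(OPTIMAL_RBS)
        rng.shuffle(shuffled)
        put(distance - 1, "".join(shuffled))

    # URR: 15 nt immediately 5' of the scanning window [distance .. distance-9]
    urr_5p = distance + 15
    if urr_5p <= utr_len:
        put(urr_5p, _au_controlled(15, urr_au, rng))
    return "".join(seq)


def _build_cds(cds_len: int, gc: float, rng: np.random.Generator) -> str:
    """ATG + random sense codons + TAA; codon choice weighted toward the
    background GC so coding AU tracks the genome composition."""
    n_codons = cds_len // 3 - 2
    weights = np.array([_codon_weight(c, gc) for c in SENSE_CODONS])
    weights = weights / weights.sum()
    body = rng.choice(len(SENSE_CODONS), size=n_codons, p=weights)
    return "ATG" + "".join(SENSE_CODONS[i] for i in body) + "TAA"


def _codon_weight(codon: str, gc: float) -> float:
    w = 1.0
    for ch in codon:
        w *= gc / 2 if ch in "GC" else (1 - gc) / 2
    return w


def _build_subsystem_map(genes: list[GeneModel], qualities: list[str]) -> pd.DataFrame:
    """Cycle genes through a small set of subsystems; the functional category
    tracks RBS quality so enrichment analyses have a planted signal
    (optimized genes -> energy metabolism, suboptimized -> regulation)."""
    cat_by_quality = {
        "optimal": "Respiration",
        "weak": "Protein Metabolism",
        "absent": "Regulation and Dormancy",
    }
    rows = []
    n_subsystems = max(3, len(genes) // 10)
    for i, g in enumerate(genes):
        rows.append(
            {
                "gene_id": g.gene_id,
                "subsystem": f"SS{(i % n_subsystems) + 1:03d}",
                "category": cat_by_quality[qualities[i]],
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "subsystem", "category"])


# ------------------------------------------------------------------ counts


def simulate_counts(dataset: SyntheticDataset, spec: SyntheticSpec | None = None) -> pd.DataFrame:
    """Draw NB RNA-seq and Ribo-seq counts for every condition x replicate.

    RNA mean is proportional to gene length x expression x depth (normalized
    per condition so the expected RNA library size equals ``depth``); the
    Ribo mean is the RNA mean times the planted true TE. Replicates share
    means. With ``center_te`` the planted TE values are rescaled once by the
    expression-weighted mean so that the two assays have comparable library
    sizes and the RPKM/FPKM ratio recovers the stored truth without a global
    scale factor (TE is a relative quantity; the rescaled values are what
    ``truth['true_te']`` records).
    """
    spec = spec or dataset.spec
    rng = np.random.default_rng(spec.seed + 1)
    n = len(dataset.genes)
    if n == 0:
        raise ValueError("dataset has no genes")

    lengths = dataset.gene_lengths.to_numpy(dtype=float)
    expr = _resolve_base_expression(spec, n, rng)
    te_raw = _resolve_true_te(spec, dataset, n)

    n_cond = len(spec.conditions)
    lfc = spec.condition_effects
    if lfc is None:
        lfc = np.zeros((n, n_cond))
    lfc = np.asarray(lfc, dtype=float)
    if lfc.shape != (n, n_cond):
        raise ValueError(f"condition_effects must have shape ({n}, {n_cond})")

    # per-condition relative transcript abundance
    weight = lengths[:, None] * expr[:, None] * np.exp2(lfc)  # (n, n_cond)
    rna_mean = spec.depth * weight / weight.sum(axis=0, keepdims=True)

    if spec.center_te:
        w = weight.mean(axis=1)
        te = te_raw * (w.sum() / float(w @ te_raw))
    else:
        te = te_raw.copy()
    tlfc = spec.translation_effects
    if tlfc is None:
        tlfc = np.zeros((n, n_cond))
    tlfc = np.asarray(tlfc, dtype=float)
    if tlfc.shape != (n, n_cond):
        raise ValueError(f"translation_effects must have shape ({n}, {n_cond})")
    ribo_mean = rna_mean * te[:, None] * np.exp2(tlfc)

    cols: dict[str, np.ndarray] = {}
    for assay, means in (("rna", rna_mean), ("ribo", ribo_mean)):
        for c, cond in enumerate(spec.conditions):
            for r in range(1, spec.n_replicates + 1):
                cols[f"{assay}_{cond}_{r}"] = _nb_draw(means[:, c], spec.dispersion, rng)

    counts = pd.DataFrame(cols, index=[g.gene_id for g in dataset.genes])
    dataset.counts = counts
    dataset.library_sizes = counts.sum(axis=0)
    dataset.truth["base_expression"] = expr
    dataset.truth["true_te"] = te
    return counts


def _resolve_base_expression(spec: SyntheticSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    if spec.base_expression is not None:
        expr = np.asarray(spec.base_expression, dtype=float)
        if expr.shape != (n,):
            raise ValueError("base_expression must have one value per gene")
        return expr
    return rng.lognormal(mean=0.0, sigma=1.0, size=n)


def _resolve_true_te(spec: SyntheticSpec, dataset: SyntheticDataset, n: int) -> np.ndarray:
    if spec.true_te is not None:
        te = np.asarray(spec.true_te, dtype=float)
        if te.shape != (n,):
            raise ValueError("true_te must have one value per gene")
    else:
        te = np.array([DEFAULT_TE_BY_QUALITY[q] for q in dataset.truth["rbs_quality"]])
    if (te <= 0).any():
        raise ValueError("true_te must be positive")
    return te


def _nb_draw(mean: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape=shape, scale=mean * dispersion)
    return rng.poisson(lam)


# ------------------------------------------------------------------ TSS coverage


def simulate_tss_coverage(dataset: SyntheticDataset, spec: SyntheticSpec | None = None) -> list[dict]:
    """Generate paired RPP-treated/untreated strand-specific 5'-end coverage.

    Each planted TSS receives ``tss_signal`` reads in the treated library of
    the dataset-pairs that support it (a seeded random subset of size
    ``tss_support``); untreated libraries carry only low-rate background
    noise placed at least 5 nt away from every planted TSS, so the planted
    truth stays recoverable by the treated-only detection rule.
    """
    spec = spec or dataset.spec
    rng = np.random.default_rng(spec.seed + 2)
    rep = spec.replicon_name
    L = len(dataset.genome[rep])
    n_ds = spec.n_tss_datasets

    supports = spec.tss_support
    if np.isscalar(supports):
        supports = [int(supports)] * len(dataset.tss_truth)
    supports = [int(s) for s in supports]
    if len(supports) != len(dataset.tss_truth):
        raise ValueError("tss_support must be scalar or one value per planted TSS")
    for s in supports:
        if not (1 <= s <= n_ds):
            raise ValueError(f"tss_support must lie in 1..{n_ds}")

    support_sets = []
    for s in supports:
        support_sets.append(tuple(sorted(rng.choice(n_ds, size=s, replace=False))))
    for t, ss in zip(dataset.tss_truth, support_sets):
        t["support"] = ss

    # mask of positions within 5 nt of any planted TSS (per strand)
    forbidden = {"+": np.zeros(L, dtype=bool), "-": np.zeros(L, dtype=bool)}
    for t in dataset.tss_truth:
        lo = max(0, t["position"] - 5)
        hi = min(L, t["position"] + 6)
        forbidden[t["strand"]][lo:hi] = True

    coverage: list[dict] = []
    for d in range(n_ds):
        pair = {"treated": {}, "untreated": {}}
        for treatment in ("treated", "untreated"):
            for strand in ("+", "-"):
                vec = np.zeros(L)
                if spec.tss_noise_rate > 0:
                    n_noise = rng.binomial(L, spec.tss_noise_rate)
                    if n_noise:
                        pos = rng.integers(0, L, size=n_noise)
                        keep = ~forbidden[strand][pos]
                        vals = rng.integers(1, 4, size=n_noise)
                        np.add.at(vec, pos[keep], vals[keep])
                pair[treatment][strand] = {rep: vec}
        for t, ss in zip(dataset.tss_truth, support_sets):
            if d in ss:
                pair["treated"][t["strand"]][rep][t["position"]] += spec.tss_signal
        coverage.append(pair)

    dataset.tss_coverage = coverage
    return coverage


# ------------------------------------------------------------------ writers


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict:
    """Write the dataset in its interchange formats and return the manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    tio.write_fasta(dataset.genome, out / "genome.fasta")
    tio.write_gff3(dataset.genes, out / "genes.gff3")
    tio.write_tsv(dataset.subsystem_map, out / "subsystem_map.tsv", index=False)
    tio.write_tsv(dataset.operons, out / "operons.tsv", index=False)
    tio.write_tsv(dataset.truth, out / "truth.tsv")
    if dataset.counts is not None:
        tio.write_tsv(dataset.counts, out / "counts.tsv")
    if dataset.tss_coverage is not None:
        covdir = out / "tss_coverage"
        covdir.mkdir(exist_ok=True)
        for d, pair in enumerate(dataset.tss_coverage):
            for treatment in ("treated", "untreated"):
                for strand, tag in (("+", "fwd"), ("-", "rev")):
                    tio.write_bedgraph(
                        pair[treatment][strand],
                        covdir / f"ds{d + 1}_{treatment}_{tag}.bedGraph",
                    )
    manifest = {
        "seed": dataset.spec.seed,
        "spec": _spec_echo(dataset.spec),
        "n_genes": len(dataset.genes),
        "genome_length": {k: len(v) for k, v in dataset.genome.items()},
        "library_sizes": (
            dataset.library_sizes.to_dict() if dataset.library_sizes is not None else None
        ),
        "n_planted_tss": len(dataset.tss_truth),
    }
    tio.write_json(manifest, out / "manifest.json")
    return manifest


def _spec_echo(spec: SyntheticSpec) -> dict:
    echo = {}
    for key, value in asdict(spec).items():
        if isinstance(value, np.ndarray):
            value = value.tolist()
        elif isinstance(value, tuple):
            value = list(value)
        echo[key] = value if _json_ok(value) else str(value)
    return echo


def _json_ok(value) -> bool:
    if isinstance(value, (str, int, float, bool)) or value is None:
        return True
    if isinstance(value, (list, tuple)):
        return all(_json_ok(v) for v in value)
    return False


def plant_te_trend(
    n_per_group: int = 80,
    slope: float = 0.8,
    noise_sd: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Plant the expression-dependent TE pattern of optimized vs
    suboptimized mRNAs.

    Four TE_max bands (low 0.02-0.1, medium-low 0.1-0.45, medium-high
    0.55-1.45, high 1.55-4.9) with ``n_per_group`` genes each; within the
    high band log2 TE rises with standardized log2 mRNA level at ``slope``
    per unit, within the low band it falls at ``-slope``, and the middle
    bands are flat. FPKM is lognormal above the analysis floor. Returns a
    frame with te_max, fpkm and the planted group label.
    """
    rng = np.random.default_rng(seed)
    bands = {
        "low": (0.02, 0.10, -slope),
        "medium-low": (0.10, 0.45, 0.0),
        "medium-high": (0.55, 1.45, 0.0),
        "high": (1.55, 4.90, slope),
    }
    rows = []
    for group, (lo, hi, s) in bands.items():
        log_fpkm = rng.normal(6.0, 1.5, size=n_per_group)
        z = (log_fpkm - 6.0) / 1.5  # standardized mRNA level
        center = np.sqrt(lo * hi)
        half_span = 0.5 * np.log2(hi / lo)
        log2_te = np.log2(center) + np.clip(
            s * z + rng.normal(0, noise_sd, n_per_group), -half_span * 0.95, half_span * 0.95
        )
        for lf, lt in zip(log_fpkm, log2_te):
            rows.append(
                {"group": group, "fpkm": float(np.exp2(lf) + FPKM_FLOOR), "te_max": float(np.exp2(lt))}
            )
    df = pd.DataFrame(rows)
    df.index = [f"t{i:04d}" for i in range(len(df))]
    return df


FPKM_FLOOR = 10.5  # keep planted genes above the mRNA-level analysis filter


def make_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Convenience: genome + counts + TSS coverage in one call."""
    ds = build_genome(spec)
    simulate_counts(ds, spec)
    simulate_tss_coverage(ds, spec)
    return ds
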