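"""End-to-end pipeline: simulate -> quantify -> subsystems -> tss -> utr -> temax.

A single :class:`PipelineConfig` carries every path, design role and
threshold; ``run_all`` executes the stages in order, writes each stage's
tables under the output directory, and finishes with a manifest recording
the seed, the thresholds actually applied, and per-stage row counts. All
randomness flows from the one config seed.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from . import quantify, subsystems, temax, tss, utr
from .synthetic import SyntheticSpec, make_dataset, write_dataset


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    outdir: str = "teflux_out"
    seed: int = 0
    # input mode: simulate everything, or read the listed files
    simulate: bool = True
    n_genes: int = 300
    dispersion: float = 0.1
    depth: float = 1e6
    tss_noise_rate: float = 0.002
    genome: str | None = None
    gff: str | None = None
    counts: str | None = None
    subsystem_map: str | None = None
    # design roles
    het_condition: str = "fructose"
    auto_conditions: tuple[str, str] = ("CO", "H2CO2")
    # thresholds
    min_reads: int = 5
    merge_window: int = 3
    low_pct: float = 20.0
    high_pct: float = 80.0
    alpha_gene: float = 0.001
    alpha_subsystem: float = 0.01

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.auto_conditions, list):
            cfg.auto_conditions = tuple(cfg.auto_conditions)
        return cfg

    def validate(self) -> None:
        if not self.simulate:
            for name in ("genome", "gff", "counts", "subsystem_map"):
                value = getattr(self, name)
                if value is None:
                    raise PipelineError("config", f"field {name!r} is required when simulate=false")
                if not Path(value).exists():
                    raise PipelineError("config", f"field {name!r}: file not found: {value}")


def run_all(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written to disk)."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "stages": {},
    }

    def stage_done(name: str, **info) -> None:
        manifest["stages"][name] = {"status": "ok", **info}

    t0 = time.time()
    # ---- stage 1: inputs -------------------------------------------------
    if config.simulate:
        spec = SyntheticSpec(
            n_genes=config.n_genes,
            dispersion=config.dispersion,
            depth=config.depth,
            tss_noise_rate=config.tss_noise_rate,
            conditions=(config.het_condition, *config.auto_conditions),
            seed=config.seed,
        )
        ds = make_dataset(spec)
        write_dataset(ds, out / "data")
        genes, genome = ds.genes, ds.genome
        counts, submap = ds.counts, ds.subsystem_map
        coverage = ds.tss_coverage
        stage_done("simulate", n_genes=len(genes), n_libraries=counts.shape[1])
    else:
        genome = tio.read_fasta(config.genome)
        genes = tio.read_gff3(config.gff)
        counts = tio.read_counts(config.counts)
        submap = tio.read_subsystem_map(config.subsystem_map)
        coverage = None
        stage_done("load", n_genes=len(genes), n_libraries=counts.shape[1])

    lengths = pd.Series({g.gene_id: g.length for g in genes})
    rna_cols = [c for c in counts.columns if c.startswith("rna_")]
    ribo_cols = [c for c in counts.columns if c.startswith("ribo_")]
    if not rna_cols or not ribo_cols:
        raise PipelineError("quantify", "counts must contain rna_* and ribo_* libraries")

    # ---- stage 2: quantify ----------------------------------------------
    try:
        rna = quantify.normalize_per_kb_per_million(counts[rna_cols], lengths)
        ribo = quantify.normalize_per_kb_per_million(counts[ribo_cols], lengths)
        tetab = quantify.compute_te(ribo, rna)
        quantify.te_percentile_sets(tetab, config.low_pct, config.high_pct)
        corr = {
            f"{assay}_{method}": quantify.replicate_correlation(mat, method=method).to_dict()
            for assay, mat in (("rna", rna), ("ribo", ribo))
            for method in ("pearson", "spearman")
        }
        tio.write_tsv(tetab.te, out / "te.tsv")
        tio.write_tsv(rna.values, out / "fpkm_rna.tsv")
        tio.write_tsv(ribo.values, out / "rpkm_ribo.tsv")
        tio.write_json(corr, out / "replicate_correlations.json")
        stage_done("quantify", n_genes=len(tetab.te), conditions=list(tetab.te.columns))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("quantify", str(exc)) from exc

    # ---- stage 3: subsystems --------------------------------------------
    try:
        condition = pd.Series({c: quantify.condition_of(c) for c in counts.columns})
        expr_all = pd.concat([ribo.values, rna.values], axis=1)
        sub = subsystems.aggregate_to_subsystems(expr_all, submap)
        subsystems.percent_normalize(sub)
        stats_tab = subsystems.build_subsystem_stats(
            counts[ribo_cols], condition, sub, config.het_condition, config.auto_conditions, submap
        )
        het_set = subsystems.call_diff_te_heterotrophic(
            stats_tab, config.het_condition, config.auto_conditions, config.alpha_subsystem
        )
        auto_set = subsystems.call_diff_te_autotrophic(
            stats_tab, config.het_condition, config.auto_conditions, config.alpha_subsystem
        )
        tio.write_tsv(stats_tab, out / "subsystem_stats.tsv")
        tio.write_json(
            {"heterotrophic": sorted(het_set), "autotrophic": sorted(auto_set)},
            out / "diff_te_calls.json",
        )
        stage_done("subsystems", n_subsystems=len(stats_tab),
                   n_het=len(het_set), n_auto=len(auto_set))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("subsystems", str(exc)) from exc

    # ---- stage 4: tss ----------------------------------------------------
    utr_lengths = None
    if coverage is not None:
        try:
            records = tss.call_tss(coverage, genes, config.min_reads, config.merge_window)
            catalog = tss.tss_catalog(records)
            utr_table, _hist, median_utr = tss.assign_utr(records, genes)
            catalog = tss.tss_catalog(records)  # utr_length now filled
            tio.write_tsv(catalog, out / "tss_catalog.tsv", index=False)
            bed = pd.DataFrame(
                {
                    "replicon": [r.replicon for r in records],
                    "start": [r.position for r in records],
                    "end": [r.position + 1 for r in records],
                    "name": [f"TSS_{r.category}_{i}" for i, r in enumerate(records)],
                    "score": [r.score for r in records],
                    "strand": [r.strand for r in records],
                }
            )
            tio.write_bed6(bed, out / "tss.bed")
            utr_lengths = utr_table.set_index("gene_id")["utr_length"]
            counts_by_cat = catalog["category"].value_counts().to_dict()
            stage_done("tss", n_tss=len(records), by_category=counts_by_cat,
                       median_utr=median_utr)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("tss", str(exc)) from exc
    else:
        manifest["stages"]["tss"] = {"status": "skipped", "reason": "no coverage input"}

    # ---- stage 5: utr features ------------------------------------------
    try:
        # CAI reference: top decile of mean Ribo RPKM
        mean_ribo = ribo.values.mean(axis=1)
        ref_ids = mean_ribo[mean_ribo >= mean_ribo.quantile(0.9)].index
        by_id = {g.gene_id: g for g in genes}
        ref_cds = [by_id[g].cds_sequence(genome) for g in ref_ids if g in by_id]
        weights = utr.cai_weights(ref_cds)
        features = utr.utr_feature_table(genes, genome, utr_lengths, weights)
        tio.write_tsv(features, out / "utr_features.tsv")
        stage_done("utr", n_genes=len(features),
                   n_urr_defined=int(features["urr_au"].notna().sum()))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("utr", str(exc)) from exc

    # ---- stage 6: temax --------------------------------------------------
    try:
        te_max = temax.compute_te_max(tetab.te)
        max_fpkm = tetab.mean_rna_fpkm.max(axis=1)
        records = temax.filter_and_quartile(te_max, max_fpkm)
        binned = temax.bin_rna(records)
        fits = {}
        for q in temax.QUARTILE_LABELS:
            try:
                fits[q] = asdict(temax.fit_trend(binned, q))
            except ValueError:
                fits[q] = None
        diff = temax.slope_difference(binned)
        cats = submap.drop_duplicates("gene_id").set_index("gene_id")["category"]
        enrich = temax.category_enrichment(binned, cats)
        tio.write_tsv(binned, out / "temax_quartiles.tsv")
        tio.write_tsv(enrich, out / "temax_enrichment.tsv", index=False)
        tio.write_json({"fits": fits, "slope_difference": diff}, out / "temax_fits.json")
        stage_done("temax", n_survivors=len(records), slope_difference=diff)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("temax", str(exc)) from exc

    manifest["runtime_s"] = round(time.time() - t0, 2)
    tio.write_json(manifest, out / "manifest.json")
    return manifest
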