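"""Readers and writers for the interchange formats.

FASTA goes through Biopython. GFF3 is written/read in the fixed dialect used
throughout the package (``gene`` features, ``ID``/``gene_id`` attributes,
1-based inclusive coordinates); bedGraph and BED6 are 0-based half-open.
All conversions go through :mod:`teflux.coords`.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .coords import from_gff3, to_gff3
from .models import GeneModel

# ---------------------------------------------------------------- FASTA


def write_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------- GFF3

_GFF_COLS = ["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"]


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for g in genes:
        s1, e1 = to_gff3(g.start, g.end)
        attrs = f"ID={g.gene_id};gene_id={g.gene_id}"
        if g.subsystem:
            attrs += f";subsystem={g.subsystem}"
        if g.category:
            attrs += f";category={g.category}"
        lines.append(
            "\t".join([g.replicon, "teflux", "gene", str(s1), str(e1), ".", g.strand, ".", attrs])
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ValueError(f"{path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}")
        seqid, _source, ftype, start1, end1, _score, strand, _phase, attributes = fields
        if ftype != "gene":
            continue
        try:
            start0, end0 = from_gff3(int(start1), int(end1))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
        attrs = _parse_attributes(attributes, path, lineno)
        gene_id = attrs.get("gene_id") or attrs.get("ID")
        if not gene_id:
            raise ValueError(f"{path}:{lineno}: gene feature without ID/gene_id attribute")
        genes.append(
            GeneModel(
                gene_id=gene_id,
                replicon=seqid,
                start=start0,
                end=end0,
                strand=strand,
                subsystem=attrs.get("subsystem", ""),
                category=attrs.get("category", ""),
            )
        )
    return genes


def _parse_attributes(attributes: str, path: str | Path, lineno: int) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in attributes.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" not in chunk:
            raise ValueError(f"{path}:{lineno}: malformed attribute {chunk!r}")
        key, value = chunk.split("=", 1)
        out[key] = value
    return out


# ---------------------------------------------------------------- bedGraph / BED6


def write_bedgraph(coverage: Mapping[str, np.ndarray], path: str | Path) -> None:
    """Write per-replicon integer coverage vectors as bedGraph (0-based
    half-open runs; zero runs are omitted)."""
    lines = []
    for replicon, vec in coverage.items():
        vec = np.asarray(vec)
        if vec.size == 0:
            continue
        # run-length encode
        change = np.flatnonzero(np.diff(vec)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [vec.size]])
        for s, e in zip(starts, ends):
            v = vec[s]
            if v != 0:
                lines.append(f"{replicon}\t{s}\t{e}\t{v:g}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_bedgraph(path: str | Path, lengths: Mapping[str, int]) -> dict[str, np.ndarray]:
    """Read bedGraph into dense per-replicon vectors of the given lengths."""
    out = {name: np.zeros(n) for name, n in lengths.items()}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track")):
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise ValueError(f"{path}:{lineno}: expected 4 fields, got {len(fields)}")
        replicon, start, end, value = fields
        if replicon not in out:
            raise ValueError(f"{path}:{lineno}: unknown replicon {replicon!r}")
        s, e = int(start), int(end)
        if not (0 <= s < e <= out[replicon].size):
            raise ValueError(f"{path}:{lineno}: interval [{s},{e}) out of bounds")
        out[replicon][s:e] = float(value)
    return out


def write_bed6(df: pd.DataFrame, path: str | Path) -> None:
    """Write a BED6 file from a frame with columns
    replicon/start/end/name/score/strand (0-based half-open)."""
    df[["replicon", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------- TSV / JSON


def read_counts(path: str | Path) -> pd.DataFrame:
    """gene_id-indexed integer count matrix (libraries in columns)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ValueError(f"{path}: negative counts")
    return df


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_subsystem_map(path: str | Path) -> pd.DataFrame:
    """gene -> subsystem (+ optional category) map; one row per membership."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "subsystem"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing required columns {sorted(required)}")
    return df


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
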