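"""Core domain records shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class GeneModel:
    """One protein-coding gene on a replicon.

    Coordinates are 0-based half-open over the CDS (start codon through stop
    codon inclusive). ``subsystem`` and ``category`` carry functional labels
    (RAST-style); either may be empty for unannotated genes.
    """

    gene_id: str
    replicon: str
    start: int
    end: int
    strand: str  # '+' or '-'
    subsystem: str = ""
    category: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"{self.gene_id}: invalid interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def start_codon_pos(self) -> int:
        """0-based genomic position of the first base of the start codon."""
        return self.start if self.strand == "+" else self.end - 1

    def cds_sequence(self, genome: dict[str, str]) -> str:
        """Coding-strand CDS sequence (reverse-complemented for '-' genes)."""
        seq = genome[self.replicon][self.start : self.end]
        return seq if self.strand == "+" else revcomp(seq)

    def upstream_sequence(self, genome: dict[str, str], n: int) -> str:
        """Up to ``n`` nt immediately 5' of the start codon, coding-strand
        orientation (last character is adjacent to the start codon). Shorter
        near a contig edge."""
        chrom = genome[self.replicon]
        if self.strand == "+":
            lo = max(0, self.start - n)
            return chrom[lo : self.start]
        hi = min(len(chrom), self.end + n)
        return revcomp(chrom[self.end : hi])


_COMP = str.maketrans("ACGTUacgtuNn", "TGCAAtgcaaNn")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class TSSRecord:
    """A called transcription start site.

    ``position`` is 0-based (converted on TSV/BED export); ``score`` counts
    the RPP dataset-pairs (1-8) supporting the site; ``category`` is one of
    P (primary), I (internal), A (antisense), O (orphan).
    """

    replicon: str
    position: int
    strand: str
    score: int
    category: str = ""
    gene_id: str = ""
    utr_length: int | None = None
    leaderless_like: bool = False
    support: tuple[int, ...] = field(default_factory=tuple)
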