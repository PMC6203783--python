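"""5'UTR and coding-region features linked to translational efficiency.

The ribosome-binding site (RBS) is located by scanning every 10-nt window
of the 25 nt upstream of the start codon and computing the hybridization
free energy of the best duplex with the 16S rRNA anti-Shine-Dalgarno
octamer (AAGGAGGU); the window with the most negative dG harbors the RBS.
Around it, the module computes the RBS distance to the start codon, the AU
percent of the 15-nt upstream RBS region (URR), the codon adaptation index
(CAI) and coding-region AU percent, dG affinity bins, and the grouped
nonparametric comparisons used to relate features to TE.

The duplex energy model is a nearest-neighbor RNA:RNA model (Turner 2004
free energies at 37 C): Watson-Crick + GU wobble stacks, tabulated 1x1
interior loops, generic penalties for small bulges and larger interior
loops, duplex initiation, terminal AU/GU penalties and dangling-end terms
at both helix ends. An adapter to an external folding engine (ViennaRNA)
can be swapped in; downstream analyses depend only on energy ranks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._nn_int11 import INT11

ASD = "AAGGAGGU"
WINDOW = 10
UPSTREAM_LEN = 25
URR_LEN = 15
MODAL_DISTANCE = 13  # validated modal RBS 5'-end distance from the start codon

DUPLEX_INIT = 4.10
TERMINAL_AU = 0.50

_PAIR_TYPES = ("CG", "GC", "GU", "UG", "AU", "UA")
# Turner 2004 stack free energies (kcal/mol, 37 C); row = pair (i,j),
# column = pair (l,k) for the stack 5'-i k-3' / 3'-j l-5'.
_STACK_TABLE = {
    "CG": {"CG": -2.40, "GC": -3.30, "GU": -2.10, "UG": -1.40, "AU": -2.10, "UA": -2.10},
    "GC": {"CG": -3.30, "GC": -3.40, "GU": -2.50, "UG": -1.50, "AU": -2.20, "UA": -2.40},
    "GU": {"CG": -2.10, "GC": -2.50, "GU": 1.30, "UG": -0.50, "AU": -1.40, "UA": -1.30},
    "UG": {"CG": -1.40, "GC": -1.50, "GU": -0.50, "UG": 0.30, "AU": -0.60, "UA": -1.00},
    "AU": {"CG": -2.10, "GC": -2.20, "GU": -1.40, "UG": -0.60, "AU": -1.10, "UA": -0.90},
    "UA": {"CG": -2.10, "GC": -2.40, "GU": -1.30, "UG": -1.00, "AU": -0.90, "UA": -1.30},
}
_WOBBLY = {"AU", "UA", "GU", "UG"}

# Turner 2004 dangling-end free energies; dangle5[pair][base] is an unpaired
# base 5'-adjacent to the closing pair, dangle3 the 3'-adjacent one.
_DANGLE5 = {
    "CG": {"A": -0.50, "C": -0.30, "G": -0.20, "U": -0.10},
    "GC": {"A": -0.20, "C": -0.30, "G": 0.00, "U": 0.00},
    "GU": {"A": -0.30, "C": -0.30, "G": -0.40, "U": -0.20},
    "UG": {"A": -0.30, "C": -0.10, "G": -0.20, "U": -0.20},
    "AU": {"A": -0.30, "C": -0.30, "G": -0.40, "U": -0.20},
    "UA": {"A": -0.30, "C": -0.10, "G": -0.20, "U": -0.20},
}
_DANGLE3 = {
    "CG": {"A": -1.10, "C": -0.40, "G": -1.30, "U": -0.60},
    "GC": {"A": -1.70, "C": -0.80, "G": -1.70, "U": -1.20},
    "GU": {"A": -0.70, "C": -0.10, "G": -0.70, "U": -0.10},
    "UG": {"A": -0.80, "C": -0.50, "G": -0.80, "U": -0.60},
    "AU": {"A": -0.70, "C": -0.10, "G": -0.70, "U": -0.10},
    "UA": {"A": -0.80, "C": -0.50, "G": -0.80, "U": -0.60},
}


def _rna(seq: str) -> str:
    seq = seq.upper().replace("T", "U")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"non-nucleotide characters: {sorted(bad)}")
    return seq


def _pair_type(x: str, y: str) -> str | None:
    p = x + y
    return p if p in _PAIR_TYPES else None


# Turner loop penalties (kcal/mol): bulges and generic interior loops by
# total unpaired size, NINIO asymmetry 0.60/nt capped at 3.00.
_BULGE = {1: 3.80, 2: 2.80, 3: 3.20, 4: 3.60, 5: 4.00, 6: 4.40}
_INTERNAL = {2: 1.00, 3: 1.00, 4: 1.10, 5: 2.00, 6: 2.00}
_NINIO_M, _NINIO_MAX = 0.60, 3.00
_MAX_GAP = 3  # largest one-sided loop considered


def duplex_energy(window: str, asd: str = ASD) -> float:
    """Free energy (kcal/mol, <= 0) of the best duplex between ``window``
    and ``asd``; 0.0 when no stable duplex forms.

    Nearest-neighbor model over all antiparallel pairings: contiguous
    stacks at Turner 2004 free energies, small bulges and interior loops at
    the tabulated loop penalties (with NINIO asymmetry), duplex initiation,
    and terminal AU/GU penalties plus dangling-end terms at both helix
    ends. A lone base pair is never stable.
    """
    w = _rna(window)
    a = _rna(asd)
    # enumerate all valid pairs (i, j): w[i] with a[j]
    pairs = [
        (i, j, pt)
        for i in range(len(w))
        for j in range(len(a))
        if (pt := _pair_type(w[i], a[j])) is not None
    ]
    if not pairs:
        return 0.0
    # dp[k] = best energy of a duplex whose 5'-most (on w) pair is pairs[k],
    # including the left-end terms, excluding init and right-end terms.
    # Pairs are antiparallel: successor pairs have larger i and smaller j.
    order = sorted(range(len(pairs)), key=lambda k: pairs[k][0])
    # open[k]: left-end terms of a duplex starting at pairs[k] (one pair so
    # far); grown[k]: best energy ending at pairs[k] with >= 2 pairs.
    open_e = [0.0] * len(pairs)
    grown = [np.inf] * len(pairs)
    for k in order:
        i, j, pt = pairs[k]
        open_e[k] = _end_terms(
            pt,
            w[i - 1] if i > 0 else None,
            a[j + 1] if j + 1 < len(a) else None,
        )
    best = 0.0
    for k2 in order:
        i2, j2, pt2 = pairs[k2]
        for k1 in order:
            i1, j1, pt1 = pairs[k1]
            if i1 >= i2 or j1 <= j2:
                continue
            di, dj = i2 - i1 - 1, j1 - j2 - 1
            if di > _MAX_GAP or dj > _MAX_GAP:
                continue
            x1 = w[i1 + 1] if di == 1 else ""
            y1 = a[j2 + 1] if dj == 1 else ""
            trans = _transition(pt1, pt2, di, dj, x1, y1)
            if trans is None:
                continue
            cand = min(open_e[k1], grown[k1]) + trans
            if cand < grown[k2]:
                grown[k2] = cand
        if np.isfinite(grown[k2]):
            total = grown[k2] + DUPLEX_INIT + _end_terms(
                pt2[::-1],
                a[j2 - 1] if j2 > 0 else None,
                w[i2 + 1] if i2 + 1 < len(w) else None,
            )
            best = min(best, total)
    return best


def _transition(pt1: str, pt2: str, di: int, dj: int, x1: str = "", y1: str = "") -> float | None:
    """Energy of joining pair 2 after pair 1 with (di, dj) unpaired bases
    on the two strands."""
    if di == 0 and dj == 0:
        return _STACK_TABLE[pt1][pt2[::-1]]
    size = di + dj
    if di == 0 or dj == 0:  # bulge
        if size not in _BULGE:
            return None
        e = _BULGE[size]
        if size == 1:
            # single-nt bulge: the flanking pairs still stack
            e += _STACK_TABLE[pt1][pt2[::-1]]
        else:
            e += (TERMINAL_AU if pt1 in _WOBBLY else 0.0) + (
                TERMINAL_AU if pt2 in _WOBBLY else 0.0
            )
        return e
    if di == 1 and dj == 1:  # 1x1 interior loop: tabulated
        return INT11.get((pt1, pt2[::-1], x1, y1), _INTERNAL[2])
    if size not in _INTERNAL:  # larger interior loop: generic penalty
        return None
    return _INTERNAL[size] + min(_NINIO_MAX, _NINIO_M * abs(di - dj))


def _end_terms(pair: str, d5: str | None, d3: str | None) -> float:
    """Terminal AU/GU penalty plus dangling-end contributions at one helix
    end; ``d5``/``d3`` are the adjacent unpaired bases (None at a sequence
    boundary)."""
    e = TERMINAL_AU if pair in _WOBBLY else 0.0
    if d5 is not None:
        e += _DANGLE5[pair][d5]
    if d3 is not None:
        e += _DANGLE3[pair][d3]
    return e


def vienna_duplex_energy(window: str, asd: str = ASD) -> float:
    """Adapter: same interface, energies from ViennaRNA's duplexfold.

    Optional cross-check backend; requires the ``RNA`` bindings.
    """
    import RNA  # deferred: optional dependency

    d = RNA.duplexfold(_rna(window), _rna(asd))
    return min(0.0, float(d.energy))


@dataclass
class RBSResult:
    window: str
    offset: int          # 0-based start of the window within the upstream region
    delta_g: float
    distance_5p: int     # window 5' end -> start codon
    distance_3p: int     # window 3' end -> start codon (= distance_5p - 9)
    truncated: bool = False


def find_rbs(upstream: str, asd: str = ASD, energy_fn=duplex_energy) -> RBSResult | None:
    """Scan all 10-nt windows of the upstream region for the strongest
    anti-SD duplex.

    The last character of ``upstream`` abuts the start codon. Ties on dG
    are broken toward the window whose 5' distance is closest to the
    validated modal distance (13 nt), then toward the most 3' window.
    Returns None for regions shorter than one window (flagged undefined).
    """
    L = len(upstream)
    if L < WINDOW:
        return None
    seq = _rna(upstream)
    candidates = []
    for i in range(L - WINDOW + 1):
        window = seq[i : i + WINDOW]
        dg = energy_fn(window, asd)
        distance_5p = L - i
        candidates.append((dg, abs(distance_5p - MODAL_DISTANCE), -i, i, window, distance_5p))
    dg, _, _, i, window, distance_5p = min(candidates)
    return RBSResult(
        window=window,
        offset=i,
        delta_g=dg,
        distance_5p=distance_5p,
        distance_3p=distance_5p - (WINDOW - 1),
        truncated=L < UPSTREAM_LEN,
    )


def urr_au(
    upstream: str, rbs: RBSResult, utr_length: int | None
) -> float | None:
    """AU percent of the 15 nt immediately 5' of the RBS window.

    ``upstream`` is any region ending at the start codon that is long
    enough to contain the URR (the RBS scan itself only uses the last 25
    nt; the URR extends further 5'). Undefined (None) when the URR does not
    fit in the available sequence or when the TSS is not at least 15 nt
    upstream of the URR 5' end — the guard against calling AU-richness on
    genomic background in a low-GC genome. ``utr_length`` is the TSS ->
    start codon distance (None when no primary TSS is known).
    """
    # window 5' base sits at distance rbs.distance_5p from the start codon
    abs_off = len(upstream) - rbs.distance_5p
    if abs_off < URR_LEN:
        return None
    if utr_length is None:
        return None
    # URR 5' end is at distance distance_5p + 15; TSS must be >= 15 nt further
    if utr_length < rbs.distance_5p + 2 * URR_LEN:
        return None
    urr = upstream[abs_off - URR_LEN : abs_off]
    return 100.0 * sum(ch in "AUT" for ch in urr.upper()) / URR_LEN


# ------------------------------------------------------------------ codon features

_STOPS = {"UAA", "UAG", "UGA"}
_CODON_TO_AA = {}


def _codon_table() -> dict[str, str]:
    if _CODON_TO_AA:
        return _CODON_TO_AA
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_rna_by_id[11]  # bacterial
    for codon, aa in table.forward_table.items():
        _CODON_TO_AA[codon] = aa
    return _CODON_TO_AA


def cai_weights(reference_cds: list[str]) -> dict[str, float]:
    """Relative adaptiveness w = codon frequency / max synonymous frequency,
    from a highly expressed reference gene set."""
    codon_to_aa = _codon_table()
    counts: dict[str, int] = {c: 0 for c in codon_to_aa}
    for cds in reference_cds:
        seq = _rna(cds)
        for i in range(0, len(seq) - len(seq) % 3, 3):
            codon = seq[i : i + 3]
            if codon in counts:
                counts[codon] += 1
    weights: dict[str, float] = {}
    by_aa: dict[str, list[str]] = {}
    for codon, aa in codon_to_aa.items():
        by_aa.setdefault(aa, []).append(codon)
    for aa, codons in by_aa.items():
        top = max(counts[c] for c in codons)
        for c in codons:
            # unobserved families fall back to uniform weight 1/0 guard
            weights[c] = counts[c] / top if top > 0 else 1.0
    return weights


def cai(cds: str, weights: dict[str, float], on_internal_stop: str = "error") -> float:
    """Codon adaptation index: geometric mean of relative adaptiveness over
    codons, excluding single-codon families (Met, Trp) and stops."""
    seq = _rna(cds)
    if len(seq) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    codon_to_aa = _codon_table()
    single = {
        aa
        for aa in set(codon_to_aa.values())
        if sum(1 for c, a in codon_to_aa.items() if a == aa) == 1
    }
    logs = []
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    for idx, codon in enumerate(codons):
        if codon in _STOPS:
            if idx != len(codons) - 1:
                if on_internal_stop == "error":
                    raise ValueError(f"internal stop codon {codon} at codon {idx}")
                continue
            continue
        aa = codon_to_aa.get(codon)
        if aa is None or aa in single:
            continue
        w = weights.get(codon, 1.0)
        if w <= 0:
            w = 0.5 / 100  # unobserved codon in reference: small positive weight
        logs.append(np.log(w))
    if not logs:
        raise ValueError("no informative codons for CAI")
    return float(np.exp(np.mean(logs)))


def coding_au(cds: str) -> float:
    """Percent A+U over the CDS."""
    seq = cds.upper()
    if not seq:
        raise ValueError("empty CDS")
    return 100.0 * sum(ch in "AUT" for ch in seq) / len(seq)


# ------------------------------------------------------------------ binning & tests

AFFINITY_RANGE = (-12.7, 0.0)
N_AFFINITY_BINS = 11


def bin_by_affinity(delta_g: pd.Series, te: pd.Series | None = None) -> pd.DataFrame:
    """Assign dG values to 11 equal-width bins spanning [-12.7, 0].

    Bin 1 is the weakest affinity (dG near 0), bin 11 the strongest.
    Out-of-range values are clamped to the end bins. Returns a frame with
    the bin assignment and, when TE is given, per-bin median TE.
    """
    lo, hi = AFFINITY_RANGE
    width = (hi - lo) / N_AFFINITY_BINS
    # bin 1 = [hi - width, hi], bin 11 = [lo, lo + width]
    idx = np.ceil((hi - delta_g.to_numpy(dtype=float)) / width).astype(int)
    idx = np.clip(idx, 1, N_AFFINITY_BINS)
    idx[np.isclose(delta_g.to_numpy(dtype=float), hi)] = 1
    out = pd.DataFrame({"delta_g": delta_g, "affinity_bin": idx}, index=delta_g.index)
    if te is not None:
        out["te"] = te
    return out


def affinity_bin_summary(binned: pd.DataFrame) -> pd.DataFrame:
    """Per-bin count and median TE."""
    return binned.groupby("affinity_bin").agg(
        n=("delta_g", "size"), median_te=("te", "median")
    )


def compare_groups(
    a, b, test: str = "rank_sum", paired: bool = False, exact_n: int = 20
) -> tuple[float, float]:
    """Two-group comparison: Mann-Whitney rank-sum or Wilcoxon signed-rank.

    Uses the exact null distribution for small samples (n <= ``exact_n``)
    and the tie-corrected normal approximation otherwise. Returns
    (statistic, two-sided p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    if test == "signed_rank" or paired:
        if a.size != b.size:
            raise ValueError("paired comparison requires equal lengths")
        d = a - b
        if np.all(d == 0):
            return 0.0, 1.0
        method = "exact" if a.size <= exact_n and not np.any(d == 0) else "approx"
        res = stats.wilcoxon(a, b, method=method, correction=False)
        return float(res.statistic), float(res.pvalue)
    if test != "rank_sum":
        raise ValueError(f"unknown test {test!r}")
    small = max(a.size, b.size) <= exact_n
    ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if small and not ties else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# ------------------------------------------------------------------ per-gene table


def utr_feature_table(
    genes,
    genome: dict[str, str],
    utr_lengths: pd.Series | None = None,
    reference_weights: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-gene feature record: RBS window/dG/distances, URR AU, CAI,
    coding AU, affinity bin.

    ``utr_lengths`` (gene -> TSS distance) gates the URR AU computation;
    genes without a known primary TSS get an undefined URR AU.
    """
    rows = []
    for gene in genes:
        # 40 nt so the URR (15 nt beyond the 25-nt scan region) is available
        upstream = gene.upstream_sequence(genome, UPSTREAM_LEN + URR_LEN)
        rbs = find_rbs(upstream[-UPSTREAM_LEN:])
        utr_len = None
        if utr_lengths is not None and gene.gene_id in utr_lengths.index:
            v = utr_lengths.loc[gene.gene_id]
            utr_len = None if pd.isna(v) else int(v)
        row = {
            "gene_id": gene.gene_id,
            "rbs_window": rbs.window if rbs else None,
            "delta_g": rbs.delta_g if rbs else np.nan,
            "rbs_distance_5p": rbs.distance_5p if rbs else np.nan,
            "rbs_distance_3p": rbs.distance_3p if rbs else np.nan,
            "urr_au": urr_au(upstream, rbs, utr_len) if rbs else None,
        }
        cds = gene.cds_sequence(genome)
        row["coding_au"] = coding_au(cds)
        if reference_weights is not None:
            row["cai"] = cai(cds, reference_weights, on_internal_stop="skip")
        rows.append(row)
    table = pd.DataFrame(rows).set_index("gene_id")
    defined = table["delta_g"].dropna()
    if len(defined):
        table.loc[defined.index, "affinity_bin"] = bin_by_affinity(defined)["affinity_bin"]
    return table
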