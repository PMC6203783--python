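"""Duplex energetics, RBS scanning, URR/CAI/AU features, grouped tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from teflux.utr import (
    MODAL_DISTANCE,
    RBSResult,
    bin_by_affinity,
    cai,
    cai_weights,
    coding_au,
    compare_groups,
    duplex_energy,
    find_rbs,
    urr_au,
    vienna_duplex_energy,
)

PERFECT_SD = "ACCUCCUU"  # exact complement of the anti-SD octamer


def brute_force_rbs(upstream: str):
    """Independent scan: enumerate every window, pick min dG with the
    documented tie-breaks (distance closest to 13, then most 3')."""
    L = len(upstream)
    best = None
    for i in range(L - 10 + 1):
        dg = duplex_energy(upstream[i : i + 10])
        dist = L - i
        key = (dg, abs(dist - MODAL_DISTANCE), -i)
        if best is None or key < best[0]:
            best = (key, i, dg, dist)
    return best[1], best[2], best[3]


class TestDuplexEnergy:
    def test_no_complementarity_scores_zero(self):
        assert duplex_energy("AAAAAAAAAA") == 0.0
        assert duplex_energy("GGGGGGGGGG") == 0.0

    def test_perfect_complement_is_global_minimum_among_sampled_windows(self, rng):
        """A window holding the full SD octamer beats 10^4 random windows."""
        perfect = duplex_energy("A" + PERFECT_SD + "A")
        assert perfect <= -11.0
        draws = ["".join(rng.choice(list("ACGU"), 10)) for _ in range(10_000)]
        sampled_min = min(duplex_energy(w) for w in draws)
        assert perfect <= sampled_min + 1e-9

    def test_anti_monotone_in_watson_crick_core_length(self):
        """Growing the complementary core never weakens the duplex."""
        for k in range(3, 9):
            shorter = PERFECT_SD[:k - 1].ljust(10, "A")
            longer = PERFECT_SD[:k].ljust(10, "A")
            assert duplex_energy(longer) <= duplex_energy(shorter) + 1e-9

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError, match="non-nucleotide"):
            duplex_energy("ACGTXACGTA")

    def test_dna_alphabet_accepted(self):
        assert duplex_energy("ACCTCCTTAA") == duplex_energy("ACCUCCUUAA")

    def test_rank_agreement_with_external_engine(self, rng):
        """The built-in nearest-neighbor model ranks 1000 random windows
        like ViennaRNA's duplexfold (Spearman > 0.95)."""
        pytest.importorskip("RNA")
        windows = ["".join(rng.choice(list("ACGU"), 10)) for _ in range(1000)]
        mine = np.array([duplex_energy(w) for w in windows])
        theirs = np.array([vienna_duplex_energy(w) for w in windows])
        from scipy.stats import spearmanr

        assert spearmanr(mine, theirs).statistic > 0.95


class TestFindRBS:
    def test_planted_perfect_sd_found_at_distance_13(self, rng):
        for _ in range(20):
            up = list(rng.choice(list("AC"), 25))
            up[13:21] = list(PERFECT_SD)  # octamer inside the distance-13 window
            res = find_rbs("".join(up))
            assert res.distance_5p == 13
            assert res.distance_3p == res.distance_5p - 9
            assert PERFECT_SD.replace("U", "T") in res.window.replace("U", "T") or \
                PERFECT_SD in res.window

    def test_degenerate_all_a_ties_break_to_modal_distance(self):
        res = find_rbs("A" * 25)
        assert res.delta_g == 0.0
        assert res.distance_5p == 13

    def test_matches_bruteforce_argmin_on_random_regions(self, rng):
        for _ in range(300):
            up = "".join(rng.choice(list("ACGU"), 25))
            res = find_rbs(up)
            i, dg, dist = brute_force_rbs(up)
            assert res.offset == i and res.delta_g == pytest.approx(dg)
            assert res.distance_5p == dist

    def test_short_region_flagged_or_undefined(self):
        assert find_rbs("ACGUACGU") is None
        res = find_rbs("ACGUACGUACGUACGU")  # 16 nt: scannable but truncated
        assert res.truncated

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGU", min_size=10, max_size=25))
    def test_property_argmin_equals_enumeration(self, up):
        res = find_rbs(up)
        i, dg, dist = brute_force_rbs(up)
        assert res.delta_g == pytest.approx(dg)
        assert res.offset == i


class TestURR:
    def _rbs(self, upstream_len=40, distance=13):
        return RBSResult(
            window="A" * 10, offset=upstream_len - 25 + (25 - distance),
            delta_g=-5.0, distance_5p=distance, distance_3p=distance - 9,
        )

    def test_all_au_is_100(self):
        up = "G" * 12 + "AUAUAUAUAUAUAUA" + "A" * 13
        res = urr_au(up, self._rbs(), utr_length=60)
        assert res == 100.0

    def test_all_gc_is_0(self):
        up = "A" * 12 + "GCGCGCGCGCGCGCG" + "A" * 13
        assert urr_au(up, self._rbs(), utr_length=60) == 0.0

    def test_nine_of_fifteen_is_60(self):
        urr = "AAAAAAAAAGGGGGG"  # 9 A of 15
        up = "G" * 12 + urr + "C" * 13
        assert urr_au(up, self._rbs(), utr_length=60) == pytest.approx(60.0)

    def test_undefined_without_tss_or_short_utr(self):
        up = "A" * 40
        assert urr_au(up, self._rbs(), utr_length=None) is None
        # TSS must be >= 15 nt upstream of the URR 5' end (distance 28):
        assert urr_au(up, self._rbs(), utr_length=42) is None
        assert urr_au(up, self._rbs(), utr_length=43) is not None

    def test_undefined_when_urr_outside_sequence(self):
        assert urr_au("A" * 25, self._rbs(upstream_len=25), utr_length=60) is None


class TestCodonFeatures:
    def test_cai_is_one_for_pure_preferred_codons(self):
        ref = ["ATGAAACGTATTTAA"] * 5  # reference defines the preferred set
        w = cai_weights(ref)
        assert cai("ATGAAACGTATTTAA", w) == pytest.approx(1.0)

    def test_cai_two_codon_toy_geometric_mean(self):
        # hand-built weights: one codon at w=1, its synonym at w=0.25
        w = {c: 1.0 for c in ["AAA", "AAG"]}
        w["AAG"] = 0.25
        got = cai("AAAAAG", w)
        assert got == pytest.approx(math.sqrt(1.0 * 0.25))

    def test_cai_self_reference_is_one(self):
        gene = "ATGGATAAACCGTTTTAA"
        w = cai_weights([gene])
        assert cai(gene, w) == pytest.approx(1.0)

    def test_internal_stop_raises_unless_skipped(self):
        w = cai_weights(["ATGAAATAA"])
        with pytest.raises(ValueError, match="stop"):
            cai("ATGTAAAAATAA", w)
        assert cai("ATGTAAAAATAA", w, on_internal_stop="skip") > 0

    def test_length_not_multiple_of_three_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            cai("ATGAA", {})

    def test_coding_au_extremes_and_mix(self):
        assert coding_au("ATATAT") == 100.0
        assert coding_au("GCGCGC") == 0.0
        assert coding_au("ATGC") == 50.0


class TestAffinityBins:
    def test_boundary_values(self):
        s = pd.Series([0.0, -12.7, -0.01])
        got = bin_by_affinity(s)["affinity_bin"]
        assert got.tolist() == [1, 11, 1]

    def test_uniform_random_matches_direct_histogram(self, rng):
        vals = pd.Series(rng.uniform(-12.7, 0, 500))
        got = bin_by_affinity(vals)["affinity_bin"]
        width = 12.7 / 11
        expected = np.ceil((0.0 - vals.to_numpy()) / width).astype(int).clip(1, 11)
        assert (got.to_numpy() == expected).all()

    def test_out_of_range_clamped(self):
        s = pd.Series([-20.0, 3.0])
        got = bin_by_affinity(s)["affinity_bin"]
        assert got.tolist() == [11, 1]


def exact_ranksum_p(a, b):
    """Brute-force two-sided Mann-Whitney p by enumerating all group
    assignments of the pooled sample (no ties)."""
    pooled = np.concatenate([a, b])
    n = len(a)
    ranks = pd.Series(pooled).rank().to_numpy()
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    m = len(pooled)
    us = []
    for combo in itertools.combinations(range(m), n):
        u = ranks[list(combo)].sum() - n * (n + 1) / 2
        us.append(u)
    us = np.array(us)
    mean_u = len(a) * len(b) / 2
    return np.mean(np.abs(us - mean_u) >= abs(u_obs - mean_u) - 1e-9)


class TestCompareGroups:
    def test_identical_groups_null(self, rng):
        x = rng.random(15)
        _, p = compare_groups(x, x.copy(), test="rank_sum")
        assert p > 0.5
        _, p = compare_groups(x, x.copy(), test="signed_rank", paired=True)
        assert p == 1.0

    def test_complete_separation_is_extreme(self, rng):
        a = rng.random(30)
        _, p = compare_groups(a + 10, a, test="rank_sum")
        assert p < 1e-6

    def test_small_n_exact_matches_enumeration(self, rng):
        for _ in range(10):
            a = rng.random(4)
            b = rng.random(4) + rng.normal(0, 0.5)
            _, p = compare_groups(a, b, test="rank_sum")
            assert p == pytest.approx(exact_ranksum_p(a, b), abs=1e-9)

    def test_paired_requires_equal_lengths(self):
        with pytest.raises(ValueError, match="equal lengths"):
            compare_groups([1, 2], [1, 2, 3], test="signed_rank", paired=True)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compare_groups([], [1.0])


class TestAssociationRecovery:
    def test_planted_optimal_features_show_higher_te(self):
        """150 optimal-RBS/high-AU genes at true TE 3 vs 150 suboptimal at
        0.3 (dispersion 0.1): the rank-sum test on estimated TE rejects
        decisively and the median ordering matches the plant."""
        from teflux.synthetic import SyntheticSpec, build_genome, simulate_counts
        from teflux import quantify

        n = 300
        quality = ["optimal"] * 150 + ["absent"] * 150
        te = np.array([3.0] * 150 + [0.3] * 150)
        spec = SyntheticSpec(
            n_genes=n, rbs_quality=quality, true_te=te, dispersion=0.1,
            depth=1e6, seed=31,
        )
        ds = build_genome(spec)
        counts = simulate_counts(ds, spec)
        lengths = ds.gene_lengths
        rna = quantify.normalize_per_kb_per_million(
            counts[[c for c in counts if c.startswith("rna_")]], lengths)
        ribo = quantify.normalize_per_kb_per_million(
            counts[[c for c in counts if c.startswith("ribo_")]], lengths)
        est = ribo.values.mean(axis=1) / rna.values.mean(axis=1)
        opt, sub = est.iloc[:150], est.iloc[150:]
        assert opt.median() > sub.median()
        _, p = compare_groups(opt, sub, test="rank_sum")
        assert p < 1e-10

    def test_affinity_bins_monotone_under_monotone_plant(self, rng):
        """Median planted TE decreases across dG bins when TE is planted
        monotone in affinity."""
        dg = pd.Series(rng.uniform(-12.7, 0, 400))
        te = pd.Series(np.exp(-0.2 * dg.to_numpy()) * rng.lognormal(0, 0.05, 400))
        binned = bin_by_affinity(dg, te)
        med = binned.groupby("affinity_bin")["te"].median()
        assert (med.diff().dropna() > 0).all()  # bin 11 = strongest = highest TE
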