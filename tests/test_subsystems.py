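"""Subsystem aggregation, percent layers, and differential-TE call rules."""

import itertools

import numpy as np
import pandas as pd
import pytest

from teflux.subsystems import (
    SubsystemMatrix,
    aggregate_to_subsystems,
    call_diff_te_autotrophic,
    call_diff_te_heterotrophic,
    percent_normalize,
)

HET, A1, A2 = "fructose", "CO", "H2CO2"


class TestAggregate:
    def test_simple_sum(self):
        values = pd.DataFrame({"ribo_A_1": [3.0, 7.0]}, index=["g1", "g2"])
        smap = pd.DataFrame({"gene_id": ["g1", "g2"], "subsystem": ["s", "s"]})
        sub = aggregate_to_subsystems(values, smap)
        assert sub.summed.loc["s", "ribo_A_1"] == 10.0

    def test_multi_membership_hand_expansion(self):
        """A 5-gene toy map with one gene in two subsystems matches the
        hand-expanded sums."""
        values = pd.DataFrame(
            {"ribo_A_1": [1.0, 2.0, 4.0, 8.0, 16.0]},
            index=[f"g{i}" for i in range(5)],
        )
        smap = pd.DataFrame(
            {
                "gene_id": ["g0", "g1", "g2", "g2", "g3"],
                "subsystem": ["sA", "sA", "sA", "sB", "sB"],
            }
        )
        sub = aggregate_to_subsystems(values, smap)
        assert sub.summed.loc["sA", "ribo_A_1"] == 1 + 2 + 4
        assert sub.summed.loc["sB", "ribo_A_1"] == 4 + 8
        assert sub.n_unmapped_genes == 1  # g4

    def test_empty_map_rejected(self):
        values = pd.DataFrame({"x": [1.0]}, index=["g1"])
        with pytest.raises(ValueError, match="empty"):
            aggregate_to_subsystems(values, pd.DataFrame(columns=["gene_id", "subsystem"]))

    def test_all_zero_matrix_flagged_degenerate(self):
        values = pd.DataFrame({"ribo_A_1": [0.0, 0.0]}, index=["g1", "g2"])
        smap = pd.DataFrame({"gene_id": ["g1", "g2"], "subsystem": ["s", "s"]})
        sub = percent_normalize(aggregate_to_subsystems(values, smap))
        assert sub.degenerate and sub.percent_within is None


class TestPercentNormalize:
    def _sub(self, data, index):
        return SubsystemMatrix(summed=pd.DataFrame(data, index=index))

    def test_single_subsystem_is_100_percent_te_one(self):
        sub = self._sub(
            {"ribo_A_1": [5.0], "ribo_A_2": [7.0], "rna_A_1": [2.0], "rna_A_2": [2.0]},
            ["only"],
        )
        percent_normalize(sub)
        assert np.allclose(sub.percent_within.loc["only"], 100.0)
        assert sub.subsystem_te.loc["only", "A"] == pytest.approx(1.0)

    def test_thirty_seventy_split(self):
        sub = self._sub({"ribo_A_1": [30.0, 70.0], "ribo_A_2": [30.0, 70.0]}, ["s1", "s2"])
        percent_normalize(sub)
        assert sub.percent_within[("ribo", "A")].tolist() == [30.0, 70.0]

    def test_random_matrix_columns_sum_to_100(self, rng):
        cols = [f"{a}_{c}_{r}" for a in ("ribo", "rna") for c in ("X", "Y") for r in (1, 2)]
        sub = self._sub(
            {c: rng.random(6) + 0.1 for c in cols}, [f"s{i}" for i in range(6)]
        )
        percent_normalize(sub)
        sums = sub.percent_within.sum(axis=0)
        assert np.allclose(sums, 100.0, atol=1e-9)
        assert np.allclose(sub.percent_across.sum(axis=0), 100.0, atol=1e-9)

    def test_depth_rescaling_of_one_library_is_invisible(self, rng):
        cols = {"ribo_A_1": rng.random(4) + 0.1, "ribo_A_2": rng.random(4) + 0.1}
        sub1 = self._sub(cols, list("abcd"))
        percent_normalize(sub1)
        # percent layers are computed per experiment; scaling a library's
        # normalized values rescales the replicate mean but not the shares
        sub2 = self._sub({k: v * (3.0 if k.endswith("1") else 1.0) for k, v in cols.items()},
                         list("abcd"))
        percent_normalize(sub2)
        assert not np.allclose(sub1.summed, sub2.summed)
        # shares differ only through the replicate mean; scaling both
        # replicates by the same factor is exactly invisible:
        sub3 = self._sub({k: v * 3.0 for k, v in cols.items()}, list("abcd"))
        percent_normalize(sub3)
        pd.testing.assert_frame_equal(sub1.percent_within, sub3.percent_within)


def _stats_row(sig1, sig2, aux_insig, pct_high, te_high, trans_base=1.0):
    """One subsystem row engineered to hit a chosen clause combination."""
    return {
        f"padj_{HET}_vs_{A1}": 0.001 if sig1 else 0.5,
        f"padj_{HET}_vs_{A2}": 0.001 if sig2 else 0.5,
        f"padj_{A1}_vs_{A2}": 0.5 if aux_insig else 0.001,
        f"trans_pct_{HET}": 10.0 if pct_high else trans_base,
        f"trans_pct_{A1}": 1.0,
        f"trans_pct_{A2}": 1.0,
        f"te_{HET}": 3.0 if te_high else 0.5,
        f"te_{A1}": 1.0,
        f"te_{A2}": 1.0,
    }


class TestHeterotrophicCall:
    def test_truth_table_over_clause_combinations(self):
        """All 16 combinations of the four clauses: only the full
        conjunction is called."""
        rows, expected = {}, set()
        for bits in itertools.product([False, True], repeat=4):
            sig1, sig2, aux, te = bits
            name = "ss_" + "".join("T" if b else "F" for b in bits)
            rows[name] = _stats_row(sig1, sig2, aux, pct_high=True, te_high=te)
            if all(bits):
                expected.add(name)
        # padding rows keep the 50th-percentile clause meaningful: their
        # translation percent is low, so every engineered row is above it
        for i in range(16):
            rows[f"pad{i}"] = _stats_row(False, False, True, pct_high=False,
                                         te_high=False, trans_base=0.01)
        stats = pd.DataFrame(rows).T
        got = call_diff_te_heterotrophic(stats, HET, (A1, A2))
        assert got == expected

    def test_all_p_one_gives_empty_set(self):
        rows = {f"s{i}": _stats_row(False, False, False, True, True) for i in range(6)}
        stats = pd.DataFrame(rows).T
        for c in stats.columns:
            if c.startswith("padj"):
                stats[c] = 1.0
        assert call_diff_te_heterotrophic(stats, HET, (A1, A2)) == set()

    def test_te_clause_alone_excludes(self):
        rows = {"good": _stats_row(True, True, True, True, True),
                "no_te": _stats_row(True, True, True, True, False)}
        for i in range(6):
            rows[f"pad{i}"] = _stats_row(False, False, True, False, False, trans_base=0.01)
        stats = pd.DataFrame(rows).T
        assert call_diff_te_heterotrophic(stats, HET, (A1, A2)) == {"good"}


class TestAutotrophicCall:
    def _auto_row(self, sig, pct_high, above_het):
        return {
            f"padj_{HET}_vs_{A1}": 0.001 if sig else 0.5,
            f"padj_{HET}_vs_{A2}": 0.001 if sig else 0.5,
            f"padj_{A1}_vs_{A2}": 0.5,
            f"trans_pct_{HET}": 1.0,
            f"trans_pct_{A1}": 10.0 if pct_high else 0.1,
            f"trans_pct_{A2}": 10.0 if pct_high else 0.1,
            f"te_{HET}": 1.0,
            f"te_{A1}": 1.0,
            f"te_{A2}": 1.0,
        }

    def test_clause_enumeration(self):
        rows, expected = {}, set()
        for bits in itertools.product([False, True], repeat=3):
            sig, pct, above = bits
            name = "ss_" + "".join("T" if b else "F" for b in bits)
            row = self._auto_row(sig, pct, above)
            if not above:
                row[f"trans_pct_{HET}"] = 50.0  # heterotrophic dominates
            rows[name] = row
            if all(bits):
                expected.add(name)
        for i in range(8):
            rows[f"pad{i}"] = self._auto_row(False, False, False)
        stats = pd.DataFrame(rows).T
        assert call_diff_te_autotrophic(stats, HET, (A1, A2)) == expected

    def test_exact_50th_percentile_excluded(self):
        """A subsystem sitting exactly at the median translation percent
        fails the strict > clause."""
        rows = {}
        for i, v in enumerate([1.0, 2.0, 3.0, 4.0, 5.0]):
            row = self._auto_row(True, True, True)
            row[f"trans_pct_{A1}"] = v
            row[f"trans_pct_{A2}"] = v
            rows[f"s{i}"] = row
        stats = pd.DataFrame(rows).T
        got = call_diff_te_autotrophic(stats, HET, (A1, A2))
        assert "s2" not in got  # the median row (3.0) is excluded
        assert {"s3", "s4"} <= got

    def test_missing_condition_column_errors(self):
        stats = pd.DataFrame({f"padj_{HET}_vs_{A1}": [0.001]}, index=["s"])
        with pytest.raises(ValueError, match="missing columns"):
            call_diff_te_autotrophic(stats, HET, (A1, A2))
        with pytest.raises(ValueError, match="missing columns"):
            call_diff_te_heterotrophic(stats, HET, (A1, A2))


class TestEndToEndCalls:
    def test_planted_subsystem_shift_is_called(self, rng):
        """Genes of one subsystem translated 8x higher in the heterotrophic
        condition (with matching TE) are called heterotrophically
        differential from raw counts."""
        from teflux.subsystems import build_subsystem_stats

        n = 60
        genes = [f"g{i}" for i in range(n)]
        smap = pd.DataFrame({
            "gene_id": genes, "subsystem": [f"s{i % 6}" for i in range(n)],
        })
        mu = rng.lognormal(5, 0.3, n) + 20
        boost = np.where(np.arange(n) % 6 == 0, 8.0, 1.0)
        cols = {}
        for cond, scale in ((HET, boost), (A1, 1.0), (A2, 1.0)):
            for r in (1, 2):
                cols[f"ribo_{cond}_{r}"] = rng.poisson(mu * scale)
                cols[f"rna_{cond}_{r}"] = rng.poisson(mu)
        counts = pd.DataFrame(cols, index=genes)
        ribo_cols = [c for c in counts if c.startswith("ribo_")]
        condition = pd.Series({c: c.split("_")[1] for c in counts.columns})

        expr = counts.astype(float)
        sub = aggregate_to_subsystems(expr, smap)
        percent_normalize(sub)
        stats = build_subsystem_stats(
            counts[ribo_cols], condition, sub, HET, (A1, A2), smap
        )
        got = call_diff_te_heterotrophic(stats, HET, (A1, A2))
        assert got == {"s0"}
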