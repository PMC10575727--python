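"""Opposite-direction rescue filtering, prioritization, and 2^-ddCt qPCR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from enteroquant.rescue import (
    DeContrastTable,
    QpcrPlate,
    delta_delta_ct,
    opposite_direction_filter,
    prioritize,
)
from enteroquant.simulate import SyntheticDeConfig, gen_de_tables

from oracles import rescue_predicate_filter


def table(name, rows):
    return DeContrastTable(name, pd.DataFrame(
        rows, columns=["gene", "log2fc", "padj", "basemean"]))


TOY_BASELINE = [
    ("g1", -2.0, 0.01, 100.0),   # reversed by treatment -> rescue
    ("g2", -2.0, 0.01, 100.0),   # same direction in treatment
    ("g3", 1.0, 0.20, 100.0),    # baseline not significant
    ("g4", 0.0, 0.001, 100.0),   # zero fold change excluded
]
TOY_TREATMENT = [
    ("g1", 1.5, 0.02, 120.0),
    ("g2", -1.0, 0.01, 120.0),
    ("g3", -1.0, 0.01, 120.0),
    ("g4", 2.0, 0.001, 120.0),
]


class TestOppositeDirectionFilter:
    def test_toy_table_enumeration(self):
        hits = opposite_direction_filter(
            table("baseline", TOY_BASELINE), table("treatment", TOY_TREATMENT))
        assert hits.genes == ["g1"]
        row = hits.table.iloc[0]
        assert row["direction"] == "down_up"
        assert row["baseline_log2fc"] == -2.0

    def test_empty_tables_rejected(self):
        empty = pd.DataFrame(columns=["gene", "log2fc", "padj", "basemean"])
        with pytest.raises(ValueError):
            opposite_direction_filter(
                DeContrastTable("b", empty), DeContrastTable("t", empty))

    def test_disjoint_gene_namespaces_rejected(self):
        with pytest.raises(ValueError, match="share no gene"):
            opposite_direction_filter(
                table("b", [("a1", -2.0, 0.01, 5.0)]),
                table("t", [("b1", 2.0, 0.01, 5.0)]))

    def test_symmetric_under_global_sign_flip(self, rng):
        n = 500
        genes = [f"g{i}" for i in range(n)]
        base = pd.DataFrame({"gene": genes, "log2fc": rng.normal(0, 2, n),
                             "padj": rng.uniform(0, 0.2, n),
                             "basemean": rng.uniform(1, 100, n)})
        treat = pd.DataFrame({"gene": genes, "log2fc": rng.normal(0, 2, n),
                              "padj": rng.uniform(0, 0.2, n),
                              "basemean": rng.uniform(1, 100, n)})
        a = opposite_direction_filter(DeContrastTable("b", base),
                                      DeContrastTable("t", treat))
        flip_b = base.assign(log2fc=-base["log2fc"])
        flip_t = treat.assign(log2fc=-treat["log2fc"])
        b = opposite_direction_filter(DeContrastTable("b", flip_b),
                                      DeContrastTable("t", flip_t))
        assert a.genes == b.genes

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_row_predicate_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 2000
        genes = [f"g{i}" for i in range(n)]

        def rand_table(name):
            return DeContrastTable(name, pd.DataFrame({
                "gene": genes,
                "log2fc": rng.normal(0, 1.5, n),
                "padj": rng.uniform(0, 1, n),
                "basemean": rng.lognormal(3, 1, n),
            }))

        b, t = rand_table("b"), rand_table("t")
        hits = opposite_direction_filter(b, t, 0.1)
        expected = rescue_predicate_filter(b.table, t.table, 0.1)
        assert set(hits.genes) == expected


class TestPrioritize:
    def _hits(self):
        rows = [
            ("weak", -2.0, 0.01, 0.5, 0.01, 100.0, "down_up"),
            ("strong", -2.0, 0.01, 3.0, 0.02, 100.0, "down_up"),
            ("rare", 2.0, 0.01, -2.0, 0.001, 5.0, "up_down"),
            ("mid", 2.0, 0.01, -2.0, 0.005, 50.0, "up_down"),
        ]
        from enteroquant.rescue import RescueGeneSet

        return RescueGeneSet(pd.DataFrame(rows, columns=[
            "gene", "baseline_log2fc", "baseline_padj", "treatment_log2fc",
            "treatment_padj", "basemean", "direction"]), fdr_cutoff=0.05)

    def test_thresholds_drop_members(self):
        ranked = prioritize(self._hits(), min_abs_log2fc=1.0,
                            max_fdr=0.05, min_basemean=10.0)
        assert ranked.genes == ["strong", "mid"]  # weak: |lfc|, rare: basemean

    def test_permissive_thresholds_keep_all(self):
        ranked = prioritize(self._hits(), 0.0, 1.0, 0.0)
        assert set(ranked.genes) == {"weak", "strong", "rare", "mid"}
        # ranked by |treatment lfc| desc, then treatment FDR asc
        assert ranked.genes[0] == "strong"
        assert ranked.genes[1:3] == ["rare", "mid"]

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            prioritize(self._hits(), min_abs_log2fc=-1.0)


class TestGeneratorRecovery:
    def test_planted_genes_recovered_and_rank_above_nulls(self):
        tables, truth = gen_de_tables(SyntheticDeConfig(seed=0))
        hits = opposite_direction_filter(tables["baseline"], tables["treatment"])
        ranked = prioritize(hits)
        planted = set(truth.data["rescue_genes"])
        recovered = planted & set(ranked.genes)
        assert len(recovered) / len(planted) >= 0.95
        # median over ranks: planted genes should dominate the top
        ranks = {g: i for i, g in enumerate(ranked.genes)}
        planted_ranks = [ranks[g] for g in planted if g in ranks]
        assert np.median(planted_ranks) < len(planted)

    def test_no_planted_genes_yields_near_empty_filter(self):
        counts = []
        for seed in range(10):
            tables, _ = gen_de_tables(SyntheticDeConfig(n_rescue=0, seed=seed))
            hits = opposite_direction_filter(tables["baseline"], tables["treatment"])
            counts.append(len(hits))
        # expected false rate: 0.05^2 * P(opposite signs) ~ 0.00125 of 2000
        assert np.mean(counts) < 10

    def test_same_seed_reproduces_tables(self):
        t1, _ = gen_de_tables(SyntheticDeConfig(seed=5))
        t2, _ = gen_de_tables(SyntheticDeConfig(seed=5))
        for name in t1:
            pd.testing.assert_frame_equal(t1[name].table, t2[name].table)


class TestDeltaDeltaCt:
    def _plate(self, rows):
        return QpcrPlate(pd.DataFrame(rows, columns=["sample", "gene", "cq"]))

    def test_identical_cq_gives_unit_fold(self):
        rows = [(s, g, 20.0) for s in ("ref", "test")
                for g in ("GAPDH", "SGK2") for _ in range(3)]
        out = delta_delta_ct(self._plate(rows), "ref")
        assert np.allclose(out["fold_change"], 1.0)

    def test_worked_example(self):
        rows = (
            [("test", "SGK2", 24.0)] * 3 + [("test", "GAPDH", 20.0)] * 3
            + [("ref", "SGK2", 26.0)] * 3 + [("ref", "GAPDH", 20.0)] * 3
        )
        out = delta_delta_ct(self._plate(rows), "ref")
        row = out[(out["sample"] == "test") & (out["gene"] == "SGK2")].iloc[0]
        assert row["delta_delta_ct"] == pytest.approx(-2.0)
        assert row["fold_change"] == pytest.approx(4.0)

    def test_missing_housekeeping_is_error(self):
        rows = [("test", "SGK2", 24.0), ("ref", "SGK2", 26.0),
                ("ref", "GAPDH", 20.0)]
        with pytest.raises(ValueError, match="housekeeping"):
            delta_delta_ct(self._plate(rows), "ref")

    @given(st.floats(-5, 5))
    def test_invariant_to_constant_cq_shift_within_sample(self, shift):
        rows = (
            [("test", "SGK2", 24.0)] * 3 + [("test", "GAPDH", 20.0)] * 3
            + [("ref", "SGK2", 26.0)] * 3 + [("ref", "GAPDH", 21.0)] * 3
        )
        plate = self._plate(rows)
        shifted = plate.table.copy()
        shifted.loc[shifted["sample"] == "test", "cq"] += shift
        if (shifted["cq"] <= 0).any():
            return
        a = delta_delta_ct(plate, "ref")
        b = delta_delta_ct(QpcrPlate(shifted), "ref")
        assert np.allclose(a["fold_change"], b["fold_change"])
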