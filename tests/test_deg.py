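import numpy as np
import pandas as pd
import pytest

from elocodon import (
    compare_abs_lfc,
    compare_down_vs_up,
    filter_degs,
    partition_organs,
)


def de_table(rows):
    return pd.DataFrame(rows, columns=["gene_id", "base_mean", "lfc", "pvalue", "padj"])


def calls(pairs, organ="hypocotyl"):
    return pd.DataFrame(
        [{"gene_id": g, "organ": organ, "direction": d, "lfc": 1.0 if d == "up" else -1.0,
          "padj": 0.01} for g, d in pairs],
        columns=["gene_id", "organ", "direction", "lfc", "padj"],
    )


class TestFilterDegs:
    def test_printed_thresholds(self):
        tbl = de_table([
            ("g1", 150, 0.6, 0.001, 0.01),
            ("g2", 500, -2.0, 0.001, 0.2),
            ("g3", 500, 0.4, 0.001, 0.01),
            ("g4", 50, -1.2, 0.001, 0.01),
        ])
        out = filter_degs(tbl)
        assert list(out["gene_id"]) == ["g1"]
        assert out.loc[0, "direction"] == "up"

    def test_boundary_values_pass(self):
        out = filter_degs(de_table([("g5", 100, -0.5, 0.01, 0.05)]))
        assert list(out["gene_id"]) == ["g5"]
        assert out.loc[0, "direction"] == "down"

    def test_empty_input(self):
        assert filter_degs(de_table([])).empty

    def test_missing_padj_never_passes(self):
        out = filter_degs(de_table([("g1", 500, 2.0, 0.001, np.nan)]))
        assert out.empty

    def test_parameter_validation(self):
        tbl = de_table([("g1", 150, 0.6, 0.001, 0.01)])
        with pytest.raises(ValueError):
            filter_degs(tbl, alpha=1.5)
        with pytest.raises(ValueError):
            filter_degs(tbl, lfc_min=-1)

    def test_monotone_in_thresholds(self, rng):
        tbl = de_table([
            (f"g{i}", rng.uniform(0, 500), rng.normal(0, 1.5),
             rng.uniform(0, 1), rng.uniform(0, 1))
            for i in range(300)
        ])
        base = set(filter_degs(tbl)["gene_id"])
        looser = set(filter_degs(tbl, alpha=0.2, lfc_min=0.1, min_mean=10)["gene_id"])
        assert base <= looser


class TestPartition:
    def test_toy_enumeration(self):
        part = partition_organs(
            calls([("g1", "up"), ("g2", "down"), ("g3", "up")]),
            calls([("g2", "up"), ("g3", "up"), ("g4", "down")], organ="cotyledon"),
        )
        assert part.shared_same_up == {"g3"}
        assert part.shared_opposite_hyp_down == {"g2"}
        assert part.hyp_only_up == {"g1"}
        assert part.cot_only_down == {"g4"}
        assert part.hyp_only_down == part.cot_only_up == frozenset()
        assert part.shared_same_down == part.shared_opposite_hyp_up == frozenset()

    def test_disjoint_sets_all_empty_shared(self):
        part = partition_organs(
            calls([("a", "up")]), calls([("b", "down")], organ="cotyledon")
        )
        assert not part.shared_same_up and not part.shared_same_down
        assert not part.shared_opposite_hyp_up and not part.shared_opposite_hyp_down

    def test_identical_sets_only_shared_same(self):
        pairs = [("a", "up"), ("b", "down")]
        part = partition_organs(calls(pairs), calls(pairs, organ="cotyledon"))
        d = part.as_dict()
        assert d["shared_same_up"] == {"a"} and d["shared_same_down"] == {"b"}
        assert all(not v for k, v in d.items() if not k.startswith("shared_same"))

    def test_duplicate_gene_raises(self):
        with pytest.raises(ValueError, match="more than once"):
            partition_organs(calls([("a", "up"), ("a", "down")]), calls([]))

    def test_disjoint_and_exhaustive_on_random_toys(self, rng):
        for _ in range(20):
            ids = [f"g{i}" for i in range(rng.integers(5, 40))]
            hyp = [(g, rng.choice(["up", "down"])) for g in ids if rng.random() < 0.6]
            cot = [(g, rng.choice(["up", "down"])) for g in ids if rng.random() < 0.6]
            part = partition_organs(calls(hyp), calls(cot, organ="cotyledon"))
            sets = list(part.as_dict().values())
            union = set().union(*sets)
            assert sum(len(s) for s in sets) == len(union)
            assert union == {g for g, _ in hyp} | {g for g, _ in cot}


class TestCompareAbsLfc:
    def _tables(self, genes, hyp_lfc, cot_lfc):
        hyp = de_table([(g, 100, l, 0.01, 0.01) for g, l in zip(genes, hyp_lfc)])
        cot = de_table([(g, 100, l, 0.01, 0.01) for g, l in zip(genes, cot_lfc)])
        return hyp, cot

    def test_median_arithmetic(self):
        genes = ["a", "b", "c"]
        hyp, cot = self._tables(genes, [1.0, 2.0, 3.0], [0.5, 1.0, 1.5])
        part = partition_organs(
            calls([(g, "up") for g in genes]),
            calls([(g, "up") for g in genes], organ="cotyledon"),
        )
        out = compare_abs_lfc(part, hyp, cot, sets=["shared_same_up"])
        row = out.iloc[0]
        assert (row["median_a"], row["median_b"]) == (2.0, 1.0)
        assert row["pct_diff"] == pytest.approx(100.0)

    def test_identical_distributions_no_difference(self):
        genes = [f"g{i}" for i in range(20)]
        lfc = list(np.linspace(0.6, 3, 20))
        hyp, cot = self._tables(genes, lfc, lfc)
        part = partition_organs(
            calls([(g, "up") for g in genes]),
            calls([(g, "up") for g in genes], organ="cotyledon"),
        )
        out = compare_abs_lfc(part, hyp, cot, sets=["shared_same_up"])
        assert out.iloc[0]["pct_diff"] == 0
        assert out.iloc[0]["p"] > 0.9

    def test_planted_organ_ratio_recovered(self, rng):
        """Hypocotyl |LFC| stochastically 1.5x cotyledon: positive, significant."""
        genes = [f"g{i}" for i in range(2000)]
        cot_lfc = rng.normal(0, 1, 2000)
        hyp_lfc = 1.5 * rng.normal(0, 1, 2000)
        hyp, cot = self._tables(genes, hyp_lfc, cot_lfc)
        part = partition_organs(
            calls([(g, "up") for g in genes]),
            calls([(g, "up") for g in genes], organ="cotyledon"),
        )
        out = compare_abs_lfc(part, hyp, cot, sets=["shared_same_up"])
        assert 20 < out.iloc[0]["pct_diff"] < 80
        assert out.iloc[0]["padj"] <= 0.05

    def test_small_set_skipped(self):
        genes = ["a", "b"]
        hyp, cot = self._tables(genes, [1.0, 2.0], [1.0, 2.0])
        part = partition_organs(
            calls([(g, "up") for g in genes]),
            calls([(g, "up") for g in genes], organ="cotyledon"),
        )
        assert compare_abs_lfc(part, hyp, cot, sets=["shared_same_up"]).empty


class TestCompareDownVsUp:
    def _profiles(self, ft_down, ft_up):
        rows = []
        for i, v in enumerate(ft_down):
            rows.append({"gene_id": f"d{i}", "F_T": v})
        for i, v in enumerate(ft_up):
            rows.append({"gene_id": f"u{i}", "F_T": v})
        df = pd.DataFrame(rows)
        for p in ("F_S", "F_2", "F_3", "F_4", "D"):
            df[p] = df["F_T"]
        return df

    def _degs(self, n_down, n_up):
        return pd.DataFrame(
            [{"gene_id": f"d{i}", "direction": "down", "lfc": -1, "padj": 0.01}
             for i in range(n_down)]
            + [{"gene_id": f"u{i}", "direction": "up", "lfc": 1, "padj": 0.01}
               for i in range(n_up)]
        )

    def test_pct_diff_formula(self):
        prof = self._profiles([0.12, 0.12, 0.12], [0.04, 0.04, 0.04])
        out = compare_down_vs_up(prof, self._degs(3, 3))
        row = out[out["label"] == "F_T"].iloc[0]
        assert row["pct_diff"] == pytest.approx(200.0)

    def test_null_no_parameter_significant(self, rng):
        ft = rng.beta(12, 68, 2000)
        prof = self._profiles(ft[:1000], ft[1000:])
        out = compare_down_vs_up(prof, self._degs(1000, 1000))
        assert not (out["padj"] <= 0.05).any()

    def test_planted_enrichment_detected(self, rng):
        down = rng.beta(18, 62, 1000)  # 1.5x the propensity of the up genes
        up = rng.beta(12, 68, 1000)
        out = compare_down_vs_up(self._profiles(down, up), self._degs(1000, 1000))
        row = out[out["label"] == "F_T"].iloc[0]
        assert row["pct_diff"] > 0
        assert row["padj"] <= 0.05

    def test_too_few_genes_raises(self):
        prof = self._profiles([0.1, 0.1], [0.2, 0.2, 0.2])
        with pytest.raises(ValueError, match=">= 3"):
            compare_down_vs_up(prof, self._degs(2, 3))

    def test_row_order_invariance(self, rng):
        down = rng.beta(18, 62, 50)
        up = rng.beta(12, 68, 50)
        prof = self._profiles(down, up)
        degs = self._degs(50, 50)
        out1 = compare_down_vs_up(prof, degs)
        shuffled = prof.sample(frac=1, random_state=1).reset_index(drop=True)
        out2 = compare_down_vs_up(shuffled, degs.sample(frac=1, random_state=2))
        pd.testing.assert_frame_equal(out1, out2)
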