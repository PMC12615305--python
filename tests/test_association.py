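"""ssGSEA scoring, immune differential, correlation screens, ORA."""

import math

import numpy as np
import pandas as pd
import pytest

from glycodelta.association import (
    AssociationThresholds,
    composite_scores,
    immune_differential,
    intersect_with_de,
    ora_enrichment,
    read_gmt,
    spearman_screen,
    ssgsea_scores,
    write_gmt,
)
from glycodelta.quant import StudyDesign


def brute_force_ssgsea(values: dict, members, alpha):
    """Running-sum ssGSEA computed longhand, independent of the library:
    walk the descending-ranked genes accumulating the weighted in-set
    CDF minus the uniform out-of-set CDF, and sum the difference."""
    ranked = sorted(values.items(), key=lambda kv: -kv[1])
    w_total = sum(abs(v) ** alpha for g, v in ranked if g in members)
    n_out = sum(1 for g, _ in ranked if g not in members)
    score, cin, cout = 0.0, 0.0, 0.0
    for g, v in ranked:
        if g in members:
            cin += abs(v) ** alpha / w_total
        else:
            cout += 1.0 / n_out
        score += cin - cout
    return score


class TestSsgsea:
    def _toy(self):
        genes = [f"g{i}" for i in range(10)]
        vals = {
            "s1": [9.0, 7.5, 6.0, 5.0, 4.2, 3.0, 2.0, 1.5, 1.0, 0.5],
            "s2": [0.3, 1.0, 8.0, 2.0, 7.0, 0.1, 5.0, 3.3, 0.9, 6.1],
        }
        return pd.DataFrame(vals, index=genes)

    def test_matches_brute_force_oracle(self):
        expr = self._toy()
        members = ["g0", "g4", "g7"]
        scores = ssgsea_scores(expr, {"set": members}, alpha_weight=0.25)
        for s in expr.columns:
            expected = brute_force_ssgsea(expr[s].to_dict(), set(members), 0.25)
            assert scores.loc["set", s] == pytest.approx(expected, abs=1e-9)

    def test_top_k_set_scores_positive_bottom_k_negative(self):
        expr = self._toy()
        top = list(expr["s1"].nlargest(3).index)
        bottom = list(expr["s1"].nsmallest(3).index)
        scores = ssgsea_scores(expr, {"top": top, "bottom": bottom})
        assert scores.loc["top", "s1"] > 0
        assert scores.loc["bottom", "s1"] < 0

    def test_rank_only_mode_invariant_to_monotone_transform(self):
        expr = self._toy()
        sets = {"set": ["g1", "g3", "g8"]}
        base = ssgsea_scores(expr, sets, alpha_weight=0.0)
        warped = ssgsea_scores(np.exp(expr / 2.0), sets, alpha_weight=0.0)
        pd.testing.assert_frame_equal(base, warped)

    def test_zero_overlap_sets_dropped_all_empty_raises(self):
        expr = self._toy()
        scores = ssgsea_scores(expr, {"ok": ["g1"], "alien": ["zz"]})
        assert list(scores.index) == ["ok"]
        with pytest.raises(ValueError, match="overlap"):
            ssgsea_scores(expr, {"alien": ["zz"]})

    def test_missing_values_dropped_per_sample(self):
        expr = self._toy()
        expr.loc["g2", "s1"] = np.nan
        scores = ssgsea_scores(expr, {"set": ["g0", "g4"]})
        reduced = expr[["s1"]].dropna()
        expected = brute_force_ssgsea(reduced["s1"].to_dict(), {"g0", "g4"}, 0.25)
        assert scores.loc["set", "s1"] == pytest.approx(expected, abs=1e-9)


class TestComposites:
    def test_single_signature_composite_equals_it(self):
        sm = pd.DataFrame({"s1": [1.0], "s2": [2.0]}, index=["Fibroblasts"])
        out = composite_scores(sm)
        assert (out.loc["StromaScore"] == out.loc["Fibroblasts"]).all()

    def test_hand_computed_means(self):
        sm = pd.DataFrame(
            {"s1": [1.0, 3.0, 5.0], "s2": [2.0, 4.0, 6.0]},
            index=["Fibroblasts", "Endothelial cells", "NK cells"],
        )
        out = composite_scores(sm)
        assert out.loc["StromaScore", "s1"] == pytest.approx(2.0)  # (1+3)/2
        assert out.loc["MicroenvironmentScore", "s2"] == pytest.approx(4.0)  # (2+4+6)/3

    def test_identical_columns_identical_composites(self):
        sm = pd.DataFrame(
            {"s1": [1.0, 2.0], "s2": [1.0, 2.0]}, index=["Fibroblasts", "NK cells"]
        )
        out = composite_scores(sm)
        assert out["s1"].equals(out["s2"])


def _two_group_design(n=8):
    rows = []
    for i in range(n):
        rows.append((f"T{i}", "B1", f"a{i}", "Tumor", pd.NA, False))
        rows.append((f"N{i}", "B1", f"b{i}", "NAT", pd.NA, False))
    return StudyDesign(
        pd.DataFrame(
            rows, columns=["sample_id", "batch", "channel", "condition", "pair_id", "is_reference"]
        )
    )


class TestImmuneDifferential:
    def test_identical_groups_ns(self):
        d = _two_group_design(4)
        sm = pd.DataFrame([[1.0] * 8], index=["sig"], columns=d.samples())
        out = immune_differential(sm, d)
        assert out.loc["sig", "call"] == "ns"

    def test_injected_twofold_shift_enriched(self, rng):
        d = _two_group_design(8)
        tumor = rng.normal(2.0, 0.1, 8)
        nat = rng.normal(1.0, 0.1, 8)
        sm = pd.DataFrame(
            [np.concatenate([tumor, nat])],
            index=["sig"],
            columns=[f"T{i}" for i in range(8)] + [f"N{i}" for i in range(8)],
        )
        out = immune_differential(sm, d)
        assert out.loc["sig", "call"] == "enriched_in_a"
        assert out.loc["sig", "p_value"] < 0.05

    def test_small_fold_gate_blocks_significant_shift(self, rng):
        # clearly significant mean shift whose min-shifted fold stays
        # under 1.25: the fold gate alone must veto the call
        n = 60
        d = _two_group_design(n)
        base = np.concatenate([[1.0], rng.normal(5.0, 0.1, n - 1)])
        sm = pd.DataFrame(
            [np.concatenate([base + 0.6, base])],
            index=["sig"],
            columns=[f"T{i}" for i in range(n)] + [f"N{i}" for i in range(n)],
        )
        out = immune_differential(sm, d, AssociationThresholds())
        assert out.loc["sig", "p_value"] < 0.05
        assert 1.0 < out.loc["sig", "fold"] < 1.25
        assert out.loc["sig", "call"] == "ns"

    def test_invariant_to_constant_offset(self, rng):
        d = _two_group_design(8)
        vals = rng.normal(size=16)
        cols = [f"T{i}" for i in range(8)] + [f"N{i}" for i in range(8)]
        sm = pd.DataFrame([vals], index=["sig"], columns=cols)
        shifted = pd.DataFrame([vals - 11.7], index=["sig"], columns=cols)
        a = immune_differential(sm, d)
        b = immune_differential(shifted, d)
        assert a.loc["sig", "fold"] == pytest.approx(b.loc["sig", "fold"])
        assert a.loc["sig", "call"] == b.loc["sig", "call"]


class TestSpearman:
    def test_perfect_and_anti_correlation(self):
        x = pd.DataFrame([[1.0, 2, 3, 4, 5, 6]], index=["x"])
        y = pd.DataFrame([[1.0, 2, 3, 4, 5, 6], [6.0, 5, 4, 3, 2, 1]], index=["same", "anti"])
        out = spearman_screen(x, y).set_index("y_id")
        assert out.loc["same", "rho"] == pytest.approx(1.0)
        assert out.loc["anti", "rho"] == pytest.approx(-1.0)
        assert bool(out.loc["same", "retained"])
        assert not bool(out.loc["anti", "retained"])  # '>0.6' is one-sided

    def test_abs_mode_retains_negative(self):
        x = pd.DataFrame([[1.0, 2, 3, 4, 5, 6]], index=["x"])
        y = pd.DataFrame([[6.0, 5, 4, 3, 2, 1]], index=["anti"])
        out = spearman_screen(x, y, use_abs=True)
        assert bool(out["retained"].iloc[0])

    def test_matches_rank_difference_formula(self, rng):
        """Tie-free vectors: rho equals 1 - 6*sum(d^2)/(n(n^2-1))."""
        n = 8
        xv = rng.permutation(np.arange(1.0, n + 1))
        yv = rng.permutation(np.arange(1.0, n + 1)) + rng.normal(0, 1e-9, n)
        x = pd.DataFrame([xv], index=["x"])
        y = pd.DataFrame([yv], index=["y"])
        out = spearman_screen(x, y, min_n=5)
        rx = pd.Series(xv).rank().to_numpy()
        ry = pd.Series(yv).rank().to_numpy()
        d2 = float(((rx - ry) ** 2).sum())
        expected = 1 - 6 * d2 / (n * (n**2 - 1))
        assert out["rho"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_pairwise_complete_minimum(self):
        x = pd.DataFrame([[1.0, 2, np.nan, 4, 5, 6]], index=["x"])
        y = pd.DataFrame([[np.nan, 2, 3, 4, 5, 6]], index=["y"])
        out = spearman_screen(x, y, min_n=5)
        assert out.empty  # only 4 paired observations


class TestIntersect:
    def test_set_semantics_and_provenance(self):
        corr = pd.DataFrame(
            {
                "x_id": ["E"] * 3,
                "y_id": ["g1", "g2", "g3"],
                "rho": [0.9, 0.8, 0.7],
                "p_value": [0.01] * 3,
                "n": [10] * 3,
                "retained": [True, True, False],
            }
        )
        de = pd.DataFrame(
            {
                "label": ["up", "down", "up"],
                "fold_change": [2.0, 0.4, 3.0],
                "p_value": [0.01, 0.02, 0.03],
                "branch": ["A_direct_up", "C_direct_down", "A_direct_up"],
            },
            index=["g1", "g2", "g3"],
        )
        hits = intersect_with_de(corr, de, label="up")
        assert list(hits["y_id"]) == ["g1"]  # g2 is down, g3 not retained
        assert hits["branch"].iloc[0] == "A_direct_up"

    def test_disjoint_gives_empty(self):
        corr = pd.DataFrame(
            {"x_id": ["E"], "y_id": ["g9"], "rho": [0.9], "p_value": [0.01], "n": [9], "retained": [True]}
        )
        de = pd.DataFrame({"label": ["up"], "fold_change": [2.0], "p_value": [0.01], "branch": ["A_direct_up"]}, index=["g1"])
        assert intersect_with_de(corr, de).empty


class TestOra:
    def brute_force_tail(self, N, K, n, k):
        """P(overlap >= k) by direct enumeration of the hypergeometric pmf."""
        total = math.comb(N, n)
        return sum(
            math.comb(K, j) * math.comb(N - K, n - j) / total
            for j in range(k, min(K, n) + 1)
        )

    def test_exact_enumeration_small_universe(self):
        universe = [f"g{i}" for i in range(18)]
        term = universe[:6]
        query = universe[2:9]  # overlap = 4
        out = ora_enrichment(query, {"t": term}, universe).set_index("term")
        assert out.loc["t", "overlap"] == 4
        expected = self.brute_force_tail(18, 6, 7, 4)
        assert out.loc["t", "p_value"] == pytest.approx(expected, abs=1e-12)

    def test_disjoint_query_upper_tail_is_one(self):
        universe = [f"g{i}" for i in range(10)]
        out = ora_enrichment(universe[5:], {"t": universe[:5]}, universe)
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_query_equals_term_equals_universe(self):
        genes = ["a", "b", "c"]
        out = ora_enrichment(genes, {"t": genes}, genes)
        assert out["overlap"].iloc[0] == 3
        assert out["p_value"].iloc[0] == pytest.approx(1.0)

    def test_bh_monotone_in_sorted_p(self, rng):
        universe = [f"g{i}" for i in range(40)]
        ann = {
            f"t{j}": list(rng.choice(universe, size=8, replace=False)) for j in range(12)
        }
        out = ora_enrichment(universe[:10], ann, universe)
        srt = out.sort_values("p_value")
        assert (np.diff(srt["bh_fdr"]) >= -1e-12).all()


def test_gmt_roundtrip(tmp_path):
    sets = {"A": ["g1", "g2"], "B": ["g3"]}
    path = tmp_path / "x.gmt"
    write_gmt(sets, path)
    assert read_gmt(path) == sets
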