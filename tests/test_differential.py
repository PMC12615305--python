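"""Feature statistics and the protein-corrected classification tree."""

import itertools

import numpy as np
import pandas as pd
import pytest

from glycodelta.differential import (
    Thresholds,
    call_protein_de,
    classify_glycopeptide,
    classify_glycopeptides,
    de_by_glycan_type,
    feature_stats,
)

TH = Thresholds()


def oracle_classify(gp_fc, gp_p, prot, th=TH):
    """Independent truth-table reading of the classification rules.

    Written directly from the verbal criteria: up needs fc>1.5 (p<.05)
    and a greater rise than the protein or a non-significant protein;
    a rising glycopeptide on a protein that rose significantly more is
    down (occupancy loss); mirror rules for decreases.
    """
    if prot is None:
        prot_sig_up = prot_sig_down = False
        prot_fc = None
    else:
        prot_fc, prot_p = prot
        prot_sig_up = prot_fc > th.fc_up and prot_p < th.alpha
        prot_sig_down = prot_fc < th.fc_down and prot_p < th.alpha
    prot_not_sig = not (prot_sig_up or prot_sig_down)

    if gp_fc > th.fc_up and gp_p < th.alpha:
        if prot_not_sig or (prot_fc is not None and gp_fc > prot_fc):
            return "up", "A_direct_up"
        if prot_sig_up and prot_fc > gp_fc:
            return "down", "D_occupancy_down"
        return "unchanged", "none"
    if gp_fc < th.fc_down and gp_p < th.alpha:
        if prot_not_sig or (prot_fc is not None and gp_fc < prot_fc):
            return "down", "C_direct_down"
        if prot_sig_down and prot_fc < gp_fc:
            return "up", "B_occupancy_up"
        return "unchanged", "none"
    return "unchanged", "none"


class TestFeatureStats:
    def _matrix(self, a, b):
        m = pd.DataFrame([a + b], index=["f"], columns=[f"s{i}" for i in range(len(a + b))])
        return m, [f"s{i}" for i in range(len(a))], [f"s{i}" for i in range(len(a), len(a + b))]

    def test_identical_groups(self):
        m, ca, cb = self._matrix([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        out = feature_stats(m, None, ca, cb)
        assert out.loc["f", "fold_change"] == pytest.approx(1.0)
        assert out.loc["f", "p_value"] == pytest.approx(1.0)

    def test_one_log2_unit_is_twofold(self):
        m, ca, cb = self._matrix([1.0, 1.0, 1.0], [0.0, 0.0, 0.0])
        out = feature_stats(m, None, ca, cb)
        assert out.loc["f", "fold_change"] == pytest.approx(2.0)

    def test_underquantified_features_excluded(self):
        m, ca, cb = self._matrix([1.0, np.nan, np.nan], [0.0, 0.0, 0.0])
        out = feature_stats(m, None, ca, cb)
        assert "f" not in out.index
        assert out.attrs["excluded"] == {"f": "fewer_than_2_values_per_group"}

    def test_design_groups_and_pairing(self, small_sim):
        from glycodelta.quant import glycopeptide_key, normalize_multibatch

        gp = small_sim.glycopeptides
        intens = gp.drop(
            columns=["accession", "site", "peptide", "site_in_peptide", "glycan_composition"]
        )
        intens.index = glycopeptide_key(gp)
        m = normalize_multibatch(intens, small_sim.design)
        unpaired = feature_stats(m, small_sim.design, "Tumor", "NAT")
        paired = feature_stats(m, small_sim.design, "Tumor", "NAT", paired=True)
        # same direction of effect either way on strongly shifted features
        # direct-up features: the observed glycopeptide fold itself rises
        # (occupancy-up features instead fall, the protein falls more)
        truth = small_sim.ground_truth
        up = truth.index[truth["true_branch"] == "A_direct_up"]
        shared = [f for f in up if f in unpaired.index and f in paired.index]
        assert len(shared) > 5
        assert (unpaired.loc[shared, "log2_fc"] > 0).mean() > 0.9
        assert (paired.loc[shared, "log2_fc"] > 0).mean() > 0.9

    def test_null_type_i_error_calibration(self, rng):
        n = 4000
        m = pd.DataFrame(rng.normal(size=(n, 20)))
        out = feature_stats(m, None, list(range(10)), list(range(10, 20)))
        rate = (out["p_value"] < 0.05).mean()
        assert rate == pytest.approx(0.05, abs=3 * np.sqrt(0.05 * 0.95 / n))


class TestProteinDE:
    @pytest.mark.parametrize(
        "fc,p,expected",
        [
            (2.0, 0.01, "sig_up"),
            (1.5, 0.01, "not_sig"),  # strict '>1.5'
            (0.67, 0.01, "not_sig"),  # strict '<0.67'
            (0.5, 0.2, "not_sig"),
            (0.5, 0.01, "sig_down"),
            (2.0, 0.05, "not_sig"),  # strict 'p < 0.05'
        ],
    )
    def test_threshold_edges(self, fc, p, expected):
        assert call_protein_de(fc, p) == expected


class TestClassifyGlycopeptide:
    @pytest.mark.parametrize(
        "gp_fc,gp_p,prot,expected_label,expected_branch",
        [
            # the four verbal rules, one constructed input each
            (3.0, 0.01, None, "up", "A_direct_up"),
            (2.0, 0.01, (4.0, 0.001), "down", "D_occupancy_down"),
            (0.5, 0.01, (0.2, 0.001), "up", "B_occupancy_up"),
            (0.3, 0.01, (0.6, 0.001), "down", "C_direct_down"),
            # protein quantified but not significant -> clause (ii)
            (2.0, 0.01, (1.2, 0.5), "up", "A_direct_up"),
            # fails both fold-change gates regardless of p
            (1.2, 0.001, (4.0, 0.001), "unchanged", "none"),
            # exact tie with a significant protein: neither clause fires
            (2.0, 0.01, (2.0, 0.001), "unchanged", "none"),
        ],
    )
    def test_branches(self, gp_fc, gp_p, prot, expected_label, expected_branch):
        pfc, pp = prot if prot else (None, None)
        label, branch, _ = classify_glycopeptide(gp_fc, gp_p, pfc, pp)
        assert (label, branch) == (expected_label, expected_branch)

    def test_grid_equivalence_with_oracle(self):
        """Full grid over glycopeptide and protein states matches the
        independent truth-table oracle, with exactly one branch firing."""
        fcs = [0.2, 0.5, 0.67, 1.0, 1.5, 2.0, 4.0]
        ps = [0.01, 0.2]
        prot_states = [None] + [(f, p) for f in fcs for p in ps]
        for gp_fc, gp_p, prot in itertools.product(fcs, ps, prot_states):
            pfc, pp = prot if prot else (None, None)
            label, branch, _ = classify_glycopeptide(gp_fc, gp_p, pfc, pp)
            assert (label, branch) == oracle_classify(gp_fc, gp_p, prot), (
                gp_fc,
                gp_p,
                prot,
            )
            # label/branch consistency (mutual exclusivity of branches)
            assert (label == "up") == (branch in ("A_direct_up", "B_occupancy_up"))
            assert (label == "down") == (branch in ("C_direct_down", "D_occupancy_down"))

    def test_occupancy_requires_protein_significance_flag(self):
        # protein fc larger but with p=0.5: occupancy branch gated off...
        label, branch, _ = classify_glycopeptide(2.0, 0.01, 4.0, 0.5)
        assert (label, branch) == ("up", "A_direct_up")  # clause (ii)
        # ...unless the requirement is relaxed — but a non-significant
        # protein still routes through clause (ii) first
        label2, branch2, _ = classify_glycopeptide(
            2.0, 0.01, 4.0, 0.5, occupancy_requires_protein_sig=False
        )
        assert (label2, branch2) == ("up", "A_direct_up")

    def test_alternate_down_cutoff_for_knockdown_mode(self):
        label, branch, _ = classify_glycopeptide(0.75, 0.01, None, None, fc_down=0.8)
        assert (label, branch) == ("down", "C_direct_down")
        label2, _, _ = classify_glycopeptide(0.75, 0.01, None, None)
        assert label2 == "unchanged"


class TestByGlycanType:
    def test_fixture_counts(self):
        calls = pd.DataFrame(
            {"label": ["up", "up", "up", "down"]},
            index=["f1", "f2", "f3", "f4"],
        )
        comp = pd.Series(
            {"f1": "N2H6F0S0", "f2": "N2H7F0S0", "f3": "N2H5F0S0", "f4": "N4H5F0S2"}
        )
        out = de_by_glycan_type(calls, comp)
        assert out.loc["mannose", "up"] == 3 and out.loc["mannose", "down"] == 0
        assert out.loc["sialylated", "down"] == 1
        assert out.to_numpy().sum() == 4

    def test_empty_calls(self):
        out = de_by_glycan_type(pd.DataFrame({"label": []}), pd.Series(dtype=object))
        assert (out.to_numpy() == 0).all()

    def test_unmapped_feature_raises(self):
        calls = pd.DataFrame({"label": ["up"]}, index=["f1"])
        with pytest.raises(KeyError, match="f1"):
            de_by_glycan_type(calls, pd.Series(dtype=object))


def test_classify_glycopeptides_table(small_sim):
    """Vectorized classification agrees with the scalar rule feature by
    feature, with parents missing from the proteome treated as not
    quantified."""
    gp_stats = pd.DataFrame(
        {"fold_change": [3.0, 0.5, 1.0], "p_value": [0.01, 0.01, 0.9]},
        index=["g1", "g2", "g3"],
    )
    prot_stats = pd.DataFrame(
        {"fold_change": [0.2], "p_value": [0.001]}, index=["P2"]
    )
    acc = pd.Series({"g1": "P1", "g2": "P2", "g3": "P2"})
    out = classify_glycopeptides(gp_stats, prot_stats, acc)
    assert out.loc["g1", "branch"] == "A_direct_up"
    assert out.loc["g1", "protein_status"] == "not_quantified"
    assert out.loc["g2", "branch"] == "B_occupancy_up"
    assert out.loc["g3", "label"] == "unchanged"
    assert "bh_fdr" in out.columns
    # BH never decreases ordered p-values
    srt = out.sort_values("p_value")
    assert (np.diff(srt["bh_fdr"]) >= -1e-12).all()
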