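"""Differential expression and protein-corrected glycopeptide calls.

Protein-level differential expression between tumor and NAT uses a
Student's t-test on log2 ratios, with a protein deemed significantly
altered when its tumor/NAT fold change is > ``fc_up`` (default 1.5) or
< ``fc_down`` (default 0.67) with p < alpha (default 0.05).

Glycopeptide abundance confounds glycosylation change with protein
abundance change, so glycopeptide calls are corrected against the
parent protein through a four-branch decision tree:

* ``A_direct_up`` — glycopeptide up (fc > fc_up, p < alpha) and either
  the protein shows no significant change (or was not quantified) or
  the glycopeptide rose more than the protein.
* ``D_occupancy_down`` — glycopeptide up, but the protein rose even
  more (significantly): relative glycosylation occupancy fell, so the
  glycopeptide is called *down*.
* ``C_direct_down`` — mirror of A for decreases.
* ``B_occupancy_up`` — glycopeptide down, but the protein fell even
  more (significantly): occupancy rose, so the call is *up*.

Exact fold-change ties between glycopeptide and protein satisfy
neither the "greater change" clause nor an occupancy branch; such a
feature is called only if the protein itself is not significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .glycans import GLYCAN_TYPES, classify_glycan
from .quant import StudyDesign

__all__ = [
    "Thresholds",
    "feature_stats",
    "call_protein_de",
    "classify_glycopeptide",
    "classify_glycopeptides",
    "de_by_glycan_type",
]

UP_BRANCHES = ("A_direct_up", "B_occupancy_up")
DOWN_BRANCHES = ("C_direct_down", "D_occupancy_down")


@dataclass(frozen=True)
class Thresholds:
    """Fold-change and significance cutoffs for differential calls.

    ``fc_up``/``fc_down`` are linear ratios (strict inequalities, i.e.
    fc must exceed 1.5 or fall below 0.67); ``fc_down_alt`` is the
    looser decrease cutoff used for single-batch knockdown experiments
    (FC < 0.8).
    """

    fc_up: float = 1.5
    fc_down: float = 0.67
    alpha: float = 0.05
    fc_down_alt: float = 0.8

    def __post_init__(self) -> None:
        if not (0 < self.fc_down < 1 < self.fc_up):
            raise ValueError("need 0 < fc_down < 1 < fc_up")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


def feature_stats(
    m: pd.DataFrame,
    design: StudyDesign | None,
    group_a,
    group_b,
    paired: bool = False,
) -> pd.DataFrame:
    """Per-feature fold change and t-test p-value between two groups.

    ``group_a``/``group_b`` are condition labels looked up in ``design``
    (e.g. ``"Tumor"``, ``"NAT"``), or explicit sample-id lists when
    ``design`` is None.  Values in ``m`` are log2; the fold change is
    the geometric ratio ``2**(mean_a - mean_b)``.  The test is a
    two-sided equal-variance Student's t-test (paired on ``pair_id``
    order when ``paired=True``).  Features with fewer than two
    quantified values in either group are excluded, with the reason in
    the returned frame's ``attrs["excluded"]``.

    Returns a DataFrame indexed by feature with columns
    ``fold_change, log2_fc, p_value, n_a, n_b``.
    """
    if design is not None:
        cols_a = design.condition_samples(group_a)
        cols_b = design.condition_samples(group_b)
        if paired:
            t = design.table
            sub = t[~t["is_reference"].astype(bool) & t["pair_id"].notna()]
            pivot = sub.pivot(index="pair_id", columns="condition", values="sample_id")
            pivot = pivot.dropna()
            cols_a = list(pivot[group_a])
            cols_b = list(pivot[group_b])
    else:
        cols_a, cols_b = list(group_a), list(group_b)
    a = m[cols_a].to_numpy(dtype=float)
    b = m[cols_b].to_numpy(dtype=float)
    n_a = np.sum(~np.isnan(a), axis=1)
    n_b = np.sum(~np.isnan(b), axis=1)
    ok = (n_a >= 2) & (n_b >= 2)
    if paired:
        both = ~np.isnan(a) & ~np.isnan(b)
        ok = np.sum(both, axis=1) >= 2

    import warnings

    with warnings.catch_warnings():
        # rows destined for exclusion produce empty-slice/small-sample noise
        warnings.simplefilter("ignore")
        mean_a = np.nanmean(a, axis=1)
        mean_b = np.nanmean(b, axis=1)
        log2_fc = mean_a - mean_b

        p = np.full(len(m), np.nan)
        if paired:
            for i in np.flatnonzero(ok):
                mask = both[i]
                res = stats.ttest_rel(a[i, mask], b[i, mask])
                p[i] = res.pvalue
                log2_fc[i] = np.mean(a[i, mask] - b[i, mask])
        else:
            res = stats.ttest_ind(a, b, axis=1, equal_var=True, nan_policy="omit")
            p = np.asarray(res.pvalue, dtype=float)
    # degenerate zero-variance rows: identical groups carry no evidence
    p = np.where(np.isnan(p) & ok & np.isclose(log2_fc, 0.0), 1.0, p)

    out = pd.DataFrame(
        {
            "fold_change": np.exp2(log2_fc),
            "log2_fc": log2_fc,
            "p_value": p,
            "n_a": n_a,
            "n_b": n_b,
        },
        index=m.index,
    )
    excluded = out.index[~ok]
    out = out.loc[ok]
    out.attrs["excluded"] = {fid: "fewer_than_2_values_per_group" for fid in excluded}
    return out


def call_protein_de(fold_change: float, p_value: float, th: Thresholds | None = None) -> str:
    """Protein DE label: ``sig_up`` / ``sig_down`` / ``not_sig``.

    Strict inequalities on both gates (fc > fc_up or fc < fc_down, and
    p < alpha).
    """
    th = th or Thresholds()
    if np.isnan(p_value) or np.isnan(fold_change):
        return "not_sig"
    if fold_change > th.fc_up and p_value < th.alpha:
        return "sig_up"
    if fold_change < th.fc_down and p_value < th.alpha:
        return "sig_down"
    return "not_sig"


def classify_glycopeptide(
    gp_fc: float,
    gp_p: float,
    prot_fc: float | None = None,
    prot_p: float | None = None,
    th: Thresholds | None = None,
    occupancy_requires_protein_sig: bool = True,
    fc_down: float | None = None,
) -> tuple[str, str, str]:
    """Classify one glycopeptide relative to its parent protein.

    Returns ``(label, branch, protein_status)`` with label in
    ``{up, down, unchanged}`` and branch in ``{A_direct_up,
    B_occupancy_up, C_direct_down, D_occupancy_down, none}``.

    ``fc_down`` overrides the decrease cutoff (e.g. ``th.fc_down_alt``
    for knockdown data).  ``occupancy_requires_protein_sig`` demands
    that an occupancy branch only fire when the protein's own change is
    itself significant; with it off, any quantified protein with a more
    extreme fold change triggers the occupancy branches.
    """
    th = th or Thresholds()
    down_cut = th.fc_down if fc_down is None else fc_down

    if prot_fc is None or (isinstance(prot_fc, float) and np.isnan(prot_fc)):
        protein_status = "not_quantified"
        prot_fc = None
    else:
        protein_status = call_protein_de(prot_fc, np.nan if prot_p is None else prot_p, th)

    gp_up = gp_fc > th.fc_up and gp_p < th.alpha
    gp_down = gp_fc < down_cut and gp_p < th.alpha
    prot_ok_up = protein_status == "sig_up" or not occupancy_requires_protein_sig
    prot_ok_down = protein_status == "sig_down" or not occupancy_requires_protein_sig

    if gp_up:
        if protein_status in ("not_sig", "not_quantified"):
            return "up", "A_direct_up", protein_status
        if gp_fc > prot_fc:
            return "up", "A_direct_up", protein_status
        if prot_fc > gp_fc and prot_ok_up:
            return "down", "D_occupancy_down", protein_status
        return "unchanged", "none", protein_status
    if gp_down:
        if protein_status in ("not_sig", "not_quantified"):
            return "down", "C_direct_down", protein_status
        if gp_fc < prot_fc:
            return "down", "C_direct_down", protein_status
        if prot_fc < gp_fc and prot_ok_down:
            return "up", "B_occupancy_up", protein_status
        return "unchanged", "none", protein_status
    return "unchanged", "none", protein_status


def classify_glycopeptides(
    gp_stats: pd.DataFrame,
    prot_stats: pd.DataFrame,
    accession_of: pd.Series,
    th: Thresholds | None = None,
    compute_fdr: bool = True,
    **kwargs,
) -> pd.DataFrame:
    """Vector version of :func:`classify_glycopeptide` over a stats table.

    ``accession_of`` maps glycopeptide feature id → parent protein
    accession; proteins absent from ``prot_stats`` are treated as not
    quantified.  Returns the glycopeptide stats augmented with
    ``label, branch, protein_status, protein_fc, protein_p`` (and
    ``bh_fdr``, reported but not used for calls).
    """
    th = th or Thresholds()
    rows = []
    for fid, row in gp_stats.iterrows():
        acc = accession_of.get(fid)
        if acc is not None and acc in prot_stats.index:
            pfc = float(prot_stats.loc[acc, "fold_change"])
            pp = float(prot_stats.loc[acc, "p_value"])
        else:
            pfc = pp = None
        label, branch, status = classify_glycopeptide(
            row["fold_change"], row["p_value"], pfc, pp, th, **kwargs
        )
        rows.append((fid, label, branch, status, pfc, pp))
    calls = pd.DataFrame(
        rows,
        columns=["feature_id", "label", "branch", "protein_status", "protein_fc", "protein_p"],
    ).set_index("feature_id")
    out = gp_stats.join(calls)
    if compute_fdr and len(out):
        out["bh_fdr"] = multipletests(out["p_value"].fillna(1.0), method="fdr_bh")[1]
    return out


def de_by_glycan_type(calls: pd.DataFrame, composition_of: pd.Series) -> pd.DataFrame:
    """Tally up/down calls per glycan class.

    ``composition_of`` maps feature id → composition string.  Returns a
    DataFrame indexed by the five glycan classes with columns
    ``up``/``down``.
    """
    unmapped = [fid for fid in calls.index if fid not in composition_of.index]
    if unmapped:
        raise KeyError(f"feature(s) without a glycan composition: {unmapped[:5]}")
    types = composition_of.loc[calls.index].map(classify_glycan)
    out = pd.DataFrame(0, index=list(GLYCAN_TYPES), columns=["up", "down"])
    for direction in ("up", "down"):
        counts = types[calls["label"] == direction].value_counts()
        out.loc[counts.index, direction] = counts.values
    return out
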