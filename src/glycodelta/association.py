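"""Immune scoring and enzyme/glycopeptide association analyses.

Single-sample GSEA (ssGSEA) scores each sample for each gene signature
from the ranks of its expression values: genes are sorted descending,
and the score is the sum over the ranked list of the difference between
the weighted in-set empirical CDF (weights ``|value|**alpha``, default
alpha 0.25) and the uniform out-of-set ECDF.  With ``alpha = 0`` the
score depends on ranks alone and is invariant to any strictly
monotone transform of a sample's values.

Composite rows summarize the signature matrix: StromaScore is the mean
of designated stromal signatures (fibroblasts, endothelial cells by
default) and MicroenvironmentScore the mean over all immune and
stromal signatures.

Differential enrichment between groups pairs a Student's t-test with a
fold gate (default >=1.25x).  Because enrichment scores can be
negative, each signature is shifted so its minimum is zero before the
fold is computed; the call is therefore invariant to adding a constant
to a signature's scores.

The Spearman screen correlates feature rows of one matrix against rows
of another over pairwise-complete samples, retaining pairs passing a
correlation threshold (positive-only ``rho > rho_min`` by default, or
two-sided ``|rho| > rho_min``) at p < alpha.  Over-representation of a
query gene set against an annotation collection uses the
hypergeometric upper tail with Benjamini–Hochberg correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quant import StudyDesign

__all__ = [
    "AssociationThresholds",
    "read_gmt",
    "write_gmt",
    "ssgsea_scores",
    "composite_scores",
    "immune_differential",
    "select_glycosyltransferases",
    "spearman_screen",
    "intersect_with_de",
    "ora_enrichment",
]

DEFAULT_STROMAL_SIGNATURES = ("Fibroblasts", "Endothelial cells")


@dataclass(frozen=True)
class AssociationThresholds:
    """Cutoffs for correlation screens and immune differential calls."""

    rho_min: float = 0.6
    alpha: float = 0.05
    immune_fold_min: float = 1.25

    def __post_init__(self) -> None:
        if not (0 < self.rho_min < 1):
            raise ValueError("rho_min must be in (0, 1)")


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT file → {set name: gene list}. Description field ignored."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            genes = [g for g in parts[2:] if g]
            if genes:
                sets[parts[0]] = genes
    if not sets:
        raise ValueError(f"no gene sets parsed from {path}")
    return sets


def write_gmt(sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def _ssgsea_one(values: pd.Series, members: set, alpha: float) -> float:
    """Raw ssGSEA enrichment score of one sample against one set."""
    v = values.dropna()
    order = v.sort_values(ascending=False, kind="stable")
    in_set = order.index.isin(members)
    n_in = int(in_set.sum())
    n_out = len(order) - n_in
    if n_in == 0 or n_out == 0:
        return np.nan
    w = np.abs(order.to_numpy()) ** alpha
    w_in = np.where(in_set, w, 0.0)
    cdf_in = np.cumsum(w_in) / w_in.sum()
    cdf_out = np.cumsum(~in_set) / n_out
    return float(np.sum(cdf_in - cdf_out))


def ssgsea_scores(
    expr: pd.DataFrame,
    sets: dict[str, list[str]],
    alpha_weight: float = 0.25,
    normalize: bool = False,
) -> pd.DataFrame:
    """ssGSEA enrichment of each signature in each sample.

    ``expr`` is a feature × sample matrix (e.g. protein log2 ratios as
    gene proxies).  Missing values are dropped per sample before
    ranking — no imputation.  Signatures with no member in the matrix
    rows are dropped with a warning; if none overlap, raises.  With
    ``normalize=True`` all scores are divided by the spread
    (max − min) of the raw score matrix, as in the common
    single-sample implementation.
    """
    kept = {}
    for name, genes in sets.items():
        members = set(genes) & set(expr.index)
        if members:
            kept[name] = members
        else:
            import logging

            logging.getLogger(__name__).warning(
                "signature %r has no member in the expression matrix; dropped", name
            )
    if not kept:
        raise ValueError("no signature overlaps the expression matrix rows")
    out = pd.DataFrame(
        {
            s: {name: _ssgsea_one(expr[s], members, alpha_weight) for name, members in kept.items()}
            for s in expr.columns
        }
    )
    out = out.loc[list(kept)]
    if normalize:
        spread = np.nanmax(out.to_numpy()) - np.nanmin(out.to_numpy())
        if spread > 0:
            out = out / spread
    out.index.name = "signature"
    return out


def composite_scores(
    sm: pd.DataFrame,
    stromal_signatures=DEFAULT_STROMAL_SIGNATURES,
    all_signatures=None,
) -> pd.DataFrame:
    """Append StromaScore / MicroenvironmentScore rows to a score matrix.

    StromaScore is the column-wise mean of the stromal signatures
    present; MicroenvironmentScore the mean over ``all_signatures``
    (default: every non-composite row).
    """
    stromal = [s for s in stromal_signatures if s in sm.index]
    if not stromal:
        raise ValueError("none of the stromal signatures are in the score matrix")
    every = list(all_signatures) if all_signatures is not None else list(sm.index)
    every = [s for s in every if s not in ("StromaScore", "MicroenvironmentScore")]
    out = sm.copy()
    out.loc["StromaScore"] = sm.loc[stromal].mean(axis=0)
    out.loc["MicroenvironmentScore"] = sm.loc[every].mean(axis=0)
    return out


def immune_differential(
    sm: pd.DataFrame,
    design: StudyDesign,
    th: AssociationThresholds | None = None,
    group_a: str = "Tumor",
    group_b: str = "NAT",
) -> pd.DataFrame:
    """Per-signature enrichment call between two sample groups.

    A signature is ``enriched_in_a``/``enriched_in_b`` when the t-test
    p-value is below alpha AND the fold difference of min-shifted
    scores is at least ``immune_fold_min`` in that direction; otherwise
    ``ns``.  Min-shifting (subtracting each signature's minimum over
    both groups) makes the fold well defined for negative enrichment
    scores and the call invariant to constant offsets.
    """
    th = th or AssociationThresholds()
    cols_a = [s for s in design.condition_samples(group_a) if s in sm.columns]
    cols_b = [s for s in design.condition_samples(group_b) if s in sm.columns]
    rows = []
    for sig in sm.index:
        a = sm.loc[sig, cols_a].to_numpy(dtype=float)
        b = sm.loc[sig, cols_b].to_numpy(dtype=float)
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if len(a) < 2 or len(b) < 2:
            rows.append((sig, np.nan, np.nan, "ns"))
            continue
        shift = min(a.min(), b.min())
        sa, sb = a - shift, b - shift
        ma, mb = sa.mean(), sb.mean()
        if ma == mb:
            fold = 1.0
        elif mb == 0 or ma == 0:
            fold = np.inf if ma > mb else 0.0
        else:
            fold = ma / mb
        p = stats.ttest_ind(a, b, equal_var=True).pvalue
        if np.isnan(p) and np.allclose(a.mean(), b.mean()):
            p = 1.0
        call = "ns"
        if p < th.alpha and fold >= th.immune_fold_min:
            call = "enriched_in_a"
        elif p < th.alpha and fold > 0 and fold <= 1.0 / th.immune_fold_min:
            call = "enriched_in_b"
        rows.append((sig, fold, p, call))
    return pd.DataFrame(
        rows, columns=["signature", "fold", "p_value", "call"]
    ).set_index("signature")


def select_glycosyltransferases(proteome_ids, gt_list) -> list[str]:
    """Quantified proteins that are in a curated glycosyltransferase list."""
    return sorted(set(proteome_ids) & set(gt_list))


def spearman_screen(
    x_matrix: pd.DataFrame,
    y_matrix: pd.DataFrame,
    th: AssociationThresholds | None = None,
    min_n: int = 5,
    use_abs: bool = False,
) -> pd.DataFrame:
    """Spearman correlation of every x row against every y row.

    Samples are matched on shared columns; each pair uses its
    pairwise-complete observations (mid-rank ties, t-approximation
    p-value) and needs at least ``min_n`` of them.  Returns all tested
    pairs with a boolean ``retained`` column: rho > rho_min (or
    |rho| > rho_min with ``use_abs``) and p < alpha.
    """
    th = th or AssociationThresholds()
    common = [c for c in x_matrix.columns if c in set(y_matrix.columns)]
    if len(common) < min_n:
        raise ValueError(f"only {len(common)} shared samples; need >= {min_n}")
    xs = x_matrix[common]
    ys = y_matrix[common]
    rows = []
    for xid, xrow in xs.iterrows():
        xv = xrow.to_numpy(dtype=float)
        for yid, yrow in ys.iterrows():
            yv = yrow.to_numpy(dtype=float)
            mask = ~np.isnan(xv) & ~np.isnan(yv)
            n = int(mask.sum())
            if n < min_n:
                continue
            rho, p = stats.spearmanr(xv[mask], yv[mask])
            stat = abs(rho) if use_abs else rho
            retained = bool(stat > th.rho_min and p < th.alpha)
            rows.append((xid, yid, rho, p, n, retained))
    return pd.DataFrame(
        rows, columns=["x_id", "y_id", "rho", "p_value", "n", "retained"]
    )


def intersect_with_de(
    correlated: pd.DataFrame, de_calls: pd.DataFrame, label: str = "up"
) -> pd.DataFrame:
    """Features both retained in a correlation screen and called DE.

    ``correlated`` is a :func:`spearman_screen` output (y_id gives the
    feature); ``de_calls`` a classified differential table.  The result
    carries provenance: rho, p, fold change, branch.
    """
    hits = correlated[correlated["retained"]]
    de_ids = set(de_calls.index[de_calls["label"] == label])
    hits = hits[hits["y_id"].isin(de_ids)].copy()
    hits["fold_change"] = hits["y_id"].map(de_calls["fold_change"])
    hits["de_p_value"] = hits["y_id"].map(de_calls["p_value"])
    hits["branch"] = hits["y_id"].map(de_calls["branch"])
    return hits.reset_index(drop=True)


def ora_enrichment(
    query, annotation: dict[str, list[str]], universe
) -> pd.DataFrame:
    """Over-representation of ``query`` in each annotation term.

    Hypergeometric upper-tail p-value of drawing at least the observed
    overlap when sampling ``len(query)`` genes from the universe, BH
    corrected across terms.  Query and terms are intersected with the
    universe first.
    """
    uni = set(universe)
    q = set(query) & uni
    if not uni:
        raise ValueError("empty universe")
    rows = []
    for term, genes in annotation.items():
        t = set(genes) & uni
        if not t:
            continue
        k = len(q & t)
        p = stats.hypergeom.sf(k - 1, len(uni), len(t), len(q))
        rows.append((term, k, len(t), p))
    out = pd.DataFrame(rows, columns=["term", "overlap", "term_size", "p_value"])
    if len(out):
        out["bh_fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)
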