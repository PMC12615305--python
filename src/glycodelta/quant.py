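"""Quantification-table handling and TMT normalization.

The tissue study design is a paired tumor/NAT TMT experiment split over
several batches, each carrying a pooled internal reference channel
labeled identically in every batch.  Quantities flow through:

1. per-batch channel-total normalization (each channel's intensity sum
   is scaled to the median channel total of its batch),
2. ratioing of every sample channel to the batch's reference channel,
3. log2 transform,
4. integration of the per-batch log2-ratio tables into one matrix.

Single-batch designs (no reference channel, e.g. knockdown cell lines)
instead use channel-total normalization followed by a plain log2
transform.  Missing values are never imputed anywhere: zero or absent
intensities stay missing through every step, and features are screened
by the fraction of samples in which they were quantified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

log = logging.getLogger(__name__)

__all__ = [
    "StudyDesign",
    "FilterPolicy",
    "FilterReport",
    "SchemaError",
    "GLYCOPEPTIDE_COLUMNS",
    "PROTEIN_COLUMNS",
    "glycopeptide_key",
    "read_design",
    "read_quant_table",
    "normalize_batch",
    "ratio_to_reference",
    "integrate_batches",
    "normalize_multibatch",
    "normalize_single_batch",
    "apply_filter",
    "pca_summary",
]

GLYCOPEPTIDE_COLUMNS = ("accession", "site", "peptide", "glycan_composition")
PROTEIN_COLUMNS = ("accession", "unique_peptides")

DESIGN_COLUMNS = ("sample_id", "batch", "channel", "condition", "pair_id", "is_reference")


class SchemaError(ValueError):
    """A table is missing required columns or violates the design contract."""


@dataclass(frozen=True)
class StudyDesign:
    """Sample → batch/channel/condition bookkeeping for a TMT study.

    ``table`` has one row per labeled channel with columns
    ``sample_id, batch, channel, condition, pair_id, is_reference``.
    Multi-batch designs must carry exactly one reference channel per
    batch; single-batch designs carry none.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in DESIGN_COLUMNS if c not in t.columns]
        if missing:
            raise SchemaError(f"design is missing column(s): {missing}")
        if t["sample_id"].duplicated().any():
            dups = sorted(t.loc[t["sample_id"].duplicated(), "sample_id"])
            raise SchemaError(f"duplicated sample_id(s) in design: {dups}")
        if t.duplicated(subset=["batch", "channel"]).any():
            raise SchemaError("duplicated (batch, channel) assignment in design")
        n_ref = t.groupby("batch")["is_reference"].sum()
        if len(self.batches) > 1 and not (n_ref == 1).all():
            raise SchemaError(
                "multi-batch design requires exactly one reference channel per "
                f"batch; got {n_ref.to_dict()}"
            )
        if len(self.batches) == 1 and n_ref.iloc[0] not in (0, 1):
            raise SchemaError("at most one reference channel per batch")
        # paired designs: a pair is one tumor plus one NAT
        paired = t[t["pair_id"].notna() & ~t["is_reference"].astype(bool)]
        for pid, grp in paired.groupby("pair_id"):
            conds = sorted(grp["condition"])
            if conds != ["NAT", "Tumor"]:
                raise SchemaError(
                    f"pair {pid!r} must have exactly one Tumor and one NAT sample, got {conds}"
                )

    @property
    def batches(self) -> list:
        return sorted(self.table["batch"].unique())

    @property
    def is_single_batch(self) -> bool:
        return len(self.batches) == 1 and not self.table["is_reference"].any()

    def samples(self, batch=None, include_reference: bool = False) -> list[str]:
        t = self.table
        if batch is not None:
            t = t[t["batch"] == batch]
        if not include_reference:
            t = t[~t["is_reference"].astype(bool)]
        return list(t["sample_id"])

    def reference_sample(self, batch) -> str:
        t = self.table
        ref = t[(t["batch"] == batch) & t["is_reference"].astype(bool)]
        if len(ref) != 1:
            raise SchemaError(f"batch {batch!r} has no unique reference channel")
        return ref["sample_id"].iloc[0]

    def condition_samples(self, condition: str) -> list[str]:
        t = self.table
        mask = (t["condition"] == condition) & ~t["is_reference"].astype(bool)
        return list(t.loc[mask, "sample_id"])


def read_design(path) -> StudyDesign:
    """Read a study design from TSV/CSV (or YAML with a ``samples`` list)."""
    path = str(path)
    if path.endswith((".yaml", ".yml")):
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        table = pd.DataFrame(data["samples"])
    else:
        table = pd.read_csv(path, sep=None, engine="python")
    if "pair_id" not in table.columns:
        table["pair_id"] = pd.NA
    if "is_reference" not in table.columns:
        table["is_reference"] = False
    table["is_reference"] = table["is_reference"].astype(bool)
    return StudyDesign(table)


@dataclass(frozen=True)
class FilterPolicy:
    """Missingness / evidence filter applied before statistics.

    ``min_fraction_quantified`` — minimum fraction of (non-reference)
    samples in which a feature must be quantified (inclusive bound).
    ``min_unique_peptides`` — minimum unique-peptide evidence; applied
    to protein tables only.
    """

    min_fraction_quantified: float = 0.5
    min_unique_peptides: int = 2

    def __post_init__(self) -> None:
        if not (0.0 < self.min_fraction_quantified <= 1.0):
            raise ValueError("min_fraction_quantified must be in (0, 1]")


@dataclass
class FilterReport:
    n_input: int
    n_retained: int
    n_dropped_missingness: int
    n_dropped_evidence: int = 0
    policy: FilterPolicy = field(default_factory=FilterPolicy)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_dropped_missingness": self.n_dropped_missingness,
            "n_dropped_evidence": self.n_dropped_evidence,
            "min_fraction_quantified": self.policy.min_fraction_quantified,
            "min_unique_peptides": self.policy.min_unique_peptides,
        }


def glycopeptide_key(df: pd.DataFrame) -> pd.Series:
    """Canonical glycopeptide feature key: accession|site|peptide|composition."""
    return (
        df["accession"].astype(str)
        + "|"
        + df["site"].astype(int).astype(str)
        + "|"
        + df["peptide"].astype(str)
        + "|"
        + df["glycan_composition"].astype(str)
    )


def read_quant_table(path, kind: str) -> pd.DataFrame:
    """Read a glycopeptide or protein quantification table.

    Delimited text (TSV or CSV, sniffed) with the annotation columns of
    ``GLYCOPEPTIDE_COLUMNS`` / ``PROTEIN_COLUMNS`` plus one numeric
    intensity column per sample.  Returns a feature × sample intensity
    DataFrame indexed by the canonical feature key, with annotation
    columns preserved in ``df.attrs["meta"]``.  Rows sharing a feature
    key (within one file) have their channel intensities summed.
    Non-positive intensities are treated as missing.
    """
    if kind not in ("glycopeptide", "protein"):
        raise ValueError(f"kind must be 'glycopeptide' or 'protein', got {kind!r}")
    df = pd.read_csv(path, sep=None, engine="python")
    required = GLYCOPEPTIDE_COLUMNS if kind == "glycopeptide" else PROTEIN_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{kind} table {path} is missing column(s): {missing}")
    sample_cols = [c for c in df.columns if c not in required]
    if not sample_cols:
        raise SchemaError(f"{kind} table {path} has no intensity columns")
    for c in sample_cols:
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = df[c].notna() & vals.isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise SchemaError(
                f"non-numeric intensity in column {c!r} of {path} at line {line}"
            )
        df[c] = vals
    key = glycopeptide_key(df) if kind == "glycopeptide" else df["accession"].astype(str)
    if key.duplicated().any():
        n_dup = int(key.duplicated().sum())
        log.warning("%s table %s: summing %d duplicate feature row(s)", kind, path, n_dup)
    meta = df[list(required)].groupby(key.values).first()
    intens = df[sample_cols].groupby(key.values).sum(min_count=1)
    intens = intens.mask(intens <= 0)
    intens.index.name = "feature_id"
    intens.attrs["meta"] = meta
    intens.attrs["kind"] = kind
    return intens


def normalize_batch(intensities: pd.DataFrame, center: str = "median") -> pd.DataFrame:
    """Scale each channel so its total matches the batch's typical total.

    Each column (channel) is multiplied by ``target / column_total``
    where ``target`` is the median (or mean) of the per-column totals
    over non-missing values.  Within-channel structure is unchanged.
    """
    if intensities.shape[1] < 1:
        raise ValueError("need at least one channel")
    totals = intensities.sum(axis=0, skipna=True)
    empty = totals[intensities.notna().sum(axis=0) == 0]
    if len(empty):
        raise ValueError(f"channel(s) with no quantified values: {list(empty.index)}")
    target = totals.median() if center == "median" else totals.mean()
    return intensities * (target / totals)


def ratio_to_reference(
    batch: pd.DataFrame, reference: str, drop_reference: bool = True
) -> pd.DataFrame:
    """Log2 sample-to-reference ratios for one normalized batch.

    Features whose reference intensity is missing get missing ratios in
    every channel of the batch (no pseudo-reference is substituted).
    The reference column itself is identically zero and is dropped by
    default.
    """
    if reference not in batch.columns:
        raise ValueError(f"reference channel {reference!r} not in batch columns")
    ref = batch[reference]
    n_lost = int((ref.isna() & batch.drop(columns=[reference]).notna().any(axis=1)).sum())
    if n_lost:
        log.warning(
            "%d feature(s) lose a batch: reference channel %s not quantified",
            n_lost,
            reference,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.log2(batch.div(ref, axis=0))
    valid = batch.notna().mul(ref.notna(), axis=0)
    ratios = ratios.where(valid)
    if drop_reference:
        ratios = ratios.drop(columns=[reference])
    return ratios


def integrate_batches(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Outer-join per-batch log2-ratio tables into one matrix.

    Sample ids must not repeat across batches; features absent from a
    batch are missing in that batch's columns.
    """
    all_cols = [c for t in tables for c in t.columns]
    if len(all_cols) != len(set(all_cols)):
        dup = sorted({c for c in all_cols if all_cols.count(c) > 1})
        raise ValueError(f"sample id(s) appear in more than one batch: {dup}")
    tables = list(tables)
    for t in tables:  # inherited attrs can hold unhashable metadata
        t.attrs = {}
    out = pd.concat(tables, axis=1, join="outer")
    out.index.name = "feature_id"
    return out


def normalize_multibatch(
    intensities: pd.DataFrame, design: StudyDesign, center: str = "median"
) -> pd.DataFrame:
    """Full multi-batch pipeline: per-batch normalize → ratio → integrate."""
    per_batch = []
    for b in design.batches:
        cols = design.samples(batch=b, include_reference=True)
        missing = [c for c in cols if c not in intensities.columns]
        if missing:
            raise SchemaError(f"intensity table lacks sample column(s) {missing}")
        sub = intensities[cols]
        sub = sub.loc[sub.notna().any(axis=1)]
        sub = normalize_batch(sub, center=center)
        per_batch.append(ratio_to_reference(sub, design.reference_sample(b)))
    return integrate_batches(per_batch)


def normalize_single_batch(
    intensities: pd.DataFrame, design: StudyDesign | None = None, center: str = "median"
) -> pd.DataFrame:
    """Channel-total normalization followed by log2 (single-batch mode)."""
    cols = design.samples() if design is not None else list(intensities.columns)
    sub = normalize_batch(intensities[cols], center=center)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log2(sub)
    return out.where(sub.notna() & (sub > 0))


def apply_filter(
    m: pd.DataFrame,
    policy: FilterPolicy | None = None,
    unique_peptides: pd.Series | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Drop features quantified in too few samples (and, for proteins,
    with insufficient unique-peptide evidence).

    The quantified fraction is computed over the columns of ``m``;
    reference channels should already have been dropped by ratioing.
    The threshold is inclusive: a feature present in exactly
    ``min_fraction_quantified`` of samples is retained.  Idempotent.
    """
    policy = policy or FilterPolicy()
    frac = m.notna().mean(axis=1)
    keep = frac >= policy.min_fraction_quantified
    n_missingness = int((~keep).sum())
    n_evidence = 0
    if unique_peptides is not None:
        up = unique_peptides.reindex(m.index)
        evid = up.notna() & (up >= policy.min_unique_peptides)
        n_evidence = int((keep & ~evid).sum())
        keep &= evid
    out = m.loc[keep]
    report = FilterReport(
        n_input=len(m),
        n_retained=len(out),
        n_dropped_missingness=n_missingness,
        n_dropped_evidence=n_evidence,
        policy=policy,
    )
    return out, report


@dataclass
class PCAResult:
    variance_ratio: np.ndarray  # per-component fraction of variance, non-increasing
    scores: pd.DataFrame  # samples × components
    n_features: int  # complete-case features used


def pca_summary(m: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """PCA of samples using complete-case features only.

    Features with any missing value are excluded (no imputation); each
    remaining feature is mean-centered across samples, no variance
    scaling (log2 ratios already share a scale).  Scores are the sample
    coordinates on the principal axes, zero-mean per component.
    """
    complete = m.dropna(axis=0)
    if complete.shape[0] < 2:
        raise ValueError(
            f"only {complete.shape[0]} feature(s) complete in all samples; "
            "PCA needs >=2 — consider a stricter missingness filter"
        )
    if complete.shape[1] < 3:
        raise ValueError("PCA needs at least 3 samples")
    x = complete.to_numpy().T  # samples × features
    k = n_components or min(x.shape[0] - 1, x.shape[1])
    p = PCA(n_components=k)
    scores = p.fit_transform(x)
    return PCAResult(
        variance_ratio=p.explained_variance_ratio_,
        scores=pd.DataFrame(
            scores, index=complete.columns, columns=[f"PC{i+1}" for i in range(k)]
        ),
        n_features=complete.shape[0],
    )
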