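"""End-to-end orchestration of the analysis stages.

``run_pipeline`` wires the stages together for one study: read tables
and design → normalize (multi-batch reference ratioing or single-batch
log2) → missingness/evidence filters → landscape and microheterogeneity
summaries → protein DE and protein-corrected glycopeptide calls →
optional association analyses (ssGSEA scoring, immune differential,
glycosyltransferase screen, enzyme–glycopeptide correlations).  Every
table it writes is TSV; the headline numbers land in ``summary.json``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .association import (
    AssociationThresholds,
    composite_scores,
    immune_differential,
    intersect_with_de,
    read_gmt,
    select_glycosyltransferases,
    spearman_screen,
    ssgsea_scores,
)
from .differential import (
    Thresholds,
    classify_glycopeptides,
    de_by_glycan_type,
    feature_stats,
    call_protein_de,
)
from .quant import (
    FilterPolicy,
    apply_filter,
    normalize_multibatch,
    normalize_single_batch,
    pca_summary,
    read_design,
    read_quant_table,
)
from .subtypes import (
    compare_cohorts,
    glycans_per_site_distribution,
    landscape_counts,
    sequon_proportions,
    sites_per_protein_distribution,
    top_glycans_by_site_count,
    type_cooccurrence_at_sites,
    type_proportions,
)

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """The pipeline configuration is inconsistent or incomplete."""


class DataError(ValueError):
    """An input table failed validation at run time."""


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run.

    ``mode`` is ``tissue_multibatch`` (reference-channel ratioing,
    tumor vs NAT) or ``cellline_singlebatch`` (total normalization +
    log2, GroupA vs GroupB, decrease cutoff ``fc_down_alt``).
    """

    glycopeptide_table: str
    design: str
    protein_table: str | None = None
    gene_sets: str | None = None  # GMT with immune/stromal signatures
    glycosyltransferases: str | None = None  # one accession per line
    mode: str = "tissue_multibatch"
    group_a: str = "Tumor"
    group_b: str = "NAT"
    thresholds: Thresholds = field(default_factory=Thresholds)
    filter_policy: FilterPolicy = field(default_factory=FilterPolicy)
    association: AssociationThresholds = field(default_factory=AssociationThresholds)
    paired: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "thresholds" in kwargs:
            kwargs["thresholds"] = Thresholds(**kwargs["thresholds"])
        if "filter_policy" in kwargs:
            kwargs["filter_policy"] = FilterPolicy(**kwargs["filter_policy"])
        if "association" in kwargs:
            kwargs["association"] = AssociationThresholds(**kwargs["association"])
        try:
            return cls(**kwargs)
        except TypeError as e:
            raise ConfigError(str(e)) from e

    def validate(self) -> None:
        if self.mode not in ("tissue_multibatch", "cellline_singlebatch"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        for name in ("glycopeptide_table", "design", "protein_table", "gene_sets", "glycosyltransferases"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{name} path does not exist: {p}")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, index=True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Run every stage; returns (and writes) the summary dictionary."""
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "version": __version__,
        "mode": cfg.mode,
        "seed": cfg.seed,
        "inputs": {
            "glycopeptide_table": _sha256(cfg.glycopeptide_table),
            "design": _sha256(cfg.design),
        },
    }

    design = read_design(cfg.design)
    gp_raw = read_quant_table(cfg.glycopeptide_table, kind="glycopeptide")
    if gp_raw.empty:
        raise DataError(f"glycopeptide table {cfg.glycopeptide_table} has no features")
    gp_meta = gp_raw.attrs["meta"]

    # --- landscape -------------------------------------------------------
    records = gp_meta.reset_index(drop=True)
    n_gp, n_sites, n_prot = landscape_counts(records)
    summary["landscape"] = {
        "n_glycopeptides": n_gp,
        "n_glycosites": n_sites,
        "n_glycoproteins": n_prot,
        "sites_per_protein": sites_per_protein_distribution(records).to_dict(),
        "glycans_per_site": glycans_per_site_distribution(records).to_dict(),
        "sequon_proportions": sequon_proportions(records).to_dict(),
        "type_proportions_site_specific": type_proportions(
            records_site_specific(records)
        ).to_dict(),
        "type_proportions_unique": type_proportions(
            records["glycan_composition"], level="unique_composition"
        ).to_dict(),
    }
    _write(top_glycans_by_site_count(records).rename("n_sites").to_frame(), outdir / "top_glycans.tsv")
    _write(type_cooccurrence_at_sites(records).rename("n_sites").to_frame(), outdir / "type_cooccurrence.tsv")

    # --- normalization ---------------------------------------------------
    if cfg.mode == "tissue_multibatch":
        if design.is_single_batch:
            raise ConfigError("mode tissue_multibatch needs a multi-batch design with references")
        gp_mat = normalize_multibatch(gp_raw, design)
    else:
        gp_mat = normalize_single_batch(gp_raw, design)
    gp_filt, gp_report = apply_filter(gp_mat, cfg.filter_policy)
    summary["glycopeptide_filter"] = gp_report.to_dict()
    _write(gp_mat, outdir / "glycopeptides_normalized.tsv")
    try:
        pca = pca_summary(gp_filt)
        summary["pca"] = {
            "variance_ratio": [float(v) for v in pca.variance_ratio[:5]],
            "pc1_pc2_fraction": float(pca.variance_ratio[:2].sum()),
            "n_complete_features": pca.n_features,
        }
        _write(pca.scores, outdir / "pca_scores.tsv")
    except ValueError as e:
        summary["pca"] = {"skipped": str(e)}

    prot_filt = None
    if cfg.protein_table:
        pr_raw = read_quant_table(cfg.protein_table, kind="protein")
        if cfg.mode == "tissue_multibatch":
            pr_mat = normalize_multibatch(pr_raw, design)
        else:
            pr_mat = normalize_single_batch(pr_raw, design)
        prot_filt, pr_report = apply_filter(
            pr_mat, cfg.filter_policy, unique_peptides=pr_raw.attrs["meta"]["unique_peptides"]
        )
        summary["protein_filter"] = pr_report.to_dict()
        _write(pr_mat, outdir / "proteins_normalized.tsv")

    # --- differential ----------------------------------------------------
    th = cfg.thresholds
    gp_stats = feature_stats(gp_filt, design, cfg.group_a, cfg.group_b, paired=cfg.paired)
    if prot_filt is not None and len(prot_filt):
        prot_stats = feature_stats(prot_filt, design, cfg.group_a, cfg.group_b, paired=cfg.paired)
        prot_stats["label"] = [
            call_protein_de(fc, p, th)
            for fc, p in zip(prot_stats["fold_change"], prot_stats["p_value"])
        ]
        _write(prot_stats, outdir / "protein_differential.tsv")
        summary["protein_de"] = {
            "n_tested": len(prot_stats),
            "n_sig_up": int((prot_stats["label"] == "sig_up").sum()),
            "n_sig_down": int((prot_stats["label"] == "sig_down").sum()),
        }
    else:
        prot_stats = pd.DataFrame(columns=["fold_change", "p_value"])

    accession_of = gp_meta["accession"]
    fc_down = th.fc_down_alt if cfg.mode == "cellline_singlebatch" else None
    calls = classify_glycopeptides(
        gp_stats, prot_stats, accession_of, th, fc_down=fc_down
    )
    for col in ("accession", "site", "glycan_composition"):
        calls[col] = gp_meta[col].reindex(calls.index)
    _write(calls, outdir / "glycopeptide_differential.tsv")
    by_type = de_by_glycan_type(calls, gp_meta["glycan_composition"])
    _write(by_type, outdir / "de_by_glycan_type.tsv")
    summary["glycopeptide_de"] = {
        "n_tested": len(calls),
        "n_up": int((calls["label"] == "up").sum()),
        "n_down": int((calls["label"] == "down").sum()),
        "branches": calls["branch"].value_counts().to_dict(),
        "by_glycan_type": {t: [int(r["up"]), int(r["down"])] for t, r in by_type.iterrows()},
    }

    # --- association -----------------------------------------------------
    if cfg.gene_sets and prot_filt is not None and len(prot_filt):
        sets = read_gmt(cfg.gene_sets)
        scores = composite_scores(
            ssgsea_scores(prot_filt, sets),
            stromal_signatures=[s for s in sets if "ibroblast" in s or "ndothelial" in s]
            or list(sets)[:1],
        )
        _write(scores, outdir / "ssgsea_scores.tsv")
        imm = immune_differential(scores, design, cfg.association, cfg.group_a, cfg.group_b)
        _write(imm, outdir / "immune_differential.tsv")
        summary["immune"] = {
            "n_signatures": len(scores),
            "n_enriched_in_a": int((imm["call"] == "enriched_in_a").sum()),
            "n_enriched_in_b": int((imm["call"] == "enriched_in_b").sum()),
        }
    if cfg.glycosyltransferases and prot_filt is not None and len(prot_filt):
        gt_list = [
            line.strip()
            for line in open(cfg.glycosyltransferases)
            if line.strip() and not line.startswith("#")
        ]
        gts = select_glycosyltransferases(prot_filt.index, gt_list)
        gt_sig = [
            g
            for g in gts
            if g in prot_stats.index and prot_stats.loc[g, "label"] != "not_sig"
        ]
        summary["glycosyltransferases"] = {
            "n_quantified": len(gts),
            "n_significant": len(gt_sig),
        }
        enz_up = [g for g in gt_sig if prot_stats.loc[g, "label"] == "sig_up"]
        if enz_up:
            corr = spearman_screen(prot_filt.loc[enz_up], gp_filt, cfg.association)
            _write(corr, outdir / "enzyme_glycopeptide_correlations.tsv", index=False)
            hits = intersect_with_de(corr, calls, label="up")
            _write(hits, outdir / "correlated_and_upregulated.tsv", index=False)
            summary["association"] = {
                "n_enzymes_up": len(enz_up),
                "n_correlated_pairs": int(corr["retained"].sum()),
                "n_correlated_and_up": int(hits["y_id"].nunique()),
            }

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def records_site_specific(records: pd.DataFrame) -> pd.Series:
    """Compositions of the distinct (accession, site, composition) triples."""
    return records.drop_duplicates(subset=["accession", "site", "glycan_composition"])[
        "glycan_composition"
    ]


def compare_runs(records_a: pd.DataFrame, records_b: pd.DataFrame) -> dict:
    """Two-cohort comparison report (exclusive/shared at both levels,
    per-cohort type proportions, top glycans)."""
    out = {}
    for level in ("site_specific", "unique_composition"):
        c = compare_cohorts(records_a, records_b, level=level)
        out[level] = {
            "exclusive_a": c.exclusive_a,
            "exclusive_b": c.exclusive_b,
            "shared": c.shared,
        }
    out["type_proportions_a"] = type_proportions(records_site_specific(records_a)).to_dict()
    out["type_proportions_b"] = type_proportions(records_site_specific(records_b)).to_dict()
    out["top_glycans_a"] = top_glycans_by_site_count(records_a).to_dict()
    out["top_glycans_b"] = top_glycans_by_site_count(records_b).to_dict()
    return out
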