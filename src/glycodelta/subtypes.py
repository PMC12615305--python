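"""Glycoproteomic landscape and cohort-comparison statistics.

Works on identification records — one row per observed glycopeptide
with columns ``accession, site, peptide, glycan_composition`` (plus an
optional ``cohort`` label).  The counting hierarchy:

* glycopeptide  = distinct (accession, site, peptide, composition),
* glycosite    = distinct (accession, site),
* glycoprotein = distinct accession,
* site-specific glycan composition = distinct (accession, site,
  composition) — a glycoform anchored to its site,
* unique glycan composition = distinct composition string, free of
  protein/site context.

Microheterogeneity summaries (sites per protein, glycans per site),
sequon-motif proportions, glycan-type proportions at either level,
two-cohort exclusive/shared set algebra, top-N glycans by site count,
per-protein glycoform diversity and glycan-type co-occurrence at sites
all derive from these keys.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .glycans import classify_glycan, classify_sequon

__all__ = [
    "CohortComparison",
    "dedupe_records",
    "landscape_counts",
    "sites_per_protein_distribution",
    "glycans_per_site_distribution",
    "sequon_proportions",
    "type_proportions",
    "compare_cohorts",
    "top_glycans_by_site_count",
    "glycoform_diversity_per_protein",
    "type_cooccurrence_at_sites",
]

RECORD_COLUMNS = ("accession", "site", "peptide", "glycan_composition")


@dataclass(frozen=True)
class CohortComparison:
    """Exclusive/shared counts between two cohorts at a given level."""

    exclusive_a: int
    exclusive_b: int
    shared: int
    level: str

    @property
    def total_a(self) -> int:
        return self.exclusive_a + self.shared

    @property
    def total_b(self) -> int:
        return self.exclusive_b + self.shared


def _check(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records are missing column(s): {missing}")
    return records


def dedupe_records(records: pd.DataFrame) -> pd.DataFrame:
    """Distinct glycopeptide rows (accession, site, peptide, composition)."""
    return _check(records).drop_duplicates(subset=list(RECORD_COLUMNS))


def landscape_counts(records: pd.DataFrame) -> tuple[int, int, int]:
    """(n_glycopeptides, n_glycosites, n_glycoproteins)."""
    r = dedupe_records(records)
    n_gp = len(r)
    n_sites = len(r.drop_duplicates(subset=["accession", "site"]))
    n_prot = r["accession"].nunique()
    return n_gp, n_sites, n_prot


def sites_per_protein_distribution(records: pd.DataFrame) -> pd.Series:
    """Proportion of glycoproteins with 1, 2, 3, … glycosites."""
    r = dedupe_records(records)
    per_protein = r.drop_duplicates(subset=["accession", "site"]).groupby("accession").size()
    dist = per_protein.value_counts(normalize=True).sort_index()
    dist.index.name = "n_sites"
    return dist


def glycans_per_site_distribution(
    records: pd.DataFrame, bins: tuple = (1, 2, (3, 5), (6, None))
) -> pd.Series:
    """Proportion of glycosites carrying various numbers of distinct
    glycan compositions, binned.

    ``bins`` entries are either an exact count or an inclusive
    ``(lo, hi)`` range with ``hi=None`` meaning unbounded.
    """
    r = _check(records).drop_duplicates(subset=["accession", "site", "glycan_composition"])
    per_site = r.groupby(["accession", "site"]).size()
    total = len(per_site)
    if total == 0:
        raise ValueError("no glycosites in records")
    out = {}
    for b in bins:
        if isinstance(b, tuple):
            lo, hi = b
            mask = per_site >= lo if hi is None else (per_site >= lo) & (per_site <= hi)
            label = f">{lo - 1}" if hi is None else f"{lo}-{hi}"
        else:
            mask = per_site == b
            label = str(b)
        out[label] = mask.sum() / total
    return pd.Series(out, name="proportion")


def sequon_proportions(
    records: pd.DataFrame, protein_seqs: dict[str, str] | None = None
) -> pd.Series:
    """Proportion of glycosites with N-X-T, N-X-S and N-X-C motifs.

    The motif is read from the peptide around the site; the ``site``
    column is a 1-based protein position, so a ``site_in_peptide``
    column (0-based) is used if present, else the first asparagine of
    the peptide.  Sites whose +2 residue lies beyond the peptide are
    resolved from ``protein_seqs`` (accession → sequence) when given;
    unresolvable or non-canonical sites are excluded from the
    denominator.
    """
    r = _check(records).drop_duplicates(subset=["accession", "site"], keep="first")
    labels = []
    for _, row in r.iterrows():
        pep = str(row["peptide"])
        if "site_in_peptide" in r.columns and pd.notna(row.get("site_in_peptide")):
            idx = int(row["site_in_peptide"])
        else:
            idx = pep.upper().find("N")
            if idx < 0:
                continue
        context = None
        if protein_seqs and row["accession"] in protein_seqs:
            seq = protein_seqs[row["accession"]]
            site0 = int(row["site"]) - 1  # 1-based protein position
            context = seq[site0 + (len(pep) - idx) :]
        try:
            labels.append(classify_sequon(pep, idx, context))
        except ValueError:
            continue
    labels = pd.Series(labels)
    labels = labels[labels != "invalid"]
    if labels.empty:
        raise ValueError("no classifiable sequons in records")
    props = labels.value_counts(normalize=True)
    return props.reindex(["NXT", "NXS", "NXC"], fill_value=0.0)


def type_proportions(compositions, level: str = "site_specific") -> pd.Series:
    """Glycan-class proportions of a composition multiset.

    ``level="site_specific"`` keeps the multiset as given (each
    site-anchored glycoform counts once); ``level="unique_composition"``
    first deduplicates to distinct composition strings.
    """
    comps = pd.Series(list(compositions), dtype=object)
    if level == "unique_composition":
        comps = comps.drop_duplicates()
    elif level != "site_specific":
        raise ValueError(f"unknown level {level!r}")
    if comps.empty:
        raise ValueError("no compositions supplied")
    return comps.map(classify_glycan).value_counts(normalize=True)


def _level_keys(records: pd.DataFrame, level: str) -> set:
    r = _check(records)
    if level == "site_specific":
        return set(
            zip(r["accession"], r["site"].astype(int), r["glycan_composition"])
        )
    if level == "unique_composition":
        return set(r["glycan_composition"])
    raise ValueError(f"unknown level {level!r}")


def compare_cohorts(
    a: pd.DataFrame, b: pd.DataFrame, level: str = "site_specific"
) -> CohortComparison:
    """Exclusive and shared glycoforms (or compositions) between cohorts."""
    ka, kb = _level_keys(a, level), _level_keys(b, level)
    return CohortComparison(
        exclusive_a=len(ka - kb),
        exclusive_b=len(kb - ka),
        shared=len(ka & kb),
        level=level,
    )


def top_glycans_by_site_count(records: pd.DataFrame, n: int = 10) -> pd.Series:
    """The ``n`` compositions borne by the most distinct glycosites.

    Ties are broken lexicographically on the composition string so the
    ranking is deterministic.
    """
    r = _check(records).drop_duplicates(subset=["accession", "site", "glycan_composition"])
    counts = r.groupby("glycan_composition").size()
    ordered = counts.sort_index().sort_values(ascending=False, kind="stable")
    return ordered.head(n)


def glycoform_diversity_per_protein(records: pd.DataFrame) -> pd.DataFrame:
    """Per-protein distinct composition and glycosite counts,
    descending by composition count then accession."""
    r = dedupe_records(records)
    g = r.groupby("accession")
    out = pd.DataFrame(
        {
            "n_unique_compositions": g["glycan_composition"].nunique(),
            "n_sites": g["site"].nunique(),
        }
    )
    return out.sort_values(
        ["n_unique_compositions", "n_sites"], ascending=False, kind="stable"
    )


def type_cooccurrence_at_sites(records: pd.DataFrame) -> pd.Series:
    """Count glycan-class subsets observed at individual glycosites.

    Each glycosite contributes exactly one subset — the set of glycan
    classes among its observed compositions — so the counts sum to the
    number of glycosites.  Index entries are '+'-joined sorted class
    names (long format, ready for UpSet-style plotting).
    """
    r = _check(records).drop_duplicates(subset=["accession", "site", "glycan_composition"])
    types = r["glycan_composition"].map(classify_glycan)
    subsets = (
        types.groupby([r["accession"], r["site"]])
        .apply(lambda s: "+".join(sorted(set(s))))
    )
    return subsets.value_counts()
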