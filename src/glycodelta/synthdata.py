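"""Synthetic paired tumor/NAT TMT glycoproteomics with known ground truth.

The generator emulates the tissue study design this package analyzes:
paired tumor and normal-adjacent (NAT) samples multiplexed into
TMT-10plex batches, each batch carrying a pooled internal reference
channel (the same channel label in every batch, built as the average
of all samples).  Per-channel log2 intensities are

    base + glycoform offset + patient effect + condition effect
         + batch effect + noise,

with a shared random patient effect on each tumor/NAT pair (so paired
and unpaired tests genuinely differ), per-feature batch effects that
the reference ratioing must cancel, per-channel loading factors that
channel-total normalization must cancel, and intensity-dependent
(missing-not-at-random) censoring of low values.

Condition effects come in five flavors, assigned so that every branch
of the protein-corrected classification has ground truth:

* ``direct_up`` / ``direct_down`` — glycopeptide-only log2 shifts on
  proteins whose abundance is flat,
* ``occupancy_down`` — the protein rises more than its glycopeptides
  (relative occupancy loss; true call *down* despite a rising
  glycopeptide),
* ``occupancy_up`` — the protein falls more than its glycopeptides,
* ``protein_only`` — the protein shifts, glycosylation does not: the
  glycopeptide fold change equals the protein's, a tie the decision
  tree deliberately leaves unchanged.

Glycan compositions are drawn per class from realistic grids (e.g.
high-mannose N2H5–N2H9) so composition-based classification
round-trips; sequon +2 residues follow the observed N-X-T/S/C mix.
Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .quant import StudyDesign

__all__ = ["SimConfig", "SimResult", "simulate", "landscape_design", "write_simulation"]

TMT10_CHANNELS = ("126", "127N", "127C", "128N", "128C", "129N", "129C", "130N", "130C", "131")
REFERENCE_CHANNEL = "128C"

# per-class composition grids: (hexnac range, hex range, fuc range, neuac range)
CLASS_GRIDS = {
    "mannose": [(2, 2), (5, 9), (0, 0), (0, 0)],
    "sialylated": [(3, 5), (4, 6), (0, 0), (1, 3)],
    "fucosylated": [(3, 5), (3, 6), (1, 2), (0, 0)],
    "complex_hybrid": [(3, 6), (3, 6), (0, 0), (0, 0)],
    "fucosylated_sialylated": [(3, 5), (4, 6), (1, 2), (1, 2)],
}

AA_POOL = "ADEFGHILMQSTVWY"  # no K/R/P/N/C to keep motif positions controllable


@dataclass
class SimConfig:
    """Generator parameters; defaults mirror the tissue study design.

    10 tumor/NAT pairs over 3 TMT-10plex batches with one pooled
    reference channel each; log2 noise sd 0.4; mild per-feature batch
    effects and per-channel loading factors; ~10% MNAR missingness.
    Sites per protein are geometric (78.8% single-site); glycoforms per
    site are 1 + NegBin(4, 0.557), giving ~9.6% single-glycan sites and
    ~25% sites with more than five glycoforms.  The glycan class
    mixture follows the site-specific proportions seen in tumor tissue
    (mannose-dominant, then fucosylated).
    """

    n_proteins: int = 300
    p_single_site: float = 0.788  # geometric parameter for sites/protein
    glycoforms_nb_size: float = 4.0
    glycoforms_nb_p: float = 0.557
    glycan_class_mixture: tuple = (0.34, 0.18, 0.225, 0.155, 0.10)
    sequon_mixture: tuple = (0.531, 0.418, 0.051)  # NXT, NXS, NXC
    n_pairs: int = 10
    n_batches: int = 3
    base_mean: float = 20.0  # log2 protein abundance
    base_sd: float = 1.5
    glycoform_offset_mean: float = -2.0
    glycoform_offset_sd: float = 1.0
    sigma_noise: float = 0.4  # log2 measurement noise
    patient_effect_sd: float = 0.3
    batch_effect_sd: float = 0.3  # per feature x batch
    channel_scale_sd: float = 0.2  # log2 per-channel loading
    missing_rate: float = 0.10  # overall MNAR target
    effect_log2fc: float = 1.0
    frac_direct_up: float = 0.05  # of glycopeptides, on flat proteins
    frac_direct_down: float = 0.04
    n_occupancy_up_proteins: int = 5
    n_occupancy_down_proteins: int = 5
    n_protein_only: int = 6
    occupancy_protein_log2fc: float = 2.0
    frac_protein_de_up: float = 0.03  # extra protein-level DE, no glycopeptides touched
    frac_single_peptide: float = 0.05  # proteins with 1 unique peptide
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.glycan_class_mixture) - 1.0) > 1e-9:
            raise ValueError("glycan_class_mixture must sum to 1")
        if abs(sum(self.sequon_mixture) - 1.0) > 1e-9:
            raise ValueError("sequon_mixture must sum to 1")
        per_batch = -(-self.n_pairs // self.n_batches)  # ceil
        if 2 * per_batch + 1 > len(TMT10_CHANNELS):
            raise ValueError(
                f"{self.n_pairs} pairs over {self.n_batches} TMT-10plex batches "
                "does not fit (2 channels per pair plus a reference)"
            )


@dataclass
class SimResult:
    glycopeptides: pd.DataFrame  # annotations + per-sample intensity columns
    proteins: pd.DataFrame
    design: StudyDesign
    ground_truth: pd.DataFrame  # per glycopeptide: deltas, true label/branch
    protein_truth: pd.DataFrame  # per protein: delta, true DE label
    config: SimConfig


def _make_design(cfg: SimConfig) -> StudyDesign:
    # pairs spread over batches as evenly as possible, pair kept within batch
    per_batch = [cfg.n_pairs // cfg.n_batches] * cfg.n_batches
    for i in range(cfg.n_pairs % cfg.n_batches):
        per_batch[i] += 1
    rows = []
    pair = 0
    for b in range(cfg.n_batches):
        batch = f"B{b + 1}"
        free = [c for c in TMT10_CHANNELS if c != REFERENCE_CHANNEL]
        for _ in range(per_batch[b]):
            pair += 1
            pid = f"P{pair:02d}"
            rows.append((f"T{pair:02d}", batch, free.pop(0), "Tumor", pid, False))
            rows.append((f"N{pair:02d}", batch, free.pop(0), "NAT", pid, False))
        rows.append((f"REF_{batch}", batch, REFERENCE_CHANNEL, "Reference", pd.NA, True))
    return StudyDesign(
        pd.DataFrame(rows, columns=["sample_id", "batch", "channel", "condition", "pair_id", "is_reference"])
    )


def _sample_compositions(rng: np.random.Generator, cls: str, k: int) -> list[str]:
    """k distinct compositions from a class grid (capped at grid size)."""
    (n0, n1), (h0, h1), (f0, f1), (s0, s1) = CLASS_GRIDS[cls]
    grid = [
        f"N{n}H{h}F{f}S{s}"
        for n in range(n0, n1 + 1)
        for h in range(h0, h1 + 1)
        for f in range(f0, f1 + 1)
        for s in range(s0, s1 + 1)
    ]
    k = min(k, len(grid))
    idx = rng.choice(len(grid), size=k, replace=False)
    return [grid[i] for i in idx]


def _make_peptide(rng: np.random.Generator, sequon_mixture) -> tuple[str, int]:
    """Random tryptic-like peptide with one sequon; returns (peptide, N index)."""
    third = rng.choice(["T", "S", "C"], p=list(sequon_mixture))
    left = "".join(rng.choice(list(AA_POOL), size=int(rng.integers(3, 7))))
    x = rng.choice(list(AA_POOL))  # never proline by pool construction
    right = "".join(rng.choice(list(AA_POOL), size=int(rng.integers(2, 5))))
    term = rng.choice(["K", "R"])
    pep = left + "N" + x + third + right + term
    return pep, len(left)


def _build_identifications(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    classes = list(CLASS_GRIDS)
    rows = []
    for p in range(cfg.n_proteins):
        acc = f"SYN{p:04d}"
        n_sites = int(rng.geometric(cfg.p_single_site))
        positions = np.sort(rng.choice(np.arange(30, 1200), size=n_sites, replace=False))
        for pos in positions:
            pep, idx = _make_peptide(rng, cfg.sequon_mixture)
            k = 1 + int(rng.negative_binomial(cfg.glycoforms_nb_size, cfg.glycoforms_nb_p))
            counts = rng.multinomial(k, cfg.glycan_class_mixture)
            comps: list[str] = []
            for cls, kc in zip(classes, counts):
                if kc:
                    comps.extend(_sample_compositions(rng, cls, int(kc)))
            for comp in comps:
                rows.append((acc, int(pos), pep, idx, comp))
    return pd.DataFrame(
        rows, columns=["accession", "site", "peptide", "site_in_peptide", "glycan_composition"]
    )


def _assign_effects(
    cfg: SimConfig, rng: np.random.Generator, ids: pd.DataFrame
) -> tuple[pd.Series, pd.Series, pd.Series]:
    """Per-protein prot_delta, per-protein role, per-glycopeptide gp_delta."""
    accs = ids["accession"].unique()
    rng.shuffle(accs)
    prot_delta = pd.Series(0.0, index=accs)
    role = pd.Series("null", index=accs)
    cursor = 0

    def take(n):
        nonlocal cursor
        sel = accs[cursor : cursor + n]
        cursor += n
        return sel

    for acc in take(cfg.n_occupancy_down_proteins):
        role[acc] = "occupancy_down"
        prot_delta[acc] = cfg.occupancy_protein_log2fc
    for acc in take(cfg.n_occupancy_up_proteins):
        role[acc] = "occupancy_up"
        prot_delta[acc] = -cfg.occupancy_protein_log2fc
    for acc in take(cfg.n_protein_only):
        role[acc] = "protein_only"
        prot_delta[acc] = cfg.effect_log2fc * (1 if rng.random() < 0.5 else -1)
    n_prot_de = int(round(cfg.frac_protein_de_up * len(accs)))
    for acc in take(n_prot_de):
        role[acc] = "protein_de_extra"
        prot_delta[acc] = cfg.effect_log2fc

    gp_delta = pd.Series(0.0, index=ids.index)
    parent_role = ids["accession"].map(role)
    gp_delta[parent_role == "occupancy_down"] = -cfg.effect_log2fc
    gp_delta[parent_role == "occupancy_up"] = cfg.effect_log2fc
    null_gp = ids.index[parent_role == "null"].to_numpy()
    rng.shuffle(null_gp)
    n_up = int(round(cfg.frac_direct_up * len(ids)))
    n_down = int(round(cfg.frac_direct_down * len(ids)))
    gp_delta[null_gp[:n_up]] = cfg.effect_log2fc
    gp_delta[null_gp[n_up : n_up + n_down]] = -cfg.effect_log2fc
    return prot_delta, role, gp_delta


def _true_call(gp_fc: float, prot_delta: float, fc_up=1.5, fc_down=0.67):
    """Ground-truth label/branch from noiseless fold changes.

    Significance gates are replaced by the truth: a change is
    'significant' iff its underlying log2 delta is non-zero.
    """
    prot_fc = float(np.exp2(prot_delta))
    prot_sig = prot_delta != 0.0
    if gp_fc > fc_up and gp_fc != 1.0:
        if not prot_sig:
            return "up", "A_direct_up"
        if gp_fc > prot_fc:
            return "up", "A_direct_up"
        if prot_fc > gp_fc and prot_delta > 0:
            return "down", "D_occupancy_down"
        return "unchanged", "none"
    if gp_fc < fc_down and gp_fc != 1.0:
        if not prot_sig:
            return "down", "C_direct_down"
        if gp_fc < prot_fc:
            return "down", "C_direct_down"
        if prot_fc < gp_fc and prot_delta < 0:
            return "up", "B_occupancy_up"
        return "unchanged", "none"
    return "unchanged", "none"


def _mnar_censor(
    rng: np.random.Generator, log2_int: np.ndarray, rate: float, slope: float = 1.0
) -> np.ndarray:
    """Boolean mask of censored entries, logistic in log2 intensity."""
    if rate <= 0:
        return np.zeros_like(log2_int, dtype=bool)
    flat = log2_int[np.isfinite(log2_int)]
    lo, hi = flat.min() - 5, flat.max() + 5
    for _ in range(60):  # bisect the midpoint to hit the target mean rate
        mid = 0.5 * (lo + hi)
        mean_p = np.mean(1.0 / (1.0 + np.exp((flat - mid) / slope)))
        if mean_p < rate:
            lo = mid
        else:
            hi = mid
    p_miss = 1.0 / (1.0 + np.exp((log2_int - mid) / slope))
    return rng.random(size=log2_int.shape) < p_miss


def simulate(cfg: SimConfig | None = None) -> SimResult:
    """Generate one synthetic study; deterministic under ``cfg.seed``."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    design = _make_design(cfg)
    ids = _build_identifications(cfg, rng)
    prot_delta, role, gp_delta = _assign_effects(cfg, rng, ids)

    dtab = design.table
    samples = dtab[~dtab["is_reference"]]
    sample_ids = list(samples["sample_id"])
    n_feat = len(ids)
    n_prot = cfg.n_proteins
    accs = sorted(ids["accession"].unique())
    acc_idx = {a: i for i, a in enumerate(accs)}

    base_prot = rng.normal(cfg.base_mean, cfg.base_sd, size=len(accs))
    gp_offset = rng.normal(cfg.glycoform_offset_mean, cfg.glycoform_offset_sd, size=n_feat)
    parent = ids["accession"].map(acc_idx).to_numpy()

    pair_ids = sorted(samples["pair_id"].unique())
    pair_idx = {p: i for i, p in enumerate(pair_ids)}
    # shared patient effect per feature (glycopeptide and protein layers separate)
    u_gp = rng.normal(0.0, cfg.patient_effect_sd, size=(n_feat, len(pair_ids)))
    u_pr = rng.normal(0.0, cfg.patient_effect_sd, size=(len(accs), len(pair_ids)))
    batches = design.batches
    b_gp = rng.normal(0.0, cfg.batch_effect_sd, size=(n_feat, len(batches)))
    b_pr = rng.normal(0.0, cfg.batch_effect_sd, size=(len(accs), len(batches)))
    bidx = {b: i for i, b in enumerate(batches)}
    all_chan = list(dtab["sample_id"])
    chan_scale = dict(zip(all_chan, rng.normal(0.0, cfg.channel_scale_sd, size=len(all_chan))))

    def layer_log2(base, u, bfx, delta, noise_sd):
        """log2 intensity matrix (features × channels incl. references)."""
        cols = {}
        # sample channels
        for _, row in samples.iterrows():
            tumor = row["condition"] == "Tumor"
            x = (
                base
                + u[:, pair_idx[row["pair_id"]]]
                + (delta if tumor else 0.0)
                + bfx[:, bidx[row["batch"]]]
            )
            if noise_sd > 0:
                x = x + rng.normal(0.0, noise_sd, size=len(base))
            cols[row["sample_id"]] = x + chan_scale[row["sample_id"]]
        # pooled reference: linear mean of every sample's noiseless amount
        pooled = np.zeros(len(base))
        for _, row in samples.iterrows():
            tumor = row["condition"] == "Tumor"
            pooled += np.exp2(base + u[:, pair_idx[row["pair_id"]]] + (delta if tumor else 0.0))
        ref_base = np.log2(pooled / len(samples))
        for b in batches:
            rid = f"REF_{b}"
            x = ref_base + bfx[:, bidx[b]]
            if noise_sd > 0:
                x = x + rng.normal(0.0, noise_sd, size=len(base))
            cols[rid] = x + chan_scale[rid]
        return pd.DataFrame(cols)

    gp_base = base_prot[parent] + gp_offset
    gp_u = u_gp
    gp_delta_total = prot_delta.loc[ids["accession"]].to_numpy() + gp_delta.to_numpy()
    gp_log2 = layer_log2(gp_base, gp_u, b_gp, gp_delta_total, cfg.sigma_noise)
    pr_log2 = layer_log2(base_prot, u_pr, b_pr, prot_delta.loc[accs].to_numpy(), cfg.sigma_noise)

    gp_mask = _mnar_censor(rng, gp_log2.to_numpy(), cfg.missing_rate)
    pr_mask = _mnar_censor(rng, pr_log2.to_numpy(), cfg.missing_rate)
    gp_int = np.exp2(gp_log2).mask(gp_mask)
    pr_int = np.exp2(pr_log2).mask(pr_mask)

    glyco = pd.concat(
        [ids[["accession", "site", "peptide", "site_in_peptide", "glycan_composition"]], gp_int],
        axis=1,
    )

    unique_pep = 2 + rng.poisson(4, size=len(accs))
    singles = rng.random(len(accs)) < cfg.frac_single_peptide
    protected = {a for a in accs if role[a] in ("occupancy_up", "occupancy_down")}
    for i, a in enumerate(accs):
        if singles[i] and a not in protected:
            unique_pep[i] = 1
    prot_tab = pd.DataFrame({"accession": accs, "unique_peptides": unique_pep})
    prot_tab = pd.concat([prot_tab, pr_int], axis=1)

    gp_fc_true = np.exp2(gp_delta_total)
    truth_rows = [
        _true_call(fc, pd_)
        for fc, pd_ in zip(gp_fc_true, prot_delta.loc[ids["accession"]].to_numpy())
    ]
    from .quant import glycopeptide_key

    truth = pd.DataFrame(
        {
            "feature_id": glycopeptide_key(ids),
            "accession": ids["accession"],
            "gp_delta": gp_delta.to_numpy(),
            "prot_delta": prot_delta.loc[ids["accession"]].to_numpy(),
            "true_fc": gp_fc_true,
            "true_label": [t[0] for t in truth_rows],
            "true_branch": [t[1] for t in truth_rows],
        }
    ).set_index("feature_id")

    ptruth = pd.DataFrame(
        {
            "accession": accs,
            "prot_delta": prot_delta.loc[accs].to_numpy(),
            "role": role.loc[accs].to_numpy(),
        }
    ).set_index("accession")
    ptruth["true_de"] = np.select(
        [ptruth["prot_delta"] > 0, ptruth["prot_delta"] < 0], ["sig_up", "sig_down"], "not_sig"
    )

    return SimResult(
        glycopeptides=glyco,
        proteins=prot_tab,
        design=design,
        ground_truth=truth,
        protein_truth=ptruth,
        config=cfg,
    )


def landscape_design(cfg: SimConfig | None = None) -> dict:
    """Closed-form expected landscape of a configuration.

    Expected glycosites per protein = 1/p (geometric); expected
    glycoforms per site = 1 + size*(1-p)/p (negative binomial; the
    small truncation from finite composition grids is ignored).
    """
    cfg = cfg or SimConfig()
    e_sites = 1.0 / cfg.p_single_site
    nb_mean = cfg.glycoforms_nb_size * (1 - cfg.glycoforms_nb_p) / cfg.glycoforms_nb_p
    e_glycoforms = 1.0 + nb_mean
    return {
        "n_proteins": cfg.n_proteins,
        "expected_sites": cfg.n_proteins * e_sites,
        "expected_glycopeptides": cfg.n_proteins * e_sites * e_glycoforms,
        "glycan_class_mixture": dict(
            zip(CLASS_GRIDS, cfg.glycan_class_mixture)
        ),
        "sites_per_protein_sd": np.sqrt((1 - cfg.p_single_site)) / cfg.p_single_site,
        "glycoforms_per_site_sd": np.sqrt(
            cfg.glycoforms_nb_size * (1 - cfg.glycoforms_nb_p)
        )
        / cfg.glycoforms_nb_p,
    }


def write_simulation(res: SimResult, outdir) -> dict[str, Path]:
    """Write the generated tables in the schemas the quant module reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "glycopeptides": outdir / "glycopeptides.tsv",
        "proteins": outdir / "proteins.tsv",
        "design": outdir / "design.tsv",
        "ground_truth": outdir / "ground_truth.tsv",
        "protein_truth": outdir / "protein_truth.tsv",
    }
    res.glycopeptides.drop(columns=["site_in_peptide"]).to_csv(
        paths["glycopeptides"], sep="\t", index=False, float_format="%.6g"
    )
    res.proteins.to_csv(paths["proteins"], sep="\t", index=False, float_format="%.6g")
    res.design.table.to_csv(paths["design"], sep="\t", index=False)
    res.ground_truth.to_csv(paths["ground_truth"], sep="\t")
    res.protein_truth.to_csv(paths["protein_truth"], sep="\t")
    return paths
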