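# glycodelta

Downstream comparative analysis for TMT-based intact
**N-glycoproteomics** — the statistics that turn glycopeptide and
protein quantification tables from a paired tumor / normal-adjacent
tissue (NAT) study into biology: batch-integrated log2 ratios, glycan
typing, site-microheterogeneity summaries, protein-corrected
differential glycopeptide calls, and immune-microenvironment
associations. Built for analysts working with multi-batch TMT designs
bridged by a pooled reference channel (and single-batch knockdown
experiments), with a synthetic-data generator so every stage is
testable end to end without any raw mass-spectrometry data.

## The core model

**Quantification.** Within each TMT batch, channel intensities are
total-normalized (each channel scaled to the batch's median channel
total), ratioed to the pooled reference channel, log2-transformed, and
integrated across batches:

    r_ij = log2( x_ij / x_i,ref )   per batch, then outer-joined.

Missing values are never imputed; features quantified in ≥50% of
samples (proteins additionally with ≥2 unique peptides) enter
statistics.

**Glycan typing.** Compositions `N#H#F#S#` (HexNAc, hexose, fucose,
NeuAc) partition into five classes — *mannose* (N2, H≥5, undecorated),
*sialylated* (S>0, F=0), *fucosylated* (F>0, S=0),
*fucosylated-sialylated* (both), *complex/hybrid* (the rest) — with
terminal decorations taking precedence, so N4H5F0S2 is sialylated and
N2H6F0S0 is high-mannose.

**Protein-corrected differential calls.** A glycopeptide's fold change
confounds glycosylation occupancy with protein abundance. With
FC gates >1.5 / <0.67 at p < 0.05 (Student's t-test on log2 ratios),
calls follow a four-branch decision tree: a significant glycopeptide
rise is *up* if the protein did not significantly change (or rose
less), but *down* if the protein rose significantly more (relative
occupancy loss); mirrored for decreases. Branches are labelled
A/C (direct) and B/D (occupancy) in every output.

**Association.** ssGSEA scores immune/stromal signatures per sample
from expression ranks (weighted running-sum statistic, exponent 0.25);
differential enrichment pairs a t-test with a ≥1.25-fold gate on
min-shifted scores. Enzyme–glycopeptide structure is screened with
Spearman correlations (rho > 0.6, p < 0.05; pairwise-complete
samples), intersected with tumor-upregulated calls, and
over-representation is tested hypergeometrically against user-supplied
GMT gene sets.

## Worked example

Simulate a study-like dataset (10 tumor/NAT pairs, 3 TMT-10plex
batches, pooled 128C reference, known injected effects) and run the
pipeline:

```python
from glycodelta.synthdata import SimConfig, simulate, write_simulation
from glycodelta.pipeline import PipelineConfig, run_pipeline

res = simulate(SimConfig(n_proteins=300, seed=42))
paths = write_simulation(res, "demo")
cfg = PipelineConfig(
    glycopeptide_table=str(paths["glycopeptides"]),
    protein_table=str(paths["proteins"]),
    design=str(paths["design"]),
)
summary = run_pipeline(cfg, "demo/out")
print("glycopeptides:", summary["landscape"]["n_glycopeptides"])
print("retained >=50%:", summary["glycopeptide_filter"]["n_retained"])
print("up:", summary["glycopeptide_de"]["n_up"], " down:", summary["glycopeptide_de"]["n_down"])
print("branches:", summary["glycopeptide_de"]["branches"])
```

which prints:

```
glycopeptides: 1534
retained >=50%: 1359
up: 101  down: 106
branches: {'none': 1152, 'A_direct_up': 76, 'C_direct_down': 70, 'D_occupancy_down': 36, 'B_occupancy_up': 25}
```

1534 distinct glycopeptides were identified on 300 glycoproteins;
1359 survive the ≥50% quantification filter. Of those, 101 are called
up and 106 down: 76 + 70 are direct changes on stable proteins, while
36 rising glycopeptides sit on proteins that rose even more (relative
occupancy loss → *down*, branch D) and 25 falling ones sit on proteins
that fell further (occupancy gain → *up*, branch B). Comparing against
`res.ground_truth` shows how well the injected labels are recovered.

The same analyses are available from a shell:

```sh
glycodelta simulate --seed 42 --out demo/
glycodelta run-all --config cfg.yaml --out demo/out/
glycodelta compare --records-a a.tsv --records-b b.tsv --out cmp.json
```

where `cfg.yaml` lists the table/design paths and optional thresholds.
Outputs are TSV tables (normalized matrices, differential calls with
branch provenance, top glycans, co-occurrence in UpSet-ready long
format) plus `summary.json`.

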