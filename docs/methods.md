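# Methods

`glycodelta` implements the downstream statistics of a comparative
TMT-based intact N-glycoproteomics study: paired tumor and
normal-adjacent-tissue (NAT) samples, multiplexed into several
TMT-10plex batches bridged by a pooled internal reference channel.
This note records the models, the parameters that matter, the
numerical choices, and what the synthetic-data tests do and do not
demonstrate.

## Quantification model

Reporter intensities for one batch form a feature × channel matrix.
The processing chain is:

1. **Channel-total normalization.** Each channel is scaled so its
   intensity total equals the *median* channel total of the batch
   (mean optional via `center=`). This removes per-channel loading
   differences exactly, because a loading factor multiplies a whole
   column. Median rather than mean for robustness to a single
   aberrant channel.
2. **Reference ratioing.** Every sample channel is divided by the
   batch's pooled reference channel and log2-transformed. Per-feature
   batch effects are shared by the reference and therefore cancel.
   The reference column is identically zero afterwards and is
   dropped. If a feature's reference intensity is missing, the
   feature's ratios are missing for the whole batch — no
   pseudo-reference is substituted, consistent with the global
   no-imputation policy.
3. **Integration.** Per-batch log2-ratio tables are outer-joined;
   features absent from a batch stay missing there.

Single-batch designs (e.g. knockdown cell lines, which carry no
reference channel) use channel-total normalization followed by a plain
log2 transform. Zero intensities are treated as missing before any
log — a zero reporter intensity is a detection failure, not a
measured abundance.

**Missingness filter.** Features quantified in at least 50% of
non-reference samples are retained (inclusive bound; `FilterPolicy`).
Protein tables additionally require ≥2 unique peptides. Missing
values are never imputed at any stage.

**PCA** uses complete-case features only (no imputation), each
mean-centered across samples, no variance scaling — log2 ratios
already share a scale. Reported: per-component variance fractions and
sample scores.

## Differential analysis

Per feature, the tumor/NAT fold change is the geometric ratio
`2^(mean_T − mean_N)` of log2 values, tested with a two-sided
equal-variance Student's t-test (unpaired by default; a `paired` flag
switches to a paired test on pair-matched samples for sensitivity
analysis). Features with fewer than two quantified values in either
group are excluded with a reason code. A protein is significantly
altered when fc > 1.5 or fc < 0.67 (strict inequalities) with
p < 0.05. Benjamini–Hochberg FDR is computed and reported alongside
raw p-values but does not gate calls (configurable); tissue-level
calls use the raw-p thresholds.

**Protein-corrected glycopeptide classification.** Glycopeptide
abundance confounds glycosylation occupancy with protein abundance.
The four-branch decision tree separates them:

| branch | glycopeptide | protein | call |
|---|---|---|---|
| A_direct_up | fc > 1.5, p < .05 | not significant / not quantified, or rose less | up |
| D_occupancy_down | fc > 1.5, p < .05 | significantly up AND rose more | down |
| C_direct_down | fc < 0.67, p < .05 | not significant / not quantified, or fell less | down |
| B_occupancy_up | fc < 0.67, p < .05 | significantly down AND fell more | up |

Choices the verbal rules leave open, resolved here:

* Occupancy branches require the protein's own change to be
  significant (`occupancy_requires_protein_sig=True`): reading "the
  protein showed an even greater decrease" as requiring a real
  protein change rather than noise. The flag exposes the other
  reading.
* Glycopeptides whose parent protein is absent from the filtered
  proteome are classified via the "no significant protein change"
  clause — in tissue data most glycoproteins do not overlap the
  quantified proteome, yet their glycopeptides still deserve calls.
* Fold-change comparisons are on the linear scale; an exact
  glycopeptide/protein tie satisfies neither "greater change" nor an
  occupancy branch, so a tied feature on a significant protein is
  left unchanged. This is a genuine identifiability limit: a
  glycopeptide tracking its protein exactly carries no occupancy
  signal.
* Single-batch knockdown mode uses the looser decrease cutoff
  fc < 0.8 (`Thresholds.fc_down_alt`).

The classifier is verified against an independently written
truth-table oracle over a full grid of fold-change/p/protein-state
combinations; exactly one branch fires per configuration.

## Glycan typing and landscape statistics

Compositions `N#H#F#S#` (HexNAc, hexose, fucose, NeuAc) are parsed
case-insensitively in any token order and canonicalized. The
five-class partition: terminal decorations decide first
(fucosylated-sialylated / sialylated / fucosylated), then
high-mannose (exactly 2 HexNAc, ≥ `mannose_min_hex` = 5 hexoses —
Man5 and larger; paucimannose falls to complex/hybrid), everything
else complex/hybrid. Hybrid vs complex cannot be distinguished from
composition alone, so they form one class. Strict validation flags
compositions with < 2 HexNAc (no chitobiose core).

Counting hierarchy: glycopeptide = (accession, site, peptide,
composition); glycosite = (accession, site); site-specific glycan
composition = (accession, site, composition); unique composition =
the string alone. Missed-cleavage variants are distinct
glycopeptides; deduplication within a cohort is joint over tumor and
NAT. Sequon motifs (N-X-S/T/C, X ≠ P) are read from the peptide, with
optional protein-sequence context when the +2 residue lies past the
peptide's C-terminus; unresolvable sites are excluded from motif
denominators. Top-N rankings break ties lexicographically on the
canonical composition string so outputs are deterministic.
Glycan-type co-occurrence assigns each glycosite the set of classes
observed there; counts sum to the number of sites and are emitted in
long format suitable for UpSet-style plotting.

## Association analyses

**ssGSEA.** Per sample, genes are ranked descending by expression
(missing values dropped, no imputation); the enrichment score is the
sum over the ranked list of the weighted in-set empirical CDF minus
the uniform out-of-set ECDF, weights `|value|^0.25`. Exponent 0.25
and the optional normalization by the score-matrix spread follow the
widely used single-sample formulation. With exponent 0 the score is a
pure rank statistic, invariant to monotone transforms — the property
test. StromaScore averages the fibroblast and endothelial signatures;
MicroenvironmentScore averages all signatures (memberships
configurable — the full 23-cell-type panel is supplied by the user as
GMT).

**Immune differential.** t-test plus a ≥1.25-fold gate. Enrichment
scores can be negative, so each signature is shifted by its pooled
minimum before the fold is computed; the call is then exactly
invariant to constant offsets. The cost is that the fold depends on
the in-cohort score range; a difference-based effect size is the
natural alternative and the shift-based fold is therefore isolated in
one place. A consequence worth knowing: a tight cluster of scores far
from the pooled minimum yields a small fold even when the t-test is
highly significant — that is the gate doing its job.

**Correlation screen.** Spearman rho with mid-rank ties and the
t-approximation p-value, pairwise-complete observations, minimum 5
shared samples. Retention is one-sided (rho > 0.6, p < 0.05) matching
the enzyme–glycopeptide screen; `use_abs=True` switches to two-sided
magnitude screening for enzyme–immune correlations, where negative
associations are the finding. Over-representation uses the
hypergeometric upper tail against a user-supplied universe with BH
correction; no pathway database is bundled or fetched.

## Synthetic data generator

`synthdata.simulate` emulates the study design: 10 tumor/NAT pairs in
3 TMT-10plex batches (pairs never split across batches), reference
channel 128C built as the pooled average of all samples. Log2
intensities are base + glycoform offset + shared patient effect
(sd 0.3) + condition effect + per-feature batch effect (sd 0.3) +
noise (sd 0.4), with per-channel loading factors (sd 0.2 log2) and
logistic intensity-dependent censoring calibrated by bisection to the
target overall missingness (default 10%) — isobaric data are missing
not at random.

Marginals are set to the landscape a tissue study reports: sites per
protein geometric with 78.8% single-site; glycoforms per site
1 + NegBin(4, 0.557) (≈9.6% single-glycan sites, ≈25% with more than
five); glycan classes mixed 34/18/22.5/15.5/10% (mannose, sialylated,
fucosylated, complex/hybrid, fucosylated-sialylated), drawn from
per-class composition grids (e.g. N2H5–N2H9 for high-mannose) so
typing round-trips; sequon +2 residues 53.1/41.8/5.1% T/S/C. Effects
cover every decision-tree branch: glycopeptide-only shifts (±1 log2)
on flat proteins, occupancy proteins (protein ±2 log2 with opposing
glycopeptide shifts), protein-only shifts (ties — ground truth
unchanged), and extra protein-level DE. Ground truth applies the same
branch semantics to the noiseless fold changes, with "significant"
meaning a non-zero underlying delta.

**What passing tests show — and don't.** Recovery results (≈92%
sensitivity, ≈5% false-call rate at the default scale) demonstrate
the pipeline's statistical machinery under the generator's
assumptions: log-normal intensities, homoscedastic noise, effects
constant across patients, a reference that is a true pooled mean, and
missingness depending only on intensity. Real tissue data add
interference/ratio compression, peptide-dependent ionization,
co-isolation, patient heterogeneity in effect size, and
identification errors — none of which are simulated, so recovery
rates here are an upper bound, not a field calibration. Problem sizes
in tests (~120–950 proteins, ~550–5000 glycopeptides) were chosen as
the package's own test scale; the statistics are size-independent.

## Numerical conventions

Strict inequalities at every threshold (fc > 1.5, fc < 0.67,
p < 0.05, rho > 0.6), matching the criteria as written. Degenerate
zero-variance groups with equal means get p = 1 (no evidence) rather
than NaN. All randomness flows from a single integer seed through
`numpy.random.default_rng`; repeated runs are byte-identical. Output
tables are TSV with floats at 6 significant digits; summary
quantities land in `summary.json`.

## Known limitations

Composition-level typing cannot separate hybrid from complex glycans
or detect LacdiNAc and linkage isomers. The occupancy correction is
relative, not a stoichiometry estimate. xCell-style deconvolution is
not implemented; ssGSEA over user-supplied signatures covers the
scoring role. Cross-cohort comparisons operate on the identification
tables as given — enrichment-chemistry and search-engine differences
between cohorts are not modeled, so between-cohort glycan-type
contrasts should be read descriptively.
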