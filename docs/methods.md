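# Methods

`rtetx` implements the analysis of retrotransposable-element (RTE)
transcriptional inclusion in esophageal adenocarcinoma (EAC): it
classifies assembled transcript contigs against gene and repeat
annotations, selects cancer-overexpressed transcripts, quantifies
subfamily enrichment, builds diagnostic z-score signatures, screens for
dual-cohort survival prognostics, measures gene-level exon/intron
splicing deficiency, and assigns HERVH-provirus subtypes.  Every step
runs end-to-end on synthetic data with planted ground truth.  This note
records the models, the parameters that matter, and the design choices
made where the design was genuinely open.

## Coordinates and annotation model

All in-memory coordinates are 0-based half-open; GTF and
RepeatMasker-style tables (1-based inclusive) are converted on read and
write.  Overlap means at least one shared base, so two half-open
intervals that merely abut do not overlap.

A gene is modelled as the union of its isoforms' exons; introns are the
gaps inside the gene body, so exons and introns tile the body exactly.
This is the only definition under which exon- and intron-collapsed
quantitation partitions a gene's signal.  Genic repeats are those
sharing at least one base with any gene body, strand-agnostically;
strand is retained for reporting only.

Repeat annotators report the long terminal repeats (LTRs) and the
internal region of an endogenous retrovirus separately.
`merge_ltr_internal` joins consecutive same-strand rows whose models
belong to the same element — an internal model (`X-int`) next to one of
its partner LTR models — within a gap tolerance (default 100 bp).  The
pairing table is editable (default: HERVH ↔ LTR7\*, HERVK ↔ LTR5\*,
HERVL ↔ MLT2\*); merged elements take the internal model's base name, so
the operation is idempotent.  Neither the gap tolerance nor the exact
pairing is canonical; both are configuration.

## Contig classification

Each contig gets one overlap category from the 2×2 of
{any block overlaps a gene body} × {any block overlaps a repeat}, and
one intron category: `fully_intronic` when every base of every block
lies within the introns of a *single* gene (blocks may occupy different
introns of that gene), `no_intron_overlap` when no base touches any
intron, `other` otherwise.  Cross-gene intron containment is classified
`other`; single-gene containment is the reading consistent with
incomplete splicing of one host gene, which is what the category is
meant to capture.

Terminal position-frequency matrices tabulate the first or last 40
bases of each contig's spliced sequence (blocks concatenated,
reverse-complemented on the minus strand).  Ambiguous bases are
excluded from the columns rather than counted as a fifth symbol;
contigs shorter than 40 bases are skipped and counted.

## Overexpression selection

For a cancer type with samples in TPM, per feature:

- `mC` — median over cancer samples; `q75C` — 75th percentile;
- `H = max(90th percentile of the matched healthy tissue,
  the largest per-tissue median over all healthy tissues)`.

Selected iff `mC > 0.5` and `3·H ≤ q75C` and `H < 0.5` (TPM).  The
selection sentence this encodes is ambiguous between a conjunctive and
a disjunctive reading of its two healthy conditions; the conjunction
through the single summary `H` is the strictest consistent reading and
is what ships, with the thresholds exposed in `SelectionThresholds`.
Percentiles use linear interpolation between order statistics (the
common scientific-software default; the quantile convention is
otherwise unstated).  The filter is monotone: raising a cancer value or
lowering a healthy value can only add, never remove, a selected
feature.

Differential repeat expression uses a two-sided Welch t-test on
log2(TPM + 0.1) with Benjamini–Hochberg correction; the fold-change is
on group means of TPM with the same 0.1 pseudocount, and the pass rule
is strict: |fold| > 6, p < 0.05, q < 0.05.  Subfamily enrichment uses
two-sided Fisher exact tests on (in-selection vs background-minus-
selection) × (overlapping vs not), sample odds ratios with a Haldane
0.5 correction when a cell is zero, and BH q over subfamilies.  The
copy-number bias diagnostic is the Spearman correlation of genomic copy
number with log odds ratio.

## Diagnostic signature

A panel is the set of features whose expressed fraction (TPM ≥ 0.5) is
at least 0.5 among cancer samples of *every* cohort and at most 0.01 in
every negative class (healthy tissues; optionally Barrett's esophagus
for the stricter sub-panel).  Samples are scored by the sum of
per-feature z-scores with statistics computed over all samples being
scored — this matches the cumulative-score definition but is a
train/test leakage caveat, so a fixed reference normalization (stored
mean/sd per feature) is also supported.  ROC AUC is the midrank
statistic (the probability a random positive outranks a random
negative, ties counting half); the operating point maximizes Youden's
J, ties broken toward higher specificity.  Mutual exclusivity is
Spearman correlation (expression is heavy-tailed).

## Exon/intron metrics

Interval-level quantification (one value per exon-union interval or
intron per sample) is collapsed per gene and layer by summation — a
linear operation, verified as such.  The splicing readout is
`log2((exon + 1) / (intron + 1))` per gene per sample; pseudocount 1
keeps zero counts finite and the log makes the ratio symmetric.  Group
comparisons of the ratio use Student's (equal-variance) t-tests.
Extreme groups (n = 10 per side) are chosen by ranking provirus TPM
with ties broken by sample id for determinism.

## Survival screening

Per feature and cohort, samples are ranked (ties by sample id) and
split into expression tertiles of size floor(n/3); the outer tertiles
are compared by a log-rank test and a univariate Cox proportional-
hazards fit on the binary high-vs-low indicator (Efron ties, via
lifelines).  Records with a zero-event group are non-estimable and
excluded.  The dual-cohort filter keeps features with Cox Wald p < 0.05
in *every* cohort separately, concordant hazard direction, and a
geometric-mean HR ≥ 2 (adverse) or ≤ 0.5 (protective); filtering on the
log-rank p or requiring the HR bound per cohort are options.  Gene-level
prognostics run the identical screen on the exon and intron layers
independently and report the intersection with a concordance flag
(same hazard direction in both layers).

Note that when several planted transcripts multiply the same hazard,
each transcript's *marginal* HR attenuates toward 1 relative to its
conditional (planted) HR; recovery checks that state a marginal HR
therefore plant one hazard covariate at a time.

## Subtypes and associations

Tumors are `high` when the subtype-defining provirus (e.g. HERVH
Xp22.32) is at or above 1 TPM; the boundary value goes to `high`, a
stated choice since only the cutoff value is canonical.  Associations
regress each feature (log2(TPM+0.1) for expression, raw 0/1 for driver
alterations) on log2(provirus TPM + 0.1) by simple OLS — implemented in
closed form and cross-checked against `scipy.stats.linregress` — with
two-sided slope t-tests and BH correction *within* each declared family
(transcripts, exon layer, intron layer, drivers), mirroring the
separate family counts of the analysis design.  Inverse-splicing genes
need intron slope > 0 and exon slope < 0 (both q < 0.05), confirmed by
the exon/intron ratio test between provirus-extreme sample groups.
The Barrett's-distance metric z-scores the top-variance genes (default
500, configurable; the metric itself is not canonical) on
log2(TPM+0.1) and takes each tumor's Euclidean distance to the BE
centroid, comparing subtypes with a two-sided Mann–Whitney test.

## Synthetic data

The generator emulates the statistical structure the analyses assume,
at desk scale.  Defaults: 2 chromosomes (450 kb + 350 kb), 40 genes of
3–7 exons, a repeat catalogue of Alu/L1/SVA subfamilies plus five
LTR7Y–HERVH-int–LTR7Y proviruses and solo LTRs; 108 contigs planted by
category (40 fully intronic, 25 exonic, 18 stand-alone RTE, 15
chimeric, 10 repeat-free) such that the planted labels agree with the
classifier run on the same annotation — a self-consistency contract
that is itself tested.  Poly(A) tracts (15 nt) are written into the
genome at the 3′ tails of target-primed stand-alone contigs at the
catalogue's per-subfamily probability.

Expression: two cancer cohorts of 60 EAC samples each, 30 + 15 healthy
samples in two tissues, 20 BE samples.  Baseline log2 TPM is
Normal(2.5, 1.0) per feature with per-sample sd 0.5.  Planted
overexpressed transcripts (30 % of contigs) are identically zero in
healthy tissue and log-normal with median 4 TPM in cancer; about half
are additionally expressed (one log2 lower) in BE.  The provirus is a
two-component mixture (modes 10 and 0.1 TPM, weight 0.5, log2 sd 0.4)
defining the subtype truth; a mutually exclusive partner transcript is
high exactly where the provirus is low.  The latent splicing deficiency
θ ∈ [0.02, 0.95] follows a Gaussian copula on standardized log2
provirus expression with correlation ρ = 0.8 (θ = 0.45 + 0.2·raw,
clipped); healthy and BE samples sit at the basal floor θ = 0.02.  For
the 25 % of genes planted as coupled, intron intervals scale with
θ·(gene level) and exon intervals with (1 − κθ)·(gene level), κ = 0.9,
exon factors clamped at 0.01 with the occurrences counted; uncoupled
genes keep the basal intron fraction.  Survival times are exponential
with hazard h₀·exp(Σβ·x) (h₀ = 1/1000 per day), covariates being the
high-expression halves of planted prognostic transcripts (default HR
0.4) and optionally the subtype; censoring is independent uniform with
the upper bound solved numerically (Brent) for the target censored
fraction (default 0.3).  Drivers are Bernoulli with subtype-conditional
rates.

Seeds: each component draws from
`SeedSequence(master_seed, spawn_key=(k,))` with a fixed `k` per
component, so changing cohort sizes does not perturb the annotation,
and the whole dataset is byte-reproducible from one integer.

What the generator does *not* emulate: read-level noise and multi-
mapping ambiguity (quantified matrices are taken as given), sequence
divergence among repeat copies, correlated gene programs, clinical
covariates, and tumor purity.  Passing recovery tests therefore show
the statistical machinery is correct under the stated generative
model, not that the biological effect sizes of real cohorts are
attainable.

## Problem sizes and numerics

Default synthetic runs use ~108 transcript features × 185 samples and
40 genes, chosen so the full pipeline (all nine stages) completes in
seconds and recovery tests over tens of replicates stay fast; survival
recovery uses 200 samples per cohort as its study condition.  Ties in
rankings are always broken by sample id; zero-variance features are
dropped (scoring), skipped (associations) or flagged with p = 1
(group tests); odds ratios at zero cells use Haldane 0.5; correlations
on constant vectors raise rather than return NaN.  Cox fits that fail
to converge (e.g. monotone likelihood) are flagged non-estimable and
never enter the prognostic filters.

## Known limitations

- The published 29/8-transcript panels, and counts such as 4844
  selected or 282 prognostic transcripts, depend on controlled-access
  cohorts; the package reproduces the procedures, not those numbers.
  Published panels can be supplied as a panel file.
- The full-cohort z-normalization of the diagnostic score leaks class
  information; use the reference-set mode for honest evaluation.
- The prognostic screen is univariate by design; no clinical
  covariates, no proportional-hazards diagnostics beyond the flag.
- Antisense-shared introns (genes whose intron signal belongs to an
  overlapping antisense unit) are not detected automatically.
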