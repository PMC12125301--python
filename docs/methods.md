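# Methods

This note records the models, conventions, and design choices behind
`tcrdyn`, in the order the pipeline applies them.

## Clonotype assembly

Input is the cellranger-vdj `filtered_contig_annotations.csv` layout; column
names are remappable via a dialect mapping, unknown columns are ignored, and
rows whose `productive` flag cannot be parsed are rejected and counted.
Clonotype calling keeps only productive TRA/TRB contigs with a non-empty CDR3
at the configured level. Per barcode and locus, contigs are ranked by UMIs
(ties: reads, then lexicographic nucleotide CDR3) and at most two distinct
chains are retained; duplicate assemblies of the same chain (identical CDR3)
collapse to the best-supported contig, since a clonotype is a *set* of
chains. The clonotype key is the sorted `chain:CDR3` concatenation, so it is
invariant to row order and barcode naming. Defaults and their rationale:

- **Nucleotide-level keys** by default (matches cellranger clonotype
  semantics and is the stricter identity); amino-acid level by configuration.
- **α-only cells are retained** and keyed by TRA alone; a `require_trb`
  switch provides the β-only convention common in repertoire work.
- Barcode GEM-well suffixes (`-1`) are stripped by a configurable regex.
  Cross-sample barcode collisions are harmless because clone matching uses
  clonotype keys, never barcodes.

## Expansion and diversity

A clone's expansion class depends only on its cell count: 1–2 not expanded,
>2 expanded, ≥10 highly expanded. Both thresholds are parameters so cut-off
sensitivity sweeps are one loop; the expanded-cell fraction is monotonically
non-increasing in the cut-off by construction. The denominator is all cells
with an assigned clonotype in the sample.

Shannon entropy is computed in bits (log₂) over clone frequencies; a nats
option exists. The Gini index uses the population (uncorrected)
mean-absolute-difference form `G = Σᵢⱼ|xᵢ−xⱼ| / (2N²x̄)` over the cell counts
of distinct observed clonotypes (no zero-padding), evaluated via the sorted
O(N log N) identity; the tests verify equality with the O(N²) definition to
1e-12. The N/(N−1) small-sample correction is available behind a flag but
off by default, as the estimator choice for TCR clonality is conventionally
the plain population form.

## Clonal dynamics

Clones are matched across a patient's pre/post pair by clonotype key (the two
tables must be built at the same key level). Fold change is computed on
**frequencies**, not raw counts, to normalize unequal cells per sample —
classification is then invariant to sequencing depth. Counts remain in the
output for the statistical test.

The fold-change classifier evaluates pre-existing clones passing the size
filter `max(pre_count, post_count) ≥ 20` (the larger timepoint, so
treatment-sensitive clones that collapse after therapy remain evaluable):
increased >2-fold, decreased <0.5-fold, both boundaries inclusive to
unchanged. Filtered-out clones are marked `not_evaluable`, never dropped;
clones absent at one timepoint are reported distinctly as `new` /
`disappeared` rather than folded into the three classes, so per-clone
trajectories are reconstructable.

The statistical classifier applies a two-sided conditional exact
(hypergeometric) test to the 2×2 table [clone cells vs other cells] × [pre vs
post], calling increased/decreased when p < α (default 0.05) and |log₂ fold
change| > 1. With a single sample per timepoint per patient no dispersion is
estimable, so a negative-binomial exact test would reduce toward this
conditional test; a dispersion-aware variant is a natural extension point.
P-values are raw, one clone at a time — the classification rule is defined
that way, and the null-calibration test shows the conditional test is itself
conservative (type-I error below nominal α). The rule is symmetric in both
directions (p < α with log₂FC < −1 for decreased).

Per-patient summaries sum expanded-clone frequency at each timepoint; the
sign of the post-minus-pre change assigns the increased/decreased group (an
exact zero, never observed in practice, ties to decreased and is logged).
`new_clone_size` is the summed post-treatment frequency of **all** clones
absent at baseline. Note an important sampling effect: at a few thousand
cells per sample, many small clones present in the tissue are unobserved at
baseline by chance, so the measured new-clone fraction is the planted burden
plus sampling turnover and is substantially larger than the planted value.
The quantity is still monotone in the true burden (the tests assert a strong
correlation with the planted truth), which is what the correlation indices
consume. This also means the synthetic cohort's patients tend to group as
"increased": concentrated new clones add expanded mass faster than the
planted sensitive clones remove it. Interpretations of the absolute new-clone
fraction on real data face the same turnover caveat.

Correlation of summaries with clinical scores uses Pearson r with an OLS
slope and two-sided p (≥3 pairs required; zero variance is an error, not a
NaN).

## Sequence similarity

The study-level question — do newly arising clones resemble pre-existing
ones? — is answered with normalized Levenshtein similarity on CDR3β amino
acids, `1 − d(a,b)/max(|a|,|b|)` (TRA fallback for β-less clones), computed
with edlib and cross-checked in the tests against an independent
dynamic-programming implementation. The cross-set summary takes, for each
clone in set A, its maximum similarity over set B and averages these maxima:
a nearest-neighbor overlap measure that depends only on sequence content, not
clone sizes or order. Identical sequences can be excluded for within-set
comparisons. A Hamming-on-equal-length alternative is available; it scores
length-discordant pairs 0.

## Hematopoietic scoring and indices

Each analyte score is `(value − reference median) / reference SD`; the
hematopoietic score is the mean of the ANC, platelet, and absolute
reticulocyte scores, and the recovery score is its post-minus-pre change
(antisymmetric under timepoint swap, invariant under consistent unit
changes). The analyte triple follows the detailed definition of the score;
an alternative triple (WBC/hemoglobin/platelets) is simply a different
reference table, as the scoring function is analyte-agnostic. Reference
medians/SDs are user-supplied; the synthetic module emits a self-consistent
reference table (ANC 3,500±1,200/µL, platelets 250,000±60,000/µL, ARC
60,000±20,000/µL — healthy-population scale). Pre- and post-treatment samples
are standardized against the same reference.

Pi correlates a baseline parameter with the post-treatment hematopoietic
score; Ti correlates a parameter's post-minus-pre change with the recovery
score. Both are Pearson/OLS and inherit Pearson's affine invariance. The
pipeline reports Ti for the new-clone burden and Pi for the baseline
expanded-cell fraction by default.

## Synthetic cohort generator

The generator emulates the study design: 16 paired patients plus 4
single-timepoint healthy donors, 2,000 cells per sample.

- **Clone sizes.** Patients draw baseline clone sizes for 8,000 clones from a
  discrete power law (zipf exponent 2.5, truncated at the sample size);
  healthy donors draw near-uniform frequencies (Dirichlet α=1 over 8,000
  clones). These choices place the expanded-cell fraction near ~25% for
  patients and ~10% for healthy donors and patient Gini near 0.25 — the
  heavy-tailed regime reported for aplastic-anemia repertoires — and were
  fixed by forward-simulating the generator alone.
- **Planted classes.** Frequency budgets (defaults: sensitive 0.12, resistant
  0.04, stable 0.06) are filled walking clones from largest to smallest;
  sensitive clones get fold effect 0.25, resistant 4, everything else 1.
  Post-treatment pre-existing frequencies are renormalized to (1 − burden).
- **New clones.** Each patient's new-clone burden is drawn uniformly in
  0.15 ± 0.12 (the spread across patients is what gives the therapeutic index
  signal to detect); 30 new clones share it with power-law sizes. With
  probability 0.5 a new clone's CDR3β is a single-substitution variant of a
  random pre-existing clone (shared-antigen-like relatedness), otherwise
  random.
- **Sequences.** CDR3s are random 8–20-mers (length ≈ 13±2 aa) over the
  20-letter alphabet with TRB `CASS…F` / TRA `CAV…F` framing; nucleotide
  CDR3s are reverse-translated with random synonymous codons, so nucleotide
  identity implies amino-acid identity but not conversely. 5% of clones carry
  a genuine second TRA chain (consistent across the clone's cells); 5% of
  cells get a decoy contig (non-productive chain or duplicate assembly) to
  exercise parser filtering.
- **Blood counts.** Pre-treatment analyte z-scores sit at −2.4±0.25
  (severe-disease regime); the post-minus-pre change of the mean z is
  `2.0 − 8.0 × burden + N(0, 0.5)` plus small per-analyte jitter, i.e.
  recovery is negatively coupled to new-clone burden by default.
- **Determinism.** Every draw derives from the config seed through named
  substreams; identical configs produce byte-identical files.

What the generator does *not* emulate: V(D)J recombination biology (gene-
segment usage is a label, CDR3s are uniform-random), sequencing error,
expression phenotypes, cell-type composition, or clinical covariates. Passing
tests therefore demonstrate that the statistics recover planted clonal and
clinical structure under multinomial sampling — not robustness to alignment
artifacts or biological confounders in real data.

## Problem sizes and numerical conventions

The test suite and acceptance script run at desk scale, chosen to exercise
the same regimes at tractable cost: calibration and planted-effect loops use
count-level simulation (no sequence or file emission); the therapeutic-index
replication uses cohorts of 16 patients with 2,000 clones and 1,000 cells per
sample; similarity replications use 200-clone repertoires. Tolerances:
frequency identities to 1e-9; oracle equivalences (Gini, edit distance,
hypergeometric p) to 1e-12 absolute or 1e-8 relative; sampled frequencies to
3 multinomial standard errors. Ties in UMI ranking resolve by reads then
lexicographic CDR3; the patient-group zero tie resolves to "decreased" with a
log message. Degenerate inputs (empty samples, zero-variance correlations,
missing analytes) raise errors naming the offender rather than propagating
NaNs.

## Known limitations

- Clone matching is exact on clonotype keys; convergent clones differing by
  one nucleotide are distinct clones (no fuzzy matching, no V/J-aware
  distance).
- The exact-test classifier ignores biological over-dispersion across
  patients; it is calibrated per clone under multinomial sampling only.
- The measured new-clone fraction conflates genuinely new clones with
  sampling turnover (see above); at low cell counts the absolute value is
  dominated by turnover.
- Single pre/post design: no multi-timepoint trajectories.
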