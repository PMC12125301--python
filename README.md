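# tcrdyn

Longitudinal single-cell TCR repertoire analysis for paired pre-/post-treatment
studies, built around the setting of immune-mediated bone-marrow failure
(severe aplastic anemia treated with immunosuppressive therapy), where
expanded cytotoxic T cell clones attack hematopoietic stem and progenitor
cells and the clinical question is how clonal dynamics after therapy relate to
blood-count recovery.

Given 10x cellranger-vdj contig annotation tables for each sample, `tcrdyn`:

- assembles per-cell **clonotypes** from productive TRA/TRB contigs (UMI-ranked,
  at most two chains per locus), keyed at nucleotide or amino-acid CDR3 level;
- quantifies **clonal expansion** — a clone is *expanded* at >2 cells with an
  identical TCR, *highly expanded* at ≥10, *not expanded* at 1–2 — and repertoire
  diversity via the Shannon entropy `H(P) = −Σᵢ pᵢ log₂ pᵢ` over clone
  frequencies and the Gini index of the clone-size distribution;
- tracks clones across a patient's paired samples and classifies per-clone
  **dynamics** among clones with ≥20 cells: *increased* (>2-fold,
  treatment-resistant), *unchanged* (0.5–2-fold, treatment-insensitive),
  *decreased* (<0.5-fold, treatment-sensitive), with clones only seen
  post-treatment labelled *new* and only pre-treatment *disappeared*; a
  statistical alternative uses a two-sided conditional exact (hypergeometric)
  test with a log₂ fold-change cut-off;
- measures **CDR3β sequence similarity** between clone sets (normalized
  Levenshtein, nearest-neighbor summaries), e.g. newly arising clones against
  pre-existing ones;
- converts blood counts (ANC, platelets, absolute reticulocytes) into
  reference-normalized scores — distance to the reference median in reference
  SDs — whose mean is the **hematopoietic score**, and its post-minus-pre change
  the **recovery score**; a **predictive index** (Pi) correlates a baseline
  parameter with the post-treatment score, a **therapeutic index** (Ti)
  correlates a parameter's change with recovery (Pearson r, OLS slope,
  two-sided p);
- ships a **synthetic cohort generator** with planted ground truth
  (power-law clone sizes, treatment-sensitive/resistant/new clones, blood
  counts negatively coupled to new-clone burden) used by the test suite to
  validate every stage against known truth.

## Worked example

Simulate a small paired cohort (4 patients, 2 healthy donors, 1,000 cells per
sample) and run the full pipeline:

```sh
tcrdyn simulate --out cohort --seed 1 --n-patients 4 --n-healthy 2 --cells 1000
tcrdyn run --manifest cohort/manifest.tsv --out results \
    --blood-counts cohort/blood_counts.tsv --reference cohort/reference.tsv
```

`results/diversity.tsv` (abridged):

```
sample_id  cohort   n_clones  shannon_bits  gini    expanded_cell_fraction
P01_pre    patient  811       9.42          0.174   0.129
P01_post   patient  645       8.42          0.339   0.348
HD01_pre   hd       896       9.75          0.094   0.023
```

Patient repertoires are more clonal than healthy donors (higher expanded
fraction and Gini, lower entropy), and this patient's post-treatment sample
gained expanded mass. `results/patient_summaries.tsv` attributes the gain:

```
patient_id  total_clone_size_change  group      new_clone_size  pre_existing_size_post
P01         0.219                    increased  0.770           0.230
```

i.e. 77% of P01's post-treatment repertoire consists of clones not observed at
baseline (planted new clones plus sampling turnover — see
`docs/methods.md`). `results/indices.json` then reports the therapeutic
index linking new-clone burden to blood-count recovery across patients:

```json
"therapeutic_index_new_clone_size": {
  "pearson_r": -0.992, "slope": -33.56, "p_value": 0.008, "n": 4
}
```

The negative r recovers the generator's planted coupling: patients acquiring
a larger new-clone burden recover less. Per-clone dynamics classes are in
`results/dynamics.tsv`, CDR3β similarity of new versus pre-existing clones in
`results/similarity.tsv`, and blood-count scores in `results/hemascore.tsv`.

The same steps are available as library functions (`tcrdyn.read_contig_table`,
`assemble_clonotypes`, `build_clone_table`, `shannon_entropy`, `gini_index`,
`match_clones`, `classify_dynamics_foldchange`, `score_panel`,
`therapeutic_index`, ...) for use in notebooks and scripts.

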