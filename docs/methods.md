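# Methods

This note records the statistical procedure implemented by `cnvclass`, the
conventions and tunable parameters it exposes, what the synthetic-data
generator does and does not emulate, and the design choices made where the
procedure itself is open to more than one reading.

## Coordinates and calling

All intervals are 0-based half-open internally. SEG and DGV-style inputs
(1-based inclusive) are converted on ingest; the report writer converts
back. Chromosome names are normalised by stripping any `chr` prefix.
Probe-in-interval containment is half-open throughout, so a probe exactly at
a converted interval end lies outside it.

Gain/loss calling uses the **unscaled** MAD of all probe log-ratios about the
array median — no 1.4826 normal-consistency factor — and the threshold is
inclusive: a segment mean exactly one MAD from the median is a call. With a
degenerate array (MAD = 0) any nonzero departure from the median is called,
with a warning. "Length" always means genomic span `end − start` in bases,
including inter-probe gaps.

Merging combines maximal runs of consecutive same-sign calls when the
combined span is strictly under 2.3 Mb (candidate admission is ≤ 2.3 Mb; both
boundary readings are deliberate and asymmetric). The merged mean is the
marker-count-weighted average of member means — the mean a segmenter would
report for the union under constant probe density — and merging is
idempotent. Candidate extraction requires at least one *normal* flank: a
chromosome end does not count, which is the conservative reading of
"flanked". Physiological-region exclusion triggers on any ≥ 1 bp overlap,
and is applied after merging when a merged run straddles such a region. Sex
chromosomes are excluded.

## Truth labeling

Segment-overlap evidence requires a same-sign called gain/loss in the paired
normal intersecting the candidate by ≥ 1 bp; sign agreement is our decision
(a tumor gain over a normal-sample loss is not treated as the same germline
event).

The conditional segmentation test conditions on the tumor's segmentation:
the null pool is the normal-sample log-ratios under the candidate plus its
immediate left and right tumor segments (whichever exist). Draws are
**without replacement** (permutation-test convention), `R = 1000` by default,
and the p-value is one-sided in the candidate's direction with ties counted
as extreme. Declaration additionally requires the candidate's normal mean to
clear the gain/loss threshold computed from the **normal** array's median and
MAD — the test asks about the normal sample's signal, so its own noise scale
is the relevant one. The conjunction makes the test strictly conservative:
under an i.i.d. null the declaration rate is well below the nominal
α = 0.01 (the acceptance run measures ≈ 0). Per-candidate RNG streams are
derived from the run seed plus the candidate's sample/chromosome/start, so
labeling is independent of candidate order.

## Features

The 18 feature columns (16 predictors plus the two Database scores) are
listed in `cnvclass.features.FEATURE_COLUMNS`; units are bases for lengths,
fractions in [0, 1] for percentages, and log-ratio units normalised by the
residual MAD for relative height and break. Defaults that matter:
centromere/telomere window 2 Mb, candidate-proximity window 500 kb.
Chromosome ends stand in for telomeres since no telomere table is consumed.

Open corners resolved here:

- `break_score` with a missing neighbor (chromosome edge) is 0, logged.
- `ds_other_candidates` for a lone candidate on its chromosome is 0 rather
  than missing — the score of a catalogue-absent region — so the models need
  no missing-value handling.
- `pct_normal`'s denominator includes all markers on the chromosome,
  including the candidate's own.
- The overlap pattern is GG/LL when every overlapping other-patient candidate
  is a gain/loss, and GL whenever both signs occur among them. The corner
  case of a single other patient contributing both signs is resolved to GL
  (the "some gains and some losses" reading); it is vanishingly rare in
  practice because mixed signs almost always involve several patients.
- Exact-breakpoint matching compares internal coordinates for equality; an
  abutting candidate therefore matches a breakpoint without overlapping.
- With a cohort of one patient the cohort features are defined as zeros /
  `None` and a warning is logged.

## Published trees

The five published rule sets are reconstructed from their prose description;
only the CNV-predicting paths are enumerated, so any feature combination on
no such path predicts CNA (this fixes the otherwise unstated complement
branches, e.g. GLAD with score ≥ 3 but relative height ≤ 1.5). Inclusive
splits: score ≥ 2.45, ≥ 3, ≥ 1.3, ≥ 3.1, ≥ 4.5; overlap ≥ 37%, ≥ 38%.
Strict splits: length < 30 Kb, < 22 Kb, < 77 Kb, < / > 396 Kb; relative
height > 1.5; matching breakpoints > / < 1.2%. Percentage thresholds are
stored as fractions to match the feature units. Whether the smoothed-CBS
tree's cohort split reads the overlap percentage or the exact-breakpoint
percentage is ambiguous in its source; it defaults to `overlap_pct` and is
rebindable via the `overlap_feature` argument.

## Trainable models

CART is a Gini-impurity tree (scikit-learn) cost-complexity pruned by
10-fold stratified cross-validation under the 1-SE rule: the chosen penalty
is the largest whose mean CV error is within one standard error of the
minimum. Defaults beyond the published description are configuration, not
constants: minimum leaf size 5, forest size 500 trees, feature subset
⌊√p⌋ per split. The univariate screen fits one logistic regression per
predictor (statsmodels) and reports likelihood-ratio p-values;
multi-level factors are expanded to indicator contrasts sharing one LR test;
perfect separation is flagged as non-convergence rather than raised, and a
constant feature reports p = 1.

Evaluation treats CNV as the positive class. Besides the standard recalls we
report predictive values (tp/(tp+fp), tn/(tn+fn)) explicitly labeled as
such, because published accuracy tables in this area sometimes quote those
under the names sensitivity/specificity. Models serialize to a
self-describing JSON text form listing every split; a loaded forest predicts
by majority vote of its frozen trees.

## Synthetic cohorts

The generator emulates exactly what the method consumes: paired
tumor/normal probe profiles on a shared grid (default spacing 9 kb,
AG244-like), germline CNV loci present in both members of a pair with a
population frequency, somatic loci in the tumor only, additive fixed
per-event shifts, Gaussian noise, a small rate of isolated outlier spikes,
and oracle segmentations whose breakpoints are the true event boundaries
jittered by ±*j* probes per sample. A redundant toy variant catalogue is
derived from the CNV loci (1–6 records each, perturbed endpoints, 1–3
source studies, carrier counts scaled by locus frequency) plus uniform
noise records.

Preset conditions: `small` = 6 patients, 2 × 30 Mb chromosomes, noise sd
0.12, jitter 1; `default` = 40 patients, 4 × 60 Mb chromosomes, noise sd
0.12, jitter 2, ~14 CNV loci (frequencies 0.15–0.6, shifts |0.4–0.6|),
5 recurrent CNA loci and 3 private CNAs expected per patient. These sizes
run the full pipeline, including R = 1000 permutation tests and forest
training, in a couple of minutes on one core and were chosen as the smallest
cohorts in which every pipeline stage (cohort features included) has
non-degenerate inputs.

What the simulator does **not** model — and hence what passing tests do not
show about real data: tumor purity and stromal contamination (which shrink
somatic shifts), wave/GC artifacts, allele-specific copy number, probe
density variation, incomplete or erroneous catalogues, and real segmenter
behaviour beyond breakpoint jitter. In particular the near-perfect held-out
accuracies on synthetic cohorts arise because every planted CNV locus is
catalogued; they validate the plumbing and the learnability of the feature
set, not an expected real-data error rate.

## Numerical notes

Permutation draws are vectorised (R × pool random keys, arg-partitioned), so
R = 1000 on typical pools costs about a millisecond per candidate.
Reproducibility is per-candidate-seeded and independent of iteration order.
Degenerate inputs: empty profiles, zero-probe candidates, and pools smaller
than the candidate raise validation errors; a zero residual MAD yields
infinite relative height only for a nonzero mean (0/0 is defined as 0).
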