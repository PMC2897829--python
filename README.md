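# cnvclass

Distinguish **germline copy-number variants (CNVs)** from **somatic
copy-number alterations (CNAs)** in tumor array-CGH data.

When tumor arrays are hybridized against an unmatched reference, germline
CNVs — gains and losses carried by healthy individuals in every cell —
appear alongside the somatic alterations that cancer studies actually care
about, and both can recur across patients. `cnvclass` implements a
classification framework for telling them apart when no paired normal is
available: it extracts *candidate CNVs* from segmented copy-number profiles,
scores them against a catalogue of known germline variants (a DGV-style
table), computes a 16-predictor feature set, and classifies each candidate
with published decision trees or with CART / random-forest models you train
yourself. When paired normals *are* available, the toolkit derives truth
labels from them — by segment overlap or by a conditional permutation test —
so that new models can be fitted and validated.

It is aimed at cancer-genomics analysts working with CBS- or GLAD-segmented
log-ratio profiles (SEG files) who need a quantitative, reproducible
alternative to ad-hoc "does it overlap the database?" filtering.

## The method

For each array, a segment with mean log-ratio $\bar{x}_s$ is called a gain
(loss) when

$$\bar{x}_s \ \ge\ \mathrm{med} + \mathrm{MAD} \qquad (\text{resp.} \le \mathrm{med} - \mathrm{MAD})$$

where med and MAD are the median and unscaled median absolute deviation of
all probe log-ratios on the array. Consecutive same-sign calls are merged
while the combined span stays under 2.3 Mb. A **candidate CNV** is a gain or
loss of span ≤ 2.3 Mb, flanked by at least one normal segment, on an
autosome, outside "physiological" rearrangement regions (immunoglobulin /
T-cell-receptor loci).

The key predictor is the **Database score**: for each probe, count the
distinct catalogued variants covering it; the candidate's score is the mean
count over its probes. *Database score II* instead averages the total number
of individuals reported to carry covering variants. The remaining predictors
cover the candidate's length, |mean| raw and normalised by the residual MAD,
the flank structure, centromere/telomere/segmental-duplication proximity, and
how often other patients in the cohort show overlapping or exactly
breakpoint-matching candidates or same-sign non-candidate alterations.

With a paired normal, a candidate is a **true CNV** if it overlaps a
same-sign called gain/loss in the normal, or if the mean $\mu$ of the $k$
normal-sample log-ratios under the candidate passes the gain/loss threshold
and a conditional permutation test: draw $k$ values (without replacement,
$R = 1000$ times) from the normal log-ratios under the candidate plus its
two flanking tumor segments, and require the fraction of draws at least as
extreme as $\mu$ to be below $\alpha = 0.01$.

Five published decision trees are hard-coded (smoothed-CBS, GLAD, and
unsmoothed-CBS full models, plus two Database-score-only stumps), e.g. the
smoothed-CBS rule: *CNV if Database score ≥ 2.45; else CNV if shorter than
30 Kb; else CNV if ≥ 37% of other patients overlap; else CNA.*

## Worked example

Everything is testable without downloads through the synthetic-cohort module,
which plants germline and somatic events on paired tumor/normal probe grids
and emits oracle segmentations plus a redundant toy variant catalogue:

```bash
$ python examples/04_train_and_evaluate.py
candidates: 362  (train patients 24, held-out 16)
CART held-out accuracy:   0.993
forest held-out accuracy: 0.993
forest ppv 0.988  npv 1.000  median per-tumor accuracy 1.000
top forest importances (mean Gini decrease):
database_score_ii    0.344
database_score       0.319
overlap_pct          0.112
matching_bkpt_pct    0.097
length_bp            0.047
pruned CART:
|--- database_score <= 0.69
|   |--- class: CNA
|--- database_score >  0.69
|   |--- class: CNV
```

40 synthetic patients are truth-labeled from their paired normals, split
60/40 *by patient*, and a 1-SE-pruned CART plus a 500-tree forest are fitted
on the training patients. Both the forest's importance ranking (Database
scores first, cohort overlap next) and the pruned tree's single
Database-score split mirror the structure the method expects; the
near-perfect accuracy reflects that every planted CNV locus is present in the
synthetic catalogue, which real catalogues are not (see `docs/methods.md`).

The other example scripts walk the earlier stages: `01_simulate_cohort.py`
(generation and file export), `02_call_and_label.py` (calling and
truth-labeling; on the small preset, 29 candidates split into 11 CNVs and 18
CNAs), `03_features_and_published_trees.py` (feature matrix and published
rules).

For shell use the same stages are exposed as a thin CLI:

```bash
cnvclass simulate --preset small --out-dir fixture --seed 11
cnvclass classify --tumor-probes fixture/tumor_probes.tsv \
    --tumor-seg fixture/tumor.seg --dgv fixture/dgv.tsv \
    --chrom-lengths fixture/chrom_lengths.tsv \
    --model cbs_smoothed_full --out report.tsv
```

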