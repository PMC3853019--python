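# Methods

## Model

`morfpssm` treats MoRF identification as per-residue binary classification.
The only input features are the values of a PSI-BLAST position-specific
scoring matrix (PSSM): an N×20 table of integer log-odds scores, one row
per residue, one column per standard amino acid in PSI-BLAST header order
(A R N D C Q E G H I L K M F P S T W Y V). No predicted disorder, solvent
accessibility or other per-residue features are used.

The core assumption is that MoRFs are conserved *relative to their own
sequence neighbourhood*, while their absolute conservation is unremarkable
(disordered regions evolve fast, and profile score levels vary with
alignment depth and composition). The transformation pipeline converts
absolute scores into that relative signal:

* **Masking** (window 2n+1 = 25): each score minus the mean of the scores
  in a centred window of the same column. The window includes the centre
  position. At the termini the window is truncated to the positions that
  exist and the mean divides by the actual count; a fixed 2n+1 denominator
  is only meaningful for full windows, and zero-padding would bias the
  local mean toward zero at the ends.
* **Filtering**: masked scores ≤ 0 become 0. Only above-local-average
  conservation survives. Filtering is idempotent.
* **Smoothing** (window 2m+1 = 13): each row replaced by the element-wise
  *sum* (not mean) of the rows in a centred window, with m all-zero rows
  conceptually appended at each end so the output keeps exactly N rows.
  Smoothing spreads conservation evidence to neighbours: isolated conserved
  positions stay weak, dense runs of conserved positions — the signature of
  a MoRF — reinforce each other.
* **Scaling**: all values divided by one global divisor and clipped to
  [−1, 1]. The divisor is the maximum absolute transformed value over the
  *training* matrices, stored in the model and reused verbatim at
  prediction time. A per-protein divisor would make train- and test-time
  feature spaces incomparable, which is why a single global ratio is used.

Four encoder ablations are available: `raw` (scaled untouched matrix),
`mask_only` (mask + filter), `smooth_only` (smoothing applied directly to
the raw matrix) and `mfs` (the full mask → filter → smooth pipeline, the
default). Note that `smooth_only` output can be negative, so the
non-negativity guarantee of the smoothed stage holds only downstream of
filtering.

Each residue is encoded by the outside sliding window: the concatenation of
the 2h+1 = 25 scaled rows centred on it (500 features), zero rows
substituting for positions beyond the termini — consistent with zero being
the neutral value both of the log-odds scale and of the scaled space.

The classifier is an RBF-kernel SVM (scikit-learn's `SVC`, which wraps
libsvm). Training uses all MoRF residues and an equal number of uniformly
down-sampled non-MoRF residues (seeded; the ratio is a parameter, so 1:2 or
unbalanced training is available). `grid_search` optimizes (C, γ) by
stratified k-fold cross-validated balanced accuracy over the canonical
coarse grid C ∈ {2⁻⁵ … 2¹⁵}, γ ∈ {2⁻¹⁵ … 2³}; folds default to 5. The
package's default hyperparameters for direct training are C = 1 and
scikit-learn's `gamma="scale"`, which are near the grid optimum on the
synthetic benchmark at a fraction of the cost; the test suite and the
worked example use them. Binary calls threshold the signed decision margin
at 0; the stored threshold is the single source of truth for calls.

## Evaluation

Evaluation is per-residue, pooled over all proteins of a test set:
sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), FPR = 1 − specificity,
accuracy = (TP+TN)/N, and balanced accuracy ACC = (sensitivity +
specificity)/2. The ROC curve sweeps all score thresholds with tied scores
grouped (one vertex per distinct score), is anchored at (0,0) and (1,1),
and AUC is its trapezoidal integral — identical to the Mann–Whitney
pair-ordering probability, which the test suite uses as an independent
oracle. Metrics with a zero denominator are reported as absent, never
coerced to 0.

## Region composition analysis

For a flank length W, residues partition into MoRF (annotated intervals),
flank (within W of a MoRF boundary, outside every MoRF — residues between
two MoRFs closer than 2W are flank, tagged once) and general non-MoRF (the
remainder; the W-flanks are excluded from it so the background is not
contaminated by near-MoRF sequence). Amino-acid compositions are pooled
counts over all residues with a tag, divided by the pooled total.
Physicochemical compositions use Taylor's overlapping amino-acid classes
(hydrophobic, polar, small, tiny, aliphatic, aromatic, positive, negative,
charged, proline); the membership map is configurable. Difference curves
report flank-minus-background fractions per feature across W = 1…30, and
each feature's trend is summarised by a Pearson correlation of difference
against W with its two-sided t-distribution p-value (scipy). Constant
series have undefined r and are reported as NaN.

## Synthetic benchmark

The generator plants the one property the predictor consumes — local
conservation contrast — into otherwise random data:

* 50 proteins by default, lengths uniform in 60–200 residues (a plausible
  band for MoRF-carrying chains that keeps desk-scale runtimes small);
  1–2 planted MoRFs per protein, lengths uniform in 5–25 residues (the
  defining band for short MoRFs), non-overlapping with ≥ 10 residues of
  separation.
* Each position is independently "conserved" with probability 0.7 inside
  MoRFs and 0.15 elsewhere. A conserved position scores ~N(+7, 2) in its
  own amino-acid column and ~N(−3, 2) elsewhere, mimicking a strongly
  constrained alignment column; a variable position scores i.i.d. ~N(−1, 2)
  in all 20 columns. Scores are rounded to integers and clipped to
  [−10, 12], a PSI-BLAST-plausible range, so parsed real PSSMs and
  generated fixtures exercise identical code paths.
* Each protein additionally receives a per-column baseline offset drawn
  N(0, 3), emulating the alignment-composition-dependent column baselines
  of real profiles. This is what makes absolute scores untrustworthy across
  proteins: the offsets form a 20-dimensional protein fingerprint that does
  not transfer, while column-wise masking cancels a per-column constant
  exactly, leaving the relative-conservation path untouched.

Two qualitative published behaviours emerge from this design rather than
being asserted: (i) raw row sums of MoRF residues sit *below* the
background (a conserved row pairs one high score with nineteen low ones),
while after mask → filter → smooth the MoRF row sums sit clearly above it;
(ii) the full `mfs` encoder outperforms the `raw` encoder on held-out
proteins (pooled AUC ≥ 0.85 at 60 training / 20 test proteins), because
the raw features carry the non-transferable baseline fingerprint.

What the benchmark does *not* show: performance on real proteins. The
generator has no evolutionary model, no realistic amino-acid composition,
no correlation between sequence and conservation beyond the own-column
peak, and its conservation contrast is sharper than real MoRF signals.
Passing tests demonstrate that the pipeline recovers the signal it is
designed to recover when that signal is present — correctness, not
biological benchmark performance. Published benchmark-scale results
additionally require the external training/test chain sets and PSI-BLAST
profiles computed against the NCBI non-redundant database, which are out of
scope here (the optional `psiblast` wrapper is a thin shell command and is
never needed by tests).

## Numerical and design notes

* Internal coordinates are 0-based half-open; annotation files are 1-based
  inclusive, converted only at I/O boundaries. Overlapping or adjacent
  annotated intervals are merged on read.
* Only the first (log-odds) 20-column block of a PSI-BLAST ASCII PSSM is
  parsed; the weighted-percentage block and information columns are
  ignored. Header column order is honoured and reordered to canonical order
  if it differs.
* Raw-stage matrices must hold integers; filtered matrices must be
  non-negative; scaled matrices must lie in [−1, 1]. These contracts are
  re-validated when matrices are read back from disk.
* Residues labelled X get no own-column peak in the generator and are
  excluded from composition denominators; in real input they are accepted
  in sequences and scored like any other position from their matrix rows.
* Matrix TSVs round-trip values losslessly (`repr` precision on write,
  round-trip float parsing on read).
* Grid-search ties break toward the first grid point in iteration order;
  fold assignment is stratified and seeded, so the whole train/predict
  path is deterministic given seeds.
* Test and acceptance problem sizes (10–60 proteins, lengths 40–200) are
  the package's chosen desk-scale study conditions; they keep the full
  suite under a minute while leaving the planted signal comfortably
  recoverable.
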