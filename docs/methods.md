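# Methods

## Assay model

MLPA quantifies template copy number through ligation-dependent
amplification: a probe pair only amplifies when its left (L) and right (R)
halves hybridise adjacently and ligate, after which a single universal
primer pair amplifies all probes at roughly equal rates. Sequencing-based
readout replaces fragment-length electrophoresis with read counting, so
probe capacity is limited only by sequence specificity. The panel modelled
here follows the DMD-SMA kit design: 80 probes over the 79 DMD exons (two
on exon 1), 8 probes on the SMN exons that do not discriminate SMN1 from
SMN2, 4 probes whose terminal base discriminates SMN1/SMN2 at exons 7 and
8, 3 chrX and 3 chrY probes for sex determination, 10 autosomal internal
references and a pre-added external-reference template — 108 genomic
probes plus the external control.

Reads are 40 bp of the ligated binding region plus an 8 bp sample index.
A read is attributed to a probe when three 10-mer *detective sequences*
match exactly at window offsets [0,10), [15,25), [30,40) of the read. The
exact offsets are a panel-level constant; the default tiles the read and
places the last window across the L/R junction, making attribution
ligation-dependent. Exact matching means any sequencing error inside the
30 interrogated bases discards the read — a deliberate trade of ~3% yield
(at error rate 10⁻³) for the elimination of cross-probe misassignment,
since no 10-mer recurs anywhere in a valid panel (enforced at load).

## Normalisation and copy-number model

Within a sample, each probe count is divided by the mean of the ten
internal-reference counts (*relative amplification*). Whether the
aggregate is the mean or the sum is provably inert for downstream copy
numbers — it is the same constant in sample and control — and the
implementation makes this literal: the sample/control ratio is computed
from raw integer counts and raw reference sums, so the two aggregation
choices give bit-identical results, and rescaling all counts by a common
factor changes nothing.

Sex is called from the Y/X ratio of relative amplifications: < 0.1 female,
> 0.5 male. The gap is reported as *indeterminate* and fails sample QC
rather than being guessed.

Relative copy number multiplies the sample/control ratio by the control's
copy state: a healthy male control contributes one DMD copy (multiplier 1;
a female control would give 2), four total SMN copies (multiplier 4 on the
total scale), and two copies of each SMN paralog and each autosomal
reference (multiplier 2). SMN is reported on the *half* scale by default
(a normal total of four appears as 2), matching the published case values;
the total scale is available via a flag and is used internally for SMN
consistency checks.

QC windows: a probe passes when rcn is within 30% of its theoretical value
(inclusive, with a 1e-9 relative epsilon against floating-point edge
cases); a probe whose residual is below 0.05 passes as `deleted_pass`.
Sample QC requires a determinate sex call and all internal references in
window; aberrant disease-gene probes are findings, not QC failures.

## Event calling

Continuous rcn values round to integer copies; zero-copy calls require
rcn < 0.35 and are confident only below the 0.05 residual ceiling, nonzero
calls are confident within ±0.3 of the integer. DMD events are maximal
contiguous runs of deviating exons, segmented run-aware:

- runs share a *direction* (gain or loss), and each event's copies come
  from the mean rcn over its exons, so one exon wobbling between adjacent
  integers cannot split a contiguous aberration;
- two same-direction runs separated by a single exon leaning their way by
  at least half the confidence band are bridged;
- boundaries are refined by likelihood: an adjacent exon joins the run
  when its value is better explained by the run's copy level than by the
  expected level, with noise proportional to level (the crossover for a
  2→3 gain sits slightly below the rounding midpoint). Zero-copy runs are
  exempt — their boundaries are crisp;
- every event must clear an evidence threshold in counting standard errors
  of the run mean (per-probe errors propagate delta-method from the four
  count terms). Thresholds are 4 for single-exon runs, 8 for two-exon
  runs, 5 for longer ones: a genuine one-copy change at the design depth
  yields z ≈ 4–6 (single) and ≥ 9 (pair), while coincident noise crossing
  the rounding midpoint lands near 3 and 7. Sub-threshold deviations and
  isolated ambiguous exons become review flags, echoing the practice that
  single-probe alterations require orthogonal confirmation.

Exon 1's two probes must agree; disagreement downgrades or flags the exon.

SMN interpretation integerises the SMN1/SMN2 exon-7/8 probes and the SMN
total (from the eight undiscriminated probes, on the total scale). SMN1
loss with SMN2 gain at an unchanged total of four is annotated
`conversion_suspected`; a one-copy mismatch between paralog sum and total
is tolerated as discriminating-probe wobble; larger mismatches are
`inconsistent`. Screening tags (`SMA_affected`, `SMA_carrier`,
`DMD_affected`, `DMD_carrier`) are string annotations derived from SMN1
exon-7 copies and DMD events, not diagnoses.

## Simulator

The generator emulates the study conditions: ~600 reads per *diploid*
probe (so one X-linked copy in a male averages ~300 — read counts are
strictly proportional to template copies, which is what makes the
control-multiplier arithmetic valid), per-probe lognormal amplification
efficiencies with CV 0.30 (reproducing the 0.26–0.36 within-sample
dispersion observed across internal-reference probes), negative-binomial
per-draw noise with size 1000 (mild extra-Poisson spread), substitution
errors at 10⁻³ per base, 15% unassignable junk reads (uniform random
40-mers, putting the analyzable fraction in the observed high-70s–80s
band), and a small constant external-reference count independent of
genomic template. Efficiencies are seeded separately from count noise and
shared across all samples of a run, as probe bias is a property of the
probe mix; this is what lets efficiency cancel in sample/control ratios,
exactly as in the physical assay.

Deleted loci emit no reads of their own; residual signal can only arise
from sequencing errors converting another probe's read, which exact
three-window matching makes vanishingly rare — hence deleted-exon rcn
lands essentially at zero, comfortably below the 0.05 ceiling.

What the simulator does not model: PCR cycle kinetics and GC-dependent
bias, index hopping, quality-score structure (a constant Q30 placeholder
is written), inter-sample efficiency drift, SNPs under probes. Passing
tests therefore demonstrate the correctness of the counting and calling
arithmetic under a faithful count-statistics model, not robustness to
every artefact of real libraries.

## Problem sizes and known limitations

Tests and the acceptance script run desk-scale problems: the full
108-probe panel, ~50–70k reads per sample, 50 replicate seeds for the
recovery and depth-sufficiency checks — a couple of minutes end to end.

At 600 reads per diploid probe, the per-probe rcn noise is 5–13%
(depending on the probe's amplification efficiency; the male control
halves X-linked counts). Consequences worth knowing:

- extreme order statistics over 65 probes (the min/max non-deleted rcn)
  fluctuate run to run by ~0.1 and can stray outside the 0.8–1.3 band that
  deep-coverage runs exhibit, even though every probe still passes the 30%
  QC window in the large majority of runs;
- exact event *boundaries* are information-limited: a boundary exon of a
  one-copy gain sits ~2σ from the decision point, so a duplication's
  reported range misses or gains one edge exon in a few percent of runs
  (the event itself is still detected); deletions are immune, their signal
  being ~0;
- single-probe SMN1/SMN2-discriminating calls wobble by design; the SMN
  total is the calibrating signal, which is why consistency tolerates a
  one-copy mismatch.

Multi-control averaging, batch-effect correction and mismatch-tolerant
barcode rescue are deliberately out of scope.
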