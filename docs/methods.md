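# Methods

## Model and assumptions

A gene's probe intensities are modeled as `Y = diag(A)·G·T` after upstream
background removal and cross-array normalization (which this package does
not perform): each probe's signal is its affinity times the summed
concentration of the isoforms it hybridizes to, with `G` binary.  Merging
the affinity and structure factors gives a non-negative factorization
`Y ≈ W·H` of internal dimension equal to the number of isoforms.  Key
assumptions:

* every probe hybridizes to at least one isoform (an all-zero structure row
  is rejected as a model violation);
* the structure matrix is dense in ones — most exons are shared between the
  isoforms of a gene — which is what allows the diagonal gauge of the
  factorization to be fixed by making the columns of `W·D` mutually similar;
* probes within a probeset share one hybridization pattern, so structure
  rows of a probeset may be pooled;
* residuals are approximately homoscedastic after the power-0.7 median
  rescale (below).

## Stages and parameters

Per gene, in order (all defaults overridable on `SpaceDecomposition` /
`PipelineConfig`):

| stage | parameter | default | rationale |
| --- | --- | --- | --- |
| homoscedastic rescale | `power` | 0.7 | residual spread grows sublinearly with probe intensity; each probe row is divided by `median(row)^0.7`.  The exponent was calibrated on single-transcript genes in the original analyses; refitting is out of scope |
| outlier repair | `n_resamples` | 250 | resamples of the four-block split; each entry gets a distribution of holdout estimates at the largest feasible rank (`min(block dims) − 1`) |
|  | `outlier_c` | 3.0 | an entry is replaced when its residual to the median estimate exceeds `c` robust SDs; the robust scale is the normal-consistent MAD (1.4826×) of the entry's estimates, floored by the global MAD of all residuals — the floor prevents the estimate spread (which underestimates the noise level) from flagging ordinary entries, and makes the correction idempotent in practice |
| rank estimation | `max_transcripts` | 6 | candidate-rank ceiling; deconvolution quality degrades beyond 4–5 isoforms and the ceiling also caps cost.  Also capped at `min(m, n) − 1` |
|  | `alpha` | 0.05 | one-sided Mann–Whitney level for "not significantly worse than the best rank"; ties handled by the normal approximation with tie correction |
| NMF | `n_iter` | 3000 | multiplicative (Lee–Seung) Frobenius updates, fixed budget, `1e-12` added to denominators; optional `tol` enables relative-loss early stopping.  Initialization: `Uniform(0,1)·sqrt(mean(Y)/k)`, seedable; `n_restarts=1` |
| Adapt | `fill_floor` | 1e-3 | entries of `W` below `fill_floor ×` column max are excluded from the log-domain objective (a near-zero entry carries no scale information); the same floor "fills" `G̃` before downstream use.  The gauge objective `Σ_i Σ_{j<k} abs(log(d_j w_ij) − log(d_k w_ik))` is convex piecewise-linear in `log d` and solved exactly by LP (HiGHS), with a pairwise-median + least-squares fallback; gauge fixed at `d_1 = 1`, so concentrations are in relative units |
| coherence | — | on | each probeset block of `G̃` is replaced by its column means (closest rank-one block); a mean of exactly 0.5 rounds up at the discretization.  Disable with `coherence=False` / `--no-coherence` — note a real splicing event that cuts through a probeset is invisible to the correction |
| threshold | `threshold` | 0.5 | binarization of `G̃`; 0.5 minimizes the overall Hamming error, while the SN=SP operating point sits higher.  Columns left empty at the threshold are dropped with a warning |

The transcript order of an estimate is arbitrary; comparisons against a
reference first resolve the column permutation by optimal assignment under
per-column L1 distance (Hungarian algorithm; unequal column counts are
zero-padded, surplus columns reported as unmatched).  The same permutation
is applied to concentration rows.

## Synthetic data

`simulate_dataset` emulates a realistic exon-array experiment:

* 33 samples (eleven conditions in triplicate is a typical tissue panel);
* 8 probesets per gene, 3–4 probes each;
* structure patterns drawn Bernoulli(0.8) per probeset — annotated human
  structure matrices are about 80% ones — with rejection sampling until all
  transcript columns are distinct and non-empty and every probe hybridizes
  somewhere;
* affinities log-normal with median 100 and log-SD 1 (heavy-tailed, as
  estimated from real arrays);
* concentrations `T[j,s] = Uniform(0,1) × f_j`, `f_j ~ Uniform(0,1)` per
  transcript, so some isoforms are systematically faint;
* noise `Y = max(0, clean·exp(N(0, 0.20)) + N(0, 0.05·median(clean)))` —
  20% multiplicative noise and a 5%-of-signal additive floor, a plausible
  post-normalization noise level for these arrays.

What the generator does **not** emulate: real probe sequence effects
(cross-hybridization, GC bias), non-functional probes, background-removal
residue, correlated noise between samples, or annotation-derived structures
whose size grows with isoform count.  Passing simulation checks therefore
demonstrates correctness of the machinery under the stated noise model, not
performance on any particular real dataset.

## Evaluation studies

`isospace.experiments` fixes the standard study designs; `scripts/acceptance.py`
runs them at their full scales (chosen so one CPU finishes in minutes):

* **Splicing-call rates** — 200 single-transcript genes give the false
  positive rate (fraction with estimated count > 1); 200 genes with 2–6
  transcripts give the false negative rate (fraction collapsing to 1).
* **Structure recovery** — 150 multi-transcript genes, true transcript
  count supplied to isolate structure estimation from rank estimation;
  confusion counts pooled over a 0.05-step threshold grid yield Hamming
  distance `HD = (FP+FN)/N`, sensitivity `SN = TP/(TP+FN)` and specificity
  `SP = TN/(TN+FP)`; reported are the interpolated SN=SP crossing, the
  HD-minimizing threshold, and the relative crossing-error reduction versus
  the baseline run (identical seeds, outlier correction/Adapt/coherence
  disabled).
* **Concentration error** — mean absolute error as a percentage of the
  truth's mean, after per-gene least-squares scale alignment (the overall
  scale is not identifiable); used to verify that the Adapt gauge fixing
  lowers the error.

A gene whose fit fails (e.g. a probe row driven to a zero median by noise
clipping) is excluded from the affected summary and counted; such failures
are rare at the default noise.

## Numerical choices and degenerate inputs

* Truncated pseudoinverses drop singular values below `1e-12 ×` the largest,
  so rank-deficient holdout blocks stay finite.
* An error table with all-equal entries (constant matrix) returns one
  transcript with a warning; a threshold grid where SN and SP never cross
  returns the nearest boundary with a warning, and coinciding curves return
  the grid midpoint.
* Corrected outlier entries are clipped at zero (intensities are
  non-negative); negative simulated intensities after additive noise are
  likewise clipped.
* The SN/SP curves are made monotone (isotonic cleanup) before the crossing
  interpolation.
* Known-structure deconvolution (`deconvolve_known_structure`) solves
  per-sample NNLS and flags the classic deconvolution ambiguity by
  comparing the nullity of the linearized `(A, T) → Y` map with the number
  of connected components of the probe–transcript graph (one free scale per
  component is the expected gauge; anything more means continuum-many exact
  solutions).  When affinities are not supplied, the leading left singular
  vector of `Y` serves as the affinity profile.

## Open design points

* The exact notion of "far from the median" for outliers, the laterality
  and level of the rank-selection test, the similarity measure for
  transcript matching, and the MAE normalization are not uniquely
  determined by the model; the choices above (robust MAD rule, one-sided
  alpha=0.05, L1/Hungarian, mean-of-truth denominator) are documented
  defaults, all configurable where they matter.
* Exact recovery on clean data is only guaranteed when the factorization is
  unique; the test suite operationalizes this as double separability (an
  anchor probe and an anchor sample per isoform).  Generic clean genes can
  admit a polytope of exact factorizations, a limitation inherited from the
  model, not from the optimizer.
* Prior information on mean probeset affinities could resolve the
  deconvolution ambiguity for affected structures; the ambiguity flag is
  the hook for it, the prior itself is not implemented.

## Known limitations

Structures with more than 4–5 isoforms over few probesets are weakly
determined, which diffuses the continuous structure estimate and lowers the
threshold at which sensitivity and specificity balance; pooled summaries
over hard gene mixes inherit this.  Rank estimation is conservative in the
direction of missing faint isoforms (by design — the alternative-splicing
call keeps a very low false positive rate).  All concentrations are
relative; comparisons across genes require external calibration.
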