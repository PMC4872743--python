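# Methods

This note records the models implemented in `sirmkit`, the assumptions they
make, the defaults that matter, and what the synthetic-data tests do and do
not establish about real data.

## Citrate atom routing

**Model.** Citrate's six carbons are tracked positionally. Positions 1–2
derive from acetyl-CoA, positions 3–6 from oxaloacetate (OAA); position 6
is the OAA carboxyl that derives from the carboxylation CO₂ — the carbon
added when α-ketoglutarate is reductively carboxylated, and the carbon the
C5 GC-MS fragment (273 m/z after MSTFA derivatization) lacks. Five base
routes form a probability simplex over citrate molecules:

| route | tracer that lights it up | labelled positions | full-molecule shift | C5-fragment shift |
| --- | --- | --- | --- | --- |
| oxidative, glucose-derived acetyl-CoA (`f_ox_glc`) | U-¹³C₆-glucose | 1–2 | m+2 | m+2 |
| oxidative glutamine via OAA (`f_ox_gln`) | U-¹³C₅-glutamine | 3–6 | m+4 | m+3 |
| reductive carboxylation (`f_red_gln`) | U-¹³C₅-glutamine | 1–5 | m+5 | m+5 |
| pyruvate carboxylase (`f_pc`) | U-¹³C₆-glucose | 3–5 | m+3 | m+3 |
| unlabelled (`f_unlab`) | — | none | m+0 | m+0 |

CO₂ fixation (`f_fix`) is orthogonal to the base simplex: under the
¹³C-bicarbonate tracer, a fraction `f_fix` of molecules carries one label at
position 6 (m+1 in full-molecule fragments, invisible to the C5 fragment).
Fragment MIDs are exact marginals of the per-carbon label-pattern
distribution over the fragment's retained positions, so the model is
exactly linear in the routing fractions.

**Assumptions.** One TCA turn only — multi-turn scrambling (m+2/m+3
mixtures from repeated cycling) is not modelled, which is appropriate for
short-pulse labelling (minutes) where most citrate has passed the cycle at
most once. Which citrate carbon the 273 m/z fragment loses is not
established analytically; modelling it as the carboxylation-derived OAA
carboxyl reproduces the observed fragment contrasts (bicarbonate label in
375/459 but not 273; glutamine-oxidative m+4→m+3 shift in the C5 fragment)
and is flagged as an inference, not a measurement.

**Inverse fit.** Minimizes the summed squared MID misfit across all
observed (tracer, fragment) pairs, with the base fractions constrained to
the simplex and every parameter to [0, 1]. Because the model is linear the
problem is a convex QP; it is solved with SLSQP (`ftol` 1e-16) and polished
by an exact KKT re-solve on the active set, so noise-free data reproduces
its generating fractions to solver precision (residual ≤ 1e-9 on a full
0.1-step simplex grid). Identifiability is checked up front by the rank of
the stacked single-route design; a glucose-only design, in which the two
glutamine routes and the unlabelled route are indistinguishable, raises an
explicit rank error. `f_fix` is estimated only when a bicarbonate-tracer
MID is present, otherwise pinned to 0; `f_pc` can be pinned by flag since
short glucose pulses often cannot separate it from acetyl-CoA labelling at
low signal.

**Uncertainty.** Residual bootstrap with 200 replicates by default,
percentile 95% intervals, fully seeded. The resampling is *scale-aware*:
relative residuals at signal-bearing positions are resampled with
replacement and reapplied multiplicatively. GC-MS intensity error is
predominantly multiplicative, so raw residuals are not exchangeable across
positions spanning orders of magnitude; with iid residual resampling the
measured coverage on the package's own 1%-noise study was ~60%, with the
relative scheme ~88% (seeded study: 40 simplex draws × 100 replicates,
chosen to keep the default test run fast).

## pSIRM quantification

Isotopologue tables are tidy frames keyed by (metabolite, fragment m/z,
mass shift) with one intensity column per sample and a cinnamic-acid
internal-standard row. Technical duplicates are averaged on the intensity
scale before MID computation.

* **Normalization** — metabolite quantity is the summed intensity over
  shifts of the quantifier fragment (by default the fragment retaining the
  most metabolite carbons, 459 m/z for citrate) divided by the sample's
  cinnamic-acid intensity; invariant to per-sample global scale.
* **Label incorporation** — the measured MID of an unlabelled
  identification standard serves as the reference for natural ¹³C
  abundance. The unlabelled component of a sample MID is reconstructed by
  scaling the reference so its m+0 matches the sample's
  (`expected_j = s0 · ref_j / ref_0`); mass above expectation at shifts ≥ 1
  is label-derived excess, and the incorporation is
  `Σ excess / (s0 + Σ excess)`, clipped to [0, 1]. Negative excess (noise
  pushing measured below expected) is clipped to 0 and accumulated as a QC
  metric. When no measured standard exists, a theoretical binomial
  natural-abundance reference over all fragment carbons (metabolite plus
  derivatization-reagent carbons, default p = 0.0107) stands in; only
  carbon isotopes enter the envelope, because the correction path is
  reference-based and the non-carbon isotope contributions cancel between
  sample and standard to first order.
* **Labelled quantity** — incorporation × normalized quantity; bounded by
  the normalized quantity with equality only at full incorporation.
* **Natural-abundance deconvolution** — for downstream routing the full
  tracer-derived MID (including its m+0 component) is recovered by
  non-negative least squares against the envelope's convolution matrix.
  This is exact on noise-free data and keeps the result a valid MID under
  noise. It is preferred over the excess-MID route for fitting because the
  envelope smears labelled species beyond the metabolite's shift range,
  which the single-turn forward model deliberately has no support for.

The empirical-reference incorporation formula is a contract, not an
unbiased estimator: with a dispersed reference (p13c > 0) it returns
`g / ((1−g)·E0 + g)` for a planted incorporation `g`, where `E0` is the
reference's m+0 mass. Its round-trip exactness is therefore verified in the
regime where the envelope is the identity; accuracy under a dispersed
envelope is the deconvolution path's job.

## Expression selection and FDR

* **Filter** — genes below the per-sample median in *every* sample of every
  experiment are discarded. "Per-sample median with all-sample consistency"
  is one reading of a 50%-quantile filter; it is the default and the
  alternative (per-dataset quantile) can be emulated by pre-filtering.
* **Error model** — per experiment, the log2 fold change
  `fc = mean(sample) − mean(control)` is divided by a spread `σ(a)`
  estimated as the centered rolling median absolute deviation (× 1.4826) of
  `fc` over a window of genes ranked by mean intensity `a`. Window default
  200 genes: narrow enough to track the strong low-intensity variance
  inflation of array data, wide enough for a stable robust estimate. The
  interface accepts a user-supplied σ table for exact replication of other
  error models. A rolling MAD over a finite window has sampling noise of
  roughly `σ·1.17/√window` per window (~8% at 200 genes), so per-window
  agreement with a flat truth at the 10% level is only testable at wide
  windows; the suite checks all windows at width 2000 and the median window
  at the default width.
* **Selection** — per experiment the threshold is the inclusive (type-7)
  empirical (1−q) quantile of |z| (q default 0.10); a gene is selected iff
  its |z| meets every experiment's threshold (≥, so boundary ties are
  selected) with an identical sign of regulation everywhere. Positive z
  means up in the knock-down sample versus control.
* **FDR** — each of `n_draws` (default 1000) draws resamples every
  experiment's z values with replacement, independently per experiment,
  destroying the cross-experiment gene matching while preserving each
  experiment's marginal z distribution (on which the decile thresholds
  depend); the selection is re-run and FDR = mean null count / observed
  count, clipped to [0, 1]. A sign-permutation null is available as an
  alternative. With no observed selections the report is explicitly
  undefined rather than 0 or 1. Note the estimate is Poisson-noisy in both
  numerator and denominator at small expected counts: at 2000 genes and
  q = 0.1 the expected null count is ≈ 0.5 per draw, so pure-null behaviour
  (estimate ≈ 1) is only measurable at much larger gene counts, which is
  how the calibration checks are sized.

## Exclusivity screen

High-expressor calls use strict inequality under both rules: mean + 1 SD
(sample SD, n−1) for tumor-panel style data, or positive deviation from the
gene's median profile for cell-line panels; thresholds are retained for
audit and constant genes yield all-false calls with a warning. Pair tests
fix both margins and use exact hypergeometric tails on the joint-high count
(upper tail = co-occurrence, lower = exclusivity); the odds ratio applies
the Haldane–Anscombe 0.5-per-cell correction only when a zero cell exists,
keeping exact ratios where defined. Classification bands default to
odds ratio < 0.1 (mutually exclusive) and > 2 (co-occurring). Clustering
z-scores genes across samples and applies euclidean-distance agglomerative
clustering, average linkage by default (single/complete/ward by flag, since
the choice is not canonical); Pearson correlations carry the two-sided
t-based test of r = 0, with pairs involving constant genes reported as
missing rather than imputed.

## Synthetic data: what it does and does not emulate

The generators produce: isotopologue tables as tracer MIDs convolved with
binomial envelopes plus log-normal multiplicative noise (unit mean,
σ² = ln(1+cv²)) and an additive Gaussian floor, clipped at zero, with an
internal-standard channel; three-replicate sample/control expression
experiments with a planted fraction of regulated genes carrying consistent
signed log2 effects and intensity-dependent noise (spread growing ~4× at
the low-intensity end of the 6–14 log2 range); and binary call vectors with
tunable marginals and planted exclusivity/co-occurrence. Default study
conditions for the selection stage follow the three-experiment,
top-decile, 1000-draw design.

Not emulated: chromatogram/spectrum-level effects (retention times,
spectral overlap, deconvolution artefacts), multi-element isotope fine
structure, probe-level array effects, batch structure, and correlated noise
across metabolites or genes. Passing tests therefore establish correctness
of the *computations* under the stated noise models, not robustness to
real-data artefacts upstream of the pipeline's inputs.

## Numerical choices and degenerate inputs

* MIDs must sum to 1 within 1e-9 with non-negative entries; renormalization
  from raw intensities rejects all-zero fragments explicitly.
* Fractions simplex validated to 1e-9; fit results are renormalized on the
  simplex after clipping solver dust.
* t-tests on degenerate replicate sets: identical groups report t = 0,
  p = 1; zero-variance separated groups report |t| = ∞, p = 0.
* Genes with zero fitted spread get z = 0 when their fold change is 0
  (0/0), otherwise the spread floor is effectively infinite and z = 0 —
  such genes cannot be selected, which is the conservative behaviour.
* All stochastic stages take explicit seeds; pipeline stages derive child
  seeds as SHA-256 of `"{global_seed}:{stage_tag}"` reduced below 2³¹, so
  any stage can be re-run in isolation and reproduce its output exactly.

## Problem sizes in the default test run

Chosen as the package's own verification design: the incorporation round
trip runs an 11-point grid × 3 fragments; routing recovery 100 random
simplex draws at 1% noise plus ~250 noise-free grid points; bootstrap
coverage 40 draws × 100 replicates; FDR calibration 20 planted datasets of
2000 genes (200 null draws each) and pure-null replicates at 50,000 genes;
hypergeometric tails exhaustively for n ≤ 12; selection oracle 400 random
small tables.

## Known limitations

* The routing fit assumes the fragment catalogue's carbon bookkeeping; a
  wrong lost-carbon assignment for 273 m/z would swap the oxidative
  glutamine and pyruvate-carboxylase diagnostics in that fragment.
* The incorporation estimator's denominator convention (above) makes it
  comparable across samples but not an absolute molar labelling fraction
  under a dispersed reference.
* The FDR null preserves marginals but not inter-gene correlation within an
  experiment; strongly co-regulated null genes can make the estimate
  anti-conservative.
* No support for compressed/binary vendor formats; inputs are delimited
  text.
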