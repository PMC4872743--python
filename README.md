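# sirmkit

Tools for **pulsed stable-isotope-resolved metabolomics (pSIRM)** readouts of
central carbon metabolism, and for the two transcriptome screens that
typically accompany such studies in cancer cell-line work:

* **pSIRM quantification** — GC-MS isotopologue tables are normalized to a
  spiked internal standard (cinnamic acid), label incorporation is estimated
  against an unlabelled reference spectrum, and the product of the two — the
  *labelled quantity* — serves as the per-metabolite pathway-activity readout.
* **Citrate carbon routing** — fragment-resolved mass isotopomer
  distributions (MIDs) of citrate under U-¹³C₆-glucose, U-¹³C₅-glutamine and
  ¹³C-bicarbonate tracers distinguish oxidative TCA metabolism (citrate m+2
  from glucose, m+4 from glutamine), reductive carboxylation of
  α-ketoglutarate (m+5), pyruvate-carboxylase anaplerosis (m+3) and direct
  CO₂ fixation (m+1). The contrast between the full-molecule fragments
  (375/459 m/z) and the C5 fragment (273 m/z), which lacks the
  carboxylation-derived carbon, localizes the fixed carbon positionally.
  A constrained least-squares fit inverts the forward atom-routing model to
  estimate the mixture fractions of these routes on the simplex.
* **Consistent-top gene selection with resampling FDR** — per-experiment
  log2 fold changes are z-transformed with an intensity-dependent error
  model; genes whose |z| is in the top decile of *every* replicate
  experiment with a consistent sign are selected, and the false-discovery
  rate of that rule is estimated by random draws that break the gene
  linkage across experiments.
* **Mutual-exclusivity / co-occurrence screen** — expression is binarized to
  high-expressor calls (mean + 1 SD, or deviation from the median gene
  profile), gene pairs are scored with hypergeometric tail probabilities and
  odds ratios, triplets are partitioned into Venn regions, and panels are
  clustered (euclidean distance on z-scores) with Pearson correlation tests.

Every input the pipeline consumes can be generated synthetically with
planted ground truth (`sirmkit.synthetic`), so each stage is testable
end-to-end against known answers.

## The core model

Citrate's six carbons are tracked positionally: two derive from acetyl-CoA,
four from oxaloacetate, and one of the OAA carboxyls is the
carboxylation-derived carbon the C5 GC-MS fragment loses. Each routing
pathway maps to a per-carbon label pattern, the observed MID of a fragment
is the mixture-weighted marginal over the fragment's retained carbons, and
the measured intensities are that MID convolved with the binomial natural
¹³C-abundance envelope over all fragment carbons (metabolite + derivatization
reagent) at p = 0.0107. The routing fit solves

```
min over f in simplex   sum over tracers, fragments  || MID_sim(f) - MID_obs ||^2
```

with residual-bootstrap confidence intervals.

## Worked example

Simulate a three-tracer citrate experiment with known routing fractions,
add 2% multiplicative measurement noise and natural abundance, correct the
measured MIDs, and invert:

```python
import numpy as np
from sirmkit import synthetic as sy, sirm, routing

truth = sy.RoutingFractions(f_ox_glc=0.35, f_ox_gln=0.25, f_red_gln=0.20,
                            f_pc=0.05, f_unlab=0.15, f_fix=0.08)
observed = {}
for tracer in (sy.Tracer.U13C6_GLUCOSE, sy.Tracer.U13C5_GLUTAMINE,
               sy.Tracer.C13_BICARBONATE):
    mids = sy.simulate_citrate_mids(truth, tracer)
    noise = sy.NoiseModel(multiplicative_cv=0.02, seed=1)
    table = sy.generate_intensity_table(mids, {"citrate": 5e5},
                                        p13c=0.0107, noise=noise)
    for mz, frag in sy.CITRATE_FRAGMENTS.items():
        mid = sirm.raw_mid(table, "citrate", mz, "S1")
        observed[(tracer, mz)] = sirm.natural_abundance_correct(mid, frag, 0.0107)

fit = routing.fit_routing_fractions(observed, n_bootstrap=200, seed=2)
print(f"residual norm: {fit.residual_norm:.4f}")
for name in routing.PARAM_NAMES:
    lo, hi = fit.intervals[name]
    print(f"{name:9s} estimate {getattr(fit.fractions, name):.3f} "
          f"(truth {getattr(truth, name):.2f}, 95% CI {lo:.3f}-{hi:.3f})")
```

prints

```
residual norm: 0.0106
f_ox_glc  estimate 0.349 (truth 0.35, 95% CI 0.343-0.354)
f_ox_gln  estimate 0.246 (truth 0.25, 95% CI 0.242-0.252)
f_red_gln estimate 0.203 (truth 0.20, 95% CI 0.198-0.208)
f_pc      estimate 0.050 (truth 0.05, 95% CI 0.046-0.054)
f_unlab   estimate 0.152 (truth 0.15, 95% CI 0.141-0.161)
f_fix     estimate 0.076 (truth 0.08, 95% CI 0.069-0.088)
```

— all six routing fractions recovered within the noise, with the reductive
(m+5) and CO₂-fixation (m+1) routes cleanly separated from the oxidative
ones. The residual norm is the remaining misfit after the inverse solve;
its bootstrap intervals cover the planted truth.

The same stages are available from the shell:

```bash
sirmkit simulate --preset citrate-routing --seed 1 --out demo/
sirmkit sirm quantify demo/isotopologues_U13C5_glutamine.tsv --out demo/lq.tsv
sirmkit run --seed 1 --out demo/run/     # end-to-end with a manifest
```

## Layout

| module | contents |
| --- | --- |
| `sirmkit.synthetic` | forward models: atom-routing simulator, intensity tables, expression and association generators |
| `sirmkit.sirm` | internal-standard normalization, MIDs, label incorporation, labelled quantities |
| `sirmkit.routing` | diagnostic-shift evidence, simplex-constrained inverse fit, condition t-tests |
| `sirmkit.expression` | low-expression filter, error-model z-transform, consistent-top selection, resampling FDR |
| `sirmkit.exclusivity` | binarization, hypergeometric pair tests, Venn partitions, clustering/correlation |
| `sirmkit.io` / `sirmkit.cli` | readers/writers, configuration, manifests, the `sirmkit` command |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
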