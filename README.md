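# voltmatrix

Voltage-matrix profiling of solid-state nanopore signals: simulate ionic
current recordings of protein analytes under a grid of applied voltages,
detect translocation events, extract baseline-agnostic or baseline-inclusive
feature vectors, assemble train-voltage × test-voltage AUC classification
matrices, and quantify mixture composition from classifier-score histograms
with capture-frequency correction.

## The problem

Solid-state nanopores sense single molecules as transient blockades of the
open-pore ionic current *I₀*. Classifiers trained on event features at one
applied voltage often look excellent there yet fail at another, for two
distinct reasons that a single-condition experiment cannot tell apart:

1. **Baseline overfitting.** Features tied to the acquisition condition —
   absolute blockade amplitude ΔI, open-pore current I₀, baseline RMS noise,
   drift — fingerprint the *setup*, not the molecule. They inflate
   same-condition performance and collapse under condition changes.
2. **Voltage-sensitive analytes.** Some species (e.g. protein–aptamer
   complexes) genuinely change their translocation signature with the
   driving field, so no feature set transfers.

The voltage matrix separates these: train a binary classifier on events
acquired at each voltage *V*ᵢ of a grid (−50 … −300 mV), evaluate it on
held-out events from every voltage *V*ⱼ, and fill a 6 × 6 grid of AUC values
(Mann–Whitney: *P*(score⁺ > score⁻) + ½ *P*(tie)). Diagonal-only inflation ⇒
shortcut learning; uniform off-diagonal performance ⇒ condition-invariant
molecular signal; distance-dependent decay ⇒ voltage-sensitive structure.

For mixed samples, the fraction of events scored above 0.5 is a biased
composition estimate whenever the bimodal score histogram drifts. The
pipeline refits the two peaks with a Gaussian mixture (EM), places the
decision boundary at the weighted-density intersection (or the density
minimum), recomputes the event fraction *r*, and converts events to
molecules with inverse capture-rate weighting

  *p* = (*r*/λ⁺) / (*r*/λ⁺ + (1−*r*)/λ⁻),

where λ± are per-class capture rates measured on pure reference runs —
undoing, e.g., a two-fold capture bias at −300 mV.

Because no public nanopore recordings accompany this problem, the package
ships a seeded trace simulator whose statistical structure carries the
phenomena the pipeline must handle: barrier-limited Poisson capture
λ(V) = α|V|·exp(−V*/|V|), run-level baseline offsets / noise / drift,
class-specific log-normal dwell and Gaussian fractional-blockage
distributions, and named scenarios (`two_marker`, `aptamer_shift`,
`baseline_overfit_demo`, `equimolar_mixture`, `serum_shift`).

## Worked example

```python
from voltmatrix import make_scenario
from voltmatrix.pipeline import run_matrix, run_mixture

cfg = make_scenario("two_marker", duration_s=20.0)   # 20 s x 3 runs x 6 voltages
res = run_matrix(cfg, seed=1, feature_set="A", min_per_class=5)
print(res.auc.round(3))
```

```
       -50   -100   -150   -200   -250   -300
-50   0.899   1.0  0.996  0.984  0.997  0.980
-100  0.899   1.0  0.999  0.996  0.985  0.973
-150  0.879   1.0  0.999  0.986  0.984  0.969
-200  0.904   1.0  0.992  0.994  0.992  0.988
-250  0.965   1.0  0.991  0.996  0.997  0.994
-300  0.939   1.0  0.993  0.995  0.995  0.996
```

Rows are training voltages, columns test voltages. The two default analytes
differ in intrinsic event shape, so set-A (event-intrinsic) AUC stays high
across the whole matrix — the voltage-invariant pattern. (The −50 mV column
is noisiest simply because the weak driving field captures few events in
20 s; at the full 60 s runs every diagonal cell clears 0.95.)

```python
cfg = make_scenario("equimolar_mixture")
est = run_mixture(cfg, -300, seed=3)
print(f"raw {est.raw_ratio_at_half:.3f}  boundary {est.boundary:.3f}  "
      f"events {est.corrected_event_ratio:.3f}  molecules {est.molecular_ratio:.3f}")
# raw 0.671  boundary 0.916  events 0.623  molecules 0.455
```

Two thirds of the detected events come from the twice-as-often-captured
class (raw ratio 0.67); the optimized boundary sits in the empty valley of
the score histogram, and the inverse-rate correction pulls the event ratio
back to the true equimolar composition (0.455 ≈ 0.5; the mean over ten
seeds is 0.47 ± 0.03).

The same stages are available from the shell:

```bash
voltmatrix run-all --scenario two_marker --seed 7 --duration 20 --out out/
voltmatrix mixture --scenario equimolar_mixture --voltage -300 --seed 3 --out out/
```

Every command writes a `provenance.json` (config hash, seeds, versions) so
outputs can be regenerated exactly. A commented configuration template is in
`examples/pipeline.yaml`.

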