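# Methods

This note documents the models, parameter choices and numerical decisions
behind `voltmatrix`, and what the synthetic-data pipeline does and does not
establish about real recordings.

## Trace generator

A recording run at voltage *V* (mV, negative) and sampling rate *f*ₛ is

  x(t) = G·V + δ_run + m·t + ε(t) − Σₖ dₖ(t),

with pore conductance *G* (default 10 nS, so the open-pore current is
G·V pA), a per-run baseline offset δ_run ~ N(0, σ_off²) (σ_off = 25 pA, or a
fixed per-sample value in the overfitting scenario), a slow linear drift of
nominal rate 0.5 pA/s, and white Gaussian noise of nominal RMS 12 pA. The
noise RMS and drift rate additionally vary run to run (5% log-normal and 20%
normal spread respectively): real acquisitions never reproduce these exactly
across runs, and that run-level variability is precisely what makes
baseline-derived features condition fingerprints rather than portable
signal. No acquisition low-pass filter is modelled; the noise is white.

Events arrive as a Poisson process with barrier-limited capture rate

  λ(V) = α·|V|·exp(−V*/|V|),

strictly increasing in |V|. The default analyte pair uses (α, V*) =
(0.046 events·s⁻¹·mV⁻¹, 61.6 mV) and (0.020, 20 mV), which places the
class rate ratio at 1.00 at −50 mV and 2.00 at −300 mV — the qualitative
regime the pipeline must handle (equal capture at weak driving, strong bias
at strong driving). Each event is a depression of depth f·|I₀,local| with
exponential edges (τ = 20 µs); the fractional blockage f is Gaussian per
class and the dwell log-normal with median scaling as (100/|V|)^γ (γ = 1).
Overlapping arrivals are rejected and redrawn (bounded retries, then an
explicit saturation error): the analysis targets isolated events.

Sign convention: blockades are rendered as negative-going excursions of the
signed trace (the trace minimum during an event is baseline − depth). All
reported depths (ΔI) are positive magnitudes; fractional blockage is
ΔI/|I₀|. Depth scales with the *local* baseline including the run offset,
so every ratio feature is offset-free by construction.

Traces are float32 (≈10⁻⁴ pA resolution at nA scale — three orders of
magnitude below the noise floor); all per-event statistics are accumulated
in float64. Every random draw derives from a `(seed, voltage, run id,
sample label)` key, so identical inputs give bit-identical traces.

Dwell/blockage distribution parameters for the default analytes and the
scenario variants are package defaults chosen to give a realistic working
point (matched-voltage separability without saturating every cell); they
are config-exposed, never hard-coded in the pipeline.

### Scenarios

* `two_marker` — the default pair above; distinct dwell (0.5 vs 1.5 ms
  median at 100 mV) and blockage (0.18 vs 0.28) distributions, both
  voltage-invariant in shape: the condition-robust case.
* `aptamer_shift` — the second class shares the first's capture model but
  its mean blockage declines with |V| (−0.11 per 250 mV from 0.216 at
  100 mV) and *crosses* the first class's level mid-grid. A monotone,
  non-crossing shift largely preserves score rankings and barely degrades
  cross-voltage AUC; the crossing reverses the learned ordering at the far
  end of the grid, producing the distance-dependent AUC decay that marks a
  voltage-sensitive analyte.
* `baseline_overfit_demo` — two classes with *identical* event statistics
  and fixed per-class run offsets of ±40 pA. Only baseline-dependent
  features can separate them, and only within a voltage condition.
* `equimolar_mixture` — the two_marker pair plus a 50:50 molar "mixture"
  sample.
* `serum_shift` — two heterogeneous samples over three event
  sub-populations; the "centrifuged" variant down-weights the long-dwell,
  shallow-blockage group (0.4 → 0.1) and mildly shifts the waveform
  statistics of the remainder.

## Event detection

Two-threshold (Schmitt-trigger) calling over a strided moving-median
baseline. The baseline is the median of non-overlapping windows (default
50 ms), linearly interpolated to the sample grid; a first pass flags
provisional event spans (deviation beyond 3× a MAD-based robust RMS toward
blockade, dilated by 2% of the window), a second pass re-medians with those
samples replaced by the first-pass baseline. The residual RMS is computed
outside flagged spans (on a ≤500 k-sample stride — the RMS needs no more
precision) and the drift slope by least squares on the window medians. The
partition-based window median is O(n) and exact; a dense rolling median
gives indistinguishable baselines at ~10× the cost.

Events enter when the blockade deviation exceeds `threshold_k`·RMS
(default 5), extend while it exceeds `exit_k`·RMS (default 2), are merged
across gaps shorter than 5 samples and dropped below 5 samples. Indices are
0-based half-open. ΔI is the mean deviation over the called span (the
extremum is reported separately); intra-event shape statistics (skewness,
Fisher kurtosis, FWHM, SD) are computed on the deviation waveform. A small
RMS floor (10⁻⁶ of the current scale) keeps thresholds finite on noise-free
synthetic traces.

Consequence of the minimum-dwell cut: at coarse sampling rates fast events
are censored in a class- and voltage-dependent way. Detected event counts
therefore estimate capture rates faithfully only at full temporal
resolution; the generator's truth annotations are used when a
sampling-rate-independent count is needed.

## Feature sets

Set A holds event-intrinsic quantities only: dwell, fractional blockage,
charge-deficit area normalized by |I₀| of the same event, skewness,
kurtosis, FWHM/dwell, intra-event SD/ΔI. Set B adds the five
baseline-dependent columns (ΔI, ΔI_max, I₀, baseline RMS, drift slope).
Membership is fixed and schema-stable; set A contains no member of the
baseline-dependent list by construction. Standardization statistics are
always learned from a designated training table (zero-variance columns pass
through, flagged); the SVM pipeline standardizes internally, the random
forest consumes raw features.

## Voltage matrix

One stratified 70/30 split per voltage condition, seeded; every matrix cell
— diagonal and off-diagonal — is evaluated on the *held-out* split of the
test voltage, so all cells share one protocol. Classifiers: random forest
(500 trees, √p features per split) and RBF-SVM with Platt-calibrated
probabilities; the positive class is the first analyte listed. AUC is the
Mann–Whitney rank statistic (ties half-credited), identical to the
trapezoidal ROC area. Feature importance is permutation importance (mean
AUC drop over column permutations), model-agnostic so forest and SVM
profiles are comparable; negative drops are clipped to zero for reporting
and kept raw alongside.

With only three runs per condition, run-fingerprint features (I₀, RMS,
drift) make off-diagonal set-B cells a lottery over run orderings: scores
are run-constant, so a single cell can land near 0 or 1. The overfitting
signature is therefore read from the aggregate — diagonal at 1.0 against an
off-diagonal *mean* at chance — not from any single cell.

## Mixture quantification

Scores of mixed-sample events are fitted with a two-component Gaussian
mixture by EM: initialization at means 0.25/0.75, equal weights, SD 0.1;
components relabeled so μ₁ < μ₂; convergence at Δlog-likelihood < 10⁻⁸ or
500 iterations. The component SD is floored at 0.02 by default: confident
classifiers emit exact 0/1 probabilities, and an unfloored component
collapses onto that point mass (the EM likelihood singularity), leaving a
spike plus a blanket component whose "boundary" hugs the peak rather than
the valley. The floor is roughly half a histogram bin — structure narrower
than that is invisible to the score-histogram method anyway. If a
component's weight falls below 0.01 the fit is flagged unimodal and the
boundary falls back to 0.5.

The boundary is the weighted-density intersection on (μ₁, μ₂) — a quadratic
solved in closed form, with the root in the density valley chosen when both
lie inside — or, as a configurable alternative, the minimum of the mixture
density located by bounded scalar minimization. If no intersection exists
between the means, or a component is narrower than 0.01 despite the floor,
the density-minimum rule is used with a warning. The corrected event ratio
is the fraction of scores beyond the boundary (default; operates on actual
events) or the high-component weight ("peak area"). The molecular fraction
applies inverse-capture-rate weighting, p = (r/λ⁺)/(r/λ⁺ + (1−r)/λ⁻), with
λ± always measured on pure reference runs at the same voltage, never on the
mixture itself. The formula is the minimal model in which each molecule of
class *c* contributes events proportionally to λ_c; it is monotone in r,
reduces to the identity at equal rates, and preserves the endpoints.

## Problem sizes and what the tests show

End-to-end checks run the chain at the scenario defaults (60 s × 3 runs per
condition at 100 kHz) where the claim concerns absolute performance
(matched-voltage AUC, mixture recovery over 10 seeds), and at reduced
duration or sampling rate where the claim is structural (matrix geometry,
determinism, scenario contrasts). Capture-ratio checks pool 40 runs per
class at −50 mV because ~120 events per class would leave the ratio
estimator's SD (≈0.13) wider than the ±0.1 band being verified.

Passing tests establish that the pipeline recovers the structure this
generator emits: white noise, ideal rectangular events, Poisson arrivals,
Gaussian blockage. Real recordings add filtered (colored) noise,
intra-event substates, censoring by the acquisition chain, clogging and
pore-to-pore geometry variation — none of which are modelled, and
performance numbers here do not transfer to them. The *mechanisms*
demonstrated (diagonal inflation from baseline features, rank reversal
under voltage-sensitive shifts, capture-bias correction) are
generator-independent.

## Known limitations

* Two-component mixtures only; no per-event posterior output.
* No multi-level event segmentation (CUSUM-style substates) and no
  adaptive per-event thresholds.
* Capture-rate correction assumes detected-event rates proportional to
  molecular concentration (no censoring correction, no interactions
  between analytes).
* The SVM path classifies mixed samples poorly when its calibration is
  extreme — mirroring its role as the less robust of the two algorithms —
  and the random forest is the default throughout.
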