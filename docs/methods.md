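# Methods

## Model

The monitored population is a stream of N binary signals; a 1 marks a
spinning (stressed) *Daphnia*. The ground truth of every run is the
stream's realized proportion P = N1/N, recomputed from the signals, not
the nominal value that generated it. A run draws one nominal proportion,
builds one stream, and draws one true sample of S individuals without
replacement; every estimator in the run then reads that same sample with
its own independent per-signal classification noise. This pairing is
deliberate: estimators are compared on identical evidence, so per-run
advantage measures the detector difference and nothing else.

Detectors are memoryless per-signal classifiers described by a 2×2
detection matrix (TP/FN and TN/FP rates; rows sum to one — a signal is
always read as something). The roster:

| name      | TP-rate       | TN-rate       |
|-----------|---------------|---------------|
| baseline  | Q + Θ         | Q − Θ         |
| mose      | Q + Δ − ϵ     | Q − Δ − ϵ     |
| lese      | Q − Δ − ϵ     | Q + Δ − ϵ     |
| random    | (ignores the sample; estimate ~ U(0,1)) |
| mole      | reads the sample once with the mose and once with the lese matrix and averages the two counting estimates |

## Parameters

| parameter           | symbol | default | meaning |
|---------------------|--------|---------|---------|
| quality             | Q      | 0.75    | shared TP = TN rate of the baseline (dimensionless probability) |
| delta               | Δ      | 0.10    | sensitivity spread of the mose/lese variants |
| sensitivity bias    | Θ      | 0.00    | antisymmetric tilt of the baseline: TP = Q+Θ, TN = Q−Θ |
| handicap            | ϵ      | 0.00    | uniform degradation of both mose/lese rates |
| asymmetry           | a      | 0.00    | uneven split of Δ between the constituents |
| stream size         | N      | 10,000  | signals per population |
| sample size         | S      | 6       | individuals in the observation chamber (4 in the second alarm measurement) |

Scenarios for the nominal proportion: uniform on [0, 1] (an
uninformative lake state), normal with mean 0.1 and sd 0.025 truncated
to [0, 1] by rejection (a mostly healthy lake; the out-of-range
probability is ~3×10⁻⁵ per draw), and fixed values for controlled
sweeps. Runs per grid cell follow the experiment defaults (10,000 for
experiments 1, 3, 4, 6; 1,000 for experiment 2; 2,500 for experiment 5);
all counts and grids are configurable.

The Θ parametrisation mirrors how Δ tilts the mose variant; it is the
natural antisymmetric choice and keeps Θ and Δ on the same scale. The
asymmetry map is Δ_mose = Δ·min(1, 1+a), Δ_lese = Δ·min(1, 1−a): it is
continuous, satisfies the three anchor cases (a = 0 gives both
constituents the full Δ; a = ±1 silences one of them), and is its own
mirror image under a ↔ −a. An alternative reading — splitting Δ between
the constituents in proportion (1+a)/2 : (1−a)/2 — contradicts the
a = 0 anchor (both at full Δ) and was rejected; the two maps coincide at
the endpoints a = ±1.

## Numerical choices

* The number of 1-signals in a stream is round(N·p), half away from
  zero, so realized and nominal proportion differ by at most 1/(2N).
* Rates pushed outside [0, 1] by extreme parameter combinations (e.g.
  Q + Δ > 1 in wide sweeps) are clamped, with a logged warning; wide
  sweeps deliberately enter that regime, so it is a supported state,
  not an error.
* Alarm and catastrophe comparisons use strict inequalities ("more
  than", "above"); with S = 6 an estimate of exactly 3/6 does not cross
  a 0.5 threshold, and 0.40 is crossed by 3/6 but not by the second
  measurement's 1/4.
* Per-run advantage is undefined when the baseline accuracy is exactly
  0 (possible only when P sits at an endpoint and every signal is
  misread, probability ≈ 0.25⁶ per run there); such runs are excluded
  from advantage means and counted separately.
* The sd of a single record is defined as 0 to keep summaries total.

## Vectorized engine and exact oracle

Drivers do not materialise streams. The number of true 1s in a sample
of S drawn without replacement from a stream with N1 ones is
Hypergeometric(N, N1, S), and a detector's count of 1-readouts given
that number is a sum of two binomials — so each grid cell is simulated
as a handful of vectorised draws. The object-level path (`run_trial`)
does materialise the stream and classify signal by signal; a test
asserts the two paths agree.

Because N ≫ S, the sample composition is Binomial(S, P) to negligible
error (a chi-square test at 20,000 replicates cannot tell them apart).
`exact_mean_accuracy` exploits this: it enumerates all
(sample-composition, detection-count) outcomes — jointly over both
constituents for the consensus — and returns the expected accuracy with
no Monte-Carlo error. Every simulated mean is validated against it on a
coarse grid.

## Advantage averaging — a caveat

Advantage is computed per paired run and then averaged; the ratio of
mean accuracies is emitted alongside (`advantage_of_means`) as a
secondary column. The two do not agree in general. The per-run ratio is
heavy-tailed under the uniform scenario: the baseline accuracy can be
arbitrarily close to zero when P is near an endpoint, so the mean of
1/A_B diverges logarithmically and the Monte-Carlo mean of the per-run
advantage fluctuates by a few hundredths even at 10,000 runs per cell.
Consequences worth knowing:

* The handicap turning point (smallest grid ϵ with negative mean
  advantage; reported as absent if no cell is negative) is knife-edge in
  the uniform scenario: the exact expected advantage crosses zero almost
  exactly at ϵ = 0.15 at the standard parameters, so finite-run sweeps
  report 0.15 or 0.20 depending on the seed. In the low-stress scenario
  the crossing is sharp and the turning point is stably 0.10.
* `advantage_of_means` is well-behaved everywhere and is the better
  column for fine quantitative comparisons; the per-run mean is kept as
  the primary column because it is the natural paired statistic.

## What the generator does and does not emulate

The generator reproduces the statistical structure of the monitoring
task: a large population with a set spinning proportion, a small sample,
independent per-signal misclassification. It does not model real image
analysis — no correlated errors across frames or individuals, no
time-varying stress levels within a run, no animal mortality other than
the fixed 6 → 4 reduction in the alarm protocol, no spatial structure in
the chamber. Passing tests therefore demonstrate properties of the
estimation method under these idealised error models, not detector
performance on real footage.

## Known limitations

* Consensus of exactly two constituents with straight averaging;
  weighted pooling and larger committees are out of scope.
* No inferential statistics on advantage (means and sds only).
* The catastrophe state is constant across a run's two measurements,
  and the second sample of 4 is a fresh draw (mortality is modelled as
  a reduced sample size, not as tracking identified survivors).
* In the low-stress scenario a baseline tilted toward specificity
  (Θ ≤ −0.10) genuinely outperforms the symmetric consensus; the
  consensus advantage is not universal across biased baselines.
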