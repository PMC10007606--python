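"""Drivers for the six simulation experiments.

Each experiment sweeps one or two parameters of the detector roster and
summarises, per grid cell, the mean Accuracy of every estimator and the
mean per-run Advantage of the tested estimator over the paired Baseline:

1. Baseline accuracy as a function of Quality (vs the Random control).
2. Mole advantage over Baseline on a Quality x Delta grid.
3. Mole advantage against Baselines with a sensitivity bias Θ.
4. Mole advantage under a handicap ϵ on its constituents, with the
   turning point (smallest grid ϵ with negative mean advantage).
5. Mole advantage at fixed population proportions as a function of the
   asymmetry parameter.
6. The two-measurement catastrophe-alarm protocol: samples of 6 then 4,
   an alarm iff both estimates exceed the alarm threshold, tallied
   against the true catastrophe state of the population.

Trials are *paired*: every estimator in a trial sees the same true
sample and differs only in its independent classification noise, so
per-run Advantage compares like with like.

All drivers run on a vectorized engine: the number of true 1s in a
sample of S signals drawn without replacement from a stream with N1 ones
is Hypergeometric(N, N1, S), and the detector's count of 1-readouts
given that number is a sum of two binomials.  This is distributionally
identical to materialising the stream and classifying signal by signal
(see :func:`run_trial`, which does exactly that for single trials), but
runs thousands of trials per millisecond.

Reproducibility: every grid cell gets its own RNG derived from
(master seed, experiment id, scenario index, cell index), so any cell
can be recomputed in isolation and full tables are bit-identical under a
fixed master seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .detection import AlgorithmSpec, classify, estimate_from_detections, mole_combine, random_estimate
from .errors import ConfigurationError, DomainError
from .metrics import AccuracyRecord, accuracy
from .population import (
    ScenarioSpec,
    draw_population_proportion,
    draw_population_proportions,
    draw_sample,
    make_stream,
)

__all__ = [
    "SCENARIO_1",
    "SCENARIO_2",
    "DEFAULT_RUNS",
    "ExperimentConfig",
    "AlarmConfig",
    "AlarmTally",
    "CASE_A",
    "CASE_B",
    "SWEEP_COLUMNS",
    "run_trial",
    "simulate_setting",
    "experiment_quality_sweep",
    "experiment_mole_advantage",
    "experiment_sensitivity_bias",
    "experiment_handicap",
    "experiment_asymmetry",
    "experiment_catastrophe",
    "alarm_decision",
    "classify_alarm",
    "turning_point",
]

SCENARIO_1 = ScenarioSpec.uniform()
SCENARIO_2 = ScenarioSpec.gaussian()

#: Runs per parameter setting, by experiment.
DEFAULT_RUNS: dict[int, int] = {1: 10_000, 2: 1_000, 3: 10_000, 4: 10_000, 5: 2_500, 6: 10_000}


def _grid(start: float, stop: float, step: float) -> tuple[float, ...]:
    n = int(round((stop - start) / step)) + 1
    return tuple(round(start + i * step, 10) for i in range(n))


DEFAULT_QUALITY_GRID = _grid(0.0, 1.0, 0.05)          # experiment 1
DEFAULT_QUALITY_GRID_EXP2 = _grid(0.5, 1.0, 0.05)     # experiment 2
DEFAULT_DELTA_GRID = _grid(0.0, 1.0, 0.10)            # experiment 2
DEFAULT_THETA_GRID = _grid(-0.15, 0.15, 0.05)         # experiment 3
DEFAULT_HANDICAP_GRID = _grid(0.0, 0.30, 0.05)        # experiment 4
DEFAULT_P_GRID = _grid(0.05, 0.95, 0.10)              # experiment 5
DEFAULT_ASYMMETRY_GRID = _grid(-1.0, 1.0, 0.25)       # experiment 5

SWEEP_COLUMNS = [
    "experiment",
    "scenario",
    "quality",
    "delta",
    "theta",
    "handicap",
    "asymmetry",
    "p_fixed",
    "algorithm",
    "runs",
    "mean_accuracy",
    "sd_accuracy",
    "mean_advantage",
    "advantage_of_means",
    "n_degenerate",
    "seed",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Shared configuration for all experiment drivers.

    Defaults follow the model's standard values: Quality 0.75, Delta 0.10,
    no sensitivity bias, no handicap, no asymmetry, a stream of 10,000
    signals and a sample of 6.  ``runs_per_setting=None`` selects the
    per-experiment default run count.
    """

    experiment_id: int = 1
    scenarios: tuple[ScenarioSpec, ...] = (SCENARIO_1, SCENARIO_2)
    runs_per_setting: int | None = None
    sample_size: int = 6
    stream_size: int = 10_000
    master_seed: int = 0
    quality: float = 0.75
    delta: float = 0.10
    sensitivity_bias: float = 0.0
    handicap: float = 0.0
    asymmetry: float = 0.0
    quality_grid: tuple[float, ...] | None = None
    delta_grid: tuple[float, ...] | None = None
    theta_grid: tuple[float, ...] | None = None
    handicap_grid: tuple[float, ...] | None = None
    p_grid: tuple[float, ...] | None = None
    asymmetry_grid: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.experiment_id not in DEFAULT_RUNS:
            raise ConfigurationError(f"experiment_id must be one of {sorted(DEFAULT_RUNS)}")
        if self.sample_size < 1:
            raise ConfigurationError("sample_size must be at least 1")
        if self.stream_size < self.sample_size:
            raise ConfigurationError("stream_size must be at least sample_size")
        if self.runs_per_setting is not None and self.runs_per_setting < 1:
            raise ConfigurationError("runs_per_setting must be at least 1")
        if self.master_seed < 0:
            raise ConfigurationError("master_seed must be non-negative")

    @property
    def runs(self) -> int:
        if self.runs_per_setting is not None:
            return self.runs_per_setting
        return DEFAULT_RUNS[self.experiment_id]


def _cell_rng(config: ExperimentConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([config.master_seed, config.experiment_id, *key])
    )


# ---------------------------------------------------------------------------
# single-trial, object-level path
# ---------------------------------------------------------------------------

def run_trial(
    specs: Sequence[AlgorithmSpec],
    scenario: ScenarioSpec,
    config: ExperimentConfig,
    rng: np.random.Generator,
) -> dict[str, AccuracyRecord]:
    """One paired trial, materialising the full stream and sample.

    Draws one nominal proportion, builds one stream, draws ONE true sample
    shared by all estimators; each counting estimator classifies it with
    its own independent noise, mole classifies it once with each
    constituent matrix and averages.  Accuracy is scored against the
    stream's realized proportion.
    """
    p_nominal = draw_population_proportion(scenario, rng)
    stream = make_stream(p_nominal, config.stream_size, rng)
    sample = draw_sample(stream, config.sample_size, rng)
    p_true = stream.proportion
    records: dict[str, AccuracyRecord] = {}
    for spec in specs:
        if spec.name in ("baseline", "mose", "lese"):
            est = estimate_from_detections(classify(sample, spec.matrix(), rng), spec.name)
        elif spec.name == "random":
            est = random_estimate(rng)
        elif spec.name == "mole":
            mat_mose, mat_lese = spec.constituent_matrices()
            est = mole_combine(
                estimate_from_detections(classify(sample, mat_mose, rng), "mose"),
                estimate_from_detections(classify(sample, mat_lese, rng), "lese"),
            )
        else:  # pragma: no cover - AlgorithmSpec already validates
            raise DomainError(f"unknown algorithm {spec.name!r}")
        records[spec.name] = accuracy(p_true, est.value)
    return records


# ---------------------------------------------------------------------------
# vectorized engine
# ---------------------------------------------------------------------------

def _sample_true_counts(
    scenario: ScenarioSpec,
    n_runs: int,
    sample_size: int,
    stream_size: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Realized proportions and per-sample true-1 counts for ``n_runs`` trials."""
    p_nominal = draw_population_proportions(scenario, n_runs, rng)
    n1 = np.floor(stream_size * p_nominal + 0.5).astype(np.int64)
    p_true = n1 / stream_size
    k = rng.hypergeometric(n1, stream_size - n1, sample_size)
    return p_true, k


def _detected_counts(
    k: np.ndarray, sample_size: int, matrix, rng: np.random.Generator
) -> np.ndarray:
    return rng.binomial(k, matrix.tp_rate) + rng.binomial(sample_size - k, matrix.fp_rate)


def simulate_setting(
    scenario: ScenarioSpec,
    n_runs: int,
    sample_size: int,
    stream_size: int,
    rng: np.random.Generator,
    baseline: AlgorithmSpec | None = None,
    mole: AlgorithmSpec | None = None,
    include_random: bool = False,
) -> dict[str, np.ndarray]:
    """Vectorized paired trials for one parameter setting.

    Returns arrays keyed by ``"p_true"`` and by estimator name.  The draw
    order (proportions, sample counts, baseline, mose, lese, random) is
    fixed, so outputs are reproducible for a given generator state.
    """
    p_true, k = _sample_true_counts(scenario, n_runs, sample_size, stream_size, rng)
    out: dict[str, np.ndarray] = {"p_true": p_true}
    if baseline is not None:
        m = baseline.matrix()
        out["baseline"] = _detected_counts(k, sample_size, m, rng) / sample_size
    if mole is not None:
        mat_mose, mat_lese = mole.constituent_matrices()
        m1_mose = _detected_counts(k, sample_size, mat_mose, rng)
        m1_lese = _detected_counts(k, sample_size, mat_lese, rng)
        out["mole"] = (m1_mose + m1_lese) / (2.0 * sample_size)
    if include_random:
        out["random"] = rng.random(n_runs)
    return out


def _accuracies(p_true: np.ndarray, estimates: np.ndarray) -> np.ndarray:
    return 1.0 - np.abs(p_true - estimates)


def _advantage_stats(acc_tested: np.ndarray, acc_baseline: np.ndarray) -> tuple[float, int, float]:
    """(mean per-run advantage, n degenerate, advantage of mean accuracies)."""
    ok = acc_baseline > 0.0
    n_degenerate = int((~ok).sum())
    adv = (acc_tested[ok] - acc_baseline[ok]) / acc_baseline[ok]
    mean_adv = float(adv.mean()) if adv.size else float("nan")
    mean_b = float(acc_baseline.mean())
    adv_of_means = (float(acc_tested.mean()) - mean_b) / mean_b if mean_b > 0 else float("nan")
    return mean_adv, n_degenerate, adv_of_means


def _row(
    config: ExperimentConfig,
    scenario: ScenarioSpec,
    algorithm: str,
    acc: np.ndarray,
    *,
    quality: float = np.nan,
    delta: float = np.nan,
    theta: float = np.nan,
    handicap: float = np.nan,
    asymmetry: float = np.nan,
    p_fixed: float = np.nan,
    adv: tuple[float, int, float] | None = None,
) -> dict:
    return {
        "experiment": config.experiment_id,
        "scenario": scenario.label,
        "quality": quality,
        "delta": delta,
        "theta": theta,
        "handicap": handicap,
        "asymmetry": asymmetry,
        "p_fixed": p_fixed,
        "algorithm": algorithm,
        "runs": acc.size,
        "mean_accuracy": float(acc.mean()),
        "sd_accuracy": float(acc.std(ddof=1)) if acc.size > 1 else 0.0,
        "mean_advantage": adv[0] if adv is not None else np.nan,
        "advantage_of_means": adv[2] if adv is not None else np.nan,
        "n_degenerate": adv[1] if adv is not None else 0,
        "seed": config.master_seed,
    }


# ---------------------------------------------------------------------------
# experiments 1-5 (parameter sweeps)
# ---------------------------------------------------------------------------

def experiment_quality_sweep(config: ExperimentConfig) -> pd.DataFrame:
    """Experiment 1: Baseline accuracy vs Quality, with the Random control."""
    grid = config.quality_grid or DEFAULT_QUALITY_GRID
    rows = []
    for si, scenario in enumerate(config.scenarios):
        for gi, q in enumerate(grid):
            rng = _cell_rng(config, si, gi)
            sim = simulate_setting(
                scenario, config.runs, config.sample_size, config.stream_size, rng,
                baseline=AlgorithmSpec("baseline", quality=q),
                include_random=True,
            )
            acc_b = _accuracies(sim["p_true"], sim["baseline"])
            acc_r = _accuracies(sim["p_true"], sim["random"])
            rows.append(_row(config, scenario, "baseline", acc_b, quality=q))
            rows.append(
                _row(config, scenario, "random", acc_r, quality=q,
                     adv=_advantage_stats(acc_r, acc_b))
            )
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def experiment_mole_advantage(config: ExperimentConfig) -> pd.DataFrame:
    """Experiment 2: mole vs Baseline on a Quality x Delta grid."""
    q_grid = config.quality_grid or DEFAULT_QUALITY_GRID_EXP2
    d_grid = config.delta_grid or DEFAULT_DELTA_GRID
    rows = []
    for si, scenario in enumerate(config.scenarios):
        for gi, (q, d) in enumerate((q, d) for q in q_grid for d in d_grid):
            rng = _cell_rng(config, si, gi)
            sim = simulate_setting(
                scenario, config.runs, config.sample_size, config.stream_size, rng,
                baseline=AlgorithmSpec("baseline", quality=q),
                mole=AlgorithmSpec("mole", quality=q, delta=d),
            )
            acc_b = _accuracies(sim["p_true"], sim["baseline"])
            acc_m = _accuracies(sim["p_true"], sim["mole"])
            rows.append(_row(config, scenario, "baseline", acc_b, quality=q, delta=d))
            rows.append(
                _row(config, scenario, "mole", acc_m, quality=q, delta=d,
                     adv=_advantage_stats(acc_m, acc_b))
            )
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def experiment_sensitivity_bias(config: ExperimentConfig) -> pd.DataFrame:
    """Experiment 3: mole (unbiased) vs Baselines tilted by a sensitivity bias Θ."""
    grid = config.theta_grid or DEFAULT_THETA_GRID
    rows = []
    for si, scenario in enumerate(config.scenarios):
        for gi, theta in enumerate(grid):
            rng = _cell_rng(config, si, gi)
            sim = simulate_setting(
                scenario, config.runs, config.sample_size, config.stream_size, rng,
                baseline=AlgorithmSpec(
                    "baseline", quality=config.quality, sensitivity_bias=theta
                ),
                mole=AlgorithmSpec("mole", quality=config.quality, delta=config.delta),
            )
            acc_b = _accuracies(sim["p_true"], sim["baseline"])
            acc_m = _accuracies(sim["p_true"], sim["mole"])
            rows.append(
                _row(config, scenario, "baseline", acc_b, quality=config.quality, theta=theta)
            )
            rows.append(
                _row(config, scenario, "mole", acc_m, quality=config.quality,
                     delta=config.delta, theta=theta,
                     adv=_advantage_stats(acc_m, acc_b))
            )
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def turning_point(
    handicaps: Sequence[float], mean_advantages: Sequence[float]
) -> float | None:
    """Smallest handicap whose mean advantage is negative; None if none is."""
    for h, a in sorted(zip(handicaps, mean_advantages)):
        if a < 0.0:
            return h
    return None


def experiment_handicap(
    config: ExperimentConfig,
) -> tuple[pd.DataFrame, dict[str, float | None]]:
    """Experiment 4: mole with handicapped constituents vs an unhandicapped Baseline.

    Returns the sweep table and, per scenario, the turning point: the
    smallest grid handicap at which mole's mean per-run advantage turns
    negative.
    """
    grid = config.handicap_grid or DEFAULT_HANDICAP_GRID
    rows = []
    points: dict[str, float | None] = {}
    for si, scenario in enumerate(config.scenarios):
        advantages = []
        for gi, eps in enumerate(grid):
            rng = _cell_rng(config, si, gi)
            sim = simulate_setting(
                scenario, config.runs, config.sample_size, config.stream_size, rng,
                baseline=AlgorithmSpec("baseline", quality=config.quality),
                mole=AlgorithmSpec(
                    "mole", quality=config.quality, delta=config.delta, handicap=eps
                ),
            )
            acc_b = _accuracies(sim["p_true"], sim["baseline"])
            acc_m = _accuracies(sim["p_true"], sim["mole"])
            adv = _advantage_stats(acc_m, acc_b)
            advantages.append(adv[0])
            rows.append(
                _row(config, scenario, "baseline", acc_b, quality=config.quality, handicap=eps)
            )
            rows.append(
                _row(config, scenario, "mole", acc_m, quality=config.quality,
                     delta=config.delta, handicap=eps, adv=adv)
            )
        points[scenario.label] = turning_point(grid, advantages)
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS), points


def experiment_asymmetry(config: ExperimentConfig) -> pd.DataFrame:
    """Experiment 5: mole advantage at fixed proportions as asymmetry varies."""
    p_grid = config.p_grid or DEFAULT_P_GRID
    a_grid = config.asymmetry_grid or DEFAULT_ASYMMETRY_GRID
    rows = []
    for gi, (p, a) in enumerate((p, a) for p in p_grid for a in a_grid):
        scenario = ScenarioSpec.fixed(p)
        rng = _cell_rng(config, 0, gi)
        sim = simulate_setting(
            scenario, config.runs, config.sample_size, config.stream_size, rng,
            baseline=AlgorithmSpec("baseline", quality=config.quality),
            mole=AlgorithmSpec(
                "mole", quality=config.quality, delta=config.delta, asymmetry=a
            ),
        )
        acc_b = _accuracies(sim["p_true"], sim["baseline"])
        acc_m = _accuracies(sim["p_true"], sim["mole"])
        rows.append(
            _row(config, scenario, "baseline", acc_b, quality=config.quality,
                 asymmetry=a, p_fixed=p)
        )
        rows.append(
            _row(config, scenario, "mole", acc_m, quality=config.quality,
                 delta=config.delta, asymmetry=a, p_fixed=p,
                 adv=_advantage_stats(acc_m, acc_b))
        )
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


# ---------------------------------------------------------------------------
# experiment 6 (catastrophe-alarm protocol)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlarmConfig:
    """Thresholds of one catastrophe case and the two-measurement sample sizes."""

    catastrophe_threshold: float
    alarm_threshold: float
    sample_sizes: tuple[int, int] = (6, 4)

    def __post_init__(self) -> None:
        for label, t in (
            ("catastrophe_threshold", self.catastrophe_threshold),
            ("alarm_threshold", self.alarm_threshold),
        ):
            if not 0.0 < t < 1.0:
                raise ConfigurationError(f"{label} must lie in (0, 1)")
        first, second = self.sample_sizes
        if not first > second >= 1:
            raise ConfigurationError(
                "first sample must be larger than the second (mortality between measurements)"
            )

    @property
    def label(self) -> str:
        return f"cat>{self.catastrophe_threshold:g}_alarm>{self.alarm_threshold:g}"


#: Case A: catastrophic above 66 % spinning, alarm above 40 % detected twice.
CASE_A = AlarmConfig(0.66, 0.40)
#: Case B: catastrophic above 30 % spinning, alarm above 25 % detected twice.
CASE_B = AlarmConfig(0.30, 0.25)


@dataclass(frozen=True)
class AlarmTally:
    """Confusion counts of the alarm protocol over one batch of runs."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def proportions(self) -> dict[str, float]:
        n = self.n
        return {"tp": self.tp / n, "fp": self.fp / n, "fn": self.fn / n, "tn": self.tn / n}


def alarm_decision(e_first: float, e_second: float, alarm_threshold: float) -> bool:
    """Alarm iff both successive estimates strictly exceed the threshold."""
    for e in (e_first, e_second):
        if not 0.0 <= e <= 1.0:
            raise DomainError("estimates must lie in [0, 1]")
    return e_first > alarm_threshold and e_second > alarm_threshold


def classify_alarm(alarm: bool, p_true: float, catastrophe_threshold: float) -> str:
    """Score an alarm decision against the true state (catastrophic iff P > threshold)."""
    catastrophic = p_true > catastrophe_threshold
    if catastrophic:
        return "TP" if alarm else "FN"
    return "FP" if alarm else "TN"


def experiment_catastrophe(
    config: ExperimentConfig,
    cases: Sequence[AlarmConfig] = (CASE_A, CASE_B),
    scenario: ScenarioSpec | None = None,
) -> dict[str, dict[str, AlarmTally]]:
    """Experiment 6: two-measurement alarm protocol, Baseline vs mole.

    Per run one population state P is drawn (uniform by default) and held
    fixed across both measurements; the first measurement uses a fresh
    true sample of 6, the second a fresh sample of 4 (two individuals
    died).  Baseline and mole read the same true samples with independent
    classification noise.  Returns ``{case label: {algorithm: tally}}``.
    """
    sizes = {c.sample_sizes for c in cases}
    if len(sizes) != 1:
        raise ConfigurationError("all alarm cases must share the same sample sizes")
    s1, s2 = sizes.pop()
    scenario = scenario if scenario is not None else ScenarioSpec.uniform()
    n_runs = config.runs
    rng = _cell_rng(config, 0, 0)

    p_nominal = draw_population_proportions(scenario, n_runs, rng)
    n1 = np.floor(config.stream_size * p_nominal + 0.5).astype(np.int64)
    p_true = n1 / config.stream_size
    k1 = rng.hypergeometric(n1, config.stream_size - n1, s1)
    k2 = rng.hypergeometric(n1, config.stream_size - n1, s2)

    base = AlgorithmSpec(
        "baseline", quality=config.quality, sensitivity_bias=config.sensitivity_bias
    )
    mole = AlgorithmSpec(
        "mole",
        quality=config.quality,
        delta=config.delta,
        handicap=config.handicap,
        asymmetry=config.asymmetry,
    )
    mat_b = base.matrix()
    mat_mose, mat_lese = mole.constituent_matrices()

    estimates: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    e1_b = _detected_counts(k1, s1, mat_b, rng) / s1
    e2_b = _detected_counts(k2, s2, mat_b, rng) / s2
    estimates["baseline"] = (e1_b, e2_b)
    e1_m = (_detected_counts(k1, s1, mat_mose, rng) + _detected_counts(k1, s1, mat_lese, rng)) / (2.0 * s1)
    e2_m = (_detected_counts(k2, s2, mat_mose, rng) + _detected_counts(k2, s2, mat_lese, rng)) / (2.0 * s2)
    estimates["mole"] = (e1_m, e2_m)

    results: dict[str, dict[str, AlarmTally]] = {}
    for case in cases:
        catastrophic = p_true > case.catastrophe_threshold
        per_alg: dict[str, AlarmTally] = {}
        for name, (e1, e2) in estimates.items():
            alarm = (e1 > case.alarm_threshold) & (e2 > case.alarm_threshold)
            per_alg[name] = AlarmTally(
                tp=int((alarm & catastrophic).sum()),
                fp=int((alarm & ~catastrophic).sum()),
                fn=int((~alarm & catastrophic).sum()),
                tn=int((~alarm & ~catastrophic).sum()),
            )
        results[case.label] = per_alg
    return results
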