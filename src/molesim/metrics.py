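"""Accuracy and Advantage metrics, run summaries, and exact oracles.

Accuracy scores one estimate against the true proportion,

    A = 1 − |P − E|,

treating over- and underestimation symmetrically.  Advantage is the
relative accuracy gain of a tested estimator over the paired baseline,

    ADV = (A − A_B) / A_B,

so ADV = 0.1 means the tested estimator was 10 % more accurate in that
run; negative values mean the baseline won.  ADV is undefined when
A_B = 0 (possible only when P and E sit at opposite ends of the unit
interval); such runs are flagged degenerate and excluded from means.

The module also carries two closed-form oracles used to validate the
Monte-Carlo machinery without simulation error:

* :func:`expected_detection_rate` — the per-signal probability that a
  detector reads 1, ``q = FP + (TP − FP)·P``;
* :func:`exact_mean_accuracy` — the exact expected Accuracy at a fixed
  proportion, obtained by enumerating all (true-composition,
  detection-count) outcomes of a small sample.  With a population stream
  far larger than the sample, the number of true 1s in the sample is
  Binomial(S, P) to negligible error, which keeps the enumeration exact
  and tiny (S ≤ 12).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .detection import AlgorithmSpec, DetectionMatrix
from .errors import DomainError

__all__ = [
    "AccuracyRecord",
    "AdvantageRecord",
    "RunSummary",
    "accuracy",
    "advantage",
    "expected_detection_rate",
    "exact_mean_accuracy",
    "summarize_runs",
]

MAX_ENUMERATION_SAMPLE = 12


@dataclass(frozen=True)
class AccuracyRecord:
    p_true: float
    estimate: float
    accuracy: float


@dataclass(frozen=True)
class AdvantageRecord:
    accuracy_tested: float
    accuracy_baseline: float
    advantage: float
    degenerate: bool = False


@dataclass(frozen=True)
class RunSummary:
    mean: float
    sd: float
    n: int
    n_degenerate: int = 0


def accuracy(p_true: float, estimate: float) -> AccuracyRecord:
    """Accuracy A = 1 − |P − E| of one estimate against the true proportion."""
    if not 0.0 <= p_true <= 1.0:
        raise DomainError("true proportion must lie in [0, 1]")
    if not 0.0 <= estimate <= 1.0:
        raise DomainError("estimate must lie in [0, 1]")
    return AccuracyRecord(p_true, estimate, 1.0 - abs(p_true - estimate))


def advantage(a_tested: float, a_baseline: float) -> AdvantageRecord:
    """Relative accuracy gain (A − A_B)/A_B; degenerate (NaN) when A_B = 0."""
    if a_baseline == 0.0:
        return AdvantageRecord(a_tested, a_baseline, math.nan, degenerate=True)
    return AdvantageRecord(a_tested, a_baseline, (a_tested - a_baseline) / a_baseline)


def expected_detection_rate(matrix: DetectionMatrix, p: float) -> float:
    """Per-signal probability of a 1-readout: FP + (TP − FP)·P."""
    if not 0.0 <= p <= 1.0:
        raise DomainError("proportion must lie in [0, 1]")
    return matrix.fp_rate + (matrix.tp_rate - matrix.fp_rate) * p


def _detected_count_pmf(k: int, s: int, matrix: DetectionMatrix) -> np.ndarray:
    """PMF of the number of 1-readouts given k true 1s among s signals."""
    pmf_true = stats.binom.pmf(np.arange(k + 1), k, matrix.tp_rate)
    pmf_false = stats.binom.pmf(np.arange(s - k + 1), s - k, matrix.fp_rate)
    return np.convolve(pmf_true, pmf_false)


def exact_mean_accuracy(spec: AlgorithmSpec, p: float, s: int) -> float:
    """Exact expected Accuracy of one estimator at fixed proportion ``p``.

    Enumerates K ~ Binomial(s, p) true 1s in the sample and, conditional
    on K, the detector's count of 1-readouts; for the mole estimator both
    constituents' counts are enumerated jointly (they are independent
    given the shared true sample).  The random estimator has the closed
    form E[1 − |p − U|] = 1 − (p² + (1−p)²)/2.
    """
    if not 0.0 <= p <= 1.0:
        raise DomainError("proportion must lie in [0, 1]")
    if s < 1 or s > MAX_ENUMERATION_SAMPLE:
        raise DomainError(f"enumeration supports 1 <= s <= {MAX_ENUMERATION_SAMPLE}")

    if spec.name == "random":
        return 1.0 - (p * p + (1.0 - p) ** 2) / 2.0

    k_pmf = stats.binom.pmf(np.arange(s + 1), s, p)

    if spec.name == "mole":
        mat_mose, mat_lese = spec.constituent_matrices()
        counts = np.arange(s + 1)
        # accuracy of the averaged estimate (m_a + m_l) / (2s)
        acc = 1.0 - np.abs(p - (counts[:, None] + counts[None, :]) / (2.0 * s))
        total = 0.0
        for k in range(s + 1):
            pmf_mose = _detected_count_pmf(k, s, mat_mose)
            pmf_lese = _detected_count_pmf(k, s, mat_lese)
            total += k_pmf[k] * float(pmf_mose @ acc @ pmf_lese)
        return total

    matrix = spec.matrix()
    acc = 1.0 - np.abs(p - np.arange(s + 1) / s)
    total = 0.0
    for k in range(s + 1):
        total += k_pmf[k] * float(_detected_count_pmf(k, s, matrix) @ acc)
    return total


def summarize_runs(
    records: Sequence[AccuracyRecord | AdvantageRecord] | Iterable[float],
) -> RunSummary:
    """Mean and sample sd of per-run metric values.

    Degenerate advantage records are excluded from the mean and counted in
    ``n_degenerate``.  The sd of a single record is 0 by convention.
    """
    values: list[float] = []
    n_degenerate = 0
    n_total = 0
    for rec in records:
        n_total += 1
        if isinstance(rec, AccuracyRecord):
            values.append(rec.accuracy)
        elif isinstance(rec, AdvantageRecord):
            if rec.degenerate:
                n_degenerate += 1
            else:
                values.append(rec.advantage)
        else:
            values.append(float(rec))
    if n_total == 0:
        raise DomainError("cannot summarize an empty set of records")
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean()) if arr.size else math.nan
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return RunSummary(mean=mean, sd=sd, n=n_total, n_degenerate=n_degenerate)
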