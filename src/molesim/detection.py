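"""Detectors and estimators for spinning-signal classification.

Every detector is summarised by a 2x2 signal-detection matrix: a true 1
is read as 1 with probability ``tp_rate`` (else misread as 0, the
FN-rate), a true 0 is read as 1 with probability ``fp_rate`` (else
correctly read as 0, the TN-rate).  No signal is ever skipped, so each
row of the matrix sums to one.

The roster:

* ``baseline`` — TP-rate = TN-rate = Quality Q, optionally tilted by a
  sensitivity bias Θ (TP = Q+Θ, TN = Q−Θ).
* ``mose`` — a *more sensitive* variant: TP = Q+Δ, TN = Q−Δ.
* ``lese`` — a *less sensitive* variant: TP = Q−Δ, TN = Q+Δ.
* ``random`` — ignores the sample and returns Uniform(0, 1).
* ``mole`` — reads the same sample once with the MoSe matrix and once
  with the LeSe matrix and averages the two counting estimates
  arithmetically; an asymmetry parameter can split Δ unevenly between
  the two constituents.

A handicap ϵ degrades MoSe/LeSe by subtracting ϵ from both their TP- and
TN-rates.  Rates that leave [0, 1] (e.g. Q + Δ > 1 in wide sweeps) are
clamped, with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DomainError
from .population import TrueSample

__all__ = [
    "ALGORITHM_NAMES",
    "DetectionMatrix",
    "AlgorithmSpec",
    "DetectedSample",
    "Estimate",
    "baseline_matrix",
    "mose_matrix",
    "lese_matrix",
    "apply_asymmetry",
    "classify",
    "estimate_from_detections",
    "random_estimate",
    "mole_combine",
]

logger = logging.getLogger(__name__)

ALGORITHM_NAMES = ("baseline", "mose", "lese", "random", "mole")


@dataclass(frozen=True)
class DetectionMatrix:
    """TP/TN rates of one detector; FP and FN follow by complement."""

    tp_rate: float
    tn_rate: float

    def __post_init__(self) -> None:
        for label, rate in (("tp_rate", self.tp_rate), ("tn_rate", self.tn_rate)):
            if not 0.0 <= rate <= 1.0:
                raise DomainError(f"{label}={rate} outside [0, 1]")

    @property
    def fn_rate(self) -> float:
        return 1.0 - self.tp_rate

    @property
    def fp_rate(self) -> float:
        return 1.0 - self.tn_rate


def _clamped(value: float, label: str) -> float:
    clipped = min(1.0, max(0.0, value))
    if clipped != value:
        logger.warning("%s rate %.4f outside [0, 1]; clamped to %.4f", label, value, clipped)
    return clipped


def baseline_matrix(q: float, theta: float = 0.0) -> DetectionMatrix:
    """Baseline detector: TP = Q + Θ, TN = Q − Θ (clamped to [0, 1])."""
    if not 0.0 <= q <= 1.0:
        raise DomainError("quality must lie in [0, 1]")
    return DetectionMatrix(_clamped(q + theta, "baseline TP"), _clamped(q - theta, "baseline TN"))


def mose_matrix(q: float, delta: float, handicap: float = 0.0) -> DetectionMatrix:
    """More-sensitive detector: TP = Q + Δ − ϵ, TN = Q − Δ − ϵ (clamped)."""
    _check_variant_params(q, delta, handicap)
    return DetectionMatrix(
        _clamped(q + delta - handicap, "MoSe TP"),
        _clamped(q - delta - handicap, "MoSe TN"),
    )


def lese_matrix(q: float, delta: float, handicap: float = 0.0) -> DetectionMatrix:
    """Less-sensitive detector: TP = Q − Δ − ϵ, TN = Q + Δ − ϵ (clamped)."""
    _check_variant_params(q, delta, handicap)
    return DetectionMatrix(
        _clamped(q - delta - handicap, "LeSe TP"),
        _clamped(q + delta - handicap, "LeSe TN"),
    )


def _check_variant_params(q: float, delta: float, handicap: float) -> None:
    if not 0.0 <= q <= 1.0:
        raise DomainError("quality must lie in [0, 1]")
    if delta < 0:
        raise DomainError("delta must be non-negative")
    if handicap < 0:
        raise DomainError("handicap must be non-negative")


def apply_asymmetry(delta: float, a: float) -> tuple[float, float]:
    """Split a shared Δ between MoSe and LeSe.

    ``a = 0`` gives both constituents the full Δ; ``a = +1`` gives MoSe the
    full Δ and LeSe none; ``a = −1`` is the mirror case.  The map is
    continuous in between: ``Δ_mose = Δ·min(1, 1+a)``,
    ``Δ_lese = Δ·min(1, 1−a)``.
    """
    if abs(a) > 1:
        raise DomainError("asymmetry must lie in [-1, 1]")
    return delta * min(1.0, 1.0 + a), delta * min(1.0, 1.0 - a)


@dataclass(frozen=True)
class AlgorithmSpec:
    """A named detector/estimator with its tunable parameters."""

    name: str
    quality: float = 0.75
    delta: float = 0.10
    sensitivity_bias: float = 0.0
    handicap: float = 0.0
    asymmetry: float = 0.0

    def __post_init__(self) -> None:
        if self.name not in ALGORITHM_NAMES:
            raise DomainError(f"unknown algorithm {self.name!r}; expected one of {ALGORITHM_NAMES}")
        if not 0.0 <= self.quality <= 1.0:
            raise DomainError("quality must lie in [0, 1]")
        if self.delta < 0:
            raise DomainError("delta must be non-negative")
        if self.handicap < 0:
            raise DomainError("handicap must be non-negative")
        if abs(self.asymmetry) > 1:
            raise DomainError("asymmetry must lie in [-1, 1]")

    def matrix(self) -> DetectionMatrix:
        """Detection matrix of a single counting detector (not mole/random)."""
        if self.name == "baseline":
            return baseline_matrix(self.quality, self.sensitivity_bias)
        if self.name == "mose":
            return mose_matrix(self.quality, self.delta, self.handicap)
        if self.name == "lese":
            return lese_matrix(self.quality, self.delta, self.handicap)
        raise DomainError(f"algorithm {self.name!r} has no single detection matrix")

    def constituent_matrices(self) -> tuple[DetectionMatrix, DetectionMatrix]:
        """(MoSe, LeSe) matrices of a mole spec, with asymmetry applied."""
        if self.name != "mole":
            raise DomainError("constituent matrices are defined for the mole algorithm only")
        d_mose, d_lese = apply_asymmetry(self.delta, self.asymmetry)
        return (
            mose_matrix(self.quality, d_mose, self.handicap),
            lese_matrix(self.quality, d_lese, self.handicap),
        )


@dataclass(frozen=True)
class DetectedSample:
    """Per-signal detector readout of one true sample."""

    detections: np.ndarray
    truth: TrueSample

    def __post_init__(self) -> None:
        arr = np.asarray(self.detections)
        if arr.shape != self.truth.states.shape:
            raise DomainError("detections and truth must have equal length")
        if not np.isin(arr, (0, 1)).all():
            raise DomainError("detections must be binary (0 or 1)")
        object.__setattr__(self, "detections", arr.astype(np.uint8))


@dataclass(frozen=True)
class Estimate:
    """A proportion estimate E, with M0/M1 tallies for counting estimators."""

    value: float
    algorithm: str
    m0: int | None = None
    m1: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise DomainError("estimate must lie in [0, 1]")


def classify(
    sample: TrueSample, matrix: DetectionMatrix, rng: np.random.Generator
) -> DetectedSample:
    """Read each signal independently: P(read 1 | true 1) = TP, P(read 1 | true 0) = FP."""
    p_one = np.where(sample.states == 1, matrix.tp_rate, matrix.fp_rate)
    detections = (rng.random(sample.size) < p_one).astype(np.uint8)
    return DetectedSample(detections, sample)


def estimate_from_detections(detected: DetectedSample, algorithm: str = "baseline") -> Estimate:
    """Counting estimate E = M1/(M0+M1) = M1/S from a detector readout."""
    s = int(detected.detections.size)
    if s < 1:
        raise DomainError("cannot estimate from an empty sample")
    m1 = int(detected.detections.sum())
    return Estimate(value=m1 / s, algorithm=algorithm, m0=s - m1, m1=m1)


def random_estimate(rng: np.random.Generator) -> Estimate:
    """Control estimator: Uniform(0, 1), independent of any sample."""
    return Estimate(value=float(rng.random()), algorithm="random")


def mole_combine(e_mose: Estimate, e_lese: Estimate) -> Estimate:
    """Consensus estimate: the arithmetic mean of the MoSe and LeSe estimates."""
    return Estimate(value=(e_mose.value + e_lese.value) / 2.0, algorithm="mole")
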