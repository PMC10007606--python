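"""Signal-stream population model.

The monitored *Daphnia* population is abstracted as a stream of ``N``
binary signals in random order; a ``1`` marks a spinning (stressed)
individual, a ``0`` a normally swimming one.  The population proportion

    P = N1 / (N0 + N1)

is the quantity the biohybrid has to estimate from a small sample drawn
from the stream.  Three regimes for the nominal proportion are supported:

``uniform``
    P drawn uniformly on [0, 1] — an uninformative lake state.
``gaussian``
    P drawn from a normal distribution (default mean 0.1, sd 0.025),
    re-drawn until it falls inside [0, 1] — a mostly healthy lake with a
    low level of background stress.
``fixed``
    a constant P, used for controlled parameter sweeps.

The number of 1-signals in a stream is ``round(N * p)`` (half away from
zero), so the *realized* proportion can differ from the nominal draw by at
most ``1/(2N)``; the realized value is the ground truth used by all
downstream accuracy computations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DomainError

__all__ = [
    "ScenarioSpec",
    "SignalStream",
    "TrueSample",
    "draw_population_proportion",
    "draw_population_proportions",
    "make_stream",
    "draw_sample",
    "n_ones_for",
]

SCENARIO_KINDS = ("uniform", "gaussian", "fixed")


@dataclass(frozen=True)
class ScenarioSpec:
    """How the nominal population proportion is drawn for each run."""

    kind: str
    gaussian_mean: float = 0.1
    gaussian_sd: float = 0.025
    fixed_value: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ConfigurationError(
                f"unknown scenario kind {self.kind!r}; expected one of {SCENARIO_KINDS}"
            )
        if self.gaussian_sd <= 0:
            raise ConfigurationError("gaussian_sd must be positive")
        if self.kind == "fixed":
            if self.fixed_value is None:
                raise ConfigurationError("fixed scenario requires fixed_value")
            if not 0.0 <= self.fixed_value <= 1.0:
                raise ConfigurationError("fixed_value must lie in [0, 1]")

    @classmethod
    def uniform(cls) -> "ScenarioSpec":
        return cls(kind="uniform")

    @classmethod
    def gaussian(cls, mean: float = 0.1, sd: float = 0.025) -> "ScenarioSpec":
        return cls(kind="gaussian", gaussian_mean=mean, gaussian_sd=sd)

    @classmethod
    def fixed(cls, value: float) -> "ScenarioSpec":
        return cls(kind="fixed", fixed_value=value)

    @property
    def label(self) -> str:
        if self.kind == "fixed":
            return f"fixed({self.fixed_value:g})"
        return self.kind


@dataclass(frozen=True)
class SignalStream:
    """An ordered stream of binary spinning signals (the population)."""

    signals: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.signals)
        if arr.ndim != 1 or arr.size < 1:
            raise DomainError("a signal stream must be a non-empty 1-d sequence")
        if not np.isin(arr, (0, 1)).all():
            raise DomainError("signals must be binary (0 or 1)")
        object.__setattr__(self, "signals", arr.astype(np.uint8))

    @property
    def n(self) -> int:
        return int(self.signals.size)

    @property
    def n_ones(self) -> int:
        return int(self.signals.sum())

    @property
    def n_zeros(self) -> int:
        return self.n - self.n_ones

    @property
    def proportion(self) -> float:
        """Realized proportion P = N1/(N0+N1), recomputed from the signals."""
        return self.n_ones / self.n


@dataclass(frozen=True)
class TrueSample:
    """The true states of the few individuals in the observation chamber."""

    states: np.ndarray
    source_proportion: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.states)
        if arr.ndim != 1 or arr.size < 1:
            raise DomainError("a sample must be a non-empty 1-d sequence")
        if not np.isin(arr, (0, 1)).all():
            raise DomainError("sample states must be binary (0 or 1)")
        object.__setattr__(self, "states", arr.astype(np.uint8))

    @property
    def size(self) -> int:
        return int(self.states.size)


def draw_population_proportions(
    scenario: ScenarioSpec, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``size`` nominal population proportions for the given scenario.

    Gaussian draws falling outside [0, 1] are rejected and re-drawn, so the
    returned values always lie in the unit interval.
    """
    if scenario.kind == "uniform":
        return rng.random(size)
    if scenario.kind == "fixed":
        return np.full(size, float(scenario.fixed_value))
    # gaussian with rejection; out-of-range probability is ~3e-5 per draw
    # at the default (0.1, 0.025), so the loop terminates almost immediately
    out = rng.normal(scenario.gaussian_mean, scenario.gaussian_sd, size)
    bad = (out < 0.0) | (out > 1.0)
    while bad.any():
        out[bad] = rng.normal(scenario.gaussian_mean, scenario.gaussian_sd, int(bad.sum()))
        bad = (out < 0.0) | (out > 1.0)
    return out


def draw_population_proportion(scenario: ScenarioSpec, rng: np.random.Generator) -> float:
    """Draw one nominal population proportion in [0, 1]."""
    return float(draw_population_proportions(scenario, 1, rng)[0])


def n_ones_for(p_nominal: float, n: int) -> int:
    """Number of 1-signals for a nominal proportion: round half away from zero."""
    return int(np.floor(n * p_nominal + 0.5))


def make_stream(p_nominal: float, n: int, rng: np.random.Generator) -> SignalStream:
    """Build a stream of ``n`` signals with ``round(n * p_nominal)`` ones in random order."""
    if n < 1:
        raise DomainError("stream size must be at least 1")
    if not 0.0 <= p_nominal <= 1.0:
        raise DomainError("nominal proportion must lie in [0, 1]")
    signals = np.zeros(n, dtype=np.uint8)
    signals[: n_ones_for(p_nominal, n)] = 1
    rng.shuffle(signals)
    return SignalStream(signals)


def draw_sample(stream: SignalStream, s: int, rng: np.random.Generator) -> TrueSample:
    """Draw ``s`` signals uniformly at random without replacement from the stream."""
    if not 1 <= s <= stream.n:
        raise DomainError(f"sample size {s} must lie in [1, {stream.n}]")
    idx = rng.choice(stream.n, size=s, replace=False)
    return TrueSample(stream.signals[idx], stream.proportion)
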