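"""Capture-trigger logic over a stream of scale readings.

The camera fires when a sliding window of consecutive scale readings shows a
plausibly stationary animal: every reading inside the configured population
weight range and the max-min spread strictly below a tolerance. A refractory
cooldown (in readings) suppresses duplicate captures of one stable plateau.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "WeightReading",
    "TriggerConfig",
    "CaptureEvent",
    "should_capture",
    "process_stream",
]


@dataclass(frozen=True)
class WeightReading:
    """A single scale reading: millisecond timestamp plus weight in kg."""

    timestamp_ms: int
    weight_kg: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.weight_kg):
            raise ValueError(f"weight_kg must be finite, got {self.weight_kg!r}")


@dataclass(frozen=True)
class TriggerConfig:
    """Parameters of the capture rule.

    ``window`` consecutive readings must all lie in
    [population_min_kg, population_max_kg] with (max - min) < max_spread_kg
    (strict). After a capture, at least ``refractory_readings`` further
    readings must arrive before the next capture; the default equals the
    window length so one plateau cannot fire twice in adjacent windows.
    """

    window: int = 4
    max_spread_kg: float = 0.2
    population_min_kg: float = 16.5
    population_max_kg: float = 117.0
    sampling_interval_s: float = 0.2
    refractory_readings: int | None = None

    def __post_init__(self) -> None:
        if self.window < 2:
            raise ValueError(f"window must be >= 2, got {self.window}")
        if self.max_spread_kg <= 0:
            raise ValueError(f"max_spread_kg must be > 0, got {self.max_spread_kg}")
        if not self.population_min_kg < self.population_max_kg:
            raise ValueError(
                "population_min_kg must be < population_max_kg, got "
                f"{self.population_min_kg} >= {self.population_max_kg}"
            )

    @property
    def refractory(self) -> int:
        return self.window if self.refractory_readings is None else self.refractory_readings


@dataclass(frozen=True)
class CaptureEvent:
    """A capture decision: when it fired and what the scale read."""

    timestamp_ms: int
    weight_kg: float
    reading_index: int


def should_capture(
    last_readings: Sequence[WeightReading], config: TriggerConfig
) -> bool:
    """Apply the window rule to exactly ``config.window`` readings.

    True iff every reading lies in the closed population range and the
    spread (max - min) is strictly below ``config.max_spread_kg``.
    """
    if len(last_readings) != config.window:
        raise ValueError(
            f"expected exactly {config.window} readings, got {len(last_readings)}"
        )
    weights = [r.weight_kg for r in last_readings]
    if any(
        w < config.population_min_kg or w > config.population_max_kg for w in weights
    ):
        return False
    return (max(weights) - min(weights)) < config.max_spread_kg


def process_stream(
    readings: Iterable[WeightReading], config: TriggerConfig
) -> list[CaptureEvent]:
    """Scan a time-ordered stream, emitting a capture at the last reading of
    every qualifying window that clears the refractory cooldown."""
    readings = list(readings)
    for prev, cur in zip(readings, readings[1:]):
        if cur.timestamp_ms < prev.timestamp_ms:
            raise ValueError(
                "readings must have non-decreasing timestamps; "
                f"{cur.timestamp_ms} follows {prev.timestamp_ms}"
            )
    events: list[CaptureEvent] = []
    last_fire: int | None = None
    w = config.window
    for end in range(w - 1, len(readings)):
        if last_fire is not None and end - last_fire < config.refractory:
            continue
        window = readings[end - w + 1 : end + 1]
        if should_capture(window, config):
            r = readings[end]
            events.append(CaptureEvent(r.timestamp_ms, r.weight_kg, end))
            last_fire = end
    return events
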