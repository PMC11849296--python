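"""Capacitance-feedback closed-loop control of stepwise sample loading.

A DropBot-class DMF instrument reports the capacitance of the actuated
electrode path at roughly 40 samples per second.  The capacitance tracks how
much liquid covers the energised electrodes, so each loading cycle has a
characteristic signature: a rise while a ~9 uL segment loads, a further rise
while it splits, and a fall back to baseline while the waste droplet is
absorbed.  The controller advances through the three sub-steps
(LOAD -> SPLIT -> WASTE_REMOVAL) by *active feedback*: after an initial
change in capacitance, the next sub-step is triggered when the rolling
standard deviation of the last ``window`` samples (the capacitance stability
index) falls below a threshold, signalling that droplet motion has stopped.

Defaults follow the instrument convention: a 15-sample window, a 2 pF
stability threshold, ~40 Hz sampling.  The standard-deviation convention is
population (``ddof=0``) and configurable.
"""

from __future__ import annotations

import json
import math
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import (
    IncompleteCycleError,
    InsufficientDataError,
    InvalidInputError,
)

PHASES = ("LOAD", "SPLIT", "WASTE_REMOVAL")


@dataclass(frozen=True)
class CapacitanceTrace:
    """A timestamped capacitance series (s, pF) with nominal sampling rate."""

    times: np.ndarray
    capacitance: np.ndarray
    sample_rate: float = 40.0

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.capacitance, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "capacitance", c)
        if t.size == 0:
            raise InvalidInputError("trace must be non-empty")
        if t.shape != c.shape:
            raise InvalidInputError("times and capacitance must have equal length")
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if np.any(c < 0):
            raise InvalidInputError("capacitance must be >= 0")
        if not self.sample_rate > 0:
            raise InvalidInputError("sample_rate must be > 0")

    def __len__(self) -> int:
        return int(self.times.size)

    def __iter__(self) -> Iterator[tuple[float, float]]:
        return zip(self.times.tolist(), self.capacitance.tolist())

    def to_file(self, path) -> None:
        """Write as two-column delimited text with a one-line header."""
        pd.DataFrame(
            {"time_s": self.times, "capacitance_pF": self.capacitance}
        ).to_csv(path, index=False)

    @classmethod
    def from_file(cls, path, sample_rate: float | None = None) -> "CapacitanceTrace":
        df = pd.read_csv(path)
        expected = ["time_s", "capacitance_pF"]
        if list(df.columns[:2]) != expected:
            raise InvalidInputError(
                f"trace file must have columns {expected}, got {list(df.columns)}"
            )
        t = df["time_s"].to_numpy(float)
        if sample_rate is None:
            dt = np.median(np.diff(t)) if t.size > 1 else 0.025
            sample_rate = 1.0 / dt
        return cls(t, df["capacitance_pF"].to_numpy(float), sample_rate)


@dataclass(frozen=True)
class ControllerConfig:
    """Feedback-controller parameters.

    ``rise_delta`` quantifies the "initial increase" that must precede a
    stability-triggered transition (and, for WASTE_REMOVAL, how close to the
    global baseline the capacitance must fall).  The default 20 pF sits well
    below the smallest phase jump of the calibrated trace signature
    (100 -> 250 pF) and well above the 2 pF noise threshold.
    """

    window: int = 15
    stability_threshold: float = 2.0
    rise_delta: float = 20.0
    phases: tuple[str, ...] = PHASES
    sd_ddof: int = 0  # population convention

    def __post_init__(self):
        if self.window < 2:
            raise InvalidInputError("window must be >= 2")
        if not self.stability_threshold > 0:
            raise InvalidInputError("stability_threshold must be > 0")
        if not self.rise_delta > 0:
            raise InvalidInputError("rise_delta must be > 0")
        if tuple(self.phases) != PHASES:
            raise InvalidInputError(f"phases must be {PHASES}")


@dataclass(frozen=True)
class PhaseRecord:
    phase: str
    start_time: float
    transition_time: float
    capacitance_at_transition: float


@dataclass(frozen=True)
class CycleLog:
    """Per-cycle ledger of the three phase transitions."""

    cycle_index: int
    records: tuple[PhaseRecord, ...]

    def __post_init__(self):
        if tuple(r.phase for r in self.records) != PHASES:
            raise InvalidInputError("cycle phases must be LOAD, SPLIT, WASTE_REMOVAL")
        times = [r.transition_time for r in self.records]
        if any(b < a for a, b in zip(times, times[1:])):
            raise InvalidInputError("transition times must be non-decreasing")

    def to_dict(self) -> dict:
        return {
            "cycle_index": self.cycle_index,
            "phases": [
                {
                    "phase": r.phase,
                    "start_time_s": r.start_time,
                    "transition_time_s": r.transition_time,
                    "capacitance_pF": r.capacitance_at_transition,
                }
                for r in self.records
            ],
        }


def write_cycle_logs(logs: Sequence[CycleLog], path) -> None:
    """Export cycle logs as JSON lines."""
    with open(path, "w") as fh:
        for log in logs:
            fh.write(json.dumps(log.to_dict()) + "\n")


def stability_index(
    trace: CapacitanceTrace, window: int = 15, ddof: int = 0
) -> np.ndarray:
    """Rolling standard deviation of the last ``window`` capacitance samples.

    Element ``i`` (for ``i >= window - 1``) is the SD of samples
    ``i - window + 1 .. i``; earlier elements are NaN (undefined).  The
    population convention (``ddof=0``) is the default.
    """
    if len(trace) < window:
        raise InsufficientDataError(
            f"trace has {len(trace)} samples; the stability index needs at "
            f"least the window length ({window})"
        )
    s = pd.Series(trace.capacitance)
    return s.rolling(window).std(ddof=ddof).to_numpy()


def _ready(
    values: Sequence[float],
    config: ControllerConfig,
    phase_baseline: float,
    direction: str,
) -> bool:
    values = np.asarray(values, dtype=float)
    if direction == "rise":
        armed = bool(np.any(values >= phase_baseline + config.rise_delta))
    else:  # fall back toward the (global) baseline
        armed = bool(np.any(values <= phase_baseline + config.rise_delta))
    if not armed or values.size < config.window:
        return False
    tail = values[-config.window:]
    sd = float(np.std(tail, ddof=config.sd_ddof))
    return sd < config.stability_threshold


def phase_transition_ready(
    history: CapacitanceTrace,
    config: ControllerConfig,
    phase_baseline: float,
    direction: str = "rise",
) -> bool:
    """True iff the current phase may hand over to the next sub-step.

    Requires (a) an initial excursion of at least ``rise_delta`` beyond
    ``phase_baseline`` -- upward for LOAD/SPLIT (``direction="rise"``),
    downward back to within ``rise_delta`` of the baseline for WASTE_REMOVAL
    (``direction="fall"``) -- and (b) the latest stability-index value below
    the threshold.  Returns False (never raises) on insufficient data.
    """
    if direction not in ("rise", "fall"):
        raise InvalidInputError("direction must be 'rise' or 'fall'")
    return _ready(history.capacitance, config, phase_baseline, direction)


def run_closed_loop(
    trace_source: CapacitanceTrace | Iterable[tuple[float, float]],
    plan: Sequence[float],
    config: ControllerConfig | None = None,
    global_baseline: float | None = None,
) -> list[CycleLog]:
    """Consume a capacitance stream, emitting one :class:`CycleLog` per segment.

    The stream is processed strictly on-line with O(window) state: a rolling
    window for the stability index, the phase-entry capacitance as the phase
    baseline, and an "armed" flag set once the initial rise (or, in
    WASTE_REMOVAL, the fall back toward the global baseline) is seen.  The
    run terminates after the final segment's WASTE_REMOVAL transition;
    trailing samples are ignored.  If the stream ends mid-phase the
    controller reports starvation by raising :class:`IncompleteCycleError`
    naming the phase.
    """
    if config is None:
        config = ControllerConfig()
    if len(plan) == 0:
        raise InvalidInputError("segment plan must be non-empty")

    tail: deque[float] = deque(maxlen=config.window)
    # running sums for an O(1) rolling SD
    s1 = 0.0
    s2 = 0.0

    logs: list[CycleLog] = []
    records: list[PhaseRecord] = []
    cycle = 0
    phase_idx = 0
    phase_start: float | None = None
    phase_baseline: float | None = None
    armed = False
    n = config.window
    denom = n - config.sd_ddof

    for t, c in iter(trace_source):
        if global_baseline is None:
            global_baseline = c
        if phase_start is None:
            phase_start = t
            phase_baseline = c
        if len(tail) == config.window:
            old = tail[0]
            s1 -= old
            s2 -= old * old
        tail.append(c)
        s1 += c
        s2 += c * c

        phase = PHASES[phase_idx]
        if phase == "WASTE_REMOVAL":
            if c <= global_baseline + config.rise_delta:
                armed = True
        else:
            if c >= phase_baseline + config.rise_delta:
                armed = True

        if armed and len(tail) == config.window:
            var = max(s2 / n - (s1 / n) ** 2, 0.0)
            if config.sd_ddof:
                var *= n / denom
            if math.sqrt(var) < config.stability_threshold:
                records.append(
                    PhaseRecord(phase, phase_start, t, c)
                )
                phase_idx += 1
                phase_start = None
                phase_baseline = None
                armed = False
                if phase_idx == len(PHASES):
                    logs.append(CycleLog(cycle, tuple(records)))
                    records = []
                    phase_idx = 0
                    cycle += 1
                    if cycle == len(plan):
                        return logs

    raise IncompleteCycleError(PHASES[phase_idx], cycle)


def plan_segments(
    total_volume: float, nominal_segment: float, policy: str = "default"
) -> list[float]:
    """Split ``total_volume`` (uL) into loading segments of ``nominal_segment``.

    ``default``: ``ceil(total / nominal)`` segments, all but the last equal to
    the nominal volume, the last the remainder (equal to the nominal when the
    division is exact).  ``merge-final``: a remainder smaller than half the
    nominal is folded into the final one or two segments instead of standing
    alone, mirroring the practice of letting the last segments run large when
    the reservoir's rising Laplace pressure makes small splits unreliable.
    Both policies conserve volume exactly.
    """
    if not total_volume > 0 or not nominal_segment > 0:
        raise InvalidInputError("total_volume and nominal_segment must be > 0")
    if policy not in ("default", "merge-final"):
        raise InvalidInputError(f"unknown policy {policy!r}")

    n = math.ceil(total_volume / nominal_segment)
    remainder = total_volume - (n - 1) * nominal_segment
    if remainder <= 0:  # float round-up of an exact division
        n -= 1
        remainder = total_volume - (n - 1) * nominal_segment
    segments = [nominal_segment] * (n - 1) + [remainder]

    if policy == "merge-final" and n >= 2 and remainder < nominal_segment / 2:
        extra = segments.pop()
        if len(segments) >= 2 and extra > nominal_segment / 4:
            # spread an awkward remainder over the final two segments
            segments[-2] += extra / 2
            segments[-1] += extra / 2
        else:
            segments[-1] += extra
    return segments
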