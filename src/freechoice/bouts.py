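"""Run/lick bout microstructure: binning, segmentation and per-bout summaries.

Wheel speed and lick contact are acquired at 500 Hz, binned to 5 Hz (mean for
speeds, logical-any for contacts) and thresholded — 10 cm s⁻¹ for running, any
contact for licking.  A bout starts at the first supra-threshold bin after at
least ``min_gap`` seconds of quiet (1 s by default, 4 s for photometry-aligned
bouts) and ends at the last supra-threshold bin before such a quiet period;
shorter quiet runs are absorbed into the bout.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

RUN_SPEED_THRESHOLD_CM_S = 10.0
UL_PER_REWARD = 6.0
LICKS_PER_REWARD = 10


class BoutError(ValueError):
    pass


@dataclasses.dataclass
class EventTrace:
    """Uniformly sampled behavioral trace (cm s⁻¹ wheel speed or 0/1 contact)."""

    t: np.ndarray
    values: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.t) != len(self.values):
            raise BoutError("t and values must have equal lengths")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def dt(self) -> float:
        return 1.0 / self.rate


@dataclasses.dataclass(frozen=True)
class Bout:
    """Contiguous supra-threshold epoch.

    ``amount`` is meters-equivalent distance for run bouts (integral of the
    binned speed) or the number of active bins for lick bouts.
    """

    t_start: float
    t_end: float
    duration: float
    amount: float
    slice: tuple[int, int] = dataclasses.field(default=(0, 0), compare=False)


@dataclasses.dataclass
class BoutParams:
    threshold: float = RUN_SPEED_THRESHOLD_CM_S
    min_gap: float = 1.0
    bin_rate: float = 5.0

    def __post_init__(self) -> None:
        if self.min_gap <= 0:
            raise BoutError("min_gap must be > 0")
        if self.threshold < 0:
            raise BoutError("threshold must be >= 0")

    @classmethod
    def run(cls, min_gap: float = 1.0) -> "BoutParams":
        return cls(threshold=RUN_SPEED_THRESHOLD_CM_S, min_gap=min_gap)

    @classmethod
    def lick(cls, min_gap: float = 1.0) -> "BoutParams":
        # any contact counts: binned contact traces are 0/1
        return cls(threshold=0.5, min_gap=min_gap)


@dataclasses.dataclass
class BoutSummary:
    count: int
    mean_duration: float | None
    mean_amount: float | None


def bin_trace(trace: EventTrace, target_rate: float, mode: str) -> EventTrace:
    """Reduce to ``target_rate`` by non-overlapping windows (mean or logical any).

    The source rate must be an integer multiple of the target rate; a trailing
    partial window is dropped.
    """
    ratio = trace.rate / target_rate
    factor = round(ratio)
    if factor < 1 or abs(ratio - factor) > 1e-9:
        raise BoutError(
            f"source rate {trace.rate} is not an integer multiple of {target_rate}"
        )
    if mode not in ("mean", "any"):
        raise BoutError(f"unknown binning mode {mode!r}")
    n_out = len(trace) // factor
    windows = trace.values[: n_out * factor].reshape(n_out, factor)
    if mode == "mean":
        out = windows.mean(axis=1)
    else:
        out = (windows > 0).any(axis=1).astype(float)
    t = trace.t[0] + np.arange(n_out) / target_rate
    return EventTrace(t, out, target_rate)


def detect_bouts(trace: EventTrace, params: BoutParams, kind: str = "run") -> list[Bout]:
    """Segment a binned trace into bouts.

    Supra-threshold runs separated by fewer than ``min_gap`` seconds of
    sub-threshold bins are merged; separations of at least ``min_gap`` split
    bouts.  A single-bin bout is assigned one bin period as its duration
    (start/end coincide); multi-bin durations are last-minus-first bin time.
    """
    if abs(trace.rate - params.bin_rate) > 1e-9:
        raise BoutError(f"trace rate {trace.rate} != bout bin rate {params.bin_rate}")
    if kind not in ("run", "lick"):
        raise BoutError(f"unknown bout kind {kind!r}")
    above = trace.values >= params.threshold
    gap_bins = round(params.min_gap * trace.rate)
    runs = _runs(above)
    merged: list[list[int]] = []
    for start, end in runs:  # end exclusive
        if merged and start - merged[-1][1] < gap_bins:
            merged[-1][1] = end
        else:
            merged.append([start, end])
    dt = trace.dt
    bouts = []
    for start, end in merged:
        t_start = float(trace.t[start])
        t_end = float(trace.t[end - 1])
        duration = max(t_end - t_start, dt)
        seg = trace.values[start:end]
        if kind == "run":
            amount = float(seg.sum() * dt)  # cm, rectangle rule over bins
        else:
            amount = float((seg >= params.threshold).sum())
        bouts.append(Bout(t_start, t_end, duration, amount, slice=(start, end)))
    return bouts


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, end) index pairs of True runs."""
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(int))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def summarize_bouts(bouts: Sequence[Bout]) -> BoutSummary:
    """Count, mean duration and mean amount per bout.

    With no bouts the count is 0 and both means are missing (None), never 0.
    """
    if len(bouts) == 0:
        return BoutSummary(0, None, None)
    durations = [b.duration for b in bouts]
    amounts = [b.amount for b in bouts]
    return BoutSummary(
        len(bouts),
        float(np.mean(durations)),
        float(np.mean(amounts)),
    )


def licks_to_volume(n_licks: int) -> float:
    """Dispensed volume in µl: 6 µl per completed group of 10 licks."""
    if n_licks < 0 or n_licks != int(n_licks):
        raise BoutError("lick count must be a nonnegative integer")
    return UL_PER_REWARD * (int(n_licks) // LICKS_PER_REWARD)
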