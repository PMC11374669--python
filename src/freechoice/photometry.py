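"""Dual-channel fiber-photometry preprocessing.

The 465-nm channel reports calcium-dependent GCaMP6s fluorescence; the 405-nm
channel is the isosbestic movement-artifact reference.  Slow photobleaching is
removed by fitting a triple-exponential-plus-offset curve to each full trace
and subtracting it; traces are then z-score normalized to the entire trace or
expressed as a percentage ΔF/F₀ where F₀ is the fitted bleach curve at each
timepoint.  Normalized signals can be aligned around behavioral events
(peri-event matrices) or averaged by concurrent maze ROI.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .tracking import PositionTrack

logger = logging.getLogger(__name__)


class PhotometryError(ValueError):
    pass


@dataclasses.dataclass
class PhotometryTrace:
    """20-Hz dual-channel trace with a processing-state tag."""

    t: np.ndarray
    ch465: np.ndarray
    ch405: np.ndarray
    rate: float
    state: str = "raw"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.ch465 = np.asarray(self.ch465, dtype=float)
        self.ch405 = np.asarray(self.ch405, dtype=float)
        if not (len(self.t) == len(self.ch465) == len(self.ch405)):
            raise PhotometryError("channel lengths differ")
        if self.state == "raw" and (np.min(self.ch465) <= 0 or np.min(self.ch405) <= 0):
            raise PhotometryError("raw channels must be strictly positive")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        return 1.0 / self.rate


@dataclasses.dataclass
class BleachModel:
    """offset + Σ aᵢ·exp(−kᵢ·t) photobleaching curve."""

    amplitudes: np.ndarray
    rates: np.ndarray
    offset: float
    residual_norm: float = np.nan

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.offset + np.exp(-np.outer(t, self.rates)) @ self.amplitudes


def _exp_design(t: np.ndarray, rates: np.ndarray) -> np.ndarray:
    cols = [np.ones_like(t)] + [np.exp(-k * t) for k in rates]
    return np.column_stack(cols)


def fit_bleach(
    t: np.ndarray,
    y: np.ndarray,
    n_exp: int = 3,
) -> tuple[BleachModel, np.ndarray]:
    """Least-squares multi-exponential bleach fit; returns model and y − fit.

    Uses variable projection: only the decay rates are optimized nonlinearly
    (with nonnegativity bounds); offset and amplitudes are solved linearly at
    each step.  Rate initializations are spread over fast (~0.1 s⁻¹), mid
    (~0.01 s⁻¹) and slow (~0.001 s⁻¹) regimes because multi-exponential fits
    are initialization sensitive.  If no start converges the fit falls back to
    a double exponential with a logged warning.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t[-1] - t[0] < 60.0:
        raise PhotometryError("need at least 60 s of data to fit bleaching")

    def residuals(log_rates: np.ndarray) -> np.ndarray:
        # keep rates within physically sensible bounds to avoid overflow
        A = _exp_design(t, np.exp(np.clip(log_rates, -30.0, 5.0)))
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        return A @ coef - y

    starts = [
        np.array([0.1, 0.01, 0.001][:n_exp]),
        np.array([0.3, 0.02, 0.0005][:n_exp]),
        np.array([0.05, 0.005, 0.002][:n_exp]),
    ]
    best = None
    for k0 in starts:
        try:
            sol = optimize.least_squares(
                residuals,
                np.log(k0),
                method="lm",
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
                max_nfev=4000,
            )
        except Exception:  # pragma: no cover - lm rarely raises
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        if n_exp > 2:
            logger.warning("triple-exponential fit failed; falling back to double")
            return fit_bleach(t, y, n_exp=2)
        raise PhotometryError("bleach fit did not converge")

    rates = np.exp(np.clip(best.x, -30.0, 5.0))
    A = _exp_design(t, rates)
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    fit = A @ coef
    model = BleachModel(
        amplitudes=coef[1:],
        rates=rates,
        offset=float(coef[0]),
        residual_norm=float(np.linalg.norm(y - fit)),
    )
    return model, y - fit


def normalize(
    values: np.ndarray,
    mode: str = "zscore",
    f0: np.ndarray | float | None = None,
) -> np.ndarray:
    """z-score over the full trace, or percentage ΔF/F₀ against ``f0``."""
    values = np.asarray(values, dtype=float)
    if mode == "zscore":
        sd = values.std()
        if sd == 0:
            raise PhotometryError("zero variance: cannot z-score")
        return (values - values.mean()) / sd
    if mode == "dff":
        if f0 is None:
            raise PhotometryError("dff normalization requires F0")
        f0 = np.asarray(f0, dtype=float)
        if np.any(f0 <= 0):
            raise PhotometryError("F0 must be strictly positive for dff")
        return 100.0 * (values - f0) / f0
    raise PhotometryError(f"unknown normalization mode {mode!r}")


@dataclasses.dataclass
class PreprocessedPhotometry:
    trace: PhotometryTrace
    bleach_465: BleachModel
    bleach_405: BleachModel


def preprocess(trace: PhotometryTrace, mode: str = "zscore") -> PreprocessedPhotometry:
    """Bleach-correct both channels, then normalize.

    ``zscore``: z-score of the subtractively corrected trace.
    ``dff``: percentage ΔF/F₀ with F₀ = the fitted bleach curve at each
    timepoint (so a purely multiplicative bleach is removed exactly).
    Each channel is fitted separately.
    """
    outputs = []
    models = []
    for raw in (trace.ch465, trace.ch405):
        model, corrected = fit_bleach(trace.t, raw)
        if mode == "zscore":
            out = normalize(corrected, "zscore")
        elif mode == "dff":
            out = normalize(raw, "dff", f0=model.predict(trace.t))
        else:
            raise PhotometryError(f"unknown normalization mode {mode!r}")
        models.append(model)
        outputs.append(out)
    new = PhotometryTrace(trace.t, outputs[0], outputs[1], trace.rate, state=mode)
    return PreprocessedPhotometry(new, models[0], models[1])


@dataclasses.dataclass
class PeriEventMatrix:
    """Trials × time matrix of normalized signal around repeated events."""

    rel_time: np.ndarray
    matrix: np.ndarray
    events_used: np.ndarray
    n_dropped: int
    window: tuple[float, float]

    @property
    def mean(self) -> np.ndarray:
        return self.matrix.mean(axis=0)

    @property
    def sem(self) -> np.ndarray:
        n = self.matrix.shape[0]
        if n < 2:
            return np.zeros(self.matrix.shape[1])
        return self.matrix.std(axis=0, ddof=1) / np.sqrt(n)

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.fill_between(self.rel_time, self.mean - self.sem, self.mean + self.sem, alpha=0.3)
        ax.plot(self.rel_time, self.mean, **kwargs)
        ax.axvline(0.0, color="k", lw=0.5)
        ax.set_xlabel("time from event (s)")
        ax.set_ylabel("signal")
        return ax


def align_events(
    values: np.ndarray,
    t: np.ndarray,
    events: Sequence[float],
    window: tuple[float, float],
    rate: float,
) -> PeriEventMatrix:
    """Extract [event − pre, event + post] segments on the trace grid.

    Events whose window would run past either end of the trace are dropped and
    counted in ``n_dropped``.  Raises if every event is dropped.
    """
    values = np.asarray(values, dtype=float)
    t = np.asarray(t, dtype=float)
    pre, post = window
    n_pre = round(pre * rate)
    n_post = round(post * rate)
    rel = np.arange(-n_pre, n_post + 1) / rate
    rows = []
    used = []
    dropped = 0
    for ev in events:
        center = round((ev - t[0]) * rate)
        lo, hi = center - n_pre, center + n_post
        if lo < 0 or hi >= len(values):
            dropped += 1
            continue
        rows.append(values[lo : hi + 1])
        used.append(ev)
    if not rows:
        raise PhotometryError("all events fell outside the trace")
    return PeriEventMatrix(rel, np.array(rows), np.array(used), dropped, window)


def roi_average(
    values: np.ndarray,
    t: np.ndarray,
    track: PositionTrack,
    groups: Sequence[str] = ("wheel", "HPF", "center"),
) -> pd.Series:
    """Mean normalized signal per concurrent ROI group.

    Each photometry sample takes the ROI label of the nearest position sample
    (the rates differ: 20 Hz signal vs 5 Hz track).  Labels not in ``groups``
    are pooled as ``other``.  A group never visited gets NaN.
    """
    if track.roi is None:
        raise PhotometryError("track must be ROI-labeled")
    idx = np.clip(
        np.round((np.asarray(t) - track.t[0]) * track.rate).astype(int),
        0,
        len(track) - 1,
    )
    labels = track.roi[idx]
    out = {}
    grouped = np.where(np.isin(labels, list(groups)), labels, "other")
    for g in list(groups) + ["other"]:
        mask = grouped == g
        out[g] = float(np.mean(values[mask])) if mask.any() else np.nan
    return pd.Series(out, name="mean_signal")
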