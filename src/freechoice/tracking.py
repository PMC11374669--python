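"""Maze geometry, xy-track preprocessing and ROI occupancy / visit / decision metrics.

Position is tracked at 5 Hz in an eight-arm radial maze (eight arms radiating
from a central zone, nine regions of interest in total) or in a simple
two-choice chamber.  Tracks are boxcar-smoothed and gap-interpolated, every
sample is assigned to a containing ROI (samples in the corridor between
polygons count as center), and occupancy, visits, arm-entry decisions and
distance traveled are derived from the labeled track.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely

logger = logging.getLogger(__name__)

CENTER = "center"

#: Default contents of the eight arms once the palatable-food (HPF) dispenser
#: is installed in the initially empty arm.
EIGHT_ARM_LABELS = (
    "wheel",
    "chow",
    "HPF",
    "novel_object",
    "novel_mouse",
    "water",
    "light",
    "dark",
)

TWO_CHOICE_LABELS = ("wheel", "HPF")


class GeometryError(ValueError):
    """Invalid maze geometry (wrong ROI count, overlapping polygons, ...)."""


class TrackError(ValueError):
    """Unusable position track (all samples invalid, missing labels, ...)."""


@dataclasses.dataclass
class PositionTrack:
    """Timestamped xy path sampled at a fixed rate (nominally 5 Hz).

    ``valid`` marks samples where the animal could be identified; invalid
    samples carry NaN coordinates until interpolated.  ``roi`` is filled by
    :func:`assign_rois`.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    rate: float
    valid: np.ndarray | None = None
    roi: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.x) & np.isfinite(self.y)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.valid) == n):
            raise TrackError("t, x, y, valid must have equal lengths")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise TrackError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        return 1.0 / self.rate

    @property
    def duration(self) -> float:
        return len(self) * self.dt

    def copy(self) -> "PositionTrack":
        return PositionTrack(
            self.t.copy(),
            self.x.copy(),
            self.y.copy(),
            self.rate,
            self.valid.copy(),
            None if self.roi is None else self.roi.copy(),
        )


@dataclasses.dataclass(frozen=True)
class Visit:
    """A maximal contiguous stay in one arm ROI."""

    roi: str
    t_enter: float
    t_exit: float

    @property
    def duration(self) -> float:
        return self.t_exit - self.t_enter


class MazeGeometry:
    """Named ROI polygons plus the arena-to-meter scale.

    Polygons are closed on their boundary: a point exactly on an edge belongs
    to the ROI.  Any point contained in no polygon is assigned to the center
    (corridor convention), so the geometry needs no explicit corridor shapes.
    """

    def __init__(
        self,
        polygons: Mapping[str, np.ndarray],
        meters_per_unit: float | None = None,
        center_label: str = CENTER,
    ) -> None:
        self.polygons = {k: np.asarray(v, dtype=float) for k, v in polygons.items()}
        self.meters_per_unit = meters_per_unit
        self.center_label = center_label
        self._shapes = {k: shapely.Polygon(v) for k, v in self.polygons.items()}
        self.validate()

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.polygons)

    @property
    def arm_labels(self) -> tuple[str, ...]:
        return tuple(k for k in self.polygons if k != self.center_label)

    def validate(self) -> None:
        for name, shape in self._shapes.items():
            if not shape.is_valid or shape.area <= 0:
                raise GeometryError(f"ROI {name!r} polygon is degenerate")
        names = list(self._shapes)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                inter = self._shapes[a].intersection(self._shapes[b])
                if inter.area > 1e-9 * min(self._shapes[a].area, self._shapes[b].area):
                    raise GeometryError(f"ROIs {a!r} and {b!r} overlap")

    def contains(self, label: str, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        # intersects == covers for points: boundary points are inside.
        return shapely.intersects_xy(self._shapes[label], x, y)

    def to_dict(self) -> dict:
        return {
            "center_label": self.center_label,
            "meters_per_unit": self.meters_per_unit,
            "polygons": {k: v.tolist() for k, v in self.polygons.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MazeGeometry":
        return cls(
            {k: np.asarray(v) for k, v in d["polygons"].items()},
            meters_per_unit=d.get("meters_per_unit"),
            center_label=d.get("center_label", CENTER),
        )


def _rect(along: tuple[float, float], half_width: float, angle: float) -> np.ndarray:
    """Axis-aligned rectangle [along0, along1] x [-hw, hw] rotated by angle."""
    a0, a1 = along
    local = np.array(
        [[a0, -half_width], [a1, -half_width], [a1, half_width], [a0, half_width]]
    )
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    return local @ rot.T


def eight_arm_geometry(
    center_half: float = 5.0,
    arm_inner: float = 12.0,
    arm_outer: float = 45.0,
    arm_half_width: float = 3.0,
    labels: Sequence[str] = EIGHT_ARM_LABELS,
    meters_per_unit: float = 0.01,
) -> MazeGeometry:
    """Abstract eight-arm layout: central square plus 8 radial arms at 45° steps.

    Units are centimeters by default (``meters_per_unit = 0.01``).  The ring
    between the central square and the arm mouths acts as the corridor:
    samples there are labeled center.
    """
    if len(labels) != 8:
        raise GeometryError("eight-arm maze needs exactly 8 arm labels")
    polys: dict[str, np.ndarray] = {
        CENTER: np.array(
            [
                [-center_half, -center_half],
                [center_half, -center_half],
                [center_half, center_half],
                [-center_half, center_half],
            ]
        )
    }
    for k, label in enumerate(labels):
        polys[label] = _rect((arm_inner, arm_outer), arm_half_width, np.pi / 4 * k)
    return MazeGeometry(polys, meters_per_unit=meters_per_unit)


def two_choice_geometry(
    box_half: float = 8.0,
    gap: float = 2.0,
    meters_per_unit: float = 0.01,
) -> MazeGeometry:
    """Two-choice chamber: wheel zone and HPF zone flanking a neutral center."""
    w = 2 * box_half
    polys = {
        CENTER: _rect((-box_half, box_half), box_half, 0.0),
        "wheel": _rect((-box_half - gap - w, -box_half - gap), box_half, 0.0),
        "HPF": _rect((box_half + gap, box_half + gap + w), box_half, 0.0),
    }
    return MazeGeometry(polys, meters_per_unit=meters_per_unit)


def default_geometry(maze_kind: str) -> MazeGeometry:
    if maze_kind == "eight_arm":
        return eight_arm_geometry()
    if maze_kind == "two_choice":
        return two_choice_geometry()
    raise GeometryError(f"unknown maze kind {maze_kind!r}")


def roi_anchor(geom: MazeGeometry, label: str) -> np.ndarray:
    """Representative interior point of an ROI (its polygon centroid)."""
    c = geom._shapes[label].centroid
    return np.array([c.x, c.y])


# ---------------------------------------------------------------------------
# track preprocessing


def smooth_and_interpolate(track: PositionTrack) -> PositionTrack:
    """Linearly interpolate invalid samples, then apply a 3-sample boxcar.

    Interpolation uses the nearest valid neighbors (edge gaps take the nearest
    valid value).  The centered three-sample moving average uses shortened
    windows at the endpoints.  Gaps are interpolated regardless of length; a
    warning is logged if more than 1% of samples are invalid.
    """
    if len(track) < 3:
        raise TrackError("need at least 3 samples to smooth")
    valid = track.valid & np.isfinite(track.x) & np.isfinite(track.y)
    if not valid.any():
        raise TrackError("all samples invalid: track unrecoverable")
    frac_invalid = 1.0 - valid.mean()
    if frac_invalid >= 0.5:
        raise TrackError(f"{frac_invalid:.0%} of samples invalid (must be < 50%)")
    if frac_invalid > 0.01:
        logger.warning("interpolating %.2f%% invalid samples", 100 * frac_invalid)

    out = track.copy()
    idx = np.arange(len(track), dtype=float)
    for coord in ("x", "y"):
        vals = getattr(out, coord)
        filled = np.interp(idx, idx[valid], vals[valid])
        setattr(out, coord, _boxcar3(filled))
    out.valid = np.ones(len(track), dtype=bool)
    return out


def _boxcar3(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    out[1:-1] = (x[:-2] + x[1:-1] + x[2:]) / 3.0
    out[0] = (x[0] + x[1]) / 2.0
    out[-1] = (x[-2] + x[-1]) / 2.0
    return out


def assign_rois(track: PositionTrack, geom: MazeGeometry) -> PositionTrack:
    """Label every sample with its containing ROI (corridor samples → center)."""
    if not track.valid.all():
        raise TrackError("track has invalid samples; smooth_and_interpolate first")
    labels = np.full(len(track), geom.center_label, dtype=object)
    unassigned = np.ones(len(track), dtype=bool)
    for label in geom.labels:
        if label == geom.center_label:
            continue
        inside = geom.contains(label, track.x, track.y) & unassigned
        labels[inside] = label
        unassigned &= ~inside
    out = track.copy()
    out.roi = labels
    return out


# ---------------------------------------------------------------------------
# metrics


def occupancy_times(track: PositionTrack, geom: MazeGeometry | None = None) -> pd.Series:
    """Seconds spent in each ROI.  Values sum to the session duration."""
    if track.roi is None:
        raise TrackError("track is unlabeled; run assign_rois first")
    labels = (
        list(geom.labels)
        if geom is not None
        else sorted(set(track.roi), key=str)
    )
    counts = pd.Series(track.roi).value_counts()
    occ = pd.Series(0.0, index=labels, name="occupancy_s")
    for label, n in counts.items():
        if label not in occ.index:
            occ[label] = 0.0
        occ[label] = n * track.dt
    return occ


def compute_visits(track: PositionTrack, center_label: str = CENTER) -> list[Visit]:
    """Maximal runs of a constant arm label.  Center runs are not visits.

    A visit's exit time is the timestamp of the first sample after the run
    (or run end + one sample period at the trace end), so its duration equals
    the number of samples times the sample period.
    """
    if track.roi is None:
        raise TrackError("track is unlabeled; run assign_rois first")
    visits: list[Visit] = []
    roi = track.roi
    n = len(roi)
    i = 0
    while i < n:
        j = i
        while j < n and roi[j] == roi[i]:
            j += 1
        if roi[i] != center_label:
            t_exit = track.t[j] if j < n else track.t[j - 1] + track.dt
            visits.append(Visit(str(roi[i]), float(track.t[i]), float(t_exit)))
        i = j
    return visits


def arm_entries(track: PositionTrack, center_label: str = CENTER) -> list[tuple[float, str]]:
    """Arm-entry events: first arm-labeled sample after >= 1 center sample."""
    if track.roi is None:
        raise TrackError("track is unlabeled; run assign_rois first")
    entries: list[tuple[float, str]] = []
    seen_center = False
    prev = None
    for t, label in zip(track.t, track.roi):
        if label == center_label:
            seen_center = True
        elif label != prev or seen_center:
            if seen_center:
                entries.append((float(t), str(label)))
            seen_center = False
        prev = label
    return entries


def entry_probability(
    entries: PositionTrack | Iterable[str] | Iterable[tuple[float, str]],
    arm_pair: tuple[str, str] = ("wheel", "HPF"),
) -> float:
    """P(entering the first arm of ``arm_pair``) among entries to either arm.

    Accepts a labeled track (entries are derived with :func:`arm_entries`), a
    sequence of entry labels, or (time, label) pairs.  0.5 is the random-choice
    reference.  Raises if no qualifying entry exists.
    """
    if isinstance(entries, PositionTrack):
        labels = [lab for _, lab in arm_entries(entries)]
    else:
        entries = list(entries)
        labels = [e[1] if isinstance(e, tuple) else str(e) for e in entries]
    target, other = arm_pair
    n_target = sum(1 for lab in labels if lab == target)
    n_either = n_target + sum(1 for lab in labels if lab == other)
    if n_either == 0:
        raise TrackError(f"no entries to {target!r} or {other!r}: probability undefined")
    return n_target / n_either


def distance_traveled(
    track: PositionTrack,
    meters_per_unit: float | None = None,
    exclude_roi: str | Sequence[str] | None = None,
    geom: MazeGeometry | None = None,
) -> float:
    """Total path length in meters, optionally excluding steps starting in an ROI.

    Each step between consecutive samples is attributed to the ROI of its
    origin sample, giving an unambiguous partition of the path.
    """
    if meters_per_unit is None and geom is not None:
        meters_per_unit = geom.meters_per_unit
    if meters_per_unit is None:
        raise GeometryError("arena-to-meter scale required (meters_per_unit)")
    steps = np.hypot(np.diff(track.x), np.diff(track.y))
    if exclude_roi is not None:
        if track.roi is None:
            raise TrackError("exclusion by ROI requires a labeled track")
        excluded = {exclude_roi} if isinstance(exclude_roi, str) else set(exclude_roi)
        keep = ~np.isin(track.roi[:-1], list(excluded))
        steps = steps[keep]
    return float(steps.sum() * meters_per_unit)
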