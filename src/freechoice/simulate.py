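"""Synthetic multi-mouse free-choice sessions with known ground truth.

Emulates the statistical structure the analysis assumes: a semi-Markov maze
trajectory alternating center and arm dwells (5 Hz), bouted wheel running and
HPF licking (500 Hz; exponential inter-bout intervals, gamma bout durations),
and dual-channel photometry (20 Hz) generated from the encoding-model
equation — known fixed weights, independent per-mouse random slopes, Gaussian
residual — with a multiplicative triple-exponential bleach envelope on both
channels and a low-pass motion artifact carried by the 405-nm channel.

The generative latent signal is stored on each session so parameter-recovery
tests can compare fitted weights against the exact truth.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _signal

from . import bouts as _bouts
from . import encoding as _encoding
from . import tracking as _tracking

#: Fixed per-mouse seed offset so a mouse's session is reproducible even when
#: the cohort is resized.
MOUSE_SEED_STRIDE = 100003


class ConfigError(ValueError):
    pass


@dataclasses.dataclass
class CohortConfig:
    n_mice: int = 10
    session_duration: float = 600.0  # free exploration lasts 10 min
    position_rate: float = 5.0
    event_rate: float = 500.0
    photometry_rate: float = 20.0
    maze_kind: str = "eight_arm"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mice < 1:
            raise ConfigError("n_mice must be >= 1")
        if self.session_duration <= 0:
            raise ConfigError("session_duration must be > 0")
        for r in (self.position_rate, self.event_rate, self.photometry_rate):
            if r <= 0:
                raise ConfigError("all rates must be > 0")
        if self.maze_kind not in ("eight_arm", "two_choice"):
            raise ConfigError(f"unknown maze kind {self.maze_kind!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        return cls(**dict(d))


@dataclasses.dataclass
class GroundTruth:
    """Generative parameters of a synthetic cohort (units: z-scored signal)."""

    beta0: float = 0.0
    beta_xy: float = 0.25
    beta_wheel: float = 0.35
    beta_lick: float = -0.30
    beta_405: float = 0.10
    sigma_b: tuple[float, float, float, float] = (0.2, 0.2, 0.2, 0.2)
    sigma_eps: float = 1.0
    bleach_amplitudes: tuple[float, float, float] = (0.15, 0.15, 0.70)
    bleach_rates: tuple[float, float, float] = (0.05, 0.005, 2e-4)  # s^-1
    gcamp_half_life: float = 1.796  # s, GCaMP6s
    #: per-mouse random slopes, shape (n_mice, 4) in the order xy, wheel,
    #: licking, iso405; drawn by generate_cohort when absent
    random_slopes: np.ndarray | None = None

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.sigma_b):
            raise ConfigError("sigma_b must be nonnegative elementwise")
        if self.sigma_eps <= 0:
            raise ConfigError("sigma_eps must be > 0")
        if any(k < 0 for k in self.bleach_rates):
            raise ConfigError("bleach rates must be >= 0")
        if self.gcamp_half_life <= 0:
            raise ConfigError("gcamp_half_life must be > 0")
        if self.random_slopes is not None:
            self.random_slopes = np.asarray(self.random_slopes, dtype=float)

    @property
    def betas(self) -> np.ndarray:
        return np.array([self.beta_xy, self.beta_wheel, self.beta_lick, self.beta_405])

    def bleach_envelope(self, t: np.ndarray) -> np.ndarray:
        a = np.asarray(self.bleach_amplitudes)
        k = np.asarray(self.bleach_rates)
        return np.exp(-np.outer(np.asarray(t), k)) @ a

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.random_slopes is not None:
            d["random_slopes"] = self.random_slopes.tolist()
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GroundTruth":
        d = dict(d)
        for key in ("sigma_b", "bleach_amplitudes", "bleach_rates"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclasses.dataclass
class BehaviorParams:
    """Rates and dwell/bout distributions of the synthetic behavior."""

    arm_probs: Mapping[str, float] | None = None  # None -> default preference
    center_dwell_mean: float = 3.0  # s, exponential
    arm_dwell_shape: float = 2.0  # gamma shape
    arm_dwell_mean: float = 8.0  # s, gamma mean
    transit_speed: float = 20.0  # cm/s between ROI anchors
    jitter_sd: float = 1.0  # cm, within-ROI wander
    jitter_tau: float = 1.0  # s, wander autocorrelation
    run_ibi_mean: float = 5.0  # s, exponential inter-bout interval
    run_bout_shape: float = 2.0
    run_bout_mean: float = 6.0  # s, gamma mean
    run_speed_mean: float = 25.0  # cm/s
    run_speed_sd: float = 4.0
    lick_ibi_mean: float = 4.0
    lick_bout_shape: float = 2.0
    lick_bout_mean: float = 3.0
    lick_rate: float = 7.0  # Hz within a bout
    lick_contact_duration: float = 0.03  # s per lick
    invalid_fraction: float = 0.0005  # tracking dropout (< 0.1% in practice)

    def resolved_arm_probs(self, arm_labels: Sequence[str]) -> np.ndarray:
        if self.arm_probs is None:
            base = {"wheel": 0.28, "HPF": 0.22}
            rest = [a for a in arm_labels if a not in base]
            probs = np.array(
                [base.get(a, (1.0 - sum(base.values())) / max(len(rest), 1)) for a in arm_labels]
            )
        else:
            probs = np.array([float(self.arm_probs.get(a, 0.0)) for a in arm_labels])
        if np.any(probs < 0) or not np.all(np.isfinite(probs)):
            raise ConfigError("arm probabilities must be finite and nonnegative")
        total = probs.sum()
        return probs / total if total > 0 else probs  # all-zero -> center only


@dataclasses.dataclass
class PhotometryParams:
    """Raw-channel construction around the generative latent signal."""

    baseline_465: float = 100.0  # a.u.
    scale_465: float = 5.0  # a.u. per z-unit of latent
    baseline_405: float = 100.0
    artifact_sd: float = 3.0  # a.u., low-pass motion artifact on 405
    artifact_tau: float = 0.5  # s
    noise_405_sd: float = 0.3  # a.u., independent white noise on 405


@dataclasses.dataclass
class SyntheticSession:
    mouse_id: str
    config: CohortConfig
    position: _tracking.PositionTrack
    wheel_speed: _bouts.EventTrace
    lick_contact: _bouts.EventTrace
    true_run_bouts: list[tuple[float, float]]
    true_lick_bouts: list[tuple[float, float]]
    drawn_run_durations: list[float]
    drawn_lick_durations: list[float]
    photo_t: np.ndarray | None = None
    photo_465: np.ndarray | None = None
    photo_405: np.ndarray | None = None
    latent: np.ndarray | None = None
    truth: GroundTruth | None = None
    mouse_index: int = 0


def _ar1_noise(n: int, sd: float, tau: float, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) noise with sd and autocorrelation time tau."""
    if n == 0 or sd == 0:
        return np.zeros(n)
    a = np.exp(-1.0 / (tau * rate))
    w = rng.standard_normal(n)
    x = _signal.lfilter([np.sqrt(1 - a**2)], [1.0, -a], w)
    x[0] = rng.standard_normal()
    return sd * x


def mouse_rng(rng_seed: int, mouse_index: int) -> np.random.Generator:
    return np.random.default_rng(rng_seed + MOUSE_SEED_STRIDE * (mouse_index + 1))


def generate_behavior(
    config: CohortConfig,
    params: BehaviorParams | None = None,
    rng: np.random.Generator | None = None,
    mouse_index: int = 0,
    geom: _tracking.MazeGeometry | None = None,
) -> SyntheticSession:
    """Generate one session's trajectory, wheel-speed and lick-contact traces."""
    params = params or BehaviorParams()
    rng = rng if rng is not None else mouse_rng(config.rng_seed, mouse_index)
    geom = geom or _tracking.default_geometry(config.maze_kind)
    arm_labels = list(geom.arm_labels)
    probs = params.resolved_arm_probs(arm_labels)

    duration = config.session_duration
    # --- semi-Markov state timeline -------------------------------------
    segments: list[tuple[str, float, float, str]] = []  # (kind, t0, t1, label)
    t = 0.0
    anchors = {lab: _tracking.roi_anchor(geom, lab) for lab in geom.labels}
    center = geom.center_label
    while t < duration:
        dwell = rng.exponential(params.center_dwell_mean)
        segments.append(("dwell", t, min(t + dwell, duration), center))
        t += dwell
        if t >= duration or probs.sum() == 0:
            if probs.sum() == 0:
                segments[-1] = ("dwell", segments[-1][1], duration, center)
                t = duration
            continue
        arm = arm_labels[rng.choice(len(arm_labels), p=probs)]
        dist = np.linalg.norm(anchors[arm] - anchors[center])
        transit = dist / params.transit_speed
        segments.append(("transit", t, min(t + transit, duration), arm))
        t += transit
        if t >= duration:
            break
        dwell = rng.gamma(
            params.arm_dwell_shape, params.arm_dwell_mean / params.arm_dwell_shape
        )
        segments.append(("dwell", t, min(t + dwell, duration), arm))
        t += dwell
        if t >= duration:
            break
        segments.append(("transit", t, min(t + transit, duration), center))
        t += transit

    # --- position samples -------------------------------------------------
    n_pos = round(duration * config.position_rate)
    t_pos = np.arange(n_pos) / config.position_rate
    x = np.zeros(n_pos)
    y = np.zeros(n_pos)
    jit_x = _ar1_noise(n_pos, params.jitter_sd, params.jitter_tau, config.position_rate, rng)
    jit_y = _ar1_noise(n_pos, params.jitter_sd, params.jitter_tau, config.position_rate, rng)
    prev_anchor = anchors[center]
    clip = min(2.0, params.jitter_sd * 2)
    for kind, t0, t1, label in segments:
        m = (t_pos >= t0) & (t_pos < t1)
        if not m.any():
            continue
        target = anchors[label]
        if kind == "dwell":
            x[m] = target[0] + np.clip(jit_x[m], -clip, clip)
            y[m] = target[1] + np.clip(jit_y[m], -clip, clip)
            prev_anchor = target
        else:
            frac = (t_pos[m] - t0) / max(t1 - t0, 1e-9)
            x[m] = prev_anchor[0] + frac * (target[0] - prev_anchor[0])
            y[m] = prev_anchor[1] + frac * (target[1] - prev_anchor[1])
    valid = rng.random(n_pos) >= params.invalid_fraction
    x[~valid] = np.nan
    y[~valid] = np.nan
    position = _tracking.PositionTrack(t_pos, x, y, config.position_rate, valid)

    # --- bouted event traces ---------------------------------------------
    n_ev = round(duration * config.event_rate)
    t_ev = np.arange(n_ev) / config.event_rate
    wheel = np.zeros(n_ev)
    lick = np.zeros(n_ev)
    run_bouts: list[tuple[float, float]] = []
    lick_bouts: list[tuple[float, float]] = []
    drawn_run: list[float] = []
    drawn_lick: list[float] = []

    def windows(label: str):
        return [(t0, t1) for kind, t0, t1, lab in segments if kind == "dwell" and lab == label]

    for w0, w1 in windows("wheel"):
        cursor = w0
        while True:
            start = cursor + rng.exponential(params.run_ibi_mean)
            if start >= w1:
                break
            dur = rng.gamma(params.run_bout_shape, params.run_bout_mean / params.run_bout_shape)
            drawn_run.append(dur)
            end = min(start + dur, w1)
            i0, i1 = round(start * config.event_rate), round(end * config.event_rate)
            if i1 > i0:
                speeds = params.run_speed_mean + _ar1_noise(
                    i1 - i0, params.run_speed_sd, 0.5, config.event_rate, rng
                )
                wheel[i0:i1] = np.maximum(speeds, _bouts.RUN_SPEED_THRESHOLD_CM_S + 2.0)
                run_bouts.append((start, end))
            cursor = end

    for w0, w1 in windows("HPF"):
        cursor = w0
        while True:
            start = cursor + rng.exponential(params.lick_ibi_mean)
            if start >= w1:
                break
            dur = rng.gamma(params.lick_bout_shape, params.lick_bout_mean / params.lick_bout_shape)
            drawn_lick.append(dur)
            end = min(start + dur, w1)
            if end > start and params.lick_rate > 0:
                times = start + np.arange(0, end - start, 1.0 / params.lick_rate)
                times = times + rng.uniform(0, 0.02, size=len(times))
                n_contact = max(1, round(params.lick_contact_duration * config.event_rate))
                for lt in times:
                    i0 = round(lt * config.event_rate)
                    lick[i0 : min(i0 + n_contact, n_ev)] = 1.0
                lick_bouts.append((start, end))
            cursor = end

    return SyntheticSession(
        mouse_id=f"mouse_{mouse_index:02d}",
        config=config,
        position=position,
        wheel_speed=_bouts.EventTrace(t_ev, wheel, config.event_rate),
        lick_contact=_bouts.EventTrace(t_ev, lick, config.event_rate),
        true_run_bouts=run_bouts,
        true_lick_bouts=lick_bouts,
        drawn_run_durations=drawn_run,
        drawn_lick_durations=drawn_lick,
        mouse_index=mouse_index,
    )


def xy_speed(position: _tracking.PositionTrack) -> np.ndarray:
    """Maze speed in the xy plane (arena units/s) from consecutive samples.

    Invalid (NaN) samples are linearly interpolated before differencing so
    tracking dropouts do not create spurious speed spikes.
    """
    idx = np.arange(len(position), dtype=float)
    valid = position.valid & np.isfinite(position.x) & np.isfinite(position.y)
    x = np.interp(idx, idx[valid], position.x[valid])
    y = np.interp(idx, idx[valid], position.y[valid])
    speed = np.hypot(np.diff(x), np.diff(y)) * position.rate
    return np.concatenate([[0.0], speed])


def generate_photometry(
    session: SyntheticSession,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
    photo: PhotometryParams | None = None,
    mouse_slopes: np.ndarray | None = None,
) -> SyntheticSession:
    """Fill the photometry channels of a behavior session from the model equation.

    latent = β₀ + Σ (β_k + b_ki)·x_k + ε over the kernel-convolved, z-scored
    behavioral regressors and the z-scored 405 trace; both raw channels are the
    latent (465) or artifact (405) around a positive baseline, multiplied by
    the triple-exponential bleach envelope.
    """
    photo = photo or PhotometryParams()
    rng = rng if rng is not None else mouse_rng(
        session.config.rng_seed + 1, session.mouse_index
    )
    if mouse_slopes is None:
        if truth.random_slopes is not None:
            mouse_slopes = truth.random_slopes[session.mouse_index]
        else:
            mouse_slopes = np.zeros(4)
    mouse_slopes = np.asarray(mouse_slopes, dtype=float)

    cfg = session.config
    rate = cfg.photometry_rate
    n = round(cfg.session_duration * rate)
    t = np.arange(n) / rate

    artifact = _ar1_noise(n, photo.artifact_sd, photo.artifact_tau, rate, rng)
    noise405 = photo.noise_405_sd * rng.standard_normal(n)
    ch405_pre = photo.baseline_405 + artifact + noise405
    iso_fluct = artifact + noise405
    iso_sd = iso_fluct.std()
    iso_z = (
        (iso_fluct - iso_fluct.mean()) / iso_sd if iso_sd > 0 else np.zeros(n)
    )

    kernel = _encoding.build_kernel(truth.gcamp_half_life, rate=rate)
    regs = _encoding.session_regressors(
        xy_speed(session.position),
        session.wheel_speed,
        session.lick_contact,
        None,
        n,
        rate=rate,
        kernel=kernel,
    )
    X = np.column_stack(
        [
            regs["xy"].to_numpy(),
            regs["wheel"].to_numpy(),
            regs["licking"].to_numpy(),
            iso_z,
        ]
    )
    eps = truth.sigma_eps * rng.standard_normal(n)
    latent = truth.beta0 + X @ (truth.betas + mouse_slopes) + eps

    env = truth.bleach_envelope(t)
    session.photo_t = t
    session.photo_465 = env * (photo.baseline_465 + photo.scale_465 * latent)
    session.photo_405 = env * ch405_pre
    session.latent = latent
    session.truth = truth
    return session


def generate_cohort(
    config: CohortConfig,
    truth: GroundTruth | None = None,
    behavior: BehaviorParams | None = None,
    photo: PhotometryParams | None = None,
    with_photometry: bool = True,
) -> tuple[list[SyntheticSession], GroundTruth]:
    """Generate all mice of a cohort; draws random slopes if truth lacks them."""
    truth = truth or GroundTruth()
    if truth.random_slopes is None:
        slope_rng = np.random.default_rng(config.rng_seed)
        truth = dataclasses.replace(
            truth,
            random_slopes=slope_rng.standard_normal((config.n_mice, 4))
            * np.asarray(truth.sigma_b),
        )
    sessions = []
    for i in range(config.n_mice):
        s = generate_behavior(config, behavior, mouse_index=i)
        if with_photometry:
            generate_photometry(
                s,
                truth,
                rng=mouse_rng(config.rng_seed + 1, i),
                photo=photo,
            )
        sessions.append(s)
    return sessions, truth


# ---------------------------------------------------------------------------
# session directory IO (plain CSV + JSON)


def write_session(directory: str | pathlib.Path, session: SyntheticSession) -> pathlib.Path:
    d = pathlib.Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    cfg = session.config
    manifest = {
        "mouse_id": session.mouse_id,
        "mouse_index": session.mouse_index,
        "rates": {
            "position": cfg.position_rate,
            "event": cfg.event_rate,
            "photometry": cfg.photometry_rate,
        },
        "session_duration": cfg.session_duration,
        "maze_kind": cfg.maze_kind,
        "rng_seed": cfg.rng_seed,
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=1))
    pos = session.position
    pd.DataFrame({"t": pos.t, "x": pos.x, "y": pos.y}).to_csv(d / "position.csv", index=False)
    pd.DataFrame({"t": session.wheel_speed.t, "speed": session.wheel_speed.values}).to_csv(
        d / "wheel.csv", index=False
    )
    pd.DataFrame(
        {"t": session.lick_contact.t, "contact": session.lick_contact.values.astype(int)}
    ).to_csv(d / "lick.csv", index=False)
    if session.photo_465 is not None:
        pd.DataFrame(
            {"t": session.photo_t, "ch465": session.photo_465, "ch405": session.photo_405}
        ).to_csv(d / "photometry.csv", index=False)
    if session.truth is not None:
        (d / "truth.json").write_text(json.dumps(session.truth.to_dict(), indent=1))
    return d


def read_session(directory: str | pathlib.Path) -> SyntheticSession:
    d = pathlib.Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    cfg = CohortConfig(
        n_mice=1,
        session_duration=manifest["session_duration"],
        position_rate=manifest["rates"]["position"],
        event_rate=manifest["rates"]["event"],
        photometry_rate=manifest["rates"]["photometry"],
        maze_kind=manifest["maze_kind"],
        rng_seed=manifest["rng_seed"],
    )
    pos = pd.read_csv(d / "position.csv")
    wheel = pd.read_csv(d / "wheel.csv")
    lick = pd.read_csv(d / "lick.csv")
    session = SyntheticSession(
        mouse_id=manifest["mouse_id"],
        config=cfg,
        position=_tracking.PositionTrack(
            pos["t"].to_numpy(), pos["x"].to_numpy(), pos["y"].to_numpy(), cfg.position_rate
        ),
        wheel_speed=_bouts.EventTrace(
            wheel["t"].to_numpy(), wheel["speed"].to_numpy(), cfg.event_rate
        ),
        lick_contact=_bouts.EventTrace(
            lick["t"].to_numpy(), lick["contact"].to_numpy(), cfg.event_rate
        ),
        true_run_bouts=[],
        true_lick_bouts=[],
        drawn_run_durations=[],
        drawn_lick_durations=[],
        mouse_index=manifest.get("mouse_index", 0),
    )
    photo_path = d / "photometry.csv"
    if photo_path.exists():
        ph = pd.read_csv(photo_path)
        session.photo_t = ph["t"].to_numpy()
        session.photo_465 = ph["ch465"].to_numpy()
        session.photo_405 = ph["ch405"].to_numpy()
    truth_path = d / "truth.json"
    if truth_path.exists():
        session.truth = GroundTruth.from_dict(json.loads(truth_path.read_text()))
    return session
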