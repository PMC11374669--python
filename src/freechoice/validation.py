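"""Reference oracles and simulation harnesses used to validate the pipeline.

Contains deliberately naive, independent reference implementations (e.g. a
sample-by-sample bout scanner) plus the standard validation experiments:
bout-segmentation oracle equivalence, mixed-model parameter recovery at the
study scale (10 mice), null-calibration (type-I error) of the figure-level
tests, and photometry self-consistency checks.  Everything is seeded and
returns plain dictionaries of summary numbers.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from . import bouts as _bouts
from . import encoding as _encoding
from . import photometry as _photometry
from . import simulate as _simulate
from . import stats as _stats


# ---------------------------------------------------------------------------
# brute-force bout oracle


def brute_force_bouts(
    values: np.ndarray, t: np.ndarray, threshold: float, min_gap: float, rate: float
) -> list[tuple[int, int]]:
    """Naive sample-by-sample bout segmentation (reference implementation).

    Returns [first, last] sample index pairs.  A bout opens at a
    supra-threshold sample preceded by >= min_gap of quiet (or trace start)
    and closes at the last supra-threshold sample before >= min_gap of quiet
    (or trace end).
    """
    gap_bins = round(min_gap * rate)
    above = [v >= threshold for v in values]
    bouts: list[tuple[int, int]] = []
    i = 0
    n = len(values)
    current_start = None
    last_above = None
    quiet = gap_bins  # trace start counts as a long quiet period
    for i in range(n):
        if above[i]:
            if current_start is None:
                current_start = i
            elif quiet >= gap_bins:
                bouts.append((current_start, last_above))
                current_start = i
            last_above = i
            quiet = 0
        else:
            quiet += 1
    if current_start is not None:
        bouts.append((current_start, last_above))
    return bouts


def bout_oracle_agreement(
    n_traces: int = 1000,
    trace_len: int = 100,
    rate: float = 5.0,
    seed: int = 0,
) -> dict:
    """Fraction of random 5-Hz traces on which detect_bouts matches the oracle."""
    rng = np.random.default_rng(seed)
    params = _bouts.BoutParams.run()
    matches = 0
    for _ in range(n_traces):
        # mix of quiet, borderline and clearly supra-threshold samples
        values = rng.choice([0.0, 5.0, 10.0, 15.0], size=trace_len)
        t = np.arange(trace_len) / rate
        trace = _bouts.EventTrace(t, values, rate)
        got = [b.slice for b in _bouts.detect_bouts(trace, params, kind="run")]
        expected = [
            (a, b + 1)
            for a, b in brute_force_bouts(values, t, params.threshold, params.min_gap, rate)
        ]
        matches += got == expected
    return {"agreement": matches / n_traces, "n": n_traces}


# ---------------------------------------------------------------------------
# mixed-model parameter recovery at the study scale


def _session_fit_inputs(session: _simulate.SyntheticSession, kernel, bleach_stride: int = 5):
    """Pipeline regressors for one synthetic session (405 via dff bleach removal)."""
    t = session.photo_t
    model, _ = _photometry.fit_bleach(t[::bleach_stride], session.photo_405[::bleach_stride])
    iso_dff = _photometry.normalize(session.photo_405, "dff", f0=model.predict(t))
    regs = _encoding.session_regressors(
        _simulate.xy_speed(session.position),
        session.wheel_speed,
        session.lick_contact,
        iso_dff,
        len(t),
        rate=session.config.photometry_rate,
        kernel=kernel,
    )
    return regs


def recovery_simulation(
    n_cohorts: int = 50,
    n_mice: int = 10,
    session_duration: float = 600.0,
    seed: int = 0,
    truth: _simulate.GroundTruth | None = None,
) -> dict:
    """Parameter-recovery experiment for the random-slope encoding model.

    For each replicate cohort, synthetic sessions are generated, the package
    builds the kernel-convolved regressors from the raw behavior (and the
    bleach-corrected 405 trace), the model is fitted to the stored generative
    latent signal, and fixed-effect errors, 95% CI coverage and sign
    agreement (lick negative, wheel and xy positive) are recorded.
    """
    base_truth = truth or _simulate.GroundTruth()
    rep_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_cohorts)
    true_vec = np.concatenate([[base_truth.beta0], base_truth.betas])
    abs_errors = []
    covered = []
    signs_ok = []
    for rep_seed in rep_seeds:
        cfg = _simulate.CohortConfig(
            n_mice=n_mice, session_duration=session_duration, rng_seed=int(rep_seed)
        )
        sessions, truth_r = _simulate.generate_cohort(
            cfg, truth=dataclasses.replace(base_truth, random_slopes=None)
        )
        kernel = _encoding.build_kernel(
            truth_r.gcamp_half_life, rate=cfg.photometry_rate
        )
        frames, ys, groups = [], [], []
        for s in sessions:
            frames.append(_session_fit_inputs(s, kernel))
            ys.append(s.latent)
            groups.append(np.repeat(s.mouse_index, len(s.latent)))
        fit = _encoding.fit_lmem(
            pd.concat(frames, ignore_index=True),
            np.concatenate(ys),
            np.concatenate(groups),
        )
        est = fit.fe_params.to_numpy()
        ci = fit.conf_int()
        abs_errors.append(np.abs(est - true_vec))
        covered.append(
            (ci["lower"].to_numpy() <= true_vec) & (true_vec <= ci["upper"].to_numpy())
        )
        signs_ok.append(
            est[fit.fe_params.index.get_loc("licking")] < 0
            and est[fit.fe_params.index.get_loc("wheel")] > 0
            and est[fit.fe_params.index.get_loc("xy")] > 0
        )
    abs_errors = np.array(abs_errors)  # (reps, 5)
    covered = np.array(covered)
    return {
        "mean_abs_error": float(abs_errors.mean()),
        "mean_abs_error_per_coef": abs_errors.mean(axis=0).tolist(),
        "coef_names": ["const", "xy", "wheel", "licking", "iso405"],
        "ci_coverage": float(covered.mean()),
        "sign_agreement": float(np.mean(signs_ok)),
        "n_cohorts": n_cohorts,
        "n_cis": int(covered.size),
    }


# ---------------------------------------------------------------------------
# null calibration of the figure-level tests


def type1_error_rates(
    n_reps: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
    n_paired: int = 12,
    n_wilcoxon: int = 15,
    n_ks: int = 100,
) -> dict:
    """Simulated type-I error of paired t, Wilcoxon, KS and the RM-ANOVA
    interaction under Gaussian null data."""
    rng = np.random.default_rng(seed)
    rej = {"paired_t": 0, "wilcoxon": 0, "ks": 0, "rm_anova": 0}
    for _ in range(n_reps):
        a = rng.standard_normal(n_paired)
        b = rng.standard_normal(n_paired)
        rej["paired_t"] += _stats.paired_t(a, b).p < alpha
        aw = rng.standard_normal(n_wilcoxon)
        bw = rng.standard_normal(n_wilcoxon)
        rej["wilcoxon"] += _stats.wilcoxon_signed_rank(aw, bw).p < alpha
        x = rng.standard_normal(n_ks)
        y = rng.standard_normal(n_ks)
        rej["ks"] += _stats.ks_two_sample(x, y).p < alpha
        cells = rng.standard_normal((4, n_paired))
        rej["rm_anova"] += _stats.rm_anova_2x2(*cells).p < alpha
    return {k: v / n_reps for k, v in rej.items()} | {"n_reps": n_reps}


# ---------------------------------------------------------------------------
# photometry self-consistency


def bleach_self_consistency(n: int = 12000, rate: float = 20.0, seed: int = 0) -> dict:
    """Fit a pure triple exponential and report residual RMS / signal RMS."""
    t = np.arange(n) / rate
    truth = _simulate.GroundTruth()
    signal = 100.0 * truth.bleach_envelope(t) + 5.0
    _, corrected = _photometry.fit_bleach(t, signal)
    ratio = float(
        np.sqrt(np.mean(corrected**2)) / np.sqrt(np.mean(signal**2))
    )
    return {"residual_rms_ratio": ratio, "n": n}


def perievent_kernel_identity(rate: float = 20.0) -> dict:
    """A single kernel-shaped transient, peri-event-aligned, must reproduce
    the kernel segment exactly."""
    kernel = _encoding.build_kernel(rate=rate)
    n = 4000
    trace = np.zeros(n)
    event_idx = 1500
    trace[event_idx : event_idx + len(kernel.values)] = kernel.values
    t = np.arange(n) / rate
    peri = _photometry.align_events(trace, t, [t[event_idx]], (5.0, 30.0), rate)
    post = peri.rel_time >= 0
    expected = kernel.values[: post.sum()]
    err = float(np.max(np.abs(peri.mean[post] - expected)))
    return {"max_abs_error": err, "n": int(post.sum())}
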