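"""End-to-end orchestration: simulate → track → bouts → photometry → encode → stats.

Every stage writes plain CSV/JSON artifacts into a run directory and a
manifest records the seed, parameters, row counts and sha256 checksums so a
rerun with the same configuration is byte-identical for deterministic stages.
A stage failure aborts the run with the failing stage named; partial outputs
are preserved.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import bouts as _bouts
from . import encoding as _encoding
from . import photometry as _photometry
from . import simulate as _simulate
from . import stats as _stats
from . import tracking as _tracking

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException) -> None:
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


DEFAULT_PLAN = [
    {
        "name": "occupancy_wheel_vs_HPF",
        "test": "paired_t",
        "a": "occ_wheel",
        "b": "occ_HPF",
        "family": 2,
    },
    {
        "name": "roi_signal_wheel_vs_HPF",
        "test": "paired_t",
        "a": "sig_wheel",
        "b": "sig_HPF",
        "family": 2,
    },
    {
        "name": "run_vs_lick_bout_count",
        "test": "wilcoxon",
        "a": "run_bouts",
        "b": "lick_bouts",
        "family": 1,
    },
]


@dataclasses.dataclass
class RunConfig:
    out_dir: str
    cohort: _simulate.CohortConfig = dataclasses.field(
        default_factory=_simulate.CohortConfig
    )
    bout_gap: float = 1.0
    perievent_gap: float = 4.0  # quiet period for photometry-aligned bouts
    kernel_half_life: float = _encoding.GCAMP6S_HALF_LIFE_S
    kernel_duration: float = _encoding.DEFAULT_KERNEL_DURATION_S
    normalize_mode: str = "dff"  # bleach removal for encoding inputs
    plan: Sequence[Mapping] = dataclasses.field(default_factory=lambda: DEFAULT_PLAN)
    log_level: str = "INFO"

    @classmethod
    def from_json(cls, path: str | pathlib.Path) -> "RunConfig":
        d = json.loads(pathlib.Path(path).read_text())
        if "cohort" in d:
            d["cohort"] = _simulate.CohortConfig.from_dict(d["cohort"])
        return cls(**d)


def _sha256(path: pathlib.Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def run_pipeline(config: RunConfig) -> pathlib.Path:
    logging.basicConfig(level=config.log_level)
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.cohort.rng_seed,
        "cohort": config.cohort.to_dict(),
        "parameters": {
            "bout_gap": config.bout_gap,
            "perievent_gap": config.perievent_gap,
            "kernel_half_life": config.kernel_half_life,
            "kernel_duration": config.kernel_duration,
            "normalize_mode": config.normalize_mode,
        },
        "stages": {},
    }

    stage = "simulate"
    try:
        sessions, truth = _simulate.generate_cohort(config.cohort)
        sim_dir = out / "sessions"
        for s in sessions:
            _simulate.write_session(sim_dir / s.mouse_id, s)
        _record(manifest, stage, sim_dir, n_rows=len(sessions))

        stage = "track"
        geom = _tracking.default_geometry(config.cohort.maze_kind)
        occ_rows, visit_rows = [], []
        labeled = {}
        dropped = 0
        for s in sessions:
            smoothed = _tracking.smooth_and_interpolate(s.position)
            dropped += int((~s.position.valid).sum())
            lab = _tracking.assign_rois(smoothed, geom)
            labeled[s.mouse_id] = lab
            occ = _tracking.occupancy_times(lab, geom)
            occ_rows.append({"mouse": s.mouse_id, **occ.to_dict()})
            for v in _tracking.compute_visits(lab):
                visit_rows.append(
                    {
                        "mouse": s.mouse_id,
                        "roi": v.roi,
                        "t_enter": v.t_enter,
                        "t_exit": v.t_exit,
                        "duration": v.duration,
                    }
                )
        occ_df = pd.DataFrame(occ_rows)
        occ_df.to_csv(out / "occupancy.csv", index=False)
        pd.DataFrame(visit_rows).to_csv(out / "visits.csv", index=False)
        logger.info("track: %d sessions, %d invalid samples interpolated", len(sessions), dropped)
        _record(manifest, stage, out / "occupancy.csv", n_rows=len(occ_df))
        _record(manifest, stage + "_visits", out / "visits.csv", n_rows=len(visit_rows))

        stage = "bouts"
        bout_rows = []
        bout_summary = {}
        for s in sessions:
            wheel5 = _bouts.bin_trace(s.wheel_speed, 5.0, "mean")
            lick5 = _bouts.bin_trace(s.lick_contact, 5.0, "any")
            run_bouts = _bouts.detect_bouts(
                wheel5, _bouts.BoutParams.run(config.bout_gap), kind="run"
            )
            lick_bouts = _bouts.detect_bouts(
                lick5, _bouts.BoutParams.lick(config.bout_gap), kind="lick"
            )
            for name, bts in (("run", run_bouts), ("lick", lick_bouts)):
                for b in bts:
                    bout_rows.append(
                        {
                            "mouse": s.mouse_id,
                            "trace": name,
                            "t_start": b.t_start,
                            "t_end": b.t_end,
                            "duration": b.duration,
                            "amount": b.amount,
                        }
                    )
            total_licks = int(lick5.values.sum())
            bout_summary[s.mouse_id] = {
                "run_bouts": len(run_bouts),
                "lick_bouts": len(lick_bouts),
                "volume_ul": _bouts.licks_to_volume(total_licks),
                "run_bout_starts": [b.t_start for b in run_bouts],
            }
        pd.DataFrame(bout_rows).to_csv(out / "bouts.csv", index=False)
        _record(manifest, stage, out / "bouts.csv", n_rows=len(bout_rows))

        stage = "photometry"
        corrected = {}
        roi_rows = []
        peri_rows = []
        for s in sessions:
            trace = _photometry.PhotometryTrace(
                s.photo_t, s.photo_465, s.photo_405, config.cohort.photometry_rate
            )
            prep = _photometry.preprocess(trace, mode=config.normalize_mode)
            z465 = _zscore(prep.trace.ch465)
            z405 = _zscore(prep.trace.ch405)
            corrected[s.mouse_id] = (z465, z405)
            roi = _photometry.roi_average(z465, s.photo_t, labeled[s.mouse_id])
            roi_rows.append({"mouse": s.mouse_id, **roi.to_dict()})
            starts = bout_summary[s.mouse_id]["run_bout_starts"]
            if starts:
                try:
                    peri = _photometry.align_events(
                        z465, s.photo_t, starts, (5.0, 10.0), trace.rate
                    )
                    for ev_i, row in enumerate(peri.matrix):
                        for rt, val in zip(peri.rel_time[::4], row[::4]):
                            peri_rows.append(
                                {
                                    "mouse": s.mouse_id,
                                    "event_id": ev_i,
                                    "rel_time": rt,
                                    "value": val,
                                }
                            )
                except _photometry.PhotometryError:
                    pass
        roi_df = pd.DataFrame(roi_rows)
        roi_df.to_csv(out / "roimeans.csv", index=False)
        pd.DataFrame(peri_rows).to_csv(out / "perievent.csv", index=False)
        _record(manifest, stage, out / "roimeans.csv", n_rows=len(roi_df))

        stage = "encode"
        kernel = _encoding.build_kernel(
            config.kernel_half_life, config.kernel_duration, config.cohort.photometry_rate
        )
        frames = []
        responses = []
        groups = []
        for s in sessions:
            z465, z405 = corrected[s.mouse_id]
            regs = _encoding.session_regressors(
                _simulate.xy_speed(s.position),
                s.wheel_speed,
                s.lick_contact,
                z405,
                len(z465),
                rate=config.cohort.photometry_rate,
                kernel=kernel,
            )
            frames.append(regs)
            responses.append(z465)
            groups.append(np.repeat(s.mouse_id, len(regs)))
        regset = _encoding.RegressorSet(
            pd.concat(frames, ignore_index=True), np.concatenate(groups)
        )
        fit = _encoding.fit_lmem(regset, np.concatenate(responses))
        (out / "fit.json").write_text(json.dumps(fit.to_dict(), indent=1))
        reg_out = regset.data.copy()
        reg_out["mouse"] = regset.groups
        reg_out.iloc[:: max(1, len(reg_out) // 20000)].to_csv(
            out / "regressors.csv", index=False
        )
        _record(manifest, stage, out / "fit.json", n_rows=fit.nobs)

        stage = "stats"
        table = occ_df.set_index("mouse")
        summary = pd.DataFrame(
            {
                "occ_wheel": table.get("wheel", pd.Series(dtype=float)),
                "occ_HPF": table.get("HPF", pd.Series(dtype=float)),
                "sig_wheel": roi_df.set_index("mouse").get("wheel"),
                "sig_HPF": roi_df.set_index("mouse").get("HPF"),
                "run_bouts": pd.Series(
                    {m: v["run_bouts"] for m, v in bout_summary.items()}, dtype=float
                ),
                "lick_bouts": pd.Series(
                    {m: v["lick_bouts"] for m, v in bout_summary.items()}, dtype=float
                ),
            }
        )
        results = run_stats_plan(summary, config.plan)
        (out / "stats.json").write_text(json.dumps(results, indent=1))
        _record(manifest, stage, out / "stats.json", n_rows=len(results))
    except Exception as exc:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise PipelineStageError(stage, exc) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def run_stats_plan(summary: pd.DataFrame, plan: Sequence[Mapping]) -> dict:
    """Run the configured per-comparison tests on a per-mouse summary table."""
    results: dict = {}
    for item in plan:
        a = summary[item["a"]].dropna()
        b = summary[item["b"]].dropna()
        common = a.index.intersection(b.index)
        a, b = a[common].to_numpy(), b[common].to_numpy()
        family = int(item.get("family", 1))
        try:
            if item["test"] == "paired_t":
                res = _stats.paired_t(a, b)
                entry = {"t": res.t, "df": res.df, "p": res.p}
            elif item["test"] == "wilcoxon":
                res = _stats.wilcoxon_signed_rank(a, b)
                entry = {"T": res.T, "p": res.p, "exact": res.exact}
            elif item["test"] == "ks":
                res = _stats.ks_two_sample(a, b)
                entry = {"D": res.D, "p": res.p}
            else:
                raise _stats.StatsError(f"unknown test {item['test']!r}")
            entry["p_bonferroni"] = _stats.bonferroni(entry["p"], family)
            entry["n"] = int(len(a))
        except _stats.StatsError as exc:
            entry = {"error": str(exc)}
        results[item["name"]] = entry
    return results


def _record(manifest: dict, stage: str, path: pathlib.Path, n_rows: int) -> None:
    entry = {"path": str(path), "n_rows": n_rows}
    if path.is_file():
        entry["sha256"] = _sha256(path)
    manifest["stages"][stage] = entry
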