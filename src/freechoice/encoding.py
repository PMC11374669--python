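"""Kernel-convolved regressors and the random-slope mixed-effects encoding model.

The orexin-neuron (HON) population calcium signal y (z-scored 465-nm trace) is
modeled as a linear mixed-effects model over kernel-convolved behavioral
regressors, with one free random slope per mouse for each regressor:

    y_ij = β₀ + Σ_k (β_k + b_ki) · x_kij + ε_ij,   b_ki ~ N(0, σ_k²),
    ε_ij ~ N(0, σ_ε²)

where i indexes mice, j samples, and x_k are maze (xy) speed, wheel speed and
lick contact convolved with a 60-s causal exponential decay kernel whose
half-life is the GCaMP6s fluorescence half-life (1.796 s), z-scored, plus the
z-scored 405-nm isosbestic trace (not convolved).  Random slopes are mutually
independent (diagonal covariance) and there is no per-mouse random intercept
by default (configurable).

Estimation is restricted maximum likelihood (REML) with the residual variance
and fixed effects profiled out, so only the variance ratios λ_k = σ_k²/σ_ε²
are optimized.  Per-group Woodbury identities on precomputed sufficient
statistics make each likelihood evaluation O(groups · q³), independent of the
number of samples.  Fixed-effect inference uses Satterthwaite degrees of
freedom; variance explained is summarized by Nakagawa's marginal/conditional
R² with the random-slope variance contribution Σ_k σ̂_k² · mean(x_k²).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, signal
from scipy import stats as sps

from . import bouts as _bouts

logger = logging.getLogger(__name__)

#: GCaMP6s fluorescence half-life in seconds (decay of the indicator response).
GCAMP6S_HALF_LIFE_S = 1.796
DEFAULT_KERNEL_DURATION_S = 60.0

REGRESSOR_NAMES = ("xy", "wheel", "licking", "iso405")


class EncodingError(ValueError):
    pass


class DegenerateRegressorError(EncodingError):
    """A regressor has zero variance (behavior never occurred); drop the column."""


# ---------------------------------------------------------------------------
# kernel


@dataclasses.dataclass(frozen=True)
class Kernel:
    """Causal exponential decay kernel k(τ) = 2^(−τ/half_life), peak 1 at τ=0."""

    half_life: float
    duration: float
    rate: float
    t: np.ndarray
    values: np.ndarray

    @property
    def decay_rate(self) -> float:
        """Equivalent rate constant λ = ln 2 / half_life (s⁻¹)."""
        return np.log(2.0) / self.half_life

    def half_time(self) -> float:
        """Lag at which the kernel falls to half its peak (log-space interpolation)."""
        logv = np.log2(self.values)
        i = int(np.searchsorted(-logv, 1.0))
        if i == 0:
            return 0.0
        frac = (-1.0 - logv[i - 1]) / (logv[i] - logv[i - 1])
        return float(self.t[i - 1] + frac * (self.t[i] - self.t[i - 1]))


def build_kernel(
    half_life: float = GCAMP6S_HALF_LIFE_S,
    duration: float = DEFAULT_KERNEL_DURATION_S,
    rate: float = 20.0,
) -> Kernel:
    """60-s decay kernel sampled at the regressor rate, peak normalized to 1."""
    if half_life <= 0 or duration <= 0:
        raise EncodingError("half_life and duration must be positive")
    if duration < half_life:
        warnings.warn("kernel duration shorter than half-life: kernel truncates early")
    t = np.arange(0.0, duration + 0.5 / rate, 1.0 / rate)
    values = np.power(2.0, -t / half_life)
    return Kernel(half_life, duration, rate, t, values)


def convolve_regressor(
    trace: np.ndarray,
    kernel: Kernel,
    zscore: bool = True,
) -> np.ndarray:
    """Causal convolution truncated to the trace length, then z-scored."""
    trace = np.asarray(trace, dtype=float)
    conv = signal.fftconvolve(trace, kernel.values)[: len(trace)]
    if not zscore:
        return conv
    sd = conv.std()
    if sd == 0:
        raise DegenerateRegressorError(
            "convolved regressor has zero variance; drop this column"
        )
    return (conv - conv.mean()) / sd


# ---------------------------------------------------------------------------
# regressor construction


@dataclasses.dataclass
class RegressorSet:
    """Convolved, z-scored predictors aligned to the 20-Hz response timebase."""

    data: pd.DataFrame  # columns: REGRESSOR_NAMES
    groups: np.ndarray  # mouse id per sample

    def __post_init__(self) -> None:
        self.groups = np.asarray(self.groups)
        if len(self.data) != len(self.groups):
            raise EncodingError("regressors and groups must have equal lengths")


def session_regressors(
    xy_speed_5hz: np.ndarray,
    wheel_500hz: _bouts.EventTrace,
    lick_500hz: _bouts.EventTrace,
    iso405_z: np.ndarray | None,
    n_samples: int,
    rate: float = 20.0,
    kernel: Kernel | None = None,
    allow_flat: bool = True,
) -> pd.DataFrame:
    """Build one session's regressor columns at the photometry rate.

    The 5-Hz maze speed is upsampled by sample-and-hold; the 500-Hz event
    traces are binned (mean for speed, any for contact).  The three behavioral
    columns are kernel-convolved and z-scored; the isosbestic column is
    z-scored without convolution.  A behavior that never occurs in the session
    yields a flat column; with ``allow_flat`` it contributes an all-zero
    regressor (the cross-session fit decides whether the column is usable),
    otherwise it raises :class:`DegenerateRegressorError`.
    """
    kernel = kernel or build_kernel(rate=rate)
    hold = max(1, round(rate / 5.0))
    xy20 = np.repeat(np.asarray(xy_speed_5hz, dtype=float), hold)[:n_samples]
    xy20 = np.pad(xy20, (0, n_samples - len(xy20)), mode="edge")
    wheel20 = _bouts.bin_trace(wheel_500hz, rate, "mean").values[:n_samples]
    lick20 = _bouts.bin_trace(lick_500hz, rate, "any").values[:n_samples]

    def _column(raw: np.ndarray, name: str) -> np.ndarray:
        try:
            return convolve_regressor(raw, kernel)
        except DegenerateRegressorError:
            if not allow_flat:
                raise
            logger.warning("%s never occurs in this session; regressor set to 0", name)
            return np.zeros(len(raw))

    cols = {
        "xy": _column(xy20, "xy"),
        "wheel": _column(wheel20, "wheel"),
        "licking": _column(lick20, "licking"),
    }
    if iso405_z is not None:
        iso = np.asarray(iso405_z, dtype=float)[:n_samples]
        sd = iso.std()
        if sd == 0:
            raise DegenerateRegressorError("isosbestic trace has zero variance")
        cols["iso405"] = (iso - iso.mean()) / sd
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# REML machinery


class _GroupStats:
    """Per-group sufficient statistics for the profiled REML likelihood."""

    __slots__ = ("n", "C", "ZtU", "ZtZ", "X", "Z", "y")

    def __init__(self, X: np.ndarray, Z: np.ndarray, y: np.ndarray) -> None:
        U = np.column_stack([X, y])
        self.n = len(y)
        self.C = U.T @ U
        self.ZtU = Z.T @ U if Z.shape[1] else np.zeros((0, U.shape[1]))
        self.ZtZ = Z.T @ Z if Z.shape[1] else np.zeros((0, 0))
        self.X = X
        self.Z = Z
        self.y = y


def _whitened_crossprods(groups: Sequence[_GroupStats], lam: np.ndarray):
    """Σ U' V⁻¹ U (V in residual-variance units) and Σ log|I + ZΛZ'| per group."""
    q = len(lam)
    sq = np.sqrt(lam)
    M = np.zeros_like(groups[0].C)
    logdet = 0.0
    for g in groups:
        if q == 0:
            M += g.C
            continue
        S = np.eye(q) + (sq[:, None] * g.ZtZ) * sq[None, :]
        sign, ld = np.linalg.slogdet(S)
        logdet += ld
        B = sq[:, None] * g.ZtU
        M += g.C - B.T @ np.linalg.solve(S, B)
    return M, logdet


def _profile(groups: Sequence[_GroupStats], lam: np.ndarray, n_total: int, p: int):
    M, logdetA = _whitened_crossprods(groups, lam)
    XtViX = M[:p, :p]
    XtViy = M[:p, -1]
    ytViy = M[-1, -1]
    beta = np.linalg.solve(XtViX, XtViy)
    rss = max(float(ytViy - XtViy @ beta), 1e-300)
    sign, ld_xtvix = np.linalg.slogdet(XtViX)
    m2l = logdetA + (n_total - p) * np.log(rss / (n_total - p)) + ld_xtvix
    return m2l, beta, rss, XtViX, logdetA


def _reml_m2l_full(
    groups: Sequence[_GroupStats],
    theta: np.ndarray,
    n_total: int,
    p: int,
) -> float:
    """−2 · REML log-likelihood (up to constants) at variance components θ.

    θ = (σ₁², …, σ_q², σ_ε²) on the natural scale.
    """
    sig2 = float(theta[-1])
    lam = np.maximum(np.asarray(theta[:-1], dtype=float), 0.0) / sig2
    M, logdetA = _whitened_crossprods(groups, lam)
    XtViX = M[:p, :p]
    XtViy = M[:p, -1]
    ytViy = M[-1, -1]
    beta = np.linalg.solve(XtViX, XtViy)
    rss = float(ytViy - XtViy @ beta)
    sign, ld_xtvix = np.linalg.slogdet(XtViX)
    return (n_total - p) * np.log(sig2) + logdetA + rss / sig2 + ld_xtvix


# ---------------------------------------------------------------------------
# model / results


class KernelEncodingModel:
    """Random-slope LMEM predicting a normalized photometry signal.

    Parameters
    ----------
    response:
        z-scored response samples, all mice concatenated.
    regressors:
        DataFrame of fixed-effect columns (already convolved and z-scored).
    groups:
        Mouse id per sample.
    random_slopes:
        Columns that get a per-mouse random slope (default: all regressors).
    random_intercept:
        Add a per-mouse random intercept.  The default follows the model
        equation, which has none.
    """

    def __init__(
        self,
        response: np.ndarray,
        regressors: pd.DataFrame,
        groups: np.ndarray,
        random_slopes: Sequence[str] | None = None,
        random_intercept: bool = False,
    ) -> None:
        self.response = np.asarray(response, dtype=float)
        self.regressors = pd.DataFrame(regressors).reset_index(drop=True)
        self.groups = np.asarray(groups)
        if not (len(self.response) == len(self.regressors) == len(self.groups)):
            raise EncodingError("response, regressors and groups lengths differ")
        self.exog_names = ["const"] + list(self.regressors.columns)
        if random_slopes is None:
            random_slopes = list(self.regressors.columns)
        unknown = set(random_slopes) - set(self.regressors.columns)
        if unknown:
            raise EncodingError(f"unknown random-slope columns {sorted(unknown)}")
        self.random_slopes = list(random_slopes)
        self.random_intercept = random_intercept
        self.re_names = (["intercept"] if random_intercept else []) + self.random_slopes

        self.group_labels = pd.unique(self.groups)
        if len(self.group_labels) < 2:
            raise EncodingError("need at least 2 mice to fit mouse-level random effects")
        n, p = len(self.response), len(self.exog_names)
        if n < 10 * (p + len(self.re_names) + 1):
            raise EncodingError("need at least 10x more samples than parameters")
        flat = [c for c in self.regressors.columns if self.regressors[c].std() == 0]
        if flat:
            raise DegenerateRegressorError(
                f"regressor(s) {flat} have zero variance; drop the column(s)"
            )

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        response_col: str,
        regressor_cols: Sequence[str],
        group_col: str,
        **kwargs,
    ) -> "KernelEncodingModel":
        return cls(
            data[response_col].to_numpy(),
            data[list(regressor_cols)],
            data[group_col].to_numpy(),
            **kwargs,
        )

    @classmethod
    def from_regressor_set(
        cls, regressors: RegressorSet, response: np.ndarray, **kwargs
    ) -> "KernelEncodingModel":
        return cls(response, regressors.data, regressors.groups, **kwargs)

    # -- design ------------------------------------------------------------

    def _design(self):
        X = np.column_stack(
            [np.ones(len(self.response))] + [self.regressors[c].to_numpy() for c in self.regressors]
        )
        z_cols = []
        if self.random_intercept:
            z_cols.append(np.ones(len(self.response)))
        z_cols += [self.regressors[c].to_numpy() for c in self.random_slopes]
        Z = np.column_stack(z_cols) if z_cols else np.zeros((len(self.response), 0))
        return X, Z

    def fit(self, start: np.ndarray | None = None) -> "KernelEncodingResults":
        """REML fit.  A variance component estimated at zero yields a
        converged-with-boundary warning, not a failure."""
        X, Z = self._design()
        y = self.response
        p, q = X.shape[1], Z.shape[1]
        n = len(y)
        stats = []
        for lab in self.group_labels:
            m = self.groups == lab
            stats.append(_GroupStats(X[m], Z[m], y[m]))

        if q:
            s0 = np.full(q, 0.3) if start is None else np.sqrt(np.asarray(start))

            def objective(s: np.ndarray) -> float:
                return _profile(stats, s**2, n, p)[0]

            sol = optimize.minimize(
                objective,
                s0,
                method="L-BFGS-B",
                bounds=[(0.0, 1e4)] * q,
                options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-10},
            )
            lam = sol.x**2
            converged = bool(sol.success)
        else:
            lam = np.zeros(0)
            converged = True

        m2l, beta, rss, XtViX, logdetA = _profile(stats, lam, n, p)
        sigma2 = rss / (n - p)
        cov_beta = sigma2 * np.linalg.inv(XtViX)
        boundary = bool(q and np.any(lam < 1e-8))
        if boundary:
            warnings.warn(
                "a random-slope variance was estimated at the boundary (0); "
                "the fit converged but is singular",
                RuntimeWarning,
            )
        return KernelEncodingResults(
            model=self,
            fe_params=pd.Series(beta, index=self.exog_names),
            cov_fe=cov_beta,
            lam=lam,
            sigma2=sigma2,
            m2l_profiled=m2l,
            converged=converged,
            boundary=boundary,
            _stats=stats,
        )


@dataclasses.dataclass
class KernelEncodingResults:
    """REML estimates, uncertainties and diagnostics of the encoding model."""

    model: KernelEncodingModel
    fe_params: pd.Series
    cov_fe: np.ndarray
    lam: np.ndarray  # variance ratios σ_k²/σ_ε²
    sigma2: float  # residual variance σ_ε²
    m2l_profiled: float
    converged: bool
    boundary: bool
    _stats: list = dataclasses.field(repr=False, default=None)
    _satt: pd.DataFrame | None = dataclasses.field(default=None, repr=False)

    # -- basic quantities --------------------------------------------------

    @property
    def nobs(self) -> int:
        return len(self.model.response)

    @property
    def ngroups(self) -> int:
        return len(self.model.group_labels)

    @property
    def sigma_eps(self) -> float:
        return float(np.sqrt(self.sigma2))

    @property
    def vc(self) -> pd.Series:
        """Random-effect variance estimates σ_k² per random-slope column."""
        return pd.Series(self.lam * self.sigma2, index=self.model.re_names)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_fe)), index=self.fe_params.index)

    @property
    def tvalues(self) -> pd.Series:
        return self.fe_params / self.bse

    # -- random effects / fitted -------------------------------------------

    @property
    def random_effects(self) -> pd.DataFrame:
        """Per-mouse BLUPs of the random slopes."""
        q = len(self.lam)
        beta = self.fe_params.to_numpy()
        rows = {}
        sq = np.sqrt(self.lam)
        for lab, g in zip(self.model.group_labels, self._stats):
            if q == 0:
                rows[lab] = np.zeros(0)
                continue
            Ztr = g.ZtU[:, -1] - g.ZtU[:, :-1] @ beta
            S = np.eye(q) + (sq[:, None] * g.ZtZ) * sq[None, :]
            ZtAinv_r = Ztr - g.ZtZ @ (sq * np.linalg.solve(S, sq * Ztr))
            rows[lab] = self.lam * ZtAinv_r
        return pd.DataFrame(rows, index=self.model.re_names).T

    @property
    def fittedvalues(self) -> np.ndarray:
        """Conditional fit Xβ̂ + Z b̂ in the original sample order."""
        X, Z = self.model._design()
        out = X @ self.fe_params.to_numpy()
        if Z.shape[1]:
            re = self.random_effects
            for lab in self.model.group_labels:
                m = self.model.groups == lab
                out[m] += Z[m] @ re.loc[lab].to_numpy()
        return out

    @property
    def resid(self) -> np.ndarray:
        return self.model.response - self.fittedvalues

    # -- inference ---------------------------------------------------------

    def satterthwaite(self) -> pd.DataFrame:
        """Per-coefficient t, Satterthwaite df and two-tailed p.

        df_i = 2 v_i² / (∇v_i' A ∇v_i) where v_i(θ) is the coefficient
        variance as a function of the variance components θ and A is the
        asymptotic covariance of θ̂ (inverse observed REML information), both
        obtained by central finite differences.  A non-positive or non-finite
        df falls back to the normal approximation (df = ∞) with a warning.
        """
        if self._satt is not None:
            return self._satt
        X, _ = self.model._design()
        p = X.shape[1]
        n = self.nobs
        theta = np.concatenate([self.lam * self.sigma2, [self.sigma2]])
        d = len(theta)

        def var_beta(th: np.ndarray) -> np.ndarray:
            sig2 = th[-1]
            lam = np.maximum(th[:-1], 0.0) / sig2
            M, _ = _whitened_crossprods(self._stats, lam)
            return sig2 * np.diag(np.linalg.inv(M[:p, :p]))

        def nll(th: np.ndarray) -> float:
            return 0.5 * _reml_m2l_full(self._stats, th, n, p)

        steps = np.maximum(1e-4 * np.abs(theta), 1e-7 * self.sigma2)
        # gradient of each coefficient variance w.r.t. theta
        grads = np.zeros((p, d))
        for i in range(d):
            hi = theta.copy()
            lo = theta.copy()
            hi[i] += steps[i]
            lo[i] = max(lo[i] - steps[i], 0.0 if i < d - 1 else steps[i])
            grads[:, i] = (var_beta(hi) - var_beta(lo)) / (hi[i] - lo[i])
        # observed information of theta
        H = np.zeros((d, d))
        f0 = nll(theta)
        for i in range(d):
            hp = theta.copy(); hm = theta.copy()
            hp[i] += steps[i]; hm[i] -= steps[i]
            H[i, i] = (nll(hp) - 2 * f0 + nll(hm)) / steps[i] ** 2
            for j in range(i + 1, d):
                hpp = theta.copy(); hpm = theta.copy()
                hmp = theta.copy(); hmm = theta.copy()
                hpp[i] += steps[i]; hpp[j] += steps[j]
                hpm[i] += steps[i]; hpm[j] -= steps[j]
                hmp[i] -= steps[i]; hmp[j] += steps[j]
                hmm[i] -= steps[i]; hmm[j] -= steps[j]
                H[i, j] = H[j, i] = (
                    nll(hpp) - nll(hpm) - nll(hmp) + nll(hmm)
                ) / (4 * steps[i] * steps[j])
        try:
            A = np.linalg.pinv(H)
        except np.linalg.LinAlgError:  # pragma: no cover
            A = np.full((d, d), np.nan)

        v = np.diag(self.cov_fe)
        df = np.empty(p)
        for i in range(p):
            denom = grads[i] @ A @ grads[i]
            df[i] = 2.0 * v[i] ** 2 / denom if denom > 0 else np.inf
            if not np.isfinite(df[i]) or df[i] <= 0:
                warnings.warn(
                    "non-positive Satterthwaite df; using normal approximation",
                    RuntimeWarning,
                )
                df[i] = np.inf
        t = self.fe_params.to_numpy() / np.sqrt(v)
        pvals = 2.0 * sps.t.sf(np.abs(t), df)
        self._satt = pd.DataFrame(
            {"t": t, "df": df, "p": pvals}, index=self.fe_params.index
        )
        return self._satt

    @property
    def pvalues(self) -> pd.Series:
        return self.satterthwaite()["p"]

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Fixed-effect CIs using Satterthwaite t quantiles."""
        satt = self.satterthwaite()
        crit = sps.t.ppf(1 - alpha / 2, satt["df"].to_numpy())
        lo = self.fe_params.to_numpy() - crit * self.bse.to_numpy()
        hi = self.fe_params.to_numpy() + crit * self.bse.to_numpy()
        return pd.DataFrame({"lower": lo, "upper": hi}, index=self.fe_params.index)

    def nakagawa_r2(self) -> dict[str, float]:
        """Nakagawa marginal / conditional R² for the mixed model.

        var_fixed = Var(Xβ̂) over samples; var_random = Σ_k σ̂_k²·mean(z_k²)
        (random-slope extension of the intercept-only formula); the residual
        is σ̂_ε².
        """
        X, Z = self.model._design()
        var_fixed = float(np.var(X @ self.fe_params.to_numpy()))
        sig2_k = self.lam * self.sigma2
        var_random = float(np.sum(sig2_k * np.mean(Z**2, axis=0))) if Z.shape[1] else 0.0
        return nakagawa_from_variances(var_fixed, var_random, self.sigma2)

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        satt = self.satterthwaite()
        ci = self.conf_int()
        r2 = self.nakagawa_r2()
        lines = [
            "Random-slope mixed-effects encoding model (REML)",
            f"  observations: {self.nobs}   mice: {self.ngroups}   "
            f"converged: {self.converged}" + ("   [boundary]" if self.boundary else ""),
            f"  sigma_eps: {self.sigma_eps:.4f}   "
            f"R2 marginal: {r2['marginal']:.3f}   conditional: {r2['conditional']:.3f}",
            "",
            f"  {'coef':<10}{'est':>10}{'se':>10}{'t':>9}{'df':>9}{'p':>11}"
            f"{'[0.025':>10}{'0.975]':>10}",
        ]
        for name in self.fe_params.index:
            lines.append(
                f"  {name:<10}{self.fe_params[name]:>10.4f}{self.bse[name]:>10.4f}"
                f"{satt.loc[name, 't']:>9.3f}{satt.loc[name, 'df']:>9.1f}"
                f"{satt.loc[name, 'p']:>11.3g}"
                f"{ci.loc[name, 'lower']:>10.4f}{ci.loc[name, 'upper']:>10.4f}"
            )
        lines.append("")
        lines.append("  random-slope sd: " + "  ".join(
            f"{k}={np.sqrt(v):.4f}" for k, v in self.vc.items()
        ))
        return "\n".join(lines)

    def plot_coefficients(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ci = self.conf_int()
        names = [n for n in self.fe_params.index if n != "const"]
        est = self.fe_params[names]
        err = np.vstack([est - ci.loc[names, "lower"], ci.loc[names, "upper"] - est])
        ax.errorbar(names, est, yerr=err, fmt="o", capsize=3)
        ax.axhline(0.0, color="k", lw=0.5)
        ax.set_ylabel("fixed-effect weight (z-units)")
        return ax

    def to_dict(self) -> dict:
        satt = self.satterthwaite()
        ci = self.conf_int()
        r2 = self.nakagawa_r2()
        return {
            "fe_params": self.fe_params.to_dict(),
            "se": self.bse.to_dict(),
            "ci_lower": ci["lower"].to_dict(),
            "ci_upper": ci["upper"].to_dict(),
            "t": satt["t"].to_dict(),
            "df": satt["df"].to_dict(),
            "p": satt["p"].to_dict(),
            "vc": self.vc.to_dict(),
            "sigma_eps": self.sigma_eps,
            "r2_marginal": r2["marginal"],
            "r2_conditional": r2["conditional"],
            "nobs": self.nobs,
            "ngroups": self.ngroups,
            "converged": self.converged,
            "boundary": self.boundary,
        }


# ---------------------------------------------------------------------------
# functional surface


def fit_lmem(
    regressors: RegressorSet | pd.DataFrame,
    response: np.ndarray,
    groups: np.ndarray | None = None,
    **kwargs,
) -> KernelEncodingResults:
    """Fit the random-slope encoding LMEM (thin wrapper over the Model class)."""
    if isinstance(regressors, RegressorSet):
        model = KernelEncodingModel.from_regressor_set(regressors, response, **kwargs)
    else:
        if groups is None:
            raise EncodingError("groups required when passing a plain DataFrame")
        model = KernelEncodingModel(response, regressors, groups, **kwargs)
    return model.fit()


def satterthwaite_pvalues(fit: KernelEncodingResults) -> pd.DataFrame:
    """Per-coefficient t, Satterthwaite df and two-tailed p."""
    return fit.satterthwaite()


def nakagawa_from_variances(
    var_fixed: float, var_random: float, var_resid: float
) -> dict[str, float]:
    """Nakagawa R² from a (fixed, random, residual) variance partition."""
    total = var_fixed + var_random + var_resid
    if total <= 0:
        raise EncodingError("total variance is zero: R2 undefined")
    return {
        "marginal": var_fixed / total,
        "conditional": (var_fixed + var_random) / total,
    }


def nakagawa_r2(fit: KernelEncodingResults) -> dict[str, float]:
    return fit.nakagawa_r2()
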