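"""Quantitative binding and remodeling kinetics.

Two small fitted models in the Model/Results idiom:

``HillModel``
    Least-squares fit of an EMSA titration to the Hill equation
    f([E]) = [E]^H / (K_D^H + [E]^H), reporting K_D (nM), the Hill
    coefficient H, R^2 and 95% confidence intervals (profile likelihood
    by default, asymptotic as fallback).  Free remodeler concentration is
    approximated by total concentration (no ligand-depletion correction),
    the standard treatment for EMSA titrations of this kind.

``InitialRateModel``
    Initial rate v0 of a remodeling or ATP-hydrolysis time course.  The
    default fits the saturating exponential A(1 - exp(-kt)) and reports
    v0 = A*k with a delta-method standard error; ``method='linear-early'``
    instead regresses the early points (signal below 30% of the maximum).

``fold_ratio`` compares two rates and rounds the way such ratios are
conventionally quoted: to the nearest integer at >= 10-fold, otherwise to
one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .synth import hill, saturating_exponential

__all__ = [
    "FlatCurveError",
    "HillModel",
    "HillResults",
    "InitialRateModel",
    "RateResults",
    "FoldRatio",
    "fold_ratio",
]


class FlatCurveError(ValueError):
    """Titration carries no binding signal (all ~0 or all ~1)."""


# ---------------------------------------------------------------------------
# Hill fit


@dataclass
class HillResults:
    """Fitted Hill-equation parameters and diagnostics."""

    kd: float
    h: float
    rsquared: float
    ci_kd: tuple[float, float]
    ci_h: tuple[float, float]
    ci_method: str
    converged: bool
    nobs: int
    ssr: float
    model: "HillModel"

    @property
    def params(self) -> pd.Series:
        return pd.Series({"kd": self.kd, "h": self.h})

    def conf_int(self) -> pd.DataFrame:
        return pd.DataFrame(
            [self.ci_kd, self.ci_h], index=["kd", "h"], columns=["lower", "upper"]
        )

    def predict(self, concentration) -> np.ndarray:
        return hill(concentration, self.kd, self.h)

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Hill equation fit (fraction bound vs concentration)",
            f"  n points      : {self.nobs}",
            f"  K_D (nM)      : {self.kd:.3g}   95% CI [{ci.loc['kd','lower']:.3g}, {ci.loc['kd','upper']:.3g}]",
            f"  H             : {self.h:.3g}   95% CI [{ci.loc['h','lower']:.3g}, {ci.loc['h','upper']:.3g}]",
            f"  R^2           : {self.rsquared:.4g}",
            f"  CI method     : {self.ci_method}",
            f"  converged     : {self.converged}",
        ]
        return "\n".join(lines)


class HillModel:
    """Hill-equation model of a binding titration.

    Parameters
    ----------
    concentration, fraction_bound : array-like
        Titration points; replicates are simply additional points.
    """

    def __init__(self, concentration, fraction_bound):
        conc = np.asarray(concentration, dtype=float)
        frac = np.asarray(fraction_bound, dtype=float)
        if conc.shape != frac.shape:
            raise ValueError("concentration and fraction_bound differ in length")
        if (conc < 0).any():
            raise ValueError("concentrations must be >= 0")
        order = np.argsort(conc, kind="stable")
        self.concentration = conc[order]
        self.fraction_bound = frac[order]
        if np.unique(conc[conc > 0]).size < 4:
            raise ValueError("need >= 4 distinct positive concentrations")
        if np.ptp(frac) < 1e-3:
            raise FlatCurveError("titration is flat; nothing to fit")

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, conc_col: str = "concentration",
        frac_col: str = "fraction_bound",
    ) -> "HillModel":
        return cls(df[conc_col].to_numpy(), df[frac_col].to_numpy())

    # -- fitting ------------------------------------------------------------

    def _ssr(self, kd: float, h: float) -> float:
        r = self.fraction_bound - hill(self.concentration, kd, h)
        return float(r @ r)

    def _profile_ssr_kd(self, kd: float) -> float:
        res = optimize.minimize_scalar(
            lambda h: self._ssr(kd, h), bounds=(1e-3, 20.0), method="bounded"
        )
        return float(res.fun)

    def _profile_ssr_h(self, h: float) -> float:
        pos = self.concentration[self.concentration > 0]
        res = optimize.minimize_scalar(
            lambda lk: self._ssr(np.exp(lk), h),
            bounds=(np.log(pos.min() / 1e3), np.log(pos.max() * 1e3)),
            method="bounded",
        )
        return float(res.fun)

    def fit(self, ci_method: str = "profile") -> HillResults:
        """Multi-start least squares, then 95% confidence intervals."""
        x, y = self.concentration, self.fraction_bound
        pos = x[x > 0]
        kd_starts = np.geomspace(pos.min(), pos.max(), 5)
        h_starts = (0.7, 1.0, 1.6)
        best = None
        for kd0 in kd_starts:
            for h0 in h_starts:
                sol = optimize.least_squares(
                    lambda p: y - hill(x, p[0], p[1]),
                    x0=[kd0, h0],
                    bounds=([1e-9, 1e-3], [1e9, 20.0]),
                    xtol=1e-14, ftol=1e-14, gtol=1e-14,
                )
                if best is None or sol.cost < best.cost:
                    best = sol
        kd, h = map(float, best.x)
        ssr = float(2 * best.cost)
        sst = float(((y - y.mean()) ** 2).sum())
        rsq = 1.0 - ssr / sst if sst > 0 else np.nan
        converged = bool(best.success) and np.isfinite(ssr)

        ci_kd = ci_h = (np.nan, np.nan)
        used = ci_method
        if converged:
            if ci_method == "profile":
                ci_kd = self._profile_ci(kd, ssr, self._profile_ssr_kd, positive_log=True)
                ci_h = self._profile_ci(h, ssr, self._profile_ssr_h, positive_log=True)
                if not (np.isfinite(ci_kd).all() and np.isfinite(ci_h).all()):
                    used = "asymptotic"
            if used == "asymptotic" or ci_method == "asymptotic":
                ci_kd, ci_h = self._asymptotic_ci(best, kd, h, ssr)
                used = "asymptotic"
        return HillResults(
            kd=kd, h=h, rsquared=rsq, ci_kd=tuple(ci_kd), ci_h=tuple(ci_h),
            ci_method=used, converged=converged, nobs=y.size, ssr=ssr, model=self,
        )

    def _profile_ci(self, est, ssr_min, profile_fun, positive_log=True, level=0.95):
        """Profile-likelihood interval via the F-statistic threshold.

        The bound solves SSR_profile(theta) = SSR_min (1 + F_{1,n-p}/(n-p)).
        """
        n, p = self.fraction_bound.size, 2
        if n <= p:
            return (np.nan, np.nan)
        thresh = ssr_min * (1.0 + stats.f.ppf(level, 1, n - p) / (n - p))
        if thresh <= ssr_min or ssr_min == 0:
            return (est, est)  # zero-residual fit: interval degenerates

        def g(log_theta):
            return profile_fun(np.exp(log_theta)) - thresh

        le = np.log(est)
        bounds = []
        for sign in (-1.0, 1.0):
            step, hi, lo = 0.25, None, le
            for _ in range(60):
                cand = le + sign * step
                if g(cand) > 0:
                    hi = cand
                    break
                lo = cand
                step *= 1.6
            if hi is None:
                bounds.append(np.nan)
                continue
            a, b = (hi, lo) if sign < 0 else (lo, hi)
            try:
                root = optimize.brentq(g, a, b, xtol=1e-10)
                bounds.append(np.exp(root))
            except ValueError:
                bounds.append(np.nan)
        return (bounds[0], bounds[1])

    def _asymptotic_ci(self, sol, kd, h, ssr, level=0.95):
        n, p = self.fraction_bound.size, 2
        dof = max(n - p, 1)
        J = sol.jac
        try:
            cov = np.linalg.inv(J.T @ J) * ssr / dof
        except np.linalg.LinAlgError:
            return (np.nan, np.nan), (np.nan, np.nan)
        tq = stats.t.ppf(0.5 + level / 2, dof)
        se = np.sqrt(np.diag(cov))
        return (kd - tq * se[0], kd + tq * se[0]), (h - tq * se[1], h + tq * se[1])


# ---------------------------------------------------------------------------
# Initial rates


@dataclass
class RateResults:
    """Initial rate of a remodeling/ATPase time course."""

    v0: float
    se: float
    method: str
    plateau: float | None
    fallback: bool
    nobs: int
    model: "InitialRateModel"

    def summary(self) -> str:
        lines = [
            "Initial-rate fit",
            f"  v0 (nM/s) : {self.v0:.4g} +/- {self.se:.2g}",
            f"  method    : {self.method}" + (" (fallback)" if self.fallback else ""),
        ]
        if self.plateau is not None:
            lines.append(f"  plateau   : {self.plateau:.4g} nM")
        return "\n".join(lines)


class InitialRateModel:
    """Initial-rate model for a time course (time in s, signal in nM)."""

    def __init__(self, time, signal):
        t = np.asarray(time, dtype=float)
        y = np.asarray(signal, dtype=float)
        if t.shape != y.shape:
            raise ValueError("time and signal differ in length")
        order = np.argsort(t, kind="stable")
        self.time, self.signal = t[order], y[order]
        if self.time.size < 4 or self.time[0] != 0:
            raise ValueError("need >= 4 time points including t = 0")

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, time_col: str = "time_s", signal_col: str = "signal_nM"
    ) -> "InitialRateModel":
        return cls(df[time_col].to_numpy(), df[signal_col].to_numpy())

    def fit(self, method: str = "exponential", early_fraction: float = 0.3) -> RateResults:
        if method == "exponential":
            return self._fit_exponential(early_fraction)
        if method == "linear-early":
            return self._fit_linear(early_fraction, fallback=False)
        raise ValueError("method must be 'exponential' or 'linear-early'")

    def _fit_exponential(self, early_fraction: float) -> RateResults:
        t, y = self.time, self.signal
        if np.ptp(y) == 0:
            return RateResults(0.0, 0.0, "exponential", float(y.max()), False, y.size, self)
        a0 = float(max(y.max(), 1e-9))
        nonzero = y > 0.05 * a0
        k0 = 1.0 / max(float(t[nonzero][0]), 1e-9) if nonzero.any() else 1.0 / t[-1]

        def f(tt, a, k):
            return a * (1.0 - np.exp(-k * tt))

        try:
            popt, pcov = optimize.curve_fit(
                f, t, y, p0=[a0, k0], bounds=([1e-12, 1e-12], [np.inf, np.inf]),
                maxfev=10000,
            )
        except RuntimeError:
            return self._fit_linear(early_fraction, fallback=True)
        a, k = map(float, popt)
        v0 = a * k
        grad = np.array([k, a])  # d(v0)/d(a, k)
        var = float(grad @ pcov @ grad)
        se = float(np.sqrt(var)) if np.isfinite(var) and var >= 0 else np.nan
        return RateResults(v0, se, "exponential", a, False, y.size, self)

    def _fit_linear(self, early_fraction: float, fallback: bool) -> RateResults:
        t, y = self.time, self.signal
        if np.ptp(y) == 0:
            return RateResults(0.0, 0.0, "linear-early", None, fallback, y.size, self)
        use = y < early_fraction * y.max()
        use |= t == 0  # always anchor the origin
        if use.sum() < 2:
            use = np.zeros_like(use)
            use[:2] = True
        tt, yy = t[use], y[use]
        X = np.column_stack([np.ones(tt.size), tt])
        beta, res, *_ = np.linalg.lstsq(X, yy, rcond=None)
        slope = float(beta[1])
        dof = tt.size - 2
        if dof > 0:
            resid = yy - X @ beta
            s2 = float(resid @ resid) / dof
            cov = s2 * np.linalg.inv(X.T @ X)
            se = float(np.sqrt(cov[1, 1]))
        else:
            se = np.nan
        return RateResults(slope, se, "linear-early", None, fallback, int(use.sum()), self)


# ---------------------------------------------------------------------------
# Fold ratios


@dataclass(frozen=True)
class FoldRatio:
    exact: float
    rounded: float

    def __str__(self) -> str:
        r = self.rounded
        return f"{r:g}x"


def _rate_value(x) -> float:
    return float(x.v0) if isinstance(x, RateResults) else float(x)


#: Fold ratios at or above this value are quoted as integers; smaller
#: ones keep one decimal (8.1x reads as "8x", 5.3x stays "5.3x").
INTEGER_FOLD_CUTOFF = 6.0


def fold_ratio(a, b) -> FoldRatio:
    """a/b with conventional rounding: nearest integer at >= 6, else 0.1."""
    av, bv = _rate_value(a), _rate_value(b)
    if bv == 0:
        raise ZeroDivisionError("denominator rate is zero")
    exact = av / bv
    rounded = (
        float(round(exact)) if abs(exact) >= INTEGER_FOLD_CUTOFF else round(exact, 1)
    )
    return FoldRatio(exact=exact, rounded=rounded)
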