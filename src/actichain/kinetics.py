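"""Organ time–activity kinetics: planar quantification, washout fits, residence times.

The measurement chain emulated here is the standard planar gamma-camera
protocol for ¹⁷⁷Lu radioligand dosimetry: anterior/posterior whole-body
scans at four windows post-injection, triple-energy-window (TEW) scatter
correction, conjugate-view (geometric-mean) organ quantification relative to
the earliest whole-body image, no attenuation correction.  Fractions of
injected activity are then fitted with mono- or bi-exponential washout
models; the analytic integral of the fit gives the residence time (MIRD
time-integrated activity coefficient, hours).

Because ²²⁵Ac cannot be imaged, the surrogate ¹⁷⁷Lu curves are converted:
divide out the ¹⁷⁷Lu physical decay (``decay_correct``) to get the purely
biological curve, then re-apply the ²²⁵Ac physical half-life
(``apply_physical_decay``).

Fitting follows the statsmodels Model/Results convention:
``TimeActivityModel(tac).fit(model="mono")`` returns an
:class:`ExponentialFitResults` carrying amplitudes, rates, their covariance
and derived quantities (effective half-life, residence time).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "LU177_HALF_LIFE_H",
    "AC225_HALF_LIFE_H",
    "PlanarCounts",
    "TimeActivityCurve",
    "ExponentialFitResults",
    "TimeActivityModel",
    "FitError",
    "tew_scatter_correct",
    "conjugate_view_fraction",
    "decay_correct",
    "apply_physical_decay",
    "fit_exponential",
    "effective_half_life",
    "residence_time",
]

LU177_HALF_LIFE_H = 159.5   #: ¹⁷⁷Lu physical half-life, hours
AC225_HALF_LIFE_H = 238.1   #: ²²⁵Ac physical half-life, hours

_MIN_RATE = 1e-6  # h^-1, lower bound for fitted washout rates


class FitError(RuntimeError):
    """Raised when an exponential fit cannot be performed or did not converge."""

    def __init__(self, message: str, initial_guess: np.ndarray | None = None):
        super().__init__(message)
        self.initial_guess = initial_guess


@dataclass(frozen=True)
class PlanarCounts:
    """Anterior/posterior counts of one structure in one planar acquisition."""

    ant: float
    post: float

    def __post_init__(self) -> None:
        if self.ant < 0 or self.post < 0:
            raise ValueError("planar counts must be >= 0")

    @property
    def geometric_mean(self) -> float:
        return math.sqrt(self.ant * self.post)


def tew_scatter_correct(
    main: float,
    lower: float,
    upper: float,
    w_main: float,
    w_lower: float,
    w_upper: float,
) -> float:
    """Triple-energy-window scatter correction.

    Estimates the scatter in the main window as the trapezoid spanned by the
    count densities of the two flanking narrow windows:

        scatter = (lower/w_lower + upper/w_upper) · w_main / 2

    and returns ``max(0, main − scatter)`` (counts cannot go negative).
    Widths are in keV.
    """
    if min(main, lower, upper) < 0:
        raise ValueError("counts must be >= 0")
    if min(w_main, w_lower, w_upper) <= 0:
        raise ValueError("window widths must be > 0")
    scatter = (lower / w_lower + upper / w_upper) * w_main / 2.0
    return max(0.0, main - scatter)


def conjugate_view_fraction(organ: PlanarCounts, whole_body_ref: PlanarCounts) -> float:
    """Fraction of injected activity by the conjugate-view geometric-mean method.

    ``sqrt(ant·post)`` of the organ divided by the same for the whole-body
    reference (earliest time point, taken as 100% of the injected activity).
    Counts are assumed scatter-corrected; no attenuation correction is
    applied.
    """
    ref_gm = whole_body_ref.geometric_mean
    if ref_gm <= 0:
        raise ValueError("whole-body reference geometric mean must be > 0")
    return organ.geometric_mean / ref_gm


@dataclass(frozen=True)
class TimeActivityCurve:
    """Organ washout samples: fraction of injected activity vs hours p.i.

    ``physical_half_life_h`` records which isotope's physical decay the
    values still embed; ``math.inf`` marks a purely biological curve.
    """

    organ: str
    times_h: tuple[float, ...]
    values: tuple[float, ...]
    sd: tuple[float, ...] | None = None
    physical_half_life_h: float = LU177_HALF_LIFE_H

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.size != v.size:
            raise ValueError("times and values must have equal length")
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0):
            raise ValueError("times must be strictly increasing and >= 0")
        if np.any(v < 0):
            raise ValueError("activity fractions must be >= 0")
        if self.sd is not None and len(self.sd) != t.size:
            raise ValueError("sd must match the number of points")
        if not (self.physical_half_life_h > 0):
            raise ValueError("physical half-life must be > 0 (inf = biological)")

    @property
    def t(self) -> np.ndarray:
        return np.asarray(self.times_h, dtype=float)

    @property
    def v(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.times_h)


def decay_correct(
    tac: TimeActivityCurve, physical_half_life_h: float | None = None
) -> TimeActivityCurve:
    """Remove physical decay, leaving the biological washout curve.

    Each value is multiplied by ``exp(+ln2 · t / T_phys)``; the returned
    curve is marked biological (infinite physical half-life).
    """
    T = tac.physical_half_life_h if physical_half_life_h is None else physical_half_life_h
    if not (T > 0):
        raise ValueError("physical half-life must be > 0")
    factor = np.exp(math.log(2.0) * tac.t / T)
    return replace(
        tac,
        values=tuple(tac.v * factor),
        physical_half_life_h=math.inf,
    )


def apply_physical_decay(
    tac_biological: TimeActivityCurve, physical_half_life_h: float
) -> TimeActivityCurve:
    """Impose a physical half-life on a biological curve (inverse of decay_correct)."""
    if not (physical_half_life_h > 0):
        raise ValueError("physical half-life must be > 0")
    factor = np.exp(-math.log(2.0) * tac_biological.t / physical_half_life_h)
    return replace(
        tac_biological,
        values=tuple(tac_biological.v * factor),
        physical_half_life_h=physical_half_life_h,
    )


def convert_isotope(
    tac: TimeActivityCurve, target_half_life_h: float = AC225_HALF_LIFE_H
) -> TimeActivityCurve:
    """Re-express a surrogate-isotope curve for another isotope's physical decay."""
    return apply_physical_decay(decay_correct(tac), target_half_life_h)


# ---------------------------------------------------------------------------
# exponential fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExponentialFitResults:
    """Fitted washout model Σᵢ Aᵢ·exp(−λᵢ t).

    Terms are ordered by rate ascending, so ``rates[0]`` is always the slow
    washout phase — the rate used downstream for effective half-life and the
    biologically-effective-dose decay constant.
    """

    model: Literal["mono", "bi"]
    amplitudes: tuple[float, ...]
    rates: tuple[float, ...]          # h^-1, ascending
    rss: float
    nobs: int
    cov: np.ndarray | None = None     # parameter covariance (A1, l1, A2, l2)
    organ: str = ""

    @property
    def terms(self) -> tuple[tuple[float, float], ...]:
        return tuple(zip(self.amplitudes, self.rates))

    @property
    def slow_rate(self) -> float:
        return self.rates[0]

    def predict(self, t: Sequence[float] | np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        A = np.asarray(self.amplitudes)[:, None]
        lam = np.asarray(self.rates)[:, None]
        return np.sum(A * np.exp(-lam * t[None, :]), axis=0)

    @property
    def effective_half_life_h(self) -> float:
        return math.log(2.0) / self.slow_rate

    @property
    def residence_time_h(self) -> float:
        """Analytic 0→∞ integral of the fitted curve, hours per unit injected."""
        if any(r <= 0 for r in self.rates):
            raise FitError("all rates must be > 0 for residence-time evaluation")
        return float(sum(A / lam for A, lam in self.terms))

    def bse(self) -> np.ndarray | None:
        """Standard errors of (A₁, λ₁, …) from the Gauss–Newton covariance."""
        if self.cov is None:
            return None
        return np.sqrt(np.diag(self.cov))

    def summary(self) -> str:
        lines = [
            f"Exponential washout fit ({self.model}), organ={self.organ or '-'}",
            f"  n points: {self.nobs}   RSS: {self.rss:.3e}",
        ]
        se = self.bse()
        for i, (A, lam) in enumerate(self.terms):
            tag = "slow" if i == 0 else "fast"
            err = ""
            if se is not None:
                err = f"  (se A={se[2 * i]:.2e}, se λ={se[2 * i + 1]:.2e})"
            lines.append(f"  {tag}: A={A:.5g} FIA, λ={lam:.5g} 1/h{err}")
        lines.append(
            f"  effective half-life: {self.effective_half_life_h:.3g} h   "
            f"residence time: {self.residence_time_h:.4g} h"
        )
        return "\n".join(lines)


def _mono_init(t: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Closed-form log-linear initializer for A·exp(−λt)."""
    pos = v > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(v[pos]), 1)
        lam0 = max(-slope, _MIN_RATE)
        A0 = math.exp(intercept)
    else:
        lam0, A0 = 0.01, max(v.max(initial=0.0), 1e-6)
    return np.array([A0, lam0])


def _bi_init(t: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Curve-peeling initializer: slow phase from the tail, fast from the residual."""
    k = max(2, len(t) // 2)
    A_s, lam_s = _mono_init(t[-k:], v[-k:])
    resid = v - A_s * np.exp(-lam_s * t)
    head = resid[: max(2, len(t) - k)] > 0
    if head.sum() >= 2:
        A_f, lam_f = _mono_init(t[: max(2, len(t) - k)][head], resid[: max(2, len(t) - k)][head])
    else:
        A_f, lam_f = max(v[0] - A_s, 1e-6), 10.0 * max(lam_s, _MIN_RATE)
    if lam_f <= lam_s:
        lam_f = 5.0 * max(lam_s, _MIN_RATE)
    return np.array([A_s, lam_s, A_f, lam_f])


class TimeActivityModel:
    """Washout model for one organ time–activity curve.

    Parameters
    ----------
    tac
        The measured curve (any isotope context; the fit is agnostic).
    weights
        Optional per-point weights for the least-squares objective.  The
        default is unweighted least squares on the linear scale.
    """

    def __init__(self, tac: TimeActivityCurve, weights: Sequence[float] | None = None):
        self.tac = tac
        self.weights = None if weights is None else np.asarray(weights, dtype=float)
        if self.weights is not None and self.weights.size != len(tac):
            raise ValueError("weights must match the number of points")

    def fit(self, model: Literal["mono", "bi"] = "mono") -> ExponentialFitResults:
        t, v = self.tac.t, self.tac.v
        n_par = {"mono": 2, "bi": 4}.get(model)
        if n_par is None:
            raise ValueError(f"unknown model {model!r}")
        if len(t) < n_par:
            raise FitError(
                f"{model} fit needs >= {n_par} points, got {len(t)}"
            )
        x0 = _mono_init(t, v) if model == "mono" else _bi_init(t, v)
        w = np.ones_like(v) if self.weights is None else self.weights

        def resid(p: np.ndarray) -> np.ndarray:
            A = p[0::2][:, None]
            lam = p[1::2][:, None]
            pred = np.sum(A * np.exp(-lam * t[None, :]), axis=0)
            return w * (pred - v)

        lower = np.array([0.0, _MIN_RATE] * (n_par // 2))
        sol = least_squares(
            resid, np.maximum(x0, lower), bounds=(lower, np.inf), method="trf"
        )
        if not sol.success:
            raise FitError(f"fit did not converge: {sol.message}", initial_guess=x0)
        p = sol.x
        # order terms by rate ascending (slow phase first)
        order = np.argsort(p[1::2])
        amps = tuple(p[0::2][order])
        rates = tuple(p[1::2][order])
        rss = float(np.sum(sol.fun**2))
        cov = None
        dof = len(t) - n_par
        if dof > 0:
            J = sol.jac[:, np.concatenate([[2 * i, 2 * i + 1] for i in order])]
            JTJ = J.T @ J
            if np.isfinite(JTJ).all():
                try:
                    cov = np.linalg.inv(JTJ) * rss / dof
                except np.linalg.LinAlgError:
                    cov = None
        return ExponentialFitResults(
            model=model,
            amplitudes=amps,
            rates=rates,
            rss=rss,
            nobs=len(t),
            cov=cov,
            organ=self.tac.organ,
        )


def fit_exponential(
    tac: TimeActivityCurve, model: Literal["mono", "bi"] = "mono"
) -> ExponentialFitResults:
    """Functional wrapper around :class:`TimeActivityModel`."""
    return TimeActivityModel(tac).fit(model=model)


def effective_half_life(fit: ExponentialFitResults) -> float:
    """ln2 over the slow-phase washout rate, hours."""
    return fit.effective_half_life_h


def residence_time(fit: ExponentialFitResults) -> float:
    """Σ Aᵢ/λᵢ — analytic 0→∞ integral of the fitted curve, hours."""
    return fit.residence_time_h
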