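"""Double-exponential fitting of stopped-flow shrinkage traces.

The light-scattering signal of an osmotic shrinkage experiment is fitted
with

    y(t) = y∞ − a1·exp(−k1·t) − a2·exp(−k2·t),   a ≥ 0, k > 0,

where the slower rate k1 is attributed to background permeation through
the lipid bilayer and the faster rate k2 to channel-mediated permeation.
The assignment rule (k2 = larger rate) is stored on the fit object.

Also provides normalisation of pyranine (HPTS) fluorescence transport
traces against the detergent-lysis full scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .synthetic import StoppedFlowTrace

__all__ = [
    "BiexpFit",
    "MonoexpFit",
    "FluorescenceTrace",
    "fit_biexponential",
    "fit_monoexponential",
    "normalize_pyranine",
]

#: relative rate separation below which a biexponential fit is flagged
RATE_COLLAPSE_TOL = 1e-3


@dataclass(frozen=True)
class BiexpFit:
    """Result of a biexponential shrinkage fit.

    ``degenerate_reason`` is ``None`` for a clean two-rate fit,
    ``"effectively single-exponential"`` when the two rates collapse, or
    ``"no channel component"`` when the fast amplitude is below the noise
    floor (blank-liposome behaviour).
    """

    y_inf: float
    a1: float
    a2: float
    k1: float
    k2: float
    residual_rms: float
    converged: bool
    k2_assignment_rule: str = "k2 = max(rates)"
    degenerate_reason: str | None = None
    fixed_k1: bool = False

    @property
    def is_degenerate(self) -> bool:
        return self.degenerate_reason is not None

    def as_dict(self) -> dict:
        return {
            "y_inf": self.y_inf,
            "a1": self.a1,
            "a2": self.a2,
            "k1_per_s": self.k1,
            "k2_per_s": self.k2,
            "residual_rms": self.residual_rms,
            "converged": self.converged,
            "k2_assignment_rule": self.k2_assignment_rule,
            "degenerate_reason": self.degenerate_reason,
            "fixed_k1": self.fixed_k1,
        }


@dataclass(frozen=True)
class MonoexpFit:
    y_inf: float
    a: float
    k: float
    residual_rms: float
    converged: bool


@dataclass(frozen=True)
class FluorescenceTrace:
    """Pyranine fluorescence record with baseline and lysis markers."""

    times_s: np.ndarray
    intensity: np.ndarray
    baseline_window_s: tuple[float, float]
    lysis_time_s: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        f = np.asarray(self.intensity, dtype=float)
        if t.shape != f.shape or t.ndim != 1:
            raise ValueError("times and intensity must be equal-length 1-D arrays")
        if not (t[0] <= self.lysis_time_s <= t[-1]):
            raise ValueError("lysis_time must lie within the record")
        lo, hi = self.baseline_window_s
        if hi <= lo or hi > self.lysis_time_s:
            raise ValueError("baseline window must precede the lysis pulse")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "intensity", f)


def robust_noise_sd(y: np.ndarray) -> float:
    """Noise scale from the MAD of first differences, / √2.

    Differencing removes the smooth trend; dividing by √2 undoes the
    variance doubling.  1.4826 converts MAD to a Gaussian sigma.
    """
    dy = np.diff(np.asarray(y, dtype=float))
    mad = np.median(np.abs(dy - np.median(dy)))
    return float(1.4826 * mad / np.sqrt(2.0))


def _peel_initial(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float, float]:
    """Exponential-peeling initial guess (y_inf, a1, a2, k_slow, k_fast).

    Log-linear fits are restricted to samples whose residual from the
    plateau clears the noise floor, so that the flat post-decay tail
    cannot corrupt the slopes.
    """
    y_inf = float(np.mean(y[-max(3, len(y) // 10):]))
    resid = y_inf - y
    span = float(max(resid.max(), 1e-9))
    floor = max(3.0 * robust_noise_sd(y), 1e-12)

    valid = np.flatnonzero(resid > floor)
    if valid.size < 8:
        # essentially flat or instantly equilibrated trace
        return y_inf, span / 2, span / 2, 1.0, 10.0

    late = valid[valid.size // 2 :]
    k_slow, a_slow = _loglinear(t[late], resid[late])
    k_slow = float(np.clip(k_slow, 1e-3, 1e4))
    a_slow = float(np.clip(a_slow, floor, 2.0 * span))

    # fast rate from the early residual after removing the slow part,
    # over the decaying head only (down to 10% of its starting value)
    early = resid - a_slow * np.exp(-k_slow * t)
    k_fast = 10.0 * k_slow
    a_fast = max(resid[0] - a_slow, 0.1 * span)
    evalid = np.flatnonzero(early > floor)
    if evalid.size >= 3:
        start = evalid[0]
        e0 = early[start]
        below = np.flatnonzero(early[start:] < 0.1 * e0)
        stop = start + (int(below[0]) if below.size else evalid.size)
        sel = np.arange(start, min(max(stop, start + 4), len(t)))
        sel = sel[early[sel] > floor]
        if sel.size >= 3:
            k_est, a_est = _loglinear(t[sel], early[sel])
            if np.isfinite(k_est) and k_est > k_slow:
                k_fast = float(np.clip(k_est, k_slow, 1e6))
                a_fast = float(np.clip(a_est, floor, 2.0 * span))
    return y_inf, a_slow, a_fast, k_slow, k_fast


def _loglinear(t: np.ndarray, r: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(t, np.log(r), 1)
    k = max(-slope, 1e-6)
    return float(k), float(np.exp(intercept))


def fit_biexponential(
    trace: StoppedFlowTrace,
    window_s: float = 2.0,
    fix_k1: float | None = None,
    n_multistarts: int = 8,
    seed: int = 0,
) -> BiexpFit:
    """Fit y(t) = y∞ − a1 e^(−k1 t) − a2 e^(−k2 t) to a shrinkage trace.

    Least squares with non-negative amplitudes and positive rates, over
    the analysis window (default 2 s).  Initialisation by exponential
    peeling followed by multistarts with rates jittered in ×[0.3, 3];
    the lowest-residual solution wins.  Rates are relabelled so that
    k2 = max(k1, k2): the channel-mediated pathway is the faster one.

    ``fix_k1`` pins the slow rate to a value determined from a blank
    (lipid-only) control instead of fitting it.
    """
    mask = trace.times_s <= window_s
    t = trace.times_s[mask]
    y = trace.signal[mask]
    if len(t) < 20:
        raise ValueError("fewer than 20 samples inside the fitting window")

    y0_inf, a_s, a_f, k_s, k_f = _peel_initial(t, y)
    if fix_k1 is not None:
        if fix_k1 <= 0:
            raise ValueError("fix_k1 must be positive")
        k_s = fix_k1

    def model(p: np.ndarray) -> np.ndarray:
        if fix_k1 is None:
            y_inf, a1, a2, lk1, lk2 = p
            k1, k2 = np.exp(lk1), np.exp(lk2)
        else:
            y_inf, a1, a2, lk2 = p
            k1, k2 = fix_k1, np.exp(lk2)
        return y_inf - a1 * np.exp(-k1 * t) - a2 * np.exp(-k2 * t)

    def residuals(p: np.ndarray) -> np.ndarray:
        return model(p) - y

    rng = np.random.default_rng(seed)
    starts = [(k_s, k_f), (k_s, 10.0 * k_f)]
    while len(starts) < max(2, n_multistarts):
        jit = np.exp(rng.uniform(np.log(0.3), np.log(3.0), size=2))
        starts.append((k_s * jit[0], k_f * jit[1]))

    best = None
    for ks, kf in starts:
        if fix_k1 is None:
            p0 = np.array([y0_inf, a_s, a_f, np.log(ks), np.log(kf)])
            lb = np.array([-np.inf, 0.0, 0.0, np.log(1e-8), np.log(1e-8)])
            ub = np.array([np.inf, np.inf, np.inf, np.log(1e8), np.log(1e8)])
        else:
            p0 = np.array([y0_inf, a_s, a_f, np.log(kf)])
            lb = np.array([-np.inf, 0.0, 0.0, np.log(1e-8)])
            ub = np.array([np.inf, np.inf, np.inf, np.log(1e8)])
        try:
            res = least_squares(
                residuals, p0, bounds=(lb, ub), ftol=1e-15, xtol=1e-15, gtol=1e-15
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res

    if best is None:
        raise RuntimeError("biexponential fit failed to converge from all starts")

    if fix_k1 is None:
        y_inf, a1, a2, lk1, lk2 = best.x
        k1, k2 = float(np.exp(lk1)), float(np.exp(lk2))
    else:
        y_inf, a1, a2, lk2 = best.x
        k1, k2 = float(fix_k1), float(np.exp(lk2))
    a1, a2 = float(a1), float(a2)

    # relabel so k2 is the faster (channel) rate
    if k1 > k2:
        k1, k2 = k2, k1
        a1, a2 = a2, a1

    rms = float(np.sqrt(np.mean(best.fun**2)))
    degenerate = None
    noise = robust_noise_sd(y)
    if abs(k2 - k1) / k2 < RATE_COLLAPSE_TOL:
        degenerate = "effectively single-exponential"
    elif a2 < 3.0 * noise:
        degenerate = "no channel component"
    elif a1 < 3.0 * noise:
        # only the fast component carries signal: a single-rate trace
        degenerate = "effectively single-exponential"

    return BiexpFit(
        y_inf=float(y_inf),
        a1=a1,
        a2=a2,
        k1=k1,
        k2=k2,
        residual_rms=rms,
        converged=bool(best.success),
        degenerate_reason=degenerate,
        fixed_k1=fix_k1 is not None,
    )


def fit_monoexponential(
    trace: StoppedFlowTrace, window_s: float = 2.0
) -> MonoexpFit:
    """Fit y(t) = y∞ − a e^(−k t); for blanks and single-rate traces."""
    mask = trace.times_s <= window_s
    t = trace.times_s[mask]
    y = trace.signal[mask]
    y0_inf, a_s, _a_f, k_s, _k_f = _peel_initial(t, y)

    def residuals(p: np.ndarray) -> np.ndarray:
        y_inf, a, lk = p
        return (y_inf - a * np.exp(-np.exp(lk) * t)) - y

    res = least_squares(
        residuals,
        np.array([y0_inf, max(a_s, 1e-6), np.log(max(k_s, 1e-6))]),
        bounds=(
            np.array([-np.inf, 0.0, np.log(1e-8)]),
            np.array([np.inf, np.inf, np.log(1e8)]),
        ),
        ftol=1e-15,
        xtol=1e-15,
        gtol=1e-15,
    )
    y_inf, a, lk = res.x
    return MonoexpFit(
        y_inf=float(y_inf),
        a=float(a),
        k=float(np.exp(lk)),
        residual_rms=float(np.sqrt(np.mean(res.fun**2))),
        converged=bool(res.success),
    )


def normalize_pyranine(trace: FluorescenceTrace, settle_fraction: float = 0.1) -> np.ndarray:
    """Fractional transport from a pyranine fluorescence trace.

    Returns (F(t) − F̄_baseline) / (F̄_postlysis − F̄_baseline), where the
    full scale is defined by detergent lysis of the liposomes.  The
    post-lysis plateau mean skips the first ``settle_fraction`` of the
    post-lysis record to let the signal settle.  Values outside
    [−0.05, 1.05] are reported with a warning, not clipped.
    """
    t, f = trace.times_s, trace.intensity
    lo, hi = trace.baseline_window_s
    baseline = f[(t >= lo) & (t <= hi)]
    if baseline.size == 0:
        raise ValueError("baseline window contains no samples")
    settle = trace.lysis_time_s + settle_fraction * (t[-1] - trace.lysis_time_s)
    plateau = f[t >= settle]
    if plateau.size == 0:
        raise ValueError("no samples after the post-lysis settle window")
    f_base = float(baseline.mean())
    f_max = float(plateau.mean())
    if f_max <= f_base:
        raise ValueError(
            "post-lysis plateau not above baseline: assay failure "
            f"(baseline {f_base:.3g}, plateau {f_max:.3g})"
        )
    frac = (f - f_base) / (f_max - f_base)
    if np.any(frac < -0.05) or np.any(frac > 1.05):
        warnings.warn(
            "normalized fluorescence outside [-0.05, 1.05]; check baseline "
            "and lysis windows",
            stacklevel=2,
        )
    return frac
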