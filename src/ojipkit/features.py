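"""Landmark extraction from OJIP transients: F_O/F_S, F_J, F_M, t_J, t_P, V_J/V_J'.

The J step is located by fitting the early fluorescence rise (0.5-5 ms by
default) with a ninth-degree polynomial in a numerically conditioned basis and
finding the real roots of its second derivative at which the third derivative is
strictly positive — i.e. local minima of the slope, which is where the rise
momentarily plateaus. Among qualifying inflections the one closest to the
canonical 2 ms timing is assigned t_J. The redox proxy is the double-normalized
fluorescence at that point,

    V_J  = (F_J - F_O) / (F_M - F_O)        (dark-acclimated)
    V_J' = (F_J' - F_S) / (F_M' - F_S)      (light-acclimated)

with F_O/F_S the initial and F_M/F_M' the maximal fluorescence of the pulse.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numpy.polynomial import Polynomial

from .transients import (
    OJIPTransient,
    QCReport,
    REASON_LOW_SNR,
    REASON_NO_INFLECTION,
    detect_saturation,
    split_baseline,
)

__all__ = [
    "FeatureConfig",
    "PolynomialFit",
    "TransientFeatures",
    "estimate_initial_level",
    "estimate_maximum",
    "fit_rise_polynomial",
    "find_inflection_times",
    "select_j_step",
    "relative_variable_fluorescence",
    "fit_quality",
    "extract_features",
    "WIDE_ACCEPT_WINDOW",
]

#: Acceptance window used for noisy grid data (wide preset).
WIDE_ACCEPT_WINDOW = (0.6, 25.0)

# Fitted F_J may overshoot F_M (or undershoot F_0) by a sliver where the
# polynomial wiggles on a plateau; overshoots within this fraction of the
# dynamic range are clamped, larger violations exclude the trace.
_RANGE_CLAMP_FRAC = 1e-3


@dataclass
class FeatureConfig:
    """Tunable knobs of the landmark extraction.

    fit_window : (t_lo, t_hi) in ms, samples used for the polynomial fit.
    accept_window : window inside which a J inflection is accepted; defaults to
        the fit window. ``FeatureConfig.wide()`` uses the 0.6-25 ms preset.
    degree : polynomial degree (9 by default).
    anchor_ms : expected J timing used to pick among candidate inflections.
    snr_rho_max : maximum relative fit residual rho = rms / (F_M - F_0) before a
        trace is rejected as too noisy for reliable F_J identification.
    min_fv_fm : minimum variable-fluorescence fraction F_V/F_M = 1 - F_0/F_M
        required of a dark-acclimated trace; a saturating pulse on open PSII
        should at least halve F_0/F_M, so smaller rises mean the pulse never
        approached closure and F_M (hence V_J) is undefined. Resolved by mode
        when left None: 0.5 in dark mode, disabled (0.0) in light mode, where
        an elevated F_S legitimately compresses the rise.
    fixed_tj_ms : evaluate F_J at this fixed time instead of detecting the
        inflection per trace — the convention used within a treatment series,
        where the J timing identified on the control is reused throughout.
    mode : 'dark' (report V_J) or 'light' (report V_J').
    fp_median_width : optional moving-median width (samples) applied only when
        locating the F_P maximum on noisy uniformly sampled traces; 0 disables.
    """

    fit_window: tuple[float, float] = (0.5, 5.0)
    accept_window: tuple[float, float] | None = None
    degree: int = 9
    anchor_ms: float = 2.0
    snr_rho_max: float = 0.02
    min_fv_fm: float | None = None
    fixed_tj_ms: float | None = None
    mode: str = "dark"
    fp_median_width: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.fit_window
        if not lo < hi:
            raise ValueError("fit_window requires t_lo < t_hi")
        if self.accept_window is None:
            self.accept_window = tuple(self.fit_window)
        alo, ahi = self.accept_window
        if not alo < ahi:
            raise ValueError("accept_window requires a_lo < a_hi")
        if self.degree < 2:
            raise ValueError("degree must be >= 2")
        if not (alo <= self.anchor_ms <= ahi):
            raise ValueError("anchor_ms must lie inside accept_window")
        if self.mode not in ("dark", "light"):
            raise ValueError("mode must be 'dark' or 'light'")
        if self.min_fv_fm is None:
            self.min_fv_fm = 0.5 if self.mode == "dark" else 0.0

    @classmethod
    def wide(cls, **kwargs) -> "FeatureConfig":
        """Preset with the wide 0.6-25 ms acceptance window for noisy grid data."""
        kwargs.setdefault("accept_window", WIDE_ACCEPT_WINDOW)
        return cls(**kwargs)


@dataclass
class PolynomialFit:
    """A least-squares polynomial fit over a time window.

    The polynomial is stored with its domain mapped to [-1, 1] (numpy
    ``Polynomial`` convention), which keeps a degree-9 fit well conditioned.
    Evaluation is defined only inside ``window``.
    """

    poly: Polynomial
    window: tuple[float, float]
    residual_rms: float
    n_points: int

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        lo, hi = self.window
        eps = 1e-9 * (hi - lo)
        if np.any(t < lo - eps) or np.any(t > hi + eps):
            raise ValueError("polynomial evaluated outside its fit window")
        return self.poly(t)

    @classmethod
    def from_polynomial(cls, poly: Polynomial, window: tuple[float, float]) -> "PolynomialFit":
        """Wrap an exact polynomial (e.g. an analytic test case) as a fit."""
        return cls(poly=poly, window=tuple(window), residual_rms=0.0,
                   n_points=len(poly.coef))


def estimate_initial_level(transient: OJIPTransient, mode: str = "dark") -> float:
    """Initial fluorescence F_O (dark) or F_S (light) at pulse onset.

    Uses the arithmetic mean of the pre-pulse baseline when one exists
    (PAM-style recordings start 10 ms before the pulse); otherwise extrapolates
    a least-squares line through the first five pulse samples to t = 0
    (PEA-style recordings have no baseline).
    """
    (t_base, f_base), (t_pulse, f_pulse) = split_baseline(transient)
    if f_base.size > 0:
        return float(np.mean(f_base))
    n = min(5, f_pulse.size)
    if n == 1:
        return float(f_pulse[0])
    line = Polynomial.fit(t_pulse[:n], f_pulse[:n], 1)
    return float(line(0.0))


def estimate_maximum(
    t_pulse: np.ndarray, f_pulse: np.ndarray, median_width: int = 0
) -> tuple[float, float]:
    """Maximal fluorescence F_M and its timing t_P over the pulse segment.

    Plain argmax with the earliest sample winning ties. ``median_width`` > 1
    applies a centered moving median first (useful on noisy uniform traces).
    """
    t_pulse = np.asarray(t_pulse, dtype=float)
    f_pulse = np.asarray(f_pulse, dtype=float)
    if f_pulse.size == 0:
        raise ValueError("empty pulse segment")
    f_loc = f_pulse
    if median_width and median_width > 1 and f_pulse.size >= median_width:
        from scipy.ndimage import median_filter

        f_loc = median_filter(f_pulse, size=median_width, mode="nearest")
    idx = int(np.argmax(f_loc))  # argmax returns the first (earliest) maximum
    return float(f_pulse[idx]), float(t_pulse[idx])


def fit_rise_polynomial(
    t_pulse: np.ndarray,
    f_pulse: np.ndarray,
    config: FeatureConfig,
    window: tuple[float, float] | None = None,
) -> PolynomialFit:
    """Least-squares degree-``config.degree`` fit of the rise inside ``window``.

    ``window`` defaults to ``config.fit_window``. Requires at least degree + 1
    in-window samples.
    """
    t_pulse = np.asarray(t_pulse, dtype=float)
    f_pulse = np.asarray(f_pulse, dtype=float)
    lo, hi = window if window is not None else config.fit_window
    if t_pulse.size == 0 or lo > t_pulse[-1] or hi < t_pulse[0]:
        raise ValueError("fit window lies outside the data range")
    mask = (t_pulse >= lo) & (t_pulse <= hi)
    n = int(np.count_nonzero(mask))
    if n < config.degree + 1:
        raise ValueError(
            f"need >= {config.degree + 1} samples inside the fit window, got {n}"
        )
    poly = Polynomial.fit(t_pulse[mask], f_pulse[mask], config.degree,
                          domain=[lo, hi])
    resid = f_pulse[mask] - poly(t_pulse[mask])
    rms = float(np.sqrt(np.mean(resid**2)))
    return PolynomialFit(poly=poly, window=(lo, hi), residual_rms=rms, n_points=n)


def find_inflection_times(fit: PolynomialFit, imag_tol: float = 1e-9) -> list[float]:
    """Qualifying inflection times of a fitted rise, ascending.

    Roots of the exact second derivative of the fitted polynomial (computed via
    the companion matrix, so closely spaced roots are not missed) that lie
    inside the fit window and at which the third derivative is strictly
    positive. Roots whose imaginary part is below ``imag_tol`` after back-
    mapping from the conditioned basis count as real. An empty list is a valid
    result.
    """
    d2 = fit.poly.deriv(2)
    if np.allclose(d2.coef, 0.0):
        return []
    d3 = fit.poly.deriv(3)
    roots = d2.roots()
    lo, hi = fit.window
    eps = 1e-12 * (hi - lo)
    out = []
    for r in np.atleast_1d(roots):
        if abs(r.imag) > imag_tol:
            continue
        t = float(r.real)
        if t < lo - eps or t > hi + eps:
            continue
        tc = min(max(t, lo), hi)
        if float(np.real(d3(tc))) > 0.0:
            out.append(tc)
    return sorted(out)


def select_j_step(
    inflections: Sequence[float], config: FeatureConfig
) -> float | None:
    """Pick the inflection nearest ``anchor_ms`` inside the acceptance window.

    Ties break toward the earlier time; returns None when no inflection
    qualifies (the caller records ``no_inflection_in_window``).
    """
    alo, ahi = config.accept_window
    candidates = [t for t in inflections if alo <= t <= ahi]
    if not candidates:
        return None
    return min(candidates, key=lambda t: (abs(t - config.anchor_ms), t))


def relative_variable_fluorescence(level: float, f0: float, fm: float) -> float:
    """Double normalization (level - F0) / (FM - F0); requires FM > F0.

    Applied pointwise it produces the double-normalized curves used to overlay
    treatments; applied at the J step it yields V_J (or V_J' with F_S, F_M').
    """
    if fm <= f0:
        raise ValueError("relative variable fluorescence requires FM > F0")
    return (level - f0) / (fm - f0)


def fit_quality(
    fit: PolynomialFit, f0: float, fm: float, config: FeatureConfig
) -> tuple[float, bool]:
    """Relative fit residual rho = rms / (FM - F0) and the reliability verdict."""
    if fm <= f0:
        raise ValueError("fit quality requires FM > F0")
    rho = fit.residual_rms / (fm - f0)
    return rho, rho <= config.snr_rho_max


@dataclass
class TransientFeatures:
    """Extracted landmarks of one transient.

    F0 holds F_O (dark mode) or F_S (light mode); FJ, FM, VJ hold the primed
    quantities in light mode. ``qc.excluded`` true means VJ/FJ/tJ are unset.
    """

    mode: str
    F0: float
    FM: float
    tP: float
    FJ: float | None = None
    tJ: float | None = None
    VJ: float | None = None
    rho: float | None = None
    qc: QCReport = field(default_factory=QCReport)
    trace_id: str = ""


def extract_features(
    transient: OJIPTransient, config: FeatureConfig | None = None
) -> TransientFeatures:
    """Run the full landmark pipeline on one transient.

    Order of operations: saturation QC, initial level, maximum (F_M, t_P),
    polynomial fit of the rise, SNR check, inflection detection, J-step
    selection, F_J evaluated from the fitted polynomial at t_J, then
    V_J(') by double normalization. Any QC failure (saturation, low SNR,
    no qualifying inflection, out-of-range F_J) yields excluded features with
    VJ unset rather than an out-of-range value. The result is a pure function
    of (transient, config).
    """
    config = config if config is not None else FeatureConfig()
    qc = QCReport() if transient.normalized_by_sp else detect_saturation(transient)
    _, (t_pulse, f_pulse) = split_baseline(transient)
    f0 = estimate_initial_level(transient, config.mode)
    fm, tp = estimate_maximum(t_pulse, f_pulse, config.fp_median_width)
    feats = TransientFeatures(
        mode=config.mode, F0=f0, FM=fm, tP=tp, qc=qc, trace_id=transient.trace_id
    )
    if qc.excluded:
        return feats
    if fm <= f0 or (fm - f0) < config.min_fv_fm * fm:
        qc.snr_ok = False
        qc.add_reason(REASON_LOW_SNR)
        return feats

    # When the acceptance window is wider than the fit window (the 0.6-25 ms
    # preset), fit over the hull of both so the selected inflection always lies
    # inside the fitted domain.
    lo = min(config.fit_window[0], config.accept_window[0])
    hi = max(config.fit_window[1], config.accept_window[1])
    fit = fit_rise_polynomial(t_pulse, f_pulse, config, window=(lo, hi))
    rho, reliable = fit_quality(fit, f0, fm, config)
    feats.rho = rho
    qc.snr_ok = bool(reliable)
    if not reliable:
        qc.add_reason(REASON_LOW_SNR)
        return feats

    if config.fixed_tj_ms is not None:
        tj = float(config.fixed_tj_ms)
        if not (lo <= tj <= hi):
            raise ValueError("fixed_tj_ms lies outside the fitted window")
    else:
        tj = select_j_step(find_inflection_times(fit), config)
    if tj is None:
        qc.add_reason(REASON_NO_INFLECTION)
        return feats
    fj = float(fit(tj))
    clamp = _RANGE_CLAMP_FRAC * (fm - f0)
    if fj > fm:
        if fj > fm + clamp:
            qc.snr_ok = False
            qc.add_reason(REASON_LOW_SNR)
            return feats
        fj = fm
    if fj < f0:
        if fj < f0 - clamp:
            qc.snr_ok = False
            qc.add_reason(REASON_LOW_SNR)
            return feats
        fj = f0
    feats.tJ = float(tj)
    feats.FJ = fj
    feats.VJ = relative_variable_fluorescence(fj, f0, fm)
    return feats
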