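"""Pyrene-trace analytics: calibration, rates, half-times and synergy fits.

A pyrene-actin polymerization time course reports filament mass as a
fluorescence increase.  Traces are calibrated to polymerized-actin
concentration by an affine map anchored on the equilibrium plateau, assuming
0.1 uM actin remains unpolymerized at equilibrium (the critical
concentration).  Summary statistics follow standard practice for pyrene
curves: the maximum polymerization rate is the steepest slope of a local
quadratic (Savitzky-Golay) fit, the half-time is the first crossing of half
the plateau, and cortactin synergy is quantified as fold activation fit to a
saturating hyperbola with the zero-cortactin background held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from io import StringIO

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.signal import savgol_filter

__all__ = [
    "PolymerizationTrace",
    "SynergyCurveFit",
    "SynergyHyperbola",
    "UNPOLYMERIZED_AT_EQ",
    "fluorescence_to_concentration",
    "max_polymerization_rate",
    "half_time_to_equilibrium",
    "fold_activation",
    "fit_synergy_hyperbola",
    "read_trace_csv",
    "write_trace_csv",
]

#: Actin left unpolymerized at equilibrium (uM) used to anchor the plateau.
UNPOLYMERIZED_AT_EQ = 0.1


@dataclass(frozen=True)
class PolymerizationTrace:
    """One polymerization time course.

    ``signal`` is fluorescence (a.u., ``mode="fluorescence"``) or polymerized
    actin in uM (``mode="concentration"``).  ``conditions`` carries assay
    metadata (Arp2/3, GST-VCA, cortactin concentrations, ...).
    """

    time: np.ndarray
    signal: np.ndarray
    total_actin: float
    mode: str = "concentration"
    conditions: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "signal", s)
        if t.ndim != 1 or t.shape != s.shape:
            raise ValueError("time and signal must be matching 1-D arrays")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(s)):
            raise ValueError("signal must be finite")
        if self.mode not in ("fluorescence", "concentration"):
            raise ValueError(f"unknown mode {self.mode!r}")


def _plateau_ok(signal: np.ndarray, tail_frac: float = 0.05,
                rel_band: float = 0.01) -> bool:
    """Plateau criterion: the trailing ``tail_frac`` of samples all lie
    within ``rel_band`` (relative to the full signal range) of their mean."""
    n_tail = max(int(round(tail_frac * signal.size)), 3)
    tail = signal[-n_tail:]
    span = np.ptp(signal)
    if span <= 0:
        return True
    return bool(np.max(np.abs(tail - tail.mean())) <= rel_band * span)


def fluorescence_to_concentration(trace: PolymerizationTrace,
                                  unpolymerized: float = UNPOLYMERIZED_AT_EQ,
                                  tail_frac: float = 0.05,
                                  rel_band: float = 0.01,
                                  ) -> PolymerizationTrace:
    """Affine-rescale a fluorescence trace to polymerized actin (uM).

    The starting baseline maps to 0 and the equilibrium plateau to
    ``total_actin - unpolymerized``.  Already-converted traces are returned
    unchanged (idempotent).
    """
    if trace.mode == "concentration":
        return trace
    if trace.total_actin <= unpolymerized:
        raise ValueError(
            f"total_actin ({trace.total_actin} uM) must exceed the "
            f"unpolymerized equilibrium pool ({unpolymerized} uM)")
    if not _plateau_ok(trace.signal, tail_frac, rel_band):
        raise ValueError("no equilibrium plateau detected in trace tail")
    n_tail = max(int(round(tail_frac * trace.signal.size)), 3)
    baseline = trace.signal[0]
    plateau = trace.signal[-n_tail:].mean()
    if plateau <= baseline:
        raise ValueError("plateau does not exceed baseline")
    scale = (trace.total_actin - unpolymerized) / (plateau - baseline)
    return replace(trace, signal=(trace.signal - baseline) * scale,
                   mode="concentration")


def max_polymerization_rate(trace: PolymerizationTrace,
                            window: int = 11) -> float:
    """Maximum slope (uM/s) of a centered local-quadratic fit of the trace.

    Implemented as the peak of a Savitzky-Golay first derivative
    (polynomial order 2) over ``window`` points; robust to the point noise
    of pyrene traces.
    """
    if trace.mode != "concentration":
        raise ValueError("trace must be in concentration mode")
    if window > trace.signal.size:
        raise ValueError(f"window ({window}) larger than trace "
                         f"({trace.signal.size} points)")
    window = max(window, 5)
    if window % 2 == 0:
        window += 1
    dt = float(np.mean(np.diff(trace.time)))
    deriv = savgol_filter(trace.signal, window_length=window, polyorder=2,
                          deriv=1, delta=dt)
    return float(np.max(deriv))


def half_time_to_equilibrium(trace: PolymerizationTrace,
                             tail_frac: float = 0.05,
                             rel_band: float = 0.01) -> float:
    """Earliest time at which the trace crosses half its plateau value,
    linearly interpolated between samples."""
    if trace.mode != "concentration":
        raise ValueError("trace must be in concentration mode")
    if not _plateau_ok(trace.signal, tail_frac, rel_band):
        raise ValueError("plateau not reached within trace")
    n_tail = max(int(round(tail_frac * trace.signal.size)), 3)
    plateau = trace.signal[-n_tail:].mean()
    half = plateau / 2.0
    above = trace.signal >= half
    if above[0]:
        return 0.0
    i = int(np.argmax(above))
    if i == 0:
        raise ValueError("trace never reaches half its plateau")
    t0, t1 = trace.time[i - 1], trace.time[i]
    s0, s1 = trace.signal[i - 1], trace.signal[i]
    return float(t0 + (half - s0) * (t1 - t0) / (s1 - s0))


def fold_activation(rate: float, reference_rate: float) -> float:
    """Ratio of a maximum polymerization rate to its cortactin-free
    reference rate."""
    if reference_rate <= 0:
        raise ValueError("reference_rate must be > 0")
    return rate / reference_rate


# ---------------------------------------------------------------------------
# Saturating-hyperbola synergy fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynergyCurveFit:
    """Parameters of fold(c) = background + amplitude * c / (half_max + c)."""

    half_max_conc: float        # uM, concentration at half-maximal synergy
    amplitude: float            # fold increase at saturation above background
    background: float           # fold activation at zero cortactin (fixed)
    residuals: np.ndarray
    identifiable: bool = True

    @property
    def max_fold(self) -> float:
        """Fold activation at saturation."""
        return self.background + self.amplitude

    def predict(self, concs) -> np.ndarray:
        c = np.asarray(concs, dtype=float)
        return self.background + self.amplitude * c / (self.half_max_conc + c)


class SynergyHyperbola:
    """Saturating-hyperbola fit of fold activation vs activator concentration.

    sklearn-style estimator: ``fit(concs, folds)`` stores ``half_max_conc_``,
    ``amplitude_``, ``background_`` and ``result_``; ``predict(concs)``
    evaluates the fitted curve.  The background is fixed to the measured
    zero-concentration activity, not floated.
    """

    def __init__(self, min_points: int = 4):
        self.min_points = min_points

    def get_params(self, deep=True):
        return {"min_points": self.min_points}

    def set_params(self, **params):
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, concs, folds):
        c = np.asarray(concs, dtype=float)
        y = np.asarray(folds, dtype=float)
        if c.shape != y.shape or c.ndim != 1:
            raise ValueError("concs and folds must be matching 1-D arrays")
        if c.size < self.min_points:
            raise ValueError(f"need >= {self.min_points} points, got {c.size}")
        zero = c == 0
        if not np.any(zero):
            raise ValueError("a zero-concentration point is required to fix "
                             "the background")
        background = float(np.mean(y[zero]))
        mask = ~zero
        cm, ym = c[mask], y[mask]
        span = float(ym.max() - background)
        identifiable = True
        if span <= 0 or np.allclose(y, y[0]):
            # flat curve: amplitude 0, half_max unidentifiable
            half_max, amplitude = float(np.median(cm)), 0.0
            identifiable = False
            residuals = y - background
        else:
            def resid(p):
                log_km, amp = p
                return background + amp * cm / (np.exp(log_km) + cm) - ym

            p0 = np.array([np.log(np.median(cm)), span])
            sol = least_squares(resid, p0, method="lm", xtol=1e-15,
                                ftol=1e-15, gtol=1e-15)
            half_max, amplitude = float(np.exp(sol.x[0])), float(sol.x[1])
            residuals = np.empty_like(y)
            residuals[zero] = y[zero] - background
            residuals[mask] = sol.fun
        self.background_ = background
        self.half_max_conc_ = half_max
        self.amplitude_ = amplitude
        self.result_ = SynergyCurveFit(half_max, amplitude, background,
                                       residuals, identifiable)
        return self

    def predict(self, concs):
        return self.result_.predict(concs)


def fit_synergy_hyperbola(concs, folds) -> SynergyCurveFit:
    """Least-squares saturating-hyperbola fit with fixed background.

    Thin wrapper over :class:`SynergyHyperbola`.
    """
    return SynergyHyperbola().fit(concs, folds).result_


# ---------------------------------------------------------------------------
# CSV IO: two-column trace files with a '#'-prefixed metadata header
# ---------------------------------------------------------------------------

def write_trace_csv(trace: PolymerizationTrace, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# mode: {trace.mode}\n")
        fh.write(f"# total_actin: {trace.total_actin}\n")
        for key, value in sorted(trace.conditions.items()):
            fh.write(f"# {key}: {value}\n")
        pd.DataFrame({"time": trace.time, "signal": trace.signal}).to_csv(
            fh, index=False)


def read_trace_csv(path) -> PolymerizationTrace:
    meta: dict = {}
    lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = value.strip()
            else:
                lines.append(line)
    df = pd.read_csv(StringIO("".join(lines)))
    mode = meta.pop("mode", "concentration")
    total = float(meta.pop("total_actin", "nan"))
    conditions = {}
    for key, value in meta.items():
        try:
            conditions[key] = float(value)
        except ValueError:
            conditions[key] = value
    return PolymerizationTrace(df["time"].to_numpy(), df["signal"].to_numpy(),
                               total_actin=total, mode=mode,
                               conditions=conditions)
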