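"""Global kinetic fitting and mechanism comparison.

Floating rate constants of a network variant are estimated by simultaneously
fitting the simulated polymerized-actin traces to an ensemble of observed
traces (one set of shared parameters across all conditions), using
Levenberg-Marquardt on log-transformed parameters so positivity is built in
(optimization backed by :mod:`lmfit`).

Quality of fit is a mean-weighted residual sum of squares: for each trace the
residual sum of squares is divided by the squared mean of the observed trace,
and the per-trace terms are averaged across the ensemble,

    qof = (1/T) * sum_j [ sum_i (sim_ji - obs_ji)^2 / mean_j(obs)^2 ].

This normalization makes the statistic invariant to rescaling all traces and
comparable across conditions of different amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import lmfit
import numpy as np
import pandas as pd

from .network import build_network
from .simulate import Conditions, add_side_sites, simulate
from .traces import PolymerizationTrace, half_time_to_equilibrium

__all__ = [
    "FitResult",
    "ThresholdScan",
    "OnRate",
    "quality_of_fit",
    "conditions_from_trace",
    "global_fit",
    "scan_k_fil_on",
    "recruitment_test",
    "k_on_from_kd",
]

_CONDITION_KEYS = ("actin_monomer", "arp23", "gst_vca_monomeric", "cortactin",
                   "preformed_side_sites", "t_end")


def conditions_from_trace(trace: PolymerizationTrace,
                          **extra) -> Conditions:
    """Build simulation :class:`Conditions` from a trace's metadata."""
    kwargs = {k: trace.conditions[k] for k in _CONDITION_KEYS
              if k in trace.conditions}
    kwargs.setdefault("actin_monomer", trace.total_actin)
    kwargs.setdefault("t_end", float(trace.time[-1]))
    kwargs.update(extra)
    return Conditions(**kwargs)


def quality_of_fit(simulated: Sequence[PolymerizationTrace],
                   observed: Sequence[PolymerizationTrace]) -> float:
    """Mean-weighted residual sum of squares across matched trace pairs.

    Simulated traces are interpolated onto each observed time grid.
    """
    if len(simulated) != len(observed) or not observed:
        raise ValueError("simulated and observed trace sets must be "
                         "non-empty and matched 1:1")
    total = 0.0
    for sim, obs in zip(simulated, observed):
        if sim.time[0] > obs.time[-1] or sim.time[-1] < obs.time[0]:
            raise ValueError("simulated and observed time ranges do not "
                             "overlap")
        sim_on_obs = np.interp(obs.time, sim.time, sim.signal)
        mean = float(np.mean(obs.signal))
        if mean == 0.0:
            raise ValueError("observed trace has zero mean; qof undefined")
        total += float(np.sum((sim_on_obs - obs.signal) ** 2)) / mean**2
    return total / len(observed)


@dataclass
class FitResult:
    """Optimized floating parameters and fit diagnostics.

    ``floated`` values are in internal units (uM^-1 s^-1 for bimolecular
    constants, s^-1 for unimolecular).
    """

    floated: dict[str, float]
    quality_of_fit: float
    per_trace_residuals: list[np.ndarray]
    converged: bool
    n_iterations: int
    at_bound: tuple[str, ...] = ()
    message: str = ""


def _simulate_ensemble(variant: str, traces, overrides):
    net = build_network(variant, overrides=overrides)
    sims = []
    for trace in traces:
        cond = conditions_from_trace(trace)
        res = simulate(net, cond, t_eval=trace.time)
        sims.append(PolymerizationTrace(res.time, res.polymerized_actin,
                                        total_actin=cond.actin_monomer,
                                        conditions=dict(trace.conditions)))
    return sims


def global_fit(variant: str,
               traces: Sequence[PolymerizationTrace],
               floated: Sequence[str] | None = None,
               bounds: dict[str, tuple[float, float]] | None = None,
               initial: dict[str, float] | None = None,
               fixed: dict[str, float] | None = None,
               allow_extra: bool = False,
               max_nfev: int | None = None) -> FitResult:
    """Fit floating rate constants jointly across a trace ensemble.

    Parameters
    ----------
    variant : str
        Network variant name; its tabulated floating-parameter list is the
        default for *floated* and constrains it unless ``allow_extra``.
    traces : sequence of PolymerizationTrace
        Observed concentration-mode traces; each must carry its reaction
        conditions in ``trace.conditions``.
    floated : sequence of str, optional
        Parameter keys (``"kN"``, ``"k-N"``, ``"k_fil_on"``) to optimize.
    bounds, initial, fixed : dict, optional
        Per-parameter (lo, hi) bounds, starting values, and non-floated
        overrides, in internal units.  Defaults start from the packaged
        table values.
    """
    net0 = build_network(variant)
    if floated is None:
        floated = net0.floated
    floated = list(floated)
    if not allow_extra:
        extra = set(floated) - set(net0.floated)
        if extra:
            raise ValueError(
                f"parameters {sorted(extra)} are not floatable for variant "
                f"{variant!r} (tabulated: {list(net0.floated)}); pass "
                "allow_extra=True to override")
    for trace in traces:
        if trace.mode != "concentration":
            raise ValueError("all traces must be in concentration mode")

    defaults = _default_values(net0)
    initial = {**{k: defaults[k] for k in floated}, **(initial or {})}
    bounds = bounds or {}
    params = lmfit.Parameters()
    names = {}
    for key in floated:
        name = key.replace("-", "m").replace("_", "")
        names[name] = key
        lo, hi = bounds.get(key, (initial[key] * 1e-4, initial[key] * 1e4))
        params.add(name, value=np.log(initial[key]), min=np.log(lo),
                   max=np.log(hi))

    n_traces = len(traces)
    means = [float(np.mean(t.signal)) for t in traces]

    def residual(p):
        overrides = dict(fixed or {})
        overrides.update({names[name]: float(np.exp(p[name].value))
                          for name in p})
        sims = _simulate_ensemble(variant, traces, overrides)
        parts = [(s.signal - t.signal) / (m * np.sqrt(n_traces))
                 for s, t, m in zip(sims, traces, means)]
        return np.concatenate(parts)

    mini = lmfit.minimize(residual, params, method="leastsq",
                          max_nfev=max_nfev)
    values = {names[name]: float(np.exp(mini.params[name].value))
              for name in mini.params}
    at_bound = tuple(
        key for name, key in names.items()
        if not (mini.params[name].min + 1e-9 < mini.params[name].value
                < mini.params[name].max - 1e-9))
    final = _simulate_ensemble(variant, traces, {**(fixed or {}), **values})
    qof = quality_of_fit(final, traces)
    residuals = [s.signal - t.signal for s, t in zip(final, traces)]
    return FitResult(floated=values, quality_of_fit=qof,
                     per_trace_residuals=residuals,
                     converged=bool(mini.success), n_iterations=mini.nfev,
                     at_bound=at_bound, message=mini.message)


def _default_values(net) -> dict[str, float]:
    out = {}
    for rid, rc in net.rate_constants.items():
        out[f"k{rid}"] = rc.k_fwd
        if rc.k_rev is not None:
            out[f"k-{rid}"] = rc.k_rev
    out["k_fil_on"] = net.rate_constants[13].k_fwd if 13 in net.rate_constants \
        else 1.37
    return out


@dataclass
class ThresholdScan:
    """Quality of fit and co-optimized parameters along a k_fil_on grid.

    ``k_fil_on_grid`` is in M^-1 s^-1 (the reporting convention);
    ``threshold`` is the least grid value whose qof falls at or below the
    cutoff, or ``None`` if the cutoff is never reached.
    """

    k_fil_on_grid: np.ndarray
    qof: np.ndarray
    co_optimized: list[dict[str, float]]
    qof_cutoff: float
    threshold: float | None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"k_fil_on_M": self.k_fil_on_grid,
                           "qof": self.qof})
        for key in (self.co_optimized[0] if self.co_optimized else {}):
            df[key] = [co[key] for co in self.co_optimized]
        return df


def scan_k_fil_on(variant: str,
                  traces: Sequence[PolymerizationTrace],
                  grid: Sequence[float],
                  qof_cutoff: float,
                  co_floated: Sequence[str] | None = None,
                  **fit_kwargs) -> ThresholdScan:
    """Profile the fit over fixed filament-side on rates.

    For each grid value (M^-1 s^-1), k_fil_on is clamped globally across
    reactions 13/19/21/22 and the remaining floating parameter(s) are
    re-optimized; the threshold is the smallest k_fil_on fitting the data at
    or below ``qof_cutoff``.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 1 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be a strictly increasing 1-D array")
    if co_floated is None:
        co_floated = [k for k in build_network(variant).floated
                      if k != "k_fil_on"]
    qofs = np.empty(grid.size)
    co_opt: list[dict[str, float]] = []
    for i, k_m in enumerate(grid):
        fixed = {"k_fil_on": k_m * 1e-6}  # M^-1 s^-1 -> uM^-1 s^-1
        fit = global_fit(variant, traces, floated=list(co_floated),
                         fixed=fixed, allow_extra=True, **fit_kwargs)
        qofs[i] = fit.quality_of_fit
        co_opt.append(dict(fit.floated))
    below = np.nonzero(qofs <= qof_cutoff)[0]
    threshold = float(grid[below[0]]) if below.size else None
    return ThresholdScan(grid, qofs, co_opt, qof_cutoff, threshold)


def recruitment_test(k_fil_on: float,
                     side_site_grid: Sequence[float],
                     conditions: Conditions | None = None,
                     variant: str = "branching") -> np.ndarray:
    """Half-times of the branching model with extra filament side sites.

    Emulates pure filament recruitment (a type II NPF concentrating Arp2/3
    complex on filament sides without touching ends): the cortactin-free
    branching network is simulated with ``side_site_grid`` uM of preformed
    side-binding sites added, at a fixed global ``k_fil_on`` (M^-1 s^-1).
    Returns the half-time to equilibrium (s) per grid point, for comparison
    with cortactin-driven half-times of the displacement model.
    """
    if k_fil_on <= 0:
        raise ValueError("k_fil_on must be > 0")
    grid = np.asarray(side_site_grid, dtype=float)
    if np.any(grid < 0):
        raise ValueError("side sites must be >= 0")
    if conditions is None:
        conditions = Conditions(actin_monomer=3.0, arp23=0.02,
                                gst_vca_monomeric=0.1, t_end=2000.0)
    net = build_network(variant, overrides={"k_fil_on": k_fil_on * 1e-6})
    t_half = np.empty(grid.size)
    for i, amount in enumerate(grid):
        res = simulate(net, add_side_sites(conditions, amount))
        trace = PolymerizationTrace(res.time, res.polymerized_actin,
                                    total_actin=conditions.actin_monomer)
        t_half[i] = half_time_to_equilibrium(trace)
    return t_half


class OnRate(NamedTuple):
    """Association rate constant in both reporting conventions."""

    per_uM_s: float
    per_M_s: float


def k_on_from_kd(k_off: float, K_D: float) -> OnRate:
    """On rate implied by an off rate (s^-1) and a K_D (uM): k_on = k_off/K_D."""
    if k_off <= 0 or K_D <= 0:
        raise ValueError("k_off and K_D must be > 0")
    per_um = k_off / K_D
    return OnRate(per_uM_s=per_um, per_M_s=per_um * 1e6)
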