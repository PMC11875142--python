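"""Steady-state fermentation performance metrics and stability calls.

For a chemostat at dilution rate ``D`` with steady-state product titre
``C_P`` (g L^-1), biomass ``C_X`` (g DCW L^-1) and consumed substrate
``C_S`` (g L^-1), the five performance parameters are

==========================  =============================  =====================
specific productivity       ``C_P * D / C_X``              g_P g_DCW^-1 h^-1
specific uptake rate        ``C_S * D / C_X``              g_S g_DCW^-1 h^-1
Yield(P/S)                  ``C_P / C_S``                  g_P g_S^-1
Yield(P/X)                  ``C_P / C_X``                  g_P g_DCW^-1
Yield(X/S)                  ``C_X / C_S``                  g_DCW g_S^-1
==========================  =============================  =====================

Both specific rates are normalised by biomass, which makes the set
algebraically closed: productivity/uptake == Yield(P/S) and
Yield(P/X) x Yield(X/S) == Yield(P/S).

The module also provides steady-state window detection, the stability
duration (time at steady state until the run ends or collapses),
patch-plating segregational-stability estimation, and the indirect
inference of structural instability (productivity lost while the plasmid
is demonstrably retained).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_data import FermentationTimeSeries, SteadyStateWindow

__all__ = [
    "MetricSet",
    "compute_metrics",
    "glucose_consumed",
    "detect_steady_state",
    "stability_duration",
    "segregational_stability",
    "StructuralCall",
    "infer_structural_instability",
]


@dataclass
class MetricSet:
    specific_productivity: float  # g_CMA g_DCW^-1 h^-1
    specific_uptake: float        # g_Glu g_DCW^-1 h^-1
    yield_ps: float               # g_CMA g_Glu^-1
    yield_px: float               # g_CMA g_DCW^-1
    yield_xs: float               # g_DCW g_Glu^-1


def compute_metrics(cma, biomass, glucose_consumed, dilution_rate) -> MetricSet:
    """Compute the five performance parameters from steady-state averages.

    Parameters are concentrations in g L^-1 (``biomass`` as dry cell
    weight) and the dilution rate in h^-1.
    """
    if biomass <= 0:
        raise ValueError("biomass must be positive")
    if glucose_consumed <= 0:
        raise ValueError("consumed glucose must be positive")
    if cma < 0:
        raise ValueError("product titre must be non-negative")
    return MetricSet(
        specific_productivity=cma * dilution_rate / biomass,
        specific_uptake=glucose_consumed * dilution_rate / biomass,
        yield_ps=cma / glucose_consumed,
        yield_px=cma / biomass,
        yield_xs=biomass / glucose_consumed,
    )


def glucose_consumed(feed, residual):
    """Consumed substrate ``feed - residual`` (g L^-1), floored at zero.

    A residual above the feed cannot happen at steady operation; it is
    floored with a warning rather than rejected, since transient samples
    can show it.
    """
    if feed < 0 or residual < 0:
        raise ValueError("feed and residual concentrations must be >= 0")
    if residual > feed:
        warnings.warn(
            f"residual glucose {residual} exceeds feed {feed}; "
            "consumed floored at 0", stacklevel=2)
        return 0.0
    return float(feed - residual)


def _cv(x):
    m = np.mean(x)
    if m == 0:
        return np.inf
    return float(np.std(x, ddof=1) / m)


def detect_steady_state(ts: FermentationTimeSeries,
                        window_residence_times: float = 3.0,
                        cv_threshold: float = 0.10) -> SteadyStateWindow | None:
    """Find the earliest stable stretch of a fermentation.

    A window of ``window_residence_times / D`` hours qualifies when the
    coefficients of variation of both titre and biomass within it fall
    below ``cv_threshold``.  The reported window runs from the start of the
    earliest qualifying window to the end of the last consecutive
    qualifying one (or the end of the series).  Returns ``None`` when no
    window qualifies.
    """
    length = window_residence_times / ts.dilution_rate
    t = ts.times
    if len(t) < 3 or t[-1] - t[0] < length:
        raise ValueError("series shorter than one evaluation window")

    starts = [i for i in range(len(t)) if t[i] + length <= t[-1] + 1e-9]
    ok = []
    for i in starts:
        j = int(np.searchsorted(t, t[i] + length, side="right"))
        seg = slice(i, max(j, i + 3))
        if seg.stop > len(t):
            break
        ok.append(_cv(ts.cma[seg]) < cv_threshold and _cv(ts.dcw[seg]) < cv_threshold)
    if not any(ok):
        return None
    first = ok.index(True)
    last = first
    while last + 1 < len(ok) and ok[last + 1]:
        last += 1
    i0 = starts[first]
    j1 = int(np.searchsorted(t, t[starts[last]] + length, side="right"))
    j1 = min(max(j1, i0 + 3), len(t))
    seg = slice(i0, j1)
    return SteadyStateWindow(
        start_time=float(t[i0]),
        end_time=float(t[j1 - 1]),
        mean_dcw=float(np.mean(ts.dcw[seg])),
        mean_cma=float(np.mean(ts.cma[seg])),
        mean_glucose_residual=float(np.mean(ts.glucose_residual[seg])),
        cv_dcw=_cv(ts.dcw[seg]),
        cv_cma=_cv(ts.cma[seg]),
    )


def stability_duration(ts: FermentationTimeSeries, window: SteadyStateWindow) -> float:
    """Stability duration: last sampled time minus the steady-state onset."""
    if not (ts.times[0] <= window.start_time <= ts.times[-1]):
        raise ValueError("window does not lie within the series")
    return float(ts.times[-1] - window.start_time)


def segregational_stability(n_grew_on_both: int, n_picked: int = 50,
                            alpha: float = 0.05):
    """Plasmid-retention estimate from patch plating.

    Colonies from a non-selective plate are patched onto selective medium;
    the fraction growing on both estimates the plasmid-bearing fraction.
    Returns ``(fraction, (lower, upper))`` with an exact Clopper-Pearson
    binomial interval at level ``1 - alpha``.
    """
    if n_picked < 1:
        raise ValueError("need at least one colony")
    if not 0 <= n_grew_on_both <= n_picked:
        raise ValueError("count must lie in [0, n_picked]")
    k, n = n_grew_on_both, n_picked
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return k / n, (lo, hi)


@dataclass
class StructuralCall:
    """Outcome of the structural-instability inference."""

    status: str          # "structural", "not_structural", "indeterminate"
    onset_time: float | None = None

    @property
    def flagged(self) -> bool:
        return self.status == "structural"


def infer_structural_instability(ts: FermentationTimeSeries,
                                 window: SteadyStateWindow,
                                 decline_fraction: float = 0.2,
                                 plasmid_floor: float = 0.9) -> StructuralCall:
    """Infer structural instability from a sustained productivity loss.

    Mutation of the product pathway on a *retained* plasmid shows up as a
    drop in titre while patch plating still finds plasmid-bearing cells.
    The call is ``structural`` when the titre stays below
    ``(1 - decline_fraction)`` times the steady-state mean for at least one
    residence time, and the plasmid-fraction observations nearest that
    stretch are all >= ``plasmid_floor``.  A drop coinciding with plasmid
    loss is ``not_structural`` (segregational); with no plasmid
    observations at all the call is ``indeterminate``.
    """
    obs_mask = ~np.isnan(ts.plasmid_fraction)
    if not obs_mask.any():
        return StructuralCall("indeterminate")

    level = (1.0 - decline_fraction) * window.mean_cma
    tau = ts.residence_time
    t = ts.times
    below = ts.cma < level
    # search for the first stretch below `level` lasting >= one residence time
    i = int(np.searchsorted(t, window.start_time))
    onset = None
    while i < len(t):
        if below[i]:
            j = i
            while j + 1 < len(t) and below[j + 1]:
                j += 1
            if t[j] - t[i] >= tau or (j == len(t) - 1 and t[j] - t[i] >= 0.5 * tau):
                onset = i
                break
            i = j + 1
        i += 1
    if onset is None:
        return StructuralCall("not_structural")

    t_on = float(t[onset])
    obs_t = t[obs_mask]
    obs_f = ts.plasmid_fraction[obs_mask]
    # nearest observations around the onset (up to two on each side)
    order = np.argsort(np.abs(obs_t - t_on))[:4]
    retained = np.all(obs_f[order] >= plasmid_floor)
    if retained:
        return StructuralCall("structural", onset_time=t_on)
    return StructuralCall("not_structural", onset_time=t_on)
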