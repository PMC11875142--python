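"""Synthetic chemostat generator for plasmid-stability analyses.

The generator is a deliberately small mechanistic test harness, not a
calibrated bioprocess model.  It reproduces the statistical structure the
analysis pipeline assumes:

* two competing populations — plasmid-bearing ``Xp`` and plasmid-free
  ``Xf`` — growing Monod-limited on a scarce feed nutrient (a phosphate
  proxy; glucose is fed in excess, mirroring phosphate-limited operation
  at roughly 1 g DCW L^-1),
* segregational loss: a fraction ``theta`` of plasmid-bearing divisions
  yields plasmid-free offspring, and plasmid-free cells may hold a growth
  advantage,
* structural instability: a seeded exponential onset time after which the
  specific production rate drops (stepwise by default, optionally as a
  gradual exponential decay),
* slow sinusoidal modulation of productivity at 37 degC, emulating the
  long-period oscillations seen in practice at that temperature,
* multiplicative log-normal measurement noise at sampling, and binomial
  patch-plating observation of the plasmid-bearing fraction.

State equations (g L^-1, h):

    mu_i = mu_max_i * S / (Ks + S)                 i in {p, f}
    dXp/dt = ((1 - theta) * mu_p - D) * Xp
    dXf/dt = (mu_f - D) * Xf + theta * mu_p * Xp
    dS/dt  = D * (S_feed - S) - (mu_p Xp + mu_f Xf) / Y_xs
    dP/dt  = q(t) * Xp - D * P
    dG/dt  = D * (G_feed - G) - g_x (mu_p Xp + mu_f Xf) - g_p q(t) Xp

with q(t) = q_cma * decay(t) * osc(t).  Integration is fixed-step RK4
(step <= sample_interval / 10) for bitwise reproducibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core_data import (FermentationTimeSeries, SteadyStateRecord,
                        SteadyStateWindow)
from .metrics import (compute_metrics, detect_steady_state, glucose_consumed,
                      infer_structural_instability)

__all__ = [
    "ChemostatParams",
    "analytic_steady_state",
    "simulate",
    "takeover_time",
    "patch_plate_sample",
    "generate_steady_state_dataset",
    "paper_like_design",
]


@dataclass
class ChemostatParams:
    """Operating conditions and rate constants for one simulated run.

    Defaults describe a stable, phosphate-limited production run at
    D = 0.033 h^-1 and 37 degC: ~1 g L^-1 biomass, 6-9 g L^-1 product
    and a residual-glucose level a few g L^-1 below the 16 g L^-1 feed,
    matching the operating envelope of the reference fermentations.
    """

    dilution_rate: float = 0.033     # h^-1
    temperature: float = 37.0        # degC
    mu_max_plasmid: float = 0.30     # h^-1
    mu_max_free: float = 0.30        # h^-1
    monod_ks: float = 0.005          # g L^-1 (limiting-nutrient proxy)
    nutrient_feed: float = 0.055     # g L^-1
    biomass_yield_on_nutrient: float = 20.0  # g DCW per g nutrient
    segregation_prob: float = 0.0    # per-division plasmid-loss probability
    structural_event_rate: float = 0.0  # h^-1; exponential onset of decay
    productivity_decay: float = 0.7  # fractional drop at the event
    gradual_decay_rate: float = 0.0  # h^-1; >0 switches to gradual decay
    q_cma: float = 0.21              # g_CMA g_DCW^-1 h^-1 when intact
    glucose_feed: float = 16.0       # g L^-1
    glucose_per_biomass: float = 3.3  # g_Glu per g DCW formed
    glucose_per_cma: float = 1.2     # g_Glu per g CMA formed
    oscillation_amplitude: float = 0.0  # fraction of q_cma, active at 37 degC
    oscillation_period: float = 90.0    # h
    noise_cv: float = 0.0            # measurement CV on dcw/cma/glucose
    sample_interval: float = 4.0     # h
    steps_per_sample: int = 10       # integrator steps per sample interval
    horizon: float = 500.0           # h
    initial_biomass: float = 0.05    # g L^-1, all plasmid-bearing
    initial_plasmid_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.segregation_prob <= 1.0:
            raise ValueError("segregation_prob must lie in [0, 1]")
        for name in ("dilution_rate", "monod_ks", "nutrient_feed",
                     "biomass_yield_on_nutrient", "glucose_feed",
                     "sample_interval", "horizon"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("mu_max_plasmid", "mu_max_free", "q_cma", "noise_cv",
                     "structural_event_rate", "glucose_per_biomass",
                     "glucose_per_cma", "oscillation_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def analytic_steady_state(p: ChemostatParams) -> dict:
    """Closed-form fixed point for a pure plasmid-bearing culture.

    Valid for ``segregation_prob = 0`` and no structural events:
    ``S* = Ks D / (mu_max - D)``, ``X* = Y (S_feed - S*)``,
    ``P* = q X* / D`` and the matching residual glucose.
    """
    D, mu = p.dilution_rate, p.mu_max_plasmid
    if D >= mu:
        raise ValueError("washout: D >= mu_max, no productive steady state")
    s = p.monod_ks * D / (mu - D)
    x = p.biomass_yield_on_nutrient * (p.nutrient_feed - s)
    if x <= 0:
        raise ValueError("feed nutrient too low to sustain biomass")
    cma = p.q_cma * x / D
    glu = p.glucose_feed - p.glucose_per_biomass * x - p.glucose_per_cma * cma
    return {"biomass": x, "nutrient": s, "cma": cma, "glucose_residual": glu}


def _decay_factor(t, tau, p: ChemostatParams):
    if tau is None or t < tau:
        return 1.0
    if p.gradual_decay_rate > 0:
        return math.exp(-p.gradual_decay_rate * (t - tau))
    return 1.0 - p.productivity_decay


def simulate(p: ChemostatParams) -> FermentationTimeSeries:
    """Integrate one chemostat run and sample it like a real fermentation."""
    rng = np.random.default_rng(p.seed)
    tau = None
    if p.structural_event_rate > 0:
        tau = float(rng.exponential(1.0 / p.structural_event_rate))

    osc_on = p.oscillation_amplitude > 0 and abs(p.temperature - 37.0) < 0.5
    two_pi_over_T = 2.0 * math.pi / p.oscillation_period

    D = p.dilution_rate
    ks, y_n = p.monod_ks, p.biomass_yield_on_nutrient
    mp, mf, theta = p.mu_max_plasmid, p.mu_max_free, p.segregation_prob
    gx, gp = p.glucose_per_biomass, p.glucose_per_cma
    sf, gf = p.nutrient_feed, p.glucose_feed

    def q_at(t):
        q = p.q_cma * _decay_factor(t, tau, p)
        if osc_on:
            q *= 1.0 + p.oscillation_amplitude * math.sin(two_pi_over_T * t)
        return q

    def deriv(t, xp, xf, s, g, prod):
        mono = s / (ks + s) if s > 0 else 0.0
        mup, muf = mp * mono, mf * mono
        growth = mup * xp + muf * xf
        q = q_at(t)
        return (
            ((1.0 - theta) * mup - D) * xp,
            (muf - D) * xf + theta * mup * xp,
            D * (sf - s) - growth / y_n,
            D * (gf - g) - gx * growth - gp * q * xp,
            q * xp - D * prod,
        )

    steps_per_sample = max(int(p.steps_per_sample), 10)
    dt = p.sample_interval / steps_per_sample
    n_samples = int(math.floor(p.horizon / p.sample_interval)) + 1
    xp = p.initial_biomass * p.initial_plasmid_fraction
    xf = p.initial_biomass * (1.0 - p.initial_plasmid_fraction)
    s, g, prod = sf, gf, 0.0

    times = np.empty(n_samples)
    dcw = np.empty(n_samples)
    cma = np.empty(n_samples)
    glu = np.empty(n_samples)
    frac = np.empty(n_samples)

    t = 0.0
    for i_sample in range(n_samples):
        if i_sample > 0:
            for _ in range(steps_per_sample):
                k1 = deriv(t, xp, xf, s, g, prod)
                k2 = deriv(t + dt / 2, xp + dt / 2 * k1[0], xf + dt / 2 * k1[1],
                           s + dt / 2 * k1[2], g + dt / 2 * k1[3], prod + dt / 2 * k1[4])
                k3 = deriv(t + dt / 2, xp + dt / 2 * k2[0], xf + dt / 2 * k2[1],
                           s + dt / 2 * k2[2], g + dt / 2 * k2[3], prod + dt / 2 * k2[4])
                k4 = deriv(t + dt, xp + dt * k3[0], xf + dt * k3[1],
                           s + dt * k3[2], g + dt * k3[3], prod + dt * k3[4])
                xp += dt / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
                xf += dt / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
                s += dt / 6 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
                g += dt / 6 * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])
                prod += dt / 6 * (k1[4] + 2 * k2[4] + 2 * k3[4] + k4[4])
                t += dt
            if min(xp, xf, s, g, prod) < -1e-6:
                raise ArithmeticError(
                    "integration produced a negative state; use a smaller "
                    "sample_interval (the step is sample_interval/10)")
            xp, xf = max(xp, 0.0), max(xf, 0.0)
            s, g, prod = max(s, 0.0), max(g, 0.0), max(prod, 0.0)
        total = xp + xf
        times[i_sample] = t
        dcw[i_sample] = total
        cma[i_sample] = prod
        glu[i_sample] = g
        frac[i_sample] = xp / total if total > 0 else np.nan

    if p.noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + p.noise_cv ** 2))
        mu_ln = -0.5 * sigma ** 2  # unit-mean log-normal
        for arr in (dcw, cma, glu):
            arr *= rng.lognormal(mu_ln, sigma, size=n_samples)

    meta = {"seed": str(p.seed)}
    if tau is not None:
        meta["structural_event_time"] = f"{tau:.3f}"
    return FermentationTimeSeries(
        times=times, dcw=dcw, cma=cma, glucose_residual=glu,
        plasmid_fraction=frac, glucose_feed=p.glucose_feed,
        dilution_rate=p.dilution_rate, temperature=p.temperature,
        metadata=meta,
    )


def takeover_time(p: ChemostatParams) -> float | None:
    """First sampled time at which plasmid-free cells hold the majority.

    Evaluated on a noise-free run; returns ``None`` when the plasmid-
    bearing fraction never drops below one half within the horizon.
    """
    if p.segregation_prob == 0 and p.mu_max_free <= p.mu_max_plasmid:
        return None
    ts = simulate(replace(p, noise_cv=0.0))
    below = np.flatnonzero(ts.plasmid_fraction < 0.5)
    return float(ts.times[below[0]]) if below.size else None


def patch_plate_sample(true_fraction, n_picked=50, seed=0):
    """Binomial patch-plating observation of a plasmid-bearing fraction.

    Returns ``(count, observed_fraction)`` for ``n_picked`` colonies.
    """
    if not 0.0 <= true_fraction <= 1.0:
        raise ValueError("true_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    k = int(rng.binomial(n_picked, true_fraction))
    return k, k / n_picked


# ---------------------------------------------------------------------------
# dataset generation

#: Condition-specific production/uptake levels used by the canned design,
#: chosen to mirror the observed condition means of the reference dataset:
#: higher specific rates at D = 0.1 h^-1, mildly higher product yield at
#: 30 degC, oscillatory productivity only at 37 degC.
CONDITION_PRESETS = {
    (0.033, 37.0): dict(q_cma=0.20, glucose_per_biomass=3.3,
                        oscillation_amplitude=0.10, expected_stability=250.0),
    (0.033, 30.0): dict(q_cma=0.22, glucose_per_biomass=2.7,
                        oscillation_amplitude=0.0, expected_stability=360.0),
    (0.1, 37.0): dict(q_cma=0.34, glucose_per_biomass=2.0,
                      oscillation_amplitude=0.10, expected_stability=330.0),
}

_STRAINS = ("none", "tet", "infA", "ssb", "proBA", "proC", "dapD")
_SIZES = {"none": 3205, "tet": 3646, "infA": 4526, "ssb": 3820,
          "proBA": 6104, "proC": 4080, "dapD": 4095}


def paper_like_design() -> list[dict]:
    """Three operating conditions x seven strains, one cell each."""
    design = []
    for (D, T), preset in CONDITION_PRESETS.items():
        for strain in _STRAINS:
            cell = dict(dilution_rate=D, temperature=T,
                        addiction_system=strain, plasmid_size=_SIZES[strain])
            cell.update(preset)
            design.append(cell)
    return design


_PARAM_FIELDS = {f for f in ChemostatParams.__dataclass_fields__}


def generate_steady_state_dataset(design, n_replicates=1, seed=0,
                                  sample_interval=4.0, horizon=500.0):
    """Simulate a steady-state summary table from a design.

    ``design`` is a list of cells, each a dict with at least
    ``dilution_rate``, ``temperature``, ``addiction_system`` and
    ``plasmid_size``.  Any :class:`ChemostatParams` field may be
    overridden per cell; ``expected_stability`` (h) programs the mean
    structural-event onset (``structural_event_rate = 1/expected``).
    Returns ``(records, ground_truth)`` where ``ground_truth`` carries each
    run's programmed parameters and realised event time, so recovery
    studies can compare estimates against the simulation truth.
    """
    rng = np.random.default_rng(seed)
    records, truth = [], []
    run = 0
    for cell in design:
        for rep in range(n_replicates):
            run += 1
            overrides = {k: v for k, v in cell.items() if k in _PARAM_FIELDS}
            expected = cell.get("expected_stability")
            if expected:
                overrides["structural_event_rate"] = 1.0 / float(expected)
            overrides.setdefault("noise_cv", 0.03)
            overrides.setdefault("sample_interval", sample_interval)
            overrides.setdefault("horizon", horizon)
            overrides["seed"] = int(rng.integers(0, 2**31 - 1))
            p = ChemostatParams(**overrides)
            ts = simulate(p)
            # emulate operational practice: a collapsed fermentation is
            # stopped a few residence times after productivity falls
            if "structural_event_time" in ts.metadata:
                stop = (float(ts.metadata["structural_event_time"])
                        + 3.0 / p.dilution_rate)
                if stop < ts.times[-1]:
                    keep = ts.times <= stop
                    ts = FermentationTimeSeries(
                        times=ts.times[keep], dcw=ts.dcw[keep],
                        cma=ts.cma[keep],
                        glucose_residual=ts.glucose_residual[keep],
                        plasmid_fraction=ts.plasmid_fraction[keep],
                        glucose_feed=ts.glucose_feed,
                        dilution_rate=ts.dilution_rate,
                        temperature=ts.temperature, metadata=ts.metadata)
            try:
                window = detect_steady_state(ts)
            except ValueError:  # run stopped before one full window fits
                window = None
            if window is None:
                # collapsed before any steady window: zero stable production,
                # metrics reported over the tail of the stopped run
                tail = slice(max(len(ts.times) - 4, 0), len(ts.times))
                window = SteadyStateWindow(
                    start_time=float(ts.times[tail][0]),
                    end_time=float(ts.times[-1]),
                    mean_dcw=float(np.mean(ts.dcw[tail])),
                    mean_cma=float(np.mean(ts.cma[tail])),
                    mean_glucose_residual=float(np.mean(ts.glucose_residual[tail])),
                )
                stability = 0.0
            else:
                call = infer_structural_instability(ts, window)
                end = call.onset_time if call.flagged else float(ts.times[-1])
                stability = max(end - window.start_time, 0.0)
            consumed = glucose_consumed(p.glucose_feed, window.mean_glucose_residual)
            m = compute_metrics(window.mean_cma, window.mean_dcw, consumed,
                                p.dilution_rate)
            records.append(SteadyStateRecord(
                ferm_id=f"S{run}",
                strain=f"sim-{cell['addiction_system']}",
                addiction_system=cell["addiction_system"],
                plasmid_size=int(cell["plasmid_size"]),
                dilution_rate=p.dilution_rate,
                temperature=p.temperature,
                total_duration=float(ts.times[-1]),
                stability_duration=float(stability),
                cma_titer=window.mean_cma,
                specific_productivity=m.specific_productivity,
                specific_uptake=m.specific_uptake,
                yield_ps=m.yield_ps, yield_px=m.yield_px, yield_xs=m.yield_xs,
                metadata={"replicate": str(rep)},
            ))
            truth.append({
                "ferm_id": f"S{run}",
                "params": p,
                "expected_stability": expected,
                "event_time": float(ts.metadata["structural_event_time"])
                if "structural_event_time" in ts.metadata else None,
                "steady_state_start": window.start_time,
            })
    return records, truth
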