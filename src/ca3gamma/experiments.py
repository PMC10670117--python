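"""Experiment protocols over the network model.

Four protocols:

- :func:`run_grid` — the factorial (krec, kext) scaling grid with
  seed-matched controls, producing the Δγ condition table.
- :func:`krec_sweep` — recurrent-scaling sweep to (and beyond) the
  seizure transition, with per-level epilepsy verdicts.
- :func:`delay_sweep` — γ-power-vs-krec slope as a function of extra
  synaptic delay on the recurrent collaterals, probing the
  phase-cancellation mechanism.
- :func:`voltage_probe` — somatic voltage response to one synchronized
  volley onto the recurrent (basal-dendrite) synapses of an otherwise
  silent network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analysis import (
    band_power,
    compute_lfp,
    delta_gamma,
    mean_rate,
    raster_gamma,
    welch_power,
)
from .config import NetworkConfig, ScalingCondition
from .engine import SimulationResult, run_paired, run_simulation
from .wiring import apply_scaling

__all__ = [
    "GridDesign",
    "DelaySweepDesign",
    "SeizureVerdict",
    "run_grid",
    "krec_sweep",
    "delay_sweep",
    "voltage_probe",
    "is_epileptic",
    "condition_metrics",
]

log = logging.getLogger(__name__)

SCALING_LEVELS = (1.0, 1.25, 1.5, 1.75)


@dataclass
class GridDesign:
    """Factorial scaling design; the control (1,1) is always included."""

    krec_levels: tuple = SCALING_LEVELS
    kext_levels: tuple = SCALING_LEVELS
    n_seeds: int = 16
    seed0: int = 0

    @property
    def seeds(self) -> list[int]:
        return [self.seed0 + i for i in range(self.n_seeds)]

    def conditions(self) -> list[tuple[float, float]]:
        conds = [
            (kr, ke) for kr in self.krec_levels for ke in self.kext_levels
        ]
        if (1.0, 1.0) not in conds:
            conds.insert(0, (1.0, 1.0))
        return conds


@dataclass
class DelaySweepDesign:
    """Extra recurrent delays (ms) × krec levels × seeds."""

    delays: tuple = (0.0, 17.0, 34.0, 51.0)
    krec_levels: tuple = (1.0, 7.0, 13.0, 19.0)
    n_seeds: int = 8
    seed0: int = 0

    def __post_init__(self) -> None:
        if any(d < 0 for d in self.delays):
            raise ValueError("delays must be >= 0")

    @property
    def seeds(self) -> list[int]:
        return [self.seed0 + i for i in range(self.n_seeds)]


@dataclass
class SeizureVerdict:
    krec: float
    is_epileptic: bool
    pyr_rate: float  # Hz


@dataclass
class EpilepsyCriterion:
    """A run is epileptic if the pyramidal rate explodes relative to its
    seed-matched baseline, or the integrator reports runaway activity."""

    rate_ratio: float = 20.0
    absolute_rate: float = 25.0  # Hz fallback when baseline rate ~ 0


def is_epileptic(result: SimulationResult, baseline_rate: float,
                 criterion: EpilepsyCriterion | None = None) -> bool:
    crit = criterion or EpilepsyCriterion()
    rate = mean_rate(result, "pyr")
    if result.overflow:
        return True
    if baseline_rate > 0.05:
        return rate > crit.rate_ratio * baseline_rate
    return rate > crit.absolute_rate


def condition_metrics(control: SimulationResult, scaled: SimulationResult,
                      krec: float, kext: float, seed: int) -> dict:
    """One tidy row of the condition table."""
    win = scaled.analysis_window
    # Welch segments capped by the analysis window (short test runs)
    seg = min(1.0, (win[1] - win[0]) / 1000.0)
    g_ctrl = band_power(welch_power(compute_lfp(control), segment_len=seg))
    g_cond = band_power(welch_power(compute_lfp(scaled), segment_len=seg))
    t_all = scaled.spike_times
    row = {
        "krec": krec,
        "kext": kext,
        "seed": seed,
        "lfp_gamma": g_cond,
        "lfp_gamma_ctrl": g_ctrl,
        "delta_gamma": delta_gamma(g_cond, g_ctrl),
        "raster_gamma": raster_gamma(t_all, win, segment_len=seg),
        "pyr_rate": mean_rate(scaled, "pyr"),
        "pyr_rate_ctrl": mean_rate(control, "pyr"),
        "epileptic": is_epileptic(scaled, mean_rate(control, "pyr")),
    }
    return row


def run_grid(design: GridDesign, base_config: NetworkConfig) -> pd.DataFrame:
    """One row per (krec, kext, seed); Δγ against the seed-matched control.

    Controls are simulated once per seed and reused across conditions.
    Failed runs are logged and excluded.
    """
    rows = []
    for seed in design.seeds:
        cfg = base_config.copy()
        cfg.seed = seed
        try:
            control = run_simulation(cfg)
        except Exception as exc:  # noqa: BLE001 - logged and skipped
            log.error("control run failed for seed %d: %s", seed, exc)
            continue
        for krec, kext in design.conditions():
            try:
                if krec == 1.0 and kext == 1.0:
                    scaled = control
                else:
                    scaled = run_simulation(
                        apply_scaling(cfg, ScalingCondition(krec=krec, kext=kext))
                    )
                rows.append(condition_metrics(control, scaled, krec, kext, seed))
            except Exception as exc:  # noqa: BLE001
                log.error(
                    "run failed (krec=%s, kext=%s, seed=%d): %s",
                    krec, kext, seed, exc,
                )
    return pd.DataFrame(rows)


def krec_sweep(levels, base_config: NetworkConfig, seeds=(0, 1, 2, 3)
               ) -> tuple[pd.DataFrame, list[SeizureVerdict]]:
    """Sweep krec (sorted ascending), flagging the epileptic regime."""
    levels = sorted(levels)
    rows = []
    for seed in seeds:
        cfg = base_config.copy()
        cfg.seed = seed
        control = run_simulation(cfg)
        base_rate = mean_rate(control, "pyr")
        for k in levels:
            scaled = (
                control if k == 1.0
                else run_simulation(apply_scaling(cfg, ScalingCondition(krec=k)))
            )
            row = condition_metrics(control, scaled, k, 1.0, seed)
            rows.append(row)
    table = pd.DataFrame(rows)
    verdicts = []
    # monotone classification: once epileptic, all higher levels epileptic
    frac = table.groupby("krec")["epileptic"].mean()
    seen = False
    for k in levels:
        seen = seen or frac.loc[k] >= 0.5
        verdicts.append(
            SeizureVerdict(
                krec=k,
                is_epileptic=bool(seen),
                pyr_rate=float(table.loc[table.krec == k, "pyr_rate"].mean()),
            )
        )
    return table, verdicts


def delay_sweep(design: DelaySweepDesign, base_config: NetworkConfig
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Slope of mean LFP-γ vs krec for each added recurrent delay.

    Returns (per-run table, per-delay summary with least-squares slopes over
    the non-epileptic range, seed-averaged).
    """
    rows = []
    for delay in design.delays:
        cfg0 = base_config.copy()
        cfg0.added_recurrent_delay = float(delay)
        for seed in design.seeds:
            cfg = cfg0.copy()
            cfg.seed = seed
            control = run_simulation(cfg)
            for k in design.krec_levels:
                scaled = (
                    control if k == 1.0
                    else run_simulation(
                        apply_scaling(cfg, ScalingCondition(krec=k))
                    )
                )
                row = condition_metrics(control, scaled, k, 1.0, seed)
                row["delay"] = delay
                rows.append(row)
    table = pd.DataFrame(rows)
    summaries = []
    for delay, sub in table.groupby("delay"):
        ok = sub[~sub.epileptic]
        means = ok.groupby("krec")["lfp_gamma"].mean()
        if len(means) >= 2:
            slope = float(np.polyfit(means.index, means.values, 1)[0])
        else:
            slope = np.nan
        summaries.append({"delay": delay, "slope": slope,
                          "n_levels": len(means)})
    return table, pd.DataFrame(summaries)


def voltage_probe(base_config: NetworkConfig, volley_t: float = 0.0,
                  pre_ms: float = 20.0, post_ms: float = 40.0,
                  rec_fraction: float = 0.1,
                  record_dt: float = 0.1) -> pd.DataFrame:
    """Somatic voltage around one synchronized recurrent volley.

    All drives onto the network are silenced, recurrent AMPA conductances
    are reduced to `rec_fraction` (default 10%) of baseline, and a single
    presynaptic spike is delivered simultaneously to the recurrent
    basal-dendrite AMPA synapses of every pyramidal cell.  Returns a frame
    with columns (t, v) for the mean somatic voltage, with t = 0 at volley
    onset (no synaptic delay applied to the exogenous event).
    """
    cfg = base_config.copy()
    for bg in cfg.background:
        bg.rate = 0.0
    cfg.ms_g = 0.0
    conv_pp = cfg.convergence.get("pyr->pyr", 0)
    g_pp = 0.0
    for syn in cfg.synapses:
        if syn.pre == "pyr" and syn.post == "pyr" and syn.receptor == "AMPA":
            g_pp = syn.g * rec_fraction
        syn.g = 0.0  # network silent; the volley is delivered exogenously
    cfg.record_dt = record_dt
    settle = 600.0  # ms; slow OLM/Ih relaxation needs a long quiet settle
    cfg.duration = settle + post_ms
    cfg.discard = 0.0
    # one event per recurrent synapse: weight = convergence × scaled g
    events = None
    if volley_t is not None:
        events = [(settle + volley_t, "pyr", "Bdend", conv_pp * g_pp)]
    res = run_simulation(cfg, extra_events=events)
    t = res.rec_times - settle - volley_t if volley_t is not None \
        else res.rec_times - settle
    v = res.v_soma.astype(float).mean(axis=1)
    sel = (t >= -pre_ms) & (t <= post_ms)
    return pd.DataFrame({"t": t[sel], "v": v[sel]})
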