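"""Synapse kernels, network wiring, background drives, and AMPA scaling.

Connectivity follows a convergence rule: each postsynaptic cell receives a
fixed number of presynaptic partners drawn uniformly without replacement
(no autapses).  All chemical synapses are peak-normalized
double-exponential conductances with a uniform 2 ms axonal/synaptic delay.
A medial-septum pacemaker inhibits every basket and OLM cell with a slow
GABAergic event once per theta period (150 ms).
"""

from __future__ import annotations

import math

import numpy as np

from .config import NetworkConfig, ScalingCondition

__all__ = [
    "double_exp_kernel",
    "double_exp_peak_time",
    "double_exp_norm",
    "build_connectivity",
    "poisson_events",
    "ms_theta_drive",
    "apply_scaling",
]


# ---------------------------------------------------------------------------
# double-exponential kernel
# ---------------------------------------------------------------------------

def double_exp_peak_time(tau1: float, tau2: float) -> float:
    """Time of the kernel maximum: t* = tau1·tau2/(tau2−tau1)·ln(tau2/tau1)."""
    if not (0 < tau1 < tau2):
        raise ValueError("need 0 < tau1 < tau2")
    return tau1 * tau2 / (tau2 - tau1) * math.log(tau2 / tau1)


def double_exp_norm(tau1: float, tau2: float) -> float:
    """Normalization N making the kernel peak equal 1."""
    tp = double_exp_peak_time(tau1, tau2)
    return 1.0 / (math.exp(-tp / tau2) - math.exp(-tp / tau1))


def double_exp_kernel(t, tau1: float, tau2: float):
    """Peak-normalized conductance factor N·(exp(−t/τ2) − exp(−t/τ1)).

    Zero for t < 0; the peak value is exactly 1, so a synapse's ``g`` is
    its peak conductance.
    """
    n = double_exp_norm(tau1, tau2)
    t = np.asarray(t, dtype=float)
    out = n * (np.exp(-t / tau2) - np.exp(-t / tau1))
    return np.where(t < 0, 0.0, out)


# ---------------------------------------------------------------------------
# wiring
# ---------------------------------------------------------------------------

def build_connectivity(
    populations: dict[str, int],
    convergence_table: dict[str, int],
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Draw presynaptic partners for every postsynaptic cell.

    Returns ``{"pre->post": edges}`` with ``edges`` an (n_edges, 2) int array
    of (pre_id, post_id) rows; each post cell has exactly the configured
    in-degree, partners drawn without replacement, autapses excluded.
    Projections are processed in sorted key order so the result depends only
    on the seed, not on dict insertion order.
    """
    conn: dict[str, np.ndarray] = {}
    for key in sorted(convergence_table):
        pre_pop, post_pop = key.split("->")
        n_pre, n_post = populations[pre_pop], populations[post_pop]
        c = convergence_table[key]
        pool = n_pre - (1 if pre_pop == post_pop else 0)
        if c > pool:
            raise ValueError(f"convergence {key}={c} exceeds pool size {pool}")
        if c == 0:
            conn[key] = np.empty((0, 2), dtype=np.int64)
            continue
        edges = np.empty((n_post * c, 2), dtype=np.int64)
        for post in range(n_post):
            pres = rng.choice(n_pre, size=c + (1 if pre_pop == post_pop else 0),
                              replace=False)
            if pre_pop == post_pop:
                pres = pres[pres != post][:c]
            edges[post * c : (post + 1) * c, 0] = pres
            edges[post * c : (post + 1) * c, 1] = post
        conn[key] = edges
    return conn


def poisson_events(rate: float, duration: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Homogeneous Poisson event times (ms) on [0, duration); rate in Hz."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if rate == 0 or duration <= 0:
        return np.empty(0)
    n = rng.poisson(rate * duration / 1000.0)
    return np.sort(rng.uniform(0.0, duration, size=n))


def ms_theta_drive(sim_duration: float, period: float = 150.0) -> np.ndarray:
    """Medial-septum pacemaker event times: t = 0, period, 2·period, … (ms)."""
    if sim_duration <= 0:
        raise ValueError("duration must be positive")
    n = int(math.floor(sim_duration / period)) + 1
    return np.arange(n) * period


# ---------------------------------------------------------------------------
# AMPA conductance scaling (post-ketamine potentiation model)
# ---------------------------------------------------------------------------

def apply_scaling(config: NetworkConfig, cond: ScalingCondition) -> NetworkConfig:
    """Return a new config with AMPA conductances scaled by (krec, kext).

    ``krec`` multiplies the recurrent pyramidal→pyramidal AMPA peak
    conductance; ``kext`` multiplies the external (background Poisson) AMPA
    conductances at the pyramidal soma and distal apical dendrite.  NMDA,
    GABAA and all interneuron drives are untouched.  The input config is not
    modified.
    """
    if cond.krec < 0 or cond.kext < 0:
        raise ValueError("scaling factors must be >= 0")
    out = config.copy()
    for syn in out.synapses:
        if syn.pre == "pyr" and syn.post == "pyr" and syn.receptor == "AMPA":
            syn.g *= cond.krec
    for bg in out.background:
        if bg.post == "pyr" and bg.receptor == "AMPA":
            bg.g *= cond.kext
    out.scaling = ScalingCondition(
        krec=config.scaling.krec * cond.krec,
        kext=config.scaling.kext * cond.kext,
    )
    return out
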