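"""Compartmental membrane dynamics for the three cell classes.

Pyramidal cells and OLM interneurons use hippocampal Traub–Miles-style
transient-Na / delayed-rectifier kinetics; pyramidal compartments add an
A-type K current (rapid inactivation) and Ih (bursting); OLM somata add
high-threshold Ca, a first-order intracellular Ca pool, and a Ca-activated
K current responsible for the after-burst quiescent period.  Basket cells
are fast-spiking Wang–Buzsáki single compartments.

Integration is fixed-step (default dt = 0.025 ms): exponential Euler for
gating variables and a semi-implicit exponential update for the voltage,
with axial currents evaluated at the neighbor's previous-step voltage.

Working units: mV, ms, nA, nS/µS, nF, mM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import CompartmentGeometry, NetworkConfig

__all__ = [
    "CellState",
    "CellModel",
    "membrane_step",
    "detect_spikes",
    "IntegrationDivergenceError",
]


class IntegrationDivergenceError(RuntimeError):
    """Raised when a membrane state becomes non-finite during integration."""


# ---------------------------------------------------------------------------
# rate functions
# ---------------------------------------------------------------------------

def vtrap(x, k):
    """x / (1 - exp(-x/k)) with the removable singularity at x = 0 filled."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x / k) < 1e-6
    safe = np.where(small, 1.0, x)
    return np.where(small, k * (1.0 + x / (2.0 * k)), safe / (1.0 - np.exp(-safe / k)))


def na_rates(v, kin):
    """Transient-Na activation/inactivation rates (pyramidal, OLM)."""
    am = kin["na_am_rate"] * vtrap(v - kin["na_am_vhalf"], kin["na_am_k"])
    bm = kin["na_bm_rate"] * vtrap(-(v - kin["na_bm_vhalf"]), kin["na_bm_k"])
    ah = kin["na_ah_rate"] * np.exp(-(v - kin["na_ah_vhalf"]) / kin["na_ah_k"])
    bh = kin["na_bh_rate"] / (1.0 + np.exp(-(v - kin["na_bh_vhalf"]) / kin["na_bh_k"]))
    return am, bm, ah, bh


def kdr_rates(v, kin):
    an = kin["kdr_an_rate"] * vtrap(v - kin["kdr_an_vhalf"], kin["kdr_an_k"])
    bn = kin["kdr_bn_rate"] * np.exp(-(v - kin["kdr_bn_vhalf"]) / kin["kdr_bn_k"])
    return an, bn


def wb_rates(v, kin):
    """Wang–Buzsáki fast-spiking kinetics (basket cells)."""
    am = kin["wb_am_rate"] * vtrap(v - kin["wb_am_vhalf"], kin["wb_am_k"])
    bm = kin["wb_bm_rate"] * np.exp(-(v - kin["wb_bm_vhalf"]) / kin["wb_bm_k"])
    ah = kin["wb_ah_rate"] * np.exp(-(v - kin["wb_ah_vhalf"]) / kin["wb_ah_k"])
    bh = kin["wb_bh_rate"] / (1.0 + np.exp(-(v - kin["wb_bh_vhalf"]) / kin["wb_bh_k"]))
    an = kin["wb_an_rate"] * vtrap(v - kin["wb_an_vhalf"], kin["wb_an_k"])
    bn = kin["wb_bn_rate"] * np.exp(-(v - kin["wb_bn_vhalf"]) / kin["wb_bn_k"])
    return am, bm, ah, bh, an, bn


def ka_inf_tau(v, kin):
    a_inf = 1.0 / (1.0 + np.exp(-(v - kin["ka_a_vhalf"]) / kin["ka_a_k"]))
    b_inf = 1.0 / (1.0 + np.exp((v - kin["ka_b_vhalf"]) / kin["ka_b_k"]))
    return a_inf, kin["ka_a_tau"], b_inf, kin["ka_b_tau"]


def ih_inf_tau(v, kin):
    q_inf = 1.0 / (1.0 + np.exp((v - kin["ih_q_vhalf"]) / kin["ih_q_k"]))
    x = (v - kin["ih_tau_vhalf"]) / kin["ih_tau_k"]
    q_tau = kin["ih_tau_amp"] / (np.exp(x) + np.exp(-x)) + kin["ih_tau_min"]
    return q_inf, q_tau


def cal_inf_tau(v, kin):
    s_inf = 1.0 / (1.0 + np.exp(-(v - kin["cal_s_vhalf"]) / kin["cal_s_k"]))
    return s_inf, kin["cal_s_tau"]


def _exp_euler(x, x_inf, tau, dt):
    return x_inf + (x - x_inf) * np.exp(-dt / tau)


# ---------------------------------------------------------------------------
# single-cell model (reference integrator)
# ---------------------------------------------------------------------------

@dataclass
class CellState:
    """Membrane state of one cell: voltages, gates, Ca pool (OLM only)."""

    v: np.ndarray  # (ncomp,) mV
    gates: dict[str, np.ndarray] = field(default_factory=dict)  # each (ncomp,)
    ca: float = 0.0  # mM, somatic pool (OLM)

    def copy(self) -> "CellState":
        return CellState(
            v=self.v.copy(),
            gates={k: g.copy() for k, g in self.gates.items()},
            ca=self.ca,
        )


# gating variables used per channel
_CHANNEL_GATES = {
    "na": ("m", "h"),
    "kdr": ("n",),
    "ka": ("a", "b"),
    "ih": ("q",),
    "cal": ("s",),
    "kca": (),
    "leak": (),
}

# topology: parent compartment index (-1 = root) for the 5-compartment
# pyramidal cell (soma, Bdend, Adend1, Adend2, Adend3) and point cells
_PYR_PARENT = np.array([-1, 0, 0, 2, 3])


def axial_conductances(geometry: list[CompartmentGeometry], parent: np.ndarray):
    """µS coupling between each compartment and its parent (0 for the root)."""
    g = np.zeros(len(geometry))
    for i, p in enumerate(parent):
        if p < 0:
            continue
        ci, cp = geometry[i], geometry[p]
        # half-cylinder axial resistances in Ω (lengths µm → cm)
        r = (
            ci.axial_resistivity * (ci.length * 1e-4 / 2.0) / ci.cross_section_cm2
            + cp.axial_resistivity * (cp.length * 1e-4 / 2.0) / cp.cross_section_cm2
        )
        g[i] = 1e6 / r  # Ω → µS
    return g


class CellModel:
    """One cell of a given type, compiled from a :class:`NetworkConfig`.

    This is the plain-NumPy reference implementation of the membrane
    dynamics; the network engine runs the same equations in a fused
    compiled loop and is cross-validated against this class.
    """

    def __init__(self, config: NetworkConfig, cell_type: str):
        self.cell_type = cell_type
        self.kin = config.kinetics
        geom = config.geometry[cell_type]
        chans = config.channels[cell_type]
        self.ncomp = len(geom)
        self.parent = (
            _PYR_PARENT if cell_type == "pyr" else np.array([-1][: self.ncomp])
        )
        area = np.array([g.area_cm2 for g in geom])
        self.c_nF = config.membrane_capacitance * area * 1e3  # µF/cm²·cm² → nF
        # densities S/cm² → absolute µS
        self.g_uS = {
            name: np.asarray(dens) * area * 1e6 for name, dens in chans.gbar.items()
        }
        self.reversal = chans.reversal
        self.g_axial = axial_conductances(geom, self.parent)
        self.uses_wb = cell_type == "bas"

    # -- state construction --------------------------------------------------

    def initial_state(self, v0: float | None = None) -> CellState:
        """Resting state with gates at their steady state for v0."""
        if v0 is None:
            v0 = self.reversal["leak"]
        v = np.full(self.ncomp, float(v0))
        st = CellState(v=v, ca=self.kin["ca_rest"])
        kin = self.kin
        if self.uses_wb:
            am, bm, ah, bh, an, bn = wb_rates(v, kin)
            st.gates = {"m": am / (am + bm), "h": ah / (ah + bh), "n": an / (an + bn)}
            return st
        am, bm, ah, bh = na_rates(v, kin)
        an, bn = kdr_rates(v, kin)
        st.gates = {"m": am / (am + bm), "h": ah / (ah + bh), "n": an / (an + bn)}
        if "ka" in self.g_uS:
            a_inf, _, b_inf, _ = ka_inf_tau(v, kin)
            st.gates["a"], st.gates["b"] = a_inf, b_inf
        if "ih" in self.g_uS:
            st.gates["q"] = ih_inf_tau(v, kin)[0]
        if "cal" in self.g_uS:
            st.gates["s"] = cal_inf_tau(v, kin)[0]
        return st

    # -- one integration step ------------------------------------------------

    def step(self, state: CellState, i_ext: np.ndarray, dt: float,
             t: float = 0.0) -> CellState:
        """Advance by dt given external/synaptic current per compartment (nA,
        depolarizing positive).  Returns a new state; raises
        :class:`IntegrationDivergenceError` on non-finite values."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        i_ext = np.asarray(i_ext, dtype=float)
        if not np.all(np.isfinite(i_ext)):
            raise ValueError("input currents must be finite")
        kin, v = self.kin, state.v
        new = state.copy()
        g = new.gates

        # gating updates (exponential Euler at the pre-step voltage)
        if self.uses_wb:
            am, bm, ah, bh, an, bn = wb_rates(v, kin)
            for name, a, b in (("m", am, bm), ("h", ah, bh), ("n", an, bn)):
                tau = 1.0 / (a + b)
                g[name] = _exp_euler(g[name], a * tau, tau, dt)
        else:
            am, bm, ah, bh = na_rates(v, kin)
            an, bn = kdr_rates(v, kin)
            for name, a, b in (("m", am, bm), ("h", ah, bh), ("n", an, bn)):
                tau = 1.0 / (a + b)
                g[name] = _exp_euler(g[name], a * tau, tau, dt)
            if "a" in g:
                a_inf, ta, b_inf, tb = ka_inf_tau(v, kin)
                g["a"] = _exp_euler(g["a"], a_inf, ta, dt)
                g["b"] = _exp_euler(g["b"], b_inf, tb, dt)
            if "q" in g:
                q_inf, q_tau = ih_inf_tau(v, kin)
                g["q"] = _exp_euler(g["q"], q_inf, q_tau, dt)
            if "s" in g:
                s_inf, s_tau = cal_inf_tau(v, kin)
                g["s"] = _exp_euler(g["s"], s_inf, s_tau, dt)
        for name in g:
            np.clip(g[name], 0.0, 1.0, out=g[name])

        # conductance accumulation: G (µS) and G·E (µS·mV) per compartment
        G = self.g_uS["leak"].copy()
        GE = self.g_uS["leak"] * self.reversal["leak"]
        g_na = self.g_uS["na"] * g["m"] ** 3 * g["h"]
        G += g_na
        GE += g_na * self.reversal["na"]
        g_k = self.g_uS["kdr"] * g["n"] ** 4
        if "ka" in self.g_uS:
            g_k = g_k + self.g_uS["ka"] * g["a"] * g["b"]
        i_ca = None
        if "cal" in self.g_uS:
            g_ca = self.g_uS["cal"] * g["s"] ** 2
            G += g_ca
            GE += g_ca * self.reversal["ca"]
            i_ca = g_ca * (v - self.reversal["ca"])  # nA, outward positive
        if "kca" in self.g_uS:
            g_k = g_k + self.g_uS["kca"] * (state.ca / (state.ca + kin["kca_kd"]))
        G += g_k
        GE += g_k * self.reversal["k"]
        if "ih" in self.g_uS:
            g_h = self.g_uS["ih"] * g["q"]
            G += g_h
            GE += g_h * self.reversal["ih"]

        # axial coupling, neighbor voltage explicit
        i_ax = np.zeros(self.ncomp)
        for i, p in enumerate(self.parent):
            if p < 0:
                continue
            ga = self.g_axial[i]
            G[i] += ga
            GE[i] += ga * v[p]
            i_ax[p] += ga * (v[i] - v[p])

        v_inf = (GE + i_ext + i_ax) / G
        new.v = v_inf + (v - v_inf) * np.exp(-dt * G / self.c_nF)

        if i_ca is not None:
            ca_inf = kin["ca_rest"] - kin["ca_alpha"] * kin["ca_tau"] * float(
                np.sum(i_ca)
            )
            new.ca = max(
                0.0,
                ca_inf + (state.ca - ca_inf) * np.exp(-dt / kin["ca_tau"]),
            )

        if not np.all(np.isfinite(new.v)):
            raise IntegrationDivergenceError(
                f"{self.cell_type} voltage diverged at t={t:.3f} ms"
            )
        return new

    def run(self, duration: float, i_ext=None, dt: float = 0.025,
            v0: float | None = None):
        """Integrate for `duration` ms; i_ext maps step→(ncomp,) nA or is a
        constant per-compartment array.  Returns (times, soma voltage trace)."""
        n = int(round(duration / dt))
        state = self.initial_state(v0)
        vm = np.empty(n + 1)
        vm[0] = state.v[0]
        const = None
        if i_ext is None:
            const = np.zeros(self.ncomp)
        elif not callable(i_ext):
            const = np.asarray(i_ext, dtype=float)
        for k in range(n):
            cur = const if const is not None else i_ext(k * dt)
            state = self.step(state, cur, dt, t=k * dt)
            vm[k + 1] = state.v[0]
        return np.arange(n + 1) * dt, vm


def membrane_step(model: CellModel, state: CellState, currents, dt: float,
                  t: float = 0.0) -> CellState:
    """Functional form of :meth:`CellModel.step`."""
    return model.step(state, np.asarray(currents, dtype=float), dt, t=t)


# ---------------------------------------------------------------------------
# spike detection
# ---------------------------------------------------------------------------

def detect_spikes(voltage: np.ndarray, dt: float, threshold: float = 0.0,
                  refractory: float = 3.0) -> np.ndarray:
    """Upward threshold-crossing times (ms) with a refractory constraint.

    The trace is assumed uniformly sampled at interval dt.  Returns strictly
    increasing times; consecutive spikes are separated by >= refractory.
    """
    v = np.asarray(voltage, dtype=float)
    if v.size < 2:
        return np.empty(0)
    crossings = np.flatnonzero((v[:-1] < threshold) & (v[1:] >= threshold)) + 1
    if crossings.size == 0:
        return np.empty(0)
    times = []
    last = -np.inf
    for idx in crossings:
        t = idx * dt
        if t - last >= refractory:
            times.append(t)
            last = t
    return np.asarray(times)
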