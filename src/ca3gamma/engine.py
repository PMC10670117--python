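"""Network assembly and seeded simulation runs.

`run_simulation` compiles a :class:`NetworkConfig` into flat arrays,
integrates the full network with the compiled kernel, and returns a
:class:`SimulationResult` holding the spike raster and the pyramidal
dendritic voltage traces needed for the LFP.

Randomness is organized as named substreams of one master seed (wiring,
initial conditions, background events), so a control/scaled pair built
from the same seed shares its wiring and background event streams exactly
and differs only in conductances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import biophysics as bp
from ._kernel import POP_BAS, POP_OLM, POP_PYR, run_network
from .config import PYR_COMPARTMENTS, NetworkConfig, ScalingCondition
from .wiring import apply_scaling, build_connectivity, double_exp_norm

__all__ = ["SimulationResult", "run_simulation", "run_paired", "CompiledNetwork"]

_POP_CODE = {"pyr": POP_PYR, "bas": POP_BAS, "olm": POP_OLM}
_GATE_TABLE_VRANGE = (-120.0, 60.0)
_GATE_TABLE_DV = 0.02


@dataclass
class SimulationResult:
    """Raster + recorded pyramidal compartment voltages + metadata."""

    spike_times: np.ndarray  # ms
    spike_gids: np.ndarray
    n_pyr: int
    n_bas: int
    n_olm: int
    rec_times: np.ndarray  # ms
    v_soma: np.ndarray  # (n_rec, n_pyr) mV, float32
    v_bdend: np.ndarray
    v_adend3: np.ndarray
    config: NetworkConfig
    duration: float
    discard: float
    seed: int
    dt: float
    overflow: bool = False
    wiring: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def population_of(self, gids) -> np.ndarray:
        gids = np.asarray(gids)
        pop = np.where(
            gids < self.n_pyr, "pyr",
            np.where(gids < self.n_pyr + self.n_bas, "bas", "olm"),
        )
        return pop

    def spikes_of(self, population: str, window=None):
        """Spike (times, local ids) of one population, optionally windowed."""
        lo = {"pyr": 0, "bas": self.n_pyr, "olm": self.n_pyr + self.n_bas}
        size = {"pyr": self.n_pyr, "bas": self.n_bas, "olm": self.n_olm}
        if population not in lo:
            raise ValueError(f"unknown population {population!r}")
        sel = (self.spike_gids >= lo[population]) & (
            self.spike_gids < lo[population] + size[population]
        )
        t = self.spike_times[sel]
        g = self.spike_gids[sel] - lo[population]
        if window is not None:
            m = (t >= window[0]) & (t < window[1])
            t, g = t[m], g[m]
        return t, g

    @property
    def analysis_window(self) -> tuple[float, float]:
        return (self.discard, self.duration)


def _gate_tables(config: NetworkConfig, dt: float):
    """Voltage-indexed gating tables built from the reference rate functions."""
    kin = config.kinetics
    v = np.arange(_GATE_TABLE_VRANGE[0], _GATE_TABLE_VRANGE[1] + _GATE_TABLE_DV / 2,
                  _GATE_TABLE_DV)
    nv = v.size

    def inf_dec(a, b):
        tau = 1.0 / (a + b)
        return a * tau, np.exp(-dt / tau)

    am, bm, ah, bh = bp.na_rates(v, kin)
    an, bn = bp.kdr_rates(v, kin)
    mi, md = inf_dec(am, bm)
    hi, hd = inf_dec(ah, bh)
    ni, nd = inf_dec(an, bn)
    a_inf, _, b_inf, _ = bp.ka_inf_tau(v, kin)
    q_inf, q_tau = bp.ih_inf_tau(v, kin)
    pyr_tab = np.column_stack(
        [mi, md, hi, hd, ni, nd, a_inf, b_inf, q_inf, np.exp(-dt / q_tau)]
    )

    wam, wbm, wah, wbh, wan, wbn = bp.wb_rates(v, kin)
    wmi, wmd = inf_dec(wam, wbm)
    whi, whd = inf_dec(wah, wbh)
    wni, wnd = inf_dec(wan, wbn)
    bas_tab = np.column_stack([wmi, wmd, whi, whd, wni, wnd])

    s_inf, _ = bp.cal_inf_tau(v, kin)
    olm_tab = np.column_stack(
        [mi, md, hi, hd, ni, nd, q_inf, np.exp(-dt / q_tau), s_inf]
    )
    return v[0], 1.0 / _GATE_TABLE_DV, nv, pyr_tab, bas_tab, olm_tab


class CompiledNetwork:
    """All kernel inputs compiled from one NetworkConfig (plus wiring rng)."""

    def __init__(self, config: NetworkConfig,
                 extra_events: list[tuple[float, str, str, float]] | None = None,
                 max_spike_rate: float = 400.0):
        """extra_events: (time ms, post population, compartment key, weight nS)
        exogenous conductance events delivered to every cell of a bucket
        (used for the voltage-probe protocol)."""
        self.config = config
        cfg = config
        dt = cfg.dt
        self.dt = dt
        self.n_steps = int(round(cfg.duration / dt))
        sizes = {"pyr": cfg.n_pyr, "bas": cfg.n_bas, "olm": cfg.n_olm}
        self.sizes = sizes

        ss = np.random.SeedSequence(cfg.seed)
        ss_wiring, ss_init, ss_bg = ss.spawn(3)
        self.kernel_seed = int(ss_bg.generate_state(1, dtype=np.uint32)[0] % (2**31))

        # ---- wiring (sorted projection order; seed-reproducible) ----
        self.wiring = build_connectivity(
            sizes, cfg.convergence, np.random.default_rng(ss_wiring)
        )

        # ---- synapse buckets ----
        # one bucket per (post population, compartment, kinetics, reversal)
        comp_index = {
            "pyr": {name: i for i, name in enumerate(PYR_COMPARTMENTS)},
            "bas": {"soma": 0},
            "olm": {"soma": 0},
        }
        bucket_key_to_id: dict[tuple, int] = {}
        bucket_rows = []  # (pop_code, comp, tau1, tau2, erev, is_nmda)

        def get_bucket(post, comp, tau1, tau2, erev, receptor):
            key = (post, comp, tau1, tau2, erev)
            if key not in bucket_key_to_id:
                bucket_key_to_id[key] = len(bucket_rows)
                bucket_rows.append(
                    (
                        _POP_CODE[post],
                        comp_index[post][comp],
                        tau1,
                        tau2,
                        erev,
                        1 if receptor == "NMDA" else 0,
                        sizes[post],
                    )
                )
            return bucket_key_to_id[key]

        # projections (chemical synapses between populations)
        proj_rows = []  # (pre_pop_code, bucket, delay_steps, g, pair_key)
        for syn in cfg.synapses:
            pair = f"{syn.pre}->{syn.post}"
            if pair not in self.wiring:
                raise ValueError(f"no convergence entry for projection {pair}")
            b = get_bucket(syn.post, syn.compartment, syn.tau1, syn.tau2,
                           syn.reversal, syn.receptor)
            delay = syn.delay
            if syn.pre == "pyr" and syn.post == "pyr":
                delay += cfg.added_recurrent_delay
            proj_rows.append(
                (_POP_CODE[syn.pre], b, int(round(delay / dt)), syn.g, pair)
            )

        # background drives
        bg_rows = []
        for bg in cfg.background:
            b = get_bucket(bg.post, bg.compartment, bg.tau1, bg.tau2,
                           bg.reversal, bg.receptor)
            bg_rows.append((b, bg.rate * dt * 1e-3, bg.g))

        # MS pacemaker buckets
        ms_buckets = [
            get_bucket(pop, "soma", cfg.ms_tau1, cfg.ms_tau2, cfg.ms_reversal,
                       "GABAA")
            for pop in ("bas", "olm")
        ]

        n_buckets = len(bucket_rows)
        self.bucket_pop = np.array([r[0] for r in bucket_rows], dtype=np.int64)
        self.bucket_comp = np.array([r[1] for r in bucket_rows], dtype=np.int64)
        self.bucket_size = np.array([r[6] for r in bucket_rows], dtype=np.int64)
        self.bucket_off = np.concatenate(
            [[0], np.cumsum(self.bucket_size)[:-1]]
        ).astype(np.int64)
        self.total_state = int(self.bucket_size.sum())
        self.bucket_norm = np.array(
            [double_exp_norm(r[2], r[3]) for r in bucket_rows]
        )
        self.bucket_d1 = np.array([np.exp(-dt / r[2]) for r in bucket_rows])
        self.bucket_d2 = np.array([np.exp(-dt / r[3]) for r in bucket_rows])
        self.bucket_erev = np.array([r[4] for r in bucket_rows])
        self.bucket_nmda = np.array([r[5] for r in bucket_rows], dtype=np.int64)
        self.bucket_key_to_id = bucket_key_to_id

        # ---- projection CSR ----
        pair_csr: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for pair, edges in self.wiring.items():
            pre_pop = pair.split("->")[0]
            n_pre = sizes[pre_pop]
            order = np.argsort(edges[:, 0], kind="stable")
            sorted_edges = edges[order]
            indptr = np.searchsorted(
                sorted_edges[:, 0], np.arange(n_pre + 1)
            ).astype(np.int64)
            pair_csr[pair] = (indptr, sorted_edges[:, 1].astype(np.int64))

        n_proj = len(proj_rows)
        self.proj_pre_pop = np.array([r[0] for r in proj_rows], dtype=np.int64)
        self.proj_bucket = np.array([r[1] for r in proj_rows], dtype=np.int64)
        self.proj_delay = np.array([r[2] for r in proj_rows], dtype=np.int64)
        self.proj_g = np.array([r[3] for r in proj_rows])
        indptr_parts, target_parts = [], []
        ip0, tg0 = [], []
        ip_off = tg_off = 0
        for r in proj_rows:
            indptr, targets = pair_csr[r[4]]
            ip0.append(ip_off)
            tg0.append(tg_off)
            indptr_parts.append(indptr)
            target_parts.append(targets)
            ip_off += indptr.size
            tg_off += targets.size
        self.proj_ip0 = np.array(ip0, dtype=np.int64)
        self.proj_tg0 = np.array(tg0, dtype=np.int64)
        self.indptr_all = (
            np.concatenate(indptr_parts) if indptr_parts
            else np.zeros(0, dtype=np.int64)
        )
        self.targets_all = (
            np.concatenate(target_parts) if target_parts
            else np.zeros(0, dtype=np.int64)
        )
        max_delay = int(self.proj_delay.max()) if n_proj else 0
        self.buflen = max_delay + 1

        # ---- exogenous events: MS pacemaker + any extras ----
        events = []
        n_theta = int(np.floor(cfg.duration / cfg.ms_period)) + 1
        for i in range(n_theta):
            step = int(round(i * cfg.ms_period / dt))
            if step < self.n_steps:
                for b in ms_buckets:
                    # ms_convergence co-active septal synapses sum linearly
                    events.append((step, b, cfg.ms_g * cfg.ms_convergence))
        if extra_events:
            for (t_ms, post, comp, w) in extra_events:
                # deliver to the AMPA bucket of that compartment
                key = None
                for (p, c, t1, t2, er), bid in bucket_key_to_id.items():
                    if p == post and c == comp and er == 0.0 and t2 < 10.0:
                        key = bid
                        break
                if key is None:
                    raise ValueError(
                        f"no AMPA bucket on {post}/{comp} for exogenous event"
                    )
                events.append((int(round(t_ms / dt)), key, w))
        events.sort()
        self.ev_step = np.array([e[0] for e in events], dtype=np.int64)
        self.ev_bucket = np.array([e[1] for e in events], dtype=np.int64)
        self.ev_w = np.array([e[2] for e in events])

        # ---- background array form ----
        self.bg_bucket = np.array([r[0] for r in bg_rows], dtype=np.int64)
        self.bg_lam = np.array([r[1] for r in bg_rows])
        self.bg_w = np.array([r[2] for r in bg_rows])

        # ---- per-population parameters ----
        geom = cfg.geometry
        chans = cfg.channels
        cm = cfg.membrane_capacitance

        def area(pop):
            return np.array([g.area_cm2 for g in geom[pop]])

        a_p = area("pyr")
        self.pyr_c = cm * a_p * 1e3  # nF
        gb = chans["pyr"].gbar
        self.pyr_gna = np.asarray(gb["na"]) * a_p * 1e6
        self.pyr_gkdr = np.asarray(gb["kdr"]) * a_p * 1e6
        self.pyr_gka = np.asarray(gb["ka"]) * a_p * 1e6
        self.pyr_gih = np.asarray(gb["ih"]) * a_p * 1e6
        self.pyr_gleak = np.asarray(gb["leak"]) * a_p * 1e6
        rev = chans["pyr"].reversal
        self.pyr_rev = (rev["na"], rev["k"], rev["ih"], rev["leak"])
        self.pyr_parent = bp._PYR_PARENT.astype(np.int64)
        self.pyr_gax = bp.axial_conductances(geom["pyr"], self.pyr_parent)

        a_b = area("bas")[0]
        gb = chans["bas"].gbar
        rev_b = chans["bas"].reversal
        self.bas_par = (
            gb["na"][0] * a_b * 1e6,
            gb["kdr"][0] * a_b * 1e6,
            gb["leak"][0] * a_b * 1e6,
            cm * a_b * 1e3,
            rev_b["na"], rev_b["k"], rev_b["leak"],
        )

        a_o = area("olm")[0]
        gb = chans["olm"].gbar
        rev_o = chans["olm"].reversal
        self.olm_par = (
            gb["na"][0] * a_o * 1e6,
            gb["kdr"][0] * a_o * 1e6,
            gb["ih"][0] * a_o * 1e6,
            gb["cal"][0] * a_o * 1e6,
            gb["kca"][0] * a_o * 1e6,
            gb["leak"][0] * a_o * 1e6,
            cm * a_o * 1e3,
            rev_o["na"], rev_o["k"], rev_o["ih"], rev_o["ca"], rev_o["leak"],
        )

        # ---- gating tables ----
        (self.v_min, self.inv_dv, self.nv,
         self.pyr_tab, self.bas_tab, self.olm_tab) = _gate_tables(cfg, dt)
        kin = cfg.kinetics
        self.ka_a_dec = float(np.exp(-dt / kin["ka_a_tau"]))
        self.ka_b_dec = float(np.exp(-dt / kin["ka_b_tau"]))
        self.cal_s_dec = float(np.exp(-dt / kin["cal_s_tau"]))
        self.ca_pars = (
            kin["kca_kd"], kin["ca_alpha"], kin["ca_tau"],
            float(np.exp(-dt / kin["ca_tau"])), kin["ca_rest"],
        )

        # ---- initial conditions (seeded jitter) ----
        rng_init = np.random.default_rng(ss_init)
        models = {pop: bp.CellModel(cfg, pop) for pop in ("pyr", "bas", "olm")}
        self.init = {}
        for pop in ("pyr", "bas", "olm"):
            n = sizes[pop]
            v0 = models[pop].reversal["leak"]
            # hyperpolarizing-only jitter: breaks symmetry without kicking
            # near-rheobase cells over threshold at t = 0
            jit = rng_init.uniform(-cfg.init_jitter, 0.0, size=n)
            self.init[pop] = v0 + jit
        self.models = models

        self.max_spikes = int(
            (cfg.n_pyr + cfg.n_bas + cfg.n_olm)
            * (cfg.duration / 1000.0)
            * max_spike_rate
        )

    def run(self) -> SimulationResult:
        cfg = self.config
        dt = self.dt
        sizes = self.sizes
        n_pyr, n_bas, n_olm = sizes["pyr"], sizes["bas"], sizes["olm"]
        kin = cfg.kinetics

        # state arrays at steady state for the (jittered) initial voltage
        v_pyr = np.tile(self.init["pyr"][:, None], (1, 5))
        g_pyr = np.empty((n_pyr, 5, 6))
        am, bm, ah, bh = bp.na_rates(v_pyr, kin)
        an, bn = bp.kdr_rates(v_pyr, kin)
        g_pyr[:, :, 0] = am / (am + bm)
        g_pyr[:, :, 1] = ah / (ah + bh)
        g_pyr[:, :, 2] = an / (an + bn)
        a_inf, _, b_inf, _ = bp.ka_inf_tau(v_pyr, kin)
        g_pyr[:, :, 3] = a_inf
        g_pyr[:, :, 4] = b_inf
        g_pyr[:, :, 5] = bp.ih_inf_tau(v_pyr, kin)[0]

        v_bas = self.init["bas"].copy()
        g_bas = np.empty((n_bas, 3))
        wam, wbm, wah, wbh, wan, wbn = bp.wb_rates(v_bas, kin)
        g_bas[:, 0] = wam / (wam + wbm)
        g_bas[:, 1] = wah / (wah + wbh)
        g_bas[:, 2] = wan / (wan + wbn)

        v_olm = self.init["olm"].copy()
        g_olm = np.empty((n_olm, 5))
        am, bm, ah, bh = bp.na_rates(v_olm, kin)
        an, bn = bp.kdr_rates(v_olm, kin)
        g_olm[:, 0] = am / (am + bm)
        g_olm[:, 1] = ah / (ah + bh)
        g_olm[:, 2] = an / (an + bn)
        g_olm[:, 3] = bp.ih_inf_tau(v_olm, kin)[0]
        g_olm[:, 4] = bp.cal_inf_tau(v_olm, kin)[0]
        ca_olm = np.full(n_olm, kin["ca_rest"])

        syn_a = np.zeros(self.total_state)
        syn_b = np.zeros(self.total_state)
        ring = np.zeros((self.buflen, self.total_state))

        record_every = max(1, int(round(cfg.record_dt / dt)))
        n_rec = int(np.ceil(self.n_steps / record_every))
        rec_soma = np.empty((n_rec, n_pyr), dtype=np.float32)
        rec_bdend = np.empty((n_rec, n_pyr), dtype=np.float32)
        rec_adend3 = np.empty((n_rec, n_pyr), dtype=np.float32)

        spike_t = np.empty(self.max_spikes)
        spike_gid = np.empty(self.max_spikes, dtype=np.int32)

        refrac_steps = int(round(3.0 / dt))

        n_spk, overflow, err_step = run_network(
            self.n_steps, dt, self.kernel_seed,
            n_pyr, n_bas, n_olm,
            v_pyr, g_pyr, v_bas, g_bas, v_olm, g_olm, ca_olm,
            self.pyr_parent, self.pyr_gax, self.pyr_c,
            self.pyr_gna, self.pyr_gkdr, self.pyr_gka, self.pyr_gih,
            self.pyr_gleak, *self.pyr_rev,
            *self.bas_par,
            *self.olm_par,
            self.v_min, self.inv_dv, self.nv,
            self.pyr_tab, self.bas_tab, self.olm_tab,
            self.ka_a_dec, self.ka_b_dec, self.cal_s_dec,
            *self.ca_pars,
            self.bucket_pop, self.bucket_comp, self.bucket_off,
            self.bucket_size, self.bucket_norm, self.bucket_d1,
            self.bucket_d2, self.bucket_erev, self.bucket_nmda,
            syn_a, syn_b,
            1 if cfg.nmda_mg_block else 0,
            self.bg_bucket, self.bg_lam, self.bg_w,
            self.proj_pre_pop, self.proj_bucket, self.proj_delay, self.proj_g,
            self.proj_ip0, self.proj_tg0, self.indptr_all, self.targets_all,
            ring,
            self.ev_step, self.ev_bucket, self.ev_w,
            refrac_steps, self.max_spikes, spike_t, spike_gid,
            record_every, rec_soma, rec_bdend, rec_adend3,
        )
        if err_step >= 0:
            raise bp.IntegrationDivergenceError(
                f"network integration diverged near t={err_step * dt:.1f} ms "
                f"(seed {cfg.seed}, krec={cfg.scaling.krec}, "
                f"kext={cfg.scaling.kext})"
            )
        return SimulationResult(
            spike_times=spike_t[:n_spk].copy(),
            spike_gids=spike_gid[:n_spk].copy(),
            n_pyr=n_pyr, n_bas=n_bas, n_olm=n_olm,
            rec_times=np.arange(n_rec) * record_every * dt,
            v_soma=rec_soma, v_bdend=rec_bdend, v_adend3=rec_adend3,
            config=cfg, duration=cfg.duration, discard=cfg.discard,
            seed=cfg.seed, dt=dt, overflow=bool(overflow),
            wiring=self.wiring,
        )


def run_simulation(config: NetworkConfig, duration: float | None = None,
                   discard: float | None = None,
                   extra_events=None) -> SimulationResult:
    """Run one seeded simulation of `config`.

    `duration`/`discard` override the config values (ms).  The result holds
    the full raster; analyses should use ``result.analysis_window``, which
    excludes the equilibration period.
    """
    cfg = config.copy()
    if duration is not None:
        cfg.duration = duration
    if discard is not None:
        cfg.discard = discard
    cfg.validate()
    return CompiledNetwork(cfg, extra_events=extra_events).run()


def run_paired(config: NetworkConfig, condition: ScalingCondition,
               **kwargs) -> tuple[SimulationResult, SimulationResult]:
    """Seed-matched (control, scaled) pair.

    Both runs are built from the same master seed, so wiring and background
    event streams are identical; only the AMPA conductances named by the
    scaling condition differ.
    """
    control = run_simulation(config, **kwargs)
    scaled = run_simulation(apply_scaling(config, condition), **kwargs)
    return control, scaled
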