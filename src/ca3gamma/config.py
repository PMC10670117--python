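"""Network parameterization.

The model is a three-population hippocampal CA3 microcircuit: 800 pyramidal
cells (five compartments: soma, one basal dendrite, three apical dendrites),
200 OLM interneurons and 200 basket interneurons (one somatic compartment
each), paced by a periodic medial-septum (MS) inhibitory drive.

Everything the simulator needs is carried by :class:`NetworkConfig`:
compartment geometry, channel densities and kinetic rate constants, the
synapse table (per-projection double-exponential kernels), the background
Poisson drive table, convergence numbers, and the AMPA scaling condition
(``krec``, ``kext``) that models post-ketamine potentiation.

Units follow the conventions of compartmental modeling: lengths in µm,
conductance densities in S/cm², point conductances in nS, times in ms,
voltages in mV, axial resistivity in Ω·cm.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field

import yaml

__all__ = [
    "CompartmentGeometry",
    "ChannelSet",
    "SynapseSpec",
    "BackgroundDrive",
    "ScalingCondition",
    "NetworkConfig",
    "default_config",
    "load_config",
    "save_config",
]

PYR_COMPARTMENTS = ("soma", "Bdend", "Adend1", "Adend2", "Adend3")


@dataclass
class CompartmentGeometry:
    """Cylindrical compartment: name, length (µm), diameter (µm), Ra (Ω·cm)."""

    name: str
    length: float
    diameter: float
    axial_resistivity: float = 150.0

    def __post_init__(self) -> None:
        if self.length <= 0 or self.diameter <= 0:
            raise ValueError(
                f"compartment {self.name!r}: length and diameter must be positive"
            )
        if self.axial_resistivity <= 0:
            raise ValueError(f"compartment {self.name!r}: Ra must be positive")

    @property
    def area_cm2(self) -> float:
        """Lateral (membrane) area in cm²."""
        import math

        return math.pi * self.diameter * self.length * 1e-8

    @property
    def cross_section_cm2(self) -> float:
        import math

        return math.pi * (self.diameter / 2.0) ** 2 * 1e-8


@dataclass
class ChannelSet:
    """Per-compartment maximal conductance densities (S/cm²) and reversals (mV).

    ``gbar[channel]`` is a list with one entry per compartment of the cell,
    ordered as in the cell's geometry list.  Channels absent from a cell type
    are simply missing from the dict.  Supported channel names:

    - ``na``   transient sodium
    - ``kdr``  delayed-rectifier potassium
    - ``ka``   A-type potassium (pyramidal: rapid inactivation)
    - ``ih``   hyperpolarization-activated mixed cation current
    - ``cal``  high-threshold (L-like) calcium (OLM)
    - ``kca``  calcium-activated potassium (OLM after-burst quiescence)
    - ``leak`` passive leak
    """

    gbar: dict[str, list[float]]
    reversal: dict[str, float]

    def __post_init__(self) -> None:
        for name, dens in self.gbar.items():
            if any(g < 0 for g in dens):
                raise ValueError(f"channel {name!r}: conductance density < 0")

    def n_compartments(self) -> int:
        return len(self.gbar["leak"])


@dataclass
class SynapseSpec:
    """A chemical projection between populations (one table row).

    ``tau1``/``tau2`` are the rise/fall time constants of the
    double-exponential conductance; ``g`` is the *peak* conductance in nS
    (the kernel is peak-normalized); ``delay`` in ms.
    """

    pre: str
    post: str
    compartment: str
    receptor: str  # AMPA | NMDA | GABAA
    tau1: float
    tau2: float
    g: float
    reversal: float
    delay: float = 2.0

    def __post_init__(self) -> None:
        if not (0 < self.tau1 < self.tau2):
            raise ValueError(
                f"{self.pre}->{self.post} {self.receptor}: need 0 < tau1 < tau2"
            )
        if self.g < 0:
            raise ValueError("peak conductance must be >= 0")
        if self.delay < 0:
            raise ValueError("synaptic delay must be >= 0")


@dataclass
class BackgroundDrive:
    """Poisson background input onto one (cell type, compartment, receptor)."""

    post: str
    compartment: str
    receptor: str
    rate: float  # Hz, per target cell
    tau1: float
    tau2: float
    g: float  # peak conductance per event, nS
    reversal: float

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("background rate must be >= 0")
        if not (0 < self.tau1 < self.tau2):
            raise ValueError("need 0 < tau1 < tau2")


@dataclass
class ScalingCondition:
    """Multiplicative AMPA-conductance scaling modeling post-ketamine LTP.

    ``krec`` scales recurrent pyramidal→pyramidal AMPA synapses; ``kext``
    scales the external (background) AMPA synapses at the pyramidal soma and
    distal apical dendrite.  The pre-ketamine control is (1, 1).
    """

    krec: float = 1.0
    kext: float = 1.0

    def __post_init__(self) -> None:
        if self.krec < 0 or self.kext < 0:
            raise ValueError("scaling factors must be >= 0")


def _default_kinetics() -> dict[str, float]:
    """Rate-equation constants for all channels (mV, ms units).

    The excitatory-cell Na/K rates are the classic hippocampal
    Traub-Miles-style formulation; basket cells use fast-spiking
    Wang–Buzsáki kinetics; A-type, Ih, L-type Ca and K(Ca) use standard
    sigmoidal steady states with fixed or bell-shaped time constants.
    Every constant is exposed here so the kinetics can be aligned to other
    published CA3 parameter sets without code changes.
    """
    return {
        # pyramidal/OLM transient Na
        "na_am_rate": 0.32, "na_am_vhalf": -54.0, "na_am_k": 4.0,
        "na_bm_rate": 0.28, "na_bm_vhalf": -27.0, "na_bm_k": 5.0,
        "na_ah_rate": 0.128, "na_ah_vhalf": -50.0, "na_ah_k": 18.0,
        "na_bh_rate": 4.0, "na_bh_vhalf": -27.0, "na_bh_k": 5.0,
        # pyramidal/OLM delayed rectifier
        "kdr_an_rate": 0.032, "kdr_an_vhalf": -52.0, "kdr_an_k": 5.0,
        "kdr_bn_rate": 0.5, "kdr_bn_vhalf": -57.0, "kdr_bn_k": 40.0,
        # A-type K (activation a, inactivation b)
        "ka_a_vhalf": -35.0, "ka_a_k": 10.0, "ka_a_tau": 2.0,
        "ka_b_vhalf": -80.0, "ka_b_k": 6.0, "ka_b_tau": 20.0,
        # Ih (activation q)
        "ih_q_vhalf": -80.0, "ih_q_k": 7.0,
        "ih_tau_amp": 200.0, "ih_tau_vhalf": -70.0, "ih_tau_k": 20.0,
        "ih_tau_min": 5.0,
        # basket (Wang–Buzsáki; m-rates sped up in lieu of the instantaneous
        # activation of the original formulation)
        "wb_am_rate": 0.5, "wb_am_vhalf": -35.0, "wb_am_k": 10.0,
        "wb_bm_rate": 20.0, "wb_bm_vhalf": -60.0, "wb_bm_k": 18.0,
        "wb_ah_rate": 0.35, "wb_ah_vhalf": -58.0, "wb_ah_k": 20.0,
        "wb_bh_rate": 5.0, "wb_bh_vhalf": -28.0, "wb_bh_k": 10.0,
        "wb_an_rate": 0.05, "wb_an_vhalf": -34.0, "wb_an_k": 10.0,
        "wb_bn_rate": 0.625, "wb_bn_vhalf": -44.0, "wb_bn_k": 80.0,
        # OLM high-threshold Ca (activation s, modeled s^2)
        "cal_s_vhalf": -20.0, "cal_s_k": 9.0, "cal_s_tau": 3.0,
        # OLM calcium pool and K(Ca)
        "ca_alpha": 3e-4,    # mM per (nA·ms) influx conversion
        "ca_tau": 200.0,     # ms, pool decay
        "ca_rest": 1e-5,     # mM
        "kca_kd": 0.01,      # mM, half-activation of K(Ca)
    }


def _default_geometry() -> dict[str, list[CompartmentGeometry]]:
    return {
        "pyr": [
            CompartmentGeometry("soma", 20.0, 20.0),
            CompartmentGeometry("Bdend", 200.0, 2.0),
            CompartmentGeometry("Adend1", 150.0, 2.5),
            CompartmentGeometry("Adend2", 150.0, 2.5),
            CompartmentGeometry("Adend3", 150.0, 2.5),
        ],
        "bas": [CompartmentGeometry("soma", 20.0, 20.0)],
        "olm": [CompartmentGeometry("soma", 20.0, 20.0)],
    }


def _default_channels() -> dict[str, ChannelSet]:
    # Densities chosen to give a quiet ~-65 mV rest, overshooting somatic
    # spikes, pyramidal input resistance in the physiological 50-200 MΩ
    # range, and OLM burst/after-burst behavior; all config-overridable.
    return {
        "pyr": ChannelSet(
            gbar={
                "na": [0.12, 0.04, 0.04, 0.04, 0.04],
                "kdr": [0.05, 0.02, 0.02, 0.02, 0.02],
                "ka": [0.014, 0.014, 0.014, 0.014, 0.014],
                "ih": [0.00015, 0.00015, 0.00015, 0.00015, 0.00015],
                "leak": [1e-4, 1e-4, 1e-4, 1e-4, 1e-4],
            },
            reversal={"na": 55.0, "k": -90.0, "ih": -30.0, "leak": -65.0},
        ),
        "bas": ChannelSet(
            # Na/K densities set high enough that strong synaptic drive
            # accelerates firing instead of causing depolarization block;
            # depolarized leak reversal keeps the cell near threshold so
            # pyramidal volleys and the septal gate dominate its timing.
            gbar={"na": [0.105], "kdr": [0.027], "leak": [5e-5]},
            reversal={"na": 55.0, "k": -90.0, "leak": -60.0},
        ),
        "olm": ChannelSet(
            gbar={
                "na": [0.1],
                "kdr": [0.05],
                "ih": [0.0005],
                "cal": [0.008],
                "kca": [0.006],
                "leak": [1e-4],
            },
            reversal={
                "na": 55.0, "k": -90.0, "ih": -30.0, "ca": 120.0, "leak": -62.0,
            },
        ),
    }


# AMPA / NMDA / GABAA kinetics shared by every table row that uses them.
_AMPA = dict(tau1=0.05, tau2=5.3, reversal=0.0)
_NMDA = dict(tau1=15.0, tau2=150.0, reversal=0.0)
_GABAA = dict(tau1=0.07, tau2=9.1, reversal=-80.0)
_GABAA_SLOW = dict(tau1=0.2, tau2=20.0, reversal=-80.0)  # OLM→pyr dendritic


def _default_synapses() -> list[SynapseSpec]:
    rows = [
        # pre, post, compartment, receptor, kinetics, peak g (nS)
        ("pyr", "pyr", "Bdend", "AMPA", _AMPA, 0.02),
        ("pyr", "pyr", "Bdend", "NMDA", _NMDA, 0.004),
        ("pyr", "bas", "soma", "AMPA", _AMPA, 0.36),
        ("pyr", "bas", "soma", "NMDA", _NMDA, 1.38),
        ("pyr", "olm", "soma", "AMPA", _AMPA, 0.36),
        ("pyr", "olm", "soma", "NMDA", _NMDA, 0.7),
        ("bas", "pyr", "soma", "GABAA", _GABAA, 0.72),
        ("bas", "bas", "soma", "GABAA", _GABAA, 4.5),
        ("olm", "pyr", "Adend2", "GABAA", _GABAA_SLOW, 72.0),
    ]
    return [
        SynapseSpec(
            pre=pre, post=post, compartment=comp, receptor=rec,
            tau1=kin["tau1"], tau2=kin["tau2"], g=g, reversal=kin["reversal"],
        )
        for pre, post, comp, rec, kin, g in rows
    ]


def _default_background() -> list[BackgroundDrive]:
    rows = [
        # post, compartment, receptor, rate Hz, kinetics, peak g (nS)
        ("pyr", "soma", "AMPA", 1000.0, _AMPA, 0.05),
        ("pyr", "soma", "GABAA", 1000.0, _GABAA, 0.012),
        ("pyr", "Adend3", "AMPA", 1000.0, _AMPA, 0.05),
        ("pyr", "Adend3", "NMDA", 10.0, _NMDA, 6.5),
        ("pyr", "Adend3", "GABAA", 1000.0, _GABAA, 0.012),
        ("bas", "soma", "AMPA", 1000.0, _AMPA, 0.02),
        ("bas", "soma", "GABAA", 1000.0, _GABAA, 0.2),
        ("olm", "soma", "AMPA", 1000.0, _AMPA, 0.0625),
        ("olm", "soma", "GABAA", 1000.0, _GABAA, 0.2),
    ]
    return [
        BackgroundDrive(
            post=post, compartment=comp, receptor=rec, rate=rate,
            tau1=kin["tau1"], tau2=kin["tau2"], g=g, reversal=kin["reversal"],
        )
        for post, comp, rec, rate, kin, g in rows
    ]


def _default_convergence() -> dict[str, int]:
    # Number of randomly chosen presynaptic partners per postsynaptic cell.
    # Not derivable from first principles; defaults follow the convergence
    # structure of published CA3 theta-gamma models and are required config
    # inputs, not constants of this package.
    return {
        "pyr->pyr": 25,
        "pyr->bas": 100,
        "pyr->olm": 10,
        "bas->pyr": 75,
        "bas->bas": 199,  # all-to-all perisomatic coupling (no autapses)
        "olm->pyr": 20,
    }


@dataclass
class NetworkConfig:
    """Full network parameterization; see module docstring for units."""

    n_pyr: int = 800
    n_bas: int = 200
    n_olm: int = 200
    geometry: dict[str, list[CompartmentGeometry]] = field(
        default_factory=_default_geometry
    )
    channels: dict[str, ChannelSet] = field(default_factory=_default_channels)
    membrane_capacitance: float = 1.0  # µF/cm²
    kinetics: dict[str, float] = field(default_factory=_default_kinetics)
    synapses: list[SynapseSpec] = field(default_factory=_default_synapses)
    background: list[BackgroundDrive] = field(default_factory=_default_background)
    convergence: dict[str, int] = field(default_factory=_default_convergence)
    scaling: ScalingCondition = field(default_factory=ScalingCondition)
    added_recurrent_delay: float = 0.0  # ms, extra delay on pyr->pyr only
    ms_period: float = 150.0  # ms, medial-septum pacemaker period
    ms_tau1: float = 20.0
    ms_tau2: float = 40.0
    ms_g: float = 1.6  # nS per septal synapse
    ms_convergence: int = 10  # septal synapses per interneuron
    ms_reversal: float = -80.0
    nmda_mg_block: bool = True  # sigmoidal Mg2+ block on NMDA conductances
    dt: float = 0.025  # ms, integration step
    record_dt: float = 1.0  # ms, voltage recording interval
    duration: float = 7000.0  # ms
    discard: float = 3000.0  # ms, equilibration excluded from analysis
    init_jitter: float = 2.0  # mV, seeded symmetry-breaking of initial V
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if min(self.n_pyr, self.n_bas, self.n_olm) <= 0:
            raise ValueError("population sizes must be positive")
        if not (self.duration > self.discard >= 0):
            raise ValueError("need duration > discard >= 0")
        if self.dt <= 0 or self.record_dt < self.dt:
            raise ValueError("need dt > 0 and record_dt >= dt")
        if self.added_recurrent_delay < 0:
            raise ValueError("added recurrent delay must be >= 0")
        for pop, geom in self.geometry.items():
            nc = self.channels[pop].n_compartments()
            if len(geom) != nc:
                raise ValueError(
                    f"{pop}: {len(geom)} compartments but {nc} channel entries"
                )
        if len(self.geometry["pyr"]) != 5:
            raise ValueError("pyramidal cells must have 5 compartments")
        if len(self.geometry["bas"]) != 1 or len(self.geometry["olm"]) != 1:
            raise ValueError("interneurons are single-compartment")
        sizes = {"pyr": self.n_pyr, "bas": self.n_bas, "olm": self.n_olm}
        for key, conv in self.convergence.items():
            pre, post = key.split("->")
            pool = sizes[pre] - (1 if pre == post else 0)
            if conv < 0 or conv > pool:
                raise ValueError(
                    f"convergence {key}={conv} exceeds presynaptic pool {pool}"
                )

    def copy(self) -> "NetworkConfig":
        return copy.deepcopy(self)

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = copy.deepcopy(d)
        d["geometry"] = {
            pop: [CompartmentGeometry(**g) for g in geoms]
            for pop, geoms in d["geometry"].items()
        }
        d["channels"] = {pop: ChannelSet(**c) for pop, c in d["channels"].items()}
        d["synapses"] = [SynapseSpec(**s) for s in d["synapses"]]
        d["background"] = [BackgroundDrive(**b) for b in d["background"]]
        d["scaling"] = ScalingCondition(**d["scaling"])
        return cls(**d)


def default_config(**overrides) -> NetworkConfig:
    """The full-size (800/200/200) baseline configuration."""
    return NetworkConfig(**overrides)


def load_config(path) -> NetworkConfig:
    with open(path) as fh:
        return NetworkConfig.from_dict(yaml.safe_load(fh))


def save_config(config: NetworkConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
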