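"""Desk-scale synthetic inputs with known statistical structure.

These generators produce oscillatory traces with closed-form band powers,
spike rasters with controllable rhythmicity, and linear X→M→Y mediation
datasets with planted path coefficients, so the spectral and inferential
machinery can be tested end to end without running the network simulator.
A reduced-scale network configuration is also provided for fast
integration tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analysis import LfpTrace
from .config import NetworkConfig, default_config

__all__ = [
    "SurrogateSpec",
    "make_surrogate_lfp",
    "make_surrogate_raster",
    "make_mediation_dataset",
    "tiny_network_config",
]


@dataclass
class SurrogateSpec:
    """Sum-of-sinusoids + white noise surrogate signal."""

    duration: float = 4.0  # s
    fs: float = 1000.0  # Hz
    components: list[tuple[float, float, float]] = field(default_factory=list)
    # (frequency Hz, amplitude, phase rad)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for f, _, _ in self.components:
            if self.fs <= 2 * f:
                raise ValueError(
                    f"sample rate {self.fs} Hz aliases a {f} Hz component"
                )


def make_surrogate_lfp(spec: SurrogateSpec) -> LfpTrace:
    """Trace with analytically known band powers (A²/2 per sinusoid)."""
    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs
    x = np.zeros(n)
    for f, a, ph in spec.components:
        x += a * np.sin(2 * np.pi * f * t + ph)
    if spec.noise_sd > 0:
        x += np.random.default_rng(spec.seed).normal(0.0, spec.noise_sd, n)
    return LfpTrace(values=x, fs=spec.fs, window=(0.0, spec.duration * 1000.0))


def make_surrogate_raster(n_cells: int, rhythm_freq: float, cell_rate: float,
                          jitter: float, duration: float,
                          seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Population volleys at `rhythm_freq` with per-spike Gaussian jitter.

    Each cell emits `cell_rate` Hz on average by participating in a random
    subset of the volleys; spike times get N(0, jitter²) ms offsets.
    Returns (times ms, cell ids) sorted by time.
    """
    if cell_rate < 0 or rhythm_freq <= 0:
        raise ValueError("rates must be nonnegative, rhythm positive")
    rng = np.random.default_rng(seed)
    period = 1000.0 / rhythm_freq
    volleys = np.arange(0.0, duration, period)
    p = min(1.0, cell_rate / rhythm_freq)  # participation probability
    times, gids = [], []
    for cell in range(n_cells):
        take = volleys[rng.random(volleys.size) < p]
        if jitter > 0:
            take = take + rng.normal(0.0, jitter, take.size)
        take = take[(take >= 0) & (take < duration)]
        times.append(take)
        gids.append(np.full(take.size, cell, dtype=np.int64))
    t = np.concatenate(times) if times else np.empty(0)
    g = np.concatenate(gids) if gids else np.empty(0, dtype=np.int64)
    order = np.argsort(t, kind="stable")
    return t[order], g[order]


def make_mediation_dataset(a: float, b: float, c_direct: float, n: int,
                           noise_m: float = 0.1, noise_y: float = 0.1,
                           seed: int = 0) -> pd.DataFrame:
    """Linear mediation data: M = a·X + e, Y = c'·X + b·M + e'.

    X cycles over the scaling-factor design levels {1, 1.25, 1.5, 1.75}.
    """
    if n < 10:
        raise ValueError("need n >= 10")
    rng = np.random.default_rng(seed)
    levels = np.array([1.0, 1.25, 1.5, 1.75])
    x = levels[np.arange(n) % 4]
    m = a * x + rng.normal(0.0, noise_m, n)
    y = c_direct * x + b * m + rng.normal(0.0, noise_y, n)
    return pd.DataFrame({"X": x, "M": m, "Y": y})


def tiny_network_config(scale: float = 0.1, **overrides) -> NetworkConfig:
    """Down-scaled network (populations and convergences × `scale`).

    Kinetic parameters, conductances and drives are unchanged, so single
    cells behave identically; only the network is smaller.
    """
    cfg = default_config(**overrides)
    if scale == 1.0:
        return cfg
    cfg.n_pyr = max(1, int(round(cfg.n_pyr * scale)))
    cfg.n_bas = max(1, int(round(cfg.n_bas * scale)))
    cfg.n_olm = max(1, int(round(cfg.n_olm * scale)))
    sizes = {"pyr": cfg.n_pyr, "bas": cfg.n_bas, "olm": cfg.n_olm}
    conv = {}
    for key, c in cfg.convergence.items():
        pre, post = key.split("->")
        pool = sizes[pre] - (1 if pre == post else 0)
        scaled = max(1, int(round(c * scale))) if c > 0 else 0
        if pool < 1 <= scaled:
            raise ValueError(
                f"convergence {key} infeasible at scale {scale}: "
                f"pool is empty"
            )
        conv[key] = min(scaled, pool)  # all-to-all projections stay feasible
    cfg.convergence = conv
    cfg.validate()
    return cfg
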