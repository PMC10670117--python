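"""Plain-text result containers: raster TSV, trace CSV, wiring dumps."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd


def save_raster_tsv(result, path) -> None:
    """Spike raster as TSV (time_ms, gid, population)."""
    pop = result.population_of(result.spike_gids)
    df = pd.DataFrame(
        {"time_ms": result.spike_times, "gid": result.spike_gids,
         "population": pop}
    )
    df.to_csv(path, sep="\t", index=False)


def load_raster_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_lfp_csv(result, path) -> None:
    """Per-sample mean dendritic voltages needed to rebuild the LFP."""
    df = pd.DataFrame(
        {
            "time_ms": result.rec_times,
            "adend3_mean": result.v_adend3.astype(float).mean(axis=1),
            "bdend_mean": result.v_bdend.astype(float).mean(axis=1),
            "soma_mean": result.v_soma.astype(float).mean(axis=1),
        }
    )
    df.to_csv(path, index=False)


def save_wiring_tsv(result, path) -> None:
    """Edge list dump: projection, pre_id, post_id."""
    rows = []
    for pair, edges in result.wiring.items():
        for pre, post in edges:
            rows.append((pair, pre, post))
    pd.DataFrame(rows, columns=["projection", "pre_id", "post_id"]).to_csv(
        path, sep="\t", index=False
    )


def save_run(result, outdir) -> None:
    """Raster + LFP traces + config snapshot under one directory."""
    from .config import save_config

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    save_raster_tsv(result, out / "raster.tsv")
    save_lfp_csv(result, out / "traces.csv")
    save_config(result.config, out / "config.yaml")
    meta = {
        "seed": result.seed,
        "duration_ms": result.duration,
        "discard_ms": result.discard,
        "dt_ms": result.dt,
        "n_spikes": int(result.spike_times.size),
        "overflow": bool(result.overflow),
        "krec": result.config.scaling.krec,
        "kext": result.config.scaling.kext,
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=1))


def save_manifest(design: dict, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (tuple, np.ndarray)):
            return list(o)
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(design, indent=1, default=default))
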