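"""Plain-text persistence of trajectories.

A run is saved as a directory with three files:

* ``trajectory.tsv`` - long format ``t, genotype_index, B, V``
* ``genes.tsv``      - long format ``t, gene, nB_gene, nV_gene``
* ``meta.json``      - parameters, seed, termination reason, first/last
  loss times (``null`` = never), and the package version.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genotype_space import build_space
from .stochastic_dynamics import SimParams, TrajectoryRecord


def _encode_times(arr: np.ndarray) -> list:
    """inf / -inf (never happened) -> None for JSON round-tripping."""
    return [float(x) if np.isfinite(x) else None for x in arr]


def _decode_times(values: list, fill: float) -> np.ndarray:
    return np.array([fill if v is None else float(v) for v in values])


def write_trajectory(traj: TrajectoryRecord, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    S, K = traj.B.shape
    L = traj.L
    t_rep = np.repeat(traj.times, K)
    pd.DataFrame(
        {
            "t": t_rep,
            "genotype_index": np.tile(np.arange(K), S),
            "B": traj.B.ravel(),
            "V": traj.V.ravel(),
        }
    ).to_csv(outdir / "trajectory.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "t": np.repeat(traj.times, L),
            "gene": np.tile(np.arange(L), S),
            "nB_gene": traj.gene_B.ravel(),
            "nV_gene": traj.gene_V.ravel(),
        }
    ).to_csv(outdir / "genes.tsv", sep="\t", index=False)
    meta = {
        "version": __version__,
        "params": dataclasses.asdict(traj.params),
        "L": L,
        "g": traj.space.pool.g,
        "K": K,
        "t_end": traj.t_end,
        "n_steps": traj.n_steps,
        "termination": traj.termination,
        "zero_events_B": traj.zero_events_B,
        "zero_events_V": traj.zero_events_V,
        "first_zero_B": _encode_times(traj.first_zero_B),
        "first_zero_V": _encode_times(traj.first_zero_V),
        "last_zero_B": _encode_times(traj.last_zero_B),
        "last_zero_V": _encode_times(traj.last_zero_V),
        "gene_first_zero_B": _encode_times(traj.gene_first_zero_B),
        "gene_first_zero_V": _encode_times(traj.gene_first_zero_V),
    }
    with open(outdir / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def read_trajectory(outdir: str | Path) -> TrajectoryRecord:
    outdir = Path(outdir)
    with open(outdir / "meta.json") as fh:
        meta = json.load(fh)
    space = build_space(meta["L"], meta["g"])
    K, L = meta["K"], meta["L"]
    params = SimParams(**meta["params"])
    df = pd.read_csv(outdir / "trajectory.tsv", sep="\t")
    times = df["t"].to_numpy()[::K]
    S = times.size
    B = df["B"].to_numpy().reshape(S, K)
    V = df["V"].to_numpy().reshape(S, K)
    gdf = pd.read_csv(outdir / "genes.tsv", sep="\t")
    gene_B = gdf["nB_gene"].to_numpy().reshape(S, L)
    gene_V = gdf["nV_gene"].to_numpy().reshape(S, L)
    return TrajectoryRecord(
        space=space,
        params=params,
        times=times,
        B=B,
        V=V,
        gene_B=gene_B,
        gene_V=gene_V,
        first_zero_B=_decode_times(meta["first_zero_B"], np.inf),
        first_zero_V=_decode_times(meta["first_zero_V"], np.inf),
        last_zero_B=_decode_times(meta["last_zero_B"], -np.inf),
        last_zero_V=_decode_times(meta["last_zero_V"], -np.inf),
        zero_events_B=meta["zero_events_B"],
        zero_events_V=meta["zero_events_V"],
        gene_first_zero_B=_decode_times(meta["gene_first_zero_B"], np.inf),
        gene_first_zero_V=_decode_times(meta["gene_first_zero_V"], np.inf),
        t_end=meta["t_end"],
        n_steps=meta["n_steps"],
        termination=meta["termination"],
    )
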