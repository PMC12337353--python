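"""Desk-scale computational experiments: scans, bisection, temperature sweeps.

Every experiment is a pure function of its configuration and a master
seed: replicate seeds are derived deterministically, so rerunning
reproduces every table bit-identically.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import BracketError, InsufficientDataError, PanlvError
from .genotype_space import build_interaction, build_space
from .observables import classify_regime, fit_gamma, persistence_times, sample_abundances
from .stochastic_dynamics import SimParams, run
from .theory import predicted_temperatures

__all__ = ["ScanSpec", "BoundaryEstimate", "scan", "find_boundary", "temperature_sweep"]

#: parameters a scan may sweep; "L" rebuilds the genotype space
SWEEPABLE = ("r", "rB", "rV", "L", "NB_target")


def _derive_seeds(master_seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(master_seed).integers(0, 2**63 - 1, size=n)


def _build_run(base: dict, parameter: str, value, seed: int, stop_when: str, T=None):
    """Run one simulation with ``parameter`` overridden to ``value``."""
    cfg = dict(base)
    cfg[parameter] = value
    if T is not None:
        cfg["T"] = T
    L = int(cfg.pop("L"))
    g = int(cfg.pop("g", 2))
    mode = cfg.pop("interaction_mode", "matched")
    density = float(cfg.pop("interaction_density", 1.0))
    int_seed = cfg.pop("interaction_seed", None)
    cfg["seed"] = int(seed)
    space = build_space(L, g)
    M = build_interaction(space, mode=mode, density=density, seed=int_seed)
    params = SimParams(**cfg)
    return run(params, space, M=M, stop_when=stop_when), space, params


@dataclass
class ScanSpec:
    """A parameter sweep: ``replicates`` runs at each of ``values``.

    ``base_config`` is a flat config mapping (must contain ``L``; see
    :mod:`panlv.config`); per-replicate seeds derive from ``master_seed``.
    """

    swept_parameter: str
    values: list
    replicates: int
    base_config: dict
    master_seed: int = 0
    stop_when: str = "horizon"
    fit_temperatures: bool = False

    def __post_init__(self):
        if self.swept_parameter not in SWEEPABLE:
            raise ValueError(
                f"swept_parameter must be one of {SWEEPABLE}, "
                f"got {self.swept_parameter!r}"
            )
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        vals = list(self.values)
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("values must be strictly increasing")


def scan(spec: ScanSpec, manifest_path: Optional[str] = None) -> pd.DataFrame:
    """Run the sweep and tabulate per-run outcomes.

    Columns: value, replicate, seed, regime, persistence times for genes
    and genotypes (censored at the horizon and flagged), fitted
    temperatures when requested, termination reason, and any per-run error.
    Individual failures are recorded per-row and the scan continues.
    """
    seeds = _derive_seeds(spec.master_seed, len(spec.values) * spec.replicates)
    rows = []
    manifest = open(manifest_path, "a") if manifest_path else None
    try:
        for i, value in enumerate(spec.values):
            for rep in range(spec.replicates):
                seed = int(seeds[i * spec.replicates + rep])
                row = {
                    "value": value,
                    "replicate": rep,
                    "seed": seed,
                    "regime": None,
                    "t_first_gene_loss": np.nan,
                    "t_first_genotype_loss": np.nan,
                    "gene_censored": True,
                    "genotype_censored": True,
                    "Theta_fit": np.nan,
                    "theta_fit": np.nan,
                    "termination": None,
                    "error": None,
                }
                try:
                    traj, _, params = _build_run(
                        spec.base_config,
                        spec.swept_parameter,
                        value,
                        seed,
                        spec.stop_when,
                    )
                    pt = persistence_times(traj)
                    label = classify_regime(traj)
                    T = params.T
                    row.update(
                        regime=label.label,
                        t_first_gene_loss=min(pt.gene_bacteria, T),
                        t_first_genotype_loss=min(pt.genotype, T),
                        gene_censored=not np.isfinite(pt.gene_bacteria),
                        genotype_censored=not np.isfinite(pt.genotype),
                        termination=traj.termination,
                    )
                    if spec.fit_temperatures:
                        try:
                            samples = sample_abundances(traj)
                            row["Theta_fit"] = fit_gamma(samples.genotype_B).theta
                            row["theta_fit"] = fit_gamma(samples.gene_B).theta
                        except (InsufficientDataError, PanlvError):
                            pass
                except Exception as exc:  # keep scanning on per-run failure
                    row["error"] = f"{type(exc).__name__}: {exc}"
                rows.append(row)
                if manifest is not None:
                    manifest.write(json.dumps({k: _jsonable(v) for k, v in row.items()}) + "\n")
    finally:
        if manifest is not None:
            manifest.close()
    return pd.DataFrame(rows)


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        v = v.item()
    if isinstance(v, float) and not math.isfinite(v):
        return None
    return v


def summarize_scan(df: pd.DataFrame) -> pd.DataFrame:
    """Per-value mean persistence times (censored rows enter at the horizon)."""
    ok = df[df["error"].isna()]
    return ok.groupby("value").agg(
        mean_gene_persistence=("t_first_gene_loss", "mean"),
        mean_genotype_persistence=("t_first_genotype_loss", "mean"),
        n_gene_censored=("gene_censored", "sum"),
        n_genotype_censored=("genotype_censored", "sum"),
        n=("replicate", "count"),
    ).reset_index()


@dataclass
class BoundaryEstimate:
    """Result of a bisection search for a regime boundary."""

    boundary_kind: str
    parameter: str
    estimate: float
    bracket: tuple
    replicates_per_point: int
    persistence_threshold: float
    evaluations: list = field(default_factory=list)


def find_boundary(
    boundary_kind: str,
    parameter: str,
    bracket: tuple,
    base_config: dict,
    replicates: int = 5,
    persistence_threshold: float = 1e4,
    master_seed: int = 0,
    max_iter: int = 12,
    min_steps: int = 6,
    rel_width: float = 0.1,
) -> BoundaryEstimate:
    """Bisect (in log space) the I/II or II/III boundary along ``parameter``.

    A parameter value is "above" the I/II boundary when the majority of
    replicate runs lose no bacterial gene within ``persistence_threshold``
    generations, and above II/III when the majority see no genotype touch
    zero (either side).  Pilot runs verify the bracket endpoints classify
    to different sides; bisection continues until at least ``min_steps``
    halvings or the bracket is narrower than ``rel_width`` of its midpoint.
    """
    if boundary_kind not in ("I_II", "II_III"):
        raise ValueError("boundary_kind must be 'I_II' or 'II_III'")
    stop_when = "first_gene_loss" if boundary_kind == "I_II" else "first_genotype_zero"
    lo, hi = float(bracket[0]), float(bracket[1])
    if not 0 < lo < hi:
        raise ValueError("bracket must satisfy 0 < low < high")
    evaluations = []
    eval_counter = [0]

    def persists(value: float) -> bool:
        seeds = _derive_seeds(master_seed + eval_counter[0], replicates)
        eval_counter[0] += 1
        n_persist = 0
        for seed in seeds:
            traj, _, _ = _build_run(
                base_config,
                parameter,
                value,
                int(seed),
                stop_when,
                T=persistence_threshold,
            )
            if boundary_kind == "I_II":
                lost = np.isfinite(traj.gene_first_zero_B).any()
            else:
                lost = traj.zero_events_B > 0 or traj.zero_events_V > 0
            n_persist += not lost
        result = n_persist * 2 > replicates
        evaluations.append({"value": value, "n_persist": n_persist, "persists": result})
        return result

    if persists(lo):
        raise BracketError(f"lower bracket endpoint {lo:g} already persists")
    if not persists(hi):
        raise BracketError(f"upper bracket endpoint {hi:g} does not persist")
    steps = 0
    while steps < max_iter:
        mid = math.sqrt(lo * hi)
        if persists(mid):
            hi = mid
        else:
            lo = mid
        steps += 1
        if steps >= min_steps and (hi - lo) < rel_width * math.sqrt(lo * hi):
            break
    return BoundaryEstimate(
        boundary_kind=boundary_kind,
        parameter=parameter,
        estimate=math.sqrt(lo * hi),
        bracket=(lo, hi),
        replicates_per_point=replicates,
        persistence_threshold=persistence_threshold,
        evaluations=evaluations,
    )


def temperature_sweep(
    r_values,
    base_config: dict,
    master_seed: int = 0,
    burn_in_fraction: float = 0.1,
    spacing: Optional[float] = None,
) -> pd.DataFrame:
    """Fit effective temperatures across transfer rates and attach predictions.

    One run per ``r``; runs that end in Regime I are flagged and their fits
    left empty.  Fits use bacterial-side genotype and gene samples.
    """
    seeds = _derive_seeds(master_seed, len(r_values))
    rows = []
    for value, seed in zip(r_values, seeds):
        traj, _, _ = _build_run(base_config, "r", value, int(seed), "horizon")
        label = classify_regime(traj, burn_in_fraction)
        row = {
            "r": value,
            "regime": label.label,
            "Theta_fit": np.nan,
            "theta_fit": np.nan,
            "Theta_pred": np.nan,
            "theta_pred": np.nan,
            "excluded": label.label == "I",
        }
        if label.label != "I":
            samples = sample_abundances(traj, burn_in_fraction, spacing)
            row["Theta_fit"] = fit_gamma(samples.genotype_B).theta
            row["theta_fit"] = fit_gamma(samples.gene_B).theta
            Theta_p, theta_p = predicted_temperatures(value, label.label)
            row["Theta_pred"] = Theta_p
            row["theta_pred"] = theta_p
        rows.append(row)
    return pd.DataFrame(rows)
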