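"""Measured quantities derived from simulated trajectories.

Lyapunov energy of a bacteria-phage pair, persistence (first-loss) times,
pooled abundance samples and their Gamma fits ("effective temperatures"),
dynamical regime labels, and boom-bust peak statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .errors import DegenerateFitError, InsufficientDataError
from .stochastic_dynamics import TrajectoryRecord

__all__ = [
    "GammaFitResult",
    "RegimeLabel",
    "PeakStats",
    "PersistenceTimes",
    "AbundanceSamples",
    "REGIME_ORDER",
    "lyapunov",
    "persistence_times",
    "sample_abundances",
    "fit_gamma",
    "classify_regime",
    "boom_peaks",
]

REGIME_ORDER = {"I": 1, "II": 2, "III": 3}


def lyapunov(B, V, n_star):
    """Lyapunov energy ``E = (B - n* ln(B/n*)) + (V - n* ln(V/n*))``.

    Conserved by the deterministic pair dynamics; minimized at
    ``B = V = n*`` with value ``2 n*``; symmetric under B <-> V.  Raises on
    nonpositive abundances, where E diverges.
    """
    B = np.asarray(B, dtype=float)
    V = np.asarray(V, dtype=float)
    if n_star <= 0:
        raise ValueError("n_star must be positive")
    if (B <= 0).any() or (V <= 0).any():
        raise ValueError("lyapunov requires strictly positive abundances")
    E = (B - n_star * np.log(B / n_star)) + (V - n_star * np.log(V / n_star))
    return float(E) if E.ndim == 0 else E


@dataclass
class PersistenceTimes:
    """First-loss times; ``inf`` marks horizon-censored (never lost)."""

    gene_bacteria: float
    gene_phage: float
    gene: float
    genotype_bacteria: float
    genotype_phage: float
    genotype: float
    horizon: float

    def censored(self, which: str = "gene") -> bool:
        return not np.isfinite(getattr(self, which))


def persistence_times(traj: TrajectoryRecord) -> PersistenceTimes:
    """Earliest times any gene / genotype abundance hits zero.

    Reported per side and combined as the minimum; detection is at step
    resolution (independent of the recording cadence).
    """
    gb = float(traj.gene_first_zero_B.min())
    gv = float(traj.gene_first_zero_V.min())
    kb = float(traj.first_zero_B.min())
    kv = float(traj.first_zero_V.min())
    return PersistenceTimes(
        gene_bacteria=gb,
        gene_phage=gv,
        gene=min(gb, gv),
        genotype_bacteria=kb,
        genotype_phage=kv,
        genotype=min(kb, kv),
        horizon=float(traj.params.T),
    )


@dataclass
class AbundanceSamples:
    """Pooled abundance snapshots (across strains and decorrelated times)."""

    genotype_B: np.ndarray
    genotype_V: np.ndarray
    gene_B: np.ndarray
    gene_V: np.ndarray
    times: np.ndarray

    @property
    def n_snapshots(self) -> int:
        return self.times.size


def sample_abundances(
    traj: TrajectoryRecord,
    burn_in_fraction: float = 0.1,
    spacing: Optional[float] = None,
    min_snapshots: int = 10,
) -> AbundanceSamples:
    """Pool genotype and gene abundances from decorrelated snapshots.

    Snapshots are taken from the recorded samples after
    ``burn_in_fraction * t_end``, at intervals of at least ``spacing``
    (default ``1/s`` model-time units, about one selection timescale).
    """
    if spacing is None:
        spacing = 1.0 / traj.params.s
    t_burn = burn_in_fraction * traj.t_end
    picked = []
    last = -np.inf
    for i, t in enumerate(traj.times):
        if t >= t_burn and t - last >= spacing - 1e-9:
            picked.append(i)
            last = t
    if len(picked) < min_snapshots:
        raise InsufficientDataError(
            f"only {len(picked)} snapshots after burn-in with spacing {spacing:g}"
        )
    idx = np.array(picked)
    return AbundanceSamples(
        genotype_B=traj.B[idx].ravel(),
        genotype_V=traj.V[idx].ravel(),
        gene_B=traj.gene_B[idx].ravel(),
        gene_V=traj.gene_V[idx].ravel(),
        times=traj.times[idx],
    )


@dataclass
class GammaFitResult:
    """Two-parameter maximum-likelihood Gamma fit of an abundance ensemble.

    ``theta`` (the scale) is the "effective temperature"; exact zeros are
    excluded before fitting and reported as ``zero_fraction``.
    """

    mean: float
    theta: float
    shape: float
    n_samples: int
    zero_fraction: float
    loglik: float


def fit_gamma(samples, min_positive: int = 100) -> GammaFitResult:
    """Fit a Gamma distribution to strictly positive abundance samples.

    Raises :class:`InsufficientDataError` with fewer than ``min_positive``
    positive samples and :class:`DegenerateFitError` if they are all equal.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if (x < 0).any():
        raise ValueError("abundance samples must be nonnegative")
    pos = x[x > 0]
    if pos.size < min_positive:
        raise InsufficientDataError(
            f"{pos.size} positive samples, need at least {min_positive}"
        )
    if np.ptp(pos) == 0:
        raise DegenerateFitError("all samples identical; Gamma MLE is degenerate")
    shape, _, scale = stats.gamma.fit(pos, floc=0)
    loglik = float(stats.gamma.logpdf(pos, shape, loc=0, scale=scale).sum())
    return GammaFitResult(
        mean=float(shape * scale),
        theta=float(scale),
        shape=float(shape),
        n_samples=int(pos.size),
        zero_fraction=float(1.0 - pos.size / x.size),
        loglik=loglik,
    )


@dataclass
class RegimeLabel:
    """Dynamical regime of a finished run.

    I: some gene was lost; II: all genes kept but some genotype touched
    zero after burn-in; III: every genotype stayed positive after burn-in.
    """

    label: str
    first_gene_loss: Optional[float]
    genotype_zero_events: int
    evidence: str

    @property
    def order(self) -> int:
        return REGIME_ORDER[self.label]


def classify_regime(
    traj: TrajectoryRecord,
    burn_in_fraction: float = 0.1,
    gene_side: str = "bacteria",
) -> RegimeLabel:
    """Label a trajectory I / II / III.

    Gene loss is judged on the bacterial side by default (where it is
    absorbing; the phage side can transiently lose and regain genes through
    bacteria-to-phage transfer); pass ``gene_side="either"`` to count both.
    """
    if gene_side == "bacteria":
        gene_loss = float(traj.gene_first_zero_B.min())
    elif gene_side == "either":
        gene_loss = min(
            float(traj.gene_first_zero_B.min()), float(traj.gene_first_zero_V.min())
        )
    else:
        raise ValueError("gene_side must be 'bacteria' or 'either'")
    zero_events = traj.zero_events_B + traj.zero_events_V
    if np.isfinite(gene_loss):
        return RegimeLabel(
            label="I",
            first_gene_loss=gene_loss,
            genotype_zero_events=zero_events,
            evidence=f"first gene lost at t={gene_loss:g}",
        )
    t_burn = burn_in_fraction * traj.t_end
    touched = (traj.last_zero_B > t_burn).any() or (traj.last_zero_V > t_burn).any()
    if touched:
        return RegimeLabel(
            label="II",
            first_gene_loss=None,
            genotype_zero_events=zero_events,
            evidence=(
                f"no gene lost; {zero_events} genotype zero-touch events "
                f"(some after burn-in t={t_burn:g})"
            ),
        )
    return RegimeLabel(
        label="III",
        first_gene_loss=None,
        genotype_zero_events=zero_events,
        evidence=f"no gene lost and no genotype at zero after burn-in t={t_burn:g}",
    )


@dataclass
class PeakStats:
    """Boom-bust peak census: (genotype, time, height) and exponential tail."""

    peaks: list
    exp_rate: float
    threshold: float

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)


def boom_peaks(
    traj: TrajectoryRecord,
    threshold_multiple: float = 5.0,
    min_peaks: int = 20,
) -> PeakStats:
    """Detect booms of bacterial genotypes and fit the peak-height tail.

    A boom is a maximal contiguous excursion of one genotype's recorded
    abundance above ``threshold_multiple * n_star``; its peak is the
    maximum within the excursion.  ``exp_rate`` is the maximum-likelihood
    exponential rate of ``peak - threshold``.
    """
    thr = threshold_multiple * traj.n_star_B
    peaks = []
    for k in range(traj.K):
        x = traj.B[:, k]
        above = x > thr
        if not above.any():
            continue
        edges = np.diff(above.astype(np.int8))
        starts = list(np.flatnonzero(edges == 1) + 1)
        ends = list(np.flatnonzero(edges == -1) + 1)
        if above[0]:
            starts.insert(0, 0)
        if above[-1]:
            ends.append(above.size)
        for a, b in zip(starts, ends):
            j = a + int(np.argmax(x[a:b]))
            peaks.append((k, float(traj.times[j]), float(x[j])))
    if len(peaks) < min_peaks:
        raise InsufficientDataError(
            f"{len(peaks)} excursions above threshold, need at least {min_peaks}"
        )
    excess = np.array([h for _, _, h in peaks]) - thr
    return PeakStats(peaks=peaks, exp_rate=float(1.0 / excess.mean()), threshold=thr)
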