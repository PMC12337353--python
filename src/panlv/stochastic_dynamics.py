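"""Stochastic birth-death dynamics of bacteria and phage with gene transfer.

The deterministic skeleton is an antisymmetric Lotka-Volterra pair model:
bacterial per-capita fitness ``s * (1 - V/nV*)`` and phage fitness
``omega * (B/nB* - 1)``, where ``nB* = NB/K`` and ``nV* = NV/K`` are the
characteristic per-strain sizes.  On top of it sit

* tau-leaped demographic noise (independent Poisson birth and death counts
  per strain and step),
* three horizontal-transfer channels (bacteria->bacteria,
  bacteria->phage, phage->phage), each moving single individuals between
  genotypes at per-capita rate ``rB`` / ``rV``, and
* a regulator that projects the totals back to ``NB_target`` / ``NV_target``
  after every step, standing in for a universal carrying capacity.

Time is measured in generations.  The demographic step includes a baseline
per-capita turnover ``turnover`` (births and deaths at rate ``turnover``
each on top of the net fitness), so that one generation carries
reproduction noise of variance ``2 * turnover * n ~ n`` per strain.  With
phages absent and no transfer this reduces to a Wright-Fisher-like neutral
drift; ``turnover = 0`` recovers a pure net-rate scheme in which noise
scales with ``|f|`` instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import GlobalExtinctionError
from .genotype_space import GenotypeSpace, InteractionMatrix, build_interaction

__all__ = [
    "SimParams",
    "CommunityState",
    "Characteristics",
    "TrajectoryRecord",
    "per_capita_fitness",
    "demographic_step",
    "regulate",
    "hgt_step_bacteria",
    "hgt_step_phage",
    "sample_gene_transfers",
    "run",
]

PHAGE_HGT_MODES = ("from_bacteria", "interphage", "off")
STOP_RULES = (
    "horizon",
    "first_gene_loss",
    "first_genotype_zero",
    "first_loss",
    "bacterial_fixation",
)

#: per-capita selection probability per step must stay below this
MAX_EVENT_PROB = 0.1


@dataclass
class SimParams:
    """Simulation parameters; rates are per capita per generation.

    Either the direct fields (``omega``, ``rV``, ``NV_target``) or the ratio
    parameterization (``rho_s = omega/s``, ``rho_r = rV/rB``,
    ``rho_n = NV/NB``) may be supplied; direct fields win.  ``r`` is a
    convenience alias that sets ``rB`` (and ``rV`` through ``rho_r``).
    """

    NB_target: int = 10_000
    NV_target: Optional[int] = None
    s: float = 5e-3
    omega: Optional[float] = None
    rho_s: float = 1.0
    rho_n: float = 1.0
    rho_r: float = 1.0
    r: Optional[float] = None
    rB: float = 0.0
    rV: Optional[float] = None
    phage_hgt_mode: str = "from_bacteria"
    hgt_collision: str = "resample"
    turnover: float = 0.5
    regulate_populations: bool = True
    dt: float = 1.0
    T: float = 20_000.0
    seed: int = 0
    record_every: Optional[int] = None

    def __post_init__(self):
        if self.r is not None:
            self.rB = float(self.r)
        if self.rV is None:
            self.rV = self.rho_r * self.rB
        if self.omega is None:
            self.omega = self.rho_s * self.s
        if self.NV_target is None:
            self.NV_target = int(round(self.rho_n * self.NB_target))
        if self.phage_hgt_mode not in PHAGE_HGT_MODES:
            raise ValueError(
                f"phage_hgt_mode must be one of {PHAGE_HGT_MODES}, "
                f"got {self.phage_hgt_mode!r}"
            )
        if self.hgt_collision not in ("resample", "noop"):
            raise ValueError("hgt_collision must be 'resample' or 'noop'")
        for name in ("s", "omega", "rB", "rV", "turnover"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.dt <= 0 or self.T <= 0:
            raise ValueError("dt and T must be positive")
        if self.NB_target <= 0 or self.NV_target <= 0:
            raise ValueError("population targets must be positive")
        if max(self.s, self.omega) * self.dt > MAX_EVENT_PROB + 1e-12:
            raise ValueError(
                f"dt={self.dt} too large: max(s, omega)*dt must be <= "
                f"{MAX_EVENT_PROB} for the tau-leap to be accurate"
            )

    @property
    def default_record_every(self) -> int:
        """Default sampling cadence: about one bacterial doubling time."""
        if self.record_every is not None:
            return int(self.record_every)
        return max(1, math.ceil(1.0 / (self.s * self.dt)))


@dataclass
class Characteristics:
    """Per-strain characteristic population sizes ``nB* = NB/K`` etc."""

    n_B_star: float
    n_V_star: float

    @classmethod
    def from_params(cls, params: SimParams, K: int) -> "Characteristics":
        return cls(n_B_star=params.NB_target / K, n_V_star=params.NV_target / K)

    @property
    def n_G_star(self) -> float:
        """Common characteristic size in the symmetric case ``rho_n = 1``."""
        return self.n_B_star


@dataclass
class CommunityState:
    """Integer abundances of each genotype at one time point."""

    B: np.ndarray
    V: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        self.B = np.asarray(self.B, dtype=np.int64)
        self.V = np.asarray(self.V, dtype=np.int64)
        if self.B.shape != self.V.shape:
            raise ValueError("B and V must have the same length K")
        if (self.B < 0).any() or (self.V < 0).any():
            raise ValueError("abundances must be nonnegative")

    @property
    def K(self) -> int:
        return self.B.size

    def copy(self) -> "CommunityState":
        return CommunityState(B=self.B.copy(), V=self.V.copy(), t=self.t)


# ----------------------------------------------------------------------
# elementary update steps (array-level helpers + state-level wrappers)
# ----------------------------------------------------------------------

def per_capita_fitness(
    state: CommunityState, params: SimParams, M: InteractionMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Per-capita growth rates ``fB = s(1 - MV/nV*)``, ``fV = omega(M'B/nB* - 1)``.

    In matched mode these reduce to the per-pair expressions; with a sparse
    interaction matrix the pressure/availability terms sum over partners.
    """
    chars = Characteristics.from_params(params, state.K)
    fB = params.s * (1.0 - M.infection_pressure(state.V) / chars.n_V_star)
    fV = params.omega * (M.host_availability(state.B) / chars.n_B_star - 1.0)
    return fB, fV


def _demographic_update(
    n: np.ndarray, f: np.ndarray, dt: float, rng: np.random.Generator, turnover: float
) -> np.ndarray:
    """Poisson births/deaths with net per-capita rate ``f`` and baseline
    turnover.  Birth rate ``max(turnover + f, 0)``, death rate chosen so the
    net mean is exactly ``f * n * dt``; deaths truncate at zero."""
    birth = np.maximum(turnover + f, 0.0)
    death = birth - f
    births = rng.poisson(n * birth * dt)
    deaths = rng.poisson(n * death * dt)
    return np.maximum(n + births - deaths, 0)


def demographic_step(
    state: CommunityState,
    fB: np.ndarray,
    fV: np.ndarray,
    dt: float,
    rng: np.random.Generator,
    turnover: float = 0.5,
) -> CommunityState:
    """One tau-leap of births and deaths on both sides (totals unconstrained).

    Strains at zero abundance receive no events; the expected change of
    strain ``k`` is ``f[k] * n[k] * dt`` (before truncation at zero), which
    matches the deterministic right-hand side to O(dt^2).
    """
    B = _demographic_update(state.B, fB, dt, rng, turnover)
    V = _demographic_update(state.V, fV, dt, rng, turnover)
    return CommunityState(B=B, V=V, t=state.t)


def _match_total(
    n: np.ndarray, target: int, rng: np.random.Generator, side: str, t: float
) -> np.ndarray:
    total = int(n.sum())
    if total == 0:
        raise GlobalExtinctionError(side, t)
    d = total - target
    if d > 0:
        # removing d individuals uniformly at random = multivariate
        # hypergeometric; caps removals at current abundance by construction
        n = n - rng.multivariate_hypergeometric(n, d)
    elif d < 0:
        n = n + rng.multinomial(-d, n / total)
    return n


def regulate(
    state: CommunityState, params: SimParams, rng: np.random.Generator
) -> CommunityState:
    """Project totals back to ``NB_target`` / ``NV_target`` exactly.

    Individuals are added (multinomial, proportional to abundance) or
    removed (multivariate hypergeometric, i.e. uniformly at random without
    replacement) so relative frequencies are unchanged in expectation and
    empty strains never gain individuals.  Raises
    :class:`~panlv.errors.GlobalExtinctionError` if a side is empty.
    """
    B = _match_total(state.B, params.NB_target, rng, "bacteria", state.t)
    V = _match_total(state.V, params.NV_target, rng, "phage", state.t)
    return CommunityState(B=B, V=V, t=state.t)


def _sample_weighted(counts: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` strain indices with probability proportional to counts."""
    cdf = np.cumsum(counts)
    u = rng.integers(0, cdf[-1], size=n)
    return np.searchsorted(cdf, u, side="right")


def sample_gene_transfers(
    space: GenotypeSpace,
    recipient_weights: np.ndarray,
    donor_weights: np.ndarray,
    n_events: int,
    rng: np.random.Generator,
    collision: str = "resample",
) -> tuple[np.ndarray, np.ndarray]:
    """Sample ``n_events`` transfer attempts.

    Recipient and donor genotypes are drawn independently proportional to
    their weights; the incoming gene is uniform among the donor's ``g``
    genes and the replaced slot uniform among the recipient's ``g`` slots.
    Returns (recipient index, product index) with ``-1`` marking NO_OP
    attempts (incoming gene already carried, or identity replacement).

    ``collision="resample"`` redraws NO_OP events (whole event) so the
    per-capita rate counts genotype-changing transfers, matching the
    definition of the transfer rate as actual transfers into a strain per
    unit time; ``"noop"`` leaves them as lost attempts, which reduces the
    effective rate by about ``g/L``.
    """
    g = space.pool.g
    rec = _sample_weighted(recipient_weights, n_events, rng)
    don = _sample_weighted(donor_weights, n_events, rng)
    genes = space.genotypes[don, rng.integers(0, g, size=n_events)]
    slots = rng.integers(0, g, size=n_events)
    prod = space.hgt_product_index(rec, slots, genes)
    if collision == "resample":
        rec, prod = _resample_collisions(
            space, recipient_weights, donor_weights, rec, prod, rng
        )
    return rec, prod


def _resample_collisions(
    space: GenotypeSpace,
    recipient_weights: np.ndarray,
    donor_weights: np.ndarray,
    rec: np.ndarray,
    prod: np.ndarray,
    rng: np.random.Generator,
    max_rounds: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Redraw NO_OP transfer events until they produce a genotype change.

    Bails out (leaving residual NO_OPs) after ``max_rounds`` or as soon as a
    round makes no progress, which happens in degenerate states where almost
    no transfer can succeed -- e.g. a monomorphic community, where recipient
    and donor always share all genes.
    """
    g = space.pool.g
    bad = np.flatnonzero(prod < 0)
    for _ in range(max_rounds):
        if bad.size == 0:
            break
        n = bad.size
        rec_new = _sample_weighted(recipient_weights, n, rng)
        don_new = _sample_weighted(donor_weights, n, rng)
        genes = space.genotypes[don_new, rng.integers(0, g, size=n)]
        slots = rng.integers(0, g, size=n)
        rec[bad] = rec_new
        prod[bad] = space.hgt_product_index(rec_new, slots, genes)
        still_bad = bad[prod[bad] < 0]
        if still_bad.size == bad.size:
            break
        bad = still_bad
    return rec, prod


def _apply_moves(n: np.ndarray, rec: np.ndarray, prod: np.ndarray) -> np.ndarray:
    """Move one individual per non-NO_OP event from recipient to product.

    The vectorized fast path assumes no strain is driven negative; in the
    rare case it would be, events are replayed in order and attempts whose
    recipient is exhausted become NO_OPs.  Total abundance is conserved
    exactly either way.
    """
    ok = prod >= 0
    rec, prod = rec[ok], prod[ok]
    if rec.size == 0:
        return n
    K = n.size
    out = n + np.bincount(prod, minlength=K) - np.bincount(rec, minlength=K)
    if out.min() >= 0:
        return out
    out = n.copy()
    for a, b in zip(rec, prod):
        if out[a] > 0:
            out[a] -= 1
            out[b] += 1
    return out


def hgt_step_bacteria(
    state: CommunityState,
    params: SimParams,
    space: GenotypeSpace,
    dt: float,
    rng: np.random.Generator,
) -> CommunityState:
    """Inter-bacteria transfer: ``Poisson(rB * NB * dt)`` attempts per step.

    A recipient CD acquiring gene B from a donor AB (replacing C) moves one
    individual CD -> BD.  Total bacterial abundance is unchanged.
    """
    NB = int(state.B.sum())
    if params.rB == 0 or NB == 0:
        return state
    n_events = int(rng.poisson(params.rB * NB * dt))
    if n_events == 0:
        return state
    rec, prod = sample_gene_transfers(
        space, state.B, state.B, n_events, rng, collision=params.hgt_collision
    )
    return CommunityState(B=_apply_moves(state.B, rec, prod), V=state.V, t=state.t)


def hgt_step_phage(
    state: CommunityState,
    params: SimParams,
    space: GenotypeSpace,
    dt: float,
    rng: np.random.Generator,
) -> CommunityState:
    """Phage-side transfer: ``Poisson(rV * NV * dt)`` attempts per step.

    In ``from_bacteria`` mode the antitoxin donor is drawn proportional to
    the bacterial abundances; in ``interphage`` mode proportional to phage
    abundances (mean-field coinfection approximation); ``off`` is a no-op.
    Total phage abundance is unchanged.
    """
    if params.phage_hgt_mode == "off" or params.rV == 0:
        return state
    NV = int(state.V.sum())
    if NV == 0:
        return state
    donors = state.B if params.phage_hgt_mode == "from_bacteria" else state.V
    if donors.sum() == 0:
        return state
    n_events = int(rng.poisson(params.rV * NV * dt))
    if n_events == 0:
        return state
    rec, prod = sample_gene_transfers(space, state.V, donors, n_events, rng)
    return CommunityState(B=state.B, V=_apply_moves(state.V, rec, prod), t=state.t)


# ----------------------------------------------------------------------
# full simulation
# ----------------------------------------------------------------------

@dataclass
class TrajectoryRecord:
    """Sampled abundances and loss-event log of one simulation run.

    Abundance snapshots are taken every ``record_every`` steps; loss events
    (first/last time a genotype or gene abundance is zero) are detected at
    step resolution regardless of the sampling cadence.  ``inf`` marks
    "never hit zero"; ``last_zero_*`` is ``-inf`` in that case.
    """

    space: GenotypeSpace
    params: SimParams
    times: np.ndarray
    B: np.ndarray
    V: np.ndarray
    gene_B: np.ndarray
    gene_V: np.ndarray
    first_zero_B: np.ndarray
    first_zero_V: np.ndarray
    last_zero_B: np.ndarray
    last_zero_V: np.ndarray
    zero_events_B: int
    zero_events_V: int
    gene_first_zero_B: np.ndarray
    gene_first_zero_V: np.ndarray
    t_end: float
    n_steps: int
    termination: str

    @property
    def K(self) -> int:
        return self.space.K

    @property
    def L(self) -> int:
        return self.space.pool.L

    @property
    def n_star_B(self) -> float:
        return self.params.NB_target / self.K

    @property
    def n_star_V(self) -> float:
        return self.params.NV_target / self.K

    def save(self, outdir) -> None:
        from .io import write_trajectory

        write_trajectory(self, outdir)

    @classmethod
    def load(cls, outdir) -> "TrajectoryRecord":
        from .io import read_trajectory

        return read_trajectory(outdir)


def _uniform_init(N: int, K: int, rng: np.random.Generator) -> np.ndarray:
    base, rem = divmod(N, K)
    n = np.full(K, base, dtype=np.int64)
    if rem:
        n += rng.multinomial(rem, np.full(K, 1.0 / K))
    return n


def run(
    params: SimParams,
    space: GenotypeSpace,
    M: Optional[InteractionMatrix] = None,
    init="uniform",
    stop_when: str = "horizon",
) -> TrajectoryRecord:
    """Simulate the community from ``t = 0`` to ``T`` (or an early stop).

    Step order: fitness -> demographic tau-leap -> bacterial HGT -> phage
    HGT -> regulation -> event tracking/recording.  The run is a pure
    function of ``(params, space, M, init)``: identical seeds give
    bit-identical records.  Global extinction of either side terminates the
    run and is recorded, not raised.

    Parameters
    ----------
    init : "uniform" or a :class:`CommunityState`.  Uniform puts
        ``floor(N/K)`` individuals in every genotype and distributes the
        remainder by a seeded multinomial.
    stop_when : one of ``horizon``, ``first_gene_loss`` (bacterial side),
        ``first_genotype_zero`` (either side), ``first_loss``,
        ``bacterial_fixation``.
    """
    if stop_when not in STOP_RULES:
        raise ValueError(f"stop_when must be one of {STOP_RULES}")
    if M is None:
        M = build_interaction(space, "matched")
    if M.M.shape != (space.K, space.K):
        raise ValueError("interaction matrix shape does not match space")
    K, L = space.K, space.pool.L
    if params.NB_target < K or params.NV_target < K:
        import warnings

        warnings.warn(
            f"population target below K={K}: some genotypes start empty",
            stacklevel=2,
        )

    rng = np.random.default_rng(params.seed)
    if isinstance(init, str):
        if init != "uniform":
            raise ValueError(f"unknown init {init!r}")
        B = _uniform_init(params.NB_target, K, rng)
        V = _uniform_init(params.NV_target, K, rng)
    else:
        B = np.array(init.B, dtype=np.int64)
        V = np.array(init.V, dtype=np.int64)

    chars = Characteristics.from_params(params, K)
    s, omega, dt, turnover = params.s, params.omega, params.dt, params.turnover
    rB, rV = params.rB, params.rV
    membership = space.membership
    record_every = params.default_record_every
    n_steps_total = int(round(params.T / dt))

    # event tracking at step resolution
    first_zero_B = np.full(K, np.inf)
    first_zero_V = np.full(K, np.inf)
    last_zero_B = np.full(K, -np.inf)
    last_zero_V = np.full(K, -np.inf)
    gene_first_zero_B = np.full(L, np.inf)
    gene_first_zero_V = np.full(L, np.inf)
    zero_events_B = 0
    zero_events_V = 0
    prev_zero_B = np.zeros(K, dtype=bool)
    prev_zero_V = np.zeros(K, dtype=bool)

    times, recB, recV, recgB, recgV = [], [], [], [], []

    def track(t: float) -> tuple[np.ndarray, np.ndarray]:
        nonlocal zero_events_B, zero_events_V, prev_zero_B, prev_zero_V
        zB = B == 0
        zV = V == 0
        entered_B = zB & ~prev_zero_B
        entered_V = zV & ~prev_zero_V
        zero_events_B += int(entered_B.sum())
        zero_events_V += int(entered_V.sum())
        first_zero_B[entered_B & np.isinf(first_zero_B)] = t
        first_zero_V[entered_V & np.isinf(first_zero_V)] = t
        last_zero_B[zB] = t
        last_zero_V[zV] = t
        prev_zero_B, prev_zero_V = zB, zV
        gB = B @ membership
        gV = V @ membership
        gene_first_zero_B[(gB == 0) & np.isinf(gene_first_zero_B)] = t
        gene_first_zero_V[(gV == 0) & np.isinf(gene_first_zero_V)] = t
        return gB, gV

    def record(t: float, gB: np.ndarray, gV: np.ndarray) -> None:
        times.append(t)
        recB.append(B.copy())
        recV.append(V.copy())
        recgB.append(gB.copy())
        recgV.append(gV.copy())

    # strains empty at t=0 are tracked like any later zero-touch
    gB, gV = track(0.0)
    record(0.0, gB, gV)

    termination = "horizon"
    t = 0.0
    step = 0
    # a side that starts empty is treated as absent (e.g. the phage-free
    # Wright-Fisher limit), not as an instant global extinction
    bacteria_active = bool(B.any())
    phage_active = bool(V.any())
    matched = M.is_identity
    inv_nV = 1.0 / chars.n_V_star
    inv_nB = 1.0 / chars.n_B_star
    f2 = np.empty(2 * K)
    phage_hgt = params.phage_hgt_mode != "off" and rV > 0
    interphage = params.phage_hgt_mode == "interphage"
    resample = params.hgt_collision == "resample"
    g = space.pool.g
    while step < n_steps_total:
        step += 1
        t = step * dt
        # fitness of both sides in one buffer, then a fused tau-leap
        f2[:K] = s * (1.0 - (V if matched else M.M @ V) * inv_nV)
        f2[K:] = omega * ((B if matched else B @ M.M) * inv_nB - 1.0)
        n2 = np.concatenate((B, V))
        birth = np.maximum(turnover + f2, 0.0)
        lam = n2 * dt
        out = n2 + rng.poisson(lam * birth) - rng.poisson(lam * (birth - f2))
        np.maximum(out, 0, out=out)
        B, V = out[:K], out[K:]
        if rB > 0:
            NB_now = int(B.sum())
            if NB_now > 0:
                n_ev = int(rng.poisson(rB * NB_now * dt))
                if n_ev:
                    # recipient and donor share the bacterial weights: one
                    # cdf, one batched draw of 2*n_ev individuals
                    cdf = np.cumsum(B)
                    idx = np.searchsorted(
                        cdf, rng.integers(0, NB_now, size=2 * n_ev), side="right"
                    )
                    rec_i, don_i = idx[:n_ev], idx[n_ev:]
                    genes = space.genotypes[don_i, rng.integers(0, g, size=n_ev)]
                    prod_i = space.hgt_product_index(
                        rec_i, rng.integers(0, g, size=n_ev), genes
                    )
                    if resample:
                        rec_i, prod_i = _resample_collisions(
                            space, B, B, rec_i, prod_i, rng
                        )
                    B = _apply_moves(B, rec_i, prod_i)
        if phage_hgt:
            NV_now = int(V.sum())
            donors = V if interphage else B
            if NV_now > 0 and donors.sum() > 0:
                n_ev = int(rng.poisson(rV * NV_now * dt))
                if n_ev:
                    rec_i, prod_i = sample_gene_transfers(
                        space, V, donors, n_ev, rng, collision=params.hgt_collision
                    )
                    V = _apply_moves(V, rec_i, prod_i)
        extinct_side = None
        if params.regulate_populations:
            try:
                if bacteria_active:
                    B = _match_total(B, params.NB_target, rng, "bacteria", t)
            except GlobalExtinctionError as exc:
                extinct_side = exc.side
            if extinct_side is None:
                try:
                    if phage_active:
                        V = _match_total(V, params.NV_target, rng, "phage", t)
                except GlobalExtinctionError as exc:
                    extinct_side = exc.side
        else:
            # unregulated runs (e.g. a single isolated pair) still terminate
            # when one side empties out
            if bacteria_active and not B.any():
                extinct_side = "bacteria"
            elif phage_active and not V.any():
                extinct_side = "phage"

        gB, gV = track(t)
        if extinct_side is not None:
            termination = f"global_extinction_{extinct_side}"
            record(t, gB, gV)
            break
        stop = False
        if stop_when in ("first_gene_loss", "first_loss") and np.isfinite(
            gene_first_zero_B
        ).any():
            termination = "first_gene_loss"
            stop = True
        if (
            not stop
            and stop_when in ("first_genotype_zero", "first_loss")
            and (zero_events_B > 0 or zero_events_V > 0)
        ):
            termination = "first_genotype_zero"
            stop = True
        if not stop and stop_when == "bacterial_fixation" and np.count_nonzero(B) == 1:
            termination = "bacterial_fixation"
            stop = True
        if stop or step % record_every == 0 or step == n_steps_total:
            record(t, gB, gV)
        if stop:
            break

    return TrajectoryRecord(
        space=space,
        params=params,
        times=np.array(times),
        B=np.array(recB),
        V=np.array(recV),
        gene_B=np.array(recgB),
        gene_V=np.array(recgV),
        first_zero_B=first_zero_B,
        first_zero_V=first_zero_V,
        last_zero_B=last_zero_B,
        last_zero_V=last_zero_V,
        zero_events_B=zero_events_B,
        zero_events_V=zero_events_V,
        gene_first_zero_B=gene_first_zero_B,
        gene_first_zero_V=gene_first_zero_V,
        t_end=t,
        n_steps=step,
        termination=termination,
    )
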