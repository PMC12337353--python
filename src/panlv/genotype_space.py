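"""Combinatorics of defense genes, genotypes, and the infection matrix.

A genotype is an unordered set of ``g`` distinct gene labels drawn from a
pool of ``L`` toxin/antitoxin pairs; it is stored canonically as a sorted
tuple.  The bacterial and phage genotype spaces are identical by
construction (a phage carrying antitoxins {a, b} is matched to the
bacterium carrying toxins {A, B}), so a single :class:`GenotypeSpace`
serves both sides.  With ``g = 2`` there are ``K = L(L-1)/2`` genotypes;
``g = 3`` gives the "tripleton" case with ``K = C(L, 3)``.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "NO_OP",
    "GenePool",
    "GenotypeSpace",
    "InteractionMatrix",
    "build_space",
    "gene_abundances",
    "hgt_product",
    "build_interaction",
]


class _NoOp:
    """Singleton marker for gene-transfer events that leave the recipient
    unchanged (incoming gene already present, or identical replacement)."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "NO_OP"

    def __bool__(self) -> bool:
        return False


NO_OP = _NoOp()


@dataclass(frozen=True)
class GenePool:
    """A pool of ``L`` distinct toxin/antitoxin gene pairs, ``g`` per genome.

    Gene labels are the integers ``0 .. L-1``.
    """

    L: int
    g: int = 2

    def __post_init__(self):
        if self.g not in (2, 3):
            raise ValueError(f"g must be 2 or 3, got {self.g}")
        if self.L < self.g:
            raise ValueError(f"need L >= g, got L={self.L}, g={self.g}")


@dataclass(frozen=True)
class GenotypeSpace:
    """Canonical enumeration of all ``g``-gene genotypes over ``L`` genes.

    Attributes
    ----------
    pool : GenePool
    genotypes : (K, g) int array, rows sorted, lexicographically ordered.
    K : number of genotypes, ``binomial(L, g)``.
    index_of : dict mapping sorted gene tuples to their canonical index.
    membership : (K, L) 0/1 array; row ``k`` marks the genes of genotype ``k``.
    """

    pool: GenePool
    genotypes: np.ndarray
    K: int
    index_of: dict
    membership: np.ndarray
    _lookup_cache: list = field(default_factory=list, repr=False, compare=False)

    # -- fast lookup ------------------------------------------------------
    @property
    def _lookup(self) -> np.ndarray:
        """Dense (L,)*g table mapping sorted label tuples to indices (-1 elsewhere)."""
        if not self._lookup_cache:
            L, g = self.pool.L, self.pool.g
            table = np.full((L,) * g, -1, dtype=np.int64)
            table[tuple(self.genotypes.T)] = np.arange(self.K)
            self._lookup_cache.append(table)
        return self._lookup_cache[0]

    def hgt_product_index(
        self, recipient_idx: np.ndarray, slots: np.ndarray, genes: np.ndarray
    ) -> np.ndarray:
        """Vectorized :func:`hgt_product` on canonical indices.

        Returns the product genotype index per event, or ``-1`` for NO_OP
        events (duplicate gene or identity replacement).
        """
        recipient_idx = np.asarray(recipient_idx, dtype=np.int64)
        if self.pool.g == 2:
            pairs = self.genotypes[recipient_idx]
            old = pairs[np.arange(recipient_idx.size), slots]
            keep = pairs[:, 0] + pairs[:, 1] - old
            prod = self._lookup[np.minimum(keep, genes), np.maximum(keep, genes)]
            prod[(keep == genes) | (old == genes)] = -1
            return prod
        n = recipient_idx.size
        geno = self.genotypes[recipient_idx].copy()
        rows = np.arange(n)
        old = geno[rows, slots].copy()
        geno[rows, slots] = genes
        geno.sort(axis=1)
        dup = (geno[:, 1:] == geno[:, :-1]).any(axis=1)
        prod = self._lookup[tuple(geno.T)]
        prod[dup | (old == genes)] = -1
        return prod

    # -- serialization ----------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write a two-column table: canonical index, comma-joined gene labels."""
        with open(path, "w") as fh:
            fh.write(f"# L={self.pool.L} g={self.pool.g}\n")
            fh.write("index\tgenes\n")
            for k, row in enumerate(self.genotypes):
                fh.write(f"{k}\t{','.join(str(x) for x in row)}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenotypeSpace":
        with open(path) as fh:
            header = fh.readline().strip()
            if not header.startswith("# L="):
                raise ValueError(f"missing space header in {path}")
            parts = dict(p.split("=") for p in header[2:].split())
            space = build_space(int(parts["L"]), int(parts["g"]))
            fh.readline()  # column names
            for k, line in enumerate(fh):
                idx, genes = line.split("\t")
                tup = tuple(int(x) for x in genes.strip().split(","))
                if int(idx) != k or space.index_of[tup] != k:
                    raise ValueError(f"non-canonical genotype table at row {k}")
        return space


def build_space(L: int, g: int = 2) -> GenotypeSpace:
    """Enumerate all ``binomial(L, g)`` genotypes in canonical (sorted) order.

    Parameters
    ----------
    L : size of the gene pool (labels ``0..L-1``).
    g : genes per genome, 2 or 3.
    """
    pool = GenePool(L=L, g=g)
    combos = list(itertools.combinations(range(L), g))
    genotypes = np.array(combos, dtype=np.int64)
    K = len(combos)
    assert K == math.comb(L, g)
    membership = np.zeros((K, L), dtype=np.int64)
    rows = np.repeat(np.arange(K), g)
    membership[rows, genotypes.ravel()] = 1
    return GenotypeSpace(
        pool=pool,
        genotypes=genotypes,
        K=K,
        index_of={tuple(c): k for k, c in enumerate(combos)},
        membership=membership,
    )


def gene_abundances(space: GenotypeSpace, counts) -> np.ndarray:
    """Sum genotype abundances into per-gene abundances.

    ``out[l] = sum_k membership[k, l] * counts[k]``; total gene mass equals
    ``g`` times the total genotype mass.
    """
    counts = np.asarray(counts)
    if counts.shape[-1] != space.K:
        raise ValueError(
            f"counts has length {counts.shape[-1]}, expected K={space.K}"
        )
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    return counts @ space.membership


def hgt_product(recipient, incoming_gene: int, replaced_slot: int):
    """Genotype produced when ``recipient[replaced_slot]`` is swapped for
    ``incoming_gene``.

    Returns the sorted gene tuple, or :data:`NO_OP` when the transfer would
    duplicate a gene or reproduce the recipient unchanged.
    """
    recipient = tuple(int(x) for x in recipient)
    g = len(recipient)
    if not 0 <= replaced_slot < g:
        raise ValueError(f"replaced_slot {replaced_slot} out of range for g={g}")
    incoming_gene = int(incoming_gene)
    if incoming_gene == recipient[replaced_slot]:
        return NO_OP
    others = recipient[:replaced_slot] + recipient[replaced_slot + 1:]
    if incoming_gene in others:
        return NO_OP
    return tuple(sorted(others + (incoming_gene,)))


@dataclass(frozen=True)
class InteractionMatrix:
    """Which phage genotypes can infect which bacterial genotypes.

    ``matched`` mode is the one-phage-one-bacterium default: the identity
    matrix in the shared canonical ordering.  ``random_sparse`` draws each
    entry independently with probability ``density`` and then repairs empty
    rows/columns so every strain has at least one partner.
    """

    M: np.ndarray
    mode: str
    density: float | None = None
    seed: int | None = None

    @property
    def is_identity(self) -> bool:
        return self.mode == "matched"

    def infection_pressure(self, V: np.ndarray) -> np.ndarray:
        """Phage load felt by each bacterial genotype: ``M @ V``."""
        return V if self.is_identity else self.M @ V

    def host_availability(self, B: np.ndarray) -> np.ndarray:
        """Susceptible hosts available to each phage genotype: ``M.T @ B``."""
        return B if self.is_identity else self.M.T @ B

    def to_files(self, prefix: str | Path) -> None:
        """Write nonzero entries as a (row, col) TSV plus a JSON header."""
        prefix = Path(prefix)
        rows, cols = np.nonzero(self.M)
        with open(prefix.with_suffix(".tsv"), "w") as fh:
            fh.write("row\tcol\n")
            for r, c in zip(rows, cols):
                fh.write(f"{r}\t{c}\n")
        with open(prefix.with_suffix(".json"), "w") as fh:
            json.dump(
                {
                    "mode": self.mode,
                    "density": self.density,
                    "seed": self.seed,
                    "shape": list(self.M.shape),
                },
                fh,
            )

    @classmethod
    def from_files(cls, prefix: str | Path) -> "InteractionMatrix":
        prefix = Path(prefix)
        with open(prefix.with_suffix(".json")) as fh:
            meta = json.load(fh)
        M = np.zeros(tuple(meta["shape"]), dtype=np.int64)
        with open(prefix.with_suffix(".tsv")) as fh:
            fh.readline()
            for line in fh:
                r, c = line.split()
                M[int(r), int(c)] = 1
        return cls(M=M, mode=meta["mode"], density=meta["density"], seed=meta["seed"])


def build_interaction(
    space: GenotypeSpace,
    mode: str = "matched",
    density: float = 1.0,
    seed: int | None = None,
) -> InteractionMatrix:
    """Build the K x K phage-bacteria infection matrix.

    ``matched`` ignores ``density``/``seed`` and returns the identity.  For
    ``random_sparse``, entries are iid Bernoulli(density) and any empty row
    or column is repaired by adding one uniformly chosen entry, so the
    realized density can exceed the nominal one slightly at low density.
    """
    K = space.K
    if mode == "matched":
        return InteractionMatrix(M=np.eye(K, dtype=np.int64), mode="matched")
    if mode != "random_sparse":
        raise ValueError(f"unknown interaction mode {mode!r}")
    if not 0 < density <= 1:
        raise ValueError(f"density must be in (0, 1], got {density}")
    rng = np.random.default_rng(seed)
    M = (rng.random((K, K)) < density).astype(np.int64)
    for i in np.flatnonzero(M.sum(axis=1) == 0):
        M[i, rng.integers(K)] = 1
    for j in np.flatnonzero(M.sum(axis=0) == 0):
        M[rng.integers(K), j] = 1
    return InteractionMatrix(M=M, mode="random_sparse", density=density, seed=seed)
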