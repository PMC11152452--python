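"""Neutral expectation for trans-species polymorphism under a clean split.

Two populations of diploid sizes N1 and N2 separate from an ancestral
population of size Na, t generations ago, with no subsequent migration.  Two
gametes are sampled from each daughter population.  A locus mutating at rate
mu (infinite sites, back-mutation neglected) can then segregate as a shared
(trans-species) polymorphism, as a polymorphism private to one sample, or as
a fixed difference.  Closed forms for the expected number of shared and total
polymorphisms, and their ratio (the trans-polymorphism fraction), are
implemented alongside a Monte-Carlo structured-coalescent simulator that
serves as an independent oracle.

Sampling two gametes per population is an upper bound on sharing: larger
samples extend the time to the MRCA and add private polymorphisms faster
than shared ones.

Conventions: time is continuous; a pair of lineages in a population of
diploid size N coalesces at rate 1/(2N) per generation, so the expected
coalescent tree length of 4 lineages in the ancestral population is
4*Na*(1 + 1/2 + 1/3) = 22*Na/3.  The convenience parameter tau = t/(2N)
expresses the split time in coalescent units for the equal-size case.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CoalescentModel",
    "PolymorphismPartition",
    "expected_shared_polymorphisms",
    "expected_total_polymorphisms",
    "trans_poly_fraction",
    "trans_poly_fraction_refined",
    "simulate_partition",
]


@dataclass(frozen=True)
class CoalescentModel:
    """Parameters of the two-population split model.

    N1, N2, Na : diploid effective sizes (individuals) of the two daughter
    populations and their common ancestor.  t : split time in generations.
    mu : mutation rate per locus per generation (small; back-mutation and
    double hits are neglected).
    """

    N1: float
    N2: float
    Na: float
    t: float
    mu: float

    def __post_init__(self) -> None:
        if not (self.N1 > 0 and self.N2 > 0 and self.Na > 0):
            raise ValueError("population sizes must be positive")
        if self.t < 0:
            raise ValueError("split time t must be non-negative")
        if not (0 <= self.mu < 1):
            raise ValueError("mutation rate mu must lie in [0, 1)")

    @classmethod
    def from_tau(cls, tau: float, Ne: float = 10_000.0, mu: float = 1e-7) -> "CoalescentModel":
        """Equal-size wrapper: tau = t/(2N), so t = 2*Ne*tau."""
        if tau < 0:
            raise ValueError("tau must be non-negative")
        return cls(N1=Ne, N2=Ne, Na=Ne, t=2.0 * Ne * tau, mu=mu)


@dataclass
class PolymorphismPartition:
    """Per-locus classification counts from the Monte-Carlo simulator.

    The five components sum to the number of simulated loci.  A locus is
    monomorphic if no mutation fell on its genealogy; otherwise it is
    classified by a mutation drawn uniformly among its mutations (with the
    small per-locus rates used throughout, multi-class loci are rare).
    """

    shared: int
    private1: int
    private2: int
    fixed_diff: int
    monomorphic: int

    @property
    def n_loci(self) -> int:
        return self.shared + self.private1 + self.private2 + self.fixed_diff + self.monomorphic

    @property
    def n_polymorphic(self) -> int:
        """Loci carrying variation in the combined 4-gamete sample."""
        return self.shared + self.private1 + self.private2 + self.fixed_diff

    @property
    def shared_fraction(self) -> float:
        if self.n_polymorphic == 0:
            return math.nan
        return self.shared / self.n_polymorphic

    def shared_fraction_se(self) -> float:
        """Binomial Monte-Carlo standard error of ``shared_fraction``."""
        m = self.n_polymorphic
        if m == 0:
            return math.nan
        f = self.shared_fraction
        return math.sqrt(max(f * (1.0 - f), 1.0 / m) / m)


# --------------------------------------------------------------- closed forms


def _pair_rate(model: CoalescentModel) -> float:
    # combined within-pair coalescence exponent coefficient: 1/(2N1) + 1/(2N2)
    return (model.N1 + model.N2) / (model.N1 * model.N2) / 2.0


def expected_shared_polymorphisms(model: CoalescentModel) -> float:
    """Expected number of shared (trans-species) polymorphisms per locus.

    Both within-population pairs must reach the ancestral population without
    coalescing (probability exp(-t/(2N1)) * exp(-t/(2N2))); given that, the
    expected length of ancestral-phase branches whose descendants are exactly
    one gamete from each population is (4/3)*Na, hence

        exp(-((N1+N2)/(N1*N2)) * t/2) * (4/3) * mu * Na.
    """
    return math.exp(-_pair_rate(model) * model.t) * (4.0 / 3.0) * model.mu * model.Na


def expected_total_polymorphisms(model: CoalescentModel) -> float:
    """Expected total polymorphisms per locus, ignoring daughter coalescence.

    The 4-lineage ancestral tree has expected length 22*Na/3; the daughter
    phase contributes 4 branches of length t.  Valid when t is small enough
    that coalescence within the daughter populations is negligible:

        (22/3)*mu*Na + 4*t*mu.
    """
    return (22.0 / 3.0) * model.mu * model.Na + 4.0 * model.t * model.mu


def trans_poly_fraction(model: CoalescentModel) -> float:
    """Fraction of polymorphisms shared between the two samples.

    Equals expected_shared/expected_total:

        2 * exp(-((N1+N2)/(N1*N2)) * t/2) / (11 + 6*t/Na)

    which is 2/11 ~ 0.18 at t = 0 (panmixia) and decays to 0 with t.
    """
    return 2.0 * math.exp(-_pair_rate(model) * model.t) / (11.0 + 6.0 * model.t / model.Na)


def _expected_total_refined(model: CoalescentModel) -> float:
    """Expected total tree length x mu, accounting for daughter coalescence.

    Each daughter population contributes expected tree length
    t + 2*Ni*(1 - exp(-t/(2Ni))) (two lineages until their coalescence, one
    thereafter).  The ancestral phase starts with K in {2, 3, 4} lineages,
    where each pair survives independently with probability exp(-t/(2Ni)),
    and a standard coalescent with k lineages has expected length
    4*Na*sum_{i<k} 1/i.
    """
    p1 = math.exp(-model.t / (2.0 * model.N1))
    p2 = math.exp(-model.t / (2.0 * model.N2))
    daughter = (
        model.t + 2.0 * model.N1 * (1.0 - p1) + model.t + 2.0 * model.N2 * (1.0 - p2)
    )
    len4 = 4.0 * model.Na * (1.0 + 0.5 + 1.0 / 3.0)
    len3 = 4.0 * model.Na * 1.5
    len2 = 4.0 * model.Na
    ancestral = (
        p1 * p2 * len4
        + (p1 * (1 - p2) + p2 * (1 - p1)) * len3
        + (1 - p1) * (1 - p2) * len2
    )
    return model.mu * (daughter + ancestral)


def trans_poly_fraction_refined(model: CoalescentModel) -> float:
    """Shared fraction with daughter-population coalescence in the denominator.

    The numerator is the same as in :func:`trans_poly_fraction` (a shared
    polymorphism is impossible once either within-population pair has
    coalesced); the total-polymorphism denominator shrinks because coalesced
    daughter pairs stop accumulating tree length.  Hence refined >= plain for
    t > 0, and both reduce to 2/11 at t = 0.
    """
    return expected_shared_polymorphisms(model) / _expected_total_refined(model)


# ------------------------------------------------------------------ simulator

# lineage bitmasks: a=1, b=2 (population 1); c=4, d=8 (population 2)
_MIXED_PAIRS = (5, 6, 9, 10)  # {a,c} {b,c} {a,d} {b,d}
_PRIVATE1 = (1, 2, 13, 14)  # {a} {b} {a,c,d} {b,c,d}
_PRIVATE2 = (4, 8, 7, 11)  # {c} {d} {a,b,c} {a,b,d}
_FIXED = (3, 12)  # {a,b} {c,d}


def simulate_partition(
    model: CoalescentModel, n_loci: int, seed: int
) -> PolymorphismPartition:
    """Monte-Carlo oracle: simulate 2+2 gametes at ``n_loci`` independent loci.

    Continuous-time structured coalescent: during the daughter phase each
    within-population pair coalesces at rate 1/(2Ni); surviving lineages enter
    the ancestral population at time t, where every pair coalesces at rate
    1/(2Na).  Mutations are Poisson with mean mu x branch length under
    infinite sites, classified by the set of sampled gametes they subtend.
    Fully vectorized over loci; deterministic given ``seed``.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    rng = np.random.default_rng(seed)
    n = int(n_loci)
    t = model.t

    # branch-length ledger per descendant-set bitmask (columns 1..14 used)
    L = np.zeros((n, 16))

    T1 = rng.exponential(2.0 * model.N1, size=n)
    T2 = rng.exponential(2.0 * model.N2, size=n)
    d1 = np.minimum(T1, t)
    d2 = np.minimum(T2, t)
    L[:, 1] += d1
    L[:, 2] += d1
    L[:, 4] += d2
    L[:, 8] += d2
    L[:, 3] += t - d1  # merged {a,b} branch for the rest of the daughter phase
    L[:, 12] += t - d2
    s1 = T1 >= t
    s2 = T2 >= t

    rows = np.arange(n)
    Na2 = 2.0 * model.Na

    # --- K = 4: both pairs survive -----------------------------------------
    i4 = np.flatnonzero(s1 & s2)
    if i4.size:
        m = i4.size
        w4 = rng.exponential(Na2 / 6.0, size=m)
        for col in (1, 2, 4, 8):
            L[i4, col] += w4
        # first merge: uniform over the 6 unordered pairs
        pair_mask = np.array([3, 12, 5, 9, 6, 10])
        rem_a = np.array([4, 1, 2, 2, 1, 1])
        rem_b = np.array([8, 2, 8, 4, 8, 4])
        u = rng.integers(0, 6, size=m)
        merged = pair_mask[u]
        ra = rem_a[u]
        rb = rem_b[u]
        w3 = rng.exponential(Na2 / 3.0, size=m)
        L[i4, merged] += w3
        L[i4, ra] += w3
        L[i4, rb] += w3
        # second merge: 3 equally likely pairs among {merged, ra, rb}
        v = rng.integers(0, 3, size=m)
        new = np.where(v == 0, merged | ra, np.where(v == 1, merged | rb, ra | rb))
        other = np.where(v == 0, rb, np.where(v == 1, ra, merged))
        w2 = rng.exponential(Na2, size=m)
        L[i4, new] += w2
        L[i4, other] += w2

    # --- K = 3: exactly one pair survives ----------------------------------
    for idx3, singles, merged_mask in (
        (np.flatnonzero(s1 & ~s2), (1, 2), 12),
        (np.flatnonzero(~s1 & s2), (4, 8), 3),
    ):
        if not idx3.size:
            continue
        m = idx3.size
        w3 = rng.exponential(Na2 / 3.0, size=m)
        L[idx3, singles[0]] += w3
        L[idx3, singles[1]] += w3
        L[idx3, merged_mask] += w3
        v = rng.integers(0, 3, size=m)
        x, y = singles
        new = np.where(v == 0, x | y, np.where(v == 1, x | merged_mask, y | merged_mask))
        other = np.where(v == 0, merged_mask, np.where(v == 1, y, x))
        w2 = rng.exponential(Na2, size=m)
        L[idx3, new] += w2
        L[idx3, other] += w2

    # --- K = 2: both pairs coalesced in the daughter phase ------------------
    i2 = np.flatnonzero(~s1 & ~s2)
    if i2.size:
        w2 = rng.exponential(Na2, size=i2.size)
        L[i2, 3] += w2
        L[i2, 12] += w2

    # mutations per class (Poisson on summed class lengths)
    class_len = np.stack(
        [
            L[:, list(_MIXED_PAIRS)].sum(axis=1),
            L[:, list(_PRIVATE1)].sum(axis=1),
            L[:, list(_PRIVATE2)].sum(axis=1),
            L[:, list(_FIXED)].sum(axis=1),
        ],
        axis=1,
    )
    counts = rng.poisson(model.mu * class_len) if model.mu > 0 else np.zeros_like(class_len, dtype=np.int64)
    total = counts.sum(axis=1)
    mono = int((total == 0).sum())

    poly = total > 0
    if poly.any():
        # assign each polymorphic locus one class, proportional to its counts
        cum = np.cumsum(counts[poly], axis=1)
        u = rng.random(cum.shape[0]) * total[poly]
        cls = (u[:, None] >= cum).sum(axis=1)
        tallies = np.bincount(cls, minlength=4)
    else:
        tallies = np.zeros(4, dtype=np.int64)

    return PolymorphismPartition(
        shared=int(tallies[0]),
        private1=int(tallies[1]),
        private2=int(tallies[2]),
        fixed_diff=int(tallies[3]),
        monomorphic=mono,
    )
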