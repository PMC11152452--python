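"""Synthetic genotype data with the structure the inversion pipeline assumes.

The generator draws unlinked loci from a continuous-time coalescent on a
population tree (times in coalescent units of 2N generations, one pairwise
coalescence per unit time, infinite-sites mutations at theta/2 per site per
unit time).  An inverted region is simulated as two arrangement haplotype
pools — panmictic across populations, reflecting suppressed recombination in
heterokaryotypes — that split ``tau_inv`` ago, with the derived pool founded
from a single ancestral haplotype (the bottleneck that makes polarization
learnable) and optional low symmetric exchange between pools standing in for
gene conversion and double crossovers.  Each individual draws two
arrangement haplotypes per its population's derived-arrangement frequency
(Hardy-Weinberg within population).  An outgroup lineage attaches above the
ingroup root.  Environmental clines tie per-population precipitation to the
derived-arrangement frequency.  Everything is deterministic given the
scenario seed, and truth tables allow exact scoring of every pipeline stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeTable

__all__ = [
    "InversionSpec",
    "EnvClineSpec",
    "RadiationScenario",
    "SimulationResult",
    "simulate_radiation",
    "simulate_env_clines",
    "default_scenario",
    "two_population_scenario",
]


# ----------------------------------------------------------------- scenario -


@dataclass
class InversionSpec:
    """Inverted-region parameters.

    span: (start, end) in bp on the simulated chromosome.
    tau_inv: arrangement divergence in coalescent units; must exceed every
    species split time for a trans-species scenario.
    derived_freq: per-population derived-arrangement frequency.
    n_loci: unlinked loci placed inside the span.
    leak_rate: symmetric per-lineage exchange rate between arrangement pools
    (gene-conversion stand-in).
    """

    span: tuple[int, int]
    tau_inv: float
    derived_freq: dict[str, float]
    n_loci: int = 400
    leak_rate: float = 0.0


@dataclass
class EnvClineSpec:
    """Environmental cline: precipitation tracks derived-arrangement frequency."""

    precip_base: float = 1200.0
    precip_effect: float = 600.0  # mm per unit derived frequency
    precip_noise: float = 10.0
    temp_mean: float = 26.0
    temp_noise: float = 1.0


@dataclass
class RadiationScenario:
    """Full specification of one synthetic radiation.

    ``tree`` is a nested tuple: a leaf is a population name, an internal node
    is ``(split_time, child, child, ...)`` with times in coalescent units
    increasing toward the root.
    """

    tree: tuple
    seed: int
    samples_per_population: int = 10
    theta: float = 0.005  # per site (4*N*mu)
    n_loci: int = 2000
    locus_length: int = 100
    chrom: str = "chr1"
    chrom_length: int = 10_000_000
    inversion: InversionSpec | None = None
    outgroup_tau: float = 4.0
    n_outgroup: int = 4
    missing_rate: float = 0.02
    env: EnvClineSpec = field(default_factory=EnvClineSpec)
    z_linked: bool = False

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        self.populations = _leaves(self.tree)
        if len(set(self.populations)) != len(self.populations):
            raise ValueError("duplicate population names in tree")
        root_time = _max_time(self.tree)
        if self.outgroup_tau <= root_time:
            raise ValueError("outgroup split must predate the ingroup root")
        if self.inversion is not None:
            inv = self.inversion
            if set(inv.derived_freq) != set(self.populations):
                raise ValueError("derived_freq must cover exactly the tree's populations")
            if any(not 0 <= f <= 1 for f in inv.derived_freq.values()):
                raise ValueError("derived-arrangement frequencies must lie in [0, 1]")
            if inv.tau_inv <= root_time:
                raise ValueError("tau_inv must exceed the deepest species split")
            if not 0 <= inv.span[0] < inv.span[1] <= self.chrom_length:
                raise ValueError("inversion span outside the chromosome")


def _leaves(node) -> list[str]:
    if isinstance(node, str):
        return [node]
    return [leaf for child in node[1:] for leaf in _leaves(child)]


def _max_time(node) -> float:
    if isinstance(node, str):
        return 0.0
    return max(float(node[0]), *(_max_time(c) for c in node[1:]))


def default_scenario(seed: int, **overrides) -> RadiationScenario:
    """Standard trans-species scenario: 6 populations in two radiations.

    Split times 0.1/0.25 within radiations and 0.5 at the root; arrangement
    divergence tau_inv = 1, exceeding every speciation event.  The
    derived-arrangement frequency declines monotonically along the sampling
    arc (P1 fixed derived .. P6 fixed ancestral) while the tree interleaves
    the geography, so close relatives can be fixed for alternative
    arrangements (the configuration that gives the cleanest F_ST scans) and
    collinear differentiation is decoupled from the cline.  The outgroup
    sits at 2 coalescent units — deep enough to predate the arrangement
    split, shallow enough that incomplete lineage sorting still leaves
    measurable shared polymorphism (the generator has no homoplasy to supply
    sharing the way recurrent mutation does in real data).
    """
    tree = (
        0.5,
        (0.25, (0.1, "P1", "P6"), "P3"),
        (0.25, (0.1, "P2", "P5"), "P4"),
    )
    inv = InversionSpec(
        span=(3_000_000, 5_000_000),
        tau_inv=1.0,
        derived_freq={
            "P1": 1.0,
            "P2": 0.8,
            "P3": 0.6,
            "P4": 0.4,
            "P5": 0.2,
            "P6": 0.0,
        },
    )
    kw = dict(tree=tree, seed=seed, inversion=inv, outgroup_tau=2.0)
    kw.update(overrides)
    return RadiationScenario(**kw)


def two_population_scenario(
    seed: int, tau: float = 0.5, n_loci: int = 2000, **overrides
) -> RadiationScenario:
    """Minimal two-population scenario for estimator-recovery checks."""
    kw = dict(
        tree=(tau, "X", "Y"),
        seed=seed,
        n_loci=n_loci,
        inversion=None,
        outgroup_tau=max(4.0, 4 * tau),
    )
    kw.update(overrides)
    return RadiationScenario(**kw)


# ------------------------------------------------------------------- result -


@dataclass
class SimulationResult:
    genotypes: GenotypeTable  # ingroup + outgroup rows
    true_karyotypes: pd.Series  # AA/AD/DD per ingroup sample (empty if no inversion)
    true_polarity: str  # "pool1_ancestral" fixed by construction
    true_span: tuple[int, int] | None
    split_times: dict[tuple[str, str], float]
    ancestral_state: np.ndarray  # per site: 0 (REF is ancestral by construction)
    inversion_site_mask: np.ndarray
    coordinates: pd.DataFrame  # per population: latitude, longitude
    environment: pd.DataFrame  # per population: precipitation, temperature

    @property
    def ingroup(self) -> GenotypeTable:
        ids = self.genotypes.samples.index[
            self.genotypes.samples["population"] != "outgroup"
        ]
        return self.genotypes.take_samples(ids)

    @property
    def outgroup(self) -> GenotypeTable:
        ids = self.genotypes.samples.index[
            self.genotypes.samples["population"] == "outgroup"
        ]
        return self.genotypes.take_samples(ids)


# --------------------------------------------------------------- genealogy --


class _Lineage:
    __slots__ = ("members", "birth")

    def __init__(self, members: list[int], birth: float):
        self.members = members
        self.birth = birth


def _coalesce(lineages, t0, t_end, rng, branches):
    """Standard coalescent among ``lineages`` from t0 until t_end (or MRCA)."""
    t = t0
    while len(lineages) > 1:
        k = len(lineages)
        w = rng.exponential(2.0 / (k * (k - 1)))
        if t + w > t_end:
            break
        t += w
        i, j = rng.integers(0, k), rng.integers(0, k - 1)
        if j >= i:
            j += 1
        a, b = lineages[i], lineages[j]
        branches.append((a.members, t - a.birth))
        branches.append((b.members, t - b.birth))
        merged = _Lineage(a.members + b.members, t)
        lineages[min(i, j)] = merged
        lineages.pop(max(i, j))
    return t


def _tree_events(node, counter=None):
    """Post-order list of (time, child_keys, parent_key); leaves keyed by name."""
    events = []

    def walk(nd):
        if isinstance(nd, str):
            return nd
        keys = [walk(c) for c in nd[1:]]
        key = ("node",) + tuple(sorted(map(str, keys)))
        events.append((float(nd[0]), keys, key))
        return key

    root = walk(node)
    events.sort(key=lambda e: e[0])
    return events, root


def _simulate_tree_locus(
    scenario: RadiationScenario,
    pop_chroms: dict[str, list[int]],
    outgroup_chroms: list[int],
    rng,
) -> list[tuple[list[int], float]]:
    """One collinear locus: genealogy branches (members, length) on the tree."""
    branches: list[tuple[list[int], float]] = []
    groups = {
        pop: [_Lineage([c], 0.0) for c in chroms] for pop, chroms in pop_chroms.items()
    }
    events, root = _tree_events(scenario.tree)
    group_time = {pop: 0.0 for pop in groups}
    for time, child_keys, parent_key in events:
        merged = []
        for key in child_keys:
            lin = groups.pop(key)
            _coalesce(lin, group_time.pop(key), time, rng, branches)
            # surviving lineages enter the parent unchanged
            merged.extend(lin)
        groups[parent_key] = merged
        group_time[parent_key] = time
    root_time = _max_time(scenario.tree)
    ingroup = groups.pop(root, None)
    if ingroup is None:  # single-population tree
        (ingroup,) = groups.values()
        groups.clear()
    _coalesce(ingroup, root_time, scenario.outgroup_tau, rng, branches)
    out = [_Lineage([c], 0.0) for c in outgroup_chroms]
    _coalesce(out, 0.0, scenario.outgroup_tau, rng, branches)
    final = ingroup + out
    _coalesce(final, scenario.outgroup_tau, math.inf, rng, branches)
    return branches


def _simulate_pool_locus(
    scenario: RadiationScenario,
    pool1: list[int],
    pool2: list[int],
    outgroup_chroms: list[int],
    rng,
) -> list[tuple[list[int], float]]:
    """One inverted-region locus: two arrangement pools, derived bottleneck."""
    inv = scenario.inversion
    branches: list[tuple[list[int], float]] = []
    l1 = [_Lineage([c], 0.0) for c in pool1]
    l2 = [_Lineage([c], 0.0) for c in pool2]
    t = 0.0
    leak = inv.leak_rate
    # two-deme structured coalescent until tau_inv
    while t < inv.tau_inv and (len(l1) + len(l2)) > 1:
        k1, k2 = len(l1), len(l2)
        c1 = k1 * (k1 - 1) / 2.0
        c2 = k2 * (k2 - 1) / 2.0
        mig = leak * (k1 + k2)
        total = c1 + c2 + mig
        if total == 0:
            break
        w = rng.exponential(1.0 / total)
        if t + w > inv.tau_inv:
            break
        t += w
        u = rng.random() * total
        if u < c1 or u < c1 + c2:
            pool = l1 if u < c1 else l2
            k = len(pool)
            i, j = rng.integers(0, k), rng.integers(0, k - 1)
            if j >= i:
                j += 1
            a, b = pool[i], pool[j]
            branches.append((a.members, t - a.birth))
            branches.append((b.members, t - b.birth))
            pool[min(i, j)] = _Lineage(a.members + b.members, t)
            pool.pop(max(i, j))
        else:
            src, dst = (l1, l2) if rng.random() < len(l1) / (len(l1) + len(l2)) else (l2, l1)
            i = rng.integers(0, len(src))
            dst.append(src.pop(i))
    # derived-pool bottleneck: star coalescence onto the single founder
    if len(l2) > 1:
        members: list[int] = []
        for lin in l2:
            branches.append((lin.members, inv.tau_inv - lin.birth))
            members.extend(lin.members)
        l2 = [_Lineage(members, inv.tau_inv)]
    ancestral = l1 + l2
    _coalesce(ancestral, inv.tau_inv, scenario.outgroup_tau, rng, branches)
    out = [_Lineage([c], 0.0) for c in outgroup_chroms]
    _coalesce(out, 0.0, scenario.outgroup_tau, rng, branches)
    _coalesce(ancestral + out, scenario.outgroup_tau, math.inf, rng, branches)
    return branches


# ---------------------------------------------------------------- mutations -


def _mutate_locus(branches, theta_locus, locus_start, locus_length, n_chrom_slots, rng):
    """Drop infinite-sites mutations on a genealogy; returns (positions, columns)."""
    carriers = []
    for members, length in branches:
        n_mut = rng.poisson(0.5 * theta_locus * length)
        carriers.extend([members] * n_mut)
    n_sites = min(len(carriers), locus_length)
    if n_sites == 0:
        return np.empty(0, dtype=np.int64), np.empty((n_chrom_slots, 0), dtype=np.int8)
    offsets = np.sort(rng.choice(locus_length, size=n_sites, replace=False))
    cols = np.zeros((n_chrom_slots, n_sites), dtype=np.int8)
    for s, members in enumerate(carriers[:n_sites]):
        cols[members, s] = 1
    return locus_start + offsets, cols


# -------------------------------------------------------------------- main --


def simulate_radiation(scenario: RadiationScenario) -> SimulationResult:
    """Generate genotypes, metadata and truth tables for one scenario."""
    rng = np.random.default_rng(scenario.seed)
    pops = scenario.populations
    n_dip = scenario.samples_per_population

    sample_rows = []
    for p, pop in enumerate(pops):
        for i in range(n_dip):
            sex = "M" if i % 2 == 0 else "F"
            sample_rows.append((f"{pop}_{i:02d}", pop, pop.split("_")[0], sex))
    for i in range(scenario.n_outgroup):
        sample_rows.append((f"OUT_{i:02d}", "outgroup", "outgroup", "M" if i % 2 == 0 else "F"))
    samples = pd.DataFrame(
        sample_rows, columns=["sample", "population", "species", "sex"]
    ).set_index("sample")

    n_samples = len(samples)
    # chromosome slots: diploid 2 per sample; z-linked females use one slot
    hemizygous = np.zeros(n_samples, dtype=bool)
    if scenario.z_linked:
        hemizygous = (samples["sex"] == "F").to_numpy()
    slot_of: list[list[int]] = []
    next_slot = 0
    for s in range(n_samples):
        k = 1 if hemizygous[s] else 2
        slot_of.append(list(range(next_slot, next_slot + k)))
        next_slot += k
    n_slots = next_slot

    pop_chroms = {pop: [] for pop in pops}
    outgroup_chroms: list[int] = []
    for s, (sid, row) in enumerate(samples.iterrows()):
        target = outgroup_chroms if row["population"] == "outgroup" else pop_chroms[row["population"]]
        target.extend(slot_of[s])

    theta_locus = scenario.theta * scenario.locus_length

    # ---- collinear loci: placed outside the inversion span ----------------
    inv = scenario.inversion
    if inv is not None:
        lo, hi = inv.span
        free = [(0, lo), (hi, scenario.chrom_length)]
    else:
        free = [(0, scenario.chrom_length)]
    free_len = sum(b - a for a, b in free)
    spacing = free_len / scenario.n_loci
    starts = []
    offset = 0.0
    for a, b in free:
        while offset + a < b - scenario.locus_length:
            starts.append(int(a + offset))
            offset += spacing
        offset -= b - a
    starts = starts[: scenario.n_loci]

    all_pos: list[np.ndarray] = []
    all_cols: list[np.ndarray] = []
    for locus_start in starts:
        branches = _simulate_tree_locus(scenario, pop_chroms, outgroup_chroms, rng)
        pos, cols = _mutate_locus(
            branches, theta_locus, locus_start, scenario.locus_length, n_slots, rng
        )
        all_pos.append(pos)
        all_cols.append(cols)

    # ---- inverted region --------------------------------------------------
    karyo = pd.Series(dtype=object)
    inv_positions_start = None
    if inv is not None:
        arrangement = np.zeros(n_slots, dtype=np.int8)  # 0 ancestral, 1 derived
        karyo_vals = {}
        for s, (sid, row) in enumerate(samples.iterrows()):
            pop = row["population"]
            if pop == "outgroup":
                continue  # outgroup carries the ancestral arrangement
            f = inv.derived_freq[pop]
            draws = rng.random(len(slot_of[s])) < f
            for slot, d in zip(slot_of[s], draws):
                arrangement[slot] = int(d)
            n_derived = int(draws.sum()) * (2 if hemizygous[s] else 1)
            karyo_vals[sid] = ("AA", "AD", "DD")[min(n_derived, 2)]
        karyo = pd.Series(karyo_vals)

        pool1 = [c for c in range(n_slots) if arrangement[c] == 0]
        pool2 = [c for c in range(n_slots) if arrangement[c] == 1]
        # outgroup slots belong to pool1 by construction; exclude from pool draws
        out_set = set(outgroup_chroms)
        pool1_in = [c for c in pool1 if c not in out_set]
        inv_lo, inv_hi = inv.span
        inv_spacing = (inv_hi - inv_lo) / inv.n_loci
        inv_positions_start = len(all_pos)
        for k in range(inv.n_loci):
            locus_start = int(inv_lo + k * inv_spacing)
            branches = _simulate_pool_locus(
                scenario, list(pool1_in), list(pool2), outgroup_chroms, rng
            )
            pos, cols = _mutate_locus(
                branches, theta_locus, locus_start, scenario.locus_length, n_slots, rng
            )
            all_pos.append(pos)
            all_cols.append(cols)

    # ---- assemble dosage matrix ------------------------------------------
    order = np.argsort([p[0] if len(p) else -1 for p in all_pos], kind="stable")
    pos = np.concatenate([all_pos[i] for i in order]) if all_pos else np.empty(0, dtype=np.int64)
    hap = (
        np.concatenate([all_cols[i] for i in order], axis=1)
        if all_pos
        else np.empty((n_slots, 0), dtype=np.int8)
    )
    # collapse duplicate positions are impossible (loci don't overlap)
    dosages = np.zeros((n_samples, hap.shape[1]), dtype=np.int8)
    for s in range(n_samples):
        slots = slot_of[s]
        if len(slots) == 2:
            dosages[s] = hap[slots[0]] + hap[slots[1]]
        else:
            dosages[s] = 2 * hap[slots[0]]

    if scenario.missing_rate > 0 and dosages.size:
        mask = rng.random(dosages.shape) < scenario.missing_rate
        dosages[mask] = MISSING

    chrom = np.array([scenario.chrom] * len(pos), dtype=object)
    table = GenotypeTable(dosages, chrom, pos, samples)

    inv_mask = np.zeros(len(pos), dtype=bool)
    if inv is not None:
        inv_mask = (pos >= inv.span[0]) & (pos < inv.span[1])

    # ---- split-time truth table -------------------------------------------
    split = {}

    def fill_splits(node):
        if isinstance(node, str):
            return [node]
        time = float(node[0])
        groups = [fill_splits(c) for c in node[1:]]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for x in groups[gi]:
                    for y in groups[gj]:
                        split[(x, y)] = split[(y, x)] = time
        return [x for g in groups for x in g]

    fill_splits(scenario.tree)

    coords, env = simulate_env_clines(scenario)

    return SimulationResult(
        genotypes=table,
        true_karyotypes=karyo,
        true_polarity="pool1_ancestral",
        true_span=inv.span if inv else None,
        split_times=split,
        ancestral_state=np.zeros(len(pos), dtype=np.int8),
        inversion_site_mask=inv_mask,
        coordinates=coords,
        environment=env,
    )


def simulate_env_clines(
    scenario: RadiationScenario,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Coordinates on an arc plus an environment table tied to the cline.

    Precipitation is a linear function of the population's derived-arrangement
    frequency plus Gaussian noise; temperature is independent noise around its
    mean.  Deterministic given the scenario seed (independent substream, so
    the tables do not change with genotype-simulation internals).
    """
    rng = np.random.default_rng((scenario.seed, 7))
    pops = scenario.populations
    env_spec = scenario.env
    lat = [-8.0 - 0.5 * (i % 3) for i in range(len(pops))]
    lon = [112.0 + 5.0 * i for i in range(len(pops))]
    coords = pd.DataFrame({"latitude": lat, "longitude": lon}, index=pops)

    if scenario.inversion is not None:
        freq = np.array([scenario.inversion.derived_freq[p] for p in pops])
    else:
        freq = np.zeros(len(pops))
    precip = (
        env_spec.precip_base
        + env_spec.precip_effect * freq
        + env_spec.precip_noise * rng.standard_normal(len(pops))
    )
    temp = env_spec.temp_mean + env_spec.temp_noise * rng.standard_normal(len(pops))
    env = pd.DataFrame({"precipitation": precip, "temperature": temp}, index=pops)
    coords.index.name = env.index.name = "population"
    return coords, env
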