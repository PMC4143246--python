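"""Synthetic SSR genotype datasets with full ground truth.

Emulates the data-generating process the donor analysis assumes: several
highly selfing diploid species, each an independent Wright-Fisher population
with stepwise microsatellite mutation (steps of one repeat unit, reflecting
at the locus allele-pool bounds), plus one amphidiploid taxon formed by a
single hybridisation between two of the diploids followed by genome
doubling.  Each amphidiploid individual carries two disomically inherited
sub-genomes that drift and mutate independently after the origin, with an
optionally faster mutation rate on sub-genome B.

Every emitted allele is traceable: the truth record stores the sub-genome of
each tetraploid product and the realised allele frequencies of every taxon,
so partition accuracy and donor calls can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .genotype import AccessionRecord, AlleleCall, GenotypeTable, MarkerDef

_MOTIF_BY_UNIT = {2: "AG", 3: "AAG", 4: "AAAG"}

#: pool half-width in repeat units; pools span center +/- POOL_HALF units
POOL_HALF = 2

#: center-to-center slot spacings (repeat units): overlapping-ladder default,
#: disjoint regime for clean partition benchmarks
_SLOT_STEP_DEFAULT = 2
_SLOT_STEP_DISJOINT = 10


@dataclass(frozen=True)
class TaxonConfig:
    name: str
    n_accessions: int
    ploidy: int = 2


@dataclass
class SimulationConfig:
    """Study design for one synthetic dataset.

    Defaults reproduce the shape of the donor study this package targets:
    38 loci, six diploid taxa (13 + 47 + 49 + 13 + 42 + 46 accessions) and
    one amphidiploid species sampled as a cultivated (7) and a wild (51)
    variety, with sub-genome A donated by ``donor_a`` and B by ``donor_b``.
    """

    n_loci: int = 38
    diploid_taxa: tuple[TaxonConfig, ...] = (
        TaxonConfig("exilis", 13),
        TaxonConfig("hirtella", 47),
        TaxonConfig("minima", 49),
        TaxonConfig("sublobata", 13),
        TaxonConfig("tenuicaulis", 42),
        TaxonConfig("trinervia", 46),
    )
    tetraploid_taxa: tuple[TaxonConfig, ...] = (
        TaxonConfig("reflexo-glabra", 7, ploidy=4),
        TaxonConfig("reflexo-wild", 51, ploidy=4),
    )
    donor_a: str = "trinervia"
    donor_b: str = "hirtella"
    n_founders: int = 1
    selfing_rate: float = 0.98
    mutation_rate: float = 1e-3
    mutation_rate_a: float = 5e-4
    mutation_rate_b: float = 2e-3
    n_generations: int = 30
    post_origin_generations: int = 40
    variety_generations: int = 15
    population_size: int = 50
    pool_n_alleles: int = 5
    dirichlet_concentration: float = 0.8
    unit_probs: Mapping[int, float] = field(
        default_factory=lambda: {2: 0.082, 3: 0.835, 4: 0.083}
    )
    disjoint_pools: bool = False
    founders_homozygous: bool = False

    def validate(self) -> None:
        problems = []
        names = [t.name for t in self.diploid_taxa + self.tetraploid_taxa]
        if len(set(names)) != len(names):
            problems.append("taxa: duplicate taxon names")
        diploid_names = {t.name for t in self.diploid_taxa}
        for d, lab in ((self.donor_a, "donor_a"), (self.donor_b, "donor_b")):
            if d not in diploid_names:
                problems.append(f"{lab}: {d!r} is not a diploid taxon")
        if self.donor_a == self.donor_b:
            problems.append("donor_a and donor_b must be distinct taxa")
        if not 0.0 <= self.selfing_rate <= 1.0:
            problems.append("selfing_rate: must be in [0, 1]")
        for lab, v in (
            ("mutation_rate", self.mutation_rate),
            ("mutation_rate_a", self.mutation_rate_a),
            ("mutation_rate_b", self.mutation_rate_b),
        ):
            if not 0.0 <= v <= 1.0:
                problems.append(f"{lab}: must be in [0, 1]")
        if self.n_loci < 1:
            problems.append("n_loci: must be >= 1")
        if self.pool_n_alleles < 1:
            problems.append("pool_n_alleles: must be >= 1")
        if self.n_founders < 1:
            problems.append("n_founders: must be >= 1")
        if any(t.ploidy != 2 for t in self.diploid_taxa):
            problems.append("diploid_taxa: ploidy must be 2")
        if any(t.ploidy != 4 for t in self.tetraploid_taxa):
            problems.append("tetraploid_taxa: ploidy must be 4")
        if problems:
            raise ValueError("invalid simulation config: " + "; ".join(problems))


@dataclass
class LocusLayout:
    """Per-locus geometry: motif unit and per-taxon allele-pool centers."""

    marker_id: str
    unit: int
    base_size: int
    centers: dict[str, int]  # diploid taxon -> pool center (bp)

    def bounds(self, taxon: str) -> tuple[int, int]:
        c = self.centers[taxon]
        return c - POOL_HALF * self.unit, c + POOL_HALF * self.unit

    def pool_sizes(self, taxon: str) -> tuple[int, ...]:
        c = self.centers[taxon]
        return tuple(c + self.unit * j for j in range(-POOL_HALF, POOL_HALF + 1))


@dataclass
class TruthRecord:
    """Ground truth accompanying a simulated table."""

    donor_a: str
    donor_b: str
    #: (accession_id, marker_id) -> (sub-genome A size, sub-genome B size)
    subgenomes: dict[tuple[str, str], tuple[int, int]]
    #: (taxon, marker_id) -> realised allele frequencies in the final population
    taxon_freqs: dict[tuple[str, str], dict[int, float]]
    loci: list[LocusLayout]


@dataclass
class SimulatedDataset:
    table: GenotypeTable
    truth: TruthRecord
    config: SimulationConfig
    seed: int


# ---------------------------------------------------------------------------
# Wright-Fisher machinery (vectorised over loci)
# ---------------------------------------------------------------------------


def _mutate(
    G: np.ndarray,
    mu: float,
    unit: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """In-place stepwise mutation: +/- one repeat unit, reflecting at the
    pool bounds.  ``unit``, ``lo``, ``hi`` have shape (L,); G is (N, L, 2)."""
    if mu <= 0:
        return
    mask = rng.random(G.shape) < mu
    if not mask.any():
        return
    steps = rng.choice(np.array([-1, 1]), size=int(mask.sum()))
    li = np.broadcast_to(unit[None, :, None], G.shape)[mask]
    lo_b = np.broadcast_to(lo[None, :, None], G.shape)[mask]
    hi_b = np.broadcast_to(hi[None, :, None], G.shape)[mask]
    vals = G[mask] + steps * li
    vals = np.where(vals > hi_b, 2 * hi_b - vals, vals)
    vals = np.where(vals < lo_b, 2 * lo_b - vals, vals)
    G[mask] = vals


def _next_generation_parents(
    n: int, selfing: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    p1 = rng.integers(n, size=n)
    outcross = rng.random(n) >= selfing
    p2 = np.where(outcross, rng.integers(n, size=n), p1)
    return p1, p2


def _gametes(
    G: np.ndarray, parents: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One random allele per locus from each parent; (N, L) sizes."""
    n, L, _ = G.shape
    pick = rng.integers(2, size=(len(parents), L))
    return G[parents[:, None], np.arange(L)[None, :], pick]


def _evolve_diploid(
    G: np.ndarray,
    n_generations: int,
    selfing: float,
    mu: float,
    unit: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    for _ in range(n_generations):
        n = G.shape[0]
        p1, p2 = _next_generation_parents(n, selfing, rng)
        G = np.stack([_gametes(G, p1, rng), _gametes(G, p2, rng)], axis=2)
        _mutate(G, mu, unit, lo, hi, rng)
    return G


def _evolve_tetraploid(
    GA: np.ndarray,
    GB: np.ndarray,
    n_generations: int,
    selfing: float,
    mu_a: float,
    mu_b: float,
    unit: np.ndarray,
    lo_a: np.ndarray,
    hi_a: np.ndarray,
    lo_b: np.ndarray,
    hi_b: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Disomic inheritance: the two sub-genomes segregate independently but
    within the same individuals (shared parent choices)."""
    for _ in range(n_generations):
        n = GA.shape[0]
        p1, p2 = _next_generation_parents(n, selfing, rng)
        GA = np.stack([_gametes(GA, p1, rng), _gametes(GA, p2, rng)], axis=2)
        GB = np.stack([_gametes(GB, p1, rng), _gametes(GB, p2, rng)], axis=2)
        _mutate(GA, mu_a, unit, lo_a, hi_a, rng)
        _mutate(GB, mu_b, unit, lo_b, hi_b, rng)
    return GA, GB


def _resize(G: np.ndarray, n_new: int, rng: np.random.Generator) -> np.ndarray:
    """Found a population of a different census size from an existing one."""
    n = G.shape[0]
    if n_new <= n:
        idx = rng.choice(n, size=n_new, replace=False)
    else:
        idx = rng.integers(n, size=n_new)
    return G[idx]


# ---------------------------------------------------------------------------
# Layout and per-taxon simulation
# ---------------------------------------------------------------------------


def _make_layout(config: SimulationConfig, rng: np.random.Generator) -> list[LocusLayout]:
    units = sorted(config.unit_probs)
    probs = np.array([config.unit_probs[u] for u in units], dtype=float)
    probs = probs / probs.sum()
    step = _SLOT_STEP_DISJOINT if config.disjoint_pools else _SLOT_STEP_DEFAULT
    diploid_names = [t.name for t in config.diploid_taxa]
    loci = []
    for l in range(config.n_loci):
        unit = int(rng.choice(units, p=probs))
        base = int(rng.integers(100, 281))
        slots = step * rng.permutation(len(diploid_names))
        centers = {
            name: base + unit * int(s) for name, s in zip(diploid_names, slots)
        }
        loci.append(LocusLayout(
            marker_id=f"L{l + 1:02d}", unit=unit, base_size=base, centers=centers,
        ))
    return loci


def _founders(
    taxon: str,
    n: int,
    loci: Sequence[LocusLayout],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Founding genotypes (n, L, 2) drawn from Dirichlet-weighted pools."""
    L = len(loci)
    k = config.pool_n_alleles
    G = np.empty((n, L, 2), dtype=np.int64)
    for li, locus in enumerate(loci):
        pool = np.array(locus.pool_sizes(taxon)[:k])
        conc = np.full(len(pool), config.dirichlet_concentration)
        freqs = rng.dirichlet(conc)
        if config.founders_homozygous:
            one = pool[rng.choice(len(pool), size=n, p=freqs)]
            G[:, li, 0] = one
            G[:, li, 1] = one
        else:
            G[:, li, :] = pool[rng.choice(len(pool), size=(n, 2), p=freqs)]
    return G


def _taxon_arrays(
    taxon: str, loci: Sequence[LocusLayout]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    unit = np.array([l.unit for l in loci])
    lo = np.array([l.bounds(taxon)[0] for l in loci])
    hi = np.array([l.bounds(taxon)[1] for l in loci])
    return unit, lo, hi


def simulate_diploid_population(
    config: SimulationConfig,
    taxon: TaxonConfig,
    loci: Sequence[LocusLayout],
    rng: np.random.Generator,
) -> np.ndarray:
    """Final-generation census population (population_size, L, 2) of one
    diploid taxon after ``n_generations`` of selfing Wright-Fisher drift
    with stepwise mutation."""
    n_pop = max(config.population_size, taxon.n_accessions)
    unit, lo, hi = _taxon_arrays(taxon.name, loci)
    G = _founders(taxon.name, n_pop, loci, config, rng)
    return _evolve_diploid(
        G, config.n_generations, config.selfing_rate, config.mutation_rate,
        unit, lo, hi, rng,
    )


def simulate_amphidiploid(
    config: SimulationConfig,
    donor_a_pop: np.ndarray,
    donor_b_pop: np.ndarray,
    loci: Sequence[LocusLayout],
    rng: np.random.Generator,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Hybridisation + genome doubling, then per-variety drift.

    Each founder amphidiploid receives one gamete from a random donor-A
    individual and one from a random donor-B individual; doubling makes both
    sub-genomes homozygous.  The combined population drifts for
    ``post_origin_generations``, then each tetraploid variety is founded
    from it and drifts separately for ``variety_generations``.  Returns
    per-variety (GA, GB) sampled to the variety's accession count.
    """
    L = len(loci)
    unit, lo_a, hi_a = _taxon_arrays(config.donor_a, loci)
    _, lo_b, hi_b = _taxon_arrays(config.donor_b, loci)
    n_total = sum(t.n_accessions for t in config.tetraploid_taxa)
    founders_a = np.empty((config.n_founders, L), dtype=np.int64)
    founders_b = np.empty((config.n_founders, L), dtype=np.int64)
    for f in range(config.n_founders):
        ia = rng.integers(donor_a_pop.shape[0])
        ib = rng.integers(donor_b_pop.shape[0])
        founders_a[f] = _gametes(donor_a_pop, np.array([ia]), rng)[0]
        founders_b[f] = _gametes(donor_b_pop, np.array([ib]), rng)[0]
    which = rng.integers(config.n_founders, size=n_total)
    GA = np.repeat(founders_a[which][:, :, None], 2, axis=2)
    GB = np.repeat(founders_b[which][:, :, None], 2, axis=2)
    GA, GB = _evolve_tetraploid(
        GA, GB, config.post_origin_generations, config.selfing_rate,
        config.mutation_rate_a, config.mutation_rate_b,
        unit, lo_a, hi_a, lo_b, hi_b, rng,
    )
    out = {}
    offset = 0
    for t in config.tetraploid_taxa:
        vA = _resize(GA[offset:offset + t.n_accessions], t.n_accessions, rng)
        vB = GB[offset:offset + t.n_accessions]
        vB = _resize(vB, t.n_accessions, rng) if vB.shape[0] != t.n_accessions else vB.copy()
        vA, vB = _evolve_tetraploid(
            vA, vB, config.variety_generations, config.selfing_rate,
            config.mutation_rate_a, config.mutation_rate_b,
            unit, lo_a, hi_a, lo_b, hi_b, rng,
        )
        out[t.name] = (vA, vB)
        offset += t.n_accessions
    return out


def _realized_freqs(G: np.ndarray, loci: Sequence[LocusLayout]) -> list[dict[int, float]]:
    out = []
    n_copies = G.shape[0] * G.shape[2]
    for li in range(len(loci)):
        sizes, counts = np.unique(G[:, li, :], return_counts=True)
        out.append({int(s): float(c) / n_copies for s, c in zip(sizes, counts)})
    return out


def generate_dataset(config: SimulationConfig, seed: int) -> SimulatedDataset:
    """Simulate a full genotype table plus ground truth, deterministically
    for a given seed.  Identical seeds yield identical outputs."""
    config.validate()
    rng = np.random.default_rng(seed)
    loci = _make_layout(config, rng)
    markers = [
        MarkerDef(l.marker_id, motif=_MOTIF_BY_UNIT.get(l.unit)) for l in loci
    ]

    pops: dict[str, np.ndarray] = {}
    for taxon in config.diploid_taxa:
        pops[taxon.name] = simulate_diploid_population(config, taxon, loci, rng)

    varieties = simulate_amphidiploid(
        config, pops[config.donor_a], pops[config.donor_b], loci, rng
    )

    accessions: list[AccessionRecord] = []
    calls: dict[tuple[str, str], list[AlleleCall]] = {}
    subgenomes: dict[tuple[str, str], tuple[int, int]] = {}
    taxon_freqs: dict[tuple[str, str], dict[int, float]] = {}

    for taxon in config.diploid_taxa:
        G = pops[taxon.name]
        sample = rng.choice(G.shape[0], size=taxon.n_accessions, replace=False)
        for fr, locus in zip(_realized_freqs(G, loci), loci):
            taxon_freqs[(taxon.name, locus.marker_id)] = fr
        for i, idx in enumerate(sample):
            acc_id = f"{taxon.name}-{i + 1:03d}"
            accessions.append(AccessionRecord(acc_id, taxon.name, ploidy=2))
            for li, locus in enumerate(loci):
                sizes = sorted(int(s) for s in G[idx, li, :])
                calls[(acc_id, locus.marker_id)] = [AlleleCall(s) for s in sizes]

    for taxon in config.tetraploid_taxa:
        GA, GB = varieties[taxon.name]
        for sub, G in (("A", GA), ("B", GB)):
            for fr, locus in zip(_realized_freqs(G, loci), loci):
                taxon_freqs[(f"{taxon.name} ({sub})", locus.marker_id)] = fr
        for i in range(taxon.n_accessions):
            acc_id = f"{taxon.name}-{i + 1:03d}"
            accessions.append(AccessionRecord(acc_id, taxon.name, ploidy=4))
            for li, locus in enumerate(loci):
                # one scored product per sub-genome (strongest peak analogue)
                a = int(GA[i, li, 0])
                b = int(GB[i, li, 0])
                subgenomes[(acc_id, locus.marker_id)] = (a, b)
                calls[(acc_id, locus.marker_id)] = [
                    AlleleCall(s) for s in sorted({a, b})
                ]

    table = GenotypeTable(accessions, markers, calls)
    truth = TruthRecord(
        donor_a=config.donor_a,
        donor_b=config.donor_b,
        subgenomes=subgenomes,
        taxon_freqs=taxon_freqs,
        loci=list(loci),
    )
    return SimulatedDataset(table=table, truth=truth, config=config, seed=seed)


# ---------------------------------------------------------------------------
# Truth-based scoring
# ---------------------------------------------------------------------------


def partition_accuracy(dataset: SimulatedDataset, partitioned) -> float:
    """Fraction of ASSIGNED or TIED tetraploid calls whose A/B assignment
    matches the simulator's truth (single-product and missing calls have no
    defined orientation and are excluded)."""
    from .partition import AssignmentStatus

    n = 0
    correct = 0
    for key, asg in partitioned.assignments.items():
        if asg.status not in (AssignmentStatus.ASSIGNED, AssignmentStatus.TIED):
            continue
        true_a, true_b = dataset.truth.subgenomes[key]
        if true_a == true_b:
            continue
        n += 1
        if (asg.a, asg.b) == (true_a, true_b):
            correct += 1
    if n == 0:
        raise ValueError("no oriented tetraploid calls to score")
    return correct / n
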