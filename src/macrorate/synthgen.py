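"""Seeded generators for every data source the pipeline consumes.

Real inputs to this kind of analysis — population-scale sequencing depth,
founder-mutation family genotypes, satellite allele spectra, carrier SNP
haplotypes — are either enormous or not redistributable.  These generators
emulate each source from its governing model so that every stage of the
pipeline can be exercised and validated end to end:

* ``simulate_depth_track`` — per-base Poisson read depth given a true
  diploid copy number and genome-wide coverage (optionally with a
  multiplicative GC-style bias);
* ``simulate_star_transmissions`` — copy-number transmission along star
  phylogenies, with Poisson(mu*t) mutation counts per branch and signed
  multistep size changes;
* ``simulate_smm_spectrum`` — allele spectra under a Kingman coalescent
  with stepwise mutation at rate theta/2 per lineage per coalescent time
  unit;
* ``simulate_haplotype_decay`` — carrier haplotypes after G generations
  of recombination/mutation decay of an ancestral haplotype;
* ``simulate_pedigree`` — Mendelian transmission of diploid copy numbers
  through a templated pedigree with per-meiosis mutation.

All generators are deterministic given their seed.  The default step
distribution is a symmetric geometric over +/-{1, 2, ...} with success
probability 0.2 (mean absolute step 5 units), reflecting that observed
macrosatellite mutations mostly change copy number by far more than one
unit; a strict one-step mode exists for testing the SMM theta estimators
under their home model.  Copy numbers are floored at 1 unit: a zero-copy
array would be unobservable to the genotyping assays being emulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .depth_profile import DepthTrack
from .lineages import FamilyRecord, FounderGroup, GenerationCounts, Individual, Pedigree
from .mrca_age import CarrierHaplotype, MarkerMap
from .theta_smm import AlleleSpectrum

__all__ = [
    "StepDistribution",
    "geometric_steps",
    "one_step",
    "StarSimConfig",
    "DepthSimConfig",
    "StarSimResult",
    "PAPER_STAR_DESIGN",
    "simulate_star_transmissions",
    "observed_generation_counts",
    "simulate_depth_track",
    "simulate_smm_spectrum",
    "simulate_haplotype_decay",
    "simulate_pedigree",
]


# ---------------------------------------------------------------------------
# Step distributions

StepDistribution = Callable[[np.random.Generator, int], np.ndarray]


def geometric_steps(p: float = 0.2) -> StepDistribution:
    """Symmetric geometric step sizes over +/-{1, 2, ...}; no zero steps."""
    if not (0 < p <= 1):
        raise ValueError("p must be in (0, 1]")

    def draw(rng: np.random.Generator, size: int) -> np.ndarray:
        magnitude = rng.geometric(p, size=size)
        sign = rng.choice((-1, 1), size=size)
        return magnitude * sign

    return draw


def one_step() -> StepDistribution:
    """Strict stepwise mutation model: +/-1 with equal probability."""

    def draw(rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.choice((-1, 1), size=size)

    return draw


def _apply_steps(allele: int, steps: np.ndarray) -> int:
    for s in steps:
        allele = max(1, allele + int(s))  # arrays cannot drop below one unit
    return allele


# ---------------------------------------------------------------------------
# Star-phylogeny transmission


@dataclass(frozen=True)
class StarSimConfig:
    """Design of a star-phylogeny transmission simulation.

    ``groups`` lists, per founder mutation, the MRCA age in generations
    (``None`` for a single extended family with no star component) and the
    within-family meiosis count of each member family.
    """

    mu: float
    groups: tuple[tuple[int | None, tuple[int, ...]], ...]
    ancestral_allele: int = 30
    step: StepDistribution = field(default_factory=geometric_steps)

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        for g_mrca, meioses in self.groups:
            if g_mrca is None and len(meioses) > 1:
                raise ValueError("multi-family group needs an MRCA age")


#: The study design of the founder-mutation dataset: one private mutation
#: observed over 17 meioses and four founder mutations with 2-4 families
#: each, ages 87/73/61/72 generations, and the published per-family
#: meiosis counts.
PAPER_STAR_DESIGN: tuple[tuple[int | None, tuple[int, ...]], ...] = (
    (None, (17,)),
    (87, (6, 6)),
    (73, (5, 2)),
    (61, (0, 0, 0, 5)),
    (72, (20, 4, 0, 0)),
)


@dataclass(frozen=True)
class StarSimResult:
    groups: tuple[FounderGroup, ...]
    #: observable within-family transmissions in which the copy number
    #: changed (each is a mutated lineage of length 1 to an observer)
    mutated_meioses: int
    #: ground truth: number of branch mutation events per (group, family)
    branch_events: tuple[tuple[int, ...], ...]


def simulate_star_transmissions(
    config: StarSimConfig, seed: int
) -> StarSimResult:
    """Simulate copy-number transmission along star phylogenies.

    Each family branch of g generations receives K ~ Poisson(mu*g)
    mutation events applied sequentially to the ancestral copy number;
    each within-family meiosis likewise receives K ~ Poisson(mu) events.
    Returns founder groups ready for lineage aggregation (meioses with an
    observed change are excluded from ``meioses_observed`` and counted in
    ``mutated_meioses``) plus the ground-truth branch event counts.
    """
    rng = np.random.default_rng(seed)
    groups: list[FounderGroup] = []
    branch_events: list[tuple[int, ...]] = []
    mutated_meioses = 0
    for gi, (g_mrca, meioses_per_family) in enumerate(config.groups):
        families = []
        events_here = []
        for fi, n_meioses in enumerate(meioses_per_family):
            allele = config.ancestral_allele
            k = rng.poisson(config.mu * g_mrca) if g_mrca is not None else 0
            if k:
                allele = _apply_steps(allele, config.step(rng, k))
            events_here.append(int(k))
            clean = 0
            for _ in range(n_meioses):
                km = rng.poisson(config.mu)
                if km:
                    new = _apply_steps(allele, config.step(rng, km))
                    if new == allele:
                        clean += 1  # net-zero change is indistinguishable
                    else:
                        mutated_meioses += 1
                else:
                    clean += 1
            families.append(
                FamilyRecord(
                    family_id=f"G{gi}F{fi}",
                    linked_alleles=frozenset({allele}),
                    meioses_observed=clean,
                )
            )
        groups.append(
            FounderGroup(
                mutation_id=f"M{gi}",
                families=tuple(families),
                g_mrca=g_mrca,
                g_ci=None if g_mrca is None else (g_mrca, g_mrca),
            )
        )
        branch_events.append(tuple(events_here))
    return StarSimResult(
        groups=tuple(groups),
        mutated_meioses=mutated_meioses,
        branch_events=tuple(branch_events),
    )


def observed_generation_counts(sim: StarSimResult) -> GenerationCounts:
    """Generation counts as an observer of the simulation would build them:
    lineage aggregation of the founder groups plus one length-1 mutated
    lineage per within-family transmission with a visible change."""
    from .lineages import aggregate_generation_counts

    base = aggregate_generation_counts(sim.groups)
    return GenerationCounts(
        t0_total=base.t0_total,
        mutated_lineages=base.mutated_lineages + (1,) * sim.mutated_meioses,
    )


# ---------------------------------------------------------------------------
# Read depth


@dataclass(frozen=True)
class DepthSimConfig:
    true_copy_number: int
    genome_doc: float
    length: int = 4913  # default matches the RNU2 repeat-unit interval
    gc_bias_factor: float = 1.0
    contig: str = "sim"
    start: int = 1

    def __post_init__(self) -> None:
        if self.true_copy_number < 0:
            raise ValueError("true_copy_number must be >= 0")
        if self.genome_doc <= 0:
            raise ValueError("genome_doc must be > 0")
        if self.length < 1:
            raise ValueError("length must be >= 1")


def simulate_depth_track(config: DepthSimConfig, seed: int) -> DepthTrack:
    """Per-base Poisson depth at mean genome_doc * CN/2 * gc_bias_factor."""
    rng = np.random.default_rng(seed)
    mean = config.genome_doc * config.true_copy_number / 2.0 * config.gc_bias_factor
    depths = rng.poisson(mean, size=config.length)
    return DepthTrack(
        contig=config.contig,
        start=config.start,
        end=config.start + config.length - 1,
        depths=depths,
    )


# ---------------------------------------------------------------------------
# Coalescent allele spectrum


def simulate_smm_spectrum(
    theta: float,
    n: int,
    seed: int,
    *,
    ancestral_size: int = 30,
    step: StepDistribution | None = None,
    diagnostics: bool = False,
) -> AlleleSpectrum | tuple[AlleleSpectrum, dict]:
    """Allele spectrum of a satellite locus under the neutral coalescent.

    A Kingman genealogy of ``n`` haploid lineages is simulated (time in
    units of 2Ne generations), mutations are scattered on branches as
    Poisson with rate theta/2 per lineage per time unit — the convention
    under which theta = 4*Ne*mu — and each mutation applies a signed step
    (default +/-1, the estimators' home model) to the repeat count.

    With ``diagnostics=True`` also returns the total branch length (in
    coalescent time units) and the number of mutations, for
    distributional checks against the closed-form coalescent moments.
    """
    if theta <= 0:
        raise ValueError("theta must be > 0")
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    draw_step = step if step is not None else one_step()

    parent = np.full(2 * n - 1, -1, dtype=int)
    branch = np.zeros(2 * n - 1)  # branch length above each node
    active = list(range(n))
    next_node = n
    t = 0.0
    birth = np.zeros(2 * n - 1)  # time at which each node starts (tips at 0)
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a, b = active[i], active[j]
        for child in (a, b):
            parent[child] = next_node
            branch[child] = t - birth[child]
        birth[next_node] = t
        # swap-pop removal keeps the merge loop O(n)
        active[j] = active[-1]
        active.pop()
        active[i] = next_node
        next_node += 1

    root = active[0]
    n_mut = rng.poisson(theta / 2.0 * branch[: root + 1])
    n_mut[root] = 0
    # accumulate net step change per branch, then propagate root -> tips
    net = np.zeros(2 * n - 1, dtype=int)
    sizes = np.zeros(2 * n - 1, dtype=int)
    for node in range(root + 1):
        if n_mut[node]:
            net[node] = int(np.sum(draw_step(rng, int(n_mut[node]))))
    order = np.argsort(-birth[: root + 1])  # root first (largest birth time)
    for node in order:
        if parent[node] == -1:
            sizes[node] = ancestral_size
        else:
            sizes[node] = max(1, sizes[parent[node]] + net[node])
    tip_sizes = sizes[:n]
    values, counts = np.unique(tip_sizes, return_counts=True)
    spectrum = AlleleSpectrum(
        counts={int(v): int(c) for v, c in zip(values, counts)}, n=n
    )
    if diagnostics:
        return spectrum, {
            "total_branch_length": float(np.sum(branch[: root + 1])),
            "n_mutations": int(np.sum(n_mut)),
        }
    return spectrum


# ---------------------------------------------------------------------------
# Haplotype decay


def simulate_haplotype_decay(
    g: int,
    marker_map: MarkerMap,
    n_carriers: int,
    seed: int,
    marker_mu: float = 0.0,
) -> list[list[CarrierHaplotype]]:
    """Phased carrier haplotypes after G generations of decay.

    Each carrier keeps the ancestral allele at marker i with probability
    ((1 - r_i)(1 - marker_mu))^g, otherwise draws the allele from the
    population frequencies.  Returns one singleton haplotype list per
    carrier (weight 1), directly consumable by ``estimate_g``.
    """
    if g < 0:
        raise ValueError("g must be >= 0")
    if n_carriers < 1:
        raise ValueError("need at least one carrier")
    rng = np.random.default_rng(seed)
    r = marker_map.recombination_fractions()
    rho = ((1.0 - r) * (1.0 - marker_mu)) ** g
    carriers = []
    for _ in range(n_carriers):
        alleles: list[str | None] = []
        for i, marker in enumerate(marker_map.markers):
            if rng.random() < rho[i]:
                alleles.append(marker.ancestral)
            else:
                options = list(marker.frequencies)
                probs = np.array([marker.frequencies[a] for a in options])
                alleles.append(str(rng.choice(options, p=probs / probs.sum())))
        carriers.append([CarrierHaplotype(alleles=tuple(alleles), weight=1.0)])
    return carriers


# ---------------------------------------------------------------------------
# Pedigree simulation


def simulate_pedigree(
    template: Sequence[int],
    founder_alleles: Sequence[int],
    mu: float,
    seed: int,
) -> Pedigree:
    """Templated multi-generation pedigree with mutating transmissions.

    ``template[k]`` is the sibship size in generation k+1: the founder
    couple has ``template[0]`` children, the first child marries an
    unrelated spouse (alleles drawn from ``founder_alleles``) and has
    ``template[1]`` children, and so on down one descending line.  Each
    meiosis transmits one parental allele at random and mutates it with
    probability 1 - exp(-mu), applying a geometric step.
    """
    if not template:
        raise ValueError("empty template")
    if mu < 0:
        raise ValueError("mu must be >= 0")
    rng = np.random.default_rng(seed)
    step = geometric_steps()
    pool = list(founder_alleles)

    def founder_pair() -> tuple[int, int]:
        return (
            int(pool[rng.integers(len(pool))]),
            int(pool[rng.integers(len(pool))]),
        )

    def transmit(parent_alleles: tuple[int, int]) -> int:
        allele = int(parent_alleles[rng.integers(2)])
        if rng.random() < -math.expm1(-mu):
            allele = _apply_steps(allele, step(rng, 1))
        return allele

    individuals: list[Individual] = []
    father = Individual(iid="F0", alleles=founder_pair(), carrier=True)
    mother = Individual(iid="M0", alleles=founder_pair())
    individuals += [father, mother]
    for gen, sibship in enumerate(template):
        children = []
        for c in range(sibship):
            child = Individual(
                iid=f"G{gen + 1}C{c}",
                father=father.iid,
                mother=mother.iid,
                alleles=(transmit(father.alleles), transmit(mother.alleles)),
            )
            individuals.append(child)
            children.append(child)
        if gen + 1 < len(template):
            father = children[0]
            mother = Individual(iid=f"S{gen + 1}", alleles=founder_pair())
            individuals.append(mother)
    return Pedigree(individuals=tuple(individuals))
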