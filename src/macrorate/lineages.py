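"""Founder-mutation lineage accounting.

Families that carry the same rare disease mutation descend from one common
ancestor even when no genealogical link is recorded.  Treating the families
of each founder mutation as radiating independently from their most recent
common ancestor (MRCA) — a star phylogeny — the copy number of a tightly
linked satellite array can be followed over hundreds of generations:

* a family whose linked array matches the inferred ancestral allele
  contributes ``g_mrca`` mutation-free generations;
* a family carrying a different allele contributes one lineage of length
  ``g_mrca`` on which at least one mutation occurred;
* genotyped parent-to-child transmissions inside a family each contribute
  one further mutation-free generation (meioses with an observed change
  would instead be lineages of length 1).

The resulting sufficient statistic — total mutation-free generations ``T0``
and the list of mutated-lineage lengths ``t_j`` — feeds the Poisson
likelihood in :mod:`macrorate.rate_mle`.  A parsimony count of the minimum
number of distinct mutation events per founder group is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "FamilyRecord",
    "FounderGroup",
    "GenerationCounts",
    "Individual",
    "Pedigree",
    "AncestralCall",
    "ancestral_allele",
    "min_mutation_events",
    "aggregate_generation_counts",
    "count_meioses",
    "read_groups_tsv",
    "write_counts_json",
]


@dataclass(frozen=True)
class FamilyRecord:
    """One family of a founder-mutation group.

    ``linked_alleles`` is the set of candidate repeat counts for the array
    linked to the disease mutation: a singleton when segregation resolves
    the linked allele, multi-valued (e.g. ``{13, 35}``) when a single
    genotyped heterozygote leaves it ambiguous.  ``meioses_observed``
    counts within-family transmissions in which the linked array was
    passed on unchanged.
    """

    family_id: str
    linked_alleles: frozenset[int]
    meioses_observed: int = 0

    def __post_init__(self) -> None:
        alleles = frozenset(int(a) for a in self.linked_alleles)
        if not alleles:
            raise ValueError(f"family {self.family_id}: empty allele set")
        if any(a < 1 for a in alleles):
            raise ValueError(f"family {self.family_id}: repeat counts must be >= 1")
        if self.meioses_observed < 0:
            raise ValueError(f"family {self.family_id}: negative meiosis count")
        object.__setattr__(self, "linked_alleles", alleles)

    @property
    def resolved(self) -> bool:
        return len(self.linked_alleles) == 1


@dataclass(frozen=True)
class FounderGroup:
    """A founder mutation with its MRCA age and member families."""

    mutation_id: str
    families: tuple[FamilyRecord, ...]
    g_mrca: int | None = None
    g_ci: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "families", tuple(self.families))
        if not self.families:
            raise ValueError(f"group {self.mutation_id}: no families")
        if self.g_mrca is not None and self.g_mrca < 1:
            raise ValueError(f"group {self.mutation_id}: g_mrca must be >= 1")
        if self.g_ci is not None:
            lo, hi = self.g_ci
            if self.g_mrca is None or not (lo <= self.g_mrca <= hi):
                raise ValueError(
                    f"group {self.mutation_id}: CI {self.g_ci} does not bracket "
                    f"g_mrca {self.g_mrca}"
                )

    def with_age(self, g: int) -> "FounderGroup":
        return FounderGroup(self.mutation_id, self.families, g_mrca=g, g_ci=(g, g))


@dataclass(frozen=True)
class GenerationCounts:
    """Sufficient statistic of the star-phylogeny Poisson likelihood."""

    t0_total: int
    mutated_lineages: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.t0_total < 0:
            raise ValueError("t0_total must be >= 0")
        lineages = tuple(int(t) for t in self.mutated_lineages)
        if any(t < 1 for t in lineages):
            raise ValueError("mutated lineage lengths must be >= 1")
        object.__setattr__(self, "mutated_lineages", lineages)


@dataclass(frozen=True)
class AncestralCall:
    """Result of inferring a group's ancestral allele by family majority."""

    alleles: frozenset[int]  # singleton, or a tie-set
    carriers: tuple[str, ...]
    non_carriers: tuple[str, ...]

    @property
    def is_tie(self) -> bool:
        return len(self.alleles) > 1


def ancestral_allele(group: FounderGroup) -> AncestralCall:
    """Infer the ancestral repeat count as the allele carried by the most
    families.

    Ambiguous allele sets count toward every member allele.  Ties are
    reported as a tie-set; carriers/non-carriers are then given for the
    first tied allele (by construction every tied partition has the same
    carrier count, and downstream generation accounting is identical).
    """
    support: dict[int, int] = {}
    for fam in group.families:
        for a in fam.linked_alleles:
            support[a] = support.get(a, 0) + 1
    best = max(support.values())
    tied = frozenset(a for a, k in support.items() if k == best)
    top = min(tied)  # deterministic representative
    carriers = tuple(f.family_id for f in group.families if top in f.linked_alleles)
    non_carriers = tuple(
        f.family_id for f in group.families if top not in f.linked_alleles
    )
    return AncestralCall(alleles=tied, carriers=carriers, non_carriers=non_carriers)


def _distinct_alleles(group: FounderGroup) -> int:
    """Number of distinct resolvable alleles in a group.

    Resolved singletons each count once.  An ambiguous set that intersects
    a resolved allele is merged with it; ambiguous sets that intersect each
    other are clustered together; each remaining cluster counts as one
    allele (parsimony: one unknown allele can explain all its candidates).
    """
    resolved = {next(iter(f.linked_alleles)) for f in group.families if f.resolved}
    ambiguous = [f.linked_alleles for f in group.families if not f.resolved]
    clusters: list[set[int]] = []
    for s in ambiguous:
        if s & resolved:
            continue
        merged = set(s)
        keep: list[set[int]] = []
        for c in clusters:
            if c & merged:
                merged |= c
            else:
                keep.append(c)
        keep.append(merged)
        clusters = keep
    return len(resolved) + len(clusters)


def min_mutation_events(groups: Iterable[FounderGroup]) -> int:
    """Minimum number of mutation events consistent with the allele data.

    Under a star phylogeny, each founder group needs at least
    ``distinct alleles - 1`` events (families sharing a derived allele are
    parsimoniously assumed to share one event on the internal history).
    """
    return sum(max(0, _distinct_alleles(g) - 1) for g in groups)


def aggregate_generation_counts(groups: Iterable[FounderGroup]) -> GenerationCounts:
    """Collapse founder groups into the likelihood's sufficient statistic.

    ``t0_total`` sums every family's observed mutation-free meioses plus,
    per group, one branch of ``g_mrca`` generations for each family whose
    linked allele is the group's ancestral allele.  Each non-ancestral
    family contributes one mutated lineage of length ``g_mrca``.  A
    single-family group with no MRCA age contributes its meioses only.
    For ancestral ties every tied partition yields identical counts (the
    tie swaps which family is the carrier but not the totals); this is
    asserted.
    """
    t0 = 0
    lineages: list[int] = []
    for group in groups:
        t0 += sum(f.meioses_observed for f in group.families)
        if group.g_mrca is None:
            if len(group.families) > 1:
                raise ValueError(
                    f"group {group.mutation_id}: MRCA age required for a "
                    f"multi-family group"
                )
            continue
        call = ancestral_allele(group)
        if call.is_tie:
            sizes = set()
            for a in call.alleles:
                sizes.add(sum(1 for f in group.families if a in f.linked_alleles))
            assert len(sizes) == 1, "tied ancestral partitions disagree on counts"
        n_anc = len(call.carriers)
        t0 += n_anc * group.g_mrca
        lineages.extend([group.g_mrca] * len(call.non_carriers))
    return GenerationCounts(t0_total=t0, mutated_lineages=tuple(lineages))


# ---------------------------------------------------------------------------
# Pedigrees and meiosis counting


@dataclass(frozen=True)
class Individual:
    iid: str
    father: str | None = None
    mother: str | None = None
    carrier: bool = False
    alleles: tuple[int, int] | None = None  # diploid repeat counts


@dataclass(frozen=True)
class Pedigree:
    individuals: tuple[Individual, ...]
    _index: dict = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "individuals", tuple(self.individuals))
        index = {ind.iid: ind for ind in self.individuals}
        if len(index) != len(self.individuals):
            raise ValueError("duplicate individual ids")
        for ind in self.individuals:
            for parent in (ind.father, ind.mother):
                if parent is not None and parent not in index:
                    raise ValueError(f"{ind.iid}: unknown parent {parent}")
        object.__setattr__(self, "_index", index)
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(iid: str) -> None:
            if state.get(iid) == 1:
                raise ValueError(f"pedigree cycle through {iid}")
            if state.get(iid) == 2:
                return
            state[iid] = 1
            ind = self._index[iid]
            for parent in (ind.father, ind.mother):
                if parent is not None:
                    visit(parent)
            state[iid] = 2

        for ind in self.individuals:
            visit(ind.iid)

    def __getitem__(self, iid: str) -> Individual:
        return self._index[iid]


def _transmitted_identifiable(
    child: Individual, parent: Individual, other: Individual | None
) -> bool:
    """Can the allele this parent transmitted be pinned down by Mendelian
    tracing from the genotypes alone?"""
    if child.alleles is None or parent.alleles is None:
        return False
    ca, cb = child.alleles
    pset = set(parent.alleles)
    candidates = {a for a in (ca, cb) if a in pset}
    if not candidates:
        return False  # Mendelian inconsistency or de novo change; not traceable
    if len({ca, cb}) == 1:
        return True  # homozygous child: transmitted allele known regardless
    if len(candidates) == 1:
        return True
    # both child alleles could have come from this parent; the other
    # parent's genotype may force the assignment
    if other is not None and other.alleles is not None:
        oset = set(other.alleles)
        from_other = {a for a in (ca, cb) if a in oset}
        if len(from_other) == 1:
            return True
    return False


def count_meioses(pedigree: Pedigree, genotyped: set[str]) -> int:
    """Count parent-to-child transmissions with an identifiable allele.

    Each genotyped child / genotyped parent pair contributes 1 when the
    transmitted allele can be identified by Mendelian tracing.  This is a
    documented counting rule for generic pedigrees; published per-family
    totals remain inputs when the full genotyped pedigree is not available.
    """
    unknown = genotyped - {ind.iid for ind in pedigree.individuals}
    if unknown:
        raise ValueError(f"genotyped ids not in pedigree: {sorted(unknown)}")
    total = 0
    for ind in pedigree.individuals:
        if ind.iid not in genotyped:
            continue
        parents = [(ind.father, ind.mother), (ind.mother, ind.father)]
        for pid, oid in parents:
            if pid is None or pid not in genotyped:
                continue
            other = pedigree[oid] if (oid is not None and oid in genotyped) else None
            if _transmitted_identifiable(ind, pedigree[pid], other):
                total += 1
    return total


# ---------------------------------------------------------------------------
# I/O


def read_groups_tsv(path: str | Path) -> list[FounderGroup]:
    """Read founder groups from TSV.

    Columns: mutation_id, g_mrca, g_lower, g_upper, family_id, alleles
    (semicolon-separated repeat counts), meioses.  Age columns may be blank
    for a single-family group with no MRCA estimate.
    """
    df = pd.read_csv(path, sep="\t", dtype={"mutation_id": str, "family_id": str})
    required = {"mutation_id", "g_mrca", "family_id", "alleles", "meioses"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"groups file {path} missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError(f"groups file {path} contains no families")
    groups: list[FounderGroup] = []
    for mutation_id, sub in df.groupby("mutation_id", sort=False):
        families = tuple(
            FamilyRecord(
                family_id=row.family_id,
                linked_alleles=frozenset(
                    int(a) for a in str(row.alleles).split(";") if a != ""
                ),
                meioses_observed=int(row.meioses),
            )
            for row in sub.itertuples()
        )
        ages = sub["g_mrca"].dropna().unique()
        if len(ages) > 1:
            raise ValueError(f"group {mutation_id}: conflicting g_mrca values")
        g_mrca = int(ages[0]) if len(ages) else None
        g_ci = None
        if {"g_lower", "g_upper"} <= set(sub.columns):
            lows = sub["g_lower"].dropna().unique()
            highs = sub["g_upper"].dropna().unique()
            if len(lows) and len(highs):
                g_ci = (int(lows[0]), int(highs[0]))
        groups.append(FounderGroup(mutation_id, families, g_mrca=g_mrca, g_ci=g_ci))
    return groups


def write_counts_json(counts: GenerationCounts, path: str | Path) -> None:
    import json

    Path(path).write_text(
        json.dumps(
            {
                "t0_total": counts.t0_total,
                "mutated_lineages": list(counts.mutated_lineages),
            },
            indent=2,
        )
        + "\n"
    )
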