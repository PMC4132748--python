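"""Founder-mutation age estimation from ancestral-haplotype decay.

Carriers of a founder mutation inherit, along with the mutation, the
haplotype of flanking markers present in the most recent common ancestor
(MRCA).  Recombination and marker mutation erode that ancestral haplotype
at a rate governed by the number of generations G since the MRCA, so the
marker data of today's carriers carry information about G.

For each marker i at recombination fraction r_i from the disease locus,
the probability that a carrier chromosome still carries the ancestral
allele after G generations is

    rho_i = ((1 - r_i) * (1 - marker_mu))^G

and the likelihood that an observed haplotype descends from the ancestor,
relative to it being an independent chromosome drawn from population
allele frequencies, is

    prod_i [ rho_i * 1{allele_i = ancestral_i} + (1 - rho_i) * p_i(allele_i) ]
    -----------------------------------------------------------------------
    prod_i p_i(allele_i)

Markers are treated independently given descent status; this ignores the
spatial contiguity of the surviving ancestral segment and is the main
modelling simplification (see the methods note).  Unphased carriers are
handled by enumerating all haplotypes consistent with the multi-locus
genotype, weighted by the population probability of the complementary
haplotype.  G is found by integer grid search; the support interval is
the set of G whose log10 likelihood lies within 0.86 of the maximum
(the conventional ~95% support region for one parameter).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Marker",
    "MarkerMap",
    "CarrierHaplotype",
    "AgeEstimate",
    "genetic_positions",
    "recombination_fraction",
    "haplotype_relative_likelihood",
    "estimate_g",
    "enumerate_weighted_haplotypes",
    "read_marker_map",
    "read_genotypes",
    "SUPPORT_DROP_LOG10",
]

#: log10-likelihood drop defining the ~95% support interval for G.
SUPPORT_DROP_LOG10 = 0.86

#: Enumeration guard: 2^20 haplotypes per individual is the ceiling.
MAX_HET_MARKERS = 20


@dataclass(frozen=True)
class Marker:
    marker_id: str
    position_bp: int
    position_cm: float
    ancestral: str
    frequencies: dict[str, float]

    def __post_init__(self) -> None:
        freqs = {str(a): float(p) for a, p in self.frequencies.items()}
        total = sum(freqs.values())
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError(
                f"marker {self.marker_id}: allele frequencies sum to {total}"
            )
        if self.ancestral not in freqs:
            raise ValueError(
                f"marker {self.marker_id}: ancestral allele {self.ancestral!r} "
                "missing from frequency table"
            )
        object.__setattr__(self, "frequencies", freqs)


@dataclass(frozen=True)
class MarkerMap:
    """Ordered markers around a disease locus, with genetic positions."""

    markers: tuple[Marker, ...]
    disease_cm: float

    def __post_init__(self) -> None:
        markers = tuple(self.markers)
        if not markers:
            raise ValueError("empty marker map")
        bp = [m.position_bp for m in markers]
        if any(nxt <= prev for prev, nxt in zip(bp, bp[1:])):
            raise ValueError("physical positions must be strictly increasing")
        cm = [m.position_cm for m in markers]
        if any(b < a for a, b in zip(cm, cm[1:])):
            raise ValueError("genetic positions must be non-decreasing")
        object.__setattr__(self, "markers", markers)

    def __len__(self) -> int:
        return len(self.markers)

    def recombination_fractions(self) -> np.ndarray:
        """Per-marker recombination fraction to the disease locus."""
        return np.array(
            [
                recombination_fraction(abs(m.position_cm - self.disease_cm))
                for m in self.markers
            ]
        )


@dataclass(frozen=True)
class CarrierHaplotype:
    """One candidate carrier haplotype with its probability weight.

    ``alleles`` holds one allele per map marker; ``None`` marks missing
    data.  When haplotypes are enumerated from an unphased genotype the
    weights of one individual's candidates sum to 1; a phased haplotype
    has weight 1.
    """

    alleles: tuple[str | None, ...]
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.weight <= 1):
            raise ValueError("weight must be in (0, 1]")
        object.__setattr__(self, "alleles", tuple(self.alleles))


@dataclass(frozen=True)
class AgeEstimate:
    g_hat: int
    support: tuple[int, int]
    loglik10: dict[int, float] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.support
        if not (lo <= self.g_hat <= hi):
            raise ValueError("support interval must contain g_hat")


def genetic_positions(
    physical_bp: Sequence[int],
    anchors: Sequence[tuple[int, float]] | None = None,
) -> list[float]:
    """Map physical positions to genetic positions (cM).

    With no anchors, 1 cM = 1 Mb.  With anchor (bp, cM) pairs, the
    proportion of physical distance between flanking anchors is mapped
    linearly onto the genetic scale; positions beyond the anchors
    extrapolate with the nearest segment's rate.
    """
    bp = list(physical_bp)
    if any(b > a for b, a in zip(bp, bp[1:])):
        raise ValueError("physical positions must be sorted")
    if anchors is None:
        return [p / 1e6 for p in bp]
    if len(anchors) < 2:
        raise ValueError("need at least 2 anchors")
    abp = np.array([a[0] for a in anchors], dtype=float)
    acm = np.array([a[1] for a in anchors], dtype=float)
    if np.any(np.diff(abp) <= 0):
        raise ValueError("anchor physical positions must be strictly increasing")
    out = []
    for p in bp:
        j = int(np.clip(np.searchsorted(abp, p) - 1, 0, len(abp) - 2))
        frac = (p - abp[j]) / (abp[j + 1] - abp[j])
        out.append(float(acm[j] + frac * (acm[j + 1] - acm[j])))
    return out


def recombination_fraction(d_cm: float) -> float:
    """Haldane map function: r = (1 - exp(-2 d / 100)) / 2."""
    if d_cm < 0:
        raise ValueError("genetic distance must be >= 0")
    return 0.5 * -math.expm1(-2.0 * d_cm / 100.0)


def haplotype_relative_likelihood(
    hap: CarrierHaplotype,
    marker_map: MarkerMap,
    g: float,
    marker_mu: float = 0.0,
) -> float:
    """Likelihood ratio: descended from the ancestral haplotype vs
    an independent chromosome from the population.

    Missing alleles contribute a factor of 1 to both numerator and
    denominator.
    """
    if g < 0:
        raise ValueError("g must be >= 0")
    if len(hap.alleles) != len(marker_map):
        raise ValueError("haplotype length does not match marker count")
    r = marker_map.recombination_fractions()
    log_ratio = 0.0
    for i, (marker, allele) in enumerate(zip(marker_map.markers, hap.alleles)):
        if allele is None:
            continue
        if allele not in marker.frequencies:
            raise ValueError(
                f"allele {allele!r} absent from frequency table of "
                f"{marker.marker_id}"
            )
        rho = ((1.0 - r[i]) * (1.0 - marker_mu)) ** g
        p = marker.frequencies[allele]
        num = rho * (1.0 if allele == marker.ancestral else 0.0) + (1.0 - rho) * p
        log_ratio += math.log(num) - math.log(p)
    return math.exp(log_ratio)


def _carrier_loglik10_grid(
    carriers: Sequence[Sequence[CarrierHaplotype]],
    marker_map: MarkerMap,
    marker_mu: float,
    g_values: np.ndarray,
) -> np.ndarray:
    """Total log10 likelihood over a grid of G values (vectorised)."""
    r = marker_map.recombination_fractions()
    retain = (1.0 - r) * (1.0 - marker_mu)  # per-marker survival per generation
    total = np.zeros(len(g_values))
    log_retain = np.log(retain)  # retain > 0 always (r < 0.5, mu < 1)
    for haps in carriers:
        if not haps:
            raise ValueError("carrier with no haplotypes")
        ratios = np.zeros((len(haps), len(g_values)))
        for k, hap in enumerate(haps):
            obs = [
                (i, a) for i, a in enumerate(hap.alleles) if a is not None
            ]
            idx = np.array([i for i, _ in obs], dtype=int)
            is_anc = np.array(
                [a == marker_map.markers[i].ancestral for i, a in obs], dtype=float
            )
            p = np.array([marker_map.markers[i].frequencies[a] for i, a in obs])
            # rho: (n_g, n_obs)
            rho = np.exp(np.outer(g_values, log_retain[idx]))
            num = rho * is_anc[None, :] + (1.0 - rho) * p[None, :]
            ratios[k] = np.sum(np.log(num) - np.log(p)[None, :], axis=1)
        # weighted mixture per carrier, in log space
        weights = np.array([h.weight for h in haps])
        m = ratios.max(axis=0)
        mix = m + np.log(np.sum(weights[:, None] * np.exp(ratios - m), axis=0))
        total += mix
    return total / math.log(10.0)


def estimate_g(
    carriers: Sequence[Sequence[CarrierHaplotype]],
    marker_map: MarkerMap,
    marker_mu: float = 0.0,
    g_range: tuple[int, int] = (1, 500),
) -> AgeEstimate:
    """Estimate generations to the MRCA by integer likelihood search.

    ``carriers`` is one list of weighted candidate haplotypes per carrier
    (a phased carrier is a singleton list).  The total log-likelihood at
    each G sums, over carriers, the log of the weighted mean relative
    likelihood of that carrier's candidates.  The support interval is the
    outermost G whose log10 likelihood is within ``SUPPORT_DROP_LOG10``
    of the maximum.
    """
    flat = [h for haps in carriers for h in haps]
    if len(flat) < 2:
        raise ValueError("need at least 2 weighted haplotypes")
    lo, hi = g_range
    if not (1 <= lo <= hi):
        raise ValueError("invalid g_range")
    g_values = np.arange(lo, hi + 1)
    ll10 = _carrier_loglik10_grid(carriers, marker_map, marker_mu, g_values)
    best = int(np.argmax(ll10))
    within = np.flatnonzero(ll10 >= ll10[best] - SUPPORT_DROP_LOG10)
    support = (int(g_values[within[0]]), int(g_values[within[-1]]))
    return AgeEstimate(
        g_hat=int(g_values[best]),
        support=support,
        loglik10={int(g): float(v) for g, v in zip(g_values, ll10)},
    )


def enumerate_weighted_haplotypes(
    genotype: Sequence[tuple[str | None, str | None]],
    marker_map: MarkerMap,
) -> list[CarrierHaplotype]:
    """All candidate carrier haplotypes consistent with an unphased
    genotype, weighted by the population probability of the partner.

    At each heterozygous marker the candidate haplotype takes one of the
    two alleles and the partner haplotype the other; assuming marker
    independence the partner's probability is the product of its allele
    frequencies, and weights are normalised to sum to 1 per individual.
    Missing markers stay missing on both haplotypes.
    """
    if len(genotype) != len(marker_map):
        raise ValueError("genotype length does not match marker count")
    het = [
        i
        for i, (a, b) in enumerate(genotype)
        if a is not None and b is not None and a != b
    ]
    if len(het) > MAX_HET_MARKERS:
        raise ValueError(
            f"{len(het)} heterozygous markers would enumerate 2^{len(het)} "
            f"haplotypes; limit is 2^{MAX_HET_MARKERS}"
        )
    base: list[str | None] = []
    for a, b in genotype:
        base.append(a if a is not None else b)  # overwritten at het sites

    haps: list[tuple[tuple[str | None, ...], float]] = []
    n_combo = 1 << len(het)
    for mask in range(n_combo):
        alleles = list(base)
        partner_logp = 0.0
        for bit, i in enumerate(het):
            a, b = genotype[i]
            take, give = (a, b) if (mask >> bit) & 1 == 0 else (b, a)
            alleles[i] = take
            freq = marker_map.markers[i].frequencies.get(give)
            if freq is None:
                raise ValueError(
                    f"allele {give!r} absent from frequency table of "
                    f"{marker_map.markers[i].marker_id}"
                )
            partner_logp += math.log(freq)
        haps.append((tuple(alleles), math.exp(partner_logp)))
    total = sum(w for _, w in haps)
    return [CarrierHaplotype(alleles=a, weight=w / total) for a, w in haps]


# ---------------------------------------------------------------------------
# I/O


def read_marker_map(path: str | Path, disease_bp: int) -> MarkerMap:
    """Read a marker map TSV.

    Columns: marker_id, bp, cm (optional; blank -> 1 cM = 1 Mb),
    ancestral, freqs (comma-separated ``allele:frequency`` pairs).
    ``disease_bp`` locates the disease locus; its genetic position uses
    the same bp -> cM convention as unanchored markers.
    """
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "ancestral": str})
    required = {"marker_id", "bp", "ancestral", "freqs"}
    if not required <= set(df.columns):
        raise ValueError(f"marker map {path} needs columns {sorted(required)}")
    markers = []
    for row in df.itertuples():
        freqs = {}
        for pair in str(row.freqs).split(","):
            allele, p = pair.split(":")
            freqs[allele.strip()] = float(p)
        cm = getattr(row, "cm", None)
        if cm is None or (isinstance(cm, float) and math.isnan(cm)):
            cm = row.bp / 1e6
        markers.append(
            Marker(
                marker_id=row.marker_id,
                position_bp=int(row.bp),
                position_cm=float(cm),
                ancestral=str(row.ancestral),
                frequencies=freqs,
            )
        )
    return MarkerMap(markers=tuple(markers), disease_cm=disease_bp / 1e6)


def read_genotypes(
    path: str | Path, marker_map: MarkerMap
) -> list[list[CarrierHaplotype]]:
    """Read unphased carrier genotypes and enumerate weighted haplotypes.

    Columns: individual, marker, allele1, allele2.  Markers absent for an
    individual are treated as missing.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"individual": str, "marker": str, "allele1": str, "allele2": str},
    )
    required = {"individual", "marker", "allele1", "allele2"}
    if not required <= set(df.columns):
        raise ValueError(f"genotype file {path} needs columns {sorted(required)}")
    order = {m.marker_id: i for i, m in enumerate(marker_map.markers)}
    carriers = []
    for _, sub in df.groupby("individual", sort=True):
        genotype: list[tuple[str | None, str | None]] = [(None, None)] * len(
            marker_map
        )
        for row in sub.itertuples():
            if row.marker not in order:
                raise ValueError(f"unknown marker {row.marker!r}")
            genotype[order[row.marker]] = (row.allele1, row.allele2)
        carriers.append(enumerate_weighted_haplotypes(genotype, marker_map))
    return carriers
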