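"""Poisson star-phylogeny maximum-likelihood mutation-rate estimation.

The number of mutations on a lineage of ``t`` generations is modelled as
Poisson with mean ``mu * t`` (reversions neglected: over the few hundred
generations observed at plausible rates, back-mutation to the exact
ancestral copy number is a second-order event).  With ``T0`` total
generations observed without any mutation and lineages of length ``t_j``
on which at least one mutation occurred, the log-likelihood is

    log L(mu) = -T0 * mu + sum_j log(1 - exp(-t_j * mu))

The "at least one mutation" terms use the exact ``1 - exp(-mu t)``
probability, never a single-event approximation.  Confidence intervals
invert the Wald acceptance region after reparameterising with
``lambda = log mu``; the likelihood is close to log-normal in shape and
the original scale is too skewed for the normal approximation.  On the
log scale the observed information at the MLE is analytic:

    I(lambda_hat) = mu_hat^2 * sum_j t_j^2 e^{t_j mu} / (e^{t_j mu} - 1)^2

(the ``-T0 mu`` term drops out because the score vanishes at the MLE),
and the interval ``exp(lambda_hat +/- z / sqrt(I))`` is log-symmetric
about the MLE by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from .lineages import FounderGroup, GenerationCounts, aggregate_generation_counts

__all__ = [
    "MleResult",
    "log_likelihood",
    "fit_mle",
    "wald_ci_log",
    "fit",
    "sensitivity_over_age_ci",
    "DEFAULT_BRACKET",
]

#: Default search bracket in mutations per generation: wide enough for any
#: plausible satellite locus.
DEFAULT_BRACKET = (1e-8, 1.0)


@dataclass(frozen=True)
class MleResult:
    """Maximum-likelihood mutation rate with a log-scale Wald interval."""

    mu_hat: float
    loglik_max: float
    ci_lower: float
    ci_upper: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if not (0 < self.ci_lower <= self.mu_hat <= self.ci_upper):
            raise ValueError("interval must satisfy 0 < lower <= mu_hat <= upper")
        if not math.isfinite(self.loglik_max):
            raise ValueError("log-likelihood at the MLE must be finite")


def log_likelihood(mu: float, counts: GenerationCounts) -> float:
    """Log-likelihood of the generation counts at rate ``mu``.

    Evaluated as ``-T0*mu + sum log(-expm1(-t*mu))`` so that lineage terms
    stay accurate when ``t*mu`` is small.
    """
    if mu <= 0:
        raise ValueError("mu must be > 0")
    ll = -counts.t0_total * mu
    for t in counts.mutated_lineages:
        ll += math.log(-math.expm1(-t * mu))
    return ll


def _score(mu: float, counts: GenerationCounts) -> float:
    """d log L / d mu = -T0 + sum_j t_j / (exp(t_j mu) - 1)."""
    s = -float(counts.t0_total)
    for t in counts.mutated_lineages:
        s += t / math.expm1(t * mu)
    return s


def fit_mle(
    counts: GenerationCounts, bracket: tuple[float, float] = DEFAULT_BRACKET
) -> float:
    """Maximize the log-likelihood over ``mu`` in ``bracket``.

    The score is strictly decreasing in ``mu`` (each lineage term is), so
    the interior maximum is the unique root of the score, found by Brent
    bracketing to relative tolerance 1e-12.  Without any mutated lineage
    the likelihood is monotone decreasing and has no interior maximum.
    """
    lo, hi = bracket
    if not (0 < lo < hi):
        raise ValueError("bracket must satisfy 0 < lo < hi")
    if not counts.mutated_lineages:
        raise ValueError(
            "no mutated lineages: likelihood is monotone in mu, MLE undefined"
        )
    s_lo, s_hi = _score(lo, counts), _score(hi, counts)
    if s_lo <= 0:  # maximum at or below the lower edge
        return lo
    if s_hi >= 0:
        return hi
    return float(
        optimize.brentq(_score, lo, hi, args=(counts,), rtol=1e-12, maxiter=200)
    )


def _observed_information_log(mu_hat: float, counts: GenerationCounts) -> float:
    """Observed information of lambda = log(mu) at the MLE (analytic)."""
    info = 0.0
    for t in counts.mutated_lineages:
        em1 = math.expm1(t * mu_hat)
        info += t * t * (em1 + 1.0) / (em1 * em1)
    return mu_hat * mu_hat * info


def wald_ci_log(
    counts: GenerationCounts, mu_hat: float, level: float = 0.95
) -> tuple[float, float]:
    """Wald interval for the rate on the log scale, back-transformed.

    ``exp(log mu_hat +/- z * I(lambda_hat)^(-1/2))``, hence log-symmetric:
    ``sqrt(lower * upper) == mu_hat`` up to rounding.
    """
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    info = _observed_information_log(mu_hat, counts)
    if not (math.isfinite(info) and info > 0):
        raise ValueError(f"non-finite or non-positive observed information: {info}")
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    half = z / math.sqrt(info)
    lam = math.log(mu_hat)
    return math.exp(lam - half), math.exp(lam + half)


def fit(
    counts: GenerationCounts,
    bracket: tuple[float, float] = DEFAULT_BRACKET,
    level: float = 0.95,
) -> MleResult:
    """Fit the MLE and its Wald interval in one call."""
    mu_hat = fit_mle(counts, bracket)
    lo, hi = wald_ci_log(counts, mu_hat, level)
    return MleResult(
        mu_hat=mu_hat,
        loglik_max=log_likelihood(mu_hat, counts),
        ci_lower=lo,
        ci_upper=hi,
        level=level,
    )


def sensitivity_over_age_ci(
    groups: Sequence[FounderGroup],
    bracket: tuple[float, float] = DEFAULT_BRACKET,
    level: float = 0.95,
) -> tuple[float, float]:
    """Envelope of the rate interval over the MRCA-age confidence bounds.

    The MRCA ages are themselves estimates; the generation counts are
    rebuilt twice — every group's age at its upper CI bound (maximum
    exposure, smallest rate) and every age at its lower bound (minimum
    exposure, largest rate) — the MLE and Wald interval are refit for
    each, and the envelope (smallest lower bound, largest upper bound) is
    returned.
    """

    def rebuilt(which: int) -> list[FounderGroup]:
        out = []
        for g in groups:
            if g.g_mrca is None:
                if len(g.families) > 1:
                    raise ValueError(f"group {g.mutation_id}: missing MRCA age")
                out.append(g)
                continue
            if g.g_ci is None:
                raise ValueError(f"group {g.mutation_id}: missing age CI")
            out.append(g.with_age(g.g_ci[which]))
        return out

    results = []
    for which in (0, 1):
        counts = aggregate_generation_counts(rebuilt(which))
        results.append(fit(counts, bracket, level))
    return min(r.ci_lower for r in results), max(r.ci_upper for r in results)
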