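"""Stepwise-mutation-model estimators of theta = 4*Ne*mu.

Two moment-style estimators of the population-scaled mutation parameter of
a satellite locus, both assuming the one-step stepwise mutation model
(SMM) at mutation-drift equilibrium:

* from the mean allele frequency ``x_bar`` (which for a sample with
  ``n_A`` distinct alleles is exactly ``1/n_A``):

      theta_xbar = 1 / (8 * x_bar^2) - 1/2

* from the number of distinct alleles ``n_A``, by inverting a
  simulation-calibrated expectation

      n_A = (c0 + c1*ln(theta) + c2*ln(theta)^2) * sqrt(1 + 2*theta)

  with sample-size-specific coefficients; the table shipped here carries
  the n = 500 calibration (c0 = 2.0357, c1 = -0.07910, c2 = -0.00007).

Both estimators are reasonably robust to multistep mutation, which real
macrosatellites clearly exhibit, but they can disagree substantially when
the one-step assumption is badly violated; they are intended for
order-of-magnitude comparison against a direct rate estimate via
``theta = 4*Ne*mu``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "AlleleSpectrum",
    "SmmCoefficients",
    "HAASL_PAYSEUR_COEFFICIENTS",
    "spectrum_summary",
    "theta_from_mean_freq",
    "expected_num_alleles",
    "theta_from_num_alleles",
    "scaled_mutation",
    "read_spectrum_tsv",
]

#: Root-finding bracket for inverting the expected-allele-count equation.
THETA_BRACKET = (1e-3, 1e7)


@dataclass(frozen=True)
class AlleleSpectrum:
    """Observed allele-size spectrum: size (repeat units) -> count."""

    counts: dict[int, int]
    n: int

    def __post_init__(self) -> None:
        counts = {int(k): int(v) for k, v in self.counts.items()}
        if not counts:
            raise ValueError("empty allele spectrum")
        if any(v < 1 for v in counts.values()):
            raise ValueError("all allele counts must be >= 1")
        if sum(counts.values()) != self.n:
            raise ValueError(
                f"allele counts sum to {sum(counts.values())}, expected n = {self.n}"
            )
        if self.n < 2:
            raise ValueError("haploid sample size must be >= 2")
        object.__setattr__(self, "counts", counts)


@dataclass(frozen=True)
class SmmCoefficients:
    """Regression coefficients of the expected-allele-count equation,
    calibrated by simulation for a particular haploid sample size."""

    c0: float
    c1: float
    c2: float
    calibrated_n: int

    def __post_init__(self) -> None:
        if self.calibrated_n <= 0:
            raise ValueError("calibrated_n must be > 0")


#: Published calibrations, keyed by haploid sample size.
HAASL_PAYSEUR_COEFFICIENTS: dict[int, SmmCoefficients] = {
    500: SmmCoefficients(c0=2.0357, c1=-0.07910, c2=-0.00007, calibrated_n=500),
}


def spectrum_summary(spectrum: AlleleSpectrum) -> tuple[int, float]:
    """Number of distinct alleles and mean allele frequency.

    The mean of the per-allele sample frequencies is exactly ``1/n_A``
    because the frequencies sum to 1; it is computed from the counts and
    checked against that identity.
    """
    n_a = len(spectrum.counts)
    x_bar = float(np.mean([c / spectrum.n for c in spectrum.counts.values()]))
    assert abs(x_bar * n_a - 1.0) < 1e-9
    return n_a, x_bar


def theta_from_mean_freq(x_bar: float) -> float:
    """theta estimate from the mean allele frequency: 1/(8 x_bar^2) - 1/2."""
    if not (0 < x_bar <= 1):
        raise ValueError("x_bar must be in (0, 1]")
    return 1.0 / (8.0 * x_bar * x_bar) - 0.5


def expected_num_alleles(theta: float, coeffs: SmmCoefficients) -> float:
    """Calibrated SMM expectation of the number of distinct alleles."""
    if theta <= 0:
        raise ValueError("theta must be > 0")
    lt = math.log(theta)
    return (coeffs.c0 + coeffs.c1 * lt + coeffs.c2 * lt * lt) * math.sqrt(
        1.0 + 2.0 * theta
    )


def theta_from_num_alleles(
    n_a: int,
    coeffs: SmmCoefficients,
    bracket: tuple[float, float] = THETA_BRACKET,
) -> float:
    """theta estimate from the distinct-allele count, by root solving.

    The calibrated expectation is increasing in theta except at the very
    bottom of the bracket, where the log-polynomial factor dominates and
    the curve turns up again as theta -> 0 (a region far outside the
    calibration's intent).  The root is therefore taken on the increasing
    branch: monotonicity is verified on a log grid from the curve's
    minimum to the top of the bracket before solving.
    """
    if n_a < 2:
        raise ValueError("need n_A >= 2")
    lo, hi = bracket

    grid = np.exp(np.linspace(math.log(lo), math.log(hi), 400))
    values = np.array([expected_num_alleles(t, coeffs) for t in grid])
    i_min = int(np.argmin(values))
    if not np.all(np.diff(values[i_min:]) > 0):
        raise ValueError(
            f"expected allele count is not monotone above its minimum on "
            f"bracket {bracket}; inverse is ill-defined"
        )
    lo_eff = float(grid[i_min])

    def f(theta: float) -> float:
        return expected_num_alleles(theta, coeffs) - n_a

    f_lo, f_hi = f(lo_eff), f(hi)
    if f_lo * f_hi > 0:
        raise ValueError(
            f"no sign change of expected_num_alleles - {n_a} on bracket "
            f"[{lo_eff:.3g}, {hi}] (f({lo_eff:.3g}) = {f_lo:.3g}, "
            f"f({hi}) = {f_hi:.3g})"
        )
    return float(optimize.brentq(f, lo_eff, hi, rtol=1e-10, maxiter=200))


def scaled_mutation(n_e: float, mu: float) -> float:
    """Population-scaled mutation parameter theta = 4 * Ne * mu."""
    if n_e <= 0:
        raise ValueError("n_e must be > 0")
    if mu < 0:
        raise ValueError("mu must be >= 0")
    return 4.0 * n_e * mu


def coefficients_for(
    n: int, table: Mapping[int, SmmCoefficients] = HAASL_PAYSEUR_COEFFICIENTS
) -> SmmCoefficients:
    """Pick the calibration closest to sample size ``n``.

    A mismatch beyond 20% warns rather than errors: the calibrations vary
    slowly in n and applying the n = 500 row to, say, n = 504 is standard
    practice.
    """
    best = min(table.values(), key=lambda c: abs(c.calibrated_n - n))
    if abs(best.calibrated_n - n) > 0.2 * best.calibrated_n:
        warnings.warn(
            f"sample size {n} differs from closest calibration "
            f"(n = {best.calibrated_n}) by more than 20%",
            stacklevel=2,
        )
    return best


def read_spectrum_tsv(path: str | Path, n: int | None = None) -> AlleleSpectrum:
    """Read an allele spectrum TSV with columns allele_size, count.

    If ``n`` is omitted it is taken as the sum of counts.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"allele_size", "count"} <= set(df.columns):
        raise ValueError(f"spectrum file {path} needs columns allele_size, count")
    counts = {int(r.allele_size): int(r.count) for r in df.itertuples()}
    if len(counts) != len(df):
        raise ValueError(f"spectrum file {path} has duplicate allele sizes")
    total = sum(counts.values())
    return AlleleSpectrum(counts=counts, n=total if n is None else n)
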