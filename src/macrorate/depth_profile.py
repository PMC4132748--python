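"""Copy-number genotyping of a macrosatellite array from read depth.

The diploid copy number of a tandem-repeat array can be read off short-read
data without assembly: reads from every repeat unit pile up on the single
unit present in the reference, so the mean depth of coverage (DOC) over the
unit scales with the total number of units in the genome.  Dividing the
unit DOC by the genome-wide DOC and doubling gives the DOC-estimated
diploid copy number (DCN):

    DCN = 2 * unit_DOC / genome_DOC

This module computes unit DOC from per-base depth tracks (``samtools
mpileup``-style three-column text), derives DCN per sample, and provides
the two validation statistics used to qualify the approach: an ordinary
least-squares r² against an orthogonal truth set (e.g. fiber-FISH counts)
and a Kruskal-Wallis rank test for copy-number differences between
populations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import Interval

__all__ = [
    "DepthTrack",
    "DcnEstimate",
    "interval_doc",
    "genome_doc_from_mapped_bases",
    "estimate_dcn",
    "regression_r2",
    "kruskal_wallis",
    "kruskal_wallis_pvalue",
    "read_depth_track",
    "read_manifest",
    "linear_recalibration",
]


@dataclass(frozen=True)
class DepthTrack:
    """Per-base read depths over a 1-based inclusive genomic interval."""

    contig: str
    start: int
    end: int
    depths: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        depths = np.asarray(self.depths, dtype=np.int64)
        if depths.ndim != 1 or len(depths) != self.end - self.start + 1:
            raise ValueError(
                f"depth array length {len(depths)} does not match interval "
                f"length {self.end - self.start + 1}"
            )
        if (depths < 0).any():
            raise ValueError("negative depth encountered")
        object.__setattr__(self, "depths", depths)

    @property
    def interval(self) -> Interval:
        return Interval(self.contig, self.start, self.end)


@dataclass(frozen=True)
class DcnEstimate:
    """DOC-estimated diploid copy number for one sample."""

    sample_id: str
    unit_doc: float
    genome_doc: float
    dcn: float

    def __post_init__(self) -> None:
        if self.unit_doc < 0:
            raise ValueError("unit_doc must be >= 0")
        if self.genome_doc <= 0:
            raise ValueError("genome_doc must be > 0")


def interval_doc(track: DepthTrack, query_start: int, query_end: int) -> float:
    """Mean depth over ``[query_start, query_end]`` (1-based inclusive).

    Zero-depth positions inside the query count toward the mean; the query
    must lie entirely within the track.
    """
    if query_start > query_end:
        raise ValueError(f"query start {query_start} > end {query_end}")
    if query_start < track.start or query_end > track.end:
        raise ValueError(
            f"query {query_start}-{query_end} outside track "
            f"{track.contig}:{track.start}-{track.end}"
        )
    lo = query_start - track.start
    hi = query_end - track.start + 1
    return float(np.mean(track.depths[lo:hi]))


def genome_doc_from_mapped_bases(total_mapped_bases: float, genome_length: float) -> float:
    """Genome-wide mean depth from a mapped-base total and reference length."""
    if genome_length <= 0:
        raise ValueError("genome_length must be > 0")
    if total_mapped_bases < 0:
        raise ValueError("total_mapped_bases must be >= 0")
    return total_mapped_bases / genome_length


def estimate_dcn(sample_id: str, unit_doc: float, genome_doc: float) -> DcnEstimate:
    """DOC-estimated diploid copy number: ``2 * unit_doc / genome_doc``."""
    if genome_doc <= 0:
        raise ValueError("genome_doc must be > 0")
    return DcnEstimate(
        sample_id=sample_id,
        unit_doc=unit_doc,
        genome_doc=genome_doc,
        dcn=2.0 * unit_doc / genome_doc,
    )


def regression_r2(pairs: Sequence[tuple[float, float]]) -> tuple[float, float, float]:
    """Ordinary least-squares fit of y on x.

    Returns ``(r_squared, slope, intercept)``.  Used to quantify agreement
    between DCN and an independent count of the same arrays.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    x = np.asarray([p[0] for p in pairs], dtype=float)
    y = np.asarray([p[1] for p in pairs], dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("x values are degenerate (all equal)")
    if np.allclose(y, y[0]):
        # no variance to explain; slope 0 fit
        return 0.0, 0.0, float(y[0])
    fit = stats.linregress(x, y)
    return float(fit.rvalue**2), float(fit.slope), float(fit.intercept)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, int]:
    """Kruskal-Wallis H with tie correction; returns ``(H, df)``.

    df = number of groups - 1.  The p-value from the chi-squared tail is
    available via :func:`kruskal_wallis_pvalue`.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("empty group")
    h, _ = stats.kruskal(*arrays)
    return float(h), len(groups) - 1


def kruskal_wallis_pvalue(h: float, df: int) -> float:
    """Chi-squared tail probability for a Kruskal-Wallis H statistic."""
    return float(stats.chi2.sf(h, df))


def read_depth_track(
    path: str | Path, interval: Interval, *, contig: str | None = None
) -> DepthTrack:
    """Read a three-column depth file (contig, 1-based position, depth).

    Positions within ``interval`` that are absent from the file are filled
    with depth 0, since pileup tools omit zero-coverage positions.  Rows on
    other contigs or outside the interval are ignored.
    """
    want = contig if contig is not None else interval.contig
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["contig", "pos", "depth"],
        dtype={"contig": str, "pos": np.int64, "depth": np.int64},
        comment="#",
    )
    df = df[(df["contig"] == want) & df["pos"].between(interval.start, interval.end)]
    depths = np.zeros(interval.length, dtype=np.int64)
    depths[df["pos"].to_numpy() - interval.start] = df["depth"].to_numpy()
    return DepthTrack(interval.contig, interval.start, interval.end, depths)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a sample manifest TSV: sample_id, depth_file, mapped_bases."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "depth_file": str})
    required = {"sample_id", "depth_file", "mapped_bases"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    return df


def linear_recalibration(
    truth_pairs: Sequence[tuple[float, float]]
) -> tuple[float, float]:
    """Fit an optional linear DCN recalibration from (dcn, truth) pairs.

    Returns ``(slope, intercept)`` mapping raw DCN to calibrated copy
    number.  Off by default in all pipelines: raw DCN is reported unless a
    truth set is supplied.
    """
    if len(truth_pairs) < 2:
        raise ValueError("need at least 2 truth pairs")
    x = np.asarray([p[0] for p in truth_pairs], dtype=float)
    y = np.asarray([p[1] for p in truth_pairs], dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("degenerate truth pairs")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)
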