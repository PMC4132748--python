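"""Named genomic intervals and shared defaults.

Coordinates are 1-based inclusive, matching pileup output.  The repeat-unit
interval is the RepeatMasker-clean portion of the RNU2 6.1 kb unit on the
hs37d5 decoy contig; the right-junction interval is single-copy flanking
sequence on chromosome 17 and serves as a negative control (its depth should
track the genome-wide mean).
"""

from __future__ import annotations

from typing import NamedTuple


class Interval(NamedTuple):
    contig: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive

    @property
    def length(self) -> int:
        return self.end - self.start + 1


#: RNU2 repeat-unit interval used for depth-of-coverage copy-number calls.
RNU2_REPEAT_UNIT = Interval("hs37d5", 7_361_154, 7_366_066)

#: Single-copy right junction of the RNU2 array (control interval).
RNU2_RIGHT_JUNCTION = Interval("17", 41_400_862, 41_401_838)

NAMED_INTERVALS: dict[str, Interval] = {
    "repeat_unit": RNU2_REPEAT_UNIT,
    "right_junction": RNU2_RIGHT_JUNCTION,
}

#: Default haploid reference length used to turn mapped-base totals into a
#: genome-wide mean depth.  This is a configuration value, not a constant of
#: the method: pass the length of whatever reference set the reads were
#: mapped to (with or without unplaced/decoy contigs) and record it.
DEFAULT_GENOME_LENGTH = 3_100_000_000

#: Standard-normal quantile for a 95% two-sided interval (not rounded).
Z_95 = 1.959964


def parse_region(text: str) -> Interval:
    """Parse ``contig:start-end`` (1-based inclusive) or a named interval."""
    if text in NAMED_INTERVALS:
        return NAMED_INTERVALS[text]
    try:
        contig, span = text.rsplit(":", 1)
        lo, hi = span.replace(",", "").split("-")
        iv = Interval(contig, int(lo), int(hi))
    except ValueError as exc:
        raise ValueError(f"cannot parse region {text!r}; expected contig:start-end") from exc
    if iv.start > iv.end:
        raise ValueError(f"region {text!r} has start > end")
    return iv
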