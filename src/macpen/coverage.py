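"""Read accounting and sample-level sequencing QC.

The capture design tiles each target nucleotide with several overlapping
smMIPs (single-molecule molecular inversion probes; eight per nucleotide on
average in this panel), so per-nucleotide fold coverage is the per-probe
average coverage multiplied by the probes-per-nucleotide tiling factor.
Mapped-read counts come from paired-end sequencing: forward plus reverse
reads, divided by two.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

DEFAULT_SMMIPS_PER_NT = 8
#: No coverage floor is published for this assay; 10x per smMIP is this
#: package's configurable default.
DEFAULT_MIN_AVG_COVERAGE = 10.0


@dataclass(frozen=True)
class SampleReadStats:
    sample_id: str
    forward_reads: int
    reverse_reads: int
    avg_smmips_coverage: float
    qc_pass: bool

    @property
    def mapped_reads(self) -> int:
        return mapped_read_count(self.forward_reads, self.reverse_reads)


def mapped_read_count(forward: int, reverse: int) -> int:
    """Mapped read pairs: (forward + reverse) / 2, rounded half-up to integer."""
    if forward < 0 or reverse < 0:
        raise ValueError("read counts must be non-negative")
    exact = Decimal(forward + reverse) / 2  # exact: denominator is 2
    return int(exact.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def per_nucleotide_coverage(
    avg_smmips_coverage: float, smmips_per_nt: float = DEFAULT_SMMIPS_PER_NT
) -> float:
    """Estimated fold coverage per nucleotide: probe coverage x tiling factor."""
    if avg_smmips_coverage < 0 or smmips_per_nt < 0:
        raise ValueError("inputs must be non-negative")
    return avg_smmips_coverage * smmips_per_nt


def sample_qc(
    stats: SampleReadStats | float, min_avg_coverage: float = DEFAULT_MIN_AVG_COVERAGE
) -> bool:
    """Pass iff average per-smMIP coverage reaches the floor.

    Failed samples get a failed verdict downstream and are excluded from the
    diagnostic-yield denominator.
    """
    coverage = (
        stats.avg_smmips_coverage if isinstance(stats, SampleReadStats) else stats
    )
    return coverage >= min_avg_coverage


def make_read_stats(
    sample_id: str,
    forward_reads: int,
    reverse_reads: int,
    avg_smmips_coverage: float,
    min_avg_coverage: float = DEFAULT_MIN_AVG_COVERAGE,
) -> SampleReadStats:
    return SampleReadStats(
        sample_id=sample_id,
        forward_reads=forward_reads,
        reverse_reads=reverse_reads,
        avg_smmips_coverage=avg_smmips_coverage,
        qc_pass=sample_qc(avg_smmips_coverage, min_avg_coverage),
    )
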