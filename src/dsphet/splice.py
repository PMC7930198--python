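"""AR-V7 quantification from spliced alignment records.

The AR-V7 transcript includes cryptic exon 3 (CE3); spliced reads bridging
the exon 3 -> CE3 junction appear in alignments as a gap (CIGAR N skip, or a
long deletion) whose skipped interval lies inside chrX:67686127-67694672.
The statistic is the number of distinct reads carrying such a gap, normalized
to spliced reads per million (SRPM) by the total aligned read count.
"""

from __future__ import annotations

import dataclasses
import re
from typing import Iterable

from .io import AlignmentRecord

__all__ = [
    "JunctionInterval", "AR_V7_JUNCTION", "JunctionCount",
    "alignment_gaps", "count_junction_spanning_reads", "srpm_normalize",
]

# a deletion this long or longer is treated like an N skip (a splice-type gap)
MIN_DELETION_GAP = 20

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


@dataclasses.dataclass(frozen=True)
class JunctionInterval:
    """1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    @classmethod
    def parse(cls, text: str) -> "JunctionInterval":
        """Parse ``chrom:start-end`` (1-based inclusive)."""
        m = re.fullmatch(r"([^:]+):(\d+)-(\d+)", text.strip())
        if not m:
            raise ValueError(f"cannot parse interval {text!r}")
        return cls(m.group(1), int(m.group(2)), int(m.group(3)))


AR_V7_JUNCTION = JunctionInterval("chrX", 67_686_127, 67_694_672)


@dataclasses.dataclass
class JunctionCount:
    """Junction-spanning read count plus a malformed-record tally."""

    count: int
    n_records: int
    n_skipped: int
    read_ids: frozenset[str]


def alignment_gaps(record: AlignmentRecord,
                   min_deletion: int = MIN_DELETION_GAP) -> list[tuple[int, int]]:
    """Splice-type gaps of a record as 1-based inclusive (first, last) skipped
    reference positions. Raises ValueError on a malformed CIGAR."""
    matched = _CIGAR_RE.findall(record.cigar)
    if not matched or "".join(f"{n}{op}" for n, op in matched) != record.cigar:
        raise ValueError(f"malformed CIGAR {record.cigar!r}")
    gaps: list[tuple[int, int]] = []
    ref = record.pos
    aligned_ref = 0
    for length_s, op in matched:
        length = int(length_s)
        if op in "M=X":
            ref += length
            aligned_ref += length
        elif op == "N" or (op == "D" and length >= min_deletion):
            gaps.append((ref, ref + length - 1))
            ref += length
        elif op == "D":
            ref += length
        # I, S, H, P consume no reference
    if aligned_ref == 0:
        raise ValueError(f"CIGAR {record.cigar!r} aligns no reference bases")
    return gaps


def count_junction_spanning_reads(records: Iterable[AlignmentRecord],
                                  junction: JunctionInterval = AR_V7_JUNCTION,
                                  min_deletion: int = MIN_DELETION_GAP
                                  ) -> JunctionCount:
    """Count distinct reads with a gap lying entirely within the junction interval.

    A record counts iff it is on the junction chromosome and has at least one
    splice-type gap whose first and last skipped positions both fall inside
    [start, end]. Reads are deduplicated by read id (paired-end mates count
    once); malformed records are skipped and tallied.
    """
    hits: set[str] = set()
    n_records = 0
    n_skipped = 0
    for rec in records:
        n_records += 1
        if rec.chrom != junction.chrom:
            continue
        try:
            gaps = alignment_gaps(rec, min_deletion=min_deletion)
        except ValueError:
            n_skipped += 1
            continue
        for g_start, g_end in gaps:
            if junction.contains(g_start) and junction.contains(g_end):
                hits.add(rec.qname)
                break
    return JunctionCount(count=len(hits), n_records=n_records,
                         n_skipped=n_skipped, read_ids=frozenset(hits))


def srpm_normalize(junction_count: int, total_aligned_reads: int) -> float:
    """Spliced reads per million: junction count / (total aligned reads / 1e6)."""
    if total_aligned_reads <= 0:
        raise ValueError("total_aligned_reads must be positive")
    if junction_count < 0:
        raise ValueError("junction_count must be non-negative")
    return junction_count / (total_aligned_reads / 1_000_000.0)
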