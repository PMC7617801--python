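"""RNA evidence helpers: allele balance and normalized intron coverage.

These reproduce the arithmetic used when inspecting RNA-seq over a candidate
pair: the fraction of reads carrying the alternate allele at a coding variant
(depressed when the allele is degraded by nonsense-mediated decay), and
per-intron read coverage normalized by total gene read count, flagging a
sample whose coverage strictly exceeds every comparison sample for an intron
(suggestive of intron retention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class IntronCoverageRow:
    sample_id: str
    intron_index: int
    intron_read_count: int
    gene_total_reads: int

    def __post_init__(self) -> None:
        if self.intron_read_count < 0 or self.gene_total_reads < 0:
            raise ValueError("read counts must be non-negative")


@dataclass(frozen=True)
class IntronCoverageResult:
    sample_id: str
    intron_index: int
    normalized: float
    outlier: bool


def allele_balance(ref_reads: int, alt_reads: int) -> tuple[float, int]:
    """Alternate-allele fraction and its percent rounded to nearest integer."""
    total = ref_reads + alt_reads
    if total <= 0:
        raise ValueError("allele balance undefined with zero reads")
    frac = alt_reads / total
    pct_exact = Decimal(100 * alt_reads) / Decimal(total)
    pct = int(pct_exact.quantize(Decimal(1), rounding=ROUND_HALF_UP))
    return frac, pct


def normalized_intron_coverage(
    rows: Sequence[IntronCoverageRow],
) -> list[IntronCoverageResult]:
    """Normalize per-intron coverage and flag strict-maximum outliers.

    The normalized value is intron_read_count / gene_total_reads.  For each
    intron, a sample is flagged when its value strictly exceeds every other
    sample's value for that intron (so ties at the maximum flag nobody, and
    at most one sample is flagged per intron).  Rows with zero gene total
    reads are excluded with a warning.
    """
    usable = []
    for r in rows:
        if r.gene_total_reads == 0:
            log.warning("sample %s intron %d: zero gene total reads; row excluded",
                        r.sample_id, r.intron_index)
            continue
        usable.append(r)

    values = {
        (r.sample_id, r.intron_index): r.intron_read_count / r.gene_total_reads
        for r in usable
    }
    by_intron: dict[int, list[tuple[str, float]]] = {}
    for (sid, idx), v in values.items():
        by_intron.setdefault(idx, []).append((sid, v))

    out = []
    for r in usable:
        v = values[(r.sample_id, r.intron_index)]
        others = [w for sid, w in by_intron[r.intron_index] if sid != r.sample_id]
        outlier = bool(others) and all(v > w for w in others)
        out.append(IntronCoverageResult(r.sample_id, r.intron_index, v, outlier))
    return out
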