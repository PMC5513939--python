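"""Read counting over miRNA loci, RPM normalization, expression filtering.

A read is assigned to a locus only if it is mapped, perfectly aligned
(edit distance 0), on the same strand, and fully contained in the locus
interval.  Reads contained in more than one locus count once per containing
locus (logged as ambiguous).  RPM scales each sample so its column sums to
one million; by default the denominator is the total assigned to miRNA loci
in that sample, with externally supplied totals as an alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import AlignmentRecord, MiRNALocus

logger = logging.getLogger(__name__)

__all__ = [
    "AssignmentResult",
    "assign_reads",
    "counts_to_table",
    "rpm_normalize",
    "mean_rpm_filter",
    "validate_counts",
]

RPM_SCALE = 1_000_000.0


@dataclass(frozen=True)
class AssignmentResult:
    """One sample's locus counts plus assignment bookkeeping."""

    counts: pd.Series          # indexed by mirna_id, integer
    n_alignments: int
    n_eligible: int            # mapped, perfect alignments
    n_assigned: int            # eligible reads contained in >= 1 locus
    n_ambiguous: int           # assigned reads contained in > 1 locus
    n_unassigned: int          # eligible reads contained in no locus


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Check a miRNA x sample count table (non-negative integers)."""
    arr = counts.to_numpy()
    if arr.size and (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if arr.size and not np.allclose(arr, np.rint(arr)):
        raise ValueError("counts must be integral")
    if counts.index.duplicated().any():
        raise ValueError("duplicate miRNA ids in count table")
    return counts


def assign_reads(
    alignments: Iterable[AlignmentRecord], loci: Sequence[MiRNALocus]
) -> AssignmentResult:
    """Count reads over miRNA loci for one sample.

    Assignment requires mapped, edit distance 0, same strand and full
    containment of the read interval in the locus interval.
    """
    ids = [loc.mirna_id for loc in loci]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate mirna_id in loci")
    counts = {mid: 0 for mid in ids}
    by_chrom: dict[tuple[str, str], list[MiRNALocus]] = {}
    for loc in loci:
        by_chrom.setdefault((loc.chrom, loc.strand), []).append(loc)

    n_total = n_eligible = n_assigned = n_ambiguous = n_unassigned = 0
    for rec in alignments:
        n_total += 1
        if not rec.mapped or rec.edit_distance != 0:
            continue
        n_eligible += 1
        hits = [
            loc
            for loc in by_chrom.get((rec.chrom, rec.strand), ())
            if loc.start <= rec.start and rec.end <= loc.end
        ]
        if not hits:
            n_unassigned += 1
            continue
        n_assigned += 1
        if len(hits) > 1:
            n_ambiguous += 1
        for loc in hits:
            counts[loc.mirna_id] += 1
    if n_ambiguous:
        logger.info("assign_reads: %d read(s) contained in multiple loci", n_ambiguous)
    return AssignmentResult(
        counts=pd.Series(counts, dtype=int),
        n_alignments=n_total,
        n_eligible=n_eligible,
        n_assigned=n_assigned,
        n_ambiguous=n_ambiguous,
        n_unassigned=n_unassigned,
    )


def counts_to_table(columns: Mapping[str, pd.Series]) -> pd.DataFrame:
    """Stack per-sample count columns (sample_id -> Series) into one table."""
    table = pd.DataFrame(columns).fillna(0).astype(int)
    table.index.name = "mirna_id"
    return validate_counts(table)


def rpm_normalize(
    counts: pd.DataFrame, totals: Mapping[str, float] | None = None
) -> pd.DataFrame:
    """Reads-per-million: rpm[i, s] = counts[i, s] / total_s * 1e6.

    ``total_s`` defaults to the column sum (reads assigned to miRNA loci in
    sample ``s``); pass ``totals`` to normalize against externally supplied
    library sizes instead.  A sample with zero total yields an all-zero
    column with a warning.
    """
    validate_counts(counts)
    if totals is None:
        denom = counts.sum(axis=0).astype(float)
    else:
        denom = pd.Series({s: float(totals[s]) for s in counts.columns})
    zero = denom == 0
    if zero.any():
        logger.warning(
            "rpm_normalize: zero-total sample(s) %s left all-zero",
            list(denom.index[zero]),
        )
    safe = denom.replace(0, np.nan)
    rpm = counts.div(safe, axis=1).mul(RPM_SCALE).fillna(0.0)
    return rpm


def mean_rpm_filter(rpm: pd.DataFrame, threshold: float = 5.0) -> set[str]:
    """miRNAs whose mean RPM over all samples is strictly above ``threshold``.

    The mean pools every sample of the dataset (cases and controls alike);
    a mean of exactly ``threshold`` is excluded.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    means = rpm.mean(axis=1)
    return set(rpm.index[means > threshold])
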