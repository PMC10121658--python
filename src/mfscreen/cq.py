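"""The chromosome-quotient statistic and the male-specificity filter.

The chromosome quotient (CQ) of a reference sequence is the ratio of female
to male genomic alignment counts, optionally normalized by library size:

    CQ = (F / N_F) / (M / N_M)

where M, F are the alignment counts of male and female whole-genome reads
against the sequence and N_M, N_F the library totals.  A sequence present
only in the male genome (hemizygous, M-linked) attracts essentially no
female alignments, so its CQ sits near 0; autosomal sequences sit near 1;
sequences with female dosage bias (e.g. on a differentiated X) near 2.

The screen's first gate keeps references with CQ < 0.2, male count > 20 and
female count < 20 — all comparisons strict.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .io import CountTable

__all__ = ["CQRecord", "CQFilterParams", "compute_cq", "compute_cq_table",
           "apply_cq_filter"]

#: Sentinel for a CQ that cannot be formed (zero male coverage).
UNDEFINED = float("nan")


@dataclass(frozen=True)
class CQRecord:
    ref_id: str
    male_count: int
    female_count: int
    cq: float  # NaN when male_count == 0
    depth_normalized: bool

    @property
    def defined(self) -> bool:
        return not math.isnan(self.cq)


@dataclass(frozen=True)
class CQFilterParams:
    """Thresholds of the male-specificity gate; comparisons are strict."""

    cq_max: float = 0.2
    male_min: int = 20
    female_max: int = 20

    def __post_init__(self) -> None:
        if self.cq_max <= 0:
            raise ValueError("cq_max must be > 0")
        if self.male_min < 0 or self.female_max < 0:
            raise ValueError("count thresholds must be >= 0")


def compute_cq(
    male_count: int,
    female_count: int,
    male_total: int | None = None,
    female_total: int | None = None,
    normalize: bool = True,
    ref_id: str = "",
) -> CQRecord:
    """Compute the chromosome quotient for one reference.

    With ``normalize`` the counts are scaled to per-library proportions
    first, making the statistic invariant to sequencing depth.  A zero male
    count leaves the quotient undefined (NaN); such a record can never pass
    the filter (it also fails the male-count clause).
    """
    if male_count < 0 or female_count < 0:
        raise ValueError("counts must be non-negative")
    if normalize:
        if not male_total or not female_total or male_total <= 0 or female_total <= 0:
            raise ValueError("positive library totals required when normalize=True")
        if male_count == 0:
            cq = UNDEFINED
        else:
            cq = (female_count / female_total) / (male_count / male_total)
    else:
        cq = UNDEFINED if male_count == 0 else female_count / male_count
    return CQRecord(ref_id, male_count, female_count, cq, normalize)


def compute_cq_table(table: CountTable, normalize: bool = True) -> list[CQRecord]:
    """Vector form of :func:`compute_cq` over a whole count table."""
    return [
        compute_cq(
            int(row.male_count),
            int(row.female_count),
            table.male_total,
            table.female_total,
            normalize=normalize,
            ref_id=str(row.Index),
        )
        for row in table.counts.itertuples()
    ]


def apply_cq_filter(
    records: list[CQRecord], params: CQFilterParams | None = None
) -> pd.DataFrame:
    """Evaluate the three strict clauses per record.

    Returns a frame indexed by ref_id with columns ``male_count``,
    ``female_count``, ``cq``, ``pass`` and ``fail_reason`` (first failing
    clause, in the order: no male coverage, cq_max, male_min, female_max).
    """
    params = params or CQFilterParams()
    rows = []
    for rec in records:
        reasons = []
        if not rec.defined:
            reasons.append("no male coverage")
        elif not rec.cq < params.cq_max:
            reasons.append("cq_max")
        if not rec.male_count > params.male_min:
            reasons.append("male_min")
        if not rec.female_count < params.female_max:
            reasons.append("female_max")
        rows.append(
            {
                "id": rec.ref_id,
                "male_count": rec.male_count,
                "female_count": rec.female_count,
                "cq": rec.cq,
                "pass": not reasons,
                "fail_reason": ";".join(reasons),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["id", "male_count", "female_count", "cq", "pass", "fail_reason"],
    )
    return df.set_index("id")
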