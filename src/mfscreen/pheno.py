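"""Knockout-experiment summaries: feminization tallies, injection tables, ddCt.

Mosaic males produced by Cas9/sgRNA embryo injection are scored per
sexually-dimorphic tissue (antennae, maxillary palps, external genitalia,
gonads) as normal, feminized or malformed.  Percentages follow the
reporting conventions of such tables: integer percent for per-tissue
feminization, one decimal for hatch rate, two decimals for adult sex
ratios — all rounded half-up.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .io import TISSUES

__all__ = [
    "TissueSummary",
    "PhenoSummary",
    "InjectionSummary",
    "DdctMeasurement",
    "summarize_phenotypes",
    "summarize_injection",
    "mosaic_total",
    "fold_change_ddct",
]


def round_half_up(x: float, decimals: int = 0) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TissueSummary:
    tissue: str
    n_feminized: int
    n_malformed: int
    n_normal: int
    n_scored: int
    total: int  # individuals in the group

    @property
    def pct_feminized(self) -> int:
        return int(round_half_up(100 * self.n_feminized / self.total))

    @property
    def formatted(self) -> str:
        return f"{self.pct_feminized}% ({self.n_feminized}/{self.total})"


@dataclass(frozen=True)
class PhenoSummary:
    group: str
    total: int
    tissues: dict[str, TissueSummary]


def summarize_phenotypes(table: pd.DataFrame, group: str) -> PhenoSummary:
    """Per-tissue feminization/malformation tallies for one group.

    ``table`` is the validated per-individual phenotype frame (see
    :func:`mfscreen.io.read_phenotypes`).  Percentages are over all
    individuals in the group, matching how such results are reported
    (e.g. "92% (36/39)").
    """
    sub = table[table["group"] == group]
    total = len(sub)
    if total == 0:
        raise ValueError(f"empty group {group!r}")
    tissues = {}
    for tissue in TISSUES:
        scores = sub[tissue]
        scored = scores != "not_scored"
        tissues[tissue] = TissueSummary(
            tissue=tissue,
            n_feminized=int((scores == "feminized").sum()),
            n_malformed=int((scores == "malformed").sum()),
            n_normal=int((scores == "normal").sum()),
            n_scored=int(scored.sum()),
            total=total,
        )
    return PhenoSummary(group=group, total=total, tissues=tissues)


@dataclass(frozen=True)
class InjectionSummary:
    label: str
    injected: int
    hatched: int
    pupae: int
    adult_female: int
    adult_male: int
    feminized_or_deformed: int

    def __post_init__(self) -> None:
        for name in (
            "injected",
            "hatched",
            "pupae",
            "adult_female",
            "adult_male",
            "feminized_or_deformed",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.injected == 0:
            raise ValueError("injected must be positive")
        if self.hatched > self.injected:
            raise ValueError("hatched exceeds injected")

    @property
    def hatch_pct(self) -> float:
        return round_half_up(100 * self.hatched / self.injected, 1)

    @property
    def adults(self) -> int:
        return self.adult_female + self.adult_male

    @property
    def female_pct(self) -> float:
        if self.adults == 0:
            return 0.0
        return round_half_up(100 * self.adult_female / self.adults, 2)

    @property
    def male_pct(self) -> float:
        if self.adults == 0:
            return 0.0
        return round_half_up(100 * self.adult_male / self.adults, 2)


def summarize_injection(
    replicates: list[dict], labels: list[str] | None = None
) -> tuple[list[InjectionSummary], InjectionSummary]:
    """Per-replicate summaries plus a pooled row.

    Each replicate dict carries injected, hatched, pupae, adult_female,
    adult_male, feminized_or_deformed.  The pooled row sums the replicate
    counts and recomputes the percentages from the sums.
    """
    if not replicates:
        raise ValueError("no replicates given")
    labels = labels or [f"rep{i + 1}" for i in range(len(replicates))]
    rows = [
        InjectionSummary(label=lab, **rep)
        for lab, rep in zip(labels, replicates, strict=True)
    ]
    pooled = InjectionSummary(
        label="pooled",
        injected=sum(r.injected for r in rows),
        hatched=sum(r.hatched for r in rows),
        pupae=sum(r.pupae for r in rows),
        adult_female=sum(r.adult_female for r in rows),
        adult_male=sum(r.adult_male for r in rows),
        feminized_or_deformed=sum(r.feminized_or_deformed for r in rows),
    )
    return rows, pooled


def mosaic_total(per_replicate_counts: list[int] | tuple[int, ...]) -> int:
    """Total mosaic individuals across injection replicates."""
    if any(c < 0 for c in per_replicate_counts):
        raise ValueError("counts must be non-negative")
    return int(sum(per_replicate_counts))


@dataclass(frozen=True)
class DdctMeasurement:
    ct_target_case: float
    ct_reference_case: float
    ct_target_control: float
    ct_reference_control: float


def fold_change_ddct(m: DdctMeasurement) -> float:
    """Relative expression by the 2^-ddCt method.

    dCt_case = Ct(target, case) - Ct(reference, case); likewise for the
    control; fold = 2 ** -(dCt_case - dCt_control).
    """
    dct_case = m.ct_target_case - m.ct_reference_case
    dct_control = m.ct_target_control - m.ct_reference_control
    return 2.0 ** -(dct_case - dct_control)
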