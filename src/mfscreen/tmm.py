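"""TMM normalization and the staged presence/absence expression filter.

TMM (trimmed mean of M-values) estimates a scaling factor per library so
that most genes show no fold change against a reference library once
library size is accounted for.  For library f against reference r, over
genes expressed in both:

    M_g = log2( (y_gf / N_f) / (y_gr / N_r) )        gene-wise log ratio
    A_g = 1/2 [ log2(y_gf / N_f) + log2(y_gr / N_r) ]  absolute abundance

The top and bottom ``logratio_trim`` of the M_g and ``abs_trim`` of the A_g
are discarded, and the factor is 2 raised to the weighted mean of the
surviving M_g with inverse asymptotic-variance weights

    w_g = 1 / [ (N_f - y_gf)/(N_f y_gf) + (N_r - y_gr)/(N_r y_gr) ]

(the delta-method/binomial variance of M_g).  Factors are rescaled so their
geometric mean is 1.  Normalized abundances are counts per million of the
effective library size N_f * factor_f, which maps zeros to zeros exactly —
a property the downstream zero/nonzero stage filter relies on.

The screen's second gate keeps references expressed after zygotic genome
activation but absent from pre-activation embryos and adult females:
E4-8 h > 0, E8-12 h > 0, E0-1 h = 0, adult female = 0 (TMM scale).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import ExpressionMatrix

__all__ = [
    "TMMParams",
    "StageRule",
    "PAPER_STAGE_RULES",
    "compute_tmm_factors",
    "normalize_matrix",
    "apply_expression_filter",
]


@dataclass(frozen=True)
class TMMParams:
    logratio_trim: float = 0.30
    abs_trim: float = 0.05
    reference_sample: str | None = None

    def __post_init__(self) -> None:
        for t in (self.logratio_trim, self.abs_trim):
            if not 0 <= t < 0.5:
                raise ValueError("trim fractions must be in [0, 0.5)")


@dataclass(frozen=True)
class StageRule:
    """One presence/absence condition on a developmental stage."""

    stage: str
    condition: str  # "eq_zero" or "gt_zero"
    aggregation: str = "mean"  # or "all_replicates"

    def __post_init__(self) -> None:
        if self.condition not in ("eq_zero", "gt_zero"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.aggregation not in ("mean", "all_replicates"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")


#: The published filter: zygotic expression in 4-8 h and 8-12 h embryos,
#: none in 0-1 h embryos (pre-activation) or adult females.
PAPER_STAGE_RULES = (
    StageRule("E4_8h", "gt_zero"),
    StageRule("E8_12h", "gt_zero"),
    StageRule("E0_1h", "eq_zero"),
    StageRule("adult_female", "eq_zero"),
)


def _select_reference(counts: np.ndarray, sample_ids: list[str]) -> int:
    # upper quartile of the nonzero library-size-scaled counts per sample;
    # reference = sample closest to the mean upper quartile
    libsize = counts.sum(axis=0)
    uq = np.empty(counts.shape[1])
    for j in range(counts.shape[1]):
        scaled = counts[:, j][counts[:, j] > 0] / libsize[j]
        uq[j] = np.quantile(scaled, 0.75) if scaled.size else 0.0
    return int(np.argmin(np.abs(uq - uq.mean())))


def _pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    logratio_trim: float,
    abs_trim: float,
) -> float:
    n_o = obs.sum()
    n_r = ref.sum()
    both = (obs > 0) & (ref > 0)
    if not both.any():
        return float("nan")
    y_o = obs[both] / n_o
    y_r = ref[both] / n_r
    m = np.log2(y_o / y_r)
    a = 0.5 * (np.log2(y_o) + np.log2(y_r))
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    # inverse of the binomial asymptotic variance of M_g
    v = (n_o - obs[both]) / (n_o * obs[both]) + (n_r - ref[both]) / (
        n_r * ref[both]
    )
    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abs_trim) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 1.0
    with np.errstate(divide="ignore"):
        f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(2.0**f)


def compute_tmm_factors(
    matrix: ExpressionMatrix, params: TMMParams | None = None
) -> pd.Series:
    """Per-sample TMM scaling factors, geometric mean 1.

    A sample sharing no co-expressed gene with the reference gets factor 1
    with a warning.
    """
    params = params or TMMParams()
    counts = matrix.values.to_numpy(dtype=float)
    sample_ids = list(matrix.values.columns)
    if len(sample_ids) < 2:
        raise ValueError("TMM needs at least 2 samples")
    libsize = counts.sum(axis=0)
    if (libsize <= 0).any():
        raise ValueError("every library total must be > 0")
    if params.reference_sample is not None:
        if params.reference_sample not in sample_ids:
            raise ValueError(
                f"reference sample {params.reference_sample!r} not in matrix"
            )
        ref_j = sample_ids.index(params.reference_sample)
    else:
        ref_j = _select_reference(counts, sample_ids)
    ref = counts[:, ref_j]
    factors = np.ones(len(sample_ids))
    for j in range(len(sample_ids)):
        f = _pair_factor(
            counts[:, j], ref, params.logratio_trim, params.abs_trim
        )
        if np.isnan(f):
            warnings.warn(
                f"sample {sample_ids[j]!r} shares no expressed gene with the "
                "reference; factor set to 1"
            )
            f = 1.0
        factors[j] = f
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=sample_ids, name="tmm_factor")


def normalize_matrix(
    matrix: ExpressionMatrix, factors: pd.Series
) -> ExpressionMatrix:
    """Scale raw counts to CPM of the effective library size.

    entry = raw / (library_total * factor) * 1e6.  Zeros map to zeros.
    """
    ids = list(matrix.values.columns)
    if set(factors.index) != set(ids):
        raise ValueError("factors do not align with matrix columns")
    f = factors.reindex(ids).to_numpy(dtype=float)
    if (f <= 0).any():
        raise ValueError("factors must be positive")
    libsize = matrix.values.sum(axis=0).to_numpy(dtype=float)
    scaled = matrix.values.to_numpy(dtype=float) / (libsize * f) * 1e6
    return ExpressionMatrix(
        pd.DataFrame(scaled, index=matrix.values.index, columns=ids),
        matrix.samples,
        normalized=True,
    )


def apply_expression_filter(
    matrix: ExpressionMatrix,
    rules: tuple[StageRule, ...] | list[StageRule] = PAPER_STAGE_RULES,
) -> pd.DataFrame:
    """Evaluate every stage rule per reference.

    Returns a frame indexed by reference id with one boolean column per rule
    (named ``<stage>:<condition>``) plus ``pass`` and ``fail_reason``.  The
    verdicts depend only on the zero pattern for eq_zero rules and are
    invariant to positive rescaling, so raw and TMM matrices agree.
    """
    stages_present = matrix.stages
    for rule in rules:
        if rule.stage not in stages_present:
            raise ValueError(
                f"rule stage {rule.stage!r} absent from sample sheet"
            )
    seen: set[str] = set()
    for rule in rules:
        if rule.stage in seen:
            raise ValueError(f"more than one rule for stage {rule.stage!r}")
        seen.add(rule.stage)

    out = pd.DataFrame(index=matrix.values.index)
    for rule in rules:
        cols = matrix.columns_for_stage(rule.stage)
        block = matrix.values[cols]
        if rule.aggregation == "mean":
            agg = block.mean(axis=1)
            ok = agg == 0 if rule.condition == "eq_zero" else agg > 0
        else:
            ok = (
                (block == 0).all(axis=1)
                if rule.condition == "eq_zero"
                else (block > 0).all(axis=1)
            )
        out[f"{rule.stage}:{rule.condition}"] = ok
    rule_cols = list(out.columns)
    out["pass"] = out[rule_cols].all(axis=1)
    out["fail_reason"] = out[rule_cols].apply(
        lambda row: ";".join(c for c in rule_cols if not row[c]), axis=1
    )
    return out
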