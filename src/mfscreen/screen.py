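"""The full M-factor candidate screen: CQ gate, expression gate, TE exclusion.

A reference is a final candidate iff it passes the chromosome-quotient
male-specificity filter AND the staged expression filter AND is not flagged
as transposase/reverse-transcriptase-derived.  The report keeps the whole
audit trail so every exclusion is attributable to a clause.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .cq import CQFilterParams, apply_cq_filter, compute_cq_table
from .io import CountTable, ExpressionMatrix, SampleMeta
from .tmm import PAPER_STAGE_RULES, StageRule, apply_expression_filter

__all__ = ["CandidateReport", "screen_candidates", "write_report",
           "te_like_from_products"]

logger = logging.getLogger(__name__)

_TE_KEYWORDS = re.compile(r"transposase|reverse\s+transcriptase", re.IGNORECASE)


def te_like_from_products(products: pd.Series) -> pd.Series:
    """Flag product descriptions that look transposase/RT-derived.

    Case-insensitive keyword match; a helper for building the annotation
    flag when only free-text products are available.
    """
    return products.fillna("").str.contains(_TE_KEYWORDS).astype(bool)


@dataclass
class CandidateReport:
    """Per-reference filter trail plus gate-count summary."""

    table: pd.DataFrame  # indexed by id
    summary: dict[str, int]

    @property
    def final_candidates(self) -> list[str]:
        sel = self.table[self.table["final_candidate"]]
        return list(sel.index)


def screen_candidates(
    count_table: CountTable,
    expression_matrix: ExpressionMatrix | None,
    annotation: pd.DataFrame | None = None,
    cq_params: CQFilterParams | None = None,
    stage_rules: tuple[StageRule, ...] = PAPER_STAGE_RULES,
    normalize_cq: bool = True,
) -> CandidateReport:
    """Run the complete screen over a validated count table.

    References absent from the expression matrix are treated as all-zero
    expression (they fail the gt_zero rules) with a logged warning,
    mirroring a quantifier that drops unexpressed contigs.  Final candidates
    are sorted by ascending CQ then id.
    """
    cq_params = cq_params or CQFilterParams()
    records = compute_cq_table(count_table, normalize=normalize_cq)
    cq_verdict = apply_cq_filter(records, cq_params)

    ids = count_table.ids
    if expression_matrix is not None and len(ids) > 0:
        missing = [i for i in ids if i not in expression_matrix.values.index]
        if missing:
            logger.warning(
                "%d reference(s) absent from expression matrix; treated as "
                "all-zero expression",
                len(missing),
            )
            filler = pd.DataFrame(
                0.0,
                index=pd.Index(missing, name=expression_matrix.values.index.name),
                columns=expression_matrix.values.columns,
            )
            padded = ExpressionMatrix(
                pd.concat([expression_matrix.values, filler]),
                expression_matrix.samples,
                normalized=expression_matrix.normalized,
            )
        else:
            padded = expression_matrix
        expr_verdict = apply_expression_filter(padded, stage_rules).reindex(ids)
    else:
        expr_verdict = pd.DataFrame(
            {"pass": False, "fail_reason": "no expression data"},
            index=pd.Index(ids, name="id"),
        )

    te = pd.Series(False, index=pd.Index(ids, name="id"))
    if annotation is not None:
        te.update(annotation["te_like"].reindex(ids).fillna(False))
        te = te.astype(bool)

    table = pd.DataFrame(index=pd.Index(ids, name="id"))
    table["male_count"] = cq_verdict["male_count"]
    table["female_count"] = cq_verdict["female_count"]
    table["cq"] = cq_verdict["cq"]
    table["cq_pass"] = cq_verdict["pass"]
    table["expression_pass"] = expr_verdict["pass"].astype(bool)
    table["te_excluded"] = te
    table["final_candidate"] = (
        table["cq_pass"] & table["expression_pass"] & ~table["te_excluded"]
    )

    reasons = []
    for ref in ids:
        r = []
        if not table.at[ref, "cq_pass"]:
            r.append(f"cq:{cq_verdict.at[ref, 'fail_reason']}")
        if not table.at[ref, "expression_pass"]:
            r.append(f"expression:{expr_verdict.at[ref, 'fail_reason']}")
        if table.at[ref, "te_excluded"]:
            r.append("transposase/RT-like")
        reasons.append(";".join(r))
    table["fail_reasons"] = reasons

    # deterministic order: candidates first, by ascending cq then id
    table = (
        table.reset_index()
        .sort_values(
            by=["final_candidate", "cq", "id"],
            ascending=[False, True, True],
            na_position="last",
            kind="mergesort",
        )
        .set_index("id")
    )

    summary = {
        "n_references": len(ids),
        "n_cq_pass": int(table["cq_pass"].sum()),
        "n_cq_and_expression_pass": int(
            (table["cq_pass"] & table["expression_pass"]).sum()
        ),
        "n_final_candidates": int(table["final_candidate"].sum()),
    }
    return CandidateReport(table, summary)


def write_report(report: CandidateReport, path: str | Path) -> None:
    """Write the per-reference TSV with a trailing commented summary block.

    Byte-stable across runs on identical input.
    """
    path = Path(path)
    with open(path, "w") as fh:
        df = report.table.reset_index()
        fh.write("\t".join(df.columns) + "\n")
        for row in df.itertuples(index=False):
            vals = []
            for v in row:
                if isinstance(v, float):
                    vals.append("NA" if pd.isna(v) else f"{v:.6g}")
                else:
                    vals.append(str(v))
            fh.write("\t".join(vals) + "\n")
        fh.write("# summary\n")
        for k, v in report.summary.items():
            fh.write(f"# {k}\t{v}\n")
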