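"""TMM normalization against a brute-force oracle, and the stage filter."""

import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from conftest import make_expression
from mfscreen.io import ExpressionMatrix, SampleMeta
from mfscreen.tmm import (
    PAPER_STAGE_RULES,
    StageRule,
    TMMParams,
    apply_expression_filter,
    compute_tmm_factors,
    normalize_matrix,
)


# ------------------------------------------------------------------- oracle

def _avg_ranks(values):
    """1-based average ranks, naive O(n^2)."""
    out = []
    for v in values:
        less = sum(1 for u in values if u < v)
        equal = sum(1 for u in values if u == v)
        out.append(less + (equal + 1) / 2)
    return out


def brute_force_tmm(counts, ref_col, logratio_trim=0.30, abs_trim=0.05):
    """Independent pure-python trimmed weighted mean of M-values."""
    n_genes, n_samples = len(counts), len(counts[0])
    lib = [sum(counts[g][j] for g in range(n_genes)) for j in range(n_samples)]
    factors = []
    for j in range(n_samples):
        m, a, w = [], [], []
        for g in range(n_genes):
            yo, yr = counts[g][j], counts[g][ref_col]
            if yo > 0 and yr > 0:
                po, pr = yo / lib[j], yr / lib[ref_col]
                m.append(math.log2(po / pr))
                a.append((math.log2(po) + math.log2(pr)) / 2)
                w.append(
                    (lib[j] - yo) / (lib[j] * yo)
                    + (lib[ref_col] - yr) / (lib[ref_col] * yr)
                )
        if not m or max(abs(x) for x in m) < 1e-6:
            factors.append(1.0)
            continue
        n = len(m)
        lo_m, hi_m = math.floor(n * logratio_trim) + 1, n - math.floor(n * logratio_trim)
        lo_a, hi_a = math.floor(n * abs_trim) + 1, n - math.floor(n * abs_trim)
        rm, ra = _avg_ranks(m), _avg_ranks(a)
        num = den = 0.0
        for i in range(n):
            if lo_m <= rm[i] <= hi_m and lo_a <= ra[i] <= hi_a:
                num += m[i] / w[i]
                den += 1 / w[i]
        factors.append(2 ** (num / den) if den else 1.0)
    gm = math.exp(sum(math.log(f) for f in factors) / len(factors))
    return [f / gm for f in factors]


def _matrix_from_array(arr):
    samples = [SampleMeta(f"s{j}", "pupae", j + 1) for j in range(arr.shape[1])]
    df = pd.DataFrame(
        np.asarray(arr, dtype=float),
        index=[f"g{i}" for i in range(arr.shape[0])],
        columns=[s.sample_id for s in samples],
    )
    return ExpressionMatrix(df, samples)


class TestTmmFactors:
    def test_identical_libraries(self, rng):
        col = rng.poisson(50, 100)
        em = _matrix_from_array(np.column_stack([col, col]))
        factors = compute_tmm_factors(em)
        assert factors.to_numpy() == pytest.approx([1.0, 1.0])

    def test_entrywise_doubling_absorbed_by_library_size(self, rng):
        a = rng.poisson(80, 200) + 1
        em = _matrix_from_array(np.column_stack([a, 2 * a]))
        factors = compute_tmm_factors(em, TMMParams(reference_sample="s0"))
        oracle = brute_force_tmm(np.column_stack([a, 2 * a]).tolist(), 0)
        assert factors.to_numpy() == pytest.approx(oracle, rel=1e-12)
        assert factors.to_numpy() == pytest.approx([1.0, 1.0], abs=1e-9)

    def test_outliers_within_trim_are_discarded(self):
        # 100 genes with M=0 plus 3 outliers at exactly M=5 (and one balancing
        # gene at M=-5 keeping library sizes equal): all within the 30% trim,
        # so the factors stay at 1
        base = np.full(100, 64.0)
        a = np.concatenate([base, [32.0, 32.0, 32.0, 3072.0]])
        b = np.concatenate([base, [1024.0, 1024.0, 1024.0, 96.0]])
        assert a.sum() == b.sum()
        em = _matrix_from_array(np.column_stack([a, b]))
        factors = compute_tmm_factors(em, TMMParams(reference_sample="s0"))
        assert factors.to_numpy() == pytest.approx([1.0, 1.0], rel=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_agrees_with_brute_force_on_poisson_matrices(self, seed):
        rng = np.random.default_rng(seed)
        lam = rng.uniform(5, 200, size=(50, 1)) * rng.uniform(0.5, 2, size=(1, 4))
        counts = rng.poisson(lam) + (rng.random((50, 4)) < 0.9)
        em = _matrix_from_array(counts)
        mine = compute_tmm_factors(em, TMMParams(reference_sample="s0"))
        oracle = brute_force_tmm(counts.tolist(), 0)
        assert np.max(np.abs(mine.to_numpy() / np.array(oracle) - 1)) < 1e-9

    def test_geometric_mean_is_one(self, rng):
        counts = rng.poisson(40, size=(60, 5)) + 1
        factors = compute_tmm_factors(_matrix_from_array(counts))
        assert np.exp(np.log(factors.to_numpy()).mean()) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_disjoint_sample_warns_factor_one(self):
        arr = np.array([[10.0, 0.0], [20.0, 0.0], [0.0, 5.0], [0.0, 7.0]])
        em = _matrix_from_array(arr)
        with pytest.warns(UserWarning, match="no expressed gene"):
            factors = compute_tmm_factors(em, TMMParams(reference_sample="s0"))
        assert factors["s1"] == pytest.approx(1.0)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
def test_agrees_with_edger(tmp_path, rng):
    """Independent cross-check against the reference TMM implementation."""
    counts = rng.poisson(
        rng.uniform(5, 200, size=(50, 1)) * rng.uniform(0.5, 2, size=(1, 4))
    )
    np.savetxt(tmp_path / "counts.txt", counts, fmt="%d")
    script = (
        'suppressMessages(library(edgeR));'
        f'x <- as.matrix(read.table("{tmp_path / "counts.txt"}"));'
        'f <- calcNormFactors(x, method="TMM", refColumn=1);'
        'cat(sprintf("%.12f ", f))'
    )
    proc = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, timeout=120
    )
    assert proc.returncode == 0, proc.stderr
    edger = np.array([float(v) for v in proc.stdout.split()])
    mine = compute_tmm_factors(
        _matrix_from_array(counts), TMMParams(reference_sample="s0")
    ).to_numpy()
    assert np.max(np.abs(mine / edger - 1)) < 1e-6


# -------------------------------------------------------------- normalization

class TestNormalizeMatrix:
    def test_definition_and_zero_preservation(self):
        arr = np.zeros((3, 2))
        arr[0, 0] = 100.0
        arr[1, 0] = 10**6 - 100.0
        arr[1, 1] = 500.0
        em = _matrix_from_array(arr)
        factors = pd.Series([1.0, 1.0], index=["s0", "s1"])
        norm = normalize_matrix(em, factors)
        assert norm.normalized
        assert norm.values.iloc[0, 0] == pytest.approx(100.0)  # CPM of 1e6 lib
        assert (norm.values.to_numpy() == 0) .sum() == (arr == 0).sum()

    def test_factor_halves_value(self):
        arr = np.array([[100.0, 100.0], [900.0, 900.0]])
        em = _matrix_from_array(arr)
        n1 = normalize_matrix(em, pd.Series([1.0, 1.0], index=["s0", "s1"]))
        n2 = normalize_matrix(em, pd.Series([1.0, 2.0], index=["s0", "s1"]))
        assert n2.values.iloc[0, 1] == pytest.approx(n1.values.iloc[0, 1] / 2)

    def test_nonpositive_factor_rejected(self):
        em = _matrix_from_array(np.ones((2, 2)))
        with pytest.raises(ValueError, match="positive"):
            normalize_matrix(em, pd.Series([1.0, 0.0], index=["s0", "s1"]))


# -------------------------------------------------------------- stage filter

class TestExpressionFilter:
    def test_published_rule_set_pass(self):
        em = make_expression(
            {
                "cand": {
                    "E4_8h": [5, 3, 7],
                    "E8_12h": [2, 0, 4],
                    "pupae": [1, 1, 1],
                    "adult_male": [9, 9, 9],
                }
            }
        )
        verdict = apply_expression_filter(em, PAPER_STAGE_RULES)
        assert verdict.loc["cand", "pass"]

    def test_maternal_leak_fails_eq_zero(self):
        em = make_expression(
            {"cand": {"E0_1h": [0.1, 0, 0], "E4_8h": [5, 3, 7], "E8_12h": [2, 0, 4]}}
        )
        verdict = apply_expression_filter(em, PAPER_STAGE_RULES)
        assert not verdict.loc["cand", "pass"]
        assert "E0_1h:eq_zero" in verdict.loc["cand", "fail_reason"]

    def test_all_zero_row_fails_gt_zero(self):
        em = make_expression({"dead": {}})
        verdict = apply_expression_filter(em, PAPER_STAGE_RULES)
        assert not verdict.loc["dead", "pass"]
        assert "E4_8h:gt_zero" in verdict.loc["dead", "fail_reason"]

    def test_all_replicates_mode_stricter_than_mean(self):
        em = make_expression({"r": {"E4_8h": [2, 0, 4], "E8_12h": [1, 1, 1]}})
        mean_rules = (StageRule("E4_8h", "gt_zero", "mean"),)
        strict_rules = (StageRule("E4_8h", "gt_zero", "all_replicates"),)
        assert apply_expression_filter(em, mean_rules).loc["r", "pass"]
        assert not apply_expression_filter(em, strict_rules).loc["r", "pass"]

    def test_missing_stage_is_hard_error(self):
        em = make_expression({"r": {}})
        em.samples = [s for s in em.samples if s.stage != "E0_1h"]
        em.values = em.values[[s.sample_id for s in em.samples]]
        with pytest.raises(ValueError, match="absent"):
            apply_expression_filter(em, PAPER_STAGE_RULES)

    def test_invariant_to_positive_rescaling(self):
        em = make_expression(
            {
                "a": {"E4_8h": [5, 3, 7], "E8_12h": [2, 0, 4]},
                "b": {"E0_1h": [1, 1, 1], "E4_8h": [5, 5, 5], "E8_12h": [1, 1, 1]},
            }
        )
        v1 = apply_expression_filter(em, PAPER_STAGE_RULES)
        scaled = ExpressionMatrix(em.values * 17.3, em.samples)
        v2 = apply_expression_filter(scaled, PAPER_STAGE_RULES)
        pd.testing.assert_series_equal(v1["pass"], v2["pass"])
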