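"""Synthetic scenarios with planted linkage classes, for end-to-end testing.

The generator emulates the data the screen consumes, with a known truth:

* a reference set of random uniform-composition contigs in three linkage
  classes — hemizygous male-specific (copy numbers male 1 / female 0, the
  planted M-factor class), autosomal (2/2) and female-dosage-biased (1/2);
* equal-depth male and female whole-genome alignment counts, Poisson with
  mean proportional to copy number and contig length (a hemizygous male
  locus gets half the autosomal male coverage; the absent sex gets mean
  leakage*depth, 0 by default);
* a staged expression design with zygotic genome activation at 6.5 h
  post-oviposition: M-linked rows are zero in stages sampled entirely
  before activation and in adult females, positive (log-normal) from the
  4-8 h embryo window onward; autosomal rows are positive everywhere
  (maternal transcripts cover the earliest embryos); female-biased rows
  are additionally elevated in adult females.

One global seed spawns independent substreams per step, so enlarging one
class does not perturb draws elsewhere.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    STAGES,
    CountTable,
    ExpressionMatrix,
    ReferenceRecord,
    SampleMeta,
    write_count_table,
    write_expression,
    write_fasta,
    write_sample_sheet,
)

__all__ = [
    "SimParams",
    "TruthTable",
    "simulate_reference_set",
    "simulate_dna_counts",
    "simulate_expression_matrix",
    "make_scenario",
]

#: Hour intervals (post-oviposition) of the embryonic stages; later stages
#: are unambiguously post-activation.
_STAGE_HOURS = {
    "E0_1h": (0.0, 1.0),
    "E2_4h": (2.0, 4.0),
    "E4_8h": (4.0, 8.0),
    "E8_12h": (8.0, 12.0),
}

#: copy number (male, female) per linkage class
CLASS_COPY = {
    "M_linked": (1, 0),
    "autosomal": (2, 2),
    "female_biased": (1, 2),
}

#: off-target alignment mass added to each library total
OFFTARGET_MASS = 1_000_000


@dataclass(frozen=True)
class SimParams:
    n_m_linked: int = 10
    n_autosomal: int = 200
    n_female_biased: int = 20
    length_range: tuple[int, int] = (500, 2000)
    depth: float = 100.0  # expected alignments per autosomal contig per sex
    leakage: float = 0.0  # fraction of depth leaking into the absent sex
    activation_hour: float = 6.5  # zygotic genome activation
    expression_mean: float = 50.0  # log-normal scale of expressed rows
    expression_sigma: float = 0.6  # log-sd of expression noise
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_m_linked, self.n_autosomal, self.n_female_biased) < 0:
            raise ValueError("class counts must be >= 0")
        if self.n_m_linked + self.n_autosomal + self.n_female_biased == 0:
            raise ValueError("at least one contig required")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if not 0 <= self.leakage < 1:
            raise ValueError("leakage must be in [0, 1)")
        if self.length_range[0] < 1 or self.length_range[1] < self.length_range[0]:
            raise ValueError("bad length_range")


@dataclass
class TruthTable:
    """Planted linkage class and copy numbers per contig — the test oracle."""

    table: pd.DataFrame  # index id; columns class, copy_male, copy_female

    def ids_of(self, cls: str) -> list[str]:
        return list(self.table.index[self.table["class"] == cls])

    def write(self, path: str | Path) -> None:
        df = self.table.reset_index()
        df.columns = ["id", "class", "copy_male", "copy_female"]
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "TruthTable":
        df = pd.read_csv(path, sep="\t", comment="#").set_index("id")
        return cls(df)


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    seqs = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(s) for s in seqs]


def simulate_reference_set(
    params: SimParams,
) -> tuple[list[ReferenceRecord], TruthTable]:
    """Random contigs of the three linkage classes; deterministic by seed."""
    rng = _substreams(params.seed, 4)[0]
    classes = (
        ["M_linked"] * params.n_m_linked
        + ["autosomal"] * params.n_autosomal
        + ["female_biased"] * params.n_female_biased
    )
    records = []
    rows = []
    counters = {c: 0 for c in CLASS_COPY}
    prefix = {"M_linked": "mlk", "autosomal": "aut", "female_biased": "fem"}
    for cls in classes:
        counters[cls] += 1
        ref_id = f"{prefix[cls]}_{counters[cls]:04d}"
        length = int(rng.integers(params.length_range[0], params.length_range[1] + 1))
        seq = "".join(rng.choice(list("ACGT"), size=length))
        records.append(ReferenceRecord(ref_id, seq, f"simulated {cls}"))
        cm, cf = CLASS_COPY[cls]
        rows.append({"id": ref_id, "class": cls, "copy_male": cm, "copy_female": cf})
    truth = TruthTable(pd.DataFrame(rows).set_index("id"))
    return records, truth


def simulate_dna_counts(truth: TruthTable, params: SimParams,
                        lengths: dict[str, int] | None = None) -> CountTable:
    """Poisson alignment counts per contig and sex.

    mean = depth * copy_number/2 * length/mean_length for a present copy;
    mean = leakage * depth for the sex with copy number 0.  Without
    ``lengths`` the length factor is 1 (the default scenario), so every
    autosomal contig's expectation is exactly ``depth``.  Library totals are
    the column sums plus a constant off-target mass, so totals always exceed
    the counts.
    """
    rng = _substreams(params.seed, 4)[1]
    df = truth.table
    n = len(df)
    if lengths:
        lens = np.array([lengths[i] for i in df.index], dtype=float)
        len_factor = lens / lens.mean()
    else:
        len_factor = np.ones(n)

    out = {}
    for sex, copy_col in (("male", "copy_male"), ("female", "copy_female")):
        copies = df[copy_col].to_numpy(dtype=float)
        mean = params.depth * copies / 2.0 * len_factor
        mean[copies == 0] = params.leakage * params.depth
        out[f"{sex}_count"] = rng.poisson(mean)

    counts = pd.DataFrame(out, index=df.index.copy())
    return CountTable(
        counts,
        male_total=int(counts["male_count"].sum()) + OFFTARGET_MASS,
        female_total=int(counts["female_count"].sum()) + OFFTARGET_MASS,
    )


def _stage_expressed(cls: str, stage: str, activation_hour: float) -> bool:
    """Whether a contig of the given class is transcribed in the stage."""
    if cls == "M_linked":
        if stage == "adult_female":
            return False
        hours = _STAGE_HOURS.get(stage)
        if hours is not None and hours[1] <= activation_hour:
            return False  # sampled entirely before zygotic activation
        return True
    return True  # autosomal / female_biased: maternal + zygotic everywhere


def simulate_expression_matrix(
    truth: TruthTable, params: SimParams
) -> ExpressionMatrix:
    """Raw stage x replicate counts honouring the planted linkage classes.

    M-linked rows: exact zeros pre-activation and in adult females, positive
    log-normal counts from E4_8h onward.  Autosomal rows positive in every
    sample; female-biased rows 2x elevated in adult females.
    """
    rng = _substreams(params.seed, 4)[2]
    samples = [
        SampleMeta(f"{stage}_r{rep}", stage, rep)
        for stage in STAGES
        for rep in range(1, params.n_replicates + 1)
    ]
    df = truth.table
    values = np.zeros((len(df), len(samples)))
    for j, s in enumerate(samples):
        for i, (ref_id, row) in enumerate(df.iterrows()):
            if not _stage_expressed(row["class"], s.stage, params.activation_hour):
                continue
            scale = params.expression_mean
            if row["class"] == "female_biased" and s.stage == "adult_female":
                scale *= 2.0
            draw = scale * rng.lognormal(0.0, params.expression_sigma)
            values[i, j] = max(1.0, round(draw))  # expressed rows stay nonzero
    matrix = pd.DataFrame(
        values, index=df.index.copy(), columns=[s.sample_id for s in samples]
    )
    matrix.index.name = "id"
    return ExpressionMatrix(matrix, samples, normalized=False)


def make_scenario(
    params: SimParams, out_dir: str | Path, force: bool = False
) -> dict[str, Path]:
    """Write a complete scenario bundle to disk and return the file paths.

    Emits references.fasta, counts.tsv, expression.tsv, samples.tsv,
    truth.tsv and a manifest.json recording the parameters and totals.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (use force)")
    out.mkdir(parents=True, exist_ok=True)

    # unit length factor: every autosomal contig's expected count is exactly
    # `depth`, so planted M-linked contigs sit at depth/2 male coverage —
    # comfortably above the strict male-count threshold at the default depth
    records, truth = simulate_reference_set(params)
    counts = simulate_dna_counts(truth, params)
    matrix = simulate_expression_matrix(truth, params)

    paths = {
        "fasta": out / "references.fasta",
        "counts": out / "counts.tsv",
        "matrix": out / "expression.tsv",
        "samples": out / "samples.tsv",
        "truth": out / "truth.tsv",
        "manifest": out / "manifest.json",
    }
    write_fasta(records, paths["fasta"])
    write_count_table(counts, paths["counts"])
    write_expression(matrix, paths["matrix"])
    write_sample_sheet(matrix.samples, paths["samples"])
    truth.write(paths["truth"])
    manifest = {
        "params": {
            **asdict(params),
            "length_range": list(params.length_range),
        },
        "male_total": counts.male_total,
        "female_total": counts.female_total,
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2) + "\n")
    return paths
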