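"""Readers and writers for every external file the screen touches.

Conventions used throughout the package (stated once, here):

* coordinates are 0-based, half-open;
* TSV files are tab-separated with a required header row, UTF-8, and
  lines starting with ``#`` are ignored;
* one SAM alignment line contributes one count (pairs are not collapsed).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "STAGES",
    "TISSUES",
    "TISSUE_SCORES",
    "PHENO_GROUPS",
    "ReferenceRecord",
    "CountTable",
    "SampleMeta",
    "ExpressionMatrix",
    "read_fasta",
    "write_fasta",
    "read_count_table",
    "write_count_table",
    "count_alignments_from_sam",
    "read_sample_sheet",
    "read_expression",
    "write_expression",
    "read_annotation",
    "read_phenotypes",
]

#: Developmental stages of the expression design.  The four embryonic windows
#: are hours post-oviposition; sex determination (zygotic genome activation of
#: the M factor) falls inside the 4-8 h window.
STAGES = (
    "E0_1h",
    "E2_4h",
    "E4_8h",
    "E8_12h",
    "pupae",
    "adult_male",
    "adult_female",
)

#: Sexually dimorphic tissues scored per mosaic individual.
TISSUES = ("antennae", "maxillary_palps", "external_genitalia", "gonads")
TISSUE_SCORES = ("normal", "feminized", "malformed", "not_scored")
PHENO_GROUPS = ("mosaic", "control", "wild_type_male", "wild_type_female")

_DNA_OK = re.compile(r"^[ACGTN]*$")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class ReferenceRecord:
    """One transcript contig of the assembly."""

    id: str
    sequence: str
    description: str = ""

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class CountTable:
    """Per-reference male/female genomic alignment counts with library totals.

    ``counts`` is indexed by reference id with integer columns ``male_count``
    and ``female_count``; ``male_total``/``female_total`` are the library sizes
    the chromosome quotient is normalized by.
    """

    counts: pd.DataFrame
    male_total: int
    female_total: int

    def __post_init__(self) -> None:
        df = self.counts
        if list(df.columns) != ["male_count", "female_count"]:
            df = df[["male_count", "female_count"]]
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise FormatError(f"duplicate id {dup!r} in count table")
        if not (df >= 0).all().all():
            raise FormatError("negative counts in count table")
        if self.male_total <= 0 or self.female_total <= 0:
            raise FormatError("library totals must be positive")
        if (df["male_count"] > self.male_total).any():
            raise FormatError("male_count exceeds male_total")
        if (df["female_count"] > self.female_total).any():
            raise FormatError("female_count exceeds female_total")
        self.counts = df.astype(int)

    @property
    def ids(self) -> list[str]:
        return list(self.counts.index)

    def __len__(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    stage: str
    replicate: int

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise FormatError(
                f"unknown stage {self.stage!r} for sample {self.sample_id!r}; "
                f"expected one of {', '.join(STAGES)}"
            )
        if self.replicate < 1:
            raise FormatError(f"replicate must be >= 1 for {self.sample_id!r}")


@dataclass
class ExpressionMatrix:
    """References x samples abundance grid with its aligned sample sheet."""

    values: pd.DataFrame
    samples: list[SampleMeta]
    normalized: bool = False

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate sample ids in sample sheet")
        if list(self.values.columns) != ids:
            missing = set(ids) - set(self.values.columns)
            extra = set(self.values.columns) - set(ids)
            if missing or extra:
                raise FormatError(
                    "matrix columns and sample sheet disagree; "
                    f"missing from matrix: {sorted(missing)}; "
                    f"missing from sheet: {sorted(extra)}"
                )
            self.values = self.values[ids]
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicate reference id {dup!r} in matrix")
        if (self.values.to_numpy() < 0).any():
            raise FormatError("negative entry in expression matrix")

    def columns_for_stage(self, stage: str) -> list[str]:
        return [s.sample_id for s in self.samples if s.stage == stage]

    @property
    def stages(self) -> set[str]:
        return {s.stage for s in self.samples}


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[ReferenceRecord]:
    """Parse a FASTA file into validated, uppercased reference records.

    Duplicate ids and non-ACGTN characters are hard errors.
    """
    records: list[ReferenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate id {rec.id}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not _DNA_OK.match(seq):
            bad = sorted(set(seq) - set("ACGTN"))
            raise FormatError(
                f"illegal character(s) {bad} in sequence {rec.id!r}"
            )
        desc = rec.description[len(rec.id):].strip()
        records.append(ReferenceRecord(rec.id, seq, desc))
    return records


def write_fasta(records: Iterable[ReferenceRecord], path: str | Path) -> None:
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seqrecs, fh, "fasta")


# ---------------------------------------------------------------------------
# TSV helpers


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing column(s) {missing}")


# ---------------------------------------------------------------------------
# Count tables


def read_count_table(
    path: str | Path, male_total: int, female_total: int
) -> CountTable:
    """Read a TSV with columns id, male_count, female_count."""
    df = _read_tsv(path)
    _require_columns(df, ["id", "male_count", "female_count"], "count table")
    out = pd.DataFrame(index=pd.Index(df["id"], name="id"))
    for col in ("male_count", "female_count"):
        try:
            vals = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise FormatError(f"non-numeric {col} in count table") from exc
        if (vals % 1 != 0).any():
            raise FormatError(f"non-integer {col} in count table")
        out[col] = vals.to_numpy(dtype=int)
    return CountTable(out, male_total=male_total, female_total=female_total)


def write_count_table(table: CountTable, path: str | Path) -> None:
    df = table.counts.reset_index()
    df.columns = ["id", "male_count", "female_count"]
    df.to_csv(path, sep="\t", index=False)


def count_alignments_from_sam(
    source, mapq_min: int = 0, primary_only: bool = True
) -> dict[str, int]:
    """Tally alignment lines per reference from SAM text (one sex at a time).

    Unmapped records (0x4) are always skipped; with ``primary_only`` secondary
    (0x100) and supplementary (0x800) records are skipped too.  References are
    taken from the ``@SQ`` header lines; every one gets an entry, so contigs
    with zero coverage appear explicitly as zeros.
    """
    if mapq_min < 0:
        raise ValueError("mapq_min must be >= 0")
    if isinstance(source, (str, Path)):
        fh = pysam.AlignmentFile(str(source), "r", check_sq=True)
    else:
        # pysam needs a real file descriptor; spool stream input to a temp file
        import tempfile

        with tempfile.NamedTemporaryFile(
            "w", suffix=".sam", delete=False
        ) as tmp:
            tmp.write(source.read())
            tmp_path = tmp.name
        fh = pysam.AlignmentFile(tmp_path, "r", check_sq=True)
    with fh:
        if fh.nreferences == 0:
            raise FormatError("SAM header has no @SQ lines")
        tally = {name: 0 for name in fh.references}
        for aln in fh:
            if aln.is_unmapped:
                continue
            if primary_only and (aln.is_secondary or aln.is_supplementary):
                continue
            if aln.mapping_quality < mapq_min:
                continue
            tally[aln.reference_name] += 1
    return tally


# ---------------------------------------------------------------------------
# Expression


def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    df = _read_tsv(path)
    _require_columns(df, ["sample_id", "stage", "replicate"], "sample sheet")
    metas = [
        SampleMeta(row.sample_id, row.stage, int(row.replicate))
        for row in df.itertuples()
    ]
    ids = [m.sample_id for m in metas]
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate sample_id in sample sheet")
    return metas


def write_sample_sheet(samples: Sequence[SampleMeta], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "stage": [s.stage for s in samples],
            "replicate": [s.replicate for s in samples],
        }
    ).to_csv(path, sep="\t", index=False)


def read_expression(
    path_matrix: str | Path,
    path_samplesheet: str | Path,
    normalized: bool = False,
) -> ExpressionMatrix:
    samples = read_sample_sheet(path_samplesheet)
    df = pd.read_csv(path_matrix, sep="\t", comment="#", index_col=0)
    df.index = df.index.astype(str)
    return ExpressionMatrix(df.astype(float), samples, normalized=normalized)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.values.copy()
    df.index.name = "id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Annotation and phenotypes


def read_annotation(
    path: str | Path, reference_ids: Iterable[str] | None = None
) -> pd.DataFrame:
    """Read an id -> product / te_like flag table.

    ``te_like`` marks transposase- or reverse-transcriptase-derived contigs,
    which the screen excludes even when they pass both filters.
    """
    df = _read_tsv(path)
    _require_columns(df, ["id", "product", "te_like"], "annotation table")
    te = df["te_like"].str.strip().str.lower()
    bad = ~te.isin({"true", "false", "1", "0", "yes", "no"})
    if bad.any():
        raise FormatError(
            f"te_like must be boolean, got {df['te_like'][bad].iloc[0]!r}"
        )
    out = pd.DataFrame(
        {
            "product": df["product"].to_numpy(),
            "te_like": te.isin({"true", "1", "yes"}).to_numpy(),
        },
        index=pd.Index(df["id"], name="id"),
    )
    if out.index.has_duplicates:
        raise FormatError("duplicate id in annotation table")
    if reference_ids is not None:
        unknown = set(out.index) - set(reference_ids)
        if unknown:
            raise FormatError(
                f"annotation ids absent from reference set: {sorted(unknown)}"
            )
    return out


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read the per-individual phenotype CSV.

    Columns: individual_id, group, then one score per tissue in
    :data:`TISSUES`, each drawn from :data:`TISSUE_SCORES`.
    """
    df = pd.read_csv(path, comment="#", dtype=str)
    _require_columns(
        df, ["individual_id", "group", *TISSUES], "phenotype table"
    )
    if df["individual_id"].duplicated().any():
        dup = df["individual_id"][df["individual_id"].duplicated()].iloc[0]
        raise FormatError(f"duplicate individual_id {dup!r}")
    bad_group = ~df["group"].isin(PHENO_GROUPS)
    if bad_group.any():
        raise FormatError(f"unknown group {df['group'][bad_group].iloc[0]!r}")
    for tissue in TISSUES:
        bad = ~df[tissue].isin(TISSUE_SCORES)
        if bad.any():
            raise FormatError(
                f"unknown score {df[tissue][bad].iloc[0]!r} for {tissue}"
            )
    return df.set_index("individual_id")
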