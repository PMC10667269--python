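"""Shared domain containers, table I/O, and cohort selection.

The central container is :class:`AnalyteMatrix`, an analyte-by-sample table of
measurements for one data type (protein groups, metabolites, RNA, miRNA,
encoded SNP genotypes, or clinical indicators).  Missing values are plain NaN
in a float matrix — nothing in the pipeline imputes them.  Sample-level
covariates (subject, age, batch, vigabatrin exposure, diagnostic group,
seizure/EEG status, outcome) live in a plain pandas DataFrame validated by
:func:`validate_metadata`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DATA_TYPES = ("protein", "metabolite", "rna", "mirna", "snp", "clinical")
SCALES = ("log2", "linear", "categorical")

#: Metadata columns every sample row must carry.
METADATA_COLUMNS = (
    "sample_id",
    "subject_id",
    "age_weeks",
    "batch",
    "vgb",
    "group",
    "seizure_history",
    "abnormal_eeg_at_draw",
    "seizure_at_draw",
    "drug_resistant_24m",
    "presymptomatic_vgb",
    "timepoint_label",
)

#: Postnatal-age strata used for the Z-score age correction and the
#: developmental-trajectory analysis: 0-10, 11-40 and >40 weeks.  Integer-week
#: boundaries are closed above (age 10.0 belongs to T1, 40.0 to T2).
AGE_TERTILES = {"T1": (0.0, 10.0), "T2": (10.0, 40.0), "T3": (40.0, np.inf)}


@dataclass
class AnalyteMatrix:
    """Analyte x sample value matrix for a single data type.

    Parameters
    ----------
    values
        DataFrame with analyte ids as the index and sample ids as columns.
        NaN marks a missing (masked) measurement.
    data_type
        One of ``protein, metabolite, rna, mirna, snp, clinical``.
    scale
        ``log2`` or ``linear`` for continuous analytes, ``categorical`` for
        binary-encoded SNP/clinical variables (values restricted to {0, 1}).
    """

    values: pd.DataFrame
    data_type: str
    scale: str

    def __post_init__(self) -> None:
        if self.data_type not in DATA_TYPES:
            raise ValueError(f"unknown data_type {self.data_type!r}")
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate analyte ids: {dups}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        self.values = self.values.astype(float)
        if self.scale == "categorical":
            arr = self.values.to_numpy()
            ok = np.isnan(arr) | (arr == 0.0) | (arr == 1.0)
            if not ok.all():
                raise ValueError("categorical matrix must contain only 0/1/missing")

    @property
    def analyte_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean DataFrame, True where the value is missing."""
        return self.values.isna()

    def copy_with(self, values: pd.DataFrame) -> "AnalyteMatrix":
        return AnalyteMatrix(values=values, data_type=self.data_type, scale=self.scale)

    def subset_samples(self, sample_ids: Sequence[str]) -> "AnalyteMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        return self.copy_with(self.values.loc[:, list(sample_ids)])


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_analyte_matrix(path: str | Path, data_type: str, scale: str) -> AnalyteMatrix:
    """Read an analyte table (analytes as rows, first column = analyte id).

    Blank cells become missing values.  Lines starting with ``#`` (provenance
    headers written by the pipeline) are skipped.  Non-numeric cells in a
    non-categorical matrix raise with the offending row/column named.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep=_sep_for(path), index_col=0, comment="#", float_precision="round_trip"
    )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate analyte ids: {dups}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(f"{path}: non-numeric value at analyte {row!r}, sample {col!r}")
        df[col] = coerced
    return AnalyteMatrix(values=df, data_type=data_type, scale=scale)


def write_analyte_matrix(matrix: AnalyteMatrix, path: str | Path, header: str | None = None) -> None:
    """Write a matrix as TSV/CSV; missing values become blank cells."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        # %.17g round-trips IEEE doubles exactly
        matrix.values.to_csv(fh, sep=_sep_for(path), na_rep="", float_format="%.17g")


def validate_metadata(meta: pd.DataFrame, matrices: Iterable[AnalyteMatrix] = ()) -> pd.DataFrame:
    """Validate a sample-metadata table and return it indexed by sample_id.

    Checks the required columns, uniqueness of sample ids, finite non-negative
    ages, one sample per control subject, and that every sample in the given
    matrices is described exactly once.
    """
    if meta.index.name == "sample_id":
        meta = meta.reset_index(drop="sample_id" in meta.columns)
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ValueError(f"metadata missing columns: {missing_cols}")
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    ages = meta["age_weeks"].to_numpy(float)
    if not np.isfinite(ages).all() or (ages < 0).any():
        raise ValueError("age_weeks must be finite and non-negative")
    bad_group = set(meta["group"].unique()) - {"control", "tsc"}
    if bad_group:
        raise ValueError(f"unknown group labels: {bad_group}")
    ctl = meta[meta["group"] == "control"]
    per_subject = ctl.groupby("subject_id").size()
    if (per_subject > 1).any():
        raise ValueError("controls must have exactly one sample per subject")
    indexed = meta.set_index("sample_id", drop=False)
    for m in matrices:
        unknown = [s for s in m.sample_ids if s not in indexed.index]
        if unknown:
            raise ValueError(f"samples missing from metadata: {unknown[:5]}")
    return indexed


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    meta = pd.read_csv(path, sep=_sep_for(path), comment="#")
    return validate_metadata(meta)


def write_sample_metadata(meta: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        meta.reset_index(drop=True).to_csv(fh, sep=_sep_for(path), index=False)


def assign_age_tertile(age_weeks: float | np.ndarray | pd.Series):
    """Map postnatal age in weeks to its stratum label T1/T2/T3.

    Total on finite non-negative ages: [0, 10] -> T1, (10, 40] -> T2,
    (40, inf) -> T3.
    """
    arr = np.asarray(age_weeks, dtype=float)
    if not np.isfinite(arr).all() or (arr < 0).any():
        raise ValueError("ages must be finite and non-negative")
    out = np.where(arr <= 10.0, "T1", np.where(arr <= 40.0, "T2", "T3"))
    if np.ndim(age_weeks) == 0:
        return str(out[()])
    if isinstance(age_weeks, pd.Series):
        return pd.Series(out, index=age_weeks.index)
    return out


def encode_snp_genotypes(genotypes: pd.DataFrame, major_allele: pd.Series) -> AnalyteMatrix:
    """Binary-encode unphased diploid genotype calls.

    ``genotypes`` is a sample x SNP table of calls like ``"T/C"``;
    ``major_allele`` maps each SNP to its major allele.  Encoding: 0 for the
    major-allele homozygote, 1 for a heterozygote or minor-allele homozygote.
    Missing calls (NaN or empty) stay missing.  An allele that is neither the
    major allele nor a single consistent alternate raises.
    """
    snps = list(genotypes.columns)
    unknown = [s for s in snps if s not in major_allele.index]
    if unknown:
        raise ValueError(f"no major allele stated for SNPs: {unknown[:5]}")
    encoded = pd.DataFrame(index=snps, columns=genotypes.index.astype(str), dtype=float)
    for snp in snps:
        major = str(major_allele[snp])
        alt_seen: set[str] = set()
        for sample, call in genotypes[snp].items():
            if call is None or (isinstance(call, float) and np.isnan(call)) or call == "":
                continue
            alleles = str(call).replace("|", "/").split("/")
            if len(alleles) != 2:
                raise ValueError(f"SNP {snp}, sample {sample}: malformed call {call!r}")
            for a in alleles:
                if a != major:
                    alt_seen.add(a)
            if len(alt_seen) > 1:
                raise ValueError(
                    f"SNP {snp}: alleles {sorted(alt_seen)} conflict with a biallelic model"
                )
            encoded.loc[snp, str(sample)] = 0.0 if alleles[0] == major and alleles[1] == major else 1.0
    return AnalyteMatrix(values=encoded, data_type="snp", scale="categorical")


@dataclass
class CohortSelection:
    """Outcome of enrollment-cohort selection for the classifier stage."""

    sample_ids: list[str]
    labels: pd.Series  # 1 = developed seizures by 24 months, 0 = seizure-free
    excluded_entry_seizure: list[str] = field(default_factory=list)
    excluded_presymptomatic_vgb: list[str] = field(default_factory=list)
    excluded_no_sample: list[str] = field(default_factory=list)

    @property
    def n_positive(self) -> int:
        return int((self.labels == 1).sum())

    @property
    def n_negative(self) -> int:
        return int((self.labels == 0).sum())


def select_classifier_cohort(meta: pd.DataFrame) -> CohortSelection:
    """Select one enrollment sample per affected subject and label outcomes.

    The classifier cohort is built from the earliest on-study sample of each
    TSC subject, excluding (a) subjects with subclinical seizures already at
    study entry, (b) subjects treated presymptomatically with vigabatrin who
    never developed seizures, and (c) subjects without a comparable enrollment
    sample.  Exclusions are applied as a union.  Labels: 1 if the subject
    developed clinical or electrographic seizures by 24 months, else 0.
    """
    meta = validate_metadata(meta.copy()).reset_index(drop=True)
    tsc = meta[meta["group"] == "tsc"]
    # contradiction check: a seizure observed at draw implies seizure history
    contradictory = tsc[(~tsc["seizure_history"].astype(bool)) & tsc["seizure_at_draw"].astype(bool)]
    if len(contradictory):
        subj = sorted(contradictory["subject_id"].unique())
        raise ValueError(f"subjects flagged seizure-free but with seizure_at_draw: {subj}")

    enrollment: dict[str, pd.Series] = {}
    for subject, rows in tsc.groupby("subject_id"):
        cand = rows[rows["timepoint_label"] == "enrollment"]
        if len(cand) == 0:
            continue
        cand = cand.sort_values(["age_weeks", "sample_id"])
        enrollment[subject] = cand.iloc[0]

    all_subjects = sorted(tsc["subject_id"].unique())
    no_sample = [s for s in all_subjects if s not in enrollment]
    entry_seizure = [
        s for s, row in enrollment.items() if bool(row["seizure_at_draw"])
    ]
    by_subject = tsc.groupby("subject_id").agg(
        seizure=("seizure_history", "any"), presympt=("presymptomatic_vgb", "any")
    )
    presympt_no_seizure = [
        s for s in all_subjects if by_subject.loc[s, "presympt"] and not by_subject.loc[s, "seizure"]
    ]
    excluded = set(no_sample) | set(entry_seizure) | set(presympt_no_seizure)
    kept = [s for s in all_subjects if s not in excluded]
    sample_ids = [str(enrollment[s]["sample_id"]) for s in kept]
    labels = pd.Series(
        [1 if by_subject.loc[s, "seizure"] else 0 for s in kept],
        index=pd.Index(sample_ids, name="sample_id"),
        name="seizure",
    )
    return CohortSelection(
        sample_ids=sample_ids,
        labels=labels,
        excluded_entry_seizure=sorted(entry_seizure),
        excluded_presymptomatic_vgb=sorted(presympt_no_seizure),
        excluded_no_sample=sorted(no_sample),
    )
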