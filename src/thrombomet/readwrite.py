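"""Reading, validation, and writing of the cohort's tabular formats.

All exchange formats are plain CSV/TSV.  Abundance is sample-major wide
format (first column = sample id, header = metabolite ids).  Missing cells
are empty or ``NA`` — never zero, which is treated as a legal abundance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .config import GROUPS, TIMEPOINTS, SimConfig
from .synthetic import Cohort

_NA_VALUES = ["", "NA", "NaN", "nan"]


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "\t" if path.suffix.lower() in (".tsv", ".txt") else ","


def median_scale(abundance: pd.DataFrame) -> pd.DataFrame:
    """Optional per-sample median normalization.

    Divides each sample by its median observed abundance and rescales by the
    grand median, preserving the overall intensity scale.  Tables are
    normally ingested as already vendor-normalized; this flag exists for raw
    exports only.
    """
    medians = abundance.median(axis=1, skipna=True)
    if (medians <= 0).any():
        bad = abundance.index[medians <= 0][0]
        raise ValueError(f"sample {bad!r} has non-positive median abundance")
    return abundance.div(medians, axis=0) * float(np.median(medians))


def read_abundance(
    path: str | Path, sep: str | None = None, scale: bool = False
) -> pd.DataFrame:
    """Read a wide-format abundance table, enforcing its invariants.

    Raises ``ValueError`` naming the offending cell for negative abundances
    and the offending id for duplicate sample/metabolite ids.  With
    ``scale=True`` applies :func:`median_scale` after validation.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep=_sep_for(path, sep), index_col=0,
        na_values=_NA_VALUES, keep_default_na=False,
    )
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    df.columns.name = "metabolite_id"
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate sample id: {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"duplicate metabolite id: {dup!r}")
    values = df.to_numpy(dtype=float)  # raises on non-numeric garbage
    bad = np.argwhere(values < 0)
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"negative abundance for sample {df.index[i]!r}, "
            f"metabolite {df.columns[j]!r}: {values[i, j]}"
        )
    df = df.astype(float)
    return median_scale(df) if scale else df


def write_abundance(table: pd.DataFrame, path: str | Path, sep: str | None = None) -> None:
    path = Path(path)
    table.to_csv(path, sep=_sep_for(path, sep), na_rep="NA")


def read_subjects(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep), na_values=_NA_VALUES,
                     keep_default_na=False, dtype=str)
    required = {"subject_id", "group", *TIMEPOINTS}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"subject table missing columns: {sorted(missing)}")
    bad_groups = set(df["group"]) - set(GROUPS)
    if bad_groups:
        raise ValueError(f"unknown group labels: {sorted(bad_groups)}")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValueError(f"duplicate subject id: {dup!r}")
    for t in TIMEPOINTS:
        df[t] = df[t].where(df[t].notna(), pd.NA)
    return df


def write_subjects(subjects: pd.DataFrame, path: str | Path, sep: str | None = None) -> None:
    path = Path(path)
    subjects.to_csv(path, sep=_sep_for(path, sep), index=False, na_rep="NA")


def read_annotation(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep), na_values=_NA_VALUES,
                     keep_default_na=False)
    if "metabolite_id" not in df.columns:
        raise ValueError("annotation table must have a metabolite_id column")
    df = df.set_index("metabolite_id")
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate annotation for metabolite {dup!r}")
    return df


def write_annotation(annotation: pd.DataFrame, path: str | Path, sep: str | None = None) -> None:
    annotation.to_csv(Path(path), sep=_sep_for(Path(path), sep), na_rep="NA")


def read_truth(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    path = Path(path)
    # keep_default_na=False so the effect class "null" survives as a string
    df = pd.read_csv(path, sep=_sep_for(path, sep), keep_default_na=False,
                     na_values=[""]).set_index("metabolite_id")
    df.index = df.index.astype(str)
    return df


def write_cohort(cohort: Cohort, outdir: str | Path, config: SimConfig | None = None) -> dict:
    """Write the cohort tables plus a JSON sidecar echoing the config/seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "abundance": outdir / "abundance.csv",
        "subjects": outdir / "subjects.csv",
        "annotation": outdir / "annotation.csv",
        "truth": outdir / "truth.csv",
    }
    write_abundance(cohort.abundance, paths["abundance"])
    write_subjects(cohort.subjects, paths["subjects"])
    write_annotation(cohort.annotation, paths["annotation"])
    cohort.truth.to_csv(paths["truth"])
    if config is not None:
        sidecar = outdir / "sim_config.json"
        sidecar.write_text(json.dumps(config.to_dict(), indent=2) + "\n")
        paths["sim_config"] = sidecar
    return {k: str(v) for k, v in paths.items()}


def read_cohort(indir: str | Path) -> Cohort:
    indir = Path(indir)
    truth_path = indir / "truth.csv"
    return Cohort(
        abundance=read_abundance(indir / "abundance.csv"),
        subjects=read_subjects(indir / "subjects.csv"),
        annotation=read_annotation(indir / "annotation.csv"),
        truth=read_truth(truth_path) if truth_path.exists() else pd.DataFrame(),
    )


@dataclass
class ValidationReport:
    """Report-only cohort consistency check (nothing is modified)."""

    orphan_samples: list = field(default_factory=list)  # in abundance, unreferenced
    missing_samples: list = field(default_factory=list)  # referenced, not in abundance
    unpaired_subjects: list = field(default_factory=list)  # lacking a Q sample
    no_acute_subjects: list = field(default_factory=list)  # lacking both T0 and T6
    unannotated_metabolites: list = field(default_factory=list)

    @property
    def is_clean(self) -> bool:
        return not any(asdict(self).values())

    def to_dict(self) -> dict:
        return asdict(self)


def validate_cohort(
    abundance: pd.DataFrame,
    subjects: pd.DataFrame,
    annotation: pd.DataFrame | None = None,
) -> ValidationReport:
    """Cross-check the three tables; flags problems without fixing them."""
    report = ValidationReport()
    referenced: set[str] = set()
    for _, row in subjects.iterrows():
        for t in TIMEPOINTS:
            if pd.notna(row[t]):
                referenced.add(str(row[t]))
                if str(row[t]) not in abundance.index:
                    report.missing_samples.append(str(row[t]))
        if pd.isna(row["Q"]):
            report.unpaired_subjects.append(row["subject_id"])
        if pd.isna(row["T0"]) and pd.isna(row["T6"]):
            report.no_acute_subjects.append(row["subject_id"])
    report.orphan_samples = [s for s in abundance.index if s not in referenced]
    if annotation is not None:
        report.unannotated_metabolites = [
            m for m in abundance.columns if m not in annotation.index
        ]
    return report
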