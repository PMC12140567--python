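"""Cohort tables: per-subject covariates plus per-region values per modality.

The on-disk schema is one delimited text file per modality (TSV or CSV,
auto-detected from the extension). Each file carries the shared columns
``subject_id``, ``group``, ``age``, ``sex``, ``education`` followed by one
column per atlas region. Region columns may appear in any order; they are
restored to the canonical atlas order on read. Sex may be coded as text
(M/F) and is mapped to {1, 0}; the mapping is recorded on the table.

Missing values are rejected — there is no imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .atlas import RoiAtlas

COVARIATE_NAMES = ("age", "sex", "education")
_META_COLS = ("subject_id", "group") + COVARIATE_NAMES

SEX_CODING = {"M": 1, "F": 0, "m": 1, "f": 0, "male": 1, "female": 0}


@dataclass
class CohortTable:
    """A validated multi-modal cohort.

    Attributes
    ----------
    atlas
        The parcellation whose region order all ROI frames follow.
    modalities
        Ordered modality labels (layers of the multiplex network).
    covariates
        DataFrame indexed by subject_id with columns group, age, sex,
        education.
    roi
        Map modality -> DataFrame (subjects x regions) of ROI values,
        same subject index as ``covariates``, columns in atlas order.
    """

    atlas: RoiAtlas
    modalities: tuple[str, ...]
    covariates: pd.DataFrame
    roi: dict[str, pd.DataFrame]
    sex_coding: dict[str, int] = field(default_factory=lambda: dict(SEX_CODING))

    def __post_init__(self) -> None:
        self.validate()

    # -- basic properties ------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.covariates)

    @property
    def subject_ids(self) -> tuple[str, ...]:
        return tuple(self.covariates.index)

    def groups(self) -> tuple[str, ...]:
        seen: list[str] = []
        for g in self.covariates["group"]:
            if g not in seen:
                seen.append(g)
        return tuple(seen)

    def group_sizes(self) -> dict[str, int]:
        return self.covariates["group"].value_counts().to_dict()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if len(self.modalities) < 1:
            raise ValueError("cohort needs at least one modality")
        if self.covariates.index.has_duplicates:
            dupes = self.covariates.index[self.covariates.index.duplicated()]
            raise ValueError(f"duplicate subject_id: {sorted(set(dupes))}")
        for cov in COVARIATE_NAMES:
            if cov not in self.covariates.columns:
                raise ValueError(f"missing covariate column {cov!r}")
        if (self.covariates["age"] < 0).any():
            raise ValueError("negative age")
        if (self.covariates["education"] < 0).any():
            raise ValueError("negative education")
        for mod in self.modalities:
            if mod not in self.roi:
                raise ValueError(f"no ROI table for modality {mod!r}")
            frame = self.roi[mod]
            if tuple(frame.columns) != self.atlas.regions:
                raise ValueError(
                    f"{mod}: region columns do not match atlas order"
                )
            if not frame.index.equals(self.covariates.index):
                raise ValueError(f"{mod}: subject index mismatch")
            if not np.isfinite(frame.to_numpy(dtype=float)).all():
                bad = frame.columns[~np.isfinite(frame.to_numpy(dtype=float)).all(axis=0)]
                raise ValueError(f"{mod}: non-finite ROI values in {list(bad)}")

    # -- manipulation ----------------------------------------------------
    def subset(self, subject_ids: Iterable[str]) -> "CohortTable":
        ids = list(subject_ids)
        missing = [s for s in ids if s not in self.covariates.index]
        if missing:
            raise KeyError(f"unknown subject ids: {missing}")
        return CohortTable(
            atlas=self.atlas,
            modalities=self.modalities,
            covariates=self.covariates.loc[ids].copy(),
            roi={m: self.roi[m].loc[ids].copy() for m in self.modalities},
            sex_coding=self.sex_coding,
        )

    def concat(self, other: "CohortTable") -> "CohortTable":
        """Pool two cohorts (same atlas and modalities, disjoint subjects)."""
        if self.atlas.regions != other.atlas.regions:
            raise ValueError("cannot pool cohorts on different atlases")
        if self.modalities != other.modalities:
            raise ValueError("cannot pool cohorts with different modalities")
        return CohortTable(
            atlas=self.atlas,
            modalities=self.modalities,
            covariates=pd.concat([self.covariates, other.covariates]),
            roi={
                m: pd.concat([self.roi[m], other.roi[m]])
                for m in self.modalities
            },
            sex_coding=self.sex_coding,
        )


def _read_table(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    return pd.read_csv(path, sep=sep, dtype={"subject_id": str, "group": str})


def _coerce_sex(series: pd.Series) -> pd.Series:
    if series.dtype == object:
        mapped = series.map(lambda v: SEX_CODING.get(str(v).strip(), v))
        return pd.to_numeric(mapped, errors="raise")
    return series


def read_cohort(
    modality_paths: Mapping[str, str | Path], atlas: RoiAtlas
) -> CohortTable:
    """Read one delimited file per modality into a validated CohortTable.

    Region columns are reordered to the canonical atlas order; a subject
    must be present in every modality file with identical covariates.

    Raises
    ------
    ValueError
        On a missing region column, a subject present in one modality but
        not another, a non-numeric ROI cell, or a duplicate subject_id.
    """
    if not modality_paths:
        raise ValueError("no modality files given")
    covariates: pd.DataFrame | None = None
    roi: dict[str, pd.DataFrame] = {}
    modalities = tuple(modality_paths)
    for mod, p in modality_paths.items():
        path = Path(p)
        if not path.exists():
            raise FileNotFoundError(f"{mod}: no such file {path}")
        df = _read_table(path)
        for col in _META_COLS:
            if col not in df.columns:
                raise ValueError(f"{mod}: missing required column {col!r}")
        if df["subject_id"].duplicated().any():
            dupes = sorted(df.loc[df["subject_id"].duplicated(), "subject_id"])
            raise ValueError(f"{mod}: duplicate subject_id {dupes}")
        df = df.set_index("subject_id")
        missing = [r for r in atlas.regions if r not in df.columns]
        if missing:
            raise ValueError(f"{mod}: missing region column(s) {missing}")
        extra = [
            c for c in df.columns
            if c not in atlas.regions and c not in _META_COLS
        ]
        if extra:
            raise ValueError(f"{mod}: unexpected column(s) {extra}")
        values = df[list(atlas.regions)]
        try:
            values = values.apply(pd.to_numeric, errors="raise")
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{mod}: non-numeric ROI value ({exc})") from exc
        cov = df[["group"] + list(COVARIATE_NAMES)].copy()
        cov["sex"] = _coerce_sex(cov["sex"])
        cov["age"] = pd.to_numeric(cov["age"], errors="raise")
        cov["education"] = pd.to_numeric(cov["education"], errors="raise")
        if covariates is None:
            covariates = cov
        else:
            if set(cov.index) != set(covariates.index):
                only_here = sorted(set(cov.index) ^ set(covariates.index))
                raise ValueError(
                    f"subjects not shared across modalities: {only_here}"
                )
            cov = cov.loc[covariates.index]
            if not cov.equals(covariates):
                raise ValueError(
                    f"{mod}: covariates disagree with earlier modality file"
                )
        roi[mod] = values.loc[covariates.index]
    assert covariates is not None
    return CohortTable(
        atlas=atlas, modalities=modalities, covariates=covariates, roi=roi
    )


def write_cohort(
    cohort: CohortTable, modality_paths: Mapping[str, str | Path]
) -> None:
    """Write one delimited file per modality in the read_cohort schema."""
    for mod in cohort.modalities:
        path = Path(modality_paths[mod])
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
        out = pd.concat([cohort.covariates, cohort.roi[mod]], axis=1)
        out.index.name = "subject_id"
        out.to_csv(path, sep=sep)


def split_by_group(
    cohort: CohortTable, groups: Iterable[str]
) -> dict[str, CohortTable]:
    """Partition a cohort into one table per requested group label."""
    out: dict[str, CohortTable] = {}
    present = set(cohort.covariates["group"])
    for g in groups:
        if g not in present:
            raise ValueError(
                f"unknown group label {g!r}; present: {sorted(present)}"
            )
        ids = cohort.covariates.index[cohort.covariates["group"] == g]
        out[g] = cohort.subset(ids)
    return out
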