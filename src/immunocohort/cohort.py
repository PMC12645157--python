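"""Core cohort containers and table I/O.

The analysis operates on two tables: a subjects x immune-population
frequency matrix (percent-of-parent units, missing cells allowed) and a
subject metadata table carrying the case/control label, demographics,
spousal linkage, cognition band, APOE genotype, herpesvirus serostatus and
optional fluid biomarkers. Both are plain CSV/TSV on disk; in memory the
frequency matrix is a :class:`CohortTable` wrapping a pandas DataFrame and
the metadata a list of :class:`SubjectRecord`.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: strings accepted as a missing cell in frequency tables (written back as empty)
MISSING_MARKERS = frozenset({"", "NA", "NaN", "nan", "na"})

#: ordered Mini-Mental State Examination bands, best to worst cognition
MMSE_BANDS = ("25-30", "20-24", "10-19", "<10")


class CohortValidationError(ValueError):
    """Raised when an input table or metadata set violates a structural invariant."""


@dataclass
class CohortTable:
    """Subjects x immune-variable frequency matrix.

    Parameters
    ----------
    data
        DataFrame indexed by subject id with one column per immune variable.
        Values are percent-of-parent frequencies (0-100); ``NaN`` marks a
        missing cell. Variable names are hierarchical gate paths such as
        ``"B/naive/transitional"``.
    provenance
        Free-text note on where the table came from (file path, generator
        seed, or a description of the transform applied).
    scale
        ``"raw"`` for percent-of-parent frequencies (non-negativity
        enforced) or ``"transformed"`` for Box-Cox/z-scored values.
    """

    data: pd.DataFrame
    provenance: str = ""
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "transformed"):
            raise CohortValidationError(f"unknown scale {self.scale!r}")
        idx = self.data.index
        if idx.duplicated().any():
            dups = sorted(set(idx[idx.duplicated()]))
            raise CohortValidationError(f"duplicate subject ids: {dups}")
        cols = self.data.columns
        if cols.duplicated().any():
            dups = sorted(set(cols[cols.duplicated()]))
            raise CohortValidationError(f"duplicate variable names: {dups}")
        vals = self.data.to_numpy(dtype=float)
        if self.scale == "raw" and np.nanmin(vals, initial=0.0) < 0:
            bad = self.data.columns[(self.data < 0).any(axis=0)].tolist()
            raise CohortValidationError(f"negative frequencies in variables: {bad}")
        # normalise dtype once so downstream numpy views are cheap
        self.data = self.data.astype(float)

    # -- basic accessors -------------------------------------------------
    @property
    def subject_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def variable_names(self) -> list[str]:
        return [str(v) for v in self.data.columns]

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_variables(self) -> int:
        return self.data.shape[1]

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean DataFrame, True where a cell is missing."""
        return self.data.isna()

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def missing_fraction(self) -> pd.Series:
        """Per-variable fraction of missing cells."""
        return self.data.isna().mean(axis=0)

    def select_variables(self, names: list[str]) -> "CohortTable":
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise KeyError(f"variables not in table: {missing}")
        return CohortTable(self.data[names].copy(), provenance=self.provenance, scale=self.scale)

    def select_subjects(self, ids: list[str]) -> "CohortTable":
        missing = [s for s in ids if s not in self.data.index]
        if missing:
            raise KeyError(f"subjects not in table: {missing}")
        return CohortTable(self.data.loc[ids].copy(), provenance=self.provenance, scale=self.scale)


@dataclass
class SubjectRecord:
    """Clinical and demographic covariates for one cohort member."""

    subject_id: str
    group: str  # "AD" or "HC"
    age: float
    sex: str  # "M" or "F"
    spouse_id: Optional[str] = None
    mmse_band: Optional[str] = None
    apoe_e4: Optional[bool] = None
    ebv_pos: Optional[bool] = None
    cmv_pos: Optional[bool] = None
    biomarkers: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.group not in ("AD", "HC"):
            raise CohortValidationError(
                f"subject {self.subject_id}: group must be AD or HC, got {self.group!r}"
            )
        if self.sex not in ("M", "F"):
            raise CohortValidationError(
                f"subject {self.subject_id}: sex must be M or F, got {self.sex!r}"
            )
        if not np.isfinite(self.age) or self.age < 0:
            raise CohortValidationError(f"subject {self.subject_id}: invalid age {self.age}")
        if self.mmse_band is not None:
            if self.mmse_band not in MMSE_BANDS:
                raise CohortValidationError(
                    f"subject {self.subject_id}: unknown MMSE band {self.mmse_band!r}"
                )
            if self.group != "AD":
                raise CohortValidationError(
                    f"subject {self.subject_id}: MMSE band given for non-AD subject"
                )


def validate_metadata(records: list[SubjectRecord]) -> None:
    """Check cross-record invariants: unique ids, symmetric opposite-group spousal links."""
    by_id: dict[str, SubjectRecord] = {}
    for rec in records:
        rec.validate()
        if rec.subject_id in by_id:
            raise CohortValidationError(f"duplicate subject id in metadata: {rec.subject_id}")
        by_id[rec.subject_id] = rec
    for rec in records:
        if rec.spouse_id is None:
            continue
        partner = by_id.get(rec.spouse_id)
        if partner is None:
            raise CohortValidationError(
                f"subject {rec.subject_id} lists spouse {rec.spouse_id} who is not in the metadata"
            )
        if partner.spouse_id != rec.subject_id:
            raise CohortValidationError(
                "asymmetric spousal linkage between "
                f"{rec.subject_id} and {rec.spouse_id}"
            )
        if partner.group == rec.group:
            raise CohortValidationError(
                f"spouses {rec.subject_id} and {rec.spouse_id} are in the same group {rec.group}"
            )


@dataclass
class RunConfig:
    """Pipeline parameters. Defaults follow the published analysis where it states them."""

    missingness_threshold: float = 0.20
    knn_k: int = 3
    boxcox_bounds: tuple[float, float] = (-5.0, 5.0)
    n_folds: int = 10
    max_features: int = 200
    rf_depth_grid: tuple = (2, 3, 4, 5, 7, 10, None)
    rf_n_trees: int = 500
    ridge_penalty: float = 1.0
    n_simulated_pairings: int = 1000
    age_bin_width: float = 10.0
    master_seed: int = 0

    def validate(self) -> None:
        if not (0.0 < self.missingness_threshold < 1.0):
            raise CohortValidationError("missingness_threshold must lie in (0, 1)")
        if self.knn_k < 1:
            raise CohortValidationError("knn_k must be >= 1")
        lo, hi = self.boxcox_bounds
        if not lo < hi:
            raise CohortValidationError("boxcox_bounds must satisfy lower < upper")
        if self.n_folds < 2:
            raise CohortValidationError("n_folds must be >= 2")
        if self.max_features < 1:
            raise CohortValidationError("max_features must be >= 1")
        if self.n_simulated_pairings < 1:
            raise CohortValidationError("n_simulated_pairings must be >= 1")

    # one master seed expands into fixed per-stage offsets so any stage can
    # be rerun in isolation and reproduce the full-pipeline result
    _STAGE_OFFSETS = {
        "synthetic": 1,
        "preprocess": 2,
        "association": 3,
        "model_selection": 4,
        "forest": 5,
        "similarity": 6,
        "spousal": 7,
        "clinical": 8,
    }

    def stage_seed(self, stage: str) -> int:
        if stage not in self._STAGE_OFFSETS:
            raise KeyError(f"unknown stage {stage!r}")
        return (int(self.master_seed) * 1009 + self._STAGE_OFFSETS[stage]) % (2**31 - 1)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["boxcox_bounds"] = list(self.boxcox_bounds)
        d["rf_depth_grid"] = [x for x in self.rf_depth_grid]
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# file I/O


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def _parse_cell(raw, row_label, col_label) -> float:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return np.nan
    s = str(raw).strip()
    if s in MISSING_MARKERS:
        return np.nan
    try:
        return float(s)
    except ValueError:
        raise CohortValidationError(
            f"non-numeric frequency cell at subject {row_label!r}, variable {col_label!r}: {raw!r}"
        ) from None


def read_frequency_table(path: str | Path, provenance: str | None = None,
                         scale: str = "raw") -> CohortTable:
    """Read a subjects x variables frequency CSV/TSV (first column = subject id)."""
    path = Path(path)
    raw = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    if raw.shape[1] < 2:
        raise CohortValidationError(f"{path}: frequency table needs an id column and >=1 variable")
    id_col = raw.columns[0]
    parsed = pd.DataFrame(index=raw[id_col].astype(str))
    for col in raw.columns[1:]:
        parsed[col] = [
            _parse_cell(v, sid, col) for v, sid in zip(raw[col], raw[id_col])
        ]
    parsed.index.name = "subject_id"
    return CohortTable(parsed, provenance=provenance or str(path), scale=scale)


def write_frequency_table(table: CohortTable, path: str | Path) -> None:
    """Write a CohortTable; missing cells become empty fields."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = table.data.copy()
    out.index.name = "subject_id"
    out.to_csv(path, sep=_sep_for(path), na_rep="")


_BOOL_MAP = {"true": True, "1": True, "yes": True, "false": False, "0": False, "no": False}


def _parse_bool(raw) -> Optional[bool]:
    s = str(raw).strip()
    if s in MISSING_MARKERS:
        return None
    try:
        return _BOOL_MAP[s.lower()]
    except KeyError:
        raise CohortValidationError(f"cannot parse boolean field value {raw!r}") from None


_META_CORE = ["subject_id", "group", "age", "sex", "spouse_id", "mmse_band", "apoe_e4", "ebv_pos", "cmv_pos"]


def read_metadata(path: str | Path) -> list[SubjectRecord]:
    """Read the subject metadata table; extra columns are kept as biomarkers."""
    path = Path(path)
    raw = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    required = {"subject_id", "group", "age", "sex"}
    missing_cols = required - set(raw.columns)
    if missing_cols:
        raise CohortValidationError(f"{path}: metadata missing columns {sorted(missing_cols)}")
    biomarker_cols = [c for c in raw.columns if c not in _META_CORE]
    records = []
    for _, row in raw.iterrows():
        def opt(col):
            if col not in raw.columns:
                return None
            s = str(row[col]).strip()
            return None if s in MISSING_MARKERS else s

        biomarkers = {}
        for c in biomarker_cols:
            s = str(row[c]).strip()
            if s not in MISSING_MARKERS:
                biomarkers[c] = float(s)
        rec = SubjectRecord(
            subject_id=str(row["subject_id"]).strip(),
            group=str(row["group"]).strip(),
            age=float(row["age"]),
            sex=str(row["sex"]).strip(),
            spouse_id=opt("spouse_id"),
            mmse_band=opt("mmse_band"),
            apoe_e4=_parse_bool(row["apoe_e4"]) if "apoe_e4" in raw.columns else None,
            ebv_pos=_parse_bool(row["ebv_pos"]) if "ebv_pos" in raw.columns else None,
            cmv_pos=_parse_bool(row["cmv_pos"]) if "cmv_pos" in raw.columns else None,
            biomarkers=biomarkers,
        )
        records.append(rec)
    validate_metadata(records)
    return records


def write_metadata(records: list[SubjectRecord], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    biomarker_names = sorted({k for r in records for k in r.biomarkers})
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "group": r.group,
            "age": r.age,
            "sex": r.sex,
            "spouse_id": r.spouse_id or "",
            "mmse_band": r.mmse_band or "",
            "apoe_e4": "" if r.apoe_e4 is None else str(r.apoe_e4).lower(),
            "ebv_pos": "" if r.ebv_pos is None else str(r.ebv_pos).lower(),
            "cmv_pos": "" if r.cmv_pos is None else str(r.cmv_pos).lower(),
        }
        for b in biomarker_names:
            row[b] = r.biomarkers.get(b, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False)


def read_cohort(freq_path: str | Path, meta_path: str | Path) -> tuple[CohortTable, list[SubjectRecord]]:
    """Read and cross-validate the frequency table and metadata.

    Subjects present in only one of the two files are reported and dropped;
    the returned table and records cover the intersection, in frequency-table
    order.
    """
    table = read_frequency_table(freq_path)
    records = read_metadata(meta_path)
    table_ids = set(table.subject_ids)
    meta_ids = {r.subject_id for r in records}
    only_table = sorted(table_ids - meta_ids)
    only_meta = sorted(meta_ids - table_ids)
    if only_table:
        logger.warning("dropping %d subjects without metadata: %s", len(only_table), only_table)
    if only_meta:
        logger.warning("dropping %d subjects without frequencies: %s", len(only_meta), only_meta)
    keep = [s for s in table.subject_ids if s in meta_ids]
    if not keep:
        raise CohortValidationError("no subjects shared between frequency table and metadata")
    table = table.select_subjects(keep)
    kept_records = [r for r in records if r.subject_id in table_ids]
    # spousal links pointing at dropped subjects are severed, not fatal
    kept_ids = {r.subject_id for r in kept_records}
    for r in kept_records:
        if r.spouse_id is not None and r.spouse_id not in kept_ids:
            logger.warning("severing spousal link %s -> %s (partner dropped)", r.subject_id, r.spouse_id)
            r.spouse_id = None
    return table, kept_records


def metadata_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Metadata as a DataFrame indexed by subject id (convenience for modelling)."""
    rows = {
        r.subject_id: {
            "group": r.group,
            "age": r.age,
            "sex": r.sex,
            "spouse_id": r.spouse_id,
            "mmse_band": r.mmse_band,
            "apoe_e4": r.apoe_e4,
            "ebv_pos": r.ebv_pos,
            "cmv_pos": r.cmv_pos,
            **r.biomarkers,
        }
        for r in records
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "subject_id"
    return df
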