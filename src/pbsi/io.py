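"""Reading, validating and writing the tabular inputs and outputs.

File dialect: UTF-8 CSV with a single header row and ``subject_id`` as the
first column; TSV is accepted by delimiter sniffing.  Sex is stored as
``{"M", "F"}`` in files and mapped to a binary indicator internally
(``F`` = 1).  Region columns are reordered to canonical atlas order on read.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import MEASURE_CLASSES, RegionAtlas, default_atlas
from .errors import TableValidationError

logger = logging.getLogger(__name__)

SEX_TO_INDICATOR = {"M": 0, "F": 1}
INDICATOR_TO_SEX = {0: "M", 1: "F"}

#: Input file names, one wide table per measure class.
MEASURE_FILES = {m: f"{m}.csv" for m in MEASURE_CLASSES}
SUBJECTS_FILE = "subjects.csv"
CLINICAL_FILE = "clinical.csv"

CLINICAL_COLUMNS = (
    "panss_positive", "panss_negative", "panss_general", "panss_total",
    "gaf", "fsiq", "mq", "illness_duration", "antipsychotic_dose",
)


@dataclass
class MorphometryTable:
    """Subjects x regions for one measure class, plus per-subject metadata.

    ``values`` is indexed by ``subject_id`` with region columns in canonical
    atlas order; ``meta`` is indexed by ``subject_id`` with columns
    ``group``, ``site``, ``age`` and ``sex`` (binary indicator, ``F`` = 1).
    """

    measure_class: str
    values: pd.DataFrame
    meta: pd.DataFrame

    @property
    def subject_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_subjects(self) -> int:
        return len(self.values)

    def validate(self, atlas: RegionAtlas | None = None,
                 require_positive: bool = True) -> "MorphometryTable":
        """Check the table contract, raising :class:`TableValidationError`."""
        atlas = atlas or default_atlas()
        expected = list(atlas.regions_for(self.measure_class))
        if list(self.values.columns) != expected:
            missing = sorted(set(expected) - set(self.values.columns))
            if missing:
                raise TableValidationError(
                    f"{self.measure_class}: missing region columns {missing}"
                )
            raise TableValidationError(
                f"{self.measure_class}: region columns not in canonical order"
            )
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise TableValidationError(f"duplicated subject_id: {dupes}")
        if not self.values.index.equals(self.meta.index):
            raise TableValidationError("values and metadata subject_id mismatch")
        for col in ("group", "site"):
            if self.meta[col].isna().any():
                bad = self.meta.index[self.meta[col].isna()].tolist()
                raise TableValidationError(f"missing {col} label for {bad}")
        if (self.meta["age"] <= 0).any() or self.meta["age"].isna().any():
            raise TableValidationError("ages must be present and > 0")
        if require_positive and not (self.values.to_numpy() > 0).all():
            raise TableValidationError(
                f"{self.measure_class}: non-positive morphometric values"
            )
        return self

    def subset(self, subject_ids) -> "MorphometryTable":
        """Row subset preserving canonical column order."""
        ids = pd.Index(subject_ids)
        return MorphometryTable(
            self.measure_class,
            self.values.loc[ids].copy(),
            self.meta.loc[ids].copy(),
        )


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV/TSV with delimiter sniffing; first column is subject_id."""
    path = Path(path)
    if not path.exists():
        raise TableValidationError(f"file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    sep = "\t" if first.count("\t") > first.count(",") else ","
    frame = pd.read_csv(path, sep=sep, dtype={"subject_id": str},
                        float_precision="round_trip")
    if "subject_id" not in frame.columns:
        raise TableValidationError(f"{path}: no subject_id column")
    return frame.set_index("subject_id")


def read_subjects(path: str | Path) -> pd.DataFrame:
    """Read the metadata table: group, site, age, sex (M/F -> 0/1)."""
    meta = _read_table(path)
    required = {"group", "site", "age", "sex"}
    missing = required - set(meta.columns)
    if missing:
        raise TableValidationError(f"{path}: missing metadata columns {sorted(missing)}")
    bad_sex = ~meta["sex"].isin(SEX_TO_INDICATOR)
    if bad_sex.any():
        raise TableValidationError(
            f"{path}: sex must be M or F, got {meta.loc[bad_sex, 'sex'].unique().tolist()}"
        )
    meta = meta.copy()
    meta["sex"] = meta["sex"].map(SEX_TO_INDICATOR).astype(int)
    meta["age"] = pd.to_numeric(meta["age"], errors="raise")
    return meta[["group", "site", "age", "sex"]]


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read the clinical score table; validates the PANSS total identity.

    A mismatch between ``panss_total`` and the subscale sum warns rather
    than fails: real data may use prorated totals.
    """
    clinical = _read_table(path)
    for col in clinical.columns:
        clinical[col] = pd.to_numeric(clinical[col], errors="coerce")
    subscales = ["panss_positive", "panss_negative", "panss_general"]
    if all(c in clinical.columns for c in subscales + ["panss_total"]):
        summed = clinical[subscales].sum(axis=1, skipna=False)
        off = (clinical["panss_total"] - summed).abs() > 1e-8
        off &= clinical["panss_total"].notna() & summed.notna()
        if off.any():
            warnings.warn(
                f"panss_total differs from subscale sum for {int(off.sum())} subjects",
                stacklevel=2,
            )
    return clinical


def read_morphometry(path: str | Path, measure_class: str,
                     atlas: RegionAtlas | None = None,
                     meta: pd.DataFrame | None = None) -> MorphometryTable:
    """Read one wide measure table, reorder to atlas order and validate.

    Unknown extra region columns are dropped with a warning; a missing
    region column or a non-numeric cell is an error identifying the
    offending column (and row, for cells).
    """
    atlas = atlas or default_atlas()
    expected = list(atlas.regions_for(measure_class))
    frame = _read_table(path)

    missing = [r for r in expected if r not in frame.columns]
    if missing:
        raise TableValidationError(
            f"{path}: missing region columns for {measure_class}: {missing}"
        )
    extra = [c for c in frame.columns if c not in expected]
    if extra:
        warnings.warn(f"{path}: dropping unknown region columns {extra}", stacklevel=2)
    frame = frame[expected]

    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & frame.notna()
    if bad.to_numpy().any():
        row, col = next(zip(*np.nonzero(bad.to_numpy())))
        raise TableValidationError(
            f"{path}: non-numeric value at subject {frame.index[row]!r}, "
            f"region {frame.columns[col]!r}"
        )

    if meta is None:
        subjects_path = Path(path).with_name(SUBJECTS_FILE)
        meta = read_subjects(subjects_path)
    unmatched = numeric.index.difference(meta.index)
    if len(unmatched):
        raise TableValidationError(
            f"{path}: subjects absent from metadata: {unmatched.tolist()}"
        )
    table = MorphometryTable(measure_class, numeric, meta.loc[numeric.index])
    return table.validate(atlas)


def read_cohort(in_dir: str | Path, atlas: RegionAtlas | None = None):
    """Read all measure tables plus metadata and clinical scores.

    Returns ``(tables, meta, clinical)`` where ``tables`` maps measure class
    to :class:`MorphometryTable`.
    """
    in_dir = Path(in_dir)
    meta = read_subjects(in_dir / SUBJECTS_FILE)
    tables = {
        m: read_morphometry(in_dir / fname, m, atlas, meta)
        for m, fname in MEASURE_FILES.items()
    }
    clinical_path = in_dir / CLINICAL_FILE
    clinical = read_clinical(clinical_path) if clinical_path.exists() else None
    return tables, meta, clinical


def write_cohort(tables: dict[str, MorphometryTable], meta: pd.DataFrame,
                 clinical: pd.DataFrame | None, out_dir: str | Path) -> list[Path]:
    """Write measure tables, ``subjects.csv`` and ``clinical.csv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for measure, table in tables.items():
        path = out_dir / MEASURE_FILES[measure]
        table.values.to_csv(path, index_label="subject_id")
        written.append(path)

    meta_out = meta.copy()
    meta_out["sex"] = meta_out["sex"].map(INDICATOR_TO_SEX)
    path = out_dir / SUBJECTS_FILE
    meta_out.to_csv(path, index_label="subject_id")
    written.append(path)

    if clinical is not None:
        path = out_dir / CLINICAL_FILE
        clinical.to_csv(path, index_label="subject_id")
        written.append(path)
    return written


def config_hash(config: dict) -> str:
    """Stable sha256 over a JSON-serialisable config mapping."""
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode("utf-8")).hexdigest()


def write_results(results: dict[str, pd.DataFrame], out_dir: str | Path,
                  manifest: dict | None = None) -> list[Path]:
    """Write analysis outputs plus a run manifest.

    ``results`` maps logical names (``pbsi_scores``, ``group_differences``,
    ``clinical_correlations``, ``demographics``) to frames; empty frames
    produce header-only files.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - depends on fs permissions
        raise TableValidationError(f"cannot create output directory {out_dir}: {exc}")
    written: list[Path] = []
    for name, frame in results.items():
        path = out_dir / f"{name}.csv"
        index = frame.index.name is not None
        frame.to_csv(path, index=index)
        written.append(path)
    if manifest is not None:
        path = out_dir / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
        written.append(path)
    return written


# -- FreeSurfer stats-table shim --------------------------------------------

_FS_MEASURE_SUFFIX = {"thickness": "_thickness", "area": "_area", "volume": "_volume"}


def from_freesurfer_table(frame: pd.DataFrame, measure_class: str) -> pd.DataFrame:
    """Best-effort header cleanup for aparcstats2table/asegstats2table output.

    Strips the per-measure column suffix and renames the id column to
    ``subject_id``.  No values are computed or changed.
    """
    frame = frame.copy()
    first = frame.columns[0]
    if first != "subject_id":
        frame = frame.rename(columns={first: "subject_id"})
    suffix = _FS_MEASURE_SUFFIX.get(measure_class, "")
    if suffix:
        frame = frame.rename(
            columns={c: c.removesuffix(suffix) for c in frame.columns}
        )
    return frame
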