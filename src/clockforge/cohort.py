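"""Cohort table model, I/O, health labeling, panel selection, and harmonization.

A cohort table is one row per blood sample: identifiers, chronological age,
sex, collection year, a panel of biomarker columns (possibly missing), ICD-10
diagnosis codes, ATC medication codes, and optional outcome columns. The
health label ("healthy" = no recorded diagnosis and no chronic medication)
defines the population the age clock is trained on.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Columns that are part of the sample metadata rather than the biomarker panel.
CORE_COLUMNS = ("sample_id", "subject_id", "age", "sex", "collection_year")
CODE_COLUMNS = ("icd_codes", "atc_codes")

#: Illustrative chronic-medication ATC prefixes (antihypertensives, diabetes
#: drugs, lipid modifiers, antithrombotics, ...). Editable via configuration;
#: this is an example list, not a clinical reconstruction.
DEFAULT_CHRONIC_ATC_PREFIXES = frozenset(
    {"A10", "B01", "C01", "C03", "C07", "C08", "C09", "C10", "H03", "N06A"}
)


class SchemaError(ValueError):
    """A mandatory column is missing or mis-mapped."""


class RowError(ValueError):
    """Rows contain unparseable mandatory values."""


class EmptySelectionError(ValueError):
    """Joint sample/biomarker filtering converged to an empty table."""

    def __init__(self, msg: str, last_nonempty: "PanelSelection | None" = None):
        super().__init__(msg)
        self.last_nonempty = last_nonempty


class HarmonizationError(ValueError):
    """No common biomarkers between two panels."""


@dataclass(frozen=True)
class BiomarkerDescriptor:
    """One biomarker in a panel: name, units, and measurement count."""

    name: str
    units: str = ""
    n_measured: int = 0

    def __post_init__(self):
        if self.n_measured < 0:
            raise ValueError(f"n_measured must be >= 0, got {self.n_measured}")


@dataclass
class CohortTable:
    """Sample-level clinical table plus its biomarker panel.

    ``frame`` holds one row per sample with the core metadata columns,
    ``icd_codes``/``atc_codes`` as frozensets, one column per panel biomarker,
    optional outcome columns, and (after :func:`label_health`) a boolean
    ``healthy`` column.
    """

    frame: pd.DataFrame
    panel: list[BiomarkerDescriptor] = field(default_factory=list)

    def __post_init__(self):
        names = [b.name for b in self.panel]
        if len(names) != len(set(names)):
            raise ValueError("biomarker names must be unique within a panel")
        missing = [n for n in names if n not in self.frame.columns]
        if missing:
            raise ValueError(f"panel biomarkers missing from table: {missing}")

    @property
    def biomarker_names(self) -> list[str]:
        return [b.name for b in self.panel]

    @property
    def n_samples(self) -> int:
        return len(self.frame)

    @property
    def has_health_label(self) -> bool:
        return "healthy" in self.frame.columns

    def biomarker_matrix(self) -> pd.DataFrame:
        return self.frame[self.biomarker_names]

    def missing_fraction(self) -> float:
        mat = self.biomarker_matrix()
        if mat.size == 0:
            return 0.0
        return float(mat.isna().to_numpy().mean())

    def refresh_counts(self) -> "CohortTable":
        """Return a copy whose panel n_measured counts match the frame."""
        counts = self.biomarker_matrix().notna().sum()
        panel = [replace(b, n_measured=int(counts[b.name])) for b in self.panel]
        return CohortTable(self.frame, panel)

    def with_frame(self, frame: pd.DataFrame) -> "CohortTable":
        return CohortTable(frame, self.panel).refresh_counts()

    def healthy_subset(self) -> "CohortTable":
        if not self.has_health_label:
            raise ValueError("table has no health label; call label_health first")
        return self.with_frame(self.frame[self.frame["healthy"]].copy())


@dataclass(frozen=True)
class PanelSelection:
    """Result of joint sample/biomarker threshold filtering."""

    min_markers_per_sample: int
    min_presence_fraction: float
    retained_panel: tuple[str, ...]
    n_samples_retained: int
    missing_fraction: float
    retained_sample_ids: tuple = ()

    def to_json(self) -> str:
        d = {
            "min_markers_per_sample": self.min_markers_per_sample,
            "min_presence_fraction": self.min_presence_fraction,
            "retained_panel": list(self.retained_panel),
            "n_samples_retained": self.n_samples_retained,
            "missing_fraction": self.missing_fraction,
        }
        return json.dumps(d, indent=2)


def _split_codes(cell, delimiter: str) -> frozenset:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return frozenset()
    if isinstance(cell, (set, frozenset)):
        return frozenset(cell)
    s = str(cell).strip()
    if not s:
        return frozenset()
    return frozenset(tok.strip() for tok in s.split(delimiter) if tok.strip())


def read_cohort(
    path,
    schema: dict[str, str] | None = None,
    biomarker_columns: list[str] | None = None,
    code_delimiter: str = ";",
    sep: str = ",",
) -> CohortTable:
    """Read a delimited cohort table into a :class:`CohortTable`.

    Parameters
    ----------
    path : file path to a UTF-8 CSV/TSV with a header row.
    schema : mapping from canonical column names (``sample_id``, ``subject_id``,
        ``age``, ``sex``, ``collection_year``, ``icd_codes``, ``atc_codes``,
        outcome names) to the file's column names. Identity for omitted keys.
    biomarker_columns : columns to treat as the biomarker panel. If None, every
        column not mapped to a core/code/outcome name is taken as a biomarker.
    code_delimiter : delimiter inside list-valued ICD/ATC cells.
    """
    raw = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
    schema = dict(schema or {})
    rename = {v: k for k, v in schema.items() if v in raw.columns}
    missing_map = {k: v for k, v in schema.items() if v not in raw.columns}
    if missing_map:
        raise SchemaError(f"mapped columns not found in file: {missing_map}")
    df = raw.rename(columns=rename)

    for col in ("sample_id", "age", "sex"):
        if col not in df.columns:
            raise SchemaError(f"mandatory column '{col}' missing from cohort file")
    if "subject_id" not in df.columns:
        df["subject_id"] = df["sample_id"]
    if "collection_year" not in df.columns:
        df["collection_year"] = np.nan

    age = pd.to_numeric(df["age"], errors="coerce")
    bad = df.index[age.isna() | ~np.isfinite(age.fillna(np.inf))]
    if len(bad):
        raise RowError(f"unparseable age in rows {list(bad[:20])}")
    df["age"] = age.astype(float)
    if (df["age"] < 0).any():
        raise RowError("negative ages present")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()[:5]
        raise RowError(f"duplicate sample_id values, e.g. {dups}")

    for col in CODE_COLUMNS:
        if col in df.columns:
            df[col] = df[col].map(lambda c: _split_codes(c, code_delimiter))
        else:
            df[col] = [frozenset()] * len(df)

    known = set(CORE_COLUMNS) | set(CODE_COLUMNS) | set(schema)
    if biomarker_columns is None:
        biomarker_columns = [c for c in df.columns if c not in known]
    else:
        extra = [
            c for c in df.columns
            if c not in known and c not in biomarker_columns
        ]
        if extra:
            logger.warning("ignoring unmapped columns: %s", extra)
            df = df.drop(columns=extra)

    for c in biomarker_columns:
        df[c] = pd.to_numeric(df[c], errors="coerce")
        vals = df[c].dropna()
        if not np.isfinite(vals).all():
            raise RowError(f"non-finite biomarker values in column '{c}'")

    panel = [
        BiomarkerDescriptor(name=c, n_measured=int(df[c].notna().sum()))
        for c in biomarker_columns
    ]
    return CohortTable(df.reset_index(drop=True), panel)


def label_health(
    table: CohortTable,
    chronic_atc_prefixes: frozenset[str] | set[str] = DEFAULT_CHRONIC_ATC_PREFIXES,
) -> CohortTable:
    """Label each sample healthy iff it has no ICD code and no chronic medication.

    A medication counts as chronic when its ATC code starts with any prefix in
    ``chronic_atc_prefixes``. Idempotent; depends only on the code columns.
    """
    prefixes = tuple(chronic_atc_prefixes)

    def _is_healthy(row) -> bool:
        if row["icd_codes"]:
            return False
        return not any(code.startswith(prefixes) for code in row["atc_codes"])

    frame = table.frame.copy()
    if len(frame):
        frame["healthy"] = frame.apply(_is_healthy, axis=1)
    else:
        frame["healthy"] = pd.Series(dtype=bool)
    return CohortTable(frame, table.panel)


def select_panel(
    table: CohortTable,
    min_markers_per_sample: int,
    min_presence_fraction: float,
) -> PanelSelection:
    """Jointly filter biomarkers and samples to a fixed point.

    Repeatedly drop biomarkers measured in fewer than ``min_presence_fraction``
    of the current samples, then samples with fewer than
    ``min_markers_per_sample`` measured biomarkers, until nothing changes.
    """
    if table.n_samples == 0:
        raise EmptySelectionError("cannot select a panel from an empty table")
    mat = table.biomarker_matrix().notna()
    markers = list(mat.columns)
    rows = mat.index
    last = None
    while True:
        sub = mat.loc[rows, markers]
        if len(rows) == 0 or len(markers) == 0:
            raise EmptySelectionError(
                "filtering converged to an empty selection", last_nonempty=last
            )
        presence = sub.mean(axis=0)
        keep_markers = [m for m in markers if presence[m] >= min_presence_fraction]
        sub = mat.loc[rows, keep_markers]
        if len(keep_markers):
            counts = sub.sum(axis=1)
            keep_rows = rows[counts >= min_markers_per_sample]
        else:
            keep_rows = rows[:0] if min_markers_per_sample > 0 else rows
        changed = (len(keep_markers) != len(markers)) or (len(keep_rows) != len(rows))
        markers, rows = keep_markers, keep_rows
        if len(rows) and len(markers):
            obs = mat.loc[rows, markers]
            last = PanelSelection(
                min_markers_per_sample=min_markers_per_sample,
                min_presence_fraction=min_presence_fraction,
                retained_panel=tuple(markers),
                n_samples_retained=len(rows),
                missing_fraction=float(1.0 - obs.to_numpy().mean()),
                retained_sample_ids=tuple(table.frame.loc[rows, "sample_id"]),
            )
        if not changed:
            break
    if last is None or last.n_samples_retained == 0 or not last.retained_panel:
        raise EmptySelectionError(
            "filtering converged to an empty selection", last_nonempty=last
        )
    return last


def apply_selection(table: CohortTable, sel: PanelSelection) -> CohortTable:
    """Restrict a table to a selection's samples and biomarker panel."""
    keep_ids = set(sel.retained_sample_ids)
    frame = table.frame[table.frame["sample_id"].isin(keep_ids)].copy()
    drop = [n for n in table.biomarker_names if n not in sel.retained_panel]
    frame = frame.drop(columns=drop)
    panel = [b for b in table.panel if b.name in sel.retained_panel]
    return CohortTable(frame.reset_index(drop=True), panel).refresh_counts()


def scan_tradeoff(
    table: CohortTable,
    presence_grid: list[float],
    count_grid: list[int],
) -> list[PanelSelection]:
    """Evaluate the sample-count / panel-size trade-off over a threshold grid."""
    if not presence_grid or not count_grid:
        raise ValueError("grids must be non-empty")
    out = []
    for frac in presence_grid:
        for count in count_grid:
            try:
                out.append(select_panel(table, count, frac))
            except EmptySelectionError as err:
                logger.warning(
                    "grid point (presence=%s, count=%s) is empty: %s", frac, count, err
                )
    return out


def harmonize_panels(
    table_a: CohortTable,
    table_b: CohortTable,
    min_markers_per_sample: int,
) -> tuple[CohortTable, CohortTable]:
    """Restrict two cohorts to their common panel (by name and units).

    Samples with fewer than ``min_markers_per_sample`` of the common markers
    are dropped. Unit mismatches on a shared name fail loudly.
    """
    by_name_a = {b.name: b for b in table_a.panel}
    by_name_b = {b.name: b for b in table_b.panel}
    common, near_miss = [], []
    for name, ba in by_name_a.items():
        if name in by_name_b:
            if ba.units != by_name_b[name].units:
                raise HarmonizationError(
                    f"unit mismatch for '{name}': "
                    f"{ba.units!r} vs {by_name_b[name].units!r}"
                )
            common.append(name)
        else:
            near_miss.append(name)
    if not common:
        raise HarmonizationError(
            f"no common biomarkers; names only in one panel: {sorted(near_miss)[:10]}"
        )
    common = sorted(common)

    def _restrict(t: CohortTable) -> CohortTable:
        frame = t.frame.drop(
            columns=[n for n in t.biomarker_names if n not in common]
        ).copy()
        counts = frame[common].notna().sum(axis=1)
        frame = frame[counts >= min_markers_per_sample].reset_index(drop=True)
        panel = sorted(
            (b for b in t.panel if b.name in common), key=lambda b: b.name
        )
        return CohortTable(frame, list(panel)).refresh_counts()

    return _restrict(table_a), _restrict(table_b)


def subsample_balanced(
    table: CohortTable, max_per_age_year: int, seed: int
) -> CohortTable:
    """Cap the number of samples per integer age year (uniform, seeded)."""
    rng = np.random.default_rng(seed)
    frame = table.frame
    years = np.floor(frame["age"].to_numpy()).astype(int)
    keep = np.zeros(len(frame), dtype=bool)
    for year in np.unique(years):
        idx = np.flatnonzero(years == year)
        if len(idx) <= max_per_age_year:
            keep[idx] = True
        else:
            keep[rng.choice(idx, size=max_per_age_year, replace=False)] = True
    return table.with_frame(frame[keep].reset_index(drop=True))


def write_cohort(table: CohortTable, path, code_delimiter: str = ";") -> None:
    """Write a cohort table back to CSV (code sets joined by the delimiter)."""
    frame = table.frame.copy()
    for col in CODE_COLUMNS:
        if col in frame.columns:
            frame[col] = frame[col].map(lambda s: code_delimiter.join(sorted(s)))
    frame.to_csv(path, index=False)
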