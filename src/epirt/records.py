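"""Coded-event tables and the binary endorsement matrix.

A patient's electronic record is reduced here to a table of dated
diagnostic-code occurrences (one row per patient, code and date, with the
family practice the patient is registered at).  The analysis cohort is the
set of patients whose first qualifying coded event falls inside a study
window; that first event date is the patient's *index date*.  Each code is
then scored as endorsed (1) or not endorsed (0) per patient, an endorsement
being at least one occurrence of the code within a fixed number of days
after the index date.  The resulting binary patient x code matrix is the
observation set for the item-response models in :mod:`epirt.irt`.

Conventions
-----------
* Dates are ISO-8601 (``YYYY-MM-DD``) everywhere.
* The post-index endorsement window is closed, ``[index, index + w]`` days;
  ``"ever"`` means every occurrence on or after the index date counts.
* Codes that no cohort patient endorses are dropped from the matrix with a
  logged notice (code lists are routinely larger than the observed set).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging
from collections.abc import Mapping
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("epirt.records")

REQUIRED_COLUMNS = ("patient_id", "practice_id", "code", "event_date")
OPTIONAL_COLUMNS = ("term", "death_date")
DEFAULT_DIALECT = {c: c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS}


class DialectError(ValueError):
    """A required column could not be resolved in the input file."""


@dataclasses.dataclass(frozen=True)
class EventRecord:
    """One coded occurrence in a patient's record."""

    patient_id: str
    practice_id: str
    code: str
    event_date: dt.date
    term: str | None = None
    death_date: dt.date | None = None

    def __post_init__(self) -> None:
        for field in ("patient_id", "practice_id", "code"):
            if not getattr(self, field):
                raise ValueError(f"{field} must be non-empty")
        if not isinstance(self.event_date, dt.date):
            raise ValueError("event_date must be a calendar date")


@dataclasses.dataclass(frozen=True)
class CohortConfig:
    """Cohort and endorsement-window definition.

    Parameters
    ----------
    window_start, window_end
        Study window; a patient's index date is the earliest event date of
        any code inside ``[window_start, window_end]``.
    post_index_window_days
        Length in days of the closed endorsement window after the index
        date, or ``"ever"`` for all occurrences on or after the index date.
    require_death_after_index
        Exclude patients whose recorded date of death precedes their index
        date (a data-quality rule for administrative records).
    """

    window_start: dt.date
    window_end: dt.date
    post_index_window_days: int | str = 30
    require_death_after_index: bool = True

    def __post_init__(self) -> None:
        if self.window_start >= self.window_end:
            raise ValueError("window_start must precede window_end")
        if self.post_index_window_days != "ever":
            if int(self.post_index_window_days) < 0:
                raise ValueError("post_index_window_days must be >= 0 or 'ever'")


def _parse_date_column(series: pd.Series, name: str, allow_missing: bool = False) -> pd.Series:
    parsed = pd.to_datetime(series, format="%Y-%m-%d", errors="coerce")
    missing = series.isna() | (series.astype(str).str.strip() == "")
    bad = parsed.isna() & ~missing
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"unparseable {name} {series.iloc[row]!r} at data row {row + 1} "
            f"(expected ISO-8601 YYYY-MM-DD)"
        )
    if not allow_missing and missing.any():
        row = int(np.flatnonzero(missing.to_numpy())[0])
        raise ValueError(f"missing {name} at data row {row + 1}")
    return parsed


def load_events(path: str | Path, dialect: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a coded-event CSV into the canonical event table.

    Parameters
    ----------
    path
        CSV file with a header row.  Lines starting with ``#`` are ignored
        (generator provenance comments).
    dialect
        Optional map from canonical column names (``patient_id``,
        ``practice_id``, ``code``, ``event_date``, optionally ``term`` and
        ``death_date``) to the column names used in the file.

    Returns
    -------
    pandas.DataFrame
        One row per occurrence, canonical column names, ``event_date`` (and
        ``death_date`` when present) parsed to datetimes.  Row count equals
        the number of data rows in the file.
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    df = pd.read_csv(path, dtype=str, comment="#", skip_blank_lines=True)
    rename = {}
    for canon in REQUIRED_COLUMNS:
        src = dialect[canon]
        if src not in df.columns:
            raise DialectError(
                f"required column {src!r} (for {canon!r}) not found in {path}"
            )
        rename[src] = canon
    for canon in OPTIONAL_COLUMNS:
        src = dialect.get(canon)
        if src is not None and src in df.columns:
            rename[src] = canon
    df = df.rename(columns=rename)
    df = df[[c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in df.columns]]
    for field in ("patient_id", "practice_id", "code"):
        if df[field].isna().any() or (df[field].astype(str).str.strip() == "").any():
            raise ValueError(f"empty {field} in {path}")
    df["event_date"] = _parse_date_column(df["event_date"], "event_date")
    if "death_date" in df.columns:
        df["death_date"] = _parse_date_column(df["death_date"], "death_date", allow_missing=True)
    return df.reset_index(drop=True)


def write_events(events: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    """Write an event table in the dialect :func:`load_events` reads."""
    out = events.copy()
    canonical = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in out.columns]
    out = out[canonical + [c for c in out.columns if c not in canonical]]
    for col in ("event_date", "death_date"):
        if col in out.columns:
            out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        out.to_csv(fh, index=False)


def deduplicate_same_date(events: pd.DataFrame) -> pd.DataFrame:
    """Keep at most one record per (patient, code, date) triple.

    Repeat entries of the same code on the same day are administrative
    duplicates, not new clinical information.  The result is sorted by
    (patient, code, date), so it does not depend on the input row order,
    and the operation is idempotent.
    """
    key = ["patient_id", "code", "event_date"]
    out = events.sort_values(list(events.columns), kind="mergesort")
    out = out.drop_duplicates(subset=key, keep="first")
    return out.sort_values(key, kind="mergesort").reset_index(drop=True)


def build_cohort(
    events: pd.DataFrame,
    config: CohortConfig,
    death_dates: Mapping[str, dt.date] | pd.Series | None = None,
) -> pd.Series:
    """Assign each eligible patient a first-event index date.

    The index date is the earliest event date of any code within the study
    window.  Patients with no in-window event are excluded; so are patients
    whose death date precedes the index date when
    ``config.require_death_after_index`` is set.

    Returns
    -------
    pandas.Series
        Index: patient_id (sorted); values: index date (Timestamp).
    """
    start = pd.Timestamp(config.window_start)
    end = pd.Timestamp(config.window_end)
    in_win = events[(events["event_date"] >= start) & (events["event_date"] <= end)]
    index_dates = in_win.groupby("patient_id")["event_date"].min().sort_index()
    if config.require_death_after_index:
        deaths = _collect_death_dates(events, death_dates)
        if deaths is not None and len(deaths):
            mapped = index_dates.index.to_series().map(deaths)
            drop = mapped.notna() & (pd.to_datetime(mapped) < index_dates)
            n_drop = int(drop.sum())
            if n_drop:
                logger.info("excluding %d patients with death before index date", n_drop)
            index_dates = index_dates[~drop.to_numpy()]
    return index_dates


def _collect_death_dates(events, death_dates):
    if death_dates is not None:
        return pd.Series(death_dates)
    if "death_date" in events.columns and events["death_date"].notna().any():
        return events.dropna(subset=["death_date"]).groupby("patient_id")["death_date"].min()
    return None


@dataclasses.dataclass
class ResponseMatrix:
    """Binary patient x code endorsement matrix with practice assignments.

    ``X[s, i]`` is 1 iff patient ``s`` endorsed code ``i`` (at least one
    occurrence inside the post-index window).  Rows align with
    ``patient_ids`` / ``practice`` / ``index_dates``; columns with
    ``code_ids``.
    """

    X: np.ndarray
    patient_ids: np.ndarray
    code_ids: np.ndarray
    practice: np.ndarray
    index_dates: np.ndarray
    terms: dict | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.uint8)
        self.patient_ids = np.asarray(self.patient_ids)
        self.code_ids = np.asarray(self.code_ids)
        self.practice = np.asarray(self.practice)
        self.index_dates = np.asarray(self.index_dates)
        n, m = self.X.shape
        if not (len(self.patient_ids) == len(self.practice) == len(self.index_dates) == n):
            raise ValueError("patient-aligned fields must match the number of rows")
        if len(self.code_ids) != m:
            raise ValueError("code_ids must match the number of columns")
        if len(np.unique(self.patient_ids)) != n:
            raise ValueError("duplicated patient_id")
        if len(np.unique(self.code_ids)) != m:
            raise ValueError("duplicated code_id")
        if not np.isin(self.X, (0, 1)).all():
            raise ValueError("entries must be 0 or 1")
        if n and (self.X.sum(axis=1) == 0).any():
            raise ValueError("every patient must endorse at least one code")

    @property
    def n_patients(self) -> int:
        return self.X.shape[0]

    @property
    def n_codes(self) -> int:
        return self.X.shape[1]

    def endorsement_counts(self) -> pd.Series:
        return pd.Series(self.X.sum(axis=0), index=self.code_ids, name="n_endorsed")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=self.patient_ids, columns=self.code_ids)

    def write(self, out_dir: str | Path) -> None:
        """Write ``matrix.csv`` (patients x codes) and ``patients.csv`` sidecar."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        frame = self.to_frame()
        frame.index.name = "patient_id"
        frame.to_csv(out_dir / "matrix.csv")
        sidecar = pd.DataFrame(
            {
                "patient_id": self.patient_ids,
                "practice_id": self.practice,
                "index_date": pd.to_datetime(self.index_dates).strftime("%Y-%m-%d"),
            }
        )
        sidecar.to_csv(out_dir / "patients.csv", index=False)

    @classmethod
    def read(cls, out_dir: str | Path) -> "ResponseMatrix":
        out_dir = Path(out_dir)
        frame = pd.read_csv(out_dir / "matrix.csv", index_col="patient_id")
        sidecar = pd.read_csv(out_dir / "patients.csv", dtype={"patient_id": str})
        sidecar = sidecar.set_index("patient_id").loc[frame.index.astype(str)]
        return cls(
            X=frame.to_numpy(dtype=np.uint8),
            patient_ids=frame.index.to_numpy(dtype=str),
            code_ids=frame.columns.to_numpy(dtype=str),
            practice=sidecar["practice_id"].to_numpy(dtype=str),
            index_dates=pd.to_datetime(sidecar["index_date"]).to_numpy(),
        )


def build_response_matrix(
    events: pd.DataFrame, cohort: pd.Series, config: CohortConfig
) -> ResponseMatrix:
    """Score each (cohort patient, code) pair as endorsed / not endorsed.

    An entry is 1 iff the patient has at least one occurrence of the code
    with event date in the closed window ``[index, index + w]`` days (every
    date on or after the index when ``post_index_window_days == "ever"``).
    Codes with no endorsement over the cohort are dropped with a logged
    notice.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    ev = events[events["patient_id"].isin(cohort.index)].copy()
    idx = ev["patient_id"].map(cohort)
    if config.post_index_window_days == "ever":
        mask = ev["event_date"] >= idx
    else:
        w = pd.Timedelta(days=int(config.post_index_window_days))
        mask = (ev["event_date"] >= idx) & (ev["event_date"] <= idx + w)
    ev = ev[mask.to_numpy()]

    patient_ids = np.asarray(sorted(cohort.index))
    all_codes = np.asarray(sorted(events["code"].unique()))
    kept_codes = np.asarray(sorted(ev["code"].unique()))
    dropped = sorted(set(all_codes) - set(kept_codes))
    if dropped:
        logger.info(
            "dropping %d codes with zero endorsements over the cohort: %s",
            len(dropped),
            ", ".join(map(str, dropped[:10])) + ("..." if len(dropped) > 10 else ""),
        )

    p_index = pd.Index(patient_ids)
    c_index = pd.Index(kept_codes)
    rows = p_index.get_indexer(ev["patient_id"])
    cols = c_index.get_indexer(ev["code"])
    X = np.zeros((len(patient_ids), len(kept_codes)), dtype=np.uint8)
    X[rows, cols] = 1

    practice = (
        events.groupby("patient_id")["practice_id"].first().loc[patient_ids].to_numpy()
    )
    terms = None
    if "term" in events.columns:
        terms = events.dropna(subset=["term"]).groupby("code")["term"].first().to_dict()
    return ResponseMatrix(
        X=X,
        patient_ids=patient_ids,
        code_ids=kept_codes,
        practice=practice,
        index_dates=cohort.loc[patient_ids].to_numpy(),
        terms=terms,
    )
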