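"""Event-table I/O in a NONMEM-style rectangular dialect.

One CSV row per event, sorted by subject and time.  Columns:

======  ===================================================================
ID      subject identifier
TIME    hours since the subject's first dose (≥ 0, non-decreasing)
EVID    1 = dose event (rate start/change/stop), 0 = observation
AMT     amount (μg) infused during the segment a dose row opens (0 for stop)
RATE    infusion rate (μg/h) from this row's TIME on; 0 terminates infusion
DV      observed concentration (ng/mL) on observation rows
MDV     1 when DV is missing, else 0
WT, AGE, SEX, SOFA, INOTR, DUR   baseline covariates, constant per subject
======  ===================================================================

Dose semantics are *rate supersession*: each dose row replaces the active
infusion rate from its TIME onward, and a zero-rate row stops the infusion,
so a piecewise-constant history with k segments is written as k rate rows
plus one stop row.  The reader reconstructs segments from this rule and
fails hard, with row numbers, on semantic violations (negative times,
unsorted events, duplicate dose times, unterminated infusions, unknown
event codes, missing DV on observation rows).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import SubjectData
from .pk import InfusionSchedule

__all__ = ["EventTable", "EventTableError", "read_event_table", "write_event_table"]

DIALECT = "dexpopk-rate-v1"
_COVARIATE_COLS = {"WT": "weight", "AGE": "age", "SEX": "sex",
                   "SOFA": "sofa", "INOTR": "inotropes", "DUR": "duration"}
_CANONICAL = ["ID", "TIME", "EVID", "AMT", "RATE", "DV", "MDV",
              "WT", "AGE", "SEX", "SOFA", "INOTR", "DUR"]


class EventTableError(ValueError):
    """Semantic violation in an event table (message carries row numbers)."""


@dataclass
class EventTable:
    """Validated tidy event records with conversion to/from subject objects."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)
        self.validate()

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        df = self.data
        missing = [c for c in ("ID", "TIME", "EVID") if c not in df.columns]
        if missing:
            raise EventTableError(f"missing required columns: {missing}")
        bad = df.index[~df["EVID"].isin([0, 1])]
        if len(bad):
            raise EventTableError(f"unknown EVID code at rows {list(bad[:5])}")
        bad = df.index[df["TIME"] < 0]
        if len(bad):
            raise EventTableError(f"negative TIME at rows {list(bad[:5])}")
        for sid, grp in df.groupby("ID", sort=False):
            t = grp["TIME"].to_numpy()
            if np.any(np.diff(t) < 0):
                raise EventTableError(f"times not sorted within subject {sid!r}")
            doses = grp[grp["EVID"] == 1]
            if doses["TIME"].duplicated().any():
                raise EventTableError(
                    f"subject {sid!r}: duplicate dose times (overlapping infusions)"
                )
            if "RATE" in grp.columns and (doses["RATE"] < 0).any():
                raise EventTableError(f"subject {sid!r}: negative infusion rate")
            obs = grp[grp["EVID"] == 0]
            if len(obs):
                mdv = obs["MDV"].to_numpy() if "MDV" in obs.columns else np.zeros(len(obs))
                dv = obs["DV"].to_numpy() if "DV" in obs.columns else np.full(len(obs), np.nan)
                bad_rows = obs.index[(mdv == 0) & ~(np.isfinite(dv) & (dv > 0))]
                if len(bad_rows):
                    raise EventTableError(
                        f"subject {sid!r}: observation without positive DV at rows "
                        f"{list(bad_rows[:5])} (set MDV=1 to flag missing)"
                    )
            for col in _COVARIATE_COLS:
                if col in grp.columns and grp[col].nunique(dropna=False) > 1:
                    raise EventTableError(
                        f"subject {sid!r}: covariate {col} not constant within subject"
                    )

    # -- conversions ----------------------------------------------------
    @classmethod
    def from_subjects(cls, subjects: Sequence[SubjectData]) -> "EventTable":
        rows = []
        for s in subjects:
            cov = {
                key: s.covariates.get(name, np.nan)
                for key, name in _COVARIATE_COLS.items()
            }
            for a, b, r in s.schedule.segments:
                rows.append(
                    {"ID": s.id, "TIME": a, "EVID": 1, "AMT": r * (b - a),
                     "RATE": r, "DV": np.nan, "MDV": 1, **cov}
                )
            rows.append(
                {"ID": s.id, "TIME": s.schedule.end, "EVID": 1, "AMT": 0.0,
                 "RATE": 0.0, "DV": np.nan, "MDV": 1, **cov}
            )
            for t, dv in zip(s.obs_times, s.dv):
                rows.append(
                    {"ID": s.id, "TIME": t, "EVID": 0, "AMT": np.nan,
                     "RATE": np.nan, "DV": dv, "MDV": 0, **cov}
                )
        df = pd.DataFrame(rows, columns=_CANONICAL)
        df = df.sort_values(["ID", "TIME", "EVID"], kind="stable", ascending=[True, True, False])
        return cls(df)

    def to_subjects(self) -> list[SubjectData]:
        subjects = []
        for sid, grp in self.data.groupby("ID", sort=False):
            doses = grp[grp["EVID"] == 1].sort_values("TIME")
            if len(doses) == 0:
                raise EventTableError(f"subject {sid!r}: no dose events")
            if float(doses["RATE"].iloc[-1]) != 0.0:
                raise EventTableError(
                    f"subject {sid!r}: infusion never terminated (last dose row "
                    "must have RATE=0)"
                )
            segments = []
            times = doses["TIME"].to_numpy(dtype=float)
            rates = doses["RATE"].to_numpy(dtype=float)
            for i in range(len(doses) - 1):
                if rates[i] > 0:
                    segments.append((times[i], times[i + 1], rates[i]))
            obs = grp[(grp["EVID"] == 0) & (grp.get("MDV", 0) == 0)]
            cov = {}
            for col, name in _COVARIATE_COLS.items():
                if col in grp.columns and pd.notna(grp[col].iloc[0]):
                    cov[name] = grp[col].iloc[0]
            subjects.append(
                SubjectData(
                    id=sid,
                    schedule=InfusionSchedule(segments),
                    obs_times=obs["TIME"].to_numpy(dtype=float),
                    dv=obs["DV"].to_numpy(dtype=float),
                    covariates=cov,
                )
            )
        return subjects


def write_event_table(table: EventTable, path) -> None:
    """Write in canonical column order with fixed significant-digit
    formatting; the dialect is recorded in a leading comment line."""
    df = table.data.reindex(columns=_CANONICAL)
    buf = _io.StringIO()
    buf.write(f"# dialect={DIALECT}\n")
    df.to_csv(buf, index=False, float_format="%.9g")
    Path(path).write_text(buf.getvalue())


def read_event_table(path) -> EventTable:
    """Read and validate an event table; raises :class:`EventTableError`
    (with row context) on any semantic violation."""
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise EventTableError(f"cannot parse {path}: {exc}") from exc
    return EventTable(df)
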