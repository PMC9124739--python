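"""Event-record datasets for therapeutic drug monitoring studies.

The canonical on-disk format is a CSV with one row per dose, observation, or
covariate/status change, in the style of pharmacometric (NONMEM-like)
datasets:

======== =====================================================================
column   meaning
======== =====================================================================
id       subject identifier
time     event time in hours from the subject's first record
evid     0 = observation, 1 = dose, 2 = covariate / CytoSorb status change
amt      dose amount, mg (doses only)
rate     zero-order infusion rate, mg/h (doses only; every dose is an
         infusion — bolus rows are rejected)
dv       observed serum concentration, mg/L (observations with mdv = 0)
mdv      missing-dependent-variable flag, 0/1
effluent effluent flow (dialysate + substitution) in effect from this time
         forward, mL/h; blank = unchanged
cyto     CytoSorb in circuit from this time forward, 0/1; blank = unchanged
filter_id adsorber installation counter; 0 while cyto = 0, incremented at
         each new installation
======== =====================================================================

Covariates are stepwise-constant and left-closed: a value applies from the
record's time forward until the next record that sets it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

COLUMNS = [
    "id",
    "time",
    "evid",
    "amt",
    "rate",
    "dv",
    "mdv",
    "effluent",
    "cyto",
    "filter_id",
]


class DatasetError(ValueError):
    """Schema or consistency violation in an event dataset."""


@dataclass(frozen=True)
class EventRecord:
    """One row of the event timeline of a single subject."""

    id: str
    time: float
    evid: int
    amt: Optional[float] = None
    rate: Optional[float] = None
    dv: Optional[float] = None
    mdv: int = 0
    effluent: Optional[float] = None
    cyto: Optional[int] = None
    filter_id: Optional[int] = None

    def __post_init__(self) -> None:
        if self.evid not in (0, 1, 2):
            raise DatasetError(f"evid must be 0, 1 or 2, got {self.evid}")
        if self.time < 0 or not math.isfinite(self.time):
            raise DatasetError(f"time must be finite and >= 0, got {self.time}")
        if self.evid == 1:
            if self.amt is None or not self.amt > 0:
                raise DatasetError("dose row requires amt > 0")
            if self.rate is None or not self.rate > 0:
                raise DatasetError(
                    "infusion rate required: every dose is a zero-order "
                    "infusion (amt with rate); bolus rows are not accepted"
                )
        else:
            if self.amt is not None or self.rate is not None:
                raise DatasetError("amt/rate are only allowed on dose rows (evid=1)")
        if self.evid == 0:
            if self.mdv == 0 and self.dv is None:
                raise DatasetError("observation with mdv=0 requires dv")
            if self.mdv == 1 and self.dv is not None:
                raise DatasetError("observation with mdv=1 must not carry dv")
        elif self.dv is not None:
            raise DatasetError("dv is only allowed on observation rows (evid=0)")
        if self.effluent is not None and not self.effluent > 0:
            raise DatasetError("effluent must be > 0 when given")
        if self.cyto is not None and self.cyto not in (0, 1):
            raise DatasetError("cyto must be 0 or 1 when given")


@dataclass
class StudyDataset:
    """Ordered event timelines of a cohort, plus free-form provenance.

    Equality compares the event timelines only; ``metadata`` is provenance
    (seed, generator config, file origin) and does not take part in
    round-trip identity.
    """

    subjects: Dict[str, List[EventRecord]]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.subjects:
            raise DatasetError("dataset needs at least one subject")
        for sid, events in self.subjects.items():
            times = [e.time for e in events]
            if any(t1 < t0 for t0, t1 in zip(times, times[1:])):
                raise DatasetError(f"subject {sid}: times must be nondecreasing")
            _check_filter_ids(sid, events)

    def __eq__(self, other) -> bool:
        if not isinstance(other, StudyDataset):
            return NotImplemented
        return self.subjects == other.subjects

    @property
    def subject_ids(self) -> List[str]:
        return list(self.subjects)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def events_for(self, sid: str) -> List[EventRecord]:
        return self.subjects[sid]

    def observations(self) -> pd.DataFrame:
        """All usable observations with carried-forward covariate status."""
        rows = []
        for sid, events in self.subjects.items():
            cyto, rate_now = 0, 0.0
            infusions: List[tuple] = []  # (end_time, rate)
            for e in events:
                if e.cyto is not None:
                    cyto = e.cyto
                if e.evid == 1:
                    infusions.append((e.time + e.amt / e.rate, e.rate))
                elif e.evid == 0 and e.mdv == 0:
                    rate_now = sum(r for end, r in infusions if end > e.time)
                    rows.append(
                        {"id": sid, "time": e.time, "dv": e.dv,
                         "cyto": cyto, "infusion_rate": rate_now}
                    )
        return pd.DataFrame(rows, columns=["id", "time", "dv", "cyto", "infusion_rate"])

    def require_estimable(self) -> None:
        """Every subject must contribute >=1 dose and >=1 observation."""
        for sid, events in self.subjects.items():
            if not any(e.evid == 1 for e in events):
                raise DatasetError(f"subject {sid} has no dose record")
            if not any(e.evid == 0 and e.mdv == 0 for e in events):
                raise DatasetError(f"subject {sid} has no usable observation")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sid, events in self.subjects.items():
            for e in events:
                rows.append([sid, e.time, e.evid, e.amt, e.rate, e.dv,
                             e.mdv, e.effluent, e.cyto, e.filter_id])
        return pd.DataFrame(rows, columns=COLUMNS)


def _check_filter_ids(sid: str, events: Sequence[EventRecord]) -> None:
    prev_cyto = 0
    prev_filter = 0
    for i, e in enumerate(events):
        if e.cyto is None:
            continue
        if e.cyto == 1 and prev_cyto == 0:
            fid = e.filter_id
            if fid is None or fid <= prev_filter:
                raise DatasetError(
                    f"subject {sid}, event {i}: filter_id must strictly "
                    f"increase across cyto 0->1 transitions (last {prev_filter})"
                )
            prev_filter = fid
        prev_cyto = e.cyto


def _opt(value) -> Optional[float]:
    return None if pd.isna(value) else float(value)


def read_dataset(path, dialect: str = "canonical") -> StudyDataset:
    """Read and validate an event-record CSV.

    Headers are matched case-insensitively. Errors name the offending file
    row (1-based, counting the header as row 1) and the violated rule.
    """
    if dialect != "canonical":
        raise DatasetError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, float_precision="round_trip")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"missing required columns: {missing}")
    subjects: Dict[str, List[EventRecord]] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        rowno = i + 2
        try:
            rec = EventRecord(
                id=str(row.id),
                time=float(row.time),
                evid=int(row.evid),
                amt=_opt(row.amt),
                rate=_opt(row.rate),
                dv=_opt(row.dv),
                mdv=int(row.mdv) if not pd.isna(row.mdv) else 0,
                effluent=_opt(row.effluent),
                cyto=None if pd.isna(row.cyto) else int(row.cyto),
                filter_id=None if pd.isna(row.filter_id) else int(row.filter_id),
            )
        except (DatasetError, ValueError, TypeError) as exc:
            raise DatasetError(f"row {rowno}: {exc}") from exc
        subjects.setdefault(rec.id, []).append(rec)
    try:
        return StudyDataset(subjects, metadata={"source": str(path)})
    except DatasetError as exc:
        raise DatasetError(str(exc)) from exc


def write_dataset(ds: StudyDataset, path) -> None:
    """Write the canonical CSV; deterministic column order and formatting,
    losslessly round-trippable through :func:`read_dataset`."""
    df = ds.to_frame()
    df.to_csv(path, index=False, float_format="%.17g")


def iso_to_hours(timestamps: Iterable[str], origin: Optional[str] = None) -> np.ndarray:
    """Convert ISO-8601 timestamps to relative hours (from `origin` or the
    earliest timestamp). Convenience for preparing the canonical format."""
    ts = pd.to_datetime(list(timestamps))
    t0 = pd.to_datetime(origin) if origin is not None else ts.min()
    return ((ts - t0).total_seconds() / 3600.0).to_numpy()


def summarize_dataset(ds: StudyDataset) -> dict:
    """Cohort/treatment summary stratified by CytoSorb status.

    Returns counts (subjects, samples, adsorber sessions), per-stratum
    n / median / range of observed concentrations and concurrent infusion
    rates, and a Welch two-sample t-test comparing on- vs off-CytoSorb
    concentrations.  An empty stratum marks the comparison unavailable.
    """
    obs = ds.observations()
    n_sessions = 0
    for events in ds.subjects.values():
        prev = 0
        for e in events:
            if e.cyto is not None:
                if e.cyto == 1 and prev == 0:
                    n_sessions += 1
                prev = e.cyto
    out: dict = {
        "n_subjects": ds.n_subjects,
        "n_samples": int(len(obs)),
        "n_cytosorb_sessions": n_sessions,
    }
    for label, flag in (("on_cytosorb", 1), ("off_cytosorb", 0)):
        sub = obs[obs["cyto"] == flag]
        out[label] = {
            "n": int(len(sub)),
            "dv_median": float(sub["dv"].median()) if len(sub) else None,
            "dv_range": [float(sub["dv"].min()), float(sub["dv"].max())] if len(sub) else None,
            "rate_median": float(sub["infusion_rate"].median()) if len(sub) else None,
            "rate_range": [float(sub["infusion_rate"].min()),
                           float(sub["infusion_rate"].max())] if len(sub) else None,
        }
    on = obs.loc[obs["cyto"] == 1, "dv"].to_numpy()
    off = obs.loc[obs["cyto"] == 0, "dv"].to_numpy()
    if len(on) >= 2 and len(off) >= 2:
        t, p = stats.ttest_ind(on, off, equal_var=False)
        out["welch_t"] = float(t)
        out["welch_p"] = float(p)
        out["comparison_available"] = True
    else:
        out["welch_t"] = out["welch_p"] = None
        out["comparison_available"] = False
    return out
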