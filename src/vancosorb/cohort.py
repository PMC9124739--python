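"""Virtual TDM cohorts with the structure of a CytoSorb/CRRT vancomycin study.

Each virtual patient receives a loading infusion followed by a continuous
maintenance infusion, undergoes continuous renal replacement therapy with a
subject-level effluent flow, and gets a small number of CytoSorb sessions
(each installing a fresh adsorber).  Serum samples are drawn sparsely over
the study horizon plus once per adsorber session.  Observations are the
model prediction of the individual (lognormal clearance random effect) plus
additive Gaussian assay noise.

The default configuration (:func:`study_mimic_config`) reproduces the
structure of the clinical cohort the model was developed on: 7 patients,
20 adsorber sessions, ~160 samples of which ~15% fall inside sessions,
loading dose 1500 mg over 2 h, maintenance rates 20-125 mg/h, effluent
flows 1.5-3.0 L/h, session durations with median ~6 h.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .dataset import EventRecord, StudyDataset
from .model import build_segments, predict_concentrations, simulate_profile
from .params import PKParameters, reference_parameters


class CohortConfigError(ValueError):
    pass


@dataclass
class CohortConfig:
    """Generator configuration; every distribution choice is explicit.

    sessions_per_subject may be a single integer or one integer per subject.
    Session durations are lognormal (median ``session_duration_median_h``,
    log-SD ``session_duration_sigma_log``) truncated to
    ``session_duration_range_h``; maintenance rates are log-uniform over
    ``maintenance_rate_range``; effluent flows uniform over
    ``effluent_range``.  ``seed`` is mandatory.
    """

    seed: int
    n_subjects: int = 7
    horizon_h: float = 480.0
    obs_per_day: float = 1.0
    extra_obs_per_session: int = 1
    loading_dose_mg: float = 1500.0
    loading_duration_h: float = 2.0
    maintenance_rate_range: Tuple[float, float] = (20.0, 125.0)
    effluent_range: Tuple[float, float] = (1500.0, 3000.0)
    sessions_per_subject: Union[int, Sequence[int]] = 3
    session_duration_range_h: Tuple[float, float] = (1.7, 27.9)
    session_duration_median_h: float = 6.0
    session_duration_sigma_log: float = 0.60
    session_earliest_start_h: float = 12.0
    n_effluent_switchers: int = 0
    true_params: PKParameters = field(default_factory=reference_parameters)
    lloq: float = 0.0
    truncate_negative: bool = False
    simulate_method: str = "reference"  # "reference" (LSODA) or "fast"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise CohortConfigError("seed is mandatory")
        if self.n_subjects < 1 or self.horizon_h <= 0:
            raise CohortConfigError("need >=1 subject and positive horizon")
        for rng_ in (self.maintenance_rate_range, self.effluent_range,
                     self.session_duration_range_h):
            if not (0 < rng_[0] <= rng_[1]):
                raise CohortConfigError(f"range {rng_} not in positive support")

    def sessions_vector(self) -> List[int]:
        s = self.sessions_per_subject
        if isinstance(s, int):
            return [s] * self.n_subjects
        s = list(s)
        if len(s) != self.n_subjects:
            raise CohortConfigError("sessions_per_subject length != n_subjects")
        return s

    def to_dict(self) -> dict:
        d = asdict(self)
        d["true_params"] = self.true_params.to_dict()
        return d


@dataclass
class GroundTruth:
    """Everything needed to reconstruct the noiseless cohort."""

    params: PKParameters
    etas: Dict[str, float]
    noiseless: pd.DataFrame  # columns id, time, conc
    config: CohortConfig

    def to_json(self, path) -> None:
        payload = {
            "params": self.params.to_dict(),
            "etas": self.etas,
            "noiseless": self.noiseless.to_dict(orient="list"),
            "config": json.loads(json.dumps(self.config.to_dict(), default=float)),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def study_mimic_config(seed: int = 0) -> CohortConfig:
    """Frozen configuration matching the clinical study structure:
    7 subjects, 20 adsorber sessions (3,3,3,3,3,3,2), 20-day horizon with
    one routine sample per day plus one per session (expected ~161 samples,
    ~15-18% during sessions), 3 subjects with a mid-study effluent change."""
    return CohortConfig(
        seed=seed,
        n_subjects=7,
        sessions_per_subject=(3, 3, 3, 3, 3, 3, 2),
        n_effluent_switchers=3,
    )


def _draw_sessions(rng: np.random.Generator, cfg: CohortConfig, n_sessions: int
                   ) -> List[Tuple[float, float]]:
    """Non-overlapping (start, end) session windows inside the horizon."""
    lo, hi = cfg.session_duration_range_h
    out: List[Tuple[float, float]] = []
    for _ in range(n_sessions):
        for attempt in range(200):
            d = cfg.session_duration_median_h * math.exp(
                rng.normal(0.0, cfg.session_duration_sigma_log)
            )
            d = min(max(d, lo), hi)
            t_earliest = cfg.session_earliest_start_h
            if t_earliest + d >= cfg.horizon_h:
                raise CohortConfigError(
                    "session does not fit between earliest start and horizon"
                )
            start = rng.uniform(t_earliest, cfg.horizon_h - d)
            if all(start >= e + 1.0 or start + d <= s - 1.0 for s, e in out):
                out.append((start, start + d))
                break
        else:
            raise CohortConfigError(
                "could not place non-overlapping CytoSorb sessions; horizon "
                "too crowded for the configured session count/durations"
            )
    return sorted(out)


def generate_cohort(config: CohortConfig) -> Tuple[StudyDataset, GroundTruth]:
    """Draw one virtual cohort; deterministic given ``config.seed``."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    p = cfg.true_params
    sessions_per = cfg.sessions_vector()
    subjects: Dict[str, List[EventRecord]] = {}
    etas: Dict[str, float] = {}
    truth_rows = []
    switchers = set(
        rng.choice(cfg.n_subjects, size=min(cfg.n_effluent_switchers, cfg.n_subjects),
                   replace=False).tolist()
    ) if cfg.n_effluent_switchers else set()

    for si in range(cfg.n_subjects):
        sid = f"S{si + 1:02d}"
        eta = float(rng.normal(0.0, p.omega_cl)) if p.omega_cl > 0 else 0.0
        rate = float(np.exp(rng.uniform(*np.log(cfg.maintenance_rate_range))))
        effluent = float(rng.uniform(*cfg.effluent_range))
        sessions = _draw_sessions(rng, cfg, sessions_per[si])
        n_reg = int(round(cfg.obs_per_day * cfg.horizon_h / 24.0))
        reg_times = np.sort(rng.uniform(cfg.loading_duration_h, cfg.horizon_h, n_reg))
        extra_times = [
            rng.uniform(s, e)
            for s, e in sessions
            for _ in range(cfg.extra_obs_per_session)
        ]
        obs_times = np.sort(np.concatenate([reg_times, extra_times]))

        events: List[EventRecord] = [
            EventRecord(sid, 0.0, 2, effluent=effluent, cyto=0, filter_id=0),
            EventRecord(sid, 0.0, 1, amt=cfg.loading_dose_mg,
                        rate=cfg.loading_dose_mg / cfg.loading_duration_h),
            EventRecord(
                sid, cfg.loading_duration_h, 1,
                amt=rate * (cfg.horizon_h - cfg.loading_duration_h), rate=rate,
            ),
        ]
        if si in switchers:
            t_sw = float(rng.uniform(cfg.horizon_h * 0.25, cfg.horizon_h * 0.75))
            new_eff = float(rng.uniform(*cfg.effluent_range))
            events.append(EventRecord(sid, t_sw, 2, effluent=new_eff))
        for k, (s, e) in enumerate(sessions, start=1):
            events.append(EventRecord(sid, s, 2, cyto=1, filter_id=k))
            events.append(EventRecord(sid, e, 2, cyto=0, filter_id=0))

        seg = build_segments(sorted(events, key=lambda ev: ev.time),
                             horizon=cfg.horizon_h)
        if cfg.simulate_method == "fast":
            clean = predict_concentrations(p, eta, seg, obs_times)
        else:
            sim = simulate_profile(p, eta, sorted(events, key=lambda ev: ev.time),
                                   obs_times)
            clean = sim.conc
        noise = rng.normal(0.0, p.sigma_add, size=len(obs_times))
        dv = clean + noise
        if cfg.truncate_negative or cfg.lloq > 0:
            dv = np.maximum(dv, cfg.lloq)
        for t, c, y in zip(obs_times, clean, dv):
            events.append(EventRecord(sid, float(t), 0, dv=float(y)))
            truth_rows.append({"id": sid, "time": float(t), "conc": float(c)})
        events.sort(key=lambda ev: (ev.time, ev.evid != 2, ev.evid))
        subjects[sid] = events
        etas[sid] = eta

    ds = StudyDataset(
        subjects,
        metadata={"seed": cfg.seed, "generator": "vancosorb.cohort", "config": cfg.to_dict()},
    )
    truth = GroundTruth(
        params=p,
        etas=etas,
        noiseless=pd.DataFrame(truth_rows, columns=["id", "time", "conc"]),
        config=cfg,
    )
    return ds, truth
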