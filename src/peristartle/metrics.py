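"""Measured quantities of the startle/behavior battery.

Raw material comes in two shapes: per-trial piezo voltage traces (200
samples at nominal 1 ms spacing, one trace per acoustic burst) and raw
stopwatch/tracker times for the five behavioral tests.  Everything here
reduces those to the per-animal numbers the downstream scoring operates
on: trial startle amplitude (max peak-to-peak voltage in the first
200 ms), session ASR (mean over the 30 bursts of a session), baseline
ASR (mean of the three pre-stress sessions), and the behavioral
endpoints (percent-of-time ratios, the signed CPA shift score, and the
open-arm ratio).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)

#: number of 1 ms samples scored per trace (first 200 ms after burst onset)
TRACE_WINDOW = 200

#: canonical behavioral endpoint column names, in scoring order
ENDPOINTS = (
    "freezing_pct",
    "immobility_pct",
    "social_pct",
    "cpa_shift_s",
    "open_arm_pct",
)

#: endpoints expressed as a percentage of time (legal range [0, 100])
PERCENT_ENDPOINTS = frozenset(e for e in ENDPOINTS if e.endswith("_pct"))

SESSION_LABELS = ("base1", "base2", "base3", "post1h", "post24h")


@dataclass
class StartleSession:
    """One animal's startle session: the 30 per-trial amplitudes."""

    animal_id: int
    label: str
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.amplitudes.ndim != 1:
            raise InputError("amplitudes must be a 1-d sequence")
        if np.any(self.amplitudes < 0):
            raise InputError("trial amplitudes must be non-negative")


@dataclass
class BehavioralEndpoints:
    """Per-animal endpoint set for the five chronic tests.

    ``social_latency_s`` is recorded for completeness but carries no
    weight in the composite score.
    """

    freezing_pct: float
    immobility_pct: float
    social_pct: float
    cpa_shift_s: float
    open_arm_pct: float
    social_latency_s: float | None = field(default=None)

    def __post_init__(self) -> None:
        for name in PERCENT_ENDPOINTS:
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise InputError(f"{name}={v} outside [0, 100]")


def startle_amplitude(trace) -> float:
    """Maximal peak-to-peak voltage within the first 200 samples.

    The amplitude is ``max - min`` over the scored window, so it is
    invariant to DC offset and scales linearly with the trace.  Traces
    longer than 200 samples are truncated to the scored window; shorter
    traces are used whole (with a logged warning).
    """
    samples = np.asarray(trace, dtype=float).ravel()
    if samples.size == 0:
        raise InputError("empty startle trace")
    if not np.all(np.isfinite(samples)):
        raise InputError("startle trace contains non-finite values")
    if samples.size < TRACE_WINDOW:
        logger.warning(
            "trace has %d samples (< %d); scoring the full trace",
            samples.size,
            TRACE_WINDOW,
        )
    window = samples[:TRACE_WINDOW]
    return float(window.max() - window.min())


def session_asr(session) -> float:
    """Session-level ASR: arithmetic mean of the trial amplitudes."""
    if isinstance(session, StartleSession):
        amps = session.amplitudes
    else:
        amps = np.asarray(session, dtype=float).ravel()
    if amps.size == 0:
        raise InputError("session has no trial amplitudes")
    return float(amps.mean())


def session_asr_median(session) -> float:
    """Median-based session summary (robust alternative to the mean)."""
    if isinstance(session, StartleSession):
        amps = session.amplitudes
    else:
        amps = np.asarray(session, dtype=float).ravel()
    if amps.size == 0:
        raise InputError("session has no trial amplitudes")
    return float(np.median(amps))


def baseline_asr(session_means) -> float:
    """Baseline ASR: mean of exactly three daily pre-stress session means."""
    vals = np.asarray(session_means, dtype=float).ravel()
    if vals.size != 3:
        raise InputError(f"baseline requires exactly 3 session values, got {vals.size}")
    return float(vals.mean())


def time_ratio(part_s: float, total_s: float) -> float:
    """Percent of ``total_s`` spent in the scored state (freezing,
    immobility, social zone)."""
    if total_s <= 0:
        raise InputError("total time must be positive")
    if part_s < 0:
        raise InputError("part time must be non-negative")
    if part_s > total_s:
        raise InputError(f"part time {part_s} exceeds total time {total_s}")
    return 100.0 * part_s / total_s


def cpa_shift_score(pre_grid_s: float, post_grid_s: float) -> float:
    """CPA shift score: post-test minus pre-test time on the grid
    (shock-paired) floor, in seconds.  Negative = avoidance developed."""
    if pre_grid_s < 0 or post_grid_s < 0:
        raise InputError("compartment times must be non-negative")
    return float(post_grid_s - pre_grid_s)


def open_arm_ratio(open_s: float, closed_s: float) -> float:
    """EPM open-arm time as a percent of open-plus-closed arm time.

    Center-platform time is excluded by construction.
    """
    if open_s < 0 or closed_s < 0:
        raise InputError("arm times must be non-negative")
    total = open_s + closed_s
    if total <= 0:
        raise InputError("open + closed arm time must be positive")
    return 100.0 * open_s / total


def sessions_from_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Reduce a trial-level table to session ASR summaries.

    ``trials`` must carry ``animal_id``, ``session`` and either an
    ``amplitude`` column or ``sample_*`` voltage columns (in which case
    amplitudes are computed per trial).  Returns one row per
    (animal_id, session) with the session mean.
    """
    df = trials.copy()
    if "amplitude" not in df.columns:
        sample_cols = [c for c in df.columns if c.startswith("sample_")]
        if not sample_cols:
            raise InputError("trials table needs an 'amplitude' or sample_* columns")
        df["amplitude"] = [
            startle_amplitude(row) for row in df[sample_cols].to_numpy()
        ]
    out = (
        df.groupby(["animal_id", "session"], sort=True)["amplitude"]
        .apply(lambda s: session_asr(s.to_numpy()))
        .rename("asr")
        .reset_index()
    )
    return out


def endpoints_from_raw_times(raw: pd.DataFrame) -> pd.DataFrame:
    """Compute the five endpoints from raw times, one row per animal.

    ``raw`` is long-format with columns ``animal_id``, ``test`` and the
    test-specific time columns: ``part_s``/``total_s`` for freezing,
    immobility and social; ``pre_s``/``post_s`` for cpa; ``open_s`` /
    ``closed_s`` for epm.
    """
    records: dict[int, dict[str, float]] = {}
    for _, row in raw.iterrows():
        rec = records.setdefault(int(row["animal_id"]), {})
        test = str(row["test"]).lower()
        if test in ("freezing", "immobility", "social"):
            key = {"freezing": "freezing_pct", "immobility": "immobility_pct",
                   "social": "social_pct"}[test]
            rec[key] = time_ratio(float(row["part_s"]), float(row["total_s"]))
        elif test == "cpa":
            rec["cpa_shift_s"] = cpa_shift_score(float(row["pre_s"]), float(row["post_s"]))
        elif test == "epm":
            rec["open_arm_pct"] = open_arm_ratio(float(row["open_s"]), float(row["closed_s"]))
        else:
            raise InputError(f"unknown behavioral test {test!r}")
    out = pd.DataFrame.from_dict(records, orient="index").rename_axis("animal_id")
    missing = [e for e in ENDPOINTS if e not in out.columns]
    if missing:
        raise InputError(f"raw times missing tests for endpoints: {missing}")
    return out[list(ENDPOINTS)].sort_index().reset_index()
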