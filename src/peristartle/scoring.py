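"""Derived quantities: decline ratio, D/ND classification, rank-based
composite PTSD-like score, and the extreme-quarter subgroup split.

The composite score is deliberately nonparametric: each of the five
behavioral endpoints is converted to within-cohort ranks oriented so
that higher rank = more PTSD-like, and the per-animal composite is the
mean of its five ranks.  Rank sums are conserved per test
(``N(N+1)/2`` with average-rank ties), so the cohort mean composite is
exactly ``(N+1)/2``.
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import InputError
from .metrics import ENDPOINTS

#: default rank orientation per endpoint; "higher_is_worse" means larger
#: raw values rank as more PTSD-like.  Open-arm and CPA-shift
#: orientations follow the classical anxiety/avoidance reading and are
#: overridable in the analysis config.
DEFAULT_DIRECTIONS: dict[str, str] = {
    "freezing_pct": "higher_is_worse",
    "immobility_pct": "higher_is_worse",
    "social_pct": "lower_is_worse",
    "cpa_shift_s": "lower_is_worse",
    "open_arm_pct": "lower_is_worse",
}

#: decline-ratio cutoff (percent) separating Declined from Not-Declined
DEFAULT_CUTOFF = 10.0

#: fraction of the scored group labeled PTSD-like (and resilient)
DEFAULT_FRACTION = 0.25


def decline_ratio(before: float, after: float) -> float:
    """Percent startle attenuation relative to the pre-stress baseline.

    ``100 * (before - after) / before``; negative values indicate
    sensitization.  Scale-invariant in (before, after).
    """
    if before <= 0:
        raise InputError("baseline ASR must be positive (animal shows no startle)")
    if after < 0:
        raise InputError("post-stress ASR must be non-negative")
    return 100.0 * (before - after) / before


def classify_decline(ratio: float, cutoff: float = DEFAULT_CUTOFF) -> str:
    """Label a decline ratio Declined ("D") or Not-Declined ("ND").

    Ratios strictly above the cutoff are D; a ratio exactly at the
    cutoff is ND (the conservative, no-call-to-vulnerable side of the
    boundary, which the definition leaves open).
    """
    if not math.isfinite(cutoff):
        raise InputError("cutoff must be finite")
    return "D" if ratio > cutoff else "ND"


def rank_transform(values, direction: str = "higher_is_worse") -> np.ndarray:
    """Within-cohort ranks (1..N, average ties) oriented so that higher
    rank = more PTSD-like."""
    vals = np.asarray(values, dtype=float)
    if vals.ndim != 1 or vals.size < 2:
        raise InputError("rank_transform needs at least 2 values")
    bad = np.flatnonzero(~np.isfinite(vals))
    if bad.size:
        raise InputError(f"non-finite endpoint value at position(s) {bad.tolist()}")
    if direction == "higher_is_worse":
        oriented = vals
    elif direction == "lower_is_worse":
        oriented = -vals
    else:
        raise InputError(f"unknown rank direction {direction!r}")
    return rankdata(oriented, method="average")


def ptsd_score(rank_lists) -> np.ndarray:
    """Per-animal composite: mean of the five per-test ranks.

    ``rank_lists`` is a sequence of equally long rank arrays in the same
    animal order.  The cohort mean of the composites equals (N+1)/2.
    """
    arrays = [np.asarray(r, dtype=float) for r in rank_lists]
    if not arrays:
        raise InputError("no rank lists supplied")
    n = arrays[0].size
    if any(a.size != n for a in arrays):
        raise InputError("rank lists differ in length")
    return np.vstack(arrays).mean(axis=0)


def round_half_up(x: float) -> int:
    """Round with .5 going up (so 0.25 * 19 = 4.75 -> 5)."""
    return int(math.floor(x + 0.5))


def extreme_split(scores, fraction: float = DEFAULT_FRACTION, ids=None) -> list[str]:
    """Label the top quarter of composite scores "PTSD-like", the bottom
    quarter "resilient", and the rest "intermediate".

    ``k = round_half_up(fraction * N)`` animals go to each extreme.
    Ties straddling the k-th position are resolved deterministically by
    ascending animal id (or position, when ids are omitted).
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    if n < 2:
        raise InputError("extreme_split needs at least 2 scores")
    if not 0 < fraction < 1:
        raise InputError(f"fraction={fraction} outside (0, 1)")
    if ids is None:
        ids = np.arange(n)
    ids = np.asarray(ids)
    if ids.size != n:
        raise InputError("ids and scores differ in length")
    k = round_half_up(fraction * n)
    if 2 * k > n:
        raise InputError(f"extreme subgroups of size {k} would overlap in a group of {n}")
    order = sorted(range(n), key=lambda i: (scores[i], ids[i]))
    labels = ["intermediate"] * n
    for i in order[:k]:
        labels[i] = "resilient"
    for i in order[n - k:]:
        labels[i] = "PTSD-like"
    return labels


def score_cohort(
    animals: pd.DataFrame,
    directions: dict[str, str] | None = None,
    cutoff: float = DEFAULT_CUTOFF,
    fraction: float = DEFAULT_FRACTION,
) -> pd.DataFrame:
    """Full scoring pass over an ``animals.csv``-schema table.

    Ranks are computed over the pooled cohort (shock and control
    together) so the composite lives on one common scale; decline
    ratios, D/ND labels and the extreme split are computed per group.
    Returns one row per animal: the five ranks, the composite, the
    1 h / 24 h decline ratios and labels, and the subgroup label.
    """
    directions = dict(DEFAULT_DIRECTIONS, **(directions or {}))
    required = {"animal_id", "group", "baseline_asr", "asr_1h", "asr_24h", *ENDPOINTS}
    missing = required - set(animals.columns)
    if missing:
        raise InputError(f"animals table missing columns: {sorted(missing)}")
    df = animals.reset_index(drop=True)
    if (df["baseline_asr"] <= 0).any():
        raise InputError(
            "animals with non-positive baseline ASR must be excluded before scoring"
        )

    out = df[["animal_id", "group"]].copy()
    ranks = {}
    for ep in ENDPOINTS:
        ranks[ep] = rank_transform(df[ep].to_numpy(), directions[ep])
        out[f"rank_{ep}"] = ranks[ep]
    out["ptsd_score"] = ptsd_score([ranks[ep] for ep in ENDPOINTS])

    for tp, col in (("1h", "asr_1h"), ("24h", "asr_24h")):
        out[f"decline_ratio_{tp}"] = [
            decline_ratio(b, a) for b, a in zip(df["baseline_asr"], df[col])
        ]
        out[f"label_{tp}"] = [
            classify_decline(r, cutoff) for r in out[f"decline_ratio_{tp}"]
        ]

    out["subgroup"] = "intermediate"
    for _, idx in out.groupby("group").groups.items():
        sub = out.loc[idx]
        out.loc[idx, "subgroup"] = extreme_split(
            sub["ptsd_score"].to_numpy(), fraction, ids=sub["animal_id"].to_numpy()
        )
    return out
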