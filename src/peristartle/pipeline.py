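"""End-to-end analysis: from an animals table to the full report.

The report mirrors the study design of a cutoff-stratified startle
cohort: shock-vs-control comparisons on all five endpoints and the
composite score, D/ND (declined vs not-declined) comparisons at 1 h and
24 h within each group, a mixed-design ANOVA of ASR over time for the
extreme (PTSD-like vs resilient) quarters, and Spearman correlations
between decline ratios and the composite score.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import stats as st
from .errors import AnalysisError, InputError
from .metrics import ENDPOINTS
from .scoring import (
    DEFAULT_CUTOFF,
    DEFAULT_DIRECTIONS,
    DEFAULT_FRACTION,
    score_cohort,
)

logger = logging.getLogger(__name__)

TIMEPOINTS = ("baseline", "1h", "24h")
_ASR_COLS = {"baseline": "baseline_asr", "1h": "asr_1h", "24h": "asr_24h"}


@dataclass(frozen=True)
class AnalysisConfig:
    """Every analysis knob in one place (YAML-serializable)."""

    decline_cutoff: float = DEFAULT_CUTOFF
    extreme_fraction: float = DEFAULT_FRACTION
    rank_directions: dict = field(default_factory=lambda: dict(DEFAULT_DIRECTIONS))
    normality_alpha: float = st.NORMALITY_ALPHA
    test_policy: str = "auto"  # auto | t | mwu

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "rank_directions" in d:
            d["rank_directions"] = dict(DEFAULT_DIRECTIONS, **d["rank_directions"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class AnalysisReport:
    """Structured pipeline output; JSON-serializable via :meth:`to_dict`."""

    metadata: dict
    exclusions: list
    group_comparisons: dict
    decline: dict
    extremes: dict
    correlations: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisReport":
        return cls(**d)


def _sem(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return 0.0
    return float(x.std(ddof=1) / np.sqrt(x.size))


def _stat(res: st.StatResult | None) -> dict | None:
    return None if res is None else res.to_dict()


def _compare(a, b, policy, alpha, what: str) -> dict | None:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        logger.warning("skipping %s: subgroup too small (n=%d vs %d)",
                       what, a.size, b.size)
        return None
    return st.independent_two_sample(a, b, policy=policy, alpha=alpha).to_dict()


def run_analysis(animals: pd.DataFrame, config: AnalysisConfig | None = None,
                 seed: int | None = None) -> AnalysisReport:
    """Run the full comparison battery on an animals table.

    Deterministic: the report is a pure function of (table, config).
    Animals with non-positive baseline ASR are excluded up front (no
    observable startle); animals missing a timepoint are dropped from
    the affected comparisons only.
    """
    t0 = time.perf_counter()
    config = config or AnalysisConfig()
    required = {"animal_id", "group", "baseline_asr", "asr_1h", "asr_24h", *ENDPOINTS}
    missing = required - set(animals.columns)
    if missing:
        raise InputError(f"animals table missing columns: {sorted(missing)}")
    df = animals.reset_index(drop=True).copy()

    excluded = df[df["baseline_asr"] <= 0]
    exclusions = [
        {"animal_id": int(r.animal_id), "reason": "no observable startle (baseline ASR <= 0)"}
        for r in excluded.itertuples()
    ]
    for e in exclusions:
        logger.warning("excluding animal %d: %s", e["animal_id"], e["reason"])
    df = df[df["baseline_asr"] > 0].reset_index(drop=True)

    counts = df["group"].value_counts()
    for g in ("shock", "control"):
        if counts.get(g, 0) < 2:
            raise AnalysisError(f"group comparison impossible: {g} group has "
                                f"{counts.get(g, 0)} analyzable animals")

    scores = score_cohort(df, directions=config.rank_directions,
                          cutoff=config.decline_cutoff,
                          fraction=config.extreme_fraction)
    merged = df.merge(scores.drop(columns=["group"]), on="animal_id")
    shock = merged[merged["group"] == "shock"]
    control = merged[merged["group"] == "control"]
    logger.info("scored %d animals (%d shock, %d control) in %.2fs",
                len(merged), len(shock), len(control), time.perf_counter() - t0)

    policy, alpha = config.test_policy, config.normality_alpha

    # -- Shock vs control on each endpoint and the composite score
    t1 = time.perf_counter()
    group_comparisons = {}
    for col in (*ENDPOINTS, "ptsd_score"):
        a, b = shock[col].dropna(), control[col].dropna()
        group_comparisons[col] = {
            "shock_mean": float(a.mean()), "shock_sem": _sem(a),
            "control_mean": float(b.mean()), "control_sem": _sem(b),
            "result": _compare(a, b, policy, alpha, f"shock vs control on {col}"),
        }

    # -- D vs ND within each group at each timepoint
    decline: dict = {}
    for gname, gdf in (("shock", shock), ("control", control)):
        decline[gname] = {}
        for tp in ("1h", "24h"):
            sub = gdf.dropna(subset=[_ASR_COLS[tp]])
            d = sub[sub[f"label_{tp}"] == "D"]
            nd = sub[sub[f"label_{tp}"] == "ND"]
            block = {
                "n_declined": len(d),
                "n_not_declined": len(nd),
                "score_comparison": _compare(
                    d["ptsd_score"], nd["ptsd_score"], policy, alpha,
                    f"{gname} {tp} D vs ND composite score"),
                "endpoints": {},
            }
            for ep in ENDPOINTS:
                block["endpoints"][ep] = {
                    "declined_mean": float(d[ep].mean()) if len(d) else None,
                    "declined_sem": _sem(d[ep]) if len(d) else None,
                    "not_declined_mean": float(nd[ep].mean()) if len(nd) else None,
                    "not_declined_sem": _sem(nd[ep]) if len(nd) else None,
                    "result": _compare(d[ep], nd[ep], policy, alpha,
                                       f"{gname} {tp} D vs ND on {ep}"),
                }
            decline[gname][tp] = block

    # -- Mixed ANOVA on ASR over time, PTSD-like vs resilient extremes
    extremes: dict = {}
    for gname, gdf in (("shock", shock), ("control", control)):
        ext = gdf[gdf["subgroup"].isin(["PTSD-like", "resilient"])]
        ext = ext.dropna(subset=[_ASR_COLS[tp] for tp in TIMEPOINTS])
        if (ext["subgroup"] == "PTSD-like").sum() < 2 or \
           (ext["subgroup"] == "resilient").sum() < 2:
            logger.warning("skipping %s extremes mixed ANOVA: subgroup too small", gname)
            extremes[gname] = None
            continue
        matrix = ext[[_ASR_COLS[tp] for tp in TIMEPOINTS]].to_numpy()
        res = st.mixed_anova_simple_effects(ext["subgroup"].to_numpy(), matrix,
                                            timepoints=TIMEPOINTS)
        extremes[gname] = {
            "n_ptsd_like": int((ext["subgroup"] == "PTSD-like").sum()),
            "n_resilient": int((ext["subgroup"] == "resilient").sum()),
            "interaction": _stat(res["interaction"]),
            "between": _stat(res["between"]),
            "within": _stat(res["within"]),
            "simple_effects": {tp: _stat(r) for tp, r in res["simple_effects"].items()},
        }

    # -- Spearman correlations: decline ratio vs composite score
    correlations: dict = {}
    for gname, gdf in (("shock", shock), ("control", control)):
        for tp in ("1h", "24h"):
            key = f"{gname}_{tp}"
            sub = gdf.dropna(subset=[f"decline_ratio_{tp}", "ptsd_score"])
            if len(sub) < 3:
                logger.warning("skipping correlation %s: n=%d", key, len(sub))
                correlations[key] = None
                continue
            correlations[key] = st.spearman(
                sub[f"decline_ratio_{tp}"], sub["ptsd_score"]).to_dict()

    cfg_dict = config.to_dict()
    cfg_hash = hashlib.sha1(
        json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest()[:12]
    metadata = {
        "n_total": int(len(merged)),
        "n_shock": int(len(shock)),
        "n_control": int(len(control)),
        "n_excluded": len(exclusions),
        "seed": seed,
        "config": cfg_dict,
        "config_hash": cfg_hash,
    }
    logger.info("analysis battery finished in %.2fs", time.perf_counter() - t1)
    return AnalysisReport(metadata=metadata, exclusions=exclusions,
                          group_comparisons=group_comparisons, decline=decline,
                          extremes=extremes, correlations=correlations)


# --- report IO ---------------------------------------------------------

def _fmt_mean(x) -> str:
    return "" if x is None else f"{x:.1f}"


def _fmt_stat(res: dict | None, what: str) -> dict:
    if res is None:
        return {f"{what}_test": "", f"{what}_statistic": "", f"{what}_p": ""}
    return {
        f"{what}_test": res["test"],
        f"{what}_statistic": "" if res["statistic"] is None else f"{res['statistic']:.3f}",
        f"{what}_p": "" if res["p"] is None else f"{res['p']:.3f}",
    }


def write_report(report: AnalysisReport, outdir, formats=("json", "csv")) -> dict:
    """Write ``report.json`` (full precision) and/or presentation CSVs
    (means ± SEM at 1 decimal, statistics at 3 decimals)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    if "json" in formats:
        p = outdir / "report.json"
        p.write_text(json.dumps(report.to_dict(), indent=2))
        paths["json"] = p
    if "csv" in formats:
        rows = []
        for ep, blk in report.group_comparisons.items():
            rows.append({
                "endpoint": ep,
                "shock_mean": _fmt_mean(blk["shock_mean"]),
                "shock_sem": _fmt_mean(blk["shock_sem"]),
                "control_mean": _fmt_mean(blk["control_mean"]),
                "control_sem": _fmt_mean(blk["control_sem"]),
                **_fmt_stat(blk["result"], "group"),
            })
        p = outdir / "group_comparisons.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        paths["group_comparisons"] = p

        rows = []
        for gname, by_tp in report.decline.items():
            for tp, blk in by_tp.items():
                for ep, e in blk["endpoints"].items():
                    rows.append({
                        "group": gname, "timepoint": tp, "endpoint": ep,
                        "n_declined": blk["n_declined"],
                        "n_not_declined": blk["n_not_declined"],
                        "declined_mean": _fmt_mean(e["declined_mean"]),
                        "declined_sem": _fmt_mean(e["declined_sem"]),
                        "not_declined_mean": _fmt_mean(e["not_declined_mean"]),
                        "not_declined_sem": _fmt_mean(e["not_declined_sem"]),
                        **_fmt_stat(e["result"], "dnd"),
                    })
        p = outdir / "decline_subgroups.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        paths["decline_subgroups"] = p

        rows = []
        for key, res in report.correlations.items():
            group, tp = key.rsplit("_", 1)
            row = {"group": group, "timepoint": tp}
            if res is None:
                row.update({"r": "", "p": "", "n": ""})
            else:
                row.update({"r": f"{res['statistic']:.2f}", "p": f"{res['p']:.3f}",
                            "n": res["n"][0]})
            rows.append(row)
        p = outdir / "correlations.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        paths["correlations"] = p

        rows = []
        for gname, blk in report.extremes.items():
            if blk is None:
                rows.append({"group": gname, "effect": "interaction", "F": "",
                             "df1": "", "df2": "", "p": ""})
                continue
            effects = [("interaction", blk["interaction"]),
                       ("between", blk["between"]), ("within", blk["within"])]
            effects += [(f"simple_{tp}", r) for tp, r in blk["simple_effects"].items()]
            for name, res in effects:
                rows.append({
                    "group": gname, "effect": name,
                    "F": f"{res['statistic']:.3f}",
                    "df1": f"{res['df'][0]:g}", "df2": f"{res['df'][1]:g}",
                    "p": f"{res['p']:.3f}",
                })
        p = outdir / "extremes_anova.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        paths["extremes_anova"] = p
    return paths


def read_report(path) -> AnalysisReport:
    """Read a ``report.json`` back into an :class:`AnalysisReport`."""
    return AnalysisReport.from_dict(json.loads(Path(path).read_text()))
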