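"""The statistical battery used by the analysis pipeline.

All tests are two-sided and no multiple-testing correction is applied
anywhere in the pipeline — every comparison is reported at its nominal
level, and readers should treat the battery as descriptive, not as a
family-wise-controlled screen.

Group comparisons dispatch between a pooled-variance Student t and a
Mann–Whitney U according to a per-sample Shapiro–Wilk normality gate
(alpha = 0.05 per sample).  Mann–Whitney results are reported as a
tie-corrected normal-approximation Z when samples are moderately sized,
and by exact enumeration of the permutation distribution when the
pooled sample is small (total n <= 12).  Repeated-measures ANOVA is
uncorrected for sphericity (a Greenhouse–Geisser option is provided);
the mixed design reports the group-by-time interaction plus
per-timepoint simple effects computed as one-way between-group ANOVAs.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats as sps

from .errors import DegenerateDataError, InputError

#: per-sample Shapiro–Wilk level for the normality gate
NORMALITY_ALPHA = 0.05

#: pooled-n threshold below which Mann–Whitney p-values are enumerated exactly
EXACT_MWU_MAX_N = 12


@dataclass
class StatResult:
    """One test's outcome: statistic, degrees of freedom, p, sizes, direction."""

    test: str
    statistic: float
    p: float
    df: tuple[float, ...] | None = None
    n: tuple[int, ...] | None = None
    direction: str | None = None
    note: str | None = field(default=None)

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": None if self.statistic is None else float(self.statistic),
            "p": None if self.p is None else float(self.p),
            "df": None if self.df is None else [float(d) for d in self.df],
            "n": None if self.n is None else [int(v) for v in self.n],
            "direction": self.direction,
            "note": self.note,
        }


def _as_sample(x, name: str, min_n: int) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < min_n:
        raise InputError(f"{name} needs at least {min_n} observations, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise InputError(f"{name} contains non-finite values")
    return arr


def normality_gate(sample_a, sample_b, alpha: float = NORMALITY_ALPHA) -> str:
    """"gaussian" iff Shapiro–Wilk accepts normality for both samples.

    Zero-variance samples are degenerate and gate to "non_gaussian".
    """
    a = _as_sample(sample_a, "sample_a", 3)
    b = _as_sample(sample_b, "sample_b", 3)
    for s in (a, b):
        if np.ptp(s) == 0:
            return "non_gaussian"
        if sps.shapiro(s).pvalue <= alpha:
            return "non_gaussian"
    return "gaussian"


def _direction(a: np.ndarray, b: np.ndarray) -> str:
    ma, mb = np.median(a), np.median(b)
    if ma > mb:
        return "a>b"
    if mb > ma:
        return "b>a"
    return "none"


def _mwu_counts(a: np.ndarray, b: np.ndarray) -> tuple[float, np.ndarray]:
    """U statistic for sample a (rank-sum form) and the pooled ranks."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r1 = ranks[: a.size].sum()
    u1 = r1 - a.size * (a.size + 1) / 2.0
    return u1, ranks


def mann_whitney_exact(a, b) -> StatResult:
    """Exact two-sided Mann–Whitney p by enumerating every assignment of
    the pooled observations to the two groups (tie-aware via average
    ranks).  Intended for small samples; cost is C(n_a+n_b, n_a)."""
    a = _as_sample(a, "sample_a", 1)
    b = _as_sample(b, "sample_b", 1)
    u_obs, ranks = _mwu_counts(a, b)
    n1, n = a.size, a.size + b.size
    offset = n1 * (n1 + 1) / 2.0
    us = np.array(
        [sum(ranks[i] for i in comb) - offset
         for comb in itertools.combinations(range(n), n1)]
    )
    eps = 1e-9
    p_le = np.mean(us <= u_obs + eps)
    p_ge = np.mean(us >= u_obs - eps)
    p = min(1.0, 2.0 * min(p_le, p_ge))
    return StatResult("mwu_exact", float(u_obs), float(p), n=(n1, b.size),
                      direction=_direction(a, b))


def mann_whitney_z(a, b, continuity: bool = True) -> StatResult:
    """Mann–Whitney U with tie-corrected normal approximation, reported
    as a Z statistic (the form the literature prints for n ~ 19+19)."""
    a = _as_sample(a, "sample_a", 2)
    b = _as_sample(b, "sample_b", 2)
    u1, ranks = _mwu_counts(a, b)
    n1, n2 = a.size, b.size
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return StatResult("mwu_z", 0.0, 1.0, n=(n1, n2), direction="none",
                          note="all pooled values tied")
    diff = u1 - mu
    cc = 0.5 * np.sign(diff) if continuity else 0.0
    z = (diff - cc) / np.sqrt(var)
    p = float(2.0 * special.ndtr(-abs(z)))
    return StatResult("mwu_z", float(abs(z)), p, n=(n1, n2), direction=_direction(a, b))


def student_t(a, b) -> StatResult:
    """Pooled-variance two-sided independent-samples t."""
    a = _as_sample(a, "sample_a", 2)
    b = _as_sample(b, "sample_b", 2)
    res = sps.ttest_ind(a, b, equal_var=True)
    df = a.size + b.size - 2
    return StatResult("t", float(res.statistic), float(res.pvalue), df=(df,),
                      n=(a.size, b.size), direction=_direction(a, b))


def independent_two_sample(a, b, policy: str = "auto",
                           alpha: float = NORMALITY_ALPHA) -> StatResult:
    """Two-group comparison with the battery's dispatch rule.

    policy "auto": Shapiro–Wilk gate, t if both samples look gaussian,
    Mann–Whitney otherwise.  "t" and "mwu" force a branch.  The
    Mann–Whitney branch enumerates the exact permutation p when the
    pooled n is at most 12 and uses the tie-corrected Z otherwise.
    """
    a = _as_sample(a, "sample_a", 2)
    b = _as_sample(b, "sample_b", 2)
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return StatResult("t", 0.0, 1.0, df=(a.size + b.size - 2,),
                          n=(a.size, b.size), direction="none",
                          note="zero pooled variance, equal samples")
    if policy == "auto":
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            branch = "mwu"  # degenerate within-group variance
        elif min(a.size, b.size) < 3:
            branch = "mwu"  # too few observations for the normality gate
        else:
            branch = "t" if normality_gate(a, b, alpha) == "gaussian" else "mwu"
    elif policy in ("t", "mwu"):
        branch = policy
        if branch == "t" and np.ptp(a) == 0 and np.ptp(b) == 0:
            branch = "mwu"  # t undefined; fall back
    else:
        raise InputError(f"unknown test policy {policy!r}")
    if branch == "t":
        return student_t(a, b)
    if a.size + b.size <= EXACT_MWU_MAX_N:
        return mann_whitney_exact(a, b)
    return mann_whitney_z(a, b)


def paired_t(before, after) -> StatResult:
    """Two-sided paired t on the per-subject differences."""
    before = _as_sample(before, "before", 2)
    after = _as_sample(after, "after", 2)
    if before.size != after.size:
        raise InputError("paired samples differ in length")
    d = after - before
    if np.ptp(d) == 0:
        if d[0] == 0:
            return StatResult("paired_t", 0.0, 1.0, df=(d.size - 1,),
                              n=(d.size,), direction="none")
        raise DegenerateDataError(
            "paired differences are constant and nonzero; t is undefined"
        )
    res = sps.ttest_rel(after, before)
    return StatResult("paired_t", float(res.statistic), float(res.pvalue),
                      df=(d.size - 1,), n=(d.size,),
                      direction="a>b" if d.mean() < 0 else "b>a")


def _col(row, *names):
    """First present field among ``names`` (pingouin renamed p-unc ->
    p_unc across versions)."""
    for name in names:
        if name in row:
            return row[name]
    raise KeyError(names)


def _rm_long(matrix: np.ndarray) -> pd.DataFrame:
    n, k = matrix.shape
    return pd.DataFrame({
        "subject": np.repeat(np.arange(n), k),
        "time": np.tile([f"t{j}" for j in range(k)], n),
        "value": matrix.ravel(),
    })


def one_way_rm_anova(matrix, correction: str | None = None) -> StatResult:
    """One-way repeated-measures ANOVA over an animals x timepoints matrix.

    df = (k-1, (k-1)(n-1)); no sphericity correction by default
    (``correction="gg"`` applies Greenhouse–Geisser via pingouin).
    Fitted through statsmodels' AnovaRM.
    """
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise InputError("need a complete animals x timepoints matrix, both dims >= 2")
    if not np.all(np.isfinite(arr)):
        raise InputError("matrix contains missing or non-finite cells (no imputation)")
    n, k = arr.shape
    df1, df2 = k - 1, (k - 1) * (n - 1)
    col_means = arr.mean(axis=0)
    ss_time = n * np.sum((col_means - arr.mean()) ** 2)
    if np.isclose(ss_time, 0.0):
        return StatResult("rm_anova", 0.0, 1.0, df=(df1, df2), n=(n,),
                          direction="none")
    if correction == "gg":
        import pingouin as pg

        tbl = pg.rm_anova(data=_rm_long(arr), dv="value", within="time",
                          subject="subject", correction=True)
        row = tbl.iloc[0]
        eps = float(row["eps"])
        return StatResult("rm_anova_gg", float(row["F"]),
                          float(_col(row, "p-GG-corr", "p_GG_corr")),
                          df=(df1 * eps, df2 * eps), n=(n,))
    from statsmodels.stats.anova import AnovaRM

    tbl = AnovaRM(_rm_long(arr), "value", "subject", within=["time"]).fit().anova_table
    row = tbl.loc["time"]
    return StatResult("rm_anova", float(row["F Value"]), float(row["Pr > F"]),
                      df=(float(row["Num DF"]), float(row["Den DF"])), n=(n,))


def one_way_anova(groups) -> StatResult:
    """One-way between-groups ANOVA (used for simple effects).

    df = (g - 1, N - g).  Zero between- and within-group variance maps
    to F = 0, p = 1 rather than NaN.
    """
    arrays = [_as_sample(g, "group", 2) for g in groups]
    if len(arrays) < 2:
        raise InputError("need at least two groups")
    ntot = sum(a.size for a in arrays)
    df1, df2 = len(arrays) - 1, ntot - len(arrays)
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return StatResult("anova", 0.0, 1.0, df=(df1, df2),
                          n=tuple(a.size for a in arrays), direction="none")
    res = sps.f_oneway(*arrays)
    f = float(res.statistic)
    p = float(res.pvalue)
    if not np.isfinite(f):  # zero within-group variance, nonzero effect
        f, p = np.inf, 0.0
    return StatResult("anova", f, p, df=(df1, df2),
                      n=tuple(a.size for a in arrays))


def mixed_anova_simple_effects(between, within, timepoints=None) -> dict:
    """Mixed-design two-way ANOVA (group x timepoint) with simple effects.

    ``between`` holds one group label per animal; ``within`` is the
    complete animals x timepoints matrix.  Returns the interaction,
    between- and within-subject main effects (via pingouin's
    mixed_anova), plus per-timepoint simple effects computed as one-way
    between-group ANOVAs — for a 5+5 design over 3 timepoints this
    yields the (2, 16) interaction and (1, 8) simple-effect dfs.
    """
    arr = np.asarray(within, dtype=float)
    labels = np.asarray(between)
    if arr.ndim != 2:
        raise InputError("within must be an animals x timepoints matrix")
    if labels.size != arr.shape[0]:
        raise InputError("one between-group label is required per animal")
    if not np.all(np.isfinite(arr)):
        raise InputError("matrix contains missing or non-finite cells (no imputation)")
    levels = list(dict.fromkeys(labels.tolist()))
    if len(levels) < 2:
        raise InputError("need at least two between-group levels")
    if any(np.sum(labels == lv) < 2 for lv in levels):
        raise InputError("each between-group level needs at least 2 animals")
    n, k = arr.shape
    if timepoints is None:
        timepoints = [f"t{j}" for j in range(k)]
    timepoints = list(timepoints)
    if len(timepoints) != k:
        raise InputError("timepoint names must match the matrix width")

    long = _rm_long(arr)
    long["time"] = np.tile(timepoints, n)
    long["group"] = np.repeat(labels, k)

    if np.ptp(arr) == 0:
        zero = lambda d1, d2: StatResult("mixed_anova", 0.0, 1.0, df=(d1, d2))
        df_b = (len(levels) - 1, n - len(levels))
        df_w = (k - 1, (k - 1) * (n - len(levels)))
        out = {"between": zero(*df_b), "within": zero(*df_w),
               "interaction": zero(*df_w)}
    else:
        import pingouin as pg

        tbl = pg.mixed_anova(data=long, dv="value", within="time",
                             subject="subject", between="group")
        tbl = tbl.set_index("Source")

        def grab(source: str, name: str) -> StatResult:
            row = tbl.loc[source]
            f = float(row["F"])
            p = float(_col(row, "p-unc", "p_unc"))
            if not np.isfinite(f):
                f, p = 0.0, 1.0
            return StatResult(name, f, p,
                              df=(float(row["DF1"]), float(row["DF2"])))

        out = {
            "between": grab("group", "mixed_between"),
            "within": grab("time", "mixed_within"),
            "interaction": grab("Interaction", "mixed_interaction"),
        }

    simple = {}
    for j, tp in enumerate(timepoints):
        groups = [arr[labels == lv, j] for lv in levels]
        simple[tp] = one_way_anova(groups)
    out["simple_effects"] = simple
    out["levels"] = levels
    return out


def spearman(x, y) -> StatResult:
    """Spearman rank correlation: Pearson on average ranks, two-sided p
    via the t approximation."""
    x = _as_sample(x, "x", 3)
    y = _as_sample(y, "y", 3)
    if x.size != y.size:
        raise InputError("x and y differ in length")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("zero-variance input: correlation undefined")
    res = sps.spearmanr(x, y)
    r = float(res.statistic)
    return StatResult("spearman", r, float(res.pvalue), n=(x.size,),
                      direction="positive" if r > 0 else ("negative" if r < 0 else "none"))
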