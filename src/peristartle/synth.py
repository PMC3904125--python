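"""Synthetic cohort generator with a latent-vulnerability model.

The generator emulates a footshock-PTSD cohort of 19 shocked and 19
control rats in which a *binary latent trait* ("vulnerable" vs
"resilient") drives both the acute 1 h startle attenuation and the
chronic PTSD-like behavioral endpoints, while the 24 h attenuation is
drawn independently of the trait — so the 1 h decline ratio predicts
later behavior and the 24 h one does not.

Model, per shocked animal:

* latent class: vulnerable with probability ``vuln_prevalence``;
* 1 h decline ratio (percent) = ``base_decline + coupling_1h *
  1[vulnerable] + Normal(0, decline_noise_sd)``;
* 24 h decline ratio: the same two-component mixture shape, but with a
  class-independent mixing draw (weight ``decline_prevalence_24h``);
* each behavioral endpoint: a draw from its stratum's truncated normal
  (location solved so the *truncated* mean equals the configured
  stratum mean; percentages truncated to [0, 100], the CPA shift is
  unbounded);
* baseline ASR: lognormal with configured mean and CV; the 1 h / 24 h
  session ASR summaries are ``baseline * (1 - decline/100)``.

Controls draw endpoints from the control strata and "decline ratios"
from the zero-centered noise distribution alone.  Each animal consumes
an independent substream spawned from (seed, animal index), so cohorts
are reproducible and insertion-order independent.
"""
from __future__ import annotations

import dataclasses
import functools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, special, stats as sps

from .errors import ConfigError, InputError
from .metrics import ENDPOINTS, PERCENT_ENDPOINTS, SESSION_LABELS

STRATA = ("vulnerable", "resilient", "control")

#: documented default seed for the shipped calibration
DEFAULT_SEED = 1234

_MAX_DECLINE = 100.0  # a 100% decline means the startle vanished entirely


@dataclass(frozen=True)
class Stratum:
    """Target mean and (pre-truncation) SD of one endpoint stratum."""

    mean: float
    sd: float


@dataclass(frozen=True)
class CohortConfig:
    """Full parameterization of a synthetic cohort.

    ``endpoint_params`` maps endpoint -> stratum ("vulnerable",
    "resilient", "control") -> :class:`Stratum`.  Percent endpoints are
    in % of session time; the CPA shift is in seconds.  Decline-model
    units are percentage points of decline ratio.
    """

    n_shock: int
    n_control: int
    vuln_prevalence: float
    coupling_1h: float
    decline_noise_sd: float
    endpoint_params: dict
    base_decline: float = 0.0
    decline_prevalence_24h: float = 0.5
    baseline_asr_mean: float = 1500.0
    baseline_asr_cv: float = 0.5
    trials_per_session: int = 30
    trial_cv: float = 0.3
    session_cv: float = 0.08
    seed: int = DEFAULT_SEED

    def validate(self) -> None:
        if self.n_shock < 0:
            raise ConfigError("n_shock must be >= 0")
        if self.n_control < 0:
            raise ConfigError("n_control must be >= 0")
        for name in ("vuln_prevalence", "decline_prevalence_24h"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        for name in ("decline_noise_sd", "baseline_asr_cv", "trial_cv", "session_cv"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.baseline_asr_mean <= 0:
            raise ConfigError("baseline_asr_mean must be positive")
        if self.trials_per_session < 1:
            raise ConfigError("trials_per_session must be >= 1")
        if self.seed < 0 or self.seed >= 2**31:
            raise ConfigError("seed must be a non-negative 31-bit integer")
        for ep in ENDPOINTS:
            strata = self.endpoint_params.get(ep)
            if strata is None:
                raise ConfigError(f"endpoint_params missing endpoint {ep!r}")
            for stratum in STRATA:
                p = strata.get(stratum)
                if p is None:
                    raise ConfigError(f"endpoint_params[{ep!r}] missing stratum {stratum!r}")
                if p.sd < 0:
                    raise ConfigError(f"endpoint_params[{ep!r}][{stratum!r}].sd must be >= 0")
                if ep in PERCENT_ENDPOINTS and not 0.0 <= p.mean <= 100.0:
                    raise ConfigError(
                        f"endpoint_params[{ep!r}][{stratum!r}].mean={p.mean} outside [0, 100]"
                    )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["endpoint_params"] = {
            ep: {s: dataclasses.asdict(p) for s, p in strata.items()}
            for ep, strata in self.endpoint_params.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        d["endpoint_params"] = {
            ep: {s: Stratum(**p) for s, p in strata.items()}
            for ep, strata in d["endpoint_params"].items()
        }
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class AnimalRecord:
    """One animal's summaries: the unit of analysis."""

    animal_id: int
    group: str  # "shock" | "control"
    baseline_asr: float
    asr_1h: float
    asr_24h: float
    freezing_pct: float
    immobility_pct: float
    social_pct: float
    cpa_shift_s: float
    open_arm_pct: float
    baseline_sessions: tuple[float, float, float] | None = None


@dataclass
class CohortData:
    """A generated cohort plus its ground truth and provenance."""

    animals: list
    truth: list  # per-animal latent class: vulnerable | resilient | control
    config: CohortConfig
    seed: int
    sessions: dict | None = None  # animal_id -> {session label: amplitudes}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec, t in zip(self.animals, self.truth):
            d = dataclasses.asdict(rec)
            d.pop("baseline_sessions")
            d["latent_truth"] = t
            rows.append(d)
        return pd.DataFrame(rows)


# --- endpoint sampling -------------------------------------------------

@functools.lru_cache(maxsize=256)
def _matched_loc(mean: float, sd: float, lo: float, hi: float) -> float:
    """Location of a truncated normal on [lo, hi] with scale ``sd``
    whose truncated mean equals ``mean``."""
    if sd == 0:
        return mean
    if not lo < mean < hi:
        raise ConfigError(f"stratum mean {mean} not inside truncation range ({lo}, {hi})")

    def gap(mu: float) -> float:
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return sps.truncnorm.mean(a, b, loc=mu, scale=sd) - mean

    lo_mu, hi_mu, step = mean, mean, sd
    while gap(lo_mu) > 0:
        lo_mu -= step
        step *= 2
    step = sd
    while gap(hi_mu) < 0:
        hi_mu += step
        step *= 2
    if lo_mu == hi_mu:
        return lo_mu
    return float(optimize.brentq(gap, lo_mu, hi_mu, xtol=1e-9))


def _sample_truncnorm(rng, loc, scale, lo, hi, size=None):
    """Inverse-CDF truncated-normal draw (cheap, vectorizable)."""
    if scale == 0:
        return np.full(size, loc) if size is not None else loc
    a = special.ndtr((lo - loc) / scale)
    b = special.ndtr((hi - loc) / scale)
    u = rng.uniform(a, b, size)
    return loc + scale * special.ndtri(u)


def sample_endpoint(rng, endpoint: str, stratum: Stratum):
    """One draw of ``endpoint`` from the given stratum: truncated normal
    with mean-matched location on [0, 100] for percentages, plain normal
    for the (unbounded) CPA shift."""
    if endpoint in PERCENT_ENDPOINTS:
        loc = _matched_loc(stratum.mean, stratum.sd, 0.0, 100.0)
        return float(_sample_truncnorm(rng, loc, stratum.sd, 0.0, 100.0))
    return float(rng.normal(stratum.mean, stratum.sd))


# --- shipped calibration ----------------------------------------------

# Decline model constants of the shipped calibration.  The 10% cutoff
# sits midway between the resilient (0) and vulnerable (0 + 20) class
# means, so misclassification is balanced; the noise SD sets how
# tightly the 1 h decline tracks the latent trait.
_COUPLING_1H = 20.0
_DECLINE_NOISE_SD = 11.0


def _mixture_weight(target_prob: float, coupling: float, noise_sd: float,
                    cutoff: float = 10.0, base: float = 0.0) -> float:
    """Mixing weight w such that w*P(hi > cutoff) + (1-w)*P(lo > cutoff)
    equals ``target_prob`` for the two-component decline mixture."""
    p_hi = special.ndtr((base + coupling - cutoff) / noise_sd)
    p_lo = special.ndtr((base - cutoff) / noise_sd)
    w = (target_prob - p_lo) / (p_hi - p_lo)
    if not 0.0 <= w <= 1.0:
        raise ConfigError("decline mixture cannot reach the target rate")
    return float(w)


@functools.lru_cache(maxsize=1)
def default_config() -> CohortConfig:
    """The shipped calibration: a 19 + 19 cohort.

    Vulnerable/resilient endpoint strata carry the subgroup means, with
    SD recovered from the printed SEM times sqrt(subgroup n) (9
    declined, 10 not-declined).  The prevalence of the latent trait and
    the 24 h mixing weight are solved so that each shocked animal is
    Declined with probability 9/19 at 1 h and 11/19 at 24 h (putting
    the Binomial median counts at 9 and 11); the decline-noise SD is
    calibrated so the median within-shock Spearman correlation between
    1 h decline ratio and composite PTSD-like score is about 0.45.
    Control endpoint strata are package choices (see docs/methods.md).
    """
    s9, s10 = math.sqrt(9.0), math.sqrt(10.0)
    endpoint_params = {
        "open_arm_pct": {
            "vulnerable": Stratum(30.3, 8.8 * s9),
            "resilient": Stratum(50.6, 8.3 * s10),
            "control": Stratum(28.0, 20.0),
        },
        "social_pct": {
            "vulnerable": Stratum(2.44, 2.6 * s9),
            "resilient": Stratum(10.9, 4.8 * s10),
            "control": Stratum(16.0, 12.0),
        },
        "cpa_shift_s": {
            "vulnerable": Stratum(-12.1, 3.9 * s9),
            "resilient": Stratum(-13.8, 6.4 * s10),
            "control": Stratum(0.0, 15.0),
        },
        "immobility_pct": {
            "vulnerable": Stratum(36.6, 5.3 * s9),
            "resilient": Stratum(22.5, 2.8 * s10),
            "control": Stratum(17.0, 9.0),
        },
        "freezing_pct": {
            "vulnerable": Stratum(53.2, 8.2 * s9),
            "resilient": Stratum(39.5, 4.5 * s10),
            "control": Stratum(12.0, 10.0),
        },
    }
    return CohortConfig(
        n_shock=19,
        n_control=19,
        vuln_prevalence=_mixture_weight(9.0 / 19.0, _COUPLING_1H, _DECLINE_NOISE_SD),
        coupling_1h=_COUPLING_1H,
        decline_noise_sd=_DECLINE_NOISE_SD,
        decline_prevalence_24h=_mixture_weight(11.0 / 19.0, _COUPLING_1H,
                                               _DECLINE_NOISE_SD),
        endpoint_params=endpoint_params,
    )


# --- generation --------------------------------------------------------

def _animal_rng(seed: int, index: int):
    """Independent substream for one animal (stable in animal index)."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(index)]))


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    sigma2 = math.log(1.0 + cv * cv)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def generate_cohort(config: CohortConfig | None = None, seed: int | None = None,
                    with_sessions: bool = False) -> CohortData:
    """Draw one cohort.  Identical (config, seed) pairs yield identical
    cohorts; ``with_sessions`` additionally synthesizes per-session
    trial amplitudes whose means reproduce the stored ASR summaries
    exactly."""
    if config is None:
        config = default_config()
    config.validate()
    if seed is None:
        seed = config.seed
    if seed < 0 or seed >= 2**31:
        raise InputError("seed must be a non-negative 31-bit integer")

    mu_ln, sd_ln = _lognormal_params(config.baseline_asr_mean, config.baseline_asr_cv) \
        if config.baseline_asr_cv > 0 else (math.log(config.baseline_asr_mean), 0.0)

    animals: list[AnimalRecord] = []
    truth: list[str] = []
    sessions: dict[int, dict[str, np.ndarray]] = {}
    n_total = config.n_shock + config.n_control
    for i in range(n_total):
        rng = _animal_rng(seed, i)
        shocked = i < config.n_shock
        if shocked:
            vulnerable = rng.random() < config.vuln_prevalence
            stratum = "vulnerable" if vulnerable else "resilient"
            d1 = (config.base_decline
                  + config.coupling_1h * vulnerable
                  + rng.normal(0.0, config.decline_noise_sd))
            declined_24 = rng.random() < config.decline_prevalence_24h
            d24 = (config.base_decline
                   + config.coupling_1h * declined_24
                   + rng.normal(0.0, config.decline_noise_sd))
        else:
            stratum = "control"
            d1 = rng.normal(0.0, config.decline_noise_sd)
            d24 = rng.normal(0.0, config.decline_noise_sd)
        d1 = min(d1, _MAX_DECLINE)
        d24 = min(d24, _MAX_DECLINE)

        baseline = float(rng.lognormal(mu_ln, sd_ln)) if sd_ln > 0 \
            else config.baseline_asr_mean
        endpoints = {
            ep: sample_endpoint(rng, ep, config.endpoint_params[ep][stratum])
            for ep in ENDPOINTS
        }
        # three daily baseline sessions averaging exactly to the baseline ASR
        jitter = rng.normal(0.0, config.session_cv, 3)
        jitter -= jitter.mean()
        base_sessions = tuple(float(baseline * (1.0 + j)) for j in jitter)

        rec = AnimalRecord(
            animal_id=i + 1,
            group="shock" if shocked else "control",
            baseline_asr=baseline,
            asr_1h=baseline * (1.0 - d1 / 100.0),
            asr_24h=baseline * (1.0 - d24 / 100.0),
            baseline_sessions=base_sessions,
            **endpoints,
        )
        animals.append(rec)
        truth.append(stratum)
        if with_sessions:
            targets = dict(zip(("base1", "base2", "base3"), base_sessions))
            targets["post1h"] = rec.asr_1h
            targets["post24h"] = rec.asr_24h
            sessions[rec.animal_id] = {
                label: _session_trials(rng, target, config)
                for label, target in targets.items()
            }

    return CohortData(animals=animals, truth=truth, config=config, seed=seed,
                      sessions=sessions if with_sessions else None)


def _session_trials(rng, target_mean: float, config: CohortConfig) -> np.ndarray:
    """Positive trial amplitudes whose mean equals ``target_mean`` exactly."""
    n = config.trials_per_session
    if target_mean <= 0:
        return np.zeros(n)
    if config.trial_cv == 0:
        return np.full(n, target_mean)
    mu, sd = _lognormal_params(1.0, config.trial_cv)
    x = rng.lognormal(mu, sd, n)
    return target_mean * x / x.mean()


def generate_trace(amplitude: float, noise_sd: float = 0.0, n_samples: int = 200,
                   seed: int | None = None) -> np.ndarray:
    """Synthesize one piezo trace with a known peak-to-peak amplitude.

    A deterministic biphasic pulse (+amplitude/2 then -amplitude/2 on a
    zero baseline) plus optional white noise; with ``noise_sd = 0`` the
    peak-to-peak span of the trace equals ``amplitude`` exactly.
    """
    if n_samples < 2:
        raise InputError("a trace needs at least 2 samples")
    if amplitude < 0:
        raise InputError("amplitude must be non-negative")
    trace = np.zeros(n_samples)
    i_peak = n_samples // 4
    i_trough = min(n_samples - 1, i_peak + max(1, n_samples // 20))
    if i_trough == i_peak:
        i_trough = i_peak + 1
    trace[i_peak] = amplitude / 2.0
    trace[i_trough] = -amplitude / 2.0
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        trace = trace + rng.normal(0.0, noise_sd, n_samples)
    return trace


# --- persistence -------------------------------------------------------

def write_cohort(cohort: CohortData, outdir, write_trials: bool = False) -> dict:
    """Write ``animals.csv`` (+ optional ``trials.csv``) and the config.

    Returns the mapping of artifact name to path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    animals_path = outdir / "animals.csv"
    cohort.to_frame().to_csv(animals_path, index=False)
    paths["animals"] = animals_path

    cfg_path = outdir / "cohort_config.yaml"
    cohort.config.to_yaml(cfg_path)
    paths["config"] = cfg_path
    meta_path = outdir / "cohort_meta.json"
    meta_path.write_text(json.dumps({"seed": cohort.seed,
                                     "n_animals": len(cohort.animals)}, indent=2))
    paths["meta"] = meta_path

    if write_trials:
        if cohort.sessions is None:
            raise InputError("cohort was generated without sessions; "
                             "use generate_cohort(..., with_sessions=True)")
        rows = []
        for animal_id, by_label in cohort.sessions.items():
            for label in SESSION_LABELS:
                for j, amp in enumerate(by_label[label], start=1):
                    rows.append({"animal_id": animal_id, "session": label,
                                 "trial": j, "amplitude": amp})
        trials_path = outdir / "trials.csv"
        pd.DataFrame(rows).to_csv(trials_path, index=False)
        paths["trials"] = trials_path
    return paths


def read_cohort_frame(path) -> pd.DataFrame:
    """Read an ``animals.csv`` table back."""
    return pd.read_csv(path)
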