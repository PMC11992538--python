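"""Synthetic focal-sample generator.

Emulates the statistical structure the downstream analysis assumes, without
any field data: per-site behavioral time budgets, habitat covariates drawn
from site-level distributions, and dive-success counts linked to covariates
through a logistic model.

Within a sample, the bout sequence is a semi-Markov chain: the next behavior
is drawn from (covariate-adjusted) categorical selection weights with no
immediate self-transition, and bout lengths are exponential with a
behavior-specific mean.  For that chain the stationary share of bouts of
behavior *i* is proportional to ``w_i (1 - w_i)`` (weights normalized to sum
to 1), which makes the generator calibratable in closed form: given target
bout frequencies, the weights solving ``w_i (1 - w_i) = f_i / c`` with
``Σ w_i = 1`` reproduce them in expectation, and expected time shares are
then ``freq × mean bout length`` renormalized.

The default configuration encodes the three-river study design: site sample
sizes 12/34/41, ~300 s samples, site time budgets and bout frequencies from
the published summary tables, and site covariate means/sds likewise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

from .ethogram import BEHAVIORS, FORAGING, Bout, EnvironmentRecord, FocalSample, ForagingOutcome

__all__ = [
    "WeightEffect",
    "SuccessEffect",
    "SiteConfig",
    "SimConfig",
    "GroundTruth",
    "stationary_bout_shares",
    "weights_for_frequencies",
    "expected_time_percents",
    "simulate_sample",
    "simulate_dataset",
    "default_config",
]

_ENV_FIELDS = (
    "avg_fish_weight_g",
    "fish_biomass_g_m2",
    "temperature_C",
    "river_width_m",
    "water_depth_m",
    "water_velocity_m_s",
    "disturbance_number",
    "disturbance_duration_s",
    "disturbance_distance_m",
)

# Covariates that cannot go negative; draws are truncated (resampled) there.
_NONNEG = {
    "avg_fish_weight_g", "fish_biomass_g_m2", "river_width_m",
    "water_depth_m", "water_velocity_m_s", "disturbance_duration_s",
    "disturbance_distance_m",
}


@dataclass(frozen=True)
class WeightEffect:
    """Linear effect of a standardized covariate on a behavior's log weight."""

    behavior: str
    covariate: str
    coef: float


@dataclass(frozen=True)
class SuccessEffect:
    """Linear effect of a standardized covariate on logit dive-success."""

    covariate: str
    coef: float


@dataclass(frozen=True)
class SiteConfig:
    """Generative parameters for one site."""

    n_samples: int
    duration_mean_s: float
    duration_sd_s: float
    #: expected bouts per sample per behavior (calibration target; 0 = never)
    bout_frequency: Mapping[str, float]
    #: mean bout duration (s) per behavior with positive frequency
    mean_bout_s: Mapping[str, float]
    #: baseline per-dive success probability
    p_success: float
    #: covariate (mean, sd); mean NaN => always missing
    covariates: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not (0.0 <= self.p_success <= 1.0):
            raise ValueError("p_success must be in [0, 1]")
        freqs = dict(self.bout_frequency)
        unknown = set(freqs) - set(BEHAVIORS)
        if unknown:
            raise ValueError(f"unknown behaviors in bout_frequency: {unknown}")
        if any(f < 0 for f in freqs.values()):
            raise ValueError("bout frequencies must be >= 0")
        if not any(f > 0 for f in freqs.values()):
            raise ValueError("at least one behavior must have positive weight")
        for b, f in freqs.items():
            if f > 0 and not self.mean_bout_s.get(b, 0) > 0:
                raise ValueError(f"behavior {b!r} needs a positive mean bout length")


@dataclass(frozen=True)
class SimConfig:
    """Full generative configuration: per-site profiles, effects, seed."""

    sites: Mapping[str, SiteConfig]
    weight_effects: tuple[WeightEffect, ...] = ()
    success_effects: tuple[SuccessEffect, ...] = ()
    seed: int = 0


@dataclass
class GroundTruth:
    """Everything the generator knew: per-sample latents + the coefficients."""

    weight_effects: list[dict]
    success_effects: list[dict]
    records: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "weight_effects": self.weight_effects,
                    "success_effects": self.success_effects,
                    "records": self.records,
                },
                fh, indent=1,
            )


# ---------------------------------------------------------------------------
# Calibration: weights <-> stationary bout shares
# ---------------------------------------------------------------------------

def stationary_bout_shares(weights: np.ndarray) -> np.ndarray:
    """Stationary bout-type distribution of the no-self-transition chain.

    For next-state probabilities ``P(j→i) = w_i / (1 - w_j)`` (i ≠ j,
    Σw = 1) the stationary distribution is ``π_i ∝ w_i (1 - w_i)`` — a
    detailed-balance identity used both for calibration and as the test
    oracle's closed form.
    """
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    if w.size == 1:
        return np.ones(1)
    pi = w * (1.0 - w)
    return pi / pi.sum()


def weights_for_frequencies(freqs: np.ndarray) -> np.ndarray:
    """Selection weights whose stationary bout shares match ``freqs``.

    Solves ``w_i (1 - w_i) = f_i / c`` with ``Σ w_i = 1``.  The dominant
    behavior may need the upper quadratic root (its weight can exceed 1/2);
    the scale ``c`` is found by 1-D root finding.
    """
    f = np.asarray(freqs, dtype=float)
    if np.any(f < 0) or not np.any(f > 0):
        raise ValueError("frequencies must be >= 0 with at least one > 0")
    pos = f > 0
    fp = f[pos] / f[pos].sum()
    if fp.size == 1:
        w = np.zeros_like(f)
        w[pos] = 1.0
        return w
    k = int(np.argmax(fp))

    def total(c: float, big_root_for_max: bool) -> float:
        disc = np.clip(1.0 - 4.0 * fp / c, 0.0, None)
        w = (1.0 - np.sqrt(disc)) / 2.0
        if big_root_for_max:
            w[k] = (1.0 + math.sqrt(max(1.0 - 4.0 * fp[k] / c, 0.0))) / 2.0
        return float(w.sum())

    c_min = 4.0 * float(fp.max())
    # All-small-roots branch is feasible only if it can reach Σw = 1 at c_min.
    if total(c_min, False) >= 1.0:
        sol = brentq(lambda c: total(c, False) - 1.0, c_min, 1e6)
        big = False
    else:
        sol = brentq(lambda c: total(c, True) - 1.0, c_min * (1 + 1e-12), 1e9)
        big = True
    disc = np.clip(1.0 - 4.0 * fp / sol, 0.0, None)
    wp = (1.0 - np.sqrt(disc)) / 2.0
    if big:
        wp[k] = (1.0 + math.sqrt(max(1.0 - 4.0 * fp[k] / sol, 0.0))) / 2.0
    w = np.zeros_like(f)
    w[pos] = wp / wp.sum()
    return w


def expected_time_percents(site: SiteConfig) -> dict[str, float]:
    """Expected long-run time share (%) per behavior under the site profile."""
    f = np.array([site.bout_frequency.get(b, 0.0) for b in BEHAVIORS])
    mu = np.array([site.mean_bout_s.get(b, 0.0) for b in BEHAVIORS])
    t = f * mu
    t = 100.0 * t / t.sum()
    return dict(zip(BEHAVIORS, t))


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

from functools import lru_cache


@lru_cache(maxsize=256)
def _cached_weights(freqs: tuple[float, ...]) -> tuple[float, ...]:
    return tuple(weights_for_frequencies(np.array(freqs)))


def _draw_covariates(
    site: SiteConfig, rng: np.random.Generator
) -> dict[str, float]:
    env: dict[str, float] = {}
    for name in _ENV_FIELDS:
        mean, sd = site.covariates.get(name, (math.nan, 0.0))
        if math.isnan(mean):
            env[name] = math.nan
        elif name == "disturbance_number":
            env[name] = float(rng.poisson(mean))
        else:
            v = float(rng.normal(mean, sd))
            if name in _NONNEG:
                # resample into the support; fall back to hard clip
                for _ in range(8):
                    if v >= 0:
                        break
                    v = float(rng.normal(mean, sd))
                v = max(v, 0.0)
            env[name] = v
    # disturbance structure is zero-inflated: no events => no duration, and
    # the closest-approach distance is undefined (missing)
    if env.get("disturbance_number", 0.0) == 0.0 or math.isnan(
        env.get("disturbance_number", math.nan)
    ):
        if not math.isnan(env.get("disturbance_duration_s", math.nan)):
            env["disturbance_duration_s"] = 0.0
        env["disturbance_distance_m"] = math.nan
    return env


def _zscores(site: SiteConfig, env: Mapping[str, float]) -> dict[str, float]:
    z: dict[str, float] = {}
    for name in _ENV_FIELDS:
        mean, sd = site.covariates.get(name, (math.nan, 0.0))
        v = env.get(name, math.nan)
        if math.isnan(mean) or math.isnan(v) or sd <= 0:
            z[name] = 0.0
        else:
            z[name] = (v - mean) / sd
    return z


def simulate_sample(
    config: SimConfig,
    site_name: str,
    rng: np.random.Generator,
    sample_id: str | None = None,
) -> tuple[FocalSample, dict]:
    """One synthetic focal sample from the named site's profile.

    Returns the sample and its ground-truth record (latent success
    probability, covariate z-scores, realized allocation).
    """
    site = config.sites[site_name]
    env = _draw_covariates(site, rng)
    z = _zscores(site, env)

    # covariate-adjusted selection weights on the log scale
    w = np.array(
        _cached_weights(
            tuple(site.bout_frequency.get(b, 0.0) for b in BEHAVIORS)
        )
    )
    logw = np.where(w > 0, np.log(np.clip(w, 1e-300, None)), -np.inf)
    for eff in config.weight_effects:
        i = BEHAVIORS.index(eff.behavior)
        if w[i] > 0:
            logw[i] += eff.coef * z[eff.covariate]
    w = np.exp(logw - np.nanmax(logw[np.isfinite(logw)]))
    w[~np.isfinite(w)] = 0.0
    if not np.any(w > 0):
        raise ValueError(f"site {site_name!r}: all selection weights are zero")
    w = w / w.sum()

    mu = np.array([site.mean_bout_s.get(b, 1.0) for b in BEHAVIORS])
    total = max(30.0, float(rng.normal(site.duration_mean_s, site.duration_sd_s)))

    pos = np.flatnonzero(w > 0)
    behaviors_seq: list[int] = []
    durations: list[float] = []
    if pos.size == 1:
        behaviors_seq = [int(pos[0])]
        durations = [total]
    else:
        # per-previous-state cumulative distributions (no self-transition)
        cdfs: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        pi0 = np.zeros(len(BEHAVIORS))
        pi0[pos] = stationary_bout_shares(w[pos])
        cum0 = np.cumsum(pi0[pos])
        cur = int(pos[np.searchsorted(cum0, rng.random() * cum0[-1])])
        elapsed = 0.0
        while True:
            d = float(rng.exponential(mu[cur]))
            if elapsed + d >= total:
                d = total - elapsed
                behaviors_seq.append(cur)
                durations.append(d)
                break
            behaviors_seq.append(cur)
            durations.append(d)
            elapsed += d
            if cur not in cdfs:
                others = pos[pos != cur]
                cdfs[cur] = (others, np.cumsum(w[others]))
            others, cum = cdfs[cur]
            cur = int(others[np.searchsorted(cum, rng.random() * cum[-1])])

    bouts = []
    idx = 0
    for beh_i, dur in zip(behaviors_seq, durations):
        if dur <= 0:  # zero-length truncated tail: drop
            continue
        bouts.append(Bout(behavior=BEHAVIORS[beh_i], duration=dur, index=idx))
        idx += 1

    n_dive = sum(1 for b in bouts if b.behavior == "diving")
    n_other_forage = sum(
        1 for b in bouts if b.behavior in FORAGING and b.behavior != "diving"
    )
    p0 = site.p_success
    if p0 <= 0.0:
        p = 0.0
    elif p0 >= 1.0:
        p = 1.0
    else:
        eta = float(logit(p0)) + sum(
            eff.coef * z[eff.covariate] for eff in config.success_effects
        )
        p = float(expit(eta))
    success = int(rng.binomial(n_dive, p)) if n_dive > 0 else 0
    failure = (n_dive - success) + n_other_forage

    sample = FocalSample(
        sample_id=sample_id or f"{site_name}-{rng.integers(1 << 30)}",
        site=site_name,
        bouts=tuple(bouts),
        outcome=ForagingOutcome(success_count=success, failure_count=failure),
        environment=EnvironmentRecord(**env),
    )
    alloc = {b: 0.0 for b in BEHAVIORS}
    for b in sample.bouts:
        alloc[b.behavior] += b.duration
    record = {
        "sample_id": sample.sample_id,
        "site": site_name,
        "p_success": p,
        "n_dive_bouts": n_dive,
        "covariate_z": z,
        "time_s": alloc,
        "total_time": sample.total_time,
    }
    return sample, record


def simulate_dataset(config: SimConfig) -> tuple[list[FocalSample], GroundTruth]:
    """All sites' samples under the config seed (deterministic per seed)."""
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth(
        weight_effects=[asdict(e) for e in config.weight_effects],
        success_effects=[asdict(e) for e in config.success_effects],
    )
    samples: list[FocalSample] = []
    for site_name, site in config.sites.items():
        for i in range(site.n_samples):
            s, rec = simulate_sample(
                config, site_name, rng, sample_id=f"{site_name}-{i + 1:03d}"
            )
            samples.append(s)
            truth.records.append(rec)
    return samples, truth


# ---------------------------------------------------------------------------
# Default configuration: the three-river winter study design
# ---------------------------------------------------------------------------

# Per-site mean bout counts per ~300 s sample (behavior frequency summaries).
_SITE_FREQ = {
    "Changjiang": {
        "resting": 3.250, "running_on_water": 1.167, "head_dipping": 0.0,
        "diving": 0.0, "flying": 0.083, "eye_submerging": 15.583,
        "swimming": 7.333, "vigilance": 22.083, "comfort": 2.750,
        "feeding": 0.250,
    },
    "Shuaishui": {
        "resting": 0.029, "running_on_water": 0.471, "head_dipping": 0.206,
        "diving": 7.265, "flying": 0.059, "eye_submerging": 11.294,
        "swimming": 6.941, "vigilance": 29.324, "comfort": 1.559,
        "feeding": 4.588,
    },
    "Jianjiang": {
        "resting": 0.0, "running_on_water": 0.683, "head_dipping": 0.024,
        "diving": 6.146, "flying": 0.073, "eye_submerging": 6.634,
        "swimming": 6.951, "vigilance": 19.512, "comfort": 2.293,
        "feeding": 2.098,
    },
}

# Per-site mean seconds per behavior per sample (time-budget summaries).
_SITE_TIME = {
    "Changjiang": {
        "resting": 41.787, "running_on_water": 6.403, "head_dipping": 0.0,
        "diving": 0.0, "flying": 1.879, "eye_submerging": 47.266,
        "swimming": 91.216, "vigilance": 79.291, "comfort": 11.489,
        "feeding": 0.798,
    },
    "Shuaishui": {
        "resting": 0.186, "running_on_water": 1.793, "head_dipping": 1.097,
        "diving": 127.601, "flying": 1.823, "eye_submerging": 37.872,
        "swimming": 50.647, "vigilance": 57.039, "comfort": 12.115,
        "feeding": 11.913,
    },
    "Jianjiang": {
        "resting": 0.0, "running_on_water": 3.016, "head_dipping": 0.211,
        "diving": 116.939, "flying": 1.527, "eye_submerging": 33.528,
        "swimming": 78.470, "vigilance": 45.576, "comfort": 15.128,
        "feeding": 6.747,
    },
}

# Sample counts and sample-duration mean/sd per site.
_SITE_N = {"Changjiang": 12, "Shuaishui": 34, "Jianjiang": 41}
_SITE_DURATION = {
    "Changjiang": (280.128, 34.356),
    "Shuaishui": (302.085, 8.207),
    "Jianjiang": (301.141, 10.730),
}

# Site covariate (mean, sd); distance is missing where no disturbances occur.
_SITE_COV = {
    "Changjiang": {
        "avg_fish_weight_g": (1.553, 0.592),
        "fish_biomass_g_m2": (5.200, 0.0),
        "temperature_C": (8.667, 1.497),
        "river_width_m": (40.000, 0.0),
        "water_depth_m": (0.900, 0.0),
        "water_velocity_m_s": (0.120, 0.0),
        "disturbance_number": (0.0, 0.0),
        "disturbance_duration_s": (0.0, 0.0),
        "disturbance_distance_m": (math.nan, 0.0),
    },
    "Shuaishui": {
        "avg_fish_weight_g": (3.213, 0.240),
        "fish_biomass_g_m2": (20.983, 8.280),
        "temperature_C": (9.317, 6.479),
        "river_width_m": (127.144, 48.308),
        "water_depth_m": (0.679, 0.307),
        "water_velocity_m_s": (0.139, 0.092),
        "disturbance_number": (1.463, 2.346),
        "disturbance_duration_s": (90.220, 116.335),
        "disturbance_distance_m": (285.350, 108.416),
    },
    "Jianjiang": {
        "avg_fish_weight_g": (2.768, 1.167),
        "fish_biomass_g_m2": (26.712, 27.770),
        "temperature_C": (11.324, 5.503),
        "river_width_m": (159.735, 27.390),
        "water_depth_m": (0.672, 0.197),
        "water_velocity_m_s": (0.227, 0.096),
        "disturbance_number": (0.677, 1.093),
        "disturbance_duration_s": (95.177, 130.965),
        "disturbance_distance_m": (235.000, 83.643),
    },
}

# Baseline per-dive success probability: mean successes / mean dive bouts.
_SITE_P0 = {
    "Changjiang": 0.0,  # no diving at this site; successes cannot occur
    "Shuaishui": 1.118 / 7.265,
    "Jianjiang": 0.902 / 6.146,
}


def default_config(seed: int = 0) -> SimConfig:
    """Three-site configuration calibrated to the winter study design."""
    sites: dict[str, SiteConfig] = {}
    for name in ("Changjiang", "Shuaishui", "Jianjiang"):
        freq = _SITE_FREQ[name]
        times = _SITE_TIME[name]
        mean_bout = {
            b: times[b] / freq[b] for b in BEHAVIORS if freq[b] > 0
        }
        dur_mean, dur_sd = _SITE_DURATION[name]
        sites[name] = SiteConfig(
            n_samples=_SITE_N[name],
            duration_mean_s=dur_mean,
            duration_sd_s=dur_sd,
            bout_frequency=freq,
            mean_bout_s=mean_bout,
            p_success=_SITE_P0[name],
            covariates=_SITE_COV[name],
        )
    return SimConfig(sites=sites, seed=seed)
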