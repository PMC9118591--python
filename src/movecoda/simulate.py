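"""Synthetic cohort generator for the walkability / 24-h behaviour analysis.

No individual-level cohort data are distributed with this package, so every
pipeline stage is exercised on simulated cohorts that reproduce the
statistical structure the analysis assumes:

* covariates drawn from the baseline distributions of a school-recruited
  cohort of 8-10-year-olds at elevated obesity risk (age ~ truncated
  N(9.6, 0.9) on [8, 11] years; 46% girls; BMI z ~ N(1.0, 1.3); 23% with
  puberty initiated; 46% measured May-October; 53% with a university-educated
  parent);
* six neighborhood indicators driven by one latent walkability factor, with
  loadings calibrated so the first principal component of their correlation
  matrix carries ~70% of the variance and the score-indicator Spearman
  profile is ordered (low-traffic streets ~ intersections > parks > land-use
  mix > park-area ratio > social disorder);
* logistic-normal 4-part compositions: Gaussian noise on pivot (ilr)
  coordinates around a mean that is the clr of the base composition
  (10, 6, 7, 0.6 hours) shifted by per-covariate clr effect vectors (each
  summing to zero); noise scaled so behaviour-hour sds are near
  (0.8, 1.1, 0.9, 0.3) h;
* optional per-minute accelerometer traces whose state totals match each
  subject's composition, with overnight removal and random daytime non-wear.

Every draw flows from a single master seed through per-stage child streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .composition import (
    DEFAULT_PARTS,
    PivotBasis,
    clr_matrix,
    pivot_inverse_matrix,
)
from .models import clr_from_percent

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "default_clr_effects",
    "clr_effect_from_percents",
    "simulate_covariates",
    "simulate_indicators",
    "simulate_compositions",
    "simulate_epochs",
    "simulate_cohort",
]

#: Score-indicator correlation targets that order the indicator loadings.
INDICATOR_RHO_PATTERN = {
    "n_intersections": 0.82,
    "land_use_mix": 0.71,
    "n_parks": 0.79,
    "low_traffic_street_length": 0.86,
    "park_area_ratio": 0.69,
    "social_disorder_segments": 0.56,
}

#: Multiplier on the rho pattern, calibrated once so the first-PC variance
#: share of the simulated indicator correlation matrix is ~0.70.
LOADING_SCALE = 1.081

#: Per-part log-scale noise sds, calibrated once so the *total* simulated
#: behaviour-hour sds (noise plus covariate effects) approximate
#: (0.8, 1.1, 0.9, 0.3) h under the default effect vectors.
PART_LOG_SD = np.array([0.04, 0.208, 0.143, 0.376])

#: Marginal transforms: indicator = transform(loading*latent + noise).
INDICATOR_MARGINALS = {
    "n_intersections": ("count", 120.0, 35.0),
    "land_use_mix": ("clip01", 0.45, 0.15),
    "n_parks": ("count", 6.0, 3.0),
    "low_traffic_street_length": ("positive", 14.0, 5.0),
    "park_area_ratio": ("clip01", 0.12, 0.06),
    "social_disorder_segments": ("count", 3.0, 2.0),
}

#: Default percent-difference effects per unit covariate on
#: (sleep, SB, LPA); the MVPA component balances the clr vector to zero.
DEFAULT_EFFECT_PERCENTS = {
    "age": (-2.05, 9.00, -3.87),
    "bmi_z": (-2.34, -0.53, 0.24),
    "summer": (-4.61, -7.14, -5.67),
    "puberty": (4.48, 16.89, -3.08),
    "edu_technical": (-6.78, -1.22, 2.51),
    "edu_university": (6.43, 2.24, -1.42),
    "walkability": (-2.73, -4.14, -2.69),
}


def clr_effect_from_percents(percents) -> np.ndarray:
    """clr effect vector from percent differences of the first D-1 parts.

    The last part's coefficient is set to minus the sum of the others, so the
    vector sums to zero exactly.
    """
    b = np.atleast_1d(np.asarray(clr_from_percent(percents), dtype=float))
    return np.append(b, -b.sum())


def default_clr_effects() -> dict[str, np.ndarray]:
    return {k: clr_effect_from_percents(v)
            for k, v in DEFAULT_EFFECT_PERCENTS.items()}


@dataclass
class SimulationConfig:
    """All generator parameters; defaults are the study conditions."""

    n_subjects: int = 409
    seed: int = 0
    # covariates
    age_mean: float = 9.6
    age_sd: float = 0.9
    age_bounds: tuple[float, float] = (8.0, 11.0)
    p_female: float = 0.46
    bmi_z_mean: float = 1.0
    bmi_z_sd: float = 1.3
    p_puberty: float = 0.23
    p_summer: float = 0.46
    edu_probs: tuple[float, float, float] = (0.22, 0.25, 0.53)
    p_unsafe: float = 0.25
    # walkability indicators
    indicator_loadings: dict = field(default_factory=dict)
    loading_scale: float = LOADING_SCALE
    # compositions
    base_hours: tuple[float, ...] = (10.0, 6.0, 7.0, 0.6)
    parts: tuple[str, ...] = DEFAULT_PARTS
    clr_effects: dict = field(default_factory=default_clr_effects)
    part_log_sd: np.ndarray = field(
        default_factory=lambda: PART_LOG_SD.copy())
    noise_scale: float = 1.0
    # epoch traces
    n_days: int = 7
    start_date: str = "2005-09-05"  # a Monday
    removal_minute: int = 1320      # 22:00
    removal_jitter: int = 20
    p_daytime_nonwear: float = 0.2
    nonwear_minutes: tuple[int, int] = (60, 90)
    p_sb_zero: float = 0.3
    deterministic_counts: bool = False

    def __post_init__(self) -> None:
        for p in (self.p_female, self.p_puberty, self.p_summer,
                  self.p_unsafe, self.p_daytime_nonwear, self.p_sb_zero):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if abs(sum(self.edu_probs) - 1.0) > 1e-9:
            raise ValueError("edu_probs must sum to 1")
        if not self.indicator_loadings:
            self.indicator_loadings = {
                k: min(self.loading_scale * v, 0.995)
                for k, v in INDICATOR_RHO_PATTERN.items()
            }
        base = np.asarray(self.base_hours, dtype=float)
        if np.any(base <= 0):
            raise ValueError("base composition must be strictly positive")
        for name, b in self.clr_effects.items():
            b = np.asarray(b, dtype=float)
            if abs(b.sum()) > 1e-12:
                raise ValueError(
                    f"clr effect vector for {name!r} must sum to 0 "
                    f"(got {b.sum():.3e})")
            if b.size != len(self.parts):
                raise ValueError(f"clr effect for {name!r} has wrong length")

    def ilr_noise_cov(self) -> np.ndarray:
        """Pivot-coordinate noise covariance implied by independent
        per-part log-scale noise: B diag(s^2) B^T."""
        basis = PivotBasis(self.parts[0], self.parts)
        B = basis.contrast_matrix()
        s = np.asarray(self.part_log_sd, dtype=float) * self.noise_scale
        return B @ np.diag(s ** 2) @ B.T


@dataclass
class SimulatedCohort:
    """A generated cohort with its ground truth."""

    cohort: pd.DataFrame          # covariates + walkability + composition
    indicators: pd.DataFrame
    ground_truth: dict
    config: SimulationConfig
    epochs: pd.DataFrame | None = None


def simulate_covariates(config: SimulationConfig,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Draw the covariate table for ``n_subjects``."""
    n = config.n_subjects
    lo, hi = config.age_bounds
    a = (lo - config.age_mean) / config.age_sd
    b = (hi - config.age_mean) / config.age_sd
    age = stats.truncnorm.rvs(a, b, loc=config.age_mean, scale=config.age_sd,
                              size=n, random_state=rng)
    sex = np.where(rng.random(n) < config.p_female, "F", "M")
    bmi_z = rng.normal(config.bmi_z_mean, config.bmi_z_sd, size=n)
    puberty = (rng.random(n) < config.p_puberty).astype(int)
    summer = (rng.random(n) < config.p_summer).astype(int)
    edu = rng.choice(["secondary", "technical", "university"], size=n,
                     p=config.edu_probs)
    safety = (rng.random(n) < config.p_unsafe).astype(int)
    return pd.DataFrame({
        "subject_id": [f"S{i + 1:04d}" for i in range(n)],
        "sex": sex,
        "age": age,
        "bmi_z": bmi_z,
        "puberty": puberty,
        "summer": summer,
        "parent_edu": edu,
        "safety": safety,
    })


def simulate_indicators(config: SimulationConfig, rng: np.random.Generator,
                        latent: np.ndarray) -> pd.DataFrame:
    """Six indicators driven by one latent factor through monotone marginal
    transforms (counts are rounded, ratios clipped to [0, 1])."""
    n = len(latent)
    out = {}
    for name, load in config.indicator_loadings.items():
        noise_sd = np.sqrt(max(1.0 - load ** 2, 1e-12))
        g = load * latent + noise_sd * rng.standard_normal(n)
        kind, loc, scale = INDICATOR_MARGINALS[name]
        x = loc + scale * g
        if kind == "count":
            x = np.clip(np.round(x), 0, None)
        elif kind == "clip01":
            x = np.clip(x, 0.0, 1.0)
        elif kind == "positive":
            x = np.clip(x, 0.0, None)
        out[name] = x
    return pd.DataFrame(out)


def simulate_compositions(config: SimulationConfig, rng: np.random.Generator,
                          covariates: pd.DataFrame,
                          walkability: np.ndarray) -> np.ndarray:
    """Logistic-normal compositions, (n, 4) minutes closed to 1440.

    The clr mean is ``clr(base) + sum_c x_c * b_c`` with continuous
    covariates centred at their generating means, so the base composition is
    the reference-subject centre.
    """
    n = len(covariates)
    base_min = np.asarray(config.base_hours, dtype=float) * 60.0
    clr_base = clr_matrix(base_min[None, :])[0]
    effect_x = {
        "age": covariates["age"].to_numpy(dtype=float) - config.age_mean,
        "bmi_z": covariates["bmi_z"].to_numpy(dtype=float)
        - config.bmi_z_mean,
        "summer": covariates["summer"].to_numpy(dtype=float),
        "puberty": covariates["puberty"].to_numpy(dtype=float),
        "edu_technical": (covariates["parent_edu"] == "technical")
        .to_numpy(dtype=float),
        "edu_university": (covariates["parent_edu"] == "university")
        .to_numpy(dtype=float),
        "walkability": np.asarray(walkability, dtype=float),
    }
    clr_mean = np.tile(clr_base, (n, 1))
    for name, b in config.clr_effects.items():
        if name not in effect_x:
            raise ValueError(f"no generating covariate named {name!r}")
        clr_mean += np.outer(effect_x[name], np.asarray(b, dtype=float))
    basis = PivotBasis(config.parts[0], config.parts)
    B = basis.contrast_matrix()
    z_mean = clr_mean @ B.T
    cov = config.ilr_noise_cov()
    if np.allclose(cov, 0.0):
        z = z_mean
    else:
        L = np.linalg.cholesky(cov + 1e-15 * np.eye(cov.shape[0]))
        z = z_mean + rng.standard_normal((n, cov.shape[0])) @ L.T
    return pivot_inverse_matrix(z, basis, total=1440.0)


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights``."""
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("weights must have positive sum")
    exact = total * w / w.sum()
    alloc = np.floor(exact).astype(int)
    rem = total - alloc.sum()
    order = np.argsort(-(exact - alloc))
    alloc[order[:rem]] += 1
    return alloc


def _draw_counts(state: int, m: int, rng: np.random.Generator,
                 config: SimulationConfig) -> np.ndarray:
    """Counts for ``m`` minutes in intensity state 0/1/2 (SB/LPA/MVPA)."""
    if config.deterministic_counts:
        return np.full(m, (50, 1000, 3000)[state])
    if state == 0:
        c = rng.integers(1, 100, size=m)
        c[rng.random(m) < config.p_sb_zero] = 0
        return c
    if state == 1:
        return rng.integers(100, 2296, size=m)
    return rng.integers(2296, 5000, size=m)


def _waking_counts(w: int, quotas: np.ndarray, rng: np.random.Generator,
                   config: SimulationConfig) -> np.ndarray:
    """Counts for a waking stretch of ``w`` minutes with per-state quotas.

    States are interleaved in short blocks; the stretch starts and ends with
    light activity so the adjacent sleep gaps are cleanly delimited.
    """
    q = quotas.copy()
    counts = np.empty(w, dtype=np.int64)
    pos = 0
    guard = min(3, q[1] // 2) if q[1] >= 2 else 0
    if guard:
        counts[:guard] = _draw_counts(1, guard, rng, config)
        counts[w - guard:] = _draw_counts(1, guard, rng, config)
        q[1] -= 2 * guard
        pos = guard
    block = {0: 8, 1: 6, 2: 2}
    state = 0
    end = w - guard
    while pos < end:
        if q.sum() == 0:
            counts[pos:end] = _draw_counts(0, end - pos, rng, config)
            break
        if q[state] > 0:
            m = min(block[state], q[state], end - pos)
            counts[pos:pos + m] = _draw_counts(state, m, rng, config)
            q[state] -= m
            pos += m
        state = (state + 1) % 3
    return counts


def simulate_epochs(config: SimulationConfig, rng: np.random.Generator,
                    target_minutes, subject_id: str) -> pd.DataFrame:
    """Per-minute counts over ``n_days`` whose state totals match the target
    composition, with overnight removal and random daytime non-wear.

    The trace starts at midnight with the tail of a pre-study night and runs
    into the morning of day ``n_days + 1`` so the last night has a refit.
    """
    target = np.asarray(target_minutes, dtype=float)
    if target.sum() > 1440.0 + 1e-6 * 1440:
        raise ValueError("target durations exceed a 1440-minute day")
    s = int(round(target[0]))
    waking_ratio = target[1:] / target[1:].sum()
    nd = config.n_days
    j = config.removal_jitter
    removal = config.removal_minute + (
        rng.integers(-j, j + 1, size=nd + 1) if j > 0
        else np.zeros(nd + 1, dtype=int))
    # refit[d] = morning refit ending the night that began on removal[d]
    refit = removal + s - 1440
    if np.any(removal < 18 * 60):
        raise ValueError("removal before 18:00; shorten jitter")
    if np.any(refit < 3 * 60) or np.any(refit > 12 * 60):
        raise ValueError(
            f"sleep target {s} min puts the morning refit outside "
            "03:00-12:00")
    days = []
    for d in range(nd):
        counts = np.zeros(1440, dtype=np.int64)
        a, b = int(refit[d]), int(removal[d + 1])
        w = b - a
        quotas = _largest_remainder(w, waking_ratio)
        counts[a:b] = _waking_counts(w, quotas, rng, config)
        if config.p_daytime_nonwear > 0 and \
                rng.random() < config.p_daytime_nonwear:
            lo, hi = config.nonwear_minutes
            L = int(rng.integers(lo, hi + 1))
            lo_start, hi_start = a + 60, b - 60 - L
            if hi_start > lo_start:
                start = int(rng.integers(lo_start, hi_start))
                counts[start:start + L] = 0
                counts[start - 3:start] = _draw_counts(1, 3, rng, config)
                counts[start + L:start + L + 3] = _draw_counts(
                    1, 3, rng, config)
        days.append(counts)
    # partial final morning: tail of the last night plus a short worn stretch
    tail = np.zeros(int(refit[nd]) + 10, dtype=np.int64)
    tail[-10:] = _draw_counts(1, 10, rng, config)
    days.append(tail)
    counts = np.concatenate(days)
    start = pd.Timestamp(config.start_date)
    ts = pd.date_range(start, periods=len(counts), freq="min")
    return pd.DataFrame({
        "subject_id": subject_id,
        "timestamp": ts,
        "cpm": counts,
    })


def simulate_cohort(config: SimulationConfig,
                    with_epochs: bool = False) -> SimulatedCohort:
    """Generate a full cohort: covariates, indicators, compositions and
    (optionally) epoch traces, all from ``config.seed``."""
    ss = np.random.SeedSequence(config.seed)
    r_cov, r_lat, r_ind, r_comp, r_epo = [
        np.random.default_rng(s) for s in ss.spawn(5)]
    covariates = simulate_covariates(config, r_cov)
    latent = r_lat.standard_normal(config.n_subjects)
    if config.n_subjects > 1:
        walk_std = (latent - latent.mean()) / latent.std(ddof=1)
    else:
        walk_std = np.zeros_like(latent)
    indicators = simulate_indicators(config, r_ind, latent)
    indicators.insert(0, "subject_id", covariates["subject_id"])
    comps = simulate_compositions(config, r_comp, covariates, walk_std)
    cohort = covariates.copy()
    cohort["walkability"] = walk_std
    for k, part in enumerate(config.parts):
        cohort[part] = comps[:, k]
    epochs = None
    if with_epochs:
        frames = [
            simulate_epochs(config, r_epo, comps[i],
                            covariates["subject_id"].iloc[i])
            for i in range(config.n_subjects)
        ]
        epochs = pd.concat(frames, ignore_index=True)
    ground_truth = {
        "latent_walkability": latent,
        "clr_effects": {k: np.asarray(v).tolist()
                        for k, v in config.clr_effects.items()},
        "base_hours": list(config.base_hours),
        "target_compositions": comps,
    }
    return SimulatedCohort(cohort=cohort, indicators=indicators,
                           ground_truth=ground_truth, config=config,
                           epochs=epochs)


def with_effects(config: SimulationConfig,
                 **effects) -> SimulationConfig:
    """Copy of ``config`` with selected clr effect vectors replaced."""
    new = dict(config.clr_effects)
    for k, v in effects.items():
        new[k] = np.asarray(v, dtype=float)
    return replace(config, clr_effects=new)
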