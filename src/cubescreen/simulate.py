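"""Synthetic cube-play data with known ground truth.

Three generators cover the three data levels the pipeline consumes:

* :func:`generate_session` — raw per-cube acceleration streams for one child,
  with ground-truth movement boundaries and shaking levels.  Movements are
  *rise-and-stop* bursts: the acceleration magnitude climbs (with optional
  tremor mounds riding on the climb) and collapses to rest the instant the
  cube is placed.  This matches how a magnitude-only trace looks when speed is
  obtained by integration — the movement ends at the placement impact, not
  with a mirrored deceleration phase.
* :func:`simulate_raters` — expert rating matrices with a tunable one-way
  intraclass correlation.
* :func:`generate_cohort` — per-experiment summary tables drawn from an
  explicit three-factor latent structure (defaults: the reference
  trembling/speed/accuracy loading pattern), with ages and performance scores.

All generators are deterministic under a fixed seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .errors import ConfigurationError
from .reference import FACTOR_NAMES, REFERENCE_LOADINGS
from .screening import PERFORMANCE_EQUATION, ScreeningEquation
from .types import SENSOR_VARIABLES, SampleStream

__all__ = [
    "LatentProfile",
    "GroundTruthEpisode",
    "Session",
    "Cohort",
    "generate_session",
    "simulate_raters",
    "generate_cohort",
    "sample_profiles",
]


@dataclass
class LatentProfile:
    """Latent characteristics of a simulated child.

    Parameters
    ----------
    trembling_rate : float
        Expected number of tremor mounds per movement (Poisson rate, >= 0).
    speed_scale : float
        Multiplier on peak movement acceleration/speed (> 0).
    accuracy_level : float
        Latent accuracy in [0, 1]; low accuracy produces extra (fumbled)
        movements and a lower floor on the weakest movement's peak
        speed/acceleration.
    n_cubes : int
        Number of cubes in the tower task (default 5).
    age_months : float
        Chronological age in months.
    seed : int
        Seed for the session generator.
    """

    trembling_rate: float = 1.5
    speed_scale: float = 1.0
    accuracy_level: float = 0.8
    n_cubes: int = 5
    age_months: float = 29.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trembling_rate < 0:
            raise ConfigurationError("trembling_rate must be >= 0")
        if self.speed_scale <= 0:
            raise ConfigurationError("speed_scale must be > 0")
        if not 0.0 <= self.accuracy_level <= 1.0:
            raise ConfigurationError("accuracy_level must lie in [0, 1]")
        if self.n_cubes < 1:
            raise ConfigurationError("n_cubes must be >= 1")


@dataclass
class GroundTruthEpisode:
    """True boundaries and shaking composition of one generated movement."""

    cube_id: str
    start_ms: float
    end_ms: float
    peak_accel: float
    shaking_levels: list[int] = field(default_factory=list)

    @property
    def shaking_count(self) -> int:
        return len(self.shaking_levels)

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms


@dataclass
class Session:
    """One simulated child-session: raw streams plus generative ground truth."""

    profile: LatentProfile
    streams: list[SampleStream]
    truth: list[GroundTruthEpisode]

    def truth_for(self, cube_id: str) -> list[GroundTruthEpisode]:
        return [e for e in self.truth if e.cube_id == cube_id]


def _make_burst(
    rng: np.random.Generator, profile: LatentProfile, amp_floor: float
) -> tuple[np.ndarray, list[int]]:
    """Build one rise-and-stop burst; returns (samples, true shaking levels).

    The burst is a strictly alternating sequence of tremor mounds (symmetric,
    half-width 1..5 samples, local minima well above the rest threshold)
    followed by a monotone rise to the burst peak.  The peak is the final
    sample: the subsequent sample is already at rest, so the terminal rise
    contributes no countable mound.
    """
    n_shake = int(rng.poisson(profile.trembling_rate))
    lo = rng.uniform(0.18, 0.30)
    samples = [lo]
    levels: list[int] = []
    for _ in range(n_shake):
        h = int(rng.integers(1, 6))
        peak = lo + rng.uniform(0.5, 1.3) * profile.speed_scale
        next_lo = rng.uniform(0.18, 0.30)
        samples.extend(np.linspace(lo, peak, h + 1)[1:])
        samples.extend(np.linspace(peak, next_lo, h + 1)[1:])
        levels.append(min(h, 4))
        lo = next_lo
    m = int(rng.integers(6, 12))
    apex = lo + (amp_floor + rng.uniform(0.0, 1.2)) * profile.speed_scale
    samples.extend(np.linspace(lo, apex, m + 1)[1:])
    return np.asarray(samples), levels


def generate_session(
    profile: LatentProfile,
    sampling_rate: float = 50.0,
    noise_sd: float = 0.0,
) -> Session:
    """Simulate the cube-tower activity for one child.

    One stream per cube; each stream holds one or more movement bursts
    separated by rest.  Ground truth records the true episode boundaries
    (exact at ``noise_sd=0``), true peak accelerations and the true shaking
    levels injected into each movement.
    """
    if sampling_rate <= 0:
        raise ConfigurationError("sampling_rate must be positive")
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    rng = np.random.default_rng(profile.seed)
    dt_ms = 1000.0 / sampling_rate
    streams: list[SampleStream] = []
    truth: list[GroundTruthEpisode] = []

    # Low accuracy lowers the weakest movement's amplitude floor and adds
    # fumbled extra movements beyond the ideal one-per-cube.
    amp_floor = 0.9 + 1.1 * profile.accuracy_level

    for c in range(profile.n_cubes):
        cube_id = f"cube{c + 1}"
        n_moves = 1 + int(rng.poisson(1.8 * (1.0 - profile.accuracy_level)))
        chunks: list[np.ndarray] = []
        pos = 0
        gap = int(round(rng.uniform(0.4, 1.2) * sampling_rate))
        chunks.append(np.zeros(gap))
        pos += gap
        for _ in range(n_moves):
            burst, levels = _make_burst(rng, profile, amp_floor)
            b0 = pos  # first burst sample index
            chunks.append(burst)
            pos += len(burst)
            truth.append(
                GroundTruthEpisode(
                    cube_id=cube_id,
                    start_ms=(b0 - 1) * dt_ms,  # last at-rest sample before the burst
                    end_ms=(pos - 1) * dt_ms,  # burst peak (placement instant)
                    peak_accel=float(burst.max()),
                    shaking_levels=levels,
                )
            )
            gap = int(round(rng.uniform(0.5, 1.5) * sampling_rate))
            chunks.append(np.zeros(gap))
            pos += gap
        accel = np.concatenate(chunks)
        if noise_sd > 0:
            accel = np.clip(accel + rng.normal(0.0, noise_sd, len(accel)), 0.0, None)
        timestamps = np.arange(len(accel)) * dt_ms
        streams.append(
            SampleStream(
                cube_id=cube_id,
                timestamps=timestamps,
                accel=accel,
                sampling_rate=sampling_rate,
            )
        )
    return Session(profile=profile, streams=streams, truth=truth)


def simulate_raters(
    true_scores: np.ndarray,
    target_reliability: float,
    k: int = 2,
    seed: int = 0,
) -> np.ndarray:
    """Simulate a (n x k) expert rating matrix with a target ICC(1,1).

    Rater noise is additive Gaussian with variance chosen from the one-way
    ANOVA decomposition: with between-child variance ``s_b^2`` (the sample
    variance of ``true_scores``) the within variance is
    ``s_b^2 (1 - rho) / rho``.  Ratings are clipped to the 1-10 scale, a small
    accepted bias.
    """
    scores = np.asarray(true_scores, dtype=float)
    if scores.ndim != 1 or len(scores) < 2:
        raise ConfigurationError("true_scores must be a vector with n >= 2")
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    if not 0.0 <= target_reliability <= 1.0:
        raise ConfigurationError("target_reliability must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    s_b = float(np.std(scores, ddof=1))
    if target_reliability == 1.0:
        noise_sd = 0.0
    else:
        rho = max(target_reliability, 1e-6)
        noise_sd = s_b * np.sqrt((1.0 - rho) / rho)
    ratings = scores[:, None] + rng.normal(0.0, noise_sd, size=(len(scores), k))
    return np.clip(ratings, 1.0, 10.0)


@dataclass
class Cohort:
    """A simulated summary-level cohort with its generative ground truth."""

    data: pd.DataFrame  # 13 sensor variables (+ performance, age)
    factors: pd.DataFrame  # true latent factor draws per child
    loadings: pd.DataFrame
    uniquenesses: pd.Series

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def generate_cohort(
    n: int,
    loadings: pd.DataFrame | None = None,
    unique_variances: np.ndarray | None = None,
    age_mean: float = 29.02,
    age_sd: float = 3.81,
    performance_equation: ScreeningEquation = PERFORMANCE_EQUATION,
    performance_noise_sd: float | None = None,
    seed: int = 0,
) -> Cohort:
    """Draw a cohort of per-experiment summaries from a 3-factor latent model.

    The 13 standardized sensor variables are ``loadings @ factors + unique
    noise`` with independent standard-normal factors.  Ages are drawn from a
    normal distribution truncated to the 23-37 month study band; performance
    is generated from the latent factors via ``performance_equation`` with
    residual noise ``performance_noise_sd`` (default: the equation's SEE) and
    is left unclipped so generative coefficients stay recoverable.
    """
    if n < 2:
        raise ConfigurationError("cohort size must be >= 2")
    if loadings is None:
        loadings = REFERENCE_LOADINGS
    loadings = pd.DataFrame(loadings)
    lam = loadings.to_numpy(dtype=float)
    communalities = (lam**2).sum(axis=1)
    if np.any(communalities > 1.0 + 1e-9):
        raise ConfigurationError("invalid loadings: some communality exceeds 1")
    if unique_variances is None:
        psi = 1.0 - communalities
    else:
        psi = np.asarray(unique_variances, dtype=float)
        if np.any(psi < 0):
            raise ConfigurationError("unique variances must be >= 0")
    rng = np.random.default_rng(seed)
    n_fact = lam.shape[1]
    factors = rng.standard_normal((n, n_fact))
    unique = rng.standard_normal((n, lam.shape[0])) * np.sqrt(psi)
    x = factors @ lam.T + unique

    # Truncated-normal ages on the study band; the parent location is shifted
    # so the *truncated* mean equals age_mean despite the asymmetric band.
    lo, hi = 23.0, 37.0
    loc = brentq(
        lambda c: truncnorm.mean((lo - c) / age_sd, (hi - c) / age_sd, loc=c, scale=age_sd)
        - age_mean,
        lo,
        hi,
    )
    ages = truncnorm.rvs(
        (lo - loc) / age_sd, (hi - loc) / age_sd, loc=loc, scale=age_sd, size=n, random_state=rng
    )

    fcols = list(loadings.columns) if loadings.shape[1] == len(FACTOR_NAMES) else [
        f"factor{j + 1}" for j in range(n_fact)
    ]
    fdf = pd.DataFrame(factors, columns=fcols)
    see = performance_equation.see if performance_noise_sd is None else performance_noise_sd
    perf = performance_equation.predict(
        fdf.get("trembling", pd.Series(np.zeros(n))),
        fdf.get("speed", pd.Series(np.zeros(n))),
        fdf.get("accuracy", pd.Series(np.zeros(n))),
    ) + rng.normal(0.0, see, n)

    columns = list(loadings.index) if len(loadings.index) == len(SENSOR_VARIABLES) else [
        str(v) for v in loadings.index
    ]
    data = pd.DataFrame(x, columns=columns)
    data["Performance scores"] = perf
    data["Age (months)"] = ages
    return Cohort(
        data=data,
        factors=fdf,
        loadings=loadings,
        uniquenesses=pd.Series(psi, index=loadings.index),
    )


def sample_profiles(n: int, seed: int = 0) -> list[LatentProfile]:
    """Draw heterogeneous child profiles for cohort-level session simulation."""
    rng = np.random.default_rng(seed)
    profiles = []
    for i in range(n):
        profiles.append(
            LatentProfile(
                trembling_rate=float(rng.lognormal(np.log(1.3), 0.5)),
                speed_scale=float(rng.lognormal(0.0, 0.3)),
                accuracy_level=float(rng.beta(5.0, 2.0)),
                n_cubes=5,
                age_months=float(np.clip(rng.normal(29.02, 3.81), 23.0, 37.0)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return profiles
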