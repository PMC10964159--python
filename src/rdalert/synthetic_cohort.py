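"""Synthetic patient-level cohort generation for threshold-alert RD studies.

Generates hospitalization records with a known discontinuity (``tau``) in the
probability of a composite deterioration outcome at a score threshold,
smooth-in-score covariates, optional treatment contamination (silent alerts /
comfort care) and optional score manipulation for density-test power studies.

All randomness flows from a single master seed through named sub-streams, so
adding a covariate or toggling contamination never perturbs the score draws.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .errors import ConfigError, ValidationError

logger = logging.getLogger(__name__)

#: canonical column order for a cohort table
COLUMNS = [
    "id",
    "max_score",
    "treated",
    "rrt",
    "icu_transfer",
    "arrest",
    "death",
    "age",
    "elixhauser",
    "days_to_max",
    "period",
    "unit",
]

EVENT_FLAGS = ["rrt", "icu_transfer", "arrest", "death"]
COVARIATES = ["age", "elixhauser", "days_to_max"]

ELIXHAUSER_RANGE = (-19.0, 89.0)

# fixed indices for named RNG sub-streams (order is part of the public
# reproducibility contract; append only)
_STREAMS = {
    "scores": 0,
    "outcome": 1,
    "event_type": 2,
    "death": 3,
    "contamination": 4,
    "covariate": 5,
    "missing": 8,
    "manipulation": 9,
    "trajectory": 10,
}


def _stream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[name],)))


def _covariate_stream(seed: int, name: str) -> np.random.Generator:
    # keyed by a stable hash of the covariate name, so adding or removing a
    # covariate never perturbs any other stream
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS["covariate"], key))
    )


@dataclass(frozen=True)
class CovariateModel:
    """Smooth-in-score covariate: mean = intercept + slope * score.

    ``family`` is ``normal`` (mean + Gaussian noise, optionally clipped) or
    ``gamma`` (strictly positive draws with the same mean and sd; no clipping,
    so the conditional mean stays exactly linear in score).
    """

    intercept: float
    slope: float
    sd: float
    lower: Optional[float] = None
    upper: Optional[float] = None
    family: str = "normal"

    def mean(self, score: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(score, dtype=float)

    def draw(self, score: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        mu = self.mean(score)
        if self.family == "gamma":
            if np.any(mu <= 0):
                raise ConfigError("gamma covariate requires a positive mean at all scores")
            shape = (mu / self.sd) ** 2
            return rng.gamma(shape, self.sd**2 / mu)
        values = mu + rng.normal(scale=self.sd, size=np.size(score))
        if self.lower is not None or self.upper is not None:
            values = np.clip(values, self.lower, self.upper)
        return values


@dataclass(frozen=True)
class TrajectoryModel:
    """Bounded random-walk score trajectories with score-dependent event hazard."""

    start_scale: float = 0.75
    step_sd: float = 3.0
    hazard_intercept: float = -7.0
    hazard_slope: float = 0.04

    def hazard(self, score: np.ndarray) -> np.ndarray:
        return special.expit(self.hazard_intercept + self.hazard_slope * np.asarray(score, float))


@dataclass(frozen=True)
class CohortConfig:
    """Full parameterization of the synthetic cohort generator."""

    n_patients: int = 10_000
    threshold: float = 65.0
    tau: float = -0.104
    # logistic score -> primary-composite probability (pre-jump)
    baseline_intercept: float = -6.30
    baseline_slope: float = 0.085
    # right-skewed score distribution: Beta(alpha, beta) scaled to [0, 100];
    # beta=None is solved so P(score >= threshold) == target_frac_above
    score_alpha: float = 2.0
    score_beta: Optional[float] = None
    target_frac_above: float = 771 / 9896
    # logistic score -> inpatient-death probability; death_jump defaults to 0
    # so the secondary composite shows an attenuated effect
    death_intercept: float = -7.5
    death_slope: float = 0.07
    death_jump: float = 0.0
    # conditional split of a primary-composite event into rrt/icu/arrest
    event_mix: tuple = (0.35, 0.55, 0.10)
    covariates: dict = field(
        default_factory=lambda: {
            "age": CovariateModel(50.0, 0.18, 12.0, 18.0, 105.0),
            "elixhauser": CovariateModel(2.0, 0.10, 9.0, *ELIXHAUSER_RANGE),
            "days_to_max": CovariateModel(1.0, 0.03, 1.5, family="gamma"),
        }
    )
    contamination_rate: float = 0.0
    manipulation_shift: float = 0.0
    manipulation_window: float = 1.0
    covariate_missing_rate: float = 0.0
    score_resolution: float = 0.1
    period: str = "active"
    unit: str = "unit_a"
    trajectory: TrajectoryModel = field(default_factory=TrajectoryModel)
    seed: int = 0

    # ------------------------------------------------------------------
    def resolved_beta(self) -> float:
        if self.score_beta is not None:
            return float(self.score_beta)
        return calibrate_score_beta(self.score_alpha, self.target_frac_above, self.threshold)

    def outcome_probability(self, score: np.ndarray, treated_effect: np.ndarray) -> np.ndarray:
        """P(primary composite | score), including the jump where effect applies."""
        base = special.expit(self.baseline_intercept + self.baseline_slope * np.asarray(score, float))
        return base + self.tau * np.asarray(treated_effect, float)

    def death_probability(self, score: np.ndarray, treated_effect: np.ndarray) -> np.ndarray:
        base = special.expit(self.death_intercept + self.death_slope * np.asarray(score, float))
        return base + self.death_jump * np.asarray(treated_effect, float)

    def attainable_scores(self) -> np.ndarray:
        res = self.score_resolution
        return np.round(np.arange(0.0, 100.0 + res / 2, res), 10)

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ConfigError("n_patients must be positive")
        if not 0.0 < self.threshold < 100.0:
            raise ConfigError("threshold must lie strictly inside (0, 100)")
        if not 0.0 <= self.contamination_rate <= 1.0:
            raise ConfigError("contamination_rate must be in [0, 1]")
        if not 0.0 <= self.manipulation_shift <= 1.0:
            raise ConfigError("manipulation_shift must be in [0, 1]")
        if self.manipulation_window <= 0:
            raise ConfigError("manipulation_window must be positive")
        if self.score_resolution <= 0:
            raise ConfigError("score_resolution must be positive")
        if abs(sum(self.event_mix) - 1.0) > 1e-9 or min(self.event_mix) < 0:
            raise ConfigError("event_mix must be a probability vector over (rrt, icu, arrest)")
        if self.score_alpha <= 0 or (self.score_beta is not None and self.score_beta <= 0):
            raise ConfigError("score distribution shape parameters must be positive")
        grid = self.attainable_scores()
        for effect in (np.zeros_like(grid), (grid >= self.threshold).astype(float)):
            for name, p in (
                ("outcome", self.outcome_probability(grid, effect)),
                ("death", self.death_probability(grid, effect)),
            ):
                bad = np.nonzero((p < 0.0) | (p > 1.0))[0]
                if bad.size:
                    raise ConfigError(
                        f"{name} probability {p[bad[0]]:.4f} outside [0, 1] "
                        f"at score {grid[bad[0]]:.1f}"
                    )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["score_beta_resolved"] = self.resolved_beta()
        return d


def calibrate_score_beta(alpha: float, target_frac_above: float, threshold: float) -> float:
    """Solve the Beta shape ``beta`` so P(100*Beta(alpha, beta) >= threshold) hits the target."""
    if not 0.0 < target_frac_above < 1.0:
        raise ConfigError("target_frac_above must be in (0, 1)")
    x = threshold / 100.0

    def excess(b: float) -> float:
        return stats.beta.sf(x, alpha, b) - target_frac_above

    return float(optimize.brentq(excess, 1e-3, 500.0, xtol=1e-10))


@dataclass
class Cohort:
    """A collection of hospitalizations plus the threshold they were generated under."""

    data: pd.DataFrame
    threshold: float = 65.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "id" in self.data.columns and self.data["id"].duplicated().any():
            raise ValidationError("record ids are not unique")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def scores(self) -> np.ndarray:
        return self.data["max_score"].to_numpy(dtype=float)

    def copy(self) -> "Cohort":
        return Cohort(self.data.copy(), self.threshold, dict(self.provenance))


@dataclass(frozen=True)
class Hospitalization:
    """One admission record (row-level convenience view of the cohort table)."""

    id: str
    max_score: float
    treated: int
    rrt: int
    icu_transfer: int
    arrest: int
    death: int
    age: float
    elixhauser: float
    days_to_max: float
    period: str = "active"
    unit: str = "unit_a"


def _round_scores(raw: np.ndarray, resolution: float) -> np.ndarray:
    return np.clip(np.round(np.round(raw / resolution) * resolution, 10), 0.0, 100.0)


def _draw_events(
    config: CohortConfig,
    scores: np.ndarray,
    effect_mask: np.ndarray,
    seed: int,
) -> dict:
    """Draw the composite outcome, split it into event types, and draw death."""
    n = scores.size
    p_primary = config.outcome_probability(scores, effect_mask)
    composite = (_stream(seed, "outcome").uniform(size=n) < p_primary).astype(np.int8)

    u = _stream(seed, "event_type").uniform(size=n)
    cut = np.cumsum(config.event_mix)
    rrt = composite * (u < cut[0])
    icu = composite * ((u >= cut[0]) & (u < cut[1]))
    arrest = composite * (u >= cut[1])

    p_death = config.death_probability(scores, effect_mask)
    death = (_stream(seed, "death").uniform(size=n) < p_death).astype(np.int8)
    return {
        "rrt": rrt.astype(np.int8),
        "icu_transfer": icu.astype(np.int8),
        "arrest": arrest.astype(np.int8),
        "death": death,
    }


def _draw_covariates(config: CohortConfig, scores: np.ndarray, seed: int) -> dict:
    out = {}
    for name, model in config.covariates.items():
        out[name] = model.draw(scores, _covariate_stream(seed, name))
    if config.covariate_missing_rate > 0:
        rng = _stream(seed, "missing")
        for name in out:
            mask = rng.uniform(size=scores.size) < config.covariate_missing_rate
            out[name] = np.where(mask, np.nan, out[name])
    return out


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate ``config.n_patients`` hospitalization records.

    The running variable is drawn from a scaled Beta distribution rounded to
    ``score_resolution``; the primary-composite probability is the smooth
    baseline curve plus ``tau`` for above-threshold, non-contaminated records.
    Fully reproducible from ``config.seed``.
    """
    config.validate()
    n = config.n_patients
    beta = config.resolved_beta()

    raw = 100.0 * _stream(config.seed, "scores").beta(config.score_alpha, beta, size=n)
    scores = _round_scores(raw, config.score_resolution)

    above = scores >= config.threshold
    contaminated = np.zeros(n, dtype=bool)
    if config.contamination_rate > 0:
        u = _stream(config.seed, "contamination").uniform(size=n)
        contaminated = above & (u < config.contamination_rate)
    treated = (above & ~contaminated).astype(np.int8)
    effect = (above & ~contaminated).astype(float)

    events = _draw_events(config, scores, effect, config.seed)
    covs = _draw_covariates(config, scores, config.seed)

    frame = pd.DataFrame(
        {
            "id": [f"h{i:07d}" for i in range(n)],
            "max_score": scores,
            "treated": treated,
            **events,
            **covs,
            "period": config.period,
            "unit": config.unit,
        }
    )[COLUMNS]

    cohort = Cohort(frame, threshold=config.threshold, provenance={"config": config.to_dict()})
    if config.manipulation_shift > 0:
        cohort = inject_manipulation(
            cohort,
            config.manipulation_shift,
            config.manipulation_window,
            seed=config.seed,
        )
    return cohort


def simulate_trajectory_max(config: CohortConfig, n_steps: int) -> Cohort:
    """Simulate per-patient score walks and record the event-censored maximum.

    Each patient follows a reflected Gaussian random walk on [0, 100]; at each
    step an event fires with probability increasing in the current score. The
    recorded running variable is the maximum score over steps strictly before
    the event step (the step-0 score if the event fires immediately); patients
    without an event contribute the maximum over all steps.
    """
    config.validate()
    if n_steps < 1:
        raise ConfigError("n_steps must be >= 1")
    n = config.n_patients
    traj = config.trajectory
    rng = _stream(config.seed, "trajectory")
    beta = config.resolved_beta()

    score = 100.0 * traj.start_scale * rng.beta(config.score_alpha, beta, size=n)
    running_max = np.full(n, -np.inf)
    prior_max = score.copy()  # max over steps strictly before the event step
    event_step = np.full(n, -1, dtype=int)
    alive = np.ones(n, dtype=bool)

    for step in range(n_steps):
        if step > 0:
            score = np.where(alive, score + rng.normal(scale=traj.step_sd, size=n), score)
            # reflect into [0, 100]
            score = np.abs(score)
            score = 200.0 - np.abs(200.0 - score - 100.0) - 100.0
            score = np.clip(score, 0.0, 100.0)
        fired = alive & (rng.uniform(size=n) < traj.hazard(score))
        newly = fired & (event_step < 0)
        # censor: freeze the pre-event maximum for patients whose event fires now
        prior_max[newly] = np.where(
            running_max[newly] > -np.inf, running_max[newly], score[newly]
        )
        event_step[newly] = step
        alive &= ~fired
        running_max = np.maximum(running_max, np.where(alive, score, -np.inf))

    no_event = event_step < 0
    prior_max[no_event] = running_max[no_event]
    max_scores = _round_scores(prior_max, config.score_resolution)

    # event type at occurrence: split composite mix plus death as its own type
    had_event = ~no_event
    u = _stream(config.seed, "event_type").uniform(size=n)
    mix = np.array(config.event_mix)
    p_death_at_event = 0.15  # share of terminal events that are deaths
    cut = np.concatenate([np.cumsum(mix) * (1 - p_death_at_event), [1.0]])
    rrt = (had_event & (u < cut[0])).astype(np.int8)
    icu = (had_event & (u >= cut[0]) & (u < cut[1])).astype(np.int8)
    arrest = (had_event & (u >= cut[1]) & (u < cut[2])).astype(np.int8)
    death = (had_event & (u >= cut[2])).astype(np.int8)

    above = max_scores >= config.threshold
    covs = _draw_covariates(config, max_scores, config.seed)
    frame = pd.DataFrame(
        {
            "id": [f"t{i:07d}" for i in range(n)],
            "max_score": max_scores,
            "treated": above.astype(np.int8),
            "rrt": rrt,
            "icu_transfer": icu,
            "arrest": arrest,
            "death": death,
            **covs,
            "period": config.period,
            "unit": config.unit,
        }
    )[COLUMNS]
    return Cohort(
        frame,
        threshold=config.threshold,
        provenance={"config": config.to_dict(), "n_steps": n_steps},
    )


def inject_manipulation(
    cohort: Cohort, shift_fraction: float, window: float, seed: int = 0
) -> Cohort:
    """Relocate a fraction of records from just below to just above the threshold.

    Moves ``shift_fraction`` of records with score in ``[c - window, c)`` to
    uniformly gridded scores in ``[c, c + window)``; all other fields are
    unchanged. Intended only to exercise density-test power.
    """
    if not 0.0 <= shift_fraction <= 1.0:
        raise ConfigError("shift_fraction must be in [0, 1]")
    if window <= 0:
        raise ConfigError("window must be positive")
    c = cohort.threshold
    out = cohort.copy()
    if shift_fraction == 0.0:
        return out

    scores = out.data["max_score"].to_numpy(dtype=float)
    source = np.nonzero((scores >= c - window) & (scores < c))[0]
    if source.size == 0:
        warnings.warn("no records in the source window; cohort returned unchanged")
        return out

    rng = _stream(seed, "manipulation")
    n_move = int(round(shift_fraction * source.size))
    moved = rng.choice(source, size=n_move, replace=False)
    res = float(out.provenance.get("config", {}).get("score_resolution", 0.1))
    n_grid = max(1, int(round(window / res)))
    new_scores = c + rng.integers(0, n_grid, size=n_move) * res
    scores[moved] = np.round(new_scores, 10)
    out.data["max_score"] = scores
    out.data.loc[out.data.index[moved], "treated"] = 1
    out.provenance["manipulation"] = {"shift_fraction": shift_fraction, "window": window}
    return out
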