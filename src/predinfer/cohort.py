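"""Synthetic participant cohort with correlated symptom dimensions.

Builds a population of simulated players whose confidence and bucket
placement depend parametrically on the normative learner's latent
variables, and whose parameters are linearly modulated by three
correlated transdiagnostic dimension scores:

* AD  — anxious-depression,
* CIT — compulsive behaviour and intrusive thought,
* SW  — social withdrawal.

The dimensions are standard-normal with moderate pairwise correlations
(defaults 0.34-0.52).  Per subject, an ``AgentParams`` bundle sets how
strongly model evidence (CPP, RU, hit feedback, |PEb|) drives confidence,
how strongly confidence modulates the size of bucket updates (the
action-confidence coupling), and the behavioural noise scales.  An
``effect map`` states how +1 SD of each dimension shifts each parameter;
the default map mirrors the direction structure the analyses are meant to
recover (CIT: inflated confidence, attenuated coupling and attenuated
evidence sensitivity; AD: lower confidence; SW: extra action updating per
unit of prediction error).

No claim is made that real participants are generated this way: the agent
is a generative inverse of the analysis models, built so that every
downstream regression has a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

import numpy as np
import pandas as pd

from .task import TaskConfig, build_schedule, sample_generative_means, sample_outcomes, score_trial, wrap_degrees, signed_arc
from .model import run_learner
from .metrics import zscore_within

__all__ = [
    "DIMENSIONS",
    "AgentParams",
    "default_dimension_corr",
    "default_effect_map",
    "zero_effect_map",
    "sample_dimension_scores",
    "map_params",
    "simulate_agent",
    "simulate_cohort",
]

DIMENSIONS = ("AD", "CIT", "SW")

#: probability that a simulated participant is female (cosmetic realism)
P_FEMALE = 0.42

#: confidence-unit scale used to standardize the agent's own confidence
#: inside the coupling mechanism (kept fixed so the mapping from the
#: coupling parameter to regression slopes is stable across subjects)
CONF_SCALE = 12.0


def default_dimension_corr() -> np.ndarray:
    """Pairwise correlations of (AD, CIT, SW); all within 0.34-0.52."""
    return np.array(
        [
            [1.00, 0.52, 0.43],
            [0.52, 1.00, 0.34],
            [0.43, 0.34, 1.00],
        ]
    )


@dataclass
class AgentParams:
    """Per-subject generative behaviour parameters.

    Confidence on trial t+1 is built from the trial-t evidence:

        c = conf_intercept - w_cpp z(CPP) - w_ru z(RU) + w_hit Hit
            - w_pe z(|PEb|) + Normal(0, conf_noise_sd),  clipped to [1, 100]

    and the bucket update magnitude on trial t is

        m = LRb_t |pe_t| (1 + coupling (-z(c))) + sw_pe_gain |PEb_t|
            + Normal(0, action_noise_sd),   m clipped at 0,

    applied along the sign of the agent's own prediction error ``pe_t``
    (particle minus own bucket), so the bucket tracks the belief in a
    mean-reverting way; the social-withdrawal gain moves the bucket in
    proportion to the learner's prediction error ``PEb_t``.  Units: confidence weights in confidence units per
    SD of the predictor; coupling in proportional change of the update per
    confidence SD; noise SDs in confidence units / degrees.
    """

    conf_intercept: float = 60.0
    w_cpp: float = 6.0
    w_ru: float = 6.0
    w_hit: float = 8.0
    w_pe: float = 4.0
    coupling: float = 0.6
    sw_pe_gain: float = 0.0
    action_noise_sd: float = 4.0
    conf_noise_sd: float = 8.0

    def __post_init__(self) -> None:
        if self.action_noise_sd < 0 or self.conf_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")


def default_effect_map() -> dict[str, dict[str, float]]:
    """Linear effect of +1 SD of each dimension on each agent parameter.

    Signs mirror the direction structure the analyses target: CIT inflates
    confidence and attenuates coupling and evidence weights; AD lowers
    confidence; SW adds action updating proportional to the prediction
    error.  Magnitudes are configuration, not empirical claims.
    """
    return {
        "AD": {"conf_intercept": -3.42},
        "CIT": {
            "conf_intercept": 6.74,
            "w_cpp": -1.5,
            "w_ru": -1.5,
            "w_hit": -2.5,
            "coupling": -0.10,
        },
        "SW": {"sw_pe_gain": 0.15},
    }


def zero_effect_map() -> dict[str, dict[str, float]]:
    return {d: {} for d in DIMENSIONS}


def sample_dimension_scores(n_subjects: int, correlation=None, seed=None) -> pd.DataFrame:
    """Sample standardized AD/CIT/SW scores (multivariate normal with the
    given correlation matrix) plus independent covariates: standardized age
    and IQ, and binary gender (1 = female)."""
    corr = default_dimension_corr() if correlation is None else np.asarray(correlation, dtype=float)
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as err:
        raise ValueError("dimension correlation matrix must be positive definite") from err
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_subjects, 3))
    scores = z @ chol.T
    return pd.DataFrame(
        {
            "subject": np.arange(n_subjects),
            "AD": scores[:, 0],
            "CIT": scores[:, 1],
            "SW": scores[:, 2],
            "age": rng.standard_normal(n_subjects),
            "gender": rng.binomial(1, P_FEMALE, n_subjects).astype(float),
            "IQ": rng.standard_normal(n_subjects),
        }
    )


def map_params(scores: pd.DataFrame, effects: dict, defaults: AgentParams | None = None) -> pd.DataFrame:
    """Deterministic linear mapping from dimension scores to agent parameters:
    ``param_i = default + sum_dim effects[dim][param] * score_i[dim]``."""
    defaults = defaults or AgentParams()
    base = asdict(defaults)
    out = pd.DataFrame({k: np.full(len(scores), v, dtype=float) for k, v in base.items()},
                       index=scores.index)
    for dim, dim_effects in effects.items():
        for param, eff in dim_effects.items():
            if param not in out.columns:
                raise KeyError(f"unknown agent parameter in effect map: {param!r}")
            out[param] += eff * scores[dim].to_numpy()
    out["action_noise_sd"] = out["action_noise_sd"].clip(lower=0.0)
    out["conf_noise_sd"] = out["conf_noise_sd"].clip(lower=0.0)
    out.insert(0, "subject", scores["subject"].to_numpy())
    return out


def simulate_agent(trials: pd.DataFrame, trace: pd.DataFrame, params: AgentParams, seed, config: TaskConfig | None = None) -> pd.DataFrame:
    """Simulate one subject's buckets, confidence, hits and points.

    ``trials`` must carry ``outcome`` per trial and ``trace`` the aligned
    learner variables.  Confidence on trial t+1 is generated from the
    trial-t evidence (z-scored within the session); the bucket update from
    trial t to t+1 is the learner's update magnitude modulated by that
    confidence, plus action noise.  The bucket starts on the first outcome
    (mirroring the learner's belief initialisation).
    """
    if len(trials) != len(trace):
        raise ValueError("trial table and learner trace are misaligned")
    cfg = config or TaskConfig()
    rng = np.random.default_rng(seed)
    n = len(trials)
    outcomes = trials["outcome"].to_numpy(dtype=float)
    alpha = trace["LRb"].to_numpy(dtype=float)
    peb = trace["PEb"].to_numpy(dtype=float)

    valid = trace["valid"].to_numpy(dtype=bool)
    z_cpp = _session_z(trace["CPP"].to_numpy(dtype=float), valid)
    z_ru = _session_z(trace["RU"].to_numpy(dtype=float), valid)
    z_pe = _session_z(np.abs(trace["PEb"].to_numpy(dtype=float)), valid)

    conf_noise = rng.normal(0.0, params.conf_noise_sd, n) if params.conf_noise_sd > 0 else np.zeros(n)
    act_noise = rng.normal(0.0, params.action_noise_sd, n) if params.action_noise_sd > 0 else np.zeros(n)

    bucket_raw = np.empty(n)       # continuous internal position
    confidence = np.empty(n)
    hit = np.zeros(n, dtype=bool)
    points = np.zeros(n, dtype=int)

    # trial 0: bucket placed blind at a uniform position, start confidence
    bucket_raw[0] = float(rng.integers(1, cfg.circle_points + 1))
    confidence[0] = float(rng.choice(cfg.confidence_start_options))

    # reference mean for standardizing own confidence in the coupling term
    conf_center = params.conf_intercept + 0.5 * params.w_hit

    for t in range(n):
        b_int = float(np.round(bucket_raw[t] - 1.0) % cfg.circle_points + 1)
        hit[t], points[t] = score_trial(b_int, outcomes[t], cfg)
        if t == n - 1:
            break
        # confidence reported on trial t+1, from trial-t evidence
        if valid[t]:
            c = (
                params.conf_intercept
                - params.w_cpp * z_cpp[t]
                - params.w_ru * z_ru[t]
                + params.w_hit * float(hit[t])
                - params.w_pe * z_pe[t]
                + conf_noise[t]
            )
        else:
            c = params.conf_intercept + params.w_hit * float(hit[t]) + conf_noise[t]
        c = float(np.clip(np.round(c), cfg.confidence_min, cfg.confidence_max))
        confidence[t + 1] = c

        pe_own = float(signed_arc(outcomes[t], bucket_raw[t]))
        if t == 0:
            # first update: jump to the first outcome, as the learner does
            bucket_raw[t + 1] = outcomes[0]
            continue
        z_own = (c - conf_center) / CONF_SCALE
        mag = (
            alpha[t] * abs(pe_own) * (1.0 + params.coupling * (-z_own))
            + params.sw_pe_gain * abs(peb[t])
            + act_noise[t]
        )
        mag = max(mag, 0.0)
        bucket_raw[t + 1] = float(wrap_degrees(bucket_raw[t] + np.sign(pe_own) * mag))

    bucket = np.round(bucket_raw - 1.0) % cfg.circle_points + 1
    return pd.DataFrame(
        {
            "bucket": bucket,
            "bucket_raw": bucket_raw,
            "confidence": confidence,
            "hit": hit,
            "points": points,
        }
    )


def _session_z(x: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Z-score over the valid trials of one session (sample SD); invalid
    entries propagate as 0 so they never contribute."""
    out = np.zeros_like(x)
    v = x[valid]
    if v.size < 2:
        return out
    sd = np.std(v, ddof=1)
    if not np.isfinite(sd) or sd == 0:
        return out
    out[valid] = (v - v.mean()) / sd
    return out


#: default SDs of subject-level parameter heterogeneity left unexplained by
#: the dimension scores (real cohorts vary beyond any three traits; this
#: also keeps the mixed models' random-effect variances off the boundary)
DEFAULT_PARAM_JITTER = {"conf_intercept": 3.0, "coupling": 0.05}


def simulate_cohort(
    n_subjects: int = 437,
    task_config: TaskConfig | None = None,
    effects: dict | None = None,
    defaults: AgentParams | None = None,
    correlation=None,
    param_jitter: dict | None = None,
    seed=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort: independent task sessions, learner traces and
    agents per subject.

    ``param_jitter`` maps agent-parameter names to SDs of independent
    normal subject-level deviations added on top of the deterministic
    dimension -> parameter mapping (pass ``{}`` for none).

    Returns ``(trials, subjects)``: a tidy trial table (subject x trial rows
    with task, behaviour and learner-trace columns, ready for
    :func:`predinfer.metrics.derive_trials`) and a subject table with
    dimension scores, covariates and the true agent parameters for
    recovery tests.  Fully reproducible from the master seed.
    """
    cfg = task_config or TaskConfig()
    effects = default_effect_map() if effects is None else effects
    defaults = defaults or AgentParams()
    if param_jitter is None:
        param_jitter = dict(DEFAULT_PARAM_JITTER)

    ss = np.random.SeedSequence(seed)
    s_scores, s_jitter, s_subjects = ss.spawn(3)
    scores = sample_dimension_scores(n_subjects, correlation=correlation, seed=s_scores)
    par_table = map_params(scores, effects, defaults)
    jrng = np.random.default_rng(s_jitter)
    for param, sd in param_jitter.items():
        if param not in par_table.columns:
            raise KeyError(f"unknown agent parameter in param_jitter: {param!r}")
        if sd > 0:
            par_table[param] += jrng.normal(0.0, sd, n_subjects)
    par_table["action_noise_sd"] = par_table["action_noise_sd"].clip(lower=0.0)
    par_table["conf_noise_sd"] = par_table["conf_noise_sd"].clip(lower=0.0)

    param_fields = [f for f in asdict(defaults)]
    subject_seeds = s_subjects.spawn(n_subjects)
    frames = []
    for i in range(n_subjects):
        s_sched, s_mean, s_out, s_agent = subject_seeds[i].spawn(4)
        schedule = build_schedule(cfg, s_sched)
        means = sample_generative_means(schedule, cfg, s_mean)
        outcomes = sample_outcomes(means, cfg, s_out)
        trace = run_learner(outcomes, schedule.hazard, cfg)

        p = AgentParams(**{f: float(par_table.iloc[i][f]) for f in param_fields})
        trial_df = schedule.to_frame()
        trial_df["mean"] = means
        trial_df["outcome"] = outcomes
        beh = simulate_agent(trial_df, trace, p, s_agent, cfg)

        trial_df = pd.concat(
            [trial_df.reset_index(drop=True), beh.reset_index(drop=True),
             trace.drop(columns=["trial"]).reset_index(drop=True)],
            axis=1,
        )
        trial_df.insert(0, "subject", i)
        frames.append(trial_df)

    trials = pd.concat(frames, ignore_index=True)
    subjects = scores.merge(par_table, on="subject", suffixes=("", "_param"))
    return trials, subjects
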