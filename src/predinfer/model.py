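"""Reduced quasi-optimal Bayesian change-point learner.

The learner tracks a point estimate ``B`` of the generative mean on the
circle with a delta rule whose learning rate is rebuilt every trial from
two sources of uncertainty:

* change-point probability (CPP, ``Omega``) — posterior probability that
  the newest outcome came from a freshly re-sampled mean rather than the
  current one, given the hazard rate ``H``;
* relative uncertainty (``tau = 1 - nu``, with ``nu`` the model
  confidence MC) — imprecision of the running mean estimate, which also
  widens the predictive variance ``sigma_t^2``.

Update equations (one trial, outcome ``X``, belief ``B``):

    delta   = signed_arc(X, B)                               (prediction error)
    sigma^2 = sigma_N^2 + (1 - nu) sigma_N^2 / nu            (predictive variance)
    Omega   = U H / (U H + N(delta; 0, sigma^2) (1 - H)),  U = 1/360
    alpha   = Omega + (1 - Omega) tau                        (learning rate)
    B'      = wrap(B + alpha delta)
    tau'    = [Omega s + (1-Omega) tau s + Omega(1-Omega)(delta (1-tau))^2]
              / (same numerator + s),            s = sigma_N^2

``RU = (1 - Omega) tau`` is the relative-uncertainty regressor used by the
downstream confidence/action analyses.  The ``tau'`` ratio measures
uncertainty: it resets to 0.5 after a certain change-point (Omega = 1) and
decays as ``tau/(1+tau)`` in a quiet world (Omega = 0), so model
confidence ``nu = 1 - tau`` grows as evidence accumulates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task import TaskConfig, signed_arc, wrap_degrees

__all__ = [
    "LearnerState",
    "signed_circular_error",
    "change_point_probability",
    "predictive_variance",
    "uncertainty_update",
    "learning_rate",
    "belief_update",
    "run_learner",
    "write_trace",
    "read_trace",
]

#: floor on model confidence nu, guarding the 1/nu in the predictive variance
NU_FLOOR = 1e-6

#: columns of the per-trial learner trace
TRACE_COLUMNS = ["trial", "valid", "B", "PEb", "CPP", "MC", "tau", "sigma2", "LRb", "RU", "B_next"]


@dataclass
class LearnerState:
    """Belief, relative uncertainty and predictive variance entering a trial."""

    B: float
    tau: float
    sigma2: float


def signed_circular_error(X, B):
    """Signed prediction error delta = X - B on the circle, in (-180, 180]."""
    return signed_arc(X, B)


def change_point_probability(delta, sigma2_t, H, config: TaskConfig | None = None):
    """Posterior probability that the outcome came from a re-sampled mean.

    Likelihood ratio of a uniform origin (density 1/circle_points, scaled by
    the hazard) against the current Gaussian predictive distribution.  The
    Gaussian density is the plain unwrapped normal evaluated at the signed
    error; see the module notes.
    """
    H = np.asarray(H, dtype=float)
    if np.any(H < 0) or np.any(H > 1):
        raise ValueError("hazard H must lie in [0, 1]")
    circle = 360 if config is None else config.circle_points
    delta = np.asarray(delta, dtype=float)
    sigma2_t = np.asarray(sigma2_t, dtype=float)
    u = 1.0 / circle
    norm = np.exp(-0.5 * delta**2 / sigma2_t) / np.sqrt(2.0 * np.pi * sigma2_t)
    out = u * H / (u * H + norm * (1.0 - H))
    return out if out.shape else float(out)


def predictive_variance(nu, sigma_N2):
    """sigma_t^2 = sigma_N^2 + (1 - nu) sigma_N^2 / nu, with nu floored."""
    nu = np.maximum(np.asarray(nu, dtype=float), NU_FLOOR)
    out = sigma_N2 + (1.0 - nu) * sigma_N2 / nu
    return out if out.shape else float(out)


def uncertainty_update(omega, tau, delta, sigma_N2):
    """Next-trial relative uncertainty tau' (model confidence nu' = 1 - tau')."""
    omega = np.asarray(omega, dtype=float)
    tau = np.asarray(tau, dtype=float)
    delta = np.asarray(delta, dtype=float)
    num = (
        omega * sigma_N2
        + (1.0 - omega) * tau * sigma_N2
        + omega * (1.0 - omega) * (delta * (1.0 - tau)) ** 2
    )
    out = num / (num + sigma_N2)
    return out if out.shape else float(out)


def learning_rate(omega, tau):
    """Dynamic learning rate alpha = Omega + (1 - Omega) tau, in [0, 1]."""
    omega = np.asarray(omega, dtype=float)
    out = omega + (1.0 - omega) * np.asarray(tau, dtype=float)
    return out if out.shape else float(out)


def belief_update(B, alpha, delta):
    """Delta-rule belief update, wrapped to the continuous circle (0, 360]."""
    out = wrap_degrees(np.asarray(B, dtype=float) + np.asarray(alpha, dtype=float) * np.asarray(delta, dtype=float))
    return out if out.shape else float(out)


def run_learner(outcomes, hazards, config: TaskConfig | None = None) -> pd.DataFrame:
    """Run the learner over one session of outcomes.

    The belief is initialised at the first outcome with maximal relative
    uncertainty (tau = 1), so the first trial carries no prediction error
    and is marked ``valid = False``; downstream regressions drop it.

    Parameters
    ----------
    outcomes, hazards
        Aligned per-trial particle locations and assumed hazard rates
        (the true block hazards of the task).
    config
        Supplies ``sigma_gen`` (generative noise SD) and the circle size;
        defaults to the standard task.

    Returns
    -------
    DataFrame with one row per trial: entering belief ``B``, prediction
    error ``PEb``, change-point probability ``CPP``, model confidence
    ``MC``, relative uncertainty regressor ``RU``, learning rate ``LRb``,
    predictive variance ``sigma2`` and updated belief ``B_next``.
    The trace is deterministic given its inputs.
    """
    if config is None:
        config = TaskConfig()
    outcomes = np.asarray(outcomes, dtype=float)
    hazards = np.asarray(hazards, dtype=float)
    if outcomes.size == 0:
        raise ValueError("outcome sequence is empty")
    if outcomes.shape != hazards.shape:
        raise ValueError("outcomes and hazards must be aligned")

    s = config.sigma_gen2
    n = outcomes.size
    cols = {k: np.full(n, np.nan) for k in ("B", "PEb", "CPP", "MC", "tau", "sigma2", "LRb", "RU", "B_next")}
    valid = np.zeros(n, dtype=bool)

    B = float(outcomes[0])
    tau = 1.0
    cols["B_next"][0] = B
    cols["tau"][0] = tau

    sqrt2pi = math.sqrt(2.0 * math.pi)
    for t in range(1, n):
        nu = max(1.0 - tau, NU_FLOOR)
        sigma2 = s + (1.0 - nu) * s / nu
        delta = float(signed_arc(outcomes[t], B))
        H = float(hazards[t])
        dens = math.exp(-0.5 * delta * delta / sigma2) / (sqrt2pi * math.sqrt(sigma2))
        u = 1.0 / config.circle_points
        omega = u * H / (u * H + dens * (1.0 - H))
        alpha = omega + (1.0 - omega) * tau
        ru = (1.0 - omega) * tau
        B_new = float(wrap_degrees(B + alpha * delta))

        cols["B"][t] = B
        cols["PEb"][t] = delta
        cols["CPP"][t] = omega
        cols["MC"][t] = 1.0 - tau
        cols["tau"][t] = tau
        cols["sigma2"][t] = sigma2
        cols["LRb"][t] = alpha
        cols["RU"][t] = ru
        cols["B_next"][t] = B_new
        valid[t] = True

        num = omega * s + (1.0 - omega) * tau * s + omega * (1.0 - omega) * (delta * (1.0 - tau)) ** 2
        tau = num / (num + s)
        B = B_new

    trace = pd.DataFrame(cols)
    trace.insert(0, "valid", valid)
    trace.insert(0, "trial", np.arange(n))
    return trace


def write_trace(trace: pd.DataFrame, path) -> None:
    trace.loc[:, [c for c in TRACE_COLUMNS if c in trace.columns]].to_csv(path, index=False)


def read_trace(path) -> pd.DataFrame:
    return pd.read_csv(path)
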