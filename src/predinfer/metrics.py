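"""Trial-level derived behaviour measures and exclusion masks.

Derived per trial (within subject):

* ``signed_update`` / ``action`` — signed and absolute circular bucket
  movement from trial t to t+1 (the last trial has no update);
* ``pe`` — signed circular distance from the bucket to the particle
  (the behavioural prediction error);
* ``lr_h`` — human learning rate, signed update divided by signed PE;
* ``conf_next`` / ``z_conf_next`` — confidence reported on trial t+1,
  raw and z-scored within subject;
* within-subject z-scores of the learner-trace regressors.

Exclusions follow the standard trial filters for error-driven learning:
trials with PE = 0 (no error to learn from) and trials whose human
learning rate exceeds the dataset-wide 99th percentile (the percentile is
recomputed on each dataset; it is a quantile rule, not a fixed cut).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .task import signed_arc

__all__ = [
    "zscore_within",
    "compute_action_updates",
    "compute_human_lr",
    "derive_trials",
    "apply_trial_exclusions",
]

LR_PERCENTILE_DEFAULT = 99.0


def zscore_within(values, groups) -> np.ndarray:
    """Z-score ``values`` within each level of ``groups`` (sample SD).

    Groups with zero variance (or a single finite value) get z = 0 and a
    warning rather than NaNs.  NaNs in ``values`` stay NaN.
    """
    s = pd.Series(np.asarray(values, dtype=float))
    g = pd.Series(np.asarray(groups))
    mean = s.groupby(g).transform("mean")
    sd = s.groupby(g).transform("std")
    degenerate = (sd == 0) | sd.isna()
    if bool((degenerate & s.notna()).any()):
        warnings.warn("zero-variance group(s) in zscore_within; z set to 0", stacklevel=2)
    z = (s - mean) / sd.where(~degenerate)
    z = z.where(~(degenerate & s.notna()), 0.0)
    return z.to_numpy()


def compute_action_updates(buckets, blocks=None):
    """Signed and absolute circular bucket change from each trial to the next.

    Returns ``(signed_update, action, crosses_block)`` aligned at trial t
    (NaN / False on the last trial).  ``crosses_block`` marks updates that
    span a block break.
    """
    buckets = np.asarray(buckets, dtype=float)
    if buckets.size < 2:
        raise ValueError("need at least two trials to compute updates")
    signed = np.full(buckets.size, np.nan)
    signed[:-1] = signed_arc(buckets[1:], buckets[:-1])
    action = np.abs(signed)
    crosses = np.zeros(buckets.size, dtype=bool)
    if blocks is not None:
        blocks = np.asarray(blocks)
        crosses[:-1] = blocks[1:] != blocks[:-1]
    return signed, action, crosses


def compute_human_lr(signed_update, pe_signed):
    """Human learning rate LRh = signed update / signed PE.

    Undefined (NaN) where PE = 0; the accompanying boolean marks those
    trials for downstream exclusion.
    """
    signed_update = np.asarray(signed_update, dtype=float)
    pe_signed = np.asarray(pe_signed, dtype=float)
    zero_pe = pe_signed == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        lr = signed_update / pe_signed
    lr[zero_pe] = np.nan
    return lr, zero_pe


def derive_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Augment a tidy trial table (one row per subject x trial, carrying the
    merged learner-trace columns) with the derived analysis variables."""
    df = trials.sort_values(["subject", "trial"]).reset_index(drop=True).copy()

    parts = []
    for _, sub in df.groupby("subject", sort=False):
        sub = sub.copy()
        signed, action, crosses = compute_action_updates(
            sub["bucket"].to_numpy(), sub["block"].to_numpy()
        )
        sub["signed_update"] = signed
        sub["action"] = action
        sub["crosses_block"] = crosses
        sub["pe"] = signed_arc(sub["outcome"].to_numpy(), sub["bucket"].to_numpy())
        sub["lr_h"], sub["zero_pe"] = compute_human_lr(signed, sub["pe"].to_numpy())
        sub["conf_next"] = sub["confidence"].shift(-1)
        parts.append(sub)
    df = pd.concat(parts, ignore_index=True)

    df["abs_peb"] = df["PEb"].abs()
    df["hit01"] = df["hit"].astype(float)
    df["z_conf_next"] = zscore_within(df["conf_next"], df["subject"])
    df["z_cpp"] = zscore_within(df["CPP"], df["subject"])
    df["z_ru"] = zscore_within(df["RU"], df["subject"])
    df["z_abs_peb"] = zscore_within(df["abs_peb"], df["subject"])
    return df


def apply_trial_exclusions(
    df: pd.DataFrame,
    percentile: float = LR_PERCENTILE_DEFAULT,
    drop_zero_pe_first: bool = True,
    exclude_block_crossings: bool = False,
) -> pd.DataFrame:
    """Flag trials unrelated to error-driven learning.

    The LRh threshold is the ``percentile``-th percentile of the pooled
    dataset's human learning rate, computed (by default) after removing
    PE = 0 trials, and applied as a one-sided upper cut.  Reasons are
    machine-readable: ``lr_outlier``, ``zero_pe`` and (optionally)
    ``block_boundary``.  The operation is idempotent: re-applying it to its
    own output reproduces the same mask.

    Returns a copy with ``excluded`` (bool), ``exclusion_reason`` (str) and
    attaches the realised threshold and excluded fraction in ``df.attrs``.
    """
    out = df.copy()
    lr = out["lr_h"].to_numpy(dtype=float)
    zero_pe = out["zero_pe"].to_numpy(dtype=bool)

    pool = lr[np.isfinite(lr)] if drop_zero_pe_first else lr
    pool = pool[np.isfinite(pool)]
    if pool.size == 0:
        raise ValueError("no finite human learning rates to compute the percentile from")
    threshold = float(np.percentile(pool, percentile))

    lr_outlier = np.isfinite(lr) & (lr > threshold)
    reasons = np.array([""] * len(out), dtype=object)
    reasons[lr_outlier] = "lr_outlier"
    reasons[zero_pe] = "zero_pe"
    excluded = lr_outlier | zero_pe
    if exclude_block_crossings:
        crossing = out["crosses_block"].to_numpy(dtype=bool)
        reasons[crossing & ~excluded] = "block_boundary"
        excluded = excluded | crossing

    has_update = np.isfinite(out["signed_update"].to_numpy(dtype=float)) | zero_pe
    if bool(np.all(excluded[has_update])):
        raise ValueError("exclusion rules removed every trial with an update")

    out["excluded"] = excluded
    out["exclusion_reason"] = reasons
    out.attrs["lr_threshold"] = threshold
    out.attrs["excluded_fraction"] = float(excluded[has_update].mean())
    return out
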