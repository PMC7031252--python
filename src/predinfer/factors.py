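"""Transdiagnostic factor scoring from questionnaire items.

Three symptom dimensions (AD, CIT, SW) are computed as weighted sums of
209 questionnaire items from nine self-report instruments.  The published
weight matrix is external input (a 209 x 3 CSV); this module implements
the scoring transform, strict label validation, and synthetic fixtures —
a weight matrix and matching item responses, both clearly synthetic — so
the pipeline is testable without any external download.

Scoring convention: item columns are standardized (mean 0, sample SD 1)
before the weighted sum, the conventional factor-score procedure.  Scoring
is therefore invariant to item scale and to column order (items and
weights are joined on their labels).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .cohort import default_dimension_corr

__all__ = [
    "INSTRUMENT_ITEMS",
    "FACTORS",
    "item_labels",
    "score_factors",
    "make_weight_fixture",
    "make_item_fixture",
]

FACTORS = ("AD", "CIT", "SW")

#: items per instrument (totalling 209 across the nine questionnaires)
INSTRUMENT_ITEMS = {
    "AUDIT": 10,   # alcohol use
    "AES": 18,     # apathy
    "SDS": 20,     # depression
    "EAT": 26,     # eating attitudes
    "BIS": 30,     # impulsivity
    "OCI": 18,     # obsessive-compulsive
    "STAI": 20,    # trait anxiety
    "SSMS": 43,    # schizotypy (short scales)
    "LSAS": 24,    # social anxiety
}

N_ITEMS = sum(INSTRUMENT_ITEMS.values())
assert N_ITEMS == 209

#: instrument -> factor assignment used only by the synthetic fixtures
_FIXTURE_PRIMARY = {
    "SDS": "AD", "STAI": "AD", "AES": "AD",
    "OCI": "CIT", "EAT": "CIT", "BIS": "CIT",
    "LSAS": "SW", "SSMS": "SW", "AUDIT": "SW",
}


def item_labels() -> list[str]:
    """Canonical item labels, e.g. ``AUDIT_01`` ... ``LSAS_24``."""
    return [f"{inst}_{i:02d}" for inst, n in INSTRUMENT_ITEMS.items() for i in range(1, n + 1)]


def score_factors(items: pd.DataFrame, weights: pd.DataFrame) -> pd.DataFrame:
    """Factor scores: column-standardized items times the weight matrix.

    ``items`` is subjects x 209 (integer questionnaire codings), ``weights``
    is 209 x 3 indexed by item label.  Labels are joined, so column order
    is irrelevant; any mismatch raises naming the offending items.
    """
    item_cols = set(items.columns)
    weight_rows = set(weights.index)
    missing = sorted(weight_rows - item_cols)
    extra = sorted(item_cols - weight_rows)
    if missing or extra:
        raise ValueError(
            "item/weight label mismatch; "
            f"missing from items: {missing[:5]}{'...' if len(missing) > 5 else ''}; "
            f"unweighted items: {extra[:5]}{'...' if len(extra) > 5 else ''}"
        )
    if items.isna().any().any():
        bad = sorted(items.columns[items.isna().any()])
        raise ValueError(f"missing responses in items: {bad[:5]}")

    X = items.loc[:, weights.index].to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    degenerate = ~np.isfinite(sd) | (sd == 0)
    if degenerate.any():
        warnings.warn("zero-variance item(s); their standardized responses set to 0")
        sd = np.where(degenerate, 1.0, sd)
    Z = (X - mu) / sd
    Z[:, degenerate] = 0.0
    scores = Z @ weights.to_numpy(dtype=float)
    return pd.DataFrame(scores, index=items.index, columns=list(weights.columns))


def make_weight_fixture(seed=None) -> pd.DataFrame:
    """SYNTHETIC 209 x 3 weight matrix (not the published weights).

    Each item loads mainly on its instrument's fixture factor (weights
    normalized to sum 1 within factor) with tiny cross-loadings, so that
    scores of items generated by :func:`make_item_fixture` reproduce the
    moderate factor inter-correlations of the real dimensions.
    """
    rng = np.random.default_rng(seed)
    labels = item_labels()
    W = pd.DataFrame(rng.normal(0.0, 0.01, (N_ITEMS, 3)), index=labels, columns=list(FACTORS))
    for f in FACTORS:
        own = [lab for lab in labels if _FIXTURE_PRIMARY[lab.split("_")[0]] == f]
        raw = rng.uniform(0.5, 1.0, len(own))
        W.loc[own, f] += raw / raw.sum()
    return W


def make_item_fixture(n_subjects: int, seed=None, correlation=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SYNTHETIC item responses: latent factors (default correlations from
    the cohort module) drive their instruments' items, discretized to a
    1-5 coding.  Returns ``(items, latents)``."""
    corr = default_dimension_corr() if correlation is None else np.asarray(correlation, dtype=float)
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(corr)
    F = rng.standard_normal((n_subjects, 3)) @ chol.T
    latents = pd.DataFrame(F, columns=list(FACTORS))

    loading = 0.7
    noise_sd = np.sqrt(1.0 - loading**2)
    labels = item_labels()
    fidx = {f: i for i, f in enumerate(FACTORS)}
    cols = {}
    for lab in labels:
        f = _FIXTURE_PRIMARY[lab.split("_")[0]]
        x = loading * F[:, fidx[f]] + rng.normal(0.0, noise_sd, n_subjects)
        cols[lab] = np.clip(np.round(x * 1.2 + 3.0), 1, 5).astype(int)
    return pd.DataFrame(cols), latents
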