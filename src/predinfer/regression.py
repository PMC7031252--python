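"""Mixed-effects analyses of coupling, levels and evidence influence.

Three model families, all linear mixed models with subject grouping,
estimated by REML (statsmodels ``MixedLM``):

* coupling — absolute bucket update (``action``) on within-subject
  z-scored confidence, with random intercept AND random confidence slope
  per subject; between-subject moderators enter as main effects plus
  moderator x confidence interactions;
* level — confidence (or action) on moderators and covariates, random
  intercept only;
* evidence — for the action update: ``|PEb|`` plus ``|PEb|`` x CPP/RU/Hit
  interactions (raw scale); for confidence: z-scored ``|PEb|``, CPP, RU
  plus Hit as main effects.  Moderators interact with every evidence term.
  Random intercept only.

All models control for standardized age and IQ and binary gender.
Alongside the classical (model-based) standard errors every fit reports
subject-clustered sandwich standard errors, and moderator terms carry
Bonferroni-adjusted p-values over the number of psychiatric independent
variables examined (9 questionnaires or 3 dimensions).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.diagnostic import het_white

__all__ = [
    "RegressionResult",
    "COVARIATES",
    "prepare_analysis_table",
    "fit_coupling_model",
    "fit_level_model",
    "fit_evidence_model",
    "robust_se",
    "white_test",
    "bonferroni",
    "percent_change_effect",
    "results_to_csv",
]

#: standardized demographic covariates entering every model
COVARIATES = ("age_z", "gender", "iq_z")

Z_CRIT = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class RegressionResult:
    """Tidy fixed-effect table plus fit metadata.

    ``table`` columns: term, estimate, se, robust_se, ci_lo, ci_hi, p,
    p_bonf.  Confidence intervals are Wald (normal approximation) on the
    classical SE; ``p_bonf`` is ``min(1, m * p)`` applied to moderator
    terms only (NaN elsewhere).
    """

    model_id: str
    table: pd.DataFrame
    n_obs: int
    n_subjects: int
    converged: bool
    re_var: dict = field(default_factory=dict)
    message: str = ""

    def coef(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "estimate"])

    def pvalue(self, term: str, adjusted: bool = False) -> float:
        col = "p_bonf" if adjusted else "p"
        return float(self.table.set_index("term").loc[term, col])


def prepare_analysis_table(derived: pd.DataFrame, subjects: pd.DataFrame, moderators=()) -> pd.DataFrame:
    """Merge derived trials with the subject table, standardize moderators
    and continuous covariates across subjects, and drop excluded rows.

    Gender stays 0/1; age, IQ and every moderator are z-scored over the
    subjects present in the data.
    """
    keep = ["subject", "age", "gender", "IQ", *moderators]
    missing = [c for c in keep if c not in subjects.columns]
    if missing:
        raise KeyError(f"subject table lacks columns: {missing}")
    df = derived.merge(subjects[keep], on="subject", how="left")

    def _z(col: str) -> np.ndarray:
        per_subject = subjects.set_index("subject")[col].loc[df["subject"].unique()]
        mu, sd = per_subject.mean(), per_subject.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"cannot standardize degenerate covariate {col!r}")
        return ((df[col] - mu) / sd).to_numpy()

    df["age_z"] = _z("age")
    df["iq_z"] = _z("IQ")
    for m in moderators:
        df[m + "_z"] = _z(m)

    if "excluded" in df.columns:
        df = df.loc[~df["excluded"]]
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

def _moderator_terms(moderators, within_terms):
    """Main effect plus interaction with every within-subject term."""
    out = []
    for m in moderators:
        mz = m + "_z"
        out.append(mz)
        out.extend(f"{mz}:{w}" for w in within_terms)
    return out


def _fit(formula: str, data: pd.DataFrame, re_formula: str, model_id: str,
         moderators=(), m_bonf: int | None = None) -> RegressionResult:
    """Fit one mixed model and assemble the tidy result.

    Non-convergence and boundary estimates are flagged on the result, not
    raised; rank-deficient fixed-effect designs raise an informative error.
    """
    cols_needed = [c for c in data.columns
                   if re.search(rf"(?<![A-Za-z0-9_]){re.escape(c)}(?![A-Za-z0-9_])", formula)]
    use = data.dropna(subset=cols_needed).copy()
    groups = use["subject"].to_numpy()

    md = smf.mixedlm(formula, use, groups=groups, re_formula=re_formula)
    rank = np.linalg.matrix_rank(md.exog)
    if rank < md.exog.shape[1]:
        bad = ", ".join(md.exog_names)
        raise ValueError(
            f"fixed-effect design is rank deficient ({rank} < {md.exog.shape[1]}); "
            f"check for constant or collinear predictors among: {bad}"
        )

    message = ""
    fit = None
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        # lbfgs is fastest but can return a degenerate solution when a
        # variance component sits on the boundary; fall back to powell
        for meth in ("lbfgs", "powell", "bfgs"):
            try:
                cand = md.fit(reml=True, method=[meth], maxiter=500)
            except (np.linalg.LinAlgError, ValueError) as err:
                message = f"estimation failed ({meth}): {err}"
                continue
            se_cand = np.asarray(cand.bse_fe)
            if np.all(np.isfinite(se_cand)) and np.all(se_cand > 0):
                fit = cand
                break
            fit = fit or cand
        if fit is None:
            return RegressionResult(model_id=model_id, table=pd.DataFrame(), n_obs=len(use),
                                    n_subjects=len(np.unique(groups)), converged=False,
                                    message=message)
        for w in caught:
            if "onverge" in str(w.message) or "boundary" in str(w.message):
                message = str(w.message)
    converged = bool(getattr(fit, "converged", True)) and "failed" not in message
    if not np.all(np.isfinite(np.asarray(fit.bse_fe))):
        converged = False
        message = message or "degenerate fixed-effect covariance"

    names = list(md.exog_names)
    est = np.asarray(fit.fe_params)
    se = np.asarray(fit.bse_fe)
    rob = robust_se(fit)
    z = np.divide(est, se, out=np.full_like(est, np.nan), where=se > 0)
    p = 2 * stats.norm.sf(np.abs(z))
    z_rob = np.divide(est, rob, out=np.full_like(est, np.nan), where=rob > 0)
    p_rob = 2 * stats.norm.sf(np.abs(z_rob))

    m = m_bonf if m_bonf is not None else max(len(moderators), 1)
    mod_terms = {t for mo in moderators for t in names if mo + "_z" in t}
    p_bonf = np.array([bonferroni(pv, m) if t in mod_terms else np.nan for t, pv in zip(names, p)])
    p_rob_bonf = np.array([bonferroni(pv, m) if t in mod_terms else np.nan for t, pv in zip(names, p_rob)])

    table = pd.DataFrame(
        {
            "term": names,
            "estimate": est,
            "se": se,
            "robust_se": rob,
            "ci_lo": est - Z_CRIT * se,
            "ci_hi": est + Z_CRIT * se,
            "p": p,
            "p_bonf": p_bonf,
            "p_robust": p_rob,
            "p_robust_bonf": p_rob_bonf,
        }
    )
    re_var = {}
    cov_re = np.atleast_2d(np.asarray(fit.cov_re))
    for i, nm in enumerate(md.data.exog_re_names or []):
        if i < cov_re.shape[0]:
            re_var[nm] = float(cov_re[i, i])
    re_var["residual"] = float(fit.scale)

    res = RegressionResult(model_id=model_id, table=table, n_obs=len(use),
                           n_subjects=len(np.unique(groups)), converged=converged,
                           re_var=re_var, message=message)
    res._fit = fit  # underlying statsmodels results, for diagnostics
    return res


def fit_coupling_model(data: pd.DataFrame, moderators=(), m_bonf: int | None = None) -> RegressionResult:
    """Action-confidence coupling: ``action ~ z_conf_next`` plus covariates,
    random intercept and random confidence slope per subject.  Moderators
    add a main effect and a moderator x confidence interaction each."""
    terms = ["z_conf_next", *COVARIATES, *_moderator_terms(moderators, ["z_conf_next"])]
    formula = "action ~ " + " + ".join(terms)
    return _fit(formula, data, re_formula="~z_conf_next",
                model_id="coupling" + ("+" + "+".join(moderators) if moderators else ""),
                moderators=moderators, m_bonf=m_bonf)


def fit_level_model(data: pd.DataFrame, dv: str = "confidence", moderators=(), m_bonf: int | None = None) -> RegressionResult:
    """Mean confidence or action level on moderators; random intercept only."""
    if dv not in ("confidence", "action"):
        raise ValueError("dv must be 'confidence' or 'action'")
    dvcol = "conf_next" if dv == "confidence" else "action"
    terms = [*COVARIATES, *_moderator_terms(moderators, [])]
    formula = f"{dvcol} ~ " + " + ".join(terms)
    return _fit(formula, data, re_formula="1",
                model_id=f"level_{dv}" + ("+" + "+".join(moderators) if moderators else ""),
                moderators=moderators, m_bonf=m_bonf)


def fit_evidence_model(data: pd.DataFrame, dv: str = "confidence", moderators=(), m_bonf: int | None = None) -> RegressionResult:
    """Influence of model evidence on confidence or on the action update.

    For ``dv='action'`` the evidence terms are ``abs_peb`` and its
    interactions with CPP, RU and Hit (raw scales); for
    ``dv='confidence'`` they are within-subject z-scored ``|PEb|``, CPP
    and RU plus the Hit indicator, with confidence kept on its raw 1-100
    scale.  Random intercept only.
    """
    if dv == "action":
        within = ["abs_peb", "abs_peb:CPP", "abs_peb:RU", "abs_peb:hit01"]
        dvcol = "action"
    elif dv == "confidence":
        within = ["z_abs_peb", "z_cpp", "z_ru", "hit01"]
        dvcol = "conf_next"
    else:
        raise ValueError("dv must be 'confidence' or 'action'")
    terms = [*within, *COVARIATES, *_moderator_terms(moderators, within)]
    formula = f"{dvcol} ~ " + " + ".join(terms)
    return _fit(formula, data, re_formula="1",
                model_id=f"evidence_{dv}" + ("+" + "+".join(moderators) if moderators else ""),
                moderators=moderators, m_bonf=m_bonf)


# ---------------------------------------------------------------------------
# robust SEs, heteroskedasticity, multiplicity
# ---------------------------------------------------------------------------

def robust_se(fit) -> np.ndarray:
    """Subject-clustered sandwich standard errors for the fixed effects of a
    fitted ``MixedLM``.

    Uses the estimated marginal covariance V_g = Z_g G Z_g' + s I per
    subject: bread A = sum X_g' V_g^-1 X_g, meat M = sum u_g u_g' with
    u_g = X_g' V_g^-1 r_g, r_g the marginal residuals; the covariance is
    A^-1 M A^-1 with a G/(G-1) small-sample factor.  With a single
    cluster this degenerates; a warning is issued and NaNs returned.
    """
    model = fit.model
    X = model.exog
    y = model.endog
    Zall = model.exog_re if model.exog_re is not None else np.ones((len(y), 1))
    G = np.atleast_2d(np.asarray(fit.cov_re))
    s = float(fit.scale)
    beta = np.asarray(fit.fe_params)
    resid = y - X @ beta

    labels = model.group_labels
    k = X.shape[1]
    A = np.zeros((k, k))
    M = np.zeros((k, k))
    n_groups = len(labels)
    if n_groups < 2:
        warnings.warn("robust_se: fewer than two clusters; sandwich is degenerate")
        return np.full(k, np.nan)

    for g in labels:
        idx = model.row_indices[g]
        Xg = X[idx]
        Zg = np.atleast_2d(Zall[idx])
        rg = resid[idx]
        ng = len(idx)
        # Woodbury: V^-1 = (I - Z (s G^-1 + Z'Z)^-1 Z') / s
        try:
            inner = np.linalg.solve(s * np.linalg.inv(G) + Zg.T @ Zg, Zg.T)
            Vinv_X = (Xg - Zg @ (inner @ Xg)) / s
            Vinv_r = (rg - Zg @ (inner @ rg)) / s
        except np.linalg.LinAlgError:
            # boundary estimate (G singular): marginal covariance is s*I
            Vinv_X = Xg / s
            Vinv_r = rg / s
        A += Xg.T @ Vinv_X
        u = Xg.T @ Vinv_r
        M += np.outer(u, u)

    Ainv = np.linalg.inv(A)
    cov = Ainv @ M @ Ainv * (n_groups / (n_groups - 1.0))
    return np.sqrt(np.diag(cov))


def white_test(resid, exog) -> tuple[float, float]:
    """White's heteroskedasticity test: auxiliary regression of squared
    residuals on the predictors, their squares and cross-products; returns
    (LM statistic, chi-square p-value)."""
    resid = np.asarray(resid, dtype=float)
    exog = np.asarray(exog, dtype=float)
    if exog.ndim == 1:
        exog = exog[:, None]
    if not np.allclose(exog[:, 0], 1.0):
        exog = np.column_stack([np.ones(len(exog)), exog])
    if np.allclose(resid, resid[0]):
        return 0.0, 1.0
    stat, p, _, _ = het_white(resid, exog)
    return float(stat), float(p)


def bonferroni(p, m: int):
    """Bonferroni adjustment: min(1, m * p), elementwise."""
    if m < 1:
        raise ValueError("m must be >= 1")
    out = np.minimum(1.0, m * np.asarray(p, dtype=float))
    return out if out.shape else float(out)


def percent_change_effect(beta_interaction: float, beta_main: float) -> float:
    """Moderation expressed as percent change of the main effect's size per
    +1 SD of the moderator: 100 * beta_interaction / |beta_main|.

    A positive value on a negative main effect is attenuation.  Undefined
    (NaN, with a warning) when the main effect is exactly zero.
    """
    if beta_main == 0:
        warnings.warn("percent_change_effect undefined for a zero main effect")
        return float("nan")
    return 100.0 * beta_interaction / abs(beta_main)


def results_to_csv(results, path) -> None:
    """Write one or more RegressionResults as a single tidy CSV."""
    if isinstance(results, RegressionResult):
        results = [results]
    rows = []
    for r in results:
        t = r.table.copy()
        t["model_id"] = r.model_id
        t["n_obs"] = r.n_obs
        t["n_subjects"] = r.n_subjects
        t["converged"] = r.converged
        rows.append(t)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
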