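"""Stepwise logistic model building for hydration-marker screening.

Reproduces, at desk scale, the exploratory procedure used to arrive at the
4-item instrument: logistic regression of a binary low/high urine
concentration outcome on candidate markers, with forward entry at
p <= 0.10 and backward retention at p < 0.05 (Wald tests), while
adjusting for demographic covariates.  Which markers are "practically
relevant" is a judgment call outside any algorithm; a manual
``forced_include`` list stands in for it.

Maximum-likelihood fitting is delegated to statsmodels (Newton/IRLS);
this module owns the stepping logic, separation handling, and the
odds-ratio reporting surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .diagnostics import auc_rank

SEPARATION_COEF_LIMIT = 25.0  # |beta| beyond this is treated as divergence


class SelectionError(ValueError):
    """Raised for invalid selection inputs."""


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit with separation diagnostics."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    cov: pd.DataFrame
    loglik: float
    converged: bool
    separation: bool
    n: int

    def odds_ratios(self, alpha: float = 0.05) -> pd.DataFrame:
        from scipy.stats import norm

        z = float(-norm.ppf(alpha / 2.0))
        lo = np.exp(self.params - z * self.bse)
        hi = np.exp(self.params + z * self.bse)
        return pd.DataFrame(
            {"odds_ratio": np.exp(self.params), "ci_low": lo, "ci_high": hi,
             "p_value": self.pvalues}
        )


def fit_logistic(X: pd.DataFrame, y) -> LogisticFit:
    """Fit a logistic regression by Newton-type IRLS.

    ``X`` must already contain a constant column if an intercept is
    wanted (see :func:`design_matrix`).  Perfect or quasi-perfect
    separation is detected and flagged on the result instead of being
    allowed to diverge silently.
    """
    X = pd.DataFrame(X).astype(float)
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or len(y) != len(X):
        raise SelectionError("outcome must be a vector matching the design matrix")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise SelectionError("outcome must be binary 0/1")
    if len(X) <= X.shape[1]:
        raise SelectionError("need n > p to fit")

    separation = False
    with warnings.catch_warnings(), np.errstate(over="ignore", divide="ignore"):
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            res = sm.Logit(y, X).fit(method="newton", maxiter=100, tol=1e-8, disp=0)
        except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
            # Separated likelihood: refit by damped binomial IRLS, which
            # returns large-but-finite estimates and a usable deviance.
            separation = True
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                with np.errstate(all="ignore"):
                    res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=50)
    if np.max(np.abs(np.asarray(res.params))) > SEPARATION_COEF_LIMIT:
        separation = True
    try:
        cov = pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns)
        bse = pd.Series(np.asarray(res.bse), index=X.columns)
        pvalues = pd.Series(np.asarray(res.pvalues), index=X.columns)
    except Exception:  # covariance undefined under separation
        cov = pd.DataFrame(np.full((X.shape[1], X.shape[1]), np.nan),
                           index=X.columns, columns=X.columns)
        bse = pd.Series(np.nan, index=X.columns)
        pvalues = pd.Series(np.nan, index=X.columns)
    return LogisticFit(
        params=pd.Series(np.asarray(res.params), index=X.columns),
        bse=bse,
        pvalues=pvalues,
        cov=cov,
        loglik=float(res.llf) if np.isfinite(res.llf) else np.nan,
        converged=bool(getattr(res, "mle_retvals", {}).get("converged", True)),
        separation=separation,
        n=len(X),
    )


def design_matrix(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Constant + selected columns; categoricals are reference-coded.

    The reference level of each categorical column is its most frequent
    category.  Constant columns are dropped (they cannot enter selection).
    """
    parts = [pd.Series(1.0, index=df.index, name="const")]
    for col in columns:
        s = df[col]
        if s.dtype == bool:
            parts.append(s.astype(float).rename(col))
        elif s.dtype.kind in "ifu":
            parts.append(s.astype(float).rename(col))
        else:
            ref = s.mode(dropna=False).iloc[0]
            dummies = pd.get_dummies(s, prefix=col, dtype=float)
            dummies = dummies.drop(columns=f"{col}_{ref}", errors="ignore")
            parts.extend(dummies[c].rename(c) for c in dummies.columns)
    X = pd.concat(parts, axis=1)
    keep = [c for c in X.columns if c == "const" or X[c].nunique() > 1]
    return X[keep]


def marker_candidates(
    features: pd.DataFrame,
    classified: pd.DataFrame,
    session: str = "afternoon",
    extra: tuple[str, ...] = ("thirst_percent", "bm_flag_ge_1pct"),
) -> tuple[pd.DataFrame, np.ndarray]:
    """Candidate matrix (four binary items + extra markers) and outcome.

    Joins one session's scored items with additional candidate markers
    from the feature table; the outcome is the binary reference label
    (1 = high concentration).  ``void duration`` is deliberately not a
    default extra: it is a direct proxy of the spot volume.
    """
    f = features[features["session"] == session].reset_index(drop=True)
    cl = classified[classified["session"] == session].reset_index(drop=True)
    if not (f["participant_id"].astype(str) == cl["participant_id"].astype(str)).all():
        raise SelectionError("features and classified tables are misaligned")
    X = cl[["intake_item", "frequency_item", "volume_item", "color_item"]].copy()
    for col in extra:
        X[col] = f[col].astype(float)
    y = (cl["reference_label"] == "high_concentration").to_numpy(dtype=float)
    return X, y


@dataclass
class SelectionResult:
    """Outcome of a stepwise run: retained markers and the final fit."""

    retained: list[str]
    table: pd.DataFrame  # coef, se, p, OR + CI per retained term
    auc: float | None
    fit: LogisticFit | None
    history: list[str] = field(default_factory=list)
    diagnostics: str = ""


def _candidate_pvalue(fit: LogisticFit, candidate: str, X: pd.DataFrame) -> float:
    """Wald p of a candidate; categoricals use their smallest indicator p."""
    cols = [c for c in X.columns if c == candidate or c.startswith(candidate + "_")]
    p = fit.pvalues[cols].min()
    return float(p) if np.isfinite(p) else 1.0


def _lr_pvalue(full: LogisticFit, reduced: LogisticFit, df: int) -> float:
    """Likelihood-ratio p-value for nested fits.

    Used instead of Wald when the full model is separated: under
    separation the Wald statistic collapses (SE -> inf) even though the
    term is maximally informative, while the deviance difference remains
    well behaved.
    """
    from scipy.stats import chi2

    if not (np.isfinite(full.loglik) and np.isfinite(reduced.loglik)):
        return 0.0 if full.separation else 1.0
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    return float(chi2.sf(stat, max(df, 1)))


def stepwise_select(
    candidates: pd.DataFrame,
    outcome,
    covariates: pd.DataFrame | None = None,
    entry_p: float = 0.10,
    stay_p: float = 0.05,
    forced_include: tuple[str, ...] = (),
) -> SelectionResult:
    """Forward-backward stepwise logistic selection with Wald p-values.

    Each forward step refits the current model plus one candidate at a
    time (covariates always adjusted for) and admits the smallest
    candidate p <= ``entry_p``; each backward step drops any retained
    candidate whose p has risen above ``stay_p``.  Ties are broken by the
    declared column order.  Covariates are adjusted for during stepping
    but dropped from the final model when not significant at ``stay_p``,
    and ``forced_include`` markers are kept regardless of p.
    """
    if candidates.shape[1] == 0:
        raise SelectionError("need at least one candidate column")
    if not (0 < stay_p <= entry_p < 1):
        raise SelectionError("need 0 < stay_p <= entry_p < 1")
    y = np.asarray(outcome, dtype=float)
    cov_cols = list(covariates.columns) if covariates is not None else []
    frame = pd.concat([candidates, covariates], axis=1) if covariates is not None else candidates

    def fit_with(cands: list[str]) -> LogisticFit:
        X = design_matrix(frame, cands + cov_cols)
        return fit_logistic(X, y)

    selected: list[str] = [c for c in forced_include if c in candidates.columns]
    remaining = [c for c in candidates.columns if c not in selected]
    # drop constant candidates up front
    remaining = [c for c in remaining if candidates[c].nunique() > 1]
    history: list[str] = []
    visited: set[frozenset] = set()

    while True:
        key = frozenset(selected)
        if key in visited:
            history.append("cycle detected; stopping at current model")
            break
        visited.add(key)
        # forward
        base_fit = fit_with(selected) if (selected or cov_cols) else None
        best_p, best_c = None, None
        for cand in remaining:
            fit = fit_with(selected + [cand])
            X_cand = design_matrix(frame, selected + [cand] + cov_cols)
            if fit.separation:
                reduced = base_fit if base_fit is not None else fit_with([])
                df = X_cand.shape[1] - design_matrix(frame, selected + cov_cols).shape[1]
                p = _lr_pvalue(fit, reduced, df)
            else:
                p = _candidate_pvalue(fit, cand, X_cand)
            if p <= entry_p and (best_p is None or p < best_p):
                best_p, best_c = p, cand
        if best_c is not None:
            selected.append(best_c)
            remaining.remove(best_c)
            history.append(f"add {best_c} (p={best_p:.4g})")
        # backward
        removed = False
        if selected:
            fit = fit_with(selected)
            X = design_matrix(frame, selected + cov_cols)
            droppable = [c for c in selected if c not in forced_include]

            def term_p(c: str) -> float:
                if fit.separation:
                    reduced = fit_with([s for s in selected if s != c])
                    df = X.shape[1] - design_matrix(
                        frame, [s for s in selected if s != c] + cov_cols
                    ).shape[1]
                    return _lr_pvalue(fit, reduced, df)
                return _candidate_pvalue(fit, c, X)

            worst = sorted(
                ((term_p(c), c) for c in droppable),
                key=lambda t: (-t[0], selected.index(t[1])),
            )
            if worst and worst[0][0] > stay_p:
                p, c = worst[0]
                selected.remove(c)
                remaining.append(c)
                history.append(f"drop {c} (p={p:.4g})")
                removed = True
        if best_c is None and not removed:
            break

    if not selected:
        return SelectionResult([], pd.DataFrame(), None, None, history,
                               "no candidate met the entry criterion")

    # final model: retained candidates plus only the covariates that earn
    # their place at stay_p
    final_fit = fit_with(selected)
    X_full = design_matrix(frame, selected + cov_cols)
    kept_covs = [
        c for c in cov_cols
        if _candidate_pvalue(final_fit, c, X_full) < stay_p
    ]
    X_final = design_matrix(frame, selected + kept_covs)
    final_fit = fit_logistic(X_final, y)
    from scipy.stats import norm

    z = float(norm.ppf(0.975))
    with np.errstate(over="ignore"):
        table = pd.DataFrame(
            {
                "coef": final_fit.params,
                "se": final_fit.bse,
                "p_value": final_fit.pvalues,
                "odds_ratio": np.exp(final_fit.params),
                "or_ci_low": np.exp(final_fit.params - z * final_fit.bse),
                "or_ci_high": np.exp(final_fit.params + z * final_fit.bse),
            }
        )
        probs = 1.0 / (1.0 + np.exp(-X_final.to_numpy() @ final_fit.params.to_numpy()))
    auc = auc_rank(probs, y, positive=1.0) if 0 < y.sum() < len(y) else None
    return SelectionResult(sorted(selected, key=list(candidates.columns).index),
                           table, auc, final_fit, history)
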