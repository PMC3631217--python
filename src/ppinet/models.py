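"""Link-scoring models: logistic regression and the drug-random-intercept GLMM.

The response for an unordered drug pair (i, j) is a Bernoulli indicator of a
known interaction; covariates come from :mod:`ppinet.covariates`.  Two model
classes are supported:

* ``LR`` — ordinary logistic regression, one row per pair, fitted by maximum
  likelihood (statsmodels).  Candidate covariate subsets are compared by AIC
  over an exhaustive search.
* ``GLMM`` — the same fixed effects plus a drug-specific random intercept.
  Each pair is represented twice in the training data, once keyed to each
  endpoint, so that every drug's intercept sees all of its pairs; this
  double-counting is deliberate and uncorrected.  Estimation maximizes the
  Laplace-approximate marginal likelihood: because every row carries exactly
  one random intercept, the conditional mode of the intercepts separates by
  drug and is found by a vectorized per-drug Newton step, and the outer
  optimization over fixed effects and intercept variance is a small smooth
  problem handed to scipy.  Random intercepts are reported at their
  conditional mode (the BLUP analogue).  Validation scoring averages the
  two directed predicted probabilities, ``(pest_ij + pest_ji) / 2``, where
  ``pest_ij`` uses drug i's intercept; drugs without an estimated intercept
  shrink to the prior mean 0.

No installed library offers maximum-likelihood binary-response GLMMs at this
scale, so the Laplace fit is authored here; the scoring contract
(intercept-averaged probabilities), not the estimation algorithm, is
normative, and ``lme4::glmer`` serves as an external cross-check in tests.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.metrics import roc_auc_score

from .covariates import COVARIATE_NAMES
from .network import canonical_pair

logger = logging.getLogger("ppinet")

__all__ = [
    "FitResult",
    "ScoredPairs",
    "fit_logistic",
    "univariate_screen",
    "subset_search_aic",
    "duplicate_for_glmm",
    "fit_glmm",
    "score_pairs",
]

#: relative log-likelihood / parameter-change convergence tolerance
CONVERGENCE_TOL = 1e-8
MAX_ITER = 200


@dataclass
class FitResult:
    """Fitted link model: coefficients, inference, and scoring metadata."""

    covariate_names: list[str]
    coefficients: pd.Series          # index: ["const", *covariate_names]
    standard_errors: pd.Series
    p_values: pd.Series
    aic: float
    model_class: str                 # "LR" | "GLMM"
    random_intercepts: dict[str, float] = field(default_factory=dict)
    variance_component: float = 0.0
    converged: bool = True
    diagnostics: str = ""

    def linear_predictor(self, table: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.covariate_names if c not in table.columns]
        if missing:
            raise KeyError(f"covariate columns missing from table: {missing}")
        x = table[self.covariate_names].to_numpy(dtype=float)
        beta = self.coefficients[self.covariate_names].to_numpy()
        return self.coefficients["const"] + x @ beta

    def to_dict(self) -> dict:
        return {
            "model_class": self.model_class,
            "covariates": self.covariate_names,
            "coefficients": self.coefficients.to_dict(),
            "standard_errors": self.standard_errors.to_dict(),
            "p_values": self.p_values.to_dict(),
            "aic": self.aic,
            "variance_component": self.variance_component,
            "converged": self.converged,
            "diagnostics": self.diagnostics,
            "random_intercepts": self.random_intercepts,
        }


@dataclass
class ScoredPairs:
    """Per-pair interaction scores (estimated probabilities in (0, 1))."""

    pairs: list[tuple[str, str]]
    scores: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "drug_a": [p[0] for p in self.pairs],
            "drug_b": [p[1] for p in self.pairs],
            "score": self.scores,
        })


def _check_design(x: np.ndarray, names: Sequence[str]) -> None:
    """Reject rank-deficient designs, naming the collinear columns."""
    xc = sm.add_constant(x, has_constant="add")
    if np.linalg.matrix_rank(xc) == xc.shape[1]:
        return
    bad = []
    rank = 1  # constant column
    kept = xc[:, :1]
    for k, name in enumerate(names):
        trial = np.column_stack([kept, x[:, k]])
        if np.linalg.matrix_rank(trial) > rank:
            kept = trial
            rank += 1
        else:
            bad.append(name)
    raise ValueError(f"singular design: collinear columns {bad}")


def fit_logistic(table: pd.DataFrame, covariate_subset: Sequence[str]) -> FitResult:
    """Maximum-likelihood logistic regression of the pair response.

    Each unordered pair must appear exactly once in ``table``.  Reports Wald
    chi-square p-values and AIC = 2k - 2 loglik.  Perfect separation or a
    degenerate (single-class) response yields ``converged=False`` with a
    diagnostic rather than an exception; a singular design raises, naming
    the collinear columns.
    """
    names = list(covariate_subset)
    if not names:
        raise ValueError("covariate subset must be nonempty")
    missing = [c for c in names if c not in table.columns]
    if missing:
        raise KeyError(f"covariates not in table: {missing}")
    if len(set(names)) < len(names):
        dupes = sorted({c for c in names if names.count(c) > 1})
        raise ValueError(f"singular design: collinear columns {dupes}")

    y = table["response"].to_numpy(dtype=float)
    x = table[names].to_numpy(dtype=float)
    _check_design(x, names)
    index = ["const", *names]

    if y.min() == y.max():
        return FitResult(
            covariate_names=names,
            coefficients=pd.Series(np.nan, index=index),
            standard_errors=pd.Series(np.nan, index=index),
            p_values=pd.Series(np.nan, index=index),
            aic=np.inf,
            model_class="LR",
            converged=False,
            diagnostics="degenerate response: single class, no finite MLE",
        )

    # Column scaling is purely numerical: covariate scales span many orders
    # of magnitude (betweenness products vs degree products) and Newton
    # steps on the raw design are ill-conditioned.  Coefficients and SEs are
    # mapped back to the natural covariate scale, so reported estimates are
    # unaffected.
    scale = x.std(axis=0)
    scale[scale == 0] = 1.0
    xc = sm.add_constant(x / scale, has_constant="add")
    unscale = np.concatenate([[1.0], scale])
    try:
        with np.errstate(all="ignore"):
            try:
                res = sm.Logit(y, xc).fit(disp=0, maxiter=MAX_ITER,
                                          tol=CONVERGENCE_TOL,
                                          warn_convergence=False)
            except Exception:
                # Newton's Hessian goes singular under (quasi-)separation;
                # a gradient method still returns a usable boundary-chasing fit
                res = sm.Logit(y, xc).fit(disp=0, method="lbfgs",
                                          maxiter=5 * MAX_ITER,
                                          warn_convergence=False)
        converged = bool(res.mle_retvals.get("converged", True))
        diag = "" if converged else "maximum-likelihood iteration did not converge"
        params = pd.Series(res.params / unscale, index=index)
        bse = pd.Series(res.bse / unscale, index=index)
        pvals = pd.Series(res.pvalues, index=index)
        aic = float(res.aic)
    except Exception as exc:  # statsmodels PerfectSeparation and kin
        return FitResult(
            covariate_names=names,
            coefficients=pd.Series(np.nan, index=index),
            standard_errors=pd.Series(np.nan, index=index),
            p_values=pd.Series(np.nan, index=index),
            aic=np.inf,
            model_class="LR",
            converged=False,
            diagnostics=f"fit failed: {exc}",
        )
    return FitResult(
        covariate_names=names,
        coefficients=params,
        standard_errors=bse,
        p_values=pvals,
        aic=aic,
        model_class="LR",
        converged=converged,
        diagnostics=diag,
    )


def univariate_screen(
    table: pd.DataFrame, covariates: Sequence[str] | None = None
) -> pd.DataFrame:
    """One logistic fit per covariate, with training-set AUROC.

    Returns a frame with columns ``covariate, estimate, std_err, p_value,
    train_auroc, converged`` — the standard screening step before subset
    search.
    """
    if table.empty:
        raise ValueError("covariate table is empty")
    names = list(covariates) if covariates is not None else [
        c for c in COVARIATE_NAMES if c in table.columns
    ]
    y = table["response"].to_numpy(dtype=float)
    rows = []
    for name in names:
        fit = fit_logistic(table, [name])
        # a separated fit still ranks perfectly; score whenever finite
        if np.isfinite(fit.coefficients).all():
            scores = expit(fit.linear_predictor(table))
            auroc = float(roc_auc_score(y, scores))
        else:
            auroc = np.nan
        rows.append({
            "covariate": name,
            "estimate": fit.coefficients[name],
            "std_err": fit.standard_errors[name],
            "p_value": fit.p_values[name],
            "train_auroc": auroc,
            "converged": fit.converged,
        })
    return pd.DataFrame(rows)


def subset_search_aic(
    table: pd.DataFrame, candidate_covariates: Sequence[str]
) -> list[FitResult]:
    """Exhaustive all-subsets logistic search ranked by ascending AIC.

    Fits every nonempty subset of the candidates (at most 20, so 2^k - 1
    fits); non-converged subsets are excluded with a log entry.  Ties break
    toward fewer covariates, then lexicographic covariate names, so the
    ranking is deterministic and invariant to candidate order.
    """
    cands = sorted(set(candidate_covariates))
    if len(cands) > 20:
        raise ValueError(f"too many candidates for exhaustive search: {len(cands)}")
    fits: list[FitResult] = []
    for k in range(1, len(cands) + 1):
        for subset in itertools.combinations(cands, k):
            fit = fit_logistic(table, list(subset))
            if not fit.converged:
                logger.info("subset %s excluded: %s", subset, fit.diagnostics)
                continue
            fits.append(fit)
    fits.sort(key=lambda f: (f.aic, len(f.covariate_names), tuple(f.covariate_names)))
    return fits


# ---------------------------------------------------------------------------
# random-intercept GLMM (PQL + BLUP)

def duplicate_for_glmm(table: pd.DataFrame) -> pd.DataFrame:
    """Represent each pair twice, once keyed to each endpoint drug.

    The returned frame has exactly twice the rows of ``table`` plus a
    ``key_drug`` column indexing the random intercept each row informs.
    """
    first = table.copy()
    first["key_drug"] = table["drug_a"].to_numpy()
    second = table.copy()
    second["key_drug"] = table["drug_b"].to_numpy()
    return pd.concat([first, second], ignore_index=True)


def fit_glmm(
    table: pd.DataFrame,
    covariate_subset: Sequence[str],
    variance: float | None = None,
) -> FitResult:
    """Random-intercept logistic GLMM on the duplicated pair table.

    Parameters
    ----------
    table
        One row per unordered pair (as for :func:`fit_logistic`); the
        duplicated two-row-per-pair design is built internally.
    covariate_subset
        Fixed-effect covariates.
    variance
        If given, the random-intercept variance is held fixed at this value
        (0 recovers ordinary logistic regression); otherwise it is estimated.

    Notes
    -----
    The marginal likelihood integrates the intercepts out with a Laplace
    approximation.  Each duplicated row informs exactly one intercept, so
    for fixed parameters the conditional mode b-hat separates by drug and a
    damped per-drug Newton iteration (vectorized with bincount) finds it;
    the outer problem over (fixed effects, intercept SD) is maximized with
    L-BFGS-B.  The approximate log-likelihood is

        l(b-hat) - sum_k b_k^2 / (2 tau^2)
                 - 1/2 sum_k log(1 + tau^2 * H_k),

    with ``H_k`` the curvature of drug k's conditional log-likelihood; the
    form is continuous at ``tau = 0``, where the model collapses to plain
    logistic regression.  Fixed-effect covariances come from the Schur
    complement of the mixed-model equations at the optimum.  A variance
    estimate collapsing to the boundary (0) is flagged in the diagnostics;
    fixed effects then match the plain logistic fit.
    """
    names = list(covariate_subset)
    if not names:
        raise ValueError("covariate subset must be nonempty")
    if len(set(names)) < len(names):
        dupes = sorted({c for c in names if names.count(c) > 1})
        raise ValueError(f"singular design: collinear columns {dupes}")
    missing = [c for c in names if c not in table.columns]
    if missing:
        raise KeyError(f"covariates not in table: {missing}")

    dup = duplicate_for_glmm(table)
    y = dup["response"].to_numpy(dtype=float)
    x = dup[names].to_numpy(dtype=float)
    _check_design(x, names)
    # numerical column scaling, as in fit_logistic; undone before reporting
    scale = x.std(axis=0)
    scale[scale == 0] = 1.0
    unscale = np.concatenate([[1.0], scale])
    xc = np.column_stack([np.ones(len(dup)), x / scale])
    drugs = sorted(dup["key_drug"].unique())
    key = dup["key_drug"].map({d: k for k, d in enumerate(drugs)}).to_numpy()
    q = len(drugs)
    p = xc.shape[1]
    index = ["const", *names]

    b_state = np.zeros(q)  # warm-started conditional mode across evaluations

    def conditional_mode(beta: np.ndarray, tau2: float) -> tuple[np.ndarray, np.ndarray]:
        """Per-drug Newton solve for the intercept mode; returns (b, H)."""
        nonlocal b_state
        if tau2 <= 0.0:
            b_state = np.zeros(q)
            mu = expit(xc @ beta)
            h = np.bincount(key, weights=np.clip(mu * (1 - mu), 1e-10, None),
                            minlength=q)
            return b_state, h
        b = b_state.copy()
        eta0 = xc @ beta
        for _ in range(100):
            mu = expit(eta0 + b[key])
            w = np.clip(mu * (1.0 - mu), 1e-12, None)
            grad = np.bincount(key, weights=y - mu, minlength=q) - b / tau2
            hess = np.bincount(key, weights=w, minlength=q) + 1.0 / tau2
            step = np.clip(grad / hess, -4.0, 4.0)
            b = b + step
            if np.max(np.abs(step)) < 1e-10:
                break
        b_state = b
        mu = expit(eta0 + b[key])
        h = np.bincount(key, weights=np.clip(mu * (1 - mu), 1e-12, None), minlength=q)
        return b, h

    def laplace_loglik(beta: np.ndarray, tau2: float) -> float:
        b, h = conditional_mode(beta, tau2)
        eta = xc @ beta + b[key]
        mu = np.clip(expit(eta), 1e-12, 1 - 1e-12)
        ll = float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
        if tau2 > 0.0:
            ll -= float(np.sum(b**2) / (2.0 * tau2))
            ll -= 0.5 * float(np.sum(np.log1p(tau2 * h)))
        return ll

    # warm start from the plain logistic fit
    start = fit_logistic(table, names)
    if start.converged and np.isfinite(start.coefficients).all():
        beta0 = start.coefficients.to_numpy() * unscale
    else:
        beta0 = np.zeros(p)
    fixed_var = variance is not None

    from scipy.optimize import minimize

    if fixed_var:
        tau2_hat = float(variance)
        obj = lambda th: -laplace_loglik(th, tau2_hat)
        res = minimize(obj, beta0, method="L-BFGS-B",
                       options={"maxiter": MAX_ITER, "ftol": CONVERGENCE_TOL})
        beta_hat = res.x
    else:
        def obj(th):
            return -laplace_loglik(th[:p], max(th[p], 0.0))

        th0 = np.concatenate([beta0, [0.25]])
        bounds = [(None, None)] * p + [(0.0, None)]
        res = minimize(obj, th0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": MAX_ITER, "ftol": CONVERGENCE_TOL})
        beta_hat, tau2_hat = res.x[:p], float(max(res.x[p], 0.0))
    converged = bool(res.success)
    loglik = -float(res.fun)

    b_hat, h = conditional_mode(beta_hat, tau2_hat)

    # fixed-effect covariance: Schur complement of the mixed-model equations
    mu = expit(xc @ beta_hat + b_hat[key])
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    xtwx = xc.T @ (xc * w[:, None])
    if tau2_hat > 0.0:
        m = np.bincount(key, weights=w, minlength=q) + 1.0 / tau2_hat
        xtwz = np.zeros((p, q))
        np.add.at(xtwz.T, key, xc * w[:, None])
        cov_beta = np.linalg.inv(xtwx - (xtwz / m) @ xtwz.T)
    else:
        cov_beta = np.linalg.inv(xtwx)

    se = np.sqrt(np.diag(cov_beta))
    from scipy.stats import chi2
    wald = (beta_hat / se) ** 2
    pvals = chi2.sf(wald, df=1)
    beta_nat = beta_hat / unscale
    se_nat = se / unscale

    n_params = p + (0 if fixed_var else 1)
    aic = 2.0 * n_params - 2.0 * loglik

    diag = ""
    if tau2_hat <= 1e-8:
        diag = "random-intercept variance at boundary (0); fixed effects match LR"
    if not converged:
        diag = (diag + "; " if diag else "") + "Laplace ML optimizer did not converge"
    return FitResult(
        covariate_names=names,
        coefficients=pd.Series(beta_nat, index=index),
        standard_errors=pd.Series(se_nat, index=index),
        p_values=pd.Series(pvals, index=index),
        aic=aic,
        model_class="GLMM",
        random_intercepts={d: float(b_hat[k]) for k, d in enumerate(drugs)},
        variance_component=float(tau2_hat),
        converged=converged,
        diagnostics=diag,
    )


def score_pairs(
    fit: FitResult,
    table: pd.DataFrame,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> ScoredPairs:
    """Predicted interaction probability per pair.

    LR scores are the inverse-logit of the fixed linear predictor.  GLMM
    scores average the two directed probabilities, each adding one
    endpoint's BLUP intercept; drugs never seen in training use the prior
    mean 0.
    """
    if pairs is None:
        keys = list(zip(table["drug_a"], table["drug_b"]))
        sub = table
    else:
        keys = [canonical_pair(*p) for p in pairs]
        indexed = table.set_index(["drug_a", "drug_b"])
        try:
            sub = indexed.loc[keys].reset_index()
        except KeyError as exc:
            raise KeyError(f"pair missing from covariate table: {exc}") from exc
    lin = fit.linear_predictor(sub)
    if fit.model_class == "GLMM":
        b_a = np.array([fit.random_intercepts.get(a, 0.0) for a, _ in keys])
        b_b = np.array([fit.random_intercepts.get(b, 0.0) for _, b in keys])
        scores = 0.5 * (expit(lin + b_a) + expit(lin + b_b))
    else:
        scores = expit(lin)
    return ScoredPairs(pairs=keys, scores=np.asarray(scores, dtype=float))
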