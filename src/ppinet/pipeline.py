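"""End-to-end prospective benchmark runs.

Convenience orchestration of the full method on one pair of snapshots:
covariate table on the training network, model fit, scores for every
training non-edge, and prospective evaluation against the later snapshot.
Used by the command-line layer, the acceptance harness, and the replicate
studies in the test-suite; all substance lives in the other modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covariates import ATCTaxonomy, COVARIATE_NAMES, build_covariate_table
from .evaluation import BENCHMARK_SPECIFICITIES, OperatingPoint, ROCResult, \
    operating_point, roc_auroc
from .models import FitResult, fit_glmm, fit_logistic, score_pairs
from .network import DDINetwork, ValidationSplit, make_validation_split, non_edges

logger = logging.getLogger("ppinet")

__all__ = ["ProspectiveEvaluation", "run_prospective", "usable_covariates"]


@dataclass
class ProspectiveEvaluation:
    """Everything one prospective run produces."""

    split: ValidationSplit
    table: pd.DataFrame
    fit: FitResult
    candidate_pairs: list[tuple[str, str]]
    scores: np.ndarray
    labels: np.ndarray
    roc: ROCResult
    operating_points: dict[float, OperatingPoint]

    @property
    def auroc(self) -> float:
        return self.roc.auroc


def usable_covariates(table: pd.DataFrame, names=COVARIATE_NAMES) -> list[str]:
    """Covariates with nonzero variance in the table.

    A constant column carries no information and makes the design singular;
    degenerate worlds (e.g. a null generator where every drug has a
    same-class neighbor, pinning ``atc_min_prod`` at 0) produce them
    legitimately.
    """
    out = []
    for c in names:
        if c not in table.columns:
            continue
        col = table[c].to_numpy(dtype=float)
        if np.ptp(col) > 0:
            out.append(c)
        else:
            logger.info("dropping constant covariate %s", c)
    return out


def run_prospective(
    train: DDINetwork,
    later: DDINetwork,
    tax: ATCTaxonomy,
    covariates=None,
    model: str = "lr",
) -> ProspectiveEvaluation:
    """Fit on the training snapshot and evaluate on the later one.

    The training table covers all pairs (edges and non-edges); the model is
    fitted there and scores the training non-edges, which are then labelled
    by whether the later snapshot reports them.  ``model`` selects plain
    logistic regression (``"lr"``) or the random-intercept mixed model
    (``"glmm"``).
    """
    split = make_validation_split(train, later)
    all_pairs = set(train.edges) | split.candidate_pairs
    table = build_covariate_table(train, tax, all_pairs)
    names = list(covariates) if covariates is not None else usable_covariates(table)
    if model == "lr":
        fit = fit_logistic(table, names)
    elif model == "glmm":
        fit = fit_glmm(table, names)
    else:
        raise ValueError(f"unknown model class: {model!r}")
    cand = sorted(split.candidate_pairs)
    scored = score_pairs(fit, table, cand)
    labels = np.array(split.labels(cand))
    roc = roc_auroc(scored.scores, labels)
    ops = {s: operating_point(scored.scores, labels, s)
           for s in BENCHMARK_SPECIFICITIES}
    return ProspectiveEvaluation(
        split=split,
        table=table,
        fit=fit,
        candidate_pairs=cand,
        scores=scored.scores,
        labels=labels,
        roc=roc,
        operating_points=ops,
    )
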