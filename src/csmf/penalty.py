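"""Cross-validated selection of the LASSO penalty.

Out-of-sample error is computed with leave-studies-out folds: the unit of
exchangeability is the study, so whole studies are held out.  The error for
a held-out study compares its empirical reported-cause fractions with the
model's predicted reported fractions G_s p_hat(x_s), where the random
effect of an unseen study is predicted at zero.  When the grid shows no
clearly best penalty, the selection rule deliberately prefers *heavier*
penalisation: the chosen lambda is the largest one whose mean error is
within one standard error of the minimum (the "one-SE rule").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import PipelineConfig, StudyDataset
from .misclassification import MisclassMatrix, aggregate_probs
from .model import MultinomialCauseModel
from .taxonomy import CauseTaxonomy


@dataclass
class CVResult:
    lam: float
    fold_errors: np.ndarray

    @property
    def mean_error(self) -> float:
        return float(self.fold_errors.mean())

    @property
    def se_error(self) -> float:
        n = len(self.fold_errors)
        return float(self.fold_errors.std(ddof=1) / np.sqrt(n))


def make_folds(studies: list[StudyDataset], n_folds: int, seed: int = 0) -> list[list[int]]:
    """Partition study indices into folds, stratified by total deaths.

    Studies are ordered by size and dealt round-robin so each fold sees a
    comparable mix of large and small studies; the within-size order is
    shuffled deterministically from the seed.
    """
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if len(studies) < n_folds:
        raise ValueError(f"{len(studies)} studies cannot fill {n_folds} folds")
    rng = np.random.default_rng(seed)
    order = sorted(
        range(len(studies)),
        key=lambda i: (studies[i].total_deaths, rng.random()),
        reverse=True,
    )
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for pos, idx in enumerate(order):
        folds[pos % n_folds].append(idx)
    return folds


def _study_error(
    study: StudyDataset, matrix: MisclassMatrix, p_hat: np.ndarray, metric: str
) -> float:
    q_hat = aggregate_probs(matrix, p_hat)
    emp = study.empirical_fractions
    if metric == "mae":
        return float(np.mean(np.abs(emp - q_hat)))
    if metric == "mse":
        return float(np.mean((emp - q_hat) ** 2))
    raise ValueError(f"unknown CV metric {metric!r}")


def cv_error(
    studies: list[StudyDataset],
    matrices: list[MisclassMatrix],
    taxonomy: CauseTaxonomy,
    lam: float,
    n_folds: int | None = None,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> CVResult:
    """Leave-studies-out cross-validation error for one penalty value.

    Returns the per-fold errors; each fold error is the mean over its
    held-out studies of the chosen discrepancy between empirical and
    predicted reported-cause fractions.
    """
    config = config or PipelineConfig()
    n_folds = n_folds or config.n_folds
    folds = make_folds(studies, n_folds, seed=seed)
    fold_errors = []
    for f, hold in enumerate(folds):
        train = [i for i in range(len(studies)) if i not in hold]
        model = MultinomialCauseModel(
            [studies[i] for i in train],
            taxonomy,
            matrices=[matrices[i] for i in train],
            config=config,
        )
        res = model.fit(lam=lam, settings=config.cv_mcmc, seed=seed + 1000 * (f + 1))
        beta_hat = res.params.values
        errs = []
        for i in hold:
            x1 = np.concatenate([[1.0], studies[i].covariates])
            from .model import _expand_eta, softmax_fractions

            p_hat = softmax_fractions(
                _expand_eta(beta_hat @ x1, taxonomy.base_index)
            )
            errs.append(_study_error(studies[i], matrices[i], p_hat, config.cv_metric))
        fold_errors.append(float(np.mean(errs)))
    return CVResult(lam, np.asarray(fold_errors))


def cv_grid(
    studies, matrices, taxonomy, config: PipelineConfig | None = None, seed: int = 0
) -> pd.DataFrame:
    """CV over the config's lambda grid; long report (lambda, fold, error)."""
    config = config or PipelineConfig()
    rows = []
    for lam in config.lambda_grid:
        r = cv_error(studies, matrices, taxonomy, lam, config=config, seed=seed)
        for f, e in enumerate(r.fold_errors):
            rows.append({"lambda": lam, "fold": f, "error": e})
    return pd.DataFrame(rows)


def select_penalty(
    lambdas: np.ndarray,
    mean_errors: np.ndarray,
    se_errors: np.ndarray,
    multiplier: float = 1.0,
) -> float:
    """One-SE rule, biased toward heavier shrinkage.

    Returns the LARGEST lambda whose mean CV error is within
    ``multiplier`` standard errors (of the minimising lambda) of the
    minimum mean error.  Ties and flat error profiles therefore resolve to
    the most penalised model.
    """
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.size == 0:
        raise ValueError("empty lambda grid")
    mean_errors = np.asarray(mean_errors, dtype=float)
    se_errors = np.asarray(se_errors, dtype=float)
    order = np.argsort(lambdas)
    lambdas, mean_errors, se_errors = lambdas[order], mean_errors[order], se_errors[order]
    i_min = int(np.argmin(mean_errors))
    threshold = mean_errors[i_min] + multiplier * se_errors[i_min]
    eligible = np.nonzero(mean_errors <= threshold)[0]
    return float(lambdas[eligible.max()])


def select_from_grid(report: pd.DataFrame, multiplier: float = 1.0) -> float:
    """Apply the one-SE rule to a long (lambda, fold, error) CV report."""
    g = report.groupby("lambda")["error"]
    means = g.mean()
    ses = g.std(ddof=1) / np.sqrt(g.count())
    return select_penalty(means.index.values, means.values, ses.values, multiplier)
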