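"""Posterior draws container and the fitted-model results object."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .diagnostics import gelman_rubin_all
from .model import _expand_eta, softmax_fractions


@dataclass
class PosteriorDraws:
    """MCMC output: chain-indexed draws of all model parameters.

    beta : (n_chains, n_iter, C-1, 1+K)
    u : (n_chains, n_iter, S, C-1)
    sigma : (n_chains, n_iter, n_sigma)
    """

    beta: np.ndarray
    u: np.ndarray
    sigma: np.ndarray
    lam: float

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    @property
    def n_iter(self) -> int:
        return self.beta.shape[1]

    def stacked(self) -> dict[str, np.ndarray]:
        """Chains concatenated: beta (M, C-1, K1), u (M, S, C-1), sigma (M, n_sigma)."""
        M = self.n_chains * self.n_iter
        return {
            "beta": self.beta.reshape(M, *self.beta.shape[2:]),
            "u": self.u.reshape(M, *self.u.shape[2:]),
            "sigma": self.sigma.reshape(M, self.sigma.shape[2]),
        }

    def flat_matrix(self) -> np.ndarray:
        """(n_chains, n_iter, n_params) view over beta, u, sigma in order."""
        m, n = self.n_chains, self.n_iter
        return np.concatenate(
            [
                self.beta.reshape(m, n, -1),
                self.u.reshape(m, n, -1),
                self.sigma.reshape(m, n, -1),
            ],
            axis=2,
        )

    def to_frame(self, names: list[str]) -> pd.DataFrame:
        """Long columnar serialisation (parameter, chain, iteration, value)."""
        flat = self.flat_matrix()
        m, n, P = flat.shape
        if len(names) != P:
            raise ValueError("name list length mismatch")
        return pd.DataFrame(
            {
                "parameter": np.repeat(names, m * n),
                "chain": np.tile(np.repeat(np.arange(m), n), P),
                "iteration": np.tile(np.arange(n), m * P),
                "value": flat.transpose(2, 0, 1).ravel(),
            }
        )


class MultinomialCauseResults:
    """Fitted-model results: posterior summaries, diagnostics, prediction."""

    def __init__(self, model, draws: PosteriorDraws, lam: float):
        self.model = model
        self.draws = draws
        self.lam = lam
        st = draws.stacked()
        self._beta_s = st["beta"]
        self._u_s = st["u"]
        self._sigma_s = st["sigma"]

    # -- statsmodels-flavoured summaries --------------------------------
    @property
    def params(self) -> pd.DataFrame:
        """Posterior mean coefficients, contrasts x covariates."""
        return pd.DataFrame(
            self._beta_s.mean(axis=0),
            index=list(self.model.taxonomy.contrast_causes),
            columns=list(self.model.covariate_names),
        )

    @property
    def bse(self) -> pd.DataFrame:
        return pd.DataFrame(
            self._beta_s.std(axis=0, ddof=1),
            index=list(self.model.taxonomy.contrast_causes),
            columns=list(self.model.covariate_names),
        )

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        lo = np.percentile(self._beta_s, 100 * alpha / 2, axis=0)
        hi = np.percentile(self._beta_s, 100 * (1 - alpha / 2), axis=0)
        rows = []
        for i, cause in enumerate(self.model.taxonomy.contrast_causes):
            for k, cov in enumerate(self.model.covariate_names):
                rows.append((cause, cov, lo[i, k], hi[i, k]))
        return pd.DataFrame(rows, columns=["contrast", "covariate", "lower", "upper"])

    @property
    def sigma_mean(self) -> float:
        return float(self._sigma_s.mean())

    def gelman_rubin(self) -> pd.Series:
        """PSRF for every parameter (beta, u, sigma)."""
        return gelman_rubin_all(self.draws.flat_matrix(), self.model.param_names)

    def diagnostics_frame(self) -> pd.DataFrame:
        psrf = self.gelman_rubin()
        flat = self.draws.flat_matrix()
        M = flat.shape[0] * flat.shape[1]
        stacked = flat.reshape(M, -1)
        return pd.DataFrame(
            {
                "psrf": psrf.values,
                "mean": stacked.mean(axis=0),
                "sd": stacked.std(axis=0, ddof=1),
            },
            index=psrf.index,
        )

    def summary(self) -> str:
        tax = self.model.taxonomy
        psrf = self.gelman_rubin()
        lines = [
            "Penalised Bayesian multinomial cause-of-death model",
            "=" * 55,
            f"Age group:        {tax.age_group.value}",
            f"Causes:           {tax.n_causes} (base: {tax.base_cause})",
            f"Studies:          {len(self.model.studies)}"
            f" ({sum(s.total_deaths for s in self.model.studies)} deaths)",
            f"LASSO lambda:     {self.lam:g}",
            f"Sigma bound:      {self.model.sigma_bound:g}"
            f"   posterior mean sigma: {self.sigma_mean:.4f}",
            f"Chains x iter:    {self.draws.n_chains} x {self.draws.n_iter}",
            f"Max PSRF:         {psrf.max():.4f}",
            "",
            "Posterior mean coefficients (rows: cause contrasts):",
            self.params.round(3).to_string(),
            "",
            "Posterior SD:",
            self.bse.round(3).to_string(),
        ]
        return "\n".join(lines)

    # -- prediction ------------------------------------------------------
    def predict_fractions(
        self,
        x: np.ndarray,
        study_id: str | None = None,
        sample_u: bool = False,
        seed: int | None = None,
    ) -> np.ndarray:
        """Cause-fraction draws for covariate vector ``x`` (no intercept slot).

        If ``study_id`` names a fitted study (a nationally representative
        study for the country), that study's random-effect draws are used;
        otherwise the random effect is zero, or — with ``sample_u=True``,
        for uncertainty propagation only — freshly sampled from
        Normal(0, sigma draws).

        Returns an (M, C) array; one fraction vector per posterior draw.
        """
        x = np.asarray(x, dtype=float)
        if x.shape[-1] != self._beta_s.shape[2] - 1:
            raise ValueError(
                f"expected {self._beta_s.shape[2] - 1} covariates, got {x.shape[-1]}"
            )
        x1 = np.concatenate([[1.0], x])
        contrasts = self._beta_s @ x1  # (M, C-1)
        if study_id is not None:
            sids = [s.study_id for s in self.model.studies]
            if study_id not in sids:
                raise KeyError(f"study {study_id!r} not in fitted model")
            contrasts = contrasts + self._u_s[:, sids.index(study_id), :]
        elif sample_u:
            rng = np.random.default_rng(seed)
            sig = self._sigma_s  # (M, n_sigma) broadcasts over contrasts
            contrasts = contrasts + rng.standard_normal(contrasts.shape) * sig
        return softmax_fractions(_expand_eta(contrasts, self.model.taxonomy.base_index))

    def fitted_study_fractions(self) -> np.ndarray:
        """(M, S, C) posterior true-cause fraction draws for the fitted studies."""
        ws = self.model._ws
        return ws.fractions(self._beta_s, self._u_s)

    # -- serialisation ---------------------------------------------------
    def save_draws(self, path: str | Path) -> None:
        self.draws.to_frame(self.model.param_names).to_csv(path, index=False)

    def save_diagnostics(self, path: str | Path) -> None:
        self.diagnostics_frame().rename_axis("parameter").to_csv(path)
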