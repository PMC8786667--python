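"""Bayesian multinomial-logit cause-of-death model with LASSO shrinkage.

The model: for study s with covariate vector x_s (intercept included), the
log odds of each true cause c relative to a designated base cause are

    eta_sc = x_s' beta_c + u_sc        (eta for the base cause fixed at 0)

with cause fractions p_s = softmax(eta_s).  The study reports categories
that may merge several true causes; its binary aggregation matrix G_s
gives reported-category probabilities q_s = G_s p_s, and observed counts
follow y_s ~ Multinomial(N_s, q_s).

Priors: non-intercept coefficients get independent Laplace(0, 1/lambda)
densities — the Bayesian LASSO, so larger lambda shrinks covariate effects
toward zero; intercepts get a wide normal; study random effects u_s are
normal with standard deviation sigma, and sigma itself is uniform on
(0, sigma_bound].  The bound (0.14 for high-mortality models, i.e. a
within-~30% change in cause odds for most studies; much tighter for
low-mortality models) caps how far any single study can pull a country's
estimates.

Posterior sampling is adaptive random-walk Metropolis-within-Gibbs,
vectorised across chains: all chains execute the same update schedule
simultaneously so the per-update numpy overhead is amortised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp
from scipy.special import gammaln

from .datatypes import MCMCSettings, PipelineConfig, StudyDataset
from .misclassification import MisclassMatrix, default_matrix
from .taxonomy import CauseTaxonomy

_TINY = 1e-300


# ---------------------------------------------------------------------------
# Parameter container and elementary model functions
# ---------------------------------------------------------------------------

@dataclass
class ModelParameters:
    """One point in parameter space.

    beta : (C-1, 1+K) — rows are non-base cause contrasts, column 0 is the
        intercept.  The base-cause contrast is implicitly zero.
    u : (S, C-1) study random effects.
    sigma : random-effect SD, scalar or per-contrast vector.
    lam : LASSO penalty (fixed per fit, selected by cross-validation).
    """

    beta: np.ndarray
    u: np.ndarray
    sigma: np.ndarray
    lam: float

    def __post_init__(self) -> None:
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        self.u = np.atleast_2d(np.asarray(self.u, dtype=float))
        self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        if self.lam <= 0:
            raise ValueError("lambda must be positive")


def linear_predictor(
    beta: np.ndarray, u_s: np.ndarray, x: np.ndarray, base_index: int
) -> np.ndarray:
    """Per-cause log odds eta (length C) with eta[base] = 0."""
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("non-finite covariates")
    beta = np.atleast_2d(beta)
    contrasts = beta @ x + np.asarray(u_s, dtype=float)
    eta = np.insert(contrasts, base_index, 0.0)
    return eta


def softmax_fractions(eta: np.ndarray) -> np.ndarray:
    """Cause fractions p = softmax(eta), max-subtracted for overflow safety.

    Works on the last axis, so stacked draws pass through unchanged.
    """
    eta = np.asarray(eta, dtype=float)
    z = eta - eta.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _expand_eta(contrasts: np.ndarray, base_index: int) -> np.ndarray:
    """Insert the zero base-cause column into a (..., C-1) contrast array."""
    return np.insert(contrasts, base_index, 0.0, axis=-1)


# ---------------------------------------------------------------------------
# Likelihood workspace
# ---------------------------------------------------------------------------

class _Workspace:
    """Precomputed structures for fast repeated likelihood evaluation.

    Flattens all studies' reported categories into one vector of length
    R = sum_s J_s and builds a sparse (R, S*C) matrix ``B`` such that the
    concatenated reported-category probabilities are B @ vec(p).
    """

    def __init__(self, studies, matrices, taxonomy):
        self.taxonomy = taxonomy
        self.S = len(studies)
        self.C = taxonomy.n_causes
        self.base = taxonomy.base_index
        self.K1 = len(studies[0].covariates) + 1
        self.X = np.column_stack(
            [np.ones(self.S), np.array([s.covariates for s in studies])]
        )
        rows, cols, vals = [], [], []
        y, starts, r = [], [], 0
        for si, (study, m) in enumerate(zip(studies, matrices)):
            J, C = m.G.shape
            if C != self.C:
                raise ValueError(f"{study.study_id}: matrix has {C} causes, expected {self.C}")
            jj, cc = np.nonzero(m.G)
            rows.extend(r + jj)
            cols.extend(si * self.C + cc)
            vals.extend([1.0] * len(jj))
            starts.append(r)
            r += J
            y.extend(study.deaths.tolist())
        self.B = sp.csr_matrix((vals, (rows, cols)), shape=(r, self.S * self.C))
        self.y = np.asarray(y, dtype=float)
        self.starts = np.asarray(starts, dtype=np.intp)
        self.N = np.array([s.total_deaths for s in studies], dtype=float)
        # multinomial normalising constant, per study
        counts_const = []
        pos = 0
        for study in studies:
            J = len(study.deaths)
            yv = self.y[pos : pos + J]
            counts_const.append(gammaln(yv.sum() + 1) - gammaln(yv + 1).sum())
            pos += J
        self.log_const = np.asarray(counts_const)

    def fractions(self, beta_stack: np.ndarray, u_stack: np.ndarray) -> np.ndarray:
        """(Ch, S, C) cause fractions from stacked (Ch, C-1, K1) betas and
        (Ch, S, C-1) random effects."""
        contrasts = np.einsum("sk,mck->msc", self.X, beta_stack) + u_stack
        return softmax_fractions(_expand_eta(contrasts, self.base))

    def study_loglik(self, p: np.ndarray, normalised: bool = False) -> np.ndarray:
        """(Ch, S) multinomial log likelihood per study (constants optional)."""
        Ch = p.shape[0]
        Q = self.B @ p.reshape(Ch, -1).T  # (R, Ch)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(self.y[:, None] > 0, self.y[:, None] * np.log(np.maximum(Q, _TINY)), 0.0)
        ll = np.add.reduceat(terms, self.starts, axis=0).T  # (Ch, S)
        if normalised:
            ll = ll + self.log_const[None, :]
        return ll


# ---------------------------------------------------------------------------
# Likelihood / prior as standalone operations
# ---------------------------------------------------------------------------

def log_likelihood(
    params: ModelParameters,
    studies: list[StudyDataset],
    matrices: list[MisclassMatrix],
    taxonomy: CauseTaxonomy,
) -> float:
    """Total multinomial log likelihood sum_s log Mult(y_s | N_s, G_s p_s).

    Includes the multinomial coefficient, so values are comparable with a
    directly computed pmf on aggregated categories.  A reported category
    with zero probability but a nonzero count yields -inf (with a warning).
    """
    if len(matrices) != len(studies):
        raise ValueError("one misclassification matrix per study required")
    ws = _Workspace(studies, matrices, taxonomy)
    p = ws.fractions(params.beta[None], np.broadcast_to(params.u, (1, ws.S, ws.C - 1)))
    Q = (ws.B @ p.reshape(1, -1).T).ravel()
    if ((Q <= 0) & (ws.y > 0)).any():
        warnings.warn("zero reported-category probability with nonzero count")
        return -np.inf
    ll = ws.study_loglik(p, normalised=True)
    return float(ll.sum())


def log_prior(
    params: ModelParameters,
    sigma_bound: float,
    intercept_sd: float = 10.0,
) -> float:
    """Joint log prior density.

    Laplace(0, 1/lambda) on non-intercept betas, Normal(0, intercept_sd)
    on intercepts, Normal(0, sigma) on random effects, Uniform(0, bound]
    on sigma (density 1/bound inside; -inf outside).
    """
    sig = params.sigma
    if (sig <= 0).any() or (sig > sigma_bound).any():
        return -np.inf
    lam = params.lam
    slopes = params.beta[:, 1:]
    lp = float(np.sum(np.log(lam / 2.0) - lam * np.abs(slopes)))
    ic = params.beta[:, 0]
    lp += float(
        np.sum(-0.5 * np.log(2 * np.pi * intercept_sd**2) - ic**2 / (2 * intercept_sd**2))
    )
    S, Cm1 = params.u.shape
    sig_full = np.broadcast_to(sig, (Cm1,)) if sig.size in (1, Cm1) else None
    if sig_full is None:
        raise ValueError("sigma must be scalar or per-contrast")
    lp += float(
        np.sum(
            -0.5 * np.log(2 * np.pi * sig_full[None, :] ** 2)
            - params.u**2 / (2 * sig_full[None, :] ** 2)
        )
    )
    lp += -np.log(sigma_bound) * sig.size
    return lp


# ---------------------------------------------------------------------------
# The model object
# ---------------------------------------------------------------------------

class MultinomialCauseModel:
    """Penalised Bayesian multinomial cause-of-death model for a set of
    studies sharing one cause taxonomy.

    Parameters
    ----------
    studies : list of StudyDataset
        All studies must share the same age group and covariate list.
    taxonomy : CauseTaxonomy
        True-cause list; its base cause fixes the reference contrast.
    matrices : list of MisclassMatrix, optional
        One per study.  If omitted, matrices are built under the default
        convention (unreported causes fold into the study's "other").
    config : PipelineConfig, optional
    sigma_bound : float, optional
        Overrides the config bound (use the low-mortality bound when
        fitting the low-mortality model).
    """

    def __init__(
        self,
        studies: list[StudyDataset],
        taxonomy: CauseTaxonomy,
        matrices: list[MisclassMatrix] | None = None,
        config: PipelineConfig | None = None,
        sigma_bound: float | None = None,
    ):
        if not studies:
            raise ValueError("at least one study required")
        self.studies = list(studies)
        self.taxonomy = taxonomy
        self.config = config or PipelineConfig()
        self.sigma_bound = (
            sigma_bound if sigma_bound is not None else self.config.sigma_bound_high
        )
        if matrices is None:
            matrices = [
                default_matrix(taxonomy, s.reported_causes, s.study_id) for s in studies
            ]
        self.matrices = list(matrices)
        self._ws = _Workspace(self.studies, self.matrices, taxonomy)
        self.covariate_names = ("intercept",) + tuple(studies[0].covariate_names)

    # -- naming ----------------------------------------------------------
    @property
    def param_names(self) -> list[str]:
        names = [
            f"beta[{c}][{k}]"
            for c in self.taxonomy.contrast_causes
            for k in self.covariate_names
        ]
        names += [
            f"u[{s.study_id}][{c}]"
            for s in self.studies
            for c in self.taxonomy.contrast_causes
        ]
        names += [f"sigma[{i}]" for i in range(self._n_sigma)]
        return names

    @property
    def _n_sigma(self) -> int:
        return (self.taxonomy.n_causes - 1) if self.config.per_contrast_sigma else 1

    # -- fitting ---------------------------------------------------------
    def fit(
        self,
        lam: float = 1.0,
        settings: MCMCSettings | None = None,
        seed: int | None = None,
    ):
        """Run the MCMC sampler; returns a :class:`MultinomialCauseResults`."""
        from .results import MultinomialCauseResults, PosteriorDraws

        st = settings or self.config.mcmc
        if seed is not None:
            st = replace(st, seed=seed)
        if st.n_chains < 2:
            raise ValueError("at least 2 chains required for convergence diagnostics")
        draws = _run_sampler(
            self._ws,
            lam=lam,
            sigma_bound=self.sigma_bound,
            intercept_sd=self.config.intercept_sd,
            n_sigma=self._n_sigma,
            settings=st,
        )
        return MultinomialCauseResults(self, PosteriorDraws(**draws), lam=lam)


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------

def _run_sampler(ws, lam, sigma_bound, intercept_sd, n_sigma, settings):
    Ch, n_keep, burn = settings.n_chains, settings.n_iter, settings.burn_in
    S, C, K1 = ws.S, ws.C, ws.K1
    Cm1 = C - 1
    rng = np.random.default_rng(settings.seed)
    sig_map = np.zeros(Cm1, dtype=np.intp) if n_sigma == 1 else np.arange(Cm1)

    for attempt in range(settings.init_retries + 1):
        beta = rng.normal(0.0, 0.1, size=(Ch, Cm1, K1))
        u = rng.normal(0.0, 0.01, size=(Ch, S, Cm1))
        sigma = np.full((Ch, n_sigma), sigma_bound / 2.0)
        p = ws.fractions(beta, u)
        ll = ws.study_loglik(p)  # (Ch, S)
        if np.isfinite(ll).all():
            break
    else:
        raise RuntimeError("non-finite posterior at initialisation after retries")

    scale_b = np.full((Ch, Cm1, K1), 0.1)
    scale_u = np.full((Ch, S), 0.05)
    scale_s = np.full((Ch, n_sigma), 0.02)
    acc_b = np.zeros((Ch, Cm1, K1))
    acc_u = np.zeros((Ch, S))
    acc_s = np.zeros((Ch, n_sigma))
    batch = 50

    out_beta = np.empty((Ch, n_keep, Cm1, K1))
    out_u = np.empty((Ch, n_keep, S, Cm1))
    out_sigma = np.empty((Ch, n_keep, n_sigma))

    lltot = ll.sum(axis=1)  # (Ch,)
    contrasts = np.einsum("sk,mck->msc", ws.X, beta) + u  # cached (Ch,S,Cm1)

    def total_from_contrasts(con):
        p = softmax_fractions(_expand_eta(con, ws.base))
        return ws.study_loglik(p)

    for it in range(burn + n_keep):
        adapting = it < burn
        # ---- beta entries, one scalar at a time --------------------------
        for c in range(Cm1):
            for k in range(K1):
                delta = scale_b[:, c, k] * rng.standard_normal(Ch)
                con_prop = contrasts.copy()
                con_prop[:, :, c] += ws.X[None, :, k] * delta[:, None]
                ll_prop = total_from_contrasts(con_prop)
                lltot_prop = ll_prop.sum(axis=1)
                b_old = beta[:, c, k]
                b_new = b_old + delta
                if k == 0:
                    dlp = (b_old**2 - b_new**2) / (2 * intercept_sd**2)
                else:
                    dlp = lam * (np.abs(b_old) - np.abs(b_new))
                log_r = lltot_prop - lltot + dlp
                acc = np.log(rng.random(Ch)) < log_r
                if acc.any():
                    beta[acc, c, k] = b_new[acc]
                    contrasts[acc] = con_prop[acc]
                    ll[acc] = ll_prop[acc]
                    lltot[acc] = lltot_prop[acc]
                acc_b[:, c, k] += acc

        # ---- u rows (all studies at once; acceptance per study) ----------
        du = scale_u[:, :, None] * rng.standard_normal((Ch, S, Cm1))
        con_prop = contrasts + du
        ll_prop = total_from_contrasts(con_prop)  # (Ch, S)
        u_new = u + du
        sig_c = sigma[:, sig_map]  # (Ch, Cm1)
        dlp_u = ((u**2 - u_new**2) / (2 * sig_c[:, None, :] ** 2)).sum(axis=2)
        log_r = ll_prop - ll + dlp_u
        acc = np.log(rng.random((Ch, S))) < log_r
        if acc.any():
            u[acc] = u_new[acc]
            contrasts[acc] = con_prop[acc]
            ll[acc] = ll_prop[acc]
            lltot = ll.sum(axis=1)
        acc_u += acc

        # ---- sigma (prior-only conditional) -------------------------------
        if n_sigma == 1:
            ss = (u**2).sum(axis=(1, 2))[:, None]
            m = np.full((Ch, 1), S * Cm1, dtype=float)
        else:
            ss = (u**2).sum(axis=1)
            m = np.full((Ch, Cm1), S, dtype=float)
        s_new = sigma + scale_s * rng.standard_normal((Ch, n_sigma))
        valid = (s_new > 0) & (s_new <= sigma_bound)
        with np.errstate(divide="ignore", invalid="ignore"):
            logp_old = -m * np.log(sigma) - ss / (2 * sigma**2)
            logp_new = np.where(valid, -m * np.log(np.abs(s_new)) - ss / (2 * s_new**2), -np.inf)
        acc = np.log(rng.random((Ch, n_sigma))) < (logp_new - logp_old)
        sigma = np.where(acc, s_new, sigma)
        acc_s += acc

        # ---- adaptation during burn-in -----------------------------------
        if adapting and (it + 1) % batch == 0:
            step = 0.15
            scale_b *= np.exp(np.where(acc_b / batch > 0.44, step, -step))
            scale_u *= np.exp(np.where(acc_u / batch > 0.28, step, -step))
            scale_s *= np.exp(np.where(acc_s / batch > 0.44, step, -step))
            acc_b[:] = 0
            acc_u[:] = 0
            acc_s[:] = 0

        if not adapting:
            j = it - burn
            out_beta[:, j] = beta
            out_u[:, j] = u
            out_sigma[:, j] = sigma

    return {"beta": out_beta, "u": out_u, "sigma": out_sigma, "lam": lam}
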