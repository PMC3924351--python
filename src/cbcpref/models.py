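"""Multinomial-logit choice models: probabilities, pooled (aggregate) fit,
and hierarchical-Bayes individual-level estimation.

The random-utility model: alternative ``i`` in a task has systematic utility
``V_i = x_i' beta`` with ``x_i`` the effects-coded profile; i.i.d. extreme-value
choice noise gives the logit choice rule

    P(i | task) = exp(s * x_i' beta) / sum_j exp(s * x_j' beta)

with ``s`` a scale (logit exponent) fixed at 1 during estimation.

Two estimators, both sklearn-style:

* :class:`AggregateChoiceLogit` pools all respondents into one beta
  (maximum likelihood, Newton-Raphson, observed-information SEs).
* :class:`HierarchicalBayesLogit` places a Normal population distribution
  ``beta_r ~ N(alpha, D)`` over respondents and samples the joint posterior
  by Gibbs: conjugate Normal draw for ``alpha``, conjugate inverse-Wishart
  draw for ``D``, and a random-walk Metropolis-Hastings step per respondent
  for ``beta_r`` against its own logit likelihood times the population prior.
  This "borrowing of strength" is what makes individual-level part-worths
  estimable from only a dozen choices per person.

Holdout tasks are excluded from estimation by default; they are reserved
for external validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from numpy.linalg import cholesky, LinAlgError
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import logsumexp, log_softmax
from scipy.stats import invwishart
from sklearn.base import BaseEstimator

from . import io
from .exceptions import (
    AlignmentError,
    ChoiceDataError,
    ConvergenceWarning,
    SeparationWarning,
)
from .schema import AttributeSchema

BETA_CAP = 20.0  # |coef| beyond this is treated as separation


# ---------------------------------------------------------------------------
# probabilities
# ---------------------------------------------------------------------------

def choice_probabilities(beta, task, schema: AttributeSchema, scale: float = 1.0):
    """Logit choice probabilities for each alternative of one task.

    ``task`` may be a ChoiceTask or any object with an ``alternatives``
    sequence of level-index profiles (0-based).  Computed through
    ``log_softmax`` so large utilities cannot overflow.
    """
    if scale <= 0:
        raise ValueError(f"scale must be positive, got {scale}")
    beta = np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(beta)):
        raise FloatingPointError("non-finite utilities passed to choice model")
    alts = getattr(task, "alternatives", task)
    X = schema.code_profiles(np.asarray(alts))
    return np.exp(log_softmax(scale * (X @ beta)))


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------

def _sorted_estimation_frame(data, schema, include_holdouts):
    df = io.validate_choice_data(pd.DataFrame(data), schema)
    if not include_holdouts:
        df = df.loc[df["task_type"] != "holdout"]
        if df.empty:
            raise ChoiceDataError("no estimation (random) tasks in the data")
    return df.sort_values(
        ["respondent_id", "wave", "position", "task_id", "alternative_id"],
        kind="stable",
    )


def task_arrays(data, schema: AttributeSchema, include_holdouts: bool = False):
    """Flatten long-format data into (X, chosen, keys).

    X has shape (n_tasks_total, k, p); ``chosen`` holds the within-task index
    of the chosen alternative; ``keys`` is a frame with one row per task
    (respondent_id, group, wave, task_id).  Requires a constant number of
    alternatives per task.
    """
    df = _sorted_estimation_frame(data, schema, include_holdouts)
    sizes = df.groupby(io.TASK_KEY, sort=False).size()
    k = int(sizes.iloc[0])
    if (sizes != k).any():
        raise ChoiceDataError(
            "tasks with differing numbers of alternatives "
            f"(found sizes {sorted(sizes.unique())})"
        )
    profiles = df[schema.names].to_numpy(dtype=int) - 1
    X = schema.code_profiles(profiles).reshape(-1, k, schema.n_params)
    chosen = np.flatnonzero(df[io.CHOSEN_COLUMN].to_numpy()) % k
    keys = (
        df.iloc[::k][["respondent_id", "group", "wave", "task_id"]]
        .reset_index(drop=True)
    )
    return X, chosen, keys


def respondent_arrays(data, schema: AttributeSchema, include_holdouts: bool = False):
    """Group tasks by respondent, padding to a common task count.

    Returns (X, chosen, mask, respondent_ids) with X of shape
    (n_respondents, T_max, k, p) and mask marking real tasks.
    """
    X, chosen, keys = task_arrays(data, schema, include_holdouts)
    ids = keys["respondent_id"].to_numpy()
    uniq, starts = np.unique(ids, return_index=True)
    order = np.argsort(starts)  # keep first-appearance order
    uniq, starts = uniq[order], starts[order]
    bounds = np.append(starts, len(ids))
    counts = np.diff(bounds)
    n, t_max = len(uniq), int(counts.max())
    k, p = X.shape[1], X.shape[2]
    Xp = np.zeros((n, t_max, k, p))
    ch = np.zeros((n, t_max), dtype=int)
    mask = np.zeros((n, t_max), dtype=bool)
    for i, (s, c) in enumerate(zip(bounds[:-1], counts)):
        Xp[i, :c] = X[s : s + c]
        ch[i, :c] = chosen[s : s + c]
        mask[i, :c] = True
    return Xp, ch, mask, list(uniq)


# ---------------------------------------------------------------------------
# pooled multinomial logit
# ---------------------------------------------------------------------------

def _mnl_loglik_grad_hess(beta, X, chosen, want_hess=True):
    U = X @ beta                                  # (N, k)
    ls = logsumexp(U, axis=1)
    ll = float(U[np.arange(len(U)), chosen].sum() - ls.sum())
    P = np.exp(U - ls[:, None])                   # (N, k)
    xbar = np.einsum("nk,nkp->np", P, X)
    grad = X[np.arange(len(U)), chosen].sum(axis=0) - xbar.sum(axis=0)
    if not want_hess:
        return ll, grad, None
    H = np.einsum("nk,nkp,nkq->pq", P, X, X) - xbar.T @ xbar
    return ll, grad, H


def fit_mnl_arrays(X, chosen, tol=1e-8, max_iter=100):
    """Newton-Raphson MLE of the pooled logit on prepared arrays.

    Returns (beta, cov, llf, converged).  ``cov`` is the inverse observed
    information.  Quasi-complete separation is detected by runaway
    coefficients; estimates are capped at +/-20 with a warning.
    """
    N, k, p = X.shape
    beta = np.zeros(p)
    ll, grad, H = _mnl_loglik_grad_hess(beta, X, chosen)
    converged = False
    for _ in range(max_iter):
        if np.max(np.abs(grad)) < tol * max(1.0, N / 100):
            converged = True
            break
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(p), grad)
        except LinAlgError:
            step = grad / max(1.0, np.abs(grad).max())
        # backtracking line search on the log-likelihood
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            ll_new, grad_new, H_new = _mnl_loglik_grad_hess(cand, X, chosen)
            if ll_new >= ll - 1e-12:
                break
            t /= 2
        beta, ll, grad, H = cand, ll_new, grad_new, H_new
        if np.max(np.abs(beta)) > BETA_CAP:
            warnings.warn(
                "quasi-complete separation: some part-worths diverge; "
                f"estimates capped at +/-{BETA_CAP}",
                SeparationWarning,
                stacklevel=3,
            )
            beta = np.clip(beta, -BETA_CAP, BETA_CAP)
            ll, grad, H = _mnl_loglik_grad_hess(beta, X, chosen)
            break
    else:
        warnings.warn("pooled logit did not converge", ConvergenceWarning,
                      stacklevel=3)
    cov = np.linalg.inv(H + 1e-12 * np.eye(p))
    return beta, cov, ll, converged


class AggregateChoiceLogit(BaseEstimator):
    """Pooled ("aggregate") multinomial logit over all respondents.

    Parameters
    ----------
    schema : AttributeSchema
    include_holdouts : bool, default False
        Whether holdout tasks enter the likelihood.
    tol, max_iter : Newton-Raphson stopping rule (gradient sup-norm).

    Attributes (after ``fit``)
    --------------------------
    coef_ : (p,) effects-coded part-worth estimates
    bse_ : (p,) standard errors from the observed information
    cov_ : (p, p) coefficient covariance
    llf_, null_llf_ : log-likelihood at the optimum and at beta = 0
    n_choices_ : number of choice tasks in the likelihood
    converged_ : bool
    """

    def __init__(self, schema=None, include_holdouts=False, tol=1e-8, max_iter=100):
        self.schema = schema
        self.include_holdouts = include_holdouts
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, data, y=None):
        if self.schema is None:
            raise ValueError("schema is required")
        X, chosen, _ = task_arrays(data, self.schema, self.include_holdouts)
        beta, cov, llf, converged = fit_mnl_arrays(
            X, chosen, tol=self.tol, max_iter=self.max_iter
        )
        self.coef_ = beta
        self.cov_ = cov
        self.bse_ = np.sqrt(np.diag(cov))
        self.llf_ = llf
        self.null_llf_ = -len(chosen) * np.log(X.shape[1])
        self.n_choices_ = len(chosen)
        self.converged_ = converged
        self.param_names_ = self.schema.param_names()
        return self

    def predict_proba(self, task, scale: float = 1.0):
        return choice_probabilities(self.coef_, task, self.schema, scale)


def fit_aggregate_logit(data, schema: AttributeSchema, **kwargs) -> AggregateChoiceLogit:
    """Functional wrapper over :class:`AggregateChoiceLogit`."""
    return AggregateChoiceLogit(schema=schema, **kwargs).fit(data)


# ---------------------------------------------------------------------------
# hierarchical Bayes
# ---------------------------------------------------------------------------

@dataclass
class FitConfig:
    """Sampler settings for :class:`HierarchicalBayesLogit`.

    Defaults are weakly-informative conventions for conjoint HB: a diffuse
    Normal prior on the population mean, an inverse-Wishart prior on the
    covariance with p + 5 degrees of freedom and identity scale, and a
    random-walk proposal adapted toward 30% acceptance during burn-in only.
    """

    n_burn: int = 10000
    n_draws: int = 10000
    thin: int = 10
    prior_mean: float = 0.0
    prior_cov_scale: float = 100.0
    iw_df_extra: int = 5
    iw_scale: float = 1.0
    initial_step: float = 0.1
    target_accept: float = 0.30
    adapt_interval: int = 25
    seed: int | None = None

    def __post_init__(self):
        if min(self.n_burn, self.n_draws, self.thin, self.adapt_interval) < 1:
            raise ValueError("chain length settings must be positive")
        if not 0 < self.target_accept < 1:
            raise ValueError("target_accept must lie in (0, 1)")


@dataclass
class HBPosterior:
    """Posterior summaries from a hierarchical-Bayes fit."""

    individual_means: np.ndarray          # (n_respondents, p)
    respondent_ids: list
    population_mean: np.ndarray           # (p,)
    population_cov: np.ndarray            # (p, p)
    draws: dict = field(default_factory=dict)
    acceptance_rate: float = float("nan")
    rhat: float = float("nan")
    config: dict = field(default_factory=dict)

    def beta_frame(self, schema: AttributeSchema) -> pd.DataFrame:
        out = pd.DataFrame({"respondent_id": self.respondent_ids})
        for j, name in enumerate(schema.param_names()):
            out[name] = self.individual_means[:, j]
        return out


def _masked_loglik(X, chosen, mask, B):
    """Per-respondent logit log-likelihood at individual betas B (n, p)."""
    U = np.einsum("ntkp,np->ntk", X, B)
    lse = logsumexp(U, axis=2)
    cu = np.take_along_axis(U, chosen[..., None], axis=2)[..., 0]
    return ((cu - lse) * mask).sum(axis=1)


def _split_rhat(chain):
    """Max split-chain potential scale reduction over parameters."""
    m = len(chain) // 2
    if m < 2:
        return float("nan")
    halves = np.stack([chain[:m], chain[m : 2 * m]])     # (2, m, p)
    means = halves.mean(axis=1)
    W = halves.var(axis=1, ddof=1).mean(axis=0)
    B = m * means.var(axis=0, ddof=1)
    var_hat = (m - 1) / m * W + B / m
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_hat / W)
    return float(np.nanmax(rhat))


class HierarchicalBayesLogit(BaseEstimator):
    """Hierarchical-Bayes multinomial logit with individual part-worths.

    Model: choices follow the logit rule at respondent-specific ``beta_r``;
    ``beta_r ~ N(alpha, D)`` across respondents;
    ``alpha ~ N(prior_mean, prior_cov_scale * I)``;
    ``D ~ InvWishart(p + iw_df_extra, iw_scale * I)``.

    Sampling alternates (i) the conjugate Normal draw of ``alpha``, (ii) the
    conjugate inverse-Wishart draw of ``D``, (iii) one random-walk
    Metropolis-Hastings update of every ``beta_r`` with proposal covariance
    ``step^2 * D``; ``step`` adapts toward ``target_accept`` during burn-in
    only, so the post-burn chain is a fixed Markov kernel.  Runs are
    bit-reproducible given ``seed``.

    Attributes (after ``fit``)
    --------------------------
    individual_means_ : (n, p) posterior-mean beta per respondent
    population_mean_, population_cov_ : posterior means of alpha and D
    acceptance_rate_ : post-burn MH acceptance frequency
    rhat_ : max split-chain R-hat over population-mean components
    posterior_ : the full :class:`HBPosterior`
    """

    def __init__(
        self,
        schema=None,
        n_burn=10000,
        n_draws=10000,
        thin=10,
        prior_mean=0.0,
        prior_cov_scale=100.0,
        iw_df_extra=5,
        iw_scale=1.0,
        initial_step=0.1,
        target_accept=0.30,
        adapt_interval=25,
        seed=None,
        include_holdouts=False,
        rhat_threshold=1.2,
    ):
        self.schema = schema
        self.n_burn = n_burn
        self.n_draws = n_draws
        self.thin = thin
        self.prior_mean = prior_mean
        self.prior_cov_scale = prior_cov_scale
        self.iw_df_extra = iw_df_extra
        self.iw_scale = iw_scale
        self.initial_step = initial_step
        self.target_accept = target_accept
        self.adapt_interval = adapt_interval
        self.seed = seed
        self.include_holdouts = include_holdouts
        self.rhat_threshold = rhat_threshold

    def fit(self, data, y=None):
        if self.schema is None:
            raise ValueError("schema is required")
        FitConfig(  # validates the chain settings
            n_burn=self.n_burn, n_draws=self.n_draws, thin=self.thin,
            target_accept=self.target_accept, adapt_interval=self.adapt_interval,
        )
        X, chosen, mask, ids = respondent_arrays(
            data, self.schema, self.include_holdouts
        )
        n, p = X.shape[0], X.shape[3]
        if n < 2:
            raise ChoiceDataError("hierarchical model needs at least 2 respondents")

        rng = np.random.default_rng(self.seed)
        # initialize at the pooled MLE: a deterministic, data-driven start
        # that avoids the slow crawl of a cold start when D is small
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            beta0, _, _, _ = fit_mnl_arrays(
                X.reshape(-1, X.shape[2], p)[mask.ravel()],
                chosen[mask],
                max_iter=25,
            )
        B = np.tile(beta0, (n, 1))
        alpha = beta0.copy()
        D = np.eye(p) * self.iw_scale
        nu0 = p + self.iw_df_extra
        prior_prec = 1.0 / self.prior_cov_scale
        m0 = np.full(p, float(self.prior_mean))

        step = float(self.initial_step)
        ll_cur = _masked_loglik(X, chosen, mask, B)

        n_iter = self.n_burn + self.n_draws
        accepted_burn = accepted_post = 0
        B_sum = np.zeros_like(B)
        alpha_sum = np.zeros(p)
        D_sum = np.zeros((p, p))
        alpha_chain, d_diag_chain = [], []
        min_d_eig = np.inf

        for it in range(n_iter):
            centered = B - alpha
            # (i) population mean | B, D  (conjugate Normal)
            D_chol = cho_factor(D, lower=True)
            Dinv = cho_solve(D_chol, np.eye(p))
            post_prec = n * Dinv + prior_prec * np.eye(p)
            prec_chol = cho_factor(post_prec, lower=True)
            post_mean = cho_solve(
                prec_chol, Dinv @ B.sum(axis=0) + prior_prec * m0
            )
            z = rng.standard_normal(p)
            Lprec = cholesky(post_prec)
            alpha = post_mean + solve_triangular(Lprec.T, z, lower=False)

            # (ii) population covariance | B, alpha  (conjugate IW)
            centered = B - alpha
            S = self.iw_scale * np.eye(p) + centered.T @ centered
            D = invwishart.rvs(df=nu0 + n, scale=S, random_state=rng)
            eig_min = float(np.linalg.eigvalsh(D)[0])
            min_d_eig = min(min_d_eig, eig_min)
            L = cholesky(D)

            # (iii) per-respondent MH step, proposal cov = step^2 * D
            prop = B + step * (rng.standard_normal((n, p)) @ L.T)
            ll_prop = _masked_loglik(X, chosen, mask, prop)
            dev_cur = solve_triangular(L, (B - alpha).T, lower=True)
            dev_prop = solve_triangular(L, (prop - alpha).T, lower=True)
            lp_cur = -0.5 * np.sum(dev_cur**2, axis=0)
            lp_prop = -0.5 * np.sum(dev_prop**2, axis=0)
            log_r = (ll_prop + lp_prop) - (ll_cur + lp_cur)
            accept = np.log(rng.random(n)) < log_r
            B[accept] = prop[accept]
            ll_cur[accept] = ll_prop[accept]

            if it < self.n_burn:
                accepted_burn += int(accept.sum())
                if (it + 1) % self.adapt_interval == 0:
                    rate = accepted_burn / (self.adapt_interval * n)
                    step *= float(np.exp(rate - self.target_accept))
                    step = float(np.clip(step, 1e-3, 10.0))
                    accepted_burn = 0
            else:
                accepted_post += int(accept.sum())
                B_sum += B
                alpha_sum += alpha
                D_sum += D
                if (it - self.n_burn) % self.thin == 0:
                    alpha_chain.append(alpha.copy())
                    d_diag_chain.append(np.diag(D).copy())

        alpha_chain = np.asarray(alpha_chain)
        self.individual_means_ = B_sum / self.n_draws
        self.respondent_ids_ = ids
        self.population_mean_ = alpha_sum / self.n_draws
        self.population_cov_ = D_sum / self.n_draws
        self.acceptance_rate_ = accepted_post / (self.n_draws * n)
        self.rhat_ = _split_rhat(alpha_chain)
        self.min_cov_eigenvalue_ = float(min_d_eig)
        self.step_ = step
        if np.isfinite(self.rhat_) and self.rhat_ > self.rhat_threshold:
            warnings.warn(
                f"population-mean split R-hat {self.rhat_:.3f} exceeds "
                f"{self.rhat_threshold}; consider longer chains",
                ConvergenceWarning,
                stacklevel=2,
            )
        self.posterior_ = HBPosterior(
            individual_means=self.individual_means_,
            respondent_ids=ids,
            population_mean=self.population_mean_,
            population_cov=self.population_cov_,
            draws={
                "alpha": alpha_chain,
                "d_diag": np.asarray(d_diag_chain),
                "final_step": step,
            },
            acceptance_rate=self.acceptance_rate_,
            rhat=self.rhat_,
            config=self.get_params(deep=False),
        )
        return self


def fit_hb(
    data, schema: AttributeSchema, config: FitConfig | None = None, **kwargs
) -> HBPosterior:
    """Functional wrapper over :class:`HierarchicalBayesLogit`.

    ``config`` supplies sampler settings; keyword arguments override both
    the config and the estimator defaults.
    """
    params = asdict(config) if config is not None else {}
    params.update(kwargs)
    est = HierarchicalBayesLogit(schema=schema, **params).fit(data)
    return est.posterior_
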