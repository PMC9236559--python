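"""Bayesian model-comparison criteria: deviance, DIC, CPO and LPML.

DIC = Dev_bar + pD with pD = Dev_bar - Dev_hat, where Dev_bar is the
posterior mean of the deviance -2 log L(Y, D | Omega) over stored draws and
Dev_hat evaluates the deviance at the component-wise posterior means
(attribute profiles by thresholding their marginal means at 0.5).  The
deviance conditions on the sampled attribute profiles rather than
marginalizing over all 2^K patterns, matching the conditional form of the
joint likelihood; conditional and marginal DIC differ in level, so only
orderings between models are meaningful here.

LPML = sum_ij log CPO_ij with the per-cell conditional predictive ordinate
computed by the stabilized harmonic-mean estimator
``log CPO_ij = -Q_max - log[(1/R) sum_r exp(-log f_r - Q_max)]`` where
Q_max is the per-cell maximum of -log f over draws.  Larger LPML (and
smaller DIC) indicates better fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from notreached.model_core import Dataset, ModelParams
from notreached.sampler import (
    PosteriorDraws,
    SamplerState,
    _PreparedData,
    cell_loglik_matrix,
    _hodina_cell_loglik_matrix,
)

__all__ = ["FitSummary", "deviance", "dic", "cpo_lpml", "stabilized_log_cpo"]


@dataclass
class FitSummary:
    dev_bar: float
    dev_hat: float
    pD: float
    dic: float
    lpml: float = None
    log_cpo: np.ndarray = None

    def to_dict(self) -> dict:
        return {"dev_bar": self.dev_bar, "dev_hat": self.dev_hat,
                "pD": self.pD, "dic": self.dic, "lpml": self.lpml}


def _state_from_params(params: ModelParams, Q) -> SamplerState:
    alpha = params.persons.alpha
    state = SamplerState(
        alpha=alpha,
        theta_h=params.persons.theta_h, theta_d=params.persons.theta_d,
        beta=params.items.beta, delta=params.items.delta,
        eta0=params.dropout.eta0, eta1=params.dropout.eta1,
        gamma=params.structure.gamma, lam=params.structure.lam,
        mu_beta=params.item_hypers.mu_beta, mu_delta=params.item_hypers.mu_delta,
        Sigma_I=params.item_hypers.Sigma_I,
        sigma_hd=params.person_hypers.sigma_hd,
        sigma_d2=params.person_hypers.sigma_d2,
    )
    state.M = alpha.astype(float) @ Q.astype(float).T
    return state


def deviance(params: ModelParams, dataset: Dataset,
             convention: str = "sequential", with_dropout: bool = True) -> float:
    """-2 log L(Y, D | Omega) at one parameter state."""
    prep = _PreparedData(dataset, convention)
    state = _state_from_params(params, dataset.Q.entries)
    ll = (cell_loglik_matrix(prep, state) if with_dropout
          else _hodina_cell_loglik_matrix(prep, state))
    if not np.isfinite(ll).all():
        raise ValueError("non-finite cell log-likelihood")
    return float(-2.0 * ll.sum())


def _deviance_at_state(state: SamplerState, prep, with_dropout: bool) -> float:
    ll = (cell_loglik_matrix(prep, state) if with_dropout
          else _hodina_cell_loglik_matrix(prep, state))
    return float(-2.0 * ll.sum())


def dic(draws: PosteriorDraws, dataset: Dataset) -> FitSummary:
    """DIC from one chain's stored draws.

    Requires the chain to have been run with ``store_deviance`` or
    ``compute_fit_metrics`` so the per-iteration deviance trace exists.
    """
    if draws.deviance is None or len(draws.deviance) == 0:
        raise ValueError("chain was run without deviance accumulation")
    cfg = draws.config
    means = draws.posterior_means()
    dev_bar = float(draws.deviance.mean())
    prep = _PreparedData(dataset, cfg.convention)
    state = SamplerState(
        alpha=means["alpha"],
        theta_h=means["theta_h"], theta_d=means["theta_d"],
        beta=means["beta"], delta=means["delta"],
        eta0=means["eta0"], eta1=means["eta1"],
        gamma=means["gamma"], lam=means["lam"],
        mu_beta=means["mu_beta"], mu_delta=means["mu_delta"],
        Sigma_I=np.array([[means["sigma_b2"], means["sigma_bd"]],
                          [means["sigma_bd"], means["sigma_d2_item"]]]),
        sigma_hd=means["sigma_hd"], sigma_d2=means["sigma_d2"],
    )
    state.M = means["alpha"].astype(float) @ dataset.Q.entries.T.astype(float)
    dev_hat = _deviance_at_state(state, prep, cfg.model != "hodina")
    pD = dev_bar - dev_hat
    lpml = None
    if draws.log_cpo is not None:
        lpml = float(draws.log_cpo.sum())
    return FitSummary(dev_bar=dev_bar, dev_hat=dev_hat, pD=pD,
                      dic=dev_bar + pD, lpml=lpml, log_cpo=draws.log_cpo)


def stabilized_log_cpo(neg_loglik_draws: np.ndarray) -> np.ndarray:
    """Reference (batch) CPO estimator from an (R, ...) array of per-draw
    negative cell log-likelihoods; the sampler computes the same quantity
    in a streaming fashion."""
    neg = np.asarray(neg_loglik_draws, dtype=float)
    if neg.shape[0] < 1:
        raise ValueError("need at least one draw")
    q_max = neg.max(axis=0)
    return -q_max - np.log(np.mean(np.exp(neg - q_max), axis=0))


def cpo_lpml(draws: PosteriorDraws, dataset: Dataset = None):
    """(per-cell log-CPO matrix, LPML) from a chain run with
    ``compute_fit_metrics=True``."""
    if draws.log_cpo is None:
        raise ValueError("chain was run without CPO accumulation")
    return draws.log_cpo, float(draws.log_cpo.sum())
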