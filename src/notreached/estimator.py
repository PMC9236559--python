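"""Scikit-learn style estimator facade over the MCMC sampler.

``DinaDropoutModel`` is the user-facing entry point: construct with a Q
matrix and sampler settings, ``fit(Y, D)`` on a response matrix with
missing indicators, then read posterior summaries off the fitted
attributes (``alpha_``, ``eta0_``, ``beta_`` ...) or classify new mastery
profiles with ``predict``.  It follows the sklearn estimator contract
(``get_params``/``set_params``, trailing-underscore fitted attributes,
``check_is_fitted``-compatible) so it composes with sklearn model
selection utilities.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from notreached.model_core import Dataset, QMatrix
from notreached.sampler import FitConfig, PriorSpec, run_chain, psrf_table
from notreached.metrics import dic as _dic

__all__ = ["DinaDropoutModel"]


class DinaDropoutModel(BaseEstimator):
    """Higher-order DINA model with a sequential dropout component.

    Parameters
    ----------
    q_matrix : array-like of shape (J, K)
        Binary item-by-attribute design matrix.
    model : {"nmar", "mar", "hodina"}
        ``nmar`` estimates the covariance between ability and dropout
        propensity (non-ignorable missingness); ``mar`` fixes it at zero;
        ``hodina`` ignores the missing-indicator matrix entirely.
    chain_length, burn_in, n_chains : int
        MCMC protocol; defaults 10,000 / 5,000 / 2.
    convention : {"sequential", "full-product"}
        Likelihood treatment of cells after the first dropout (sequential:
        they contribute nothing).
    compute_fit_metrics : bool
        Accumulate the deviance trace and per-cell CPO terms during
        sampling so DIC and LPML are available after the fit.
    random_state : int
        Seed for all chains.

    Attributes
    ----------
    alpha_ : (N, K) int array — estimated mastery profiles (posterior
        marginal means thresholded at 0.5).
    alpha_proba_ : (N, K) float array — posterior mastery probabilities.
    theta_h_, theta_d_ : (N,) posterior-mean ability / dropout propensity.
    beta_, delta_ : (J,) posterior-mean item intercepts / interactions.
    guess_, slip_ : (J,) implied guessing and slipping probabilities.
    eta0_, eta1_ : dropout intercept / position slope.
    gamma_, lam_ : (K,) higher-order slopes / intercepts.
    sigma_hd_, sigma_d2_ : person covariance components.
    psrf_ : dict of Gelman-Rubin factors per monitored parameter
        (``n_chains >= 2`` only).
    fit_summary_ : :class:`notreached.metrics.FitSummary` (DIC/LPML) when
        ``compute_fit_metrics`` is set.
    """

    def __init__(self, q_matrix=None, model="nmar", chain_length=10_000,
                 burn_in=5_000, n_chains=2, convention="sequential",
                 compute_fit_metrics=False, priors=None, random_state=0):
        self.q_matrix = q_matrix
        self.model = model
        self.chain_length = chain_length
        self.burn_in = burn_in
        self.n_chains = n_chains
        self.convention = convention
        self.compute_fit_metrics = compute_fit_metrics
        self.priors = priors
        self.random_state = random_state

    def _config(self) -> FitConfig:
        return FitConfig(
            model=self.model, chain_length=self.chain_length,
            burn_in=self.burn_in, n_chains=self.n_chains,
            seed=self.random_state, convention=self.convention,
            priors=self.priors if self.priors is not None else PriorSpec(),
            compute_fit_metrics=self.compute_fit_metrics,
            store_deviance=self.compute_fit_metrics,
        )

    def fit(self, Y, D=None):
        """Fit the model by MCMC.

        Parameters
        ----------
        Y : (N, J) array with NaN at missing cells, or a
            :class:`notreached.model_core.Dataset`.
        D : optional (N, J) binary missing-indicator matrix; derived from
            the NaN pattern of Y when omitted.
        """
        if isinstance(Y, Dataset):
            dataset = Y
        else:
            Y = np.asarray(Y, dtype=float)
            if D is None:
                D = np.isnan(Y).astype(np.int8)
            if self.q_matrix is None:
                raise ValueError("q_matrix is required")
            dataset = Dataset(Y=Y, D=np.asarray(D), Q=QMatrix(np.asarray(self.q_matrix)))
        config = self._config()
        chains = run_chain(dataset, config)
        self.chains_ = chains
        self.dataset_ = dataset
        self.n_features_in_ = dataset.J

        # pool posterior means across chains
        pooled_alpha = np.mean([c.alpha_mean for c in chains], axis=0)
        self.alpha_proba_ = pooled_alpha
        self.alpha_ = (pooled_alpha >= 0.5).astype(np.int8)
        self.theta_h_ = np.mean([c.theta_h_mean for c in chains], axis=0)
        self.theta_d_ = np.mean([c.theta_d_mean for c in chains], axis=0)
        means = [c.posterior_means() for c in chains]

        def pool(name):
            return np.mean([m[name] for m in means], axis=0)

        self.beta_ = pool("beta")
        self.delta_ = pool("delta")
        from scipy.special import expit
        self.guess_ = expit(self.beta_)
        self.slip_ = 1.0 - expit(self.beta_ + self.delta_)
        self.gamma_ = pool("gamma")
        self.lam_ = pool("lam")
        self.eta0_ = float(pool("eta0"))
        self.eta1_ = float(pool("eta1"))
        self.mu_beta_ = float(pool("mu_beta"))
        self.mu_delta_ = float(pool("mu_delta"))
        self.Sigma_I_ = np.array([
            [float(pool("sigma_b2")), float(pool("sigma_bd"))],
            [float(pool("sigma_bd")), float(pool("sigma_d2_item"))]])
        self.sigma_hd_ = float(pool("sigma_hd"))
        self.sigma_d2_ = float(pool("sigma_d2"))
        self.acceptance_ = {k: float(np.mean([c.acceptance[k] for c in chains]))
                            for k in chains[0].acceptance}
        self.psrf_ = psrf_table(chains) if len(chains) >= 2 else None
        self.fit_summary_ = None
        if self.compute_fit_metrics:
            # DIC/LPML from the first chain (criteria are per-fit, chains agree
            # after convergence); pooling chains would mix estimator variants.
            self.fit_summary_ = _dic(chains[0], dataset)
        return self

    def predict(self, Y=None, D=None):
        """Estimated mastery profiles for the fitted examinees."""
        check_is_fitted(self, "alpha_")
        return self.alpha_

    def predict_proba(self, Y=None):
        check_is_fitted(self, "alpha_proba_")
        return self.alpha_proba_

    def score(self, Y=None, D=None):
        """LPML of the fit (higher is better); requires fit metrics."""
        check_is_fitted(self, "fit_summary_")
        if self.fit_summary_ is None or self.fit_summary_.lpml is None:
            raise ValueError("fit with compute_fit_metrics=True to score")
        return self.fit_summary_.lpml
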