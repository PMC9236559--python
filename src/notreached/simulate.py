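"""Synthetic data generation for the joint response + dropout model.

The generator reproduces the data-generating process of the simulation
studies: item parameters drawn from a bivariate normal with mean
``(mu_beta, mu_delta) = (-2.197, 4.394)`` (mean guessing and slipping
effects of 0.1) and covariance ``[[1, -0.8], [-0.8, 1]]``; person ability
and dropout propensity bivariate normal with ``var(theta_h) = 1``,
``var(theta_d) = 0.25`` and correlation rho in {0, -0.3, -0.5, -0.8};
higher-order attribute intercepts ``lambda = (-1, -0.5, 0, 0.5, 1)`` and
slopes ``gamma_k = 1.5``; and a *sequential* dropout mechanism whose
(eta0, eta1) pairs (1, -0.7) / (1, -0.32) / (1, -0.18) yield overall
missing-cell proportions of about 3.8%, 12% and 25% on a 30-item test.

``expected_missing_proportion`` is an independent Gauss-Hermite quadrature
oracle for those proportions; it is what pins the mechanism down as
sequential — independent per-cell Bernoulli dropout at the same (eta0,
eta1) would give roughly 2%/4%/9% instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from notreached.model_core import (
    AttributeStructureParams,
    Dataset,
    DropoutParams,
    ItemHyperParams,
    ItemResponseParams,
    ModelParams,
    PersonHyperParams,
    PersonParams,
    QMatrix,
    attribute_prob,
    conjunction,
)

__all__ = [
    "DROPOUT_LEVELS",
    "SimulationCondition",
    "TruthBundle",
    "draw_item_params",
    "draw_person_params",
    "draw_attributes",
    "draw_responses",
    "draw_dropout",
    "expected_missing_proportion",
    "make_q_matrix",
    "simulate_condition",
]

# (eta0, eta1) pairs calibrated to 3.8% / 12% / 25% missing cells at J = 30
DROPOUT_LEVELS = {
    "low": (1.0, -0.7),
    "medium": (1.0, -0.32),
    "high": (1.0, -0.18),
}

_DEFAULT_LAMBDA = (-1.0, -0.5, 0.0, 0.5, 1.0)


@dataclass
class SimulationCondition:
    """One cell of the simulation design.

    Defaults are the study conditions: N = 500 examinees, J = 30 items,
    K = 5 attributes, correlation rho = -0.3 between ability and dropout
    propensity, medium dropout, R = 30 replications.
    """

    N: int = 500
    J: int = 30
    K: int = 5
    rho: float = -0.3
    dropout_level: str = "medium"
    sigma_d2: float = 0.25
    mu_beta: float = -2.197
    mu_delta: float = 4.394
    Sigma_I: tuple = ((1.0, -0.8), (-0.8, 1.0))
    lam: tuple = None
    gamma: tuple = None
    R: int = 30
    seed: int = 0

    def __post_init__(self):
        if abs(self.rho) >= 1:
            raise ValueError("|rho| must be < 1")
        if self.dropout_level not in DROPOUT_LEVELS:
            raise ValueError("dropout_level must be one of %s" % list(DROPOUT_LEVELS))
        if self.lam is None:
            self.lam = _DEFAULT_LAMBDA[: self.K]
        if self.gamma is None:
            self.gamma = (1.5,) * self.K
        if len(self.lam) != self.K or len(self.gamma) != self.K:
            raise ValueError("lam and gamma must have length K")

    @property
    def eta(self) -> tuple:
        return DROPOUT_LEVELS[self.dropout_level]

    @property
    def sigma_hd(self) -> float:
        # rho is a correlation; sd(theta_h) = 1, sd(theta_d) = sqrt(sigma_d2)
        return self.rho * np.sqrt(self.sigma_d2)


@dataclass
class TruthBundle:
    """Generating parameter values (including the realized alpha matrix)."""

    params: ModelParams
    condition: SimulationCondition = field(repr=False, default=None)


def draw_item_params(hypers: ItemHyperParams, J: int, rng: np.random.Generator) -> ItemResponseParams:
    """J iid draws of (beta_j, delta_j) from the bivariate normal hyper-law."""
    draws = rng.multivariate_normal([hypers.mu_beta, hypers.mu_delta],
                                    hypers.Sigma_I, size=J,
                                    method="cholesky")
    return ItemResponseParams(beta=draws[:, 0], delta=draws[:, 1])


def draw_person_params(sigma_hd: float, sigma_d2: float, N: int,
                       rng: np.random.Generator):
    """N iid draws of (theta_h, theta_d) with var(theta_h) fixed at 1."""
    hypers = PersonHyperParams(sigma_hd=sigma_hd, sigma_d2=sigma_d2)  # validates PD
    draws = rng.multivariate_normal([0.0, 0.0], hypers.Sigma_P, size=N,
                                    method="cholesky")
    return draws[:, 0], draws[:, 1]


def draw_attributes(theta_h, gamma, lam, rng: np.random.Generator) -> np.ndarray:
    """Independent Bernoulli mastery per (person, attribute)."""
    theta_h = np.asarray(theta_h, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if gamma.shape != lam.shape:
        raise ValueError("gamma and lam must have matching length")
    p = attribute_prob(theta_h[:, None], gamma[None, :], lam[None, :])
    return (rng.random(p.shape) < p).astype(np.int8)


def draw_responses(alpha, Q: QMatrix, items: ItemResponseParams,
                   rng: np.random.Generator) -> np.ndarray:
    """Complete (pre-missingness) Bernoulli response matrix under DINA."""
    eta = conjunction(np.asarray(alpha), Q.entries)
    p = expit(items.beta[None, :] + items.delta[None, :] * eta)
    return (rng.random(p.shape) < p).astype(np.int8)


def draw_dropout(theta_d, eta0: float, eta1: float, J: int,
                 rng: np.random.Generator, mechanism: str = "sequential") -> np.ndarray:
    """Missing-indicator matrix D.

    ``sequential`` (default): scan positions 1..J; the first success of the
    per-position hazard marks the dropout point and every later item is
    missing, so D is monotone within each row.  ``independent``: iid
    Bernoulli per cell at the same hazards (diagnostic variant only).
    """
    theta_d = np.asarray(theta_d, dtype=float)
    N = theta_d.shape[0]
    dp = DropoutParams(eta0=eta0, eta1=eta1)
    H = expit(theta_d[:, None] - dp.beta_d(J)[None, :])
    U = rng.random((N, J))
    hit = U < H
    if mechanism == "independent":
        return hit.astype(np.int8)
    if mechanism != "sequential":
        raise ValueError("unknown dropout mechanism: %r" % (mechanism,))
    # first hit per row; J means "never dropped"
    any_hit = hit.any(axis=1)
    first = np.where(any_hit, hit.argmax(axis=1), J)
    return (np.arange(J)[None, :] >= first[:, None]).astype(np.int8)


def expected_missing_proportion(eta0: float, eta1: float, J: int,
                                sigma_d2: float, mechanism: str = "sequential",
                                n_nodes: int = 61) -> float:
    """Quadrature oracle for the expected overall missing-cell proportion.

    Integrates over theta_d ~ N(0, sigma_d2) with Gauss-Hermite nodes.
    Sequential: sum_j P(first dropout at j) * (J - j + 1) / J.  Independent:
    mean of the per-cell hazards.
    """
    if sigma_d2 <= 0:
        raise ValueError("sigma_d2 must be positive")
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    theta = nodes * np.sqrt(2.0 * sigma_d2)
    w = weights / np.sqrt(np.pi)
    beta_d = DropoutParams(eta0=eta0, eta1=eta1).beta_d(J)
    H = expit(theta[:, None] - beta_d[None, :])  # (nodes, J)
    if mechanism == "independent":
        return float(w @ H.mean(axis=1))
    if mechanism != "sequential":
        raise ValueError("unknown dropout mechanism: %r" % (mechanism,))
    surv = np.cumprod(1.0 - H, axis=1)
    prev_surv = np.hstack([np.ones((len(theta), 1)), surv[:, :-1]])
    first = prev_surv * H  # P(first dropout at j | theta)
    frac = (J - np.arange(1, J + 1) + 1) / J
    return float(w @ (first @ frac))


def make_q_matrix(J: int, K: int, design: str = "identity-complete") -> QMatrix:
    """Deterministic identity-complete Q-matrix fixture.

    Rows: a K x K identity block (each attribute measured alone, which
    anchors identifiability), a block of K adjacent two-attribute pairs
    (k, k+1 mod K), and remaining rows cycling through that same
    singles-then-pairs sequence.  Requires J >= 2K.
    """
    if design != "identity-complete":
        raise ValueError("unknown Q-matrix design: %r" % (design,))
    if J < 2 * K:
        raise ValueError("identity-complete design needs J >= 2K")
    singles = np.eye(K, dtype=np.int8)
    pairs = np.zeros((K, K), dtype=np.int8)
    for k in range(K):
        pairs[k, k] = 1
        pairs[k, (k + 1) % K] = 1
    cycle = np.vstack([singles, pairs])
    reps = int(np.ceil(J / (2 * K)))
    rows = np.vstack([cycle] * reps)[:J]
    return QMatrix(entries=rows)


def simulate_condition(cond: SimulationCondition, rep_index: int = 0,
                       mechanism: str = "sequential"):
    """Generate one replication: (Dataset, TruthBundle).

    Deterministic given ``(cond.seed, rep_index)``; replications use
    independent child seeds so any single replication is reproducible on
    its own.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cond.seed).spawn(rep_index + 1)[rep_index])
    Q = make_q_matrix(cond.J, cond.K)
    item_hypers = ItemHyperParams(mu_beta=cond.mu_beta, mu_delta=cond.mu_delta,
                                  Sigma_I=np.asarray(cond.Sigma_I, dtype=float))
    items = draw_item_params(item_hypers, cond.J, rng)
    theta_h, theta_d = draw_person_params(cond.sigma_hd, cond.sigma_d2, cond.N, rng)
    alpha = draw_attributes(theta_h, cond.gamma, cond.lam, rng)
    Y_complete = draw_responses(alpha, Q, items, rng)
    eta0, eta1 = cond.eta
    D = draw_dropout(theta_d, eta0, eta1, cond.J, rng, mechanism=mechanism)
    Y = Y_complete.astype(float)
    Y[D == 1] = np.nan
    dataset = Dataset(Y=Y, D=D, Q=Q)
    truth = TruthBundle(
        params=ModelParams(
            items=items,
            item_hypers=item_hypers,
            structure=AttributeStructureParams(gamma=np.asarray(cond.gamma),
                                               lam=np.asarray(cond.lam)),
            dropout=DropoutParams(eta0=eta0, eta1=eta1),
            persons=PersonParams(theta_h=theta_h, theta_d=theta_d, alpha=alpha),
            person_hypers=PersonHyperParams(sigma_hd=cond.sigma_hd,
                                            sigma_d2=cond.sigma_d2),
        ),
        condition=cond,
    )
    return dataset, truth
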