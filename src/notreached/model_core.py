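"""Model equations and parameter containers.

Pure, stateless probability functions for the three model components:

* DINA response model on the logit scale: ``logit P(y=1) = beta_j +
  delta_j * prod_k alpha_ik^q_jk`` — an item is answered correctly with
  probability ``1 - s_j`` by examinees mastering every required attribute
  and with the guessing probability ``g_j`` by everyone else.
* Sequential dropout model: the hazard of dropping out at item position j
  is ``invlogit(theta_d - beta_d_j)`` with the linear position restriction
  ``beta_d_j = eta0 + (j - J) * eta1``, so ``eta0`` is the difficulty
  threshold of the last item and a negative ``eta1`` makes late items the
  likeliest dropout points.
* Higher-order attribute structure: ``logit P(alpha_ik=1) = theta_h *
  gamma_k - lambda_k``, a single continuous ability generating mastery of
  all K attributes.

All logistic evaluations go through :func:`scipy.special.expit` /
``log_expit`` with logit arguments clamped at +/-36 so probabilities stay
inside (0, 1) in double precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, log_expit, logit

LOGIT_CLAMP = 36.0

__all__ = [
    "QMatrix",
    "ItemResponseParams",
    "ItemHyperParams",
    "AttributeStructureParams",
    "DropoutParams",
    "PersonParams",
    "PersonHyperParams",
    "Dataset",
    "ModelParams",
    "response_prob",
    "reparameterize_gs",
    "inverse_reparameterize",
    "dropout_hazard",
    "attribute_prob",
    "conjunction",
    "cell_loglik",
]


def _clamp(x):
    return np.clip(x, -LOGIT_CLAMP, LOGIT_CLAMP)


# ---------------------------------------------------------------------------
# containers


@dataclass
class QMatrix:
    """Binary J x K item-by-attribute design matrix.

    ``entries[j, k] == 1`` declares that item j requires attribute k.  Every
    item must require at least one attribute.
    """

    entries: np.ndarray

    def __post_init__(self):
        q = np.asarray(self.entries)
        if q.ndim != 2:
            raise ValueError("Q matrix must be 2-dimensional")
        if not np.isin(q, (0, 1)).all():
            raise ValueError("Q matrix entries must be 0 or 1")
        if (q.sum(axis=1) < 1).any():
            raise ValueError("every Q-matrix row needs at least one attribute")
        self.entries = q.astype(np.int8)

    @property
    def J(self) -> int:
        return self.entries.shape[0]

    @property
    def K(self) -> int:
        return self.entries.shape[1]


@dataclass
class ItemResponseParams:
    """Per-item intercept (beta) and interaction (delta) on the logit scale."""

    beta: np.ndarray
    delta: np.ndarray

    @property
    def guess(self) -> np.ndarray:
        """g_j = invlogit(beta_j)."""
        return expit(self.beta)

    @property
    def slip(self) -> np.ndarray:
        """s_j = 1 - invlogit(beta_j + delta_j)."""
        return 1.0 - expit(self.beta + self.delta)

    @property
    def idi(self) -> np.ndarray:
        """Item discrimination index 1 - s_j - g_j."""
        return 1.0 - self.slip - self.guess


@dataclass
class ItemHyperParams:
    """Bivariate-normal hyper-distribution of (beta_j, delta_j)."""

    mu_beta: float
    mu_delta: float
    Sigma_I: np.ndarray

    def __post_init__(self):
        S = np.asarray(self.Sigma_I, dtype=float)
        if S.shape != (2, 2) or not np.allclose(S, S.T):
            raise ValueError("Sigma_I must be symmetric 2x2")
        if np.linalg.eigvalsh(S)[0] <= 0:
            raise ValueError("Sigma_I must be positive-definite")
        self.Sigma_I = S


@dataclass
class AttributeStructureParams:
    """Higher-order slopes gamma_k (> 0) and intercepts lambda_k."""

    gamma: np.ndarray
    lam: np.ndarray

    def __post_init__(self):
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.lam = np.asarray(self.lam, dtype=float)
        if (self.gamma <= 0).any():
            raise ValueError("gamma_k must be positive")


@dataclass
class DropoutParams:
    """Linear position restriction beta_d_j = eta0 + (j - J) * eta1."""

    eta0: float
    eta1: float

    def beta_d(self, J: int) -> np.ndarray:
        j = np.arange(1, J + 1)
        return self.eta0 + (j - J) * self.eta1


@dataclass
class PersonParams:
    theta_h: np.ndarray
    theta_d: np.ndarray
    alpha: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.alpha)
        if not np.isin(a, (0, 1)).all():
            raise ValueError("alpha entries must be 0 or 1")
        self.alpha = a.astype(np.int8)


@dataclass
class PersonHyperParams:
    """Covariance of (theta_h, theta_d); mean fixed at 0, var(theta_h) at 1."""

    sigma_hd: float
    sigma_d2: float

    def __post_init__(self):
        if self.sigma_d2 <= 0:
            raise ValueError("sigma_d2 must be positive")
        if self.sigma_hd**2 >= self.sigma_d2:
            raise ValueError("sigma_hd^2 < sigma_d2 required for a PD covariance")

    @property
    def Sigma_P(self) -> np.ndarray:
        return np.array([[1.0, self.sigma_hd], [self.sigma_hd, self.sigma_d2]])


@dataclass
class ModelParams:
    """One full parameter state of the joint model."""

    items: ItemResponseParams
    item_hypers: ItemHyperParams
    structure: AttributeStructureParams
    dropout: DropoutParams
    persons: PersonParams
    person_hypers: PersonHyperParams


@dataclass
class Dataset:
    """Responses Y (NaN = missing), missing indicators D and the Q matrix.

    ``d_ij = 1`` iff ``Y_ij`` is missing.  Under monotone (not-reached)
    missingness each row of D is a terminal run of ones.
    """

    Y: np.ndarray
    D: np.ndarray
    Q: QMatrix
    monotone: bool = field(default=False)

    def __post_init__(self):
        Y = np.asarray(self.Y, dtype=float)
        D = np.asarray(self.D)
        if Y.shape != D.shape:
            raise ValueError("Y and D must have the same shape")
        if Y.shape[1] != self.Q.J:
            raise ValueError("Y has %d columns but Q has %d rows" % (Y.shape[1], self.Q.J))
        if not np.isin(D, (0, 1)).all():
            raise ValueError("D entries must be 0 or 1")
        miss = np.isnan(Y)
        if not (miss == (D == 1)).all():
            raise ValueError("d_ij = 1 must coincide exactly with missing Y_ij")
        obs = Y[~miss]
        if not np.isin(obs, (0, 1)).all():
            raise ValueError("observed responses must be 0 or 1")
        self.Y = Y
        self.D = D.astype(np.int8)
        self.monotone = bool(np.all(np.diff(self.D, axis=1) >= 0))

    @property
    def N(self) -> int:
        return self.Y.shape[0]

    @property
    def J(self) -> int:
        return self.Y.shape[1]

    @property
    def missing_proportion(self) -> float:
        return float(self.D.mean())


# ---------------------------------------------------------------------------
# probability functions


def conjunction(alpha, q):
    """DINA "and"-gate term prod_k alpha_k^{q_k} for profile(s) and Q row(s).

    Accepts (..., K) profile arrays against a (K,) row or an (N, K) alpha
    against a (J, K) Q, returning the (N, J) indicator that every required
    attribute is mastered.
    """
    alpha = np.asarray(alpha)
    q = np.asarray(q)
    if alpha.shape[-1] != q.shape[-1]:
        raise ValueError("alpha and q disagree on the number of attributes")
    if alpha.ndim == 2 and q.ndim == 2:
        need = q.sum(axis=1)
        return (alpha @ q.T == need).astype(np.int8)
    return ((alpha * q) == q).all(axis=-1).astype(np.int8)


def response_prob(alpha_row, q_row, beta, delta):
    """P(correct) for a profile on one item: invlogit(beta + delta * and-gate).

    Equals ``g_j`` when any required attribute is absent and ``1 - s_j``
    when all are mastered.
    """
    q_row = np.asarray(q_row)
    if q_row.sum() < 1:
        raise ValueError("item requires no attribute")
    eta = conjunction(np.asarray(alpha_row), q_row)
    return expit(_clamp(beta + delta * eta))


def reparameterize_gs(g, s):
    """(guess, slip) -> (beta, delta): beta = logit(g), delta = logit(1-s) - logit(g)."""
    g = np.asarray(g, dtype=float)
    s = np.asarray(s, dtype=float)
    if ((g <= 0) | (g >= 1) | (s <= 0) | (s >= 1)).any():
        raise ValueError("g and s must lie strictly in (0, 1)")
    beta = logit(g)
    delta = logit(1.0 - s) - beta
    return beta, delta


def inverse_reparameterize(beta, delta):
    """(beta, delta) -> (guess, slip); exact inverse of :func:`reparameterize_gs`."""
    beta = np.asarray(beta, dtype=float)
    delta = np.asarray(delta, dtype=float)
    return expit(beta), 1.0 - expit(beta + delta)


def dropout_hazard(theta_d, j, J, eta0, eta1):
    """Hazard of dropping out at position j: invlogit(theta_d - eta0 - (j-J)*eta1)."""
    j = np.asarray(j)
    if ((j < 1) | (j > J)).any():
        raise ValueError("item position out of range 1..J")
    beta_d = eta0 + (j - J) * eta1
    return expit(_clamp(np.asarray(theta_d, dtype=float) - beta_d))


def attribute_prob(theta_h, gamma_k, lam_k):
    """Mastery probability invlogit(theta_h * gamma_k - lambda_k); gamma_k > 0."""
    if np.any(np.asarray(gamma_k) <= 0):
        raise ValueError("gamma_k must be positive")
    return expit(_clamp(np.asarray(theta_h, dtype=float) * gamma_k - lam_k))


def cell_loglik(dataset: Dataset, params: ModelParams, i: int, j: int,
                convention: str = "sequential") -> float:
    """Log-likelihood contribution of one (person, item) cell.

    Observed cell: ``log(1 - h_ij) + log P(y | alpha)``.  The first dropped
    cell in a row: ``log h_ij``.  Cells after the first dropped cell
    contribute 0 under the ``sequential`` convention (monotone mechanism:
    once out, later items carry no information) or ``log h_ij`` under the
    literal ``full-product`` convention.
    """
    if convention not in ("sequential", "full-product"):
        raise ValueError("unknown likelihood convention: %r" % (convention,))
    Q = dataset.Q
    h = dropout_hazard(params.persons.theta_d[i], j + 1, Q.J,
                       params.dropout.eta0, params.dropout.eta1)
    if dataset.D[i, j] == 0:
        p = response_prob(params.persons.alpha[i], Q.entries[j],
                          params.items.beta[j], params.items.delta[j])
        p_y = p if dataset.Y[i, j] == 1 else 1.0 - p
        return float(np.log1p(-h) + np.log(p_y))
    first_drop = np.argmax(dataset.D[i])  # first 1 in this row
    if j == first_drop or convention == "full-product":
        return float(np.log(h))
    return 0.0


def row_loglik(y_row, d_row, theta_d, alpha_row, items: ItemResponseParams,
               dropout: DropoutParams, Q: QMatrix,
               convention: str = "sequential") -> float:
    """Log-likelihood of one examinee's full row of cells.

    Reference (non-vectorized) form used by tests and by
    :func:`cell-level <cell_loglik>` oracles; the sampler uses the
    vectorized equivalent in :mod:`notreached.sampler`.
    """
    if convention not in ("sequential", "full-product"):
        raise ValueError("unknown likelihood convention: %r" % (convention,))
    J = Q.J
    total = 0.0
    dropped = False
    for j in range(J):
        h = dropout_hazard(theta_d, j + 1, J, dropout.eta0, dropout.eta1)
        if d_row[j] == 0:
            p = response_prob(alpha_row, Q.entries[j], items.beta[j], items.delta[j])
            p_y = p if y_row[j] == 1 else 1.0 - p
            total += np.log1p(-h) + np.log(p_y)
        elif not dropped:
            total += np.log(h)
            dropped = True
        elif convention == "full-product":
            total += np.log(h)
    return float(total)
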