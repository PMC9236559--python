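"""Replication harness: recovery metrics and the three simulation studies.

Study I varies test size (N, J) at K = 5; Study II varies the number of
attributes (K = 5 vs 3) at N = 500, J = 20; Study III compares the NMAR,
MAR and HO-DINA fits on NMAR-generated data across dropout levels and
ability-propensity correlations.  Recovery is summarized by signed bias
and RMSE per parameter, and attribute classification by the per-attribute
correct classification rate (ACCR) and whole-pattern rate (PCCR).

``reduced`` scale (R = 3 replications, 4,000 iterations / 2,000 burn-in)
is the desk-run default; ``full`` scale uses the study protocol (R = 30,
10,000 / 5,000).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from notreached.estimator import DinaDropoutModel
from notreached.simulate import SimulationCondition, simulate_condition

__all__ = ["bias_rmse", "accr_pccr", "run_study", "StudyResult",
           "STUDY_CONDITIONS"]


def bias_rmse(estimates, truth):
    """Signed bias and RMSE over replications.

    ``estimates`` is an (R, ...) array of per-replication estimates,
    ``truth`` the generating value(s).  Vector parameters are averaged
    element-wise; callers that want a single table row average the result
    across elements afterwards.
    """
    est = np.asarray(estimates, dtype=float)
    if est.shape[0] < 1:
        raise ValueError("need at least one replication")
    err = est - np.asarray(truth, dtype=float)[None, ...]
    bias = err.mean(axis=0)
    rmse = np.sqrt((err**2).mean(axis=0))
    return bias, rmse


def accr_pccr(alpha_hat, alpha_true):
    """Attribute-wise and whole-pattern correct classification rates."""
    a_hat = np.asarray(alpha_hat)
    a_true = np.asarray(alpha_true)
    if a_hat.shape != a_true.shape:
        raise ValueError("alpha_hat and alpha_true must have the same shape")
    agree = a_hat == a_true
    accr = agree.mean(axis=0)
    pccr = agree.all(axis=1).mean()
    return accr, float(pccr)


@dataclass
class StudyResult:
    """Aggregated metrics for one simulation condition."""

    condition: SimulationCondition
    model: str
    R: int
    bias: dict = field(default_factory=dict)
    rmse: dict = field(default_factory=dict)
    accr: np.ndarray = None
    pccr: float = None
    dic: float = None
    lpml: float = None
    dic_reps: list = None
    lpml_reps: list = None
    pccr_reps: list = None
    scale: str = "reduced"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.bias:
            rows.append({
                "model": self.model, "parameter": name,
                "bias": np.mean(self.bias[name]),
                "rmse": np.mean(self.rmse[name]),
                "N": self.condition.N, "J": self.condition.J,
                "K": self.condition.K, "rho": self.condition.rho,
                "dropout": self.condition.dropout_level,
                "R": self.R, "scale": self.scale,
            })
        return pd.DataFrame(rows)


def _load_study_conditions() -> dict:
    from importlib import resources

    import yaml

    with resources.files("notreached.data").joinpath("studies.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    return {study: [SimulationCondition(**cond) for cond in conds]
            for study, conds in raw.items()}


STUDY_CONDITIONS = _load_study_conditions()

_SCALES = {
    "reduced": {"R": 3, "chain_length": 4_000, "burn_in": 2_000},
    "full": {"R": 30, "chain_length": 10_000, "burn_in": 5_000},
}

# truth entries recoverable as scalars or small vectors from a TruthBundle
_SCALAR_TRUTH = ("eta0", "eta1", "mu_beta", "mu_delta",
                 "sigma_b2", "sigma_bd", "sigma_d2_item",
                 "sigma_hd", "sigma_d2")


def _truth_values(truth, cond):
    p = truth.params
    return {
        "beta": p.items.beta, "delta": p.items.delta,
        "gamma": p.structure.gamma, "lam": p.structure.lam,
        "eta0": p.dropout.eta0, "eta1": p.dropout.eta1,
        "mu_beta": cond.mu_beta, "mu_delta": cond.mu_delta,
        "sigma_b2": cond.Sigma_I[0][0], "sigma_bd": cond.Sigma_I[0][1],
        "sigma_d2_item": cond.Sigma_I[1][1],
        "sigma_hd": cond.sigma_hd, "sigma_d2": cond.sigma_d2,
        "theta_h": p.persons.theta_h, "theta_d": p.persons.theta_d,
    }


def _fit_estimates(est: DinaDropoutModel):
    return {
        "beta": est.beta_, "delta": est.delta_,
        "gamma": est.gamma_, "lam": est.lam_,
        "eta0": est.eta0_, "eta1": est.eta1_,
        "mu_beta": est.mu_beta_, "mu_delta": est.mu_delta_,
        "sigma_b2": est.Sigma_I_[0, 0], "sigma_bd": est.Sigma_I_[0, 1],
        "sigma_d2_item": est.Sigma_I_[1, 1],
        "sigma_hd": est.sigma_hd_, "sigma_d2": est.sigma_d2_,
        "theta_h": est.theta_h_, "theta_d": est.theta_d_,
    }


def fit_condition(cond: SimulationCondition, model: str = "nmar",
                  R: int = 3, chain_length: int = 4_000, burn_in: int = 2_000,
                  n_chains: int = 1, seed: int = 0,
                  compute_fit_metrics: bool = False,
                  scale_label: str = "reduced") -> StudyResult:
    """Simulate R replications of one condition and fit one model variant."""
    per_rep = {}
    accrs, pccrs, dics, lpmls = [], [], [], []
    truths = []
    for r in range(R):
        dataset, truth = simulate_condition(cond, rep_index=r)
        truths.append(truth)
        est = DinaDropoutModel(
            model=model, chain_length=chain_length, burn_in=burn_in,
            n_chains=n_chains, random_state=seed * 1000 + r,
            compute_fit_metrics=compute_fit_metrics,
        ).fit(dataset)
        ests = _fit_estimates(est)
        hodina = model == "hodina"
        for name, val in ests.items():
            if hodina and name in ("eta0", "eta1", "sigma_hd", "sigma_d2", "theta_d"):
                continue
            per_rep.setdefault(name, []).append(np.asarray(val, dtype=float))
        accr, pccr = accr_pccr(est.alpha_, truth.params.persons.alpha)
        accrs.append(accr)
        pccrs.append(pccr)
        if compute_fit_metrics and est.fit_summary_ is not None:
            dics.append(est.fit_summary_.dic)
            lpmls.append(est.fit_summary_.lpml)
    tv = _truth_values(truths[0], cond)
    result = StudyResult(condition=cond, model=model, R=R, scale=scale_label)
    for name, reps in per_rep.items():
        # item- and person-parameter truths differ per replication
        if name in ("theta_h", "theta_d", "beta", "delta"):
            errs = [reps[r] - _truth_values(truths[r], cond)[name]
                    for r in range(R)]
            err = np.stack(errs)
            result.bias[name] = err.mean()
            result.rmse[name] = np.sqrt((err**2).mean())
        else:
            b, rm = bias_rmse(np.stack(reps), tv[name])
            result.bias[name] = np.mean(b)
            result.rmse[name] = np.mean(rm)
    result.accr = np.mean(np.stack(accrs), axis=0)
    result.pccr = float(np.mean(pccrs))
    result.pccr_reps = [float(p) for p in pccrs]
    if dics:
        result.dic = float(np.mean(dics))
        result.lpml = float(np.mean(lpmls))
        result.dic_reps = [float(x) for x in dics]
        result.lpml_reps = [float(x) for x in lpmls]
    return result


def run_study(study: str, scale: str = "reduced", seed: int = 0,
              conditions=None, models=None) -> list:
    """Run one of the simulation studies and return a list of StudyResult.

    Study III fits all three model variants per condition; Studies I and II
    fit the NMAR model only.
    """
    if study not in STUDY_CONDITIONS:
        raise ValueError("study must be one of %s" % list(STUDY_CONDITIONS))
    if scale not in _SCALES:
        raise ValueError("scale must be 'reduced' or 'full'")
    s = _SCALES[scale]
    conds = conditions if conditions is not None else STUDY_CONDITIONS[study]
    model_list = models if models is not None else (
        ["nmar", "mar", "hodina"] if study == "III" else ["nmar"])
    results = []
    for ci, cond in enumerate(conds):
        cond.seed = seed + ci
        for model in model_list:
            results.append(fit_condition(
                cond, model=model, R=s["R"],
                chain_length=s["chain_length"], burn_in=s["burn_in"],
                seed=seed + ci, scale_label=scale,
                compute_fit_metrics=(study == "III")))
    return results


def results_frame(results) -> pd.DataFrame:
    """Long-format table: one row per parameter x condition x model."""
    frames = [r.to_frame() for r in results]
    df = pd.concat(frames, ignore_index=True)
    return df
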