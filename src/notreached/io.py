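"""File I/O, raw-code preprocessing and configuration.

Datasets travel as plain CSV: a response matrix Y with empty cells for
missing responses, a 0/1 missing-indicator matrix D, and the binary Q
matrix.  Raw computer-based assessment exports use the PISA coding scheme
{0: no credit, 1: full credit, 6: not reached, 7: not applicable,
8: invalid, 9: nonresponse}; :func:`recode` applies the study's filtering
rules, which keep only dropout-type missingness: examinees with any 7 or 8
are removed, then examinees with any 9 are removed, and remaining 6-coded
cells become missing with d = 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from notreached.model_core import Dataset, QMatrix

__all__ = ["RAW_CODES", "FilterReport", "recode", "read_dataset",
           "write_dataset", "read_q_matrix", "write_q_matrix",
           "pisa2018_albania_q"]

RAW_CODES = (0, 1, 6, 7, 8, 9)


@dataclass
class FilterReport:
    """Row counts at each stage of the raw-code filter."""

    n_raw: int
    n_removed_invalid: int      # any code 7 (not applicable) or 8 (invalid)
    n_after_invalid: int
    n_removed_nonresponse: int  # any code 9
    n_final: int
    non_monotone_rows: int      # rows where a 6 precedes an answered cell

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def recode(raw, Q: QMatrix, strict: bool = False):
    """Filter and recode a raw coded matrix into a Dataset.

    Returns ``(Dataset, FilterReport)``.  With ``strict=True`` rows whose
    not-reached (6) cells are not a terminal run are rejected; otherwise
    they are kept with a warning count in the report, and every 6 cell is
    treated as missing.
    """
    raw = np.asarray(raw)
    if not np.isin(raw, RAW_CODES).all():
        bad = np.unique(raw[~np.isin(raw, RAW_CODES)])
        raise ValueError("unknown raw codes: %s" % bad)
    n_raw = raw.shape[0]
    keep = ~np.isin(raw, (7, 8)).any(axis=1)
    step1 = raw[keep]
    n_removed_invalid = n_raw - step1.shape[0]
    keep9 = ~(step1 == 9).any(axis=1)
    final = step1[keep9]
    n_removed_nonresponse = step1.shape[0] - final.shape[0]

    D = (final == 6).astype(np.int8)
    non_monotone = int((np.diff(D, axis=1) < 0).any(axis=1).sum())
    if strict and non_monotone:
        raise ValueError(
            "%d rows have a not-reached (6) cell followed by an answered "
            "cell; rerun without strict to keep them" % non_monotone)
    Y = final.astype(float)
    Y[D == 1] = np.nan
    dataset = Dataset(Y=Y, D=D, Q=Q)
    report = FilterReport(
        n_raw=n_raw, n_removed_invalid=n_removed_invalid,
        n_after_invalid=step1.shape[0],
        n_removed_nonresponse=n_removed_nonresponse,
        n_final=final.shape[0], non_monotone_rows=non_monotone)
    return dataset, report


# ---------------------------------------------------------------------------
# CSV round trip


def write_dataset(dataset: Dataset, directory) -> None:
    """Write Y.csv (empty cell = missing), D.csv and Q.csv into a directory."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    J = dataset.J
    cols = [f"item{j+1}" for j in range(J)]
    Y = pd.DataFrame(dataset.Y, columns=cols)
    # keep observed 0/1 as integers in the file
    Y = Y.astype("Int64")
    Y.to_csv(d / "Y.csv", index=False)
    pd.DataFrame(dataset.D, columns=cols).to_csv(d / "D.csv", index=False)
    write_q_matrix(dataset.Q, d / "Q.csv")


def read_dataset(directory) -> Dataset:
    """Read a dataset written by :func:`write_dataset`; validates invariants."""
    d = Path(directory)
    Y = pd.read_csv(d / "Y.csv").to_numpy(dtype=float)
    D = pd.read_csv(d / "D.csv").to_numpy()
    Q = read_q_matrix(d / "Q.csv")
    return Dataset(Y=Y, D=D, Q=Q)


def write_q_matrix(Q: QMatrix, path) -> None:
    cols = [f"attr{k+1}" for k in range(Q.K)]
    pd.DataFrame(Q.entries, columns=cols).to_csv(path, index=False)


def read_q_matrix(path) -> QMatrix:
    return QMatrix(pd.read_csv(path).to_numpy())


def write_manifest(path, **entries) -> None:
    """JSON manifest embedding everything needed to rerun a step."""
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=2, default=str)


def save_draws(draws, directory) -> None:
    """Persist one chain as per-parameter CSV (iteration x component) plus a
    JSON manifest with the run configuration and acceptance rates."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    blocks = {
        "beta": draws.beta, "delta": draws.delta,
        "gamma": draws.gamma, "lam": draws.lam,
    }
    for name, arr in blocks.items():
        cols = [f"{name}{i+1}" for i in range(arr.shape[1])]
        pd.DataFrame(arr, columns=cols).to_csv(d / f"{name}.csv", index=False)
    scalars = pd.DataFrame({
        "eta0": draws.eta0, "eta1": draws.eta1,
        "mu_beta": draws.mu_beta, "mu_delta": draws.mu_delta,
        "sigma_b2": draws.sigma_b2, "sigma_bd": draws.sigma_bd,
        "sigma_d2_item": draws.sigma_d2_item,
        "sigma_hd": draws.sigma_hd, "sigma_d2": draws.sigma_d2,
    })
    scalars.to_csv(d / "scalars.csv", index=False)
    cfg = draws.config
    write_manifest(d / "draws.json", step="draws", model=cfg.model,
                   chain_length=cfg.chain_length, burn_in=cfg.burn_in,
                   seed=cfg.seed, convention=cfg.convention,
                   acceptance={k: float(v) for k, v in draws.acceptance.items()})


def draws_long_frame(draws) -> pd.DataFrame:
    """Flat long-format export (iteration, parameter, value) of the
    monitored traces, for generic MCMC-diagnostics tooling."""
    frames = []
    for name, trace in draws.params().items():
        frames.append(pd.DataFrame({
            "iteration": np.arange(1, len(trace) + 1),
            "parameter": name, "value": trace}))
    return pd.concat(frames, ignore_index=True)


def pisa2018_albania_q() -> QMatrix:
    """Packaged 9-item, 4-attribute Q matrix of the PISA 2018 Albania
    mathematics cluster (change & relationship, quantity, space & shape,
    uncertainty & data)."""
    with resources.files("notreached.data").joinpath("pisa2018_albania_q.csv").open() as fh:
        df = pd.read_csv(fh, index_col=0)
    return QMatrix(df.to_numpy().T)
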