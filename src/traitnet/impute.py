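"""Multiple imputation by chained equations with predictive mean matching.

Each column with missing cells is regressed on all other columns; regression
parameters receive a Bayesian draw (scaled inverse-chi-squared residual
variance, normal coefficients), and every missing cell is filled with the
*observed* value of a donor sampled uniformly from the ``donors`` nearest
predicted means (type-1 matching: observed predictions use the least-squares
coefficients, missing predictions use the drawn coefficients). The sweep
over columns repeats ``maxit`` times and the whole chain runs ``m`` times
independently, yielding m completed tables whose observed cells are
untouched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = ["ImputationSet", "PMMImputer", "pmm_impute"]


@dataclass
class ImputationSet:
    """m completed trait tables plus the settings that produced them."""

    completed_tables: list[pd.DataFrame]
    m: int
    maxit: int
    donors: int
    seed: Optional[int]

    def __iter__(self):
        return iter(self.completed_tables)

    def __len__(self):
        return len(self.completed_tables)


class PMMImputer(BaseEstimator):
    """Chained-equations imputer with predictive-mean-matching donors.

    Parameters mirror the canonical chained-equations defaults: ``m``
    independent chains, ``maxit`` sweeps per chain, ``donors`` nearest
    candidates per missing cell. After :meth:`fit`, ``imputations_`` holds
    the m completed tables; :meth:`transform` returns the first one (the
    full set is the object of interest for pooled downstream analyses).
    """

    def __init__(self, m: int = 5, maxit: int = 50, donors: int = 5,
                 random_state: Optional[int] = None):
        self.m = m
        self.maxit = maxit
        self.donors = donors
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None) -> "PMMImputer":
        X = self._validate(X)
        mask = X.isna().to_numpy()
        data = X.to_numpy(dtype=float)
        rng = np.random.default_rng(self.random_state)
        chains = []
        for _ in range(self.m):
            chain_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
            chains.append(self._run_chain(data, mask, chain_rng))
        self.imputations_ = [
            pd.DataFrame(c, index=X.index, columns=X.columns) for c in chains
        ]
        self.missing_mask_ = pd.DataFrame(mask, index=X.index, columns=X.columns)
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "imputations_"):
            raise ValueError("PMMImputer is not fitted")
        return self.imputations_[0].copy()

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X, y).transform(X)

    def _validate(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X)
        non_numeric = [c for c in X.columns
                       if not np.issubdtype(X[c].dtype, np.number)]
        if non_numeric:
            raise ValueError(f"non-numeric columns cannot be imputed: {non_numeric}")
        n_obs = X.notna().sum(axis=0)
        empty = list(X.columns[n_obs == 0])
        if empty:
            raise ValueError(f"columns entirely missing: {empty}")
        starved = list(X.columns[(n_obs < self.donors) & (n_obs < len(X))])
        if starved:
            raise ValueError(
                f"columns with fewer than donors={self.donors} observed values: "
                f"{starved}"
            )
        if not (X.notna().all(axis=0)).any():
            raise ValueError("need at least one fully observed column")
        return X

    def _run_chain(self, data: np.ndarray, mask: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
        filled = data.copy()
        n, p = data.shape
        cols = [j for j in range(p) if mask[:, j].any()]
        # initial fill: random draws from each column's observed values
        for j in cols:
            obs = data[~mask[:, j], j]
            filled[mask[:, j], j] = rng.choice(obs, size=int(mask[:, j].sum()),
                                               replace=True)
        if not cols:
            return filled
        for _ in range(self.maxit):
            for j in cols:
                filled[:, j] = self._impute_column(filled, data, mask, j, rng)
        return filled

    def _impute_column(self, filled, data, mask, j, rng) -> np.ndarray:
        n, p = filled.shape
        miss = mask[:, j]
        obs = ~miss
        others = [k for k in range(p) if k != j]
        X = np.column_stack([np.ones(n), filled[:, others]])
        y = data[:, j]
        Xo, yo = X[obs], y[obs]
        q = X.shape[1]
        ridge = 1e-8 * np.eye(q)
        xtx = Xo.T @ Xo + ridge
        beta_hat = np.linalg.solve(xtx, Xo.T @ yo)
        resid = yo - Xo @ beta_hat
        df = max(int(obs.sum()) - q, 1)
        sigma2 = float(resid @ resid) / rng.chisquare(df)
        xtx_inv = np.linalg.inv(xtx)
        # symmetrize before Cholesky to absorb round-off
        chol = np.linalg.cholesky((xtx_inv + xtx_inv.T) / 2 + ridge)
        beta_draw = beta_hat + np.sqrt(sigma2) * chol @ rng.standard_normal(q)
        yhat_obs = Xo @ beta_hat
        yhat_mis = X[miss] @ beta_draw
        out = filled[:, j].copy()
        k = min(self.donors, yhat_obs.size)
        for i, yh in zip(np.flatnonzero(miss), yhat_mis):
            d = np.abs(yhat_obs - yh)
            candidates = np.argpartition(d, k - 1)[:k]
            out[i] = yo[rng.choice(candidates)]
        return out


def pmm_impute(
    table: pd.DataFrame,
    m: int = 5,
    maxit: int = 50,
    donors: int = 5,
    seed: Optional[int] = None,
) -> ImputationSet:
    """Impute a trait table m times; thin wrapper over :class:`PMMImputer`."""
    imp = PMMImputer(m=m, maxit=maxit, donors=donors, random_state=seed)
    imp.fit(table)
    return ImputationSet(
        completed_tables=imp.imputations_, m=m, maxit=maxit, donors=donors,
        seed=seed,
    )
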