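"""Backward stepwise linear regression with an exit p-threshold."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["StepwiseResult", "backward_stepwise"]


@dataclass
class StepwiseResult:
    retained: list[str]
    params: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    r2: float
    adj_r2: float
    f_stat: float
    f_p: float
    df_model: int
    df_resid: int
    path: list[dict] = field(default_factory=list)
    dropped_collinear: list[str] = field(default_factory=list)

    @property
    def summary(self) -> dict:
        return {"retained": self.retained, "r2": self.r2,
                "adj_r2": self.adj_r2, "F": self.f_stat, "p": self.f_p,
                "df": (self.df_model, self.df_resid)}


def _drop_collinear(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    dropped = []
    cols = list(X.columns)
    while cols:
        M = np.column_stack([np.ones(len(X))] + [X[c].to_numpy() for c in cols])
        if np.linalg.matrix_rank(M) == M.shape[1]:
            break
        # drop the last column that does not reduce rank when removed
        for c in reversed(cols):
            rest = [k for k in cols if k != c]
            M2 = np.column_stack([np.ones(len(X))] + [X[k].to_numpy() for k in rest])
            if np.linalg.matrix_rank(M2) == np.linalg.matrix_rank(M):
                dropped.append(c)
                cols = rest
                break
        else:  # pragma: no cover
            break
    if dropped:
        warnings.warn(f"dropping collinear predictors before stepping: {dropped}",
                      UserWarning, stacklevel=3)
    return X[cols], dropped


def backward_stepwise(data: pd.DataFrame, outcome: str,
                      predictors: list[str],
                      exit_threshold: float = 0.05) -> StepwiseResult:
    """Backward elimination from the full OLS model.

    Iteratively removes the least significant predictor whose p exceeds the
    exit threshold until every retained term passes; the full elimination
    path is logged.  Requires more observations than candidate predictors.
    """
    if len(data) <= len(predictors):
        raise ValueError("need more observations than candidate predictors")
    y = data[outcome].to_numpy(dtype=float)
    X, dropped = _drop_collinear(data[list(predictors)].astype(float))
    current = list(X.columns)
    path: list[dict] = []
    while True:
        exog = (sm.add_constant(X[current]) if current
                else pd.DataFrame({"const": np.ones(len(y))}))
        model = sm.OLS(y, exog).fit()
        pvals = model.pvalues.drop("const", errors="ignore")
        if pvals.empty or pvals.max() <= exit_threshold:
            break
        worst = pvals.idxmax()
        path.append({"dropped": worst, "p": float(pvals[worst]),
                     "r2_before": float(model.rsquared)})
        current.remove(worst)
    fp = float(model.f_pvalue) if current else float("nan")
    fstat = float(model.fvalue) if current else float("nan")
    return StepwiseResult(
        retained=current,
        params=model.params, tvalues=model.tvalues, pvalues=model.pvalues,
        r2=float(model.rsquared) if current else 0.0,
        adj_r2=float(model.rsquared_adj) if current else 0.0,
        f_stat=fstat, f_p=fp,
        df_model=int(model.df_model), df_resid=int(model.df_resid),
        path=path, dropped_collinear=dropped)
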