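"""Metabolite subset selection per food group: RRR-VIP and LASSO.

RRR-VIP fits a rank-1 reduced rank regression of the food's adjusted intake
on all metabolites and keeps those with VIP strictly greater than the
threshold (default 0.85).  LASSO solves the L1-penalized least-squares path
on standardized predictors and keeps the metabolites with nonzero
coefficients at the penalty minimizing 5-fold cross-validated squared error
(the CV minimum; a one-standard-error rule is available as an option).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold

from .rrr import fit_rrr, vip_scores


class SelectionError(ValueError):
    pass


@dataclass
class SelectionResult:
    """Selected metabolites for one food by one method.

    ``statistic`` holds the VIP score (RRR-VIP, sorted descending) or the
    standardized LASSO coefficient (sorted descending by signed value).
    """

    food: str
    method: str  # "RRR-VIP" or "LASSO"
    selected: list[str]
    statistic: pd.Series
    settings: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.selected)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "food": self.food,
                "method": self.method,
                "metabolite": self.selected,
                "statistic": self.statistic.loc[self.selected].to_numpy(),
            }
        )


def select_by_vip(
    X: pd.DataFrame, y, threshold: float = 0.85, food: str = ""
) -> SelectionResult:
    """Rank-1 RRR of ``y`` on all predictors; keep VIP > threshold (strict)."""
    model = fit_rrr(X, y, rank=1)
    vip = vip_scores(model).vip
    keep = vip[vip > threshold].sort_values(ascending=False)
    return SelectionResult(
        food=food,
        method="RRR-VIP",
        selected=list(keep.index),
        statistic=keep,
        settings={"threshold": threshold, "rank": 1},
    )


def lasso_select(
    X: pd.DataFrame,
    y,
    n_folds: int = 5,
    seed: int = 0,
    rule: str = "min",
    n_alphas: int = 100,
) -> SelectionResult:
    """LASSO with ``n_folds``-fold cross-validated penalty choice.

    Predictors are standardized (unit variance, ddof=1) before penalization
    and the intercept is left unpenalized; coefficients are reported on the
    standardized scale.  ``rule='min'`` takes the CV-error minimum,
    ``rule='1se'`` the sparsest penalty within one standard error of it.
    """
    Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"x{j + 1}" for j in range(Xa.shape[1])
    ]
    ya = np.asarray(y, dtype=float).ravel()
    n = ya.size
    if n < n_folds:
        raise SelectionError(f"need n >= n_folds (n={n}, folds={n_folds})")
    if ya.std() == 0:
        raise SelectionError("constant response: LASSO undefined")
    scale = Xa.std(axis=0, ddof=1)
    if (scale == 0).any():
        bad = [names[j] for j in np.flatnonzero(scale == 0)]
        raise SelectionError(f"zero-variance predictors: {bad}")
    Xs = (Xa - Xa.mean(axis=0)) / scale

    cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fit = LassoCV(alphas=n_alphas, cv=cv, fit_intercept=True).fit(Xs, ya)
    if rule == "min":
        alpha = float(fit.alpha_)
        coef = fit.coef_
    elif rule == "1se":
        mean_mse = fit.mse_path_.mean(axis=1)
        se_mse = fit.mse_path_.std(axis=1, ddof=1) / np.sqrt(n_folds)
        i_min = int(np.argmin(mean_mse))
        limit = mean_mse[i_min] + se_mse[i_min]
        # alphas_ is decreasing: the first index within the limit is sparsest
        i_1se = int(np.flatnonzero(mean_mse <= limit)[0])
        alpha = float(fit.alphas_[i_1se])
        from sklearn.linear_model import Lasso

        coef = Lasso(alpha=alpha, fit_intercept=True).fit(Xs, ya).coef_
    else:
        raise SelectionError(f"unknown penalty rule {rule!r}")

    stat = pd.Series(coef, index=names, name="coefficient")
    keep = stat[stat != 0.0].sort_values(ascending=False)
    return SelectionResult(
        food="",
        method="LASSO",
        selected=list(keep.index),
        statistic=keep,
        settings={
            "n_folds": n_folds,
            "seed": seed,
            "alpha": alpha,
            "rule": rule,
        },
    )


def select_both(
    X: pd.DataFrame,
    y,
    food: str,
    vip_threshold: float = 0.85,
    lasso_folds: int = 5,
    seed: int = 0,
) -> dict[str, SelectionResult]:
    vip_sel = select_by_vip(X, y, threshold=vip_threshold, food=food)
    lasso_sel = lasso_select(X, y, n_folds=lasso_folds, seed=seed)
    lasso_sel.food = food
    return {"RRR-VIP": vip_sel, "LASSO": lasso_sel}


def selections_to_csv(results: list[SelectionResult], path) -> None:
    """One row per selected metabolite: food, method, metabolite, statistic."""
    frames = [r.to_frame() for r in results]
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["food", "method", "metabolite", "statistic"])
    )
    out.to_csv(path, index=False)
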