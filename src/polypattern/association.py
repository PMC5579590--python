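"""Partial Pearson correlation screening of metabolite-food associations.

Correlations are computed between center/batch-residualized log metabolite
excretions and energy-adjusted log intakes, conditional on sex, BMI and age.
Food groups qualify as "polyphenol-rich" (and enter the pattern analysis)
when at least ``min_significant`` metabolites are significantly positively
correlated and at least one correlation reaches ``min_r``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocessing import CovariateSet, IntakeTable, MetaboliteMatrix


class AssociationError(ValueError):
    pass


@dataclass
class CorrelationTable:
    """Foods x metabolites partial correlations with two-sided p-values."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: int
    covariate_names: list[str]

    @property
    def foods(self) -> list[str]:
        return list(self.r.index)

    @property
    def metabolites(self) -> list[str]:
        return list(self.r.columns)

    def to_csv(self, r_path, p_path=None) -> None:
        # conventional layout: metabolites as rows, foods as columns
        self.r.T.to_csv(r_path)
        if p_path is not None:
            self.p.T.to_csv(p_path)


def _residuals_on(z: np.ndarray | None, v: np.ndarray) -> np.ndarray:
    n = v.shape[0]
    if z is None or z.size == 0:
        X = np.ones((n, 1))
    else:
        X = np.column_stack([np.ones(n), z])
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta


def partial_pearson(
    x: np.ndarray, y: np.ndarray, Z: np.ndarray | None = None
) -> tuple[float, float]:
    """Partial Pearson correlation of ``x`` and ``y`` given covariates ``Z``.

    Both variables are residualized on an intercept plus ``Z``; the Pearson
    correlation of the residuals is tested with ``t = r * sqrt(df / (1 - r^2))``
    on ``df = n - 2 - k`` degrees of freedom (k covariates), two-sided.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    if y.size != n:
        raise AssociationError(f"length mismatch: {n} vs {y.size}")
    if Z is not None:
        Z = np.asarray(Z, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        if Z.shape[0] != n:
            raise AssociationError("covariate rows do not match x/y length")
    k = 0 if Z is None else Z.shape[1]
    if n <= k + 2:
        raise AssociationError(f"need n > k + 2 (n={n}, k={k})")
    rx = _residuals_on(Z, x)
    ry = _residuals_on(Z, y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise AssociationError("zero residual variance: correlation undefined")
    r = float(np.clip(np.dot(rx, ry) / (n * sx * sy), -1.0, 1.0))
    df = n - 2 - k
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p


def correlation_screen(
    metabolites: MetaboliteMatrix,
    intakes: IntakeTable,
    cov: CovariateSet,
) -> CorrelationTable:
    """Partial Pearson correlation of every (food, metabolite) pair.

    Vectorized: all columns are residualized on [1, sex, bmi, age] once and
    the residual cross-correlation matrix is formed; this is exactly the
    pairwise :func:`partial_pearson` computation.
    """
    metabolites.require_stage("residualized")
    if intakes.stage != "adjusted":
        raise AssociationError("intakes must be energy-adjusted before screening")
    subj = metabolites.subjects
    if not subj.equals(intakes.values.index) or not subj.equals(cov.frame.index):
        raise AssociationError("subject indices of inputs do not match")
    Z = cov.matrix()
    n, k = Z.shape[0], Z.shape[1]
    M = _residuals_on(Z, metabolites.values.to_numpy(dtype=float))
    F = _residuals_on(Z, intakes.values.to_numpy(dtype=float))
    Ms = M.std(axis=0)
    Fs = F.std(axis=0)
    if (Ms == 0).any() or (Fs == 0).any():
        raise AssociationError("zero residual variance in some column")
    R = (F.T @ M) / (n * np.outer(Fs, Ms))
    R = np.clip(R, -1.0, 1.0)
    df = n - 2 - k
    with np.errstate(divide="ignore"):
        T = R * np.sqrt(df / (1.0 - R * R))
    P = 2.0 * stats.t.sf(np.abs(T), df)
    P[np.abs(R) >= 1.0] = 0.0
    foods = intakes.food_names
    mets = metabolites.metabolite_names
    return CorrelationTable(
        r=pd.DataFrame(R, index=foods, columns=mets),
        p=pd.DataFrame(P, index=foods, columns=mets),
        n=n,
        covariate_names=["sex", "bmi", "age"],
    )


def preselect_food_groups(
    tab: CorrelationTable,
    alpha: float = 0.05,
    min_significant: int = 5,
    min_r: float = 0.3,
) -> list[str]:
    """Food groups with >= ``min_significant`` significantly positively
    correlated metabolites and at least one (signed) r >= ``min_r``.

    Significance is counted over positive correlations only: the screen
    looks for biomarker candidates, i.e. metabolites whose excretion rises
    with intake.
    """
    selected = []
    for food in tab.foods:
        r = tab.r.loc[food]
        p = tab.p.loc[food]
        n_sig_pos = int(((p < alpha) & (r > 0)).sum())
        if n_sig_pos >= min_significant and r.max() >= min_r:
            selected.append(food)
    return selected
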