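"""Preprocessing of urinary metabolite excretions and food-intake tables.

The fixed transformation chain for metabolites is

    raw -> censor-handled -> logged -> imputed -> residualized

implemented by :func:`replace_below_loq` (below-LOQ values set to LOQ/2),
:func:`exclude_censored_metabolites` (drop metabolites almost entirely
censored), :func:`log_transform`, :func:`em_impute` (multivariate-normal EM
for missing-at-random values) and :func:`residualize` (general-linear-model
residuals removing center and laboratory-batch effects).  Intakes are
``log(x + 1)`` transformed and energy-adjusted by residualization.  Each
stage stamps its tag and refuses out-of-order input.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("polypattern")

STAGES = ("raw", "censor-handled", "logged", "imputed", "residualized")
INTAKE_STAGES = ("raw", "logged", "adjusted")


class StageError(ValueError):
    """Raised when a transform is applied out of pipeline order."""


class PreprocessingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# containers


@dataclass
class MetaboliteMatrix:
    """Subjects x metabolites excretions (umol/24 h raw; log or residual
    units after transforms) with censoring/missingness masks and
    center/batch labels.

    Missing entries are NaN in ``values`` until the imputed stage; the
    original missingness is retained in :attr:`missing`.
    """

    values: pd.DataFrame
    below_loq: pd.DataFrame
    loq: pd.Series
    center: pd.Series
    batch: pd.Series
    stage: str = "raw"
    missing: pd.DataFrame | None = None
    em_info: dict | None = None

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise StageError(f"unknown stage {self.stage!r}")
        if self.below_loq.shape != self.values.shape:
            raise PreprocessingError("below_loq mask shape differs from values")
        if self.missing is None:
            self.missing = self.values.isna()

    @property
    def metabolite_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def subjects(self) -> pd.Index:
        return self.values.index

    def require_stage(self, *stages: str) -> None:
        if self.stage not in stages:
            raise StageError(
                f"operation requires stage in {stages}, matrix is at {self.stage!r}"
            )


@dataclass
class IntakeTable:
    """Subjects x food-groups intakes (g/day) for one instrument.

    ``raw`` is always retained; consumer status is derived from it as
    intake > 0.  ``values`` holds the current working representation
    (raw, logged, or energy-adjusted residuals).
    """

    raw: pd.DataFrame
    instrument: str
    energy: pd.Series
    values: pd.DataFrame | None = None
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.instrument not in ("24-HDR", "DQ"):
            raise PreprocessingError(f"unknown instrument {self.instrument!r}")
        if (self.raw.to_numpy() < 0).any():
            raise PreprocessingError("raw intakes must be >= 0")
        if self.values is None:
            self.values = self.raw.copy()
        if self.stage not in INTAKE_STAGES:
            raise StageError(f"unknown intake stage {self.stage!r}")

    @property
    def consumer(self) -> pd.DataFrame:
        return self.raw > 0

    @property
    def food_names(self) -> list[str]:
        return list(self.raw.columns)


@dataclass
class CovariateSet:
    """Subject covariates: sex (binary), BMI (kg/m2), age (years)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing_cols = {"sex", "bmi", "age"} - set(self.frame.columns)
        if missing_cols:
            raise PreprocessingError(f"covariates missing columns {sorted(missing_cols)}")
        if self.frame[["sex", "bmi", "age"]].isna().any().any():
            raise PreprocessingError("covariates contain absent values")
        if (self.frame["bmi"] <= 0).any() or (self.frame["age"] <= 0).any():
            raise PreprocessingError("bmi and age must be positive")

    def matrix(self) -> np.ndarray:
        return self.frame[["sex", "bmi", "age"]].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# censoring


def replace_below_loq(m: MetaboliteMatrix) -> MetaboliteMatrix:
    """Replace every below-LOQ value by LOQ/2 (half-LOQ single imputation)."""
    m.require_stage("raw")
    values = m.values.copy()
    for col in values.columns:
        flagged = m.below_loq[col].to_numpy()
        if not flagged.any():
            continue
        loq = m.loq.get(col, np.nan)
        if not np.isfinite(loq):
            raise PreprocessingError(f"metabolite {col!r} has flagged values but no LOQ")
        values.loc[flagged, col] = loq / 2.0
    out = replace(m, values=values, stage="censor-handled")
    out.missing = m.missing.copy()
    return out


def exclude_censored_metabolites(
    m: MetaboliteMatrix, threshold: float = 0.98
) -> MetaboliteMatrix:
    """Drop metabolites whose below-LOQ fraction (among observed entries)
    is >= ``threshold``; survivor order is preserved."""
    m.require_stage("raw", "censor-handled")
    observed = ~m.missing
    n_obs = observed.sum(axis=0).replace(0, np.nan)
    frac = (m.below_loq & observed).sum(axis=0) / n_obs
    keep = [c for c in m.values.columns if not frac[c] >= threshold]
    dropped = [c for c in m.values.columns if c not in keep]
    if dropped:
        logger.info("excluding %d/%d metabolites with >= %.0f%% below LOQ: %s",
                    len(dropped), m.values.shape[1], 100 * threshold, dropped)
    if not keep:
        warnings.warn("all metabolites excluded by the censoring filter")
    out = replace(
        m,
        values=m.values[keep].copy(),
        below_loq=m.below_loq[keep].copy(),
        loq=m.loq[keep].copy(),
    )
    out.missing = m.missing[keep].copy()
    return out


# ---------------------------------------------------------------------------
# log transform


def log_transform(values: pd.DataFrame, offset: float = 0.0) -> pd.DataFrame:
    """Elementwise natural log of ``values + offset``; NaN stays NaN."""
    arr = values.to_numpy(dtype=float) + offset
    bad = (arr <= 0) & ~np.isnan(arr)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise PreprocessingError(
            f"nonpositive value at row {values.index[i]!r}, column "
            f"{values.columns[j]!r}: log undefined"
        )
    return pd.DataFrame(np.log(arr), index=values.index, columns=values.columns)


def log_metabolites(m: MetaboliteMatrix) -> MetaboliteMatrix:
    m.require_stage("censor-handled")
    out = replace(m, values=log_transform(m.values, offset=0.0), stage="logged")
    out.missing = m.missing.copy()
    return out


# ---------------------------------------------------------------------------
# EM imputation


class EMConvergenceError(RuntimeError):
    def __init__(self, msg, last_change):
        super().__init__(msg)
        self.last_change = last_change


def _mvn_em(
    X: np.ndarray, tol: float, max_iter: int, ridge: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """EM for a multivariate normal with values missing at random.

    Returns (mean, covariance, completed matrix, info).  Rows are grouped by
    missing pattern; the M-step covariance includes the conditional-variance
    correction and a small ridge for stability.
    """
    n, p = X.shape
    obs = ~np.isnan(X)
    mu = np.nanmean(X, axis=0)
    X0 = np.where(obs, X, mu)
    sigma = np.cov(X0, rowvar=False, ddof=1)
    sigma = np.atleast_2d(sigma) + ridge * np.trace(np.atleast_2d(sigma)) / p * np.eye(p)

    patterns: dict[bytes, np.ndarray] = {}
    for i in range(n):
        patterns.setdefault(obs[i].tobytes(), []).append(i)
    patterns = {k: np.asarray(v) for k, v in patterns.items()}

    loglik = -np.inf
    info = {"n_iter": 0, "final_change": np.nan, "final_loglik_change": np.nan}
    for it in range(1, max_iter + 1):
        Xc = np.where(obs, X, 0.0)
        S_corr = np.zeros((p, p))
        new_loglik = 0.0
        for key, rows in patterns.items():
            o = np.frombuffer(key, dtype=bool)
            m_ = ~o
            xo = X[np.ix_(rows, o)]
            if m_.any():
                Soo = sigma[np.ix_(o, o)]
                Smo = sigma[np.ix_(m_, o)]
                sol = np.linalg.solve(Soo, (xo - mu[o]).T)  # |o| x rows
                cond_mean = mu[m_][None, :] + (Smo @ sol).T
                Xc[np.ix_(rows, m_)] = cond_mean
                cond_cov = sigma[np.ix_(m_, m_)] - Smo @ np.linalg.solve(Soo, Smo.T)
                S_corr[np.ix_(m_, m_)] += len(rows) * cond_cov
            else:
                Soo = sigma[np.ix_(o, o)]
            # observed-data log-likelihood for this pattern
            if o.any():
                sign, logdet = np.linalg.slogdet(Soo)
                dev = xo - mu[o]
                maha = np.einsum("ij,ji->i", dev, np.linalg.solve(Soo, dev.T))
                new_loglik += float(
                    -0.5 * (len(rows) * (o.sum() * np.log(2 * np.pi) + logdet)
                            + maha.sum())
                )
        mu_new = Xc.mean(axis=0)
        dev = Xc - mu_new
        sigma_new = (dev.T @ dev + S_corr) / n
        sigma_new += ridge * np.trace(sigma_new) / p * np.eye(p)
        change = max(
            float(np.max(np.abs(mu_new - mu))), float(np.max(np.abs(sigma_new - sigma)))
        )
        info.update(
            n_iter=it,
            final_change=change,
            final_loglik_change=new_loglik - loglik,
        )
        mu, sigma, loglik = mu_new, sigma_new, new_loglik
        if change < tol:
            break
    else:
        raise EMConvergenceError(
            f"EM did not converge in {max_iter} iterations "
            f"(last parameter change {info['final_change']:.3e})",
            info["final_change"],
        )

    # final completion at the converged parameters
    Xc = np.where(obs, X, 0.0)
    for key, rows in patterns.items():
        o = np.frombuffer(key, dtype=bool)
        m_ = ~o
        if not m_.any():
            continue
        Soo = sigma[np.ix_(o, o)]
        Smo = sigma[np.ix_(m_, o)]
        sol = np.linalg.solve(Soo, (X[np.ix_(rows, o)] - mu[o]).T)
        Xc[np.ix_(rows, m_)] = mu[m_][None, :] + (Smo @ sol).T
    return mu, sigma, Xc, info


def em_impute(
    m: MetaboliteMatrix,
    tol: float = 1e-6,
    max_iter: int = 500,
    ridge: float = 1e-8,
) -> MetaboliteMatrix:
    """Impute missing log-abundances by their multivariate-normal conditional
    expectations at the EM-converged mean and covariance.

    Observed entries are preserved exactly.  The returned matrix carries
    ``em_info`` with the iteration count, final parameter change, final
    log-likelihood change, and the fitted (mean, covariance).
    """
    m.require_stage("logged")
    X = m.values.to_numpy(dtype=float)
    n_obs_per_col = (~np.isnan(X)).sum(axis=0)
    if (n_obs_per_col < 2).any():
        bad = [c for c, k in zip(m.values.columns, n_obs_per_col) if k < 2]
        raise PreprocessingError(f"columns with < 2 observed values: {bad}")
    if not np.isnan(X).any():
        out = replace(m, values=m.values.copy(), stage="imputed")
        out.missing = m.missing.copy()
        out.em_info = {"n_iter": 0, "final_change": 0.0, "final_loglik_change": 0.0}
        return out
    mu, sigma, Xc, info = _mvn_em(X, tol=tol, max_iter=max_iter, ridge=ridge)
    info = dict(info, mean=mu, covariance=sigma)
    out = replace(
        m,
        values=pd.DataFrame(Xc, index=m.values.index, columns=m.values.columns),
        stage="imputed",
    )
    out.missing = m.missing.copy()
    out.em_info = info
    logger.info("EM imputation converged in %d iterations (delta %.2e)",
                info["n_iter"], info["final_change"])
    return out


# ---------------------------------------------------------------------------
# residualization


def build_design(design: pd.DataFrame) -> pd.DataFrame:
    """Intercept + dummy-encoded categoricals + numeric covariates."""
    parts = [pd.Series(1.0, index=design.index, name="intercept")]
    for col in design.columns:
        s = design[col]
        if s.dtype.kind in "OUSb" or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            parts.append(dummies)
        else:
            parts.append(s.astype(float))
    return pd.concat(parts, axis=1)


def _aliased_columns(X: pd.DataFrame) -> list[str]:
    aliased, rank = [], 0
    arr = X.to_numpy(dtype=float)
    for j, col in enumerate(X.columns):
        r = np.linalg.matrix_rank(arr[:, : j + 1])
        if r == rank:
            aliased.append(col)
        rank = r
    return aliased


def residualize(values: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Columnwise least-squares residuals from regression on
    intercept + ``design`` (categoricals dummy-encoded)."""
    if values.isna().any().any():
        raise PreprocessingError("residualize requires complete values (impute first)")
    X = build_design(design.loc[values.index])
    Xa = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xa) < Xa.shape[1]:
        raise PreprocessingError(
            f"rank-deficient design; aliased columns: {_aliased_columns(X)}"
        )
    beta, *_ = np.linalg.lstsq(Xa, values.to_numpy(dtype=float), rcond=None)
    resid = values.to_numpy(dtype=float) - Xa @ beta
    return pd.DataFrame(resid, index=values.index, columns=values.columns)


def residualize_metabolites(m: MetaboliteMatrix) -> MetaboliteMatrix:
    """Remove center and batch effects from imputed log-abundances."""
    m.require_stage("imputed")
    design = pd.DataFrame({"center": m.center, "batch": m.batch})
    out = replace(m, values=residualize(m.values, design), stage="residualized")
    out.missing = m.missing.copy()
    out.em_info = m.em_info
    return out


# ---------------------------------------------------------------------------
# full chains


def preprocess_metabolites(
    m: MetaboliteMatrix,
    exclusion_fraction: float = 0.98,
    em_tol: float = 1e-6,
    em_max_iter: int = 500,
) -> MetaboliteMatrix:
    """raw -> censor-handled -> (exclusion) -> logged -> imputed -> residualized."""
    m = replace_below_loq(m)
    m = exclude_censored_metabolites(m, threshold=exclusion_fraction)
    m = log_metabolites(m)
    m = em_impute(m, tol=em_tol, max_iter=em_max_iter)
    return residualize_metabolites(m)


def log_intakes(t: IntakeTable, offset: float = 1.0) -> IntakeTable:
    t_new = replace(t, values=log_transform(t.raw, offset=offset), stage="logged")
    return t_new


def adjust_intakes_for_energy(t: IntakeTable) -> IntakeTable:
    """Residualize log intakes on (untransformed) energy intake."""
    if t.stage != "logged":
        raise StageError(f"energy adjustment requires logged intakes, got {t.stage!r}")
    design = pd.DataFrame({"energy": t.energy})
    return replace(t, values=residualize(t.values, design), stage="adjusted")


def preprocess_intakes(t: IntakeTable, offset: float = 1.0) -> IntakeTable:
    """log(x + offset) then energy adjustment by GLM residuals."""
    return adjust_intakes_for_energy(log_intakes(t, offset=offset))
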