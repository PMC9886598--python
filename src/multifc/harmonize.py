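"""Parametric empirical-Bayes ComBat harmonization of feature tables.

The model per feature v and site i is the Johnson location/scale model

    y_ijv = alpha_v + x_ij' beta_v + gamma_iv + delta_iv eps_ijv,

with additive site effects gamma and multiplicative site effects delta.
Biological covariates (age, sex, group) enter the mean model so that real
group/age/sex differences are preserved while scanner effects are removed.
Site effects are standardized, given normal (gamma) and inverse-gamma
(delta^2) priors whose hyperparameters are estimated across features by
method of moments, and shrunk via iterated conditional-posterior updates.
The adjusted data are

    y*_ijv = sigma_v / delta*_iv * (z_ijv - gamma*_iv) + alpha_v + x_ij' beta_v.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import FEATURE_COLUMNS, validate_feature_table

__all__ = ["CombatModel", "fit_combat", "apply_combat", "harmonize_table"]

DEFAULT_COVARIATES = ("age", "sex", "group")
_CONV_TOL = 1e-4
_MAX_ITER = 200


@dataclass
class CombatModel:
    """Fitted ComBat parameters for one feature set."""

    feature_names: tuple[str, ...]
    covariate_names: tuple[str, ...]
    site_order: tuple[str, ...]
    site_sizes: dict[str, int]
    age_center: float
    alpha: np.ndarray  # (F,) grand intercept per feature
    beta: np.ndarray  # (C, F) covariate coefficients
    sigma2: np.ndarray  # (F,) pooled residual variance
    gamma_hat: np.ndarray  # (S, F) naive standardized site means
    delta2_hat: np.ndarray  # (S, F) naive standardized site variances
    gamma_star: np.ndarray  # (S, F) EB-shrunk additive effects
    delta2_star: np.ndarray  # (S, F) EB-shrunk squared multiplicative effects
    gamma_bar: np.ndarray  # (S,) prior mean of gamma
    tau2: np.ndarray  # (S,) prior variance of gamma
    lam: np.ndarray  # (S,) inverse-gamma shape (a) of the delta^2 prior
    theta: np.ndarray  # (S,) inverse-gamma rate (b) of the delta^2 prior
    n_iter: dict[str, int] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "feature_names": list(self.feature_names),
            "covariate_names": list(self.covariate_names),
            "site_order": list(self.site_order),
            "site_sizes": self.site_sizes,
            "age_center": self.age_center,
            "alpha": self.alpha.tolist(),
            "beta": self.beta.tolist(),
            "sigma2": self.sigma2.tolist(),
            "gamma_star": self.gamma_star.tolist(),
            "delta2_star": self.delta2_star.tolist(),
            "gamma_bar": self.gamma_bar.tolist(),
            "tau2": self.tau2.tolist(),
            "lam": self.lam.tolist(),
            "theta": self.theta.tolist(),
            "n_iter": self.n_iter,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _covariate_matrix(
    df: pd.DataFrame, covariates: tuple[str, ...], age_center: float
) -> np.ndarray:
    cols = []
    for name in covariates:
        v = df[name]
        if name == "sex" and v.dtype == object:
            v = v.map({"F": 0, "M": 1})
        v = v.to_numpy(dtype=float)
        if name == "age":
            v = v - age_center
        cols.append(v)
    return np.column_stack(cols) if cols else np.empty((len(df), 0))


def fit_combat(
    features: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    feature_names: tuple[str, ...] = FEATURE_COLUMNS,
) -> CombatModel:
    """Fit the parametric EB ComBat model on a feature table.

    The table needs a ``site`` column, the covariate columns, and the
    feature columns.  Age is centered before regression; site effects are
    constrained to a site-size-weighted zero mean, which makes alpha the
    grand intercept.
    """
    for c in ("site", *covariates):
        if c not in features.columns:
            raise ValueError(f"feature table lacks required column {c!r}")
    sites = tuple(pd.unique(features["site"]))
    if len(sites) < 2:
        raise ValueError("nothing to harmonize: ComBat needs at least 2 sites")
    counts = features["site"].value_counts()
    small = counts[counts < 2]
    if not small.empty:
        raise ValueError(f"every site needs >= 2 subjects; too small: {small.index.tolist()}")

    Y = features.loc[:, list(feature_names)].to_numpy(dtype=float)  # (N, F)
    if not np.isfinite(Y).all():
        raise ValueError("feature matrix contains non-finite values")
    N, F = Y.shape
    age_center = float(features["age"].mean()) if "age" in covariates else 0.0
    X = _covariate_matrix(features, covariates, age_center)  # (N, C)
    site_idx = np.array([sites.index(s) for s in features["site"]])
    S = len(sites)
    B = np.zeros((N, S))
    B[np.arange(N), site_idx] = 1.0
    n_i = B.sum(axis=0)

    design = np.column_stack([B, X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        # identify which covariate columns are collinear with the rest
        bad = []
        for j, name in enumerate(covariates):
            reduced = np.delete(design, S + j, axis=1)
            if np.linalg.matrix_rank(reduced) == np.linalg.matrix_rank(design):
                bad.append(name)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad or 'site block'}")

    coef, *_ = np.linalg.lstsq(design, Y, rcond=None)
    site_means = coef[:S]  # (S, F)
    beta = coef[S:]  # (C, F)
    alpha = (n_i / N) @ site_means  # grand intercept, n_i-weighted

    fitted = design @ coef
    sigma2 = ((Y - fitted) ** 2).mean(axis=0)  # pooled over all subjects
    if np.any(sigma2 <= 0):
        raise ValueError("a feature has zero residual variance; cannot standardize")

    stand_mean = alpha[None, :] + X @ beta  # (N, F)
    Z = (Y - stand_mean) / np.sqrt(sigma2)[None, :]

    gamma_hat = np.vstack([Z[site_idx == i].mean(axis=0) for i in range(S)])
    delta2_hat = np.vstack([Z[site_idx == i].var(axis=0, ddof=1) for i in range(S)])

    gamma_bar = gamma_hat.mean(axis=1)
    tau2 = gamma_hat.var(axis=1, ddof=1)
    m = delta2_hat.mean(axis=1)
    s2 = delta2_hat.var(axis=1, ddof=1)
    lam = (2.0 * s2 + m**2) / s2
    theta = (m * s2 + m**3) / s2

    gamma_star = np.empty_like(gamma_hat)
    delta2_star = np.empty_like(delta2_hat)
    n_iter: dict[str, int] = {}
    for i in range(S):
        g_old = gamma_hat[i].copy()
        d_old = delta2_hat[i].copy()
        zi = Z[site_idx == i]  # (n_i, F)
        n = zi.shape[0]
        it = 0
        while it < _MAX_ITER:
            it += 1
            g_new = (n * tau2[i] * gamma_hat[i] + d_old * gamma_bar[i]) / (
                n * tau2[i] + d_old
            )
            sum2 = ((zi - g_new[None, :]) ** 2).sum(axis=0)
            d_new = (theta[i] + 0.5 * sum2) / (n / 2.0 + lam[i] - 1.0)
            change = max(
                np.max(np.abs(g_new - g_old) / np.abs(g_old)),
                np.max(np.abs(d_new - d_old) / d_old),
            )
            g_old, d_old = g_new, d_new
            if change < _CONV_TOL:
                break
        gamma_star[i] = g_old
        delta2_star[i] = d_old
        n_iter[sites[i]] = it

    return CombatModel(
        feature_names=tuple(feature_names),
        covariate_names=tuple(covariates),
        site_order=sites,
        site_sizes={s: int(counts[s]) for s in sites},
        age_center=age_center,
        alpha=alpha,
        beta=beta,
        sigma2=sigma2,
        gamma_hat=gamma_hat,
        delta2_hat=delta2_hat,
        gamma_star=gamma_star,
        delta2_star=delta2_star,
        gamma_bar=gamma_bar,
        tau2=tau2,
        lam=lam,
        theta=theta,
        n_iter=n_iter,
    )


def apply_combat(model: CombatModel, features: pd.DataFrame) -> pd.DataFrame:
    """Remove the fitted site effects; covariate columns pass through."""
    unseen = set(features["site"]) - set(model.site_order)
    if unseen:
        raise KeyError(f"sites not present in the fitted model: {sorted(unseen)}")
    Y = features.loc[:, list(model.feature_names)].to_numpy(dtype=float)
    X = _covariate_matrix(features, model.covariate_names, model.age_center)
    site_idx = np.array([model.site_order.index(s) for s in features["site"]])

    stand_mean = model.alpha[None, :] + X @ model.beta
    Z = (Y - stand_mean) / np.sqrt(model.sigma2)[None, :]
    adjusted = (Z - model.gamma_star[site_idx]) / np.sqrt(model.delta2_star[site_idx])
    Y_star = adjusted * np.sqrt(model.sigma2)[None, :] + stand_mean

    out = features.copy()
    out.loc[:, list(model.feature_names)] = Y_star
    return out


def harmonize_table(
    features: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> tuple[pd.DataFrame, CombatModel]:
    """Fit-and-apply convenience wrapper for the standard feature table."""
    validate_feature_table(features)
    model = fit_combat(features, covariates=covariates)
    return apply_combat(model, features), model
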