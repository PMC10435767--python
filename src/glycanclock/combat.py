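"""Parametric empirical-Bayes batch correction (ComBat) for log-scale
glycan measurements.

The model per peak g and batch i is

    y_ijg = alpha_g + X beta_g + gamma_ig + delta_ig * eps_ijg

with additive batch location effects gamma and multiplicative scale
effects delta on the standardized residual scale. gamma_ig are shrunk
toward a normal prior and delta_ig^2 toward an inverse-gamma prior, both
estimated by moments across peaks, via the standard iterative EB
equations; the adjusted data subtract gamma* and divide by delta* before
restoring the pooled location/scale model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class BatchModel:
    """Fitted batch-effect model: EB-shrunk per-batch location (gamma) and
    scale (delta) per peak, plus the prior hyperparameters."""

    batches: list
    gamma_star: pd.DataFrame   # batches x peaks, additive on standardized scale
    delta_star: pd.DataFrame   # batches x peaks, multiplicative (>0)
    gamma_bar: pd.Series       # per-batch normal prior mean
    tau_sq: pd.Series          # per-batch normal prior variance
    lambda_: pd.Series         # per-batch inverse-gamma shape
    theta: pd.Series           # per-batch inverse-gamma scale


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def _it_sol(
    z: np.ndarray,
    g_hat: np.ndarray,
    d_hat: np.ndarray,
    g_bar: float,
    t2: float,
    a: float,
    b: float,
    conv: float = 1e-4,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterate the EB posterior equations for one batch.

    z: standardized data for this batch (n_i x G), NaN-free.
    """
    n = np.full(z.shape[1], z.shape[0], dtype=float)
    g_old, d_old = g_hat.copy(), d_hat.copy()
    change = 1.0
    while change > conv:
        g_new = (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)
        sum2 = ((z - g_new) ** 2).sum(axis=0)
        d_new = (0.5 * sum2 + b) / (n / 2 + a - 1)
        change = max(
            np.abs(g_new - g_old).max() / np.abs(g_old).max() if np.abs(g_old).max() > 0 else 0.0,
            np.abs(d_new - d_old).max() / d_old.max(),
        )
        g_old, d_old = g_new, d_new
    return g_old, d_old


def combat(
    data: pd.DataFrame,
    batch: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, BatchModel]:
    """Remove batch effects from ``data`` (samples x peaks, log scale).

    ``covariates`` (samples x p, numeric, no intercept) are biological
    effects to preserve. Returns the adjusted table and the fitted
    BatchModel. With a single batch the data are returned unchanged and
    the model is the identity.
    """
    batch = batch.loc[data.index]
    levels = sorted(pd.unique(batch), key=str)
    n, n_peaks = data.shape
    counts = batch.value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"batches with fewer than 2 samples: {small}")

    if len(levels) == 1:
        ident = BatchModel(
            batches=levels,
            gamma_star=pd.DataFrame(0.0, index=levels, columns=data.columns),
            delta_star=pd.DataFrame(1.0, index=levels, columns=data.columns),
            gamma_bar=pd.Series(0.0, index=levels),
            tau_sq=pd.Series(0.0, index=levels),
            lambda_=pd.Series(np.nan, index=levels),
            theta=pd.Series(np.nan, index=levels),
        )
        return data.copy(), ident

    # design: batch indicators + optional covariates
    batch_design = pd.get_dummies(pd.Categorical(batch, categories=levels)).astype(float)
    batch_design.index = data.index
    batch_design.columns = levels
    if covariates is not None and covariates.shape[1] > 0:
        cov = covariates.loc[data.index].astype(float)
        design = pd.concat([batch_design, cov], axis=1)
    else:
        design = batch_design
    X = design.to_numpy()
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "design matrix is rank deficient: a batch is confounded with a "
            "covariate to preserve"
        )

    Y = data.to_numpy(dtype=float)
    beta_hat, *_ = np.linalg.lstsq(X, Y, rcond=None)
    n_batches = len(levels)
    sizes = np.array([counts[b] for b in levels], dtype=float)
    grand_mean = (sizes / n) @ beta_hat[:n_batches]

    stand_mean = np.outer(np.ones(n), grand_mean)
    if X.shape[1] > n_batches:
        stand_mean = stand_mean + X[:, n_batches:] @ beta_hat[n_batches:]
    var_pooled = ((Y - X @ beta_hat) ** 2).mean(axis=0)
    if (var_pooled <= 0).any():
        raise ValueError("zero residual variance in at least one peak")
    Z = (Y - stand_mean) / np.sqrt(var_pooled)

    gamma_hat = np.linalg.lstsq(batch_design.to_numpy(), Z, rcond=None)[0]
    delta_hat = np.vstack([
        Z[(batch == b).to_numpy()].var(axis=0, ddof=1) for b in levels
    ])

    gamma_bar = gamma_hat.mean(axis=1)
    tau_sq = gamma_hat.var(axis=1, ddof=0)  # population moment, per combat.py lineage
    a_prior = np.array([_aprior(delta_hat[i]) for i in range(n_batches)])
    b_prior = np.array([_bprior(delta_hat[i]) for i in range(n_batches)])

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    for i, b in enumerate(levels):
        zi = Z[(batch == b).to_numpy()]
        gamma_star[i], delta_star[i] = _it_sol(
            zi, gamma_hat[i], delta_hat[i], gamma_bar[i], tau_sq[i],
            a_prior[i], b_prior[i],
        )

    batch_idx = pd.Categorical(batch, categories=levels).codes
    adj = (Z - gamma_star[batch_idx]) / np.sqrt(delta_star[batch_idx])
    adj = adj * np.sqrt(var_pooled) + stand_mean

    corrected = pd.DataFrame(adj, index=data.index, columns=data.columns)
    model = BatchModel(
        batches=levels,
        gamma_star=pd.DataFrame(gamma_star, index=levels, columns=data.columns),
        delta_star=pd.DataFrame(np.sqrt(delta_star), index=levels, columns=data.columns),
        gamma_bar=pd.Series(gamma_bar, index=levels),
        tau_sq=pd.Series(tau_sq, index=levels),
        lambda_=pd.Series(a_prior, index=levels),
        theta=pd.Series(b_prior, index=levels),
    )
    return corrected, model
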