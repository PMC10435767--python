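"""Cohort association statistics.

Per-cohort case-control contrasts on rank-INT-transformed glycan variables
(OLS with age and sex as covariates), a sibling-paired random-intercept
model, inverse-variance fixed-effects meta-analysis across cohorts, and
Benjamini-Hochberg control of the false discovery rate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import rank_inverse_normal


@dataclass
class EffectEstimate:
    """Standardized group effect of one trait in one cohort."""

    trait: str
    cohort: str
    beta: float
    se: float
    stat: float
    p: float
    df: float
    n: int
    model: str = "ols"

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("standard error must be positive")


@dataclass
class MetaResult:
    """Fixed-effects pooled estimate across cohorts."""

    trait: str
    beta: float
    se: float
    z: float
    p: float
    q: float | None = None
    inputs: list[EffectEstimate] = field(default_factory=list)


def _design(meta: pd.DataFrame, covariates: tuple[str, ...]) -> pd.DataFrame:
    """Design matrix: intercept, DS indicator, then covariates.

    ``group`` is coded DS=1/control=0 and ``sex`` F=1/M=0; other listed
    covariates must already be numeric.
    """
    cols = {"const": np.ones(len(meta))}
    cols["group"] = (meta["group"] == "DS").astype(float)
    for c in covariates:
        if c == "sex":
            cols["sex"] = (meta["sex"] == "F").astype(float)
        else:
            cols[c] = meta[c].astype(float)
    return pd.DataFrame(cols, index=meta.index)


def fit_glm(
    trait: pd.Series,
    meta: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "sex"),
    subgroup: pd.Series | None = None,
    trait_name: str | None = None,
) -> EffectEstimate:
    """OLS of a (rank-INT) trait on group + covariates; returns the group
    coefficient as the standardized effect. ``subgroup`` is an optional
    boolean filter for co-morbidity contrasts."""
    y = trait.copy()
    m = meta.loc[y.index]
    if subgroup is not None:
        keep = subgroup.loc[y.index].astype(bool)
        y, m = y[keep], m[keep]
    keep = y.notna()
    y, m = y[keep], m[keep]
    if m["group"].nunique() < 2:
        raise ValueError("subgroup contains only one group level")
    X = _design(m, covariates)
    if len(y) < X.shape[1] + 2:
        raise ValueError("too few samples for the design")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    res = sm.OLS(y.to_numpy(dtype=float), X).fit()
    return EffectEstimate(
        trait=trait_name or (trait.name or "trait"),
        cohort=str(m["cohort"].iloc[0]) if "cohort" in m else "",
        beta=float(res.params["group"]),
        se=float(res.bse["group"]),
        stat=float(res.tvalues["group"]),
        p=float(res.pvalues["group"]),
        df=float(res.df_resid),
        n=int(res.nobs),
        model="ols",
    )


def fit_paired(
    trait: pd.Series,
    meta: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "sex"),
    trait_name: str | None = None,
) -> EffectEstimate:
    """Sibling-paired contrast: random-intercept linear mixed model with
    family as the grouping factor, fitted by REML. A zero between-family
    variance collapses to OLS at the boundary."""
    y = trait.copy()
    m = meta.loc[y.index]
    keep = y.notna()
    y, m = y[keep], m[keep]
    fams = m["family_id"]
    if fams.nunique() < 5:
        raise ValueError("need at least 5 families")
    X = _design(m, covariates)
    mod = sm.MixedLM(y.to_numpy(dtype=float), X, groups=fams.to_numpy())
    res = None
    for method in ("lbfgs", "powell", "cg"):
        try:
            # boundary (zero family variance) fits emit convergence noise
            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = mod.fit(reml=True, method=method)
            break
        except np.linalg.LinAlgError:
            continue
    if res is None:
        raise RuntimeError("REML optimisation failed for all optimizers")
    beta = float(res.fe_params["group"])
    se = float(res.bse_fe["group"])
    z = beta / se
    p = 2 * stats.norm.sf(abs(z))
    est = EffectEstimate(
        trait=trait_name or (trait.name or "trait"),
        cohort=str(m["cohort"].iloc[0]) if "cohort" in m else "",
        beta=beta,
        se=se,
        stat=z,
        p=float(p),
        df=float(len(y) - X.shape[1]),
        n=int(len(y)),
        model="mixed",
    )
    est.family_var = float(res.cov_re.iloc[0, 0])  # type: ignore[attr-defined]
    est.resid_var = float(res.scale)  # type: ignore[attr-defined]
    return est


def meta_fixed(estimates: list[EffectEstimate]) -> MetaResult:
    """Inverse-variance fixed-effects pooling of per-cohort estimates."""
    if not estimates:
        raise ValueError("need at least one estimate")
    traits = {e.trait for e in estimates}
    if len(traits) > 1:
        raise ValueError(f"cannot pool across traits: {sorted(traits)}")
    w = np.array([1.0 / e.se**2 for e in estimates])
    b = np.array([e.beta for e in estimates])
    pooled = float((w * b).sum() / w.sum())
    se = float(1.0 / math.sqrt(w.sum()))
    z = pooled / se
    p = float(2 * stats.norm.sf(abs(z)))
    return MetaResult(
        trait=estimates[0].trait, beta=pooled, se=se, z=z, p=p, inputs=list(estimates)
    )


def bh_adjust(pvals: np.ndarray | pd.Series | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    arr = np.asarray(pvals, dtype=float)
    if arr.size == 0:
        return arr
    if np.isnan(arr).any() or (arr <= 0).any() or (arr > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(arr, method="fdr_bh")
    return q


def associate_all(
    ranked: pd.DataFrame,
    meta: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "sex"),
) -> pd.DataFrame:
    """Per-cohort GLM for every analysis variable, fixed-effects pooling
    across cohorts, BH adjustment across all variables. Returns a tidy
    frame (trait, cohort rows including 'META')."""
    rows: list[dict] = []
    metas: list[MetaResult] = []
    for var in ranked.columns:
        per_cohort = []
        for cohort, idx in meta.groupby("cohort").groups.items():
            sub_meta = meta.loc[idx]
            if sub_meta["group"].nunique() < 2:
                continue
            # re-ranking within cohort keeps effects comparable across
            # cohorts (rank-INT is invariant to the earlier pooled ranking)
            y = rank_inverse_normal(ranked.loc[idx, var])
            est = fit_glm(y, sub_meta, covariates, trait_name=var)
            per_cohort.append(est)
            rows.append(
                {
                    "trait": var, "cohort": cohort, "beta": est.beta,
                    "se": est.se, "p": est.p, "n": est.n,
                }
            )
        pooled = meta_fixed(per_cohort)
        metas.append(pooled)
        rows.append(
            {
                "trait": var, "cohort": "META", "beta": pooled.beta,
                "se": pooled.se, "p": pooled.p,
                "n": sum(e.n for e in per_cohort),
            }
        )
    out = pd.DataFrame(rows)
    is_meta = out["cohort"] == "META"
    out.loc[is_meta, "q"] = bh_adjust(out.loc[is_meta, "p"].to_numpy())
    return out
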