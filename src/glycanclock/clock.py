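"""Glycan-age trend fitting and the biological-age shift.

For each trait and cohort a linear age trend is fitted within the DS and
control groups on the raw percentage scale. The glycan-age shift is the
horizontal offset between the two lines: the control age whose expected
trait level equals the DS expectation at age x, minus x,

    delta(x) = (a_DS * x + b_DS - b_ctrl) / a_ctrl - x.

For parallel lines this is the constant (b_DS - b_ctrl) / a_ctrl. A
positive shift means the DS group is biologically older, for both
age-increasing traits elevated in DS (the agalactosylated G0 pattern) and
age-decreasing traits reduced in DS (the digalactosylated G2 pattern).
A group-by-age interaction test checks the equal-slopes assumption
(equal slopes argue against an amplified-instability model, which would
predict accelerating divergence with age).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class TrendFit:
    """Within-group linear age trend of a raw-scale trait."""

    trait: str
    cohort: str
    group: str
    slope: float
    intercept: float
    cov: np.ndarray      # 2x2 covariance of (intercept, slope)
    n: int
    resid_sd: float
    age_range: tuple[float, float]

    def predict(self, age: np.ndarray | float) -> np.ndarray | float:
        return self.slope * np.asarray(age, dtype=float) + self.intercept


@dataclass
class ParallelSlopesTest:
    """Group-by-age interaction: difference in ageing rate between groups."""

    trait: str
    cohort: str
    interaction: float
    se: float
    p: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p < 0.05


@dataclass
class AgeShiftEstimate:
    """Horizontal DS-vs-control offset of the trait-age trend, in years."""

    trait: str
    cohort: str
    grid: np.ndarray
    shift: np.ndarray    # delta(x) per grid age
    minimum: float
    maximum: float
    average: float
    ci: tuple[float, float] | None = None


def fit_trend(
    trait: pd.Series,
    meta: pd.DataFrame,
    group: str,
    trait_name: str | None = None,
) -> TrendFit:
    """OLS of a raw-percentage trait on age within one group."""
    m = meta.loc[trait.index]
    keep = (m["group"] == group) & trait.notna()
    y = trait[keep].to_numpy(dtype=float)
    ages = m.loc[keep, "age"].to_numpy(dtype=float)
    if len(y) < 3:
        raise ValueError(f"need at least 3 subjects in group {group!r}")
    if np.ptp(ages) == 0:
        raise ValueError("degenerate ages: all equal")
    X = sm.add_constant(ages)
    res = sm.OLS(y, X).fit()
    return TrendFit(
        trait=trait_name or (trait.name or "trait"),
        cohort=str(m["cohort"].iloc[0]) if "cohort" in m else "",
        group=group,
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        cov=np.asarray(res.cov_params()),
        n=int(res.nobs),
        resid_sd=float(np.sqrt(res.scale)),
        age_range=(float(ages.min()), float(ages.max())),
    )


def test_parallel_slopes(
    trait: pd.Series, meta: pd.DataFrame, trait_name: str | None = None
) -> ParallelSlopesTest:
    """Single-model OLS with group, age and group x age; the interaction
    coefficient is the between-group difference in %/year ageing rate."""
    m = meta.loc[trait.index]
    keep = trait.notna()
    y = trait[keep].to_numpy(dtype=float)
    m = m[keep]
    g = (m["group"] == "DS").astype(float).to_numpy()
    age = m["age"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(y)), g, age, g * age])
    if np.linalg.matrix_rank(X) < 4:
        raise ValueError("rank-deficient design (one group or degenerate ages)")
    res = sm.OLS(y, X).fit()
    return ParallelSlopesTest(
        trait=trait_name or (trait.name or "trait"),
        cohort=str(m["cohort"].iloc[0]) if "cohort" in m else "",
        interaction=float(res.params[3]),
        se=float(res.bse[3]),
        p=float(res.pvalues[3]),
        n=int(res.nobs),
    )


def age_shift(
    fit_ds: TrendFit,
    fit_ctrl: TrendFit,
    grid: np.ndarray | None = None,
    slope_tol: float = 1e-6,
) -> AgeShiftEstimate:
    """Evaluate the glycan-age shift delta(x) on an age grid.

    Default grid: integer ages over the intersection of the two groups'
    observed age ranges.
    """
    if abs(fit_ctrl.slope) <= slope_tol:
        raise ValueError("control slope is (near) zero: shift undefined")
    if fit_ds.slope * fit_ctrl.slope < 0:
        raise ValueError("opposite-sign slopes: shift undefined")
    if grid is None:
        lo = max(fit_ds.age_range[0], fit_ctrl.age_range[0])
        hi = min(fit_ds.age_range[1], fit_ctrl.age_range[1])
        if hi <= lo:
            raise ValueError("group age ranges do not overlap")
        grid = np.arange(np.ceil(lo), np.floor(hi) + 1.0)
    grid = np.asarray(grid, dtype=float)
    delta = (fit_ds.slope * grid + fit_ds.intercept - fit_ctrl.intercept) / fit_ctrl.slope - grid
    return AgeShiftEstimate(
        trait=fit_ds.trait,
        cohort=fit_ds.cohort,
        grid=grid,
        shift=delta,
        minimum=float(delta.min()),
        maximum=float(delta.max()),
        average=float(delta.mean()),
    )


def combine_shifts(per_cohort: list[AgeShiftEstimate] | list[float]) -> float:
    """Unweighted arithmetic mean of per-cohort average shifts."""
    if not per_cohort:
        raise ValueError("need at least one cohort")
    if isinstance(per_cohort[0], AgeShiftEstimate):
        traits = {e.trait for e in per_cohort}  # type: ignore[union-attr]
        if len(traits) > 1:
            raise ValueError(f"cannot combine shifts across traits: {sorted(traits)}")
        values = [e.average for e in per_cohort]  # type: ignore[union-attr]
    else:
        values = [float(v) for v in per_cohort]
    return float(np.mean(values))


def cohort_shift(
    trait: pd.Series,
    meta: pd.DataFrame,
    grid: np.ndarray | None = None,
    trait_name: str | None = None,
) -> AgeShiftEstimate:
    """Fit both group trends in one cohort and evaluate the shift."""
    f_ds = fit_trend(trait, meta, "DS", trait_name)
    f_ct = fit_trend(trait, meta, "control", trait_name)
    return age_shift(f_ds, f_ct, grid)


def bootstrap_shift_ci(
    traits_by_cohort: dict[str, tuple[pd.Series, pd.DataFrame]],
    n_boot: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
    grid: np.ndarray | None = None,
) -> dict:
    """Nonparametric bootstrap of the per-cohort and combined average
    shift: subjects resampled with replacement within group within cohort.

    ``traits_by_cohort`` maps cohort name to (trait series, metadata).
    Returns percentile CIs keyed by cohort plus "combined"; reproducible
    for a fixed seed.
    """
    if n_boot < 200:
        raise ValueError("need at least 200 bootstrap replicates")
    rng = np.random.default_rng(seed)
    point: dict[str, float] = {}
    draws: dict[str, np.ndarray] = {}
    for cohort, (trait, meta) in traits_by_cohort.items():
        m = meta.loc[trait.index]
        idx_ds = m.index[m["group"] == "DS"]
        idx_ct = m.index[m["group"] == "control"]
        if len(idx_ds) < 3 or len(idx_ct) < 3:
            raise ValueError(f"{cohort}: a group is degenerate for resampling")
        point[cohort] = cohort_shift(trait, m, grid).average
        reps = np.empty(n_boot)
        for b in range(n_boot):
            take = np.concatenate([
                rng.choice(idx_ds, size=len(idx_ds), replace=True),
                rng.choice(idx_ct, size=len(idx_ct), replace=True),
            ])
            # duplicate-safe positional resample
            t_b = trait.loc[take].reset_index(drop=True)
            m_b = m.loc[take].reset_index(drop=True)
            reps[b] = cohort_shift(t_b, m_b, grid).average
        draws[cohort] = reps
    combined_reps = np.mean(np.column_stack(list(draws.values())), axis=1)
    lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)
    out = {
        cohort: {
            "estimate": point[cohort],
            "ci": (float(np.percentile(d, lo)), float(np.percentile(d, hi))),
        }
        for cohort, d in draws.items()
    }
    out["combined"] = {
        "estimate": float(np.mean(list(point.values()))),
        "ci": (
            float(np.percentile(combined_reps, lo)),
            float(np.percentile(combined_reps, hi)),
        ),
    }
    return out


def clock_report(
    traits: pd.DataFrame,
    meta: pd.DataFrame,
    clock_traits: tuple[str, ...] = ("G0", "G2"),
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per trait x cohort: group trend coefficients, interaction p, and
    shift summary; plus a combined row per trait."""
    rows = []
    for trait_name in clock_traits:
        shifts = []
        for cohort, idx in meta.groupby("cohort").groups.items():
            y = traits.loc[idx, trait_name]
            m = meta.loc[idx]
            f_ds = fit_trend(y, m, "DS", trait_name)
            f_ct = fit_trend(y, m, "control", trait_name)
            par = test_parallel_slopes(y, m, trait_name)
            est = age_shift(f_ds, f_ct, grid)
            shifts.append(est)
            rows.append({
                "trait": trait_name, "cohort": cohort,
                "slope_ds": f_ds.slope, "intercept_ds": f_ds.intercept,
                "slope_control": f_ct.slope, "intercept_control": f_ct.intercept,
                "interaction_p": par.p,
                "shift_min": est.minimum, "shift_max": est.maximum,
                "shift_mean": est.average,
            })
        rows.append({
            "trait": trait_name, "cohort": "COMBINED",
            "shift_mean": combine_shifts(shifts),
        })
    return pd.DataFrame(rows)
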