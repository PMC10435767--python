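"""Preprocessing of glycan peak tables.

Raw integrated peak areas are made comparable across samples by total-area
normalisation, log-transformed (batch effects are multiplicative and the
area distributions right-skewed), batch-corrected with the parametric
empirical-Bayes procedure, and reduced to analysis variables: 22 retained
peaks plus six derived traits, each rank-transformed to standard normal
for association analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

from .combat import BatchModel, combat
from .traits import DEFAULT_EXCLUDED, TRAIT_FORMULAS

DEFAULT_EB_COVARIATES: tuple[str, ...] = ("group", "age", "sex")


def _set_stage(pt: pd.DataFrame, stage: str) -> pd.DataFrame:
    pt.attrs = dict(pt.attrs)
    pt.attrs["stage"] = stage
    return pt


def normalize_total_area(raw: pd.DataFrame, on_nonpositive: str = "reject") -> pd.DataFrame:
    """Express each peak as a percentage of the sample's total area.

    ``on_nonpositive``: "reject" fails on any non-positive peak value;
    "floor" replaces non-positive values by half the smallest positive
    value in that peak column before normalising.
    """
    values = raw.astype(float).copy()
    totals = values.sum(axis=1)
    bad_total = totals <= 0
    if bad_total.any():
        raise ValueError(
            f"non-positive total area for sample(s): {list(values.index[bad_total])}"
        )
    nonpos = values <= 0
    if nonpos.any().any():
        if on_nonpositive == "reject":
            rows = values.index[nonpos.any(axis=1)]
            raise ValueError(f"non-positive peak value in sample(s): {list(rows)}")
        elif on_nonpositive == "floor":
            for col in values.columns[nonpos.any(axis=0)]:
                pos = values.loc[values[col] > 0, col]
                if pos.empty:
                    raise ValueError(f"peak {col} has no positive values to floor from")
                values.loc[values[col] <= 0, col] = pos.min() / 2.0
        else:
            raise ValueError(f"unknown on_nonpositive policy: {on_nonpositive!r}")
    out = 100.0 * values.div(values.sum(axis=1), axis=0)
    return _set_stage(out, "normalized")


def log_transform(pt: pd.DataFrame) -> pd.DataFrame:
    if (pt <= 0).any().any():
        raise ValueError("log transform requires strictly positive values")
    out = np.log(pt.astype(float))
    return _set_stage(out, "log")


def batch_correct(
    pt: pd.DataFrame,
    meta: pd.DataFrame,
    preserve: tuple[str, ...] = DEFAULT_EB_COVARIATES,
) -> tuple[pd.DataFrame, BatchModel]:
    """Empirical-Bayes batch (plate) correction of a log-stage table.

    ``preserve`` names metadata columns whose biological signal the
    covariate model protects from removal; categorical columns are dummy
    coded. Plates must have at least 2 samples. A single plate yields the
    identity correction.
    """
    if pt.attrs.get("stage") not in (None, "log"):
        raise ValueError(f"batch correction expects a log-stage table, got {pt.attrs['stage']!r}")
    if "plate" not in meta.columns:
        raise ValueError("metadata must carry a 'plate' column")
    meta = meta.loc[pt.index]
    cov = None
    if preserve:
        cov = pd.get_dummies(meta[list(preserve)], drop_first=True).astype(float)
    corrected, model = combat(pt, meta["plate"], cov)
    return _set_stage(corrected, "batch_corrected"), model


def exclude_peaks(
    pt: pd.DataFrame, excluded: tuple[str, ...] = DEFAULT_EXCLUDED
) -> pd.DataFrame:
    """Drop poorly resolved peaks (no renormalisation; exclusion is post hoc)."""
    unknown = [p for p in excluded if p not in pt.columns]
    if unknown:
        raise KeyError(f"unknown peak name(s): {unknown}")
    remaining = [c for c in pt.columns if c not in set(excluded)]
    if not remaining:
        raise ValueError("excluding all peaks leaves an empty table")
    out = pt[remaining].copy()
    out.attrs = dict(pt.attrs)
    return out


def derived_traits(pt: pd.DataFrame) -> pd.DataFrame:
    """Six derived glycosylation traits as sums of member peak percentages.

    Expects a percentage-scale table (batch-corrected log values must be
    exponentiated back first, see ``to_percent``).
    """
    out = {}
    for trait, members in TRAIT_FORMULAS.items():
        missing = [m for m in members if m not in pt.columns]
        if missing:
            raise KeyError(f"trait {trait} needs missing peak column(s): {missing}")
        out[trait] = pt[list(members)].sum(axis=1)
    return pd.DataFrame(out, index=pt.index)


def to_percent(pt: pd.DataFrame) -> pd.DataFrame:
    """Map a log-scale table back to the percentage scale."""
    out = np.exp(pt.astype(float))
    return _set_stage(out, "normalized")


def rank_inverse_normal(values: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Rank-based inverse-normal transform: value_i -> ndtri((r_i - 0.5)/n),
    with average ranks for ties. Output has mean ~0 and SD ~1.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expects a 1-D vector")
    mask = ~np.isnan(arr)
    n = int(mask.sum())
    if n < 3:
        raise ValueError("need at least 3 non-missing values")
    finite = arr[mask]
    if np.ptp(finite) == 0:
        raise ValueError("all values identical: ranks are degenerate")
    ranks = rankdata(finite, method="average")
    transformed = ndtri((ranks - 0.5) / n)
    out = np.full_like(arr, np.nan)
    out[mask] = transformed
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


def preprocess_pipeline(
    raw: pd.DataFrame,
    meta: pd.DataFrame,
    excluded: tuple[str, ...] = DEFAULT_EXCLUDED,
    eb_covariates: tuple[str, ...] = DEFAULT_EB_COVARIATES,
    batch_correction: bool = True,
) -> dict:
    """Full preprocessing chain: normalise -> log -> batch-correct ->
    exclude peaks -> derived traits (percentage scale) -> rank-INT of all
    analysis variables.

    Samples with any missing peak are dropped (count recorded). Returns a
    dict with the corrected peak table, derived traits, rank-INT analysis
    table, the fitted batch model and the number of dropped samples.
    """
    complete = raw.dropna()
    n_dropped = len(raw) - len(complete)
    meta = meta.loc[complete.index]
    norm = normalize_total_area(complete)
    logged = log_transform(norm)
    if batch_correction:
        corrected, model = batch_correct(logged, meta, eb_covariates)
    else:
        corrected, model = logged, None
    kept = exclude_peaks(corrected, excluded)
    percent = to_percent(kept)
    traits = derived_traits(percent)
    analysis = pd.concat([percent, traits], axis=1)
    ranked = analysis.apply(rank_inverse_normal, axis=0)
    return {
        "normalized": norm,
        "corrected": kept,
        "percent": percent,
        "traits": traits,
        "ranked": ranked,
        "batch_model": model,
        "n_dropped": n_dropped,
        "meta": meta,
    }
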