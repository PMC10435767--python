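"""End-to-end analysis runner chaining all pipeline stages.

simulate -> preprocess -> associate -> ageing clock -> singleton PCA, with
all randomness derived from one master seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import clock, pca, simulate
from .association import associate_all, meta_fixed, fit_glm
from .preprocess import preprocess_pipeline, rank_inverse_normal


def _child_seed(master: int, stream: int) -> int:
    """Deterministic 31-bit sub-seed for an independent stream."""
    return int(np.random.SeedSequence([master, stream]).generate_state(1)[0] % (2**31))


def simulate_adult_cohorts(
    seed: int,
    cohorts: tuple[str, ...] = simulate.ADULT_COHORTS,
    trends: dict[str, simulate.TraitTrendParams] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate and stack the three adult cohorts."""
    peaks_list, meta_list, truth = [], [], {}
    for i, name in enumerate(cohorts):
        spec = simulate.DEFAULT_COHORTS[name]
        tr = (trends or simulate.DEFAULT_TRENDS)[name]
        pk, mt = simulate.simulate_cohort(spec, tr, seed=_child_seed(seed, i))
        truth[name] = pk.attrs["ground_truth"]
        peaks_list.append(pk)
        meta_list.append(mt)
    peaks = pd.concat(peaks_list)
    peaks.attrs["stage"] = "raw"
    peaks.attrs["ground_truth"] = truth
    return peaks, pd.concat(meta_list)


def run_adult_pipeline(
    seed: int,
    trends: dict[str, simulate.TraitTrendParams] | None = None,
    bootstrap: int = 0,
) -> dict:
    """Full adult-cohort analysis on synthetic data.

    Returns preprocessing outputs, the association table, the clock report
    with combined G0/G2 shifts, and (optionally) bootstrap CIs.
    """
    peaks, meta = simulate_adult_cohorts(seed, trends=trends)
    prep = preprocess_pipeline(peaks, meta)
    assoc = associate_all(prep["ranked"], prep["meta"])
    report = clock.clock_report(prep["traits"], prep["meta"])
    out = {
        "peaks": peaks,
        "meta": prep["meta"],
        "prep": prep,
        "association": assoc,
        "clock": report,
        "combined_shift": {
            t: float(
                report.loc[(report["trait"] == t) & (report["cohort"] == "COMBINED"),
                           "shift_mean"].iloc[0]
            )
            for t in ("G0", "G2")
        },
    }
    if bootstrap:
        by_cohort = {
            c: (prep["traits"].loc[idx, "G0"], prep["meta"].loc[idx])
            for c, idx in prep["meta"].groupby("cohort").groups.items()
        }
        out["bootstrap_G0"] = clock.bootstrap_shift_ci(
            by_cohort, n_boot=bootstrap, seed=_child_seed(seed, 90)
        )
    return out


def recover_pooled_effect(
    trait: str,
    effect_size: float,
    n_seeds: int = 20,
    seed: int = 0,
) -> float:
    """Pooled fixed-effects estimate of a known standardized DS effect,
    averaged over generator seeds.

    Each replicate generates the three adult cohorts with the DS offset on
    the latent ``trait`` scale calibrated so that the rank-INT GLM group
    coefficient equals ``effect_size``, runs the full preprocessing chain
    and per-cohort GLMs, and pools the cohort estimates by inverse
    variance.
    """
    pooled = np.empty(n_seeds)
    for r in range(n_seeds):
        trends = {
            name: simulate.with_standardized_effect(
                simulate.DEFAULT_TRENDS[name],
                trait,
                effect_size,
                _pooled_age_range(simulate.DEFAULT_COHORTS[name]),
            )
            for name in simulate.ADULT_COHORTS
        }
        res_seed = _child_seed(seed, 1000 + r)
        peaks, meta = simulate_adult_cohorts(res_seed, trends=trends)
        prep = preprocess_pipeline(peaks, meta)
        estimates = []
        for cohort, idx in prep["meta"].groupby("cohort").groups.items():
            y = rank_inverse_normal(prep["traits"].loc[idx, trait])
            estimates.append(fit_glm(y, prep["meta"].loc[idx], trait_name=trait))
        pooled[r] = meta_fixed(estimates).beta
    return float(pooled.mean())


def _pooled_age_range(spec: simulate.CohortSpec) -> tuple[float, float]:
    lo = min(spec.age_range_control[0], spec.age_range_ds[0])
    hi = max(spec.age_range_control[1], spec.age_range_ds[1])
    return lo, hi


def run_children_pipeline(seed: int, k: int = 3) -> dict:
    """Children cohort analysis: PCA on the 24 measured peaks with the
    singleton excluded from the fit and projected afterwards."""
    from .preprocess import normalize_total_area

    peaks, meta = simulate.simulate_children(seed=_child_seed(seed, 50))
    norm = normalize_total_area(peaks)
    is_single = meta["group"] == "singleton"
    train = norm[~is_single]
    model = pca.fit_pca(train, standardize=True)
    result = {"model": model, "meta": meta, "peaks": norm}
    if is_single.any():
        sample = norm[is_single].iloc[0]
        scores, assigned, dist = pca.project_and_assign(
            model, sample, meta.loc[train.index, "group"], k=k
        )
        result.update(
            {"singleton_scores": scores, "assigned": assigned, "distances": dist}
        )
    return result
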