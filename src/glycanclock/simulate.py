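"""Synthetic IgG-glycan cohort generator.

Emulates the statistical structure of case-control glycomics cohorts of
adults with Down syndrome (DS) and euploid controls: linear age trends in
the derived traits G0/G1/G2, a DS intercept offset, compositional closure
of the 24 chromatogram peaks to 100%, plate-level multiplicative batch
effects, sibling pairs with a family-level random intercept, and a children
cohort including a singleton child with a segmental duplication whose trait
values follow the DS distribution.

Generation is latent-trait-first: per subject the controlled traits G0, G1
and G2 are drawn around their group trend lines, the sialylated trait S
absorbs the compositional remainder, trait totals are split over member
peaks by fixed weights, and multiplicative technical/plate noise is applied
before renormalising each row to 100%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .traits import PARTITION_TRAITS, PEAKS, TRAIT_FORMULAS

# ---------------------------------------------------------------------------
# Parameter containers

@dataclass(frozen=True)
class GroupLine:
    """Linear age trend of a trait within one group: mean = slope*age + intercept."""

    slope: float   # % per year
    intercept: float  # % at age 0

    def at(self, age: np.ndarray | float) -> np.ndarray | float:
        return self.slope * np.asarray(age, dtype=float) + self.intercept


@dataclass(frozen=True)
class CohortSpec:
    """Design of one case-control cohort."""

    name: str
    n_control: int
    n_ds: int
    age_range_control: tuple[float, float]
    age_range_ds: tuple[float, float]
    sex_ratio: float = 0.5          # fraction female
    n_plates: int = 7
    sibling_pairs: int = 0
    family_sd: float = 0.0          # SD of family random intercept, % units
    comorbidity_rates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_control < 0 or self.n_ds < 0 or self.n_plates < 1:
            raise ValueError("counts must be non-negative and n_plates >= 1")
        for lo, hi in (self.age_range_control, self.age_range_ds):
            if not hi > lo:
                raise ValueError(f"age range ({lo}, {hi}) must have positive width")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must be in [0, 1]")
        for flag, p in self.comorbidity_rates.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"comorbidity rate {flag}={p} outside [0, 1]")
        if self.sibling_pairs < 0:
            raise ValueError("sibling_pairs must be >= 0")


@dataclass(frozen=True)
class TraitTrendParams:
    """Age-trend and noise parameterisation of the controlled traits.

    ``lines[trait][group]`` gives the trend line for trait in {G0, G1, G2}
    and group in {control, DS}. ``noise_sd`` is the between-subject SD of
    each latent trait in % units; ``peak_log_sd`` the log-scale SD of
    multiplicative technical noise per peak; ``batch_sd`` the log-scale SD
    of the per-plate multiplicative effect; ``fixed_fractions`` the small
    constant percentages assigned to the orphan peaks GP5/GP20/GP21.
    """

    lines: dict[str, dict[str, GroupLine]]
    noise_sd: dict[str, float]
    peak_log_sd: float = 0.03
    batch_sd: float = 0.10
    fixed_fractions: dict[str, float] = field(
        default_factory=lambda: {"GP5": 1.0, "GP20": 0.5, "GP21": 0.5}
    )

    def __post_init__(self) -> None:
        if sum(self.fixed_fractions.values()) >= 100.0:
            raise ValueError("fixed fractions must sum to < 100")
        for trait in ("G0", "G1", "G2"):
            if trait not in self.lines:
                raise ValueError(f"missing trend line for {trait}")

    @property
    def closure_budget(self) -> float:
        """Percentage available to G0+G1+G2+S after the fixed orphan peaks."""
        return 100.0 - sum(self.fixed_fractions.values())


@dataclass(frozen=True)
class PeakSplitWeights:
    """How each controlled trait total is distributed over its member peaks."""

    weights: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        for trait in PARTITION_TRAITS:
            if trait not in self.weights:
                raise ValueError(f"missing split weights for {trait}")
            w = self.weights[trait]
            if set(w) != set(TRAIT_FORMULAS[trait]):
                raise ValueError(
                    f"{trait} weights must cover exactly its member peaks"
                )
            vals = np.array(list(w.values()))
            if (vals < 0).any() or not math.isclose(vals.sum(), 1.0, abs_tol=1e-9):
                raise ValueError(f"{trait} weights must be >= 0 and sum to 1")


# ---------------------------------------------------------------------------
# Default parameterisation: three adult DS cohorts (FRA/ITA/UK)

def default_weights() -> PeakSplitWeights:
    """Plausible relative abundances within each trait group (the dominant
    biantennary structures FA2, FA2[6]G1, FA2G2 and FA2G2S1 carry most of
    their group's mass)."""
    return PeakSplitWeights(
        weights={
            "G0": {"GP1": 0.12, "GP2": 0.08, "GP3": 0.05, "GP4": 0.65, "GP6": 0.10},
            "G1": {"GP7": 0.10, "GP8": 0.45, "GP9": 0.25, "GP10": 0.12, "GP11": 0.08},
            "G2": {"GP12": 0.08, "GP13": 0.12, "GP14": 0.65, "GP15": 0.15},
            "S": {
                "GP16": 0.10, "GP17": 0.08, "GP18": 0.45, "GP19": 0.07,
                "GP22": 0.05, "GP23": 0.15, "GP24": 0.10,
            },
        }
    )


#: Printed trend lines for the two traits that change the most with age,
#: per cohort and group; G1 lines are mild generator defaults (the source
#: figures print no G1 equations).
DEFAULT_TRENDS: dict[str, TraitTrendParams] = {
    "FRA": TraitTrendParams(
        lines={
            "G0": {"control": GroupLine(0.43, 6.72), "DS": GroupLine(0.44, 11.42)},
            "G2": {"control": GroupLine(-0.22, 28.25), "DS": GroupLine(-0.25, 25.96)},
            "G1": {"control": GroupLine(-0.05, 25.0), "DS": GroupLine(-0.05, 24.0)},
        },
        noise_sd={"G0": 6.5, "G1": 3.0, "G2": 4.0},
    ),
    "ITA": TraitTrendParams(
        lines={
            "G0": {"control": GroupLine(0.26, 13.74), "DS": GroupLine(0.33, 15.96)},
            "G2": {"control": GroupLine(-0.17, 26.04), "DS": GroupLine(-0.18, 23.23)},
            "G1": {"control": GroupLine(-0.05, 25.0), "DS": GroupLine(-0.05, 24.0)},
        },
        noise_sd={"G0": 6.5, "G1": 3.0, "G2": 4.0},
    ),
    "UK": TraitTrendParams(
        lines={
            "G0": {"control": GroupLine(0.29, 11.63), "DS": GroupLine(0.40, 14.92)},
            "G2": {"control": GroupLine(-0.18, 26.79), "DS": GroupLine(-0.20, 23.22)},
            "G1": {"control": GroupLine(-0.05, 25.0), "DS": GroupLine(-0.05, 24.0)},
        },
        noise_sd={"G0": 6.5, "G1": 3.0, "G2": 4.0},
    ),
}

#: Cohort designs: sizes, age ranges and co-morbidity fractions of the
#: three adult DS cohorts, plus the Italian sibling-pair sub-cohort.
DEFAULT_COHORTS: dict[str, CohortSpec] = {
    "FRA": CohortSpec(
        name="FRA", n_control=109, n_ds=98,
        age_range_control=(22.0, 67.0), age_range_ds=(30.0, 67.0),
        sex_ratio=0.51,
        comorbidity_rates={
            "autoimmune": 0.35, "thyroid": 0.23, "dementia": 0.20, "infection": 0.15,
        },
    ),
    "ITA": CohortSpec(
        name="ITA", n_control=53, n_ds=57,
        age_range_control=(22.0, 66.0), age_range_ds=(22.0, 66.0),
        sex_ratio=0.44,
        comorbidity_rates={
            "autoimmune": 0.39, "thyroid": 0.43, "dementia": 0.0, "infection": 0.29,
        },
    ),
    "UK": CohortSpec(
        name="UK", n_control=42, n_ds=53,
        age_range_control=(22.0, 82.0), age_range_ds=(22.0, 73.0),
        sex_ratio=0.41,
        comorbidity_rates={
            "autoimmune": 0.48, "thyroid": 0.46, "dementia": 0.25, "infection": 0.15,
        },
    ),
    "ITA_SIB": CohortSpec(
        name="ITA_SIB", n_control=35, n_ds=35,
        age_range_control=(9.0, 52.0), age_range_ds=(10.0, 58.0),
        sex_ratio=0.5, sibling_pairs=35, family_sd=3.0,
    ),
}

ADULT_COHORTS: tuple[str, ...] = ("FRA", "ITA", "UK")


class ClosureError(ValueError):
    """Configured trait means exceed the compositional closure budget."""


# ---------------------------------------------------------------------------
# Core generation

def _check_feasible(spec: CohortSpec, trends: TraitTrendParams) -> None:
    """Raise ClosureError naming the age at which the configured trait means
    break compositional closure or go non-positive."""
    budget = trends.closure_budget
    for group, (lo, hi) in (
        ("control", spec.age_range_control),
        ("DS", spec.age_range_ds),
    ):
        for age in np.linspace(lo, hi, 101):
            total = 0.0
            for trait in ("G0", "G1", "G2"):
                m = trends.lines[trait][group].at(age)
                if m <= 0:
                    raise ClosureError(
                        f"{spec.name}/{group}: configured {trait} mean "
                        f"{m:.2f}% is non-positive at age {age:.1f}"
                    )
                total += m
            if total >= budget:
                raise ClosureError(
                    f"{spec.name}/{group}: configured G0+G1+G2 means total "
                    f"{total:.2f}% at age {age:.1f}, exceeding the closure "
                    f"budget of {budget:.2f}%"
                )


def _draw_latent_traits(
    rng: np.random.Generator,
    means: dict[str, np.ndarray],
    noise_sd: dict[str, float],
    budget: float,
    family_effect: dict[str, np.ndarray] | None = None,
) -> dict[str, np.ndarray]:
    """Draw latent G0/G1/G2 per subject; rejection-redraw infeasible rows."""
    n = len(next(iter(means.values())))
    out = {t: np.empty(n) for t in ("G0", "G1", "G2")}
    for t in ("G0", "G1", "G2"):
        mu = means[t].copy()
        if family_effect is not None and t in family_effect:
            mu = mu + family_effect[t]
        out[t] = mu + rng.normal(0.0, noise_sd.get(t, 0.0), size=n)
    # redraw rows where a trait is <= 0 or the sum leaves no room for S
    for _ in range(100):
        total = out["G0"] + out["G1"] + out["G2"]
        bad = (total >= budget - 0.5) | (out["G0"] <= 0) | (out["G1"] <= 0) | (out["G2"] <= 0)
        if not bad.any():
            break
        idx = np.flatnonzero(bad)
        for t in ("G0", "G1", "G2"):
            mu = means[t][idx]
            if family_effect is not None and t in family_effect:
                mu = mu + family_effect[t][idx]
            out[t][idx] = mu + rng.normal(0.0, noise_sd.get(t, 0.0), size=len(idx))
    else:  # pragma: no cover - defaults never reach this
        raise ClosureError("could not draw feasible trait values in 100 rounds")
    return out


def _traits_to_peaks(
    latent: dict[str, np.ndarray],
    budget: float,
    weights: PeakSplitWeights,
    fixed: dict[str, float],
    n: int,
) -> pd.DataFrame:
    """Split trait totals over member peaks; S absorbs the remainder."""
    s_total = budget - latent["G0"] - latent["G1"] - latent["G2"]
    totals = {**latent, "S": s_total}
    peaks = pd.DataFrame(0.0, index=range(n), columns=list(PEAKS))
    for trait in PARTITION_TRAITS:
        for peak, w in weights.weights[trait].items():
            peaks[peak] = totals[trait] * w
    for peak, frac in fixed.items():
        peaks[peak] = frac
    return peaks


def _apply_noise_and_close(
    rng: np.random.Generator,
    peaks: pd.DataFrame,
    plates: np.ndarray,
    n_plates: int,
    peak_log_sd: float,
    batch_sd: float,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Multiplicative technical + plate noise, then renormalise rows to 100."""
    values = peaks.to_numpy()
    if peak_log_sd > 0:
        z = rng.normal(0.0, peak_log_sd, size=values.shape)
        values = values * np.exp(z - 0.5 * peak_log_sd**2)
    plate_effects = np.zeros((n_plates, values.shape[1]))
    if batch_sd > 0:
        plate_effects = rng.normal(0.0, batch_sd, size=plate_effects.shape)
        values = values * np.exp(plate_effects[plates])
    values = 100.0 * values / values.sum(axis=1, keepdims=True)
    out = pd.DataFrame(values, index=peaks.index, columns=peaks.columns)
    return out, plate_effects


def _assign_plates(rng: np.random.Generator, groups: np.ndarray, n_plates: int) -> np.ndarray:
    """Blocked randomisation: shuffle within group, deal round-robin so each
    plate receives a near-equal share of each group."""
    plates = np.empty(len(groups), dtype=int)
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        rng.shuffle(idx)
        plates[idx] = np.arange(len(idx)) % n_plates
    return plates


def calibrate_offset(
    effect_size: float,
    line: GroupLine,
    age_range: tuple[float, float],
    noise_sd: float,
) -> float:
    """Latent intercept offset whose rank-INT-scale GLM group coefficient
    equals ``effect_size``.

    The rank inverse-normal transform rescales the pooled trait to unit SD,
    so an offset d on the raw scale appears as d / S on the transformed
    scale, where S^2 = noise_sd^2 + slope^2 * Var(age) + d^2/4 for balanced
    groups with uniform ages. Solving d / S = effect_size gives
    d = effect_size * sqrt((noise_sd^2 + slope^2 * Var(age)) / (1 - effect_size^2 / 4)).
    """
    if abs(effect_size) >= 2.0:
        raise ValueError("standardized effect must satisfy |d| < 2 for calibration")
    var_age = (age_range[1] - age_range[0]) ** 2 / 12.0
    base = noise_sd**2 + line.slope**2 * var_age
    return effect_size * math.sqrt(base / (1.0 - effect_size**2 / 4.0))


def with_standardized_effect(
    trends: TraitTrendParams,
    trait: str,
    effect_size: float,
    age_range: tuple[float, float],
) -> TraitTrendParams:
    """Return trends where the DS line for ``trait`` is the control line
    shifted by the latent offset calibrated to ``effect_size`` (parallel
    groups; other traits get equal control/DS lines, i.e. a pure null)."""
    lines: dict[str, dict[str, GroupLine]] = {}
    for t, by_group in trends.lines.items():
        ctrl = by_group["control"]
        if t == trait:
            d = calibrate_offset(effect_size, ctrl, age_range, trends.noise_sd[t])
            lines[t] = {"control": ctrl, "DS": GroupLine(ctrl.slope, ctrl.intercept + d)}
        else:
            lines[t] = {"control": ctrl, "DS": ctrl}
    return TraitTrendParams(
        lines=lines,
        noise_sd=dict(trends.noise_sd),
        peak_log_sd=trends.peak_log_sd,
        batch_sd=trends.batch_sd,
        fixed_fractions=dict(trends.fixed_fractions),
    )


def simulate_cohort(
    spec: CohortSpec,
    trends: TraitTrendParams | None = None,
    weights: PeakSplitWeights | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one cohort's peak table and sample metadata.

    Returns ``(peaks, meta)``; ``peaks.attrs["ground_truth"]`` carries the
    full parameter set used, and ``peaks.attrs["plate_effects"]`` the drawn
    per-plate log-scale effects. Deterministic given (spec, trends, weights,
    seed).
    """
    if trends is None:
        trends = DEFAULT_TRENDS.get(spec.name, DEFAULT_TRENDS["FRA"])
    if weights is None:
        weights = default_weights()
    _check_feasible(spec, trends)

    rng = np.random.default_rng(seed)
    n = spec.n_control + spec.n_ds
    groups = np.array(["control"] * spec.n_control + ["DS"] * spec.n_ds)
    ages = np.concatenate([
        rng.uniform(*spec.age_range_control, size=spec.n_control),
        rng.uniform(*spec.age_range_ds, size=spec.n_ds),
    ])
    sexes = np.where(rng.random(n) < spec.sex_ratio, "F", "M")

    # sibling pairing: first `sibling_pairs` controls and DS subjects share
    # a family; everyone else is a singleton family
    family = np.array([f"{spec.name}_fam{i:04d}" for i in range(n)], dtype=object)
    family_effect = None
    if spec.sibling_pairs > 0:
        k = min(spec.sibling_pairs, spec.n_control, spec.n_ds)
        for i in range(k):
            family[spec.n_control + i] = family[i]
        if spec.family_sd > 0:
            family_effect = {}
            fam_ids, fam_idx = np.unique(family, return_inverse=True)
            for t in ("G0", "G1", "G2"):
                per_fam = rng.normal(0.0, spec.family_sd, size=len(fam_ids))
                family_effect[t] = per_fam[fam_idx]

    means = {
        t: np.where(
            groups == "DS",
            trends.lines[t]["DS"].at(ages),
            trends.lines[t]["control"].at(ages),
        )
        for t in ("G0", "G1", "G2")
    }
    latent = _draw_latent_traits(rng, means, trends.noise_sd, trends.closure_budget, family_effect)
    peaks = _traits_to_peaks(latent, trends.closure_budget, weights, trends.fixed_fractions, n)

    plates = _assign_plates(rng, groups, spec.n_plates)
    peaks, plate_effects = _apply_noise_and_close(
        rng, peaks, plates, spec.n_plates, trends.peak_log_sd, trends.batch_sd
    )

    sample_ids = [f"{spec.name}_{i:04d}" for i in range(n)]
    peaks.index = pd.Index(sample_ids, name="sample_id")
    meta = pd.DataFrame(
        {
            "cohort": spec.name,
            "group": groups,
            "age": ages,
            "sex": sexes,
            "plate": plates,
            "family_id": family,
        },
        index=peaks.index,
    )
    for flag, rate in spec.comorbidity_rates.items():
        draws = rng.random(n) < rate
        meta[flag] = np.where(meta["group"] == "DS", draws, False)

    peaks.attrs["stage"] = "raw"
    peaks.attrs["ground_truth"] = ground_truth_dict(spec, trends, weights, seed)
    peaks.attrs["plate_effects"] = plate_effects
    return peaks, meta


# ---------------------------------------------------------------------------
# Children cohort

#: Child-range trend defaults: high infant agalactosylation declining with
#: age; the DS offsets and the tight within-group spread reproduce the
#: clearly separated DS and euploid clusters seen in young children, with
#: a rank-INT G0 group effect in the vicinity of the large reported child
#: effect.
CHILD_TRENDS = TraitTrendParams(
    lines={
        "G0": {"control": GroupLine(-1.0, 25.0), "DS": GroupLine(-1.0, 33.0)},
        "G1": {"control": GroupLine(0.0, 28.0), "DS": GroupLine(0.0, 28.0)},
        "G2": {"control": GroupLine(0.5, 20.0), "DS": GroupLine(0.5, 16.5)},
    },
    noise_sd={"G0": 2.0, "G1": 2.0, "G2": 2.0},
)

CHILD_AGE_RANGE: tuple[float, float] = (0.5, 5.25)


def simulate_children(
    n_ds: int = 38,
    n_control: int = 17,
    singleton: bool = True,
    seed: int = 0,
    trends: TraitTrendParams | None = None,
    weights: PeakSplitWeights | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the children cohort: DS and euploid children plus, when
    ``singleton`` is set, one extra child (group label ``singleton``) whose
    trait values follow the DS distribution — emulating a child with a
    segmental duplication rather than full trisomy 21."""
    if n_ds < 0 or n_control < 0:
        raise ValueError("cohort sizes must be >= 0")
    if trends is None:
        trends = CHILD_TRENDS
    spec = CohortSpec(
        name="CHILD",
        n_control=n_control,
        n_ds=n_ds + (1 if singleton else 0),
        age_range_control=CHILD_AGE_RANGE,
        age_range_ds=CHILD_AGE_RANGE,
        n_plates=1,
    )
    peaks, meta = simulate_cohort(spec, trends, weights, seed=seed)
    if singleton:
        # last DS row becomes the singleton: DS-distribution trait values,
        # distinct label
        last = peaks.index[-1]
        meta.loc[last, "group"] = "singleton"
        new_ids = list(peaks.index[:-1]) + ["CRO_SINGLETON"]
        peaks.index = pd.Index(new_ids, name="sample_id")
        meta.index = peaks.index
    peaks.attrs["ground_truth"]["singleton"] = singleton
    return peaks, meta


def ground_truth_dict(
    spec: CohortSpec,
    trends: TraitTrendParams,
    weights: PeakSplitWeights,
    seed: int,
) -> dict:
    """JSON-serialisable record of the generating parameters."""
    return {
        "spec": asdict(spec),
        "trends": {
            "lines": {
                t: {g: asdict(l) for g, l in by_group.items()}
                for t, by_group in trends.lines.items()
            },
            "noise_sd": dict(trends.noise_sd),
            "peak_log_sd": trends.peak_log_sd,
            "batch_sd": trends.batch_sd,
            "fixed_fractions": dict(trends.fixed_fractions),
        },
        "weights": {t: dict(w) for t, w in weights.weights.items()},
        "seed": seed,
    }
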