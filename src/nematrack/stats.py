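"""Variability decomposition and screen power analysis.

Given a plate x timepoint table of aroused-maximum-speed scores labelled by
experiment, the decomposition separates the coefficient of variation (CV)
into a between-experiment component (CV of per-experiment means about the
population mean) and a within-experiment plate component (CV of plate scores
after rescaling each experiment's mean onto the population mean).  A
resampling null -- fictitious plates drawn from the pooled distribution of
plate-mean-normalized per-animal scores -- predicts how much plate-to-plate
CV is expected from stochastic sampling alone; agreement between the two
indicates minimal systematic plate effects.

The power analysis asks what change in the peak-to-day-3 speed ratio a
screen can detect.  Under a normal approximation, a shift is detectable with
probability ``power`` at significance ``alpha`` when

    d_mu >= sigma0 * (icdf_N(0,1)(1 - alpha) + icdf_N(0,1)(power))

(one-sided; ``1 - alpha/2`` for two-sided), with sigma0 the standard
deviation of the ratio measurement.  A Monte Carlo companion draws synthetic
control and condition plate sets and measures the empirical detection rate.

All Monte Carlo draws use numpy's PCG64 generator with a single stated seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ScoreMatrix",
    "VarianceDecomposition",
    "PowerParams",
    "PowerResult",
    "decompose_variability",
    "stochastic_null_cv",
    "min_detectable_shift",
    "monte_carlo_power",
    "fold_change_for_power",
]


@dataclass
class ScoreMatrix:
    """Plate x timepoint score table with experiment/condition labels.

    ``scores``: DataFrame indexed by plate_id, one column per timepoint.
    ``experiment`` / ``condition``: Series indexed by plate_id.
    ``n_animals``: animals contributing to each entry (same shape as scores).
    ``animal_scores``: optional tidy frame (plate_id, t_days, score) of the
    underlying per-animal scores, needed for the stochastic-sampling null.
    """

    scores: pd.DataFrame
    experiment: pd.Series
    condition: pd.Series | None = None
    n_animals: pd.DataFrame | None = None
    animal_scores: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = set(self.scores.index) - set(self.experiment.index)
        if missing:
            raise ValueError(f"plates without experiment label: {sorted(missing)}")

    def select(self, condition: str) -> "ScoreMatrix":
        """Restrict to plates of one condition."""
        if self.condition is None:
            raise ValueError("no condition labels present")
        keep = self.condition[self.condition == condition].index
        return ScoreMatrix(
            scores=self.scores.loc[keep],
            experiment=self.experiment.loc[keep],
            condition=self.condition.loc[keep],
            n_animals=None if self.n_animals is None else self.n_animals.loc[keep],
            animal_scores=None
            if self.animal_scores is None
            else self.animal_scores[self.animal_scores["plate_id"].isin(keep)],
        )


@dataclass
class VarianceDecomposition:
    """Per-timepoint CVs: between experiments, between plates, sampling null."""

    table: pd.DataFrame  # index t, columns cv_experiment, cv_plate[, cv_stochastic_expected]

    @property
    def cv_experiment(self) -> pd.Series:
        return self.table["cv_experiment"]

    @property
    def cv_plate(self) -> pd.Series:
        return self.table["cv_plate"]


def decompose_variability(scores: ScoreMatrix) -> VarianceDecomposition:
    """Split plate-score variability into experiment and plate components.

    At each timepoint: population mean = mean over all plates;
    cv_experiment = SD of per-experiment means / population mean;
    plate scores are normalized by scaling each experiment's mean onto the
    population mean, and cv_plate = SD of normalized scores / population
    mean.  Sample SDs (n-1) throughout.  Timepoints with fewer than two
    plates are dropped.  If per-animal scores are attached, the expected
    stochastic-sampling CV (pooled normalized-animal SD / sqrt(median
    animals per plate)) is reported alongside.
    """
    exp = scores.experiment
    if exp.nunique() < 2:
        raise ValueError("need at least 2 experiments to decompose variability")
    rows = []
    for t in scores.scores.columns:
        col = scores.scores[t].dropna()
        if len(col) < 2:
            continue
        pop_mean = col.mean()
        if pop_mean == 0:
            continue
        exp_means = col.groupby(exp.loc[col.index]).mean()
        cv_exp = exp_means.std(ddof=1) / pop_mean if len(exp_means) > 1 else np.nan
        normalized = col * (pop_mean / exp_means.loc[exp.loc[col.index]].values)
        cv_plate = normalized.std(ddof=1) / pop_mean
        row = {"t": t, "cv_experiment": cv_exp, "cv_plate": cv_plate}
        rows.append(row)
    table = pd.DataFrame(rows).set_index("t")
    if scores.animal_scores is not None and scores.n_animals is not None:
        expected = []
        n_med = int(np.median(scores.n_animals.values))
        for t in table.index:
            sub = scores.animal_scores[scores.animal_scores["t_days"] == t]
            if sub.empty:
                expected.append(np.nan)
                continue
            plate_means = sub.groupby("plate_id")["score"].transform("mean")
            norm = (sub["score"] / plate_means).to_numpy()
            expected.append(float(np.std(norm, ddof=1)) / math.sqrt(n_med))
        table["cv_stochastic_expected"] = expected
    return VarianceDecomposition(table=table)


def stochastic_null_cv(
    animal_scores: pd.DataFrame | dict,
    n_per_plate: int,
    n_fictitious: int = 1000,
    seed: int = 0,
) -> float:
    """Plate-level CV expected from stochastic sampling alone.

    Each animal score is normalized by its plate mean; fictitious plates of
    ``n_per_plate`` animals are drawn with replacement from the pooled
    normalized scores, and the SD of the fictitious plate means is returned
    (their population mean is 1 by construction, so the SD is the CV).

    ``animal_scores`` is either a tidy frame with columns plate_id and score
    (a single timepoint), or a mapping plate_id -> array of scores.
    """
    if isinstance(animal_scores, dict):
        groups = [np.asarray(v, dtype=float) for v in animal_scores.values()]
    else:
        groups = [
            g.to_numpy(dtype=float)
            for _, g in animal_scores.groupby("plate_id")["score"]
        ]
    pooled = np.concatenate([g / g.mean() for g in groups if len(g) and g.mean() != 0])
    if pooled.size == 0:
        raise ValueError("no normalized animal scores to sample from")
    rng = np.random.Generator(np.random.PCG64(seed))
    draws = rng.choice(pooled, size=(n_fictitious, n_per_plate), replace=True)
    return float(np.std(draws.mean(axis=1), ddof=1))


@dataclass
class PowerParams:
    """Inputs to the minimum-detectable-shift calculation.

    ``cv_peak`` and ``cv_day3`` are the CVs of the peak-speed and day-3-speed
    *measurements*, i.e. of the per-condition mean over
    ``n_condition_plates`` plates (four plates per condition give a CV of
    roughly 5-8% for these quantities).
    """

    cv_peak: float = 0.055
    cv_day3: float = 0.077
    alpha: float = 0.05
    power: float = 0.8
    sided: Literal["one", "two"] = "one"
    n_control_plates: int = 30
    n_condition_plates: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")
        if self.sided not in ("one", "two"):
            raise ValueError("sided must be 'one' or 'two'")


@dataclass
class PowerResult:
    """Detectability summary: d_mu/sigma0 multiplier and fractional change."""

    multiplier: float
    min_detectable_fraction: float
    empirical_detection_rate: float | None = None


def min_detectable_shift(params: PowerParams) -> PowerResult:
    """Smallest detectable change in the peak-to-day-3 ratio (normal theory).

    multiplier = icdf(1 - alpha) + icdf(power), with 1 - alpha/2 for a
    two-sided test; the fractional change applies the multiplier to the
    ratio's CV obtained by naive error propagation,
    sqrt(cv_peak**2 + cv_day3**2).
    """
    tail = 1 - params.alpha if params.sided == "one" else 1 - params.alpha / 2
    multiplier = float(sps.norm.ppf(tail) + sps.norm.ppf(params.power))
    cv_ratio = math.hypot(params.cv_peak, params.cv_day3)
    return PowerResult(
        multiplier=multiplier,
        min_detectable_fraction=multiplier * cv_ratio,
    )


def _default_plate_generator(
    params: PowerParams,
) -> Callable[[np.random.Generator, int, float], tuple[np.ndarray, np.ndarray]]:
    """Normal per-plate (peak, day3) scores realizing the normal-ratio model.

    The analytic approximation treats the peak-to-day-3 ratio as a normal
    variable whose CV comes from naive error propagation,
    sqrt(cv_peak**2 + cv_day3**2).  This generator realizes exactly that:
    day3 = peak x ratio with the ratio drawn normal at the propagated CV (a
    plain ratio of two independent normals would be slightly skewed and
    over-dispersed relative to the approximation).  Per-plate CVs are
    ``cv * sqrt(n_condition_plates)`` so that the mean over a condition set
    of ``n_condition_plates`` plates has the stated measurement-level CV.
    """
    scale = math.sqrt(params.n_condition_plates)
    cv_ratio = math.hypot(params.cv_peak, params.cv_day3)

    def gen(rng: np.random.Generator, n: int, fold: float):
        # the fold change shifts the mean only, not the noise, matching the
        # analytic model's "increases only the mean" assumption
        peak = rng.normal(1.0, params.cv_peak * scale, n)
        ratio = rng.normal(fold, cv_ratio * scale, n)
        return peak, peak * ratio

    return gen


def monte_carlo_power(
    params: PowerParams,
    fold_change: float,
    n_reps: int = 2000,
    seed: int = 0,
    test: Literal["set_z", "rank"] = "set_z",
    generator: Callable[[np.random.Generator, int, float], tuple[np.ndarray, np.ndarray]]
    | None = None,
    n_resample_sets: int = 400,
) -> float:
    """Empirical detection rate for a day-3 fold change of ``fold_change``.

    Each repetition draws ``n_control_plates`` control plates and
    ``n_condition_plates`` condition plates (condition day-3 scores
    multiplied by ``fold_change``) from ``generator`` and computes per-plate
    day3/peak ratios.

    test="set_z" (default): the condition measurement is the mean ratio of
    its plate set; the null distribution of such measurements is estimated
    by resampling fictitious sets of the same size from the control plates,
    and the measurement is declared detected when it falls outside the
    alpha-level normal tail of that null.  This is the Monte Carlo analogue
    of the analytic ``min_detectable_shift`` approximation.

    test="rank": a Mann-Whitney U test between the control and condition
    per-plate ratios at level alpha (a plate-level comparison; it needs a
    larger fold change than the set-level test to reach the same power).

    Deterministic for a given seed.
    """
    if generator is None:
        generator = _default_plate_generator(params)
    rng = np.random.Generator(np.random.PCG64(seed))
    zcrit = (
        sps.norm.ppf(1 - params.alpha)
        if params.sided == "one"
        else sps.norm.ppf(1 - params.alpha / 2)
    )
    detected = 0
    n_ctrl = params.n_control_plates
    n_cond = params.n_condition_plates
    for _ in range(n_reps):
        cpk, cd3 = generator(rng, n_ctrl, 1.0)
        xpk, xd3 = generator(rng, n_cond, fold_change)
        with np.errstate(divide="ignore", invalid="ignore"):
            r_ctrl = cd3 / cpk
            r_cond = xd3 / xpk
        if test == "rank":
            if np.ptp(np.concatenate([r_ctrl, r_cond])) == 0:
                continue  # degenerate: never detected
            alt = "two-sided" if params.sided == "two" else "greater"
            p = sps.mannwhitneyu(r_cond, r_ctrl, alternative=alt).pvalue
            detected += p < params.alpha
        else:
            sets = rng.choice(r_ctrl, size=(n_resample_sets, n_cond), replace=True)
            null_means = sets.mean(axis=1)
            m_hat = null_means.mean()
            s_hat = null_means.std(ddof=1)
            x = r_cond.mean()
            if s_hat == 0:
                detected += x != m_hat
                continue
            z = (x - m_hat) / s_hat
            detected += (abs(z) > zcrit) if params.sided == "two" else (z > zcrit)
    return detected / n_reps


def fold_change_for_power(
    params: PowerParams,
    target_power: float = 0.8,
    n_reps: int = 1000,
    seed: int = 0,
    test: Literal["set_z", "rank"] = "rank",
    bracket: tuple[float, float] = (1.02, 2.0),
    tol: float = 0.005,
) -> float:
    """Fold change at which ``monte_carlo_power`` reaches ``target_power``.

    Bisection with common random numbers (the same seed at every candidate
    fold), under which the detection rate is monotone in the fold change.
    """
    lo, hi = bracket
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        rate = monte_carlo_power(params, mid, n_reps=n_reps, seed=seed, test=test)
        if rate < target_power:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
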