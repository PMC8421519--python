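"""AUC inflammation index, AUC-based group tests, and power analysis.

The cumulative severity of the hypothermic episode is summarized by the
area between the normal-temperature line and the fitted curve,

    AUC = integral_0^tmax (T_n - T(t)) dt          [degC * h],

evaluated on the model prediction rather than the sparse raw observations
(five samples in 24 h make raw-data interpolation unreliable).  Group
comparisons of the AUC need subject-level curves, so each subject gets an
individual fit of the damage and clearance parameters around the
population fit.  Power calculations use Cohen's d with the exact
noncentral-t power function of the two-sided two-sample t-test.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .data import Dataset
from .model import KineticParams, _predict_on_grid, _quadrature_grid, predict_temps
from .regression import FitResult, FitError
from .tables import PairwiseTable

__all__ = [
    "AUCSummary",
    "auc",
    "subject_aucs",
    "auc_group_tests",
    "cohens_d",
    "sample_size_ttest",
    "power_two_sample_t",
]

logger = logging.getLogger(__name__)

#: Quadrature step (hours) for the AUC integral; far below reporting precision.
AUC_STEP = 0.01

#: Minimum distinct sampling times for a subject-level fit.
MIN_TIMES_SUBJECT = 3


def auc(params: KineticParams, t_max: float = 24.0, step: float = AUC_STEP) -> float:
    """AUC of the model curve from 0 to ``t_max`` (degC * h).

    The trajectory is evaluated on a fine grid (default 0.01 h) and
    integrated with the trapezoid rule.  Excursions above ``T_n`` are
    integrated signed, not clipped.
    """
    if not t_max > 0:
        raise ValueError("t_max must be positive")
    grid = np.arange(0.0, t_max + step / 2.0, step)
    if grid[-1] < t_max:
        grid = np.append(grid, t_max)
    temps = predict_temps(params, grid)
    return float(np.trapezoid(params.T_n - temps, grid))


@dataclass
class AUCSummary:
    """Subject-level AUCs with group summaries.

    ``per_subject`` columns: subject, group, auc, p0, k, fallback (True when
    the clearance rate had to be fixed at the population value).
    ``group_stats`` columns: group, mean, sd, n.
    """

    per_subject: pd.DataFrame
    group_stats: pd.DataFrame
    t_max: float
    excluded: tuple = ()

    def group_values(self, group: str) -> np.ndarray:
        return self.per_subject.loc[
            self.per_subject["group"] == group, "auc"
        ].to_numpy()


def _fit_subject(times, log_obs, T_n, r, s, p0_start, k_start):
    """Least-squares fit of (log p0, log k) for one subject; k-fixed fallback."""
    grid, idx = _quadrature_grid(times)

    def resid2(x):
        pars = KineticParams(T_n=T_n, r=r, p0=math.exp(x[0]), k=math.exp(x[1]), s=s)
        pred = _predict_on_grid(pars, grid, idx)
        if not np.all(np.isfinite(pred)) or np.any(pred <= 0):
            return np.full(log_obs.shape, 1e3)
        return log_obs - np.log(pred)

    lo = [math.log(1e-4), math.log(1e-3)]
    hi = [math.log(50.0), math.log(10.0)]
    x0 = np.clip(
        [math.log(max(p0_start, 1e-3)), math.log(k_start)],
        np.array(lo) + 1e-9,
        np.array(hi) - 1e-9,
    )
    res = least_squares(resid2, x0, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12)
    if res.success and np.all(np.isfinite(res.x)):
        return math.exp(res.x[0]), math.exp(res.x[1]), False

    def resid1(x):
        pars = KineticParams(T_n=T_n, r=r, p0=math.exp(x[0]), k=k_start, s=s)
        pred = _predict_on_grid(pars, grid, idx)
        if not np.all(np.isfinite(pred)) or np.any(pred <= 0):
            return np.full(log_obs.shape, 1e3)
        return log_obs - np.log(pred)

    res1 = least_squares(
        resid1, x0[:1], bounds=(lo[:1], hi[:1]), method="trf", xtol=1e-12, ftol=1e-12
    )
    if res1.success and np.isfinite(res1.x[0]):
        return math.exp(res1.x[0]), k_start, True
    return None


def subject_aucs(
    dataset: Dataset, population_fit: FitResult, t_max: float = 24.0
) -> AUCSummary:
    """Per-subject AUCs from individual kinetic fits.

    Five observations cannot support four free parameters per animal, so
    the normal temperature and autoregulation force are fixed at the
    population-fit values (group-specific where stratified) and only the
    damage strength and clearance rate are estimated per subject, falling
    back to a fixed clearance rate when that fit fails.  Subjects whose fit
    still fails, or with fewer than 3 distinct sampling times, are excluded
    with a logged count.
    """
    if t_max > dataset.df["time_h"].max():
        logger.warning(
            "t_max=%.1f h extrapolates beyond the last observation (%.1f h)",
            t_max,
            dataset.df["time_h"].max(),
        )
    rows = []
    excluded = []
    for group in dataset.groups:
        T_n = population_fit.estimate("T_n", group)
        r = population_fit.estimate("r", group)
        p0_pop = population_fit.estimate("p0", group)
        k_pop = population_fit.estimate("k", group)
        s = population_fit.formula.s
        for subject in dataset.subjects_in(group):
            sub = dataset.subject_frame(subject).sort_values("time_h")
            times = sub["time_h"].to_numpy()
            if len(np.unique(times)) < MIN_TIMES_SUBJECT:
                excluded.append(subject)
                continue
            fitted = _fit_subject(
                times, np.log(sub["temp_C"].to_numpy()), T_n, r, s, p0_pop, k_pop
            )
            if fitted is None:
                excluded.append(subject)
                continue
            p0_i, k_i, fallback = fitted
            pars = KineticParams(T_n=T_n, r=r, p0=p0_i, k=k_i, s=s)
            rows.append(
                {
                    "subject": subject,
                    "group": group,
                    "auc": auc(pars, t_max=t_max),
                    "p0": p0_i,
                    "k": k_i,
                    "fallback": fallback,
                }
            )
    if excluded:
        logger.warning("%d subject(s) excluded from AUC analysis", len(excluded))
    per_subject = pd.DataFrame(rows)
    if per_subject.empty:
        raise FitError("no subject could be fitted for the AUC analysis")
    stats_df = (
        per_subject.groupby("group", sort=False)["auc"]
        .agg(mean="mean", sd="std", n="size")
        .reset_index()
    )
    return AUCSummary(
        per_subject=per_subject,
        group_stats=stats_df,
        t_max=t_max,
        excluded=tuple(excluded),
    )


def auc_group_tests(summary: AUCSummary, pairs=None) -> PairwiseTable:
    """One-way ANOVA plus BH-adjusted pairwise Welch t-tests on subject AUCs.

    The omnibus F statistic and p-value are stored in the table's ``extra``
    mapping under ``anova_F`` / ``anova_p``.
    """
    groups = list(summary.group_stats["group"])
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    samples = [summary.group_values(g) for g in groups]
    if any(len(x) < 2 for x in samples):
        raise ValueError("every group needs >= 2 subjects with AUCs")
    if all(np.ptp(x) == 0 for x in samples) and np.ptp(np.concatenate(samples)) == 0:
        anova_F, anova_p = 0.0, 1.0
    else:
        anova_F, anova_p = stats.f_oneway(*samples)
    if pairs is None:
        pairs = list(itertools.combinations(groups, 2))
    records = []
    for a, b in pairs:
        xa, xb = summary.group_values(a), summary.group_values(b)
        if np.ptp(np.concatenate([xa, xb])) == 0:
            records.append((a, b, 0.0, 1.0))
            continue
        t_stat, p = stats.ttest_ind(xa, xb, equal_var=False)
        records.append((a, b, float(t_stat), float(p)))
    return PairwiseTable.from_records(
        records,
        method="Welch t-test on subject AUCs",
        adjustment="benjamini-hochberg",
        extra={"anova_F": float(anova_F), "anova_p": float(anova_p), "t_max": summary.t_max},
    )


def cohens_d(delta: float, sd_pooled: float) -> float:
    """Cohen's effect size ``d = delta / sd_pooled`` (dimensionless)."""
    if not sd_pooled > 0:
        raise ValueError("sd_pooled must be positive")
    return float(delta) / float(sd_pooled)


def power_two_sample_t(d: float, n_per_group: int, alpha: float = 0.05) -> float:
    """Exact power of the two-sided two-sample t-test at effect size ``d``.

    Uses the noncentral-t distribution with ``2n - 2`` degrees of freedom
    and noncentrality ``d * sqrt(n/2)`` for equal group sizes ``n``.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    dof = 2 * n_per_group - 2
    nc = d * math.sqrt(n_per_group / 2.0)
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, dof)
    return float(stats.nct.sf(t_crit, dof, nc) + stats.nct.cdf(-t_crit, dof, nc))


def sample_size_ttest(
    d: float, alpha: float = 0.05, power: float = 0.80, n_max: int = 1_000_000
) -> int:
    """Smallest per-group ``n`` giving the requested two-sided t-test power.

    Integer search upward from 2 on the exact noncentral-t power function.
    """
    if not d > 0:
        raise ValueError("effect size d must be positive")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must be in (0, 1)")
    for n in range(2, n_max + 1):
        if power_two_sample_t(d, n, alpha) >= power:
            return n
    raise ValueError(f"requested power not attainable with n <= {n_max}")
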