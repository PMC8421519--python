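"""Likelihood-ratio machinery and comparator tests for grouped curves.

The working likelihood is the concentrated Gaussian likelihood of the
log-temperature residuals defined in :mod:`kinresp.regression`, under which
the deviance between nested least-squares fits reduces to
``n * log(RSS_reduced / RSS_full)``, referenced to a chi-square distribution
with the difference in parameter counts as degrees of freedom.

Whole-curve comparison of two groups follows the collapse construction:
refit after relabelling the pair as a single group and compare against the
fully stratified fit.  Comparisons across the integer gamma shape ``s`` use
the ad-hoc one-degree-of-freedom convention (``s`` is not a nested
continuous parameter, so this is a precision heuristic, not an exact test).
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import Dataset
from .regression import FitError, FitResult, Formula, fit
from .tables import PairwiseTable

__all__ = [
    "LRTest",
    "lr_test",
    "deviance",
    "select_shape",
    "pairwise_curve_tests",
    "single_timepoint_test",
    "timecourse_anova",
    "subsample_experiment",
    "SubsampleResult",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LRTest:
    """A likelihood-ratio comparison of two fits of the same data."""

    deviance: float
    df: int
    p: float


def deviance(full: FitResult, reduced: FitResult) -> float:
    """``2 log LR = n log(RSS_reduced / RSS_full)``, clipped at zero."""
    if full.n_obs != reduced.n_obs:
        raise ValueError(
            f"fits are on different data: n_obs {full.n_obs} != {reduced.n_obs}"
        )
    return max(full.n_obs * math.log(reduced.rss / full.rss), 0.0)


def lr_test(full: FitResult, reduced: FitResult) -> LRTest:
    """Likelihood-ratio test of a reduced fit against a nesting full fit.

    For fits with identical stratification but different gamma shape ``s``,
    the ad-hoc one-degree-of-freedom convention applies.  Otherwise the
    reduced stratification must nest in the full one and the degrees of
    freedom are the parameter-count difference.
    """
    if full.n_obs != reduced.n_obs:
        raise ValueError(
            f"fits are on different data: n_obs {full.n_obs} != {reduced.n_obs}"
        )
    if full.formula.s != reduced.formula.s:
        if not full.formula.same_stratification(reduced.formula):
            raise ValueError(
                "fits differ in both shape s and stratification; not comparable"
            )
        df = 1
    else:
        if not reduced.formula.is_nested_in(full.formula):
            raise ValueError("reduced formula is not nested in the full formula")
        df = full.n_params - reduced.n_params
        if df < 0:
            raise ValueError("full fit has fewer parameters than reduced fit")
    dev = deviance(full, reduced)
    p = 1.0 if df == 0 else float(stats.chi2.sf(dev, df))
    return LRTest(deviance=dev, df=df, p=p)


def select_shape(
    dataset: Dataset,
    formula: Formula,
    candidates=(1, 2, 3, 4),
    alpha: float = 0.05,
    *,
    multistart: bool = True,
) -> int:
    """Step-up selection of the integer gamma shape ``s``.

    Fits ``formula`` at each candidate shape in ascending order and steps to
    the larger shape while it improves the likelihood with ad-hoc 1-df
    significance below ``alpha``; stops at the first non-improvement.  A
    candidate whose fit fails is excluded with a warning.
    """
    cand = sorted(int(s) for s in candidates)
    if not cand or any(s < 1 for s in cand):
        raise ValueError("candidates must be positive integers")

    def fit_s(s):
        try:
            f = fit(dataset, formula.with_s(s), multistart=multistart)
        except FitError as exc:
            warnings.warn(f"shape s={s} excluded: {exc}", stacklevel=2)
            return None
        if not f.converged:
            warnings.warn(f"shape s={s} excluded: fit did not converge", stacklevel=2)
            return None
        return f

    current_s, current_fit = None, None
    for s in cand:
        f = fit_s(s)
        if f is None:
            if current_s is not None:
                break
            continue
        if current_fit is None:
            current_s, current_fit = s, f
            continue
        dev = current_fit.n_obs * math.log(current_fit.rss / f.rss)
        p = float(stats.chi2.sf(max(dev, 0.0), 1))
        logger.info(
            "shape selection: s=%d vs s=%d, deviance=%.2f, ad-hoc p=%.3g",
            s,
            current_s,
            dev,
            p,
        )
        if dev > 0 and p < alpha:
            current_s, current_fit = s, f
        else:
            break
    if current_s is None:
        raise FitError("no candidate shape could be fitted")
    return current_s


def _default_pairs(groups):
    return list(itertools.combinations(groups, 2))


def pairwise_curve_tests(
    dataset: Dataset,
    formula: Formula,
    pairs=None,
    *,
    full_fit: FitResult | None = None,
    multistart: bool = True,
) -> PairwiseTable:
    """Whole-curve LR comparison of every group pair by group collapsing.

    For each unordered pair the two groups are relabelled as one, the model
    is refitted, and the deviance against the fully stratified fit is
    referenced to a chi-square with as many degrees of freedom as there are
    stratified parameters in the formula.  Rows whose collapsed refit fails
    are flagged with NaN; the rest are returned.  P-values are reported raw
    (unadjusted), as is conventional for this table.
    """
    if len(dataset.groups) < 2:
        raise ValueError("need at least 2 groups for pairwise comparison")
    df_test = len(formula.by_group_params)
    if df_test == 0:
        raise ValueError("formula has no stratified parameters; groups are identical")
    if full_fit is None:
        full_fit = fit(dataset, formula, multistart=multistart)
    if pairs is None:
        pairs = _default_pairs(dataset.groups)

    records = []
    for a, b in pairs:
        try:
            collapsed = fit(dataset.merge_groups(a, b), formula, multistart=multistart)
            if not collapsed.converged:
                raise FitError(collapsed.message)
            dev = deviance(full_fit, collapsed)
            p = float(stats.chi2.sf(dev, df_test))
            records.append((a, b, dev, p))
        except (FitError, ValueError) as exc:
            logger.warning("pair (%s, %s) flagged: %s", a, b, exc)
            records.append((a, b, float("nan"), float("nan")))
    return PairwiseTable.from_records(
        records,
        method="whole-curve likelihood-ratio chi-square",
        adjustment="none",
        extra={"df": df_test, "formula": formula},
    )


def single_timepoint_test(dataset: Dataset, t: float, pairs=None) -> PairwiseTable:
    """Two-sided Welch t-tests on raw temperatures at a single time point.

    This is the conventional single-time-point comparison the kinetic
    analysis is benchmarked against.  P-values are Benjamini-Hochberg
    adjusted across the supplied pair family.
    """
    df = dataset.df
    at_t = df[np.isclose(df["time_h"], t)]
    if at_t.empty:
        raise ValueError(f"no measurements at t={t} h")
    if pairs is None:
        pairs = _default_pairs(dataset.groups)
    records = []
    for a, b in pairs:
        xa = at_t.loc[at_t["group"] == a, "temp_C"].to_numpy()
        xb = at_t.loc[at_t["group"] == b, "temp_C"].to_numpy()
        if len(xa) < 2 or len(xb) < 2:
            raise ValueError(
                f"group {a if len(xa) < 2 else b!r} has < 2 subjects at t={t} h"
            )
        if np.ptp(np.concatenate([xa, xb])) == 0:
            records.append((a, b, 0.0, 1.0))
            continue
        stat, p = stats.ttest_ind(xa, xb, equal_var=False)
        records.append((a, b, float(stat), float(p)))
    return PairwiseTable.from_records(
        records,
        method=f"Welch t-test at t={t} h",
        adjustment="benjamini-hochberg",
        extra={"t": t},
    )


def timecourse_anova(dataset: Dataset, pairs=None) -> PairwiseTable:
    """Pairwise linear-model (ANOVA-style) comparison of time courses.

    For each pair, the linear model ``log T ~ group + time + group:time``
    (time continuous) is tested against ``log T ~ time`` by a likelihood
    ratio on the Gaussian working likelihood — the standard linear
    comparator that ignores the nonlinear kinetics.
    """
    import statsmodels.formula.api as smf

    if pairs is None:
        pairs = _default_pairs(dataset.groups)
    df = dataset.df.assign(log_temp=np.log(dataset.df["temp_C"]))
    records = []
    for a, b in pairs:
        sub = df[df["group"].isin([a, b])]
        full = smf.ols("log_temp ~ C(group) * time_h", data=sub).fit()
        red = smf.ols("log_temp ~ time_h", data=sub).fit()
        n = len(sub)
        df_test = int(full.df_model - red.df_model)
        if df_test < 1:
            raise ValueError(f"collinear design for pair ({a}, {b})")
        if full.ssr <= 0:
            dev = 0.0
        else:
            dev = max(n * math.log(red.ssr / full.ssr), 0.0)
        p = float(stats.chi2.sf(dev, df_test))
        if red.ssr == full.ssr:
            p = 1.0
        records.append((a, b, dev, p))
    return PairwiseTable.from_records(
        records,
        method="linear-model LR (group + time + interaction vs time)",
        adjustment="none",
    )


@dataclass
class SubsampleResult:
    """Outcome of repeated reduced-sample reanalyses.

    ``concordance`` holds, per pair and method, the fraction of replicates
    whose significance call (at ``alpha``) agrees with the full-data call.
    """

    full_lr: PairwiseTable
    full_anova: PairwiseTable
    replicates: list = field(default_factory=list)
    concordance: pd.DataFrame | None = None
    alpha: float = 0.05

    @property
    def mean_concordance(self) -> pd.Series:
        return self.concordance.mean(axis=0)


def subsample_experiment(
    dataset: Dataset,
    n_per_group: int,
    n_reps: int,
    seed: int,
    *,
    formula: Formula,
    alpha: float = 0.05,
    multistart: bool = True,
) -> SubsampleResult:
    """Reduced-sample robustness experiment.

    Draws ``n_per_group`` subjects per group (without replacement, seeded),
    reruns the whole-curve LR table and the linear-model comparator on each
    replicate, and reports how often each pair's significance call agrees
    with the full-data conclusion.  With ``n_per_group`` equal to every
    group's size the replicates reproduce the full-data result exactly.
    """
    for g in dataset.groups:
        n_g = len(dataset.subjects_in(g))
        if n_g < n_per_group:
            raise ValueError(
                f"group {g!r} has {n_g} subjects, fewer than n_per_group={n_per_group}"
            )
    rng = np.random.default_rng(seed)
    full_lr = pairwise_curve_tests(dataset, formula, multistart=multistart)
    full_anova = timecourse_anova(dataset)
    pair_index = list(zip(full_lr.table["group1"], full_lr.table["group2"]))

    replicates = []
    agree = {"lr": [], "anova": []}
    for _ in range(n_reps):
        chosen = []
        for g in dataset.groups:
            subjects = sorted(dataset.subjects_in(g))
            chosen.extend(rng.choice(subjects, size=n_per_group, replace=False))
        sub = dataset.subset_subjects(chosen)
        rep_lr = pairwise_curve_tests(sub, formula, multistart=multistart)
        rep_anova = timecourse_anova(sub)
        replicates.append({"lr": rep_lr, "anova": rep_anova})
        for method, rep_tab, full_tab in (
            ("lr", rep_lr, full_lr),
            ("anova", rep_anova, full_anova),
        ):
            agree[method].append(
                [
                    (rep_tab.p_value(a, b) < alpha) == (full_tab.p_value(a, b) < alpha)
                    for a, b in pair_index
                ]
            )

    concordance = pd.DataFrame(
        {
            "lr": np.mean(agree["lr"], axis=0),
            "anova": np.mean(agree["anova"], axis=0),
        },
        index=pd.MultiIndex.from_tuples(pair_index, names=["group1", "group2"]),
    )
    return SubsampleResult(
        full_lr=full_lr,
        full_anova=full_anova,
        replicates=replicates,
        concordance=concordance,
        alpha=alpha,
    )
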