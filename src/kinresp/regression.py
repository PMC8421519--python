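"""Stratified nonlinear least-squares fitting of the kinetic model.

Grouped temperature time courses are fitted by minimizing the sum of squared
residuals of *log* temperature — the repeated measurements are approximately
lognormal, so the Gaussian working likelihood lives on the log scale.  Each
of the four kinetic parameters can independently be shared across groups or
stratified by group (dose-response style "prediction formulas"), which is
what makes nested likelihood-ratio comparisons of entire curves possible.

All four parameters are strictly positive and are optimized as logarithms;
point estimates, standard errors and Wald confidence intervals are formed on
the log scale and exponentiated, so intervals are asymmetric about the
natural-scale estimate by construction.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .data import Dataset
from .model import KineticParams, _predict_on_grid, _quadrature_grid
from .tables import PairwiseTable

__all__ = [
    "PARAM_NAMES",
    "Formula",
    "FitResult",
    "FitError",
    "count_parameters",
    "fit",
    "confidence_intervals",
    "compare_params",
    "concentrated_loglik",
]

logger = logging.getLogger(__name__)

PARAM_NAMES = ("T_n", "r", "p0", "k")

# Optimization box on the log scale; generous around physiological values.
_LOG_BOUNDS = {
    "T_n": (math.log(20.0), math.log(50.0)),
    "r": (math.log(1e-4), math.log(2.0)),
    "p0": (math.log(1e-4), math.log(50.0)),
    "k": (math.log(1e-3), math.log(10.0)),
}

#: Minimum number of distinct sampling times required per group for a
#: group-level fit (the standard design has 5: 0, 6, 12, 18, 24 h).
MIN_TIMES_GROUP = 5


class FitError(RuntimeError):
    """Raised when a fit cannot be attempted (invalid inputs or design)."""


@dataclass(frozen=True)
class Formula:
    """Stratification pattern: which parameters vary by group.

    Each of ``T_n``, ``r``, ``p0``, ``k`` is either ``"shared"`` (one value
    for all groups) or ``"by_group"`` (one value per group).  The gamma
    shape ``s`` is fixed, not estimated.

    The conventional ladder of prediction formulas is available through
    :meth:`pred`:

    ====== =========================================
    level  stratification
    ====== =========================================
    0      all four parameters by group
    1      T_n shared; r, k, p0 by group
    2      T_n, r shared; k, p0 by group
    3      T_n, r, k shared; p0 by group
    4      T_n, r, p0 shared; k by group
    ====== =========================================
    """

    T_n: str = "by_group"
    r: str = "by_group"
    p0: str = "by_group"
    k: str = "by_group"
    s: int = 1

    def __post_init__(self):
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if v not in ("shared", "by_group"):
                raise ValueError(
                    f"stratification for {name} must be 'shared' or 'by_group', got {v!r}"
                )
        if not float(self.s) == int(self.s) or int(self.s) < 1:
            raise ValueError(f"shape s must be a positive integer, got {self.s!r}")
        object.__setattr__(self, "s", int(self.s))

    @classmethod
    def pred(cls, level: int, s: int = 1) -> "Formula":
        patterns = {
            0: dict(T_n="by_group", r="by_group", p0="by_group", k="by_group"),
            1: dict(T_n="shared", r="by_group", p0="by_group", k="by_group"),
            2: dict(T_n="shared", r="shared", p0="by_group", k="by_group"),
            3: dict(T_n="shared", r="shared", p0="by_group", k="shared"),
            4: dict(T_n="shared", r="shared", p0="shared", k="by_group"),
        }
        if level not in patterns:
            raise ValueError(f"prediction formula level must be 0..4, got {level}")
        return cls(s=s, **patterns[level])

    def stratification(self, name: str) -> str:
        if name not in PARAM_NAMES:
            raise ValueError(f"unknown parameter {name!r}")
        return getattr(self, name)

    @property
    def by_group_params(self) -> tuple:
        return tuple(p for p in PARAM_NAMES if getattr(self, p) == "by_group")

    def with_s(self, s: int) -> "Formula":
        return replace(self, s=s)

    def n_parameters(self, n_groups: int) -> int:
        if n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        return sum(
            n_groups if getattr(self, p) == "by_group" else 1 for p in PARAM_NAMES
        )

    def is_nested_in(self, full: "Formula") -> bool:
        """True if every stratified parameter here is also stratified in ``full``."""
        return all(
            getattr(full, p) == "by_group"
            for p in PARAM_NAMES
            if getattr(self, p) == "by_group"
        )

    def same_stratification(self, other: "Formula") -> bool:
        return all(getattr(self, p) == getattr(other, p) for p in PARAM_NAMES)


def count_parameters(formula: Formula, n_groups: int) -> int:
    """Degrees-of-freedom bookkeeping used by likelihood-ratio tests."""
    return formula.n_parameters(n_groups)


def parameter_keys(formula: Formula, groups) -> tuple:
    """Packing order of the optimized parameter vector.

    Keys are ``(name, stratum)`` with ``stratum`` a group label for
    stratified parameters and ``None`` for shared ones.
    """
    keys = []
    for name in PARAM_NAMES:
        if getattr(formula, name) == "by_group":
            keys.extend((name, g) for g in groups)
        else:
            keys.append((name, None))
    return tuple(keys)


def concentrated_loglik(rss: float, n_obs: int) -> float:
    """Gaussian log-likelihood with the residual variance profiled out.

    ``l = -(n/2) (log(2 pi rss / n) + 1)``.  Shared by fitting and the
    likelihood-ratio machinery so deviances are self-consistent.
    """
    rss = max(float(rss), 1e-300)
    return -0.5 * n_obs * (math.log(2.0 * math.pi * rss / n_obs) + 1.0)


@dataclass
class FitResult:
    """Stratified log-level estimates with the quantities LR tests need."""

    formula: Formula
    groups: tuple
    keys: tuple
    log_estimates: dict
    log_se: dict
    cov_log: np.ndarray | None
    rss: float
    n_obs: int
    n_params: int
    loglik: float
    converged: bool
    message: str = ""
    singular: bool = False
    n_starts: int = 1
    estimates: dict = field(init=False)

    def __post_init__(self):
        self.estimates = {k: math.exp(v) for k, v in self.log_estimates.items()}

    @property
    def df_resid(self) -> int:
        return self.n_obs - self.n_params

    def estimate(self, name: str, group: str | None = None) -> float:
        """Natural-scale estimate of a parameter (group label for stratified)."""
        key = (name, group if self.formula.stratification(name) == "by_group" else None)
        return self.estimates[key]

    def group_params(self, group: str) -> KineticParams:
        """Kinetic parameters implied by the fit for one group."""
        return KineticParams(
            T_n=self.estimate("T_n", group),
            r=self.estimate("r", group),
            p0=self.estimate("p0", group),
            k=self.estimate("k", group),
            s=self.formula.s,
        )

    def summary(self):
        """Tidy frame of estimates with log-scale standard errors."""
        import pandas as pd

        rows = [
            {
                "parameter": name,
                "stratum": "(shared)" if g is None else g,
                "estimate": self.estimates[(name, g)],
                "log_estimate": self.log_estimates[(name, g)],
                "log_se": self.log_se.get((name, g), float("nan")),
            }
            for (name, g) in self.keys
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _group_arrays(dataset: Dataset, groups):
    """Per-group quadrature grids, observation indices and log temperatures."""
    out = []
    for g in groups:
        sub = dataset.group_frame(g)
        t_unique, inv = np.unique(sub["time_h"].to_numpy(), return_inverse=True)
        grid, idx = _quadrature_grid(t_unique)
        out.append((g, grid, idx, inv, np.log(sub["temp_C"].to_numpy())))
    return out


def _starting_values(dataset: Dataset, formula: Formula, groups) -> dict:
    """Deterministic starting rule from coarse curve features.

    T_n starts at the maximum of the group's mean temperature profile, p0 at
    the log-drop ``ln(T(0)/T_min)`` of that profile (the depth the damage
    term alone would produce), r and k at typical murine values.
    """
    per_group = {}
    for g in groups:
        sub = dataset.group_frame(g)
        prof = sub.groupby("time_h")["temp_C"].mean().sort_index()
        t_start = float(prof.iloc[0])
        t_min = float(prof.min())
        per_group[g] = {
            "T_n": float(prof.max()),
            "r": 0.05,
            "p0": max(math.log(t_start / t_min), 0.01),
            "k": 0.4,
        }
    start = {}
    for name, g in parameter_keys(formula, groups):
        if g is not None:
            start[(name, g)] = per_group[g][name]
        elif name == "T_n":
            start[(name, None)] = max(v["T_n"] for v in per_group.values())
        elif name == "p0":
            start[(name, None)] = float(
                np.mean([v["p0"] for v in per_group.values()])
            )
        else:
            start[(name, None)] = per_group[groups[0]][name]
    return start


def _make_residual(group_data, formula: Formula, keys, groups):
    kidx = {key: i for i, key in enumerate(keys)}
    strat = {name: formula.stratification(name) for name in PARAM_NAMES}
    s = formula.s

    def theta_to_params(theta, g):
        def get(name):
            stratum = g if strat[name] == "by_group" else None
            return math.exp(theta[kidx[(name, stratum)]])

        return KineticParams(T_n=get("T_n"), r=get("r"), p0=get("p0"), k=get("k"), s=s)

    def residual(theta):
        parts = []
        for g, grid, idx, inv, log_obs in group_data:
            pars = theta_to_params(theta, g)
            pred = _predict_on_grid(pars, grid, idx)
            if not np.all(np.isfinite(pred)) or np.any(pred <= 0):
                parts.append(np.full(log_obs.shape, 1e3))
                continue
            parts.append(log_obs - np.log(pred)[inv])
        return np.concatenate(parts)

    return residual, theta_to_params


def fit(
    dataset: Dataset,
    formula: Formula,
    *,
    multistart: bool = True,
    start_values: dict | None = None,
) -> FitResult:
    """Fit the kinetic model to grouped data by log-scale least squares.

    Minimizes ``sum (log T_obs - log T_pred)^2`` over log-parameters with a
    trust-region reflective solver inside generous positivity bounds.  A
    small deterministic multi-start grid (p0 and k starts scaled by 0.5, 1
    and 2) guards against local minima; the best residual sum of squares
    wins, so the result is deterministic given the data.

    Non-convergence is reported through ``converged``/``message`` on the
    returned result, never silently.  ``start_values`` (natural-scale values
    keyed like the packed parameters) overrides the deterministic starting
    rule, e.g. for robustness checks against perturbed starts.
    """
    groups = dataset.groups
    if dataset.n_obs == 0 or not groups:
        raise FitError("dataset is empty")
    for g in groups:
        n_times = dataset.group_frame(g)["time_h"].nunique()
        if n_times < MIN_TIMES_GROUP:
            raise FitError(
                f"group {g!r} has only {n_times} distinct sampling times; "
                f"group-level fitting needs >= {MIN_TIMES_GROUP}"
            )

    keys = parameter_keys(formula, groups)
    group_data = _group_arrays(dataset, groups)
    residual, _ = _make_residual(group_data, formula, keys, groups)

    start = _starting_values(dataset, formula, groups)
    if start_values:
        start.update(start_values)
    lb = np.array([_LOG_BOUNDS[name][0] for name, _ in keys])
    ub = np.array([_LOG_BOUNDS[name][1] for name, _ in keys])
    x0 = np.array([math.log(start[key]) for key in keys])
    x0 = np.clip(x0, lb + 1e-9, ub - 1e-9)

    scales = (1.0, 0.5, 2.0) if multistart else (1.0,)
    shift_idx = [i for i, (name, _) in enumerate(keys) if name in ("p0", "k")]

    best = None
    for scale in scales:
        x_start = x0.copy()
        x_start[shift_idx] += math.log(scale)
        x_start = np.clip(x_start, lb + 1e-9, ub - 1e-9)
        res = least_squares(
            residual,
            x_start,
            bounds=(lb, ub),
            method="trf",
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
        )
        if best is None or 2 * res.cost < 2 * best.cost - 1e-14:
            best = res

    res = best
    rss = float(res.fun @ res.fun)
    n_obs = dataset.n_obs
    n_params = len(keys)
    converged = bool(res.success and np.all(np.isfinite(res.x)))

    # Gauss-Newton covariance of the log-parameters
    cov = None
    log_se = {}
    singular = False
    dof = n_obs - n_params
    if converged and dof > 0:
        J = res.jac
        JTJ = J.T @ J
        sigma2 = rss / dof
        rank = np.linalg.matrix_rank(JTJ)
        if rank < n_params:
            singular = True
            cov = sigma2 * np.linalg.pinv(JTJ)
        else:
            cov = sigma2 * np.linalg.inv(JTJ)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        log_se = {key: float(se[i]) for i, key in enumerate(keys)}

    result = FitResult(
        formula=formula,
        groups=tuple(groups),
        keys=keys,
        log_estimates={key: float(res.x[i]) for i, key in enumerate(keys)},
        log_se=log_se,
        cov_log=cov,
        rss=rss,
        n_obs=n_obs,
        n_params=n_params,
        loglik=concentrated_loglik(rss, n_obs),
        converged=converged,
        message=str(res.message),
        singular=singular,
        n_starts=len(scales),
    )
    if not converged:
        logger.warning("fit did not converge: %s (formula=%s)", res.message, formula)
    return result


def confidence_intervals(fit_result: FitResult, level: float = 0.95) -> dict:
    """Natural-scale Wald intervals from the log-scale fit.

    Endpoints are ``exp(log_estimate +- t_q * log_se)`` with a Student-t
    quantile on ``n_obs - n_params`` residual degrees of freedom; the
    exponentiation makes them asymmetric about the point estimate.  Entries
    with unavailable curvature (singular fits) are ``None``.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if not fit_result.converged:
        raise FitError("confidence intervals require a converged fit")
    tq = stats.t.ppf(0.5 + level / 2.0, fit_result.df_resid)
    out = {}
    for key in fit_result.keys:
        se = fit_result.log_se.get(key)
        if se is None or not np.isfinite(se) or (fit_result.singular and se == 0):
            out[key] = None
            continue
        centre = fit_result.log_estimates[key]
        out[key] = (math.exp(centre - tq * se), math.exp(centre + tq * se))
    return out


def compare_params(
    fit_result: FitResult, parameter: str, pairs=None
) -> PairwiseTable:
    """Pairwise two-sided t-tests of a stratified parameter between groups.

    Contrasts are formed on the log scale; the contrast variance uses the
    full Gauss-Newton covariance (including the covariance term, since
    strata share residual information through shared parameters).  The
    p-values are referenced to a Student-t distribution with the residual
    degrees of freedom and Benjamini-Hochberg adjusted across the supplied
    family (default: all unordered group pairs).
    """
    if parameter not in PARAM_NAMES:
        raise ValueError(f"unknown parameter {parameter!r}")
    if fit_result.formula.stratification(parameter) != "by_group":
        raise FitError(
            f"parameter {parameter!r} is shared in this fit; no strata to contrast"
        )
    if fit_result.cov_log is None:
        raise FitError("parameter contrasts require a converged, non-degenerate fit")
    if pairs is None:
        pairs = list(itertools.combinations(fit_result.groups, 2))

    kidx = {key: i for i, key in enumerate(fit_result.keys)}
    dof = fit_result.df_resid
    records = []
    for a, b in pairs:
        ia, ib = kidx[(parameter, a)], kidx[(parameter, b)]
        diff = fit_result.log_estimates[(parameter, a)] - fit_result.log_estimates[
            (parameter, b)
        ]
        var = (
            fit_result.cov_log[ia, ia]
            + fit_result.cov_log[ib, ib]
            - 2.0 * fit_result.cov_log[ia, ib]
        )
        if var <= 0 or not np.isfinite(var):
            records.append((a, b, float("nan"), float("nan")))
            continue
        t_stat = diff / math.sqrt(var)
        p = 2.0 * stats.t.sf(abs(t_stat), dof)
        records.append((a, b, t_stat, p))
    return PairwiseTable.from_records(
        records,
        method=f"log-scale t contrast of {parameter}",
        adjustment="benjamini-hochberg",
        extra={"df": dof, "parameter": parameter},
    )
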