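"""Mixed-model and permutation comparisons of partner traits.

Category and month effects on a partner trait are tested with normal-response
linear mixed models fitted by maximum likelihood: the factor of interest is
fixed, and random intercepts are included for community and for month nested
within community.  Contrasts are reported with Wald z statistics; families
of contrasts receive a single-step (max-|Z|) multiplicity adjustment
computed from the joint normal distribution of the contrast estimates — the
same adjustment multcomp's ``glht`` applies.  When the random structure is
degenerate (zero estimated variance, or too few groups), the degenerate term
is dropped and the refit is flagged in the result.

A stratified permutation test (labels shuffled within community-month
strata) is provided as a small-sample alternative with exact finite-sample
validity.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("pollinet")

ALPHA_LEVELS = (0.05, 0.001)  # presentation thresholds: * and ***


@dataclass(frozen=True)
class ComparisonSpec:
    """What to compare: one trait, one factor, optional log transform."""

    trait: str
    guild: str = "visitor"
    factor: Literal["category", "month"] = "category"
    transform: Literal["none", "log"] = "none"
    method: Literal["mixed_model", "permutation"] = "mixed_model"


@dataclass
class ComparisonResult:
    contrast: str
    estimate: float
    se: float
    z: float
    p: float
    p_adj: float
    n: int
    flags: tuple[str, ...] = ()

    def significance(self) -> str:
        if self.p_adj < 0.001:
            return "***"
        if self.p_adj < 0.05:
            return "*"
        return ""


def _prepare(df: pd.DataFrame, value_col: str, transform: str) -> pd.DataFrame:
    data = df.copy()
    if transform == "log":
        if (data[value_col] <= 0).any():
            raise ValueError("log transform requires strictly positive trait values")
        data[value_col] = np.log(data[value_col])
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    return data


def _fit_lmm(data: pd.DataFrame, value_col: str, factor_col: str):
    """ML mixed-model fit with a fallback chain for degenerate variance.

    Returns (params, cov, names, flags): fixed-effect estimates, their
    covariance, coefficient names, and flags describing any simplification.
    """
    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    formula = f"{value_col} ~ C({factor_col})"
    flags: list[str] = []
    if float(np.std(data[value_col].to_numpy(dtype=float))) < 1e-12:
        # a perfectly constant response carries no evidence either way
        flags.append("constant_response")

    def _extract(fit):
        fe = fit.fe_params if hasattr(fit, "fe_params") else fit.params
        names = list(fe.index)
        cov = np.asarray(fit.cov_params())[: len(names), : len(names)]
        return np.asarray(fe), cov, names

    attempts = [
        ("full", dict(re_formula="1", vc_formula={"cm": "0 + C(month)"})),
        ("community_only", dict(re_formula="1")),
    ]
    n_comm = data["community"].nunique()
    n_cm = data.groupby(["community", "month"]).ngroups
    if n_comm < 2:
        attempts = []
        flags.append("no_random_structure")
    elif n_cm <= n_comm:
        attempts = attempts[1:]
        flags.append("month_term_dropped:degenerate_strata")
    for name, kw in attempts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                warnings.simplefilter("ignore", UserWarning)
                md = smf.mixedlm(formula, data, groups=data["community"], **kw)
                fit = md.fit(reml=False, method="lbfgs", maxiter=200)
            params, cov, names = _extract(fit)
            if not (np.isfinite(params).all() and np.isfinite(cov).all()):
                raise ValueError("non-finite mixed-model estimates")
            if (np.diag(cov) <= 0).any():
                raise ValueError("degenerate fixed-effect covariance")
            # singular random structure -> refit without the degenerate term
            vcomp = getattr(fit, "vcomp", np.array([]))
            if name == "full" and vcomp.size and (vcomp < 1e-8).all():
                flags.append("month_variance_zero:refit")
                continue
            if name != "full":
                flags.append(f"random_structure:{name}")
            return params, cov, names, tuple(flags)
        except Exception as exc:  # singular fits raise LinAlgError and kin
            flags.append(f"{name}_failed:{type(exc).__name__}")
            continue
    # final fallback: ordinary least squares
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.ols(formula, data).fit()
    params, cov, names = _extract(fit)
    flags.append("fallback:ols")
    return params, cov, names, tuple(flags)


def single_step_adjust(
    z: np.ndarray, cov: np.ndarray, n_samples: int = 40000, seed: int = 0
) -> np.ndarray:
    """max-|Z| single-step adjusted p-values for a family of Wald contrasts.

    p_adj[k] = 1 - P(|Z_j| <= |z_k| for all j) under the joint normal with
    the contrasts' correlation matrix, estimated by seeded Monte Carlo over
    the (possibly rank-deficient) correlation.  For a family of one this
    reduces to the two-sided raw p, which is also a hard lower bound so the
    adjusted value is never below the raw one.
    """
    z = np.atleast_1d(np.asarray(z, dtype=float))
    k = z.size
    raw = 2 * stats.norm.sf(np.abs(z))
    if k == 1:
        return raw
    sd = np.sqrt(np.diag(cov))
    corr = cov / np.outer(sd, sd)
    corr = (corr + corr.T) / 2
    vals, vecs = np.linalg.eigh(corr)
    factor = vecs * np.sqrt(np.clip(vals, 0.0, None))
    rng = np.random.default_rng(seed)
    maxabs = np.abs(rng.standard_normal((n_samples, k)) @ factor.T).max(axis=1)
    p_adj = np.array([(maxabs >= zi).mean() for zi in np.abs(z)])
    return np.clip(np.maximum(p_adj, raw), 0.0, 1.0)


def _contrast_results(
    params: np.ndarray,
    cov: np.ndarray,
    names: list[str],
    contrasts: list[tuple[str, np.ndarray]],
    n: int,
    flags: tuple[str, ...],
) -> list[ComparisonResult]:
    L = np.vstack([c for _, c in contrasts])
    est = L @ params
    vcov = L @ cov @ L.T
    se = np.sqrt(np.maximum(np.diag(vcov), 1e-300))
    if "constant_response" in flags:
        est = np.zeros_like(est)
        z = np.zeros_like(est)
        p = np.ones_like(est)
        p_adj = np.ones_like(est)
    else:
        z = est / se
        p = 2 * stats.norm.sf(np.abs(z))
        p_adj = single_step_adjust(z, vcov)
    return [
        ComparisonResult(
            contrast=label,
            estimate=float(e),
            se=float(s),
            z=float(zz),
            p=float(pp),
            p_adj=float(pa),
            n=n,
            flags=flags,
        )
        for (label, _), e, s, zz, pp, pa in zip(contrasts, est, se, z, p, p_adj)
    ]


def _level_columns(names: list[str], factor_col: str, levels: list) -> dict:
    """Map factor level -> indicator vector over the fixed-effect columns
    (reference level maps to the intercept-only vector)."""
    k = len(names)
    cols = {}
    for lev in levels:
        vec = np.zeros(k)
        vec[0] = 1.0  # intercept
        key = f"C({factor_col})[T.{lev}]"
        if key in names:
            vec[names.index(key)] = 1.0
        cols[lev] = vec
    return cols


def compare_categories(
    profiles: pd.DataFrame,
    spec: ComparisonSpec,
    value_col: str | None = None,
) -> list[ComparisonResult]:
    """Test a trait difference between specialization categories.

    ``profiles`` needs columns: the trait, ``category``, ``community`` and
    ``month``.  Fits trait ~ category with random intercepts for community
    and month-within-community; reports one Wald-z contrast per non-reference
    category, single-step adjusted over the family.
    """
    value_col = value_col or spec.trait
    data = _prepare(profiles, value_col, spec.transform)
    levels = sorted(data["category"].unique())
    if len(levels) < 2:
        raise ValueError("need at least two categories to compare")
    counts = data.groupby("category")[value_col].count()
    if (counts < 2).any():
        raise ValueError("every category needs at least two observations")
    params, cov, names, flags = _fit_lmm(data, value_col, "category")
    lev_cols = _level_columns(names, "category", levels)
    ref = levels[0]
    contrasts = [
        (f"{lev} - {ref}", lev_cols[lev] - lev_cols[ref]) for lev in levels[1:]
    ]
    return _contrast_results(params, cov, names, contrasts, len(data), flags)


def compare_months(
    profiles: pd.DataFrame,
    spec: ComparisonSpec,
    value_col: str | None = None,
) -> tuple[list[ComparisonResult], dict[int, str]]:
    """All-pairs month contrasts for one category's profiles, with compact
    letter-display groups (months sharing a letter do not differ)."""
    value_col = value_col or spec.trait
    data = _prepare(profiles, value_col, spec.transform)
    month_counts = data.groupby("month")[value_col].count()
    thin = month_counts[month_counts < 2].index.tolist()
    if thin:
        logger.warning("dropping month(s) with a single observation: %s", thin)
        data = data[~data["month"].isin(thin)]
    levels = sorted(data["month"].unique())
    if len(levels) < 2:
        raise ValueError("need at least two months represented")
    params, cov, names, flags = _fit_lmm(data, value_col, "month")
    lev_cols = _level_columns(names, "month", levels)
    contrasts = [
        (f"month {b} - month {a}", lev_cols[b] - lev_cols[a])
        for a, b in itertools.combinations(levels, 2)
    ]
    results = _contrast_results(params, cov, names, contrasts, len(data), flags)
    sig_pairs = {
        frozenset(pair): res.p_adj < 0.05
        for pair, res in zip(itertools.combinations(levels, 2), results)
    }
    letters = significance_letters(levels, sig_pairs)
    return results, letters


def significance_letters(levels: Sequence, sig_pairs: dict) -> dict:
    """Compact letter display via insert-and-absorb.

    ``sig_pairs`` maps frozenset({a, b}) -> True when a and b differ
    significantly.  Levels sharing a letter are mutually non-significant.
    """
    groups: list[set] = [set(levels)]
    for pair, sig in sig_pairs.items():
        if not sig:
            continue
        a, b = tuple(pair)
        new_groups: list[set] = []
        for g in groups:
            if a in g and b in g:
                new_groups.append(g - {a})
                new_groups.append(g - {b})
            else:
                new_groups.append(g)
        # absorb subsets
        groups = []
        for g in sorted(new_groups, key=len, reverse=True):
            if g and not any(g <= h for h in groups):
                groups.append(g)
    groups.sort(key=lambda g: (min(levels.index(x) for x in g), -len(g)))
    out: dict = {lev: "" for lev in levels}
    for letter, g in zip("abcdefghijklmnopqrstuvwxyz", groups):
        for lev in g:
            out[lev] += letter
    return {lev: "".join(sorted(s)) for lev, s in out.items()}


def permutation_compare(
    profiles: pd.DataFrame,
    spec: ComparisonSpec,
    n_perm: int = 999,
    seed: int = 0,
    value_col: str | None = None,
) -> list[ComparisonResult]:
    """Stratified permutation test of a two-level category difference.

    Labels are shuffled within (community, month) strata; the statistic is
    the difference of category means.  p = (1 + #{|T*| >= |T|}) / (1 + n).
    Strata with fewer than two observations are excluded (flagged).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    value_col = value_col or spec.trait
    data = _prepare(profiles, value_col, spec.transform)
    levels = sorted(data["category"].unique())
    if len(levels) != 2:
        raise ValueError("permutation comparison requires exactly two categories")
    sizes = data.groupby(["community", "month"])[value_col].transform("size")
    flags: tuple[str, ...] = ()
    if (sizes < 2).any():
        flags = ("strata_excluded:singletons",)
        data = data[sizes >= 2]
    a, b = levels
    values = data[value_col].to_numpy()
    labels = data["category"].to_numpy()
    strata = data.groupby(["community", "month"]).indices

    def statistic(lab):
        return values[lab == b].mean() - values[lab == a].mean()

    t_obs = statistic(labels)
    rng = np.random.default_rng(seed)
    hits = 0
    lab = labels.copy()
    for _ in range(n_perm):
        for idx in strata.values():
            lab[idx] = rng.permutation(lab[idx])
        if abs(statistic(lab)) >= abs(t_obs) - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    se = abs(t_obs) / max(abs(stats.norm.ppf(p / 2)), 1e-6)
    return [
        ComparisonResult(
            contrast=f"{b} - {a}",
            estimate=float(t_obs),
            se=float(se),
            z=float("nan"),
            p=float(p),
            p_adj=float(p),
            n=len(data),
            flags=flags,
        )
    ]


def results_frame(results: Sequence[ComparisonResult], **extra) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                **extra,
                "contrast": r.contrast,
                "estimate": r.estimate,
                "se": r.se,
                "z": r.z,
                "p": r.p,
                "p_adj": r.p_adj,
                "n": r.n,
                "significance": r.significance(),
                "flags": ";".join(r.flags),
            }
        )
    return pd.DataFrame(rows)
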