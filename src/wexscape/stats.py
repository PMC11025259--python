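"""Two-cohort comparison statistics.

Continuous per-sample features are compared with the Wilcoxon rank-sum
test (exact for small tie-free samples, normal approximation with tie
correction otherwise); binary features with Fisher's exact test (two-sided
p as the sum of hypergeometric probabilities not exceeding that of the
observed table; conditional-MLE odds ratio).  Covariate adjustment uses a
logistic model of the group indicator on the feature plus subtype/age
terms, reporting the Wald p-value and odds ratio per feature unit.
Multiple testing within a family is controlled by Benjamini–Hochberg
q-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats.contingency import odds_ratio as _odds_ratio
from statsmodels.stats.multitest import multipletests

from .core import CohortDataset, Group, ValidationError


@dataclass
class ComparisonResult:
    feature: str
    test: str                     # wilcoxon | fisher | logit
    statistic: float
    p_value: float
    odds_ratio: Optional[float] = None
    q_value: Optional[float] = None
    group_summaries: dict = field(default_factory=dict)
    adjusted: Optional["ComparisonResult"] = None
    unreliable: bool = False      # e.g. separation in the logistic model


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Rank-sum test: exact p for pooled n <= 20 without ties, otherwise
    normal approximation with tie correction.  Returns (U statistic of the
    first sample, two-sided p)."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def fisher_exact(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    Returns (conditional-MLE odds ratio, two-sided p).  Each margin must
    be positive.
    """
    table = np.array([[a, b], [c, d]], dtype=int)
    if (table < 0).any():
        raise ValidationError("table entries must be nonnegative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValidationError("every margin of the 2x2 table must be positive")
    _, p = sps.fisher_exact(table, alternative="two-sided")
    or_ = _odds_ratio(table, kind="conditional").statistic
    return float(or_), float(p)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def logit_adjusted(
    group: Sequence[int],
    feature: Sequence[float],
    subtype: Optional[Sequence[str]] = None,
    age: Optional[Sequence[float]] = None,
) -> ComparisonResult:
    """Logistic regression of the group indicator (1 = case cohort) on the
    feature plus covariates; Wald p and OR = exp(beta) for the feature.

    Perfect separation is flagged via ``unreliable`` rather than raised.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    y = np.asarray(list(group), dtype=float)
    f = np.asarray(list(feature), dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValidationError("group must be 0/1 coded")
    data = {"feature": f}
    X = pd.DataFrame(data)
    if subtype is not None:
        dummies = pd.get_dummies(pd.Series(list(subtype)), prefix="subtype", drop_first=True)
        if dummies.shape[1] == 0:
            pass  # single subtype level: adjustment degenerates to crude model
        X = pd.concat([X, dummies.astype(float)], axis=1)
    if age is not None:
        X["age"] = np.asarray(list(age), dtype=float)
    X = sm.add_constant(X, has_constant="add")
    unreliable = False
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except (PerfectSeparationWarning, Exception):
            # refit with regularisation for a usable (flagged) estimate
            unreliable = True
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, X).fit_regularized(disp=0, alpha=1e-4, maxiter=500)
    beta = float(fit.params["feature"])
    try:
        p = float(fit.pvalues["feature"])
    except Exception:
        p, unreliable = float("nan"), True
    if not np.isfinite(p):
        unreliable = True
    return ComparisonResult(
        feature="feature",
        test="logit",
        statistic=beta,
        p_value=p,
        odds_ratio=float(np.exp(beta)),
        unreliable=unreliable,
    )


def compare_feature(
    dataset: CohortDataset,
    feature: Callable[[str], float],
    name: str,
    kind: str = "continuous",
    adjust: Sequence[str] = (),
    case_group: Group = Group.IBC,
) -> ComparisonResult:
    """Compare one per-sample feature between the two groups.

    ``feature`` maps sample_id -> value (NaN to skip a sample).
    ``kind='continuous'`` dispatches to Wilcoxon with median (range)
    summaries; ``kind='binary'`` to Fisher with n/% summaries.  With
    ``adjust`` (subset of {"subtype", "age"}) an adjusted logistic result
    is attached.
    """
    values, groups, subtypes, ages = [], [], [], []
    for s in dataset.samples:
        v = feature(s.sample_id)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            continue
        values.append(float(v))
        groups.append(s.group)
        subtypes.append(s.subtype.value)
        ages.append(s.age)
    if not values:
        raise ValidationError(f"feature {name!r} is missing for every sample")
    values = np.array(values)
    is_case = np.array([g is case_group for g in groups])
    if is_case.all() or (~is_case).all():
        raise ValidationError(f"feature {name!r}: need samples in both groups")
    x, y = values[is_case], values[~is_case]
    other = next(g for g in groups if g is not case_group)
    if kind == "continuous":
        stat, p = wilcoxon_rank_sum(x, y)
        result = ComparisonResult(
            feature=name, test="wilcoxon", statistic=stat, p_value=p,
            group_summaries={
                case_group.value: _median_range(x),
                other.value: _median_range(y),
            },
        )
    elif kind == "binary":
        a, b = int(x.sum()), int(len(x) - x.sum())
        c, d = int(y.sum()), int(len(y) - y.sum())
        if a + c == 0 or b + d == 0:
            # constant feature: no association to test
            or_, p = float("nan"), 1.0
        else:
            or_, p = fisher_exact(a, b, c, d)
        result = ComparisonResult(
            feature=name, test="fisher", statistic=float("nan"), p_value=p,
            odds_ratio=or_,
            group_summaries={
                case_group.value: {"n_pos": a, "n": a + b, "pct": 100.0 * a / (a + b)},
                other.value: {"n_pos": c, "n": c + d, "pct": 100.0 * c / (c + d)},
            },
        )
    else:
        raise ValidationError(f"unknown feature kind {kind!r}")
    if adjust:
        result.adjusted = logit_adjusted(
            is_case.astype(int), values,
            subtype=subtypes if "subtype" in adjust else None,
            age=ages if "age" in adjust else None,
        )
        result.adjusted.feature = name
    return result


def _median_range(v: np.ndarray) -> dict:
    return {"median": float(np.median(v)), "min": float(v.min()), "max": float(v.max())}


def apply_fdr(results: Sequence[ComparisonResult]) -> list[ComparisonResult]:
    """Attach BH q-values across one family of comparisons."""
    q = bh_fdr([r.p_value for r in results])
    for r, qv in zip(results, q):
        r.q_value = float(qv)
    return list(results)


def results_to_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "feature": r.feature, "test": r.test, "statistic": r.statistic,
            "odds_ratio": r.odds_ratio, "p_value": r.p_value, "q_value": r.q_value,
        }
        for grp, summ in r.group_summaries.items():
            for k, v in summ.items():
                row[f"{grp}_{k}"] = v
        if r.adjusted is not None:
            row["adjusted_or"] = r.adjusted.odds_ratio
            row["adjusted_p"] = r.adjusted.p_value
            row["adjusted_unreliable"] = r.adjusted.unreliable
        rows.append(row)
    return pd.DataFrame(rows)
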