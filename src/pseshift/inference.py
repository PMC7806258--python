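"""Classical inference on PSE shifts, difference limens and covariates.

The study designs are fully balanced and complete, so all repeated-measures
and mixed ANOVAs reduce to an orthogonal sum-of-squares decomposition with
the participant as the within-subject error stratum: each effect is tested
against the interaction of its within-subject part with subjects nested in
between-subject groups.  F tests are uncorrected for sphericity.  All
p-values are two-sided.

Emitted results carry the field's standard effect sizes and their printed
identities hold by construction: Cohen's dz = t / sqrt(n) for paired designs
and partial eta^2 = F*df1 / (F*df1 + df2) for ANOVA effects.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "TestResult",
    "paired_t",
    "one_sample_t",
    "mixed_anova",
    "quadratic_dose_contrast",
    "pearson_r",
    "within_subject_sem",
    "pool_baseline",
    "adjust_pvalues",
]


@dataclass(frozen=True)
class TestResult:
    """One statistical comparison: statistic, dfs, p, effect size, n."""

    label: str
    statistic: float           # t or F (or r's t; see effect_size for r)
    df1: float
    p_value: float
    effect_size: float
    effect_size_type: str      # "cohen_dz", "cohen_d", "partial_eta_sq", "r"
    n: int
    df2: float | None = None

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def paired_t(x, y=None, label: str = "paired_t") -> TestResult:
    """Two-sided paired t-test with Cohen's dz = mean(diff)/SD(diff) = t/sqrt(n).

    Pass paired samples ``(x, y)`` or precomputed differences ``x`` alone.
    Zero-variance differences leave the effect size undefined (NaN, with a
    warning); t is 0 and p is 1 when the mean difference is also 0.
    """
    x = np.asarray(x, dtype=float)
    diff = x - np.asarray(y, dtype=float) if y is not None else x
    diff = diff[np.isfinite(diff)]
    n = diff.size
    if n < 2:
        raise ValueError("need at least 2 finite pairs")
    sd = diff.std(ddof=1)
    if sd == 0.0:
        warnings.warn(f"{label}: zero-variance differences; effect size undefined")
        t = 0.0 if diff.mean() == 0 else math.copysign(math.inf, diff.mean())
        return TestResult(label, t, n - 1, 1.0 if t == 0 else 0.0, float("nan"),
                          "cohen_dz", n)
    t = diff.mean() / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    dz = diff.mean() / sd
    assert math.isclose(dz, t / math.sqrt(n), rel_tol=1e-12)
    return TestResult(label, float(t), n - 1, float(p), float(dz), "cohen_dz", n)


def one_sample_t(values, mu0: float = 0.0, label: str = "one_sample_t") -> TestResult:
    """Two-sided one-sample t-test against ``mu0`` (e.g. chance = 1/3)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    return paired_t(v - mu0, label=label)


# ---------------------------------------------------------------------------
# Balanced mixed-design ANOVA


def _subset_label(subset: tuple[str, ...]) -> str:
    return ":".join(subset)


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    within: list[str] | tuple[str, ...] = (),
    between: list[str] | tuple[str, ...] = (),
) -> pd.DataFrame:
    """Mixed-design ANOVA for balanced complete layouts.

    Every main effect and interaction of the ``within`` and ``between``
    factors is returned with F, dfs, two-sided p and partial eta^2.  Within
    effects (and their interactions with between factors) are tested against
    the effect x subject-within-groups stratum; between effects against
    subjects within groups.  Duplicate subject x condition rows are averaged
    first; an unbalanced or incomplete layout is rejected.
    """
    within, between = list(within), list(between)
    if not within and not between:
        raise ValueError("need at least one factor")
    d = (
        data.groupby([subject, *between, *within], observed=True)[dv]
        .mean().reset_index()
    )
    subj_cells = d[[subject, *between]].drop_duplicates()
    if subj_cells[subject].duplicated().any():
        raise ValueError("a subject appears in more than one between-subject cell")

    blevels = {f: sorted(d[f].unique()) for f in between}
    wlevels = {f: sorted(d[f].unique()) for f in within}
    n_cells = int(np.prod([len(v) for v in blevels.values()])) if between else 1
    n_subj = subj_cells[subject].nunique()
    n_w = int(np.prod([len(v) for v in wlevels.values()])) if within else 1
    if n_subj % n_cells:
        raise ValueError("unbalanced design: unequal subjects per between-subject cell")
    m = n_subj // n_cells
    if between:
        counts = subj_cells.groupby(between, observed=True).size()
        if len(counts) != n_cells or counts.nunique() != 1:
            raise ValueError("unbalanced design: unequal subjects per between-subject cell")
    if len(d) != n_subj * n_w:
        raise ValueError("incomplete design: every subject needs every within combination")

    d = d.sort_values([*between, subject, *within], kind="mergesort")
    shape = [len(blevels[f]) for f in between] + [m] + [len(wlevels[f]) for f in within]
    Y = d[dv].to_numpy(dtype=float).reshape(shape)
    N = Y.size
    axis_of = {f: i for i, f in enumerate(between)}
    s_axis = len(between)
    axis_of.update({f: s_axis + 1 + j for j, f in enumerate(within)})

    def project(effect: set[str], subject_op: str) -> np.ndarray:
        """Apply Q (center) on effect axes, P (average) elsewhere.

        subject_op: 'P' average over subjects, 'Q' center subjects within
        cell, 'I' leave the subject axis alone.  Between axes are left alone
        when subject_op != 'P' (error strata keep the group structure).
        """
        e = Y
        for f in within:
            ax = axis_of[f]
            mean = e.mean(axis=ax, keepdims=True)
            e = e - mean if f in effect else mean
        if subject_op == "P":
            e = e.mean(axis=s_axis, keepdims=True)
            for f in between:
                ax = axis_of[f]
                mean = e.mean(axis=ax, keepdims=True)
                e = e - mean if f in effect else mean
        else:  # error strata: center subjects within their between cell
            e = e - e.mean(axis=s_axis, keepdims=True)
        return e

    def ss(e: np.ndarray) -> float:
        return float((e ** 2).sum() * (N / e.size))

    # error strata, keyed by the within-part of the effect they serve
    err: dict[tuple[str, ...], tuple[float, float]] = {}
    df_subj = n_cells * (m - 1)
    if df_subj <= 0:
        raise ValueError("need at least 2 subjects per between-subject cell")
    err[()] = (ss(project(set(), "Q")), float(df_subj))
    for r in range(1, len(within) + 1):
        for V in itertools.combinations(within, r):
            dfe = df_subj * int(np.prod([len(wlevels[f]) - 1 for f in V]))
            err[V] = (ss(project(set(V), "Q")), float(dfe))

    rows = []
    factors = between + within
    for r in range(1, len(factors) + 1):
        for A in itertools.combinations(factors, r):
            V = tuple(f for f in within if f in A)
            df1 = float(np.prod([
                len((blevels | wlevels)[f]) - 1 for f in A
            ]))
            ss_a = ss(project(set(A), "P"))
            ss_e, df2 = err[V]
            ms_a, ms_e = ss_a / df1, ss_e / df2
            F = ms_a / ms_e if ms_e > 0 else float("inf")
            p = float(stats.f.sf(F, df1, df2))
            peta = ss_a / (ss_a + ss_e) if (ss_a + ss_e) > 0 else float("nan")
            if np.isfinite(F):
                assert math.isclose(peta, F * df1 / (F * df1 + df2), rel_tol=1e-9)
            rows.append({
                "effect": _subset_label(A), "SS": ss_a, "df1": df1,
                "SS_error": ss_e, "df2": df2, "F": F, "p_value": p,
                "partial_eta_sq": peta,
                "error_term": _subset_label(V) + ":subject" if V else "subject",
            })
    return pd.DataFrame(rows)


def quadratic_dose_contrast(
    values, doses=(0, 12, 24), label: str = "quadratic_dose"
) -> TestResult:
    """Quadratic trend over three within-subject dose levels.

    ``values`` is an (n, 3) array of per-participant scores at the doses in
    ascending order.  The contrast c_i = x_i(d0) - 2 x_i(d1) + x_i(d2)
    annihilates linear trends; F = t^2 of a one-sample t on c against 0, with
    df (1, n-1) and partial eta^2 = F/(F + df2).  Rows with a missing dose
    level are excluded (logged).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("expected an (n, 3) array of per-participant dose scores")
    keep = np.isfinite(x).all(axis=1)
    if not keep.all():
        logger.info("quadratic contrast: excluded %d participant(s) with a "
                    "missing dose level", int((~keep).sum()))
    x = x[keep]
    c = x[:, 0] - 2.0 * x[:, 1] + x[:, 2]
    t_res = paired_t(c, label=label)
    n = t_res.n
    F = t_res.statistic ** 2
    df2 = float(n - 1)
    p = float(stats.f.sf(F, 1, df2))
    return TestResult(label, float(F), 1.0, p, F / (F + df2), "partial_eta_sq",
                      n, df2=df2)


def pearson_r(x, y, label: str = "pearson_r") -> TestResult:
    """Pearson correlation with two-sided p from t = r sqrt((n-2)/(1-r^2))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 finite pairs")
    r, p = stats.pearsonr(x, y)
    t = r * math.sqrt((n - 2) / max(1e-300, 1.0 - r ** 2))
    return TestResult(label, float(t), n - 2, float(p), float(r), "r", n)


def within_subject_sem(
    data: pd.DataFrame, dv: str, subject: str, within: list[str] | tuple[str, ...]
) -> pd.Series:
    """Per-condition SEMs adjusted for individual differences.

    Cousineau centering (subtract each participant's mean, add the grand
    mean) with the Morey sqrt(k/(k-1)) correction for k within conditions.
    With k = 1 this reduces to the ordinary SEM.
    """
    within = list(within)
    d = data.copy()
    k = d.groupby(within, observed=True).ngroups
    if k > 1:
        subj_mean = d.groupby(subject, observed=True)[dv].transform("mean")
        d["_adj"] = d[dv] - subj_mean + d[dv].mean()
    else:  # a single condition: centering would wipe the data entirely
        d["_adj"] = d[dv]
    morey = math.sqrt(k / (k - 1)) if k > 1 else 1.0
    sem = d.groupby(within, observed=True)["_adj"].agg(
        lambda v: v.std(ddof=1) / math.sqrt(len(v))
    )
    return sem * morey


def pool_baseline(
    no_drug, saline, label: str = "baseline_pooling"
) -> tuple[np.ndarray, TestResult]:
    """Concatenate no-drug and saline baseline cohorts after an equivalence check.

    A two-sample t compares the cohorts; pooling proceeds regardless (the two
    are treated as one baseline), but a significant difference is logged as a
    warning for the record.
    """
    a = np.asarray(no_drug, dtype=float)
    b = np.asarray(saline, dtype=float)
    t, p = stats.ttest_ind(a[np.isfinite(a)], b[np.isfinite(b)])
    n = int(np.isfinite(a).sum() + np.isfinite(b).sum())
    sd_pool = np.concatenate([a[np.isfinite(a)], b[np.isfinite(b)]]).std(ddof=1)
    d = (np.nanmean(a) - np.nanmean(b)) / sd_pool if sd_pool > 0 else float("nan")
    check = TestResult(label, float(t), n - 2, float(p), float(d), "cohen_d", n)
    if p < 0.05:
        warnings.warn(f"{label}: cohorts differ (t={t:.2f}, p={p:.3f}); "
                      "pooled anyway per protocol")
    return np.concatenate([a, b]), check


def adjust_pvalues(pvals, method: str = "bonferroni") -> np.ndarray:
    """Family-wise correction for rating-scale style families of tests."""
    p = np.asarray(pvals, dtype=float)
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    if method == "holm":
        order = np.argsort(p)
        out = np.empty_like(p)
        out[order] = np.maximum.accumulate(
            np.minimum((p.size - np.arange(p.size)) * p[order], 1.0))
        return out
    raise ValueError(f"unknown correction method {method!r}")
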