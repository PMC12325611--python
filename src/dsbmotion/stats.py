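"""Group comparisons for Rc cohorts and plating-assay viability.

Two comparison modes, matching common practice for per-cell Rc data:
a two-sided unpaired Student t-test for a single pairwise contrast, and
one-way ANOVA with Dunnett's many-to-one correction when several mutant
conditions are compared against the same wild-type reference. Day-paired
cohorting restricts each contrast to acquisition days on which both the
condition and the reference were imaged, guarding against day-to-day
microscopy variation. Significance tiers follow the conventional
ns / * / ** / *** thresholds at 0.05 / 0.01 / 0.001.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


def significance_tier(p: float) -> str:
    """ns p >= 0.05, * p < 0.05, ** p < 0.01, *** p < 0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class ComparisonResult:
    contrast: str
    statistic: float
    df: float
    p_raw: float
    p_adjusted: float
    n_a: int
    n_b: int
    method: str
    flags: list[str] = field(default_factory=list)

    @property
    def tier(self) -> str:
        return significance_tier(self.p_adjusted)


def t_test_two_sided(
    group_a: np.ndarray, group_b: np.ndarray, welch: bool = False, contrast: str = "a vs b"
) -> ComparisonResult:
    """Classical two-sided unpaired t-test (pooled variance by default).

    Student's pooled-variance form is the default to match the usual
    "unpaired t-test" of graphing software; Welch's unequal-variance form
    is available behind ``welch=True``. Two constant, identical groups have
    an undefined statistic; the comparison is reported as p = 1 with a flag.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    flags = []
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            flags.append("zero_variance_identical_means")
            df = len(a) + len(b) - 2
            return ComparisonResult(
                contrast, 0.0, df, 1.0, 1.0, len(a), len(b), "student_t", flags
            )
    res = sps.ttest_ind(a, b, equal_var=not welch)
    method = "welch_t" if welch else "student_t"
    return ComparisonResult(
        contrast=contrast,
        statistic=float(res.statistic),
        df=float(res.df),
        p_raw=float(res.pvalue),
        p_adjusted=float(res.pvalue),
        n_a=len(a),
        n_b=len(b),
        method=method,
        flags=flags,
    )


def anova_dunnett(
    cohorts: pd.DataFrame,
    reference: str,
    value_col: str = "rc_um",
    condition_col: str = "condition",
    seed: int = 0,
) -> tuple[float, float, list[ComparisonResult]]:
    """One-way ANOVA plus Dunnett many-to-one comparisons against a reference.

    Returns ``(F, anova_p, comparisons)``. Raw per-contrast p-values come
    from the pooled-error t statistic (pooled MSE, N - k df); adjusted
    p-values come from the equicorrelated multivariate-t distribution via
    ``scipy.stats.dunnett`` (quasi-Monte-Carlo integration, seeded for
    reproducibility; the method string on each result records this).
    Adjusted p is floored at raw p so integration wiggle can never invert
    the ordering.
    """
    conditions = list(dict.fromkeys(cohorts[condition_col]))
    if reference not in conditions:
        raise ValueError(f"reference condition {reference!r} not present")
    groups = {
        c: cohorts.loc[cohorts[condition_col] == c, value_col].to_numpy(dtype=float)
        for c in conditions
    }
    for c, g in groups.items():
        if len(g) < 2:
            raise ValueError(f"condition {c!r} has fewer than 2 observations")
    others = [c for c in conditions if c != reference]
    if not others:
        raise ValueError("need at least one non-reference condition")

    f_stat, anova_p = sps.f_oneway(*groups.values())

    # pooled-error t per contrast (the statistic Dunnett's procedure adjusts)
    ref = groups[reference]
    n_total = sum(len(g) for g in groups.values())
    k = len(groups)
    mse = sum(np.sum((g - g.mean()) ** 2) for g in groups.values()) / (n_total - k)
    df = n_total - k

    dunnett_res = sps.dunnett(
        *(groups[c] for c in others),
        control=ref,
        alternative="two-sided",
        rng=np.random.default_rng(seed),
    )
    out = []
    for i, c in enumerate(others):
        g = groups[c]
        se = np.sqrt(mse * (1.0 / len(g) + 1.0 / len(ref)))
        t = (g.mean() - ref.mean()) / se if se > 0 else 0.0
        p_raw = float(2.0 * sps.t.sf(abs(t), df)) if se > 0 else 1.0
        p_adj = max(float(dunnett_res.pvalue[i]), p_raw)
        out.append(
            ComparisonResult(
                contrast=f"{c} vs {reference}",
                statistic=float(t),
                df=float(df),
                p_raw=p_raw,
                p_adjusted=min(p_adj, 1.0),
                n_a=len(g),
                n_b=len(ref),
                method="dunnett_two_sided_mvt_qmc",
            )
        )
    return float(f_stat), float(anova_p), out


def day_paired_filter(
    cohorts: pd.DataFrame,
    reference: str,
    condition_col: str = "condition",
    day_col: str = "day",
) -> pd.DataFrame:
    """Keep, per condition, only the days on which the reference was also run.

    Day-to-day variation in microscopy makes cross-day contrasts unreliable,
    so each condition is restricted to acquisition days shared with the
    reference; the reference itself is restricted to days shared with at
    least one condition. A condition with no overlapping days is an error.
    """
    if day_col not in cohorts.columns:
        raise ValueError(f"day labels required in column {day_col!r}")
    ref_days = set(cohorts.loc[cohorts[condition_col] == reference, day_col])
    if not ref_days:
        raise ValueError(f"reference condition {reference!r} not present")
    keep = []
    cond_days_union: set = set()
    for c in dict.fromkeys(cohorts[condition_col]):
        if c == reference:
            continue
        days = set(cohorts.loc[cohorts[condition_col] == c, day_col])
        overlap = days & ref_days
        if not overlap:
            raise ValueError(f"condition {c!r} shares no acquisition day with {reference!r}")
        cond_days_union |= overlap
        keep.append(
            cohorts[(cohorts[condition_col] == c) & cohorts[day_col].isin(overlap)]
        )
    keep.append(
        cohorts[
            (cohorts[condition_col] == reference) & cohorts[day_col].isin(cond_days_union)
        ]
    )
    return pd.concat(keep, ignore_index=True)


@dataclass
class ViabilityResult:
    condition: str
    survival: float  # summed selective / summed permissive
    sem: float  # across per-plate ratios
    n_plates: int
    normalized: float | None = None  # vs reference condition when applicable


def viability(
    selective_counts: np.ndarray,
    permissive_counts: np.ndarray,
    condition: str = "condition",
) -> ViabilityResult:
    """Clonogenic survival: colonies on selective over permissive plates.

    The point estimate pools colonies across the plate triplicate
    (sum/sum); the SEM is computed across the per-plate ratios.
    """
    sel = np.asarray(selective_counts, dtype=float)
    per = np.asarray(permissive_counts, dtype=float)
    if sel.shape != per.shape:
        raise ValueError("count arrays must have the same length")
    if np.any(per <= 0):
        raise ValueError("permissive colony counts must all be positive")
    ratios = sel / per
    survival = float(sel.sum() / per.sum())
    sem = float(ratios.std(ddof=1) / np.sqrt(len(ratios))) if len(ratios) > 1 else 0.0
    return ViabilityResult(condition=condition, survival=survival, sem=sem, n_plates=len(sel))


def normalize_to(result: ViabilityResult, reference: ViabilityResult) -> ViabilityResult:
    """Express survival relative to a reference condition.

    Used to factor out a treatment's intrinsic toxicity, e.g. dividing the
    survival of nocodazole-treated mutants by that of nocodazole-treated
    wild type.
    """
    if reference.survival <= 0:
        raise ValueError("reference survival must be positive")
    return ViabilityResult(
        condition=result.condition,
        survival=result.survival,
        sem=result.sem,
        n_plates=result.n_plates,
        normalized=result.survival / reference.survival,
    )


def comparisons_to_frame(comparisons: list[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contrast": c.contrast,
                "n_a": c.n_a,
                "n_b": c.n_b,
                "stat": c.statistic,
                "df": c.df,
                "p_raw": c.p_raw,
                "p_adj": c.p_adjusted,
                "tier": c.tier,
                "method": c.method,
            }
            for c in comparisons
        ]
    )
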