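"""Cohort estimation and the method-comparison statistical pipeline.

Per-subject dental ages under several population standards, DA-CA
summaries by 1-year age group and sex, paired t-tests against zero bias,
one-way ANOVA across standards, Scheffe pairwise contrasts, and
SPSS-convention homogeneous subsets.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import CoverageError, DentageError, RatingError
from .staging import (
    SEXES,
    StageWeightTable,
    ToothStageRating,
    assign_age_group,
    compute_maturity_score,
)
from .standards import ConversionStandard

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class SubjectResult:
    """One subject's score and per-standard dental ages and differences.

    ``dental_age`` / ``difference`` only carry keys for standards whose
    coverage includes the subject; excluded standards are absent, not zero.
    """

    subject_id: str
    sex: str
    ca_years: float
    age_group: str
    maturity_score: float
    dental_age: Mapping[str, float]
    difference: Mapping[str, float]


def estimate_cohort(
    ratings: Sequence[ToothStageRating],
    weight_tables: Mapping[str, StageWeightTable],
    standards: Sequence[ConversionStandard],
    *,
    extrapolate: bool = False,
) -> list[SubjectResult]:
    """Score every subject and convert under every applicable standard.

    A standard applies to a subject when the subject's sex matches and the
    score (and chronological age, if the standard restricts ages) falls
    inside the standard's coverage; otherwise that standard's entries are
    simply absent for the subject.
    """
    if not standards:
        raise DentageError("need at least one conversion standard")
    results = []
    for rating in ratings:
        try:
            table = weight_tables[rating.sex]
        except KeyError:
            raise RatingError(
                f"subject {rating.subject_id}: no weight table for sex "
                f"{rating.sex!r}"
            ) from None
        try:
            score = compute_maturity_score(rating, table)
            ca = rating.ca
            group = assign_age_group(ca)
        except DentageError as exc:
            raise type(exc)(f"subject {rating.subject_id}: {exc}") from None
        da: dict[str, float] = {}
        diff: dict[str, float] = {}
        for std in standards:
            if std.sex != rating.sex:
                continue
            if not (extrapolate or std.covers_subject(score, ca)):
                continue
            try:
                age = std.score_to_age(score, extrapolate=extrapolate)
            except CoverageError:
                continue
            da[std.name] = age
            diff[std.name] = age - ca
        results.append(
            SubjectResult(
                subject_id=rating.subject_id,
                sex=rating.sex,
                ca_years=ca,
                age_group=group.label,
                maturity_score=score,
                dental_age=da,
                difference=diff,
            )
        )
    return results


# ---------------------------------------------------------------------------
# Paired t and group summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    ci95: tuple[float, float]
    degenerate: bool = False


def paired_t(differences: Sequence[float]) -> TTestResult:
    """Two-sided one-sample t-test of paired differences against zero.

    With zero spread and a nonzero mean the p-value is reported as the
    0-limit with ``degenerate`` set.
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise DentageError("paired t-test needs at least 2 differences")
    n = d.size
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    tcrit = float(stats.t.ppf(0.975, df))
    if sd == 0.0:
        if mean == 0.0:
            return TTestResult(t=0.0, df=df, p=1.0, ci95=(0.0, 0.0))
        return TTestResult(
            t=math.copysign(math.inf, mean), df=df, p=0.0,
            ci95=(mean, mean), degenerate=True,
        )
    se = sd / math.sqrt(n)
    t = mean / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return TTestResult(t=t, df=df, p=p, ci95=(mean - tcrit * se, mean + tcrit * se))


def t_from_moments(mean: float, sd: float, n: int) -> TTestResult:
    """Paired t-test and CI reconstructed from summary moments alone."""
    if n < 2 or sd <= 0:
        raise DentageError("need n >= 2 and sd > 0")
    df = n - 1
    se = sd / math.sqrt(n)
    t = mean / se
    p = 2.0 * float(stats.t.sf(abs(t), df))
    tcrit = float(stats.t.ppf(0.975, df))
    return TTestResult(t=t, df=df, p=p, ci95=(mean - tcrit * se, mean + tcrit * se))


@dataclass(frozen=True)
class GroupStats:
    """Summary of DA-CA differences for one age group (or a total row)."""

    label: str
    n: int
    mean: float
    sd: float | None = None
    ci95: tuple[float, float] | None = None
    p_value: float | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DentageError("group must contain at least one subject")
        if self.sd is not None and self.sd < 0:
            raise DentageError("sd cannot be negative")


@dataclass(frozen=True)
class GroupSummary:
    groups: tuple[GroupStats, ...]
    total: GroupStats
    standard: str
    sex: str


def _stats_for(label: str, diffs: np.ndarray) -> GroupStats:
    n = diffs.size
    mean = float(diffs.mean())
    if n == 1:
        return GroupStats(label=label, n=1, mean=mean)
    tt = paired_t(diffs)
    return GroupStats(
        label=label, n=n, mean=mean, sd=float(diffs.std(ddof=1)),
        ci95=tt.ci95, p_value=tt.p,
    )


def group_summary(
    results: Sequence[SubjectResult], standard: str, sex: str
) -> GroupSummary:
    """Per-age-group mean/sd/CI/p of DA-CA plus an all-group total.

    Groups with a single subject report the mean only (sd/CI/p unavailable).
    """
    by_group: dict[str, list[float]] = {}
    pooled: list[float] = []
    for r in results:
        if r.sex != sex or standard not in r.difference:
            continue
        by_group.setdefault(r.age_group, []).append(r.difference[standard])
        pooled.append(r.difference[standard])
    if not pooled:
        raise DentageError(
            f"no results for standard {standard!r} and sex {sex!r}"
        )
    groups = tuple(
        _stats_for(label, np.asarray(by_group[label]))
        for label in sorted(by_group)
    )
    total = _stats_for("TOTAL", np.asarray(pooled))
    return GroupSummary(groups=groups, total=total, standard=standard, sex=sex)


def weighted_mean(ns: Sequence[int], means: Sequence[float]) -> float:
    """Sample-size-weighted mean of group means."""
    if len(ns) == 0 or len(ns) != len(means):
        raise DentageError("need matching non-empty n and mean sequences")
    if any(n < 1 for n in ns):
        raise DentageError("all group sizes must be >= 1")
    return float(np.dot(ns, means) / np.sum(ns))


def weighted_total(groups: Sequence[GroupStats]) -> float:
    """Weighted mean over group summaries; equals the pooled-subject mean
    exactly when computed from unrounded group means."""
    return weighted_mean([g.n for g in groups], [g.mean for g in groups])


# ---------------------------------------------------------------------------
# One-way ANOVA and Scheffe post hoc
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float
    ms_within: float


def _as_samples(samples_by_standard: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    out = {k: np.asarray(v, dtype=float) for k, v in samples_by_standard.items()}
    if len(out) < 2:
        raise DentageError("ANOVA needs at least 2 standards")
    for k, v in out.items():
        if v.size < 2:
            raise DentageError(f"standard {k!r}: need at least 2 observations")
    return out


def oneway_anova(samples_by_standard: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA across standards."""
    samples = _as_samples(samples_by_standard)
    k = len(samples)
    ns = np.array([v.size for v in samples.values()])
    means = np.array([v.mean() for v in samples.values()])
    big_n = int(ns.sum())
    grand = float(np.dot(ns, means) / big_n)
    ss_between = float(np.dot(ns, (means - grand) ** 2))
    ss_within = float(sum(((v - v.mean()) ** 2).sum() for v in samples.values()))
    df_b, df_w = k - 1, big_n - k
    if ss_within == 0.0:
        raise DentageError("zero within-group variance everywhere; F undefined")
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    f = ms_b / ms_w
    p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(f=f, df_between=df_b, df_within=df_w, p=p, ms_within=ms_w)


@dataclass(frozen=True)
class PairwiseComparison:
    standard_i: str
    standard_j: str
    mean_difference: float
    std_error: float
    adjusted_p: float
    ci95: tuple[float, float]


def scheffe_pairwise(
    samples_by_standard: Mapping[str, Sequence[float]],
    alpha: float = DEFAULT_ALPHA,
) -> list[PairwiseComparison]:
    """Scheffe-adjusted pairwise contrasts between all ordered pairs.

    SE = sqrt(MSW (1/n_i + 1/n_j)); adjusted p = P(F_{k-1,N-k} >=
    (diff/SE)^2 / (k-1)); CI half-width = sqrt((k-1) F_crit) * SE.
    Antisymmetry of entries (i, j) and (j, i) holds exactly.
    """
    samples = _as_samples(samples_by_standard)
    anova = oneway_anova(samples)
    k = len(samples)
    f_crit = float(stats.f.ppf(1.0 - alpha, anova.df_between, anova.df_within))
    out = []
    names = list(samples)
    for i in names:
        for j in names:
            if i == j:
                continue
            diff = float(samples[i].mean() - samples[j].mean())
            se = math.sqrt(anova.ms_within * (1.0 / samples[i].size + 1.0 / samples[j].size))
            fstat = (diff / se) ** 2 / (k - 1)
            p_adj = float(stats.f.sf(fstat, anova.df_between, anova.df_within))
            half = math.sqrt((k - 1) * f_crit) * se
            out.append(
                PairwiseComparison(
                    standard_i=i, standard_j=j, mean_difference=diff,
                    std_error=se, adjusted_p=p_adj, ci95=(diff - half, diff + half),
                )
            )
    return out


@dataclass(frozen=True)
class HomogeneousSubset:
    members: tuple[str, ...]  # ordered by ascending mean
    means: tuple[float, ...]
    significance: float


@dataclass(frozen=True)
class SubsetsResult:
    subsets: tuple[HomogeneousSubset, ...]
    harmonic_n: float
    note: str = "harmonic-mean sample size used for unequal n (SPSS convention)"


def scheffe_subsets(
    samples_by_standard: Mapping[str, Sequence[float]],
    alpha: float = DEFAULT_ALPHA,
) -> SubsetsResult:
    """Homogeneous subsets under the Scheffe criterion.

    Standards are sorted by ascending mean; with the common standard error
    built from the harmonic mean of the group sizes, every maximal run of
    consecutive standards whose extreme pair is non-significant forms one
    subset.  Each subset reports the adjusted p of its extreme-pair
    comparison as its significance (1.0 for singletons).
    """
    samples = _as_samples(samples_by_standard)
    anova = oneway_anova(samples)
    k = len(samples)
    n_h = k / sum(1.0 / v.size for v in samples.values())
    se = math.sqrt(anova.ms_within * 2.0 / n_h)

    def adj_p(diff: float) -> float:
        fstat = (diff / se) ** 2 / (k - 1)
        return float(stats.f.sf(fstat, anova.df_between, anova.df_within))

    order = sorted(samples, key=lambda name: samples[name].mean())
    means = [float(samples[name].mean()) for name in order]
    # Maximal runs [i, j] whose extreme pair is non-significant; with a
    # common SE, inner pairs have smaller mean gaps and are then
    # automatically non-significant too.
    runs: list[tuple[int, int]] = []
    for i in range(k):
        j = i
        while j + 1 < k and adj_p(means[j + 1] - means[i]) > alpha:
            j += 1
        runs.append((i, j))
    maximal = [
        (i, j)
        for (i, j) in runs
        if not any((a <= i and j <= b) and (a, b) != (i, j) for a, b in runs)
    ]
    subsets = []
    for i, j in sorted(set(maximal)):
        sig = 1.0 if i == j else adj_p(means[j] - means[i])
        subsets.append(
            HomogeneousSubset(
                members=tuple(order[i : j + 1]),
                means=tuple(means[i : j + 1]),
                significance=sig,
            )
        )
    return SubsetsResult(subsets=tuple(subsets), harmonic_n=n_h)


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SexComparison:
    sex: str
    summaries: tuple[GroupSummary, ...]
    anova: AnovaResult | None
    pairwise: tuple[PairwiseComparison, ...]
    subsets: SubsetsResult | None


@dataclass(frozen=True)
class MethodComparisonReport:
    per_sex: Mapping[str, SexComparison]
    alpha: float


def compare_methods(
    results: Sequence[SubjectResult],
    standard_names: Sequence[str] | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> MethodComparisonReport:
    """Assemble the full comparison report from per-subject results.

    ANOVA/Scheffe sections require at least two standards with >= 2
    observations for a sex; otherwise they are None for that sex.
    """
    if standard_names is None:
        seen: dict[str, None] = {}
        for r in results:
            for name in r.difference:
                seen.setdefault(name)
        standard_names = list(seen)
    per_sex = {}
    for sex in SEXES:
        summaries = []
        samples: dict[str, np.ndarray] = {}
        for name in standard_names:
            diffs = [
                r.difference[name]
                for r in results
                if r.sex == sex and name in r.difference
            ]
            if not diffs:
                continue
            summaries.append(group_summary(results, name, sex))
            samples[name] = np.asarray(diffs)
        if not summaries:
            continue
        eligible = {k: v for k, v in samples.items() if v.size >= 2}
        if len(eligible) >= 2:
            anova = oneway_anova(eligible)
            pairwise = tuple(scheffe_pairwise(eligible, alpha))
            subsets = scheffe_subsets(eligible, alpha)
        else:
            anova, pairwise, subsets = None, (), None
        per_sex[sex] = SexComparison(
            sex=sex, summaries=tuple(summaries), anova=anova,
            pairwise=pairwise, subsets=subsets,
        )
    return MethodComparisonReport(per_sex=per_sex, alpha=alpha)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

_TIDY_COLUMNS = (
    "sex", "standard", "group", "n", "mean", "sd", "ci_lo", "ci_hi", "p_value",
)


def _fmt(value: float | None, decimals: int) -> str:
    return "" if value is None else f"{value:.{decimals}f}"


def write_report_csv(report: MethodComparisonReport, path: str | Path) -> None:
    """Tidy CSV: one row per sex x standard x age group plus TOTAL rows.

    Means/SD to 2 decimals, p-values to 3.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_TIDY_COLUMNS)
        for sex, comp in report.per_sex.items():
            for summary in comp.summaries:
                for g in list(summary.groups) + [summary.total]:
                    ci = g.ci95 or (None, None)
                    writer.writerow(
                        [
                            sex, summary.standard, g.label, g.n,
                            _fmt(g.mean, 2), _fmt(g.sd, 2),
                            _fmt(ci[0], 2), _fmt(ci[1], 2),
                            _fmt(g.p_value, 3),
                        ]
                    )


def report_to_dict(report: MethodComparisonReport) -> dict:
    out: dict = {"alpha": report.alpha, "per_sex": {}}
    for sex, comp in report.per_sex.items():
        sec: dict = {"summaries": [], "anova": None, "pairwise": [], "subsets": None}
        for summary in comp.summaries:
            sec["summaries"].append(
                {
                    "standard": summary.standard,
                    "groups": [
                        {
                            "label": g.label, "n": g.n, "mean": g.mean,
                            "sd": g.sd, "ci95": list(g.ci95) if g.ci95 else None,
                            "p_value": g.p_value,
                        }
                        for g in list(summary.groups) + [summary.total]
                    ],
                }
            )
        if comp.anova is not None:
            sec["anova"] = {
                "f": comp.anova.f, "df_between": comp.anova.df_between,
                "df_within": comp.anova.df_within, "p": comp.anova.p,
            }
        sec["pairwise"] = [
            {
                "i": p.standard_i, "j": p.standard_j,
                "mean_difference": p.mean_difference, "std_error": p.std_error,
                "adjusted_p": p.adjusted_p, "ci95": list(p.ci95),
            }
            for p in comp.pairwise
        ]
        if comp.subsets is not None:
            sec["subsets"] = {
                "harmonic_n": comp.subsets.harmonic_n,
                "note": comp.subsets.note,
                "subsets": [
                    {
                        "members": list(s.members),
                        "means": list(s.means),
                        "significance": s.significance,
                    }
                    for s in comp.subsets.subsets
                ],
            }
        out["per_sex"][sex] = sec
    return out


def write_report_json(report: MethodComparisonReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report_to_dict(report), fh, indent=1)
        fh.write("\n")
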