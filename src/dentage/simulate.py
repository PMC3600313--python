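"""Synthetic cohort generation and model-recovery checks.

Generates cohorts with the structure the pipeline assumes: chronological
ages drawn uniformly within 1-year bins, a latent maturity score from a
monotone generating model plus Gaussian rating noise on the score scale,
and stage maps obtained by greedy decomposition of the target score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import DentageError, FitError, WeightTableError
from .staging import (
    SEXES,
    STAGES,
    TEETH,
    StageWeightTable,
    ToothStageRating,
)
from .standards import CubicModel, PolynomialFit, fit_polynomial

#: Default per-(sex, age-group) subject counts: 217 boys and 205 girls
#: across the ten 1-year bins.
DEFAULT_COUNTS: dict[str, dict[int, int]] = {
    "male": {4: 7, 5: 12, 6: 26, 7: 28, 8: 26, 9: 30, 10: 30, 11: 16, 12: 30, 13: 12},
    "female": {4: 9, 5: 20, 6: 22, 7: 40, 8: 38, 9: 24, 10: 24, 11: 6, 12: 12, 13: 10},
}


def _default_models() -> dict[str, CubicModel]:
    from .standards import load_builtin

    return {
        "male": load_builtin("saudi_male_cubic"),
        "female": load_builtin("saudi_female_cubic"),
    }


@dataclass
class CohortConfig:
    """Configuration of a synthetic cohort.

    ``counts`` maps sex -> age-group lower bound -> subject count;
    ``models`` holds the generating score->age cubic per sex; ``sigma`` is
    the rating-noise standard deviation in maturity-score units;
    ``biases`` are optional per-standard age offsets in years for use with
    :class:`~dentage.standards.ShiftedStandard`.
    """

    counts: Mapping[str, Mapping[int, int]] = field(
        default_factory=lambda: {s: dict(g) for s, g in DEFAULT_COUNTS.items()}
    )
    models: Mapping[str, CubicModel] = field(default_factory=_default_models)
    sigma: float = 2.0
    biases: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0
    #: When True, reject bins that do not overlap the generating model's
    #: attainable age range instead of clamping their subjects' latent
    #: scores to the range edge.
    strict_coverage: bool = False

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise DentageError("sigma must be non-negative")
        for sex, groups in self.counts.items():
            if sex not in SEXES:
                raise DentageError(f"unknown sex {sex!r} in counts")
            for lower, n in groups.items():
                if n < 0:
                    raise DentageError(f"negative count for {sex} group {lower}")

    @classmethod
    def from_document(cls, doc: Mapping) -> "CohortConfig":
        from .standards import load_standard

        kwargs: dict = {}
        if "counts" in doc:
            kwargs["counts"] = {
                sex: {int(k): int(v) for k, v in groups.items()}
                for sex, groups in doc["counts"].items()
            }
        if "models" in doc:
            kwargs["models"] = {
                sex: load_standard(m) for sex, m in doc["models"].items()
            }
        for key in ("sigma", "seed", "strict_coverage"):
            if key in doc:
                kwargs[key] = doc[key]
        if "biases" in doc:
            kwargs["biases"] = dict(doc["biases"])
        return cls(**kwargs)


@dataclass(frozen=True)
class GroundTruth:
    """Latent values behind one simulated subject."""

    subject_id: str
    sex: str
    ca_years: float
    latent_score: float


def decompose_score_to_stages(
    target_score: float, weight_table: StageWeightTable
) -> dict[str, str]:
    """Greedy round-robin stage map whose score approaches the target.

    Teeth are advanced one stage at a time in canonical order, skipping any
    advancement that would push the cumulative score above the target.  The
    achieved score is <= target and within the table's largest single-stage
    increment of it.
    """
    if not isinstance(weight_table, StageWeightTable):
        raise WeightTableError("weight_table must be a StageWeightTable")
    if not (0.0 <= target_score <= 100.0):
        raise DentageError(f"target score {target_score} outside [0, 100]")
    level = {t: 0 for t in TEETH}
    score = 0.0
    advanced = True
    while advanced:
        advanced = False
        for tooth in TEETH:
            if level[tooth] >= len(STAGES) - 1:
                continue
            nxt = weight_table.weight(tooth, STAGES[level[tooth] + 1])
            cur = weight_table.weight(tooth, STAGES[level[tooth]])
            if score + (nxt - cur) <= target_score + 1e-12:
                score += nxt - cur
                level[tooth] += 1
                advanced = True
    return {t: STAGES[level[t]] for t in TEETH}


def simulate_cohort(
    config: CohortConfig,
    weight_tables: Mapping[str, StageWeightTable],
) -> tuple[list[ToothStageRating], list[GroundTruth]]:
    """Draw a cohort and its ground truth, reproducibly from the seed.

    For each configured (sex, bin) cell: CA ~ Uniform within the bin, the
    latent score is the model's inverse at CA (clamped to the model's
    attainable age range) plus Normal(0, sigma) noise clipped to the score
    range, and the stage map is the greedy decomposition of the latent
    score.
    """
    rng = np.random.default_rng(config.seed)
    ratings: list[ToothStageRating] = []
    truths: list[GroundTruth] = []
    for sex in SEXES:
        groups = config.counts.get(sex, {})
        if not groups:
            continue
        try:
            model = config.models[sex]
        except KeyError:
            raise DentageError(f"no generating model for sex {sex!r}") from None
        try:
            table = weight_tables[sex]
        except KeyError:
            raise DentageError(f"no weight table for sex {sex!r}") from None
        age_lo, age_hi = model.age_range
        smin, smax = model.score_range
        for lower in sorted(groups):
            n = groups[lower]
            if n == 0:
                continue
            if config.strict_coverage and (lower + 1 <= age_lo or lower >= age_hi):
                raise DentageError(
                    f"model {model.name} (ages [{age_lo:.2f}, {age_hi:.2f}]) "
                    f"cannot cover bin {lower}.00-{lower}.99"
                )
            cas = rng.uniform(lower, lower + 1, size=n)
            noise = rng.normal(0.0, config.sigma, size=n) if config.sigma > 0 else np.zeros(n)
            for i in range(n):
                ca = float(cas[i])
                latent = model.age_to_score(min(max(ca, age_lo), age_hi))
                latent = float(np.clip(latent + noise[i], smin, smax))
                stages = decompose_score_to_stages(latent, table)
                sid = f"{sex[0].upper()}{lower:02d}-{i + 1:03d}"
                ratings.append(
                    ToothStageRating(
                        subject_id=sid, sex=sex, stages=stages, ca_years=ca
                    )
                )
                truths.append(
                    GroundTruth(
                        subject_id=sid, sex=sex, ca_years=ca, latent_score=latent
                    )
                )
    return ratings, truths


@dataclass(frozen=True)
class RecoveryReport:
    """Cubic refit from a simulated cohort with errors vs the generator."""

    fit: PolynomialFit
    coefficient_errors: tuple[float, float, float, float]
    n: int


def recover_model(
    ratings: Sequence[ToothStageRating],
    weight_table: StageWeightTable,
    generating_model: CubicModel,
    *,
    degree: int = 3,
) -> RecoveryReport:
    """Refit the age-vs-score polynomial from a (single-sex) cohort.

    Scores are recomputed from the stage maps (so quantization error from
    the decomposition is included), and chronological age is regressed on
    them.
    """
    from .staging import compute_maturity_score

    if not ratings:
        raise FitError("empty cohort")
    scores = [compute_maturity_score(r, weight_table) for r in ratings]
    ages = [r.ca for r in ratings]
    fit = fit_polynomial(scores, ages, degree, weight_table.sex)
    if degree == 3:
        errs = tuple(
            abs(a - b)
            for a, b in zip(fit.model.coefficients, generating_model.coefficients)
        )
    else:
        errs = (abs(fit.model.intercept - generating_model.b0),
                abs(fit.model.slope - generating_model.b1), 0.0, 0.0)
    return RecoveryReport(fit=fit, coefficient_errors=errs, n=len(ratings))


def save_ground_truth(truths: Sequence[GroundTruth], path: str | Path) -> None:
    doc = [
        {
            "subject_id": t.subject_id,
            "sex": t.sex,
            "ca_years": t.ca_years,
            "latent_score": t.latent_score,
        }
        for t in truths
    ]
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")
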