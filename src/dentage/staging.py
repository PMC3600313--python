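"""Tooth-stage ratings, maturity scores, chronological age and reliability.

The seven left mandibular permanent teeth (FDI 31-37, third molar excluded)
are each rated on the ordinal scale 0 < A < B < ... < H.  A sex-specific
stage-weight table converts the seven ratings into a maturity score on a
0-100 scale, where 100 means full maturation of all assessed teeth.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import AgeRangeError, RatingError, ReliabilityError, WeightTableError

#: Canonical tooth order: central/lateral incisor, canine, premolars, molars.
TEETH: tuple[str, ...] = ("I1", "I2", "C", "PM1", "PM2", "M1", "M2")

#: Ordinal stage codes; "0" means no calcification.
STAGES: tuple[str, ...] = ("0", "A", "B", "C", "D", "E", "F", "G", "H")

STAGE_INDEX: dict[str, int] = {code: i for i, code in enumerate(STAGES)}

SEXES: tuple[str, str] = ("male", "female")

#: Decimal-age year length in days (conventional).
DAYS_PER_YEAR = 365.25

#: Validated chronological-age window, half-open.
CA_MIN, CA_MAX = 4.0, 14.0

_COHORT_COLUMNS = (
    "subject_id",
    "sex",
    "birth_date",
    "exam_date",
    "ca_years",
) + TEETH


def stage_numeric(code: str) -> int:
    """Ordinal numeric encoding of a stage code: 0 -> 0, A -> 1, ..., H -> 8."""
    try:
        return STAGE_INDEX[code]
    except KeyError:
        raise RatingError(f"unknown stage code {code!r}") from None


def chronological_age(birth_date: date, exam_date: date) -> float:
    """Decimal age in years between birth and examination.

    Computed as (exam_date - birth_date) in days divided by 365.25.
    """
    if exam_date < birth_date:
        raise RatingError(
            f"exam date {exam_date.isoformat()} precedes birth date "
            f"{birth_date.isoformat()}"
        )
    return (exam_date - birth_date).days / DAYS_PER_YEAR


@dataclass(frozen=True)
class AgeGroup:
    """One-year chronological-age bin, half-open [lower, lower + 1)."""

    lower: int

    def __post_init__(self) -> None:
        if self.lower not in range(int(CA_MIN), int(CA_MAX)):
            raise AgeRangeError(
                f"age-group lower bound {self.lower} outside "
                f"[{int(CA_MIN)}, {int(CA_MAX) - 1}]"
            )

    @property
    def upper(self) -> int:
        return self.lower + 1

    @property
    def label(self) -> str:
        return f"{self.lower}.00-{self.lower}.99"

    def __contains__(self, ca_years: float) -> bool:
        return self.lower <= ca_years < self.upper


#: The ten 1-year bins covering the validated range.
AGE_GROUPS: tuple[AgeGroup, ...] = tuple(
    AgeGroup(k) for k in range(int(CA_MIN), int(CA_MAX))
)


def assign_age_group(ca_years: float) -> AgeGroup:
    """Bin a chronological age into its 1-year group.

    Raises :class:`AgeRangeError` for ages outside the validated
    half-open window [4, 14).
    """
    if not (CA_MIN <= ca_years < CA_MAX):
        raise AgeRangeError(
            f"chronological age {ca_years} out of validated range "
            f"[{CA_MIN}, {CA_MAX})"
        )
    return AGE_GROUPS[int(np.floor(ca_years)) - int(CA_MIN)]


@dataclass(frozen=True)
class ToothStageRating:
    """One subject's stage codes for the seven assessed teeth.

    Chronological age is given either directly (``ca_years``) or via
    ``birth_date`` and ``exam_date``; when both are present the dates win
    for provenance but must agree with ``ca_years`` being absent.
    """

    subject_id: str
    sex: str
    stages: Mapping[str, str]
    birth_date: date | None = None
    exam_date: date | None = None
    ca_years: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise RatingError(
                f"subject {self.subject_id}: sex must be one of {SEXES}, "
                f"got {self.sex!r}"
            )
        missing = [t for t in TEETH if t not in self.stages]
        if missing:
            raise RatingError(
                f"subject {self.subject_id}: missing stage for tooth "
                f"{missing[0]}"
            )
        extra = [t for t in self.stages if t not in TEETH]
        if extra:
            raise RatingError(
                f"subject {self.subject_id}: unknown tooth {extra[0]!r}"
            )
        for tooth in TEETH:
            code = self.stages[tooth]
            if code not in STAGE_INDEX:
                raise RatingError(
                    f"subject {self.subject_id}: unknown stage {code!r} "
                    f"for tooth {tooth}"
                )
        if self.ca_years is None:
            if self.birth_date is None or self.exam_date is None:
                raise RatingError(
                    f"subject {self.subject_id}: need ca_years or both "
                    "birth_date and exam_date"
                )
            if self.exam_date < self.birth_date:
                raise RatingError(
                    f"subject {self.subject_id}: exam date precedes birth date"
                )
        elif self.ca_years < 0:
            raise RatingError(
                f"subject {self.subject_id}: negative ca_years {self.ca_years}"
            )

    @property
    def ca(self) -> float:
        """Chronological age in decimal years."""
        if self.ca_years is not None:
            return float(self.ca_years)
        return chronological_age(self.birth_date, self.exam_date)

    def numeric_stages(self) -> tuple[int, ...]:
        """Ordinal stage encoding in canonical tooth order."""
        return tuple(stage_numeric(self.stages[t]) for t in TEETH)


@dataclass(frozen=True)
class StageWeightTable:
    """Sex-specific (tooth, stage) -> score-contribution map.

    Invariants: weight(tooth, "0") == 0, weights non-decreasing in stage
    order per tooth, and the full-maturity total sums to 100.
    """

    sex: str
    weights: Mapping[str, Mapping[str, float]]
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise WeightTableError(f"sex must be one of {SEXES}, got {self.sex!r}")
        for tooth in TEETH:
            if tooth not in self.weights:
                raise WeightTableError(f"missing weights for tooth {tooth}")
            row = self.weights[tooth]
            for stage in STAGES:
                if stage not in row:
                    raise WeightTableError(
                        f"tooth {tooth}: missing weight for stage {stage}"
                    )
            if row["0"] != 0:
                raise WeightTableError(f"tooth {tooth}: weight at stage 0 must be 0")
            vals = [float(row[s]) for s in STAGES]
            if any(b < a for a, b in zip(vals, vals[1:])):
                raise WeightTableError(
                    f"tooth {tooth}: weights must be non-decreasing in stage order"
                )
        extra = [t for t in self.weights if t not in TEETH]
        if extra:
            raise WeightTableError(f"unknown tooth {extra[0]!r} in weight table")
        total = sum(float(self.weights[t]["H"]) for t in TEETH)
        if abs(total - 100.0) > 1e-9:
            raise WeightTableError(
                f"full-maturity total must be 100, got {total!r}"
            )

    def weight(self, tooth: str, stage: str) -> float:
        if tooth not in TEETH:
            raise WeightTableError(f"unknown tooth {tooth!r}")
        if stage not in STAGE_INDEX:
            raise WeightTableError(f"unknown stage {stage!r} for tooth {tooth}")
        return float(self.weights[tooth][stage])

    def increments(self, tooth: str) -> tuple[float, ...]:
        """Per-stage weight increments for one tooth, stage 0->A ... G->H."""
        vals = [self.weight(tooth, s) for s in STAGES]
        return tuple(b - a for a, b in zip(vals, vals[1:]))

    def max_increment(self) -> float:
        """Largest single-stage weight increment across all teeth."""
        return max(max(self.increments(t)) for t in TEETH)

    def to_document(self) -> dict:
        return {
            "sex": self.sex,
            "provenance": self.provenance,
            "weights": {t: {s: self.weights[t][s] for s in STAGES} for t in TEETH},
        }

    @classmethod
    def from_document(cls, doc: Mapping) -> "StageWeightTable":
        try:
            sex = doc["sex"]
            weights = doc["weights"]
        except (KeyError, TypeError) as exc:
            raise WeightTableError(f"weight-table document missing field: {exc}")
        return cls(sex=sex, weights=weights, provenance=doc.get("provenance", ""))


def load_weight_table(path: str | Path) -> StageWeightTable:
    """Load and validate a stage-weight table from a JSON file."""
    with open(path) as fh:
        return StageWeightTable.from_document(json.load(fh))


def load_demo_weights(sex: str) -> StageWeightTable:
    """Packaged synthetic demo weight table (not literature reference values)."""
    from importlib.resources import files

    if sex not in SEXES:
        raise WeightTableError(f"sex must be one of {SEXES}, got {sex!r}")
    text = files("dentage.data").joinpath(f"demo_weights_{sex}.json").read_text()
    return StageWeightTable.from_document(json.loads(text))


def save_weight_table(table: StageWeightTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(table.to_document(), fh, indent=1)
        fh.write("\n")


def compute_maturity_score(rating: ToothStageRating, table: StageWeightTable) -> float:
    """Sum of per-tooth stage weights; dental maturity on the 0-100 scale.

    The sum is invariant under tooth enumeration order; the table's sex
    must match the rating's.
    """
    if table.sex != rating.sex:
        raise RatingError(
            f"subject {rating.subject_id}: rating sex {rating.sex!r} does not "
            f"match weight-table sex {table.sex!r}"
        )
    return float(sum(table.weight(t, rating.stages[t]) for t in TEETH))


@dataclass(frozen=True)
class ReliabilityResult:
    """Cronbach's alpha between rating sessions."""

    alpha: float
    n_items: int
    n_ratings: int

    def __post_init__(self) -> None:
        if self.alpha > 1.0 + 1e-12:
            raise ReliabilityError(f"alpha cannot exceed 1, got {self.alpha}")


def cronbach_alpha(
    ratings_a: Sequence[float], ratings_b: Sequence[float]
) -> ReliabilityResult:
    """Two-session Cronbach's alpha over paired item scores.

    The two rating sessions are the k = 2 items and each rated
    tooth-subject is a case:  alpha = k/(k-1) * (1 - sum(item variances) /
    variance(item sums)), with n-1 denominators throughout.
    """
    a = np.asarray(ratings_a, dtype=float)
    b = np.asarray(ratings_b, dtype=float)
    if a.ndim != 1 or a.shape != b.shape:
        raise ReliabilityError("rating vectors must be 1-d and of equal length")
    if a.size < 2:
        raise ReliabilityError("need at least 2 paired ratings")
    var_total = float(np.var(a + b, ddof=1))
    if var_total == 0.0:
        raise ReliabilityError("alpha undefined: zero variance of rating sums")
    var_items = float(np.var(a, ddof=1) + np.var(b, ddof=1))
    # alpha <= 1 holds analytically for two items; trim float cancellation.
    alpha = min(2.0 * (1.0 - var_items / var_total), 1.0)
    return ReliabilityResult(alpha=alpha, n_items=2, n_ratings=int(a.size))


# ---------------------------------------------------------------------------
# Cohort CSV dialect
# ---------------------------------------------------------------------------

def read_cohort_csv(
    path: str | Path, *, allow_out_of_range: bool = False
) -> list[ToothStageRating]:
    """Read a cohort CSV into validated ratings.

    Header must be ``subject_id,sex,birth_date,exam_date,ca_years,I1,...,M2``
    with ISO-8601 dates; ``ca_years`` may be empty when both dates are
    present.  Subjects with chronological age outside [4, 14) are rejected
    unless ``allow_out_of_range`` (estimation-only use).
    """
    ratings: list[ToothStageRating] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or tuple(reader.fieldnames) != _COHORT_COLUMNS:
            raise RatingError(
                f"cohort CSV header must be {','.join(_COHORT_COLUMNS)}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                rating = _rating_from_row(row)
            except (RatingError, ValueError) as exc:
                raise RatingError(f"{path}, line {lineno}: {exc}") from None
            if not allow_out_of_range and not (CA_MIN <= rating.ca < CA_MAX):
                raise AgeRangeError(
                    f"{path}, line {lineno}: subject {rating.subject_id} has "
                    f"chronological age {rating.ca:.4f} out of validated "
                    f"range [{CA_MIN}, {CA_MAX})"
                )
            ratings.append(rating)
    return ratings


def _rating_from_row(row: Mapping[str, str]) -> ToothStageRating:
    birth = date.fromisoformat(row["birth_date"]) if row["birth_date"] else None
    exam = date.fromisoformat(row["exam_date"]) if row["exam_date"] else None
    ca = float(row["ca_years"]) if row["ca_years"] else None
    return ToothStageRating(
        subject_id=row["subject_id"],
        sex=row["sex"],
        stages={t: row[t] for t in TEETH},
        birth_date=birth,
        exam_date=exam,
        ca_years=ca,
    )


def write_cohort_csv(ratings: Iterable[ToothStageRating], path: str | Path) -> None:
    """Write ratings in the cohort CSV dialect (ages to 5 decimals)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COHORT_COLUMNS)
        for r in ratings:
            writer.writerow(
                [
                    r.subject_id,
                    r.sex,
                    r.birth_date.isoformat() if r.birth_date else "",
                    r.exam_date.isoformat() if r.exam_date else "",
                    f"{r.ca_years:.5f}" if r.ca_years is not None else "",
                ]
                + [r.stages[t] for t in TEETH]
            )
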