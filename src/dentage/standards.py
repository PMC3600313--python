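"""Score-to-age conversion standards: lookup tables and polynomial models.

A *conversion standard* maps a 0-100 maturity score to a dental age for one
sex.  Three realizations exist: a monotone (score, age) lookup table with
linear interpolation, a cubic polynomial, and a linear model.  Standards are
interchangeable throughout the comparison pipeline and serialize to a common
JSON document.
"""

from __future__ import annotations

import bisect
import json
from abc import ABC, abstractmethod
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from numpy.polynomial import Polynomial
from scipy.optimize import brentq

from .errors import CoverageError, FitError, StandardFormatError

_MONOTONE_GRID_STEP = 0.01


class ConversionStandard(ABC):
    """Common interface of all score-to-age conversions."""

    name: str
    sex: str

    @abstractmethod
    def score_to_age(self, score: float, *, extrapolate: bool = False) -> float:
        """Dental age at a maturity score.

        Scores outside the standard's coverage raise :class:`CoverageError`
        unless ``extrapolate`` is set, in which case the conversion is
        extended beyond coverage and the caller is expected to flag the
        result (see :meth:`in_score_coverage`).
        """

    @property
    @abstractmethod
    def score_coverage(self) -> tuple[float, float] | None:
        """Closed score interval of validity, or None for an empty table."""

    @property
    def age_coverage(self) -> tuple[float, float] | None:
        """Optional closed age interval restricting which subjects the
        standard applies to (None = unrestricted)."""
        return None

    def in_score_coverage(self, score: float) -> bool:
        cov = self.score_coverage
        return cov is not None and cov[0] <= score <= cov[1]

    def covers_subject(self, score: float, ca_years: float | None = None) -> bool:
        """Whether a subject (score, chronological age) is inside coverage."""
        if not self.in_score_coverage(score):
            return False
        if ca_years is not None and self.age_coverage is not None:
            lo, hi = self.age_coverage
            if not (lo <= ca_years <= hi):
                return False
        return True

    @abstractmethod
    def to_document(self) -> dict:
        """Serialize to the standard JSON document."""


@dataclass(frozen=True)
class TableStandard(ConversionStandard):
    """Monotone (score, age) lookup table with linear interpolation.

    Scores strictly increase; ages are non-decreasing.  At tabulated grid
    points the tabulated age is returned exactly; between grid points the
    two adjacent pairs are linearly interpolated.
    """

    name: str
    sex: str
    scores: tuple[float, ...]
    ages: tuple[float, ...]
    score_limits: tuple[float, float] | None = None
    age_limits: tuple[float, float] | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.scores) != len(self.ages):
            raise StandardFormatError(
                f"{self.name}: pairs mismatch ({len(self.scores)} scores, "
                f"{len(self.ages)} ages)"
            )
        s = self.scores
        if any(b <= a for a, b in zip(s, s[1:])):
            raise StandardFormatError(f"{self.name}: scores must strictly increase")
        a = self.ages
        if any(y < x for x, y in zip(a, a[1:])):
            raise StandardFormatError(f"{self.name}: ages must be non-decreasing")
        if self.score_limits is not None and s:
            lo, hi = self.score_limits
            if lo < s[0] or hi > s[-1]:
                raise StandardFormatError(
                    f"{self.name}: score coverage [{lo}, {hi}] exceeds the "
                    f"pairs' span [{s[0]}, {s[-1]}]"
                )

    @property
    def score_coverage(self) -> tuple[float, float] | None:
        if self.score_limits is not None:
            return self.score_limits
        if not self.scores:
            return None
        return (self.scores[0], self.scores[-1])

    @property
    def age_coverage(self) -> tuple[float, float] | None:
        return self.age_limits

    def score_to_age(self, score: float, *, extrapolate: bool = False) -> float:
        if not self.scores:
            raise CoverageError(f"{self.name}: empty table has no coverage")
        if not self.in_score_coverage(score) and not extrapolate:
            lo, hi = self.score_coverage
            raise CoverageError(
                f"{self.name}: score {score} outside coverage [{lo}, {hi}]"
            )
        i = bisect.bisect_left(self.scores, score)
        if i < len(self.scores) and self.scores[i] == score:
            return self.ages[i]  # exact grid point, no arithmetic
        return float(np.interp(score, self.scores, self.ages))

    def to_document(self) -> dict:
        doc: dict = {
            "name": self.name,
            "sex": self.sex,
            "variant": "table",
            "pairs": [[s, a] for s, a in zip(self.scores, self.ages)],
            "provenance": self.provenance,
        }
        coverage = {}
        if self.score_limits is not None:
            coverage["score"] = list(self.score_limits)
        if self.age_limits is not None:
            coverage["age"] = list(self.age_limits)
        if coverage:
            doc["coverage"] = coverage
        return doc


def _poly_is_monotone(coefs: Sequence[float], lo: float, hi: float) -> bool:
    """Strict increase of a polynomial checked on a 0.01-step grid."""
    if hi <= lo:
        return True
    n = max(2, int(round((hi - lo) / _MONOTONE_GRID_STEP)) + 1)
    grid = np.linspace(lo, hi, n)
    vals = np.polynomial.polynomial.polyval(grid, coefs)
    return bool(np.all(np.diff(vals) > 0))


@dataclass(frozen=True)
class CubicModel(ConversionStandard):
    """Cubic age-prediction polynomial: age = b0 + b1 x + b2 x^2 + b3 x^3.

    ``published_coefficients`` optionally carries rounded literature
    coefficients as metadata; they are never used for prediction.
    """

    b0: float
    b1: float
    b2: float
    b3: float
    sex: str
    score_range: tuple[float, float] = (0.0, 100.0)
    name: str = "cubic"
    provenance: str = ""
    published_coefficients: Mapping[str, float] | None = None
    validate: bool = True

    def __post_init__(self) -> None:
        lo, hi = self.score_range
        if not (0.0 <= lo < hi <= 100.0):
            raise StandardFormatError(
                f"{self.name}: score range [{lo}, {hi}] must lie within [0, 100]"
            )
        monotone = _poly_is_monotone(self.coefficients, lo, hi)
        object.__setattr__(self, "is_monotone", monotone)
        if self.validate and not monotone:
            raise StandardFormatError(
                f"{self.name}: polynomial is not strictly increasing on "
                f"[{lo}, {hi}]"
            )

    @property
    def coefficients(self) -> tuple[float, float, float, float]:
        return (self.b0, self.b1, self.b2, self.b3)

    def __call__(self, score: float) -> float:
        x = score
        return self.b0 + x * (self.b1 + x * (self.b2 + x * self.b3))

    @property
    def score_coverage(self) -> tuple[float, float] | None:
        return self.score_range

    @property
    def age_range(self) -> tuple[float, float]:
        """Attainable age interval over the valid score range."""
        lo, hi = self.score_range
        return (self(lo), self(hi))

    def score_to_age(self, score: float, *, extrapolate: bool = False) -> float:
        if not self.in_score_coverage(score) and not extrapolate:
            lo, hi = self.score_range
            raise CoverageError(
                f"{self.name}: score {score} outside coverage [{lo}, {hi}]"
            )
        return self(score)

    def age_to_score(self, age: float, *, clamp: bool = False) -> float:
        """Inverse conversion by bisection on the monotone score interval."""
        if not self.is_monotone:
            raise StandardFormatError(
                f"{self.name}: inverse undefined for a non-monotone model"
            )
        lo, hi = self.score_range
        alo, ahi = self(lo), self(hi)
        # Absorb boundary rounding (e.g. tabulated ages printed to 5
        # decimals) before rejecting.
        tol = 1e-5
        if not (alo - tol <= age <= ahi + tol):
            if not clamp:
                raise CoverageError(
                    f"{self.name}: age {age} outside attainable range "
                    f"[{alo:.5f}, {ahi:.5f}]"
                )
            return lo if age < alo else hi
        if age <= alo:
            return lo
        if age >= ahi:
            return hi
        return float(brentq(lambda x: self(x) - age, lo, hi, xtol=1e-12))

    def to_document(self) -> dict:
        doc: dict = {
            "name": self.name,
            "sex": self.sex,
            "variant": "poly",
            "coefficients": {
                "b0": self.b0,
                "b1": self.b1,
                "b2": self.b2,
                "b3": self.b3,
            },
            "coverage": {"score": list(self.score_range)},
            "provenance": self.provenance,
        }
        if self.published_coefficients is not None:
            doc["published_coefficients"] = dict(self.published_coefficients)
        return doc


@dataclass(frozen=True)
class LinearModel(ConversionStandard):
    """Linear age-prediction model: age = intercept + slope * score."""

    slope: float
    intercept: float
    sex: str
    score_range: tuple[float, float] = (0.0, 100.0)
    name: str = "linear"
    provenance: str = ""

    def __post_init__(self) -> None:
        lo, hi = self.score_range
        if not (0.0 <= lo < hi <= 100.0):
            raise StandardFormatError(
                f"{self.name}: score range [{lo}, {hi}] must lie within [0, 100]"
            )

    def __call__(self, score: float) -> float:
        return self.intercept + self.slope * score

    @property
    def score_coverage(self) -> tuple[float, float] | None:
        return self.score_range

    def score_to_age(self, score: float, *, extrapolate: bool = False) -> float:
        if not self.in_score_coverage(score) and not extrapolate:
            lo, hi = self.score_range
            raise CoverageError(
                f"{self.name}: score {score} outside coverage [{lo}, {hi}]"
            )
        return self(score)

    def to_document(self) -> dict:
        return {
            "name": self.name,
            "sex": self.sex,
            "variant": "poly",
            "coefficients": {"slope": self.slope, "intercept": self.intercept},
            "coverage": {"score": list(self.score_range)},
            "provenance": self.provenance,
        }


@dataclass(frozen=True)
class ShiftedStandard(ConversionStandard):
    """A standard with a constant age offset; used to inject known biases."""

    base: ConversionStandard
    offset_years: float
    name: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            object.__setattr__(self, "name", f"{self.base.name}+{self.offset_years}y")

    @property
    def sex(self) -> str:  # type: ignore[override]
        return self.base.sex

    @property
    def score_coverage(self) -> tuple[float, float] | None:
        return self.base.score_coverage

    @property
    def age_coverage(self) -> tuple[float, float] | None:
        cov = self.base.age_coverage
        if cov is None:
            return None
        return (cov[0] + self.offset_years, cov[1] + self.offset_years)

    def score_to_age(self, score: float, *, extrapolate: bool = False) -> float:
        return self.base.score_to_age(score, extrapolate=extrapolate) + self.offset_years

    def to_document(self) -> dict:
        raise StandardFormatError("shifted standards are in-memory only")


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PolynomialFit:
    """A fitted conversion model with goodness-of-fit summaries."""

    model: ConversionStandard
    rmse: float
    r_squared: float
    n: int


def fit_polynomial(
    scores: Sequence[float],
    ages: Sequence[float],
    degree: int,
    sex: str,
    *,
    name: str | None = None,
) -> PolynomialFit:
    """Ordinary least-squares polynomial of age on maturity score.

    Degree 1 or 3.  The fit is performed on a centered/scaled domain to
    keep the raw cubic basis well conditioned, then mapped back to raw
    coefficients.  The returned model's valid score range is the observed
    score span.
    """
    if degree not in (1, 3):
        raise FitError(f"degree must be 1 or 3, got {degree}")
    x = np.asarray(scores, dtype=float)
    y = np.asarray(ages, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise FitError("scores and ages must be 1-d and of equal length")
    if x.size < degree + 1:
        raise FitError(f"need at least {degree + 1} pairs for degree {degree}")
    if np.unique(x).size < degree + 1:
        raise FitError(
            f"rank-deficient design: only {np.unique(x).size} distinct scores"
        )
    poly = Polynomial.fit(x, y, deg=degree)  # scaled/centered domain
    coefs = poly.convert().coef
    coefs = np.pad(coefs, (0, degree + 1 - coefs.size))
    pred = poly(x)
    resid = y - pred
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    span = (float(x.min()), float(x.max()))
    if name is None:
        name = f"{sex}-degree{degree}-fit"
    model: ConversionStandard
    if degree == 1:
        model = LinearModel(
            slope=float(coefs[1]), intercept=float(coefs[0]), sex=sex,
            score_range=_clip_span(span), name=name,
        )
    else:
        model = CubicModel(
            b0=float(coefs[0]), b1=float(coefs[1]), b2=float(coefs[2]),
            b3=float(coefs[3]), sex=sex, score_range=_clip_span(span),
            name=name, validate=False,
        )
    return PolynomialFit(model=model, rmse=rmse, r_squared=r2, n=int(x.size))


def _clip_span(span: tuple[float, float]) -> tuple[float, float]:
    return (max(0.0, span[0]), min(100.0, span[1]))


def generate_prediction_table(
    model: CubicModel | LinearModel,
    scores: Sequence[float],
    *,
    name: str | None = None,
    decimals: int = 5,
) -> TableStandard:
    """Evaluate a model on a score grid into a lookup table.

    Ages are reported rounded to ``decimals`` places; the model must be
    monotone non-decreasing over the requested scores.
    """
    xs = [float(s) for s in scores]
    if any(b <= a for a, b in zip(xs, xs[1:])):
        raise StandardFormatError("score grid must strictly increase")
    cov = model.score_coverage
    for s in xs:
        if not (cov[0] <= s <= cov[1]):
            raise CoverageError(
                f"{model.name}: score {s} outside validity [{cov[0]}, {cov[1]}]"
            )
    ages = [round(model(s), decimals) for s in xs]
    if any(y < x for x, y in zip(ages, ages[1:])):
        raise StandardFormatError(
            f"{model.name}: model is not monotone over the requested scores"
        )
    return TableStandard(
        name=name or f"{model.name}-table",
        sex=model.sex,
        scores=tuple(xs),
        ages=tuple(ages),
        provenance=f"evaluated from model {model.name}",
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def load_standard(source: str | Path | Mapping) -> ConversionStandard:
    """Build a standard from a JSON document (path or parsed mapping)."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            doc = json.load(fh)
    else:
        doc = source
    if not isinstance(doc, Mapping):
        raise StandardFormatError("standard document must be a JSON object")
    for key in ("name", "sex", "variant"):
        if key not in doc:
            raise StandardFormatError(f"missing required field: {key}")
    variant = doc["variant"]
    coverage = doc.get("coverage", {})
    if not isinstance(coverage, Mapping):
        raise StandardFormatError("coverage: must be an object")
    score_cov = _interval(coverage, "score")
    age_cov = _interval(coverage, "age")
    if variant == "table":
        pairs = doc.get("pairs")
        if not isinstance(pairs, list):
            raise StandardFormatError("pairs: required list for variant 'table'")
        scores, ages = [], []
        for i, pair in enumerate(pairs):
            if not (isinstance(pair, (list, tuple)) and len(pair) == 2):
                raise StandardFormatError(f"pairs[{i}]: must be a [score, age] pair")
            scores.append(float(pair[0]))
            ages.append(float(pair[1]))
        return TableStandard(
            name=doc["name"], sex=doc["sex"],
            scores=tuple(scores), ages=tuple(ages),
            score_limits=score_cov, age_limits=age_cov,
            provenance=doc.get("provenance", ""),
        )
    if variant == "poly":
        coefs = doc.get("coefficients")
        if not isinstance(coefs, Mapping):
            raise StandardFormatError("coefficients: required object for variant 'poly'")
        if {"slope", "intercept"} <= set(coefs):
            return LinearModel(
                slope=float(coefs["slope"]), intercept=float(coefs["intercept"]),
                sex=doc["sex"], score_range=score_cov or (0.0, 100.0),
                name=doc["name"], provenance=doc.get("provenance", ""),
            )
        missing = [k for k in ("b0", "b1", "b2", "b3") if k not in coefs]
        if missing:
            raise StandardFormatError(f"coefficients.{missing[0]}: missing")
        published = doc.get("published_coefficients")
        return CubicModel(
            b0=float(coefs["b0"]), b1=float(coefs["b1"]),
            b2=float(coefs["b2"]), b3=float(coefs["b3"]),
            sex=doc["sex"], score_range=score_cov or (0.0, 100.0),
            name=doc["name"], provenance=doc.get("provenance", ""),
            published_coefficients=published,
        )
    raise StandardFormatError(f"variant: unknown tag {variant!r}")


def _interval(coverage: Mapping, key: str) -> tuple[float, float] | None:
    if key not in coverage:
        return None
    val = coverage[key]
    if not (isinstance(val, (list, tuple)) and len(val) == 2):
        raise StandardFormatError(f"coverage.{key}: must be a [lo, hi] pair")
    lo, hi = float(val[0]), float(val[1])
    if hi < lo:
        raise StandardFormatError(f"coverage.{key}: lo must not exceed hi")
    return (lo, hi)


def save_standard(standard: ConversionStandard, path: str | Path | None = None) -> dict:
    """Serialize a standard; write to ``path`` when given. Returns the document."""
    doc = standard.to_document()
    if path is not None:
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
            fh.write("\n")
    return doc


# ---------------------------------------------------------------------------
# Packaged standards
# ---------------------------------------------------------------------------

_BUILTIN_FILES = {
    "saudi_male_table": "saudi_male_table.json",
    "saudi_female_table": "saudi_female_table.json",
    "saudi_male_cubic": "saudi_male_cubic.json",
    "saudi_female_cubic": "saudi_female_cubic.json",
    "demo_french_canadian_male": "demo_french_canadian_male.json",
    "demo_french_canadian_female": "demo_french_canadian_female.json",
    "demo_belgian_male": "demo_belgian_male.json",
    "demo_belgian_female": "demo_belgian_female.json",
    "demo_kuwaiti_male": "demo_kuwaiti_male.json",
    "demo_kuwaiti_female": "demo_kuwaiti_female.json",
    "demo_alemran_male": "demo_alemran_male.json",
    "demo_alemran_female": "demo_alemran_female.json",
}


def available_builtins() -> tuple[str, ...]:
    """Keys of the standards shipped as package data."""
    return tuple(sorted(_BUILTIN_FILES))


def load_builtin(key: str) -> ConversionStandard:
    """Load a packaged standard by key (see :func:`available_builtins`)."""
    from importlib.resources import files

    try:
        fname = _BUILTIN_FILES[key]
    except KeyError:
        raise StandardFormatError(
            f"unknown builtin standard {key!r}; available: "
            f"{', '.join(available_builtins())}"
        ) from None
    doc = json.loads(files("dentage.data").joinpath(fname).read_text())
    return load_standard(doc)
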