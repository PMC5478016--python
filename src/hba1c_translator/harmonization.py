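"""Convert heterogeneous published effect-size formulations and pool evidence.

Published associations between HbA1c and complication incidence come in
three common shapes:

* ``per_absolute`` — fractional incidence drop per 1 percentage-point
  absolute HbA1c reduction (the model's native form);
* ``per_relative`` — fractional drop per 10% *relative* HbA1c reduction,
  i.e. I(H) = I0 * (1-r) ** (log(H/H0) / log(0.9));
* ``odds_ratio`` — an OR per 1% HbA1c step from a multivariable logistic
  model, anchored by a baseline risk at the study's mean HbA1c.

Each non-native form is converted by generating its incidence curve on a
fine HbA1c grid and least-squares fitting the native exponential form in
log space (the native model is log-linear in HbA1c, so the fit is a plain
linear regression). A conversion is accepted only when the fitted curve
stays within a configurable maximum relative deviation of the original —
converted studies whose shape the native form cannot mimic are excluded
from pooling, not silently distorted.

Pooling follows different rules per pillar. Effect sizes: person-year
weighted mean, plus the unweighted median and the single study closest to
both (ties resolved toward the smaller effect — the conservative,
underestimating choice). Incidences: each record is first normalized to
the reference HbA1c, then averaged UNWEIGHTED — a person-year weighted
mean would let one mega-study dominate the pool.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ParameterError
from .evidence_model import DiabetesType, EffectSize, IncidenceRecord
from .risk_engine import transfer_incidence

logger = logging.getLogger(__name__)

#: HbA1c grid for curve fitting: the supported window at 0.05% resolution.
DEFAULT_GRID = np.arange(6.5, 11.5 + 1e-9, 0.05)

#: Maximum relative deviation for a conversion to count as "very close".
DEFAULT_FIT_TOLERANCE = 0.05

#: Above this anchor risk the rare-disease OR≈RR reading degrades notably.
RARE_DISEASE_RISK_LIMIT = 0.10

DeviationKind = Literal["per_absolute", "per_relative", "odds_ratio"]


class DeviationForm(BaseModel):
    """One study's association in whichever of the three forms it was published.

    ``magnitude`` means: fraction a per 1% absolute HbA1c (per_absolute);
    fraction r per 10% relative HbA1c reduction (per_relative); or the OR
    per 1% absolute HbA1c *increase* (odds_ratio, stored normalized so that
    OR > 1, i.e. lower HbA1c means lower risk).
    """

    model_config = ConfigDict(frozen=True)

    kind: DeviationKind
    magnitude: float
    anchor_hba1c: Optional[float] = None
    baseline_risk: Optional[float] = None

    @model_validator(mode="after")
    def _by_kind(self) -> "DeviationForm":
        if self.kind in ("per_absolute", "per_relative"):
            if not (0.0 < self.magnitude < 1.0):
                raise ValueError(f"{self.kind} magnitude {self.magnitude} outside (0, 1)")
        else:
            if self.magnitude <= 1.0:
                raise ValueError(
                    f"odds_ratio magnitude {self.magnitude} must be > 1 per 1% increase "
                    "(normalize a protective OR per decrease as its reciprocal)")
        if self.kind in ("per_relative", "odds_ratio") and self.anchor_hba1c is None:
            raise ValueError(f"{self.kind} requires anchor_hba1c")
        if self.kind == "odds_ratio":
            if self.baseline_risk is None:
                raise ValueError("odds_ratio requires baseline_risk at the anchor")
            if not (0.0 < self.baseline_risk < 1.0):
                raise ValueError(f"baseline_risk {self.baseline_risk} outside (0, 1)")
        return self


@dataclass(frozen=True)
class FitResult:
    """Best per-absolute fit of a deviation form over the HbA1c grid."""

    a_fit: float
    max_rel_dev: float
    accepted: bool


def _curve(form: DeviationForm, grid: np.ndarray) -> np.ndarray:
    """Incidence curve (arbitrary scale) implied by the form over the grid."""
    if form.kind == "per_absolute":
        anchor = form.anchor_hba1c if form.anchor_hba1c is not None else float(grid[0])
        return (1.0 - form.magnitude) ** (anchor - grid)
    if form.kind == "per_relative":
        h0 = form.anchor_hba1c
        expo = np.log(grid / h0) / math.log(0.9)
        return (1.0 - form.magnitude) ** expo
    # odds_ratio: logistic risk with slope ln(OR), intercept from the anchor
    if form.baseline_risk > RARE_DISEASE_RISK_LIMIT:
        logger.warning(
            "odds_ratio form with baseline_risk %.3g > %.2g: rare-disease "
            "approximation degrades", form.baseline_risk, RARE_DISEASE_RISK_LIMIT)
    beta1 = math.log(form.magnitude)
    beta0 = math.log(form.baseline_risk / (1.0 - form.baseline_risk)) - beta1 * form.anchor_hba1c
    return 1.0 / (1.0 + np.exp(-(beta0 + beta1 * grid)))


def to_per_absolute(form: DeviationForm, grid: Optional[np.ndarray] = None,
                    tolerance: float = DEFAULT_FIT_TOLERANCE) -> FitResult:
    """Best-fit trend line of type "fractional change per 1% absolute HbA1c".

    A per_absolute input is returned unchanged (exact fit). Other forms are
    fitted by linear least squares of log incidence against HbA1c; the
    native model gives ``log I(H) = const - log(1-a) * (h0 - H)``, so the
    fitted slope s versus H maps to ``a = 1 - exp(-s)``.
    """
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    if grid.size < 2:
        raise ParameterError("fit grid needs at least two points")
    if form.kind == "per_absolute":
        return FitResult(a_fit=form.magnitude, max_rel_dev=0.0, accepted=True)
    curve = _curve(form, grid)
    slope, intercept = np.polyfit(grid, np.log(curve), 1)
    # native model: log I = const - ln(1-a) * (h0 - H), i.e. slope vs H is -ln(1-a)
    a_fit = 1.0 - math.exp(-slope)
    fitted = np.exp(intercept + slope * grid)
    max_rel_dev = float(np.max(np.abs(fitted - curve) / curve))
    return FitResult(a_fit=a_fit, max_rel_dev=max_rel_dev,
                     accepted=max_rel_dev <= tolerance)


# ---------------------------------------------------------------------------
# Raw study tables and the conversion gate
# ---------------------------------------------------------------------------

class RawAssociationStudy(BaseModel):
    """One row of an association evidence table, in its published form."""

    model_config = ConfigDict(frozen=True)

    source_id: str
    kind: DeviationKind
    magnitude: float
    anchor_hba1c: Optional[float] = None
    baseline_risk: Optional[float] = None
    person_years: float = Field(gt=0.0)
    diabetes_type: DiabetesType = "mixed"

    def form(self) -> DeviationForm:
        return DeviationForm(kind=self.kind, magnitude=self.magnitude,
                             anchor_hba1c=self.anchor_hba1c,
                             baseline_risk=self.baseline_risk)


def read_association_table(path: str | Path) -> list[RawAssociationStudy]:
    """Read a delimited association-evidence table (one study per row)."""
    df = pd.read_csv(path)
    studies = []
    for idx, row in df.iterrows():
        fields = {k: (None if pd.isna(v) else v) for k, v in row.items()}
        try:
            studies.append(RawAssociationStudy(**fields))
        except Exception as exc:
            raise ParameterError(f"{path} row {idx}: {exc}") from exc
    return studies


def harmonize_studies(
    studies: Sequence[RawAssociationStudy],
    grid: Optional[np.ndarray] = None,
    tolerance: float = DEFAULT_FIT_TOLERANCE,
) -> tuple[list[EffectSize], list[tuple[RawAssociationStudy, FitResult]]]:
    """Convert each study to the per-absolute form, gating on fit quality.

    Returns the accepted studies as :class:`EffectSize` values ready for
    pooling, and the rejected (study, fit) pairs whose curves the native
    form could not reproduce within tolerance (these are logged and
    excluded from pooling by default).
    """
    accepted: list[EffectSize] = []
    rejected: list[tuple[RawAssociationStudy, FitResult]] = []
    for study in studies:
        fit = to_per_absolute(study.form(), grid=grid, tolerance=tolerance)
        if fit.accepted:
            accepted.append(EffectSize(a=fit.a_fit, person_years=study.person_years,
                                       study_mean_hba1c=study.anchor_hba1c,
                                       diabetes_type=study.diabetes_type,
                                       source_id=study.source_id))
        else:
            logger.warning("study '%s': best per-absolute fit deviates %.1f%% > %.1f%%; excluded",
                           study.source_id, 100 * fit.max_rel_dev, 100 * tolerance)
            rejected.append((study, fit))
    return accepted, rejected


# ---------------------------------------------------------------------------
# Pooling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PooledAssociation:
    """Person-year weighted mean, unweighted median, and the representative study.

    ``selected`` is the single study value closest to both the weighted
    mean and the median (minimizing the summed absolute distances); it and
    the weighted mean are both exposed so the user can choose either
    pooling convention.
    """

    weighted_mean: float
    median: float
    selected: float
    selected_source_id: str


def pool_associations(studies: Sequence[EffectSize]) -> PooledAssociation:
    """Pool per-absolute effect sizes across studies."""
    if not studies:
        raise ParameterError("cannot pool an empty list of effect-size studies")
    a = np.array([s.a for s in studies], dtype=float)
    py = np.array([s.person_years for s in studies], dtype=float)
    weighted_mean = float(np.sum(py * a) / np.sum(py))
    median = float(np.median(a))
    # representative study: closest to mean and median combined; tie -> smaller a
    # (conservative: prefer underestimating the effect)
    order = sorted(range(len(studies)),
                   key=lambda k: (abs(a[k] - weighted_mean) + abs(a[k] - median), a[k]))
    best = order[0]
    return PooledAssociation(weighted_mean=weighted_mean, median=median,
                             selected=float(a[best]),
                             selected_source_id=studies[best].source_id)


def pool_incidences(records: Sequence[IncidenceRecord], a: float,
                    reference_hba1c: float) -> float:
    """Normalize every record to the reference HbA1c, then average unweighted."""
    if not records:
        raise ParameterError("cannot pool an empty list of incidence records")
    normalized = []
    for record in records:
        if record.study_mean_hba1c is None:
            raise ParameterError(
                f"incidence record '{record.source_id}' lacks a study mean HbA1c")
        normalized.append(transfer_incidence(record.incidence, a,
                                             record.study_mean_hba1c, reference_hba1c))
    return float(np.mean(normalized))
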