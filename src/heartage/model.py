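"""Piecewise functional-heart-age scoring from left atrial volumetry.

The score maps left atrial end-systolic volume (LA ESV, mL) to a predicted
"functional heart age" through three segment-wise linear equations, then adds
a threshold correction driven by the LA ejection fraction (LA EF, %):
low LA EF marks reduced atrial pump efficiency and ages the prediction.

Segment membership convention: [0, 15) mL -> low segment, [15, 50] mL ->
mid segment, (50, inf) -> high segment (boundary volumes belong to the mid
segment).  EF bands are half-open [lower, upper), so each EF maps to exactly
one band; EF at or above the last bound receives no correction.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "HeartAgeModelParams",
    "HeartAgePrediction",
    "DEFAULT_PARAMS",
    "base_age",
    "ef_correction",
    "predict_heart_age",
    "predict_cohort",
    "load_params",
    "save_params",
]

#: Published segment coefficients: (intercept [years], slope [years/mL]).
_DEFAULT_SEGMENTS = ((6.4026, 0.2468), (-18.0342, 2.3140), (87.9207, 0.05241))
#: LA ESV segment boundaries (mL).
_DEFAULT_BREAKPOINTS = (15.0, 50.0)
#: (EF upper bound [%], additive correction [years]); above the last bound -> 0.
_DEFAULT_EF_BANDS = ((55.0, 20.0), (58.0, 15.0), (60.0, 5.0), (62.0, 2.0))


class DomainError(ValueError):
    """An input lies outside the model's physiological domain."""


class MissingInputError(ValueError):
    """A required input is missing (NaN/None); the model never imputes."""


@dataclass(frozen=True)
class HeartAgeModelParams:
    """Parameters of the piecewise heart-age score.

    Attributes
    ----------
    esv_breakpoints
        Strictly increasing LA ESV boundaries (mL) between segments.
    segments
        One ``(intercept, slope)`` pair per segment,
        ``len(segments) == len(esv_breakpoints) + 1``.
    ef_bands
        ``(ef_upper_bound_pct, correction_years)`` with strictly increasing
        bounds and non-increasing corrections; EF >= last bound adds 0 years.
    """

    esv_breakpoints: tuple[float, ...] = _DEFAULT_BREAKPOINTS
    segments: tuple[tuple[float, float], ...] = _DEFAULT_SEGMENTS
    ef_bands: tuple[tuple[float, float], ...] = _DEFAULT_EF_BANDS

    def __post_init__(self) -> None:
        bps = tuple(float(b) for b in self.esv_breakpoints)
        segs = tuple((float(a), float(b)) for a, b in self.segments)
        bands = tuple((float(u), float(c)) for u, c in self.ef_bands)
        object.__setattr__(self, "esv_breakpoints", bps)
        object.__setattr__(self, "segments", segs)
        object.__setattr__(self, "ef_bands", bands)
        if any(b2 <= b1 for b1, b2 in zip(bps, bps[1:])):
            raise ValueError("esv_breakpoints must be strictly increasing")
        if len(segs) != len(bps) + 1:
            raise ValueError(
                f"expected {len(bps) + 1} segments for {len(bps)} breakpoints, "
                f"got {len(segs)}"
            )
        ubs = [u for u, _ in bands]
        if any(u2 <= u1 for u1, u2 in zip(ubs, ubs[1:])):
            raise ValueError("ef band upper bounds must be strictly increasing")
        corrs = [c for _, c in bands]
        if any(c2 > c1 for c1, c2 in zip(corrs, corrs[1:])):
            raise ValueError("ef band corrections must be non-increasing")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "esv_breakpoints_ml": list(self.esv_breakpoints),
            "segments": [
                {"intercept_yr": a, "slope_yr_per_ml": b} for a, b in self.segments
            ],
            "ef_bands": [
                {"ef_upper_pct": u, "correction_yr": c} for u, c in self.ef_bands
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HeartAgeModelParams":
        return cls(
            esv_breakpoints=tuple(d["esv_breakpoints_ml"]),
            segments=tuple(
                (s["intercept_yr"], s["slope_yr_per_ml"]) for s in d["segments"]
            ),
            ef_bands=tuple(
                (b["ef_upper_pct"], b["correction_yr"]) for b in d["ef_bands"]
            ),
        )


def save_params(params: HeartAgeModelParams, path) -> None:
    """Write model parameters to a YAML file (full decimal precision)."""
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


def load_params(path=None) -> HeartAgeModelParams:
    """Load parameters from YAML; with no path, load the shipped defaults."""
    if path is None:
        text = (
            resources.files("heartage").joinpath("data/default_model.yaml").read_text()
        )
        return HeartAgeModelParams.from_dict(yaml.safe_load(text))
    with open(path) as fh:
        return HeartAgeModelParams.from_dict(yaml.safe_load(fh))


DEFAULT_PARAMS = HeartAgeModelParams()


@dataclass(frozen=True)
class HeartAgePrediction:
    """One subject's functional-heart-age prediction.

    ``functional_age = base_age + ef_correction`` unless the sum was negative
    and floored at zero, in which case ``floored`` is set.
    """

    base_age: float
    ef_correction: float
    functional_age: float
    segment_index: int
    ef_band_index: int | None
    floored: bool = False
    subject_id: object | None = None


def _segment_index(la_esv: float, breakpoints: Sequence[float]) -> int:
    # bisect_right puts a boundary value into the upper segment; the last
    # breakpoint is pulled back so e.g. ESV 50 stays in the mid segment.
    i = bisect_right(breakpoints, la_esv)
    if i == len(breakpoints) and la_esv == breakpoints[-1]:
        i -= 1
    return i


def _check_esv(la_esv: float) -> float:
    if la_esv is None or (isinstance(la_esv, float) and math.isnan(la_esv)):
        raise MissingInputError("LA ESV is missing")
    la_esv = float(la_esv)
    if not math.isfinite(la_esv) or la_esv < 0:
        raise DomainError(f"LA ESV must be finite and >= 0 mL, got {la_esv!r}")
    return la_esv


def _check_ef(la_ef: float) -> float:
    if la_ef is None or (isinstance(la_ef, float) and math.isnan(la_ef)):
        raise MissingInputError("LA EF is missing")
    la_ef = float(la_ef)
    if not math.isfinite(la_ef) or not 0.0 <= la_ef <= 100.0:
        raise DomainError(f"LA EF must lie in [0, 100] %, got {la_ef!r}")
    return la_ef


def base_age(la_esv: float, params: HeartAgeModelParams = DEFAULT_PARAMS) -> float:
    """Segment-wise linear heart age (years) from LA ESV (mL), no EF term."""
    la_esv = _check_esv(la_esv)
    intercept, slope = params.segments[_segment_index(la_esv, params.esv_breakpoints)]
    return intercept + slope * la_esv


def ef_correction(la_ef: float, params: HeartAgeModelParams = DEFAULT_PARAMS) -> float:
    """Additive age correction (years) for LA EF (%); 0 above the last band."""
    la_ef = _check_ef(la_ef)
    for upper, corr in params.ef_bands:
        if la_ef < upper:
            return corr
    return 0.0


def _ef_band_index(la_ef: float, params: HeartAgeModelParams) -> int | None:
    for i, (upper, _) in enumerate(params.ef_bands):
        if la_ef < upper:
            return i
    return None


def predict_heart_age(
    la_esv: float,
    la_ef: float,
    params: HeartAgeModelParams = DEFAULT_PARAMS,
    subject_id=None,
) -> HeartAgePrediction:
    """Full functional-heart-age prediction for one subject.

    Parameters
    ----------
    la_esv : float
        Left atrial end-systolic volume, mL (>= 0, finite).
    la_ef : float
        Left atrial ejection fraction, % (0..100).

    Returns
    -------
    HeartAgePrediction
        ``functional_age = base + correction``, floored at 0 years (the low
        segment's intercept keeps defaults positive, but re-derived parameter
        sets may not).
    """
    la_esv = _check_esv(la_esv)
    la_ef = _check_ef(la_ef)
    base = base_age(la_esv, params)
    corr = ef_correction(la_ef, params)
    total = base + corr
    floored = total < 0.0
    return HeartAgePrediction(
        base_age=base,
        ef_correction=corr,
        functional_age=max(total, 0.0),
        segment_index=_segment_index(la_esv, params.esv_breakpoints),
        ef_band_index=_ef_band_index(la_ef, params),
        floored=floored,
        subject_id=subject_id,
    )


def predict_cohort(
    cohort,
    params: HeartAgeModelParams = DEFAULT_PARAMS,
    missing: str = "raise",
) -> list[HeartAgePrediction | None]:
    """Element-wise prediction over a cohort, order-preserving.

    ``cohort`` may be a pandas DataFrame with ``la_esv_ml``/``la_ef_pct``
    (optionally ``subject_id``) columns, or an iterable of objects exposing
    ``la_esv``/``la_ef`` attributes, or ``(la_esv, la_ef)`` pairs.
    ``missing='null'`` maps records with missing inputs to ``None`` instead of
    raising; nothing is ever imputed.
    """
    if missing not in ("raise", "null"):
        raise ValueError("missing must be 'raise' or 'null'")
    rows: list[tuple[object, float, float]] = []
    if isinstance(cohort, pd.DataFrame):
        ids = (
            cohort["subject_id"]
            if "subject_id" in cohort.columns
            else cohort.index
        )
        for sid, esv, ef in zip(ids, cohort["la_esv_ml"], cohort["la_ef_pct"]):
            rows.append((sid, esv, ef))
    else:
        for i, rec in enumerate(cohort):
            if hasattr(rec, "la_esv"):
                rows.append((getattr(rec, "subject_id", i), rec.la_esv, rec.la_ef))
            else:
                esv, ef = rec
                rows.append((i, esv, ef))
    out: list[HeartAgePrediction | None] = []
    for sid, esv, ef in rows:
        try:
            out.append(predict_heart_age(esv, ef, params, subject_id=sid))
        except MissingInputError:
            if missing == "raise":
                raise MissingInputError(
                    f"subject {sid!r}: missing LA ESV or LA EF"
                ) from None
            out.append(None)
    return out


def predictions_frame(predictions: Iterable[HeartAgePrediction | None]) -> pd.DataFrame:
    """Tabulate predictions (None rows become NaN) for CSV output."""
    rows = []
    for p in predictions:
        if p is None:
            rows.append(
                {
                    "subject_id": None,
                    "base_age_yr": np.nan,
                    "ef_correction_yr": np.nan,
                    "functional_heart_age_yr": np.nan,
                }
            )
        else:
            rows.append(
                {
                    "subject_id": p.subject_id,
                    "base_age_yr": p.base_age,
                    "ef_correction_yr": p.ef_correction,
                    "functional_heart_age_yr": p.functional_age,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "base_age_yr",
            "ef_correction_yr",
            "functional_heart_age_yr",
        ],
    )
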