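"""Synthetic CMR cohorts with the statistical structure the pipeline assumes.

Healthy subjects are built by inverting the heart-age score: chronological
age is drawn uniformly over the age range, LA EF declines linearly with age
(66 -> 55 % by default, plus jitter), and LA ESV is the model inverse of
(age - EF-band correction) plus Gaussian scatter, so that with zero noise the
scorer recovers chronological age exactly on the interior of the mid
segment.  Outside the mid segment's age span the inverse continues with a
blunted slope (a configurable fraction of the mid-segment slope), mirroring
how the derivation damps the extreme segments.

All remaining chamber metrics are drawn from log-normal/normal marginals
whose medians sit at the reference healthy medians, tied together by one
shared per-subject "heart size" latent factor; the volumetric identities
(SV = EDV - ESV, EF = 100*SV/EDV, CO = SV*HR) hold exactly by construction.
Unhealthy cohorts start from the same machinery and then apply per-metric
multiplicative/additive shifts (defaults reproduce the direction and rough
magnitude of the healthy-vs-unhealthy median contrasts), sample comorbidity
flags, and push LA volumetry toward the obesity-class medians.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .metrics import ContourSeries, MYOCARDIAL_DENSITY_G_PER_ML
from .model import DEFAULT_PARAMS, HeartAgeModelParams, ef_correction

__all__ = [
    "CohortConfig",
    "SubjectRecord",
    "generate_healthy",
    "generate_unhealthy",
    "generate_contours",
    "write_cohort",
    "read_cohort",
    "cohort_frame",
    "model_inverse",
]

#: Reference healthy medians (the generator's calibration targets).
HEALTHY_MEDIANS = {
    "la_gls_pct": -28.0,
    "lv_edv_ml": 126.0,
    "lv_ef_pct": 62.0,
    "lv_mass_g": 85.0,
    "lv_per_ml_per_s": 382.0,
    "lv_pfr_ml_per_s": 448.0,
    "lv_gls_pct": -21.0,
    "ra_edv_ml": 65.0,
    "ra_ef_pct": 53.0,
    "ra_gls_pct": -28.0,
    "rv_edv_ml": 70.0,
    "rv_ef_pct": 62.0,
    "rv_gls_pct": -32.0,
    "heart_rate_bpm": 62.0,
}

#: Default unhealthy-vs-healthy contrasts (multiplicative for sizes/rates,
#: additive percentage points for EF/GLS), from the reference median tables.
DEFAULT_UNHEALTHY_SHIFTS = {
    "la_esv_ml": 28.0 / 23.0,
    "la_ef_pct": -3.0,
    "la_gls_pct": +2.0,
    "lv_edv_ml": 138.0 / 126.0,
    "lv_ef_pct": +1.0,
    "lv_mass_g": 111.0 / 85.0,
    "lv_per_ml_per_s": 414.0 / 382.0,
    "lv_pfr_ml_per_s": 464.0 / 448.0,
    "lv_gls_pct": -1.0,
    "ra_edv_ml": 75.0 / 65.0,
    "ra_ef_pct": -1.0,
    "ra_gls_pct": +1.0,
    "rv_edv_ml": 82.0 / 70.0,
    "rv_ef_pct": 0.0,
    "rv_gls_pct": +1.0,
    "heart_rate_bpm": 1.035,
}

#: Extra LA shifts per obesity class (multiplier on LA ESV, additive LA EF),
#: steering class strata toward the obesity-class reference medians
#: (class III: LA ESV ~54 mL, LA EF ~49 %).
DEFAULT_OBESITY_CLASS_SHIFTS = {
    "obesity I": (31.0 / 28.0, -1.0),
    "obesity II": (33.0 / 28.0, -2.0),
    "obesity III": (54.0 / 28.0, -13.0),
}

DEFAULT_PREVALENCES = {
    "hyperlipidaemia": 0.15,
    "hypertension": 0.22,
    "diabetes": 0.11,
    "atrial_fibrillation": 0.06,
    "myocardial_infarction": 0.06,
}

#: Study-style per-decade group sizes, usable as an age weighting preset.
STUDY_GROUP_SIZES = (43, 82, 99, 92, 80, 89, 78)

COHORT_COLUMNS = [
    "subject_id", "age_yr", "sex", "bmi", "heart_rate_bpm",
    "hyperlipidaemia", "hypertension", "diabetes", "atrial_fibrillation",
    "myocardial_infarction", "health_status",
    "la_edv_ml", "la_esv_ml", "la_sv_ml", "la_ef_pct", "la_gls_pct",
    "lv_edv_ml", "lv_esv_ml", "lv_sv_ml", "lv_ef_pct", "lv_mass_g",
    "lv_per_ml_per_s", "lv_pfr_ml_per_s", "lv_co_ml_per_min", "lv_gls_pct",
    "ra_edv_ml", "ra_esv_ml", "ra_sv_ml", "ra_ef_pct", "ra_gls_pct",
    "rv_edv_ml", "rv_esv_ml", "rv_sv_ml", "rv_ef_pct", "rv_co_ml_per_min",
    "rv_gls_pct",
]


@dataclass(frozen=True)
class CohortConfig:
    """Generative settings for a synthetic cohort.

    ``noise_sd_years`` is the LA ESV scatter around the model inverse,
    expressed in years and converted to mL through the mid-segment slope.
    ``ef_decline`` is the (start, end) of the linear LA EF trend across the
    age range; ``ef_jitter_sd`` its per-subject scatter.  With
    ``encode_ef_corrections`` (default) the inverse subtracts the EF-band
    correction before mapping age to ESV, making the zero-noise generator the
    exact inverse of the full scorer on the interior domain.
    """

    n: int = 191
    seed: int = 0
    age_range: tuple[float, float] = (10.0, 85.0)
    ef_decline: tuple[float, float] = (66.0, 55.0)
    #: (age, EF) knee of the decline: slow drift before it, steep after,
    #: matching the observed acceleration after the fifth decade.  None gives
    #: a plain linear decline.
    ef_knee: tuple[float, float] | None = (50.0, 64.0)
    ef_jitter_sd: float = 3.0
    noise_sd_years: float = 5.0
    blunt_fraction: float = 0.25
    encode_ef_corrections: bool = True
    use_study_age_weights: bool = False
    size_factor_sd: float = 0.10
    prevalences: dict = field(default_factory=lambda: dict(DEFAULT_PREVALENCES))
    unhealthy_shifts: dict = field(
        default_factory=lambda: dict(DEFAULT_UNHEALTHY_SHIFTS)
    )
    obesity_class_shifts: dict = field(
        default_factory=lambda: dict(DEFAULT_OBESITY_CLASS_SHIFTS)
    )

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must be (lo, hi) with lo < hi")
        if self.noise_sd_years < 0 or self.ef_jitter_sd < 0:
            raise ValueError("noise settings must be >= 0")
        if not 0 < self.blunt_fraction <= 1:
            raise ValueError("blunt_fraction must lie in (0, 1]")
        for k, v in self.prevalences.items():
            if not 0 <= v <= 1:
                raise ValueError(f"prevalence {k}={v} outside [0, 1]")


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's demographics, comorbidity flags, and chamber metrics."""

    subject_id: str
    age_yr: float
    sex: str
    bmi: float
    heart_rate_bpm: float
    hyperlipidaemia: bool
    hypertension: bool
    diabetes: bool
    atrial_fibrillation: bool
    myocardial_infarction: bool
    health_status: str
    la_edv_ml: float
    la_esv_ml: float
    la_sv_ml: float
    la_ef_pct: float
    la_gls_pct: float
    lv_edv_ml: float
    lv_esv_ml: float
    lv_sv_ml: float
    lv_ef_pct: float
    lv_mass_g: float
    lv_per_ml_per_s: float
    lv_pfr_ml_per_s: float
    lv_co_ml_per_min: float
    lv_gls_pct: float
    ra_edv_ml: float
    ra_esv_ml: float
    ra_sv_ml: float
    ra_ef_pct: float
    ra_gls_pct: float
    rv_edv_ml: float
    rv_esv_ml: float
    rv_sv_ml: float
    rv_ef_pct: float
    rv_co_ml_per_min: float
    rv_gls_pct: float

    # scorer-facing aliases
    @property
    def la_esv(self) -> float:
        return self.la_esv_ml

    @property
    def la_ef(self) -> float:
        return self.la_ef_pct


def model_inverse(
    age_years,
    params: HeartAgeModelParams = DEFAULT_PARAMS,
    blunt_fraction: float = 0.25,
):
    """LA ESV whose mid-segment score equals ``age_years``.

    Exact inverse of the mid segment on its age span; beyond it the mapping
    continues from the breakpoints with ``blunt_fraction`` of the mid slope
    (in age-per-mL terms), keeping the age->ESV curve continuous and
    monotone.  Clipped to >= 0.2 mL.
    """
    a = np.asarray(age_years, dtype=float)
    lo, hi = params.esv_breakpoints
    c, m = params.segments[1]
    age_lo = c + m * lo
    age_hi = c + m * hi
    mb = blunt_fraction * m
    esv = np.where(
        a < age_lo,
        lo + (a - age_lo) / mb,
        np.where(a > age_hi, hi + (a - age_hi) / mb, (a - c) / m),
    )
    return np.maximum(esv, 0.2)


def _sample_ages(rng: np.random.Generator, cfg: CohortConfig, n: int) -> np.ndarray:
    lo, hi = cfg.age_range
    if not cfg.use_study_age_weights:
        return rng.uniform(lo, hi, n)
    from .derivation import DECADE_GROUPS

    weights = np.array(STUDY_GROUP_SIZES, dtype=float)
    weights /= weights.sum()
    groups = rng.choice(len(weights), size=n, p=weights)
    ages = np.empty(n)
    for gi, (glo, ghi) in enumerate(DECADE_GROUPS):
        mask = groups == gi
        ages[mask] = rng.uniform(
            max(glo, lo), min(ghi + 0.999, hi), int(mask.sum())
        )
    return ages


def _healthy_frame(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n
    lo, hi = cfg.age_range
    age = _sample_ages(rng, cfg, n)
    sex = np.where(rng.random(n) < 0.55, "F", "M")
    bmi = np.clip(rng.normal(21.5, 1.8, n), 16.0, 24.9)
    hr = HEALTHY_MEDIANS["heart_rate_bpm"] * np.exp(rng.normal(0, 0.12, n))

    ef_start, ef_end = cfg.ef_decline
    if cfg.ef_knee is not None:
        knee_age, knee_ef = cfg.ef_knee
        la_ef = np.interp(age, [lo, knee_age, hi], [ef_start, knee_ef, ef_end])
    else:
        la_ef = ef_start + (ef_end - ef_start) * (age - lo) / (hi - lo)
    la_ef = np.clip(la_ef + rng.normal(0, cfg.ef_jitter_sd, n), 35.0, 85.0)

    corr = (
        np.array([ef_correction(e) for e in la_ef])
        if cfg.encode_ef_corrections
        else np.zeros(n)
    )
    _, mid_slope = DEFAULT_PARAMS.segments[1]
    esv_noise_ml = cfg.noise_sd_years / mid_slope
    la_esv = model_inverse(age - corr, DEFAULT_PARAMS, cfg.blunt_fraction)
    la_esv = np.maximum(la_esv + rng.normal(0, esv_noise_ml, n), 0.2)

    la_edv = la_esv / (1.0 - la_ef / 100.0)
    la_gls = np.clip(
        rng.normal(HEALTHY_MEDIANS["la_gls_pct"], 3.5, n), -45.0, -5.0
    )

    size = np.exp(rng.normal(0, cfg.size_factor_sd, n))
    lv_edv = HEALTHY_MEDIANS["lv_edv_ml"] * size * np.exp(rng.normal(0, 0.12, n))
    lv_ef = np.clip(rng.normal(HEALTHY_MEDIANS["lv_ef_pct"], 3.0, n), 50.0, 75.0)
    lv_mass = HEALTHY_MEDIANS["lv_mass_g"] * size * np.exp(rng.normal(0, 0.15, n))
    lv_per = HEALTHY_MEDIANS["lv_per_ml_per_s"] * size * np.exp(
        rng.normal(0, 0.15, n)
    )
    lv_pfr = HEALTHY_MEDIANS["lv_pfr_ml_per_s"] * size * np.exp(
        rng.normal(0, 0.18, n)
    )
    lv_gls = np.clip(rng.normal(HEALTHY_MEDIANS["lv_gls_pct"], 2.5, n), -40.0, -5.0)

    ra_edv = HEALTHY_MEDIANS["ra_edv_ml"] * size * np.exp(rng.normal(0, 0.13, n))
    ra_ef = np.clip(rng.normal(HEALTHY_MEDIANS["ra_ef_pct"], 4.0, n), 30.0, 70.0)
    ra_gls = np.clip(rng.normal(HEALTHY_MEDIANS["ra_gls_pct"], 3.0, n), -45.0, -5.0)

    rv_edv = HEALTHY_MEDIANS["rv_edv_ml"] * size * np.exp(rng.normal(0, 0.15, n))
    rv_ef = np.clip(rng.normal(HEALTHY_MEDIANS["rv_ef_pct"], 3.5, n), 45.0, 75.0)
    rv_gls = np.clip(rng.normal(HEALTHY_MEDIANS["rv_gls_pct"], 3.0, n), -50.0, -10.0)

    frame = pd.DataFrame(
        {
            "subject_id": [f"S{i:05d}" for i in range(n)],
            "age_yr": age,
            "sex": sex,
            "bmi": bmi,
            "heart_rate_bpm": hr,
            "hyperlipidaemia": np.zeros(n, dtype=bool),
            "hypertension": np.zeros(n, dtype=bool),
            "diabetes": np.zeros(n, dtype=bool),
            "atrial_fibrillation": np.zeros(n, dtype=bool),
            "myocardial_infarction": np.zeros(n, dtype=bool),
            "health_status": ["healthy"] * n,
            "la_esv_ml": la_esv,
            "la_ef_pct": la_ef,
            "la_edv_ml": la_edv,
            "la_gls_pct": la_gls,
            "lv_edv_ml": lv_edv,
            "lv_ef_pct": lv_ef,
            "lv_mass_g": lv_mass,
            "lv_per_ml_per_s": lv_per,
            "lv_pfr_ml_per_s": lv_pfr,
            "lv_gls_pct": lv_gls,
            "ra_edv_ml": ra_edv,
            "ra_ef_pct": ra_ef,
            "ra_gls_pct": ra_gls,
            "rv_edv_ml": rv_edv,
            "rv_ef_pct": rv_ef,
            "rv_gls_pct": rv_gls,
        }
    )
    return _recompute_derived(frame)


def _recompute_derived(frame: pd.DataFrame) -> pd.DataFrame:
    """Re-establish SV/EF/CO identities from the primary quantities."""
    f = frame
    f["la_edv_ml"] = f["la_esv_ml"] / (1.0 - f["la_ef_pct"] / 100.0)
    f["la_sv_ml"] = f["la_edv_ml"] - f["la_esv_ml"]
    for ch in ("lv", "ra", "rv"):
        f[f"{ch}_esv_ml"] = f[f"{ch}_edv_ml"] * (1.0 - f[f"{ch}_ef_pct"] / 100.0)
        f[f"{ch}_sv_ml"] = f[f"{ch}_edv_ml"] - f[f"{ch}_esv_ml"]
    f["lv_co_ml_per_min"] = f["lv_sv_ml"] * f["heart_rate_bpm"]
    f["rv_co_ml_per_min"] = f["rv_sv_ml"] * f["heart_rate_bpm"]
    return f[COHORT_COLUMNS]


def _to_records(frame: pd.DataFrame) -> list[SubjectRecord]:
    return [SubjectRecord(**row) for row in frame.to_dict("records")]


def generate_healthy(config: CohortConfig) -> list[SubjectRecord]:
    """Synthetic healthy cohort (normal BMI, no comorbidities, LV EF >= 50)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    if config.n == 0:
        return []
    return _to_records(_healthy_frame(config, rng))


def generate_unhealthy(config: CohortConfig) -> list[SubjectRecord]:
    """Synthetic comorbid cohort: healthy machinery plus per-metric shifts,
    comorbidity flags, BMI >= 25 for the purely overweight stratum, and
    obesity-class pushes on LA volumetry."""
    config.validate()
    rng = np.random.default_rng(config.seed + 1_000_003)
    if config.n == 0:
        return []
    f = _healthy_frame(config, rng)
    n = config.n
    sh = config.unhealthy_shifts

    for col in (
        "la_esv_ml", "lv_edv_ml", "lv_mass_g", "lv_per_ml_per_s",
        "lv_pfr_ml_per_s", "ra_edv_ml", "rv_edv_ml", "heart_rate_bpm",
    ):
        f[col] = f[col] * sh.get(col, 1.0)
    for col in (
        "la_ef_pct", "lv_ef_pct", "ra_ef_pct", "rv_ef_pct",
        "la_gls_pct", "lv_gls_pct", "ra_gls_pct", "rv_gls_pct",
    ):
        f[col] = f[col] + sh.get(col, 0.0)
    f["la_ef_pct"] = f["la_ef_pct"].clip(15.0, 85.0)
    f["lv_ef_pct"] = f["lv_ef_pct"].clip(50.0, 80.0)  # LV EF < 50 % excluded

    flags = {}
    for name, prev in config.prevalences.items():
        flags[name] = rng.random(n) < prev
        f[name] = flags[name]
    any_flag = np.column_stack(list(flags.values())).any(axis=1)
    # right-skewed BMI: median ~27.5, ~29 % obese, ~2 % class III
    bmi = np.clip(27.5 * np.exp(rng.normal(0.0, 0.17, n)), 18.0, 60.0)
    # subjects with no disease flag qualify only through overweight/obesity
    forced = ~any_flag & (bmi < 25.0)
    bmi[forced] = 25.1 + np.abs(rng.normal(2.0, 2.5, int(forced.sum())))
    f["bmi"] = bmi
    f["health_status"] = "unhealthy"

    if config.obesity_class_shifts:
        from .stats import classify_bmi

        cls = f["bmi"].map(classify_bmi)
        for label, (esv_mult, ef_add) in config.obesity_class_shifts.items():
            mask = (cls == label).to_numpy()
            f.loc[mask, "la_esv_ml"] *= esv_mult
            f.loc[mask, "la_ef_pct"] = (f.loc[mask, "la_ef_pct"] + ef_add).clip(
                15.0, 85.0
            )
    return _to_records(_recompute_derived(f))


def cohort_frame(cohort: list[SubjectRecord]) -> pd.DataFrame:
    """Tabulate records in the canonical column order."""
    if not cohort:
        return pd.DataFrame(columns=COHORT_COLUMNS)
    return pd.DataFrame([asdict(r) for r in cohort])[COHORT_COLUMNS]


def write_cohort(cohort, path) -> None:
    """Write a cohort (records or DataFrame) to CSV, full precision."""
    frame = cohort if isinstance(cohort, pd.DataFrame) else cohort_frame(cohort)
    frame.to_csv(path, index=False)


def read_cohort(path, require_metrics: bool = True) -> pd.DataFrame:
    """Read a cohort CSV; extra columns are preserved, missing ones fatal."""
    frame = pd.read_csv(path)
    required = COHORT_COLUMNS if require_metrics else ["subject_id", "age_yr"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"cohort file {path} is missing columns: {missing}")
    return frame


_CHAMBER_LMAX_CM = {"LA": 6.0, "RA": 6.0, "LV": 9.0, "RV": 8.0}


def generate_contours(
    record: SubjectRecord, phases: int = 32
) -> dict[str, ContourSeries]:
    """Smooth per-chamber area/length curves consistent with the record.

    The volume curve is a raised cosine anchored so the extreme phases hit
    the record's EDV and ESV exactly (``phases`` must be even and >= 8); the
    length excursion matches the chamber's GLS; the LV epicardial series
    carries a constant myocardial shell reproducing ``lv_mass_g`` at density
    1.05 g/mL.  Areas follow from inverting the area-length formula.
    """
    if phases < 8 or phases % 2:
        raise ValueError("phases must be even and >= 8")
    rr = 60000.0 / record.heart_rate_bpm
    t = np.arange(phases) * rr / phases
    s = 0.5 * (1.0 + np.cos(2.0 * np.pi * t / rr))  # 1 at ED, 0 at ES
    out: dict[str, ContourSeries] = {}

    def build(chamber: str, edv: float, esv: float, gls_pct: float,
              volumes: np.ndarray | None = None, lmax: float | None = None):
        if volumes is None:
            if esv > edv:
                raise ValueError(f"{chamber}: ESV {esv} exceeds EDV {edv}")
            volumes = esv + (edv - esv) * s
        lmax = lmax or _CHAMBER_LMAX_CM[chamber]
        lengths = lmax * (1.0 + gls_pct / 100.0 * (1.0 - s))
        areas = np.sqrt(3.0 * np.pi * lengths * volumes / 8.0)
        out[chamber] = ContourSeries(
            chamber=chamber, phase_times=t, areas=areas, lengths=lengths,
            rr_interval=rr,
        )
        return volumes

    build("LA", record.la_edv_ml, record.la_esv_ml, record.la_gls_pct)
    build("RA", record.ra_edv_ml, record.ra_esv_ml, record.ra_gls_pct)
    lv_vol = build("LV", record.lv_edv_ml, record.lv_esv_ml, record.lv_gls_pct)
    build("RV", record.rv_edv_ml, record.rv_esv_ml, record.rv_gls_pct)
    shell = record.lv_mass_g / MYOCARDIAL_DENSITY_G_PER_ML
    build(
        "LV_epi", 0.0, 0.0, record.lv_gls_pct,
        volumes=lv_vol + shell, lmax=_CHAMBER_LMAX_CM["LV"] + 1.0,
    )
    return out
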