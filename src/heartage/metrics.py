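"""Chamber metrics from time-resolved four-chamber contour or volume data.

Volumes use the single-plane area-length estimate V = 8*A^2 / (3*pi*L) with
A the planimetered chamber area (cm^2) and L the long-axis length (cm);
1 cm^3 == 1 mL.  From the volume-time curve of one cardiac cycle the module
derives EDV/ESV (curve max/min), SV = EDV - ESV, EF = 100*SV/EDV,
CO = SV * heart rate, the LV peak ejection/filling rates (extreme time
derivatives, mL/s), global longitudinal strain (percent shortening of the
long-axis length, negative), and LV mass from the end-diastolic
epicardial-endocardial shell at myocardial density 1.05 g/mL.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ContourSeries",
    "VolumeTimeSeries",
    "ChamberMetrics",
    "MYOCARDIAL_DENSITY_G_PER_ML",
    "area_length_volume",
    "volumes_from_contours",
    "basic_metrics",
    "peak_rates",
    "gls",
    "lv_mass",
]

CHAMBERS = ("LA", "RA", "LV", "RV", "LV_epi")

#: Standard myocardial tissue density used for LV mass (g/mL).
MYOCARDIAL_DENSITY_G_PER_ML = 1.05

MIN_PHASES = 8


class GeometryError(ValueError):
    """Contour or volume data violate chamber geometry."""


@dataclass(frozen=True)
class ContourSeries:
    """Per-phase area (cm^2) and long-axis length (cm) of one chamber."""

    chamber: str
    phase_times: np.ndarray  # ms from the R-wave, strictly increasing
    areas: np.ndarray
    lengths: np.ndarray
    rr_interval: float  # ms

    def __post_init__(self) -> None:
        t = np.asarray(self.phase_times, dtype=float)
        a = np.asarray(self.areas, dtype=float)
        ln = np.asarray(self.lengths, dtype=float)
        object.__setattr__(self, "phase_times", t)
        object.__setattr__(self, "areas", a)
        object.__setattr__(self, "lengths", ln)
        if self.chamber not in CHAMBERS:
            raise ValueError(f"unknown chamber {self.chamber!r}")
        if not (len(t) == len(a) == len(ln)):
            raise ValueError("phase_times, areas, lengths must have equal length")
        if len(t) < MIN_PHASES:
            raise ValueError(f"need >= {MIN_PHASES} phases, got {len(t)}")
        if np.any(np.diff(t) <= 0):
            raise ValueError("phase_times must be strictly increasing")
        if np.any(a < 0):
            raise GeometryError("areas must be >= 0")
        if np.any(ln <= 0):
            raise GeometryError("lengths must be > 0")
        if self.rr_interval <= t[-1] - t[0]:
            raise ValueError("rr_interval must exceed the sampled span")


@dataclass(frozen=True)
class VolumeTimeSeries:
    """Chamber volume (mL) over one cardiac cycle."""

    chamber: str
    phase_times: np.ndarray  # ms
    volumes: np.ndarray  # mL
    rr_interval: float  # ms

    def __post_init__(self) -> None:
        t = np.asarray(self.phase_times, dtype=float)
        v = np.asarray(self.volumes, dtype=float)
        object.__setattr__(self, "phase_times", t)
        object.__setattr__(self, "volumes", v)
        if len(t) != len(v):
            raise ValueError("phase_times and volumes must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("phase_times must be strictly increasing")
        if np.any(v < 0):
            raise GeometryError("volumes must be >= 0")

    @property
    def n_phases(self) -> int:
        return len(self.volumes)


@dataclass(frozen=True)
class ChamberMetrics:
    edv: float  # mL
    esv: float  # mL
    sv: float  # mL
    ef: float  # %
    co: float | None = None  # mL/min
    per: float | None = None  # mL/s
    pfr: float | None = None  # mL/s
    gls: float | None = None  # %
    mass: float | None = None  # g


def area_length_volume(area: float, length: float) -> float:
    """Single-plane area-length chamber volume, mL.

    V = 8*A^2 / (3*pi*L); homogeneous of degree 3 (scaling A by k and L by k
    scales V by k^3).
    """
    if length <= 0:
        raise GeometryError(f"length must be > 0 cm, got {length!r}")
    if area < 0:
        raise GeometryError(f"area must be >= 0 cm^2, got {area!r}")
    return 8.0 * area * area / (3.0 * np.pi * length)


def volumes_from_contours(contours: ContourSeries) -> VolumeTimeSeries:
    """Per-phase area-length volumes, preserving the phase grid."""
    vols = np.empty(len(contours.areas))
    for i, (a, ln) in enumerate(zip(contours.areas, contours.lengths)):
        try:
            vols[i] = area_length_volume(a, ln)
        except GeometryError as exc:  # pragma: no cover - guarded by type
            raise GeometryError(f"phase {i}: {exc}") from None
    return VolumeTimeSeries(
        chamber=contours.chamber,
        phase_times=contours.phase_times,
        volumes=vols,
        rr_interval=contours.rr_interval,
    )


def basic_metrics(vts: VolumeTimeSeries, heart_rate: float) -> ChamberMetrics:
    """EDV/ESV/SV/EF/CO from a volume curve.

    EDV is the curve maximum, ESV the minimum (the end-diastolic phase is
    wherever the chamber is fullest, not a fixed trigger phase).
    """
    if heart_rate <= 0:
        raise ValueError(f"heart_rate must be > 0 bpm, got {heart_rate!r}")
    v = vts.volumes
    edv = float(v.max())
    esv = float(v.min())
    if edv == esv:
        raise GeometryError("degenerate volume curve: no ejection (EDV == ESV)")
    sv = edv - esv
    return ChamberMetrics(
        edv=edv,
        esv=esv,
        sv=sv,
        ef=100.0 * sv / edv,
        co=sv * heart_rate,
    )


def _cyclic_derivative(vts: VolumeTimeSeries) -> np.ndarray:
    """dV/dt in mL/s by central differences on the cyclically extended curve."""
    t = vts.phase_times
    v = vts.volumes
    T = vts.rr_interval
    t_ext = np.concatenate(([t[-1] - T], t, [t[0] + T]))
    v_ext = np.concatenate(([v[-1]], v, [v[0]]))
    dv = (v_ext[2:] - v_ext[:-2]) / (t_ext[2:] - t_ext[:-2])  # mL/ms
    return dv * 1000.0


def peak_rates(vts: VolumeTimeSeries) -> tuple[float, float]:
    """LV peak ejection and filling rates (both positive, mL/s).

    Ejection is the cyclic interval from the EDV phase to the ESV phase,
    filling the complement; the rate extrema are taken over the central
    differences of the cyclically extended curve, no smoothing.
    """
    if vts.n_phases < MIN_PHASES:
        raise ValueError(
            f"need >= {MIN_PHASES} phases to resolve rates, got {vts.n_phases}"
        )
    v = vts.volumes
    n = len(v)
    i_ed = int(np.argmax(v))
    i_es = int(np.argmin(v))
    if i_ed == i_es:
        raise GeometryError("degenerate volume curve: no ejection (EDV == ESV)")
    dvdt = _cyclic_derivative(vts)
    idx = np.arange(n)
    ejection = (idx - i_ed) % n <= (i_es - i_ed) % n
    filling = ~ejection | (idx == i_ed) | (idx == i_es)
    per = float(np.max(-dvdt[ejection]))
    pfr = float(np.max(dvdt[filling]))
    return per, pfr


def gls(lengths) -> float:
    """Global longitudinal strain, %: peak shortening of the long axis.

    100 * (min(L) - max(L)) / max(L); negative for shortening, 0 for a
    constant length curve.  The same convention applies to atria and
    ventricles.
    """
    ln = np.asarray(lengths, dtype=float)
    if np.any(ln <= 0):
        raise GeometryError("lengths must be > 0")
    lmax = ln.max()
    return float(100.0 * (ln.min() - lmax) / lmax)


def lv_mass(
    epi_vts: VolumeTimeSeries,
    endo_vts: VolumeTimeSeries,
    density: float = MYOCARDIAL_DENSITY_G_PER_ML,
) -> float:
    """LV mass (g) from the epicardial-endocardial shell at end diastole."""
    if len(epi_vts.volumes) != len(endo_vts.volumes):
        raise ValueError("epicardial and endocardial series must share phases")
    i_ed = int(np.argmax(endo_vts.volumes))
    shell = float(epi_vts.volumes[i_ed] - endo_vts.volumes[i_ed])
    if shell < 0:
        raise GeometryError(
            "epicardial volume below endocardial volume at end diastole"
        )
    return shell * density
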